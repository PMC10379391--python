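"""Variant catalog construction: HGVS parsing, clinical-significance filtering,
and cDNA-to-genomic coordinate mapping.

The catalog holds the modern-human germline variants of a single gene,
restricted to single-nucleotide variants and 1-bp indels, classified as
pathogenic (PV: ClinVar "Pathogenic"/"Likely pathogenic") or benign
(BV: "Benign"/"Likely benign"). Variants of uncertain significance and
conflicting interpretations are excluded. Genomic coordinates are 0-based
half-open internally; HGVS anchors stay 1-based at the interface.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "HgvsChange",
    "GenomicVariant",
    "DomainMap",
    "HgvsParseError",
    "UnsupportedSpanError",
    "CoordinateError",
    "parse_hgvs_c",
    "classify_significance",
    "map_to_genomic",
    "hgvs_from_genomic",
    "assign_domain",
    "build_catalog",
    "write_catalog_tsv",
    "read_catalog_tsv",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement; gaps ('-') are preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


class HgvsParseError(ValueError):
    """The HGVS cDNA string cannot be interpreted."""


class UnsupportedSpanError(ValueError):
    """The event spans more than one base pair and is excluded by design."""


class CoordinateError(ValueError):
    """A cDNA anchor or intron offset falls outside the transcript model."""


# ---------------------------------------------------------------------------
# Transcript model and coordinate arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS bounds of one transcript.

    exons are genomic (start, end) intervals, 0-based half-open, sorted by
    genomic coordinate and non-overlapping. cds_start/cds_end are 0-based
    offsets into the *spliced transcript* (transcript orientation: for a
    minus-strand transcript offset 0 is the genomically-rightmost exonic base).
    """

    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ex = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", ex)
        for (a, b) in ex:
            if not a < b:
                raise ValueError(f"empty exon [{a},{b})")
        for (a1, b1), (a2, b2) in zip(ex, ex[1:]):
            if b1 > a2:
                raise ValueError("exons must be sorted and non-overlapping")
        if not 0 <= self.cds_start < self.cds_end <= self.exonic_length:
            raise ValueError("CDS bounds outside spliced transcript")

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    def _exons_tx_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]

    def transcript_to_genomic(self, t: int) -> int:
        """Spliced-transcript offset (0-based) -> genomic position (0-based)."""
        if not 0 <= t < self.exonic_length:
            raise CoordinateError(f"transcript offset {t} outside transcript")
        acc = 0
        for a, b in self._exons_tx_order():
            length = b - a
            if t < acc + length:
                off = t - acc
                return a + off if self.strand == "+" else b - 1 - off
            acc += length
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, g: int) -> Optional[int]:
        """Genomic position -> spliced-transcript offset, or None if intronic/outside."""
        acc = 0
        for a, b in self._exons_tx_order():
            if a <= g < b:
                off = g - a if self.strand == "+" else b - 1 - g
                return acc + off
            acc += b - a
        return None

    def cds_to_genomic(self, c: int) -> int:
        """1-based CDS coordinate -> genomic position."""
        if not 1 <= c <= self.cds_length:
            raise CoordinateError(f"CDS position {c} outside CDS (1..{self.cds_length})")
        return self.transcript_to_genomic(self.cds_start + c - 1)

    def is_exonic(self, g: int) -> bool:
        return any(a <= g < b for a, b in self.exons)

    def in_intron(self, g: int) -> bool:
        if self.is_exonic(g):
            return False
        return self.exons[0][0] <= g < self.exons[-1][1]

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "transcript_id": self.transcript_id,
                "chromosome": self.chromosome,
                "strand": self.strand,
                "exons": [list(e) for e in self.exons],
                "cds_start": self.cds_start,
                "cds_end": self.cds_end,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TranscriptModel":
        d = json.loads(text)
        return cls(
            transcript_id=d["transcript_id"],
            chromosome=d["chromosome"],
            strand=d["strand"],
            exons=tuple(tuple(e) for e in d["exons"]),
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
        )

    @classmethod
    def from_bed12(cls, line: str) -> "TranscriptModel":
        """One BED12 line -> TranscriptModel (thickStart/thickEnd = CDS)."""
        f = line.rstrip("\n").split("\t")
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        tm = cls(f[3] if name else "bed12", chrom, strand, exons, 0, sum(sizes))
        ts = tm.genomic_to_transcript(thick_start if strand == "+" else thick_end - 1)
        te = tm.genomic_to_transcript(thick_end - 1 if strand == "+" else thick_start)
        if ts is None or te is None:
            raise ValueError("thickStart/thickEnd not exonic")
        return replace(tm, cds_start=ts, cds_end=te + 1)


# ---------------------------------------------------------------------------
# HGVS cDNA notation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HgvsChange:
    """A parsed 1-bp HGVS cDNA change.

    cds_anchor is the 1-based CDS coordinate; intron_offset is the signed
    +n/-n offset for intronic variants (None for exonic). For SNVs ref_base
    and alt_base are the coding-strand bases; del1 stores the deleted base in
    ref_base; dup1/ins1 store the inserted base in alt_base.
    """

    raw: str
    kind: str  # SNV | del1 | dup1 | ins1
    cds_anchor: int
    intron_offset: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("SNV", "del1", "dup1", "ins1"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "SNV":
            if not self.ref_base or not self.alt_base or self.ref_base == self.alt_base:
                raise ValueError("SNV requires distinct ref and alt bases")
        if self.intron_offset == 0:
            raise ValueError("intron offset of 0 is not valid HGVS")


_ANCHOR = r"(?P<anchor>\d+)(?P<off>[+-]\d+)?"
_RE_SNV = re.compile(rf"^c\.{_ANCHOR}(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_RE_DEL = re.compile(rf"^c\.{_ANCHOR}del(?P<base>[ACGT])?$")
_RE_DUP = re.compile(rf"^c\.{_ANCHOR}dup(?P<base>[ACGT])?$")
_RE_INS = re.compile(
    rf"^c\.{_ANCHOR}_(?P<anchor2>\d+)(?P<off2>[+-]\d+)?ins(?P<bases>[ACGT]+)$"
)
_RE_MULTI = re.compile(r"^c\.[\d+*-]+_[\d+*-]+(del|dup|delins|inv)")


def parse_hgvs_c(raw: str) -> HgvsChange:
    """Parse an HGVS cDNA string; only SNVs and 1-bp indels are accepted.

    Raises UnsupportedSpanError for events spanning >1 bp (e.g. c.100_102del)
    and HgvsParseError for anything else unreadable (including UTR anchors
    like c.-5 or c.*12, which the catalog does not model).
    """
    s = raw.strip()
    if not s.startswith("c."):
        raise HgvsParseError(f"not a cDNA (c.) description: {raw!r}")

    m = _RE_SNV.match(s)
    if m:
        return HgvsChange(
            raw=s, kind="SNV", cds_anchor=int(m["anchor"]),
            intron_offset=int(m["off"]) if m["off"] else None,
            ref_base=m["ref"], alt_base=m["alt"],
        )
    m = _RE_INS.match(s)
    if m:
        if len(m["bases"]) != 1:
            raise UnsupportedSpanError(f"insertion of >1 bp excluded: {raw!r}")
        a1, a2 = int(m["anchor"]), int(m["anchor2"])
        o1 = int(m["off"]) if m["off"] else None
        o2 = int(m["off2"]) if m["off2"] else None
        # HGVS requires insertion between adjacent positions
        adjacent = (
            (o1 is None and o2 is None and a2 == a1 + 1)
            or (o1 is not None and o2 is not None and a1 == a2 and o2 == o1 + 1)
            or (o1 is not None and o2 is None) or (o1 is None and o2 is not None)
        )
        if not adjacent:
            raise UnsupportedSpanError(f"non-adjacent insertion bounds: {raw!r}")
        return HgvsChange(raw=s, kind="ins1", cds_anchor=a1, intron_offset=o1,
                          alt_base=m["bases"])
    if _RE_MULTI.match(s):
        raise UnsupportedSpanError(f"multi-bp event excluded: {raw!r}")
    m = _RE_DEL.match(s)
    if m:
        return HgvsChange(raw=s, kind="del1", cds_anchor=int(m["anchor"]),
                          intron_offset=int(m["off"]) if m["off"] else None,
                          ref_base=m["base"])
    m = _RE_DUP.match(s)
    if m:
        return HgvsChange(raw=s, kind="dup1", cds_anchor=int(m["anchor"]),
                          intron_offset=int(m["off"]) if m["off"] else None,
                          alt_base=m["base"])
    raise HgvsParseError(f"unparseable HGVS cDNA string: {raw!r}")


# ---------------------------------------------------------------------------
# Clinical significance
# ---------------------------------------------------------------------------

_PV_STRINGS = {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}
_BV_STRINGS = {"benign", "likely benign", "benign/likely benign"}


def classify_significance(sig: str) -> str:
    """ClinVar significance string -> 'PV', 'BV' or 'excluded'.

    Case-insensitive exact match on the canonical strings; combined strings
    like "Pathogenic/Likely pathogenic" map to their class. Everything else
    (VUS, conflicting interpretations, risk factors, ...) is excluded.
    """
    s = " ".join(str(sig).strip().lower().split())
    if s in _PV_STRINGS:
        return "PV"
    if s in _BV_STRINGS:
        return "BV"
    return "excluded"


# ---------------------------------------------------------------------------
# Genomic mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicVariant:
    """A catalog entry on genome-forward coordinates.

    pos is 0-based. For SNVs ref/alt are single bases; for 1-bp deletions
    ref is the deleted base and alt is empty; for insertions/duplications
    ref is empty, alt is the inserted base, and pos is the base AFTER which
    the material is inserted (forward strand).
    """

    hgvs_c: str
    chromosome: str
    pos: int
    ref: str
    alt: str
    kind: str
    var_class: str
    consequence: str = "unknown"
    domain: str = "none"
    protein: str = ""

    def __post_init__(self):
        if self.var_class not in ("PV", "BV"):
            raise ValueError(f"var_class must be PV or BV, got {self.var_class!r}")
        if self.kind == "SNV" and self.ref == self.alt:
            raise ValueError("SNV with ref == alt")

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.pos, self.ref, self.alt)


def _intronic_genomic(change: HgvsChange, tm: TranscriptModel) -> int:
    g_anchor = tm.cds_to_genomic(change.cds_anchor)
    off = change.intron_offset
    g = g_anchor + off if tm.strand == "+" else g_anchor - off
    if not tm.in_intron(g):
        raise CoordinateError(
            f"{change.raw}: intron offset {off} does not land in an intron"
        )
    return g


def map_to_genomic(change: HgvsChange, tm: TranscriptModel) -> tuple[str, int, str, str]:
    """HgvsChange -> (chromosome, pos, ref, alt) on the genome forward strand.

    Alleles given in coding-strand HGVS are reverse-complemented for
    minus-strand transcripts. Insertions/duplications are re-anchored to the
    forward-strand base after which the material is inserted.
    """
    if change.intron_offset is not None:
        g = _intronic_genomic(change, tm)
    else:
        g = tm.cds_to_genomic(change.cds_anchor)

    flip = tm.strand == "-"

    def fwd(base: Optional[str]) -> str:
        if base is None:
            return ""
        return revcomp(base) if flip else base

    if change.kind == "SNV":
        return tm.chromosome, g, fwd(change.ref_base), fwd(change.alt_base)
    if change.kind == "del1":
        return tm.chromosome, g, fwd(change.ref_base) or "N", ""
    # ins1 / dup1: inserted after the anchor in transcript orientation.
    # On a minus-strand transcript "after" means the next lower genomic
    # coordinate, so the forward-strand anchor base is g-1.
    pos = g if not flip else g - 1
    return tm.chromosome, pos, "", fwd(change.alt_base or "N")


def hgvs_from_genomic(
    chromosome: str,
    pos: int,
    ref: str,
    alt: str,
    kind: str,
    tm: TranscriptModel,
) -> HgvsChange:
    """Inverse of map_to_genomic for positions within the transcript span."""
    if chromosome != tm.chromosome:
        raise CoordinateError("chromosome mismatch")
    flip = tm.strand == "-"

    def cds_of(g: int) -> int:
        t = tm.genomic_to_transcript(g)
        if t is None:
            raise CoordinateError(f"position {g} is not exonic")
        c = t - tm.cds_start + 1
        if not 1 <= c <= tm.cds_length:
            raise CoordinateError(f"position {g} outside CDS")
        return c

    def tx_base(b: str) -> str:
        return revcomp(b) if flip else b

    def anchor_parts(g: int) -> tuple[int, Optional[int], str]:
        """(cds_anchor, intron_offset|None, offset string) for a genomic pos."""
        if tm.is_exonic(g):
            return cds_of(g), None, ""
        if not tm.in_intron(g):
            raise CoordinateError(f"position {g} outside the transcript span")
        c, off = _nearest_exonic_anchor(g, tm)
        return c, off, f"+{off}" if off > 0 else str(off)

    if kind == "SNV":
        c, off, offs = anchor_parts(pos)
        return HgvsChange(raw=f"c.{c}{offs}{tx_base(ref)}>{tx_base(alt)}", kind="SNV",
                          cds_anchor=c, intron_offset=off,
                          ref_base=tx_base(ref), alt_base=tx_base(alt))
    if kind == "del1":
        c, off, offs = anchor_parts(pos)
        return HgvsChange(raw=f"c.{c}{offs}del{tx_base(ref)}", kind="del1",
                          cds_anchor=c, intron_offset=off, ref_base=tx_base(ref))
    # ins1/dup1: genomic anchor is the forward base after which alt inserted;
    # transcript anchor is that base on '+', the next one on '-'.
    g_anchor = pos if not flip else pos + 1
    c = cds_of(g_anchor)
    base = tx_base(alt)
    return HgvsChange(raw=f"c.{c}dup{base}" if kind == "dup1" else
                      f"c.{c}_{c + 1}ins{base}",
                      kind=kind, cds_anchor=c, alt_base=base)


def _nearest_exonic_anchor(g: int, tm: TranscriptModel) -> tuple[int, int]:
    """For an intronic genomic position, the HGVS anchor (CDS coord of the
    nearest exon boundary base) and signed offset, in transcript orientation."""
    best = None
    for a, b in tm.exons:
        for gb in (a, b - 1):
            d = abs(g - gb)
            if best is None or d < best[0]:
                best = (d, gb)
    gb = best[1]
    t = tm.genomic_to_transcript(gb)
    c = t - tm.cds_start + 1
    off = g - gb if tm.strand == "+" else gb - g
    return c, off


def left_normalize(pos: int, ref: str, alt: str, kind: str, seq: str,
                   origin: int = 0) -> tuple[int, str, str]:
    """Left-align a 1-bp indel against the reference sequence (VCF convention).

    seq is the forward-strand reference of the region starting at genomic
    coordinate `origin`. SNVs are returned unchanged.
    """
    if kind == "SNV":
        return pos, ref, alt
    i = pos - origin
    if kind == "del1":
        base = ref or seq[i]
        while i > 0 and seq[i - 1] == base:
            i -= 1
        return i + origin, base, ""
    base = alt
    while i > 0 and seq[i] == base:
        i -= 1
    return i + origin, "", base


# ---------------------------------------------------------------------------
# Protein domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping protein-domain intervals on 1-based cDNA coords."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        iv = tuple((str(n), int(a), int(b)) for n, a, b in self.intervals)
        object.__setattr__(self, "intervals", iv)
        for (_, a, b) in iv:
            if not a <= b:
                raise ValueError("domain interval start must be <= end")
        for (_, _, b1), (_, a2, _) in zip(iv, iv[1:]):
            if b1 >= a2:
                raise ValueError("domain intervals must be sorted, non-overlapping")

    def domain_of(self, cds_anchor: int) -> str:
        for name, a, b in self.intervals:
            if a <= cds_anchor <= b:
                return name
        return "none"

    @classmethod
    def from_mapping(cls, m: Mapping[str, Sequence[int]]) -> "DomainMap":
        iv = sorted(((n, v[0], v[1]) for n, v in m.items()), key=lambda x: x[1])
        return cls(tuple(iv))


def assign_domain(change: HgvsChange, dm: DomainMap) -> str:
    """Domain containing the variant's cDNA anchor; intronic variants use
    their nearest exonic anchor (the HGVS anchor itself); else 'none'."""
    return dm.domain_of(change.cds_anchor)


# ---------------------------------------------------------------------------
# Catalog assembly
# ---------------------------------------------------------------------------

@dataclass
class Exclusion:
    name: str
    reason: str
    detail: str = ""


def build_catalog(
    rows: pd.DataFrame | Iterable[Mapping],
    tm: TranscriptModel,
    dm: Optional[DomainMap] = None,
    reference: Optional[str] = None,
    reference_origin: int = 0,
) -> tuple[list[GenomicVariant], list[Exclusion]]:
    """Filter and map a raw variant table into a catalog.

    rows must provide columns: name (HGVS c.), significance, consequence and
    optionally protein. Filters are applied in order: clinical significance,
    1-bp span / parseability, coordinate mapping. Every dropped row is logged
    with a machine-readable reason. If `reference` (forward-strand sequence of
    the region starting at `reference_origin`) is given, 1-bp indels are
    left-normalized against it.

    Raises ValueError if two kept rows map to the same (pos, ref, alt) with
    conflicting classes.
    """
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
    else:
        records = list(rows)

    kept: list[GenomicVariant] = []
    excluded: list[Exclusion] = []
    by_key: dict[tuple, GenomicVariant] = {}

    for row in records:
        name = str(row.get("name", "")).strip()
        var_class = classify_significance(row.get("significance", ""))
        if var_class == "excluded":
            excluded.append(Exclusion(name, "significance",
                                      str(row.get("significance", ""))))
            continue
        try:
            change = parse_hgvs_c(name)
        except UnsupportedSpanError as e:
            excluded.append(Exclusion(name, "multi_bp_span", str(e)))
            continue
        except HgvsParseError as e:
            excluded.append(Exclusion(name, "unparseable_hgvs", str(e)))
            continue
        try:
            chrom, pos, ref, alt = map_to_genomic(change, tm)
        except CoordinateError as e:
            excluded.append(Exclusion(name, "coordinate_error", str(e)))
            continue
        if reference is not None and change.kind != "SNV":
            pos, ref, alt = left_normalize(pos, ref, alt, change.kind,
                                           reference, reference_origin)
        domain = assign_domain(change, dm) if dm is not None else "none"
        gv = GenomicVariant(
            hgvs_c=change.raw, chromosome=chrom, pos=pos, ref=ref, alt=alt,
            kind=change.kind, var_class=var_class,
            consequence=str(row.get("consequence", "unknown")),
            domain=domain, protein=str(row.get("protein", "") or ""),
        )
        prev = by_key.get(gv.key)
        if prev is not None:
            if prev.var_class != gv.var_class:
                raise ValueError(
                    f"conflicting classes at {gv.key}: {prev.hgvs_c}={prev.var_class} "
                    f"vs {gv.hgvs_c}={gv.var_class}"
                )
            excluded.append(Exclusion(name, "duplicate", f"of {prev.hgvs_c}"))
            continue
        by_key[gv.key] = gv
        kept.append(gv)

    return kept, excluded


_CATALOG_COLS = ["hgvs_c", "protein", "chrom", "pos", "ref", "alt", "kind",
                 "class", "consequence", "domain"]


def catalog_to_frame(catalog: Sequence[GenomicVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hgvs_c": v.hgvs_c, "protein": v.protein, "chrom": v.chromosome,
                "pos": v.pos, "ref": v.ref, "alt": v.alt, "kind": v.kind,
                "class": v.var_class, "consequence": v.consequence,
                "domain": v.domain,
            }
            for v in catalog
        ],
        columns=_CATALOG_COLS,
    )


def write_catalog_tsv(catalog: Sequence[GenomicVariant], path) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[GenomicVariant]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"ref": str, "alt": str})
    out = []
    for r in df.to_dict("records"):
        out.append(GenomicVariant(
            hgvs_c=r["hgvs_c"], chromosome=str(r["chrom"]), pos=int(r["pos"]),
            ref=str(r["ref"]), alt=str(r["alt"]), kind=r["kind"],
            var_class=r["class"], consequence=r.get("consequence", "unknown"),
            domain=r.get("domain", "none"), protein=str(r.get("protein", "")),
        ))
    return out
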