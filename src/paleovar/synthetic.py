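"""Synthetic inputs with known ground truth for every pipeline stage.

The generator produces (i) a multi-species alignment evolved along a known
phylogeny with an HKY-like substitution bias (optional CpG transition
multiplier) and rare 1-bp indels, emitted as UCSC-dialect MAF with randomized
strand flips and block splits; (ii) a ClinVar-style variant table with planted
shared/unshared pathogenic and benign variants plus excluded distractors
(VUS, multi-bp events); (iii) an ancient cohort: dated, located samples with
pileups drawn at configurable coverage, base error and terminal C>T
deamination. Every stage records its truth so recovery is testable.

All randomness flows through one numpy Generator: a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .ancient import AncientSample, PileupColumn, PileupObservation, \
    write_pileups_tsv, write_samples_tsv
from .catalog import DomainMap, GenomicVariant, TranscriptModel, \
    build_catalog, hgvs_from_genomic
from .crossspecies import NO_ALIGNMENT, NOT_SHARED, SHARED, CladeDef
from .maf import MafBlock, MafRow, write_maf

__all__ = [
    "SimConfig",
    "TrueAlignment",
    "evolve_sequences",
    "emit_maf",
    "plant_catalog",
    "simulate_ancient",
    "simulate_all",
    "toy_transcript",
    "toy_domains",
    "DEFAULT_TREE",
    "DEFAULT_CLADES",
]

DEFAULT_TREE = (
    "(((human:0.010,chimp:0.012):0.055,(mouse:0.17,rat:0.16):0.11):0.06,"
    "((dog:0.13,cow:0.16):0.07,chicken:0.45):0.04,"
    "(zebrafish:0.95,coelacanth:0.75):0.25);"
)

DEFAULT_CLADES = {
    "Primates": ["chimp"],
    "Euarchontoglires": ["mouse", "rat"],
    "Laurasiatheria": ["dog", "cow"],
    "Aves": ["chicken"],
    "Fish": ["zebrafish", "coelacanth"],
}

DEFAULT_LOCATIONS = [
    ("Anatolia", 39.0, 35.0),
    ("Iberia", 40.4, -3.7),
    ("Steppe", 48.0, 67.0),
    ("Levant", 31.8, 35.2),
    ("Britain", 52.5, -1.9),
    ("Tian Shan", 42.5, 80.0),
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline (defaults are the
    standing conditions; see docs/methods.md for the rationale)."""

    # alignment arm
    tree: str = DEFAULT_TREE
    ref_species: str = "human"
    length: int = 3000
    kappa: float = 2.0              # transition/transversion ratio
    cpg_multiplier: float = 4.0     # extra substitution rate at CpG sites
    indel_rate: float = 0.02        # 1-bp indels per site per unit branch
    strand_flip_prob: float = 0.3   # minus-strand representation of MAF rows
    block_min: int = 40             # MAF block width range (columns)
    block_max: int = 90

    # catalog arm
    n_pv: int = 60
    n_bv: int = 120
    pv_shared_fraction: float = 0.05
    bv_shared_fraction: float = 0.70
    bv_intron_fraction: float = 0.30
    n_vus: int = 8                  # excluded-by-significance distractors
    n_multibp: int = 4              # excluded-by-span distractors
    n_indels: int = 4               # planted 1-bp indel variants (PV)
    indel_flank: int = 3

    # ancient arm
    n_samples: int = 40
    coverage: float = 6.0
    read_length: int = 60
    base_error: float = 0.002
    deamination_rate: float = 0.2
    damage_window: int = 2
    date_range: tuple[int, int] = (270, 48_426)
    carrier_prob: float = 0.04
    locations: Sequence[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_LOCATIONS))
    clades: dict = field(default_factory=lambda: dict(DEFAULT_CLADES))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "date_range" in d:
            d["date_range"] = tuple(d["date_range"])
        if "locations" in d:
            d["locations"] = [tuple(x) for x in d["locations"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class TrueAlignment:
    """Column-true multiple alignment: the generator's ground truth."""

    species: list[str]
    rows: dict  # species -> aligned string (same length, '-' for gaps)
    ref_species: str

    @property
    def width(self) -> int:
        return len(self.rows[self.ref_species])

    def ref_positions(self) -> np.ndarray:
        """Per-column reference position (-1 where the reference is gapped)."""
        out = np.full(self.width, -1, dtype=int)
        pos = 0
        for i, ch in enumerate(self.rows[self.ref_species]):
            if ch != "-":
                out[i] = pos
                pos += 1
        return out

    def column_of(self, ref_pos: int) -> int:
        cols = np.flatnonzero(self.ref_positions() == ref_pos)
        if len(cols) != 1:
            raise IndexError(f"reference position {ref_pos} not in alignment")
        return int(cols[0])

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace("-", "")

    def state_at(self, ref_pos: int, species: str) -> str:
        """Species state at a reference position: base, 'N', 'gap' or 'absent'
        (same vocabulary as the MAF index)."""
        try:
            col = self.column_of(ref_pos)
        except IndexError:
            return "absent"
        ch = self.rows[species][col]
        if ch == "-":
            return "gap"
        return ch if ch in "ACGT" else "N"


def _branch_evolve(parent: dict, columns: list, t: float, cfg: SimConfig,
                   rng: np.random.Generator, id_counter: list) -> dict:
    """Evolve one branch: per-site single-event substitution with probability
    1-exp(-r*t) (r = 1, or cpg_multiplier at CpG context), HKY-like target
    choice, and geometric-free 1-bp indels at rate indel_rate/2 each."""
    p_del = -math.expm1(-cfg.indel_rate / 2.0 * t)
    p_ins = p_del
    p_ti = cfg.kappa / (cfg.kappa + 2.0)

    ordered = [(cid, parent[cid]) for cid in columns if cid in parent]
    child: dict = {}
    insertions: list[tuple[int, str]] = []  # (after column id, base)
    n = len(ordered)
    for i, (cid, base) in enumerate(ordered):
        if rng.random() < p_del:
            pass  # deleted: absent in child
        else:
            mult = 1.0
            if cfg.cpg_multiplier != 1.0:
                nxt = ordered[i + 1][1] if i + 1 < n else None
                prv = ordered[i - 1][1] if i > 0 else None
                if (base == "C" and nxt == "G") or (base == "G" and prv == "C"):
                    mult = cfg.cpg_multiplier
            p_sub = -math.expm1(-mult * t)
            if rng.random() < p_sub:
                if rng.random() < p_ti:
                    base = _TRANSITION[base]
                else:
                    base = _TRANSVERSIONS[base][rng.integers(2)]
            child[cid] = base
        if rng.random() < p_ins:
            new_base = "ACGT"[rng.integers(4)]
            insertions.append((cid, new_base))
    for cid, new_base in insertions:
        new_id = id_counter[0]  # globally unique negative id
        id_counter[0] -= 1
        columns.insert(columns.index(cid) + 1, new_id)
        child[new_id] = new_base
    return child


def evolve_sequences(cfg: SimConfig, rng: np.random.Generator) -> TrueAlignment:
    """Evolve the root sequence along the configured tree; returns the true
    column-level alignment of all leaves."""
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    columns = list(range(cfg.length))
    root_chars = {i: "ACGT"[j] for i, j in
                  enumerate(rng.choice(4, size=cfg.length,
                                       p=[0.3, 0.2, 0.2, 0.3]))}
    leaves: dict[str, dict] = {}
    id_counter = [-1]

    def recurse(node, chars):
        kids = node.child_nodes()
        if not kids:
            leaves[node.taxon.label] = chars
            return
        for child in kids:
            t = child.edge.length or 0.0
            recurse(child, _branch_evolve(chars, columns, t, cfg, rng,
                                          id_counter))

    recurse(tree.seed_node, root_chars)

    if cfg.ref_species not in leaves:
        raise ValueError(f"reference species {cfg.ref_species!r} not a tree leaf")
    # drop columns absent from every leaf
    kept = [cid for cid in columns if any(cid in ch for ch in leaves.values())]
    species = [cfg.ref_species] + sorted(sp for sp in leaves if sp != cfg.ref_species)
    rows = {sp: "".join(leaves[sp].get(cid, "-") for cid in kept)
            for sp in species}
    return TrueAlignment(species=species, rows=rows, ref_species=cfg.ref_species)


# ---------------------------------------------------------------------------
# MAF emission
# ---------------------------------------------------------------------------

def emit_maf(aln: TrueAlignment, cfg: SimConfig, rng: np.random.Generator,
             protect: Optional[Sequence[int]] = None) -> list[MafBlock]:
    """Split the true alignment into MAF blocks with randomized widths and
    minus-strand representation of non-reference rows.

    protect: reference positions near which no block boundary is placed
    (within indel_flank + 2 bases), so planted indel contexts stay intact.
    """
    refpos = aln.ref_positions()
    width = aln.width
    protected = set()
    if protect:
        pad = cfg.indel_flank + 2
        for p in protect:
            protected.update(range(p - pad, p + pad + 1))

    # choose breakpoint columns
    bounds = [0]
    c = 0
    while c < width:
        c += int(rng.integers(cfg.block_min, cfg.block_max + 1))
        if c >= width:
            break
        # shift forward until the boundary is legal: reference base present on
        # both sides of the cut and not inside a protected indel context
        while c < width:
            left_ref = refpos[:c][refpos[:c] >= 0]
            right_ref = refpos[c:][refpos[c:] >= 0]
            if len(left_ref) and len(right_ref) and \
               int(right_ref[0]) not in protected and \
               int(left_ref[-1]) not in protected:
                break
            c += 1
        if c < width:
            bounds.append(c)
    bounds.append(width)

    ungapped = {sp: aln.ungapped(sp) for sp in aln.species}
    cum = {}
    for sp in aln.species:
        row = aln.rows[sp]
        arr = np.cumsum([ch != "-" for ch in row])
        cum[sp] = arr  # bases consumed up to and including column i

    blocks = []
    for a, b in zip(bounds, bounds[1:]):
        rows = []
        for sp in aln.species:
            text = aln.rows[sp][a:b]
            size = len(text) - text.count("-")
            if size == 0:
                continue
            start = int(cum[sp][a - 1]) if a > 0 else 0
            strand = "+"
            if sp != aln.ref_species and rng.random() < cfg.strand_flip_prob:
                strand = "-"
            rows.append(MafRow(
                species=sp, src=f"{sp}.region", start=start, size=size,
                strand=strand, src_size=len(ungapped[sp]), text=text))
        # reference row first, as in UCSC MAFs
        rows.sort(key=lambda r: (r.species != aln.ref_species, r.species))
        blocks.append(MafBlock(tuple(rows)))
    return blocks


# ---------------------------------------------------------------------------
# Catalog planting
# ---------------------------------------------------------------------------

def toy_transcript(cfg: SimConfig) -> TranscriptModel:
    """Three-exon plus-strand transcript over the reference region; the CDS
    covers the full spliced transcript (no UTRs in the toy gene)."""
    L = cfg.length
    exons = (
        (50, int(L * 0.30)),
        (int(L * 0.38), int(L * 0.62)),
        (int(L * 0.70), L - 50),
    )
    exonic = sum(b - a for a, b in exons)
    return TranscriptModel("SYN-TX1", "region", "+", exons, 0, exonic)


def toy_domains(tm: TranscriptModel) -> DomainMap:
    n = tm.cds_length
    return DomainMap((
        ("coiled-coil", max(1, int(n * 0.02)), int(n * 0.10)),
        ("ETGE", int(n * 0.15), int(n * 0.20)),
        ("ChAM", int(n * 0.35), int(n * 0.45)),
        ("WD40", int(n * 0.70), int(n * 0.95)),
    ))


def _ref_col_array(aln: TrueAlignment) -> np.ndarray:
    """cols[p] = alignment column of reference base p."""
    ref_row = np.frombuffer(aln.rows[aln.ref_species].encode(), dtype=np.uint8)
    return np.flatnonzero(ref_row != ord("-"))


def _truth_call_snv(aln: TrueAlignment, cols: np.ndarray, pos: int, alt: str,
                    species: str) -> str:
    ch = aln.rows[species][int(cols[pos])]
    if ch == "-" or ch not in "ACGT":
        return NO_ALIGNMENT
    return SHARED if ch == alt else NOT_SHARED


def _truth_call_del(aln: TrueAlignment, cols: np.ndarray, pos: int,
                    species: str, k: int) -> str:
    """Deletion truth directly from the true alignment (same semantics as the
    pipeline's rule, computed without MAF/index machinery)."""
    ref_row, sp_row = aln.rows[aln.ref_species], aln.rows[species]
    ch = sp_row[int(cols[pos])]
    if ch in "ACGT":
        return NOT_SHARED
    if ch == "N":
        return NO_ALIGNMENT
    if pos - k < 0 or pos + 1 + k > len(cols):
        return NO_ALIGNMENT
    for c in list(cols[pos - k:pos]) + list(cols[pos + 1:pos + 1 + k]):
        c = int(c)
        if sp_row[c] == "-" or sp_row[c] == "N" or sp_row[c] != ref_row[c]:
            return NO_ALIGNMENT
    return SHARED


def plant_catalog(
    aln: TrueAlignment,
    tm: TranscriptModel,
    dm: DomainMap,
    cfg: SimConfig,
    rng: np.random.Generator,
    force_share_species: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Plant a variant table on the evolved alignment.

    Shared variants take an alternate allele some species actually carries at
    the chosen column; unshared variants take an allele no species carries.
    With force_share_species set, every variant is placed where that species
    carries a non-reference base and takes it as the alternate allele, so the
    whole column of that species is shared (a generation error is raised when
    the alignment offers too few such columns).
    Returns (raw variant table, truth matrix of per-species sharing calls,
    planted indel positions). Raises RuntimeError when the requested planting
    cannot be satisfied on this alignment.
    """
    ref_seq = aln.ungapped(aln.ref_species)
    others = [sp for sp in aln.species if sp != aln.ref_species]
    cols = _ref_col_array(aln)

    def cds_coord(p: int):
        t = tm.genomic_to_transcript(p)
        if t is None:
            return None
        c = t - tm.cds_start + 1
        return c if 1 <= c <= tm.cds_length else None

    exonic = [p for p in range(len(ref_seq)) if cds_coord(p) is not None]
    intronic = [p for p in range(len(ref_seq)) if tm.in_intron(p)]

    def carriers_at(p: int) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        col = int(cols[p])
        for sp in others:
            st = aln.rows[sp][col]
            if st in "ACGT" and st != ref_seq[p]:
                out.setdefault(st, []).append(sp)
        return out

    used: set[int] = set()
    rows = []
    truth_rows = {}

    def plant_snv(var_class: str, want_shared: bool, pool: list[int],
                  consequence_pool: list[str]) -> None:
        order = rng.permutation(len(pool))
        for idx in order:
            p = pool[int(idx)]
            if p in used:
                continue
            ref = ref_seq[p]
            if ref not in "ACGT":
                continue
            carr = carriers_at(p)
            if force_share_species is not None:
                st = aln.rows[force_share_species][int(cols[p])]
                if st not in "ACGT" or st == ref:
                    continue
                alt = st
            elif want_shared:
                alts = sorted(carr)
                if not alts:
                    continue
                alt = alts[int(rng.integers(len(alts)))]
            else:
                alts = [b for b in "ACGT" if b != ref and b not in carr]
                if not alts:
                    continue
                alt = alts[int(rng.integers(len(alts)))]
            used.add(p)
            change = hgvs_from_genomic("region", p, ref, alt, "SNV", tm)
            sig_pool = (["Pathogenic", "Likely pathogenic"] if var_class == "PV"
                        else ["Benign", "Likely benign"])
            rows.append({
                "name": change.raw, "protein": "",
                "significance": sig_pool[int(rng.integers(2))],
                "consequence": consequence_pool[int(rng.integers(len(consequence_pool)))],
            })
            truth_rows[change.raw] = {
                sp: _truth_call_snv(aln, cols, p, alt, sp) for sp in others}
            return
        raise RuntimeError(
            f"could not place a {'shared' if want_shared else 'unshared'} "
            f"{var_class} SNV: no eligible column left")

    for _ in range(cfg.n_pv):
        plant_snv("PV", bool(rng.random() < cfg.pv_shared_fraction), exonic,
                  ["stopgain", "nonsynonymous SNV", "startloss"])
    for _ in range(cfg.n_bv):
        if intronic and rng.random() < cfg.bv_intron_fraction:
            plant_snv("BV", bool(rng.random() < cfg.bv_shared_fraction),
                      intronic, ["intron"])
        else:
            plant_snv("BV", bool(rng.random() < cfg.bv_shared_fraction), exonic,
                      ["synonymous SNV", "nonsynonymous SNV"])

    # planted 1-bp deletions (PV): half at columns where some species shows a
    # clean gap (shared), half where no species is gapped (unshared)
    indel_positions: list[int] = []
    if cfg.n_indels:
        k = cfg.indel_flank
        shared_pool, unshared_pool = [], []
        for p in exonic:
            if p in used or ref_seq[p] not in "ACGT":
                continue
            calls = {sp: _truth_call_del(aln, cols, p, sp, k) for sp in others}
            if any(c == SHARED for c in calls.values()):
                shared_pool.append(p)
            elif all(c == NOT_SHARED for c in calls.values()):
                unshared_pool.append(p)
        want = [(True, shared_pool), (False, unshared_pool)]
        planted = 0
        for i in range(cfg.n_indels):
            shared, pool = want[i % 2]
            pool = [p for p in pool if p not in used]
            if not pool:
                continue
            p = pool[int(rng.integers(len(pool)))]
            used.add(p)
            change = hgvs_from_genomic("region", p, ref_seq[p], "", "del1", tm)
            rows.append({"name": change.raw, "protein": "",
                         "significance": "Pathogenic",
                         "consequence": "frameshift deletion"})
            truth_rows[change.raw] = {
                sp: _truth_call_del(aln, cols, p, sp, k) for sp in others}
            indel_positions.append(p)
            planted += 1

    # distractors the catalog must exclude
    cds_len = tm.cds_length
    for _ in range(cfg.n_vus):
        c = int(rng.integers(1, cds_len + 1))
        g = tm.cds_to_genomic(c)
        ref = ref_seq[g]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        rows.append({"name": f"c.{c}{ref}>{alt}", "protein": "",
                     "significance": "Uncertain significance",
                     "consequence": "nonsynonymous SNV"})
    for _ in range(cfg.n_multibp):
        c = int(rng.integers(1, cds_len - 3))
        rows.append({"name": f"c.{c}_{c + 2}del", "protein": "",
                     "significance": "Pathogenic",
                     "consequence": "frameshift deletion"})

    table = pd.DataFrame(rows)[["name", "protein", "significance", "consequence"]]
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    truth = pd.DataFrame.from_dict(truth_rows, orient="index", columns=others)
    truth.index.name = "variant"
    return table, truth, indel_positions


# ---------------------------------------------------------------------------
# Ancient cohort simulation
# ---------------------------------------------------------------------------

def simulate_ancient(
    cfg: SimConfig,
    reference: str,
    catalog: Sequence[GenomicVariant],
    rng: np.random.Generator,
) -> tuple[list[AncientSample], dict, dict]:
    """Draw dated, located samples and their damaged pileups.

    Carrier variants (SNVs only: pileups carry base observations) are applied
    to every read covering their position. Deamination converts C->T within
    the damage window of a read's 5' terminus on forward reads, and the
    mirrored G->A near the read-frame 5' terminus of reverse reads, with
    probability `deamination_rate`. Returns (samples, pileups by sample,
    truth: sample -> sorted carrier HGVS list).
    """
    L = len(reference)
    eligible = [v for v in catalog if v.kind == "SNV"]
    qual_vals = np.array([12, 18, 25, 32, 37, 40])
    qual_p = np.array([0.03, 0.04, 0.13, 0.30, 0.30, 0.20])

    samples: list[AncientSample] = []
    pileups: dict[str, list[PileupColumn]] = {}
    truth: dict[str, list[str]] = {}
    lo, hi = cfg.date_range
    w = cfg.damage_window

    for i in range(cfg.n_samples):
        sid = f"anc{i:03d}"
        loc, lat, lon = cfg.locations[int(rng.integers(len(cfg.locations)))]
        sample = AncientSample(sample_id=sid,
                               date_bp=float(rng.integers(lo, hi + 1)),
                               location=loc, lat=lat, lon=lon,
                               source_ref="synthetic")
        samples.append(sample)
        carried = [v for v in eligible if rng.random() < cfg.carrier_prob]
        truth[sid] = sorted(v.hgvs_c for v in carried)
        alt_at = {v.pos: v.alt for v in carried}

        obs_at: dict[int, list[PileupObservation]] = {}
        rl = cfg.read_length
        n_reads = int(rng.poisson(cfg.coverage * L / rl))
        for _ in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            reverse = bool(rng.random() < 0.5)
            quals = rng.choice(qual_vals, size=rl, p=qual_p)
            for j in range(rl):
                pos = start + j
                base = alt_at.get(pos, reference[pos])
                # sequencing error
                if rng.random() < cfg.base_error:
                    base = [b for b in "ACGT" if b != base][int(rng.integers(3))]
                d5 = j if not reverse else rl - 1 - j
                d3 = rl - 1 - j if not reverse else j
                # post-mortem deamination near the read's 5' terminus
                if d5 <= w and rng.random() < cfg.deamination_rate:
                    if not reverse and base == "C":
                        base = "T"
                    elif reverse and base == "G":
                        base = "A"
                obs_at.setdefault(pos, []).append(PileupObservation(
                    base=base, qual=int(quals[j]), dist5=d5, dist3=d3,
                    reverse=reverse))
        pileups[sid] = [
            PileupColumn(pos=p, observations=tuple(obs), ref=reference[p])
            for p, obs in sorted(obs_at.items())
        ]
    return samples, pileups, truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir, seed: int) -> dict:
    """Generate every pipeline input under `outdir`; returns file paths and
    in-memory truth objects. Byte-identical for a fixed (cfg, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    aln = evolve_sequences(cfg, rng)
    tm = toy_transcript(cfg)
    dm = toy_domains(tm)
    table, truth_sharing, indel_positions = plant_catalog(aln, tm, dm, cfg, rng)
    blocks = emit_maf(aln, cfg, rng, protect=indel_positions)

    reference = aln.ungapped(aln.ref_species)
    catalog, _ = build_catalog(table, tm, dm)
    samples, pileups, truth_carriers = simulate_ancient(cfg, reference,
                                                        catalog, rng)

    paths = {
        "maf": outdir / "alignment.maf",
        "reference": outdir / "reference.fa",
        "variants": outdir / "variants.tsv",
        "transcript": outdir / "transcript.json",
        "domains": outdir / "domains.json",
        "clades": outdir / "clades.yaml",
        "samples": outdir / "samples.tsv",
        "pileups": outdir / "pileups.tsv",
        "truth": outdir / "truth.json",
    }
    write_maf(blocks, paths["maf"])
    with open(paths["reference"], "w") as fh:
        fh.write(f">{aln.ref_species}.region\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i:i + 70] + "\n")
    table.to_csv(paths["variants"], sep="\t", index=False)
    with open(paths["transcript"], "w") as fh:
        fh.write(tm.to_json())
    with open(paths["domains"], "w") as fh:
        json.dump({n: [a, b] for n, a, b in dm.intervals}, fh, indent=2)
    with open(paths["clades"], "w") as fh:
        yaml.safe_dump(cfg.clades, fh)
    write_samples_tsv(samples, paths["samples"])
    write_pileups_tsv(pileups, paths["pileups"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "sharing": {v: truth_sharing.loc[v].to_dict()
                        for v in truth_sharing.index},
            "carriers": truth_carriers,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "alignment": aln,
        "transcript": tm,
        "domains": dm,
        "table": table,
        "truth_sharing": truth_sharing,
        "catalog": catalog,
        "samples": samples,
        "pileups": pileups,
        "truth_carriers": truth_carriers,
        "blocks": blocks,
    }
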