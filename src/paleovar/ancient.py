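"""Ancient-sample genotyping, catalog intersection, and carrier dating.

A transparent threshold caller over per-sample pileups stands in for a full
mapping/GATK pipeline: a variant is called where enough quality-passing reads
support one non-reference base, and post-mortem deamination artifacts
(C>T near the 5' read terminus; G>A on reverse-orientation reads) are flagged
rather than silently removed. Called variants are intersected with the modern
catalog to produce carrier records, per-variant timelines dated by the oldest
carrier, and cohort summaries.

Dates are point estimates in years before present (BP). A date stored with
censored=True is an open-ended floor ("older than" the stored value).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog import GenomicVariant, parse_hgvs_c

__all__ = [
    "AncientSample",
    "PileupObservation",
    "PileupColumn",
    "GenotypeCall",
    "CarrierRecord",
    "VariantTimeline",
    "call_variants",
    "flag_damage",
    "call_sample",
    "intersect_catalog",
    "build_timelines",
    "cohort_summary",
    "read_samples_tsv",
    "write_samples_tsv",
    "read_pileups_tsv",
    "write_pileups_tsv",
    "load_timeline_table",
    "timelines_to_frame",
]

DAMAGE_SUSPECT = "damage_suspect"
LOW_DEPTH = "low_depth"


@dataclass(frozen=True)
class AncientSample:
    sample_id: str
    date_bp: float
    location: str = ""
    lat: Optional[float] = None
    lon: Optional[float] = None
    source_ref: str = ""

    def __post_init__(self):
        if not self.date_bp > 0:
            raise ValueError("date_bp must be positive")


@dataclass(frozen=True)
class PileupObservation:
    base: str
    qual: int
    dist5: int  # distance from the read's 5' terminus (read orientation)
    dist3: int  # distance from the read's 3' terminus
    reverse: bool

    def __post_init__(self):
        if self.base not in "ACGTN":
            raise ValueError(f"bad base {self.base!r}")
        if self.dist5 < 0 or self.dist3 < 0:
            raise ValueError("terminal distances must be >= 0")


@dataclass(frozen=True)
class PileupColumn:
    pos: int
    observations: tuple[PileupObservation, ...]
    ref: Optional[str] = None


@dataclass(frozen=True)
class GenotypeCall:
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int
    flags: frozenset = frozenset()

    def __post_init__(self):
        if not 0 < self.alt_depth <= self.depth:
            raise ValueError("0 < alt_depth <= depth required")

    @property
    def key(self) -> tuple:
        return (self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CarrierRecord:
    sample_id: str
    hgvs_c: str
    date_bp: Optional[float]
    location: str = ""
    censored: bool = False  # date_bp is an "older than" floor
    lat: Optional[float] = None
    lon: Optional[float] = None


@dataclass(frozen=True)
class VariantTimeline:
    hgvs_c: str
    carriers: tuple[CarrierRecord, ...]
    arisen_time_bp: float
    arisen_censored: bool = False
    protein: str = ""
    mutation_type: str = ""
    domain: str = ""

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_variants(
    columns: Iterable[PileupColumn],
    reference: str,
    region_start: int = 0,
    min_baseq: int = 20,
    min_alt: int = 2,
    min_depth: int = 3,
) -> list[GenotypeCall]:
    """Threshold caller: emit a call where >= min_alt quality-passing reads
    support one non-reference base. Columns with depth < min_depth still
    report (ancient data are sparse) but carry the low_depth flag.
    """
    calls = []
    for col in columns:
        i = col.pos - region_start
        if not 0 <= i < len(reference):
            raise ValueError(
                f"pileup position {col.pos} outside the reference region"
            )
        ref_base = reference[i].upper()
        passing = [o for o in col.observations
                   if o.qual >= min_baseq and o.base in "ACGT"]
        if not passing:
            continue
        counts = Counter(o.base for o in passing if o.base != ref_base)
        if not counts:
            continue
        # deterministic tie-break: highest count, then lexicographic base
        alt, alt_depth = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if alt_depth < min_alt:
            continue
        flags = set()
        if len(passing) < min_depth:
            flags.add(LOW_DEPTH)
        calls.append(GenotypeCall(pos=col.pos, ref=ref_base, alt=alt,
                                  depth=len(passing), alt_depth=alt_depth,
                                  flags=frozenset(flags)))
    return calls


def flag_damage(call: GenotypeCall, column: PileupColumn, window: int = 2,
                min_baseq: int = 20) -> GenotypeCall:
    """Mark deamination-suspect transition calls.

    A C>T call is suspect when every supporting observation is a forward read
    within `window` bases of its 5' terminus; a G>A call when every supporting
    observation is a reverse-orientation read within `window` of its (read
    frame) 5' terminus. Any interior or opposite-orientation support clears
    the call.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    support = [o for o in column.observations
               if o.base == call.alt and o.qual >= min_baseq]
    if not support:
        return call
    suspect = False
    if call.ref == "C" and call.alt == "T":
        suspect = all((not o.reverse) and o.dist5 <= window for o in support)
    elif call.ref == "G" and call.alt == "A":
        suspect = all(o.reverse and o.dist5 <= window for o in support)
    if suspect:
        return replace(call, flags=call.flags | {DAMAGE_SUSPECT})
    return call


def call_sample(
    columns: Sequence[PileupColumn],
    reference: str,
    region_start: int = 0,
    min_baseq: int = 20,
    min_alt: int = 2,
    min_depth: int = 3,
    damage_window: int = 2,
) -> list[GenotypeCall]:
    """call_variants followed by damage flagging on every call."""
    by_pos = {c.pos: c for c in columns}
    calls = call_variants(columns, reference, region_start,
                          min_baseq, min_alt, min_depth)
    return [flag_damage(c, by_pos[c.pos], damage_window, min_baseq)
            for c in calls]


# ---------------------------------------------------------------------------
# Intersection and timelines
# ---------------------------------------------------------------------------

def intersect_catalog(
    calls_by_sample: Mapping[str, Sequence[GenotypeCall]],
    catalog: Sequence[GenomicVariant],
    samples: Mapping[str, AncientSample],
    drop_damage_pv: bool = True,
) -> tuple[list[CarrierRecord], list[dict]]:
    """Match per-sample calls against the catalog.

    Returns carrier records plus a log of calls dropped because they were
    damage-suspect hits on pathogenic variants (default policy).
    """
    by_key = {(v.pos, v.ref, v.alt): v for v in catalog}
    records: list[CarrierRecord] = []
    dropped: list[dict] = []
    for sid in sorted(calls_by_sample):
        sample = samples[sid]
        for call in calls_by_sample[sid]:
            v = by_key.get(call.key)
            if v is None:
                continue
            if DAMAGE_SUSPECT in call.flags and drop_damage_pv and v.var_class == "PV":
                dropped.append({"sample_id": sid, "hgvs_c": v.hgvs_c,
                                "reason": DAMAGE_SUSPECT, "pos": call.pos})
                continue
            records.append(CarrierRecord(
                sample_id=sid, hgvs_c=v.hgvs_c, date_bp=sample.date_bp,
                location=sample.location, lat=sample.lat, lon=sample.lon,
            ))
    return records, dropped


def _anchor_of(hgvs_c: str) -> int:
    try:
        return parse_hgvs_c(hgvs_c).cds_anchor
    except ValueError:
        return 10 ** 9


def build_timelines(
    records: Sequence[CarrierRecord],
    meta: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[VariantTimeline]:
    """Group carrier records per variant and date each variant by its oldest
    carrier. Timelines are ordered by (carrier count desc, cDNA anchor asc).
    Variants with no carriers produce no timeline.

    meta optionally supplies per-variant protein / mutation_type / domain
    labels for the output table.
    """
    groups: dict[str, list[CarrierRecord]] = defaultdict(list)
    for r in records:
        groups[r.hgvs_c].append(r)
    timelines = []
    for hgvs, carriers in groups.items():
        dated = [c for c in carriers if c.date_bp is not None]
        if not dated:
            raise ValueError(f"no dated carrier for {hgvs}; cannot assign arisen time")
        oldest = max(dated, key=lambda c: c.date_bp)
        m = dict(meta.get(hgvs, {})) if meta else {}
        timelines.append(VariantTimeline(
            hgvs_c=hgvs,
            carriers=tuple(sorted(carriers,
                                  key=lambda c: -(c.date_bp or -1.0))),
            arisen_time_bp=float(oldest.date_bp),
            arisen_censored=bool(oldest.censored),
            protein=m.get("protein", ""),
            mutation_type=m.get("mutation_type", ""),
            domain=m.get("domain", ""),
        ))
    timelines.sort(key=lambda t: (-t.carrier_count, _anchor_of(t.hgvs_c)))
    return timelines


def cohort_summary(timelines: Sequence[VariantTimeline],
                   cutoff_bp: float = 10_000) -> dict:
    """Cohort-level counts: temporal percentages are computed on carriers,
    mutation-type / domain / recurrence percentages on variants.

    Carrier dating conventions: a censored date (floor f, true age > f) counts
    as older than the cutoff when f >= cutoff_bp; an undated co-carrier of a
    dated variant counts as within the cutoff.
    """
    n_variants = len(timelines)
    carriers = [c for t in timelines for c in t.carriers]
    n_carriers = len(carriers)

    def within(c: CarrierRecord) -> bool:
        if c.date_bp is None:
            return True
        if c.censored:
            return c.date_bp < cutoff_bp
        return c.date_bp <= cutoff_bp

    n_within = sum(1 for c in carriers if within(c))
    dated = [c.date_bp for c in carriers if c.date_bp is not None]

    type_counts = Counter(t.mutation_type or "unknown" for t in timelines)
    domain_counts = Counter(t.domain or "none" for t in timelines)
    count_hist = Counter(t.carrier_count for t in timelines)
    n_multi = sum(1 for t in timelines if t.carrier_count >= 2)

    def pct(x, n):
        return round(100.0 * x / n, 1) if n else 0.0

    return {
        "n_variants": n_variants,
        "n_carriers": n_carriers,
        "cutoff_bp": cutoff_bp,
        "carriers_within_cutoff": n_within,
        "pct_carriers_within_cutoff": pct(n_within, n_carriers),
        "oldest_carrier_bp": max(dated) if dated else None,
        "youngest_carrier_bp": min(dated) if dated else None,
        "mutation_types": dict(sorted(type_counts.items())),
        "mutation_type_pct": {k: pct(v, n_variants)
                              for k, v in sorted(type_counts.items())},
        "domains": dict(sorted(domain_counts.items())),
        "domain_pct": {k: pct(v, n_variants)
                       for k, v in sorted(domain_counts.items())},
        "n_multi_carrier_variants": n_multi,
        "pct_multi_carrier_variants": pct(n_multi, n_variants),
        "carrier_count_histogram": {str(k): v
                                    for k, v in sorted(count_hist.items())},
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_samples_tsv(samples: Sequence[AncientSample], path) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "date_bp": s.date_bp, "location": s.location,
        "lat": s.lat, "lon": s.lon, "source_ref": s.source_ref,
    } for s in samples]).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> dict[str, AncientSample]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = {}
    for r in df.to_dict("records"):
        s = AncientSample(
            sample_id=str(r["sample_id"]), date_bp=float(r["date_bp"]),
            location=str(r.get("location", "") or ""),
            lat=None if pd.isna(r.get("lat")) else float(r["lat"]),
            lon=None if pd.isna(r.get("lon")) else float(r["lon"]),
            source_ref=str(r.get("source_ref", "") or ""),
        )
        out[s.sample_id] = s
    return out


def _encode_obs(o: PileupObservation) -> str:
    return f"{o.base}:{o.qual}:{o.dist5}:{o.dist3}:{'R' if o.reverse else 'F'}"


def _decode_obs(s: str) -> PileupObservation:
    base, qual, d5, d3, orient = s.split(":")
    return PileupObservation(base=base, qual=int(qual), dist5=int(d5),
                             dist3=int(d3), reverse=orient == "R")


def write_pileups_tsv(pileups: Mapping[str, Sequence[PileupColumn]], path) -> None:
    """Pileup TSV: sample_id, pos, ref, obs (comma-joined base:qual:d5:d3:F/R)."""
    rows = []
    for sid in sorted(pileups):
        for col in sorted(pileups[sid], key=lambda c: c.pos):
            rows.append({
                "sample_id": sid, "pos": col.pos, "ref": col.ref or "N",
                "obs": ",".join(_encode_obs(o) for o in col.observations),
            })
    pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "obs"]).to_csv(
        path, sep="\t", index=False)


def read_pileups_tsv(path) -> dict[str, list[PileupColumn]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "obs": str})
    out: dict[str, list[PileupColumn]] = defaultdict(list)
    for r in df.to_dict("records"):
        obs = tuple(_decode_obs(s) for s in str(r["obs"]).split(",") if s)
        out[str(r["sample_id"])].append(
            PileupColumn(pos=int(r["pos"]), observations=obs, ref=str(r["ref"])))
    return dict(out)


def load_timeline_table(path) -> tuple[list[CarrierRecord],
                                       dict[str, dict[str, str]]]:
    """Load a variant-level carrier table (the published-counts path).

    Expected columns: carrier_count, hgvs_c, protein, mutation_type, domain,
    arisen_time_bp, censored (0/1), carrier_dates_bp (optional comma list of
    known carrier dates, oldest first). Rows expand into one CarrierRecord per
    carrier; carriers beyond the known dates are undated.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records: list[CarrierRecord] = []
    meta: dict[str, dict[str, str]] = {}
    for r in df.to_dict("records"):
        hgvs = str(r["hgvs_c"])
        n = int(r["carrier_count"])
        censored = bool(int(r.get("censored", 0) or 0))
        raw = r.get("carrier_dates_bp", "")
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            raw = ""
        raw_dates = str(raw).strip()
        if raw_dates:
            dates = [float(x) for x in raw_dates.split(",")]
        else:
            dates = [float(r["arisen_time_bp"])]
        if len(dates) > n:
            raise ValueError(f"{hgvs}: more dates than carriers")
        for i in range(n):
            records.append(CarrierRecord(
                sample_id=f"{hgvs}#{i + 1}",
                hgvs_c=hgvs,
                date_bp=dates[i] if i < len(dates) else None,
                censored=censored and i == 0,
            ))
        meta[hgvs] = {
            "protein": str(r.get("protein", "")),
            "mutation_type": str(r.get("mutation_type", "")),
            "domain": str(r.get("domain", "")),
        }
    return records, meta


def timelines_to_frame(timelines: Sequence[VariantTimeline]) -> pd.DataFrame:
    """Variant-level table: carrier_count, cDNA, protein, mutation type,
    domain, arisen time (censored rendered as '>floor')."""
    rows = []
    for t in timelines:
        rows.append({
            "carrier_count": t.carrier_count,
            "hgvs_c": t.hgvs_c,
            "protein": t.protein,
            "mutation_type": t.mutation_type,
            "domain": t.domain,
            "arisen_time_bp": (f">{int(t.arisen_time_bp)}" if t.arisen_censored
                               else int(t.arisen_time_bp)),
        })
    return pd.DataFrame(rows, columns=["carrier_count", "hgvs_c", "protein",
                                       "mutation_type", "domain",
                                       "arisen_time_bp"])


def write_carriers_tsv(records: Sequence[CarrierRecord], path) -> None:
    pd.DataFrame([{
        "sample_id": r.sample_id, "hgvs_c": r.hgvs_c, "date_bp": r.date_bp,
        "location": r.location, "lat": r.lat, "lon": r.lon,
        "censored": int(r.censored),
    } for r in records]).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
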