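"""Cross-species allele sharing.

Each catalog variant is projected through the multiple alignment to every
non-reference species and scored as shared (the species carries the human
ALT allele at the aligned position), not_shared (it carries the reference
or another base), or no_alignment (gap, N, or no aligning block). Sharing
rates divide shared counts by the full catalog size: unaligned cells stay
in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import GenomicVariant
from .maf import ABSENT, GAP, MafIndex

__all__ = [
    "SHARED",
    "NOT_SHARED",
    "NO_ALIGNMENT",
    "CladeDef",
    "is_shared_snv",
    "is_shared_indel",
    "compute_sharing",
    "sharing_summary",
    "SharingSummary",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

SHARED = "shared"
NOT_SHARED = "not_shared"
NO_ALIGNMENT = "no_alignment"

_TSV_CODE = {SHARED: "S", NOT_SHARED: "N", NO_ALIGNMENT: "."}
_TSV_DECODE = {v: k for k, v in _TSV_CODE.items()}


@dataclass(frozen=True)
class CladeDef:
    """Named clades partitioning the non-reference species."""

    clades: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        seen: set[str] = set()
        for _, members in self.clades:
            dup = seen & set(members)
            if dup:
                raise ValueError(f"species in more than one clade: {sorted(dup)}")
            seen |= set(members)

    @property
    def species(self) -> set[str]:
        return {sp for _, members in self.clades for sp in members}

    def clade_of(self, species: str) -> Optional[str]:
        for name, members in self.clades:
            if species in members:
                return name
        return None

    @classmethod
    def from_mapping(cls, m: Mapping[str, Sequence[str]]) -> "CladeDef":
        return cls(tuple((str(k), tuple(v)) for k, v in m.items()))

    @classmethod
    def from_yaml(cls, path) -> "CladeDef":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Sharing calls
# ---------------------------------------------------------------------------

def is_shared_snv(v: GenomicVariant, state: str) -> str:
    """Ternary sharing call for an SNV given the species state at its position."""
    if v.kind != "SNV":
        raise ValueError("is_shared_snv requires an SNV")
    if state in (GAP, ABSENT, "N"):
        return NO_ALIGNMENT
    return SHARED if state == v.alt else NOT_SHARED


def _ref_columns(index: MafIndex, pos: int):
    """(block, cols array of ref-base columns, index of pos within cols)."""
    i_entry = None
    from bisect import bisect_right
    i = bisect_right(index._starts, pos) - 1
    if i < 0:
        return None
    start, end, block, cols = index._entries[i]
    if not start <= pos < end:
        return None
    return block, cols, pos - start


def _flanks_ok(block, cols, i, species_row, ref_row, k) -> bool:
    """k adjacent reference-base columns on each side exist in the block and
    the species base there is non-gap and equals the reference base."""
    if i - k < 0 or i + 1 + k > len(cols):
        return False
    for c in list(cols[i - k:i]) + list(cols[i + 1:i + 1 + k]):
        rc, sc = ref_row.text[c], species_row.text[c]
        if sc == "-" or sc == "N" or sc != rc:
            return False
    return True


def is_shared_indel(v: GenomicVariant, index: MafIndex, species: str,
                    flank: int = 3) -> str:
    """Ternary sharing call for a 1-bp indel.

    A deletion is shared when the species shows a gap aligned to the deleted
    reference base with `flank` matching non-gap columns on each side; an
    insertion/duplication is shared when the species carries exactly one extra
    copy of the inserted base in reference-gap columns between the anchor base
    and its successor, with the same flank requirement. When the flanking
    context cannot be established the call is no_alignment.
    """
    if v.kind not in ("del1", "dup1", "ins1"):
        raise ValueError("is_shared_indel requires a 1-bp indel")

    if v.kind == "del1":
        hit = _ref_columns(index, v.pos)
        if hit is None:
            return NO_ALIGNMENT
        block, cols, i = hit
        row = block.row_for(species)
        ref_row = block.row_for(index.ref_species)
        if row is None:
            return NO_ALIGNMENT
        ch = row.text[cols[i]]
        if ch in "ACGT":
            return NOT_SHARED
        if ch == "N":
            return NO_ALIGNMENT
        # species shows a gap; require clean flanks to trust it
        if _flanks_ok(block, cols, i, row, ref_row, flank):
            return SHARED
        return NO_ALIGNMENT

    # insertion / duplication: anchored at the base AFTER which alt inserted
    hit1 = _ref_columns(index, v.pos)
    hit2 = _ref_columns(index, v.pos + 1)
    if hit1 is None or hit2 is None or hit1[0] is not hit2[0]:
        return NO_ALIGNMENT
    block, cols, i = hit1
    row = block.row_for(species)
    ref_row = block.row_for(index.ref_species)
    if row is None:
        return NO_ALIGNMENT
    c1, c2 = int(cols[i]), int(cols[i + 1])
    inserted = [row.text[c] for c in range(c1 + 1, c2) if row.text[c] != "-"]
    # flanks: the anchor base and its successor count as the innermost flank
    if not _flanks_ok(block, cols, i, row, ref_row, flank) or \
       not _flanks_ok(block, cols, i + 1, row, ref_row, flank):
        return NO_ALIGNMENT
    if inserted == [v.alt]:
        return SHARED
    return NOT_SHARED


# ---------------------------------------------------------------------------
# Matrix and summaries
# ---------------------------------------------------------------------------

def compute_sharing(
    catalog: Sequence[GenomicVariant],
    index: MafIndex,
    species: Optional[Sequence[str]] = None,
    flank: int = 3,
) -> pd.DataFrame:
    """Variants x species sharing matrix (values shared/not_shared/no_alignment)."""
    if species is None:
        species = index.species
    data = {}
    for v in catalog:
        row = {}
        for sp in species:
            if v.kind == "SNV":
                row[sp] = is_shared_snv(v, index.get_base(v.pos, sp))
            else:
                row[sp] = is_shared_indel(v, index, sp, flank=flank)
        data[v.hgvs_c] = row
    mat = pd.DataFrame.from_dict(data, orient="index", columns=list(species))
    mat.index.name = "variant"
    return mat


@dataclass
class SharingSummary:
    per_species: pd.DataFrame        # shared / not_shared / no_alignment / rate
    per_variant: pd.Series           # species sharing each variant
    n_variants: int
    n_variants_shared: int           # variants shared with >= 1 species
    variant_sharing_fraction: float  # n_variants_shared / n_variants
    n_species_sharing: int           # species sharing >= 1 variant
    per_clade: Optional[pd.DataFrame] = None

    def rates(self) -> pd.Series:
        return self.per_species["rate"]


def sharing_summary(matrix: pd.DataFrame,
                    clades: Optional[CladeDef] = None) -> SharingSummary:
    """Per-species, per-clade and per-variant sharing counts and rates.

    The per-species sharing rate is shared count / catalog size (unaligned
    cells remain in the denominator).
    """
    n_variants = len(matrix)
    counts = pd.DataFrame({
        SHARED: (matrix == SHARED).sum(axis=0),
        NOT_SHARED: (matrix == NOT_SHARED).sum(axis=0),
        NO_ALIGNMENT: (matrix == NO_ALIGNMENT).sum(axis=0),
    })
    counts["rate"] = counts[SHARED] / n_variants if n_variants else 0.0
    per_variant = (matrix == SHARED).sum(axis=1)
    n_shared = int((per_variant > 0).sum())
    per_clade = None
    if clades is not None:
        rows = []
        for name, members in clades.clades:
            members = [m for m in members if m in counts.index]
            sub = counts.loc[members]
            rows.append({
                "clade": name,
                "n_species": len(members),
                "shared_total": int(sub[SHARED].sum()),
                "n_species_sharing": int((sub[SHARED] > 0).sum()),
                "mean_rate": float(sub["rate"].mean()) if len(members) else 0.0,
            })
        per_clade = pd.DataFrame(rows).set_index("clade")
    return SharingSummary(
        per_species=counts,
        per_variant=per_variant,
        n_variants=n_variants,
        n_variants_shared=n_shared,
        variant_sharing_fraction=(n_shared / n_variants) if n_variants else 0.0,
        n_species_sharing=int((counts[SHARED] > 0).sum()),
        per_clade=per_clade,
    )


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write the sharing matrix with compact S/N/. cell codes."""
    matrix.replace(_TSV_CODE).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.replace(_TSV_DECODE)
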