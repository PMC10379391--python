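"""MAF (Multiple Alignment Format) reading and reference-coordinate projection.

Blocks are tokenized with Bio.AlignIO's "maf" parser ('i'/'e'/'q' status lines
are ignored; only 's' rows are used). Rows recorded on the '-' strand are
normalized at read time: their aligned text is reverse-complemented into the
alignment (reference-forward) frame and their start is converted to a
forward-strand offset (srcSize - start - size), so every downstream base
lookup works on one frame.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, replace
from io import StringIO
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import AlignIO

from .catalog import revcomp

__all__ = [
    "MafRow",
    "MafBlock",
    "MafIndex",
    "read_maf",
    "write_maf",
    "BASE_STATES",
    "GAP",
    "ABSENT",
]

GAP = "gap"
ABSENT = "absent"
BASE_STATES = {"A", "C", "G", "T", "N"}


@dataclass(frozen=True)
class MafRow:
    """One 's' row, normalized to the alignment (forward) frame.

    start is the forward-strand offset of the first base; text is the aligned
    sequence (with '-') in alignment orientation; strand records how the row
    was written in the file (it no longer affects interpretation).
    """

    species: str
    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def __post_init__(self):
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.size:
            raise ValueError(
                f"{self.src}: ungapped text length {ungapped} != size {self.size}"
            )


@dataclass(frozen=True)
class MafBlock:
    rows: tuple[MafRow, ...]

    def __post_init__(self):
        lengths = {len(r.text) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows of one block must have equal aligned length")

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def row_for(self, species: str) -> Optional[MafRow]:
        hit = None
        for r in self.rows:
            if r.species == species:
                if hit is not None:
                    warnings.warn(
                        f"species {species} appears twice in a block; first row wins"
                    )
                    return hit
                hit = r
        return hit


def _species_of(src: str) -> str:
    return src.split(".", 1)[0]


def _normalize_row(rec) -> MafRow:
    ann = rec.annotations
    text = str(rec.seq).upper()
    start, size, src_size = ann["start"], ann["size"], ann["srcSize"]
    if ann["strand"] == -1:
        text = revcomp(text)
        start = src_size - start - size
        strand = "-"
    else:
        strand = "+"
    return MafRow(species=_species_of(rec.id), src=rec.id, start=start,
                  size=size, strand=strand, src_size=src_size, text=text)


def read_maf(path_or_text: str, from_text: bool = False) -> list[MafBlock]:
    """Read a UCSC-dialect MAF file (the '##maf' header is optional)."""
    if from_text:
        handle = StringIO(path_or_text)
    else:
        handle = open(path_or_text)
    try:
        text = handle.read()
    finally:
        handle.close()
    if not text.lstrip().startswith("##maf"):
        text = "##maf version=1\n" + text
    blocks = []
    for aln in AlignIO.parse(StringIO(text), "maf"):
        blocks.append(MafBlock(tuple(_normalize_row(rec) for rec in aln)))
    return blocks


def write_maf(blocks: Iterable[MafBlock], path) -> None:
    """Write blocks as MAF; rows marked strand '-' are re-expressed on the
    minus strand (text reverse-complemented, start converted) on output."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("\na score=0.0\n")
            for r in b.rows:
                text, start = r.text, r.start
                if r.strand == "-":
                    text = revcomp(text)
                    start = r.src_size - r.start - r.size
                fh.write(f"s {r.src} {start} {r.size} {r.strand} {r.src_size} {text}\n")


def flip_row_strand(block: MafBlock, species: str) -> MafBlock:
    """Return a copy of the block with one species row marked for minus-strand
    representation on output (used to exercise strand invariance)."""
    rows = tuple(
        replace(r, strand="-" if r.strand == "+" else "+")
        if r.species == species else r
        for r in block.rows
    )
    return MafBlock(rows)


class MafIndex:
    """Sub-linear lookup from reference coordinates into MAF blocks.

    Blocks must be non-overlapping on the reference; the reference row is
    required in every block and must be recorded on '+'.
    """

    def __init__(self, blocks: Sequence[MafBlock], ref_species: str):
        self.ref_species = ref_species
        entries = []
        for b in blocks:
            ref = b.row_for(ref_species)
            if ref is None:
                raise ValueError(f"block lacks reference species {ref_species!r}")
            if ref.strand == "-":
                raise ValueError("reference row must be recorded on '+'")
            cols = np.flatnonzero(np.frombuffer(ref.text.encode(), dtype=np.uint8)
                                  != ord("-"))
            entries.append((ref.start, ref.start + ref.size, b, cols))
        entries.sort(key=lambda e: e[0])
        for (s1, e1, *_), (s2, _, *_) in zip(entries, entries[1:]):
            if s2 < e1:
                raise ValueError(
                    f"blocks overlap on the reference ({s1}-{e1} vs {s2}-...)"
                )
        self._starts = [e[0] for e in entries]
        self._entries = entries
        self.species = sorted({r.species for _, _, b, _ in entries for r in b.rows}
                              - {ref_species})

    def lookup(self, pos: int) -> Optional[tuple[MafBlock, int]]:
        """(block, alignment column) covering reference position pos, or None."""
        i = bisect_right(self._starts, pos) - 1
        if i < 0:
            return None
        start, end, block, cols = self._entries[i]
        if not start <= pos < end:
            return None
        return block, int(cols[pos - start])

    def get_base(self, pos: int, species: str) -> str:
        """State of `species` aligned to reference position pos, in the
        reference forward frame: one of 'A','C','G','T','N','gap','absent'."""
        hit = self.lookup(pos)
        if hit is None:
            return ABSENT
        block, col = hit
        row = block.row_for(species)
        if row is None:
            return ABSENT
        ch = row.text[col]
        if ch == "-":
            return GAP
        return ch if ch in "ACGT" else "N"

    def column_states(self, pos: int, species_list: Sequence[str]) -> dict[str, str]:
        return {sp: self.get_base(pos, sp) for sp in species_list}

    def iter_ref_positions(self) -> Iterator[int]:
        for start, end, _, _ in self._entries:
            yield from range(start, end)
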