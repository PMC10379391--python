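"""Catalog construction: HGVS parsing, significance filtering, coordinate
mapping (both strands), domain assignment, and assembly bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from paleovar import load_palb2_domains
from paleovar.catalog import (
    CoordinateError,
    DomainMap,
    HgvsParseError,
    TranscriptModel,
    UnsupportedSpanError,
    assign_domain,
    build_catalog,
    hgvs_from_genomic,
    map_to_genomic,
    parse_hgvs_c,
    classify_significance,
    revcomp,
)


# ---------------------------------------------------------------------------
# parse_hgvs_c
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, kind, anchor, offset, ref, alt",
    [
        ("c.3G>A", "SNV", 3, None, "G", "A"),
        ("c.2996+264T>C", "SNV", 2996, 264, "T", "C"),
        ("c.3114-51T>A", "SNV", 3114, -51, "T", "A"),
        ("c.211+1G>A", "SNV", 211, 1, "G", "A"),
        ("c.103delC", "del1", 103, None, "C", None),
        ("c.173dupT", "dup1", 173, None, None, "T"),
        ("c.100_101insA", "ins1", 100, None, None, "A"),
    ],
)
def test_parse_hgvs_cases(raw, kind, anchor, offset, ref, alt):
    ch = parse_hgvs_c(raw)
    assert (ch.kind, ch.cds_anchor, ch.intron_offset) == (kind, anchor, offset)
    assert ch.ref_base == ref and ch.alt_base == alt


@pytest.mark.parametrize("raw", ["c.100_102del", "c.50_60dup", "c.10_11insATG"])
def test_parse_rejects_multibase_events(raw):
    with pytest.raises(UnsupportedSpanError):
        parse_hgvs_c(raw)


@pytest.mark.parametrize("raw", ["p.Met1Ile", "c.-5A>G", "c.*12A>G", "g.100A>G",
                                 "c.100A>", "c.100delinsAT"])
def test_parse_rejects_unsupported_notation(raw):
    with pytest.raises(HgvsParseError):
        parse_hgvs_c(raw)


# ---------------------------------------------------------------------------
# classify_significance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sig, expected",
    [
        ("Pathogenic", "PV"),
        ("Likely pathogenic", "PV"),
        ("Pathogenic/Likely pathogenic", "PV"),
        ("BENIGN", "BV"),
        ("likely benign", "BV"),
        ("Uncertain significance", "excluded"),
        ("Conflicting interpretations of pathogenicity", "excluded"),
        ("risk factor", "excluded"),
        ("", "excluded"),
    ],
)
def test_classify_significance(sig, expected):
    assert classify_significance(sig) == expected


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------

def test_plus_strand_single_exon_mapping(single_exon_tm):
    chrom, pos, ref, alt = map_to_genomic(parse_hgvs_c("c.3G>A"), single_exon_tm)
    assert (chrom, pos, ref, alt) == ("chr1", 1012, "G", "A")


def test_intronic_plus_one_is_first_intron_base(two_exon_tm):
    _, pos, ref, alt = map_to_genomic(parse_hgvs_c("c.211+1G>A"), two_exon_tm)
    assert pos == 221  # exon 1 ends at 221 (half-open)
    _, pos2, *_ = map_to_genomic(parse_hgvs_c("c.212-1G>A"), two_exon_tm)
    assert pos2 == 320  # last intronic base before exon 2


def _coordinate_table(tm: TranscriptModel) -> list[int]:
    """Exhaustive transcript-offset -> genomic-position table, built by
    enumeration (independent of TranscriptModel.transcript_to_genomic)."""
    order = tm.exons if tm.strand == "+" else tuple(reversed(tm.exons))
    table = []
    for a, b in order:
        rng = range(a, b) if tm.strand == "+" else range(b - 1, a - 1, -1)
        table.extend(rng)
    return table


def test_minus_strand_mapping_matches_enumeration_oracle():
    tm = TranscriptModel("toy-", "chr1", "-", ((100, 160), (200, 260)), 5, 100)
    table = _coordinate_table(tm)
    for c, hgvs in [(3, "c.3G>A"), (1, "c.1A>T"), (95, "c.95C>G")]:
        ch = parse_hgvs_c(hgvs)
        chrom, pos, ref, alt = map_to_genomic(ch, tm)
        assert pos == table[tm.cds_start + c - 1]
        assert ref == revcomp(ch.ref_base) and alt == revcomp(ch.alt_base)


def test_anchor_beyond_cds_raises(single_exon_tm):
    with pytest.raises(CoordinateError):
        map_to_genomic(parse_hgvs_c("c.500A>G"), single_exon_tm)


def test_intron_offset_beyond_intron_raises(two_exon_tm):
    with pytest.raises(CoordinateError):
        map_to_genomic(parse_hgvs_c("c.211+500G>A"), two_exon_tm)


@st.composite
def _transcripts_and_changes(draw):
    strand = draw(st.sampled_from("+-"))
    n_exons = draw(st.integers(1, 3))
    start = draw(st.integers(0, 50))
    exons = []
    g = start
    for _ in range(n_exons):
        length = draw(st.integers(20, 60))
        exons.append((g, g + length))
        g += length + draw(st.integers(10, 40))
    exonic = sum(b - a for a, b in exons)
    cds_start = draw(st.integers(0, 5))
    cds_end = draw(st.integers(exonic - 5, exonic))
    tm = TranscriptModel("h", "chrT", strand, tuple(exons), cds_start, cds_end)
    c = draw(st.integers(1, tm.cds_length))
    ref, alt = draw(st.sampled_from(
        [(a, b) for a in "ACGT" for b in "ACGT" if a != b]))
    return tm, f"c.{c}{ref}>{alt}"


@given(_transcripts_and_changes())
def test_mapping_round_trip_identity(tc):
    """map_to_genomic followed by its inverse reproduces the HGVS change on
    random transcripts of either strand."""
    tm, hgvs = tc
    ch = parse_hgvs_c(hgvs)
    chrom, pos, ref, alt = map_to_genomic(ch, tm)
    back = hgvs_from_genomic(chrom, pos, ref, alt, "SNV", tm)
    assert back.raw == ch.raw


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "hgvs, domain",
    [
        ("c.3256C>T", "WD40"),
        ("c.1240C>T", "ChAM"),
        ("c.211+1G>A", "ETGE"),  # intronic: nearest exonic anchor decides
        ("c.48+1G>C", "coiled-coil"),
        ("c.1837C>T", "none"),
        ("c.1500A>G", "none"),
    ],
)
def test_assign_domain_on_bundled_map(hgvs, domain):
    dm = load_palb2_domains()
    assert assign_domain(parse_hgvs_c(hgvs), dm) == domain


def test_domain_map_rejects_overlap():
    with pytest.raises(ValueError):
        DomainMap((("a", 1, 10), ("b", 5, 20)))


# ---------------------------------------------------------------------------
# build_catalog
# ---------------------------------------------------------------------------

def _table(rows):
    return pd.DataFrame(rows, columns=["name", "protein", "significance",
                                       "consequence"])


def test_build_catalog_filters_and_logs(single_exon_tm):
    rows = _table([
        ("c.3G>A", "p.Met1Ile", "Pathogenic", "startloss"),
        ("c.5A>G", "", "Uncertain significance", "nonsynonymous SNV"),
        ("c.10_12del", "", "Benign", "frameshift deletion"),
    ])
    kept, excluded = build_catalog(rows, single_exon_tm)
    assert len(kept) == 1 and kept[0].hgvs_c == "c.3G>A"
    reasons = {e.name: e.reason for e in excluded}
    assert reasons == {"c.5A>G": "significance", "c.10_12del": "multi_bp_span"}
    # partition: kept + excluded covers the input
    assert len(kept) + len(excluded) == len(rows)


def test_build_catalog_empty_table(single_exon_tm):
    kept, excluded = build_catalog(_table([]), single_exon_tm)
    assert kept == [] and excluded == []


def test_conflicting_duplicate_is_hard_error(single_exon_tm):
    rows = _table([
        ("c.3G>A", "", "Pathogenic", "startloss"),
        ("c.3G>A", "", "Benign", "startloss"),
    ])
    with pytest.raises(ValueError, match="conflicting"):
        build_catalog(rows, single_exon_tm)


def test_same_class_duplicate_logged_not_fatal(single_exon_tm):
    rows = _table([
        ("c.3G>A", "", "Pathogenic", "startloss"),
        ("c.3G>A", "", "Likely pathogenic", "startloss"),
    ])
    kept, excluded = build_catalog(rows, single_exon_tm)
    assert len(kept) == 1 and excluded[0].reason == "duplicate"


def test_positions_match_enumeration_oracle(two_exon_tm):
    """Catalog genomic positions equal the exhaustive coordinate table."""
    rows = _table([
        ("c.1A>G", "", "Pathogenic", "startloss"),
        ("c.50C>T", "", "Benign", "synonymous SNV"),
        ("c.211G>A", "", "Pathogenic", "splice site"),
        ("c.212C>G", "", "Likely benign", "nonsynonymous SNV"),
        ("c.400T>C", "", "Likely pathogenic", "stopgain"),
    ])
    kept, excluded = build_catalog(rows, two_exon_tm)
    assert not excluded
    table = _coordinate_table(two_exon_tm)
    for v in kept:
        c = parse_hgvs_c(v.hgvs_c).cds_anchor
        assert v.pos == table[two_exon_tm.cds_start + c - 1]


def test_minus_strand_catalog_mirrors_plus_strand():
    """A catalog built on a minus-strand transcript equals the plus-strand
    catalog of the reverse-complemented locus."""
    N = 500
    plus = TranscriptModel("p", "chrT", "+", ((40, 140), (200, 320)), 0, 220)
    minus = TranscriptModel("m", "chrT", "-",
                            tuple(sorted((N - b, N - a) for a, b in plus.exons)),
                            0, 220)
    rows = _table([
        ("c.10A>G", "", "Pathogenic", "stopgain"),
        ("c.120C>T", "", "Benign", "synonymous SNV"),
        ("c.200T>A", "", "Likely pathogenic", "stopgain"),
    ])
    kept_p, _ = build_catalog(rows, plus)
    kept_m, _ = build_catalog(rows, minus)
    for vp, vm in zip(kept_p, kept_m):
        assert vm.pos == N - 1 - vp.pos
        assert vm.ref == revcomp(vp.ref) and vm.alt == revcomp(vp.alt)
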