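"""Threshold calling, deamination flagging, catalog intersection, carrier
timelines, and cohort summaries (including the bundled carrier table)."""

import pytest

from paleovar import load_ancient_carrier_table
from paleovar.ancient import (
    DAMAGE_SUSPECT,
    LOW_DEPTH,
    AncientSample,
    CarrierRecord,
    GenotypeCall,
    PileupColumn,
    PileupObservation,
    build_timelines,
    call_sample,
    call_variants,
    cohort_summary,
    flag_damage,
    intersect_catalog,
    read_pileups_tsv,
    timelines_to_frame,
    write_pileups_tsv,
)
from paleovar.catalog import GenomicVariant

REF = "ACGTACGTAC"  # positions 0..9


def _obs(base, qual=30, d5=10, d3=10, reverse=False):
    return PileupObservation(base=base, qual=qual, dist5=d5, dist3=d3,
                             reverse=reverse)


def _col(pos, obs):
    return PileupColumn(pos=pos, observations=tuple(obs))


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_no_columns_no_calls():
    assert call_variants([], REF) == []


def test_concordant_alt_observations_called_clean():
    col = _col(1, [_obs("T")] * 5)  # ref C at pos 1
    (call,) = call_variants([col], REF)
    assert (call.alt, call.alt_depth, call.depth) == ("T", 5, 5)
    assert call.flags == frozenset()


def test_low_depth_reported_with_flag():
    col = _col(1, [_obs("T")] * 2)
    (call,) = call_variants([col], REF)
    assert LOW_DEPTH in call.flags and call.alt_depth == 2


def test_quality_filter_and_min_alt():
    col = _col(1, [_obs("T", qual=10)] * 5 + [_obs("T", qual=30)])
    assert call_variants([col], REF) == []  # one passing alt read < min_alt


def test_reference_column_mismatch_is_input_error():
    with pytest.raises(ValueError, match="outside the reference"):
        call_variants([_col(99, [_obs("A")])], REF)


def test_alt_tie_broken_deterministically():
    col = _col(0, [_obs("C")] * 3 + [_obs("G")] * 3)  # ref A
    (call,) = call_variants([col], REF)
    assert call.alt == "C"


# ---------------------------------------------------------------------------
# damage flagging
# ---------------------------------------------------------------------------

def _call(pos, ref, alt, depth, alt_depth):
    return GenotypeCall(pos=pos, ref=ref, alt=alt, depth=depth,
                        alt_depth=alt_depth)


def test_non_transition_never_flagged():
    col = _col(0, [_obs("G", d5=0)] * 3)  # ref A: A>G with terminal support
    call = flag_damage(_call(0, "A", "G", 3, 3), col)
    assert DAMAGE_SUSPECT not in call.flags


def test_ct_all_terminal_flagged():
    col = _col(1, [_obs("T", d5=d) for d in (0, 1, 2)])
    call = flag_damage(_call(1, "C", "T", 3, 3), col, window=2)
    assert DAMAGE_SUSPECT in call.flags


def test_ct_with_interior_support_not_flagged():
    col = _col(1, [_obs("T", d5=0), _obs("T", d5=1), _obs("T", d5=9, d3=9)])
    call = flag_damage(_call(1, "C", "T", 3, 3), col, window=2)
    assert DAMAGE_SUSPECT not in call.flags


def test_ga_flagged_only_on_reverse_terminal_support():
    rev = [_obs("A", d5=1, reverse=True), _obs("A", d5=2, reverse=True)]
    col = _col(2, rev)  # ref G
    call = flag_damage(_call(2, "G", "A", 2, 2), col, window=2)
    assert DAMAGE_SUSPECT in call.flags
    fwd = [_obs("A", d5=1, reverse=False)] + rev
    call2 = flag_damage(_call(2, "G", "A", 3, 3), _col(2, fwd), window=2)
    assert DAMAGE_SUSPECT not in call2.flags


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

def _pv(hgvs, pos, ref, alt):
    return GenomicVariant(hgvs_c=hgvs, chromosome="r", pos=pos, ref=ref,
                          alt=alt, kind="SNV", var_class="PV")


def test_intersect_matching_call_yields_record():
    cat = [_pv("c.2C>T", 1, "C", "T")]
    samples = {"s1": AncientSample("s1", 5000.0, "Steppe")}
    calls = {"s1": [_call(1, "C", "T", 5, 5)]}
    records, dropped = intersect_catalog(calls, cat, samples)
    assert len(records) == 1 and records[0].hgvs_c == "c.2C>T"
    assert records[0].date_bp == 5000.0 and not dropped


def test_intersect_non_catalog_call_ignored():
    cat = [_pv("c.2C>T", 1, "C", "T")]
    samples = {"s1": AncientSample("s1", 5000.0)}
    calls = {"s1": [_call(5, "C", "T", 5, 5)]}
    records, _ = intersect_catalog(calls, cat, samples)
    assert records == []


def test_intersect_drops_damage_suspect_pv_hits():
    cat = [_pv("c.2C>T", 1, "C", "T")]
    samples = {"s1": AncientSample("s1", 5000.0)}
    call = GenotypeCall(pos=1, ref="C", alt="T", depth=3, alt_depth=3,
                        flags=frozenset({DAMAGE_SUSPECT}))
    records, dropped = intersect_catalog({"s1": [call]}, cat, samples)
    assert records == [] and dropped[0]["reason"] == DAMAGE_SUSPECT
    records2, _ = intersect_catalog({"s1": [call]}, cat, samples,
                                    drop_damage_pv=False)
    assert len(records2) == 1


# ---------------------------------------------------------------------------
# timelines
# ---------------------------------------------------------------------------

def _records(hgvs, dates):
    return [CarrierRecord(sample_id=f"s{i}", hgvs_c=hgvs, date_bp=d)
            for i, d in enumerate(dates)]


def test_arisen_time_is_oldest_carrier():
    """Four carriers dated 9860/4475/2175/1450 BP date the variant to 9860."""
    (tl,) = build_timelines(_records("c.3256C>T", [9860, 4475, 2175, 1450]))
    assert tl.arisen_time_bp == 9860 and tl.carrier_count == 4


def test_single_carrier_dates_variant():
    (tl,) = build_timelines(_records("c.49-1G>A", [689]))
    assert tl.arisen_time_bp == 689


def test_arisen_time_order_free():
    import itertools
    for perm in itertools.permutations([9860, 4475, 2175, 1450]):
        (tl,) = build_timelines(_records("c.1A>G", list(perm)))
        assert tl.arisen_time_bp == 9860


def test_timeline_ordering_count_desc_then_anchor_asc():
    recs = (_records("c.212-1G>A", [2275, 100])
            + _records("c.211+1G>A", [10050, 100])
            + _records("c.3G>A", [31630]))
    tls = build_timelines(recs)
    assert [t.hgvs_c for t in tls] == ["c.211+1G>A", "c.212-1G>A", "c.3G>A"]


def test_carrier_counts_partition_records():
    recs = _records("c.1A>G", [1, 2]) + _records("c.2A>G", [3, 4, 5])
    tls = build_timelines(recs)
    assert sum(t.carrier_count for t in tls) == len(recs)
    for t in tls:
        dates = [c.date_bp for c in t.carriers]
        assert t.arisen_time_bp >= max(dates)
        assert t.arisen_time_bp in dates


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def test_bundled_carrier_table_summary():
    records, meta = load_ancient_carrier_table()
    tls = build_timelines(records, meta)
    s = cohort_summary(tls)
    assert s["n_variants"] == 50
    assert s["n_carriers"] == 71
    assert s["carriers_within_cutoff"] == 64
    assert s["pct_carriers_within_cutoff"] == 90.1
    assert s["mutation_types"]["stopgain"] == 32
    assert s["mutation_type_pct"]["stopgain"] == 64.0
    assert s["domains"]["WD40"] == 18
    assert s["n_multi_carrier_variants"] == 16
    assert s["carrier_count_histogram"]["3"] == 3
    assert s["oldest_carrier_bp"] == 32895
    assert s["youngest_carrier_bp"] == 689
    # the censored ">10,000" rows render with their floor
    frame = timelines_to_frame(tls)
    assert (frame["arisen_time_bp"] == ">10000").sum() == 2
    assert len(frame) == 50


def test_all_recent_carriers_are_100_percent():
    tls = build_timelines(_records("c.1A>G", [100, 200, 300]))
    s = cohort_summary(tls, cutoff_bp=10_000)
    assert s["pct_carriers_within_cutoff"] == 100.0


def test_empty_timeline_set_is_defined():
    s = cohort_summary([])
    assert s["n_variants"] == 0 and s["n_carriers"] == 0
    assert s["oldest_carrier_bp"] is None


def test_undated_carrier_needs_dated_sibling():
    rec = CarrierRecord(sample_id="s", hgvs_c="c.1A>G", date_bp=None)
    with pytest.raises(ValueError, match="no dated carrier"):
        build_timelines([rec])


# ---------------------------------------------------------------------------
# synthetic-cohort recovery
# ---------------------------------------------------------------------------

def _carrier_recovery(bundle):
    ref = bundle["alignment"].ungapped("human")
    samples = {s.sample_id: s for s in bundle["samples"]}
    calls = {sid: call_sample(cols, ref)
             for sid, cols in bundle["pileups"].items()}
    records, _ = intersect_catalog(calls, bundle["catalog"], samples)
    found = {}
    for r in records:
        found.setdefault(r.sample_id, set()).add(r.hgvs_c)
    tp = fn = 0
    for sid, truth in bundle["truth_carriers"].items():
        truth = set(truth)
        got = found.get(sid, set())
        tp += len(truth & got)
        fn += len(truth - got)
    return tp, fn


def test_planted_carriers_recovered(sim_bundle):
    """At ~6x coverage with deamination 0.2, the default thresholds recover
    planted carriers with sensitivity >= 0.95."""
    tp, fn = _carrier_recovery(sim_bundle)
    assert tp + fn > 0
    assert tp / (tp + fn) >= 0.95


def test_pileup_tsv_round_trip(tmp_path, sim_bundle):
    p = tmp_path / "pile.tsv"
    write_pileups_tsv(sim_bundle["pileups"], p)
    back = read_pileups_tsv(p)
    sid = sorted(sim_bundle["pileups"])[0]
    orig = sim_bundle["pileups"][sid]
    assert [c.pos for c in back[sid]] == [c.pos for c in orig]
    assert back[sid][0].observations == orig[0].observations
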