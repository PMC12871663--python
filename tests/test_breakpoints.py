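"""Variant filtering, AD-ratio genotype states, windowing, breakpoint calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satdrive import (
    TractSpec,
    VariantRecord,
    WindowSummary,
    ad_ratio,
    call_breakpoints,
    classify_state,
    filter_variants,
    gen_variant_table,
    site_states,
    window_states,
)


def rec(pos=100, qual=45.0, ref=20, alt=20, total=None, contig="ctg"):
    total = total if total is not None else ref + alt
    return VariantRecord(
        contig=contig, position=pos, qual=qual, ref_depth=ref, alt_depth=alt, total_depth=total
    )


class TestFilterVariants:
    def test_qual_threshold_is_strict(self):
        records = [rec(qual=29.0), rec(qual=30.0), rec(qual=31.0)]
        kept = filter_variants(records)
        assert [r.qual for r in kept] == [31.0]

    def test_interpolated_quartiles(self):
        # depths 10,20,30,40,50 -> q25=20, q75=40 (linear interpolation);
        # band inclusive, so 10 and 50 fall out
        records = [rec(total=d, ref=d // 2, alt=d - d // 2) for d in (10, 20, 30, 40, 50)]
        kept = filter_variants(records)
        assert sorted(r.total_depth for r in kept) == [20, 30, 40]

    def test_uniform_depth_all_pass(self):
        records = [rec(total=33, ref=16, alt=17) for _ in range(7)]
        assert len(filter_variants(records)) == 7

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert filter_variants([]) == []

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(0)
        records = [
            rec(pos=i, qual=float(rng.uniform(0, 60)), total=int(rng.integers(5, 80)),
                ref=1, alt=1)
            for i in range(200)
        ]
        kept = filter_variants(records)
        assert set(id(r) for r in kept) <= set(id(r) for r in records)

    def test_idempotent_with_frozen_quantiles(self):
        # refiltering survivors with the same explicit band keeps them all
        records = [rec(pos=i, total=d, ref=d, alt=0, qual=50.0)
                   for i, d in enumerate((10, 20, 30, 40, 50))]
        kept = filter_variants(records)
        lo, hi = 20, 40
        again = [r for r in kept if lo <= r.total_depth <= hi and r.qual > 30]
        assert again == kept


class TestAdRatioAndState:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(1, 9, 0.9), (50, 50, 0.5), (0, 37, 1.0), (37, 0, 0.0)]
    )
    def test_ratio_arithmetic(self, ref, alt, expected):
        assert ad_ratio(rec(ref=ref, alt=alt)) == pytest.approx(expected)

    def test_zero_depth_is_undefined_and_uncertain(self):
        r = rec(ref=0, alt=0, total=10)
        assert ad_ratio(r) is None
        assert classify_state(ad_ratio(r)) == "uncertain"

    @pytest.mark.parametrize(
        "ratio,state",
        [
            (0.9, "alternate"), (0.95, "alternate"), (1.0, "alternate"),
            (0.1, "reference"), (0.0, "reference"),
            (0.3, "heterozygous"), (0.5, "heterozygous"), (0.7, "heterozygous"),
            (0.2, "uncertain"), (0.70001, "uncertain"), (0.89999, "uncertain"),
            (0.10001, "uncertain"), (0.29999, "uncertain"),
        ],
    )
    def test_threshold_table(self, ratio, state):
        assert classify_state(ratio) == state

    @given(ratio=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_total_function_partition(self, ratio):
        assert classify_state(ratio) in {"alternate", "reference", "heterozygous", "uncertain"}


class TestWindowStates:
    def test_pure_alternate_window(self):
        records = [rec(pos=p, ref=1, alt=40) for p in range(1, 101)]
        windows = window_states(site_states(records), window_size=50_000, contig_length=50_000)
        assert len(windows) == 1
        assert windows[0].alternate_frequency == 1.0

    def test_half_alternate(self):
        records = [rec(pos=p, ref=1, alt=40) for p in range(1, 51)] + [
            rec(pos=p, ref=40, alt=1) for p in range(51, 101)
        ]
        windows = window_states(site_states(records), 50_000, 50_000)
        assert windows[0].alternate_frequency == 0.5

    def test_uncertain_excluded_from_denominator(self):
        records = [rec(pos=1, ref=1, alt=40), rec(pos=2, ref=8, alt=2)]  # alt + uncertain
        windows = window_states(site_states(records), 50_000, 50_000)
        assert windows[0].alternate_frequency == 1.0
        assert windows[0].n_uncertain == 1

    def test_windows_tile_contig(self):
        records = [rec(pos=p) for p in (1, 60_000, 200_001)]
        windows = window_states(site_states(records), 50_000, 210_000)
        assert len(windows) == 5
        assert [w.start for w in windows] == [0, 50_000, 100_000, 150_000, 200_000]
        assert windows[2].is_empty and windows[3].is_empty
        assert not windows[4].is_empty

    def test_generator_truth_no_noise(self):
        spec = TractSpec(
            contig_length=500_000,
            tracts=((250_000, "reference"), (500_000, "alternate")),
            sites_per_kb=1.0,
            noise=0.0,
            error_fraction=0.0,
            seed=5,
        )
        records, _ = gen_variant_table(spec)
        windows = window_states(site_states(records), 50_000, 500_000)
        for w in windows:
            if w.is_empty:
                continue
            expected = 0.0 if w.end <= 250_000 else (1.0 if w.start >= 250_000 else None)
            if expected is not None:
                assert w.alternate_frequency == expected

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            window_states([], 0)


def make_windows(labels, n_sites=40, window=50_000):
    """Windows matching a string of labels: r, a, h, m (mixed/ambiguous)."""
    comp = {
        "r": dict(n_reference=n_sites, n_heterozygous=0, n_alternate=0),
        "a": dict(n_reference=0, n_heterozygous=0, n_alternate=n_sites),
        "h": dict(n_reference=0, n_heterozygous=n_sites, n_alternate=0),
        "m": dict(n_reference=n_sites // 2, n_heterozygous=0, n_alternate=n_sites // 2),
    }
    return [
        WindowSummary(contig="ctg", start=i * window, end=(i + 1) * window,
                      n_uncertain=0, **comp[c])
        for i, c in enumerate(labels)
    ]


class TestCallBreakpoints:
    def test_step_function_single_call(self):
        windows = make_windows("r" * 10 + "a" * 10)
        calls = call_breakpoints(windows)
        assert len(calls) == 1
        b = calls[0]
        assert (b.left_state, b.right_state) == ("reference", "alternate")
        # interval spans the 10th and 11th windows
        assert b.start >= windows[9].start and b.end <= windows[10].end

    def test_all_heterozygous_no_calls(self):
        assert call_breakpoints(make_windows("h" * 12)) == []

    def test_mixed_window_bridged(self):
        calls = call_breakpoints(make_windows("r" * 8 + "m" + "a" * 8))
        assert len(calls) == 1
        assert calls[0].start < 9 * 50_000 < calls[0].end

    def test_same_state_runs_not_called(self):
        # an ambiguous gap inside one tract must not produce a call
        assert call_breakpoints(make_windows("r" * 5 + "m" + "r" * 5)) == []

    def test_het_to_alternate_transition(self):
        calls = call_breakpoints(make_windows("h" * 6 + "a" * 6))
        assert len(calls) == 1
        assert (calls[0].left_state, calls[0].right_state) == ("heterozygous", "alternate")

    def test_too_few_windows_warns(self):
        with pytest.warns(UserWarning):
            assert call_breakpoints(make_windows("ra")) == []

    def test_short_runs_ignored(self):
        # a single discordant window is noise, not two breakpoints
        assert call_breakpoints(make_windows("r" * 6 + "a" + "r" * 6)) == []


class TestBreakpointRecovery:
    @pytest.mark.parametrize("seed", range(6))
    def test_single_breakpoint_recovered(self, seed):
        truth_pos = 917_000  # not a window multiple
        spec = TractSpec(
            contig_length=2_000_000,
            tracts=((truth_pos, "reference"), (2_000_000, "alternate")),
            sites_per_kb=2.0,
            noise=0.05,
            seed=seed,
        )
        records, truth = gen_variant_table(spec)
        kept = filter_variants(records)
        states = site_states(kept)
        windows = window_states(states, 50_000, spec.contig_length)
        calls = call_breakpoints(windows, states=states)
        assert len(calls) == 1
        assert abs(calls[0].midpoint - truth[0]) <= 50_000

    def test_three_tracts_two_breakpoints(self):
        spec = TractSpec(
            contig_length=3_000_000,
            tracts=((800_000, "reference"), (1_900_000, "heterozygous"), (3_000_000, "alternate")),
            sites_per_kb=2.0,
            noise=0.03,
            seed=17,
        )
        records, truth = gen_variant_table(spec)
        kept = filter_variants(records)
        states = site_states(kept)
        windows = window_states(states, 50_000, spec.contig_length)
        calls = call_breakpoints(windows, states=states)
        assert len(calls) == 2
        for call, t in zip(calls, truth):
            assert abs(call.midpoint - t) <= 50_000
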