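"""Crossover caller: segmentation rule, oracle equivalence, fidelity."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meicross as mc
from meicross.calling import (
    HET,
    HOM_RECURRENT,
    MISSING,
    CallerParams,
    Segment,
    call_crossovers,
    classify_chromosomes,
    segment_genotype_vector,
)
from meicross.pipeline import evaluate_calls, truth_events

P = CallerParams()  # min_run 5, max_background 1


# ---------------------------------------------------------------------------
# independent brute-force oracle


def _supported(segment_vals, genotype, R, B):
    """Does a block contain >= R concordant markers with gaps <= B each?"""
    cnt = gap = 0
    for v in segment_vals:
        if v == genotype:
            cnt += 1
            gap = 0
            if cnt >= R:
                return True
        else:
            gap += 1
            if gap > B:
                cnt = 0
                gap = 0
    return False


def brute_force_segmentation(values, R, B):
    """Enumerate every segmentation of an informative 0/1 vector.

    Returns (genotypes, boundaries) of the valid segmentation minimizing
    (discordance, n_segments, first-genotype mismatch with first marker,
    boundary positions); None if no valid segmentation exists.
    """
    n = len(values)
    best = None
    for g0 in (0, 1):
        for k in range(n):  # number of switches
            for bounds in itertools.combinations(range(1, n), k):
                cuts = (0,) + bounds + (n,)
                genos = [(g0 + i) % 2 for i in range(k + 1)]
                ok = True
                cost = 0
                for (a, b), g in zip(itertools.pairwise(cuts), genos):
                    block = values[a:b]
                    if not _supported(block, g, R, B):
                        ok = False
                        break
                    cost += sum(v != g for v in block)
                if not ok:
                    continue
                key = (cost, k, g0 != values[0], bounds)
                if best is None or key < best[0]:
                    best = (key, genos, bounds)
    if best is None:
        return None
    return best[1], best[2]


def _to_oracle_form(segments, informative):
    """Convert Segment list to (genotypes, boundaries) over informative indices."""
    inv = {orig: k for k, orig in enumerate(informative)}
    genos = [s.genotype for s in segments]
    bounds = tuple(inv[s.first_index] for s in segments[1:])
    return genos, bounds


class TestSegmentationExamples:
    def test_constant_vector_single_segment(self):
        assert segment_genotype_vector([HET] * 100, P) == [Segment(HET, 0, 99)]

    def test_isolated_discordant_marker_absorbed(self):
        segs = segment_genotype_vector([1] * 50 + [0] + [1] * 49, P)
        assert segs == [Segment(1, 0, 99)]

    def test_clean_switch_called_between_runs(self):
        segs = segment_genotype_vector([1] * 50 + [0] * 50, P)
        assert segs == [Segment(1, 0, 49), Segment(0, 50, 99)]

    def test_short_terminal_exchange_not_called(self):
        # 3 trailing discordant markers cannot support a segment
        assert len(segment_genotype_vector([1] * 97 + [0] * 3, P)) == 1
        assert len(segment_genotype_vector([0] * 3 + [1] * 97, P)) == 1

    def test_short_internal_exchange_absorbed_as_background(self):
        assert len(segment_genotype_vector([1] * 47 + [0] * 3 + [1] * 50, P)) == 1

    def test_missing_calls_transparent(self):
        segs = segment_genotype_vector([1] * 10 + [MISSING] * 5 + [0] * 10, P)
        assert segs == [Segment(1, 0, 9), Segment(0, 15, 24)]

    def test_all_missing_vector_flagged_empty(self):
        with pytest.warns(UserWarning, match="all-missing"):
            assert segment_genotype_vector([MISSING] * 10, P) == []

    def test_unsegmentable_vector_falls_back_to_majority(self):
        with pytest.warns(UserWarning, match="no valid segmentation"):
            segs = segment_genotype_vector([1, 0, 1, 0, 1, 0, 1], P)
        assert len(segs) == 1 and segs[0].genotype == 1

    def test_min_run_must_exceed_max_background(self):
        with pytest.raises(ValueError):
            CallerParams(min_run=2, max_background=2)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "vector",
        [
            [1, 1, 1, 0, 0, 0],
            [1, 1, 0, 1, 1, 0, 0, 0, 0],
            [0, 1, 1, 1, 1, 0, 0, 0, 1],
            [1, 0, 0, 1, 1, 1, 0, 0, 1, 1],
            [1, 1, 1, 1, 0, 1, 0, 0, 0, 0, 0],
        ],
    )
    def test_hand_picked_vectors(self, vector):
        params = CallerParams(min_run=3, max_background=1)
        oracle = brute_force_segmentation(vector, 3, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs = segment_genotype_vector(vector, params)
        if oracle is None:
            assert len(segs) == 1  # majority fallback
        else:
            assert _to_oracle_form(segs, list(range(len(vector)))) == oracle

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        values=st.lists(st.sampled_from([0, 1, 1, -1]), min_size=1, max_size=12),
        min_run=st.integers(2, 4),
        max_background=st.integers(0, 1),
    )
    def test_matches_exhaustive_enumeration(self, values, min_run, max_background):
        """DP output equals the minimum-discordance enumeration oracle."""
        if min_run <= max_background:
            max_background = min_run - 1
        params = CallerParams(min_run=min_run, max_background=max_background)
        informative = [i for i, v in enumerate(values) if v != MISSING]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs = segment_genotype_vector(values, params)
        if not informative:
            assert segs == []
            return
        inf_values = [values[i] for i in informative]
        oracle = brute_force_segmentation(inf_values, min_run, max_background)
        if oracle is None:
            maj = int(np.bincount(inf_values, minlength=2).argmax())
            assert segs == [Segment(maj, informative[0], informative[-1])]
        else:
            assert _to_oracle_form(segs, informative) == oracle

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(values=st.lists(st.sampled_from([0, 1, 1, -1]), min_size=1, max_size=40))
    def test_mirror_symmetry(self, values):
        """Reversing marker order mirrors the segmentation.

        The leftmost-tie-break solution of the reversed vector equals the
        mirrored rightmost-tie-break solution of the original.
        """
        n = len(values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = segment_genotype_vector(values, P, tie_break="rightmost")
            rev = segment_genotype_vector(values[::-1], P, tie_break="leftmost")
        mirrored = [
            Segment(s.genotype, n - 1 - s.last_index, n - 1 - s.first_index)
            for s in reversed(fwd)
        ]
        assert rev == mirrored


class TestCallCrossovers:
    def _simulate(self, n, markers, error, missing, seed, params=None):
        specs = mc.default_chromosomes()
        sim = params or mc.mutant_params()
        rng = np.random.default_rng(seed)
        mm = mc.random_marker_map(specs, markers, seed=int(rng.integers(2**31)))
        meioses = mc.simulate_meiosis(sim, specs, n, seed=int(rng.integers(2**31)))
        gm = mc.simulate_backcross_genotypes(
            [[g for _, g in row] for row in meioses], mm,
            error_rate=error, missing_rate=missing,
            seed=int(rng.integers(2**31)), specs=specs,
        )
        return meioses, mm, gm

    def test_noiseless_recovery_exact(self):
        """Every callable truth breakpoint recovered, no false calls.

        A breakpoint is callable when at least ``min_run`` markers flank it
        on both sides (toward the span ends and toward neighboring
        crossovers); the run-support rule cannot call anything else.
        """
        meioses, mm, gm = self._simulate(50, 300, 0.0, 0.0, seed=21)
        events = call_crossovers(gm)
        truth = truth_events(meioses, gm.individuals)
        callable_truth = {}
        for (ind, chrom), pos in truth.items():
            markers = mm[chrom]
            keep = []
            for p in pos:
                before = np.searchsorted(markers, p, side="right")
                flanked = before >= 5 and len(markers) - before >= 5
                isolated = all(
                    abs(np.searchsorted(markers, q) - before) >= 5
                    for q in pos if q != p
                )
                if flanked and isolated:
                    keep.append(p)
            callable_truth[(ind, chrom)] = np.asarray(keep)
        res = evaluate_calls(callable_truth, events, mm)
        assert res.recall == 1.0
        assert res.false_call_rate == 0.0
        # noiseless events sit exactly between adjacent markers
        for ev in events:
            markers = mm[ev.chromosome]
            i = np.searchsorted(markers, ev.left_bp)
            assert markers[i] == ev.left_bp and markers[i + 1] == ev.right_bp

    def test_fidelity_degrades_monotonically_with_error_rate(self):
        recalls, false_rates = [], []
        for error in (0.0, 0.01, 0.05):
            meioses, mm, gm = self._simulate(60, 300, error, 0.0, seed=22)
            events = call_crossovers(gm)
            res = evaluate_calls(truth_events(meioses, gm.individuals), events, mm)
            recalls.append(res.recall)
            false_rates.append(res.false_call_rate)
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert false_rates[0] <= false_rates[2]

    def test_determinism(self):
        _, _, gm = self._simulate(20, 200, 0.01, 0.02, seed=23)
        assert call_crossovers(gm) == call_crossovers(gm)

    def test_sparse_chromosome_yields_no_calls(self):
        gm = mc.GenotypeMatrix(
            individuals=["a"],
            positions={"I": np.array([100, 200, 300])},
            calls={"I": np.array([[1, 1, 1]], dtype=np.int8)},
        )
        with pytest.warns(UserWarning, match="informative"):
            assert call_crossovers(gm, CallerParams(min_run=5)) == []

    def test_events_sorted_and_non_overlapping_per_chromosome(self):
        _, _, gm = self._simulate(40, 300, 0.005, 0.02, seed=24)
        events = call_crossovers(gm)
        by_key = {}
        for ev in events:
            by_key.setdefault((ev.individual, ev.chromosome), []).append(ev)
        for evs in by_key.values():
            for a, b in zip(evs, evs[1:]):
                assert a.right_bp <= b.left_bp


class TestClassifyChromosomes:
    def test_no_events_all_zero_class(self):
        census = classify_chromosomes([], 10, ["I", "II"])
        assert (census["zero"] == 10).all()
        assert census.values.sum() == 20

    def test_counts_sum_to_individuals(self):
        events = [
            mc.CrossoverEvent("a", "I", 100, 200),
            mc.CrossoverEvent("a", "I", 500, 600),
            mc.CrossoverEvent("b", "I", 100, 200),
        ]
        census = classify_chromosomes(events, 5, ["I"])
        assert census.loc["I"].to_dict() == {"zero": 3, "one": 1, "two_plus": 1}

    def test_printed_census_emulation(self):
        """28 double-CO chromosomes among 84 individuals x 6 chromosomes."""
        chroms = ["I", "II", "III", "IV", "V", "X"]
        events = []
        k = 0
        for chrom in chroms:
            for _ in range(5 if chrom != "X" else 3):  # 28 doubles total
                ind = f"F2_{k:03d}"
                events.append(mc.CrossoverEvent(ind, chrom, 1_000_000, 1_100_000))
                events.append(mc.CrossoverEvent(ind, chrom, 9_000_000, 9_100_000))
                k += 1
        census = classify_chromosomes(events, 84, chroms)
        assert census["two_plus"].sum() == 28
        assert census.values.sum() == 84 * 6

    def test_obligate_transmission_splits_evenly(self):
        specs = mc.default_chromosomes()
        meioses = mc.simulate_meiosis(mc.wildtype_params(), specs, 2000, seed=25)
        truth = truth_events(meioses)
        events = [
            mc.CrossoverEvent(ind, chrom, int(p), int(p) + 1)
            for (ind, chrom), pos in truth.items()
            for p in pos
        ]
        census = classify_chromosomes(events, 2000, [s.name for s in specs])
        frac_one = census["one"].sum() / census.values.sum()
        assert census["two_plus"].sum() == 0
        assert abs(frac_one - 0.5) < 3 * np.sqrt(0.25 / 12_000)
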