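import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import sampen_bruteforce, sampen_value_bruteforce

from cpet_entropy.preprocess import Signal, standardize
from cpet_entropy.sampen import (
    R_GRID,
    SampEnParams,
    cohort_entropy_table,
    default_params,
    match_probabilities,
    sample_entropy,
)
from cpet_entropy.synthetic import generate_cohort, mix_process
from cpet_entropy.vt1 import detect_vt1


class TestMatchProbabilities:
    def test_constant_signal_all_match(self):
        b, a, counts = match_probabilities(np.full(30, 1.5), m=2, r=0.2)
        assert b == 1.0 and a == 1.0
        assert counts["pairs"] == 28 * 27

    def test_small_pattern_matches_triple_loop(self):
        x = np.array([1.0, 2, 3, 1, 2, 3, 1, 2])
        b, a, _ = match_probabilities(x, m=2, r=0.5)
        bb, aa = sampen_bruteforce(x, 2, 0.5)
        assert (b, a) == (bb, aa)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            match_probabilities(np.arange(3.0), m=2, r=0.2)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_random_signals_match_bruteforce(self, m):
        rng = np.random.default_rng(m)
        for _ in range(25):
            n = rng.integers(m + 5, 60)
            x = rng.standard_normal(n)
            r = rng.choice([0.1, 0.2, 0.35])
            b, a, _ = match_probabilities(x, m, r)
            bb, aa = sampen_bruteforce(x, m, r)
            assert b == pytest.approx(bb, abs=0)
            assert a == pytest.approx(aa, abs=0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_a_never_exceeds_b_and_r_monotone(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        b1, a1, _ = match_probabilities(x, 2, 0.15)
        b2, a2, _ = match_probabilities(x, 2, 0.30)
        assert a1 <= b1 and a2 <= b2
        assert b2 >= b1 and a2 >= a1


class TestSampleEntropy:
    def test_constant_signal_zero_entropy(self):
        res = sample_entropy(np.full(30, 2.0), SampEnParams(2, 0.2))
        assert res.status == "defined" and res.value == 0.0

    def test_period_two_signal_zero_entropy(self):
        x = np.tile([0.0, 1.0], 20)
        res = sample_entropy(x, SampEnParams(2, 0.5))
        assert res.status == "defined" and res.value == pytest.approx(0.0)

    def test_infinite_status_when_only_m_matches(self):
        # m-templates (single values) match at the repeated 0s, but no pair
        # of consecutive-value templates stays within r.
        x = np.array([0.0, 5.0, 0.0, 9.0, 0.0, 13.0])
        res = sample_entropy(x, SampEnParams(1, 0.5))
        assert res.status == "infinite" and np.isinf(res.value)
        assert res.value_repr() == "infinite"

    def test_undefined_status_when_no_matches(self):
        x = np.array([0.0, 10.0, 30.0, 70.0, 150.0, 310.0])
        res = sample_entropy(x, SampEnParams(1, 0.5))
        assert res.status == "undefined" and np.isnan(res.value)

    def test_value_matches_bruteforce_on_random_signals(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            x = rng.standard_normal(50)
            res = sample_entropy(x, SampEnParams(2, 0.2))
            v, status = sampen_value_bruteforce(x, 2, 0.2)
            assert res.status == status
            if status == "defined":
                assert res.value == pytest.approx(v, rel=1e-12)

    def test_mix_entropy_increases_with_p(self):
        params = SampEnParams(2, 0.2)
        means = []
        for p in (0.1, 0.5, 0.9):
            vals = [
                sample_entropy(
                    standardize(Signal(mix_process(200, p, rng=np.random.default_rng(s)))),
                    params,
                ).value
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestDefaultParams:
    def test_long_signals_get_m2_and_first_defined_radius(self):
        rng = np.random.default_rng(5)
        sigs = [
            standardize(Signal(mix_process(150, 0.5, rng=rng))) for _ in range(6)
        ]
        params = default_params(sigs)
        assert params.m == 2
        assert params.r in R_GRID
        smaller = [r for r in R_GRID if r < params.r]
        for r in smaller:
            assert any(
                sample_entropy(s, SampEnParams(2, r)).status != "defined" for s in sigs
            )

    def test_short_signal_forces_m1(self):
        rng = np.random.default_rng(6)
        sigs = [Signal(rng.standard_normal(45)), Signal(rng.standard_normal(80))]
        assert default_params(sigs).m == 1

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            default_params([])


class TestCohortEntropyTable:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        records, truths = generate_cohort(participants_per_cell=2, seed=77)
        vt1 = {r.participant_id: detect_vt1(r) for r in records}
        return records, truths, vt1

    def test_counts_and_schema(self, small_cohort):
        records, _, vt1 = small_cohort
        table, exclusions = cohort_entropy_table(records, vt1, SampEnParams(2, 0.2))
        assert len(table) + len(exclusions) == len(records) * 12
        assert list(table.columns) == [
            "participant_id", "metric", "sex", "pubertal", "side", "sampen",
        ]
        assert table.sampen.ge(0).all()

    def test_deterministic_regeneration(self, small_cohort):
        records, _, vt1 = small_cohort
        t1, _ = cohort_entropy_table(records, vt1, SampEnParams(2, 0.2))
        records2, _ = generate_cohort(participants_per_cell=2, seed=77)
        vt12 = {r.participant_id: detect_vt1(r) for r in records2}
        t2, _ = cohort_entropy_table(records2, vt12, SampEnParams(2, 0.2))
        assert t1.equals(t2)

    def test_tight_radius_exclusions_are_logged(self, small_cohort):
        records, _, vt1 = small_cohort
        table, excl = cohort_entropy_table(records, vt1, SampEnParams(2, 0.01))
        assert len(table) + len(excl) == len(records) * 12
        assert all(e["reason"].startswith(("sampen", "degenerate")) for e in excl)
        assert excl  # r this tight cannot keep every segment defined
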