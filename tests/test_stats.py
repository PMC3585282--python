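"""Replicate statistics: aggregation, ANOVA, t-tests, ΔΔCt, A(F;P) rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ecisfit import simulate as sim
from ecisfit.errors import DegenerateDataError, InvalidArgumentError
from ecisfit.stats import (
    aggregate_electrodes,
    anova_oneway,
    ddct,
    format_afp,
    parse_afp,
    ttest,
)


def experiment_table(rows):
    return pd.DataFrame(rows, columns=["experiment_id", "condition",
                                       "electrode_id", "value"])


class TestAggregateElectrodes:
    def test_four_electrode_mean(self):
        t = experiment_table([("X1", "ctrl", f"e{i}", v)
                              for i, v in enumerate([2.0, 4.0, 4.0, 6.0])])
        out = aggregate_electrodes(t)
        assert out.loc[0, "mean"] == 4.0
        assert out.loc[0, "n_electrodes"] == 4

    def test_single_electrode_identity(self):
        out = aggregate_electrodes(experiment_table([("X1", "ctrl", "e1", 3.3)]))
        assert out.loc[0, "mean"] == 3.3

    def test_permutation_invariance(self):
        rows = [("X1", "a", "e1", 1.0), ("X1", "a", "e2", 5.0),
                ("X2", "a", "e1", 2.0), ("X2", "b", "e1", 7.0)]
        a = aggregate_electrodes(experiment_table(rows))
        b = aggregate_electrodes(experiment_table(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_table_raises(self):
        with pytest.raises(DegenerateDataError):
            aggregate_electrodes(experiment_table([]))


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        assert anova_oneway([3.0, 3.0, 3.0], [3.0, 3.0], [3.0, 3.0]) == (0.0, 1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        f, p_f = anova_oneway(a, b)
        t = ttest(a, b, mode="unpaired")
        assert f == pytest.approx(t.t**2, rel=1e-12)
        assert p_f == pytest.approx(t.p, rel=1e-12)

    def test_closed_form_oracle(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: SSB=6 (df 2), SSW=6 (df 6) -> F=3
        f, p = anova_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert f == pytest.approx(3.0, rel=1e-12)
        assert p == pytest.approx(0.125, rel=1e-10)  # sf of F(2,6) at 3, frozen

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(0, 1), 1, rng.integers(3, 9))
                      for _ in range(k)]
            f, p = anova_oneway(*groups)
            ref = sps.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)

    def test_zero_within_variance_with_unequal_means(self):
        f, p = anova_oneway([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(f) and p == 0.0

    def test_group_size_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            anova_oneway([1.0, 2.0])
        with pytest.raises(InvalidArgumentError):
            anova_oneway([1.0], [2.0, 3.0])


class TestTtest:
    def test_paired_closed_form_oracle(self):
        # d = {-1,-1,-2,-2}: mean -1.5, sd 1/sqrt(3) -> t = -3*sqrt(3), df 3
        res = ttest([1, 2, 3, 4], [2, 3, 5, 6], mode="paired")
        assert res.t == pytest.approx(-5.196152422706632, rel=1e-12)
        assert res.p == pytest.approx(0.013846832988859045, rel=1e-10)
        assert res.df == 3

    def test_identical_paired_samples_degenerate(self):
        res = ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="paired")
        assert res.degenerate

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0, 8.0], [2.0, 2.5, 5.0, 6.0]
        for mode in ("paired", "unpaired"):
            r1, r2 = ttest(a, b, mode=mode), ttest(b, a, mode=mode)
            assert r1.t == pytest.approx(-r2.t, rel=1e-12)
            assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a = rng.normal(0, 1, n)
            b = rng.normal(0.3, 1.2, n)
            r = ttest(a, b, mode="paired")
            ref = sps.ttest_rel(a, b)
            assert r.t == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)
            m = int(rng.integers(3, 12))
            c = rng.normal(0.1, 0.8, m)
            r = ttest(a, c, mode="unpaired")
            ref = sps.ttest_ind(a, c, equal_var=True)
            assert r.t == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)
            r = ttest(a, c, mode="unpaired", equal_var=False)
            ref = sps.ttest_ind(a, c, equal_var=False)
            assert r.t == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)


class TestDdct:
    def test_definitional_arithmetic(self):
        t = pd.DataFrame([
            ("untreated", "HPRT", 20.0), ("untreated", "RAP2A", 24.0),
            ("kd", "HPRT", 20.0), ("kd", "RAP2A", 25.0),
        ], columns=["sample_id", "gene", "ct_cycles"])
        out = ddct(t).set_index("sample_id")
        assert out.loc["kd", "dct"] == 5.0
        assert out.loc["untreated", "dct"] == 4.0
        assert out.loc["kd", "ddct"] == 1.0
        assert out.loc["kd", "fold_2_neg_ddct"] == pytest.approx(0.5)

    def test_reference_sample_is_zero(self):
        t = pd.DataFrame([
            ("untreated", "HPRT", 19.5), ("untreated", "G1", 23.0),
            ("untreated", "G2", 27.0),
        ], columns=["sample_id", "gene", "ct_cycles"])
        out = ddct(t)
        assert (out["ddct"] == 0).all()
        assert (out["fold_2_neg_ddct"] == 1.0).all()

    @settings(deadline=None, derandomize=True)
    @given(offset=st.floats(-5, 5))
    def test_per_sample_offset_invariance(self, offset):
        base = pd.DataFrame([
            ("untreated", "HPRT", 20.0), ("untreated", "G", 24.0),
            ("kd", "HPRT", 20.3), ("kd", "G", 26.1),
        ], columns=["sample_id", "gene", "ct_cycles"])
        shifted = base.copy()
        shifted.loc[shifted["sample_id"] == "kd", "ct_cycles"] += offset
        pd.testing.assert_frame_equal(ddct(base), ddct(shifted))

    def test_missing_reference_gene_named(self):
        t = pd.DataFrame([("untreated", "G", 24.0), ("kd", "G", 25.0),
                          ("untreated", "HPRT", 20.0)],
                         columns=["sample_id", "gene", "ct_cycles"])
        with pytest.raises(InvalidArgumentError, match="HPRT"):
            ddct(t)

    def test_generator_round_trip(self):
        """Mean 2^-ΔΔCt over independent experiments recovers the knockdown.

        Within one experiment every replicate shares the reference sample's
        measurement noise, so the average is taken across experiments, as
        in the assay itself.
        """
        folds = []
        for seed in range(4):
            table = sim.generate_ct_table({"RAP2A": 0.25}, n_replicates=3, seed=seed)
            out = ddct(table)
            folds.append(out[out["sample_id"] != "untreated"]["fold_2_neg_ddct"].mean())
        assert np.mean(folds) == pytest.approx(0.25, rel=0.2)


class TestAfpFormat:
    @pytest.mark.parametrize("f,p", [(12.34, 0.0012), (3.0, 0.125),
                                     (250.7, 3.2e-7), (0.0, 1.0)])
    def test_round_trip(self, f, p):
        f2, p2 = parse_afp(format_afp(f, p, precision=6))
        assert f2 == pytest.approx(f, rel=1e-5)
        assert p2 == pytest.approx(p, rel=1e-5)

    def test_below_machine_marker(self):
        s = format_afp(np.inf, 0.0)
        assert "<" in s
        assert parse_afp(s)[1] == 0.0

    def test_rejects_garbage(self):
        with pytest.raises(InvalidArgumentError):
            parse_afp("F=3, P=0.1")
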