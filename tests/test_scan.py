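"""Regression core, FDR, QQ diagnostics, null calibration and the
group-size sweep."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import grscan as gs
from grscan.scan import P_FLOOR, _ols_indicator_scan
from conftest import make_cohort, make_weights


def naive_bh(p):
    """Textbook step-up reference: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    return q


class TestFitGroupAssociation:
    def test_reduces_to_two_sample_t(self, rng):
        y = rng.normal(size=24)
        labels = np.array(["low"] * 10 + ["high"] * 10 + ["excluded"] * 4)
        es, se, p = gs.fit_group_association(y, labels)
        lo, hi = y[:10], y[10:20]
        t, p_ref = stats.ttest_ind(hi, lo, equal_var=True)
        assert es == pytest.approx(hi.mean() - lo.mean(), rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_exact_separation_hits_underflow_floor(self):
        y = np.array([0.0] * 6 + [1.0] * 6)
        labels = np.array(["low"] * 6 + ["high"] * 6)
        es, se, p = gs.fit_group_association(y, labels)
        assert es == pytest.approx(1.0)
        assert p == P_FLOOR

    def test_matches_statsmodels_with_covariates(self, rng):
        """Independent cross-check of the vectorized solver against
        statsmodels OLS on random covariate-adjusted designs."""
        import statsmodels.api as sm

        for _ in range(20):
            n = int(rng.integers(20, 50))
            nlow = n // 2
            labels = np.array(["low"] * nlow + ["high"] * (n - nlow))
            cov = pd.DataFrame(
                {
                    "age": rng.normal(size=n),
                    "sex": rng.choice(["m", "f"], size=n),
                    "pc1": rng.normal(size=n),
                }
            )
            y = rng.normal(size=n) + 0.3 * (labels == "high")
            es, se, p = gs.fit_group_association(y, labels, cov)
            X = np.column_stack(
                [
                    np.ones(n),
                    (labels == "high").astype(float),
                    cov["age"],
                    (cov["sex"] == "m").astype(float),
                    cov["pc1"],
                ]
            )
            fit = sm.OLS(y, X).fit()
            assert es == pytest.approx(fit.params[1], rel=1e-8)
            assert se == pytest.approx(fit.bse[1], rel=1e-8)
            assert p == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_label_swap_negates_es_only(self, rng):
        y = rng.normal(size=30)
        labels = np.array(["low"] * 15 + ["high"] * 15)
        swapped = np.where(labels == "low", "high", "low")
        es1, se1, p1 = gs.fit_group_association(y, labels)
        es2, se2, p2 = gs.fit_group_association(y, swapped)
        assert es2 == pytest.approx(-es1, rel=1e-12)
        assert se2 == pytest.approx(se1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_empty_group_rejected(self, rng):
        y = rng.normal(size=5)
        with pytest.raises(ValueError, match="non-empty"):
            gs.fit_group_association(y, ["low"] * 5)

    def test_rank_deficiency_names_collinear_column(self, rng):
        n = 20
        labels = np.array(["low"] * 10 + ["high"] * 10)
        cov = pd.DataFrame({"dup": (labels == "high").astype(float)})
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            gs.fit_group_association(rng.normal(size=n), labels, cov)

    def test_zero_variance_gene_flagged(self):
        X = np.column_stack([np.ones(10), np.repeat([0.0, 1.0], 5)])
        Y = np.ones((10, 1))
        es, se, p, flags = _ols_indicator_scan(X, Y, ["intercept", "high"])
        assert es[0] == 0.0 and p[0] == 1.0 and flags[0] == "zero_variance"


class TestRunScan:
    def test_record_counts_and_order(self, rng):
        cohort = make_cohort(rng.integers(0, 3, (30, 3)), rng.normal(size=(5, 30)))
        wt = make_weights(["v1", "v2", "v3"], [1.2, 1.4, 1.6])
        chunks = list(gs.run_scan(cohort, wt, config=gs.ScanConfig(q_fraction=0.3)))
        assert len(chunks) == 7
        keys = [c["combination"].iloc[0] for c in chunks]
        assert keys == ["v1", "v2", "v3", "v1+v2", "v1+v3", "v2+v3", "v1+v2+v3"]
        assert all(len(c) == 5 for c in chunks)

    def test_single_variant_single_gene(self, rng):
        cohort = make_cohort(rng.integers(0, 3, (20, 1)), rng.normal(size=(1, 20)))
        wt = make_weights(["v1"], [1.5])
        records, log = gs.run_series(cohort, wt)
        assert len(records) == 1
        assert log["n_tests_planned"] == 1

    def test_null_scan_false_positive_rate(self):
        """All-null cohort: share of raw p < 0.05 is within 3 SEs of 5%
        (SE from between-gene variation, genes being independent)."""
        cfg = gs.SimulationConfig(
            n_individuals=300, n_variants=5, n_genes=200, seed=17
        )
        cohort, wt, _ = gs.simulate_cohort(cfg)
        records, _ = gs.run_series(cohort, wt)
        hits = records.assign(hit=records["p"] < 0.05).groupby("gene_id")["hit"].mean()
        se = hits.std(ddof=1) / np.sqrt(len(hits))
        assert abs(hits.mean() - 0.05) < 3 * se

    def test_covariate_confound_removed(self, rng):
        """A gene driven purely by an age covariate that tracks the GRS is
        significant when age is omitted and null when age is adjusted for."""
        n = 200
        dosage = rng.binomial(2, 0.4, size=(n, 1))
        age = dosage[:, 0] + 0.3 * rng.normal(size=n)
        y = 1.0 * age + 0.2 * rng.normal(size=n)
        cov = pd.DataFrame({"age": age})
        cohort = make_cohort(dosage, y[None, :], covariates=cov)
        wt = make_weights(["v1"], [1.5])
        grs = gs.compute_grs(cohort.genotypes, wt, ("v1",))
        labels = gs.stratify(grs, 0.3).labels
        _, _, p_adjusted = gs.fit_group_association(y, labels, cov)
        _, _, p_unadjusted = gs.fit_group_association(y, labels)
        assert p_unadjusted < 1e-6
        assert p_adjusted > 0.01


class TestAdjustFDR:
    def test_hand_worked_vectors(self):
        np.testing.assert_allclose(gs.adjust_fdr([0.01]), [0.01])
        # p*m/rank = .04,.04,.04,.04 after cumulative min from the top
        np.testing.assert_allclose(
            gs.adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(gs.adjust_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_naive_reference(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-12, 1, size=int(rng.integers(1, 200)))
            np.testing.assert_allclose(gs.adjust_fdr(p), naive_bh(p), rtol=1e-12)

    def test_q_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=500)
        q = gs.adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            gs.adjust_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            gs.adjust_fdr([1.5])


class TestQQData:
    def test_exact_uniform_grid_is_diagonal(self):
        m = 99
        p = np.arange(1, m + 1) / (m + 1)
        qq = gs.qq_data(p)
        np.testing.assert_allclose(qq["observed"], qq["expected"], atol=1e-12)

    def test_planted_signal_tops_the_plot(self, rng):
        p = np.append(rng.uniform(size=999), 1e-9)
        qq = gs.qq_data(p)
        top = qq.iloc[-1]
        assert top["observed"] == pytest.approx(9.0)
        assert top["observed"] > top["expected"] + 5

    def test_uniform_sample_hugs_diagonal(self, rng):
        p = rng.uniform(size=10_000)
        qq = gs.qq_data(p)
        lower = qq.iloc[: int(0.99 * len(qq))]
        assert (lower["observed"] - lower["expected"]).abs().max() < 0.2


class TestCalibrateGroupSize:
    def test_huge_effects_select_smallest_q(self):
        cfg = gs.SimulationConfig(
            n_individuals=400,
            n_variants=3,
            n_genes=4,
            noise_sd=1e-6,
            covariate_spec=(),
            planted_effects=(
                gs.PlantedEffect("G0001", ("rs1001", "rs1002", "rs1003"), 0.5),
                gs.PlantedEffect("G0002", ("rs1001", "rs1002", "rs1003"), 0.5),
            ),
            seed=3,
        )
        cohort, wt, _ = gs.simulate_cohort(cfg)
        res = gs.calibrate_group_size(cohort, wt, None, ["G0001", "G0002"])
        assert res.selected_q == 0.05
        assert res.table["all_replicated"].all()

    def test_all_null_selects_nothing(self):
        cfg = gs.SimulationConfig(n_individuals=300, n_variants=3, n_genes=4, seed=5)
        cohort, wt, _ = gs.simulate_cohort(cfg)
        with pytest.warns(UserWarning, match="no group size"):
            res = gs.calibrate_group_size(cohort, wt, None, ["G0001", "G0002"])
        assert res.selected_q is None
        assert not res.table["all_replicated"].any()

    def test_requires_known_genes(self, tiny_cohort):
        wt = make_weights(["v1", "v2", "v3"], [1.2, 1.3, 1.4])
        with pytest.raises(ValueError):
            gs.calibrate_group_size(tiny_cohort, wt, None, [])
        with pytest.raises(KeyError):
            gs.calibrate_group_size(tiny_cohort, wt, None, ["nope"])


def test_resumed_scan_matches_uninterrupted_run(rng):
    """Restarting from a checkpoint cursor reproduces the remaining records
    of a single uninterrupted scan exactly."""
    cohort = make_cohort(rng.integers(0, 3, (30, 3)), rng.normal(size=(4, 30)))
    wt = make_weights(["v1", "v2", "v3"], [1.2, 1.4, 1.6])
    cfg = gs.ScanConfig(q_fraction=0.3)
    full = list(gs.run_scan(cohort, wt, config=cfg))
    head, tail_expected = full[:3], full[3:]
    cursor = head[-1]["combination"].iloc[0].split("+")
    tail = list(gs.run_scan(cohort, wt, config=cfg, start_after=cursor))
    assert len(tail) == len(tail_expected)
    for a, b in zip(tail, tail_expected):
        pd.testing.assert_frame_equal(a, b)
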