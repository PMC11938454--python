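"""MR estimators against closed forms and independent oracles, plus
diagnostics and the bidirectional driver."""

import numpy as np
import pandas as pd
import pytest

from brainpath.errors import ValidationError
from brainpath.mr import (
    InstrumentSet,
    assoc_scan,
    cochran_q,
    diagnostics,
    egger_through_origin,
    i2_gx,
    ivw,
    leave_one_out,
    mr_egger,
    run_bidirectional,
    weighted_median,
)


def make_instruments(bx, by, sex=None, sey=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    k = len(bx)
    return InstrumentSet(
        tuple(f"v{i}" for i in range(k)),
        bx,
        np.full(k, 0.01) if sex is None else np.asarray(sex, float),
        by,
        np.full(k, 0.01) if sey is None else np.asarray(sey, float),
    )


def random_instruments(rng, k=6, theta=0.3):
    bx = rng.uniform(-0.5, 0.5, size=k)
    sex = rng.uniform(0.01, 0.05, size=k)
    sey = rng.uniform(0.01, 0.05, size=k)
    by = theta * bx + rng.normal(0, 0.02, size=k)
    return make_instruments(bx, by, sex, sey)


# --- independent oracles ----------------------------------------------------


def wls_through_origin_oracle(bx, by, sey):
    """Generic weighted least squares through the origin via lstsq."""
    w = np.sqrt(1.0 / np.asarray(sey, float) ** 2)
    X = (w * np.asarray(bx, float)).reshape(-1, 1)
    y = w * np.asarray(by, float)
    return float(np.linalg.lstsq(X, y, rcond=None)[0][0])


def weighted_median_oracle(bx, by, sey):
    """Brute-force cumulative-weight interpolation of the Wald ratios."""
    bx, by, sey = map(np.asarray, (bx, by, sey))
    ratios = by / bx
    weights = bx**2 / sey**2
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    for j in range(len(r)):
        if s[j] >= 0.5:
            if j == 0:
                return float(r[0])
            return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))
    return float(r[-1])


def wls_with_intercept_oracle(bx, by, sey):
    w = np.sqrt(1.0 / np.asarray(sey, float) ** 2)
    X = np.column_stack([w, w * np.asarray(bx, float)])
    y = w * np.asarray(by, float)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return float(beta[0]), float(beta[1])


# --- IVW --------------------------------------------------------------------


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        inst = make_instruments([0.2], [0.08])
        assert ivw(inst).theta == pytest.approx(0.08 / 0.2, abs=1e-12)

    def test_homogeneous_instruments(self):
        inst = make_instruments([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        assert ivw(inst).theta == pytest.approx(0.5, abs=1e-12)
        q, df, p = cochran_q(inst)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_matches_wls_oracle_on_random_instruments(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            inst = random_instruments(rng)
            oracle = wls_through_origin_oracle(inst.beta_exposure, inst.beta_outcome, inst.se_outcome)
            assert ivw(inst).theta == pytest.approx(oracle, abs=1e-10)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(34)
        inst = random_instruments(rng)
        flipped = InstrumentSet(
            inst.variant_ids,
            inst.beta_exposure * np.array([1, -1, 1, -1, 1, 1]),
            inst.se_exposure,
            inst.beta_outcome * np.array([1, -1, 1, -1, 1, 1]),
            inst.se_outcome,
        )
        assert ivw(flipped).theta == pytest.approx(ivw(inst).theta, abs=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ValidationError):
            make_instruments([0.1], [0.05], sey=[0.0])


class TestWeightedMedian:
    def test_equal_weight_median(self):
        inst = make_instruments([1.0, 1.0, 1.0], [1.0, 2.0, 9.0])
        est = weighted_median(inst, n_boot=200, seed=0)
        assert est.theta == pytest.approx(2.0, abs=1e-12)

    def test_identical_ratios_give_small_se(self):
        inst = make_instruments([0.1, 0.2, 0.4], [0.03, 0.06, 0.12],
                                sex=[1e-5, 1e-5, 1e-5], sey=[1e-4, 1e-4, 1e-4])
        est = weighted_median(inst, n_boot=200, seed=1)
        assert est.theta == pytest.approx(0.3, abs=1e-10)
        assert est.se < 0.01

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(35)
        for k in (3, 4, 5, 6):
            inst = random_instruments(rng, k=k)
            oracle = weighted_median_oracle(inst.beta_exposure, inst.beta_outcome, inst.se_outcome)
            est = weighted_median(inst, n_boot=200, seed=2)
            assert est.theta == pytest.approx(oracle, abs=1e-10)

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(36)
        inst = random_instruments(rng, k=5)
        ratios = inst.beta_outcome / inst.beta_exposure
        est = weighted_median(inst, n_boot=200, seed=3)
        assert ratios.min() - 1e-12 <= est.theta <= ratios.max() + 1e-12

    def test_needs_three_instruments(self):
        with pytest.raises(ValidationError):
            weighted_median(make_instruments([0.1, 0.2], [0.05, 0.1]))


class TestEgger:
    def test_exact_proportional_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_instruments(bx, 0.4 * bx)
        est = mr_egger(inst)
        assert est.theta == pytest.approx(0.4, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_fit_recovers_pleiotropy_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_instruments(bx, 0.4 * bx + 0.02)
        est = mr_egger(inst)
        assert est.theta == pytest.approx(0.4, abs=1e-10)
        assert est.intercept == pytest.approx(0.02, abs=1e-10)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            inst = random_instruments(rng).oriented()
            i0, slope = wls_with_intercept_oracle(inst.beta_exposure, inst.beta_outcome, inst.se_outcome)
            est = mr_egger(inst)
            assert est.theta == pytest.approx(slope, abs=1e-10)
            assert est.intercept == pytest.approx(i0, abs=1e-10)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        rng = np.random.default_rng(38)
        for _ in range(10):
            inst = random_instruments(rng)
            assert egger_through_origin(inst) == pytest.approx(ivw(inst).theta, abs=1e-10)

    def test_equal_exposure_betas_unidentifiable(self):
        inst = make_instruments([0.2, 0.2, 0.2], [0.1, 0.2, 0.3])
        with pytest.raises(ValidationError):
            mr_egger(inst)

    def test_needs_three_instruments(self):
        with pytest.raises(ValidationError):
            mr_egger(make_instruments([0.1, 0.2], [0.05, 0.1]))


class TestDiagnostics:
    def test_cochran_q_closed_form_for_symmetric_pair(self):
        # equal weights w = bx^2/sey^2 = 1; ratios theta +/- delta around IVW
        delta = 0.3
        inst = make_instruments([1.0, 1.0], [0.5 + delta, 0.5 - delta], sey=[1.0, 1.0])
        q, df, p = cochran_q(inst)
        assert q == pytest.approx(2 * 1.0 * delta**2, abs=1e-12)
        assert df == 1

    def test_cochran_q_nominal_rejection_rate(self):
        """Valid instruments with exact normal outcome noise: Q ~ chi2(k-1)."""
        rng = np.random.default_rng(39)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.5, size=6)
            sey = np.full(6, 0.05)
            by = 0.3 * bx + rng.normal(0, sey)
            inst = make_instruments(bx, by, sex=np.full(6, 1e-6), sey=sey)
            if cochran_q(inst)[2] < 0.05:
                rejections += 1
        assert 0.03 < rejections / reps < 0.08

    def test_i2_limits(self):
        # distinct exposure betas with tiny SE: Q_GX huge -> I2 ~ 1
        inst = make_instruments([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], sex=[1e-6] * 3)
        assert i2_gx(inst) > 0.999
        # identical exposure betas: Q_GX = 0 -> I2 = 0, weak-instrument flag
        inst0 = make_instruments([0.2, 0.2, 0.2], [0.1, 0.1, 0.1])
        assert i2_gx(inst0) == 0.0
        assert diagnostics(inst0).instrument_strength_flag

    def test_i2_hand_computed(self):
        bx = np.array([0.1, 0.3])
        sex = np.array([0.1, 0.1])
        w = 1 / sex**2
        mean_w = (w * bx).sum() / w.sum()
        q_gx = float((w * (bx - mean_w) ** 2).sum())
        expected = max(0.0, (q_gx - 1) / q_gx)
        inst = make_instruments(bx, [0.05, 0.15], sex=sex)
        assert i2_gx(inst) == pytest.approx(expected, abs=1e-12)

    def test_leave_one_out_homogeneous(self):
        inst = make_instruments([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        full = ivw(inst).theta
        loo = leave_one_out(inst)
        assert len(loo) == 3
        for _, est in loo:
            assert est.theta == pytest.approx(full, abs=1e-12)

    def test_leave_one_out_isolates_outlier(self):
        # common ratio 0.5 with one planted outlier ratio 3.0
        inst = make_instruments([0.1, 0.2, 0.3, 0.2], [0.05, 0.10, 0.15, 0.60])
        full = ivw(inst).theta
        loo = dict(leave_one_out(inst))
        assert abs(loo["v3"].theta - 0.5) < abs(full - 0.5)
        assert loo["v3"].theta == pytest.approx(0.5, abs=1e-12)


class TestEstimatorCoverage:
    def test_all_estimators_cover_truth_with_valid_instruments(self):
        """With all-valid instruments and exact normal noise, all three
        estimators' 95% CIs cover the true effect at the nominal rate."""
        rng = np.random.default_rng(40)
        theta = 0.3
        reps = 300
        covered = {"IVW": 0, "weighted_median": 0, "MR_Egger": 0}
        for rep in range(reps):
            bx = rng.uniform(0.2, 0.6, size=8)
            sey = np.full(8, 0.05)
            by = theta * bx + rng.normal(0, sey)
            inst = make_instruments(bx, by, sex=np.full(8, 1e-6), sey=sey)
            for est in (ivw(inst), weighted_median(inst, n_boot=200, seed=rep), mr_egger(inst)):
                lo, hi = est.ci
                if lo <= theta <= hi:
                    covered[est.method] += 1
        assert abs(covered["IVW"] / reps - 0.95) <= 0.03
        assert covered["weighted_median"] / reps >= 0.92
        assert covered["MR_Egger"] / reps >= 0.92


class TestAssocScanAndDriver:
    def _frame(self, n=1200, seed=50):
        rng = np.random.default_rng(seed)
        data = {
            "v1": rng.binomial(2, 0.3, size=n).astype(float),
            "v2": rng.binomial(2, 0.2, size=n).astype(float),
            "v3": rng.binomial(2, 0.4, size=n).astype(float),
            "age": rng.normal(64, 8, size=n),
            "sex": rng.binomial(1, 0.5, size=n).astype(float),
        }
        # one-way causal chain: variants -> measure -> outcome
        data["measure"] = (
            0.4 * data["v1"] + 0.3 * data["v2"] + 0.35 * data["v3"] + rng.normal(size=n)
        )
        data["outcome"] = 0.5 * data["measure"] + rng.normal(size=n)
        return pd.DataFrame(data)

    def test_noiseless_scan_beta(self):
        n = 400
        rng = np.random.default_rng(51)
        d = rng.binomial(2, 0.3, size=n).astype(float)
        frame = pd.DataFrame({"v1": d, "t": 0.5 * d})
        scan = assoc_scan(frame, "t", ["v1"], covariates=())
        assert scan["beta"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        assert scan["se"].iloc[0] < 1e-10

    def test_known_effects_recovered(self):
        frame = self._frame()
        scan = assoc_scan(frame, "measure", ["v1", "v2", "v3"], covariates=("age", "sex"))
        for vid, truth in zip(("v1", "v2", "v3"), (0.4, 0.3, 0.35)):
            row = scan[scan["variant"] == vid].iloc[0]
            assert abs(row["beta"] - truth) < 3 * row["se"]

    def test_monomorphic_variant_dropped_with_warning(self):
        frame = self._frame()
        frame["v2"] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = assoc_scan(frame, "measure", ["v1", "v2"], covariates=())
        assert scan["variant"].tolist() == ["v1"]

    def test_bidirectional_detects_planted_direction(self):
        frame = self._frame(n=4000, seed=52)
        table = run_bidirectional(
            frame, ["measure"], ["v1", "v2", "v3"], outcome="outcome",
            covariates=("age", "sex"), seed=7,
        )
        fwd = table[(table["direction"] == "forward") & (table["method"] == "IVW")].iloc[0]
        rev = table[(table["direction"] == "reverse") & (table["method"] == "IVW")].iloc[0]
        assert fwd["p"] < 1e-4
        assert abs(fwd["theta"] - 0.5) < 3 * fwd["se"]
        # with strictly one-way causation every instrument reaches the
        # outcome through the measure, so the reverse estimate collapses
        # onto the mediated-only association 1/0.5 rather than a genuine
        # outcome -> measure effect
        assert abs(rev["theta"] - 2.0) < 3 * rev["se"]

    def test_single_measure_fdr_equals_raw_p(self):
        frame = self._frame(n=1500, seed=53)
        table = run_bidirectional(frame, ["measure"], ["v1", "v2", "v3"],
                                  outcome="outcome", covariates=(), seed=8)
        ok = table["p"].notna()
        assert np.allclose(table.loc[ok, "p_fdr"], table.loc[ok, "p"])
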