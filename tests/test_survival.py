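"""Concordance, Cox fitting, stratified CV, forward selection, evaluation."""

import numpy as np
import pandas as pd
import pytest

from radstab import synthgen
from radstab.survival import (ConvergenceError, CoxPHModel,
                              concordance_index, evaluate_signature, fit_cox,
                              forward_select, risk_stratify, stratified_folds,
                              survival_strata)

import oracles


def random_survival(rng, n=25):
    time = rng.exponential(2.0, n)
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[0] = 1
    risk = rng.normal(size=n)
    return risk, time, event


class TestConcordanceIndex:
    def test_perfect_and_random_anchors(self, rng):
        time = np.sort(rng.exponential(1.0, 20))
        event = np.ones(20, int)
        assert concordance_index(-time, time, event) == 1.0
        assert concordance_index(np.zeros(20), time, event) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        risk, time, event = random_survival(rng, n=rng.integers(6, 30))
        assert concordance_index(risk, time, event) == pytest.approx(
            oracles.cindex_pairs(risk, time, event), abs=1e-12)

    def test_sksurv_cross_check(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        risk, time, event = random_survival(rng, 40)
        ref = sksurv_metrics.concordance_index_censored(
            event.astype(bool), time, risk)[0]
        assert concordance_index(risk, time, event) == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        risk, time, event = random_survival(rng)
        c = concordance_index(risk, time, event)
        assert concordance_index(np.exp(3 * risk), time, event) == pytest.approx(c)

    def test_all_censored_error(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1.0, 2.0], [0, 0])


class TestCoxPHModel:
    def test_binary_covariate_recovery(self):
        feats = pd.DataFrame({"f": np.random.default_rng(0).integers(0, 2, 2000)
                              .astype(float)})
        rec = synthgen.simulate_survival(
            feats.set_axis([f"p{i}" for i in range(2000)]),
            synthgen.SurvivalGenSpec(beta={"f": np.log(2)}, baseline_rate=0.25,
                                     censor_rate=0.04, admin_censor_time=8.0,
                                     seed=4))
        m = CoxPHModel().fit(feats, time=rec["time_years"], event=rec["event"])
        assert m.coef_[0] == pytest.approx(np.log(2), abs=0.1)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        X = rng.normal(size=(150, 3))
        time = rng.exponential(1.0 / np.exp(X @ [0.5, -0.3, 0.0]))
        event = (rng.random(150) < 0.8).astype(int)
        m = CoxPHModel(penalty=0.0, standardize=False).fit(X, time=time, event=event)
        df = pd.DataFrame(X, columns=list("abc"))
        df["t"], df["e"] = time, event
        cf = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(m.coef_, cf.params_.values, atol=1e-5)

    def test_loglik_path_nondecreasing(self, rng):
        risk, time, event = random_survival(rng, 100)
        X = rng.normal(size=(100, 4))
        m = CoxPHModel().fit(X, time=time, event=event)
        assert np.all(np.diff(m.log_likelihood_path_) >= -1e-10)

    def test_maximum_beats_grid(self, rng):
        """Partial likelihood at the fit is at least the best of a 21-point
        grid around it (independent loop-based likelihood oracle)."""
        x = rng.normal(size=60)
        time = rng.exponential(1.0 / np.exp(0.7 * x))
        event = np.ones(60, int)
        m = CoxPHModel(penalty=0.0, standardize=False).fit(
            x[:, None], time=time, event=event)
        beta_hat = m.coef_[0]
        ll_hat = oracles.cox_loglik_loops(x, time, event, beta_hat)
        grid = beta_hat + np.linspace(-0.5, 0.5, 21)
        lls = [oracles.cox_loglik_loops(x, time, event, b) for b in grid]
        assert ll_hat >= max(lls) - 1e-9

    def test_null_data_small_coefficient(self, rng):
        X = rng.normal(size=(300, 1))
        time = rng.exponential(1.0, 300)
        event = np.ones(300, int)
        m = CoxPHModel().fit(X, time=time, event=event)
        assert abs(m.coef_[0]) < 2.0 / np.sqrt(300)  # ~2 SE under the null

    def test_constant_feature_named_in_error(self, rng):
        X = pd.DataFrame({"ok": rng.normal(size=30), "flat": np.ones(30)})
        with pytest.raises(ValueError, match="flat"):
            CoxPHModel().fit(X, time=rng.exponential(1, 30),
                             event=np.ones(30, int))

    def test_separation_raises(self):
        # risk perfectly orders an uncensored outcome: monotone likelihood
        time = np.arange(1.0, 41.0)
        x = -time
        with pytest.raises(ConvergenceError):
            CoxPHModel(penalty=0.0).fit(x[:, None], time=time,
                                        event=np.ones(40, int))

    def test_sklearn_params_round_trip(self):
        m = CoxPHModel(penalty=0.5, max_iter=10)
        assert m.get_params()["penalty"] == 0.5
        m.set_params(penalty=0.1)
        assert m.penalty == 0.1


class TestStratifiedFolds:
    def test_interval_labels(self):
        strata = survival_strata([0.5, 1.5, 2.5, 3.5], [0, 0, 0, 0])
        assert list(strata // 2) == [0, 1, 2, 3]

    def test_boundary_time_one_in_first_interval(self):
        assert survival_strata([1.0], [0])[0] // 2 == 0
        assert survival_strata([1.0 + 1e-9], [0])[0] // 2 == 1

    def test_balanced_strata_give_one_per_fold(self, rng):
        rows = []
        for interval, t in enumerate([0.5, 1.5, 2.5, 3.5]):
            for e in (0, 1):
                for r in range(5):
                    rows.append({"patient_id": f"p{interval}{e}{r}",
                                 "time_years": t, "event": e})
        records = pd.DataFrame(rows)
        plan = stratified_folds(records, n_folds=5, seed=1)
        df = pd.DataFrame({"fold": plan.fold, "stratum": plan.stratum})
        counts = df.groupby(["fold", "stratum"]).size()
        assert (counts == 1).all() and len(counts) == 40

    def test_partition_and_determinism(self, rng):
        records = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(23)],
            "time_years": rng.exponential(2, 23),
            "event": rng.integers(0, 2, 23)})
        a = stratified_folds(records, seed=3)
        b = stratified_folds(records, seed=3)
        assert np.array_equal(a.fold, b.fold)
        assert sorted(np.bincount(a.fold, minlength=5)) in ([4, 4, 5, 5, 5],)


class TestForwardSelect:
    def test_true_signal_selected_first(self, rng):
        n = 120
        signal = rng.normal(size=n)
        time = rng.exponential(1.0 / np.exp(1.5 * signal))
        event = np.ones(n, int)
        X = pd.DataFrame({"noise1": rng.normal(size=n), "signal": signal,
                          "noise2": rng.normal(size=n)})
        sel = forward_select(X, time, event)
        assert sel[0] == "signal"

    def test_duplicate_feature_adds_nothing(self, rng):
        n = 100
        signal = rng.normal(size=n)
        time = rng.exponential(1.0 / np.exp(signal))
        event = np.ones(n, int)
        X = pd.DataFrame({"a_signal": signal, "b_copy": signal.copy()})
        sel = forward_select(X, time, event)
        assert sel == ["a_signal"]

    def test_first_pick_matches_univariate_scan_oracle(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"f{i}" for i in range(6)])
        time = rng.exponential(1.0, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        sel = forward_select(X, time, event, max_k=1)
        scores = {}
        for c in X.columns:
            ci = oracles.cindex_pairs(X[c].to_numpy(), time, event)
            scores[c] = max(ci, 1 - ci)
        assert sel[0] == max(sorted(scores), key=lambda c: scores[c])

    def test_constant_features_skipped(self, rng):
        X = pd.DataFrame({"flat": np.ones(50), "x": rng.normal(size=50)})
        sel = forward_select(X, rng.exponential(1, 50), np.ones(50, int))
        assert sel == ["x"]


class TestEvaluateSignature:
    def _table(self, values: dict, patients):
        frames = {}
        for seg, df in values.items():
            for p in patients:
                frames[(p, seg)] = df.loc[p]
        t = pd.DataFrame(frames).T
        t.index = pd.MultiIndex.from_tuples(t.index,
                                            names=["patient_id", "segmentation_id"])
        return t

    def test_identical_variants_give_identical_values(self, rng):
        n = 30
        patients = [f"p{i}" for i in range(n)]
        base = pd.DataFrame({"f1": rng.normal(size=n), "f2": rng.normal(size=n)},
                            index=patients)
        table = self._table({"manual-00": base, "auto-000": base, "auto-001": base},
                            patients)
        records = pd.DataFrame({"patient_id": patients,
                                "time_years": rng.exponential(2, n),
                                "event": np.ones(n, int)})
        cv = stratified_folds(records, seed=0)
        dist = evaluate_signature(table, records, ["f1", "f2"], cv)
        per_fold = dist.values.groupby("fold")["c_index"].nunique()
        assert (per_fold == 1).all()
        assert len(dist.values) == 5 * 3

    def test_pure_noise_features_are_random_predictors(self, rng):
        n = 60
        patients = [f"p{i}" for i in range(n)]
        segs = {f"auto-{i:03d}": pd.DataFrame(
            rng.normal(size=(n, 3)), columns=list("abc"), index=patients)
            for i in range(10)}
        segs["manual-00"] = pd.DataFrame(rng.normal(size=(n, 3)),
                                         columns=list("abc"), index=patients)
        table = self._table(segs, patients)
        records = pd.DataFrame({"patient_id": patients,
                                "time_years": rng.exponential(2, n),
                                "event": np.ones(n, int)})
        cv = stratified_folds(records, seed=1)
        dist = evaluate_signature(table, records, list("abc"), cv)
        assert dist.mean == pytest.approx(0.5, abs=0.08)

    def test_empty_signature_rejected(self, small_feature_table, small_cohort):
        cv = stratified_folds(small_cohort.survival, seed=0)
        with pytest.raises(ValueError):
            evaluate_signature(small_feature_table, small_cohort.survival, [], cv)


class TestRiskStratify:
    def _fit(self, rng, n=41):
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / np.exp(1.5 * x))
        event = np.ones(n, int)
        X = pd.DataFrame({"x": x}, index=[f"p{i}" for i in range(n)])
        records = pd.DataFrame({"patient_id": X.index, "time_years": time,
                                "event": event})
        model = fit_cox(X, time, event)
        return model, X, records

    def test_median_split_sizes(self, rng):
        model, X, records = self._fit(rng, n=41)
        groups, _ = risk_stratify(model, X, records)
        counts = groups["risk_group"].value_counts()
        assert sorted(counts) == [20, 21]
        # boundary (score == median) goes to the high-risk group
        med = groups["risk_score"].median()
        assert (groups.loc[groups["risk_score"] >= med, "risk_group"] == "high").all()

    def test_high_risk_group_has_higher_event_rate(self, rng):
        x = rng.normal(size=200)
        spec = synthgen.SurvivalGenSpec(beta={"x": 1.5}, baseline_rate=0.3,
                                        censor_rate=0.1, admin_censor_time=5.0,
                                        seed=9)
        feats = pd.DataFrame({"x": x}, index=[f"p{i}" for i in range(200)])
        records = synthgen.simulate_survival(feats, spec)
        model = fit_cox(feats, records["time_years"], records["event"])
        groups, km = risk_stratify(model, feats, records)
        rates = groups.groupby("risk_group")["event"].mean()
        assert rates["high"] > rates["low"]
        assert set(km) == {"high", "low"}

    def test_km_product_limit_by_hand(self):
        from lifelines import KaplanMeierFitter
        model = CoxPHModel()
        records = pd.DataFrame({"patient_id": list("abc"),
                                "time_years": [1.0, 2.0, 3.0],
                                "event": [1, 1, 1]})
        kmf = KaplanMeierFitter().fit(records["time_years"], records["event"])
        sf = kmf.survival_function_["KM_estimate"]
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[2.0] == pytest.approx(1 / 3)
        assert sf.loc[3.0] == pytest.approx(0.0)
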