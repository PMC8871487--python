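"""Proportional-hazards survival modelling over segmentation variants.

The central experiment: Cox models are trained per cross-validation fold on
the *manual*-outline features of the training patients (restricted to an
ICC signature, with sequential forward selection), then evaluated on the
test fold once per segmentation variant — the manual outline plus each
perturbed outline.  The spread of the resulting C-index distribution
isolates how segmentation variability propagates into model performance.

:class:`CoxPHModel` is a scikit-learn style estimator maximizing the Breslow
partial likelihood by Newton iterations with step-halving and a small ridge
penalty for numerical stability; it exposes the per-iteration log partial
likelihood trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

YEAR_BINS = (1.0, 2.0, 3.0)  # survival-interval strata boundaries (years)


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed to converge."""


# --------------------------------------------------------------------------
# Harrell's concordance index
# --------------------------------------------------------------------------

def concordance_index(risk, time, event) -> float:
    """Harrell's C for right-censored data.

    Comparable pairs are (i, j) with time_i < time_j and event_i = 1; a pair
    is concordant when risk_i > risk_j, and tied risks contribute weight 0.5.
    Raises ``ValueError`` when no pair is comparable (e.g. all censored).
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lt = time[:, None] < time[None, :]
    comparable = lt & (event[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (all censored or all times tied)")
    gt = risk[:, None] > risk[None, :]
    eq = risk[:, None] == risk[None, :]
    concordant = (gt & comparable).sum() + 0.5 * (eq & comparable).sum()
    return float(concordant / n_comp)


# --------------------------------------------------------------------------
# Cox proportional-hazards estimator
# --------------------------------------------------------------------------

def _unpack_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept (time, event) tuples, 2-column arrays, DataFrames or structured
    arrays with 'time'/'event' fields (scikit-survival order included)."""
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    if isinstance(y, pd.DataFrame):
        return y["time_years"].to_numpy(float), y["event"].to_numpy(int)
    arr = np.asarray(y)
    if arr.dtype.names:
        names = set(arr.dtype.names)
        tname = "time_years" if "time_years" in names else "time"
        ename = "event"
        return arr[tname].astype(float), arr[ename].astype(int)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise TypeError("y must provide time and event")


class CoxPHModel(BaseEstimator):
    """Cox proportional-hazards model (Breslow ties, Newton + step-halving).

    Parameters
    ----------
    penalty : float
        Ridge penalty on the coefficients (default 1e-6, for stability only).
    tol : float
        Convergence threshold on max |score| / n.
    max_iter : int
        Newton iteration budget.
    standardize : bool
        Center/scale features from the training data; the risk score is the
        linear predictor on standardized features.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray of log hazard ratios (standardized scale if enabled)
    feature_names_in_ : list of column names (when fit on a DataFrame)
    mean_, scale_ : standardization parameters
    log_likelihood_path_ : penalized log partial likelihood per iteration
    n_iter_, converged_ : convergence diagnostics
    """

    def __init__(self, penalty: float = 1e-6, tol: float = 1e-8,
                 max_iter: int = 100, standardize: bool = True):
        self.penalty = penalty
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    # -- internals ---------------------------------------------------------
    def _loglik_grad_hess(self, z, time, event, beta):
        """Breslow log partial likelihood, score and observed information."""
        order = np.argsort(time, kind="stable")
        z = z[order]
        time = time[order]
        event = event[order] == 1
        n, p = z.shape
        lp = z @ beta
        lp -= lp.max()  # overflow guard; cancels in all ratios and in ll up to const
        w = np.exp(lp)

        # reverse-cumulative risk-set sums; tie groups share the sum taken at
        # the first member of the group (risk set = {j : t_j >= t_i})
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * z)[::-1], axis=0)[::-1]
        s2 = np.cumsum((w[:, None, None] * (z[:, :, None] * z[:, None, :]))[::-1],
                       axis=0)[::-1]
        uniq, first_idx = np.unique(time, return_index=True)
        first = first_idx[np.searchsorted(uniq, time)]

        e = np.flatnonzero(event)
        fe = first[e]
        ll = float(lp[e].sum() - np.log(s0[fe]).sum())
        grad = z[e].sum(axis=0) - (s1[fe] / s0[fe, None]).sum(axis=0)
        mu = s1[fe] / s0[fe, None]
        info = (s2[fe] / s0[fe, None, None]).sum(axis=0) - (mu[:, :, None] * mu[:, None, :]).sum(axis=0)
        # ridge
        ll -= 0.5 * self.penalty * float(beta @ beta)
        grad -= self.penalty * beta
        info += self.penalty * np.eye(p)
        return ll, grad, info

    # -- API ---------------------------------------------------------------
    def fit(self, X, y=None, *, time=None, event=None):
        if y is not None:
            time, event = _unpack_y(y)
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            Xv = X.to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            self.feature_names_in_ = [f"x{i}" for i in range(Xv.shape[1])]
        n, p = Xv.shape
        if n != len(time) or n != len(event):
            raise ValueError("X and survival data lengths differ")
        if event.sum() == 0:
            raise ValueError("no observed events: partial likelihood undefined")
        if n < 2 * p:
            log.warning("fitting %d features on only %d samples", p, n)

        if self.standardize:
            self.mean_ = Xv.mean(axis=0)
            self.scale_ = Xv.std(axis=0)
            zero = self.scale_ == 0
            if zero.any():
                bad = [self.feature_names_in_[i] for i in np.flatnonzero(zero)]
                raise ValueError(f"constant feature(s) cannot be standardized: {bad}")
            z = (Xv - self.mean_) / self.scale_
        else:
            self.mean_ = np.zeros(p)
            self.scale_ = np.ones(p)
            z = Xv

        beta = np.zeros(p)
        ll, grad, info = self._loglik_grad_hess(z, time, event, beta)
        path = [ll]
        converged = False
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) / n < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            # step-halving: never decrease the penalized log partial likelihood
            factor = 1.0
            for _ in range(30):
                new_beta = beta + factor * step
                new_ll, new_grad, new_info = self._loglik_grad_hess(z, time, event, new_beta)
                if new_ll >= ll - 1e-12:
                    break
                factor /= 2.0
            else:
                break
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            path.append(ll)
            if np.max(np.abs(beta)) > 50:
                worst = self.feature_names_in_[int(np.argmax(np.abs(beta)))]
                raise ConvergenceError(
                    f"coefficients diverging (monotone likelihood / separation) "
                    f"for feature {worst!r}")
        else:
            it = self.max_iter
        if not converged and np.max(np.abs(grad)) / n >= self.tol:
            worst = self.feature_names_in_[int(np.argmax(np.abs(grad)))]
            raise ConvergenceError(
                f"no convergence in {self.max_iter} iterations (worst score "
                f"component: {worst!r})")

        self.coef_ = beta
        self.n_iter_ = it
        self.converged_ = converged
        self.log_likelihood_path_ = np.asarray(path)
        return self

    def predict(self, X) -> np.ndarray:
        """Risk score: linear predictor on (standardized) features."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_in_].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return (X - self.mean_) / self.scale_ @ self.coef_

    def score(self, X, y) -> float:
        """Harrell's C of the risk scores on (X, y)."""
        time, event = _unpack_y(y)
        return concordance_index(self.predict(X), time, event)


def fit_cox(X, time, event, penalty: float = 1e-6) -> CoxPHModel:
    """Functional wrapper over :class:`CoxPHModel`."""
    return CoxPHModel(penalty=penalty).fit(X, time=time, event=event)


# --------------------------------------------------------------------------
# Stratified cross-validation
# --------------------------------------------------------------------------

def survival_strata(time, event) -> np.ndarray:
    """Stratum label: one-year interval (<=1, 1-2, 2-3, >3) x event status."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    interval = np.digitize(time, YEAR_BINS, right=True)  # t == 1.0 -> "<=1"
    return interval * 2 + event


@dataclass
class CVPlan:
    """Fold assignment per patient plus the strata it balanced."""

    patient_id: np.ndarray
    fold: np.ndarray
    stratum: np.ndarray
    n_folds: int

    def train_test(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        return self.patient_id[self.fold != f], self.patient_id[self.fold == f]


def stratified_folds(records: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Assign patients to folds, balancing survival-interval x event strata.

    Members of each stratum are shuffled (seeded) and dealt round-robin,
    with the starting fold rotating across strata so remainders spread
    evenly.  Strata smaller than the fold count are distributed as evenly as
    possible with a warning.
    """
    if len(records) < n_folds:
        raise ValueError(f"need at least {n_folds} patients for {n_folds} folds")
    rng = np.random.default_rng(seed)
    pid = records["patient_id"].to_numpy()
    strat = survival_strata(records["time_years"], records["event"])
    fold = np.empty(len(pid), int)
    offset = 0
    for s in np.unique(strat):
        idx = np.flatnonzero(strat == s)
        if len(idx) < n_folds:
            log.warning("stratum %d has only %d member(s) for %d folds",
                        s, len(idx), n_folds)
        rng.shuffle(idx)
        fold[idx] = (offset + np.arange(len(idx))) % n_folds
        offset += len(idx)
    return CVPlan(patient_id=pid, fold=fold, stratum=strat, n_folds=n_folds)


# --------------------------------------------------------------------------
# Sequential forward selection
# --------------------------------------------------------------------------

def _univariate_c(col: np.ndarray, time, event) -> float:
    """Direction-agnostic univariate discriminatory power max(c, 1-c)."""
    c = concordance_index(col, time, event)
    return max(c, 1.0 - c)


def forward_select(X: pd.DataFrame, time, event, max_k: int = 5,
                   min_improvement: float = 0.005,
                   penalty: float = 1e-6) -> list[str]:
    """Greedy forward selection by training C-index.

    The first feature is the one with the highest univariate C-index; each
    later step adds the candidate maximizing the fitted multivariate model's
    training C, stopping when the best improvement falls below
    ``min_improvement`` or ``max_k`` features are selected.  Ties break by
    feature name; constant features are skipped with a log message.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    candidates = []
    for name in sorted(X.columns):
        if X[name].to_numpy(float).std() == 0:
            log.info("forward selection: skipping constant feature %s", name)
            continue
        candidates.append(name)
    if not candidates:
        raise ValueError("no usable (non-constant) features")

    best_name, best_c = None, -np.inf
    for name in candidates:
        c = _univariate_c(X[name].to_numpy(float), time, event)
        if c > best_c:
            best_name, best_c = name, c
    selected = [best_name]
    current_c = best_c

    while len(selected) < max_k:
        best_name, best_c = None, current_c + min_improvement
        for name in candidates:
            if name in selected:
                continue
            try:
                model = CoxPHModel(penalty=penalty).fit(
                    X[selected + [name]], time=time, event=event)
                c = concordance_index(model.predict(X[selected + [name]]), time, event)
            except (ConvergenceError, ValueError):
                continue
            if c > best_c:
                best_name, best_c = name, c
        if best_name is None:
            break
        selected.append(best_name)
        current_c = best_c
    return selected


# --------------------------------------------------------------------------
# Signature evaluation across segmentation variants
# --------------------------------------------------------------------------

@dataclass
class CIndexDistribution:
    """Test-fold C-indices of one signature, indexed by (fold, segmentation)."""

    signature: str
    values: pd.DataFrame  # columns: fold, segmentation_id, c_index
    selected: dict[int, list[str]] = field(default_factory=dict)
    incomplete: bool = False

    @property
    def mean(self) -> float:
        return float(self.values["c_index"].mean())

    @property
    def sd(self) -> float:
        """SD pooled over all (fold, segmentation) values.

        At small cohort sizes this is dominated by fold-to-fold noise; see
        :meth:`variant_sd` for the segmentation-induced component.
        """
        return float(self.values["c_index"].std(ddof=1))

    def per_variant(self) -> pd.Series:
        """C per segmentation variant, averaged over folds.

        Averaging over the same folds for every variant cancels the shared
        fold-mean component, isolating segmentation-induced variability.
        """
        return self.values.groupby("segmentation_id")["c_index"].mean()

    @property
    def variant_sd(self) -> float:
        """SD of the fold-averaged C across segmentation variants."""
        return float(self.per_variant().std(ddof=1))


def evaluate_signature(feature_table: pd.DataFrame, records: pd.DataFrame,
                       signature_features: list[str], cv: CVPlan,
                       signature_name: str = "all", manual_id: str = "manual-00",
                       max_k: int = 5, penalty: float = 1e-6,
                       refit_per_variant: bool = False) -> CIndexDistribution:
    """C-index distribution of one ICC signature across segmentation variants.

    ``feature_table`` is wide-format indexed by (patient_id, segmentation_id).
    Per fold, features are forward-selected and the Cox model fit on the
    training patients' *manual*-outline features; the fitted model is then
    scored on the test fold once per segmentation variant, using that
    variant's features (``refit_per_variant`` refits on each variant's
    training features instead).  Failed folds are skipped with a log message
    and the distribution flagged incomplete.
    """
    if not signature_features:
        raise ValueError("empty signature")
    recs = records.set_index("patient_id")
    seg_ids = list(feature_table.index.get_level_values("segmentation_id").unique())
    available = set(feature_table.index.get_level_values(0))
    missing = set(cv.patient_id) - available
    if missing:
        log.warning("%d patient(s) missing from the feature table "
                    "(excluded lesions?): %s", len(missing), sorted(missing)[:5])
    rows = []
    selected_per_fold: dict[int, list[str]] = {}
    incomplete = False
    for f in range(cv.n_folds):
        train_pid, test_pid = cv.train_test(f)
        train_pid = np.array([p for p in train_pid if p in available])
        test_pid = np.array([p for p in test_pid if p in available])
        if len(test_pid) == 0 or len(train_pid) < 2:
            incomplete = True
            continue
        try:
            X_train = feature_table.xs(manual_id, level="segmentation_id").loc[
                train_pid, signature_features]
            t_train = recs.loc[train_pid, "time_years"].to_numpy()
            e_train = recs.loc[train_pid, "event"].to_numpy()
            selected = forward_select(X_train, t_train, e_train, max_k=max_k,
                                      penalty=penalty)
            model = CoxPHModel(penalty=penalty).fit(X_train[selected],
                                                    time=t_train, event=e_train)
        except (ConvergenceError, ValueError) as exc:
            log.warning("fold %d (%s): model fit failed, skipping (%s)",
                        f, signature_name, exc)
            incomplete = True
            continue
        selected_per_fold[f] = selected
        t_test = recs.loc[test_pid, "time_years"].to_numpy()
        e_test = recs.loc[test_pid, "event"].to_numpy()
        for seg in seg_ids:
            seg_feats = feature_table.xs(seg, level="segmentation_id")
            try:
                if refit_per_variant:
                    Xtr = seg_feats.loc[train_pid, selected]
                    m = CoxPHModel(penalty=penalty).fit(Xtr, time=t_train, event=e_train)
                else:
                    m = model
                risk = m.predict(seg_feats.loc[test_pid, selected])
                c = concordance_index(risk, t_test, e_test)
            except (ConvergenceError, ValueError) as exc:
                log.warning("fold %d seg %s (%s): evaluation failed (%s)",
                            f, seg, signature_name, exc)
                incomplete = True
                continue
            rows.append({"fold": f, "segmentation_id": seg, "c_index": c})
    values = pd.DataFrame(rows, columns=["fold", "segmentation_id", "c_index"])
    return CIndexDistribution(signature=signature_name, values=values,
                              selected=selected_per_fold, incomplete=incomplete)


# --------------------------------------------------------------------------
# Risk stratification
# --------------------------------------------------------------------------

def risk_stratify(model: CoxPHModel, X: pd.DataFrame,
                  records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Median split of risk scores into low/high groups + per-group KM curves.

    Scores below the median are low risk; scores at or above it are high risk
    (the boundary goes high, since only "below the median" is low by
    definition).  Returns the labelled records and a Kaplan-Meier summary
    (time, survival probability, at-risk count) per group via lifelines.
    """
    from lifelines import KaplanMeierFitter

    risk = model.predict(X)
    med = float(np.median(risk))
    labels = np.where(risk < med, "low", "high")
    if np.all(risk == risk[0]):
        log.warning("all risk scores equal: single risk group")
        labels = np.full(len(risk), "all")
    out = records.copy()
    out["risk_score"] = risk
    out["risk_group"] = labels
    km: dict[str, pd.DataFrame] = {}
    for group in np.unique(labels):
        sub = out[out["risk_group"] == group]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_years", "survival"]
        km[group] = sf
    return out, km
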