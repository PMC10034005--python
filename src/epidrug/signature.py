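"""Prognostic gene signatures: resampling Lasso–Cox selection, stepwise AIC
refit, linear risk scores, optimal cutpoints and survival evaluation.

The selection stage repeats cross-validated L1-penalized Cox regression
many times with re-drawn fold assignments and counts, per gene, how often
its coefficient is nonzero at the CV-selected penalty. The most stable
genes are refit by bidirectional stepwise search minimizing the partial-
likelihood AIC, giving a linear risk score

    RiskScore = sum_g beta_g * expression_g .

Samples split at the cutoff maximizing the log-rank statistic (the
maximally selected rank statistic, as in survminer's ``surv_cutpoint``)
into high/low-risk groups, compared by Kaplan–Meier/log-rank and a
hazard ratio, with discrimination summarized by IPCW time-dependent AUC
at fixed horizons.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class SelectionFrequency:
    counts: pd.Series          # gene -> number of runs with nonzero coefficient
    n_runs: int


@dataclass
class SignatureModel:
    genes: list[str]
    coefficients: list[float]
    z_mean: float = 0.0
    z_sd: float = 1.0
    cutoff: float | None = None     # on the z-scored score scale
    provenance: str = "training"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SurvivalEval:
    logrank_stat: float
    p: float
    hazard_ratio: float
    n_high: int
    n_low: int
    auc_by_horizon: dict = field(default_factory=dict)
    cutoff: float | None = None


class StepwiseError(RuntimeError):
    """A Cox fit failed to converge during stepwise selection."""


# ---------------------------------------------------------------------------
# helpers


def _check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    surv = survival[["time", "event"]].astype(float)
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0.0, 1.0]).all():
        raise ValueError("event indicators must be 0/1")
    return surv


def _breslow_neg_loglik(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Negative Cox partial log-likelihood (Breslow) for fixed risk scores."""
    order = np.argsort(-time, kind="stable")  # descending time
    s = scores[order]
    t = time[order]
    e = event[order]
    s = s - s.max()  # guard exp overflow
    cum = np.logaddexp.accumulate(s)  # log of risk-set sums, descending time
    # risk set of subject i (ascending position in descending order) = prefix
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        # subjects with time >= t_i: those at positions 0..j where t >= t_i
        j = np.searchsorted(-t, -t[i], side="right") - 1
        ll += s[i] - cum[j]
    return -ll


# ---------------------------------------------------------------------------
# resampling Lasso-Cox selection


def lasso_frequency_selection(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    n_runs: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    rule: str = "1se",
) -> SelectionFrequency:
    """Count, per gene, nonzero Lasso–Cox coefficients over repeated CV runs.

    Each run re-draws the fold assignment, scores the shared penalty path by
    held-out partial-likelihood deviance, picks the penalty by ``rule``
    ("1se": the sparsest penalty within one standard error of the CV
    minimum, the conventional cv.glmnet choice; "min": the CV minimum),
    and records which genes are nonzero in the full-data path there.

    Parameters
    ----------
    expr
        Genes x samples log2 expression.
    survival
        Indexed by sample id with ``time`` and ``event`` columns.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    surv = _check_survival(survival.loc[expr.columns])
    n_events = int(surv["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the survival table")
    if n_events < 10:
        logger.warning("only %d events; selection frequencies will be unstable", n_events)
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")

    X = expr.T.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    n = len(time)
    if cv_folds < 2 or cv_folds > n:
        raise ValueError("cv_folds must be in [2, n_samples]")

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, fit_baseline_model=False)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    full_coefs = path.coef_  # (p, n_alphas)

    if rule not in {"min", "1se"}:
        raise ValueError("rule must be 'min' or '1se'")
    rng = np.random.default_rng(seed)
    counts = np.zeros(expr.shape[0], dtype=int)
    for _ in range(n_runs):
        fold = rng.permutation(np.arange(n) % cv_folds)
        dev = np.full((cv_folds, len(alphas)), np.inf)
        for f in range(cv_folds):
            test = fold == f
            fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit.fit(X[~test], y[~test])
            coefs = fit.coef_
            # sksurv may truncate the path; align by alpha value
            fitted = {round(a, 12): j for j, a in enumerate(fit.alphas_)}
            for j, a in enumerate(alphas):
                jj = fitted.get(round(a, 12))
                if jj is None:
                    continue
                sc = X[test] @ coefs[:, jj]
                dev[f, j] = _breslow_neg_loglik(sc, time[test], event[test])
        usable = np.isfinite(dev).all(axis=0)
        mean = np.full(len(alphas), np.inf)
        mean[usable] = dev[:, usable].mean(axis=0)
        best = int(np.argmin(mean))
        if rule == "1se":
            se = dev[:, best].std(ddof=1) / np.sqrt(cv_folds)
            limit = mean[best] + se
            # alphas are descending: the sparsest admissible penalty is first
            best = int(np.flatnonzero(mean <= limit)[0])
        counts += full_coefs[:, best] != 0
    return SelectionFrequency(
        counts=pd.Series(counts, index=expr.index, name="n_selected"), n_runs=n_runs
    )


def select_top_genes(freq: SelectionFrequency, cap: int = 3) -> list[str]:
    """Genes before the largest drop of the sorted frequency curve, capped.

    The elbow rule: sort frequencies descending and cut at the largest gap
    between consecutive values; at most ``cap`` genes are returned.
    """
    s = freq.counts.sort_values(ascending=False, kind="stable")
    s = s[s > 0]
    if s.empty:
        return []
    if len(s) == 1:
        return [s.index[0]]
    vals = s.to_numpy(dtype=float)
    gaps = vals[:-1] - vals[1:]
    # a flat curve has no elbow: keep every selected gene (up to the cap)
    cut = len(s) if gaps.max() <= 0 else int(np.argmax(gaps)) + 1
    return list(s.index[: min(cut, cap)])


# ---------------------------------------------------------------------------
# stepwise AIC Cox


def _cox_fit(df: pd.DataFrame, genes: Sequence[str]) -> tuple[float, pd.Series]:
    """(AIC, coefficients) for a Cox model on the given genes."""
    if not genes:
        ll0 = -_breslow_neg_loglik(
            np.zeros(len(df)), df["time"].to_numpy(), df["event"].to_numpy()
        )
        return -2.0 * ll0, pd.Series(dtype=float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[list(genes) + ["time", "event"]], duration_col="time", event_col="event")
    return float(cph.AIC_partial_), cph.params_.copy()


def stepwise_aic_cox(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    candidates: Sequence[str] | None = None,
) -> pd.Series:
    """Bidirectional stepwise Cox regression minimizing the partial AIC.

    Starts from the full candidate set and repeatedly applies the single
    add/drop move that lowers AIC most, until no move improves. Returns the
    selected genes' coefficients. A single candidate is returned as its
    univariate Cox coefficient without a search.
    """
    candidates = list(candidates) if candidates is not None else list(expr.index)
    if not candidates:
        raise ValueError("need at least one candidate gene")
    missing = [g for g in candidates if g not in expr.index]
    if missing:
        raise ValueError(f"candidate genes absent from expression matrix: {missing}")
    surv = _check_survival(survival.loc[expr.columns])
    df = expr.loc[candidates].T.join(surv)

    try:
        if len(candidates) == 1:
            return _cox_fit(df, candidates)[1]
        current = list(candidates)
        best_aic, best_coefs = _cox_fit(df, current)
    except ConvergenceError as err:
        raise StepwiseError(f"Cox fit failed to converge for subset {candidates}") from err

    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, list[str], pd.Series]] = []
        for g in current:
            subset = [x for x in current if x != g]
            try:
                aic, coefs = _cox_fit(df, subset)
                moves.append((aic, subset, coefs))
            except ConvergenceError:
                logger.warning("dropping %s: Cox fit failed; move skipped", g)
        for g in candidates:
            if g in current:
                continue
            subset = current + [g]
            try:
                aic, coefs = _cox_fit(df, subset)
                moves.append((aic, subset, coefs))
            except ConvergenceError:
                logger.warning("adding %s: Cox fit failed; move skipped", g)
        if moves:
            aic, subset, coefs = min(moves, key=lambda m: m[0])
            if aic < best_aic - 1e-8:
                best_aic, best_coefs, current = aic, coefs, subset
                improved = True
    if len(best_coefs) == 0:
        logger.warning("stepwise search emptied the model; no gene improves on the null")
    return best_coefs


# ---------------------------------------------------------------------------
# risk scores, cutpoints, evaluation


def risk_score(expr: pd.DataFrame, model: SignatureModel, zscore: bool = False) -> pd.Series:
    """Linear risk score per sample; optionally z-scored with stored constants."""
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise ValueError(f"model genes missing from expression matrix: {missing}")
    coefs = pd.Series(model.coefficients, index=model.genes, dtype=float)
    score = expr.loc[model.genes].T @ coefs
    score.name = "risk_score"
    if zscore:
        score = (score - model.z_mean) / model.z_sd
    return score


def optimal_cutpoint(
    scores: pd.Series,
    survival: pd.DataFrame,
    min_group_fraction: float = 0.1,
) -> float:
    """Cutoff maximizing the two-sample log-rank statistic over all splits.

    Candidate cutoffs are midpoints between consecutive distinct score
    values; splits leaving either group below ``min_group_fraction`` of the
    samples are inadmissible. Deterministic: ties keep the smallest cutoff.
    """
    surv = _check_survival(survival.loc[scores.index])
    vals = np.sort(np.unique(scores.to_numpy(dtype=float)))
    if vals.size < 2:
        raise ValueError("need at least 2 distinct scores to place a cutpoint")
    n = len(scores)
    min_n = max(1, int(np.ceil(min_group_fraction * n)))
    s = scores.to_numpy(dtype=float)
    t = surv["time"].to_numpy()
    e = surv["event"].to_numpy()
    best_stat, best_cut = -np.inf, None
    for lo, hi in zip(vals[:-1], vals[1:]):
        cut = 0.5 * (lo + hi)
        high = s > cut
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
        stat = float(res.test_statistic)
        if np.isfinite(stat) and stat > best_stat + 1e-12:
            best_stat, best_cut = stat, cut
    if best_cut is None:
        raise ValueError("no admissible cutpoint under the group-size constraint")
    return float(best_cut)


def km_logrank(groups: Mapping[str, str], survival: pd.DataFrame) -> SurvivalEval:
    """Two-group log-rank test, hazard ratio and group sizes.

    ``groups`` maps sample id to 'high'/'low'. The hazard ratio comes from a
    univariate Cox fit on the high-group indicator; HR > 1 means the
    high-score group dies faster. Zero events overall gives the degenerate
    convention statistic 0, p = 1.
    """
    g = pd.Series(dict(groups))
    surv = _check_survival(survival.loc[g.index])
    high = (g == "high").to_numpy()
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("both groups must be non-empty")
    t = surv["time"].to_numpy()
    e = surv["event"].to_numpy()
    if e.sum() == 0:
        return SurvivalEval(0.0, 1.0, float("nan"), int(high.sum()), int((~high).sum()))
    res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    df = pd.DataFrame({"time": t, "event": e, "high": high.astype(float)})
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
    except ConvergenceError:
        hr = float("nan")
    return SurvivalEval(
        logrank_stat=float(res.test_statistic),
        p=float(res.p_value),
        hazard_ratio=hr,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )


def km_curves(groups: Mapping[str, str], survival: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier step functions per group (columns: time, survival)."""
    g = pd.Series(dict(groups))
    surv = _check_survival(survival.loc[g.index])
    out = {}
    for name in sorted(g.unique()):
        mask = (g == name).to_numpy()
        km = KaplanMeierFitter()
        km.fit(surv["time"].to_numpy()[mask], surv["event"].to_numpy()[mask])
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[name] = sf
    return out


def time_dependent_roc(
    scores: pd.Series,
    survival: pd.DataFrame,
    horizons: Sequence[float],
    train_survival: pd.DataFrame | None = None,
) -> dict[float, float]:
    """IPCW cumulative/dynamic AUC at each horizon.

    The censoring distribution is estimated from ``train_survival`` (the
    evaluation cohort itself by default). Horizons with no preceding event
    or beyond the follow-up range are reported as NaN.
    """
    surv = _check_survival(survival.loc[scores.index])
    tr = _check_survival(train_survival) if train_survival is not None else surv
    y_train = Surv.from_arrays(event=tr["event"].astype(bool), time=tr["time"])
    y_test = Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])
    est = scores.to_numpy(dtype=float)
    out: dict[float, float] = {}
    for h in horizons:
        has_event_before = bool(((surv["time"] <= h) & (surv["event"] == 1)).any())
        if not has_event_before or h >= surv["time"].max():
            out[float(h)] = float("nan")
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aucs, _ = cumulative_dynamic_auc(y_train, y_test, est, [h])
            out[float(h)] = float(aucs[0])
        except ValueError:
            out[float(h)] = float("nan")
    return out


def fit_signature(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    n_runs: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
    top_cap: int = 3,
    horizons: Sequence[float] = (1.0, 3.0, 5.0),
    min_group_fraction: float = 0.1,
) -> tuple[SignatureModel, SurvivalEval, SelectionFrequency]:
    """Full training chain: selection -> stepwise refit -> score -> cutoff -> eval."""
    freq = lasso_frequency_selection(expr, survival, n_runs=n_runs, cv_folds=cv_folds, seed=seed)
    top = select_top_genes(freq, cap=top_cap)
    if not top:
        raise ValueError("no gene was ever selected by the Lasso runs")
    coefs = stepwise_aic_cox(expr, survival, candidates=top)
    if coefs.empty:
        coefs = stepwise_aic_cox(expr, survival, candidates=top[:1])
    model = SignatureModel(genes=list(coefs.index), coefficients=[float(c) for c in coefs])
    raw = risk_score(expr, model)
    model.z_mean = float(raw.mean())
    model.z_sd = float(raw.std(ddof=0)) or 1.0
    z = (raw - model.z_mean) / model.z_sd
    model.cutoff = optimal_cutpoint(z, survival, min_group_fraction=min_group_fraction)
    ev = evaluate_cohort(expr, survival, model, horizons=horizons, refit_cutoff=False)
    return model, ev, freq


def evaluate_cohort(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    model: SignatureModel,
    horizons: Sequence[float] = (1.0, 3.0, 5.0),
    refit_cutoff: bool = True,
    min_group_fraction: float = 0.1,
) -> SurvivalEval:
    """Score a cohort with frozen coefficients and evaluate the split."""
    z = risk_score(expr, model, zscore=True)
    cutoff = (
        optimal_cutpoint(z, survival, min_group_fraction=min_group_fraction)
        if refit_cutoff or model.cutoff is None
        else model.cutoff
    )
    groups = {s: ("high" if v > cutoff else "low") for s, v in z.items()}
    ev = km_logrank(groups, survival)
    ev.auc_by_horizon = time_dependent_roc(z, survival, horizons)
    ev.cutoff = float(cutoff)
    return ev


def validate_signature(
    model: SignatureModel,
    cohorts: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    horizons: Sequence[float] = (1.0, 3.0, 5.0),
) -> list[SurvivalEval]:
    """Apply frozen coefficients to each cohort, re-deriving its cutoff."""
    return [
        evaluate_cohort(expr, surv, model, horizons=horizons, refit_cutoff=True)
        for expr, surv in cohorts
    ]
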