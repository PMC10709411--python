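"""Eigengene-based survival modeling and risk stratification.

Three stages: (1) an L1-penalized Cox regression over all candidate
eigengenes picks the first three features to enter the regularization
path; (2) a Weibull accelerated-failure-time (AFT) model is fit to every
non-empty subset of the three, and each fit's predicted log survival
times are thresholded into low/intermediate/high risk groups by
recall-constrained, precision-maximizing cutoffs; (3) the subset whose
low-vs-high log-rank p-value is smallest wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import WeibullAFTFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger("munet")


class CutoffError(ValueError):
    """No cutoff satisfies the recall constraint."""


def _check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    sub = survival[["time", "event"]].dropna()
    sub = sub.astype({"time": float, "event": int})
    if not sub["event"].isin([0, 1]).all():
        raise ValueError("event must be binary 0/1")
    return sub


def lasso_select_eigengenes(eigengenes: pd.DataFrame,
                            survival: pd.DataFrame,
                            k: int = 3) -> list[str]:
    """First ``k`` eigengenes to enter the lasso-Cox path.

    ``eigengenes`` is a feature x sample matrix (all three variants
    stacked); patients are restricted to those with usable time/event.
    Walking the penalty grid from strongest to weakest, the first ``k``
    distinct features to gain a nonzero coefficient are returned in
    order of entry.  If fewer than ``k`` ever enter, those that do are
    returned (logged).
    """
    surv = _check_survival(survival)
    patients = [p for p in eigengenes.columns if p in surv.index]
    surv = surv.loc[patients]
    if surv["event"].sum() == 0:
        raise ValueError("no events among modeled patients")
    if eigengenes.shape[0] <= k:
        return list(eigengenes.index)
    X = eigengenes.loc[:, patients].T.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    y = Surv.from_arrays(event=surv["event"].astype(bool).to_numpy(),
                         time=surv["time"].to_numpy())
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=200,
                                   alpha_min_ratio=0.001, max_iter=200000)
    model.fit(X, y)
    coefs = model.coef_  # (n_features, n_alphas), alphas descending
    order: list[str] = []
    names = list(eigengenes.index)
    for col in range(coefs.shape[1]):
        active = np.flatnonzero(np.abs(coefs[:, col]) > 0)
        for idx in active:
            if names[idx] not in order:
                order.append(names[idx])
        if len(order) >= k:
            break
    if len(order) < k:
        logger.info("lasso_select_eigengenes: only %d/%d eigengenes entered "
                    "the path", len(order), k)
    return order[:k]


@dataclass
class AFTFit:
    """Weibull AFT fit: log T = b0 + sum_j b_j x_j + sigma * eps."""

    intercept: float
    coefficients: pd.Series            # per-eigengene b_j
    scale: float                       # sigma (1 / Weibull shape rho)
    linear_predictor: pd.Series        # predicted log survival time per patient
    fitter: WeibullAFTFitter = field(repr=False)


def fit_aft(design: pd.DataFrame, survival: pd.DataFrame) -> AFTFit:
    """Fit a Weibull AFT model of survival time on eigengene values.

    ``design`` is patient x eigengene.  Zero-variance columns are
    excluded from the regression and reported with coefficient 0.  The
    linear predictor is the predicted log characteristic life
    b0 + sum b_j x_j; larger means longer predicted survival.
    """
    surv = _check_survival(survival)
    patients = [p for p in design.index if p in surv.index]
    if len(patients) < 10:
        raise ValueError("need at least 10 patients with survival data")
    surv = surv.loc[patients]
    if surv["event"].sum() < 1:
        raise ValueError("need at least one event")
    X = design.loc[patients].astype(float)
    usable = [c for c in X.columns if X[c].std() > 0]
    dropped = [c for c in X.columns if c not in usable]
    if dropped:
        logger.info("fit_aft: zero-variance covariates excluded: %s", dropped)
    frame = X[usable].copy()
    frame.columns = [str(c) for c in usable]
    frame["time"] = np.maximum(surv["time"].to_numpy(), 1e-8)
    frame["event"] = surv["event"].to_numpy()
    fitter = WeibullAFTFitter(penalizer=0.0)
    # near-collinear eigengene subsets (e.g. E^e with E^em) make the Hessian
    # singular; only point estimates are used downstream, so those warnings
    # are noise here and hard failures fall back to a small ridge penalty
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(frame, duration_col="time", event_col="event")
        except Exception as first_err:
            logger.info("fit_aft: unpenalized fit failed (%s); retrying with "
                        "a small ridge penalty", first_err)
            fitter = WeibullAFTFitter(penalizer=0.01)
            fitter.fit(frame, duration_col="time", event_col="event")
    params = fitter.params_["lambda_"]
    intercept = float(params["Intercept"])
    coefs = pd.Series({c: float(params.get(str(c), 0.0)) if c in usable else 0.0
                       for c in design.columns})
    rho = float(np.exp(fitter.params_["rho_"]["Intercept"]))
    lp = intercept + (X[usable].to_numpy() @ coefs[usable].to_numpy()
                      if usable else 0.0)
    lp = pd.Series(np.broadcast_to(lp, (len(patients),)).copy(), index=patients)
    return AFTFit(intercept=intercept, coefficients=coefs, scale=1.0 / rho,
                  linear_predictor=lp, fitter=fitter)


def find_alive_cutoff(predictions: pd.Series | np.ndarray,
                      positives: pd.Series | np.ndarray,
                      direction: str,
                      min_recall: float) -> float:
    """Recall-constrained, precision-maximizing cutoff on AFT predictions.

    ``direction="high"``: the flagged group is predictions *below* the
    cutoff (short predicted survival) and ``positives`` marks deceased
    patients.  ``direction="low"``: the group is predictions *above* the
    cutoff and ``positives`` marks patients alive (censored).  Candidate
    cutoffs are midpoints of sorted unique predictions; among those whose
    group achieves recall >= ``min_recall`` on the positive class the one
    maximizing precision is returned, ties broken toward the smaller
    group (the more conservative risk call).
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    preds = np.asarray(predictions, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    if preds.shape != pos.shape:
        raise ValueError("predictions and positives must align")
    if not np.all(np.isfinite(preds)):
        raise ValueError("predictions must be finite")
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise CutoffError("no positive-class patients; cannot satisfy recall")
    uniq = np.unique(preds)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best: tuple[float, int, float] | None = None  # (precision, -size, cutoff)
    for cut in cuts:
        in_group = preds < cut if direction == "high" else preds > cut
        size = int(in_group.sum())
        if size == 0:
            continue
        tp = int((in_group & pos).sum())
        recall = tp / n_pos
        if recall < min_recall:
            continue
        precision = tp / size
        key = (precision, -size)
        if best is None or key > (best[0], best[1]):
            best = (precision, -size, float(cut))
    if best is None:
        raise CutoffError(
            f"no cutoff reaches recall >= {min_recall}; lower min_recall")
    return best[2]


@dataclass
class Stratification:
    """Low/intermediate/high risk partition with its log-rank p-value."""

    group_of: pd.Series
    log_rank_p: float

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.group_of.value_counts()
        return {g: int(counts.get(g, 0)) for g in ("low", "intermediate", "high")}


def stratify_risk(predictions: pd.Series,
                  low_cutoff: float,
                  high_cutoff: float) -> pd.Series:
    """Partition patients by predicted survival time.

    Predictions below ``high_cutoff`` are high risk, above ``low_cutoff``
    low risk, the rest intermediate.  Requires high_cutoff <= low_cutoff.
    """
    if low_cutoff < high_cutoff:
        raise ValueError(
            f"overlapping cutoffs: low_cutoff {low_cutoff:.4g} < "
            f"high_cutoff {high_cutoff:.4g}")
    preds = predictions.astype(float)
    group = pd.Series("intermediate", index=preds.index, dtype=object)
    group[preds < high_cutoff] = "high"
    group[preds > low_cutoff] = "low"
    group.name = "risk_group"
    return group


def logrank_pvalue(times: pd.Series | np.ndarray,
                   events: pd.Series | np.ndarray,
                   groups: pd.Series | np.ndarray) -> float:
    """Two-group log-rank test p-value (chi-square, 1 df).

    ``groups`` must contain exactly two distinct labels, both non-empty.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.tolist()}")
    mask = groups == labels[0]
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    result = logrank_test(times[mask], times[~mask],
                          event_observed_A=events[mask],
                          event_observed_B=events[~mask])
    return float(result.p_value)


@dataclass
class RiskModel:
    """Selected eigengenes, AFT fit, and risk cutoffs."""

    candidate_eigengenes: list[str]
    chosen_subset: list[str]
    aft: AFTFit
    low_cutoff: float
    high_cutoff: float
    min_recall_low: float
    min_recall_high: float


def _evaluate_subset(subset: tuple[str, ...],
                     eigengenes: pd.DataFrame,
                     surv: pd.DataFrame,
                     min_recall_low: float,
                     min_recall_high: float,
                     ) -> tuple[float, RiskModel, Stratification]:
    design = eigengenes.loc[list(subset)].T
    aft = fit_aft(design, surv)
    lp = aft.linear_predictor
    deceased = surv.loc[lp.index, "event"].astype(bool).to_numpy()
    high_cut = find_alive_cutoff(lp.to_numpy(), deceased, "high", min_recall_high)
    low_cut = find_alive_cutoff(lp.to_numpy(), ~deceased, "low", min_recall_low)
    group = stratify_risk(lp, low_cutoff=low_cut, high_cutoff=high_cut)
    extreme = group.isin(["low", "high"])
    p = logrank_pvalue(surv.loc[lp.index, "time"][extreme],
                       surv.loc[lp.index, "event"][extreme],
                       group[extreme])
    model = RiskModel(candidate_eigengenes=[], chosen_subset=list(subset),
                      aft=aft, low_cutoff=low_cut, high_cutoff=high_cut,
                      min_recall_low=min_recall_low,
                      min_recall_high=min_recall_high)
    return p, model, Stratification(group_of=group, log_rank_p=p)


def select_best_subset(candidates: list[str],
                       eigengenes: pd.DataFrame,
                       survival: pd.DataFrame,
                       min_recall_low: float = 0.2,
                       min_recall_high: float = 0.05,
                       ) -> tuple[RiskModel, Stratification]:
    """Best eigengene subset by smallest low-vs-high log-rank p-value.

    Evaluates every non-empty subset of ``candidates`` (seven for three
    candidates): AFT fit, cutoff derivation, stratification, log-rank
    test.  Ties break toward fewer eigengenes, then lexicographic IDs.
    Subsets for which no admissible pair of cutoffs exists are skipped.
    """
    surv = _check_survival(survival)
    patients = [p for p in eigengenes.columns if p in surv.index]
    surv = surv.loc[patients]
    sub_eig = eigengenes.loc[:, patients]
    results: list[tuple[float, int, tuple[str, ...], RiskModel, Stratification]] = []
    for size in range(1, len(candidates) + 1):
        for subset in combinations(sorted(candidates), size):
            try:
                p, model, strat = _evaluate_subset(
                    subset, sub_eig, surv, min_recall_low, min_recall_high)
            except (CutoffError, ValueError) as err:
                logger.info("select_best_subset: subset %s skipped (%s)",
                            subset, err)
                continue
            results.append((p, size, subset, model, strat))
    if not results:
        raise CutoffError("every candidate subset failed the cutoff search")
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    p, _, subset, model, strat = results[0]
    model.candidate_eigengenes = list(candidates)
    logger.info("select_best_subset: chose %s (log-rank p = %.3g)", subset, p)
    return model, strat


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier curve coordinates (time, at-risk, survival estimate)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    table = km.event_table
    out = pd.DataFrame({
        "time": km.survival_function_.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].reindex(km.survival_function_.index)
                                    .to_numpy(dtype=float),
        "survival": km.survival_function_.iloc[:, 0].to_numpy(dtype=float),
    })
    return out
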