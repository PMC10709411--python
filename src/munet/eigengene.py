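"""Module eigengenes from expression, methylation, and their combination.

For every module the eigengene is the first principal component of the
member genes' standardized profiles — a weighted average

    E^e = sum_i alpha^e_i g^e_i        (expression)
    E^m = sum_i alpha^m_i g^m_i        (gene-level methylation)
    E^em = (1 - mu) E^e + mu E^m       (combined)

whose weights are fit on a risk-balanced patient set: intermediate-risk
patients are excluded and the minority of {low, high} is oversampled to
parity, so neither extreme dominates the principal direction.  The same
weights (and the same standardization statistics) are then applied to
every patient, including intermediate-risk ones, by pure projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from munet.eigenloci import EigenlociResult, principal_direction
from munet.network import ModuleAssignment

logger = logging.getLogger("munet")


def balance_by_oversampling(gold_risk: pd.Series, seed: int = 1) -> list[str]:
    """Equalize low- and high-risk counts by duplicating the minority.

    ``gold_risk`` maps sample ID -> {low, intermediate, high} (missing
    allowed).  Intermediate-risk and unlabeled samples are excluded.
    The minority class is replicated whole as many times as fits, then a
    seeded sample without replacement covers the remainder, so both
    classes end with the majority count.  Deterministic given the seed.
    """
    labels = gold_risk.dropna().astype(str)
    low = sorted(labels.index[labels == "low"])
    high = sorted(labels.index[labels == "high"])
    if not low or not high:
        raise ValueError(
            "balance_by_oversampling needs at least one low- and one high-risk "
            "sample; use unbalanced PCA for single-class cohorts")
    minority, majority = (low, high) if len(low) <= len(high) else (high, low)
    target = len(majority)
    reps, rem = divmod(target, len(minority))
    balanced = list(majority) + list(minority) * reps
    if rem:
        rng = np.random.default_rng(seed)
        balanced += sorted(rng.choice(minority, size=rem, replace=False))
    return sorted(balanced)


@dataclass
class EigengeneSet:
    """Per-module eigengene matrices plus the weights behind them."""

    Ee: pd.DataFrame                    # module x sample, expression-based
    Em: pd.DataFrame                    # module x sample, methylation-based
    Eem: pd.DataFrame                   # module x sample, mu-combined
    alpha_e: dict[int, pd.Series]       # module -> gene weights
    alpha_m: dict[int, pd.Series]
    mu: float
    balanced_sample_ids: list[str]

    def stacked(self) -> pd.DataFrame:
        """All eigengenes as one feature x sample matrix.

        Feature IDs follow the ``<module><variant>`` convention, e.g.
        ``"3e"``, ``"3m"``, ``"3em"``.
        """
        blocks = []
        for suffix, df in (("e", self.Ee), ("m", self.Em), ("em", self.Eem)):
            if df.empty:
                continue
            blk = df.copy()
            blk.index = [f"{m}{suffix}" for m in df.index]
            blocks.append(blk)
        if not blocks:
            return pd.DataFrame()
        out = pd.concat(blocks, axis=0)
        out.index.name = "eigengene"
        return out


def _module_eigengene(data: pd.DataFrame,
                      genes: list[str],
                      balanced: list[str],
                      ) -> tuple[pd.Series, pd.Series] | None:
    """PCA weights on balanced samples, projection onto all samples.

    Genes are centered and scaled with statistics computed over the
    balanced multiset (duplicates counted), so intermediate-risk samples
    are projected with frozen statistics, never refit.
    """
    present = [g for g in genes if g in data.index]
    if not present:
        return None
    full = data.loc[present].to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(data.columns)}
    bal_idx = [cols[s] for s in balanced]
    bal = full[:, bal_idx]
    mean = bal.mean(axis=1)
    sd = bal.std(axis=1)
    usable = sd > 0
    if not usable.any():
        return None
    if not usable.all():
        logger.info("eigengene: dropped %d genes constant on balanced samples",
                    int((~usable).sum()))
        present = [g for g, u in zip(present, usable) if u]
        full, mean, sd = full[usable], mean[usable], sd[usable]
    z_bal = (full[:, bal_idx] - mean[:, None]) / sd[:, None]
    z_full = (full - mean[:, None]) / sd[:, None]
    if len(present) == 1:
        weights = np.array([1.0])
    else:
        try:
            weights, _ = principal_direction(z_bal)
        except ValueError:
            return None
    scores = weights @ z_full
    # orient toward the module's mean standardized profile on balanced samples
    mp = z_bal.mean(axis=0)
    align = float((weights @ z_bal) @ (mp - mp.mean()))
    if align < 0:
        weights, scores = -weights, -scores
    return (pd.Series(weights, index=present),
            pd.Series(scores, index=data.columns))


def compute_module_eigengenes(expr: pd.DataFrame,
                              eigenloci: pd.DataFrame | EigenlociResult,
                              modules: ModuleAssignment,
                              balanced: list[str],
                              mu: float) -> EigengeneSet:
    """Eigengenes E^e, E^m, E^em for every non-zero module.

    Module 0 (outlier genes) gets no eigengene.  E^m's sign is aligned
    to E^e per module (PCA signs are arbitrary; only with a shared
    orientation is the combination E^em meaningful).  E^em exists for
    modules that have both an expression and a methylation eigengene.
    """
    if isinstance(eigenloci, EigenlociResult):
        eigenloci = eigenloci.values
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    missing = [s for s in balanced if s not in expr.columns
               or s not in eigenloci.columns]
    if missing:
        raise ValueError(f"balanced samples absent from data: {missing[:5]}")
    Ee_rows, Em_rows = {}, {}
    alpha_e: dict[int, pd.Series] = {}
    alpha_m: dict[int, pd.Series] = {}
    for module in modules.modules:
        genes = modules.genes_in(module)
        if len(genes) == 1:
            logger.info("eigengene: module %d has a single gene", module)
        res_e = _module_eigengene(expr, genes, balanced)
        if res_e is not None:
            alpha_e[module], score_e = res_e
            Ee_rows[module] = score_e
        res_m = _module_eigengene(eigenloci, genes, balanced)
        if res_m is not None:
            w_m, score_m = res_m
            if res_e is not None and score_e.std() > 0 and score_m.std() > 0:
                r = float(np.corrcoef(score_e.to_numpy(),
                                      score_m.to_numpy())[0, 1])
                if r < 0:
                    w_m, score_m = -w_m, -score_m
            alpha_m[module] = w_m
            Em_rows[module] = score_m
    Ee = pd.DataFrame(Ee_rows).T if Ee_rows else pd.DataFrame(columns=expr.columns)
    Em = pd.DataFrame(Em_rows).T if Em_rows else pd.DataFrame(columns=expr.columns)
    Ee.index.name = Em.index.name = "module"
    shared = Ee.index.intersection(Em.index)
    Eem = combine_eigengenes(Ee.loc[shared], Em.loc[shared], mu) if len(shared) \
        else pd.DataFrame(columns=expr.columns)
    return EigengeneSet(Ee=Ee, Em=Em, Eem=Eem, alpha_e=alpha_e, alpha_m=alpha_m,
                        mu=float(mu), balanced_sample_ids=list(balanced))


def combine_eigengenes(Ee: pd.DataFrame, Em: pd.DataFrame,
                       mu: float) -> pd.DataFrame:
    """Exact elementwise combination E^em = (1 - mu) E^e + mu E^m."""
    if not Ee.index.equals(Em.index) or not Ee.columns.equals(Em.columns):
        raise ValueError("E^e and E^m must share the same module x sample grid")
    out = (1.0 - mu) * Ee + mu * Em
    out.index.name = "module"
    return out
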