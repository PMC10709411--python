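"""Seeded generator of coupled expression/methylation/survival cohorts.

The generator plants the structure the analysis is meant to recover:
gene modules driven by per-module latent factors shared (by default)
between expression and gene-level methylation, CpG beta values derived
from each gene's methylation latent through an inverse-logit link (so
betas stay in (0, 1)), a 450K-like loci-per-gene distribution with most
genes below six loci, Weibull accelerated-failure-time survival times
driven by one prognostic module's latent, uniform administrative
censoring calibrated to a target rate, missing betas completely at
random, and noisy tertile-based clinical risk labels.  Every quantity
needed to score recovery (module labels, latents, AFT parameters,
coupling signs) is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from munet.io import LocusGeneMap

SIGNALS = ("both", "expression", "methylation")


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated cohort."""

    module_of_gene: pd.Series            # gene -> module (0 = noise gene)
    latent_factors: pd.DataFrame         # module x sample latents driving omics
    prognostic_module: int
    aft_b0: float
    aft_b1: float
    aft_scale: float
    expr_sign: pd.Series                 # per gene, expression loading sign
    meth_sign: pd.Series                 # per gene, methylation loading sign
    missing_rate: float
    censoring_rate: float
    signal: str                          # which layer carries the survival latent
    survival_latent: pd.Series | None = None  # z_surv when a contrast is planted


@dataclass
class SyntheticCohort:
    """The five artifacts of one simulated cohort plus its ground truth."""

    expression: pd.DataFrame             # gene x sample, raw scale (>= 0)
    methylation: pd.DataFrame            # locus x sample betas with missing
    locus_gene_map: LocusGeneMap
    clinical: pd.DataFrame               # id-indexed: time, event, gold_risk
    truth: SyntheticTruth


def _default_loci_per_gene(rng: np.random.Generator, n: int) -> np.ndarray:
    """1 + Poisson(1.5) truncated at 9: ~93% of genes get < 6 loci."""
    counts = 1 + rng.poisson(1.5, size=n)
    return np.minimum(counts, 9)


def simulate_cohort(n_samples: int = 150,
                    n_modules: int = 3,
                    genes_per_module: int = 30,
                    n_noise_genes: int = 30,
                    within_module_cor: float | Sequence[float] = 0.8,
                    anticor_fraction: float = 0.5,
                    prognostic_effect: float = 1.0,
                    aft_intercept: float = 6.5,
                    aft_scale: float = 0.5,
                    censoring_rate: float = 0.3,
                    missing_rate: float = 0.05,
                    label_flip_rate: float = 0.1,
                    signal: str = "both",
                    shared_latent_cor: float = 0.95,
                    prognostic_weights: dict[int, float] | None = None,
                    loci_per_gene: Callable[[np.random.Generator, int],
                                            np.ndarray] | None = None,
                    seed: int = 1) -> SyntheticCohort:
    """Simulate one cohort with planted modules and survival signal.

    Parameters mirror the study conditions they emulate: each module k
    has a per-sample latent z_k; a gene in module k loads on z_k with
    coefficient a_g in [0.5, 1] (random sign) and Gaussian noise scaled
    so that |cor(gene, z_k)| = ``within_module_cor``.  The methylation
    latent of a gene loads on the same z_k, with its sign flipped
    relative to expression for a fraction ``anticor_fraction`` of genes
    (promoter-style anti-correlation).

    ``signal`` decouples one layer: with ``"expression"`` the module
    genes' methylation latents all collapse onto one shared
    co-regulation latent (correlation ``shared_latent_cor`` with it,
    independent of every module latent), so methylation carries neither
    module structure nor survival information — and vice versa for
    ``"methylation"``.  Only the named layer is then informative.

    Survival: log T = b0 + b1 * z_surv + scale * Gumbel, where z_surv
    is the prognostic module's latent by default, or — when
    ``prognostic_weights`` maps several modules to weights — the
    normalized weighted contrast of their latents (a hazard no single
    module recovers alone; see the multi-module hazard switch).
    Censoring is administrative at a Uniform(0, H) horizon calibrated
    to the requested rate.  Gold-standard risk labels are
    survival-aligned tertiles of z_surv with a ``label_flip_rate``
    fraction reassigned at random.
    """
    if signal not in SIGNALS:
        raise ValueError(f"signal must be one of {SIGNALS}")
    if not (0 <= missing_rate < 1 and 0 <= censoring_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if np.isscalar(within_module_cor):
        module_cors = [float(within_module_cor)] * n_modules
    else:
        module_cors = [float(x) for x in within_module_cor]
        if len(module_cors) != n_modules:
            raise ValueError("within_module_cor list must have n_modules entries")
    if any(not 0 < x < 1 for x in module_cors):
        raise ValueError("within_module_cor must be in (0, 1)")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    modules = list(range(1, n_modules + 1))
    prognostic_module = 1
    if prognostic_weights is not None:
        bad = sorted(set(prognostic_weights) - set(modules))
        if bad:
            raise ValueError(f"prognostic_weights for unknown modules: {bad}")

    z = pd.DataFrame(rng.standard_normal((n_modules, n_samples)),
                     index=modules, columns=samples)
    # shared co-regulation latent for the uninformative layer, if any
    v = rng.standard_normal(n_samples)
    shared_noise = np.sqrt(1.0 / shared_latent_cor ** 2 - 1.0) \
        if 0 < shared_latent_cor < 1 else 0.0

    genes = [f"G{m:02d}_{i + 1:03d}" for m in modules
             for i in range(genes_per_module)]
    genes += [f"GN_{i + 1:03d}" for i in range(n_noise_genes)]
    module_of = pd.Series(
        [m for m in modules for _ in range(genes_per_module)]
        + [0] * n_noise_genes, index=genes, name="module")

    noise_scales = {m: np.sqrt(1.0 / r ** 2 - 1.0)
                    for m, r in zip(modules, module_cors)}
    expr_rows, meth_latent_rows = [], []
    expr_sign, meth_sign = {}, {}
    for gene in genes:
        m = module_of[gene]
        if m == 0:
            expr_sign[gene] = 1
            meth_sign[gene] = 1
            expr_rows.append(rng.standard_normal(n_samples))
            meth_latent_rows.append(rng.standard_normal(n_samples))
            continue
        a = rng.uniform(0.5, 1.0)
        s_e = 1 if rng.random() < 0.5 else -1
        s_m = -s_e if rng.random() < anticor_fraction else s_e
        expr_sign[gene] = s_e
        meth_sign[gene] = s_m
        zk = z.loc[m].to_numpy()
        noise_scale = noise_scales[m]
        if signal == "methylation":
            # expression collapses onto the shared uninformative latent
            expr_rows.append(a * (v + shared_noise
                                  * rng.standard_normal(n_samples)))
        else:
            expr_rows.append(s_e * a * zk
                             + a * noise_scale * rng.standard_normal(n_samples))
        if signal == "expression":
            meth_latent_rows.append(a * (v + shared_noise
                                         * rng.standard_normal(n_samples)))
        else:
            meth_latent_rows.append(
                s_m * a * zk
                + a * noise_scale * rng.standard_normal(n_samples))
    expr_latent = np.vstack(expr_rows)
    meth_latent = np.vstack(meth_latent_rows)

    # raw expression on a positive scale; log10(raw + 1) recovers ~(latent + 2)
    expression = pd.DataFrame(np.power(10.0, expr_latent + 2.0),
                              index=genes, columns=samples)
    expression.index.name = "gene"

    counts = (loci_per_gene or _default_loci_per_gene)(rng, len(genes))
    pairs, beta_rows, locus_ids = [], [], []
    for gi, gene in enumerate(genes):
        for j in range(int(counts[gi])):
            locus = f"cg{gi:04d}_{j}"
            offset = rng.normal(0.0, 1.0)
            noise = rng.normal(0.0, 0.3, size=n_samples)
            logit = meth_latent[gi] + offset + noise
            beta_rows.append(1.0 / (1.0 + np.exp(-logit)))
            locus_ids.append(locus)
            pairs.append((locus, gene))
    methylation = pd.DataFrame(np.vstack(beta_rows), index=locus_ids,
                               columns=samples)
    methylation.index.name = "locus"
    if missing_rate > 0:
        mask = rng.random(methylation.shape) < missing_rate
        methylation = methylation.mask(mask)
    lgmap = LocusGeneMap.from_pairs(pairs)

    if prognostic_weights is None:
        zp = z.loc[prognostic_module].to_numpy()
    else:
        w = np.array([prognostic_weights.get(m, 0.0) for m in modules])
        w = w / np.linalg.norm(w)
        zp = w @ z.to_numpy()  # unit-variance multi-module contrast
    gumbel = np.log(-np.log(rng.uniform(size=n_samples)))  # standard Gumbel(min)
    log_t = aft_intercept + prognostic_effect * zp + aft_scale * gumbel
    t = np.exp(log_t)
    horizon = _calibrate_horizon(t, censoring_rate, rng)
    c = rng.uniform(0.0, horizon, size=n_samples)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)

    risk_score = prognostic_effect * zp if prognostic_effect != 0 else zp
    tertiles = np.quantile(risk_score, [1 / 3, 2 / 3])
    labels = np.where(risk_score <= tertiles[0], "high",
                      np.where(risk_score <= tertiles[1], "intermediate", "low"))
    flip = rng.random(n_samples) < label_flip_rate
    for i in np.flatnonzero(flip):
        others = [g for g in ("low", "intermediate", "high") if g != labels[i]]
        labels[i] = others[rng.integers(len(others))]

    clinical = pd.DataFrame({"time": time, "event": event, "gold_risk": labels},
                            index=pd.Index(samples, name="id"))
    truth = SyntheticTruth(
        module_of_gene=module_of,
        latent_factors=z,
        prognostic_module=prognostic_module,
        aft_b0=aft_intercept, aft_b1=prognostic_effect, aft_scale=aft_scale,
        expr_sign=pd.Series(expr_sign), meth_sign=pd.Series(meth_sign),
        missing_rate=missing_rate, censoring_rate=censoring_rate,
        signal=signal,
        survival_latent=pd.Series(zp, index=samples, name="z_surv"))
    return SyntheticCohort(expression=expression, methylation=methylation,
                           locus_gene_map=lgmap, clinical=clinical, truth=truth)


def _calibrate_horizon(t: np.ndarray, censoring_rate: float,
                       rng: np.random.Generator) -> float:
    """Horizon H with P(Uniform(0,H) < T) ~= censoring rate, by bisection."""
    if censoring_rate == 0:
        return float(t.max() * 1e6)
    u = rng.uniform(size=(64, t.size))  # frozen draws keep calibration smooth

    def rate(h: float) -> float:
        return float((u * h < t[None, :]).mean())

    lo, hi = float(t.min()) * 1e-3, float(t.max()) * 1e3
    if rate(hi) > censoring_rate:
        raise ValueError("infeasible censoring rate calibration")
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if rate(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def truth_report(truth: SyntheticTruth,
                 module_of: pd.Series,
                 eigengenes: pd.DataFrame | None = None,
                 selected: list[str] | None = None,
                 clinical: pd.DataFrame | None = None) -> dict:
    """Score a run against the planted truth.

    Returns a dict with the adjusted Rand index of detected vs planted
    module labels, the best absolute correlation of each planted
    module's latent with any detected eigengene, the rank (1-based) at
    which a prognostic-module eigengene appears in the lasso selection
    (None if absent), and — when ``clinical`` is supplied — the absolute
    error of the AFT coefficient obtained by regressing survival on the
    standardized best prognostic-matching eigengene (standardization
    puts the coefficient on the latent's unit scale).
    """
    from sklearn.metrics import adjusted_rand_score

    shared_genes = [g for g in module_of.index if g in truth.module_of_gene.index]
    if not shared_genes:
        raise ValueError("no overlap between detected and planted gene labels")
    ari = float(adjusted_rand_score(
        truth.module_of_gene.loc[shared_genes].to_numpy(),
        module_of.loc[shared_genes].to_numpy()))
    report: dict = {"module_ari": ari}

    if eigengenes is not None and not eigengenes.empty:
        shared_samples = [s for s in eigengenes.columns
                          if s in truth.latent_factors.columns]
        E = eigengenes.loc[:, shared_samples].to_numpy(dtype=float)
        cors = {}
        for m in truth.latent_factors.index:
            zk = truth.latent_factors.loc[m, shared_samples].to_numpy(dtype=float)
            best = 0.0
            for row in E:
                if row.std() == 0:
                    continue
                best = max(best, abs(float(np.corrcoef(row, zk)[0, 1])))
            cors[int(m)] = best
        report["eigengene_abs_cor"] = cors
        zp = truth.latent_factors.loc[truth.prognostic_module,
                                      shared_samples].to_numpy(dtype=float)
        prog_match = {}
        for name, row in zip(eigengenes.index, E):
            if row.std() > 0:
                prog_match[name] = abs(float(np.corrcoef(row, zp)[0, 1]))
        report["prognostic_best_match"] = max(prog_match, key=prog_match.get) \
            if prog_match else None

        if selected is not None:
            rank = None
            for i, name in enumerate(selected, start=1):
                if prog_match.get(name, 0.0) >= 0.5:
                    rank = i
                    break
            report["prognostic_selection_rank"] = rank
        best_name = report["prognostic_best_match"]
        if clinical is not None and best_name is not None:
            from munet.survival import fit_aft

            row = eigengenes.loc[best_name, shared_samples].astype(float)
            design = pd.DataFrame(
                {"prognostic": (row - row.mean()) / row.std()})
            fit = fit_aft(design, clinical)
            report["aft_b1_abs_error"] = float(
                abs(abs(fit.coefficients["prognostic"]) - abs(truth.aft_b1)))
    return report
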