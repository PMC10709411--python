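"""End-to-end orchestration: mu grid search and bootstrap stability.

A run executes preprocess -> eigenloci once (both are mu-independent),
then for every mu on the grid: network construction, module detection,
eigengene computation, and survival analysis.  The best mu is the one
whose low-vs-high log-rank p-value is smallest (ties toward smaller mu,
i.e. the simpler expression-weighted model).  Everything is
deterministic given the config seed; outputs carry a config hash and a
run refuses to overwrite a directory written under a different hash
unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from munet import eigengene as eg
from munet import eigenloci as el
from munet import network as nw
from munet import preprocess as pp
from munet import survival as sv
from munet.io import (LocusGeneMap, harmonize_samples, read_clinical,
                      read_locus_gene_map, read_matrix, write_matrix)
from munet.synthdata import SyntheticCohort

logger = logging.getLogger("munet")

DEFAULT_MU_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class RunConfig:
    """All knobs of a full run; see docs/methods.md for rationale."""

    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID
    cor_cutoff: float = 0.2
    election_rule: str = "either"
    offset: float = 1.0
    expression_normalized: bool = False
    max_missing_frac: float = 0.5
    max_loci: int = 6
    rsq_cut: float = 0.75
    min_module_size: int = 5
    merge_cor: float = 0.85
    min_recall_low: float = 0.2
    min_recall_high: float = 0.05
    gold_standard: str = "precomputed"
    seed: int = 1
    # input paths; unused when a cohort object is passed directly
    expression_path: str | None = None
    methylation_path: str | None = None
    map_path: str | None = None
    clinical_path: str | None = None

    def __post_init__(self) -> None:
        grid = tuple(float(m) for m in self.mu_grid)
        if any(not 0.0 <= m <= 1.0 for m in grid):
            raise ValueError("mu_grid values must lie in [0, 1]")
        if sorted(set(grid)) != list(grid):
            raise ValueError("mu_grid must be sorted and unique")
        object.__setattr__(self, "mu_grid", grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        if "mu_grid" in raw:
            raw["mu_grid"] = tuple(raw["mu_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mu_grid"] = list(self.mu_grid)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MuResult:
    """Per-mu stage outcomes; p is NaN when a stage failed."""

    mu: float
    n_modules: int = 0
    selected_eigengenes: list[str] = field(default_factory=list)
    chosen_subset: list[str] = field(default_factory=list)
    log_rank_p: float = float("nan")
    group_sizes: dict[str, int] = field(default_factory=dict)
    error: str | None = None


@dataclass
class RunResult:
    """Grid-search outcome plus provenance."""

    per_mu: dict[float, MuResult]
    best_mu: float
    config_hash: str
    seed: int
    modules_at_best: pd.Series | None = field(default=None, repr=False)
    eigengenes_at_best: pd.DataFrame | None = field(default=None, repr=False)
    risk_model: sv.RiskModel | None = field(default=None, repr=False)
    stratification: sv.Stratification | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "best_mu": self.best_mu,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "per_mu": {
                f"{mu:.1f}": {
                    "n_modules": r.n_modules,
                    "selected_eigengenes": r.selected_eigengenes,
                    "chosen_subset": r.chosen_subset,
                    "log_rank_p": None if np.isnan(r.log_rank_p)
                    else float(r.log_rank_p),
                    "group_sizes": r.group_sizes,
                    "error": r.error,
                }
                for mu, r in sorted(self.per_mu.items())
            },
        }


@dataclass
class _Prepared:
    """Mu-independent intermediates shared by every grid point."""

    expr: pd.DataFrame          # normalized, elected genes x samples
    eigenloci: pd.DataFrame     # gene-level methylation x samples
    clinical: pd.DataFrame      # prepared survival table
    model_samples: list[str]    # triple-complete sample IDs


def _load_inputs(config: RunConfig) -> SyntheticCohort:
    for name in ("expression_path", "methylation_path", "map_path",
                 "clinical_path"):
        if getattr(config, name) is None:
            raise ValueError(f"config lacks {name} and no cohort was passed")
    return SyntheticCohort(
        expression=read_matrix(config.expression_path),
        methylation=read_matrix(config.methylation_path),
        locus_gene_map=read_locus_gene_map(config.map_path),
        clinical=read_clinical(config.clinical_path),
        truth=None,  # type: ignore[arg-type]
    )


def _prepare(config: RunConfig, cohort: SyntheticCohort) -> _Prepared:
    t0 = _time.perf_counter()
    expr = cohort.expression if config.expression_normalized \
        else pp.normalize_expression(cohort.expression, offset=config.offset)
    meth = pp.clean_methylation(cohort.methylation,
                                max_missing_frac=config.max_missing_frac)
    clinical = pp.prepare_survival(cohort.clinical, config.gold_standard)
    election = pp.elect_features(expr, meth, clinical,
                                 cor_cutoff=config.cor_cutoff,
                                 rule=config.election_rule)
    election = pp.compute_union(election, cohort.locus_gene_map)
    expr_sub = expr.loc[[g for g in expr.index
                         if g in election.selected_genes]]
    meth_sub = meth.loc[[l for l in meth.index
                         if l in election.selected_loci]]
    logger.info("prepare: %d genes, %d loci elected (of %d / %d) [%.2fs]",
                expr_sub.shape[0], meth_sub.shape[0], expr.shape[0],
                meth.shape[0], _time.perf_counter() - t0)
    if expr_sub.shape[0] == 0 and meth_sub.shape[0] == 0:
        raise ValueError("feature election removed every gene and locus; "
                         "lower cor_cutoff")
    eloci = el.compute_eigenloci(meth_sub, cohort.locus_gene_map,
                                 max_loci=config.max_loci)
    (expr_h, eloci_h), _ = harmonize_samples(
        [expr_sub, eloci.values], ["columns", "columns"])
    model_samples = [s for s in expr_h.columns if s in clinical.index]
    if len(model_samples) < 10:
        raise ValueError("fewer than 10 triple-complete samples")
    return _Prepared(expr=expr_h, eigenloci=eloci_h, clinical=clinical,
                     model_samples=model_samples)


def _run_single_mu(config: RunConfig, prepared: _Prepared,
                   mu: float) -> tuple[MuResult, dict]:
    """One grid point: network -> modules -> eigengenes -> survival."""
    result = MuResult(mu=mu)
    artifacts: dict = {}
    try:
        net = nw.integrated_adjacency(prepared.expr, prepared.eigenloci, mu)
        nw.pick_soft_power(net, rsq_cut=config.rsq_cut)
        modules = nw.detect_modules(net,
                                    min_module_size=config.min_module_size,
                                    merge_cor=config.merge_cor)
        result.n_modules = len(modules.modules)
        artifacts["modules"] = modules
        if not modules.modules:
            raise ValueError("no modules detected (all genes in module 0)")
        gold = prepared.clinical.loc[
            [s for s in prepared.model_samples], "gold_risk"]
        balanced = eg.balance_by_oversampling(gold, seed=config.seed)
        eigs = eg.compute_module_eigengenes(
            prepared.expr, prepared.eigenloci, modules, balanced, mu)
        stacked = eigs.stacked()
        artifacts["eigengenes"] = eigs
        artifacts["stacked"] = stacked
        if stacked.empty:
            raise ValueError("no eigengenes computed")
        surv = prepared.clinical.loc[prepared.model_samples]
        selected = sv.lasso_select_eigengenes(
            stacked.loc[:, prepared.model_samples], surv)
        result.selected_eigengenes = list(selected)
        model, strat = sv.select_best_subset(
            selected, stacked.loc[:, prepared.model_samples], surv,
            min_recall_low=config.min_recall_low,
            min_recall_high=config.min_recall_high)
        result.chosen_subset = list(model.chosen_subset)
        result.log_rank_p = float(strat.log_rank_p)
        result.group_sizes = strat.group_sizes
        artifacts["risk_model"] = model
        artifacts["stratification"] = strat
    except Exception as err:  # a failed grid point is recorded, not fatal
        result.error = f"{type(err).__name__}: {err}"
        logger.warning("mu=%.1f failed: %s", mu, result.error)
    return result, artifacts


def run_pipeline(config: RunConfig,
                 cohort: SyntheticCohort | None = None,
                 out_dir: str | Path | None = None,
                 force: bool = False) -> RunResult:
    """Full grid-search run; returns the best-mu result.

    ``cohort`` may be an in-memory cohort (e.g. from
    :func:`munet.synthdata.simulate_cohort`); otherwise the input paths
    of ``config`` are read.  With ``out_dir`` set, all per-mu artifacts
    and a results JSON are written; the directory must be empty, carry
    the same config hash, or ``force`` must be set.
    """
    if cohort is None:
        cohort = _load_inputs(config)
    cfg_hash = config.hash()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        hash_file = out_path / "config_hash.txt"
        if hash_file.exists() and hash_file.read_text().strip() != cfg_hash \
                and not force:
            raise ValueError(
                f"{out_path} holds results for a different config "
                f"({hash_file.read_text().strip()} != {cfg_hash}); "
                "use force=True to overwrite")
    prepared = _prepare(config, cohort)
    per_mu: dict[float, MuResult] = {}
    best_artifacts: dict = {}
    for mu in config.mu_grid:
        t0 = _time.perf_counter()
        result, artifacts = _run_single_mu(config, prepared, mu)
        logger.info("mu=%.1f: %d modules, p=%.3g [%.2fs]", mu,
                    result.n_modules, result.log_rank_p,
                    _time.perf_counter() - t0)
        per_mu[mu] = result
        if artifacts:
            artifacts["_mu"] = mu
            best_artifacts.setdefault("all", {})[mu] = artifacts
    valid = [(r.log_rank_p, mu) for mu, r in per_mu.items()
             if not np.isnan(r.log_rank_p)]
    if not valid:
        raise RuntimeError("every mu grid point failed; see log")
    best_mu = min(valid)[1]
    best = best_artifacts["all"][best_mu]
    run_result = RunResult(
        per_mu=per_mu, best_mu=best_mu, config_hash=cfg_hash, seed=config.seed,
        modules_at_best=best["modules"].module_of,
        eigengenes_at_best=best.get("stacked"),
        risk_model=best.get("risk_model"),
        stratification=best.get("stratification"))
    if out_path is not None:
        _write_outputs(config, run_result, best_artifacts["all"], out_path,
                       prepared)
    return run_result


def _write_outputs(config: RunConfig, result: RunResult, all_artifacts: dict,
                   out_path: Path, prepared: _Prepared) -> None:
    (out_path / "config_hash.txt").write_text(result.config_hash + "\n")
    with (out_path / "config.json").open("w") as handle:
        json.dump(config.to_dict(), handle, sort_keys=True, indent=1)
        handle.write("\n")
    with (out_path / "results.json").open("w") as handle:
        json.dump(result.to_dict(), handle, sort_keys=True, indent=1)
        handle.write("\n")
    write_matrix(prepared.expr, out_path / "expression.elected.tsv")
    write_matrix(prepared.eigenloci, out_path / "eigenloci.tsv")
    for mu, artifacts in sorted(all_artifacts.items()):
        mu_dir = out_path / f"mu_{mu:.1f}"
        mu_dir.mkdir(exist_ok=True)
        if "modules" in artifacts:
            artifacts["modules"].module_of.rename("module").to_csv(
                mu_dir / "modules.tsv", sep="\t")
        if "stacked" in artifacts and not artifacts["stacked"].empty:
            write_matrix(artifacts["stacked"], mu_dir / "eigengenes.tsv")
        if "risk_model" in artifacts:
            model: sv.RiskModel = artifacts["risk_model"]
            strat: sv.Stratification = artifacts["stratification"]
            with (mu_dir / "risk_model.json").open("w") as handle:
                json.dump({
                    "candidate_eigengenes": model.candidate_eigengenes,
                    "chosen_subset": model.chosen_subset,
                    "aft_intercept": model.aft.intercept,
                    "aft_coefficients": {
                        str(k): float(v)
                        for k, v in model.aft.coefficients.items()},
                    "aft_scale": model.aft.scale,
                    "low_cutoff": model.low_cutoff,
                    "high_cutoff": model.high_cutoff,
                    "min_recall_low": model.min_recall_low,
                    "min_recall_high": model.min_recall_high,
                    "log_rank_p": float(strat.log_rank_p),
                    "group_sizes": strat.group_sizes,
                }, handle, sort_keys=True, indent=1)
                handle.write("\n")
            strat.group_of.to_csv(mu_dir / "stratification.tsv", sep="\t")
            _write_km(strat, prepared, mu_dir)


def _write_km(strat: sv.Stratification, prepared: _Prepared,
              mu_dir: Path) -> None:
    frames = []
    surv = prepared.clinical
    for grp in ("low", "intermediate", "high"):
        ids = [i for i in strat.group_of.index[strat.group_of == grp]]
        if not ids:
            continue
        curve = sv.km_curve(surv.loc[ids, "time"].to_numpy(),
                            surv.loc[ids, "event"].to_numpy())
        curve.insert(0, "group", grp)
        frames.append(curve)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            mu_dir / "km_curves.tsv", sep="\t", index=False,
            float_format="%.10g")


def bootstrap_stability(config: RunConfig,
                        cohort: SyntheticCohort,
                        n_iterations: int,
                        seed: int | None = None,
                        best_mu: float | None = None) -> dict:
    """Patient-level bootstrap of the network -> survival stages.

    Patients are resampled with replacement (same n) at a fixed mu (the
    base run's best mu unless given); preprocessing and eigenloci are
    computed once on the original cohort and their columns resampled,
    matching the view that only the patient sample — not the feature
    universe — is random.  Returns the mean and variance of the
    per-iteration log-rank p-values plus the per-iteration records.
    Iterations that fail are recorded as missing; more than 20% failures
    aborts.
    """
    seed = config.seed if seed is None else seed
    prepared = _prepare(config, cohort)
    if best_mu is None:
        base = run_pipeline(config, cohort=cohort)
        best_mu = base.best_mu
    rng = np.random.default_rng(seed)
    samples = prepared.model_samples
    n = len(samples)
    records: list[dict] = []
    failures = 0
    for it in range(n_iterations):
        draw = rng.integers(0, n, size=n)
        picked = [samples[i] for i in draw]
        new_ids = [f"{s}.b{j}" for j, s in enumerate(picked)]
        expr_b = prepared.expr.loc[:, picked].set_axis(new_ids, axis=1)
        eloci_b = prepared.eigenloci.loc[:, picked].set_axis(new_ids, axis=1)
        clin_b = prepared.clinical.loc[picked].set_axis(new_ids, axis=0)
        boot_prep = _Prepared(expr=expr_b, eigenloci=eloci_b, clinical=clin_b,
                              model_samples=new_ids)
        boot_config = dataclasses.replace(config, seed=int(seed + it + 1))
        result, _ = _run_single_mu(boot_config, boot_prep, best_mu)
        if np.isnan(result.log_rank_p):
            failures += 1
            records.append({"iteration": it, "log_rank_p": None,
                            "error": result.error})
        else:
            records.append({"iteration": it,
                            "log_rank_p": float(result.log_rank_p),
                            "error": None})
        if failures > 0.2 * n_iterations:
            raise RuntimeError(
                f"bootstrap aborted: {failures} failures in {it + 1} iterations")
    ps = np.array([r["log_rank_p"] for r in records
                   if r["log_rank_p"] is not None])
    return {
        "mu": float(best_mu),
        "n_iterations": n_iterations,
        "n_failures": failures,
        "mean_p": float(ps.mean()) if ps.size else float("nan"),
        "var_p": float(ps.var(ddof=1)) if ps.size > 1 else float("nan"),
        "iterations": records,
    }
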