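"""Normalization, cleaning, feature election, and gene/locus union expansion.

Expression is variance-stabilized by a base-10 log with a small offset.
Methylation loci with too many missing beta values are dropped; the rest
are mean-imputed per locus.  Clinical rows without usable survival data
are removed and a cohort-specific gold-standard rule assigns each patient
a low/intermediate/high risk label.  Genes and loci that correlate only
weakly with survival are dropped (feature "election"), then the retained
sets are expanded so that every selected gene brings its loci and every
selected locus brings its genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from munet.io import LocusGeneMap

logger = logging.getLogger("munet")

GOLD_STANDARDS = ("lungStage", "afpIshak", "cytogenetics", "braak", "precomputed")

#: tumor-stage buckets for the lung gold standard
_LUNG_LOW = {"I", "IA", "IB", "II", "IIA"}
_LUNG_HIGH = {"IIIB", "IV"}
_LUNG_INTERMEDIATE = {"IIB", "III", "IIIA"}


def normalize_expression(raw: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log10(value + offset) transform of a non-negative expression matrix."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    vals = raw.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("expression values must be non-negative before normalization")
    out = pd.DataFrame(np.log10(vals + offset), index=raw.index, columns=raw.columns)
    out.attrs["log10_normalized"] = True
    out.attrs["log10_offset"] = float(offset)
    return out


def clean_methylation(meth: pd.DataFrame, max_missing_frac: float = 0.5) -> pd.DataFrame:
    """Drop loci with too many missing betas; mean-impute the rest.

    A locus whose fraction of missing entries exceeds ``max_missing_frac``
    is removed (an all-missing locus is always removed, never imputed).
    Remaining missing entries are replaced by the locus mean over observed
    samples, so each retained locus keeps its observed mean.
    """
    vals = meth.to_numpy(dtype=float)
    missing = ~np.isfinite(vals)
    frac = missing.mean(axis=1) if vals.shape[1] else np.ones(vals.shape[0])
    keep = frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("clean_methylation: dropped %d loci with > %.0f%% missing betas",
                    n_dropped, 100 * max_missing_frac)
    vals = vals[keep]
    missing = missing[keep]
    if vals.size:
        with np.errstate(invalid="ignore"):
            row_means = np.nanmean(np.where(missing, np.nan, vals), axis=1)
        vals = np.where(missing, row_means[:, None], vals)
    return pd.DataFrame(vals, index=meth.index[keep], columns=meth.columns)


def _lung_stage_risk(stage: str) -> str:
    token = str(stage).strip().upper().removeprefix("STAGE").strip()
    if token in _LUNG_LOW:
        return "low"
    if token in _LUNG_HIGH:
        return "high"
    if token in _LUNG_INTERMEDIATE:
        return "intermediate"
    raise ValueError(f"unknown tumor stage token: {stage!r}")


def _afp_ishak_risk(afp: float, ishak: float) -> str:
    if not np.isfinite(afp) or not np.isfinite(ishak):
        return "intermediate"
    if afp > 500 or ishak == 6:
        return "high"
    if afp < 250 and ishak in (0, 1, 2):
        return "low"
    return "intermediate"


def _braak_risk(score: float) -> str:
    if not np.isfinite(score):
        raise ValueError("missing Braak score")
    score = int(score)
    if score not in range(0, 7):
        raise ValueError(f"unknown Braak score token: {score!r}")
    if score <= 2:
        return "low"
    if score >= 5:
        return "high"
    return "intermediate"


_PRECOMPUTED_ALIASES = {
    "favorable": "low", "low": "low",
    "intermediate": "intermediate", "normal": "intermediate",
    "poor": "high", "adverse": "high", "high": "high",
}


def prepare_survival(clinical: pd.DataFrame, gold_standard: str) -> pd.DataFrame:
    """Clean the clinical table and attach gold-standard risk labels.

    Rows with missing survival ``time`` or ``event`` are removed.
    ``gold_standard`` selects the labeling rule:

    - ``lungStage``: stages I/IA/IB/II/IIA -> low, IIIB/IV -> high,
      remaining stages -> intermediate (column ``stage``).
    - ``afpIshak``: AFP > 500 or Ishak = 6 -> high; AFP < 250 and Ishak in
      {0,1,2} -> low; else intermediate (columns ``afp``, ``ishak``).
    - ``braak``: Braak 0-2 -> low, 5-6 -> high, 3-4 -> intermediate
      (column ``braak``).
    - ``cytogenetics`` / ``precomputed``: pass a provided
      favorable/intermediate/poor (or low/intermediate/high) column
      through (column ``cytogenetics`` or ``gold_risk``).
    """
    if gold_standard not in GOLD_STANDARDS:
        raise ValueError(f"unknown gold standard rule: {gold_standard!r}")
    df = clinical.copy()
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    n0 = len(df)
    df = df[pd.to_numeric(df["time"], errors="coerce").notna()
            & pd.to_numeric(df["event"], errors="coerce").notna()]
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        bad = sorted(df.loc[~df["event"].isin([0, 1]), "event"].unique())
        raise ValueError(f"event values outside {{0,1}}: {bad}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if n0 - len(df):
        logger.info("prepare_survival: removed %d cases with missing time/event",
                    n0 - len(df))

    if gold_standard == "lungStage":
        _require(df, "stage", gold_standard)
        df["gold_risk"] = [_lung_stage_risk(s) for s in df["stage"]]
    elif gold_standard == "afpIshak":
        _require(df, "afp", gold_standard)
        _require(df, "ishak", gold_standard)
        df["gold_risk"] = [
            _afp_ishak_risk(a, i)
            for a, i in zip(pd.to_numeric(df["afp"], errors="coerce"),
                            pd.to_numeric(df["ishak"], errors="coerce"))
        ]
    elif gold_standard == "braak":
        _require(df, "braak", gold_standard)
        df["gold_risk"] = [_braak_risk(b)
                           for b in pd.to_numeric(df["braak"], errors="coerce")]
    else:  # cytogenetics / precomputed passthrough
        col = "cytogenetics" if gold_standard == "cytogenetics" else "gold_risk"
        if col not in df.columns and "gold_risk" in df.columns:
            col = "gold_risk"
        _require(df, col, gold_standard)
        labels = []
        for tok in df[col]:
            key = str(tok).strip().lower()
            if key not in _PRECOMPUTED_ALIASES:
                raise ValueError(f"unknown risk class token: {tok!r}")
            labels.append(_PRECOMPUTED_ALIASES[key])
        df["gold_risk"] = labels
    return df


def _require(df: pd.DataFrame, col: str, rule: str) -> None:
    if col not in df.columns:
        raise ValueError(f"gold standard rule {rule!r} requires column {col!r}")


@dataclass(frozen=True)
class FeatureElection:
    """Genes and loci retained by the survival-correlation filter."""

    selected_genes: frozenset[str]
    selected_loci: frozenset[str]
    cor_cutoff: float

    def __len__(self) -> int:
        return len(self.selected_genes) + len(self.selected_loci)


def _survival_correlations(features: pd.DataFrame,
                           survival: pd.DataFrame) -> pd.DataFrame:
    """|Pearson r| of each feature row with survival time and with event.

    Uses the samples shared between the feature matrix and the clinical
    table (pairwise complete).  Zero-variance features get correlation 0.
    """
    shared = [s for s in features.columns if s in survival.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for election")
    X = features.loc[:, shared].to_numpy(dtype=float)
    out = {}
    for name in ("time", "event"):
        y = survival.loc[shared, name].to_numpy(dtype=float)
        yc = y - y.mean()
        ynorm = np.sqrt((yc ** 2).sum())
        Xc = X - X.mean(axis=1, keepdims=True)
        xnorm = np.sqrt((Xc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ yc) / (xnorm * ynorm)
        r[~np.isfinite(r)] = 0.0  # zero-variance feature or outcome
        out[name] = np.abs(r)
    return pd.DataFrame(out, index=features.index)


def elect_features(expr: pd.DataFrame,
                   meth: pd.DataFrame,
                   survival: pd.DataFrame,
                   cor_cutoff: float = 0.2,
                   rule: str = "either") -> FeatureElection:
    """Keep features that correlate with survival time or vital status.

    A gene (locus) is kept iff its absolute Pearson correlation with
    survival time, or with the event indicator, reaches ``cor_cutoff``
    over the samples shared with the clinical table.  ``rule="both"``
    demands both correlations exceed the cutoff.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    agg = np.maximum if rule == "either" else np.minimum

    def _select(features: pd.DataFrame) -> frozenset[str]:
        if features.shape[0] == 0:
            return frozenset()
        cors = _survival_correlations(features, survival)
        score = agg(cors["time"].to_numpy(), cors["event"].to_numpy())
        n_zero = int((cors.max(axis=1) == 0).sum())
        if n_zero:
            logger.info("elect_features: %d zero-variance features scored 0", n_zero)
        return frozenset(features.index[score >= cor_cutoff])

    return FeatureElection(
        selected_genes=_select(expr),
        selected_loci=_select(meth),
        cor_cutoff=float(cor_cutoff),
    )


def compute_union(election: FeatureElection, lgmap: LocusGeneMap) -> FeatureElection:
    """Expand the election by gene<->locus correspondence (idempotent).

    Output genes = elected genes plus the genes of every elected locus;
    output loci = elected loci plus the loci of every elected gene.
    The expansion iterates to a fixed point so that, even under
    many-to-many locus/gene maps, applying the union twice changes
    nothing.  Features without a mapping pass through unchanged.
    """
    genes = set(election.selected_genes)
    loci = set(election.selected_loci)
    while True:
        new_genes = {g for l in loci for g in lgmap.genes_of(l)} - genes
        new_loci = {l for g in genes for l in lgmap.loci_of(g)} - loci
        if not new_genes and not new_loci:
            break
        genes |= new_genes
        loci |= new_loci
    unmapped = [g for g in election.selected_genes if not lgmap.loci_of(g)]
    if unmapped:
        logger.info("compute_union: %d selected genes have no mapped loci",
                    len(unmapped))
    return replace(election,
                   selected_genes=frozenset(genes),
                   selected_loci=frozenset(loci))
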