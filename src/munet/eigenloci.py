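"""Gene-level methylation summaries ("eigenloci") from locus-level betas.

Each gene's CpG loci are collapsed to one value per sample: the first
principal component of the (centered, unscaled) beta rows, i.e. a
weighted average of its loci.  Genes with many loci are first reduced to
their densest co-methylated core via fast-greedy community detection on
the absolute-correlation graph, so a handful of discordant loci cannot
dominate the summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import igraph as ig
import numpy as np
import pandas as pd

from munet.io import LocusGeneMap

logger = logging.getLogger("munet")


def principal_direction(X: np.ndarray | pd.DataFrame,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of a features x samples matrix.

    Rows are centered internally (never scaled).  Returns ``(weights,
    scores)`` where ``weights`` is the unit-norm first left singular
    vector over features and ``scores = weights @ centered(X)`` over
    samples.  The sign is fixed so that the scores correlate
    non-negatively with the mean feature profile; if that correlation is
    exactly zero the largest-magnitude weight is made positive.
    """
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 1 feature and >= 2 samples")
    centered = A - A.mean(axis=1, keepdims=True)
    if not np.any(np.abs(centered) > 0):
        raise ValueError("zero variance: all features are constant across samples")
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    weights = U[:, 0]
    scores = weights @ centered
    mean_profile = A.mean(axis=0)
    mp_centered = mean_profile - mean_profile.mean()
    align = float(scores @ mp_centered)
    if align < 0:
        weights, scores = -weights, -scores
    elif align == 0 and weights[np.argmax(np.abs(weights))] < 0:
        weights, scores = -weights, -scores
    return weights, scores


def _mean_abs_pairwise_cor(R: np.ndarray, members: list[int]) -> float:
    pairs = list(combinations(members, 2))
    return float(np.mean([abs(R[i, j]) for i, j in pairs]))


def find_core(beta_sub: np.ndarray | pd.DataFrame) -> list[int] | list[str]:
    """Densest co-methylated locus community of a loci x samples block.

    Builds the complete graph on loci weighted by absolute Pearson
    correlation, runs fast-greedy modularity community detection, and
    returns the community whose members have the highest mean absolute
    pairwise correlation.  Singleton communities are excluded from the
    argmax unless every community is a singleton, in which case the full
    locus set is returned.  Constant loci are removed before graph
    construction; if fewer than two loci remain, the remainder is
    returned as-is.

    Returns row labels when given a DataFrame, row positions otherwise.
    """
    labels = list(beta_sub.index) if isinstance(beta_sub, pd.DataFrame) \
        else list(range(np.asarray(beta_sub).shape[0]))
    A = np.asarray(beta_sub, dtype=float)
    sd = A.std(axis=1)
    alive = np.flatnonzero(sd > 0)
    if alive.size < len(labels):
        logger.info("find_core: removed %d constant loci", len(labels) - alive.size)
    if alive.size < 2:
        return [labels[i] for i in alive]
    R = np.corrcoef(A[alive])
    n = alive.size
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    weights = [abs(R[i, j]) for i, j in edges]
    graph = ig.Graph(n=n, edges=edges)
    communities = graph.community_fastgreedy(weights=weights).as_clustering()
    groups = [list(c) for c in communities]
    candidates = [g for g in groups if len(g) >= 2]
    if not candidates:
        logger.info("find_core: all communities are singletons; keeping all loci")
        return [labels[i] for i in alive]
    best = max(candidates, key=lambda g: (_mean_abs_pairwise_cor(R, g), -len(g)))
    return [labels[alive[i]] for i in best]


@dataclass
class EigenlociResult:
    """Gene-level methylation matrix plus per-gene PCA bookkeeping."""

    values: pd.DataFrame            # gene x sample
    weights: dict[str, pd.Series]   # gene -> locus weights (unit norm)
    core_loci: dict[str, list[str]]  # gene -> loci actually used

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def compute_eigenloci(meth: pd.DataFrame,
                      lgmap: LocusGeneMap,
                      max_loci: int = 6) -> EigenlociResult:
    """One methylation value per gene per sample from cleaned betas.

    A gene with fewer than ``max_loci`` mapped loci is summarized by the
    first principal component of all of them; with ``max_loci`` or more,
    by the principal component of its :func:`find_core` subset.  Genes
    with no mapped locus present in the matrix, or whose loci are all
    constant, are omitted (and logged).
    """
    rows: dict[str, np.ndarray] = {}
    weights: dict[str, pd.Series] = {}
    core_loci: dict[str, list[str]] = {}
    omitted: list[str] = []
    locus_set = set(meth.index)
    for gene in sorted(lgmap.genes):
        loci = [l for l in lgmap.loci_of(gene) if l in locus_set]
        if not loci:
            omitted.append(gene)
            continue
        block = meth.loc[loci]
        used = loci if len(loci) < max_loci else list(find_core(block))
        if not used:
            omitted.append(gene)
            continue
        try:
            w, scores = principal_direction(meth.loc[used])
        except ValueError:
            omitted.append(gene)  # all-constant loci
            continue
        rows[gene] = scores
        weights[gene] = pd.Series(w, index=used)
        core_loci[gene] = list(used)
    if omitted:
        logger.info("compute_eigenloci: omitted %d genes (no usable loci): %s",
                    len(omitted), ", ".join(omitted[:10]))
    values = pd.DataFrame(rows, index=meth.columns).T
    values.index.name = "gene"
    return EigenlociResult(values=values, weights=weights, core_loci=core_loci)
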