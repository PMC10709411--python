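"""The mu-integrated gene network: adjacency, soft power, and modules.

Edge weights blend the two omic layers:

    W(g_i, g_j) = (1 - mu) * |cor_E(g_i, g_j)| + mu * |cor_M(g_i, g_j)|

where cor_E is the Pearson correlation of expression profiles and cor_M
of gene-level methylation (eigenloci) profiles, and mu in [0, 1] sets the
relative contribution of methylation.  W is raised elementwise to a
soft-thresholding power chosen so that connectivity approximates a
scale-free degree distribution, converted to topological-overlap
similarity, and clustered hierarchically into gene modules; genes that
cannot be confidently assigned go to module 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from munet.eigenloci import EigenlociResult, principal_direction

logger = logging.getLogger("munet")

MIN_SHARED_SAMPLES = 3  # below this, a pairwise correlation is no evidence


@dataclass
class IntegratedNetwork:
    """Symmetric gene x gene similarity with its integrative factor.

    Keeps references to the underlying expression and eigenloci matrices
    so that downstream module merging can compute cluster eigengenes.
    """

    W: pd.DataFrame
    mu: float
    genes: list[str]
    soft_power: int | None = None
    expr: pd.DataFrame | None = field(default=None, repr=False)
    eigenloci: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class ModuleAssignment:
    """Gene -> module map; module 0 holds unassigned (outlier) genes."""

    module_of: pd.Series  # index gene, int module id

    @property
    def sizes(self) -> pd.Series:
        return self.module_of.value_counts().sort_index()

    @property
    def modules(self) -> list[int]:
        return sorted(m for m in self.module_of.unique() if m != 0)

    def genes_in(self, module: int) -> list[str]:
        return list(self.module_of.index[self.module_of == module])


def _abs_cor_block(data: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """|Pearson r| between the given genes' rows; 0 where undefined.

    Genes absent from ``data`` (missing that data type) or with fewer
    than :data:`MIN_SHARED_SAMPLES` observations contribute 0, the
    no-evidence convention.
    """
    n = len(genes)
    out = np.zeros((n, n))
    present = [i for i, g in enumerate(genes) if g in data.index]
    if len(present) < 2 or data.shape[1] < MIN_SHARED_SAMPLES:
        return out
    sub = data.loc[[genes[i] for i in present]].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(sub)
    R[~np.isfinite(R)] = 0.0  # zero-variance rows
    R[sd == 0, :] = 0.0
    R[:, sd == 0] = 0.0
    idx = np.asarray(present)
    out[np.ix_(idx, idx)] = np.abs(R)
    return out


def integrated_adjacency(expr: pd.DataFrame,
                         eigenloci: pd.DataFrame | EigenlociResult,
                         mu: float) -> IntegratedNetwork:
    """Build W(mu) over the union of expression and methylation genes.

    A gene present in only one layer contributes only that layer's term;
    the missing term counts as 0.  The diagonal is set to 0.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    if isinstance(eigenloci, EigenlociResult):
        eigenloci = eigenloci.values
    genes = sorted(set(expr.index) | set(eigenloci.index))
    both = set(expr.index) & set(eigenloci.index)
    if len(both) < len(genes):
        logger.info("integrated_adjacency: %d/%d genes have both data types",
                    len(both), len(genes))
    W = np.zeros((len(genes), len(genes)))
    if mu < 1.0:
        W += (1.0 - mu) * _abs_cor_block(expr, genes)
    if mu > 0.0:
        W += mu * _abs_cor_block(eigenloci, genes)
    np.fill_diagonal(W, 0.0)
    W = np.clip(0.5 * (W + W.T), 0.0, 1.0)
    Wdf = pd.DataFrame(W, index=genes, columns=genes)
    return IntegratedNetwork(W=Wdf, mu=float(mu), genes=genes,
                             expr=expr, eigenloci=eigenloci)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free (log-log degree) fit.

    Connectivities are binned into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity per bin) and
    the squared correlation is signed by the negated slope, so a rising
    degree distribution scores negatively.  Returns NaN when degenerate.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    total = k.size
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / total))
    if len(xs) < 3:
        return float("nan")
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    if np.allclose(xs_a, xs_a[0]) or np.allclose(ys_a, ys_a[0]):
        return float("nan")
    slope, _ = np.polyfit(xs_a, ys_a, 1)
    r = np.corrcoef(xs_a, ys_a)[0, 1]
    return float(r * r * np.sign(-slope))


def pick_soft_power(net: IntegratedNetwork,
                    rsq_cut: float = 0.75,
                    candidate_powers: list[int] | None = None) -> int:
    """Smallest power whose scale-free fit reaches ``rsq_cut``.

    For each candidate power beta the adjacency is W**beta and the fit
    statistic comes from :func:`scale_free_fit` of its connectivities.
    If no candidate reaches the cut, the best-fitting power is returned
    and the non-convergence is logged.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 21))
    W = net.W.to_numpy()
    fits: dict[int, float] = {}
    for beta in candidate_powers:
        k = np.power(W, beta).sum(axis=1)
        fit = scale_free_fit(k)
        if np.isnan(fit):
            logger.info("pick_soft_power: degenerate connectivity at power %d", beta)
            continue
        fits[beta] = fit
        if fit >= rsq_cut:
            net.soft_power = beta
            return beta
    if not fits:
        # e.g. a fully uniform network: every connectivity identical
        first = min(candidate_powers)
        logger.warning("pick_soft_power: fit undefined at every power; using %d",
                       first)
        net.soft_power = first
        return first
    best = max(fits, key=lambda b: (fits[b], -b))
    logger.info("pick_soft_power: no power reached R^2 >= %.2f; using %d "
                "(fit %.3f)", rsq_cut, best, fits[best])
    net.soft_power = best
    return best


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency (diag 0).

    TOM(i,j) = (sum_u A(i,u)A(u,j) + A(i,j)) / (min(k_i,k_j) + 1 - A(i,j))
    with unit diagonal.  Values lie in [0, 1] for adjacencies in [0, 1].
    """
    A = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip(0.5 * (tom + tom.T), 0.0, 1.0)


def _cluster_summary(net: IntegratedNetwork, genes: list[str]) -> np.ndarray | None:
    """First PC of the mu-weighted standardized profiles of a cluster.

    Expression rows enter with weight sqrt(1 - mu) and eigenloci rows
    with weight sqrt(mu), each z-scored first, so the summary respects
    the same balance as the network edges.
    """
    rows = []
    for gene in genes:
        for data, w in ((net.expr, np.sqrt(1.0 - net.mu)),
                        (net.eigenloci, np.sqrt(net.mu))):
            if w == 0.0 or data is None or gene not in data.index:
                continue
            x = data.loc[gene].to_numpy(dtype=float)
            sd = x.std()
            if sd > 0:
                rows.append(w * (x - x.mean()) / sd)
    if not rows:
        return None
    try:
        _, scores = principal_direction(np.vstack(rows))
    except ValueError:
        return None
    return scores


def _merge_close_modules(net: IntegratedNetwork,
                         clusters: list[list[str]],
                         merge_cor: float) -> list[list[str]]:
    """Iteratively merge clusters whose summary profiles correlate highly."""
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        summaries = [_cluster_summary(net, c) for c in clusters]
        best: tuple[float, int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                si, sj = summaries[i], summaries[j]
                if si is None or sj is None:
                    continue
                if si.std() == 0 or sj.std() == 0:
                    continue
                r = abs(float(np.corrcoef(si, sj)[0, 1]))
                if r > merge_cor and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        logger.info("detect_modules: merged two modules (eigengene |r| %.3f)", best[0])
    return clusters


def _modularity(A: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a partition on a weighted adjacency (diag 0)."""
    total = A.sum()
    if total <= 0:
        return 0.0
    q = 0.0
    deg = A.sum(axis=1)
    for lab in np.unique(labels):
        members = labels == lab
        q += A[np.ix_(members, members)].sum() / total \
            - (deg[members].sum() / total) ** 2
    return float(q)


def _best_modularity_cut(Z: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Cut the dendrogram at the level maximizing modularity on A.

    Candidate cut heights are the midpoints between consecutive distinct
    merge heights (plus one above the root); the partition whose
    modularity on the soft-thresholded adjacency is largest wins, ties
    going to the coarser (higher) cut.  A dendrogram with no positive
    merge height (all genes identical) is a single cluster.
    """
    heights = np.unique(Z[:, 2])
    if heights.max() <= 0:
        return np.ones(Z.shape[0] + 1, dtype=int)
    levels = np.concatenate([(heights[:-1] + heights[1:]) / 2.0,
                             [heights.max() + 1.0]])
    best_labels = None
    best_key: tuple[float, float] | None = None
    for t in levels:
        labels = fcluster(Z, t=t, criterion="distance")
        if np.unique(labels).size == 1 and t != levels[-1]:
            continue
        key = (_modularity(A, labels), t)
        if best_key is None or key > best_key:
            best_key = key
            best_labels = labels
    return best_labels


def detect_modules(net: IntegratedNetwork,
                   min_module_size: int = 5,
                   merge_cor: float = 0.85) -> ModuleAssignment:
    """Hierarchical TOM clustering of the soft-thresholded network.

    The adjacency W**softPower is converted to topological overlap;
    average-linkage clustering of 1 - TOM is cut at the dendrogram level
    that maximizes modularity of the induced partition on the adjacency
    (an adaptive stand-in for a dynamic tree cut).  Clusters smaller
    than ``min_module_size`` become module 0, clusters whose summary
    eigengenes correlate above ``merge_cor`` are merged, and the
    surviving modules are labeled 1..K by decreasing size (ties broken
    by smallest member gene symbol).
    """
    genes = net.genes
    if net.soft_power is None:
        raise ValueError("call pick_soft_power before detect_modules")
    if len(genes) < min_module_size:
        logger.warning("detect_modules: fewer genes (%d) than min_module_size (%d); "
                       "all genes -> module 0", len(genes), min_module_size)
        return ModuleAssignment(pd.Series(0, index=pd.Index(genes, name="gene")))
    A = np.power(net.W.to_numpy(), net.soft_power)
    if A.sum() == 0:
        logger.warning("detect_modules: similarity is identically zero; "
                       "no modules")
        return ModuleAssignment(pd.Series(0, index=pd.Index(genes, name="gene")))
    tom = topological_overlap(A)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = _best_modularity_cut(Z, A)
    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(gene)
    big = [c for c in clusters.values() if len(c) >= min_module_size]
    small = [g for c in clusters.values() if len(c) < min_module_size for g in c]
    if small:
        logger.info("detect_modules: %d genes in undersized clusters -> module 0",
                    len(small))
    big = _merge_close_modules(net, big, merge_cor)
    big.sort(key=lambda c: (-len(c), min(c)))
    module_of = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for mid, members in enumerate(big, start=1):
        module_of.loc[members] = mid
    return ModuleAssignment(module_of=module_of)
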