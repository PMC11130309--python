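"""Cell-level quality control, doublet flagging, demultiplexing, normalization.

The filtering thresholds are the study's published ones: cells with fewer
than 1000 detected genes or with more than 20% of UMIs from mitochondrial
genes are excluded (both read as strict inequalities, so boundary cells are
kept).  Doublet flagging is a simplified simulated-doublet nearest-neighbor
score with the two published Scrublet parameters (6% expected rate, 95th
percentile score cut); hashtag demultiplexing clusters the log-normalized
tag matrix with Leiden community detection at resolution 1.2 and assigns
only communities dominated by a single tag.

Pipeline order is fixed: filter -> doublets -> demux -> normalize -> HVG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "filter_cells",
    "flag_doublets",
    "demux_hashtags",
    "assign_tag_communities",
    "normalize_log",
    "select_hvg",
]

PIPELINE_ORDER = ("filter", "doublets", "demux", "normalize", "hvg")


@dataclass(frozen=True)
class QCThresholds:
    min_genes_detected: int = 1000
    max_mito_fraction: float = 0.20
    mito_gene_prefix: str = "mt-"
    expected_doublet_rate: float = 0.06
    doublet_score_percentile: float = 95.0
    min_umi: int | None = None  # optional extra UMI filter

    def __post_init__(self) -> None:
        if not 0.0 < self.max_mito_fraction < 1.0:
            raise ValueError("max_mito_fraction must lie in (0, 1)")
        if not 0.0 <= self.expected_doublet_rate < 0.5:
            raise ValueError("expected_doublet_rate must lie in [0, 0.5)")


@dataclass
class NormalizedMatrix:
    """log1p of size-normalized counts with an optional HVG mask."""

    values: sp.csr_matrix
    target_sum: float
    genes: pd.Index
    hvg_mask: np.ndarray | None = None


def _as_csr(counts) -> sp.csr_matrix:
    X = sp.csr_matrix(counts)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty count matrix")
    if X.nnz and X.data.min() < 0:
        raise ValueError("counts must be nonnegative")
    return X


def filter_cells(counts, genes, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Kept-cell mask: genes detected >= minimum AND mito fraction <= maximum.

    ``genes`` is the ordered gene-symbol sequence of the matrix columns;
    mitochondrial genes are recognized by prefix (case-insensitive).
    """
    thresholds = thresholds or QCThresholds()
    X = _as_csr(counts)
    genes = pd.Index(genes)
    if len(genes) != X.shape[1]:
        raise ValueError("gene list does not match matrix width")

    X.eliminate_zeros()
    detected = np.diff(X.indptr)
    mito = genes.str.lower().str.startswith(thresholds.mito_gene_prefix.lower())
    total = np.asarray(X.sum(axis=1)).ravel()
    if mito.any():
        mito_counts = np.asarray(X[:, np.flatnonzero(mito)].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            frac = np.divide(mito_counts, total, out=np.zeros_like(total, float),
                             where=total > 0)
        keep = (detected >= thresholds.min_genes_detected) & \
               (frac <= thresholds.max_mito_fraction)
    else:
        warnings.warn("no mitochondrial genes found; mito filter passes all cells")
        keep = detected >= thresholds.min_genes_detected
    if thresholds.min_umi is not None:
        keep &= total > thresholds.min_umi
    return keep


def flag_doublets(
    counts,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    n_hvg: int = 250,
    n_pcs: int = 15,
    n_neighbors: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated-doublet nearest-neighbor score and percentile flag.

    Simulated doublets (sums of random observed-cell pairs; pool size scales
    with the expected doublet rate) are embedded together with the observed
    cells in a common PCA space of log-normalized highly variable genes.
    Each observed cell's score is the fraction of its nearest neighbors that
    are simulated doublets; cells scoring strictly above the
    ``doublet_score_percentile`` of all observed scores are flagged.

    Returns ``(scores, flags)``.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    thresholds = thresholds or QCThresholds()
    Xs = _as_csr(counts)
    n = Xs.shape[0]
    if n < 100:
        raise ValueError("flag_doublets requires at least 100 cells")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0B]))
    # simulated-doublet pool: expected rate is the pool-size multiplier
    n_sim = max(300, int(round(n * thresholds.expected_doublet_rate * 5)))
    left = rng.integers(0, n, n_sim)
    right = rng.integers(0, n - 1, n_sim)
    right[right >= left] += 1

    libs = np.asarray(Xs.sum(axis=1)).ravel().astype(np.float32)
    if (libs == 0).any():
        raise ValueError("all-zero cells cannot be scored")

    # variance-ranked gene restriction on the library-normalized log counts
    norm = normalize_log(Xs)
    nv = norm.values
    mean = np.bincount(nv.indices, weights=nv.data, minlength=nv.shape[1]) / n
    sq = np.bincount(nv.indices, weights=nv.data.astype(np.float64) ** 2,
                     minlength=nv.shape[1]) / n
    var = np.maximum(sq - mean**2, 0.0)
    top = np.argsort(-var, kind="stable")[: min(n_hvg, Xs.shape[1])]

    obs = np.asarray(norm.values[:, top].todense(), dtype=np.float32)
    raw_top = np.asarray(Xs[:, top].todense(), dtype=np.float32)
    sim = raw_top[left] + raw_top[right]
    sim *= (1e4 / (libs[left] + libs[right]))[:, None]
    np.log1p(sim, out=sim)
    sub = np.concatenate([obs, sim], axis=0)

    svd = PCA(n_components=min(n_pcs, sub.shape[1] - 1),
              svd_solver="randomized", random_state=seed)
    emb = svd.fit_transform(sub)

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]  # drop self
    scores = (idx >= n).mean(axis=1)

    cut = np.percentile(scores, thresholds.doublet_score_percentile)
    flags = scores > cut
    return scores, flags


def demux_hashtags(
    hashtag_matrix,
    resolution: float = 1.2,
    dominance_fraction: float = 0.9,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Assign cells to hashtags via community detection on the tag matrix.

    Cells are clustered on log-normalized tag counts with Leiden communities
    at the given resolution; a community is assigned to tag ``t`` only when
    ``t`` is the argmax tag for at least ``dominance_fraction`` of its cells
    and no other tag dominates more than the complement.  Cells of ambiguous
    communities are returned as ``"unassigned"``.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    tags = pd.DataFrame(hashtag_matrix)
    if tags.shape[1] < 2:
        raise ValueError("demultiplexing requires at least 2 tags")
    M = tags.to_numpy(float)
    if (M < 0).any():
        raise ValueError("hashtag counts must be nonnegative")

    libs = M.sum(axis=1)
    libs[libs == 0] = 1.0
    logn = np.log1p(M / libs[:, None] * 100.0)

    k = min(n_neighbors, len(tags) - 1)
    adj = kneighbors_graph(logn, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=len(tags), edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    assignment = assign_tag_communities(M, membership, list(tags.columns),
                                        dominance_fraction)
    return pd.Series(assignment, index=tags.index, name="hashtag")


def assign_tag_communities(
    tag_counts: np.ndarray,
    membership: np.ndarray,
    tag_names: Sequence[str],
    dominance_fraction: float = 0.9,
) -> np.ndarray:
    """Community -> tag assignment by the exclusive-dominance rule.

    A community is assigned to the tag that is the per-cell argmax for at
    least ``dominance_fraction`` of its members, provided no second tag is
    argmax in more than the complement; otherwise all its cells are
    ``"unassigned"`` (e.g. a 50/50 split between two tags).
    """
    M = np.asarray(tag_counts)
    argmax_tag = M.argmax(axis=1)
    assignment = np.full(M.shape[0], "unassigned", object)
    for cl in np.unique(membership):
        cells = np.flatnonzero(membership == cl)
        frac = np.bincount(argmax_tag[cells], minlength=M.shape[1]) / cells.size
        order = np.argsort(-frac, kind="stable")
        if frac[order[0]] >= dominance_fraction and frac[order[1]] <= 1 - dominance_fraction:
            assignment[cells] = tag_names[order[0]]
    return assignment


def normalize_log(counts, genes=None, target_sum: float = 1e4) -> NormalizedMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p."""
    X = _as_csr(counts)
    libs = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(libs == 0)
    if zero.size:
        raise ValueError(f"all-zero cell(s) at row(s) {zero[:5].tolist()}; "
                         "run filter_cells first")
    # single-allocation scaling; indices/indptr are shared with the input
    data = X.data.astype(np.float32)
    data *= np.repeat((target_sum / libs).astype(np.float32),
                      np.diff(X.indptr))
    np.log1p(data, out=data)
    out = sp.csr_matrix((data, X.indices, X.indptr), shape=X.shape)
    if genes is None:
        genes = pd.RangeIndex(X.shape[1])
    return NormalizedMatrix(values=out, target_sum=float(target_sum),
                            genes=pd.Index(genes))


def select_hvg(normalized: NormalizedMatrix, n_top: int = 4000,
               n_bins: int = 20) -> np.ndarray:
    """Dispersion-ranked highly-variable-gene mask.

    Per-gene dispersion (variance/mean of the normalized values) is z-scored
    within bins of genes of similar mean expression; the top ``n_top`` genes
    by normalized dispersion are selected, with ties broken by gene symbol
    so the mask is fully deterministic.  Zero-variance genes are never
    selected.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    X = normalized.values
    if n_top > X.shape[1]:
        n_top = X.shape[1]
    n_cells, n_genes_total = X.shape
    mean = np.bincount(X.indices, weights=X.data,
                       minlength=n_genes_total) / n_cells
    sq = np.bincount(X.indices, weights=X.data.astype(np.float64) ** 2,
                     minlength=n_genes_total) / n_cells
    var = np.maximum(sq - mean**2, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    variable = var > 1e-12

    # bin by mean expression; z-score dispersion within bin
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), int)
    bins[order] = np.minimum(
        (np.arange(len(mean)) * n_bins) // max(len(mean), 1), n_bins - 1
    )
    zdisp = np.zeros(len(mean))
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            continue
        d = disp[members]
        sd = d.std()
        zdisp[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    symbols = np.asarray(normalized.genes.astype(str))
    candidates = np.flatnonzero(variable)
    n_sel = min(n_top, candidates.size)
    rank = np.lexsort((symbols[candidates], -zdisp[candidates]))
    chosen = candidates[rank[:n_sel]]
    mask = np.zeros(X.shape[1], bool)
    mask[chosen] = True
    return mask
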