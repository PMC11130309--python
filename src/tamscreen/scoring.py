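"""Rank-based signature scores, Z-ranks, pathway scores, pseudobulk correlation.

``ucell_like_score`` is a Mann-Whitney-U-based per-cell signature score:
within each cell, genes are ranked by expression (descending, mid-ranks for
ties), ranks are capped at ``r_max``, and

    U = sum(R_i) - n(n+1)/2,    score = max(0, 1 - U / (n * r_max))

so the score lies in [0, 1] and is invariant under any strictly monotone
transform of the cell's expression vector.  Signatures default to the top 3
differentially expressed genes per subcluster (Wilcoxon rank-sum vs rest).

``pathway_score`` is the binned-control expression score (mean of set genes
minus mean of expression-matched control genes), delegated to scanpy's
score_genes.  ``pseudobulk_correlation`` applies the study's significance
rule to per-sample profiles: Pearson r > 0.3 (strict) and p < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "ucell_like_score",
    "ucell_scores",
    "top_marker_genes",
    "score_rank_z",
    "pathway_score",
    "pseudobulk_profile",
    "pseudobulk_correlation",
]


def _rank_descending(values: np.ndarray) -> np.ndarray:
    """Mid-ranks of a vector ranked by descending value (rank 1 = largest)."""
    return stats.rankdata(-values, method="average")


def ucell_like_score(cell_expression, gene_set, genes=None, r_max: int = 1500) -> float:
    """Rank-based signature score of a single cell."""
    if isinstance(cell_expression, pd.Series):
        genes = cell_expression.index
        values = cell_expression.to_numpy(float)
    else:
        values = np.asarray(cell_expression, float).ravel()
        if genes is None:
            raise ValueError("gene symbols required alongside a bare vector")
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    index = pd.Index(genes)
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"signature gene(s) absent from universe: {missing}")

    ranks = np.minimum(_rank_descending(values), r_max)
    pos = index.get_indexer(gene_set)
    n = len(gene_set)
    u = ranks[pos].sum() - n * (n + 1) / 2
    return float(max(0.0, 1.0 - u / (n * r_max)))


def ucell_scores(matrix, genes, gene_set, r_max: int = 1500) -> np.ndarray:
    """Vectorized ucell_like_score over the rows of a cell x gene matrix."""
    X = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, float)
    index = pd.Index(genes)
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"signature gene(s) absent from universe: {missing}")
    pos = index.get_indexer(gene_set)
    n = len(gene_set)
    ranks = np.apply_along_axis(_rank_descending, 1, X)
    ranks = np.minimum(ranks, r_max)
    u = ranks[:, pos].sum(axis=1) - n * (n + 1) / 2
    return np.maximum(0.0, 1.0 - u / (n * r_max))


def top_marker_genes(
    normalized,
    genes,
    cluster_labels,
    n_top: int = 3,
) -> dict[str, list[str]]:
    """Top DEGs per cluster by Wilcoxon rank-sum vs the rest.

    Genes are ranked by the signed standardized statistic, descending; ties
    are broken by gene symbol so signatures are reproducible.
    """
    import scanpy as sc
    import anndata as ad

    X = sp.csr_matrix(normalized)
    adata = ad.AnnData(X=X, var=pd.DataFrame(index=pd.Index(genes)))
    adata.obs["cluster"] = pd.Categorical(np.asarray(cluster_labels, dtype=object))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(adata, "cluster", method="wilcoxon", n_genes=X.shape[1])
    out: dict[str, list[str]] = {}
    res = adata.uns["rank_genes_groups"]
    for group in res["names"].dtype.names:
        names = np.asarray(res["names"][group])
        scores = np.asarray(res["scores"][group], float)
        order = np.lexsort((names, -scores))
        out[group] = [str(n) for n in names[order[:n_top]]]
    return out


def score_rank_z(
    scores: pd.Series,
    subcluster_labels: pd.Series,
    sample_labels: pd.Series,
) -> pd.DataFrame:
    """Within-sample Z-standardization of subcluster mean scores.

    For each sample, subcluster mean signature scores are standardized to
    mean 0 / sd 1 across that sample's subclusters.  Samples with a single
    subcluster yield NaN and are flagged.
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, float),
        "subcluster": np.asarray(subcluster_labels, dtype=object),
        "sample": np.asarray(sample_labels, dtype=object),
    })
    means = df.groupby(["sample", "subcluster"], sort=True)["score"].mean().unstack()
    z = means.sub(means.mean(axis=1), axis=0).div(means.std(axis=1, ddof=0), axis=0)
    single = means.notna().sum(axis=1) < 2
    if single.any():
        warnings.warn(
            f"sample(s) {list(means.index[single])} have a single subcluster; Z undefined"
        )
        z.loc[single] = np.nan
    return z


def pathway_score(
    normalized,
    genes,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control pathway score per cell (scanpy score_genes)."""
    import scanpy as sc
    import anndata as ad

    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    adata = ad.AnnData(
        X=sp.csr_matrix(normalized), var=pd.DataFrame(index=pd.Index(genes))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.score_genes(
            adata, gene_set, score_name="score",
            ctrl_size=n_ctrl, n_bins=n_bins, random_state=seed,
        )
    return adata.obs["score"].to_numpy(float)


def pseudobulk_profile(
    normalized,
    genes,
    sample_labels,
    subset_mask=None,
    variables: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-sample mean expression of selected genes over a stated cell subset.

    ``variables`` adds precomputed per-cell quantities (e.g. pathway scores)
    averaged over the same subset.
    """
    X = sp.csr_matrix(normalized)
    samples = pd.Series(np.asarray(sample_labels, dtype=object), name="sample")
    if subset_mask is None:
        subset_mask = np.ones(X.shape[0], bool)
    subset_mask = np.asarray(subset_mask, bool)
    dense = np.asarray(X[subset_mask].todense())
    sub_samples = samples[subset_mask]
    frame = pd.DataFrame(dense, columns=pd.Index(genes), index=sub_samples.index)
    frame["sample"] = sub_samples.to_numpy()
    prof = frame.groupby("sample", sort=True).mean()
    if variables:
        extra = pd.DataFrame(
            {k: np.asarray(v, float)[subset_mask] for k, v in variables.items()}
        )
        extra["sample"] = sub_samples.to_numpy()
        prof = prof.join(extra.groupby("sample", sort=True).mean())
    prof.attrs["subset_cells"] = int(subset_mask.sum())
    return prof


def pseudobulk_correlation(
    profiles: pd.DataFrame,
    variables: list[str] | None = None,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    signed: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation with the study's significance rule.

    Returns (r, p, significant) matrices.  p comes from the exact t
    transform t = r sqrt(n-2) / sqrt(1 - r^2) against t(n-2), two-sided.
    Significance requires r strictly above ``r_threshold`` (or |r| above,
    with ``signed=False``) AND p < ``p_threshold``.  Zero-variance
    variables give NaN r and are never significant.
    """
    cols = variables or list(profiles.columns)
    if len(profiles) < 4:
        raise ValueError("pseudobulk correlation needs at least 4 samples")
    data = profiles[cols].to_numpy(float)
    n = data.shape[0]
    sd = data.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance variable(s): {[c for c, d in zip(cols, degenerate) if d]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        tstat = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    effect = r_df if signed else r_df.abs()
    sig = (effect > r_threshold) & (p_df < p_threshold) & r_df.notna()
    return r_df, p_df, sig
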