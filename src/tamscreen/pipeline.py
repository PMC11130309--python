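"""End-to-end discordance screen on a replicated single-cell experiment.

Stages, in the fixed QC order: cell filtering -> doublet flagging ->
normalization -> HVG selection -> expression clustering (a thin PCA+KMeans
plumbing step; cluster labels are otherwise an input) -> marker-rule
annotation -> per-sample ligand-receptor interaction calling -> the
replicate-pairwise interaction count for the treated-vs-vehicle contrast of
each tumor model -> the discordance screen (units up in the resistant
contrast, down in the sensitive one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import annotate, diffcount, interactions, qc
from .simulate import SyntheticExperiment, arm_key

logger = logging.getLogger("tamscreen.pipeline")

__all__ = [
    "PipelineOptions",
    "AnnotatedExperiment",
    "ScreenResult",
    "cluster_expression",
    "annotate_experiment",
    "run_discordance_screen",
]


@dataclass
class PipelineOptions:
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    n_hvg: int = 4000
    n_hvg_clustering: int = 300
    n_clusters: int = 25
    n_pcs: int = 30
    n_perm: int = 300
    alpha: float = 0.05
    min_magnitude: int | None = None  # default: ceil(0.75 * a * b)
    trim: float = 0.10
    min_fraction: float = 0.10
    # communication axes of interest: tumor <-> myeloid by default
    type_pairs: list[tuple[str, str]] | None = None


@dataclass
class AnnotatedExperiment:
    """QC-passing cells with normalized expression and predicted labels."""

    normalized: qc.NormalizedMatrix
    cell_meta: pd.DataFrame      # sample, arm, cluster, lineage, subtype, label
    genes: pd.Index
    qc_mask: np.ndarray          # over the original experiment's cells
    doublet_flags: np.ndarray    # over QC-passing cells


@dataclass
class ScreenResult:
    annotated: AnnotatedExperiment
    interaction_tables: dict[str, pd.DataFrame]
    count_sensitive: diffcount.InteractionCountResult
    count_resistant: diffcount.InteractionCountResult
    screen: pd.DataFrame

    @property
    def hits(self) -> list[tuple[str, str, str]]:
        return [tuple(u) for u in self.screen.index]


def cluster_expression(
    normalized: qc.NormalizedMatrix,
    n_clusters: int = 30,
    n_pcs: int = 25,
    n_hvg: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Plumbing cluster labels: PCA of scaled HVG expression + KMeans.

    Expression graph-clustering internals are not part of this package's
    contribution; any externally supplied label vector can be used in its
    place throughout the pipeline.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    mask = qc.select_hvg(normalized, n_top=n_hvg)
    X = np.asarray(normalized.values[:, np.flatnonzero(mask)].todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    n_pcs = min(n_pcs, X.shape[1] - 1, X.shape[0] - 1)
    emb = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=min(n_clusters, X.shape[0]), n_init=3,
                random_state=seed)
    return km.fit_predict(emb)


def _cluster_profiles(normalized: qc.NormalizedMatrix, clusters: np.ndarray,
                      genes: pd.Index) -> pd.DataFrame:
    ids, inv = np.unique(clusters, return_inverse=True)
    onehot = sp.csr_matrix(
        (np.ones(len(inv), np.float32), (inv, np.arange(len(inv)))),
        shape=(len(ids), len(inv)),
    )
    sums = np.asarray((onehot @ normalized.values).todense())
    sizes = np.bincount(inv, minlength=len(ids))[:, None]
    return pd.DataFrame(sums / sizes, index=pd.Index(ids, name="cluster"),
                        columns=genes)


#: compartments re-clustered at finer grain before final annotation, the way
#: T and myeloid populations are conventionally re-clustered in scRNA-seq
_REFINED_COMPARTMENTS: dict[str, tuple[str, ...]] = {
    "T": ("Tcm", "Treg", "CD8_naive", "T_prolif"),
    "myeloid": (annotate.MYELOID_LABEL,),
}


def _refine_clusters(
    normalized: qc.NormalizedMatrix,
    clusters: np.ndarray,
    lineages: pd.Series,
    seed: int,
) -> np.ndarray:
    """Sub-cluster the T and myeloid compartments of a coarse clustering."""
    refined = np.asarray(clusters, int).copy()
    next_id = refined.max() + 1
    for name, labels in _REFINED_COMPARTMENTS.items():
        members = [c for c in lineages.index if lineages.at[c] in labels]
        cells = np.flatnonzero(np.isin(refined, members))
        if cells.size < 100:
            continue
        sub_norm = qc.NormalizedMatrix(
            values=normalized.values[cells],
            target_sum=normalized.target_sum,
            genes=normalized.genes,
        )
        k = max(2, min(10, cells.size // 150))
        sub = cluster_expression(sub_norm, n_clusters=k, seed=seed)
        refined[cells] = next_id + sub
        next_id += k
    return refined


def annotate_experiment(
    normalized: qc.NormalizedMatrix,
    clusters: np.ndarray,
    genes: pd.Index,
    malignant_mask: np.ndarray | None = None,
    lineage_rules: annotate.MarkerRuleSet | None = None,
    refine: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-level lineage + myeloid subtype annotation, per cell.

    ``malignant_mask`` marks cells known to be malignant (ground truth in
    synthetic data, or a user-supplied CNV-based mask); a cluster whose
    cells are mostly masked is labeled malignant before the marker rules
    apply.  With ``refine=True`` the T and myeloid compartments of the
    coarse clustering are sub-clustered before the final rule pass, which
    resolves closely related subpopulations that share lineage markers.
    Returns a frame with cluster / lineage / subtype / label / c5ar1_class
    columns.
    """
    profiles = _cluster_profiles(normalized, clusters, genes)
    lineages = annotate.assign_lineage(profiles, lineage_rules)

    if refine:
        clusters = _refine_clusters(normalized, clusters, lineages, seed)
        profiles = _cluster_profiles(normalized, clusters, genes)
        lineages = annotate.assign_lineage(profiles, lineage_rules)

    if malignant_mask is not None:
        malignant_mask = np.asarray(malignant_mask, bool)
        for c in profiles.index:
            cells = clusters == c
            if malignant_mask[cells].mean() > 0.5:
                lineages.at[c] = "malignant"

    cell_lineage = pd.Series(lineages.loc[clusters].to_numpy(object))

    # myeloid subtyping on myeloid clusters only
    myeloid_clusters = [c for c in profiles.index
                        if lineages.at[c] == annotate.MYELOID_LABEL]
    subtype = pd.Series("non-myeloid", index=cell_lineage.index, dtype=object)
    if myeloid_clusters:
        sub_labels = annotate.subtype_myeloid(profiles.loc[myeloid_clusters])
        for c in myeloid_clusters:
            subtype[clusters == c] = sub_labels.at[c]

    label = cell_lineage.where(cell_lineage != annotate.MYELOID_LABEL, subtype)

    # C5ar1 split of TAM_C3 cells (per-cell detection on normalized values)
    c5ar1_class = pd.Series("n/a", index=cell_lineage.index, dtype=object)
    if "C5ar1" in genes:
        tam3 = np.flatnonzero(label.to_numpy() == "TAM_C3")
        if tam3.size:
            vals = pd.Series(
                np.asarray(
                    normalized.values[tam3, genes.get_loc("C5ar1")].todense()
                ).ravel(),
                index=tam3,
            )
            c5ar1_class.iloc[tam3] = annotate.split_c5ar1(vals).to_numpy()

    return pd.DataFrame({
        "cluster": clusters,
        "lineage": cell_lineage.to_numpy(object),
        "subtype": subtype.to_numpy(object),
        "label": label.to_numpy(object),
        "c5ar1_class": c5ar1_class.to_numpy(object),
    })


def prepare_experiment(
    experiment: SyntheticExperiment,
    options: PipelineOptions | None = None,
    seed: int = 0,
    use_truth_malignant: bool = True,
) -> AnnotatedExperiment:
    """QC, normalization and annotation of a (synthetic) experiment."""
    options = options or PipelineOptions()
    logger.info("pipeline order: %s", " -> ".join(qc.PIPELINE_ORDER))

    keep = qc.filter_cells(experiment.counts, experiment.genes,
                           options.qc_thresholds)
    counts = experiment.counts[np.flatnonzero(keep)]
    meta = experiment.cell_meta.loc[keep].copy()

    _, doublet_flag = qc.flag_doublets(counts, options.qc_thresholds, seed=seed)
    counts = counts[np.flatnonzero(~doublet_flag)]
    meta = meta.loc[~doublet_flag].copy()

    normalized = qc.normalize_log(counts, genes=experiment.genes)
    normalized.hvg_mask = qc.select_hvg(normalized, n_top=options.n_hvg)

    clusters = cluster_expression(
        normalized, n_clusters=options.n_clusters, n_pcs=options.n_pcs,
        n_hvg=options.n_hvg_clustering, seed=seed,
    )
    malignant = (
        (meta["cell_type"] == "malignant").to_numpy()
        if use_truth_malignant and "cell_type" in meta else None
    )
    ann = annotate_experiment(normalized, clusters, pd.Index(experiment.genes),
                              malignant_mask=malignant, seed=seed)
    ann.index = meta.index
    meta = pd.concat([meta, ann], axis=1)
    return AnnotatedExperiment(
        normalized=normalized, cell_meta=meta,
        genes=pd.Index(experiment.genes),
        qc_mask=keep, doublet_flags=doublet_flag,
    )


def run_discordance_screen(
    experiment: SyntheticExperiment,
    options: PipelineOptions | None = None,
    lr_db: pd.DataFrame | None = None,
    seed: int = 0,
) -> ScreenResult:
    """The full screen for interactions up in resistant / down in sensitive.

    For each tumor model the treated samples (condition A) are compared
    with the vehicle samples (condition B) over all a x b replicate pairs;
    the screen returns units whose interaction count is at least
    +min_magnitude in the resistant contrast and at most -min_magnitude in
    the sensitive one.
    """
    options = options or PipelineOptions()
    lr_db = lr_db if lr_db is not None else interactions.load_lr_database()
    prepared = prepare_experiment(experiment, options, seed=seed)
    meta = prepared.cell_meta

    type_pairs = options.type_pairs
    if type_pairs is None:
        myeloid = list(annotate.TAM_SUBTYPES) + list(annotate.MONO_SUBTYPES)
        type_pairs = [("malignant", m) for m in myeloid]
        type_pairs += [(m, "malignant") for m in myeloid]

    tables: dict[str, pd.DataFrame] = {}
    for i, sample in enumerate(dict.fromkeys(meta["sample"])):
        cells = np.flatnonzero((meta["sample"] == sample).to_numpy())
        tables[sample] = interactions.call_interactions(
            prepared.normalized.values[cells],
            prepared.genes,
            meta["label"].to_numpy(object)[cells],
            lr_db,
            sample_id=sample,
            alpha=options.alpha,
            n_perm=options.n_perm,
            min_fraction=options.min_fraction,
            trim=options.trim,
            seed=seed * 1000003 + i,
            type_pairs=type_pairs,
        )

    sample_arm = meta.groupby("sample", sort=False)["arm"].first()

    def contrast(model: str) -> diffcount.InteractionCountResult:
        treated = [s for s, a in sample_arm.items() if a == arm_key(model, "treated")]
        vehicle = [s for s, a in sample_arm.items() if a == arm_key(model, "vehicle")]
        design = diffcount.ComparisonDesign(tuple(treated), tuple(vehicle))
        return diffcount.interaction_count(
            [tables[s] for s in treated], [tables[s] for s in vehicle], design
        )

    count_res = contrast("resistant")
    count_sen = contrast("sensitive")
    min_mag = options.min_magnitude
    if min_mag is None:
        min_mag = int(np.ceil(0.75 * count_res.design.a * count_res.design.b))
    screen = diffcount.screen_discordant(count_sen, count_res, min_mag)
    return ScreenResult(
        annotated=prepared,
        interaction_tables=tables,
        count_sensitive=count_sen,
        count_resistant=count_res,
        screen=screen,
    )
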