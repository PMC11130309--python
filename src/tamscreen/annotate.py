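"""Marker-rule cell annotation: lineages, myeloid subtypes, C5ar1 split.

Lineage assignment follows an ordered rule table (first match wins): a
cluster matches a rule when all of the rule's required-high markers are
"expressed" and required-low markers are not.  "Expressed" is decided at
cluster level by default — the cluster's mean normalized expression,
z-scored across clusters, exceeds a threshold — with a per-cell detected
(> 0) mode available.  Myeloid cells are further subtyped by the
characteristic DEG pairs of the TAM/monocyte subclusters (Hexb/Gatm ->
TAM_C0, Il1b/Rgs1 -> TAM_C1, Mrc1/Pf4 -> TAM_C3, Lsp1/Napsa -> TAM_C4,
S100a6/S100a10 -> Mono_C2, Cebpb/Mcl1 -> Mono_C5), with the monocyte vs
macrophage branch decided by relative Cd14 vs Cd68 expression.  TAM_C3 is
split into C5ar1-high and C5ar1-low populations.

Annotation is a pure function of expression and rules; there is no
randomness anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerRule",
    "MarkerRuleSet",
    "AnnotationResult",
    "default_lineage_rules",
    "default_subtype_rules",
    "assign_lineage",
    "subtype_myeloid",
    "split_c5ar1",
    "composition_table",
    "build_annotation_result",
]

MYELOID_LABEL = "monocyte/macrophage"
TAM_SUBTYPES = ("TAM_C0", "TAM_C1", "TAM_C3", "TAM_C4")
MONO_SUBTYPES = ("Mono_C2", "Mono_C5")


@dataclass(frozen=True)
class MarkerRule:
    label: str
    high: tuple[str, ...]
    low: tuple[str, ...] = ()


@dataclass
class MarkerRuleSet:
    """Ordered marker rules plus the expression-threshold mode."""

    rules: Sequence[MarkerRule]
    mode: Literal["cluster_z", "detected"] = "cluster_z"
    z_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty rule set")
        labels = [r.label for r in self.rules]
        # duplicate labels are allowed only as alternative routes to the
        # same label (e.g. fibroblast via Dcn OR Acta2)
        seen: dict[str, None] = {}
        for lab in labels:
            seen[lab] = None
        self.labels = list(seen)


def default_lineage_rules() -> MarkerRuleSet:
    """The study's lineage rule table, in its stated order."""
    return MarkerRuleSet(rules=(
        MarkerRule("Tcm", ("Ptprc", "Cd3e", "Cd4", "Tcf7")),
        MarkerRule("Treg", ("Ptprc", "Cd3e", "Cd4", "Foxp3")),
        MarkerRule("CD8_naive", ("Ptprc", "Cd3e", "Cd8a", "Ccr7")),
        MarkerRule("T_prolif", ("Ptprc", "Cd3e", "Mki67")),
        MarkerRule("NK", ("Ptprc", "Ncr1", "Nkg7")),
        MarkerRule("B", ("Cd79a", "Cd19")),
        MarkerRule("pDC", ("Clec10a", "Siglech", "Cd300c")),
        MarkerRule("fibroblast", ("Dcn",)),
        MarkerRule("fibroblast", ("Acta2",)),
        MarkerRule("endothelial", ("Epas1",)),
        MarkerRule(MYELOID_LABEL, ("Itgam", "Cd14", "Adgre1")),
    ))


def default_subtype_rules() -> dict[str, tuple[str, ...]]:
    """Characteristic DEG pair per myeloid subcluster."""
    return {
        "TAM_C0": ("Hexb", "Gatm"),
        "TAM_C1": ("Il1b", "Rgs1"),
        "TAM_C3": ("Mrc1", "Pf4"),
        "TAM_C4": ("Lsp1", "Napsa"),
        "Mono_C2": ("S100a6", "S100a10"),
        "Mono_C5": ("Cebpb", "Mcl1"),
    }


@dataclass
class AnnotationResult:
    """Per-cell labels plus per-sample composition."""

    cells: pd.DataFrame        # lineage, subtype, c5ar1_class per cell
    composition: pd.DataFrame  # samples x labels fractions


def _expressed_matrix(profiles: pd.DataFrame, ruleset: MarkerRuleSet) -> pd.DataFrame:
    """Boolean clusters/cells x genes matrix of the 'expressed' relation."""
    if ruleset.mode == "detected":
        return profiles > 0
    mean = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    z = (profiles - mean).div(sd.where(sd > 0, 1.0), axis=1)
    return (z > ruleset.z_threshold) & (profiles > 0)


def assign_lineage(
    cluster_profiles: pd.DataFrame,
    rules: MarkerRuleSet | None = None,
) -> pd.Series:
    """First-match lineage label per cluster (rows of ``cluster_profiles``).

    ``cluster_profiles`` holds mean normalized expression per cluster.  A
    rule whose high-marker is absent from the gene universe is inert and is
    skipped with a warning.
    """
    rules = rules or default_lineage_rules()
    genes = set(cluster_profiles.columns)
    usable: list[MarkerRule] = []
    for rule in rules.rules:
        missing = [g for g in rule.high if g not in genes]
        if missing:
            warnings.warn(
                f"rule {rule.label!r} inert: marker(s) {missing} absent from universe"
            )
            continue
        usable.append(rule)
    if not usable:
        raise ValueError("no usable rules for this gene universe")

    expressed = _expressed_matrix(cluster_profiles, rules)
    labels = pd.Series("unassigned", index=cluster_profiles.index, dtype=object)
    for idx in cluster_profiles.index:
        for rule in usable:
            ok_high = all(bool(expressed.at[idx, g]) for g in rule.high)
            ok_low = all(
                g not in genes or not bool(expressed.at[idx, g]) for g in rule.low
            )
            if ok_high and ok_low:
                labels.at[idx] = rule.label
                break
    return labels


def subtype_myeloid(
    myeloid_profiles: pd.DataFrame,
    subtype_rules: dict[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """Subtype label per myeloid cluster (or cell) from DEG-pair scores.

    Within the myeloid compartment, expression is z-scored across the
    provided rows; each row is first branched into monocyte (higher Cd14)
    or macrophage (higher Cd68), then assigned the branch subtype whose DEG
    pair has the highest mean z-score, ties broken by label.  All-zero rows
    are "unassigned".
    """
    if len(myeloid_profiles) == 0:
        raise ValueError("empty myeloid set")
    subtype_rules = subtype_rules or default_subtype_rules()
    genes = set(myeloid_profiles.columns)
    needed = {g for pair in subtype_rules.values() for g in pair} | {"Cd14", "Cd68"}
    missing = needed - genes
    if missing:
        raise ValueError(f"myeloid subtype markers absent from universe: {sorted(missing)}")

    X = myeloid_profiles
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    z = (X - mean).div(sd.where(sd > 0, 1.0), axis=1)

    labels = pd.Series("unassigned", index=X.index, dtype=object)
    nonzero = X.sum(axis=1) > 0
    mono_branch = z["Cd14"] > z["Cd68"]
    for idx in X.index:
        if not nonzero.at[idx]:
            continue
        branch = MONO_SUBTYPES if mono_branch.at[idx] else TAM_SUBTYPES
        scores = {
            lab: float(np.mean([z.at[idx, g] for g in subtype_rules[lab]]))
            for lab in branch
        }
        labels.at[idx] = min(scores, key=lambda lab: (-scores[lab], lab))
    return labels


def split_c5ar1(
    tam_c3_expression: pd.DataFrame | pd.Series,
    gene: str = "C5ar1",
    threshold_mode: Literal["detected", "median"] = "detected",
) -> pd.Series:
    """Classify TAM_C3 cells as C5ar1 hi/lo.

    Default rule: hi iff the gene is detected (> 0).  ``median`` mode splits
    at the median (strictly above -> hi).
    """
    if isinstance(tam_c3_expression, pd.DataFrame):
        if gene not in tam_c3_expression.columns:
            raise ValueError(f"{gene} absent from gene universe")
        values = tam_c3_expression[gene]
    else:
        values = tam_c3_expression
    if threshold_mode == "detected":
        hi = values > 0
    elif threshold_mode == "median":
        hi = values > values.median()
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return pd.Series(np.where(hi, "hi", "lo"), index=values.index, name="c5ar1_class")


def composition_table(
    cell_labels: pd.DataFrame,
    group_by: str = "sample",
    label_col: str = "label",
) -> pd.DataFrame:
    """Per-sample label fractions (each row sums to 1)."""
    if cell_labels.groupby(group_by).size().min() < 1:
        raise ValueError("every sample needs at least one labeled cell")
    counts = pd.crosstab(cell_labels[group_by], cell_labels[label_col])
    return counts.div(counts.sum(axis=1), axis=0)


def build_annotation_result(
    cell_labels: pd.DataFrame,
    group_by: str = "sample",
    label_col: str = "label",
) -> AnnotationResult:
    """Bundle per-cell labels with their per-sample composition table."""
    return AnnotationResult(
        cells=cell_labels,
        composition=composition_table(cell_labels, group_by, label_col),
    )


def label_ratio(
    composition: pd.DataFrame, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-sample ratio of two label fractions; zero denominators give +inf
    with a ``degenerate`` flag rather than an error."""
    num = composition.get(numerator, pd.Series(0.0, index=composition.index))
    den = composition.get(denominator, pd.Series(0.0, index=composition.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return pd.DataFrame({
        "ratio": ratio,
        "degenerate": np.asarray(den) == 0,
    }, index=composition.index)
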