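"""Synthetic single-cell experiments and patient cohorts.

This module generates data with the statistical structure the downstream
analysis assumes: a 2-model x 2-treatment replicated tumor design
(PARPi-sensitive and PARPi-resistant models, vehicle or PARPi treated),
a malignant + myeloid + lymphoid cell-type mixture with rule-compatible
marker genes, a planted malignant->TAM ligand-receptor program whose
strength is condition dependent, and patient cohorts whose survival hazard
and response probability depend on a myeloid-ratio covariate.

Counts follow a negative-binomial model: cell ``c`` of type ``t`` in arm
``a`` has gene-``g`` mean proportional to

    base_share(g) * marker_multiplier(t, g) * program_multiplier(a, t, g)

renormalized within the cell and scaled to a log-normal library size.
Doublets are sums of two generated cells of the same sample. Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PlantedProgram",
    "BimodalMarker",
    "SimulationConfig",
    "SyntheticExperiment",
    "CohortParams",
    "SyntheticCohort",
    "default_config",
    "generate_experiment",
    "generate_hashtags",
    "generate_cohort",
    "load_experiment_tables",
    "MITO_GENES",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedProgram:
    """A condition-dependent ligand->receptor program.

    ``strength_by_arm`` multiplies the ligand gene's mean in sender cells and
    the receptor gene's mean in receiver cells, per arm.  Differential
    behaviour across conditions ("up in resistant contrasts, down in
    sensitive contrasts") is encoded purely through these multipliers.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    strength_by_arm: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.ligand == self.receptor:
            raise ConfigurationError("planted program ligand must differ from receptor")
        for arm, s in self.strength_by_arm.items():
            if s < 0:
                raise ConfigurationError(f"negative program strength for arm {arm!r}")


@dataclass(frozen=True)
class BimodalMarker:
    """A marker expressed by only a fraction of cells of one type.

    Emulates the C5ar1-high / C5ar1-low dichotomy inside TAM_C3: a fraction
    ``fraction_hi`` of cells of the type carry ``multiplier`` on the gene's
    mean, the rest stay at baseline.
    """

    gene: str
    fraction_hi: float
    multiplier: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_hi <= 1.0:
            raise ConfigurationError("fraction_hi must lie in [0, 1]")
        if self.multiplier <= 0:
            raise ConfigurationError("bimodal marker multiplier must be positive")


MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2",
    "mt-Co3", "mt-Atp6", "mt-Cytb", "mt-Nd4",
)

#: named genes with fixed baseline relative-expression shares; everything the
#: marker rules, LR database and QC need lives here.  Filler genes make up the
#: rest of the universe with log-normal shares.
_NAMED_GENE_SHARES: dict[str, float] = {
    # abundant housekeeping ligand (ribosomal protein S19)
    "Rps19": 4e-3,
    # rare receptor; near-silent outside its planted population
    "C5ar1": 1.6e-6,
    # pan-immune / lineage markers
    "Ptprc": 1.2e-4, "Cd3e": 1.2e-4, "Cd4": 1.2e-4, "Tcf7": 1.2e-4,
    "Foxp3": 1.2e-4, "Cd8a": 1.2e-4, "Ccr7": 1.2e-4, "Mki67": 1.2e-4,
    "Ncr1": 1.2e-4, "Nkg7": 1.2e-4, "Cd79a": 1.2e-4, "Cd19": 1.2e-4,
    "Clec10a": 1.2e-4, "Siglech": 1.2e-4, "Cd300c": 1.2e-4,
    "Dcn": 1.2e-4, "Acta2": 1.2e-4, "Col1a1": 1.2e-4,
    "Epas1": 1.2e-4, "Pecam1": 1.2e-4,
    "Krt8": 1.2e-4, "Krt18": 1.2e-4, "Epcam": 1.2e-4,
    # myeloid lineage and subtype markers
    "Itgam": 1.2e-4, "Cd14": 1.2e-4, "Adgre1": 1.2e-4, "Cd68": 1.2e-4,
    "Hexb": 1.2e-4, "Gatm": 1.2e-4, "Il1b": 1.2e-4, "Rgs1": 1.2e-4,
    "Mrc1": 1.2e-4, "Pf4": 1.2e-4, "Lsp1": 1.2e-4, "Napsa": 1.2e-4,
    "S100a6": 1.2e-4, "S100a10": 1.2e-4, "Cebpb": 1.2e-4, "Mcl1": 1.2e-4,
    "Msr1": 1.2e-4, "Il10": 1.2e-4,
    # ligand / receptor genes of the curated LR table
    "Csf1": 8e-5, "Csf1r": 8e-5, "Cx3cl1": 8e-5, "Cx3cr1": 8e-5,
    "Ccl7": 8e-5, "Ccr2": 8e-5, "Cxcl16": 8e-5, "Cxcr6": 8e-5,
    "Cd86": 8e-5, "Cd28": 8e-5, "Tnf": 8e-5, "Tnfrsf1b": 8e-5,
    "Itgb2": 8e-5, "Cd226": 8e-5, "Lgals9": 8e-5, "Il34": 8e-5,
    "App": 8e-5, "Mif": 8e-5, "Cd74": 2e-4,
}

#: combined mitochondrial share of a healthy cell's library (~5%)
_MITO_TOTAL_SHARE = 0.05


def _t_cell(extra: dict[str, float]) -> dict[str, float]:
    base = {"Ptprc": 10.0, "Cd3e": 25.0, "Cxcr6": 10.0, "Cd28": 12.0}
    base.update(extra)
    return base


def _tam(extra: dict[str, float]) -> dict[str, float]:
    base = {
        "Ptprc": 8.0, "Itgam": 15.0, "Adgre1": 20.0, "Cd68": 25.0,
        "Cd14": 6.0, "Csf1r": 15.0, "Tnfrsf1b": 8.0, "Itgb2": 8.0,
        "Cd74": 15.0,
    }
    base.update(extra)
    return base


def _mono(extra: dict[str, float]) -> dict[str, float]:
    base = {
        "Ptprc": 8.0, "Itgam": 15.0, "Adgre1": 8.0, "Cd14": 25.0,
        "Cd68": 6.0, "Csf1r": 10.0, "Ccr2": 15.0, "Itgb2": 8.0,
    }
    base.update(extra)
    return base


def default_marker_table() -> dict[str, dict[str, float]]:
    """Mean-expression multipliers per cell type, mirroring the marker rules."""
    return {
        "malignant": {"Krt8": 25.0, "Krt18": 25.0, "Epcam": 25.0, "Rps19": 3.0,
                      "Lgals9": 8.0, "Il34": 12.0, "App": 10.0, "Mif": 10.0,
                      "Csf1": 10.0},
        "TAM_C0": _tam({"Hexb": 30.0, "Gatm": 30.0, "Cx3cr1": 15.0}),
        "TAM_C1": _tam({"Il1b": 30.0, "Rgs1": 30.0, "Cxcl16": 15.0,
                        "Cd86": 12.0, "Tnf": 10.0, "Ccl7": 10.0}),
        "TAM_C3": _tam({"Mrc1": 30.0, "Pf4": 30.0, "Msr1": 20.0, "Il10": 15.0}),
        "TAM_C4": _tam({"Lsp1": 30.0, "Napsa": 30.0, "Adgre1": 8.0}),
        "Mono_C2": _mono({"S100a6": 30.0, "S100a10": 30.0}),
        "Mono_C5": _mono({"Cebpb": 30.0, "Mcl1": 30.0}),
        "T_cm": _t_cell({"Cd4": 20.0, "Tcf7": 30.0}),
        "T_reg": _t_cell({"Cd4": 20.0, "Foxp3": 30.0}),
        "CD8_naive": _t_cell({"Cd8a": 25.0, "Ccr7": 30.0}),
        "T_prolif": _t_cell({"Mki67": 30.0}),
        "NK": {"Ptprc": 10.0, "Ncr1": 30.0, "Nkg7": 30.0, "Itgb2": 10.0,
               "Cd226": 12.0, "Tnf": 8.0},
        "B": {"Ptprc": 10.0, "Cd79a": 30.0, "Cd19": 30.0, "Cd74": 20.0},
        "pDC": {"Ptprc": 10.0, "Clec10a": 30.0, "Siglech": 30.0, "Cd300c": 30.0,
                "Cd74": 15.0},
        "fibroblast": {"Dcn": 40.0, "Acta2": 25.0, "Col1a1": 30.0,
                       "Ccl7": 15.0, "Csf1": 8.0},
        "endothelial": {"Epas1": 30.0, "Pecam1": 30.0, "Cx3cl1": 20.0},
    }


_SENSITIVE_FRACTIONS = {
    "malignant": 0.40, "TAM_C0": 0.07, "TAM_C1": 0.08, "TAM_C3": 0.06,
    "TAM_C4": 0.03, "Mono_C2": 0.04, "Mono_C5": 0.03, "T_cm": 0.05,
    "T_reg": 0.04, "CD8_naive": 0.05, "T_prolif": 0.02, "NK": 0.04,
    "B": 0.04, "pDC": 0.02, "fibroblast": 0.02, "endothelial": 0.01,
}
_RESISTANT_FRACTIONS = {
    "malignant": 0.40, "TAM_C0": 0.05, "TAM_C1": 0.05, "TAM_C3": 0.12,
    "TAM_C4": 0.03, "Mono_C2": 0.06, "Mono_C5": 0.04, "T_cm": 0.04,
    "T_reg": 0.04, "CD8_naive": 0.04, "T_prolif": 0.02, "NK": 0.03,
    "B": 0.04, "pDC": 0.02, "fibroblast": 0.01, "endothelial": 0.01,
}

ARMS = (
    ("sensitive", "vehicle"),
    ("sensitive", "treated"),
    ("resistant", "vehicle"),
    ("resistant", "treated"),
)


def arm_key(model: str, treatment: str) -> str:
    return f"{model}:{treatment}"


def default_planted_program(null: bool = False) -> PlantedProgram:
    """The study's discordant program: malignant Rps19 -> TAM_C3 C5ar1.

    The program is "on" (strength 1.0, receptor detectable in TAM_C3) in the
    resistant-treated and sensitive-vehicle arms and suppressed elsewhere, so
    treated-vs-vehicle contrasts see it go up in the resistant model and down
    in the sensitive model.  With ``null=True`` every arm has strength 1.0,
    removing the differential while keeping the interaction present.
    """
    if null:
        strengths = {arm_key(m, t): 1.0 for m, t in ARMS}
    else:
        strengths = {
            arm_key("resistant", "treated"): 1.0,
            arm_key("resistant", "vehicle"): 0.005,
            arm_key("sensitive", "vehicle"): 1.0,
            arm_key("sensitive", "treated"): 0.005,
        }
    return PlantedProgram(
        ligand="Rps19", receptor="C5ar1",
        sender="malignant", receiver="TAM_C3",
        strength_by_arm=strengths,
    )


@dataclass
class SimulationConfig:
    """Full description of a synthetic replicated single-cell experiment."""

    arms: Sequence[tuple[str, str]] = ARMS
    n_samples_per_arm: Mapping[str, int] | int = field(
        default_factory=lambda: {
            arm_key("sensitive", "vehicle"): 2,
            arm_key("sensitive", "treated"): 4,
            arm_key("resistant", "vehicle"): 2,
            arm_key("resistant", "treated"): 4,
        }
    )
    cells_per_sample: int = 1000
    cell_type_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            arm_key("sensitive", "vehicle"): dict(_SENSITIVE_FRACTIONS),
            arm_key("sensitive", "treated"): dict(_SENSITIVE_FRACTIONS),
            arm_key("resistant", "vehicle"): dict(_RESISTANT_FRACTIONS),
            arm_key("resistant", "treated"): dict(_RESISTANT_FRACTIONS),
        }
    )
    marker_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_marker_table
    )
    bimodal_markers: Mapping[str, Sequence[BimodalMarker]] = field(
        default_factory=lambda: {
            "TAM_C3": (BimodalMarker("C5ar1", fraction_hi=0.5, multiplier=400.0),)
        }
    )
    planted_programs: Sequence[PlantedProgram] = field(
        default_factory=lambda: (default_planted_program(),)
    )
    n_genes: int = 2000
    # each type also up-regulates a block of background genes, emulating the
    # broad transcriptional programs that make real cell types separable
    n_program_genes: int = 20
    program_multiplier: float = 6.0
    nb_dispersion: float = 2.0
    library_size_mean: int = 12000
    library_size_sigma: float = 0.35
    base_log_sigma: float = 1.5
    low_quality_fraction: float = 0.03
    low_quality_library_factor: float = 0.08
    low_quality_mito_boost: float = 6.0
    doublet_rate: float = 0.06
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.cells_per_sample < 50:
            raise ConfigurationError("cells_per_sample must be >= 50")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be positive")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ConfigurationError("doublet_rate must lie in [0, 1]")
        keys = [arm_key(m, t) for m, t in self.arms]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate arms")
        for key in keys:
            fr = self.cell_type_fractions.get(key)
            if fr is None:
                raise ConfigurationError(f"no cell-type fractions for arm {key!r}")
            total = float(sum(fr.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"fractions for arm {key!r} sum to {total}, expected 1"
                )
        types = set().union(*(set(f) for f in self.cell_type_fractions.values()))
        for t, markers in self.marker_table.items():
            if t not in types:
                raise ConfigurationError(f"marker_table type {t!r} not a configured cell type")
            for g, m in markers.items():
                if m <= 0:
                    raise ConfigurationError(f"non-positive multiplier for {t}/{g}")
        for t in self.bimodal_markers:
            if t not in types:
                raise ConfigurationError(f"bimodal marker type {t!r} not a configured cell type")
        for prog in self.planted_programs:
            if prog.sender not in types or prog.receiver not in types:
                raise ConfigurationError(
                    f"planted program refers to unknown cell type "
                    f"({prog.sender!r} -> {prog.receiver!r})"
                )

    def samples_for_arm(self, key: str) -> int:
        if isinstance(self.n_samples_per_arm, int):
            return self.n_samples_per_arm
        return int(self.n_samples_per_arm[key])

    def sample_ids(self) -> list[tuple[str, str]]:
        """Ordered (sample_id, arm_key) pairs across all arms."""
        out = []
        for model, treatment in self.arms:
            key = arm_key(model, treatment)
            for i in range(self.samples_for_arm(key)):
                out.append((f"{model}_{treatment}_{i + 1}", key))
        return out


def default_config(seed: int = 0, *, null: bool = False,
                   **overrides) -> SimulationConfig:
    """The default study design; ``null=True`` removes the planted differential."""
    cfg = SimulationConfig(seed=seed, **overrides)
    if null:
        cfg = dataclasses.replace(
            cfg, planted_programs=(default_planted_program(null=True),)
        )
    return cfg


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """A generated multi-sample experiment with full ground truth."""

    counts: sp.csr_matrix            # cells x genes, nonnegative integers
    cell_meta: pd.DataFrame          # sample, arm, cell_type, is_doublet, ...
    gene_meta: pd.DataFrame          # indexed by gene symbol
    truth: SimulationConfig

    @property
    def genes(self) -> list[str]:
        return list(self.gene_meta.index)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )
        return adata

    def write(self, outdir: str | Path) -> None:
        """Write Matrix Market counts plus TSV annotation / truth tables."""
        from scipy.io import mmwrite

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "counts.mtx"), self.counts.astype(np.int64))
        self.cell_meta.to_csv(outdir / "cells.tsv", sep="\t")
        self.gene_meta.to_csv(outdir / "genes.tsv", sep="\t")


def load_experiment_tables(outdir: str | Path):
    """Read back the MTX counts and TSV annotation tables of ``write``.

    Returns ``(counts, cell_meta, gene_meta)``; the simulation config itself
    is not round-tripped.
    """
    from scipy.io import mmread

    outdir = Path(outdir)
    counts = sp.csr_matrix(mmread(outdir / "counts.mtx"))
    cell_meta = pd.read_csv(outdir / "cells.tsv", sep="\t", index_col=0)
    gene_meta = pd.read_csv(outdir / "genes.tsv", sep="\t", index_col=0)
    return counts, cell_meta, gene_meta


def _gene_universe(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene symbols and baseline relative-expression shares (sum to 1)."""
    named = list(_NAMED_GENE_SHARES)
    n_named = len(named) + len(MITO_GENES)
    if config.n_genes < n_named + 10:
        raise ConfigurationError(f"n_genes must be at least {n_named + 10}")
    n_filler = config.n_genes - n_named
    filler = [f"Gene{i:04d}" for i in range(1, n_filler + 1)]
    symbols = named + list(MITO_GENES) + filler

    shares = np.empty(config.n_genes)
    shares[: len(named)] = [_NAMED_GENE_SHARES[g] for g in named]
    shares[len(named): n_named] = _MITO_TOTAL_SHARE / len(MITO_GENES)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
    raw = rng.lognormal(mean=0.0, sigma=config.base_log_sigma, size=n_filler)
    residual = 1.0 - shares[:n_named].sum()
    shares[n_named:] = raw / raw.sum() * residual

    meta = pd.DataFrame(index=pd.Index(symbols, name="gene"))
    meta["base_share"] = shares
    meta["is_mito"] = meta.index.str.startswith("mt-")
    return meta, shares


def generate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Draw a full replicated experiment from the configured count model."""
    config.validate()
    gene_meta, base_shares = _gene_universe(config)
    symbols = list(gene_meta.index)
    gene_index = {g: i for i, g in enumerate(symbols)}
    theta = config.nb_dispersion
    mito_cols = np.flatnonzero(gene_meta["is_mito"].to_numpy())

    # per-type transcriptional program blocks over the filler genes
    all_types = sorted(set().union(*(set(f) for f in config.cell_type_fractions.values())))
    filler = [g for g in symbols if g.startswith("Gene")]
    program_of_type: dict[str, list[str]] = {}
    for i, ctype in enumerate(all_types):
        lo = i * config.n_program_genes
        hi = lo + config.n_program_genes
        program_of_type[ctype] = filler[lo:hi] if hi <= len(filler) else []
    gene_meta["program_type"] = ""
    for ctype, block in program_of_type.items():
        gene_meta.loc[block, "program_type"] = ctype

    # per-(arm, type) multiplier vectors, constant across cells
    type_mult: dict[tuple[str, str], np.ndarray] = {}
    for model, treatment in config.arms:
        key = arm_key(model, treatment)
        for ctype in all_types:
            mult = np.ones(config.n_genes, dtype=np.float32)
            for g, m in config.marker_table.get(ctype, {}).items():
                if g in gene_index:
                    mult[gene_index[g]] *= m
            for g in program_of_type.get(ctype, ()):
                mult[gene_index[g]] *= config.program_multiplier
            for prog in config.planted_programs:
                s = float(prog.strength_by_arm.get(key, 1.0))
                if ctype == prog.sender and prog.ligand in gene_index:
                    mult[gene_index[prog.ligand]] *= s
                if ctype == prog.receiver and prog.receptor in gene_index:
                    mult[gene_index[prog.receptor]] *= s
            type_mult[(key, ctype)] = mult

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[pd.DataFrame] = []
    root = np.random.SeedSequence([config.seed, 0xCE11])
    sample_seeds = root.spawn(len(config.sample_ids()))

    for (sample_id, key), seq in zip(config.sample_ids(), sample_seeds):
        rng = np.random.default_rng(seq)
        n = config.cells_per_sample
        fractions = config.cell_type_fractions[key]
        types = sorted(fractions)
        probs = np.array([fractions[t] for t in types], float)
        counts_per_type = rng.multinomial(n, probs / probs.sum())
        cell_types = np.repeat(np.array(types, object), counts_per_type)
        rng.shuffle(cell_types)

        mu = np.empty((n, config.n_genes), dtype=np.float32)
        for t in types:
            rows = np.flatnonzero(cell_types == t)
            if rows.size:
                mu[rows] = base_shares * type_mult[(key, t)]

        # bimodal (fraction-hi) markers
        hi_flags: dict[str, np.ndarray] = {}
        for t, markers in config.bimodal_markers.items():
            rows = np.flatnonzero(cell_types == t)
            for bm in markers:
                if bm.gene not in gene_index or rows.size == 0:
                    continue
                hi = rows[rng.random(rows.size) < bm.fraction_hi]
                mu[hi, gene_index[bm.gene]] *= bm.multiplier
                flag = np.zeros(n, bool)
                flag[hi] = True
                hi_flags[f"hi_{bm.gene}"] = flag

        # library sizes; a small fraction of low-quality cells with tiny
        # libraries and inflated mitochondrial content feeds the QC filter
        libs = rng.lognormal(
            mean=math.log(config.library_size_mean) - config.library_size_sigma**2 / 2,
            sigma=config.library_size_sigma, size=n,
        )
        low_q = rng.random(n) < config.low_quality_fraction
        libs[low_q] *= config.low_quality_library_factor
        if mito_cols.size:
            mu[np.ix_(low_q, mito_cols)] *= config.low_quality_mito_boost

        mu /= mu.sum(axis=1, keepdims=True)
        mu *= libs[:, None].astype(np.float32)

        p = theta / (theta + mu.astype(np.float64))
        counts = rng.negative_binomial(theta, p).astype(np.int32)

        # doublets: selected rows become the sum of themselves and a partner
        n_doub = int(round(config.doublet_rate * n))
        is_doublet = np.zeros(n, bool)
        partner = np.full(n, -1, np.int64)
        if n_doub:
            targets = rng.choice(n, size=n_doub, replace=False)
            partners = rng.integers(0, n - 1, size=n_doub)
            partners[partners >= targets] += 1  # partner != target
            original = counts.copy()
            counts[targets] = original[targets] + original[partners]
            is_doublet[targets] = True
            partner[targets] = partners

        blocks.append(sp.csr_matrix(counts))
        meta = pd.DataFrame({
            "sample": sample_id,
            "arm": key,
            "cell_type": pd.array(cell_types, dtype="str"),
            "is_doublet": is_doublet,
            "doublet_partner": partner,
            "low_quality": low_q,
        })
        for col, flag in hi_flags.items():
            meta[col] = flag
        meta_rows.append(meta)

    cell_meta = pd.concat(meta_rows, ignore_index=True)
    cell_meta.index = pd.Index(
        [f"cell_{i:06d}" for i in range(len(cell_meta))], name="cell"
    )
    counts_all = sp.vstack(blocks, format="csr")
    return SyntheticExperiment(
        counts=counts_all, cell_meta=cell_meta, gene_meta=gene_meta, truth=config
    )


# ---------------------------------------------------------------------------
# hashtag oligo matrix
# ---------------------------------------------------------------------------

def generate_hashtags(
    experiment: SyntheticExperiment,
    n_tags: int | None = None,
    signal_to_noise: float = 10.0,
    seed: int = 0,
    background_mean: float = 20.0,
    tag_of_sample: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Cell x tag count matrix for hashing-based demultiplexing.

    Each cell's true sample tag has Poisson mean ``signal_to_noise *
    background_mean``; all tags share the Poisson background.  In the
    noiseless limit (``background_mean=0``) the argmax tag identifies the
    sample exactly.
    """
    samples = list(dict.fromkeys(experiment.cell_meta["sample"]))
    if n_tags is None:
        n_tags = len(samples)
    if n_tags < len(samples):
        raise ConfigurationError(
            f"n_tags={n_tags} is fewer than the {len(samples)} samples"
        )
    if signal_to_noise <= 0:
        raise ConfigurationError("signal_to_noise must be positive")
    if tag_of_sample is None:
        tag_of_sample = {s: i for i, s in enumerate(samples)}
    else:
        used = list(tag_of_sample[s] for s in samples)
        if len(set(used)) != len(used):
            raise ConfigurationError("two samples share one hashtag id")
        if max(used) >= n_tags:
            raise ConfigurationError("tag id out of range")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A65]))
    n = experiment.n_cells
    tags = np.array([tag_of_sample[s] for s in experiment.cell_meta["sample"]])
    lam = np.full((n, n_tags), float(background_mean))
    lam[np.arange(n), tags] = signal_to_noise * max(background_mean, 1.0)
    counts = rng.poisson(lam)
    return pd.DataFrame(
        counts,
        index=experiment.cell_meta.index,
        columns=[f"tag_{i}" for i in range(n_tags)],
    )


# ---------------------------------------------------------------------------
# patient cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Generator parameters for a synthetic ICB-treated patient cohort.

    ``log_hazard_coef`` acts on the cohort-standardized C5aR1hi/CD86hi ratio
    in an exponential survival model (time unit: days); ``logistic_coef``
    acts on the same covariate in the logistic model for non-response (NE).
    """

    n_myeloid_mean: float = 300.0
    class_probs: tuple[float, float, float] = (0.15, 0.25, 0.60)  # c5ar1hi, cd86hi, other
    dirichlet_concentration: float = 8.0
    baseline_hazard: float = 1.0 / 365.0
    log_hazard_coef: float = 0.8
    censoring_rate: float = 1.0 / 1095.0
    logistic_coef: float = 1.5
    logistic_intercept: float = 0.0
    pseudocount: float = 1.0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline hazard must be positive")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring rate must be nonnegative")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ConfigurationError("class probabilities must sum to 1")


@dataclass
class SyntheticCohort:
    """Per-patient table plus the generator parameters used."""

    table: pd.DataFrame
    params: CohortParams

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=True)


def generate_cohort(
    n_patients: int,
    params: CohortParams | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a cohort with ratio-dependent survival and response.

    Survival times are exponential with hazard ``baseline *
    exp(beta * z)`` where ``z`` is the cohort-standardized ratio; censoring is
    an independent exponential clock.  Response NE (no T-cell expansion) is
    Bernoulli with logit linear in ``z``.
    """
    if n_patients < 8:
        raise ConfigurationError("n_patients must be >= 8")
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))

    n_myeloid = rng.poisson(params.n_myeloid_mean, size=n_patients)
    n_myeloid = np.maximum(n_myeloid, 20)
    probs = rng.dirichlet(
        np.asarray(params.class_probs) * params.dirichlet_concentration,
        size=n_patients,
    )
    counts = np.stack([rng.multinomial(n, p) for n, p in zip(n_myeloid, probs)])
    c5, cd86, other = counts[:, 0], counts[:, 1], counts[:, 2]
    ratio = (c5 + params.pseudocount) / (cd86 + params.pseudocount)
    z = (ratio - ratio.mean()) / ratio.std(ddof=0)

    hazard = params.baseline_hazard * np.exp(params.log_hazard_coef * z)
    event_time = rng.exponential(1.0 / hazard)
    if params.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / params.censoring_rate, size=n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)

    logit = params.logistic_intercept + params.logistic_coef * z
    p_ne = 1.0 / (1.0 + np.exp(-logit))
    response = np.where(rng.random(n_patients) < p_ne, "NE", "E")

    table = pd.DataFrame({
        "c5ar1_hi": c5,
        "cd86_hi": cd86,
        "other": other,
        "ratio": ratio,
        "standardized_ratio": z,
        "response": response,
        "time_days": time,
        "event": event,
        "timepoint": "on",
    }, index=pd.Index([f"patient_{i + 1:03d}" for i in range(n_patients)],
                      name="patient_id"))
    return SyntheticCohort(table=table, params=params)
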