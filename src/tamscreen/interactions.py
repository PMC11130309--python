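"""Per-sample ligand-receptor interaction calling with a permutation null.

An interaction between a sender and a receiver cell type is scored only
when the ligand is expressed by more than 10% of sender cells and the
receptor by more than 10% of receiver cells (strict inequalities).  The
interaction strength is the product of trimmed means — the mean over the
central 80% of cells ranked by that gene's expression, i.e. a 10% trim per
side — of the ligand in senders and the receptor in receivers.
Significance comes from a CellPhoneDB-style permutation null: cell-type
labels are shuffled jointly over the union of sender and receiver cells,
and p = (1 + #{permuted strength >= observed}) / (1 + n_perm), so p is
never exactly zero and remains valid (super-uniform) under label
exchangeability.
"""

from __future__ import annotations

import math
import zlib
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "load_lr_database",
    "expressed_genes",
    "trimmed_mean",
    "interaction_strength",
    "permutation_test",
    "call_interactions",
]

INTERACTION_COLUMNS = (
    "pair_id", "ligand", "receptor", "sender", "receiver",
    "strength", "p", "significant",
)


def load_lr_database(path: str | Path | None = None) -> pd.DataFrame:
    """Two-column ligand/receptor table with a derived ``pair_id``.

    Without a path, the curated mouse subset shipped with the package is
    used (it contains the Rps19-C5ar1, Csf1-Csf1r, Cx3cl1-Cx3cr1, Ccl7-Ccr2
    and companion pairs).  Many-to-one ligand->receptor mappings are
    allowed; duplicated (ligand, receptor) rows are not.
    """
    if path is None:
        ref = resources.files("tamscreen.data") / "lr_pairs_mouse.tsv"
        with resources.as_file(ref) as p:
            db = pd.read_csv(p, sep="\t")
    else:
        db = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"}.issubset(db.columns):
        raise ValueError("LR database needs 'ligand' and 'receptor' columns")
    if len(db) == 0:
        raise ValueError("empty LR database")
    if db.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows in LR database")
    db = db.copy()
    db["pair_id"] = db["ligand"] + "_" + db["receptor"]
    return db


def expressed_genes(
    type_matrix, genes, min_fraction: float = 0.10
) -> set[str]:
    """Genes detected in strictly more than ``min_fraction`` of the cells."""
    X = sp.csr_matrix(type_matrix)
    if X.shape[0] == 0:
        return set()
    frac = np.asarray((X > 0).mean(axis=0)).ravel()
    genes = np.asarray(pd.Index(genes))
    return set(genes[frac > min_fraction])


def _trim_k(n: int, trim: float) -> int:
    # the central-80% contract drops ceil(trim*n) cells per side whenever
    # trim*n is fractional (6 cells, trim 0.10 -> 1 per side)
    return int(math.ceil(trim * n - 1e-9))


def trimmed_mean(values, trim: float = 0.10) -> float:
    """Mean over the central (1 - 2*trim) of values ranked by magnitude."""
    x = np.asarray(values, float).ravel()
    n = x.size
    if n == 0:
        return 0.0
    k = _trim_k(n, trim)
    if 2 * k >= n:
        return float(np.mean(x))
    part = np.partition(x, (k, n - k - 1))
    return float(part[k: n - k].mean())


def interaction_strength(
    ligand_values,
    receptor_values,
    trim: float = 0.10,
    gate: bool = True,
) -> float:
    """Product of sender-ligand and receiver-receptor trimmed means.

    ``gate=False`` marks an interaction that failed the expressed-genes
    filter; its strength is 0 by contract.
    """
    if not gate:
        return 0.0
    return trimmed_mean(ligand_values, trim) * trimmed_mean(receptor_values, trim)


def _trimmed_means_rows(mat: np.ndarray, trim: float) -> np.ndarray:
    """Row-wise trimmed means of a 2-D array (permutations x cells)."""
    n = mat.shape[1]
    k = _trim_k(n, trim)
    if 2 * k >= n or n == 0:
        return mat.mean(axis=1) if n else np.zeros(mat.shape[0])
    part = np.partition(mat, (k, n - k - 1), axis=1)
    return part[:, k: n - k].mean(axis=1)


def permutation_test(
    ligand_values,
    receptor_values,
    sender_mask,
    receiver_mask,
    n_perm: int = 1000,
    trim: float = 0.10,
    seed: int = 0,
) -> float:
    """Permutation p-value for one ligand/receptor/sender/receiver unit.

    ``ligand_values``/``receptor_values`` span all cells of the sample;
    ``sender_mask``/``receiver_mask`` select the two (disjoint) cell types.
    Labels are shuffled over the union of the two types.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    lig = np.asarray(ligand_values, float).ravel()
    rec = np.asarray(receptor_values, float).ravel()
    s = np.asarray(sender_mask, bool).ravel()
    r = np.asarray(receiver_mask, bool).ravel()
    if (s & r).any():
        raise ValueError("sender and receiver masks overlap")

    observed = trimmed_mean(lig[s], trim) * trimmed_mean(rec[r], trim)
    if observed == 0.0:
        return 1.0

    union = np.flatnonzero(s | r)
    ns = int(s.sum())
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, union.size)), axis=1)
    sender_idx = union[perm[:, :ns]]
    receiver_idx = union[perm[:, ns:]]
    null = (
        _trimmed_means_rows(lig[sender_idx], trim)
        * _trimmed_means_rows(rec[receiver_idx], trim)
    )
    return float((1 + np.sum(null >= observed)) / (1 + n_perm))


def call_interactions(
    normalized,
    genes,
    cell_types,
    lr_db: pd.DataFrame,
    sample_id: str = "sample",
    alpha: float = 0.05,
    n_perm: int = 1000,
    min_fraction: float = 0.10,
    min_cells_per_type: int = 10,
    trim: float = 0.10,
    seed: int = 0,
    type_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """InteractionTable for one sample.

    One row per (LR pair, sender, receiver) whose ligand and receptor pass
    the expressed-genes filter in their respective types.  ``type_pairs``
    restricts the sender/receiver universe to the communication axes of
    interest (e.g. malignant -> TAM subtypes); by default every ordered
    pair of distinct sufficiently large types is scored.  Permutation
    draws are shared across all pairs of a given sender/receiver combination
    (one shuffle set per combination), which is the standard CellPhoneDB
    economy and keeps the table deterministic for a given seed.
    """
    if len(lr_db) == 0:
        raise ValueError("empty LR database")
    X = sp.csr_matrix(normalized)
    genes = pd.Index(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    labels = np.asarray(cell_types, dtype=object)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("cell_types length does not match matrix")

    types = sorted({t for t in np.unique(labels)})
    members = {t: np.flatnonzero(labels == t) for t in types}
    usable = [t for t in types if members[t].size >= min_cells_per_type]

    # per-type expressed-gene sets restricted to database genes
    db_genes = sorted(
        (set(lr_db["ligand"]) | set(lr_db["receptor"])) & set(genes)
    )
    if db_genes:
        cols = [gene_pos[g] for g in db_genes]
        sub = X[:, cols]
        det = (sub > 0).astype(np.int8)
        expressed: dict[str, set[str]] = {}
        for t in usable:
            frac = np.asarray(det[members[t]].mean(axis=0)).ravel()
            expressed[t] = {g for g, f in zip(db_genes, frac) if f > min_fraction}
        dense = {g: np.asarray(sub[:, i].todense()).ravel()
                 for i, g in enumerate(db_genes)}
    else:
        expressed = {t: set() for t in usable}
        dense = {}

    if type_pairs is None:
        wanted = [(s, r) for s in usable for r in usable if s != r]
    else:
        wanted = [
            (s, r) for s, r in type_pairs
            if s in usable and r in usable and s != r
        ]

    rows = []
    combos: dict[tuple[str, str], list[dict]] = {}
    for sender, receiver in wanted:
        hits = lr_db[
            lr_db["ligand"].isin(expressed[sender])
            & lr_db["receptor"].isin(expressed[receiver])
        ]
        if len(hits):
            combos[(sender, receiver)] = hits.to_dict("records")

    for (sender, receiver), hits in sorted(combos.items()):
        s_idx = members[sender]
        r_idx = members[receiver]
        union = np.concatenate([s_idx, r_idx])
        ns = s_idx.size
        combo_tag = zlib.crc32(f"{sender}|{receiver}".encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1A7E, combo_tag]))
        perm = np.argsort(rng.random((n_perm, union.size)), axis=1)
        send_cells = union[perm[:, :ns]]
        recv_cells = union[perm[:, ns:]]
        null_lig: dict[str, np.ndarray] = {}
        null_rec: dict[str, np.ndarray] = {}
        for row in hits:
            lig, rec = row["ligand"], row["receptor"]
            lv, rv = dense[lig], dense[rec]
            observed = trimmed_mean(lv[s_idx], trim) * trimmed_mean(rv[r_idx], trim)
            if observed == 0.0:
                p = 1.0
            else:
                if lig not in null_lig:
                    null_lig[lig] = _trimmed_means_rows(lv[send_cells], trim)
                if rec not in null_rec:
                    null_rec[rec] = _trimmed_means_rows(rv[recv_cells], trim)
                null = null_lig[lig] * null_rec[rec]
                p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
            rows.append({
                "pair_id": row["pair_id"], "ligand": lig, "receptor": rec,
                "sender": sender, "receiver": receiver,
                "strength": observed, "p": p,
                "significant": bool(p <= alpha and observed > 0),
            })

    table = pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS))
    table.attrs["sample_id"] = sample_id
    table.attrs["alpha"] = alpha
    table.attrs["n_perm"] = n_perm
    return table
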