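"""Replicate-pairwise differential interaction counting.

The interaction count estimate compares two conditions with independent
replicates: every sample of condition A is compared with every sample of
condition B, giving a x b comparison pairs.  For each interaction unit
(an LR pair between a sender and a receiver type), n_up counts the pairs
where the interaction increased and n_dn the pairs where it decreased, and

    N = n_up - n_dn            (per unit; summed over units for a total)

all in exact integer arithmetic.  "Increased" defaults to presence of a
significant call in the A sample but not the B sample (presence mode); a
strength-fold alternative (A >= tau * B among rows significant in either
sample) is available.  Units absent from both samples of a pair are
"unchanged".  Receptor-level counts are the sums over that receptor's
ligands.  The discordance screen returns units with N >= +m in the
resistant contrast and N <= -m in the sensitive contrast, ranked by
N_resistant - N_sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonDesign",
    "InteractionCountResult",
    "pairwise_delta",
    "interaction_count",
    "aggregate_by_receptor",
    "screen_discordant",
]

UNIT_KEY = ["pair_id", "sender", "receiver"]


@dataclass(frozen=True)
class ComparisonDesign:
    condition_a: tuple[str, ...]
    condition_b: tuple[str, ...]
    mode: Literal["presence", "strength"] = "presence"
    tau: float = 1.5

    def __post_init__(self) -> None:
        if len(self.condition_a) < 1 or len(self.condition_b) < 1:
            raise ValueError("both conditions need at least one replicate")
        if set(self.condition_a) & set(self.condition_b):
            raise ValueError("conditions must be disjoint")

    @property
    def a(self) -> int:
        return len(self.condition_a)

    @property
    def b(self) -> int:
        return len(self.condition_b)


@dataclass
class InteractionCountResult:
    """Per-unit n_up / n_dn / N over all a x b comparison pairs."""

    counts: pd.DataFrame  # indexed by (pair_id, sender, receiver)
    design: ComparisonDesign

    @property
    def total_n(self) -> int:
        return int(self.counts["N"].sum())

    @property
    def k(self) -> int:
        return len(self.counts)


def _unit_frame(table: pd.DataFrame) -> pd.DataFrame:
    cols = UNIT_KEY + ["strength", "significant"]
    if len(table) == 0:
        return pd.DataFrame(columns=cols).set_index(UNIT_KEY)
    return table[cols].set_index(UNIT_KEY)


def pairwise_delta(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    mode: Literal["presence", "strength"] = "presence",
    tau: float = 1.5,
) -> pd.Series:
    """Per-unit call in {up, down, unchanged} for one comparison pair.

    Presence mode: up iff significant in the A sample and not in B, down
    iff the converse.  Strength mode: among units significant in either
    sample, up iff strength_A >= tau * strength_B, down symmetrically.
    """
    a = _unit_frame(table_a)
    b = _unit_frame(table_b)
    units = a.index.union(b.index).drop_duplicates()
    sig_a = a["significant"].reindex(units, fill_value=False).astype(bool)
    sig_b = b["significant"].reindex(units, fill_value=False).astype(bool)

    if mode == "presence":
        up = sig_a & ~sig_b
        dn = sig_b & ~sig_a
    elif mode == "strength":
        sa = a["strength"].reindex(units, fill_value=0.0).astype(float)
        sb = b["strength"].reindex(units, fill_value=0.0).astype(float)
        either = sig_a | sig_b
        up = either & (sa >= tau * sb) & (sa > 0)
        dn = either & (sb >= tau * sa) & (sb > 0)
        both = up & dn
        up &= ~both
        dn &= ~both
    else:
        raise ValueError(f"unknown mode {mode!r}")

    call = pd.Series("unchanged", index=units, dtype=object)
    call[up] = "up"
    call[dn] = "down"
    return call


def interaction_count(
    tables_a: Sequence[pd.DataFrame],
    tables_b: Sequence[pd.DataFrame],
    design: ComparisonDesign | None = None,
) -> InteractionCountResult:
    """Accumulate up/down calls over all a x b ordered comparison pairs."""
    if len(tables_a) == 0 or len(tables_b) == 0:
        raise ValueError("both conditions need at least one interaction table")
    if design is None:
        design = ComparisonDesign(
            condition_a=tuple(
                t.attrs.get("sample_id", f"A{i}") for i, t in enumerate(tables_a)
            ),
            condition_b=tuple(
                t.attrs.get("sample_id", f"B{i}") for i, t in enumerate(tables_b)
            ),
        )
    if design.a != len(tables_a) or design.b != len(tables_b):
        raise ValueError("design replicate counts do not match supplied tables")

    ups: dict[tuple, int] = {}
    dns: dict[tuple, int] = {}
    for ta in tables_a:
        for tb in tables_b:
            call = pairwise_delta(ta, tb, mode=design.mode, tau=design.tau)
            for unit, c in call.items():
                if c == "up":
                    ups[unit] = ups.get(unit, 0) + 1
                    dns.setdefault(unit, 0)
                elif c == "down":
                    dns[unit] = dns.get(unit, 0) + 1
                    ups.setdefault(unit, 0)
                else:
                    ups.setdefault(unit, 0)
                    dns.setdefault(unit, 0)

    units = sorted(ups)
    counts = pd.DataFrame(
        {
            "n_up": [ups[u] for u in units],
            "n_dn": [dns[u] for u in units],
        },
        index=pd.MultiIndex.from_tuples(units, names=UNIT_KEY)
        if units else pd.MultiIndex.from_arrays([[], [], []], names=UNIT_KEY),
        dtype=np.int64,
    )
    counts["N"] = counts["n_up"] - counts["n_dn"]
    return InteractionCountResult(counts=counts, design=design)


def aggregate_by_receptor(
    result: InteractionCountResult, lr_db: pd.DataFrame
) -> InteractionCountResult:
    """Sum per-ligand counts into per-receptor counts (same sender/receiver)."""
    counts = result.counts.reset_index()
    mapping = lr_db.set_index("pair_id")["receptor"]
    missing = set(counts["pair_id"]) - set(mapping.index)
    if missing:
        raise ValueError(f"pair(s) absent from LR database: {sorted(missing)}")
    counts["pair_id"] = counts["pair_id"].map(mapping)
    agg = (
        counts.groupby(UNIT_KEY, sort=True)[["n_up", "n_dn", "N"]]
        .sum()
        .astype(np.int64)
    )
    return InteractionCountResult(counts=agg, design=result.design)


def screen_discordant(
    count_sensitive: InteractionCountResult,
    count_resistant: InteractionCountResult,
    min_magnitude: int = 1,
) -> pd.DataFrame:
    """Units up in the resistant contrast AND down in the sensitive contrast.

    Returns units with N_resistant >= +min_magnitude and N_sensitive <=
    -min_magnitude, ranked by N_resistant - N_sensitive descending, ties
    broken lexicographically on the unit key.
    """
    sen = count_sensitive.counts["N"]
    res = count_resistant.counts["N"]
    if len(sen) and len(res) and len(sen.index.intersection(res.index)) == 0:
        raise ValueError("sensitive and resistant results share no units")
    units = sen.index.union(res.index)
    sen = sen.reindex(units, fill_value=0)
    res = res.reindex(units, fill_value=0)

    hit = (res >= min_magnitude) & (sen <= -min_magnitude)
    out = pd.DataFrame({
        "N_sensitive": sen[hit],
        "N_resistant": res[hit],
    })
    out["score"] = out["N_resistant"] - out["N_sensitive"]
    out = (
        out.reset_index()
        .sort_values(["score"] + UNIT_KEY, ascending=[False, True, True, True])
        .set_index(UNIT_KEY)
    )
    return out
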