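"""Combined regulator ranking.

A key regulator is one that is itself differentially expressed *and*
whose regulon is enriched in the differential signal.  The two evidence
channels are combined symmetrically:

    score = f(-log P_E) + f(-log P_D),    f(x) = (x - min x) / (max x - min x)

where P_D is the regulator's own differential p-value and P_E its
enrichment p-value.  Min-max normalization makes the score independent
of the log base and bounds it in [0, 2]; a channel whose p-values are all
equal contributes 0 (an uninformative channel carries no weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RegulatorRanking", "minmax", "rank_regulators"]

P_FLOOR = 1e-300


@dataclass
class RegulatorRanking:
    """Ranked regulator table: p_d, p_e, score and 1-based rank."""

    table: pd.DataFrame  # index regulator; columns rank, p_d, p_e, score, ...

    @property
    def regulator_ids(self) -> list[str]:
        return self.table.index.tolist()

    def top(self, k: int) -> list[str]:
        return self.table.index[:k].tolist()

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "regulator"
        out.to_csv(path, sep="\t", float_format="%.6g")


def minmax(x) -> np.ndarray:
    """Min-max map to [0, 1]; a constant vector maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("minmax of an empty vector")
    if not np.isfinite(x).all():
        raise ValueError("minmax requires finite values")
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def rank_regulators(p_d, p_e, extra: pd.DataFrame | None = None) -> RegulatorRanking:
    """Combine the P_D and P_E vectors into the final regulator ranking.

    ``p_d`` and ``p_e`` are Series indexed by the same regulator IDs
    (order may differ).  NaN entries (regulator absent from the DE table,
    or NA enrichment) are treated as p = 1, i.e. no evidence.  Ties in
    the score are broken by smaller p_e, then smaller p_d, then ID;
    ranks are dense and start at 1.  ``extra`` columns (log_fc, es,
    n_targets, overlap, ...) are carried into the output table.
    """
    p_d = pd.Series(p_d, dtype=float)
    p_e = pd.Series(p_e, dtype=float)
    if set(p_d.index) != set(p_e.index):
        only_d = sorted(set(p_d.index) - set(p_e.index))
        only_e = sorted(set(p_e.index) - set(p_d.index))
        raise ValueError(
            f"regulator ID sets differ: only in p_d {only_d[:5]}, only in p_e {only_e[:5]}"
        )
    p_e = p_e.reindex(p_d.index)
    p_d = p_d.fillna(1.0).clip(P_FLOOR, 1.0)
    p_e = p_e.fillna(1.0).clip(P_FLOOR, 1.0)

    score = minmax(-np.log(p_e.to_numpy())) + minmax(-np.log(p_d.to_numpy()))
    table = pd.DataFrame(
        {"p_d": p_d, "p_e": p_e, "score": score}, index=p_d.index
    )
    if extra is not None:
        table = table.join(extra.reindex(table.index), how="left")
    table = table.sort_values(
        ["score", "p_e", "p_d"], ascending=[False, True, True], kind="mergesort"
    )
    # deterministic final tie-break by ID among fully tied rows
    table["_id"] = table.index
    table = table.sort_values(
        ["score", "p_e", "p_d", "_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns="_id")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return RegulatorRanking(table)
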