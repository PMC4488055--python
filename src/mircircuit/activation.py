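"""Cross-dataset activation calling for genes and miRNAs.

An entity is called up/down in one dataset when the corrected p-value and
fold change clear the per-dataset thresholds (default adj_p < 0.01 and
|log2FC| > 1, i.e. linear fold change > 2).  The activating frequency is the
fraction of datasets in which the entity carries such a call; an entity is
finally selected when that frequency strictly exceeds the kind-specific
threshold — > 50 % for protein-coding genes, > 25 % for miRNAs.  All
threshold comparisons are strict inequalities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .io_formats import ExpressionStatRow

__all__ = ["SelectionThresholds", "call_dataset", "frequencies", "select",
           "activation_table"]

logger = logging.getLogger(__name__)

Kind = Literal["gene", "mirna"]


@dataclass(frozen=True)
class SelectionThresholds:
    """Per-dataset call thresholds and cross-dataset frequency cutoffs.

    ``fc_min`` is a linear fold change applied symmetrically as
    |log2fc| > log2(fc_min).
    """

    fc_min: float = 2.0
    p_max: float = 0.01
    gene_freq_min: float = 0.5
    mirna_freq_min: float = 0.25

    def __post_init__(self) -> None:
        if self.fc_min <= 0 or self.p_max <= 0:
            raise ValueError("fc_min and p_max must be positive")
        for freq in (self.gene_freq_min, self.mirna_freq_min):
            if not 0.0 < freq < 1.0:
                raise ValueError("frequency thresholds must lie in (0, 1)")

    def freq_min(self, kind: Kind) -> float:
        return self.gene_freq_min if kind == "gene" else self.mirna_freq_min


def call_dataset(
    rows: Sequence[ExpressionStatRow],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Per-(entity, dataset) direction calls.

    Returns a DataFrame indexed by (entity_id, dataset_id) with a ``call``
    column in {up, down, ns}.  Unmeasured rows are excluded entirely (they
    never enter frequency denominators).  Duplicate (entity, dataset) rows
    are an error.
    """
    seen: set[tuple[str, str]] = set()
    records = []
    log_fc_min = math.log2(thresholds.fc_min)
    for row in rows:
        key = (row.entity_id, row.dataset_id)
        if key in seen:
            raise ValueError(f"duplicate (entity, dataset) row: {key}")
        seen.add(key)
        if not row.measured:
            continue
        if row.adj_p < thresholds.p_max and row.log2fc > log_fc_min:
            call = "up"
        elif row.adj_p < thresholds.p_max and row.log2fc < -log_fc_min:
            call = "down"
        else:
            call = "ns"
        records.append((row.entity_id, row.dataset_id, call))
    df = pd.DataFrame(records, columns=["entity_id", "dataset_id", "call"])
    return df.set_index(["entity_id", "dataset_id"])


def frequencies(
    calls: pd.DataFrame,
    denominator: Literal["measured", "all"] = "measured",
    n_datasets_total: int | None = None,
) -> pd.DataFrame:
    """Activating frequencies per entity.

    up_freq = (#datasets called up) / denominator, likewise down_freq.  The
    default denominator is the number of datasets in which the entity was
    measured; ``denominator="all"`` divides by ``n_datasets_total`` instead
    (which must then be given).  Entities measured in zero datasets are
    dropped with a logged warning.
    """
    if denominator == "all" and n_datasets_total is None:
        raise ValueError("denominator='all' requires n_datasets_total")
    rows = []
    for entity, group in calls.groupby(level="entity_id", sort=True):
        n_measured = len(group)
        if n_measured == 0:  # pragma: no cover - groupby never yields empties
            continue
        denom = n_measured if denominator == "measured" else n_datasets_total
        n_up = int((group["call"] == "up").sum())
        n_down = int((group["call"] == "down").sum())
        rows.append((entity, n_up / denom, n_down / denom, n_measured))
    return pd.DataFrame(
        rows, columns=["entity_id", "up_freq", "down_freq", "n_measured"]
    ).set_index("entity_id")


def select(
    table: pd.DataFrame,
    kind: Kind,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Final activation states from a frequency table.

    The state is the direction whose frequency strictly exceeds the
    kind-specific threshold; if both directions exceed it the larger
    frequency wins, and an exact tie falls back to ns (logged).
    """
    freq_min = thresholds.freq_min(kind)
    states = []
    for entity, row in table.iterrows():
        up_ok = row["up_freq"] > freq_min
        down_ok = row["down_freq"] > freq_min
        if up_ok and down_ok:
            if row["up_freq"] == row["down_freq"]:
                logger.warning(
                    "entity %s: up and down frequencies tied at %.3f; "
                    "calling ns", entity, row["up_freq"],
                )
                state = "ns"
            else:
                state = "up" if row["up_freq"] > row["down_freq"] else "down"
        elif up_ok:
            state = "up"
        elif down_ok:
            state = "down"
        else:
            state = "ns"
        states.append(state)
    out = table.copy()
    out["state"] = states
    return out


def activation_table(
    rows: Sequence[ExpressionStatRow],
    kind: Kind,
    thresholds: SelectionThresholds = SelectionThresholds(),
    denominator: Literal["measured", "all"] = "measured",
    n_datasets_total: int | None = None,
) -> pd.DataFrame:
    """Convenience pipeline: per-dataset calls -> frequencies -> final states."""
    calls = call_dataset(rows, thresholds)
    table = frequencies(calls, denominator, n_datasets_total)
    dropped = {r.entity_id for r in rows} - set(table.index)
    if dropped:
        logger.warning(
            "%d entities measured in zero datasets were dropped: %s",
            len(dropped), sorted(dropped)[:10],
        )
    return select(table, kind, thresholds)
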