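"""Item-wise RSM-activity fit (IRAF): the per-item representational strength.

For one item, the IRAF is the Pearson correlation between that item's row of
a (time-corrected) activity pattern matrix and the same item's row of a model
RSM, with the self-similarity cell excluded from both vectors.  Computed per
participant, ROI, phase and feature type, the values form a long-format table
ready for mixed-model analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .apm import APMatrix
from .rsm import ModelRSM

logger = logging.getLogger(__name__)

IRAF_COLUMNS = [
    "participant", "roi_id", "roi_class", "phase",
    "feature_type", "item", "iraf", "memory",
]


@dataclass
class APMRecord:
    """One corrected APM with its analysis keys."""

    participant: str
    roi_id: str
    roi_class: str
    phase: str
    apm: APMatrix


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    xm = x - x.mean()
    ym = y - y.mean()
    return float(xm @ ym / np.sqrt((xm @ xm) * (ym @ ym)))


def compute_iraf(apm: APMatrix, rsm: ModelRSM, item: str,
                 exclude_items: set[str] | None = None) -> float:
    """Correlate one item's APM row with its model-RSM row (self excluded).

    Only items present in both matrices enter the vectors, so an APM that
    also contains unmodelled trials (e.g. novel retrieval items) is aligned
    automatically.  A constant row yields NaN with a logged warning.
    """
    shared = [i for i in rsm.item_ids if i in set(apm.item_ids)]
    if item not in shared:
        raise KeyError(f"item {item!r} not present in both matrices")
    use = [i for i in shared if i != item and not (exclude_items and i in exclude_items)]
    a_idx = {i: k for k, i in enumerate(apm.item_ids)}
    r_idx = {i: k for k, i in enumerate(rsm.item_ids)}
    av = np.array([apm.values[a_idx[item], a_idx[j]] for j in use])
    rv = np.array([rsm.values[r_idx[item], r_idx[j]] for j in use])
    r = _pearson(av, rv)
    if np.isnan(r):
        logger.warning("undefined IRAF for item %r (constant row)", item)
    return r


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Monotone variance-stabilizing transform of a correlation."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def build_iraf_table(
    apms: Iterable[APMRecord],
    rsms: dict[str, ModelRSM],
    trials: pd.DataFrame,
    use_fisher_z: bool = False,
) -> pd.DataFrame:
    """Long-format IRAF table: participant x ROI x phase x feature type x item.

    Memory labels are read from the trial table (one resolved label per
    participant x item); rows with an undefined IRAF are dropped with a
    logged count.  Only valid old items carrying a memory label are included.
    """
    for cat in ("visual", "semantic"):
        if cat not in rsms:
            raise ValueError(f"missing model RSM for feature type {cat!r}")
    mem = (
        trials[trials["memory"].isin(["remembered", "forgotten"])]
        .drop_duplicates(["participant", "concept_id"])
        .set_index(["participant", "concept_id"])["memory"]
    )
    rows = []
    n_dropped = 0
    for rec in apms:
        if not rec.apm.corrected:
            raise ValueError("APMs must be time-corrected before IRAF")
        for feature_type, rsm in rsms.items():
            shared = [i for i in rsm.item_ids if i in set(rec.apm.item_ids)]
            for item in shared:
                key = (rec.participant, item)
                if key not in mem.index:
                    continue
                value = compute_iraf(rec.apm, rsm, item)
                if np.isnan(value):
                    n_dropped += 1
                    continue
                if use_fisher_z:
                    value = float(fisher_z(value))
                rows.append(
                    (rec.participant, rec.roi_id, rec.roi_class, rec.phase,
                     feature_type, item, value, mem.loc[key])
                )
    if n_dropped:
        logger.info("dropped %d undefined IRAF rows", n_dropped)
    return pd.DataFrame(rows, columns=IRAF_COLUMNS)
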