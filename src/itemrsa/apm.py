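"""Activity pattern matrices (APMs) with trial exclusion and time correction.

An APM holds the Pearson correlation between the multivoxel activation
patterns of every pair of trials in an ROI.  Before model comparison, trials
are filtered (catch trials; trials whose object could not be named at
encoding, which also removes that item's retrieval trial), and the component
of pattern similarity explained by temporal proximity within a run is
regressed out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import BetaPatterns
from .rsm import fold_sym, tril_vec

logger = logging.getLogger(__name__)

#: columns every trial table must carry
TRIAL_COLUMNS = [
    "participant", "trial_id", "phase", "run", "slot", "onset",
    "concept_id", "status", "response", "valid", "memory",
]

PHASES = ("encoding", "retrieval")
STATUSES = ("target", "catch", "new")
RESPONSES = ("1", "2", "3", "4", "none", "no_match", "dont_know")
MEMORY = ("remembered", "forgotten", "not_applicable")


@dataclass
class TimeRSM:
    """Within-run temporal proximity, 1 (same time) to 0 (furthest apart)."""

    item_ids: list[str]
    values: np.ndarray


@dataclass
class APMatrix:
    roi_id: str
    phase: str
    item_ids: list[str]
    values: np.ndarray
    corrected: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError("APM must be square over item_ids")


def filter_trials(table: pd.DataFrame) -> list[str]:
    """Trial ids retained for pattern analysis.

    Excluded are catch trials and any encoding trial on which the participant
    signalled not knowing the object's name (a don't-know / no-match press);
    an item flagged that way at encoding is also excluded from retrieval.
    """
    if table["trial_id"].duplicated().any():
        dup = table.loc[table["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise ValueError(f"duplicate trial id {dup!r}")
    valid_ids: list[str] = []
    for _, sub in table.groupby("participant", sort=False):
        enc = sub[sub["phase"] == "encoding"]
        unknown = enc.loc[
            enc["response"].isin(["dont_know", "no_match"]), "concept_id"
        ]
        bad_concepts = set(unknown)
        keep = (
            (sub["status"] != "catch")
            & ~(
                (sub["phase"] == "encoding")
                & sub["response"].isin(["dont_know", "no_match"])
            )
            & ~(
                (sub["phase"] == "retrieval")
                & sub["concept_id"].isin(bad_concepts)
            )
        )
        valid_ids.extend(sub.loc[keep, "trial_id"].tolist())
    return valid_ids


def build_apm(
    betas: BetaPatterns,
    valid_ids: list[str],
    phase: str = "encoding",
    item_ids: list[str] | None = None,
) -> APMatrix:
    """Pearson-correlate the voxel patterns of all pairs of valid trials.

    ``item_ids`` relabels rows (typically trial -> concept); defaults to the
    trial ids themselves.
    """
    index = {t: k for k, t in enumerate(betas.trial_ids)}
    rows = [index[t] for t in valid_ids if t in index]
    kept_trials = [t for t in valid_ids if t in index]
    if len(rows) < 3:
        raise ValueError("need at least 3 valid trials")
    pats = betas.values[rows]
    if pats.shape[1] < 3:
        raise ValueError("need at least 3 voxels")
    sd = pats.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance pattern for trial {kept_trials[flat[0]]!r}"
        )
    values = np.corrcoef(pats)
    np.fill_diagonal(values, 1.0)
    if item_ids is None:
        item_ids = kept_trials
    elif len(item_ids) != len(kept_trials):
        raise ValueError("item_ids length must match the retained trials")
    return APMatrix(betas.roi_id, phase, list(item_ids), values, corrected=False)


def build_time_rsm(table: pd.DataFrame, valid_ids: list[str]) -> TimeRSM:
    """Temporal-proximity matrix over the valid trials, in their given order.

    Within a run, cell (i, j) = 1 - |t_i - t_j| / D where D is the largest
    within-run onset distance; cells in different runs are 0; a run with a
    single valid trial contributes 0 off-diagonal cells.
    """
    sub = table.set_index("trial_id").loc[valid_ids]
    onsets = sub["onset"].to_numpy(dtype=float)
    runs = sub["run"].to_numpy()
    n = len(valid_ids)
    values = np.zeros((n, n))
    for run in np.unique(runs):
        idx = np.flatnonzero(runs == run)
        if idx.size < 2:
            continue
        t = onsets[idx]
        dist = np.abs(t[:, None] - t[None, :])
        d_max = dist.max()
        if d_max == 0:
            sim = np.ones_like(dist)
        else:
            sim = 1.0 - dist / d_max
        values[np.ix_(idx, idx)] = sim
    np.fill_diagonal(values, 1.0)
    return TimeRSM(list(valid_ids), values)


def regress_time(apm: APMatrix, time_rsm: TimeRSM) -> APMatrix:
    """Regress temporal proximity out of the APM (off-diagonal OLS residuals).

    A constant temporal predictor degenerates to mean-centering, with a
    logged warning.  The corrected matrix has an undefined (NaN) diagonal.
    """
    if apm.corrected:
        raise ValueError("APM is already time-corrected")
    if len(time_rsm.item_ids) != len(apm.item_ids):
        raise ValueError("APM and time RSM must cover the same trials")
    y = tril_vec(apm.values)
    x = tril_vec(time_rsm.values)
    if np.ptp(x) == 0:
        logger.warning(
            "time RSM off-diagonal is constant; falling back to mean-centering"
        )
        resid = y - y.mean()
    else:
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    values = fold_sym(resid, len(apm.item_ids))
    return APMatrix(apm.roi_id, apm.phase, list(apm.item_ids), values, corrected=True)
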