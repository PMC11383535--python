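"""Recognition-response scoring: confidence collapsing and bias adjustment.

Old/new recognition confidence is given on a 4-point scale (1 = definitely
new ... 4 = definitely old).  "Probably" and "definitely" responses collapse
to a binary old/new judgment.  Participants whose mean response to genuinely
new items is significantly above 2 (one-sample t test) show an "old" response
bias; for them, "probably old" (3) responses to old items are demoted to
forgotten.  Hit rates are summarized per participant and at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class BiasSummary:
    """One participant's false-alarm-tendency test."""

    participant: str
    mean_new: float
    se_new: float
    t: float
    p: float
    flagged: bool
    n_new: int


@dataclass
class HitSummary:
    per_participant: pd.DataFrame  # valid_trials, hits, adjusted_hits, rate
    group_mean: float
    group_se: float


def collapse_confidence(responses) -> np.ndarray:
    """Map 4-point confidence to binary judgments: {3,4} -> old, {1,2} -> new."""
    r = np.asarray(responses, dtype=float)
    if np.any(~np.isin(r, [1, 2, 3, 4])):
        bad = r[~np.isin(r, [1, 2, 3, 4])][0]
        raise ValueError(f"response {bad!r} outside the 1-4 confidence scale")
    return np.where(r >= 3, "old", "new")


def false_alarm_tendency(new_item_responses, participant: str = "",
                         alpha: float = 0.05) -> BiasSummary:
    """Mean response to new items tested against 2 ("probably new").

    t = (mean - 2) / SE with n - 1 df and a two-sided p; a participant is
    flagged as old-biased iff the mean exceeds 2 significantly.
    """
    r = np.asarray(new_item_responses, dtype=float)
    if np.any(~np.isin(r, [1, 2, 3, 4])):
        raise ValueError("responses must be on the 1-4 scale")
    n = len(r)
    if n < 2:
        raise ValueError("need at least 2 new-item responses")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in new-item responses; t undefined")
    mean = float(r.mean())
    se = float(sd / np.sqrt(n))
    t = (mean - 2.0) / se
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return BiasSummary(participant, mean, se, float(t), p,
                       flagged=bool(mean > 2.0 and p < alpha), n_new=n)


def bias_report(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-participant false-alarm-tendency table from a retrieval trial table."""
    out = []
    for pid, sub in trials.groupby("participant", sort=False):
        new = sub[(sub["phase"] == "retrieval") & (sub["status"] == "new")]
        resp = pd.to_numeric(new["response"], errors="coerce").dropna()
        b = false_alarm_tendency(resp.to_numpy(), participant=str(pid), alpha=alpha)
        out.append((b.participant, b.n_new, b.mean_new, b.se_new, b.t, b.p, b.flagged))
    return pd.DataFrame(
        out, columns=["participant", "n_new", "mean_new", "se_new", "t", "p", "flagged"]
    )


def adjust_memory_labels(trials: pd.DataFrame, flags: dict[str, bool]) -> pd.DataFrame:
    """Resolve remembered/forgotten labels, demoting biased "probably old".

    For every valid old-item trial the label follows the collapsed judgment;
    for participants flagged as old-biased, a "probably old" (3) response is
    counted as forgotten.  Invalid trials keep ``not_applicable``.  Demotion
    is monotone: no forgotten trial ever becomes remembered.
    """
    known = set(trials["participant"].astype(str))
    unknown = set(map(str, flags)) - known
    if unknown:
        raise ValueError(f"flags given for unknown participants: {sorted(unknown)}")
    out = trials.copy()
    resp = pd.to_numeric(out["response"], errors="coerce")
    old_valid = (out["status"] == "target") & out["valid"] & resp.notna()
    is_flagged = out["participant"].astype(str).map(lambda p: bool(flags.get(p, False)))
    remembered = old_valid & (resp >= 3) & ~(is_flagged & (resp == 3))
    out.loc[:, "memory"] = "not_applicable"
    out.loc[old_valid & remembered, "memory"] = "remembered"
    out.loc[old_valid & ~remembered, "memory"] = "forgotten"
    return out


def summarize_hit_rates(counts: pd.DataFrame) -> HitSummary:
    """Group hit-rate summary from per-participant trial counts.

    ``counts`` needs columns participant, valid_trials, hits, adjusted_hits;
    rate = adjusted_hits / valid_trials, group SE = sample SD / sqrt(n).
    With a single participant the SE is undefined (NaN).
    """
    if len(counts) < 1:
        raise ValueError("need at least one participant")
    zero = counts[counts["valid_trials"] <= 0]
    if len(zero):
        raise ValueError(
            f"participant {zero['participant'].iloc[0]!r} has no valid trials"
        )
    if (counts["adjusted_hits"] > counts["hits"]).any():
        raise ValueError("adjusted hits cannot exceed raw hits")
    per = counts.copy()
    per["rate"] = per["adjusted_hits"] / per["valid_trials"]
    n = len(per)
    mean = float(per["rate"].mean())
    se = float(per["rate"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return HitSummary(per, mean, se)


def hit_counts(adjusted_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant valid/hit/adjusted-hit counts from resolved labels.

    Valid trials are the retrieval-phase old-item trials retained by the
    exclusion rules; hits use the collapsed judgment, adjusted hits the
    resolved memory label.
    """
    rows = []
    ret = adjusted_trials[
        (adjusted_trials["phase"] == "retrieval")
        & (adjusted_trials["status"] == "target")
        & adjusted_trials["valid"]
    ]
    for pid, sub in ret.groupby("participant", sort=False):
        resp = pd.to_numeric(sub["response"], errors="coerce")
        rows.append((
            str(pid),
            len(sub),
            int((resp >= 3).sum()),
            int((sub["memory"] == "remembered").sum()),
        ))
    return pd.DataFrame(rows, columns=["participant", "valid_trials", "hits", "adjusted_hits"])


def load_reference_summary() -> pd.DataFrame:
    """Packaged behavioral summary of the 19-participant recognition study.

    Columns: per-participant valid-trial, hit and adjusted-hit counts, the
    mean and SE of responses to new items, the printed bias t test, and the
    old-bias flag.
    """
    with resources.files("itemrsa.data").joinpath("recognition_summary.csv").open() as fh:
        return pd.read_csv(fh, dtype={"participant": str})
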