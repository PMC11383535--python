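"""Single-trial GLM: double-gamma HRF, trial-wise design matrices, OLS betas.

Every trial gets its own regressor (an impulse at the trial onset convolved
with the hemodynamic response), and all trials of a run are estimated
simultaneously in one least-squares model alongside any nuisance regressors
and an intercept.  The per-voxel trial coefficients are the single-trial
activation patterns consumed by the similarity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .lmm import RankError

HRF_DEFAULTS = dict(
    peak_delay=6.0,        # s, delay of the positive gamma peak
    undershoot_delay=16.0,  # s
    peak_disp=1.0,          # s, dispersion (gamma scale)
    undershoot_disp=1.0,    # s
    p_u_ratio=6.0,          # peak-to-undershoot amplitude ratio
)


@dataclass
class BoldRun:
    """One run of (synthetic or real) BOLD data."""

    tr: float
    n_scans: int
    signal: np.ndarray      # scans x voxels
    onsets: np.ndarray      # per-trial seconds
    run_id: str = "run-1"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.signal.shape[0] != self.n_scans:
            raise ValueError("signal row count must equal n_scans")
        dur = self.tr * self.n_scans
        if np.any(self.onsets < 0) or np.any(self.onsets >= dur):
            raise ValueError("onsets must lie within the run")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class DesignMatrix:
    columns: np.ndarray       # scans x (n_trials + n_nuisance + 1)
    column_roles: list[str]   # "trial:<id>" | "nuisance:<name>" | "intercept"

    @property
    def trial_indices(self) -> list[int]:
        return [k for k, r in enumerate(self.column_roles) if r.startswith("trial:")]

    @property
    def trial_ids(self) -> list[str]:
        return [r.split(":", 1)[1] for r in self.column_roles if r.startswith("trial:")]


@dataclass
class BetaPatterns:
    """Trial-by-voxel GLM coefficients for one ROI."""

    roi_id: str
    trial_ids: list[str]
    values: np.ndarray  # trials x voxels

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.trial_ids):
            raise ValueError("row count must match trial_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")


def _hrf_continuous(t: np.ndarray, peak_delay, undershoot_delay,
                    peak_disp, undershoot_disp, p_u_ratio) -> np.ndarray:
    """Unnormalized double-gamma response evaluated at arbitrary times (s)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (
        sps.gamma.pdf(tp, a=peak_delay / peak_disp, scale=peak_disp)
        - sps.gamma.pdf(tp, a=undershoot_delay / undershoot_disp,
                        scale=undershoot_disp) / p_u_ratio
    )
    return out


def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = HRF_DEFAULTS["peak_delay"],
    undershoot_delay: float = HRF_DEFAULTS["undershoot_delay"],
    peak_disp: float = HRF_DEFAULTS["peak_disp"],
    undershoot_disp: float = HRF_DEFAULTS["undershoot_disp"],
    p_u_ratio: float = HRF_DEFAULTS["p_u_ratio"],
) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the scan interval.

    The kernel is the difference of two gamma densities (positive peak minus
    a scaled late undershoot), sampled every ``tr`` seconds over ``duration``
    and normalized to a maximum of 1.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < 24:
        raise ValueError("duration must cover the HRF support (>= 24 s)")
    if peak_disp <= 0 or undershoot_disp <= 0:
        raise ValueError("dispersions must be positive")
    t = np.arange(0.0, duration + tr / 2, tr)
    h = _hrf_continuous(t, peak_delay, undershoot_delay,
                        peak_disp, undershoot_disp, p_u_ratio)
    return h / h.max()


def build_design(
    onsets: np.ndarray,
    n_scans: int,
    tr: float,
    nuisance: dict[str, np.ndarray] | None = None,
    trial_ids: list[str] | None = None,
    **hrf_params,
) -> DesignMatrix:
    """One HRF-convolved regressor per trial, plus nuisance and intercept.

    Trial regressors are the continuous double-gamma response evaluated at
    scan times relative to each onset (an impulse convolution), so onsets
    need not be scan-aligned.
    """
    onsets = np.asarray(onsets, dtype=float)
    params = {**HRF_DEFAULTS, **hrf_params}
    run_end = n_scans * tr
    ids = trial_ids if trial_ids is not None else [str(k) for k in range(len(onsets))]
    if len(ids) != len(onsets):
        raise ValueError("trial_ids length must match onsets")
    cols, roles = [], []
    scan_times = np.arange(n_scans) * tr
    for tid, onset in zip(ids, onsets):
        if onset < 0 or onset >= run_end:
            raise ValueError(f"trial {tid!r} onset {onset} s is outside the run")
        cols.append(_hrf_continuous(scan_times - onset, **params))
        roles.append(f"trial:{tid}")
    for name, col in (nuisance or {}).items():
        col = np.asarray(col, dtype=float)
        if col.shape != (n_scans,):
            raise ValueError(f"nuisance regressor {name!r} must have {n_scans} rows")
        cols.append(col)
        roles.append(f"nuisance:{name}")
    cols.append(np.ones(n_scans))
    roles.append("intercept")
    return DesignMatrix(np.column_stack(cols), roles)


def estimate_betas(run: BoldRun, design: DesignMatrix, roi_id: str = "roi") -> BetaPatterns:
    """Simultaneous OLS of all regressors; returns trial coefficients only.

    A rank-deficient design raises :class:`RankError` rather than silently
    falling back to a pseudo-inverse.
    """
    X = design.columns
    if X.shape[0] != run.n_scans:
        raise ValueError("design rows must equal the run's scan count")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient (collinear regressors)")
    coef, *_ = np.linalg.lstsq(X, run.signal, rcond=None)
    return BetaPatterns(roi_id, design.trial_ids, coef[design.trial_indices])
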