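"""Synthetic study generator with known planted effects.

Every downstream stage (model RSMs, single-trial GLM, APMs, IRAF, behavioral
adjustment, mixed models, decoding) is validated against data generated here,
where the ground truth is known by construction:

* feature norms with two category blocks whose RSM overlap is tunable;
* per-trial voxel patterns built as random projections of each item's
  (centered) category feature vectors, weighted by planted coefficients that
  may depend on ROI class, memory phase and memory outcome, plus i.i.d.
  Gaussian voxel noise;
* 4-point old/new confidence responses driven by a latent per-item memory
  strength shared with the pattern planting, with a controllable "old" bias;
* optional BOLD runs obtained by convolving true betas with the double-gamma
  HRF.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm as glm_mod
from .glm import BetaPatterns, BoldRun
from .rsm import FeatureNorms

ROI_CLASSES = ("OTC", "IPC", "other")
OUTCOMES = ("remembered", "forgotten")


@dataclass
class StudyDesign:
    """Counts and timing of a two-phase recognition-memory study.

    The defaults mirror a 19-participant design with 300 old objects, 60
    catch items and 100 novel retrieval foils, two encoding runs, a 2 s TR
    and a 2-7 s jittered inter-trial interval.
    """

    n_participants: int = 19
    n_old: int = 300
    n_catch: int = 60
    n_new: int = 100
    n_runs_encoding: int = 2
    n_runs_retrieval: int = 4
    tr: float = 2.0
    iti_range: tuple[float, float] = (2.0, 7.0)
    trial_duration: float = 1.25
    p_dont_know: float = 0.08
    roi_spec: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("otc-1", "OTC", 80), ("ipc-1", "IPC", 80)]
    )

    def __post_init__(self):
        if min(self.n_participants, self.n_old, self.n_new) <= 0:
            raise ValueError("participant and item counts must be positive")
        if self.n_catch < 0 or not 0 <= self.p_dont_know < 1:
            raise ValueError("invalid catch count or don't-know rate")
        for _, cls, nv in self.roi_spec:
            if cls not in ROI_CLASSES:
                raise ValueError(f"unknown ROI class {cls!r}")
            if nv < 3:
                raise ValueError("ROIs need at least 3 voxels")


@dataclass
class PlantedEffects:
    """Ground-truth pattern weights and noise level.

    ``weights[(group, phase, outcome)] = (w_v, w_s)`` scales the visual and
    semantic signal components (per-voxel SD units), where ``group`` is an
    ROI class (OTC/IPC/other) or a specific ROI id -- an id entry overrides
    its class.  ``noise_sd`` is the i.i.d. voxel noise SD.  Outcomes without
    an entry fall back to the mean of the remembered/forgotten weights (used
    for catch and novel items).
    """

    weights: dict[tuple[str, str, str], tuple[float, float]]
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def lookup(self, roi_id: str, roi_class: str, phase: str,
               outcome: str) -> tuple[float, float]:
        for group in (roi_id, roi_class):
            key = (group, phase, outcome)
            if key in self.weights:
                return self.weights[key]
        for group in (roi_id, roi_class):
            both = [self.weights.get((group, phase, o)) for o in OUTCOMES]
            if all(w is not None for w in both):
                return (
                    (both[0][0] + both[1][0]) / 2.0,
                    (both[0][1] + both[1][1]) / 2.0,
                )
        raise KeyError(
            f"planted weights missing for ({roi_id}/{roi_class}, {phase}, {outcome})"
        )


def uniform_effects(w_v: float, w_s: float, noise_sd: float = 1.0,
                    roi_classes=ROI_CLASSES) -> PlantedEffects:
    """Identical weights for every ROI class, phase and outcome (a null truth)."""
    weights = {}
    for cls in roi_classes:
        for phase in ("encoding", "retrieval"):
            for out in OUTCOMES:
                weights[(cls, phase, out)] = (w_v, w_s)
    return PlantedEffects(weights, noise_sd)


@dataclass
class SyntheticStudy:
    norms: FeatureNorms
    trials: pd.DataFrame
    patterns: dict[tuple[str, str, str], BetaPatterns]  # (participant, roi, phase)
    truth: PlantedEffects
    design: StudyDesign
    theta: pd.Series  # latent memory strength per old concept


def gen_feature_norms(
    n_concepts: int,
    n_visual: int,
    n_semantic: int,
    cross_corr: float,
    seed: int,
) -> FeatureNorms:
    """Feature norms whose visual/semantic RSM overlap tracks ``cross_corr``.

    Underlying feature values are Gaussian; each semantic feature is a convex
    mixture (weight ``cross_corr``) of a duplicated visual feature and a
    fresh draw, so the two derived RSMs are identical at ``cross_corr = 1``
    and unrelated in expectation at 0.  Values are rectified at zero and
    column-normalized to a maximum of 1; any feature left with fewer than two
    nonzero entries has its two largest-magnitude entries restored.
    """
    if not np.isfinite(cross_corr) or not 0.0 <= cross_corr <= 1.0:
        raise ValueError("cross_corr must lie in [0, 1]")
    if n_concepts < 3 or n_visual < 2 or n_semantic < 2:
        raise ValueError("need >= 3 concepts and >= 2 features per category")
    rng = np.random.default_rng(seed)
    vis = rng.normal(0.4, 1.0, size=(n_concepts, n_visual))
    fresh = rng.normal(0.4, 1.0, size=(n_concepts, n_semantic))
    dup = vis[:, np.arange(n_semantic) % n_visual]
    sem = cross_corr * dup + (1.0 - cross_corr) * fresh
    raw = np.hstack([vis, sem])
    values = np.clip(raw, 0.0, None)
    # every feature must be reported for at least two concepts
    for j in range(values.shape[1]):
        nz = values[:, j] > 0
        if nz.sum() < 2:
            top = np.argsort(np.abs(raw[:, j]))[-2:]
            values[top, j] = np.abs(raw[top, j])
    # every concept needs variance within each category block (tiny norms can
    # rectify a whole block row to a constant); the repair uses the concept
    # index so duplicated blocks receive the identical fix
    for lo, hi in ((0, n_visual), (n_visual, n_visual + n_semantic)):
        block = values[:, lo:hi]
        for i in np.flatnonzero(block.std(axis=1) == 0):
            block[i, i % (hi - lo)] += 0.5 + block[i, 0]
    values /= values.max(axis=0, keepdims=True)
    concepts = [f"concept_{k:04d}" for k in range(n_concepts)]
    features = [f"vis_{k:04d}" for k in range(n_visual)] + [
        f"sem_{k:04d}" for k in range(n_semantic)
    ]
    cats = np.array(["visual"] * n_visual + ["semantic"] * n_semantic)
    return FeatureNorms(concepts, features, cats, values)


DEFAULT_THRESHOLDS = (-1.0, 0.0, 1.0)


def gen_behavior(
    theta: np.ndarray,
    bias: float,
    thresholds: tuple[float, float, float],
    seed: int,
    n_new: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Confidence responses from latent strengths under an equal-variance model.

    Old item i produces ``theta_i + bias + noise``; a new item produces
    ``bias + noise`` (standard normal noise); the value is binned by three
    ascending thresholds into 1 (definitely new) ... 4 (definitely old).
    Returns (old_responses, new_responses).
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not (thresholds[0] < thresholds[1] < thresholds[2]):
        raise ValueError("thresholds must be strictly ascending")
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    old_lat = theta + bias + rng.normal(0, 1, size=theta.shape)
    new_lat = bias + rng.normal(0, 1, size=n_new)

    def bin_(x):
        return (1 + np.searchsorted(thresholds, x, side="right")).astype(int)

    return bin_(old_lat), bin_(new_lat)


def _run_onsets(n_trials: int, n_runs: int, design: StudyDesign, rng) -> pd.DataFrame:
    """Assign trials to runs with jittered onsets; returns run/slot/onset."""
    base = n_trials // n_runs
    sizes = [base + (1 if r < n_trials % n_runs else 0) for r in range(n_runs)]
    rows = []
    k = 0
    for run, size in enumerate(sizes, start=1):
        t = 0.0
        for slot in range(size):
            rows.append((run, slot, t))
            t += design.trial_duration + rng.uniform(*design.iti_range)
            k += 1
    return pd.DataFrame(rows, columns=["run", "slot", "onset"])


def gen_study(
    design: StudyDesign,
    truth: PlantedEffects,
    norms: FeatureNorms,
    seed: int,
    theta_mean: float = 0.45,
    bias: float = 0.0,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> SyntheticStudy:
    """Generate trials, responses and per-ROI trial patterns with known truth.

    The latent memory strength theta_i (mean ``theta_mean``, SD 1) drives
    both the confidence response and the outcome-dependent pattern weights,
    keeping behavioral labels and neural planting consistent.  Per ROI, two
    voxel loading maps (visual/semantic) are drawn once and frozen; a trial's
    pattern is the weighted sum of the projections of the item's centered,
    unit-norm category feature vectors plus Gaussian voxel noise.
    """
    needed = design.n_old + design.n_catch + design.n_new
    if len(norms.concept_ids) < needed:
        raise ValueError(
            f"norms provide {len(norms.concept_ids)} concepts; design needs {needed}"
        )
    rng = np.random.default_rng(seed)
    concepts = list(norms.concept_ids)
    old = concepts[: design.n_old]
    catch = concepts[design.n_old: design.n_old + design.n_catch]
    new = concepts[design.n_old + design.n_catch: needed]

    # centered, unit-norm category feature vectors per concept
    comps = {}
    for cat in ("visual", "semantic"):
        block = norms.category_block(cat)
        centered = block - block.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(centered, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        comps[cat] = {c: v for c, v in zip(concepts, centered / nrm)}

    # frozen voxel loading maps per ROI
    loadings = {}
    for roi_id, roi_class, n_vox in design.roi_spec:
        loadings[roi_id] = (
            rng.normal(0, 1, size=(n_vox, comps["visual"][old[0]].size)),
            rng.normal(0, 1, size=(n_vox, comps["semantic"][old[0]].size)),
        )

    theta_item = pd.Series(
        rng.normal(theta_mean, 1.0, size=design.n_old), index=old, name="theta"
    )

    all_trials = []
    patterns: dict[tuple[str, str, str], BetaPatterns] = {}
    for p in range(design.n_participants):
        pid = f"sub-{p + 1:02d}"
        psub = _participant_trials(
            pid, design, rng, old, catch, new, theta_item, bias, thresholds
        )
        all_trials.append(psub)
        for roi_id, roi_class, n_vox in design.roi_spec:
            V, S = loadings[roi_id]
            for phase in ("encoding", "retrieval"):
                ph = psub[psub["phase"] == phase]
                rows = np.empty((len(ph), n_vox))
                for k, (_, tr_row) in enumerate(ph.iterrows()):
                    cid = tr_row["concept_id"]
                    outcome = tr_row["memory"]
                    w_v, w_s = truth.lookup(roi_id, roi_class, phase, outcome)
                    # unit feature vectors + N(0,1) loadings give per-voxel
                    # signal SD = w, so w / noise_sd is the per-voxel SNR
                    signal = w_v * (V @ comps["visual"][cid]) + w_s * (
                        S @ comps["semantic"][cid]
                    )
                    rows[k] = signal + truth.noise_sd * rng.normal(0, 1, size=n_vox)
                patterns[(pid, roi_id, phase)] = BetaPatterns(
                    roi_id, ph["trial_id"].tolist(), rows
                )
    trials = pd.concat(all_trials, ignore_index=True)
    return SyntheticStudy(norms, trials, patterns, truth, design, theta_item)


def _participant_trials(pid, design, rng, old, catch, new, theta_item,
                        bias, thresholds) -> pd.DataFrame:
    enc_items = list(old) + list(catch)
    order = rng.permutation(len(enc_items))
    enc_items = [enc_items[k] for k in order]
    enc_t = _run_onsets(len(enc_items), design.n_runs_encoding, design, rng)
    dont_know = rng.random(len(enc_items)) < design.p_dont_know

    ret_items = list(old) + list(new)
    order = rng.permutation(len(ret_items))
    ret_items = [ret_items[k] for k in order]
    ret_t = _run_onsets(len(ret_items), design.n_runs_retrieval, design, rng)

    theta_old = theta_item.loc[[c for c in ret_items if c in theta_item.index]]
    resp_seed = int(rng.integers(0, 2**31 - 1))
    old_resp, new_resp = gen_behavior(
        theta_old.to_numpy(), bias, thresholds, resp_seed,
        n_new=sum(1 for c in ret_items if c not in theta_item.index),
    )
    old_map = dict(zip(theta_old.index, old_resp))
    memory_map = {
        c: ("remembered" if r >= 3 else "forgotten") for c, r in old_map.items()
    }

    rows = []
    for k, cid in enumerate(enc_items):
        is_catch = cid in set(catch)
        dk = bool(dont_know[k]) and not is_catch
        resp = "no_match" if is_catch else ("dont_know" if dk else "none")
        valid = not (is_catch or dk)
        mem = memory_map.get(cid, "not_applicable") if valid else "not_applicable"
        rows.append((
            pid, f"{pid}_enc_{k:04d}", "encoding", int(enc_t.run[k]),
            int(enc_t.slot[k]), float(enc_t.onset[k]), cid,
            "catch" if is_catch else "target", resp, valid, mem,
        ))
    new_iter = iter(new_resp)
    enc_excluded = {
        cid for k, cid in enumerate(enc_items)
        if dont_know[k] and cid not in set(catch)
    }
    for k, cid in enumerate(ret_items):
        is_new = cid not in theta_item.index
        resp = str(next(new_iter)) if is_new else str(old_map[cid])
        valid = not (not is_new and cid in enc_excluded)
        mem = memory_map[cid] if (not is_new and valid) else "not_applicable"
        rows.append((
            pid, f"{pid}_ret_{k:04d}", "retrieval", int(ret_t.run[k]),
            int(ret_t.slot[k]), float(ret_t.onset[k]), cid,
            "new" if is_new else "target", resp, valid, mem,
        ))
    from .apm import TRIAL_COLUMNS

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def gen_bold(
    onsets: np.ndarray,
    true_betas: np.ndarray,
    tr: float,
    n_scans: int,
    noise_sd: float,
    seed: int,
    run_id: str = "run-1",
) -> BoldRun:
    """Forward BOLD model: HRF-convolved impulses scaled by true betas.

    ``signal = D @ true_betas + noise`` where D holds the per-trial
    double-gamma regressors, so the GLM stage recovers ``true_betas`` exactly
    on noiseless data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    onsets = np.asarray(onsets, dtype=float)
    true_betas = np.atleast_2d(np.asarray(true_betas, dtype=float))
    if len(onsets) != true_betas.shape[0]:
        raise ValueError("one beta row per onset required")
    if n_scans * tr < onsets.max(initial=0.0) + 30.0:
        raise ValueError("run must extend at least 30 s past the last onset")
    design = glm_mod.build_design(onsets, n_scans, tr)
    D = design.columns[:, design.trial_indices]
    rng = np.random.default_rng(seed)
    signal = D @ true_betas + noise_sd * rng.normal(0, 1, size=(n_scans, true_betas.shape[1]))
    return BoldRun(tr=tr, n_scans=n_scans, signal=signal, onsets=onsets, run_id=run_id)
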