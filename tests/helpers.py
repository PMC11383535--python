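"""Shared fixtures-in-code: a planted validation study and its pipeline run.

The study plants three qualitatively different ROIs:

* ``otc-1`` (OTC class): stronger representations at encoding than retrieval,
  identical for remembered and forgotten items;
* ``ipc-ret`` (IPC class): a memory-success gap at retrieval only;
* ``ipc-flip`` (IPC class): forgotten > remembered at encoding but
  remembered > forgotten at retrieval (the encoding-retrieval flip).

Weights are chosen so each planted per-voxel signal gap is about 0.6 noise
SDs, comfortably above the recovery threshold of 3*sigma/sqrt(n_voxels)
(~0.39 SDs at 60 voxels).
"""

from __future__ import annotations

import pandas as pd

from itemrsa import apm, behavior, iraf, rsm, simulate as sm, stats

ROI_SPEC = [("otc-1", "OTC", 60), ("ipc-ret", "IPC", 60), ("ipc-flip", "IPC", 60)]


def planted_truth(noise_sd: float = 1.0) -> sm.PlantedEffects:
    w = {}
    for out in ("remembered", "forgotten"):
        w[("OTC", "encoding", out)] = (1.0, 1.0)
        w[("OTC", "retrieval", out)] = (0.45, 0.45)
        w[("ipc-ret", "encoding", out)] = (0.6, 0.6)
    w[("ipc-ret", "retrieval", "remembered")] = (0.9, 0.9)
    w[("ipc-ret", "retrieval", "forgotten")] = (0.3, 0.3)
    w[("ipc-flip", "encoding", "remembered")] = (0.3, 0.3)
    w[("ipc-flip", "encoding", "forgotten")] = (0.9, 0.9)
    w[("ipc-flip", "retrieval", "remembered")] = (0.9, 0.9)
    w[("ipc-flip", "retrieval", "forgotten")] = (0.3, 0.3)
    return sm.PlantedEffects(w, noise_sd=noise_sd)


def small_design(**overrides) -> sm.StudyDesign:
    kwargs = dict(
        n_participants=8, n_old=30, n_catch=3, n_new=10, roi_spec=ROI_SPEC
    )
    kwargs.update(overrides)
    return sm.StudyDesign(**kwargs)


def study_to_iraf(study: sm.SyntheticStudy) -> pd.DataFrame:
    """Behavioral adjustment -> filtering -> APM -> time regression -> IRAF."""
    rsms = {c: rsm.build_model_rsm(study.norms, c) for c in ("visual", "semantic")}
    report = behavior.bias_report(study.trials)
    flags = dict(zip(report["participant"], report["flagged"]))
    trials = behavior.adjust_memory_labels(study.trials, flags)
    valid = set(apm.filter_trials(trials))
    roi_class = {r: c for r, c, _ in study.design.roi_spec}
    records = []
    for (pid, roi, phase), betas in study.patterns.items():
        psub = trials[(trials["participant"] == pid) & (trials["phase"] == phase)]
        ids = [t for t in psub["trial_id"] if t in valid]
        concepts = psub.set_index("trial_id").loc[ids, "concept_id"].tolist()
        raw = apm.build_apm(betas, ids, phase=phase, item_ids=concepts)
        time_rsm = apm.build_time_rsm(psub, ids)
        records.append(
            iraf.APMRecord(pid, roi, roi_class[roi], phase, apm.regress_time(raw, time_rsm))
        )
    return iraf.build_iraf_table(records, rsms, trials)


def run_planted_seed(seed: int) -> dict[str, bool]:
    """One end-to-end recovery run; returns per-check booleans."""
    norms = sm.gen_feature_norms(45, 24, 20, cross_corr=0.2, seed=seed)
    study = sm.gen_study(small_design(), planted_truth(), norms, seed=seed + 1)
    table = study_to_iraf(study)
    effects, posthoc = stats.per_roi_analysis(
        table, flip_rule=stats.FlipRule(enc_t_threshold=-2.0)
    )
    e = effects.set_index(["roi_id", "effect"])
    means = table[table["roi_id"] == "otc-1"].groupby("phase")["iraf"].mean()
    patterns = posthoc.drop_duplicates("roi_id").set_index("roi_id")["pattern"]
    return {
        "otc_phase_effect": bool(e.loc[("otc-1", "phase"), "q"] < 0.05),
        "otc_encoding_stronger": bool(means["encoding"] > means["retrieval"]),
        "ret_interaction": bool(e.loc[("ipc-ret", "memory:phase"), "q"] < 0.05),
        "flip_interaction": bool(e.loc[("ipc-flip", "memory:phase"), "q"] < 0.05),
        "ret_label": patterns["ipc-ret"] == "retrieval_success",
        "flip_label": patterns["ipc-flip"] == "encoding_retrieval_flip",
    }
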