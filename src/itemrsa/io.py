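"""Readers/writers for on-disk formats and the pipeline orchestrator.

Tables and matrices travel as CSV with explicit ids (never positional
indices); volumetric data use NIfTI at the real-data boundary; configuration
is YAML/JSON.  ``run_pipeline`` chains the simulation and analysis stages and
writes a manifest with the seed, a config hash and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import apm as apm_mod
from . import behavior as behavior_mod
from . import decode as decode_mod
from . import iraf as iraf_mod
from . import rsm as rsm_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .apm import MEMORY, PHASES, RESPONSES, STATUSES, TRIAL_COLUMNS
from .rsm import FeatureNorms, ModelRSM

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- tables ---

def load_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    table = pd.read_csv(path, dtype={"participant": str, "trial_id": str,
                                     "concept_id": str, "response": str})
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    return validate_trial_table(table)


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    if table["trial_id"].duplicated().any():
        dup = table.loc[table["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise ValueError(f"duplicate trial id {dup!r}")
    for col, vocab in [("phase", PHASES), ("status", STATUSES),
                       ("response", RESPONSES), ("memory", MEMORY)]:
        bad = ~table[col].astype(str).isin(vocab)
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(
                f"row {row}: invalid {col} value {table.loc[row, col]!r}"
            )
    new_at_enc = (table["status"] == "new") & (table["phase"] == "encoding")
    if new_at_enc.any():
        raise ValueError("status 'new' is only allowed in the retrieval phase")
    catch_valid = (table["status"] == "catch") & table["valid"].astype(bool)
    if catch_valid.any():
        raise ValueError("catch trials cannot be marked valid")
    return table


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ----------------------------------------------------------------- norms ---

def write_norms(norms: FeatureNorms, path) -> None:
    """Feature-by-concept CSV: feature id, category, one column per concept."""
    df = pd.DataFrame(norms.values.T, index=norms.feature_ids,
                      columns=norms.concept_ids)
    df.insert(0, "category", norms.categories)
    df.to_csv(path, index_label="feature_id")


def load_norms(path) -> FeatureNorms:
    df = pd.read_csv(path, index_col="feature_id")
    cats = df.pop("category").to_numpy()
    return FeatureNorms(
        list(df.columns), list(df.index), cats, df.to_numpy().T
    )


# ------------------------------------------------------------------ RSMs ---

def write_rsm(rsm: ModelRSM, path) -> None:
    pd.DataFrame(rsm.values, index=rsm.item_ids, columns=rsm.item_ids).to_csv(
        path, index_label=f"item_id#{rsm.category}"
    )


def load_rsm(path) -> ModelRSM:
    df = pd.read_csv(path, index_col=0)
    label = df.index.name or "item_id#visual"
    category = label.split("#", 1)[1] if "#" in label else "visual"
    return ModelRSM(list(df.columns), df.to_numpy(), category)


# ----------------------------------------------------------------- NIfTI ---

def load_roi_patterns(beta_path, mask_path) -> dict[int, "sim_mod.BetaPatterns"]:
    """Per-ROI trial-by-voxel patterns from a 4-D beta image and a label mask."""
    betas = nib.load(str(beta_path))
    mask = nib.load(str(mask_path))
    if betas.shape[:3] != mask.shape:
        raise ValueError(
            f"beta grid {betas.shape[:3]} does not match mask grid {mask.shape}"
        )
    data = np.asanyarray(betas.dataobj)
    labels = np.asanyarray(mask.dataobj).astype(int)
    out = {}
    for label in np.unique(labels):
        if label == 0:
            continue
        sel = labels == label
        if not sel.any():
            logger.warning("ROI label %d is empty; skipped", label)
            continue
        mat = data[sel].T  # trials x voxels
        trial_ids = [str(k) for k in range(mat.shape[0])]
        out[int(label)] = sim_mod.BetaPatterns(str(label), trial_ids, mat)
    return out


def write_roi_patterns(patterns: dict[int, np.ndarray], beta_path, mask_path,
                       affine=None) -> None:
    """Pack per-ROI trial-by-voxel arrays into a 4-D volume plus label mask."""
    n_trials = next(iter(patterns.values())).shape[0]
    total_vox = sum(v.shape[1] for v in patterns.values())
    dim = int(np.ceil(total_vox ** (1 / 3))) + 1
    vol = np.zeros((dim, dim, dim, n_trials))
    labels = np.zeros((dim, dim, dim), dtype=np.int16)
    flat_idx = 0
    coords = np.array(np.unravel_index(np.arange(dim**3), (dim, dim, dim))).T
    for label, mat in patterns.items():
        nv = mat.shape[1]
        for v in range(nv):
            x, y, z = coords[flat_idx]
            vol[x, y, z, :] = mat[:, v]
            labels[x, y, z] = label
            flat_idx += 1
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vol, affine), str(beta_path))
    nib.save(nib.Nifti1Image(labels, affine), str(mask_path))


# ---------------------------------------------------------------- config ---

def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    alpha = cfg.get("alpha", 0.05)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# -------------------------------------------------------------- pipeline ---

def run_pipeline(cfg: dict, out_dir) -> dict:
    """Simulate a study and run every analysis stage, writing CSV outputs.

    Stages: norms -> model RSMs -> study (trial patterns) -> APM + time
    correction -> behavioral adjustment -> IRAF table -> per-ROI mixed models
    with FDR and post hoc patterns -> cross-phase decoding.  Returns the
    manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    ncfg = cfg.get("norms", {})
    norms = sim_mod.gen_feature_norms(
        n_concepts=ncfg.get("n_concepts", 60),
        n_visual=ncfg.get("n_visual", 40),
        n_semantic=ncfg.get("n_semantic", 30),
        cross_corr=ncfg.get("cross_corr", 0.25),
        seed=seed,
    )
    write_norms(norms, out / "norms.csv")
    rsms = {c: rsm_mod.build_model_rsm(norms, c) for c in ("visual", "semantic")}
    for cat, r in rsms.items():
        write_rsm(r, out / f"rsm_{cat}.csv")

    dcfg = cfg.get("design", {})
    design = sim_mod.StudyDesign(**dcfg)
    wcfg = cfg.get("truth", {"w_v": 0.6, "w_s": 0.6, "noise_sd": 1.0})
    truth = sim_mod.uniform_effects(
        wcfg.get("w_v", 0.6), wcfg.get("w_s", 0.6), wcfg.get("noise_sd", 1.0)
    )
    study = sim_mod.gen_study(design, truth, norms, seed=seed,
                              bias=cfg.get("bias", 0.0))
    write_trial_table(study.trials, out / "trials.csv")

    report = behavior_mod.bias_report(study.trials, alpha=cfg.get("alpha", 0.05))
    report.to_csv(out / "behavior_report.csv", index=False)
    flags = dict(zip(report["participant"], report["flagged"]))
    trials = behavior_mod.adjust_memory_labels(study.trials, flags)

    valid = set(apm_mod.filter_trials(trials))
    roi_class = {r: c for r, c, _ in design.roi_spec}
    records = []
    for (pid, roi, phase), betas in study.patterns.items():
        psub = trials[(trials["participant"] == pid) & (trials["phase"] == phase)]
        ids = [t for t in psub["trial_id"] if t in valid and t in set(betas.trial_ids)]
        concepts = psub.set_index("trial_id").loc[ids, "concept_id"].tolist()
        raw = apm_mod.build_apm(betas, ids, phase=phase, item_ids=concepts)
        time_rsm = apm_mod.build_time_rsm(psub, ids)
        corrected = apm_mod.regress_time(raw, time_rsm)
        records.append(iraf_mod.APMRecord(pid, roi, roi_class[roi], phase, corrected))
    iraf_table = iraf_mod.build_iraf_table(
        records, rsms, trials, use_fisher_z=cfg.get("fisher_z", False)
    )
    iraf_table.to_csv(out / "iraf.csv", index=False)

    effects, posthoc = stats_mod.per_roi_analysis(iraf_table)
    effects.to_csv(out / "effects.csv", index=False)
    posthoc.to_csv(out / "posthoc.csv", index=False)

    results = decode_mod.classify_all_rois(iraf_table, seed=seed)
    pd.DataFrame(
        [(r.roi_id, r.accuracy, r.n_test, r.correct) for r in results],
        columns=["roi_id", "accuracy", "n_test", "correct"],
    ).to_csv(out / "classify.csv", index=False)

    manifest = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "n_trials": int(len(trials)),
        "n_valid_trials": int(len(valid)),
        "n_iraf_rows": int(len(iraf_table)),
        "n_rois_converged": int(effects["roi_id"].nunique()),
        "stages": ["norms", "rsm", "simulate", "behavior", "apm", "iraf",
                   "stats", "classify"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
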