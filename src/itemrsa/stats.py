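"""Mixed-model inference on IRAF tables.

Per-ROI models regress the item-wise representational strength on memory
success (remembered vs. forgotten), memory phase (encoding vs. retrieval) and
representation type (visual vs. semantic) with all interactions, crossed
random intercepts (participant, stimulus, optionally more), REML estimation,
Type III F tests under sum-to-zero coding with Satterthwaite denominator df,
Benjamini-Hochberg FDR across ROIs, post hoc marginal-mean contrasts, an
area-level phase-by-area model, and a simulation-based power analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, RandomStructure, fit_reml

logger = logging.getLogger(__name__)


@dataclass
class MixedModelSpec:
    """Fixed factors (sum-to-zero coded), interactions, random intercepts."""

    response: str
    fixed_factors: list[str]
    interactions: str | list[tuple[str, ...]] = "full"
    random_intercepts: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.random_intercepts:
            raise ValueError("at least one random intercept is required")

    def terms(self) -> list[tuple[str, ...]]:
        mains = [(f,) for f in self.fixed_factors]
        if self.interactions == "full":
            inter = [
                c
                for k in range(2, len(self.fixed_factors) + 1)
                for c in itertools.combinations(self.fixed_factors, k)
            ]
        else:
            inter = [tuple(t) for t in self.interactions]
        return mains + inter


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list, list[str]]:
    """Sum-to-zero (deviation) coding; last sorted level is the reference."""
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise ValueError(f"factor needs >= 2 observed levels, got {levels}")
    cols = np.zeros((len(values), len(levels) - 1))
    arr = np.asarray(values)
    for j, lev in enumerate(levels[:-1]):
        cols[arr == lev, j] = 1.0
        cols[arr == levels[-1], j] = -1.0
    names = [str(lev) for lev in levels[:-1]]
    return cols, levels, names


def build_fixed_design(
    data: pd.DataFrame, spec: MixedModelSpec
) -> tuple[np.ndarray, list[str], dict[str, list[int]], dict[str, list]]:
    """Sum-coded fixed design with intercept; returns term -> column indices."""
    main_cols: dict[str, np.ndarray] = {}
    levels: dict[str, list] = {}
    col_names_by_factor: dict[str, list[str]] = {}
    for f in spec.fixed_factors:
        cols, lev, names = _sum_code(data[f])
        main_cols[f] = cols
        levels[f] = lev
        col_names_by_factor[f] = names
    X = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    slices: dict[str, list[int]] = {}
    pos = 1
    for term in spec.terms():
        term_name = ":".join(term)
        blocks = [main_cols[f] for f in term]
        cols = blocks[0]
        labels = [[f"{term[0]}{n}"] for n in col_names_by_factor[term[0]]]
        labels = [l[0] for l in labels]
        for f, blk in zip(term[1:], blocks[1:]):
            cols = np.concatenate(
                [cols[:, [i]] * blk for i in range(cols.shape[1])], axis=1
            )
            labels = [
                f"{a}:{f}{b}" for a in labels for b in col_names_by_factor[f]
            ]
        X.append(cols)
        slices[term_name] = list(range(pos, pos + cols.shape[1]))
        names.extend(labels)
        pos += cols.shape[1]
    return np.hstack(X), names, slices, levels


@dataclass
class MixedModelResult:
    fit: LMMFit
    spec: MixedModelSpec
    term_columns: dict[str, list[int]]
    levels: dict[str, list]

    @property
    def converged(self) -> bool:
        return self.fit.converged


def fit_lmm(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelResult:
    """REML fit of the specified crossed random-intercepts model."""
    for col in spec.fixed_factors + spec.random_intercepts + [spec.response]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} not found in data")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X, names, slices, levels = build_fixed_design(data, spec)
    struct = RandomStructure.from_frame(data, spec.random_intercepts)
    fit = fit_reml(y, X, struct, fixed_names=names)
    if not fit.converged:
        logger.warning("mixed model did not converge; flagging for exclusion")
    return MixedModelResult(fit, spec, slices, levels)


def type3_anova(result: MixedModelResult) -> pd.DataFrame:
    """Type III F test per fixed term with Satterthwaite denominator df.

    Under sum-to-zero coding each term's Type III hypothesis is that its own
    coefficients vanish in the full model.  ``sum_sq`` is reported on the
    lmerTest scale (F * df_num * residual variance).
    """
    if not result.converged:
        raise ValueError("cannot test a non-converged model")
    fit = result.fit
    rows = []
    for term, cols in result.term_columns.items():
        L = np.zeros((len(cols), fit.p))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        F, df_num, df_den, p = fit.ftest(L)
        rows.append((term, F, df_num, df_den, F * df_num * fit.sigma2, p))
    return pd.DataFrame(
        rows, columns=["effect", "F", "df_num", "df_den", "sum_sq", "p"]
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p values to adjust")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cell_rows(result: MixedModelResult) -> tuple[pd.DataFrame, np.ndarray]:
    """Design row of every factor-level cell of the full factorial grid."""
    spec = result.spec
    grids = [result.levels[f] for f in spec.fixed_factors]
    cells = pd.DataFrame(
        list(itertools.product(*grids)), columns=spec.fixed_factors
    )
    X, _, _, _ = build_fixed_design(cells, spec)
    return cells, X


def posthoc_means(
    result: MixedModelResult,
    within: str = "phase",
    factor: str = "memory",
    positive_level: str = "remembered",
    negative_level: str = "forgotten",
) -> pd.DataFrame:
    """Marginal-mean differences (e.g. remembered - forgotten) per phase.

    Marginal means average the model's cell predictions over the remaining
    factors; each difference gets a Satterthwaite t test.
    """
    if not result.converged:
        raise ValueError("cannot test a non-converged model")
    for lev in (positive_level, negative_level):
        if lev not in result.levels[factor]:
            raise ValueError(f"no observations for {factor}={lev!r}")
    cells, Xc = _cell_rows(result)
    rows = []
    for wlev in result.levels[within]:
        pos = (cells[within] == wlev) & (cells[factor] == positive_level)
        neg = (cells[within] == wlev) & (cells[factor] == negative_level)
        if pos.sum() == 0 or neg.sum() == 0:
            raise ValueError(f"empty cell for {within}={wlev!r}")
        ell = Xc[pos.to_numpy()].mean(axis=0) - Xc[neg.to_numpy()].mean(axis=0)
        est, se, df, t, p = result.fit.contrast(ell)
        rows.append((
            f"{wlev} {positive_level}-{negative_level}",
            wlev, est, se, df, t, p,
        ))
    return pd.DataFrame(
        rows, columns=["label", within, "estimate", "se", "df", "t", "p"]
    )


@dataclass
class FlipRule:
    """Configurable sorting of phase-by-success interaction patterns.

    ``retrieval_success`` requires a significant positive retrieval
    remembered-forgotten contrast; ``encoding_retrieval_flip`` additionally
    requires the encoding contrast t below ``enc_t_threshold`` (0 labels any
    numerically negative encoding contrast a flip).
    """

    ret_alpha: float = 0.05
    enc_t_threshold: float = 0.0


def classify_flip_pattern(
    enc_t: float, enc_p: float, ret_t: float, ret_p: float,
    rule: FlipRule | None = None,
) -> str:
    """Sort an ROI into {retrieval_success, encoding_retrieval_flip, none}."""
    for v in (enc_t, ret_t):
        if v is None or not np.isfinite(v):
            raise ValueError("both phase contrasts are required")
    rule = rule or FlipRule()
    if not (ret_t > 0 and ret_p < rule.ret_alpha):
        return "none"
    if enc_t < rule.enc_t_threshold:
        return "encoding_retrieval_flip"
    return "retrieval_success"


def per_roi_analysis(
    iraf: pd.DataFrame,
    spec: MixedModelSpec | None = None,
    flip_rule: FlipRule | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the three-factor model in every ROI; FDR across all ROIs x terms.

    Returns (effects table with q values, post hoc/pattern table).  ROIs whose
    model does not converge are excluded with a log entry.
    """
    spec = spec or MixedModelSpec(
        response="iraf",
        fixed_factors=["memory", "phase", "feature_type"],
        random_intercepts=["participant", "item"],
    )
    effects = []
    posthocs = []
    for roi, sub in iraf.groupby("roi_id", sort=True):
        res = fit_lmm(sub, spec)
        if not res.converged:
            logger.warning("ROI %s: model did not converge; excluded", roi)
            continue
        tab = type3_anova(res)
        tab.insert(0, "roi_id", roi)
        effects.append(tab)
        ph = posthoc_means(res)
        enc = ph[ph["phase"] == "encoding"].iloc[0]
        ret = ph[ph["phase"] == "retrieval"].iloc[0]
        pattern = classify_flip_pattern(
            enc["t"], enc["p"], ret["t"], ret["p"], flip_rule
        )
        ph = ph.assign(roi_id=roi, pattern=pattern)
        posthocs.append(ph)
    if not effects:
        raise ValueError("no ROI model converged")
    eff = pd.concat(effects, ignore_index=True)
    eff["q"] = fdr_adjust(eff["p"].to_numpy())
    post = pd.concat(posthocs, ignore_index=True)
    return eff, post


def fit_area_model(
    iraf: pd.DataFrame,
    area_map: dict[str, str],
    feature_as_random: bool = True,
) -> pd.DataFrame:
    """Phase-by-area model on remembered trials across IPC/OTC ROI groups.

    Random intercepts: feature type (unless ``feature_as_random`` is False,
    in which case it joins the fixed part), participant, stimulus and ROI.
    """
    data = iraf[iraf["memory"] == "remembered"].copy()
    data["area"] = data["roi_id"].map(area_map)
    if data["area"].isna().any():
        missing = sorted(data.loc[data["area"].isna(), "roi_id"].unique())
        raise ValueError(f"ROIs without an area assignment: {missing}")
    if data["area"].nunique() < 2:
        raise ValueError("both areas must be represented")
    for area, sub in data.groupby("area"):
        if sub["roi_id"].nunique() < 2:
            logger.warning(
                "area %s has a single ROI; its intercept is weakly identified", area
            )
    fixed = ["phase", "area"]
    rand = ["participant", "item", "roi_id"]
    if feature_as_random:
        rand = ["feature_type"] + rand
    else:
        fixed.append("feature_type")
    spec = MixedModelSpec(
        response="iraf", fixed_factors=fixed, random_intercepts=rand
    )
    res = fit_lmm(data, spec)
    if not res.converged:
        raise ValueError("area model did not converge")
    return type3_anova(res)


@dataclass
class PowerEstimate:
    power: float
    reps: int
    mc_se: float
    effect_size_d: float
    alpha: float

    def __post_init__(self):
        expected = np.sqrt(self.power * (1 - self.power) / self.reps)
        if abs(self.mc_se - expected) > 1e-9:
            raise ValueError("mc_se inconsistent with power and reps")


def power_sim(
    d: float,
    alpha: float,
    n_participants: int,
    n_items: int,
    n_phases: int = 2,
    n_types: int = 2,
    reps: int = 50,
    seed: int = 0,
    participant_sd: float = 0.1,
    item_sd: float = 0.1,
) -> PowerEstimate:
    """Simulation-based power for a fixed binary-condition effect.

    Each replicate simulates ``response = d * condition + participant
    intercept + item intercept + residual`` (unit residual SD) over the full
    participant x item x phase x type grid, with the condition split along
    the phase factor; the condition effect is tested at ``alpha`` in the
    crossed random-intercepts model.  Power is the rejection proportion.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if min(n_participants, n_items, n_phases, n_types) < 2:
        raise ValueError("every design factor needs at least 2 levels")
    rng = np.random.default_rng(seed)
    n = n_participants * n_items * n_phases * n_types
    p_idx = np.repeat(np.arange(n_participants), n_items * n_phases * n_types)
    i_idx = np.tile(
        np.repeat(np.arange(n_items), n_phases * n_types), n_participants
    )
    cond = np.tile(
        np.repeat(np.arange(n_phases) % 2, n_types), n_participants * n_items
    ).astype(float)
    X = np.column_stack([np.ones(n), cond])
    frame = pd.DataFrame({"participant": p_idx, "item": i_idx})
    struct = RandomStructure.from_frame(frame, ["participant", "item"])
    hits = 0
    for _ in range(reps):
        u_p = rng.normal(0, participant_sd, n_participants)
        u_i = rng.normal(0, item_sd, n_items)
        y = d * cond + u_p[p_idx] + u_i[i_idx] + rng.normal(0, 1, n)
        fit = fit_reml(y, X, struct, ["(Intercept)", "condition"])
        *_, p = fit.contrast([0.0, 1.0])
        if p < alpha:
            hits += 1
    power = hits / reps
    return PowerEstimate(
        power=power,
        reps=reps,
        mc_se=float(np.sqrt(power * (1 - power) / reps)),
        effect_size_d=d,
        alpha=alpha,
    )
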