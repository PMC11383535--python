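"""Mixed-model engine, Type III tests, FDR, post hocs, power simulation."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from itemrsa.lmm import RandomStructure, fit_reml
from itemrsa.stats import (
    FlipRule,
    MixedModelSpec,
    PowerEstimate,
    classify_flip_pattern,
    fdr_adjust,
    fit_area_model,
    fit_lmm,
    posthoc_means,
    power_sim,
    type3_anova,
)

SPEC3 = MixedModelSpec(
    response="iraf",
    fixed_factors=["memory", "phase", "feature_type"],
    random_intercepts=["participant", "item"],
)


def simulate_factorial(rng, n_p=8, n_i=16, b=None, sd_p=0.3, sd_i=0.3):
    """Balanced participant x item x phase x type data with optional effects.

    ``b`` maps factor name -> half-difference between its two levels.
    """
    b = b or {}
    u_p = rng.normal(0, sd_p, n_p)
    u_i = rng.normal(0, sd_i, n_i)
    mem = rng.random((n_p, n_i)) < 0.5
    rows = []
    for p in range(n_p):
        for i in range(n_i):
            m = "remembered" if mem[p, i] else "forgotten"
            for ph in ("encoding", "retrieval"):
                for ft in ("visual", "semantic"):
                    y = u_p[p] + u_i[i] + rng.normal()
                    y += b.get("memory", 0.0) * (1 if m == "remembered" else -1)
                    y += b.get("phase", 0.0) * (1 if ph == "encoding" else -1)
                    y += b.get("memory:phase", 0.0) * (
                        (1 if m == "remembered" else -1)
                        * (1 if ph == "encoding" else -1)
                    )
                    rows.append((f"p{p:02d}", f"i{i:02d}", ph, ft, m, y))
    return pd.DataFrame(
        rows,
        columns=["participant", "item", "phase", "feature_type", "memory", "iraf"],
    )


class TestREMLEngine:
    def test_matches_lmerTest_oracle(self, tmp_path, rng):
        """Estimates, SEs, Satterthwaite df, F and REML loglik against R."""
        n_p, n_i = 10, 20
        u_p = rng.normal(0, 0.5, n_p)
        u_i = rng.normal(0, 0.3, n_i)
        rows = []
        for p in range(n_p):
            for i in range(n_i):
                for x in (-1.0, 1.0):
                    rows.append((f"p{p}", f"i{i}", x,
                                 0.3 * x + u_p[p] + u_i[i] + rng.normal()))
        df = pd.DataFrame(rows, columns=["participant", "item", "x", "y"])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lmerTest))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(y ~ x + (1|participant) + (1|item), data=d)\n"
            "co <- summary(m)$coefficients\n"
            "a <- anova(m, type=3)\n"
            "cat(co['x','Estimate'], co['x','Std. Error'], co['x','df'],"
            " a['x','F value'], a['x','DenDF'], as.numeric(logLik(m)), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        est_r, se_r, df_r, f_r, dendf_r, ll_r = map(float, out.stdout.split())

        X = np.column_stack([np.ones(len(df)), df["x"]])
        struct = RandomStructure.from_frame(df, ["participant", "item"])
        fit = fit_reml(df["y"].to_numpy(), X, struct)
        est, se, dfree, t, p = fit.contrast([0.0, 1.0])
        F, _, dden, _ = fit.ftest([[0.0, 1.0]])
        assert est == pytest.approx(est_r, rel=1e-5)
        assert se == pytest.approx(se_r, rel=1e-4)
        assert dfree == pytest.approx(df_r, rel=5e-3)
        assert F == pytest.approx(f_r, rel=1e-4)
        assert dden == pytest.approx(dendf_r, rel=5e-3)
        assert fit.loglik_reml == pytest.approx(ll_r, abs=1e-3)

    def test_zero_variance_limit_matches_ols(self, rng):
        """With no true grouping variance the fixed effects collapse to OLS."""
        n = 400
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        frame = pd.DataFrame({"g": rng.integers(0, 10, n).astype(str)})
        struct = RandomStructure.from_frame(frame, ["g"])
        X = np.column_stack([np.ones(n), x])
        fit = fit_reml(y, X, struct)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-4)

    def test_balanced_two_group_matches_classical_anova(self, rng):
        """Single near-zero random intercept: F equals one-way ANOVA F."""
        n_per = 60
        a = rng.normal(0.0, 1, n_per)
        b = rng.normal(0.4, 1, n_per)
        y = np.concatenate([a, b])
        grp = np.array([1.0] * n_per + [-1.0] * n_per)
        frame = pd.DataFrame({"block": (np.arange(2 * n_per) % 6).astype(str)})
        struct = RandomStructure.from_frame(frame, ["block"])
        X = np.column_stack([np.ones(2 * n_per), grp])
        fit = fit_reml(y, X, struct)
        F, _, dden, _ = fit.ftest([[0.0, 1.0]])
        F_classic = sps.f_oneway(a, b).statistic
        assert F == pytest.approx(F_classic, abs=1e-3 * F_classic + 1e-3)
        assert dden == pytest.approx(2 * n_per - 2, rel=0.02)

    def test_variance_component_recovery(self):
        """Median recovered participant variance within 20% over 50 seeds."""
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_p, reps = 25, 30
            u = rng.normal(0, 0.5, n_p)
            pid = np.repeat(np.arange(n_p), reps)
            y = u[pid] + rng.normal(0, 1.0, n_p * reps)
            frame = pd.DataFrame({"participant": pid.astype(str)})
            struct = RandomStructure.from_frame(frame, ["participant"])
            fit = fit_reml(y, np.ones((len(y), 1)), struct)
            estimates.append(fit.re_var["participant"])
        assert abs(np.median(estimates) - 0.25) < 0.05

    def test_refit_is_deterministic(self, rng):
        data = simulate_factorial(rng, n_p=4, n_i=8)
        r1 = fit_lmm(data, SPEC3)
        r2 = fit_lmm(data, SPEC3)
        assert np.array_equal(r1.fit.beta, r2.fit.beta)
        assert r1.fit.sigma2 == r2.fit.sigma2


class TestType3Anova:
    def test_all_seven_terms_reported(self, rng):
        data = simulate_factorial(rng, n_p=5, n_i=10)
        tab = type3_anova(fit_lmm(data, SPEC3))
        assert len(tab) == 7
        assert set(tab["effect"]) >= {"memory", "phase", "feature_type",
                                      "memory:phase"}
        assert (tab["F"] >= 0).all()
        assert (tab["df_den"] <= len(data)).all()

    def test_planted_interaction_is_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = simulate_factorial(rng, n_p=10, n_i=30,
                                      b={"memory:phase": 0.25})
            tab = type3_anova(fit_lmm(data, SPEC3)).set_index("effect")
            if tab.loc["memory:phase", "p"] < 0.05:
                hits += 1
        assert hits >= 18


class TestFDR:
    def test_step_up_hand_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_are_fixed_point(self):
        assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bh_properties(self, ps):
        q = fdr_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p-rank
        # permutation invariance
        perm = order[::-1]
        assert np.allclose(fdr_adjust(np.asarray(ps)[perm]), q[perm])


class TestPosthoc:
    def test_balanced_design_equals_cell_means(self, rng):
        data = simulate_factorial(rng, n_p=6, n_i=12, b={"memory": 0.2},
                                  sd_p=0.0, sd_i=0.0)
        res = fit_lmm(data, SPEC3)
        ph = posthoc_means(res).set_index("phase")
        for phase in ("encoding", "retrieval"):
            sub = data[data["phase"] == phase]
            cells = sub.groupby(["memory", "feature_type"])["iraf"].mean()
            simple = (
                cells.xs("remembered", level="memory").mean()
                - cells.xs("forgotten", level="memory").mean()
            )
            assert ph.loc[phase, "estimate"] == pytest.approx(simple, abs=1e-6)
            assert ph.loc[phase, "t"] == pytest.approx(
                ph.loc[phase, "estimate"] / ph.loc[phase, "se"], abs=1e-9
            )

    def test_null_contrasts_stay_small(self):
        inside = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            data = simulate_factorial(rng, n_p=8, n_i=16)
            ph = posthoc_means(fit_lmm(data, SPEC3))
            if (ph["t"].abs() <= 2).all():
                inside += 1
        assert inside >= 30 * 0.93 - 2  # both contrasts within +/-2 usually


class TestFlipClassification:
    def test_reference_patterns(self):
        assert classify_flip_pattern(-1.0, 0.31, 3.7, 0.0002) == "encoding_retrieval_flip"
        assert classify_flip_pattern(0.2, 0.8, 0.5, 0.6) == "none"

    def test_threshold_is_configurable(self):
        args = (-1.647, 0.100, 2.732, 0.006)
        assert classify_flip_pattern(*args) == "encoding_retrieval_flip"
        assert classify_flip_pattern(
            *args, rule=FlipRule(enc_t_threshold=-2.0)
        ) == "retrieval_success"

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError):
            classify_flip_pattern(np.nan, 0.5, 2.0, 0.01)


class TestAreaModel:
    def test_planted_phase_by_area_interaction(self, rng):
        rows = []
        for p in range(8):
            for i in range(20):
                for roi, area in [("o1", "OTC"), ("o2", "OTC"),
                                  ("p1", "IPC"), ("p2", "IPC")]:
                    for ph in ("encoding", "retrieval"):
                        for ft in ("visual", "semantic"):
                            gap = 0.5 if area == "OTC" else 0.1
                            y = (gap if ph == "encoding" else 0.0) + rng.normal(0, 0.3)
                            rows.append((f"p{p}", f"i{i}", roi, area, ph, ft,
                                         "remembered", y))
        iraf = pd.DataFrame(rows, columns=[
            "participant", "item", "roi_id", "area", "phase", "feature_type",
            "memory", "iraf",
        ])
        tab = fit_area_model(
            iraf, {"o1": "OTC", "o2": "OTC", "p1": "IPC", "p2": "IPC"}
        ).set_index("effect")
        assert tab.loc["phase", "p"] < 0.01
        assert tab.loc["phase:area", "p"] < 0.01

    def test_unmapped_roi_rejected(self, rng):
        data = simulate_factorial(rng, n_p=4, n_i=6)
        data["roi_id"] = "r1"
        with pytest.raises(ValueError):
            fit_area_model(data, {"other": "OTC"})


class TestPowerSim:
    def test_null_size_matches_alpha(self):
        est = power_sim(d=0.0, alpha=0.05, n_participants=8, n_items=30,
                        reps=60, seed=2)
        assert est.power <= 0.05 + 2 * max(est.mc_se, np.sqrt(0.05 * 0.95 / 60))

    def test_saturating_effect(self):
        est = power_sim(d=3.0, alpha=0.05, n_participants=5, n_items=10,
                        reps=20, seed=3)
        assert est.power >= 0.99

    def test_mc_se_invariant(self):
        est = PowerEstimate(power=0.8, reps=50,
                            mc_se=float(np.sqrt(0.8 * 0.2 / 50)),
                            effect_size_d=0.4, alpha=0.05)
        assert est.mc_se == pytest.approx(np.sqrt(0.8 * 0.2 / 50))
        with pytest.raises(ValueError):
            PowerEstimate(power=0.8, reps=50, mc_se=0.2, effect_size_d=0.4,
                          alpha=0.05)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            power_sim(d=0.4, alpha=0.05, n_participants=1, n_items=10)
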