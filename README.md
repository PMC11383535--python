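# itemrsa

Item-wise representational similarity analysis (RSA) of memory encoding and
retrieval.

`itemrsa` is for cognitive-neuroimaging researchers who want to relate
single-trial fMRI activation patterns to stimulus feature models at the level
of individual items, and to ask how representational strength changes between
memory encoding and retrieval and with memory success. It implements the full
analysis chain around the **item-wise RSM-activity fit (IRAF)** statistic,
together with a synthetic-study generator that plants known effects so every
stage can be validated end to end.

## The statistic

Given feature norms (a nonnegative concept × feature matrix of normalized
report frequencies, each feature labelled *visual* or *semantic*), the model
RSM for a category is the item × item matrix of Pearson correlations between
concepts' category feature vectors. From single-trial voxel patterns in an
ROI, the activity pattern matrix (APM) holds Pearson correlations between all
trial pairs, corrected for within-run temporal proximity by regressing out a
time RSM (scaled 1 = same time to 0 = furthest apart within a run).

For item *i* the IRAF is

```
IRAF_i = corr( APM[i, -i],  RSM[i, -i] )
```

— the Pearson correlation between item *i*'s pattern-similarity vector and
its model-similarity vector, self-similarity excluded. One value per
participant × ROI × phase × feature type × item forms a long table analysed
with crossed random-intercept linear mixed models:

```
iraf ~ memory * phase * feature_type + (1 | participant) + (1 | item)
```

fit by REML, with Type III F tests under sum-to-zero coding, Satterthwaite
denominator degrees of freedom, Benjamini–Hochberg FDR across ROIs, and post
hoc marginal-mean contrasts (remembered − forgotten per phase) that sort ROIs
into *retrieval-success* and *encoding–retrieval flip* patterns.

Supporting stages: a single-trial GLM (one double-gamma-HRF regressor per
trial, all trials estimated simultaneously), recognition-bias adjustment
(participants whose mean response to new items is significantly above 2 on
the 4-point scale have "probably old" hits demoted to forgotten), a linear
SVM that decodes feature type from encoding IRAFs and transfers to retrieval,
and a simulation-based power analysis for the mixed model.

## Worked example

```python
import numpy as np
from itemrsa import simulate as sm, rsm, stats
from itemrsa.behavior import load_reference_summary, summarize_hit_rates

# behavioral reproduction from the packaged 19-participant summary table
s = summarize_hit_rates(load_reference_summary())
print(f"group adjusted hit rate: {s.group_mean:.3f} (SE {s.group_se:.3f})")

# model RSMs from synthetic feature norms
norms = sm.gen_feature_norms(n_concepts=60, n_visual=40, n_semantic=30,
                             cross_corr=0.25, seed=1)
rv = rsm.build_model_rsm(norms, "visual")
rs = rsm.build_model_rsm(norms, "semantic")
cmp = rsm.compare_rsms(rv, rs)
print(f"visual-semantic RSM overlap: global rho = {cmp.global_rho:.3f}, "
      f"mean item-wise rho = {np.nanmean(cmp.itemwise_rho):.3f}")

# power for a d = 0.4 condition effect in the crossed mixed model
est = stats.power_sim(d=0.4, alpha=0.05, n_participants=19, n_items=300,
                      reps=50, seed=7)
print(f"power at d=0.4, alpha=.05: {est.power:.2f} (MC SE {est.mc_se:.3f})")
```

prints

```
group adjusted hit rate: 0.618 (SE 0.032)
visual-semantic RSM overlap: global rho = 0.078, mean item-wise rho = 0.081
power at d=0.4, alpha=.05: 1.00 (MC SE 0.000)
```

The hit rate is the group mean of per-participant adjusted hits / valid
trials (0.62 ± 0.03); the RSM overlap quantifies how much the two feature
models share (here low, since the synthetic blocks were generated with a
cross-correlation of 0.25); the power estimate is the proportion of simulated
replicates in which the condition effect was detected at α = .05 — with
~22,800 observations a d = 0.4 effect is detected essentially always.

A full synthetic-study pipeline (norms → RSMs → trial patterns → APMs →
IRAF → mixed models → decoding) runs from a YAML config:

```
itemrsa run --config config.yaml --seed 3 --out out/
```

writing `trials.csv`, `iraf.csv`, `effects.csv` (Type III F, Satterthwaite
df, FDR q per ROI), `posthoc.csv` (per-phase contrasts and pattern labels),
`classify.csv` and a reproducibility manifest.

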