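# alloptical

Analysis pipeline for **all-optical interrogation of barrel cortex**:
trial-aligned two-photon calcium imaging combined with targeted two-photon
photostimulation during a bilateral whisker discrimination task.  The package
is aimed at systems neuroscientists who have trial-aligned fluorescence
traces, a behavioral trial table and photostimulation spiral-site coordinates
and want the standard chain of analyses for this experiment class — plus a
synthetic session generator with known ground truth to validate every stage.

## What it computes

Given somatic and neuropil fluorescence per neuron × trial × frame:

1. **Preprocessing** — the neuropil contamination coefficient *c* ∈ [0, 1] is
   estimated per neuron by robust (bisquare IRLS) regression of the somatic
   on the neuropil trace, the scaled neuropil is subtracted, and each 210-frame
   trial (1 s pre + 6 s post stimulus at 30 Hz) is normalised as
   ΔF/F = (F − F₀)/F₀ with F₀ the mean over the 30-frame pre-stimulus
   baseline.  The evoked response is the mean ΔF/F over the 15 frames
   0.5–1 s post-stimulus.
2. **Ensemble classification** — per-neuron stimulus selectivity is the ROC
   AUC for contra vs. ipsi unilateral trials; neurons are contra-/ipsi-coding
   when a one-tailed Wilcoxon rank-sum test (P < 0.05 per direction) is
   significant, otherwise non-coding.  Choice probability (CP), action
   probability (AP), detect probability (DP) and the signed whisker
   responsiveness 2·(AUC(TS, catch) − ½) follow the same ROC machinery.
3. **Photostimulation effects** — neurons are parsed into target zones
   (lateral distance ≤ 15 μm from a spiral site) and network; activation /
   suppression per condition uses one-tailed rank-sum tests (TS vs. TS+PS by
   default).  Derived metrics: activated/suppressed counts, net population
   change, the **linear-sum deficit** (measured TS+PS response minus TS + PS
   responses — a proxy for sensory-evoked suppression of photostimulation
   responses), network whisker-response suppression vs. the number of
   activated targets within 200 μm, bilateral suppression, and
   follower-selectivity summaries.
4. **Behavior** — 4-parameter logistic psychometric fits with the threshold
   stimulus (TS) defined by the 50% crossing, fooling index, photostimulation
   choice bias ΔP(report contra) and reaction-time shifts.
5. **Inference** — within-session effects are isolated by mean-centering the
   two photostimulation conditions per session; Pearson correlations,
   z-scored multiple linear regression, and a control-trial resampling null
   (fake "TS+PS" subsamples drawn from control TS trials) locate the observed
   activation-vs-bias correlation against chance.

The `simulate` module generates complete synthetic sessions — traces,
behavior, target groups, video features — from a documented generative model
with sparse (~14% + 14%) stimulus-coding ensembles, variable opsin efficacy,
sensory-evoked sparing of whisker-responsive targets and a logistic choice
model whose bias per activated target is a known coefficient.

## Worked example

```python
from alloptical.simulate import SimConfig, generate_session
from alloptical.pipeline import (preprocess_session, compute_ensembles,
                                 summarize_photostim, behavior_summary)

cfg = SimConfig(n_neurons=120, n_trials=320, seed=1)
bundle = generate_session(cfg)
pre = preprocess_session(bundle)
print(f"neuropil coefficient: {pre.neuropil.coefficient.mean():.3f} "
      f"(generator truth {cfg.neuropil_coeff_true})")

ens = compute_ensembles(pre.evoked, bundle.trial_table)
print("ensemble classes:", ens["class"].value_counts().to_dict())

summary, _ = summarize_photostim(pre.evoked, bundle.trial_table,
                                 bundle.roi_centroids, bundle.spiral_sites, ens)
cols = ["condition", "n_activated_targets", "n_suppressed_followers",
        "deficit_non_coding", "delta_p"]
print(summary[cols].round(3).to_string(index=False))
print("true responder counts:", bundle.ground_truth.true_activated_count)

metrics, fit, extras = behavior_summary(bundle.trial_table)
print(f"threshold stimulus: {fit.ts:+.3f}  "
      f"P(correct at TS) = {fit.predict(fit.ts):.2f}")
```

prints

```
neuropil coefficient: 0.697 (generator truth 0.7)
ensemble classes: {'non-coding': 74, 'ipsi-coding': 24, 'contra-coding': 22}
condition  n_activated_targets  n_suppressed_followers  deficit_non_coding  delta_p
   contra                   29                      10              -0.037    0.032
     ipsi                   26                       8              -0.041    0.127
true responder counts: {'contra': 26, 'ipsi': 20}
threshold stimulus: -0.066  P(correct at TS) = 0.50
```

Reading this: the robust regression recovers the known neuropil coefficient;
roughly a fifth of neurons land in each stimulus-coding ensemble (14% true
coding plus detection noise); the zone-based activated-target counts track the
generator's true responder counts (plus incidental zone members); non-coding
target groups show a negative linear-sum deficit (their photostimulation
response is suppressed when paired with whisker input); and the fitted
psychometric curve evaluated at the estimated threshold stimulus is 50% by
construction.

## Command line

Each pipeline stage reads and writes a session directory
(`trials.csv`, `traces.h5`, `rois.csv`, `spirals.csv`, `video.csv`, …):

```bash
alloptical simulate --seed 1 --out session/
alloptical preprocess --session session/
alloptical ensembles  --session session/
alloptical photostim  --session session/
alloptical behavior   --session session/
alloptical movement   --session session/
alloptical infer --seed 1 --out results/ session/ other_session/ ...
alloptical report --session session/
```

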