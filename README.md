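# vrgaze

A tested, reusable pipeline for VR eye-tracking dwell-time analysis,
built around a cross-cultural visual-attention study design: five
cultural samples (Czechia, Ghana, Taiwan, eastern Turkey, western
Turkey) free-viewing 3D scenes for 4 s each while a head-mounted
eye-tracker records gaze at 90 Hz. Each scene contains two salient
focal objects wrapped in invisible convex collider meshes (the 3D
analogue of 2D regions of interest, inflated to 110% of object size);
everything else is background. The scientific question is *context
sensitivity*: how much attention a viewer allocates to focal objects
versus the scene around them, the oculomotor signature of analytic
versus holistic cognitive style.

The package covers the full chain:

- **`scene_model`** — convex collider geometry, ray–collider
  intersection, per-sample gaze classification (FO1 / FO2 /
  background / missing);
- **`synthetic_gaze`** — a generative model of 90 Hz gaze streams and
  whole cohorts: semi-Markov alternation between focal and background
  looks, angular noise (accuracy 0.84°, precision 0.16°), sample
  drop-out and blink gaps, group-level dwell distributions;
- **`gaze_events`** — visit detection with the field's merge rule (a
  < 32 ms hit on another object between two looks at the same object is
  bridged) and minimum-duration rule (> 50 ms), dwell times and data
  loss per trial, participant-level aggregation;
- **`quality_control`** — the exclusion cascade (technical failure →
  \>5% data loss → failed validation → ADHD history) and a
  standardized-residual outlier screen for the depth analysis;
- **`stats_engine`** — Welch's heteroscedastic one-way ANOVA,
  Games–Howell post-hocs, Hedges *g*, mixed group × object-type ANOVA
  with ω² and Holm–Bonferroni adjustment, simple main effects with
  generalized η², ANCOVA, and a-priori power analysis via the
  noncentral *F*;
- **`pipeline` / `cli`** — reproducible simulate → process → qc →
  analyze → report runs and a summary-table verification mode.

A distinctive feature is **summary mode**: every statistic that is
mathematically derivable from printed group descriptives (n, mean, SD)
— Welch *F* with

F = [Σ wᵢ(x̄ᵢ − x̄_w)²/(k−1)] / [1 + 2(k−2)Λ/(k²−1)],  wᵢ = nᵢ/sᵢ²,
df₂ = (k²−1)/(3Λ),  Λ = Σ(1 − wᵢ/Σw)²/(nᵢ−1)

— classical ω², pairwise differences with Tukey-HSD-style intervals,
Games–Howell p-values, Hedges *g*, and t-based group CIs — can be
recomputed without any raw data, so published tables are independently
verifiable.

## Worked example

Verify the bundled five-country descriptives table end to end:

```bash
python analysis/02_verify_summary_tables.py
```

prints (abridged):

```
Focal object dwell descriptives (reconstructed CIs, ms)
  Czechia        n=42    1547.14 (506.07)  [1389.44, 1704.84]
  ...
  Total sample   n=242   1309.58 (590.93)  [1234.75, 1384.41]

Welch ANOVA: F(4, 108.84) = 73.94, p = 3.8e-30, omega^2 = 0.386

Pairwise post-hoc reconstruction
  Czechia—Ghana       diff     330 [   47,   613]  p=0.050  g= 0.62 [0.17, 1.06]
  Czechia—Taiwan      diff     859 [  594,  1124]  p=0.000  g= 2.21 [1.70, 2.73]
  ...
```

The Welch test says the five groups differ strongly in mean focal
dwell (about 39% of variance explained); the pairwise rows give the
group contrasts in ms and in standardized units (Taiwanese
participants dwell ~860 ms less per 4-s trial on focal objects than
Czech participants, *g* ≈ 2.2 — the holistic/analytic contrast).

A full synthetic replication (simulate a 40-per-group cohort with
attrition, classify gaze, detect visits, clean, analyze):

```bash
python analysis/03_run_synthetic_study.py
# or: vrgaze run-all --seed 42 --n-per-group 40 --out results/run
```

The numbered scripts under `analysis/` are thin drivers; all
computation lives in `src/vrgaze` and is importable.

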