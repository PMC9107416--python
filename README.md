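# falffmvpa

Multivariate pattern analysis of pre/post resting-state fMRI cohorts based
on the fractional amplitude of low-frequency fluctuations (fALFF), built
for two-arm intervention studies (e.g. transcutaneous vagus nerve
stimulation vs. sham) that ask: *did the treatment leave a lasting imprint
on spontaneous brain activity, and does that imprint relate to behavior?*

The package covers the full analysis chain:

1. **fALFF feature extraction.** For each voxel (or ROI time series) the
   un-filtered BOLD signal is Fourier-transformed, the power spectrum is
   square-rooted to per-bin amplitudes *a(f)*, and

   - ALFF = mean of *a(f)* over 0.01 ≤ f ≤ 0.08 Hz,
   - fALFF = Σ_band *a(f)* / Σ_{f>0} *a(f)* ∈ [0, 1].

   Maps are z-scored within an analysis mask (zfALFF) and sessions are
   compared as Δ = post − pre; positive Δ means increased spontaneous
   activity. ROI means are taken over MNI spheres (3 or 6 mm) or atlas
   labels, optionally intersected with a grey-matter mask.
2. **Classification.** A linear soft-margin SVM with leave-one-out
   cross-validation (CA = correct predictions / n), and sequential
   floating forward selection (SFFS) over the ROI features: greedy
   forward additions maximizing LOOCV accuracy with conditional backward
   removals. The best subset is the smallest one achieving the top CA.
   Reported per subset: CA, sensitivity, specificity, balanced accuracy
   and the diagnostic odds ratio.
3. **Dual permutation controls.** The *traditional* control re-runs LOOCV
   on the chosen subset under relabelled groups (null mean ≈ 50 %). The
   *feature selection control* (FSC) re-runs the entire SFFS search per
   relabelling, so the optimism of selecting features on the same data is
   part of the null; its mean exceeds 50 % and the excess (mean − 50)
   estimates overfitting. Relabelling flips exactly half of each group;
   p = (1 + #{null ≥ experimental}) / (n_perm + 1); effect size
   d_z = (experimental CA − null mean) / null SD. The sizing rule
   n = 4/W² gives the permutations needed to resolve a CA difference W.
4. **Behavioral regression.** Stepwise OLS (AIC/BIC, marginality
   enforced) of hunger/satiety rating differences on subset-ROI Δ-zfALFF,
   the treatment indicator and ROI×treatment interactions, plus per-group
   regressions on a hemispheric asymmetry index (right − left).
5. **Synthetic cohorts.** A generator producing band-limited BOLD-like
   signals (320 volumes at TR 1.5 s by default) with group×session
   amplitude effects injected into chosen ROIs and ratings linearly
   coupled to ROI activity with a group interaction — so every stage is
   testable without real data, and nulls are exactly null.

## Worked example

A synthetic cohort of 17 + 17 subjects with 8 salience-network-like ROIs,
a 2× low-frequency amplitude increase injected into three of them
(post session, treatment arm only):

```bash
cat > demo.json <<'JSON'
{
  "out_dir": "demo_run",
  "synth": {"n_per_group": 17,
            "rois": ["dACC_L","dACC_R","aPFC_L","aPFC_R",
                     "aINS_L","aINS_R","LPC_L","LPC_R"],
            "effect_rois": ["aINS_L","aINS_R","aPFC_L"],
            "effect_size": 2.0},
  "n_perm_traditional": 1000,
  "n_perm_fsc": 100,
  "seed": 42
}
JSON
falffmvpa run --config demo.json
```

Output (about 6 minutes on one core):

```
best subset: aPFC_L aINS_R (CA 88.24%)
traditional control mean 47.10% p=0.0010
FSC mean 69.09% p=0.0099 overfitting 19.09%
```

Reading this: SFFS found a 2-ROI subset of the injected regions that
classifies 88.2 % of subjects correctly under LOOCV. The fixed-subset
null stays near chance (47.1 %), so the accuracy is not a relabelling
artifact (p = 0.001). The selection-aware null reaches 69.1 % on average
— a ≈19 % optimism that searching for a good subset produces even on
relabelled data — yet the experimental accuracy still exceeds it
(p = 0.0099), so the subset carries real group information of roughly
88 − 69 ≈ 19 % beyond what selection alone can manufacture.
`demo_run/` contains the per-subset classification table, both control
summaries (with full null CA distributions), the stepwise regression
table and a manifest tying everything to the master seed; the same run
with the same seed reproduces the CSVs byte for byte.

The bundled ROI catalogs (`falffmvpa.bundled_catalog`) provide the
resting-state-network spheres (radius 6 mm) and a 13-region brainstem
set; the brainstem atlas nuclei are synthetic sphere stand-ins — supply
real atlas label volumes where exact masks matter.

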