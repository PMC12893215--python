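# melophys

Change-point-driven analysis of music-evoked physiological responses.

The package implements a full, reproducible pipeline linking expressive
musical structure to listener physiology:

1. **`synthetic`** — a cohort generator with known ground truth: musical
   feature series (tempo, loudness, spectral centroid, MFCC, harmonic
   tension diameter) with planted change points, expert-style annotation
   events (7 categories: Novel Melody, Return, Resolve/Release, Melodic
   Interaction, Significant Melody, Standout Articulation, Runs/Fast
   Sequence), and per-listener physiology (RR intervals with respiratory
   sinus arrhythmia, respiration waveform, beat-wise blood pressure)
   with planted event-locked responses whose sign can depend on the
   listener's baseline autonomic archetype.
2. **`preprocess`** — raw signals → nine analysis channels at 5 Hz: RR,
   respiratory intervals, SYS/DIA/PP, and instantaneous LF/HF band
   powers and peak frequencies (PLF/PHF/FLF/FHF) from a 50-sample
   Hamming-window STFT, with the HF band centred on the instantaneous
   respiratory frequency Fr(t) ± 0.125 Hz.
3. **`baseline`** — HRV summaries (RMSSD, Poincaré SD1/SD2, Baevsky
   stress index), cohort-standardized PNS/SNS composite indices, and
   k-means stratification into three autonomic clusters.
4. **`changepoints`** — ensemble change-point detection: Gaussian
   mean-shift and nonparametric empirical-distribution costs, solved
   exactly (PELT) or greedily (binary segmentation) across a grid of
   penalties/normalizations/resolutions; consensus thresholding and
   minimum-spacing merging; increase/decrease direction labelling.
5. **`gkf`** — Gaussian-kernel event-density series and the CCA input
   matrices X (n×12 musical) and Y (n×9 physiological, listener-averaged),
   sampled at musical change-point onsets.
6. **`cca`** — canonical correlation analysis with loadings, relative
   covariance shares, Wilks' lambda, surrogate-based variate retention,
   and permutation p-values.
7. **`graph`** — change-point connectivity graphs: concentric rings of
   supra-threshold loadings (|loading| > 0.3), red/blue by sign, with
   music–physiology association edges.
8. **`events`** — event-locked difference analysis: 10-s pre/post
   windows (8/12-s sensitivity), paired t or Wilcoxon by normality,
   Bonferroni correction over the 17 × 9 = 153 category–signal grid.
9. **`individual`** — subject-wise CCA, cosine similarity to the group
   loading pattern, and B-spline GAMs of similarity on baseline and
   demographic predictors with Benjamini–Hochberg correction.
10. **`pipeline` / `cli` / `io`** — configuration, serialization, and an
    end-to-end driver with per-stage derived seeds.

## CLI

```sh
melophys simulate   --config cfg.yaml --out cohort/ --seed 1
melophys preprocess --in cohort/ --out channels/
melophys baseline   --in cohort/ --out profiles.csv --seed 1
melophys detect     --in cohort/ --grid cfg.yaml --out cps/
melophys matrices   --in cohort/ --sigma 2.0 --out matrices/
melophys cca        --x matrices/X.csv --y matrices/Y.csv --surrogates 100 \
                    --permutations 199 --seed 1 --out cca.json
melophys graph      --cca cca.json --out graphs/ --threshold 0.3
melophys events     --in cohort/ --windows 8,10,12 --out events/
melophys individual --in cohort/ --out individual/ --seed 1
melophys run-all    --config cfg.yaml --out results/ --seed 1
```

`cfg.yaml` holds a `PipelineConfig` mapping (see
`melophys.pipeline.PipelineConfig`); every field has a sensible default,
so an empty file works.

## Notes

- Detector-grid penalties, the consensus threshold, merge spacing, and
  the Gaussian-kernel width are configuration with documented defaults.
- PNS/SNS indices are standardized within-cohort (no proprietary
  population norms), which preserves ordering and clustering.
- Intermediate and scratch outputs belong under `scratch/`.
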