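# mmrtf — probabilistic time–frequency mismatch response analysis

`mmrtf` analyzes auditory oddball EEG: repeated presentations of a frequent
"standard" sound interleaved with a rare "deviant" elicit a mismatch
response, and this package estimates that response as a *probability
surface* over the time–frequency plane rather than as an averaged waveform.
It is aimed at evoked-response researchers working with single-channel
(vertex vs linked mastoids) recordings — in particular paradigms like
speech-contrast discrimination in sleeping infants — and at anyone who
needs a tested, scriptable reimplementation of this class of pipeline with
a simulator that provides ground truth.

## The method

For one subject and block, the **MMR_TF** is defined as the probability
that the complex mean of the deviant-minus-standard difference exceeds
zero at each point of a Morlet wavelet decomposition (6 cycles, 128
log-spaced scales, 1.94–48.40 Hz):

- signal estimate `M = | mean_n ( d_rd − s_rs ) |²` over n = 1001 bootstrap
  draws of one random deviant and one random standard trial,
- error estimate `E` likewise from label-blind pairs,
- per scale k, `MM_k = M_k / sqrt(Σ_j M²_jk + Σ_j E²_jk)` (and `EE_k`
  alike), so each scale carries unit energy,
- `p = C(MM)` where `C` is the kernel-smoothed CDF of the pooled MM and EE
  values.

Group analysis is a modified joint DISTATIS: each surface becomes spectral
and temporal cross-product matrices, double-centered and normalized by
their first eigenvalue; condition compromises are means within condition,
the grand compromise the mean of condition compromises; eigenvectors with
pvaf ≥ 1% (pvaf = √λ / Σ√λ) form the projection bases, weighted by the
relative contributions `rc_F = λ¹_F/(λ¹_F+λ¹_T)`, `rc_T = 1 − rc_F`.
Condition means `g` and the grand mean `G` of the projections are scaled
to [0, 1]. Features come from the quasi-likelihood map
`qLE = CDF(B)²(G)` with `B = max_d g^d`, thresholded at 0.8, labeled into
connected components, and summarized by centroids (frequency, latency,
relative probability) of their marginal distributions. The separation of
the two theta components feeds the surprise statistic
`S = −log( dF / (C · dT) )`.

A synthetic sleep-EEG oddball simulator (`mmrtf.synth`) generates
85%/15% standard/deviant blocks (no two deviants in succession, 1200 ms
ISI) over an 11-channel 10–20 montage with 1/f-shaped, delta/theta-heavy
background noise, and injects a parameterized deviant cascade — gamma
(34 Hz, 25 ms), beta (17 Hz, 60 ms), theta-1 (5 Hz, 70 ms) and theta-2
(6 Hz, 220 ms, both thetas sweeping downward after their peak) — so every
stage can be validated against known ground truth. See `docs/methods.md`
for the model, its assumptions, and its measured limits.

## Worked example

```python
from mmrtf.pipeline import RunConfig, run_pipeline

cfg = RunConfig(n_subjects=4, n_trials=200, fs=250.0, n_boot=301, seed=1)
res = run_pipeline(cfg)
print(round(res.report["rc_F"], 4), res.report["feature_names"])
print(res.centroids.head(6).to_string(index=False))
```

prints (elided):

```
0.4962 ['theta-1', 'theta-2', 'theta-3', 'theta-4']
feature condition  freq_hz  latency_ms       rp
theta-1 nonspeech 2.146857       164.0 0.921282
theta-1     vowel 2.040809       172.0 0.936823
theta-1 consonant 2.040809       172.0 0.854599
theta-2 nonspeech 2.984060       444.0 0.923066
theta-2     vowel 2.984060       444.0 0.855287
theta-2 consonant 2.984060       432.0 0.888315
```

`rc_F ≈ 0.50` says the spectral and temporal dimensions contribute about
equally to the group compromise. The centroid table lists, per extracted
feature and condition, the frequency (Hz), latency (ms after onset) and
relative probability of the feature's joint maximum — at this small cohort
size the supra-threshold features sit in the low-theta band, the region
the estimator weights most heavily (see `docs/methods.md`). The same run
from the shell:

```bash
mmrtf run --seed 1 --n-subjects 4 --n-trials 200 --out results/demo
```

writes `config.json`, `report.json`, `centroids.csv`, per-block surfaces
(`surfaces.h5`) and heat maps of the grand and condition compromises.
Individual stages (`mmrtf synth|preprocess|channels|tfr|mmr|group|features`)
exchange HDF5/TSV artifacts so a pipeline can be re-run stage by stage.

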