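# alismoke

Analysis toolkit for cigarette-smoke exposure studies of small-airway
epithelial cells differentiated at the air–liquid interface (ALI).

Repeated whole-smoke exposure during differentiation alters the airway
epithelium: barrier resistance (TEER) drops, ciliary beating declines,
secretory-cell markers shift (MUC5AC up, SCGB1A1 down), and a broad
transcriptional signature appears that can be compared against airway
brushings from human smokers. `alismoke` implements the complete
quantitative chain for such a study, with seeded synthetic-data
generators so every stage can be validated against known ground truth:

1. **Ciliary beat-frequency (CBF) mapping** — each pixel of a 2D+time
   video stack is detrended and transformed to a one-sided power
   spectrum; the pixel is *active* when the in-band peak power exceeds
   `snr_threshold` × the median in-band power, and its CBF is the peak
   frequency. The map yields the % area covered by active cilia and the
   mean CBF (healthy cultures: 5–20 % area, 7–10 Hz).
2. **Adjusted-AUC longitudinal statistics** — an endpoint measured at
   days *d₁ < … < d_k* is condensed to its adjusted AUC (trapezoidal
   area / (d_k − d₁), i.e. the time-averaged level). Because both
   treatments are applied to cultures from the same donor, AUCs are
   analyzed with a repeated-measurement model (fixed factors group,
   treatment, group×treatment; compound-symmetry covariance), and the
   one-sided contrast μ₍g,CS₎ − μ₍g,Air₎ is tested on the within-subject
   degrees of freedom, direction fixed a priori per endpoint.
   Comparative-Ct arithmetic converts adjusted ΔCt AUCs to fold changes:
   `fold = 2^|AUC_air − AUC_smoke|` (lower ΔCt ⇒ higher expression).
3. **Differential expression** — per-transcript OLS with cell-means
   condition coding plus donor covariates (the `~0+group+donorID`
   design), two-sided t-tests, Benjamini–Hochberg q-values, and
   signature selection at q < 0.05. An optional pooled-variance mode
   serves very small paired designs.
4. **Signature transfer** — per-transcript min–max normalization to
   [0, 1] *independently per dataset*, joining on transcripts
   significant in both comparisons, UPGMA clustering on the correlation
   distance 1 − r, cross-validated random-forest ROC/AUC with the
   signature as feature vector, robustness via removal of the ten most
   label-correlated transcripts, and the direction-consistency overlap
   (fraction of shared significant transcripts deregulated the same
   way).

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/01_cilia_frequency_map.py` builds a 100×100×512 video
at 30 fps with a patch covering 10.24 % of the field beating at 8.5 Hz
(noise sd = amplitude/5) and prints:

```
true beating area : 10.24 % at 8.5 Hz
active area       : 11.07 %
mean CBF          : 8.44 Hz
active pixels     : 1107 of 10000
```

— the detected area tracks the true patch (within the criterion's
measured ~1 % false-positive rate) and the mean CBF lands within one
spectral bin (30/512 ≈ 0.06 Hz) of truth. Likewise
`python examples/04_signature_transfer.py` generates two cohorts whose
shared 50-transcript signature has 14 % of directions flipped in vivo
and prints a direction consistency of `43 (86.0%)` of 50 shared
transcripts, with random-forest AUC 1.000 that survives top-10 feature
ablation.

A thin CLI mirrors the library for shell use:

```sh
ali simulate --seed 1 --out demo/
ali cilia --in demo/video.tif --band 2 14 --snr 15 --out demo/map
ali stats --in demo/endpoints.csv --out demo/
ali run --config config.json
```

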