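# mexmri

Quantitative analysis of Magnetization EXchange (MEX) MRI for liver
fibrosis studies in rodents.

MEX acquisitions selectively suppress the free-water signal, wait a delay
`t_LM`, and image; the early recovered signal is dominated by magnetization
exchanged back from semisolid (macromolecular-bound) protons — collagen,
proteoglycans and other matrix components that accumulate in fibrosis.
`mexmri` turns a delay-series of magnitude images into quantitative maps of
the macromolecular fraction and free-water T1, and carries the analysis
through to histology validation and group statistics.

## The model

Each voxel's normalized recovery is a two-pool curve under fast exchange
(τ_exc ≪ T1) and a 90° excitation:

    S(t_LM) / S_eq = F·(1 − e^(−t_LM/τ_exc)) + (1 − F)·(1 − e^(−t_LM/T1))

* **F** — fraction of protons in semisolids (the fibrosis biomarker),
* **T1** — longitudinal relaxation of free water (tracks inflammation),
* **τ_exc** — exchange time between the pools (ms).

Measured curves are normalized by the longest-delay volume and fitted by
bounded trust-region nonlinear least squares. Voxels enter the maps only
when the fit reaches **R² > 0.95**, which automatically rejects blood
vessels and other high-liquid voxels; the whole-ROI summed signal is fitted
once more for the group-level estimate (typically R² > 0.999). F maps are
summarized by normalized histograms and the **high-F fraction** — the
percentage of valid voxels with F > 0.1.

Stained sections (picrosirius red for rats, Masson trichrome for mice) are
quantified by converting RGB images to YCbCr (BT.601 studio swing) and
counting pixels inside inclusive per-channel gates
(PSR: Y 0–184, Cb 121–144, Cr 136–255; MT: Y 67–255, Cb 129–255,
Cr 119–159). Group comparisons use Welch's t-test, paired t-tests across
timepoints, one-sided tests against inflammation scores, and Pearson
correlation with 95% prediction bands.

Everything is exercised on synthetic phantoms generated by the package
itself (liver-shaped ROI, vessels, smooth fibrosis heterogeneity,
imperfect-suppression baseline, Rician noise), with named presets carrying
the rat/mouse group means.

## Worked example

```python
from mexmri import (RAT_SCHEDULE, NoiseModel, PSR_GATE, fit_map, fit_roi,
                    high_f_fraction, make_phantom, make_stain_image,
                    segment_stain, simulate_series)

phantom = make_phantom("rat_fibrosis", (32, 32, 1), seed=0)
series = simulate_series(phantom, RAT_SCHEDULE,
                         NoiseModel(snr=50, suppression=0.99, seed=0))
pmap = fit_map(series)
roi = fit_roi(series)
print(f"valid voxels: {pmap.valid.sum()} / {series.roi.sum()}")
print(f"ROI fit: F = {roi.params.F:.4f} ± {roi.ci95[0]:.4f}, "
      f"T1 = {roi.params.T1:.0f} ± {roi.ci95[1]:.0f} ms, R² = {roi.r2:.5f}")
print(f"high-F fraction: {high_f_fraction(pmap):.2f}%")

img, _ = make_stain_image(PSR_GATE, 0.1187, (200, 200), seed=0)
print(f"PSR in-gate: {segment_stain(img, PSR_GATE).fraction_percent:.2f}%")
```

prints

```
valid voxels: 559 / 560
ROI fit: F = 0.1074 ± 0.0016, T1 = 1861 ± 30 ms, R² = 0.99999
high-F fraction: 68.87%
PSR in-gate: 11.87%
```

The phantom's true tissue-mean F is 0.100; the fitted 0.107 reflects the
simulated 99% (imperfect) suppression, which biases F upward by up to
0.01 here — the residual baseline is absorbed into the fast-exchange term.
One vessel voxel fails the R² gate and is excluded. The stain image was
constructed with exactly 11.87% in-gate pixels and the gate recovers that
percentage exactly.

The same stages are available from the shell:

```bash
mexmri simulate --preset rat_fibrosis --size 32 --seed 0 --out sim/
mexmri fit --series sim/series.nii.gz --mask sim/mask.nii.gz \
           --schedule sim/schedule.json --out fit/
mexmri histology slide.png --stain PSR --out stain.csv
mexmri stats --table group_table.csv --out stats/
mexmri report --out run/ --seed 0        # full simulate→fit→analyze→stats chain
```

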