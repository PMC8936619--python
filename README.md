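# gastricnet

Analysis toolkit for **gastric–brain phase coupling** at rest: from raw-like
electrogastrogram (EGG) and fMRI time series to the *gastric network* — the
set of voxels whose BOLD signal is phase-locked to the stomach's ~0.05 Hz
electrical rhythm above a cross-participant surrogate chance level — with
cluster-based group inference, effect sizes, anatomical annotation along
parcellations and cortical gradients, and cohort-level covariate statistics.

The package is aimed at researchers analysing simultaneous EGG/fMRI
resting-state recordings, and at anyone who wants a fully tested, synthetic
re-implementation of this analysis style with analytically known ground
truth.

## The model

The gastric rhythm is a slow (0.033–0.066 Hz, "normogastric") electrical
oscillation of the stomach, measurable with cutaneous abdominal electrodes.
For each participant the EGG channel with the sharpest normogastric
spectral peak (Welch estimate, 200-s windows, 150-s overlap, peak power
> 15 µV²) defines the gastric peak frequency f₀. Both the EGG and every
voxel's cleaned BOLD series are band-passed f₀ ± 0.015 Hz with a zero-phase
FIR filter, trimmed by 15 volumes per edge (450 volumes at TR 2 s → 420
retained, 840 s), and converted to instantaneous phase via the Hilbert
transform. Coupling is quantified by the phase-locking value

    PLV = | (1/T) Σₜ exp( i(φ_voxel(t) − φ_gastric(t)) ) |

which is 1 for any constant lag and near 0 without a stable lag. Because
narrow-band signals are autocorrelated, chance level is estimated
empirically: each participant's BOLD phases are paired with every *other*
participant's gastric phase, and the voxelwise median of those surrogate
PLVs is the chance PLV. Coupling strength = empirical − chance. Group
inference compares the two with a cluster-mass sign-flip permutation test
(voxel threshold p < 0.005 one-sided, cluster threshold Monte-Carlo
p < 0.025 one-sided, max-statistic corrected); effect size is the paired
Cohen's d = t/√n.

The synthetic cohort generator plants a compact voxel region whose BOLD
carries `cos(φ_gastric + delay + η)` with i.i.d. von Mises(0, κ) jitter η,
so the long-run PLV of a coupled voxel is known in closed form:
PLV → I₁(κ)/I₀(κ). Drift, a shared CSF-like signal, aliased cardiac
pulsation, and broadband noise are layered on top, giving every pipeline
stage a measurable ground truth.

## Worked example

```python
import gastricnet as gn
from gastricnet.pipeline import load_cohort, run_group

cfg = gn.SimulationConfig(n_participants=8, grid_shape=(12, 12, 6),
                          n_coupled_voxels=40, seed=3)
out = gn.simulate_cohort(cfg, "cohort")       # NIfTI + TSV + CSV + manifest
res = run_group(load_cohort(out), n_perm=200, seed=0)

truth = gn.make_ground_truth(cfg)
net = res.network_mask
print("planted voxels recovered:",
      (net & truth.coupled_mask).sum() / truth.coupled_mask.sum())
print("false positive fraction:",
      (net & ~truth.coupled_mask).sum() / (~truth.coupled_mask).sum())
print(res.cohort_table[["egg_f0", "mean_coupling", "lf_hrv"]].head(3))
```

prints (seed 3):

```
planted voxels recovered: 1.0
false positive fraction: 0.0
   egg_f0  mean_coupling       lf_hrv
0   0.045       0.491807  1248.002909
1   0.050       0.679133  1242.566381
2   0.045       0.677953  1248.123687
```

All 40 planted voxels are recovered with no false positives; per-participant
EGG peak frequencies land inside the configured 0.041–0.057 Hz range and the
mean coupling strength (empirical − chance PLV over the detected network) is
far above zero, as planted. The same objects feed the annotation layer
(`parcel_overlap`, `gradient_profile`, `gradient_null`) and the covariate
battery (`robust_regression`, `two_sample_t`, `jzs_bf_two_sample`,
`adjust_pvalues`, `power_sample_size`, `roi_covariate_scan`,
`voxelwise_glm`).

A command-line interface mirrors the two batch entry points:

```bash
gastricnet simulate --config cohort.json --out DIR --seed 1
gastricnet covary --cohort cohort.csv --coupling roi.csv --method robust --adjust fdr
```

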