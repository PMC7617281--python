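# ssfse-t2

Quantitative T2 mapping for single-shot fast spin echo (SS-FSE) MRI of
the fetal brain: slice-profile-corrected extended-phase-graph (EPG)
signal dictionaries, voxelwise dictionary matching into T2 and
fit-quality maps, and a numerical fetal phantom with a partial-Fourier
k-space forward model for sequence selection and validation.

## The problem

Fetal motion rules out conventional relaxometry sequences, so fetal T2
measurement has to be built on the clinical workhorse: T2-weighted
SS-FSE slices acquired at several echo times. Those signals are far
from mono-exponential. A long train of refocusing pulses with realistic
(finite-bandwidth) slice profiles produces stimulated-echo pathways
that slow the apparent decay, and the effective flip angle varies
continuously across the slice. Fitting `S0 * exp(-TE/T2)` to such data
gives systematically wrong T2.

This package instead simulates the actual signal physics and fits by
dictionary matching:

1. **Slice profiles.** Each RF pulse (excitation `θ0`, first refocusing
   `θ1`, steady refocusing `θ2..N`) is Bloch-simulated through its
   waveform, and the through-plane flip angle is defined from the
   longitudinal magnetization at the end of the pulse,
   `θ(z) = arccos(Mz(z, t_end))`.
2. **EPG echo trains.** For every slice position z, the echo train is
   simulated with the extended phase graph formalism (configuration
   states F(+k), F(−k), Z(k)), and the complex signals are integrated
   across the slice: `S(T2) = ∫ S_EPG(θ(z), T2, T1, ESP) dz`.
3. **Dictionary.** Entries `S_T2` tabulate the signal at the echo that
   encodes the k-space centre of each contrast (the TE is set by the
   partial-Fourier "halfscan" factor under linear ordering), for
   T2 = 25..3000 ms at 1 ms steps with T1 fixed at 3000 ms (SS-FSE
   signals depend only weakly on T1; the residual bias is under 2% over
   the physiological T1 band).
4. **Matching.** Per voxel,
   `T2_hat = argmax_T2 (S_T2/|S_T2|) · (s/|s|)`, with fit quality
   `E = 1 − best scalar product ∈ [0, 1]`.

The numerical phantom (elliptical maternal body, circular amniotic
fluid pocket, procedural fetal brain with WM mean T2 = 216 ms and GM
mean T2 = 129 ms) is pushed through an EPG + partial-Fourier k-space
forward model and refitted, reproducing the experiment that selects the
third echo time from {250, 300, 350, 400} ms.

## Worked example

```python
import numpy as np
from ssfse_t2 import (MultiContrastVolume, T2DictionaryModel, SequenceParams,
                      build_dictionary)
from ssfse_t2.phantom import (make_fetal_phantom, forward_acquire,
                              default_noise_sigma)

seqs = [SequenceParams.from_te_preset(te) for te in (80, 180, 400)]
dictionary = build_dictionary(seqs)            # T2 = 25..3000 ms @ 1 ms, T1 = 3000 ms

phantom = make_fetal_phantom(size=256, seed=1)
sigma = default_noise_sigma(phantom)           # WM SNR ~ 30 at TE 80
acqs = [forward_acquire(phantom, s, sigma, seed=i) for i, s in enumerate(seqs)]

volume = MultiContrastVolume(volumes=[a.image[..., None] for a in acqs],
                             tes=dictionary.tes,
                             mask=(phantom.pd_map > 0)[..., None])
result = T2DictionaryModel(volume, dictionary).fit()
print(result.summary())
print(result.roi_statistics(phantom.label_map[..., None], erode=1))
```

Output:

```
T2 dictionary fit
============================================
voxels fitted        38133
voxels flagged       0
T2 median [IQR] ms   101.0 [77.0, 385.0]
fit quality E median 2.99e-04
dictionary hash      d3c1e32fd573656f

 label     n     mean_t2      sd_t2
     1 23210   84.525506  24.982039
     2  8658 2191.841418 520.382143
     3  2113  221.231425  22.198760
     4  1106  128.788427  15.667660
     5   321  132.433022  15.433811
     6   154 2264.922078 511.878018
```

Label 3 is fetal white matter: fitted 221.2 ± 22.2 ms against a
ground-truth ROI mean of 217.8 ms. Labels 4/5 are cortical and deep
grey matter (128.8 and 132.4 ms vs 130.3 ms truth). Label 1 is the
maternal body (T2 = 80 ms; the upward shift reflects the Rician noise
floor), label 2 the amniotic fluid, where T2 ≈ 2000 ms sits at the flat
end of the dictionary and is estimated with low precision — exactly the
behaviour seen on scanner data. The median fit quality E ~ 3e-4 means
the dictionary shapes explain the voxel signals almost perfectly.

The same operations are scriptable from the shell:

```bash
ssfse-t2 build-dict --seq-config seqs.yaml -o dict.csv
ssfse-t2 fit --in te80.nii.gz --in te180.nii.gz --in te400.nii.gz \
         --tes 80 --tes 180 --tes 400 --mask mask.nii.gz --dict dict.csv -o maps/
ssfse-t2 simulate-phantom --size 256 --seed 1 -o phantom/
ssfse-t2 te-experiment --te3 250 --te3 300 --te3 350 --te3 400 -o summary.csv
ssfse-t2 roi-stats --map maps/t2_map.nii.gz --labels labels.nii.gz --erode 1 -o stats.csv
```

## Scope

Upstream steps of the in vivo pipeline — slice-to-volume motion
correction, super-resolution, denoising, masking and segmentation — are
out of scope; the fitter assumes co-registered per-TE volumes and
refuses misaligned inputs.
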