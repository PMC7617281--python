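# Methods

## Signal model

An SS-FSE shot is one excitation followed by `tse_factor` refocusing
pulses at a fixed echo spacing (ESP). Phase-encode lines are acquired
in linear order starting from the truncated side of k-space, so with a
partial-Fourier ("halfscan") factor `h` and `N_full = matrix / SENSE`
full-sampling line positions, the k-space centre — which sets the
effective TE — is encoded at echo `round((h − 0.5) · N_full)`. The
built-in presets follow the clinical protocol (TE 80/180/400 ms at
halfscan 0.587/0.709/0.966, ESP 6.2/6.1/6.1 ms, train lengths
82/99/135); the arithmetic places their centre echoes at 13/30/67,
i.e. actual TEs of 80.6/183/408.7 ms. The TE-400 preset keeps its
nominal label; the simulated echo index is the source of truth.

Because shot TRs are tens of seconds, every train starts from thermal
equilibrium and TR does not enter the simulation.

### Slice profiles

RF pulses are modelled as Hann-windowed sincs (default duration 3 ms,
time-bandwidth 4) with the slice-select gradient chosen so the
small-tip FWHM equals the slice thickness (2.5 mm), and the amplitude
calibrated to the nominal on-resonance flip. The vendor's waveforms and
refocusing schedule are proprietary, so the three nominal angles
(excitation 90°, first refocus, steady refocus — both defaulting to
180°) are configurable, and every experiment records its pulse
configuration. The framework's mathematics is pulse-agnostic.

Each pulse is Bloch-simulated independently from equilibrium
(piecewise-constant rotations about the effective field; relaxation
during the ~3 ms pulse is neglected by default, though the stepper
accepts finite T1/T2), and its through-plane flip-angle profile is
`θ(z) = arccos(Mz(z, t_end))`. This collapses the full magnetization
state to one angle per position — the approximation that makes the EPG
train tractable — and is exact on resonance.

### EPG echo trains and slice integration

The train is simulated per slice position with the extended phase
graph: RF mixing of (F(+k), F(−k)*, Z(k)) triplets, one unit of
gradient dephasing per half echo spacing, relaxation attenuation, and
the echo read from F(0). States are tracked to order 2·n_echoes, which
is exact (higher orders cannot refocus into F(0) within the train);
crushers are absorbed into the dephasing operator as usual. The CPMG
convention is used (refocusing 90° out of phase with excitation). The
implementation is a numba kernel batched over (T1, T2) pairs; a
transparent `EPGStateSet` class exposes the three operators for
state-level property tests. Correctness is pinned three ways: the
ideal-CPMG closed form (error < 1e-10), an equispaced-phase isochromat
ensemble whose mean transverse magnetization equals F(0) by discrete
Fourier orthogonality (agreement ~1e-15, asserted < 1e-4), and
kernel-vs-state-class equivalence.

Signals are integrated across the slice with uniform quadrature over 64
points spanning ±2 slice thicknesses, and the magnitude of the complex
mean is taken (acquired images are magnitude). The raw integral carries
a slowly converging common-mode scale from the discretised slice edges
(~0.9% change on halving the spacing), but matching is scale-invariant:
the **normalized** signal shape changes by < 0.03% and T2 estimates in
the tissue range are unchanged, which is the convergence that matters.

### Dictionary and matching

The dictionary tabulates the slice-integrated magnitude at each
contrast's centre echo for T2 = 25..3000 ms in 1 ms steps (2976
entries) at fixed T1 = 3000 ms. Entries are stored unnormalized;
normalization happens at match time. Matching maximises the normalized
scalar product by exhaustive search (2976 × 3 dot products per voxel is
cheap; no compression), with ties resolved to the smaller T2 and
degenerate voxels (non-finite, or no positive element) flagged as NaN
and excluded from all statistics. Fixing T1 is justified empirically:
over T1 ∈ {2400, 3600} ms (a ±20% band standing in for the unpublished
physiological spread) and T2 ∈ [100, 500] ms, the worst relative T2
bias against the T1 = 3000 ms dictionary is 0.9%.

The mono-exponential baseline (`min ‖S0 e^(−TE/T2) − S‖²`, log-linear
initialisation, nonlinear refinement) exists to quantify what the
dictionary buys: on slice-integrated reduced-flip-angle signals with
true T2 = 200 ms it returns ~262 ms (stimulated-echo pathways slow the
apparent decay, so the exponential fit overestimates), while matching
recovers 200 ± 1 ms.

## Numerical phantom and forward model

The phantom is a 2D quantitative slice on a 256² grid: an elliptical
maternal body (T1 = 1000, T2 = 80 ms), a circular amniotic-fluid pocket
(T1 = 2800, T2 = 2000 ms), and a procedural fetal brain — a cortical
ribbon around white matter with two deep-grey nuclei and small CSF
spaces, whose outline is perturbed by seed-dependent low-order
harmonics. Fetal tissues take neonatal-like baselines scaled by +20% in
T1 and +40% in T2 (the fetal brain's higher water content), chosen so
the scaled means are WM T2 = 216 ms and combined cortical/deep GM
T2 = 129 ms; a smooth multiplicative random field (3% coefficient of
variation) adds realistic spatial heterogeneity. Proton densities are
0.80/1.00/0.85/0.90/0.90/1.00 for body/fluid/WM/cGM/dGM/CSF.

The forward model computes the full slice-integrated echo train per
pixel — cached over (T1, T2) pairs quantized on a relative grid (0.4%
in T2, 1% in T1, both below the fit's discrimination) — and assembles
k-space line by line: the row acquired at echo e is taken from the FFT
of the image whose pixel values equal the train signal at echo e.
The phantom grid is the reconstruction grid; the acquisition samples
the central `matrix/SENSE = 144` line positions, with the
partial-Fourier window inside them, and unacquired rows stay zero
(plain zero-fill + inverse FFT, no homodyne/POCS). Complex Gaussian
noise is added before the magnitude; the default level sets WM
magnitude SNR ≈ 30 at TE 80 (a plausible clinical figure). No SENSE or
coil sensitivities are modelled, and the simulation is single-slice
(through-plane motion and slice-to-volume reconstruction live
upstream). With a matched matrix and halfscan = 1 the model reproduces
the row-wise-filtered FFT oracle to machine precision.

What the phantom does **not** emulate: a real neonatal relaxometry
slice (the geometry is procedural), coil arrays, B0/B1
inhomogeneity, motion, and multi-compartment/partial-volume decay
within a voxel. Passing tests therefore demonstrate the correctness and
self-consistency of the signal model and fitting chain under realistic
acquisition artifacts — not in vivo accuracy.

## TE-selection experiment

For each candidate third TE ∈ {250, 300, 350, 400} ms the experiment
simulates the {80, 180, TE3} acquisitions (sharing the noisy TE-80/180
images across candidates), rebuilds the matching dictionary per TE set,
fits, and reports mean and SD of (predicted − truth) over WM and
combined-GM ROIs after one-pixel in-plane erosion. At the default
noise, WM error SD falls monotonically with TE3 (≈26 → 22 ms) — the
longer third TE adds T2 encoding — and mean errors sit near ±3 ms.

Two caveats are worth stating because they are physics, not bugs.
First, magnitude (Rician) noise inflates the weakest TE element, so
voxel T2 is biased slightly upward (~+2 ms in WM at this SNR); combined
with ringing of the very bright fluid into the thin cortical ribbon at
long TE (~−3 ms in GM, noiseless), individual ROI means can brush or
slightly exceed 3 ms depending on the noise realisation. Second, GM
(T2 = 129 ms) at TE3 = 400 has per-voxel SNR ≈ 3.6, so its error SD is
noise-floor-dominated and can tick up at the last TE3 even though WM
improves monotonically. A signal-domain Monte Carlo (no k-space step)
reproduces both effects at the same SNR.

## Numerical choices and limitations

- z-grid: 64 uniform points over ±2 slice thicknesses; convergence
  assessed on the normalized signal shape (above).
- Dictionary grid: 1 ms resolution bounds the quantization error at
  0.5 ms; ties break toward smaller T2.
- Exponential fits above T2 = 5000 ms (e.g. constant signals) are
  flagged rather than reported.
- Echo-index arithmetic is clipped to the train and refuses
  configurations whose centre echo falls outside it.
- Dictionary CSV serialization uses 17 significant digits; round-trips
  are bit-exact and carry a provenance hash of the full sequence
  configuration.
- Estimator precision is bounded by the 3-TE protocol itself: with
  every TE element at SNR 20 the median relative T2 error over
  [100, 400] ms is ~6%, dropping below 5% from SNR 25.
- Very long T2 (amniotic fluid, ~2000 ms) sits on the flat part of the
  signal manifold and is estimated with low precision by design; the
  target range is fetal tissue (~100–400 ms).
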