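# Methods

## The problem

A cryo-electron tomogram is reconstructed from a tilt series collected over
a restricted angular range (typically ±40° to ±60°) at very low electron
dose. Two degradations follow directly from the acquisition: heavy shot
noise, and the *missing wedge* — the wedge-shaped region of Fourier space
that no projection samples, which elongates every density along the beam
axis and distorts its shape. Both are irreversible in any single tomogram,
so there is no experimental ground truth to learn from.

This package implements a knowledge-transfer restoration: training pairs
with genuine ground truth are *manufactured*, either by mapping a
subtomogram average back into each raw particle's orientation (strategy 1)
or by simulating the entire degradation process on known structures
(strategy 2). A 3D U-Net trained on such pairs learns the mapping from
degraded to clean densities and is then applied to unseen data by tiled
prediction. The restored volumes are simultaneously denoised and
wedge-compensated; the price, inherent to regression on low-SNR data, is
the loss of high-frequency detail — restored maps are reliable at the
level of overall shape and conformation, not high-resolution features, and
the approach only restores structures similar to what it was trained on.

## Specimen model and conformational sampling

Structures are represented as pseudo-atomic point models (PDB input or
generated toys). The built-in `disc_with_arms` toy mimics a nucleosome
with flexible linker DNA: a rigid disc-shaped core (radius 26 Å,
half-thickness 7 Å) carrying two ~28 Å arms that leave the rim
tangentially and curve out of plane.

Flexibility is modelled with a standard anisotropic elastic network model:
unit-constant harmonic springs join every atom pair within a distance
cutoff (default 8 Å for atomistic models, 16 Å for coarse pseudo-atom
toys; there is no single published convention, so both are parameters).
The 3N×3N Hessian is diagonalised exactly; modes are indexed 1-based, the
first six are zero-frequency rigid-body motions, and deformations start at
mode 7. For the toy nucleosome the low deformational modes move the arms
3–6× more than the core, as expected for appendages on a rigid body; the
standard conditions deform along modes 7 and 13. Conformational ensembles are
drawn by displacing along chosen modes with independent uniform amplitudes
in [−250, 250] (ENM-native units; `mode_rmsd_per_unit_amplitude` converts
— for a 200-atom toy, amplitude 250 on mode 7 corresponds to ≈18 Å RMSD,
i.e. visibly swinging arms). Mode displacement preserves the centroid
exactly because deformational eigenvectors are orthogonal to the
translational null space.

Models are rasterised as sums of isotropic Gaussians with width
σ = resolution/(π√2), the common pdb2mrc convention; each atom's kernel is
normalised to its weight before clipping, so integrated density equals
total weight up to edge clipping.

## Forward model

Volumes are cubic grids indexed (z, y, x) with z the beam axis and y the
tilt axis; rotations are intrinsic ZYZ (rot, tilt, psi) about the voxel
box//2, matching STAR-table conventions, with shifts applied after
rotation.

The projector integrates along tilted rays using per-angle sparse bilinear
interpolation operators; backprojection is the literal matrix transpose,
so the pair is adjoint to machine precision (a property the test suite
asserts at 1e-4 relative on random volumes). At 0° tilt the projection is
exactly the axis sum; in-plane mass is conserved to <0.1% for compact
phantoms.

CTF modulation uses the standard weak-phase form
CTF(f) = −√(1−A²)·sin χ − A·cos χ with
χ = πλΔz f² − (π/2)C_s λ³ f⁴ and the relativistic electron wavelength;
defaults are 300 kV, 3 µm underfocus, C_s 2.7 mm, 7% amplitude contrast,
constant per tilt (no defocus gradient). White Gaussian noise is added
per stack with σ = √(var(signal)/SNR) — the variance-ratio definition of
SNR — and the simulation pipeline orders the steps as in acquisition plus
correction: project → CTF-modulate → add noise → phase-flip (multiply by
sign CTF) → reconstruct.

Reconstruction is weighted back-projection: exact ramp |k| along the
in-plane axis perpendicular to the tilt axis, backprojection, scale
π/(2·n_tilt). One deliberate deviation from the naive algorithm: the
reconstruction's Fourier transform is restricted to the region the scheme
actually samples (`enforce_support=True`). Real-space smearing in a
finite box otherwise leaks ~15% of spectral power into the wedge as sinc
tails — an artefact of the small desk-scale boxes — whereas
production reconstruction programs based on central-slice Fourier
insertion produce the sharply empty wedge familiar from tomogram FFTs.
Enforcing the support reproduces that behaviour and gives the restoration
network the honest version of the problem (a genuinely empty wedge to
fill). The wedge mask itself treats a tilt at θ as sampling the same
central plane as θ±180°, is Friedel-symmetrised with OR (assigning the
even-box Nyquist plane to the sampled region), and always samples DC and
the tilt axis.

## Training pairs

Strategy 1 transforms a reference map into each particle's frame using its
alignment parameters (the stored transform maps reference → particle; an
`invert_transforms` flag accommodates packages using the opposite
convention). The reference is used as-is — not re-modulated by the CTF —
since it stands for a corrected, high-SNR average; a flag could re-degrade
it if ever needed. Strategy 2 renders a conformation, applies a random
rigid transform (uniform orientations, cos-uniform tilt; shifts uniform
within ±box/16), and degrades it through the forward model.

All pairs are z-scored per volume (mean 0, SD 1); a constant volume maps
to zeros with a degenerate flag rather than NaNs. Every stochastic draw
(transform, noise seed) is recorded in a JSON manifest from which the pair
set regenerates bit-identically — the hash-equality contract the tests
enforce.

## Network and training

The restorer is a plain 3D U-Net: per level two 3×3×3 convolutions with
leaky-ReLU (slope 0.1), 2× max-pool down, nearest-neighbour upsampling and
skip concatenation up, 1×1×1 output convolution, channel width doubling
per level. Layers, backpropagation and the Adam optimiser are implemented
directly in NumPy (channels-last, k³ shifted matrix products; the input
gradient is the exact transposed convolution), with gradient correctness
pinned against finite differences in the test suite. Everything is
float32 and fully deterministic per seed.

Two presets:

| preset | depth | base channels | patch | loss | lr | use |
|---|---|---|---|---|---|---|
| full-scale | 3 | 32 | 64³ | L2 | 3e-4 | full-size runs |
| desk | 2 | 8 | 32³ | L2 | 1e-3 | tests, CPU-scale experiments |

The desk preset (~89k parameters) trains with batch 4 and random 24³
crops of the 32³ pairs; 500 iterations take ≈4 min on one CPU core. The
network is fully convolutional, so any patch size divisible by 2^depth
works at prediction time regardless of the training patch. No
augmentation is applied by default. Training splits off a seeded 10%
validation set and records per-iteration training loss plus periodic
validation loss.

Whole volumes are restored tile-wise: overlapping patches (default 64³,
overlap 16) predicted independently and recombined by central cropping —
each output voxel comes from the single tile whose centre is nearest
(midpoint partition of the overlap), which keeps prediction bit-reproducible
and avoids seam averaging. Volumes smaller than a patch are zero-padded,
predicted, and cropped.

## Evaluation

**Region SNR (dB).** Real data has no ground truth, so SNR is estimated
from paired signal/background regions on a micrograph (an average of ~10
consecutive slices; averaging n independent-noise slices reduces noise
variance n-fold). Per pair, with background mean μ_b and variance v_b and
signal pixels x_s, the signal is s = x_s − μ_b with variance v_s, and the
estimate is the mean over pairs of 10(log₁₀ v_s − log₁₀ v_b). Variances
are unbiased (n−1) sample variances; the estimator is exactly invariant
to global shift and scale. Regions are user-chosen; a tiling helper can
propose pairs as a convenience.

**Correlation and wedge occupancy.** Pearson correlation against ground
truth is the fidelity metric for simulated data. Wedge occupancy — the
fraction of non-DC spectral power inside the missing wedge — quantifies
compensation: a WBP input has an empty wedge (fraction ~0), a white
spectrum would put the mask's voxel fraction there, and restoration moves
volumes from the former toward the latter.

**Template matching.** Exhaustive rotational search on a uniform ZYZ grid
with Fourier-accelerated normalized cross-correlation per orientation
(`skimage.feature.match_template`), keeping the per-voxel best
orientation, then greedy non-maximum suppression (ties break toward
smaller coordinates). A brute-force spatial-domain oracle pins the NCC
map to 1e-6 in the tests. Matched peaks are paired one-to-one to known
coordinates greedily by correlation within a radius (default half the
template box), yielding per-axis offsets and RMS. No wedge-weighted
correlation is implemented — the point under test is that restoration
makes plain correlation sufficient.

## Desk-scale study conditions

The standard closed-loop experiment (`workflows.closed_loop_desk_run`)
simulates 200 training pairs of 32³ toy nucleosomes at 4.44 Å/voxel,
SNR 0.1, ±40° coverage with 2° steps, CTF as above — the hardest
condition family exercised on simulated data — trains the desk preset for
500 iterations, and evaluates 20 held-out particles. Typical outcome:
median CC(input, truth) ≈ 0.2, median CC(restored, truth) ≈ 0.85, wedge
occupancy increased for 100% of held-out particles.

The picking benchmark (`workflows.tomogram_picking_benchmark`) simulates
a 128³ tomogram containing 8 rigid toy particles at SNR 0.1, ±60°,
restores it with the closed-loop model (trained at ±40° — restoration
generalises across the easier wedge), and template-matches both raw and
restored tomograms on a 90° angular grid. Particle orientations are drawn
from that same grid: with continuous orientations a 90° search's
quantisation error (several voxels, present even on noise-free data)
would dominate localisation and mask the effect being measured. With the
confound controlled, localisation reflects noise and wedge effects only;
typical outcome: all 8 particles recovered at zero offset on the restored
tomogram, and per-particle template correlation ≈0.9 restored vs ≈0.3
raw. A finer angular search would remove the confound directly at ~10×
the compute.

## What the synthetic data does and does not show

The generator emulates the geometry and statistics that make tomogram
restoration hard — tilt-limited sampling, CTF oscillation and phase
flipping, strong white noise, continuous conformational heterogeneity —
and passing the closed loop shows the whole chain (pair manufacture,
training, tiled prediction, evaluation) works end to end. It does not
emulate structured noise sources (detector correlations, radiation
damage, alignment errors, gold fiducials), crowding by untrained
structures, or defocus gradients across the field; conclusions about real
micrographs require real data at full scale. The known limitations of the
approach itself carry over from the underlying method: only trained
targets restore faithfully, and high-frequency information is not
recovered.

## Numerical choices and degenerate inputs

- Rigid-body modes (1–6) are rejected for displacement; a disconnected
  spring graph raises with its component count rather than silently
  adding zero modes.
- Trilinear interpolation everywhere (rotations, rays); round-trip
  contracts are stated as correlation bounds (>0.99), not bit equality.
- Zero-variance volumes: normalization returns zeros with a flag;
  Pearson correlation raises rather than returning NaN.
- Single-tilt stacks reconstruct (one smeared plane) — degenerate but
  valid.
- NCC threshold ≥1 returns an empty match list with a warning.
- Checkpoints are single-file NumPy archives carrying weights, the
  architecture configuration, the normalization tag and the training
  manifest hash; prediction is a pure function of (weights, input).
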