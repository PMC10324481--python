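# Methods

## Crystallographic model

All cells are primitive orthogonal boxes (space group P1, angles 90°);
maps are periodic real fields sampled on regular voxel grids with the
convention that voxel index `i` on an axis of `n` voxels lies at fractional
coordinate `i/n` (0-based, half-open, index `n` wraps to 0).

Structure factors are computed by direct summation over point scatterers,

    F(h,k,l) = Σ_j f_j · exp(−B_j s²/4) · exp(+2πi h·x_j),   s² = 1/d²,

with `f_j` the atomic number and `B_j` an isotropic displacement parameter
(default 15 Å²) whose Gaussian attenuation suppresses series-termination
ripple. This point-scatterer-plus-B model reproduces the qualitative
appearance of small-molecule maps without a form-factor table; a
multi-Gaussian form factor would slot into the same attenuation hook.
Reflections are enumerated Friedel-uniquely over the sphere `d ≥ d_min`
(boundary inclusive; of each Friedel pair the lexicographically larger index
triple is stored). F(0,0,0) — which experimental data never include — is
carried separately and excluded from synthesis by default, so density maps
are zero-mean; closed-form tests can opt back in.

Density and Patterson maps are synthesized by scattering the coefficients
(values and conjugates at ±h) onto the FFT grid and transforming with the
−2πi inverse convention and 1/V prefactor. The Patterson synthesis uses
squared amplitudes and zero phases, making it exactly real and
centrosymmetric; it equals the circular autocorrelation of the band-limited
density times V/N (N = voxel count), a relation used as an oracle in the
tests. One numerical subtlety: when `d_min` equals exactly twice the grid
spacing, reflections on the Nyquist shell alias +h and −h onto one FFT bin,
where squared-amplitude synthesis (2|F|²) and density autocorrelation
(4 Re²F) legitimately differ; the oracle identity therefore holds strictly
inside Nyquist, and the shipped dataset configurations (d_min 1.5 Å at
0.5–0.6 Å spacing) are far inside.

Map normalization is affine min-max per map, `v' = 2(v−min)/(max−min) − 1`;
a symmetric divide-by-max-|v| mode is available. The affine form was chosen
because the target normalization is described by its extrema; constant maps
normalize to all-zero rather than raising so degenerate fixtures pass
through the pipeline.

## Data generation

Each training example is one heavy-atom dipeptide in a cubic P1 cell:
center of mass translated to the cell center (removing the translation the
Patterson map cannot see), structure factors to 1.5 Å, density and
Patterson synthesis on the configured grid, per-map normalization.
Dipeptides come either from parsed PDB files (adjacent residue pairs, first
altloc, hydrogens and HETATM dropped, numbering gaps treated as chain
breaks) or from the built-in generator, which assembles idealized geometry
from internal coordinates: standard bond lengths and angles, trans peptide
bond, backbone φ/ψ drawn from broad α/β rectangles, side-chain torsions
uniform, and Cα chirality forced L by construction (the signed volume
(N−CA)·[(C−CA)×(CB−CA)] is kept positive, the value an ideal L-alanine
gives). Rings are idealized planar and proline is approximate — the
generator supplies plausible, deterministic geometry, not energy-minimized
conformers.

Truncation to dialanine keeps N, Cα, C, O, Cβ per residue and renames to
ALA; glycine keeps its four backbone atoms and gains no Cβ, because
truncation never invents atoms. Examples whose periodic images collide are
rejected: a pair fails if its minimum-image distance is below 2.0 Å unless
it is a covalent contact (direct distance < 1.9 Å that is also the minimum
image). Splits are assigned at source granularity so no source structure
contributes to both train and validation.

What the synthetic generator does not emulate: real conformational
statistics (no Ramachandran density, no rotamer library), crystal packing,
solvent, disorder, or measurement noise. Tests passing on this data
demonstrate the correctness of the pipeline and the learnability of the
mapping at small scale — not performance on real PDB-derived corpora.

## Network and training

The model is a 3D residual U-net in three phases: Encoding (two 7³
convolutions with batch norm + ReLU, then 2³ stride-2 max pooling),
Learning Features (residual blocks of 7³ conv/BN/ReLU + 7³ conv/BN with an
optional squeeze-and-excitation gate at reduction 2, skip add, ReLU; closed
by nearest-neighbor ×2 upsampling), and Decoding (5³ conv/BN/ReLU, 5³ conv
to one channel, tanh). Encoding and Learning Features convolutions use
periodic (circular) same-padding — a Patterson map is a function on the
torus of the unit cell, so these phases are equivariant to circular shifts,
a property the tests verify — while Decoding, which localizes a centered
molecule, uses zero padding. Weights are He-normal initialized from a
seeded generator.

Exact per-layer widths: baseline 1→23→25 in, seven residual blocks at 25,
25→23→1 out (3,286,837 trainable scalars including batch-norm affine
terms); enlarged 1→25→30, eight blocks at 30, 30→25→1 (5,311,141). The
baseline assignment of 23- vs 25-channel layers is a reasoned
reconstruction from the stated widths and the ~3×10⁶ parameter budget.

All layers and their reverse-mode gradients are implemented directly in
NumPy. Circular convolution is evaluated in Fourier space (a circular
cross-correlation is a per-frequency product with the conjugate kernel
spectrum; both the input and the weight gradient are again circular
(de)correlations, so one FFT machinery serves forward and backward), and
zero-padded convolution reuses it on a zero-embedded grid. Every layer's
gradient is pinned by central-difference checks in the test suite. Batch
normalization uses batch statistics in training and running averages
(momentum 0.1, ε 1e-5) in evaluation; evaluation mode is therefore fully
deterministic.

The loss is voxel MSE, optionally plus `w·(1 − CC)` with the Pearson CC of
the two maps; `w` defaults to 0.1, keeping the weight heavily on the MSE
term. The learning rate decays exponentially in two phases
(`base_lr · d1^min(e,p1) · d2^max(0,e−p1)`); shipped presets are
(0.86, 12 epochs, 0.9991) with Adam for the dialanine experiments and
(0.91, 18, 0.9989) with AdamW (decoupled weight decay 3×10⁻²) for the
all-residue experiment. `base_lr` defaults to 1×10⁻³ (the original value
came from a learning-rate finder and is not published). Gradient
accumulation multiplies the effective batch; optimizer steps per epoch are
`ceil(n_batches / accumulation)`. The checkpoint kept is the epoch with the
highest validation median CC. Batches require a uniform grid shape; mixed
shapes are rejected with a clear error.

## Evaluation

Pearson CC is computed over all voxels or over a centered cube (e.g. the
central 6 Å of an enlarged cell whose borders are empty by construction).
Phase error transforms both maps back to structure factors at the working
`d_min` and averages the absolute wrapped phase difference (degrees, [0,
180]) in 20 equal-width shells of 1/d²; means are amplitude-weighted by the
true map's amplitudes (the convention of phase-matching tools), with an
unweighted mode available since either could match published curves.
Because phases ignore scale and CC ignores positive affine maps,
normalization needs no inversion before scoring. No origin or hand search
is applied before comparison — examples are centered by construction and
the cell is P1 — which is a documented limitation for maps that are not.
Empty shells are reported as absent (NaN), never as zero. F(0,0,0) is
excluded throughout.

## Problem sizes and the overfit demonstration

The oracle and symmetry checks run on 16³–20³ grids with up to six random
atoms; these sizes are where the brute-force references (per-voxel
summation, shift-by-shift autocorrelation) remain exact and fast. The
learning claim is demonstrated at desk scale by memorization: a reduced
U-net (1→8→10 channels, two residual blocks, 5³/3³ kernels, ~64k
parameters) trained with Adam at a constant 2×10⁻³ for 250 full-batch
epochs on eight synthetic dialanine examples (10 Å cell, 0.5 Å spacing,
20³ grids) drives the training MSE below 10% of its initial value with a
median training CC above 0.9. This verifies that the architecture,
gradients and loss can fit the Patterson→density mapping; the published
headline metrics (median CC ≈ 0.9–0.98 on tens of thousands of PDB-derived
examples after GPU-scale training) are out of scope for this package's test
conditions.

## Known limitations

- P1 orthogonal cubic cells only; no space-group symmetry, non-90° angles
  or variable cell sizes.
- Point scatterers with a single global B by default; no form factors,
  anomalous signal, anisotropy or occupancy.
- The dipeptide generator trades realism for determinism (see above).
- Training is single-process CPU NumPy: suitable for reduced models and
  small datasets, not for the full 3×10⁶-parameter network on 10⁵
  examples.
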