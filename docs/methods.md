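# Methods

## Structure representation and secondary structure

All alignment work operates on Cα traces: an ordered list of coordinates
(Å) with a three-state secondary-structure string (H/E/C).  PDB input goes
through Biopython; only the first MODEL is read (NMR ensembles are
multi-model), alternate locations other than blank/'A' are skipped, and
author residue numbers are kept as labels only — indexing is positional.
A consecutive Cα–Cα distance above 4.2 Å is recorded as a chain-break
warning, not an error.

Secondary structure is assigned from Cα geometry alone, P-SEA style:
helix when d(i,i+2) ∈ [5.1, 6.1], d(i,i+3) ∈ [4.8, 5.8] and
d(i,i+4) ∈ [5.7, 6.7] Å across a 5-residue window; strand when
d(i,i+2) ∈ [6.4, 7.0] Å across a 3-residue window; coil otherwise.  The
rule uses internal distances only, so it is rigid-motion invariant, and the
identical rule classifies natives and decoys — the property the decoy
matching depends on.  The windows are tight: roughly 1 Å of coordinate
noise already fragments an ideal helix's assignment, which is why synthetic
kin models carry their template's string (below).

## Double-dynamic-programming alignment

Each residue's *environment* is its row of the intramolecular distance
matrix.  For a candidate pair (i, j) a low-level dynamic program walks the
two environments outward from the anchored pair (left and right of the
diagonal separately) with element similarity s(Δd) = w/(1 + (Δd/σ₀)²),
σ₀ = 3 Å, neighbour weight w = 1/(10 + d̄) (d̄ the mean of the two compared
distances), and gap penalty 0.02 per skipped element.  Environments are
compared over a ±15-residue sequence window around the anchor; the
weighting makes remote neighbours nearly irrelevant (w < 1/40 beyond
~30 Å), so the window loses little signal while bounding the cost — this
window is the package's own problem-size choice and applies identically to
natives and decoys.

The resulting n₁×n₂ matrix is sharpened by three soft-iteration cycles:
select the best path by a high-level dynamic program (free end gaps,
internal gap 1.0/residue, fixed tie-break), double the weight of on-path
cells, recompute.  The final path defines the residue pairing; the raw
score sums on-path cells above a noise floor (5% of the matrix maximum) and
is normalized by the shorter chain length.  The whole procedure is
deterministic and, because it sees only internal distances, invariant under
independent rigid motions of either input.  The low-level pass is compiled
with numba.

## Decoys and significance

A decoy preserves the native's full ordered secondary-structure segment
list — a stricter reading of "same size and composition" that fixes segment
lengths and order and randomizes only the 3D packing.  Helix/strand
segments keep ideal local geometry; coils are self-avoiding 3.8 Å walks;
segments are attached at bonded steps (3.8 ± 0.2 Å) under random
orientations, greedily choosing among clash-free candidates the most
compact placement.  Constraints: non-bonded (|i−j| > 2) Cα pairs ≥ 4.0 Å,
radius of gyration ≤ 1.3·(2.2·N^0.38) Å.  Construction is deterministic per
seed; child seeds derive from SHA-256 of (master seed, pair label,
replicate), so every decoy is individually reproducible.

The background for a native pair is the score distribution of n
decoy-vs-decoy alignments (default 1000; the property tests use 200).
Z = (S_native − μ)/σ.  Panel-wide combination is one-tailed: Stouffer
Σz/√k against the normal upper tail (default), and a one-sample t-test of
the Z values against zero (reported alongside, since the two can differ by
orders of magnitude — the t-test penalizes panel heterogeneity).  Note the
t-test probability is *not* monotone in a single Z (a bumped value can
inflate the sample variance faster than the mean); only Stouffer has that
per-element monotonicity.  Combined probabilities are computed in log space
(`logsf`), so extreme Z values do not underflow.  The printed exponent
convention reports −⌊log₁₀ p⌋, and the forward-vs-reverse differential is
log₁₀(T_NN·T_CC) − log₁₀(T_NC·T_CN), also available directly from log-space
values.

For a single-quartet panel the per-pairing probability degenerates to the
plain normal tail of its Z (Stouffer with k = 1); the t-test needs at least
two viruses and is then omitted.

## Synthetic domains

The generators emulate compact all-α domains: a 4-helix "N-like" layout
(46 residues) and a 5-helix "C-like" layout (54 residues), helices on a
serpentine grid of axes (10.5 Å within rows, 8.9 Å between rows,
antiparallel), loops as clash-avoiding bridging walks.  Sizes are roughly
half the real domains' — a deliberate choice that keeps the
decoy-background simulations fast while preserving the bundle topology;
nothing in the statistics depends on absolute size.  A homology quartet
consists of two independent 1.0 Å-noise copies of each template: the
forward pairs (NN, CC) are true structural kin, the cross pairs are not.
Kin models keep the template's secondary-structure string (construction
ground truth) rather than re-deriving it from the noisy geometry; the
iid-noise `perturb` operation, by contrast, always re-assigns.

What the synthetic data do not capture: real loop-length variation between
homologs, sequence-dependent packing, insertions/deletions, and genuinely
homologous-but-divergent topologies.  Passing tests therefore demonstrate
that the statistics separate designed kinship from designed non-kinship
under controlled noise — not that any particular real pair of domains is
related.

## Sedimentation equilibrium

σ_red = M(1−v̄ρ)ω²/(2RT) in CGS units (cm⁻²).  The monomer–dimer signal is
ε[c_m + 2·K_A·c_m²·ξ]·ξ with ξ = exp(σ(r²−r₀²)): K_A is defined on the
molar monomer scale and the dimer carries twice the per-mole signal, the
convention of mass-proportional interference optics.  ε defaults to
3.3 fringes/(mg·ml⁻¹) converted through the monomer mass.  The global fit
(scipy `least_squares`, Levenberg–Marquardt) shares log M or log K_A across
profiles with per-profile log c_ref and baseline free; five log-spaced K_A
starts (10³–10⁹ M⁻¹) guard against local optima, and log-parameterization
with clipping keeps trial steps finite.  χ² is the reduced chi-square
(noise-weighted when a noise sd is supplied).

Synthetic datasets use three speeds (15 000/20 000/25 000 rpm), radii
6.9–7.4 cm, 40 points/profile, and Gaussian noise with sd equal to a
fraction (default 0.5%) of each loading's *reference* signal ε·c₀ — a
constant per profile, like optical read noise; making the noise
proportional to the steeply graded signal itself would overweight the cell
base and is not how interference noise behaves.

## ¹⁵N relaxation

Rigid isotropic rotor, J(ω) = (2/5)τc/(1+(ωτc)²), standard dipolar + CSA
rates with rNH = 1.02 Å, Δσ = −160 ppm, γH = 2.675×10⁸,
γN = −2.712×10⁷ rad s⁻¹ T⁻¹ (field-standard values).  τc is obtained by
bracketed root-finding of the T1/T2 ratio on [0.1, 100] ns, seeded by the
closed form τc ≈ √(6T1/T2 − 7)/(4πν_N); the forward→inverse round trip is
the identity to better than 0.5% across 2–30 ns and 600–950 MHz.  The
ensemble value is a 10%-per-tail trimmed mean over residues with
hetNOE > 0.75 (per-residue inversion then averaging, rather than averaging
rates first; with uniform rigid-core values the two coincide).  Decay
tables are fit to I(t) = I₀e^(−t/T) by nonlinear least squares seeded from
the log-linear fit.  No chemical-exchange (Rex) or model-free S² terms —
the rigid-rotor assumption is exactly what the τc statement presumes.

## Sphere-model surface areas

Shrake–Rupley-style numeric SASA with a deterministic golden-spiral point
set (default 960 points/sphere, probe 1.4 Å).  On Cα-only models each
residue is one 3.0 Å sphere; a small van der Waals radius table supports
full-atom sphere sets.  Buried interface area is the two-sided total
SASA(A)+SASA(B)−SASA(A∪B) (per-side value is half for a symmetric
interface); totals use compensated summation so the operation is exactly
symmetric in its arguments.  Agreement with closed forms: isolated sphere
within 1%, two-sphere overlap (spherical caps) within 2%; refining 960 →
4000 points moves areas by < 2%.

## Numerical and design notes

- Kabsch superposition uses the SVD with determinant correction;
  collinear inputs are flagged degenerate, not rejected.  Q-score uses
  R₀ = 3.0 Å.
- Alignment tie-breaks are fixed (up over diagonal over left), so all
  pipeline outputs are bit-reproducible for a given seed.
- `combine_z` sorts its inputs, making permutation invariance exact in
  floating point.
- Degenerate inputs raise early with specific messages: empty structures,
  unknown chains, sub-minimal pools (n < 10 backgrounds, < 2 profiles,
  < 3 decay points), zero-variance backgrounds, T1/T2 ratios outside the
  invertible range.

## Known limitations

- The alignment constants (σ₀, weights, gap costs, iteration count) are
  fixed for reproducibility, not tuned to reproduce any published per-pair
  Z value; per-structure Z-scores on real coordinates will differ from any
  particular published table.
- Decoy realism stops at the stated constraints — no fragment libraries or
  Ramachandran statistics.
- The sedimentation model is ideal (no nonideality/B22, no mass
  conservation across the cell) and the association model is strictly
  monomer–dimer.
- Sphere SASA on Cα models approximates residues as uniform spheres;
  absolute areas depend on that radius choice and are not comparable to
  full-atom values.
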