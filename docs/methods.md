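# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `repave`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Scope and design stance

The package reproduces the *methodology* of replica-averaged
NMR-restrained ensemble determination — restraint energetics, the
annealing/collection protocol, tensor computation, SAXS/NOE validation
and landscape analysis — on a synthetic two-subdomain hinge protein with
known ground truth.  It deliberately does not contain an explicit-solvent
MD engine, a trained chemical-shift predictor, or a hydration-layer SAXS
model; each of those stages is replaced by a simpler, fully documented
component behind the same interface, so that trained or full-physics
implementations can be plugged in without touching the rest of the
pipeline.

## The synthetic hinge protein

`synthetic.build_hinge_template` constructs a Cα-trace protein of three
rigid blocks: a "core" helix (default 20 residues), a hinge (4
residues) and a "hairpin" helix (10 residues).  Helices use the
canonical Cα parameters (2.3 Å radius, 1.5 Å rise, 100°/residue, giving
3.8 Å consecutive spacing).  Construction places each subdomain's Cα
centroid exactly on its helical axis and the hinge centroid exactly at
the pivot, so the region-centroid bending angle of a template built at
θ equals θ to machine precision — this gives the landscape code an exact
geometric oracle.  Per residue, pseudo N and H atoms ride in a local
frame built only from within-block neighbours; they are therefore
rigid under hinge rotation, and the N–H bond orientations of the
hairpin rotate with it, making RDCs genuinely informative about the
hinge angle.

The single default degree of freedom is the bending angle, drawn from a
truncated normal on (0°, 180°).  The real protein's hinge variability
is of course higher-dimensional (torsion, internal breathing); passing
the recovery tests here demonstrates correctness of the machinery, not
that one angle suffices for a real system.  What the generator does not
emulate: side chains, realistic Ramachandran statistics, solvent, and
measurement systematics other than i.i.d. Gaussian noise on RDCs and
multiplicative Gaussian noise on SAXS intensities.

Default study conditions used by the tests and the acceptance script:
generating angle distribution 95° ± 8° (200 conformations), RDC noise
0.5 Hz, SAXS noise 2%, sampler started at 130°.

## Alignment tensors and RDCs

`D = d_max ûᵀ S û` with `d_max` = 21 700 Hz for N–H (1.02 Å bond-length
convention; the constant cancels in Q-factors and is configurable).
Two routes to S:

- **SVD fit** (`svd_fit_tensor`): linear least squares over the 5 free
  components; minimum-norm solution with a warning if the design matrix
  is rank-deficient; Q = RMS(D_calc − D_exp)/RMS(D_exp).
- **Steric prediction** (`steric_tensor`): alignment by obstruction
  between parallel planar barriers.  For each direction n of the barrier
  normal in the molecular frame (Fibonacci grid, default 5000
  directions), the molecule's extent w(n) along n excludes positions;
  the orientation weight is max(0, 1 − w(n)/L) with barrier spacing L
  defaulting to twice the maximal extent.  S is the weighted average of
  (3nnᵀ − 1)/2 times a scalar medium **order parameter** that absorbs
  orientational averaging.  The default order scale (0.01) is chosen so
  the toy protein's couplings span roughly ±10–20 Hz, the magnitude
  typical of amide RDCs in weakly aligning media (|S_zz| ≈ 10⁻³).

Eigenvalues are labelled |S_zz| ≥ |S_yy| ≥ |S_xx| with ties broken by
signed value, so principal-axis labels are deterministic.  Missing amide
hydrogens are rebuilt 1.02 Å from N along the in-plane bisector of
C(i−1)–N(i)–CA(i).

## Restraint energies

`E_RDC = α Σ_records (⟨D⟩_replicas − D_exp)²` — the sum-over-records
convention is adopted (the per-record alternative differs only by a
rescaling of α).  Deviations are unweighted by the record error by
default, with per-record error weighting available as an option.
Gradients are analytic through û per replica; the alignment tensor is
held constant between its periodic updates (every 250 steps by
default), matching the stated protocol — differentiating through the
steric tensor would couple all atoms through the shape integral for no
benefit at these update frequencies.

Chemical-shift restraints follow MUMO: replicas are partitioned into
rotating groups (default 4 of 16; replica r belongs to group
((r + step) mod M)/g, so membership rotates deterministically with the
step counter) and the penalty acts on each group's average shift.  The
default predictor is intentionally simple: δ = random-coil value +
amplitude × cos τ, with τ the Cα pseudo-dihedral of residues
(i−1 … i+2); residues lacking the quadruple get the random-coil value.
This makes ground-truth recovery exact and keeps the gradient analytic
(standard four-point dihedral derivatives, verified against central
finite differences to 10⁻⁵ relative).  It is *not* CamShift; trained
predictors satisfying the same `predict → (shifts, gradients)` contract
plug in directly.  The CS force constant β has no defensible default
and is required configuration.

Force-constant schedule: α ramps linearly from zero over the
equilibration (discarded) phase to α_max = 1000 J mol⁻¹ Hz⁻², and is
scaled to 10% of maximum whenever T ≥ 350 K (the midpoint of the
300–400 K annealing range; the threshold is configurable because the
original protocol does not state one).

## The sampler

Restrained MD is replaced by Metropolis Monte Carlo over the hinge
angle of each replica: the findings of interest concern the *sampled
ensemble*, not dynamics, and one collective degree of freedom keeps the
artifact desk-scale while preserving the full energy decomposition
E_total = E_FF + E_RDC (+ E_CS), reported per evaluation and summing
exactly.  "Steps" are MC sweeps with 1 ps ≡ 1 sweep by default
(`ps_per_step` configurable), so the reference protocol maps to 50
cycles × 500 sweeps, collection from the final 100 sweeps at 5-sweep
intervals, first 20 cycles discarded — 9600 structures for 16 replicas
and 8 ns of sampling per cycle across replicas.

Within a cycle the temperature rises linearly to 400 K over the first
40% of steps, cools linearly back over the next 40%, and holds 300 K for
the collection window (the protocol's profile shape is unstated; only
the base-temperature collection matters for the ensemble).  Move size is
auto-tuned toward 25–50% acceptance during discarded cycles only and
frozen afterwards, preserving detailed balance in the collected
ensemble; acceptance below 1% in any cycle emits a diagnostic warning.

The toy force field is a harmonic hinge potential (optionally flat), a
soft excluded-volume repulsion between Cα atoms of different blocks,
and intra-subdomain elastic-network springs (identically zero under
rigid moves; evaluated as a diagnostic).  The default hinge stiffness
(1 J mol⁻¹ deg⁻²) is set so that the calibrated restraint weight
α_max = 1000 J mol⁻¹ Hz⁻² dominates the force-field preference by
roughly an order of magnitude for the default toy — mirroring the
method's own design, in which the restraint force constant is
calibrated until agreement with the data governs the sampling.

**Tensor route in the recovery experiment.**  The sampler never rotates
the molecule globally (the core block is fixed in the laboratory
frame), so the aligning medium's tensor is constant in the lab frame;
the recovery experiment therefore generates and restrains with one
fixed steric tensor computed from the template, keeping the forward
model self-consistent.  Per-replica steric tensors recomputed every 250
steps remain the default for shape-changing applications and are
exercised by the test suite; they carry less angle information because
the tensor adapts to the shape it aligns.

## Validation

SAXS back-calculation uses the Debye formula over one Gaussian dummy
form factor per residue at the Cα (amplitude 60 e⁻, effective radius
2.5 Å).  This is an explicit simplification: no per-residue-type
factors, no excluded-volume or hydration-shell fitting; the amplitude
cancels in the χ² scale fit and the shape term preserves low-angle
sensitivity (verified against the analytic homogeneous-sphere form
factor to <5% for sR < 3).  χ² is the error-weighted mean squared
residual after a closed-form least-squares scale (optional additive
constant behind a flag, since buffer subtraction makes it ambiguous);
zero experimental σ is an error directing to unweighted mode.
`chi2_bootstrap` reports a block-bootstrap spread over contiguous
blocks; whether this matches the resampling behind published ± values
is assumed, not known.

NOE checking is per-structure by default (fulfilled iff
lower ≤ d ≤ upper + tolerance, default tolerance 0.5 Å) because the
reported distributions are per-structure; ensemble ⟨r⁻⁶⟩⁻¹ᐟ⁶ checking
is available as an option.  Unresolvable restraints are excluded from
denominators and listed, never silently dropped.

## Landscape analysis

The bending angle places its vertex at the hinge-region (region II) Cα
centroid — the three-region definition does not itself name a vertex,
and hinge-as-vertex is the only geometrically sensible reading.
"Centers of mass of the Cα atoms" is read as unweighted Cα centroids
(equal masses cancel).  Default landscape coordinates are the bending
angle and the *unweighted Cα* Rg; heavy-atom mass-weighted Rg is the
default of `radius_of_gyration` itself and is what the public-structure
checks use.  Default bins are 2° × 0.25 Å (no binning is prescribed by
the protocol); F = −ln P in k_BT, minimum shifted to zero, empty bins
masked (NaN), never clamped.  The landscape is relative — temperature
enters only through the unit.

Secondary structure: full-backbone mode implements the Kabsch–Sander
hydrogen-bond energy (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, bond iff E < −0.5) with the standard H placement 1.0 Å from N
opposite the preceding carbonyl, assigning H (α) and G (3₁₀) from
consecutive n-turns — pooled into "helix" — and E from parallel or
antiparallel bridge patterns (isolated bridges count as strand, a
documented simplification of the ladder rule; turns and bends are out
of scope).  Cα-only models use a virtual-dihedral fallback with windows
around the canonical α-helix Cα geometry (τ ≈ +50°, θ ≈ 90°).

## Numerical conventions and degenerate inputs

- Energies J/mol, R = 8.314462618 J mol⁻¹ K⁻¹; angles degrees at the
  API surface, radians internally.
- Saupe tensors are symmetrized and de-traced on construction; an
  asymmetric input (beyond 10⁻⁹) is an error, not silently fixed.
- All-zero experimental RDCs fit a zero tensor with Q reported as 0
  (the Q denominator vanishes).
- A structure collapsing a region (missing residues, zero-length
  internuclear vectors, collinear dihedral geometry) raises a named
  error rather than propagating NaN.
- Every stochastic routine takes an explicit seed and creates its own
  `numpy` Generator; there is no global random state, and fixed seeds
  reproduce ensembles bit-for-bit.

## Problem sizes

The suite and acceptance script run the pipeline at deliberately modest
sizes chosen as adequate for their statistical checks: 34-residue toy
(500-residue variant for noise-calibration checks), generating
ensembles of 200–2000 conformations, and a 20-cycle × 200-sweep × 16
replica annealing run for the recovery experiment (the full 50 × 500
protocol is exercised through its collector arithmetic and a
scaled-down run that obeys the same formula).  Monte-Carlo assertions
use 3σ bands or fixed-seed replicates as noted in the tests.

## Known limitations

- One hinge degree of freedom; no torsional or intra-subdomain motion
  by default.
- The steric alignment model captures shape→tensor covariance, not the
  electrostatics of charged media (e.g. phage at low salt); salt
  screening is not modelled and no parameter pretends otherwise.
- The default shift predictor is a caricature with the right contract,
  not a trained model.
- SAXS dummy form factors ignore residue identity; absolute intensities
  are meaningless, only shapes and χ² comparisons are.
- The public-structure Rg checks depend on coordinate files the
  repository does not ship; without them those three acceptance tests
  fail by design.
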