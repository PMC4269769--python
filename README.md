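# repave

**Replica-averaged NMR-restrained ensembles for hinge-motion proteins.**

Multidomain proteins such as the Josephin domain of ataxin-3 — a globular
catalytic subdomain plus a mobile α-helical hairpin joined at a hinge — do
not have a single structure in solution: their function depends on the
*distribution* of inter-subdomain orientations.  `repave` implements, at
desk scale, the ensemble-determination methodology used to characterize
such motions: NMR observables (residual dipolar couplings and chemical
shifts) are imposed as **replica-averaged restraints** on a sampler, the
resulting conformational ensemble is validated against independent NOE
and small-angle X-ray scattering (SAXS) data, and the motion is summarized
as a free-energy landscape over a bending-angle × radius-of-gyration
plane.

The package is aimed at structural-bioinformatics practitioners and
method developers who want a fully testable, dependency-light
implementation of every stage of this pipeline, with a synthetic
two-subdomain hinge-protein generator providing known ground truth.

## The model

An RDC between nuclei a–b reports the orientation of the internuclear
unit vector **û** relative to the molecular alignment frame,

    D = d_max · ûᵀ S û ,

with **S** the traceless symmetric Saupe order matrix.  Restraints enter
through a hybrid energy

    E_total = E_FF + E_RDC ,     E_RDC = α · Σ_k ( ⟨D_k^calc⟩_replicas − D_k^exp )² ,

where ⟨·⟩ is the average over M = 16 simultaneous replicas — the penalty
acts on the *ensemble average*, not on individual structures, which is
what makes the restrained ensemble a model of the conformational
distribution.  Each replica carries its own alignment tensor, recomputed
periodically by a structure-based steric model (obstruction between
planar barriers).  Chemical-shift restraints follow the MUMO scheme:
they are averaged over rotating sub-groups of 4 replicas to limit
over-fitting.  Sampling follows a simulated-annealing protocol
(300–400 K, 50 cycles, force constant α ramped to 1000 J mol⁻¹ Hz⁻² and
scaled to 10% at high temperature); only the base-temperature tail of
each post-equilibration cycle is collected, which for 16 replicas yields
9600 structures.

Validation uses the Debye formula
`I(s) = Σᵢⱼ fᵢ(s) fⱼ(s) sin(s·rᵢⱼ)/(s·rᵢⱼ)` with residue-level dummy
form factors and the error-weighted reduced χ² after a closed-form scale
fit, plus per-structure NOE distance-bound fulfillment.  Analysis
computes the inter-subdomain bending angle (vertex at the hinge-region
Cα centroid), Rg, contact maps, secondary-structure occupancy
(Kabsch–Sander hydrogen-bond criterion) and the free-energy landscape
F = −ln P in k_BT units.

## Worked example

```python
import numpy as np
from repave import alignment, landscape, sampler, synthetic

# 1. toy hinge protein and a "ground-truth" ensemble at 95 deg
model = synthetic.build_hinge_template(synthetic.HingeTopology(20, 10, 4))
truth = synthetic.sample_hinge_ensemble(
    model, synthetic.AngleDistributionSpec(95.0, 8.0), 200, seed=11)

# 2. forward-model replica-averaged RDCs (fixed lab-frame steric tensor)
tensor = alignment.steric_tensor(model.template)
data = synthetic.synth_rdc_from_ensemble(truth, d_max=21_700.0,
                                         noise_sd=0.5, seed=12,
                                         tensor=tensor)

# 3. restrained annealing started far from the truth (130 deg)
ff = sampler.ToyForceField(hinge_rest_angle=130.0)
protocol = sampler.AnnealingProtocol(n_cycles=20, discard_cycles=8,
                                     steps_per_cycle=200)
bundle = sampler.RestraintBundle(rdc_records=data, tensor=tensor)
ens, log = sampler.run_restrained_sampling(model, ff, bundle, protocol,
                                           n_replicas=16, seed=1,
                                           initial_angle=130.0)
regions = landscape.RegionSpec.from_hinge_model(model)
angles = [landscape.bending_angle(s, regions) for s in ens]
grid = landscape.free_energy_landscape(ens, regions)
```

Output:

```
34 synthetic RDCs, range [-13.4, 8.4] Hz
collected 1536 structures; mean bending angle 93.2 deg (truth 95.0, start 130.0)
free-energy landscape mode: 93 deg, 13.9 A
```

The restraints pull the sampler from its force-field minimum at 130°
back to the 95° basin the data were generated from — the unrestrained
control (`run_unrestrained_sampling`) stays near 124° — and the
landscape mode sits on the recovered basin.

## Command line

```bash
repave generate --topology 20,10,4 --mean-angle 110 --sd 8 -n 2000 --seed 7 \
       -o toy.pdb --rdc toy_rdc.tsv --noe toy_noe.tsv --saxs toy_saxs.dat
repave rdc-fit toy.pdb toy_rdc.tsv           # Saupe tensor + Q-factor
repave sample --template 20,10,4 --rdc toy_rdc.tsv --replicas 16 \
       --cycles 50 --discard 20 --seed 1 -o ensemble.pdb --log run.json
repave saxs-fit ensemble.pdb toy_saxs.dat    # chi2 fit report (JSON)
repave noe-check ensemble.pdb toy_noe.tsv --tolerance 0.5
repave landscape ensemble.pdb --toy-topology 20,10,4 -o fel.tsv
```

## File dialects

PDB files are standard (multi-model via MODEL/ENDMDL).  RDC and NOE
tables have no community standard; the dialects defined here are
whitespace-delimited with `#` comments:

    # RDC: residue atom_a atom_b value_hz [error_hz] [medium]
    12  N  H  -4.25  0.50  pf1

    # NOE: residue_i atom_i residue_j atom_j upper_A [lower_A]
    5  CA  21  CA  7.85  0.0

SAXS profiles are 2- or 3-column `.dat` (s in Å⁻¹, intensity, optional
σ); header lines are tolerated.

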