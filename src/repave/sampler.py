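"""Annealed Metropolis Monte-Carlo sampling of the hinge model under
replica-averaged restraints.

This is the desk-scale stand-in for the restrained MD engine: the
sampled degree of freedom is the hinge bending angle of each replica
(subdomains move as rigid bodies), the driving energy is

    E_total = E_ff + E_rdc (+ E_cs)

and the protocol mirrors the annealing structure of the original
method: repeated cycles between a base and a high temperature, a
force-constant ramp during the discarded equilibration cycles, alignment
tensors recomputed periodically per replica, and structures collected
only in the base-temperature window at the end of each retained cycle.
"Steps" are MC sweeps; the picosecond bookkeeping of the protocol maps
proportionally (1 ps ≡ ``ps_per_step`` sweeps' worth, configurable).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import SaupeTensor, steric_tensor
from .ensemble_io import ConformationEnsemble, RdcRecord, Structure
from .restraints import (CsRestraintSpec, ReplicaState, RestraintSchedule,
                         cs_restraint_energy, scheduled_alpha)
from .synthetic import HingeModel

__all__ = [
    "AnnealingProtocol",
    "ToyForceField",
    "RestraintBundle",
    "EnergyBreakdown",
    "SamplingLog",
    "metropolis_accept",
    "run_restrained_sampling",
    "run_unrestrained_sampling",
    "ensemble_rdc_q",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)


@dataclass(frozen=True)
class AnnealingProtocol:
    """Simulated-annealing cycle structure.

    Defaults mirror the reference protocol: 50 cycles between 300 and
    400 K, 500 ps per cycle (1 ps ≡ 1 sweep), the first 20 cycles
    discarded, and collection from the final 20% of each retained cycle
    (the base-temperature window) at 5 ps intervals — which for 16
    replicas yields 9600 collected structures.
    """

    t_low: float = 300.0
    t_high: float = 400.0
    n_cycles: int = 50
    steps_per_cycle: int = 500
    discard_cycles: int = 20
    collection_window: float = 0.2
    collection_interval: int = 5
    ps_per_step: float = 1.0
    equilibration_steps: int = 0

    def __post_init__(self):
        if not (0 < self.collection_window <= 1):
            raise ValueError("collection window must be in (0, 1]")
        if self.discard_cycles >= self.n_cycles:
            raise ValueError("discard_cycles must be < n_cycles")
        if self.collection_interval < 1 or self.steps_per_cycle < 1:
            raise ValueError("intervals and steps must be >= 1")
        if self.t_high < self.t_low:
            raise ValueError("t_high must be >= t_low")

    @property
    def window_steps(self) -> int:
        return int(round(self.collection_window * self.steps_per_cycle))

    @property
    def frames_per_replica_per_cycle(self) -> int:
        return self.window_steps // self.collection_interval

    def n_collected(self, n_replicas: int) -> int:
        """Collected-ensemble size implied by the protocol arithmetic."""
        return (n_replicas * (self.n_cycles - self.discard_cycles)
                * self.frames_per_replica_per_cycle)

    def sampling_per_cycle_ns(self, n_replicas: int) -> float:
        """Total sampling per cycle across replicas, in ns."""
        return self.steps_per_cycle * self.ps_per_step * n_replicas / 1000.0

    def temperature(self, step_in_cycle: int) -> float:
        """Linear heat to t_high, linear cool back, then the base-
        temperature collection window."""
        s = self.steps_per_cycle
        w = self.window_steps
        h = max((s - w) // 2, 1)
        cool_len = max(s - w - h, 1)
        if step_in_cycle < h:
            frac = step_in_cycle / h
            return self.t_low + frac * (self.t_high - self.t_low)
        if step_in_cycle < s - w:
            frac = (step_in_cycle - h) / cool_len
            return self.t_high - frac * (self.t_high - self.t_low)
        return self.t_low

    def collect_at(self, step_in_cycle: int) -> bool:
        start = self.steps_per_cycle - self.window_steps
        if step_in_cycle < start:
            return False
        return (step_in_cycle - start + 1) % self.collection_interval == 0


@dataclass(frozen=True)
class ToyForceField:
    """Toy force field standing in for the molecular-mechanics term.

    Terms: a harmonic hinge-angle potential (flat when
    ``hinge_rest_angle`` is None), a soft excluded-volume repulsion
    between Cα atoms of different rigid blocks, and intra-subdomain
    elastic-network springs (identically zero under rigid-subdomain
    moves; evaluated for completeness via :meth:`elastic_energy`).
    Energies in J/mol; angles in degrees.
    """

    k_hinge: float = 1.0            # J/mol/deg^2
    hinge_rest_angle: float | None = None
    k_excluded: float = 5000.0      # J/mol per clashing pair
    r_excluded: float = 4.0         # Å soft-core radius
    k_elastic: float = 1000.0       # J/mol/Å^2 (diagnostic term)

    def hinge_energy(self, angle_deg: float) -> float:
        if self.hinge_rest_angle is None:
            return 0.0
        d = angle_deg - self.hinge_rest_angle
        return self.k_hinge * d * d

    def excluded_energy(self, coords_a: np.ndarray,
                        coords_b: np.ndarray) -> float:
        d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :],
                           axis=-1)
        clash = d < self.r_excluded
        if not clash.any():
            return 0.0
        x = 1.0 - d[clash] / self.r_excluded
        return float(self.k_excluded * np.sum(x * x))

    def elastic_energy(self, structure: Structure, reference: Structure,
                       blocks) -> float:
        """Elastic-network energy of intra-block Cα distance deviations
        from the reference (zero for rigid subdomains)."""
        e = 0.0
        resids = structure.topology.residue_indices
        names = structure.topology.atom_names
        for lo, hi in blocks:
            idx = np.where((names == "CA") & (resids >= lo) & (resids <= hi))[0]
            cur = structure.coords[idx]
            ref = reference.coords[idx]
            dc = np.linalg.norm(cur[:, None] - cur[None, :], axis=-1)
            dr = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
            iu = np.triu_indices(len(idx), k=1)
            e += self.k_elastic * np.sum((dc[iu] - dr[iu]) ** 2)
        return float(e)


@dataclass
class RestraintBundle:
    """Everything the restrained sampler needs about the data terms."""

    rdc_records: list[RdcRecord] | None = None
    schedule: RestraintSchedule = field(default_factory=RestraintSchedule)
    d_max: float = 21_700.0
    tensor: SaupeTensor | None = None   # fixed tensor; None -> steric per replica
    order_scale: float = 1e-2
    steric_orientations: int = 2000
    ramp_over_discard: bool = True
    cs_spec: CsRestraintSpec | None = None
    cs_observed: dict | None = None
    cs_beta: float = 0.0


@dataclass
class EnergyBreakdown:
    """Decomposition of the hybrid energy; terms sum exactly to total."""

    ff: float
    rdc: float = 0.0
    cs: float = 0.0

    @property
    def total(self) -> float:
        return self.ff + self.rdc + self.cs


@dataclass
class SamplingLog:
    """Per-cycle convergence traces."""

    acceptance: list = field(default_factory=list)
    mean_angle: list = field(default_factory=list)
    rg: list = field(default_factory=list)
    helix_fraction: list = field(default_factory=list)
    energies: list = field(default_factory=list)  # EnergyBreakdown per cycle
    alpha: list = field(default_factory=list)
    step_sigma: float = 0.0
    collected_angles: list = field(default_factory=list)


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion; energies in J/mol."""
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / (GAS_CONSTANT * temperature))


def _ca_rg(coords: np.ndarray, ca_mask: np.ndarray) -> float:
    ca = coords[ca_mask]
    c = ca - ca.mean(axis=0)
    return float(np.sqrt((c**2).sum() / len(ca)))


class _RdcTerm:
    """Caches per-replica back-calculated couplings for O(1 replica)
    updates during MC."""

    def __init__(self, model: HingeModel, bundle: RestraintBundle,
                 n_replicas: int):
        topo = model.topology
        matched, skipped = [], []
        for rec in bundle.rdc_records:
            i_n = topo.atom_index(rec.residue_index, rec.atom_a)
            i_h = topo.atom_index(rec.residue_index, rec.atom_b)
            if i_n is None or i_h is None:
                skipped.append(rec)
            else:
                matched.append((rec, i_n, i_h))
        if len(matched) == 0:
            raise ValueError("no RDC records match the template topology")
        if skipped:
            warnings.warn(f"{len(skipped)} RDC records unmatched in topology",
                          RuntimeWarning, stacklevel=3)
        self.records = [m[0] for m in matched]
        self.ia = np.array([m[1] for m in matched])
        self.ib = np.array([m[2] for m in matched])
        self.exp = np.array([m[0].value for m in matched])
        self.d_max = bundle.d_max
        self.bundle = bundle
        self.tensors = [None] * n_replicas
        self.calc = np.zeros((n_replicas, len(matched)))

    def couplings(self, coords: np.ndarray, tensor: SaupeTensor) -> np.ndarray:
        v = coords[self.ib] - coords[self.ia]
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        return self.d_max * np.einsum("ki,ij,kj->k", u, tensor.matrix, u)

    def refresh_tensor(self, m: int, structure: Structure):
        if self.bundle.tensor is not None:
            self.tensors[m] = self.bundle.tensor
        else:
            self.tensors[m] = steric_tensor(
                structure, order_scale=self.bundle.order_scale,
                n_orientations=self.bundle.steric_orientations)
        self.calc[m] = self.couplings(structure.coords, self.tensors[m])

    def energy(self, alpha: float) -> float:
        dev = self.calc.mean(axis=0) - self.exp
        return float(alpha * np.sum(dev**2))

    def delta(self, m: int, new_coords: np.ndarray, alpha: float
              ) -> tuple[float, np.ndarray]:
        new_row = self.couplings(new_coords, self.tensors[m])
        mean = self.calc.mean(axis=0)
        mean_new = mean + (new_row - self.calc[m]) / len(self.calc)
        de = alpha * (np.sum((mean_new - self.exp) ** 2)
                      - np.sum((mean - self.exp) ** 2))
        return float(de), new_row


def _run(model: HingeModel, forcefield: ToyForceField,
         bundle: RestraintBundle | None, protocol: AnnealingProtocol,
         n_replicas: int, seed: int, initial_angle: float | None,
         initial_step_deg: float):
    rng = np.random.default_rng(seed)
    theta0 = (initial_angle if initial_angle is not None
              else model.reference_angle)
    angles = np.full(n_replicas, float(theta0))
    coords = [model.coords_at(a) for a in angles]

    topo = model.topology
    resids = topo.residue_indices
    names = topo.atom_names
    ca_mask = names == "CA"
    hp_lo, hp_hi = model.spec.hairpin_range
    hairpin_ca = ca_mask & (resids >= hp_lo) & (resids <= hp_hi)
    other_ca = ca_mask & (resids < hp_lo)

    use_rdc = bundle is not None and bundle.rdc_records is not None
    use_cs = (bundle is not None and bundle.cs_spec is not None
              and bundle.cs_observed)
    rdc_term = _RdcTerm(model, bundle, n_replicas) if use_rdc else None
    schedule = bundle.schedule if bundle is not None else RestraintSchedule()
    if bundle is not None and bundle.ramp_over_discard:
        schedule = dataclasses.replace(
            schedule,
            ramp_steps=protocol.discard_cycles * protocol.steps_per_cycle)

    def ff_energy(m: int) -> float:
        return (forcefield.hinge_energy(angles[m])
                + forcefield.excluded_energy(coords[m][hairpin_ca],
                                             coords[m][other_ca]))

    def cs_energy(step: int) -> float:
        state = ReplicaState(
            [Structure(topo, c) for c in coords], step=step)
        return cs_restraint_energy(state, bundle.cs_spec,
                                   bundle.cs_observed, bundle.cs_beta).energy

    e_ff = np.array([ff_energy(m) for m in range(n_replicas)])
    if use_rdc:
        for m in range(n_replicas):
            rdc_term.refresh_tensor(m, Structure(topo, coords[m]))

    sigma = float(initial_step_deg)
    log = SamplingLog()
    collected = []
    collected_angles = []
    global_step = 0
    from .landscape import ss_occupancy_ca  # deferred: avoids import cycle risk

    for cycle in range(protocol.n_cycles):
        n_acc = n_prop = 0
        for s_in in range(protocol.steps_per_cycle):
            temp = protocol.temperature(s_in)
            alpha = (scheduled_alpha(schedule, global_step, temp)
                     if use_rdc else 0.0)
            if use_rdc and global_step % schedule.tensor_update_interval == 0 \
                    and global_step > 0 and bundle.tensor is None:
                for m in range(n_replicas):
                    rdc_term.refresh_tensor(m, Structure(topo, coords[m]))
            for m in range(n_replicas):
                prop = angles[m] + rng.normal(0.0, sigma)
                n_prop += 1
                if not (1.0 < prop < 179.0):
                    continue
                new_coords = model.coords_at(prop)
                e_ff_new = (forcefield.hinge_energy(prop)
                            + forcefield.excluded_energy(
                                new_coords[hairpin_ca], new_coords[other_ca]))
                de = e_ff_new - e_ff[m]
                new_row = None
                if use_rdc and alpha > 0:
                    de_rdc, new_row = rdc_term.delta(m, new_coords, alpha)
                    de += de_rdc
                elif use_rdc:
                    new_row = rdc_term.couplings(new_coords, rdc_term.tensors[m])
                if use_cs:
                    old_c = coords[m]
                    coords[m] = new_coords
                    e_cs_new = cs_energy(global_step)
                    coords[m] = old_c
                    de += e_cs_new - cs_energy(global_step)
                if metropolis_accept(de, temp, rng):
                    angles[m] = prop
                    coords[m] = new_coords
                    e_ff[m] = e_ff_new
                    if use_rdc and new_row is not None:
                        rdc_term.calc[m] = new_row
                    n_acc += 1
            if cycle >= protocol.discard_cycles and protocol.collect_at(s_in):
                for m in range(n_replicas):
                    collected.append(coords[m].copy())
                    collected_angles.append(angles[m])
            global_step += 1
        acc_rate = n_acc / max(n_prop, 1)
        if acc_rate < 0.01:
            warnings.warn(
                f"cycle {cycle}: acceptance rate {acc_rate:.3%} < 1% — "
                "move size likely misconfigured", RuntimeWarning, stacklevel=3)
        # move-size auto-tuning only during discarded cycles (preserves
        # detailed balance in the collected ensemble)
        if cycle < protocol.discard_cycles:
            if acc_rate > 0.5:
                sigma = min(sigma * 1.3, 45.0)
            elif acc_rate < 0.25:
                sigma = max(sigma / 1.3, 0.1)
        log.acceptance.append(acc_rate)
        log.mean_angle.append(float(angles.mean()))
        log.rg.append(_ca_rg(coords[0], ca_mask))
        log.helix_fraction.append(float(np.mean(
            ss_occupancy_ca(Structure(topo, coords[0]))[0])))
        alpha_now = (scheduled_alpha(schedule, global_step, protocol.t_low)
                     if use_rdc else 0.0)
        e_rdc = rdc_term.energy(alpha_now) if use_rdc else 0.0
        e_cs = cs_energy(global_step) if use_cs else 0.0
        log.energies.append(EnergyBreakdown(float(e_ff.sum()), e_rdc, e_cs))
        log.alpha.append(alpha_now)
    log.step_sigma = sigma
    log.collected_angles = collected_angles
    ensemble = ConformationEnsemble(topology=topo, coords=np.stack(collected))
    return ensemble, log


def run_restrained_sampling(model: HingeModel, forcefield: ToyForceField,
                            bundle: RestraintBundle,
                            protocol: AnnealingProtocol,
                            n_replicas: int = 16, seed: int = 0,
                            initial_angle: float | None = None,
                            initial_step_deg: float = 4.0):
    """Replica-averaged restrained annealing run.

    Returns ``(ensemble, log)``; the ensemble holds only structures from
    the base-temperature collection windows of post-discard cycles, so
    its size equals ``protocol.n_collected(n_replicas)``.
    """
    if bundle is None:
        raise ValueError("restrained run requires a restraint bundle "
                         "(use run_unrestrained_sampling otherwise)")
    return _run(model, forcefield, bundle, protocol, n_replicas, seed,
                initial_angle, initial_step_deg)


def run_unrestrained_sampling(model: HingeModel, forcefield: ToyForceField,
                              protocol: AnnealingProtocol,
                              n_replicas: int = 16, seed: int = 0,
                              initial_angle: float | None = None,
                              initial_step_deg: float = 4.0):
    """Control run with all restraint terms removed (identical protocol
    and random-number usage otherwise)."""
    return _run(model, forcefield, None, protocol, n_replicas, seed,
                initial_angle, initial_step_deg)


def ensemble_rdc_q(ensemble: ConformationEnsemble, records, d_max: float,
                   tensor: SaupeTensor | None = None,
                   order_scale: float = 1e-2,
                   steric_orientations: int = 2000) -> float:
    """Q-factor of the ensemble-averaged back-calculated couplings
    against the given records (per-structure steric tensors unless a
    fixed tensor is supplied)."""
    from .alignment import back_calc_rdc
    mean = None
    exp = None
    for structure, w in zip(ensemble, ensemble.weights):
        t = tensor if tensor is not None else steric_tensor(
            structure, order_scale=order_scale,
            n_orientations=steric_orientations)
        pred = back_calc_rdc(structure, t, d_max, records)
        if mean is None:
            mean = w * pred.calc
            exp = np.array([r.value for r in pred.records])
        else:
            mean = mean + w * pred.calc
    rms_exp = np.sqrt(np.mean(exp**2))
    if rms_exp == 0:
        return 0.0
    return float(np.sqrt(np.mean((mean - exp) ** 2)) / rms_exp)
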