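"""Synthetic two-subdomain hinge proteins and synthetic observables.

The generator builds a toy protein of two internally rigid subdomains —
a "core" and a "hairpin", each an idealized Cα helix — joined by a short
hinge.  The single default degree of freedom is the bending angle at the
hinge, so every downstream stage (tensor fitting, replica-averaged
restraints, sampling, landscapes) can be tested against known ground
truth.  Pseudo N and H atoms ride rigidly in each residue's local frame,
which makes back-calculated RDCs sensitive to the hinge angle exactly as
amide N–H couplings are in a real hinge protein.

Geometry notes: subdomain helices use a 2.3 Å radius / 1.5 Å rise /
100° twist Cα trace (3.8 Å consecutive spacing).  Each subdomain's Cα
centroid is placed exactly on its axis, and the hinge centroid exactly
at the pivot, so the region-centroid bending angle of a template built
at angle θ equals θ by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from ._geometry import rotation_matrix
from .alignment import SaupeTensor, back_calc_rdc, steric_tensor
from .ensemble_io import (ConformationEnsemble, NoeRestraint, RdcRecord,
                          SaxsProfile, Structure, Topology)

__all__ = [
    "HingeTopology",
    "AngleDistributionSpec",
    "HingeModel",
    "build_hinge_template",
    "sample_hinge_ensemble",
    "synth_rdc",
    "synth_rdc_from_ensemble",
    "synth_noe",
    "synth_saxs",
    "build_peptide_backbone",
    "ideal_alpha_helix",
]

_RISE = 1.5        # Å per residue along the helix axis
_RADIUS = 2.3      # Å helix radius
_TWIST = 100.0     # degrees per residue
_GAP = 6.0         # Å clearance between hinge pivot and subdomain ends


@dataclass(frozen=True)
class HingeTopology:
    """Residue counts of the toy hinge protein."""

    n_res_core: int = 20
    n_res_hairpin: int = 10
    n_res_hinge: int = 4

    def __post_init__(self):
        if self.n_res_hinge < 1:
            raise ValueError("hinge must contain at least one residue")
        if self.n_res_core < 3 or self.n_res_hairpin < 3:
            raise ValueError("subdomains need >= 3 residues (non-collinear)")
        if self.total < 12:
            raise ValueError("toy protein needs >= 12 residues total")

    @property
    def total(self) -> int:
        return self.n_res_core + self.n_res_hairpin + self.n_res_hinge

    @property
    def core_range(self) -> tuple[int, int]:
        return (1, self.n_res_core)

    @property
    def hinge_range(self) -> tuple[int, int]:
        return (self.n_res_core + 1, self.n_res_core + self.n_res_hinge)

    @property
    def hairpin_range(self) -> tuple[int, int]:
        return (self.n_res_core + self.n_res_hinge + 1, self.total)


@dataclass(frozen=True)
class AngleDistributionSpec:
    """Truncated-normal law for the hinge bending angle on (0°, 180°)."""

    mean_angle: float
    sd_angle: float

    def __post_init__(self):
        if not (0.0 < self.mean_angle < 180.0):
            raise ValueError("mean angle must lie in (0, 180) degrees")
        if self.sd_angle <= 0:
            raise ValueError("angle sd must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (0.0 - self.mean_angle) / self.sd_angle
        b = (180.0 - self.mean_angle) / self.sd_angle
        return truncnorm.rvs(a, b, loc=self.mean_angle, scale=self.sd_angle,
                             size=n, random_state=rng)


def _helix_ca(n: int) -> np.ndarray:
    """Idealized helical Cα trace along +z, Cα centroid exactly at the
    origin (on the axis)."""
    k = np.arange(n, dtype=float)
    ang = np.radians(_TWIST) * k
    pts = np.column_stack((_RADIUS * np.cos(ang), _RADIUS * np.sin(ang),
                           _RISE * k))
    return pts - pts.mean(axis=0)


def _residue_frames(ca: np.ndarray, blocks) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Orthonormal local frame (t, e2, e3) per residue, built only from
    within-block Cα neighbours so frames are rigid under hinge rotation."""
    frames = []
    for lo, hi in blocks:
        for i in range(lo, hi + 1):
            p = max(i - 1, lo)
            nx = min(i + 1, hi)
            t = ca[nx] - ca[p]
            if np.linalg.norm(t) < 1e-9:  # single-residue block
                t = np.array([1.0, 0.0, 0.0])
            t = t / np.linalg.norm(t)
            d = ca[i] - 0.5 * (ca[p] + ca[nx])
            d = d - np.dot(d, t) * t
            if np.linalg.norm(d) < 1e-9:
                d = np.cross(t, [0.0, 0.0, 1.0])
                if np.linalg.norm(d) < 1e-9:
                    d = np.cross(t, [0.0, 1.0, 0.0])
            e2 = d / np.linalg.norm(d)
            e3 = np.cross(t, e2)
            frames.append((t, e2, e3))
    return frames


class HingeModel:
    """A hinge-protein template plus the bookkeeping needed to pose it
    at any bending angle (hairpin rotates rigidly about the hinge
    pivot)."""

    def __init__(self, topology_spec: HingeTopology, topology: Topology,
                 template_coords: np.ndarray, pivot: np.ndarray,
                 axis: np.ndarray, reference_angle: float):
        self.spec = topology_spec
        self.topology = topology
        self._template = np.asarray(template_coords, dtype=float)
        self.pivot = np.asarray(pivot, dtype=float)
        self.axis = np.asarray(axis, dtype=float)
        self.reference_angle = float(reference_angle)
        lo, hi = topology_spec.hairpin_range
        self.hairpin_mask = ((topology.residue_indices >= lo)
                             & (topology.residue_indices <= hi))

    @property
    def template(self) -> Structure:
        return Structure(self.topology, self._template.copy(), model_id=1)

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"core": self.spec.core_range,
                "hinge": self.spec.hinge_range,
                "hairpin": self.spec.hairpin_range}

    def coords_at(self, angle_deg: float) -> np.ndarray:
        if not (0.0 < angle_deg < 180.0):
            raise ValueError("bending angle must lie in (0, 180) degrees")
        delta = np.radians(angle_deg - self.reference_angle)
        rot = rotation_matrix(self.axis, -delta)
        coords = self._template.copy()
        moving = coords[self.hairpin_mask] - self.pivot
        coords[self.hairpin_mask] = moving @ rot.T + self.pivot
        return coords

    def at_angle(self, angle_deg: float, model_id: int = 1) -> Structure:
        return Structure(self.topology, self.coords_at(angle_deg), model_id)


def build_hinge_template(topology: HingeTopology = HingeTopology(),
                         seed: int = 0,
                         bending_angle: float = 120.0) -> HingeModel:
    """Construct the toy hinge protein posed at ``bending_angle``
    (default 120°).

    Deterministic for a fixed seed (the construction is in fact fully
    deterministic; the seed is accepted for interface symmetry with the
    samplers).
    """
    if not (0.0 < bending_angle < 180.0):
        raise ValueError("bending angle must lie in (0, 180) degrees")
    nc, nh, np_ = topology.n_res_core, topology.n_res_hinge, topology.n_res_hairpin
    half = np.radians(bending_angle) / 2.0

    u1 = np.array([np.sin(half), 0.0, np.cos(half)])    # core direction
    u2 = np.array([-np.sin(half), 0.0, np.cos(half)])   # hairpin direction

    def _axis_rotation(u):
        """Rotation taking +z to u (about y; u lies in the xz plane)."""
        ang = np.arctan2(u[0], u[2])
        return rotation_matrix(np.array([0.0, 1.0, 0.0]), ang)

    # core: residue nc nearest the hinge -> reverse z order
    core_local = _helix_ca(nc)[::-1]
    d_core = (nc - 1) * _RISE / 2.0 + _GAP
    core = core_local @ _axis_rotation(u1).T + d_core * u1

    # hinge: compact zigzag centred exactly at the origin (the pivot)
    k = np.arange(nh, dtype=float)
    hinge = np.column_stack((1.165 * (-1.0) ** k, 3.0 * k, np.zeros(nh)))
    hinge -= hinge.mean(axis=0)

    # hairpin: residue 1 of the block nearest the hinge -> natural z order
    hp_local = _helix_ca(np_)
    d_hp = (np_ - 1) * _RISE / 2.0 + _GAP
    hairpin = hp_local @ _axis_rotation(u2).T + d_hp * u2

    ca = np.vstack([core, hinge, hairpin])
    blocks = [(0, nc - 1), (nc, nc + nh - 1), (nc + nh, topology.total - 1)]
    frames = _residue_frames(ca, blocks)

    chain_ids, res_idx, res_names, atom_names, elements = [], [], [], [], []
    coords = []
    for i in range(topology.total):
        t, e2, e3 = frames[i]
        n_pos = ca[i] + 1.45 * (e2 - 0.5 * t) / np.linalg.norm(e2 - 0.5 * t)
        h_dir = 0.9 * e2 + 0.3 * t + 0.3 * e3
        h_pos = n_pos + 1.02 * h_dir / np.linalg.norm(h_dir)
        for name, el, pos in (("N", "N", n_pos), ("CA", "C", ca[i]),
                              ("H", "H", h_pos)):
            chain_ids.append("A")
            res_idx.append(i + 1)
            res_names.append("ALA")
            atom_names.append(name)
            elements.append(el)
            coords.append(pos)
    topo = Topology(chain_ids, res_idx, res_names, atom_names, elements)
    return HingeModel(topology, topo, np.asarray(coords),
                      pivot=np.zeros(3), axis=np.array([0.0, 1.0, 0.0]),
                      reference_angle=bending_angle)


def sample_hinge_ensemble(model: HingeModel, spec: AngleDistributionSpec,
                          n: int, seed: int = 0) -> ConformationEnsemble:
    """Draw ``n`` conformations with i.i.d. truncated-normal bending
    angles; subdomain-internal coordinates are exactly those of the
    template."""
    if n < 1:
        raise ValueError("need n >= 1 structures")
    rng = np.random.default_rng(seed)
    angles = spec.sample(n, rng)
    coords = np.stack([model.coords_at(a) for a in angles])
    return ConformationEnsemble(topology=model.topology, coords=coords)


def synth_rdc(structure: Structure, tensor: SaupeTensor, d_max: float,
              noise_sd: float = 0.0, seed: int = 0,
              medium: str = "synthetic") -> list[RdcRecord]:
    """Forward-model N–H RDCs from a known Saupe tensor, plus Gaussian
    noise of sd ``noise_sd`` Hz.  Residues without an N–H vector are
    skipped with a warning."""
    resids = structure.topology.residue_ids
    probes = [RdcRecord(int(r), "N", "H", 0.0) for r in resids]
    pred = back_calc_rdc(structure, tensor, d_max, probes)
    if pred.skipped:
        warnings.warn(
            f"{len(pred.skipped)} residues lack an N-H vector; skipped",
            RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, noise_sd, size=len(pred.records))
             if noise_sd > 0 else np.zeros(len(pred.records)))
    return [
        RdcRecord(rec.residue_index, "N", "H", float(d + eps),
                  error=float(noise_sd), medium=medium)
        for rec, d, eps in zip(pred.records, pred.calc, noise)
    ]


def synth_rdc_from_ensemble(ensemble: ConformationEnsemble, d_max: float,
                            noise_sd: float = 0.0, seed: int = 0,
                            tensor: SaupeTensor | None = None,
                            order_scale: float = 1e-2,
                            medium: str = "synthetic") -> list[RdcRecord]:
    """Ensemble-averaged synthetic RDCs.

    The observable is the weighted ensemble mean of per-structure
    couplings; if ``tensor`` is None each structure uses its own steric
    alignment tensor (the same structure-based route the restrained
    sampler uses), so data and forward model are self-consistent.
    """
    resids = ensemble.topology.residue_ids
    probes = [RdcRecord(int(r), "N", "H", 0.0) for r in resids]
    mean = None
    kept = None
    for structure, w in zip(ensemble, ensemble.weights):
        t = tensor if tensor is not None else steric_tensor(
            structure, order_scale=order_scale)
        pred = back_calc_rdc(structure, t, d_max, probes)
        if mean is None:
            mean = w * pred.calc
            kept = pred.records
        else:
            mean = mean + w * pred.calc
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, noise_sd, size=len(kept))
             if noise_sd > 0 else np.zeros(len(kept)))
    return [
        RdcRecord(rec.residue_index, "N", "H", float(d + eps),
                  error=float(noise_sd), medium=medium)
        for rec, d, eps in zip(kept, mean, noise)
    ]


def synth_noe(reference: Structure, contact_cutoff: float = 8.0,
              padding: float = 0.5) -> list[NoeRestraint]:
    """Cα–Cα upper-bound restraints from a reference conformation: one
    restraint per pair with |i−j| ≥ 3 and distance < cutoff, bound =
    distance + padding."""
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    ca = reference.select(atom_names=["CA"])
    resids = ca.topology.residue_indices
    coords = ca.coords
    restraints = []
    n = len(resids)
    for a in range(n):
        for b in range(a + 1, n):
            if abs(int(resids[b]) - int(resids[a])) < 3:
                continue
            d = float(np.linalg.norm(coords[b] - coords[a]))
            if d < contact_cutoff:
                restraints.append(NoeRestraint(
                    int(resids[a]), "CA", int(resids[b]), "CA",
                    upper_bound=d + padding))
    return restraints


def synth_saxs(ensemble: ConformationEnsemble, s_grid: np.ndarray,
               noise_frac: float = 0.0, seed: int = 0,
               form_factor=None) -> SaxsProfile:
    """Ensemble-averaged Debye profile with multiplicative Gaussian
    noise; sigma = noise_frac × ideal intensity (absent for
    noise_frac = 0)."""
    from .validation import ensemble_profile  # local import: no cycle at load
    ideal = ensemble_profile(ensemble, s_grid, form_factor)
    if noise_frac < 0:
        raise ValueError("noise fraction must be >= 0")
    if noise_frac == 0:
        return ideal
    rng = np.random.default_rng(seed)
    factor = 1.0 + rng.normal(0.0, noise_frac, size=len(ideal))
    return SaxsProfile(ideal.s, ideal.intensity * factor,
                       noise_frac * ideal.intensity)


# ------------------------------------------------- idealized backbones

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANG = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8}


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d given chain a-b-c."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide_backbone(n_res: int, phi: float, psi: float,
                           omega: float = 180.0) -> Structure:
    """Idealized poly-alanine backbone (N, CA, C, O per residue) with
    uniform (φ, ψ) dihedrals and standard bond geometry.  Intended for
    secondary-structure tests and demonstrations."""
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    pos = {}
    pos[(1, "N")] = np.zeros(3)
    pos[(1, "CA")] = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.radians(_ANG["N-CA-C"])
    pos[(1, "C")] = pos[(1, "CA")] + _BOND["CA-C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        pos[(i + 1, "N")] = _place(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                                   _BOND["C-N"], _ANG["CA-C-N"], psi)
        pos[(i + 1, "CA")] = _place(pos[(i, "CA")], pos[(i, "C")],
                                    pos[(i + 1, "N")],
                                    _BOND["N-CA"], _ANG["C-N-CA"], omega)
        pos[(i + 1, "C")] = _place(pos[(i, "C")], pos[(i + 1, "N")],
                                   pos[(i + 1, "CA")],
                                   _BOND["CA-C"], _ANG["N-CA-C"], phi)
    for i in range(1, n_res + 1):
        nxt = pos.get((i + 1, "N"))
        if nxt is None:
            ref_tor = psi - 180.0
            pos[(i, "O")] = _place(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                                   _BOND["C-O"], _ANG["CA-C-O"], ref_tor)
        else:
            # O opposite the next N across the C(sp2) plane
            pos[(i, "O")] = _place(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                                   _BOND["C-O"], _ANG["CA-C-O"], psi - 180.0)
    chain_ids, res_idx, res_names, atom_names, elements, coords = [], [], [], [], [], []
    for i in range(1, n_res + 1):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            chain_ids.append("A")
            res_idx.append(i)
            res_names.append("ALA")
            atom_names.append(name)
            elements.append(el)
            coords.append(pos[(i, name)])
    topo = Topology(chain_ids, res_idx, res_names, atom_names, elements)
    return Structure(topo, np.asarray(coords))


def ideal_alpha_helix(n_res: int) -> Structure:
    """Canonical α-helix backbone (φ = −57°, ψ = −47°)."""
    return build_peptide_backbone(n_res, phi=-57.0, psi=-47.0)
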