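"""Saupe alignment tensors and RDC back-calculation.

An RDC between nuclei a and b reports the orientation of the unit
internuclear vector û relative to the molecular alignment frame:

    D = d_max · ûᵀ S û

with S the traceless symmetric Saupe order matrix (5 independent
components) and d_max the maximal coupling of the pair (gyromagnetic
constants and bond length folded into one configurable scalar).  Two
routes to S are provided: a least-squares fit to measured couplings
(the standard SVD determination) and a structure-based steric
prediction that emulates obstruction by planar alignment media.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import fibonacci_sphere
from .ensemble_io import RdcRecord, Structure

__all__ = [
    "DEFAULT_D_MAX_NH",
    "SaupeTensor",
    "RdcPrediction",
    "back_calc_rdc",
    "back_calc_rdc_with_grad",
    "svd_fit_tensor",
    "steric_tensor",
    "reconstruct_amide_h",
]

# Maximal N-H dipolar coupling in Hz for the 1.02 Å bond-length
# convention.  It cancels in Q-factors and is configurable everywhere.
DEFAULT_D_MAX_NH = 21_700.0


@dataclass(frozen=True)
class SaupeTensor:
    """Traceless symmetric 3×3 order matrix."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("Saupe tensor must be 3x3")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("Saupe tensor must be symmetric")
        # symmetrize exactly and remove numerical trace
        m = 0.5 * (m + m.T)
        m = m - np.eye(3) * (np.trace(m) / 3.0)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def zero(cls) -> "SaupeTensor":
        return cls(np.zeros((3, 3)))

    @classmethod
    def from_components(cls, sxx: float, syy: float, sxy: float,
                        sxz: float, syz: float) -> "SaupeTensor":
        """Build from the 5 independent components (Szz = −Sxx−Syy)."""
        return cls(np.array([
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ]))

    @property
    def components(self) -> np.ndarray:
        """(Sxx, Syy, Sxy, Sxz, Syz)."""
        m = self.matrix
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors ordered |Szz| ≥ |Syy| ≥ |Sxx|.

        Columns of the returned matrix are (x, y, z) principal axes.
        Ties in |value| are broken by signed value (deterministic labels).
        """
        vals, vecs = np.linalg.eigh(self.matrix)
        order = sorted(range(3), key=lambda i: (abs(vals[i]), vals[i]))
        vals = vals[order]
        vecs = vecs[:, order]
        return vals, vecs

    @property
    def axial(self) -> float:
        """Largest-magnitude eigenvalue Szz (sets the RDC scale)."""
        return float(self.eigensystem()[0][2])

    @property
    def rhombicity(self) -> float:
        """(Sxx − Syy)/Szz with the |Szz| ≥ |Syy| ≥ |Sxx| ordering;
        0 for an axially symmetric tensor."""
        vals, _ = self.eigensystem()
        sxx, syy, szz = vals
        if szz == 0:
            return 0.0
        return float((sxx - syy) / szz)

    def rotated(self, rotation: np.ndarray) -> "SaupeTensor":
        r = np.asarray(rotation, dtype=float)
        return SaupeTensor(r @ self.matrix @ r.T)

    def scaled(self, factor: float) -> "SaupeTensor":
        return SaupeTensor(self.matrix * factor)


@dataclass
class RdcPrediction:
    """Back-calculated couplings for a set of records plus fit
    diagnostics against the records' experimental values."""

    records: list[RdcRecord]
    calc: np.ndarray
    q_factor: float = 0.0
    rmsd: float = 0.0
    skipped: list[RdcRecord] = field(default_factory=list)

    def __post_init__(self):
        self.calc = np.asarray(self.calc, dtype=float)
        if self.q_factor < 0:
            raise ValueError("Q-factor must be non-negative")


def reconstruct_amide_h(structure: Structure, residue_index: int) -> np.ndarray:
    """Place a missing amide H 1.02 Å from N along the in-plane bisector
    of C(i−1)–N(i)–CA(i), pointing away from both neighbours."""
    topo = structure.topology
    i_n = topo.atom_index(residue_index, "N")
    i_ca = topo.atom_index(residue_index, "CA")
    i_c_prev = topo.atom_index(residue_index - 1, "C")
    if i_n is None or i_ca is None or i_c_prev is None:
        raise KeyError(
            f"cannot reconstruct amide H of residue {residue_index}: "
            "need N, CA and preceding C")
    n = structure.coords[i_n]
    v1 = structure.coords[i_c_prev] - n
    v2 = structure.coords[i_ca] - n
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bisector = -(v1 + v2)
    norm = np.linalg.norm(bisector)
    if norm < 1e-9:
        raise ValueError(
            f"degenerate geometry at residue {residue_index} (collinear)")
    return n + 1.02 * bisector / norm


def _bond_vectors(structure: Structure, records, allow_reconstruct=True):
    """Internuclear vectors for records; returns (used_records, vectors,
    skipped_records)."""
    used, vecs, skipped = [], [], []
    for rec in records:
        topo = structure.topology
        ia = topo.atom_index(rec.residue_index, rec.atom_a)
        ib = topo.atom_index(rec.residue_index, rec.atom_b)
        pa = structure.coords[ia] if ia is not None else None
        pb = structure.coords[ib] if ib is not None else None
        if pb is None and rec.atom_b == "H" and allow_reconstruct:
            try:
                pb = reconstruct_amide_h(structure, rec.residue_index)
            except (KeyError, ValueError):
                pb = None
        if pa is None and rec.atom_a == "H" and allow_reconstruct:
            try:
                pa = reconstruct_amide_h(structure, rec.residue_index)
            except (KeyError, ValueError):
                pa = None
        if pa is None or pb is None:
            skipped.append(rec)
            continue
        r = pb - pa
        if np.linalg.norm(r) < 1e-9:
            raise ValueError(
                f"zero-length internuclear vector for residue "
                f"{rec.residue_index} {rec.atom_a}-{rec.atom_b}")
        used.append(rec)
        vecs.append(r)
    return used, (np.asarray(vecs, dtype=float) if vecs
                  else np.empty((0, 3))), skipped


def back_calc_rdc(structure: Structure, tensor: SaupeTensor, d_max: float,
                  records) -> RdcPrediction:
    """Back-calculate D = d_max ûᵀ S û for each record.

    Records whose atoms cannot be resolved (after amide-H
    reconstruction) are reported in ``skipped``.  Q-factor and RMSD are
    computed against the records' experimental values.
    """
    used, vecs, skipped = _bond_vectors(structure, records)
    if len(used) == 0:
        return RdcPrediction(used, np.empty(0), 0.0, 0.0, skipped)
    u = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    calc = d_max * np.einsum("ki,ij,kj->k", u, tensor.matrix, u)
    exp = np.array([r.value for r in used])
    diff = calc - exp
    rmsd = float(np.sqrt(np.mean(diff**2)))
    rms_exp = float(np.sqrt(np.mean(exp**2)))
    q = rmsd / rms_exp if rms_exp > 0 else 0.0
    return RdcPrediction(used, calc, q, rmsd, skipped)


def back_calc_rdc_with_grad(structure: Structure, tensor: SaupeTensor,
                            d_max: float, records):
    """Couplings plus analytic gradients w.r.t. the two atom positions.

    Returns ``(used_records, calc, atom_pairs, grad_b, skipped)`` where
    ``grad_b[k]`` is dD_k/d(pos of atom_b); the gradient w.r.t. atom_a is
    its negative.  ``atom_pairs[k]`` are topology indices (ia, ib); a
    reconstructed H has ib = -1 (its gradient is attributed to N, a
    documented approximation used only when structures lack explicit H).
    """
    used, vecs, skipped = _bond_vectors(structure, records)
    topo = structure.topology
    pairs = []
    for rec in used:
        ia = topo.atom_index(rec.residue_index, rec.atom_a)
        ib = topo.atom_index(rec.residue_index, rec.atom_b)
        pairs.append((ia if ia is not None else -1,
                      ib if ib is not None else -1))
    if len(used) == 0:
        return used, np.empty(0), pairs, np.empty((0, 3)), skipped
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    u = vecs / norms
    s_u = u @ tensor.matrix.T  # S û (symmetric S)
    d_over = np.einsum("ki,ki->k", u, s_u)  # ûᵀSû
    calc = d_max * d_over
    # dD/dr = d_max (2 S û − 2 (ûᵀSû) û)/|r|
    grad_b = d_max * 2.0 * (s_u - d_over[:, None] * u) / norms
    return used, calc, pairs, grad_b, skipped


def svd_fit_tensor(structure: Structure, rdc_records, d_max: float
                   ) -> tuple[SaupeTensor, RdcPrediction]:
    """Least-squares Saupe tensor from measured couplings.

    Solves min_S Σ(D_calc − D_exp)² over the 5 independent components
    via SVD-based least squares; returns the tensor and the prediction
    (with Q-factor) it implies.
    """
    used, vecs, skipped = _bond_vectors(structure, rdc_records)
    if len(used) < 5:
        raise ValueError(
            f"Saupe fit underdetermined: {len(used)} usable records (< 5)")
    u = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    design = np.column_stack([
        ux**2 - uz**2, uy**2 - uz**2, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz,
    ])
    exp = np.array([r.value for r in used]) / d_max
    sol, residuals, rank, _ = np.linalg.lstsq(design, exp, rcond=None)
    if rank < 5:
        warnings.warn(
            "rank-deficient RDC design matrix; returning minimum-norm "
            "Saupe solution", RuntimeWarning, stacklevel=2)
    tensor = SaupeTensor.from_components(*sol)
    pred = back_calc_rdc(structure, tensor, d_max, used)
    pred.skipped.extend(skipped)
    return tensor, pred


def steric_tensor(structure: Structure, order_scale: float = 1e-2,
                  barrier_spacing: float | None = None,
                  n_orientations: int = 5000) -> SaupeTensor:
    """Structure-based steric alignment prediction.

    Models alignment by obstruction between parallel planar barriers:
    for each direction n of the barrier normal in the molecular frame
    (quasi-uniform grid of ``n_orientations`` directions), the molecule's
    extent w(n) along n excludes a fraction of positions between barriers
    a distance L apart, weighting that orientation by
    max(0, 1 − w(n)/L).  The order matrix is the weighted average of
    (3 n nᵀ − 1)/2, scaled by ``order_scale`` — the medium order
    parameter that absorbs orientational averaging.

    ``barrier_spacing`` defaults to twice the molecule's maximal extent.
    """
    coords = np.asarray(structure.coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("steric tensor needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    dirs = fibonacci_sphere(n_orientations)
    proj = centered @ dirs.T  # (n_atoms, n_dirs)
    extent = proj.max(axis=0) - proj.min(axis=0)
    if barrier_spacing is None:
        barrier_spacing = 2.0 * float(extent.max())
    w = np.clip(1.0 - extent / barrier_spacing, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError(
            "barrier spacing smaller than the molecule in every "
            "orientation; increase barrier_spacing")
    outer = np.einsum("ki,kj->kij", dirs, dirs)
    second = np.einsum("k,kij->ij", w, outer) / total
    s = order_scale * 1.5 * (second - np.eye(3) / 3.0)
    return SaupeTensor(s)
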