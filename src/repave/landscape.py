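"""Ensemble characterization: bending angle, radius of gyration,
free-energy landscape, reference-structure projection, contact maps and
secondary-structure occupancy.

The two reaction coordinates are (i) the inter-subdomain bending angle,
defined at the hinge-region Cα centroid as the angle between the vectors
to the globular-region and loop-region Cα centroids, and (ii) the radius
of gyration.  The landscape is a 2D histogram over these coordinates
converted to free energies F = −ln P in k_BT units, shifted so the mode
is zero; empty bins are masked, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import angle_between, dihedral
from .ensemble_io import ConformationEnsemble, Structure

__all__ = [
    "RegionSpec",
    "LandscapeGrid",
    "bending_angle",
    "radius_of_gyration",
    "free_energy_landscape",
    "project_structures",
    "contact_map",
    "ss_occupancy",
    "ss_occupancy_ca",
]

# Default residue regions for the Josephin-domain bending angle:
# region I the globular subdomain, region II the hinge (angle vertex),
# region III the hairpin-side loop.  Author PDB numbering, inclusive.
_DEFAULT_I = ((111, 113), (122, 125), (162, 165))
_DEFAULT_II = ((32, 35),)
_DEFAULT_III = ((45, 48), (58, 61))


@dataclass(frozen=True)
class RegionSpec:
    """Three disjoint residue-range sets defining the bending angle."""

    region_i: tuple = _DEFAULT_I
    region_ii: tuple = _DEFAULT_II
    region_iii: tuple = _DEFAULT_III

    def __post_init__(self):
        sets = [set(self.residues(r)) for r in ("I", "II", "III")]
        if any(not s for s in sets):
            raise ValueError("every region must contain residues")
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("regions must be disjoint")

    def residues(self, region: str) -> list[int]:
        ranges = {"I": self.region_i, "II": self.region_ii,
                  "III": self.region_iii}[region]
        out: list[int] = []
        for lo, hi in ranges:
            out.extend(range(lo, hi + 1))
        return out

    @classmethod
    def from_hinge_model(cls, model) -> "RegionSpec":
        """Regions for a synthetic hinge model: core → I, hinge → II
        (vertex), hairpin → III."""
        r = model.regions
        return cls((r["core"],), (r["hinge"],), (r["hairpin"],))


def _region_centroid(structure: Structure, residues: list[int]) -> np.ndarray:
    topo = structure.topology
    missing = [r for r in residues if topo.atom_index(r, "CA") is None]
    if missing:
        raise ValueError(f"region residues missing Cα atoms: {missing}")
    idx = [topo.atom_index(r, "CA") for r in residues]
    return structure.coords[idx].mean(axis=0)


def bending_angle(structure: Structure, regions: RegionSpec) -> float:
    """Inter-subdomain bending angle in degrees ([0, 180]).

    Vertex at the region-II (hinge) Cα centroid; the angle is between
    the vectors from that vertex to the region-I and region-III Cα
    centroids (unweighted centroids — equal Cα masses cancel).
    """
    c1 = _region_centroid(structure, regions.residues("I"))
    c2 = _region_centroid(structure, regions.residues("II"))
    c3 = _region_centroid(structure, regions.residues("III"))
    return angle_between(c1 - c2, c3 - c2)


def radius_of_gyration(structure: Structure, selection: str = "all",
                       mass_weighted: bool = True) -> float:
    """Rg = sqrt(Σ w_i |r_i − r̄|² / Σ w_i) in Å.

    ``selection``: "all", "heavy" (non-hydrogen) or "ca".  The default
    (all atoms, mass-weighted) is the conventional Rg; the Cα-only
    unweighted mode matches landscape coordinates.
    """
    topo = structure.topology
    if selection == "all":
        mask = np.ones(len(topo), dtype=bool)
    elif selection == "heavy":
        mask = topo.elements != "H"
    elif selection == "ca":
        mask = topo.atom_names == "CA"
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not mask.any():
        raise ValueError("selection matches no atoms")
    coords = structure.coords[mask]
    w = topo.masses[mask] if mass_weighted else np.ones(mask.sum())
    center = np.average(coords, axis=0, weights=w)
    return float(np.sqrt(np.average(((coords - center) ** 2).sum(axis=1),
                                    weights=w)))


@dataclass
class LandscapeGrid:
    """2D free-energy surface over (bending angle, Rg).

    ``free_energy`` is −ln P in k_BT units with the minimum shifted to
    zero; empty bins carry NaN and are flagged in ``empty_mask``.
    """

    angle_edges: np.ndarray
    rg_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    empty_mask: np.ndarray

    @property
    def mode_angle(self) -> float:
        """Bin-center angle of the landscape mode (F = 0)."""
        i, _ = np.unravel_index(np.nanargmax(self.probability),
                                self.probability.shape)
        return float(0.5 * (self.angle_edges[i] + self.angle_edges[i + 1]))

    @property
    def mode_rg(self) -> float:
        _, j = np.unravel_index(np.nanargmax(self.probability),
                                self.probability.shape)
        return float(0.5 * (self.rg_edges[j] + self.rg_edges[j + 1]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (angle_lo, angle_hi, rg_lo, rg_hi, P, F)."""
        rows = []
        for i in range(self.probability.shape[0]):
            for j in range(self.probability.shape[1]):
                rows.append({
                    "angle_lo": self.angle_edges[i],
                    "angle_hi": self.angle_edges[i + 1],
                    "rg_lo": self.rg_edges[j],
                    "rg_hi": self.rg_edges[j + 1],
                    "probability": self.probability[i, j],
                    "free_energy_kT": self.free_energy[i, j],
                })
        return pd.DataFrame(rows)


def _default_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def free_energy_landscape(ensemble: ConformationEnsemble,
                          regions: RegionSpec,
                          angle_bins: np.ndarray | None = None,
                          rg_bins: np.ndarray | None = None,
                          angle_bin_width: float = 2.0,
                          rg_bin_width: float = 0.25,
                          rg_selection: str = "ca",
                          rg_mass_weighted: bool = False) -> LandscapeGrid:
    """Weighted 2D histogram of (bending angle, Rg) → free energies.

    Default bins are 2° × 0.25 Å spanning the observed range; explicit
    edges override.  Probabilities use the ensemble weights (uniform by
    default, i.e. all structures enter equally).
    """
    angles = np.array([bending_angle(s, regions) for s in ensemble])
    rgs = np.array([radius_of_gyration(s, rg_selection, rg_mass_weighted)
                    for s in ensemble])
    if angle_bins is None:
        angle_bins = _default_edges(angles, angle_bin_width)
    if rg_bins is None:
        rg_bins = _default_edges(rgs, rg_bin_width)
    hist, ae, re = np.histogram2d(angles, rgs, bins=[angle_bins, rg_bins],
                                  weights=ensemble.weights)
    total = hist.sum()
    if total <= 0:
        raise ValueError("bins do not cover the observed coordinates")
    prob = hist / total
    empty = prob == 0
    free = np.full_like(prob, np.nan)
    with np.errstate(divide="ignore"):
        free[~empty] = -np.log(prob[~empty])
    free -= np.nanmin(free)
    return LandscapeGrid(ae, re, prob, free, empty)


def project_structures(structures: dict, regions: RegionSpec,
                       rg_selection: str = "ca",
                       rg_mass_weighted: bool = False) -> pd.DataFrame:
    """(angle, Rg) coordinates of named reference structures/ensembles
    for overlay on a landscape.

    Returns a DataFrame (name, model_id, angle, rg, error); structures
    whose numbering does not resolve the regions get an error entry
    instead of coordinates.
    """
    rows = []
    for name, item in structures.items():
        members = ([item] if isinstance(item, Structure) else list(item))
        for s in members:
            try:
                rows.append({
                    "name": name, "model_id": s.model_id,
                    "angle": bending_angle(s, regions),
                    "rg": radius_of_gyration(s, rg_selection,
                                             rg_mass_weighted),
                    "error": "",
                })
            except (ValueError, KeyError) as exc:
                rows.append({"name": name, "model_id": s.model_id,
                             "angle": np.nan, "rg": np.nan,
                             "error": str(exc)})
    return pd.DataFrame(rows)


def contact_map(ensemble: ConformationEnsemble,
                cutoff: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Residue-residue contact frequencies over the ensemble.

    Entry (i, j) is the weighted fraction of structures in which the
    Cα–Cα distance is *strictly* below ``cutoff`` (a pair at exactly the
    cutoff is not a contact).  Returns ``(residue_ids, matrix)``;
    the matrix is symmetric with unit diagonal.
    """
    ca = ensemble.select(atom_names=["CA"])
    resids = ca.topology.residue_indices
    n = len(resids)
    freq = np.zeros((n, n))
    for coords, w in zip(ca.coords, ca.weights):
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        freq += w * (d < cutoff)
    np.fill_diagonal(freq, 1.0)
    return resids.copy(), freq


# ------------------------------------------------ secondary structure

_HB_CUTOFF = -0.5   # kcal/mol Kabsch–Sander hydrogen-bond threshold
_KS_FACTOR = 0.084 * 332.0


def _ks_hbonds(structure: Structure, resids: list[int]) -> set:
    """Kabsch–Sander hydrogen bonds: (acceptor i, donor j) meaning CO of
    residue i accepts the amide H of residue j.

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol; a bond
    forms iff E < −0.5.  Missing amide H is placed 1.0 Å from N along
    the C(j−1)→O(j−1) ... O→C direction (the DSSP convention).
    """
    topo = structure.topology
    pos = {}
    for r in resids:
        entry = {}
        for name in ("N", "CA", "C", "O", "H"):
            idx = topo.atom_index(r, name)
            if idx is not None:
                entry[name] = structure.coords[idx]
        pos[r] = entry
    h_pos = {}
    for r in resids:
        if "H" in pos[r]:
            h_pos[r] = pos[r]["H"]
            continue
        prev = pos.get(r - 1)
        if prev is None or "C" not in prev or "O" not in prev \
                or "N" not in pos[r]:
            continue
        d = prev["C"] - prev["O"]
        h_pos[r] = pos[r]["N"] + d / np.linalg.norm(d)
    bonds = set()
    for i in resids:       # acceptor: needs C, O
        if "C" not in pos[i] or "O" not in pos[i]:
            continue
        for j in resids:   # donor: needs N, H
            if abs(i - j) < 2:
                continue
            if "N" not in pos[j] or j not in h_pos:
                continue
            r_on = np.linalg.norm(pos[i]["O"] - pos[j]["N"])
            r_ch = np.linalg.norm(pos[i]["C"] - h_pos[j])
            r_oh = np.linalg.norm(pos[i]["O"] - h_pos[j])
            r_cn = np.linalg.norm(pos[i]["C"] - pos[j]["N"])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clash: treat as no bond
            e = _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < _HB_CUTOFF:
                bonds.add((i, j))
    return bonds


def _ks_assign(structure: Structure) -> dict[int, str]:
    """Per-residue class: 'H' (α-helix), 'G' (3₁₀), 'E' (strand) or ''.

    DSSP subset: n-turn(i, n) iff CO(i) bonds NH(i+n); a minimal helix
    needs two consecutive turns; strand residues come from parallel or
    antiparallel bridge patterns (|i−j| ≥ 3; isolated bridges count,
    a documented simplification of the ladder rule).
    """
    resids = [int(r) for r in structure.topology.residue_ids]
    hb = _ks_hbonds(structure, resids)
    rset = set(resids)
    turn4 = {i for i in resids if (i, i + 4) in hb}
    turn3 = {i for i in resids if (i, i + 3) in hb}
    cls: dict[int, str] = {r: "" for r in resids}
    for i in resids:
        if i - 1 in turn4 and i in turn4:
            for k in range(i, i + 4):
                if k in rset:
                    cls[k] = "H"
    for i in resids:
        if i - 1 in turn3 and i in turn3:
            for k in range(i, i + 3):
                if k in rset and cls[k] == "":
                    cls[k] = "G"
    for i in resids:
        for j in resids:
            if j - i < 3:
                continue
            para = (((i - 1, j) in hb and (j, i + 1) in hb)
                    or ((j - 1, i) in hb and (i, j + 1) in hb))
            anti = (((i, j) in hb and (j, i) in hb)
                    or ((i - 1, j + 1) in hb and (j - 1, i + 1) in hb))
            if para or anti:
                for k in (i, j):
                    if cls[k] == "":
                        cls[k] = "E"
    return cls


def ss_occupancy_ca(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Cα-only virtual-dihedral secondary-structure fallback.

    Residue i is helical if the Cα pseudo-dihedral τ(i−1, i, i+1, i+2)
    and pseudo-angle θ(i−1, i, i+1) fall in the canonical α/3₁₀ window,
    extended/strand-like for large |τ| and open θ.  Returns boolean
    helix and sheet arrays over the residue list.
    """
    topo = structure.topology
    resids = [int(r) for r in topo.residue_ids]
    helix = np.zeros(len(resids), dtype=bool)
    sheet = np.zeros(len(resids), dtype=bool)
    for k, i in enumerate(resids):
        idx = [topo.atom_index(j, "CA") for j in (i - 1, i, i + 1, i + 2)]
        if any(q is None for q in idx[:3]):
            continue
        p = [structure.coords[q] for q in idx[:3]]
        theta = angle_between(p[0] - p[1], p[2] - p[1])
        if idx[3] is not None:
            tau = np.degrees(dihedral(p[0], p[1], p[2],
                                      structure.coords[idx[3]]))
        else:
            tau = None
        if tau is not None and 20.0 <= tau <= 80.0 and 75.0 <= theta <= 110.0:
            helix[k] = True
        elif (tau is None or abs(tau) >= 140.0) and 110.0 <= theta <= 150.0:
            sheet[k] = True
    return helix, sheet


def ss_occupancy(ensemble: ConformationEnsemble, mode: str = "auto"
                 ) -> pd.DataFrame:
    """Per-residue helix and sheet fractions over the ensemble.

    ``mode``: "backbone" (Kabsch–Sander hydrogen-bond criterion; pools
    α- and 3₁₀-helix classes into helix), "ca" (virtual-dihedral
    fallback for Cα-only models) or "auto".  Returns a DataFrame
    (residue, helix_fraction, sheet_fraction); fractions are
    weight-averaged over structures and satisfy helix + sheet ≤ 1.
    """
    topo = ensemble.topology
    names = set(topo.atom_names.tolist())
    has_backbone = {"N", "CA", "C", "O"} <= names
    if mode == "auto":
        mode = "backbone" if has_backbone else "ca"
    if mode == "backbone" and not has_backbone:
        raise ValueError(
            "full-backbone secondary structure needs N, CA, C, O atoms; "
            "use mode='ca' for Cα-only models")
    if mode not in ("backbone", "ca"):
        raise ValueError(f"unknown mode {mode!r}")
    resids = [int(r) for r in topo.residue_ids]
    helix = np.zeros(len(resids))
    sheet = np.zeros(len(resids))
    for structure, w in zip(ensemble, ensemble.weights):
        if mode == "backbone":
            cls = _ks_assign(structure)
            h = np.array([cls[r] in ("H", "G") for r in resids])
            e = np.array([cls[r] == "E" for r in resids])
        else:
            h, e = ss_occupancy_ca(structure)
        helix += w * h
        sheet += w * e
    # guard against accumulation error pushing the partition past 1
    total = helix + sheet
    over = total > 1.0
    if over.any():
        helix[over] /= total[over]
        sheet[over] /= total[over]
    return pd.DataFrame({"residue": resids, "helix_fraction": helix,
                         "sheet_fraction": sheet})
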