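"""Structural data model and file I/O.

The in-memory containers mirror how trajectory libraries store ensembles:
one shared :class:`Topology` (atom metadata) plus a coordinate array per
model.  PDB reading and writing are delegated to :mod:`biotite`; the
plain-text RDC/NOE/SAXS table dialects are defined here (documented in the
README — no community standard exists for RDC/NOE tables).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "AtomRecord",
    "Topology",
    "Structure",
    "ConformationEnsemble",
    "RdcRecord",
    "NoeRestraint",
    "SaxsProfile",
    "PdbParseError",
    "TopologyError",
    "TableParseError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_rdc_table",
    "write_rdc_table",
    "read_noe_table",
    "write_noe_table",
    "read_saxs_profile",
    "write_saxs_profile",
]


class PdbParseError(ValueError):
    """Raised for malformed PDB content (names the offending line)."""


class TopologyError(ValueError):
    """Raised when models of an ensemble disagree in atom count/metadata."""


class TableParseError(ValueError):
    """Raised for malformed data-table rows (names the row)."""


# Fallback masses for the elements that occur in protein work; biotite
# supplies masses for everything else it knows.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "X": 12.011,
}


def _element_mass(element: str) -> float:
    element = element.strip().upper() or "X"
    try:
        m = bst.info.mass(element)
        if m is not None and m > 0:
            return float(m)
    except Exception:
        pass
    return _MASSES.get(element, 12.011)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position.  A read-only view into a
    :class:`Structure`."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    mass: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.mass <= 0:
            raise ValueError("atom mass must be positive")
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")


class Topology:
    """Shared per-atom metadata for all structures of an ensemble."""

    def __init__(self, chain_ids, residue_indices, residue_names, atom_names,
                 elements, masses=None):
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U4")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        if masses is None:
            masses = [_element_mass(e) for e in self.elements]
        self.masses = np.asarray(masses, dtype=float)
        n = len(self.atom_names)
        for arr in (self.chain_ids, self.residue_indices, self.residue_names,
                    self.elements, self.masses):
            if len(arr) != n:
                raise TopologyError("topology field lengths disagree")
        if n == 0:
            raise TopologyError("topology must contain at least one atom")
        if np.any(self.residue_indices < 1):
            raise TopologyError("residue indices are 1-based (must be >= 1)")
        if np.any(self.masses <= 0):
            raise TopologyError("atom masses must be positive")
        self._index: dict[tuple[int, str], int] = {}
        for i, (ri, an) in enumerate(zip(self.residue_indices, self.atom_names)):
            self._index.setdefault((int(ri), str(an)), i)

    def __len__(self) -> int:
        return len(self.atom_names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            np.array_equal(self.residue_indices, other.residue_indices)
            and np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.residue_names, other.residue_names)
            and np.array_equal(self.chain_ids, other.chain_ids)
        )

    def atom_index(self, residue_index: int, atom_name: str):
        """Index of atom ``(residue_index, atom_name)`` or None."""
        return self._index.get((int(residue_index), str(atom_name)))

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.residue_indices)

    def selection_mask(self, atom_names: Sequence[str] | None = None,
                       chain_id: str | None = None) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        return mask

    def subset(self, mask: np.ndarray) -> "Topology":
        return Topology(
            self.chain_ids[mask], self.residue_indices[mask],
            self.residue_names[mask], self.atom_names[mask],
            self.elements[mask], self.masses[mask],
        )


class Structure:
    """A single conformation: a Topology plus an (n_atoms, 3) coordinate
    array in Å."""

    def __init__(self, topology: Topology, coords: np.ndarray, model_id: int = 1):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(topology), 3):
            raise TopologyError(
                f"coordinate shape {coords.shape} does not match topology "
                f"({len(topology)} atoms)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.topology = topology
        self.coords = coords
        self.model_id = int(model_id)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        t = self.topology
        for i in range(len(t)):
            yield AtomRecord(
                str(t.chain_ids[i]), int(t.residue_indices[i]),
                str(t.residue_names[i]), str(t.atom_names[i]),
                str(t.elements[i]), self.coords[i], float(t.masses[i]),
            )

    def atom_position(self, residue_index: int, atom_name: str) -> np.ndarray:
        i = self.topology.atom_index(residue_index, atom_name)
        if i is None:
            raise KeyError(f"atom {atom_name} of residue {residue_index} "
                           "not in topology")
        return self.coords[i]

    def select(self, atom_names: Sequence[str] | None = None,
               chain_id: str | None = None) -> "Structure":
        mask = self.topology.selection_mask(atom_names, chain_id)
        if not mask.any():
            raise ValueError("selection matches no atoms")
        return Structure(self.topology.subset(mask), self.coords[mask],
                         self.model_id)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, float).T
        if translation is not None:
            coords = coords + np.asarray(translation, float)
        return Structure(self.topology, coords, self.model_id)


class ConformationEnsemble:
    """Ordered, optionally weighted collection of same-topology structures."""

    def __init__(self, structures: Sequence[Structure] | None = None,
                 weights: Sequence[float] | None = None, *,
                 topology: Topology | None = None,
                 coords: np.ndarray | None = None,
                 model_ids: Sequence[int] | None = None):
        if structures is not None:
            structures = list(structures)
            if not structures:
                raise ValueError("ensemble must contain at least one structure")
            topology = structures[0].topology
            for s in structures[1:]:
                if s.n_atoms != structures[0].n_atoms or s.topology != topology:
                    raise TopologyError(
                        "all structures in an ensemble must share one topology")
            coords = np.stack([s.coords for s in structures])
            model_ids = [s.model_id for s in structures]
        elif topology is None or coords is None:
            raise ValueError("provide structures or (topology, coords)")
        else:
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 3 or coords.shape[1:] != (len(topology), 3):
                raise TopologyError("coords must be (n_models, n_atoms, 3)")
        self.topology = topology
        self.coords = coords
        self.model_ids = (list(model_ids) if model_ids is not None
                          else list(range(1, len(coords) + 1)))
        n = len(coords)
        if weights is None:
            weights = np.full(n, 1.0 / n)
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (n,):
                raise ValueError("one weight per structure required")
            if np.any(weights < 0):
                raise ValueError("weights must be non-negative")
            total = weights.sum()
            if total <= 0:
                raise ValueError("weights must not all be zero")
            weights = weights / total
        self.weights = weights

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self) -> Iterator[Structure]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Structure:
        return Structure(self.topology, self.coords[i], self.model_ids[i])

    @property
    def structures(self) -> list[Structure]:
        return list(self)

    def select(self, atom_names: Sequence[str] | None = None,
               chain_id: str | None = None) -> "ConformationEnsemble":
        mask = self.topology.selection_mask(atom_names, chain_id)
        if not mask.any():
            raise ValueError("selection matches no atoms")
        return ConformationEnsemble(
            topology=self.topology.subset(mask),
            coords=self.coords[:, mask, :],
            model_ids=self.model_ids, weights=self.weights)


@dataclass
class RdcRecord:
    """One residual dipolar coupling measurement (Hz)."""

    residue_index: int
    atom_a: str
    atom_b: str
    value: float
    error: float = 1.0
    medium: str = ""

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError("RDC atom pair must be two distinct atoms")
        if not np.isfinite(self.value):
            raise ValueError("RDC value must be finite")
        if self.error < 0:
            raise ValueError("RDC error must be >= 0")


@dataclass
class NoeRestraint:
    """An NOE-derived distance bound between two atoms (Å)."""

    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    upper_bound: float
    lower_bound: float = 0.0

    def __post_init__(self):
        if not (self.upper_bound > self.lower_bound >= 0.0):
            raise ValueError("require upper_bound > lower_bound >= 0")


@dataclass
class SaxsProfile:
    """1D scattering profile: momentum transfer s (Å⁻¹), intensity and
    optional uncertainty."""

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must be 1D and equally long")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.s.shape:
                raise ValueError("sigma must match the s grid")

    def __len__(self) -> int:
        return len(self.s)


# ----------------------------------------------------------------- PDB I/O

def _locate_bad_atom_line(path) -> int | None:
    """Best-effort scan for the first ATOM/HETATM line with unparsable
    coordinate fields; returns a 1-based line number."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def read_pdb_ensemble(path, selection: Sequence[str] | None = None,
                      chain_id: str | None = None) -> ConformationEnsemble:
    """Read a (multi-)model PDB file into a :class:`ConformationEnsemble`.

    ``selection`` optionally restricts to the given atom names (e.g.
    ``["CA"]``); ``chain_id`` restricts to one chain.  Alternate locations
    keep the first variant.  A single-model file yields an ensemble of
    size 1 with weight 1.
    """
    path = Path(path)
    try:
        pdb_file = bpdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="first")
    except bst.BadStructureError as exc:
        raise TopologyError(
            f"{path.name}: inconsistent atom records across models "
            f"({exc})") from exc
    except Exception as exc:
        if "must be equal" in str(exc):  # biotite's model-mismatch wording
            raise TopologyError(
                f"{path.name}: inconsistent atom counts across models "
                f"({exc})") from exc
        lineno = _locate_bad_atom_line(path)
        if lineno is not None:
            raise PdbParseError(
                f"{path.name}: malformed ATOM record at line {lineno}") from exc
        raise PdbParseError(f"{path.name}: cannot parse PDB file ({exc})") from exc
    if stack.array_length() == 0:
        raise PdbParseError(f"{path.name}: no atoms found")
    elements = [e if e else "X" for e in stack.element]
    topo = Topology(stack.chain_id, stack.res_id, stack.res_name,
                    stack.atom_name, elements)
    ens = ConformationEnsemble(topology=topo, coords=np.asarray(stack.coord))
    if chain_id is not None or selection is not None:
        ens = ens.select(atom_names=selection, chain_id=chain_id)
    return ens


def write_pdb_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write an ensemble as a MODEL/ENDMDL-delimited PDB file."""
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    t = ensemble.topology
    n = len(t)
    arrays = []
    for coords in ensemble.coords:
        arr = bst.AtomArray(n)
        arr.chain_id = t.chain_ids
        arr.res_id = t.residue_indices
        arr.res_name = t.residue_names
        arr.atom_name = t.atom_names
        arr.element = t.elements
        arr.hetero = np.zeros(n, dtype=bool)
        arr.coord = np.asarray(coords, dtype=np.float32)
        arrays.append(arr)
    stack = bst.stack(arrays)
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(stack)
    if len(ensemble) == 1:
        # biotite flattens a depth-1 stack; keep explicit MODEL/ENDMDL
        body = [ln for ln in pdb_file.lines if not ln.startswith("END")]
        pdb_file.lines = ["MODEL        1"] + body + ["ENDMDL", "END"]
    pdb_file.write(str(path))


# --------------------------------------------------------------- table I/O

def _data_rows(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            yield lineno, line.split()


def read_rdc_table(path) -> list[RdcRecord]:
    """Read a whitespace-delimited RDC table.

    Columns: ``residue atom_a atom_b value [error] [medium]``; ``#``
    starts a comment; blank lines are skipped.  A missing error column
    defaults to 1.0 Hz.
    """
    records: list[RdcRecord] = []
    for lineno, cols in _data_rows(path):
        if len(cols) < 4:
            raise TableParseError(
                f"{path}: line {lineno}: expected >= 4 columns, got {len(cols)}")
        try:
            resi = int(cols[0])
            value = float(cols[3])
            error = float(cols[4]) if len(cols) > 4 else 1.0
        except ValueError as exc:
            raise TableParseError(
                f"{path}: line {lineno}: non-numeric field ({exc})") from exc
        medium = cols[5] if len(cols) > 5 else ""
        records.append(RdcRecord(resi, cols[1], cols[2], value, error, medium))
    return records


def write_rdc_table(records: Iterable[RdcRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue atom_a atom_b value_hz error_hz medium\n")
        for r in records:
            fh.write(f"{r.residue_index}\t{r.atom_a}\t{r.atom_b}\t"
                     f"{r.value:.4f}\t{r.error:.4f}\t{r.medium or '-'}\n")


def read_noe_table(path) -> list[NoeRestraint]:
    """Read a whitespace-delimited NOE bound table.

    Columns: ``residue_i atom_i residue_j atom_j upper [lower]``.
    """
    restraints: list[NoeRestraint] = []
    for lineno, cols in _data_rows(path):
        if len(cols) < 5:
            raise TableParseError(
                f"{path}: line {lineno}: expected >= 5 columns, got {len(cols)}")
        try:
            ri, rj = int(cols[0]), int(cols[2])
            upper = float(cols[4])
            lower = float(cols[5]) if len(cols) > 5 else 0.0
        except ValueError as exc:
            raise TableParseError(
                f"{path}: line {lineno}: non-numeric field ({exc})") from exc
        restraints.append(NoeRestraint(ri, cols[1], rj, cols[3], upper, lower))
    return restraints


def write_noe_table(restraints: Iterable[NoeRestraint], path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_i atom_i residue_j atom_j upper_A lower_A\n")
        for r in restraints:
            fh.write(f"{r.residue_i}\t{r.atom_i}\t{r.residue_j}\t{r.atom_j}\t"
                     f"{r.upper_bound:.3f}\t{r.lower_bound:.3f}\n")


def read_saxs_profile(path) -> SaxsProfile:
    """Read a 2/3-column SAXS ``.dat`` file (s, I, [sigma]).

    Non-numeric header lines are tolerated and skipped; after the first
    numeric row every remaining row must parse.
    """
    s, i_vals, sig = [], [], []
    started = False
    ncols = None
    for lineno, cols in _data_rows(path):
        try:
            vals = [float(c) for c in cols]
        except ValueError:
            if started:
                raise TableParseError(
                    f"{path}: line {lineno}: non-numeric row inside data block")
            continue  # header line
        if len(vals) < 2:
            raise TableParseError(
                f"{path}: line {lineno}: expected >= 2 columns")
        started = True
        if ncols is None:
            ncols = min(len(vals), 3)
        s.append(vals[0])
        i_vals.append(vals[1])
        if ncols >= 3 and len(vals) >= 3:
            sig.append(vals[2])
    if not started:
        raise TableParseError(f"{path}: no data rows found")
    sigma = np.asarray(sig) if len(sig) == len(s) else None
    try:
        return SaxsProfile(np.asarray(s), np.asarray(i_vals), sigma)
    except ValueError as exc:
        raise TableParseError(f"{path}: {exc}") from exc


def write_saxs_profile(profile: SaxsProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# s_invA intensity sigma\n")
        for k in range(len(profile)):
            sig = profile.sigma[k] if profile.sigma is not None else ""
            fh.write(f"{profile.s[k]:.6f}\t{profile.intensity[k]:.8e}"
                     + (f"\t{sig:.8e}" if sig != "" else "") + "\n")
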