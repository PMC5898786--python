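"""Structure and ensemble I/O.

Reads and writes multi-model PDB files behind a minimal ``Ensemble``
container (topology + ``n_frames x n_atoms x 3`` coordinates in Å) and
provides the atom-selection primitives the rest of the pipeline relies on
(protein heavy atoms, backbone atoms, water oxygens, residue ranges).

Parsing and serialization are delegated to :mod:`biotite`; a thin
pre-validation pass adds line-numbered error messages and rejects
insertion codes, which the supported entries do not use.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Topology",
    "Ensemble",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "select",
]

WATER_RESIDUE_NAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})


class PDBFormatError(ValueError):
    """Raised for malformed or unsupported PDB content."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, with the derived flags used in selections."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOM_NAMES

    @property
    def is_water_oxygen(self) -> bool:
        return self.residue_name in WATER_RESIDUE_NAMES and self.element == "O"


class Topology:
    """Ordered atom table plus the residue list derived from it.

    Residue identity is the pair ``(chain, residue_seq)`` in author
    numbering; insertion codes are not supported.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        # vectorized columns for fast selection
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element for a in self.atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.residue_seqs = np.array([a.residue_seq for a in self.atoms], dtype=int)
        self.chains = np.array([a.chain for a in self.atoms], dtype=object)
        self.is_heavy = self.elements != "H"
        self.is_water = np.array(
            [a.is_water_oxygen for a in self.atoms], dtype=bool
        )
        self.residues: list[tuple[str, int, str]] = []
        self._residue_of_atom = np.empty(len(self.atoms), dtype=int)
        seen: dict[tuple[str, int], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.residue_seq)
            if key not in seen:
                seen[key] = len(self.residues)
                self.residues.append((a.chain, a.residue_seq, a.residue_name))
            self._residue_of_atom[i] = seen[key]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_index_of_atom(self, atom_index: int) -> int:
        return int(self._residue_of_atom[atom_index])

    @property
    def atom_residue_indices(self) -> np.ndarray:
        """Per-atom index into :attr:`residues`."""
        return self._residue_of_atom

    def atoms_of_residue(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self._residue_of_atom == residue_index)


class Ensemble:
    """A topology plus per-frame coordinates in Å.

    ``frame_interval`` (ps between consecutive frames) is optional and only
    required by the kinetics stage.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        frame_interval: float | None = None,
    ):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coordinates.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coordinates.shape[1]} does not match "
                f"topology ({topology.n_atoms})"
            )
        if coordinates.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(coordinates)):
            raise ValueError("coordinates contain non-finite values")
        self.topology = topology
        self.coordinates = coordinates
        self.frame_interval = frame_interval

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, index: int) -> "Ensemble":
        """Single-frame view as a new Ensemble."""
        return Ensemble(self.topology, self.coordinates[index : index + 1])

    def subset_frames(self, indices: Iterable[int]) -> "Ensemble":
        idx = np.asarray(list(indices), dtype=int)
        return Ensemble(self.topology, self.coordinates[idx], self.frame_interval)


def _validate_pdb_text(path: Path) -> None:
    """Line-level sanity pass so errors carry line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"{path}: malformed {record} line {lineno}: too short"
                )
            try:
                int(line[22:26])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path}: malformed {record} line {lineno}: {exc}"
                ) from None
            icode = line[26].strip()
            if icode:
                raise PDBFormatError(
                    f"{path}: line {lineno}: insertion code {icode!r} not supported"
                )


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    return stripped[0]


def read_pdb(
    path: str | Path,
    model_policy: Literal["all_models", "first_model"] = "all_models",
) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    Each MODEL record becomes one frame; files without MODEL records yield a
    single frame. Atom order must be identical across models. Alternate
    locations other than ``' '``/``'A'`` are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    pdb = PDBFile.read(path)
    try:
        if model_policy == "first_model":
            arr = pdb.get_structure(model=1, altloc="first")
            stack = struc.stack([arr])
        elif model_policy == "all_models":
            stack = pdb.get_structure(altloc="first")
            if isinstance(stack, struc.AtomArray):
                stack = struc.stack([stack])
        else:
            raise ValueError(f"unknown model_policy: {model_policy!r}")
    except Exception as exc:
        if isinstance(exc, ValueError) and "model_policy" in str(exc):
            raise
        raise PDBFormatError(
            f"{path}: inconsistent models (differing atom counts or order): {exc}"
        ) from exc

    elements = stack.element
    atoms = []
    for i in range(stack.array_length()):
        elem = elements[i].strip().capitalize() if elements[i].strip() else ""
        if not elem:
            elem = _element_from_name(stack.atom_name[i])
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=stack.atom_name[i],
                element=elem,
                residue_name=stack.res_name[i],
                residue_seq=int(stack.res_id[i]),
                chain=stack.chain_id[i],
            )
        )
    return Ensemble(Topology(atoms), np.asarray(stack.coord, dtype=float))


def write_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an ensemble with zero frames")
    top = ensemble.topology
    n = top.n_atoms
    arrays = []
    for f in range(ensemble.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = ensemble.coordinates[f]
        arr.atom_name = top.names.astype("U6")
        arr.res_name = top.residue_names.astype("U5")
        arr.res_id = top.residue_seqs
        arr.chain_id = top.chains.astype("U4")
        arr.element = np.array([e.upper() for e in top.elements], dtype="U2")
        arr.hetero = np.array(
            [rn in WATER_RESIDUE_NAMES for rn in top.residue_names], dtype=bool
        )
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def select(topology: Topology, selector) -> list[int]:
    """Atom indices for a named selection, in topology order.

    ``selector`` is ``"heavy"``, ``"backbone"``, ``"water_oxygen"``,
    ``"hydrogen"``, or ``("residue_range", chain, first, last)`` with an
    inclusive author-numbering range.
    """
    if isinstance(selector, str):
        if selector == "heavy":
            mask = topology.is_heavy & ~np.isin(
                topology.residue_names.astype(str), list(WATER_RESIDUE_NAMES)
            )
        elif selector == "backbone":
            mask = np.isin(topology.names.astype(str), list(BACKBONE_ATOM_NAMES)) & ~np.isin(
                topology.residue_names.astype(str), list(WATER_RESIDUE_NAMES)
            )
        elif selector == "water_oxygen":
            mask = topology.is_water
        elif selector == "hydrogen":
            mask = ~topology.is_heavy
        else:
            raise ValueError(f"unknown selector: {selector!r}")
        return list(np.flatnonzero(mask))
    try:
        kind, chain, first, last = selector
    except Exception:
        raise ValueError(f"unknown selector: {selector!r}") from None
    if kind != "residue_range":
        raise ValueError(f"unknown selector: {selector!r}")
    mask = (
        (topology.chains.astype(str) == chain)
        & (topology.residue_seqs >= first)
        & (topology.residue_seqs <= last)
    )
    return list(np.flatnonzero(mask))
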