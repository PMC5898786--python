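"""Molecular features of conformational states.

Per-state characterization used throughout the pipeline:

* **Interhelical angles** — each helix is summarized by the principal
  eigenvector of its heavy backbone atoms (N, CA, C, O), oriented in
  sequence direction; the angle between helices u and v follows from
  u·v = |u||v| cos α. Default helix boundaries are the canonical
  calmodulin definitions (helices A–H; holo ensembles truncate helix A
  to 13–18).
* **Secondary structure** — per-residue helix/strand/coil frequencies
  over frames. The default assigner is a simplified Kabsch–Sander
  implementation (hydrogen-bond energy
  E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, bond when
  E < −0.5; 8 classes reduced to helix = {H,G,I}, strand = {E,B},
  coil = rest). An MDTraj-backed DSSP assigner can be plugged in.
* **Solvent exposure** — per-residue count of water oxygens within
  4.5 Å of any heavy atom of the residue, averaged over frames;
  relative exposure divides each state's profile by the across-state
  mean, giving the s_j^(i) weights of the conformational-selection
  matching score.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import BACKBONE_ATOM_NAMES, Ensemble, Topology

__all__ = [
    "HelixDefinition",
    "DEFAULT_CAM_HELICES",
    "cam_helices",
    "helix_vector",
    "interhelical_angles",
    "kabsch_sander_assign",
    "mdtraj_dssp_assign",
    "secondary_structure_frequency",
    "ss_frequency_difference",
    "solvent_exposure",
    "relative_exposure",
]


@dataclasses.dataclass(frozen=True)
class HelixDefinition:
    """Inclusive author-numbered residue range forming one helix."""

    id: str
    chain: str
    first_residue: int
    last_residue: int

    def __post_init__(self):
        if self.last_residue - self.first_residue < 2:
            raise ValueError(f"helix {self.id}: needs at least 3 residues")


#: Canonical calmodulin helix boundaries (Kuboniwa-style definitions).
#: Helix A shortens to 13-18 in the calcium-loaded (holo) protein.
DEFAULT_CAM_HELICES: tuple[HelixDefinition, ...] = (
    HelixDefinition("A", "A", 6, 18),
    HelixDefinition("B", "A", 29, 38),
    HelixDefinition("C", "A", 45, 54),
    HelixDefinition("D", "A", 65, 74),
    HelixDefinition("E", "A", 83, 91),
    HelixDefinition("F", "A", 102, 111),
    HelixDefinition("G", "A", 118, 127),
    HelixDefinition("H", "A", 139, 145),
)


def cam_helices(holo: bool = False, chain: str = "A") -> tuple[HelixDefinition, ...]:
    """Calmodulin helix table; ``holo=True`` applies the 13-18 helix-A range."""
    helices = [dataclasses.replace(h, chain=chain) for h in DEFAULT_CAM_HELICES]
    if holo:
        helices[0] = HelixDefinition("A", chain, 13, 18)
    return tuple(helices)


# ---------------------------------------------------------------------------
# interhelical angles


def _helix_backbone_indices(topology: Topology, helix: HelixDefinition) -> np.ndarray:
    names = topology.names.astype(str)
    mask = (
        (topology.chains.astype(str) == helix.chain)
        & (topology.residue_seqs >= helix.first_residue)
        & (topology.residue_seqs <= helix.last_residue)
        & np.isin(names, list(BACKBONE_ATOM_NAMES))
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"helix {helix.id}: no backbone atoms in range")
    return idx


def helix_vector(
    frame_coordinates: np.ndarray, helix: HelixDefinition, topology: Topology
) -> np.ndarray:
    """Unit helix-axis vector: principal eigenvector of the heavy backbone
    atoms, oriented along the sequence direction (first CA → last CA)."""
    idx = _helix_backbone_indices(topology, helix)
    pts = frame_coordinates[idx]
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] - evals[-2] < 1e-12:
        raise ValueError(
            f"helix {helix.id}: degenerate point cloud, axis undefined"
        )
    axis = evecs[:, -1]
    names = topology.names.astype(str)[idx]
    seqs = topology.residue_seqs[idx]
    ca = idx[names == "CA"]
    if ca.size < 2:
        raise ValueError(f"helix {helix.id}: fewer than 2 CA atoms")
    first_ca = ca[np.argmin(seqs[names == "CA"])]
    last_ca = ca[np.argmax(seqs[names == "CA"])]
    direction = frame_coordinates[last_ca] - frame_coordinates[first_ca]
    if axis @ direction < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _helix_pairs(helices: Sequence[HelixDefinition], pairs: str):
    n = len(helices)
    if pairs == "all":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    if pairs == "within_lobe":
        half = n // 2
        first = [(i, j) for i in range(half) for j in range(i + 1, half)]
        second = [(i, j) for i in range(half, n) for j in range(i + 1, n)]
        return first + second
    raise ValueError(f"unknown pair mode: {pairs!r}")


def interhelical_angles(
    ensemble: Ensemble,
    helices: Sequence[HelixDefinition],
    pairs: str = "within_lobe",
    frames: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tidy table of interhelical angles (degrees, in [0, 180]) per frame.

    ``within_lobe`` pairs the helices of the first half of the table among
    themselves and likewise the second half (A–D and E–H for calmodulin).
    """
    if len(helices) < 2:
        raise ValueError("need at least 2 helices")
    pair_idx = _helix_pairs(helices, pairs)
    frame_list = range(ensemble.n_frames) if frames is None else frames
    rows = []
    for f in frame_list:
        coords = ensemble.coordinates[f]
        vecs = [helix_vector(coords, h, ensemble.topology) for h in helices]
        for i, j in pair_idx:
            cosang = float(np.clip(vecs[i] @ vecs[j], -1.0, 1.0))
            rows.append(
                {
                    "frame": f,
                    "pair": f"{helices[i].id}-{helices[j].id}",
                    "angle_deg": float(np.degrees(np.arccos(cosang))),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# secondary structure


_KS_COUPLING = 0.084 * 332.0  # kcal/mol·Å, partial-charge H-bond model
_KS_CUTOFF = -0.5  # kcal/mol
_PEPTIDE_BOND_BREAK = 2.5  # Å; larger C–N separation starts a new segment


def _protein_backbone_table(topology: Topology):
    """Per protein residue: indices of N, CA, C, O atoms (or -1)."""
    names = topology.names.astype(str)
    res_of = topology.atom_residue_indices
    water = topology.is_water
    residues = sorted({res_of[i] for i in range(topology.n_atoms) if not water[i]})
    table = np.full((len(residues), 4), -1, dtype=int)
    order = {"N": 0, "CA": 1, "C": 2, "O": 3}
    for row, r in enumerate(residues):
        for a in topology.atoms_of_residue(r):
            pos = order.get(names[a])
            if pos is not None and table[row, pos] == -1:
                table[row, pos] = a
    return residues, table


def kabsch_sander_assign(ensemble: Ensemble, frame: int) -> np.ndarray:
    """3-class secondary structure for one frame: 'H', 'E' or 'C' per residue.

    Simplified Kabsch–Sander: amide hydrogens are constructed from the
    preceding carbonyl (H = N + unit(C_prev − O_prev)); n-turns
    (n = 3, 4, 5) define G/H/I helices from two consecutive turns;
    parallel/antiparallel bridge patterns define strand (E and isolated
    bridges B both map to strand). Residues with missing backbone atoms
    are assigned coil with a warning.
    """
    top = ensemble.topology
    residues, table = _protein_backbone_table(top)
    n = len(residues)
    coords = ensemble.coordinates[frame]
    missing = np.any(table < 0, axis=1)
    if np.any(missing):
        warnings.warn(
            f"{int(missing.sum())} residue(s) missing backbone atoms; assigned coil",
            stacklevel=2,
        )

    # segment starts at chain breaks (C(i-1)–N(i) too far or different chain)
    new_segment = np.ones(n, dtype=bool)
    chains = [top.residues[r][0] for r in residues]
    for i in range(1, n):
        if missing[i] or missing[i - 1] or chains[i] != chains[i - 1]:
            continue
        c_prev = coords[table[i - 1, 2]]
        n_cur = coords[table[i, 0]]
        if np.linalg.norm(c_prev - n_cur) <= _PEPTIDE_BOND_BREAK:
            new_segment[i] = False

    # virtual amide hydrogens
    h_pos = np.full((n, 3), np.nan)
    for i in range(n):
        if missing[i] or new_segment[i]:
            continue
        c_prev = coords[table[i - 1, 2]]
        o_prev = coords[table[i - 1, 3]]
        d = c_prev - o_prev
        h_pos[i] = coords[table[i, 0]] + d / np.linalg.norm(d)

    def hbond(acceptor: int, donor: int) -> bool:
        """CO of `acceptor` accepts the NH of `donor`."""
        if acceptor < 0 or donor < 0 or acceptor >= n or donor >= n:
            return False
        if missing[acceptor] or missing[donor] or np.any(np.isnan(h_pos[donor])):
            return False
        if abs(acceptor - donor) < 2:
            return False
        c = coords[table[acceptor, 2]]
        o = coords[table[acceptor, 3]]
        nn = coords[table[donor, 0]]
        h = h_pos[donor]
        r_on = np.linalg.norm(o - nn)
        r_ch = np.linalg.norm(c - h)
        r_oh = np.linalg.norm(o - h)
        r_cn = np.linalg.norm(c - nn)
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return True  # clashing geometry: treat as bonded per KS convention
        e = _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        return e < _KS_CUTOFF

    turn = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n - m):
            turn[m][i] = hbond(i, i + m)

    ss = np.array(["C"] * n, dtype="U1")
    for m, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, n - m):
            if turn[m][i - 1] and turn[m][i]:
                block = slice(i, i + m)
                free = ss[block] == "C"
                if code == "H" or np.all(free):
                    ss[block][free] = code
                    ss[block] = np.where(ss[block] == "C", code, ss[block])

    # bridges → strand
    for i in range(1, n - 1):
        if ss[i] == "H":
            continue
        for j in range(i + 3, n - 1):
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if para or anti:
                if ss[i] == "C":
                    ss[i] = "E"
                if ss[j] == "C":
                    ss[j] = "E"
    # reduce 8-class codes: helix = {H, G, I}, strand = {E, B}, coil = rest
    ss[np.isin(ss, ("G", "I"))] = "H"
    return ss


def mdtraj_dssp_assign(ensemble: Ensemble, frame: int) -> np.ndarray:
    """DSSP via MDTraj (simplified 3-class), pluggable alternative assigner."""
    import mdtraj as md

    top = ensemble.topology
    residues, table = _protein_backbone_table(top)
    mtop = md.Topology()
    ch = mtop.add_chain()
    keep = []
    for row, r in enumerate(residues):
        chain, seq, rname = top.residues[r]
        res = mtop.add_residue(rname if len(rname) == 3 else "ALA", ch, resSeq=seq)
        for col, (aname, elem) in enumerate(
            (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
        ):
            if table[row, col] >= 0:
                mtop.add_atom(aname, md.element.get_by_symbol(elem), res)
                keep.append(table[row, col])
    xyz = ensemble.coordinates[frame][keep][None, :, :] / 10.0  # Å → nm
    traj = md.Trajectory(xyz, mtop)
    codes = md.compute_dssp(traj, simplified=True)[0]
    return np.array([c if c in ("H", "E") else "C" for c in codes], dtype="U1")


def secondary_structure_frequency(
    ensemble: Ensemble,
    frames: Sequence[int] | None = None,
    assigner: Callable[[Ensemble, int], np.ndarray] = kabsch_sander_assign,
) -> pd.DataFrame:
    """Per-residue helix/strand/coil frequencies over the selected frames."""
    residues, _ = _protein_backbone_table(ensemble.topology)
    frame_list = list(range(ensemble.n_frames)) if frames is None else list(frames)
    counts = np.zeros((len(residues), 3))
    classes = {"H": 0, "E": 1, "C": 2}
    for f in frame_list:
        ss = assigner(ensemble, f)
        for i, code in enumerate(ss):
            counts[i, classes[code]] += 1
    freqs = counts / len(frame_list)
    keys = [ensemble.topology.residues[r] for r in residues]
    return pd.DataFrame(
        freqs,
        columns=["helix", "strand", "coil"],
        index=pd.MultiIndex.from_tuples(
            [(c, s) for c, s, _ in keys], names=["chain", "residue"]
        ),
    )


def ss_frequency_difference(
    target: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-residue, per-class frequency difference target − reference."""
    if not target.index.equals(reference.index):
        raise ValueError("secondary-structure tables cover different residues")
    return target - reference


# ---------------------------------------------------------------------------
# solvent exposure


def solvent_exposure(
    ensemble: Ensemble,
    cutoff: float = 4.5,
    frames: Sequence[int] | None = None,
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Mean per-residue water-oxygen contact counts.

    A water oxygen is in contact with a residue when it lies strictly
    within ``cutoff`` of at least one heavy atom of that residue; each
    water counts once per residue per frame. Returns one row per state
    (or a single row ``"all"``), one column per protein residue.
    """
    top = ensemble.topology
    water_idx = np.flatnonzero(top.is_water)
    if water_idx.size == 0:
        raise ValueError(
            "ensemble contains no water oxygens; generate a water shell or "
            "supply a solvated ensemble"
        )
    res_of = top.atom_residue_indices
    protein_res = sorted(
        {
            res_of[i]
            for i in range(top.n_atoms)
            if top.is_heavy[i] and not top.is_water[i]
        }
    )
    res_atoms = [
        top.atoms_of_residue(r)[top.is_heavy[top.atoms_of_residue(r)]]
        for r in protein_res
    ]
    frame_list = (
        np.arange(ensemble.n_frames) if frames is None else np.asarray(list(frames))
    )
    counts = np.zeros((frame_list.size, len(protein_res)))
    for fi, f in enumerate(frame_list):
        coords = ensemble.coordinates[f]
        tree = cKDTree(coords[water_idx])
        for ri, atoms in enumerate(res_atoms):
            hits = tree.query_ball_point(coords[atoms], r=cutoff)
            distinct = set()
            for ai, h in zip(atoms, hits):
                for w in h:
                    # strict inequality at the cutoff
                    if np.linalg.norm(coords[water_idx[w]] - coords[ai]) < cutoff:
                        distinct.add(w)
            counts[fi, ri] = len(distinct)
    columns = [top.residues[r][1] for r in protein_res]
    if labels is None:
        return pd.DataFrame(
            counts.mean(axis=0)[None, :], index=["all"], columns=columns
        )
    labels = np.asarray(list(labels))
    if labels.size != frame_list.size:
        raise ValueError("labels length must match the number of selected frames")
    states = np.unique(labels)
    profile = np.vstack([counts[labels == s].mean(axis=0) for s in states])
    return pd.DataFrame(profile, index=states, columns=columns)


def relative_exposure(profiles: pd.DataFrame) -> pd.DataFrame:
    """State-relative exposure s_j^(i): each residue's per-state exposure
    divided by its mean over states; residues unexposed in every state get 0."""
    if profiles.shape[0] < 2:
        raise ValueError("relative exposure needs at least 2 states")
    mean = profiles.mean(axis=0)
    zero = mean == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} residue(s) have zero exposure in every state; "
            "their relative exposure is set to 0",
            stacklevel=2,
        )
    safe = mean.replace(0.0, np.nan)
    s = profiles.divide(safe, axis=1).fillna(0.0)
    return s
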