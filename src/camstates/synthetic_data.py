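"""Synthetic CaM-like ensembles with known ground truth.

Every downstream stage of the pipeline (domain decomposition, state
clustering, angle/exposure features, kinetics, binding classification) is
exercised against data generated here, where the planted truth is exact:

* a two-lobe, eight-helix protein — two bundles of idealized α-helices
  (poly-alanine backbone N, CA, C, O plus a pseudo-CB side-chain atom)
  joined by an extended flexible linker;
* discrete conformational states that differ in planted interhelical
  angles, realized by rigidly rotating whole helices, so the angle ground
  truth is exact by construction;
* independent per-frame lobe orientations (the two lobes are internally
  rigid but mobile relative to each other), giving the quasi-rigid
  contrast the domain decomposition relies on;
* an oxygen-only water shell on a jittered grid with per-residue (and
  optionally per-state) burial factors, driving solvent-exposure
  differences between states;
* toy protein–peptide complexes whose CaM-side contact residue sets are
  planted exactly.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .state_features import HelixDefinition
from .structure_io import AtomRecord, Ensemble, Topology

__all__ = [
    "SyntheticConfig",
    "WaterShellConfig",
    "GroundTruth",
    "GenerationError",
    "generate_ensemble",
    "generate_water_shell",
    "generate_complex",
    "generate_label_sequence",
    "feasible_contact_residues",
    "default_state_plan",
]


class GenerationError(RuntimeError):
    """Raised when a geometric construction cannot satisfy its constraints."""


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class WaterShellConfig:
    """Shell of water oxygens around the protein.

    Waters live on a jittered grid at ``spacing`` Å, kept only when their
    distance to the nearest protein heavy atom falls in
    ``[min_dist, max_dist]``. ``burial_mask`` gives each residue a survival
    probability for waters whose nearest residue it is: 1 keeps the full
    shell (exposed), 0 strips it (buried). It may be a single per-residue
    vector or a mapping ``state index -> vector`` for state-dependent
    burial.
    """

    min_dist: float = 2.6
    max_dist: float = 6.0
    spacing: float = 2.8
    burial_mask: object | None = None

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("water grid spacing must be positive")
        if self.min_dist >= self.max_dist:
            raise ValueError("water shell needs min_dist < max_dist")


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-lobe protein.

    ``planted_states`` maps helix pairs (single-letter ids) to target
    interhelical angles in degrees, one mapping per state. Frame states
    are drawn i.i.d. from ``state_weights`` unless a row-stochastic
    ``transition_matrix`` is supplied, in which case a Markov chain is
    realized. ``lobe_wobble_deg`` sets the scale of the independent
    per-frame rigid reorientation of each lobe (0 freezes the lobes).
    """

    n_helices_per_lobe: int = 4
    helix_length: int = 10
    linker_length: int = 8
    planted_states: Sequence[Mapping[tuple[str, str], float]] = dataclasses.field(
        default_factory=lambda: default_state_plan(4)
    )
    state_weights: Sequence[float] | None = None
    transition_matrix: np.ndarray | None = None
    coord_noise_sd: float = 0.15
    n_frames: int = 300
    lobe_wobble_deg: float = 90.0
    water_shell: WaterShellConfig = dataclasses.field(default_factory=WaterShellConfig)
    seed: int = 0
    sequence: Sequence[str] | None = None  # 3-letter residue names, optional

    def __post_init__(self):
        for state in self.planted_states:
            for pair, angle in state.items():
                if not 0.0 <= angle <= 180.0:
                    raise ValueError(
                        f"target angle {angle} for pair {pair} outside [0, 180]"
                    )
        if self.state_weights is not None:
            w = np.asarray(self.state_weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("state_weights must sum to 1")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("transition_matrix rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.planted_states)

    @property
    def n_residues(self) -> int:
        return 2 * self.n_helices_per_lobe * self.helix_length + self.linker_length


def default_state_plan(n_states: int) -> list[dict[tuple[str, str], float]]:
    """Planted states separated by 25° steps of two helix-pair angles per lobe.

    Adjacent states differ by 25° in (A,B) and (C,D) within lobe 1 and in
    (E,F) and (G,H) within lobe 2, mimicking the concerted helix
    re-packing that distinguishes open and closed lobe conformations.
    """
    states = []
    for s in range(n_states):
        states.append(
            {
                ("A", "B"): 40.0 + 25.0 * s,
                ("C", "D"): 140.0 - 25.0 * s,
                ("E", "F"): 150.0 - 25.0 * s,
                ("G", "H"): 45.0 + 25.0 * s,
            }
        )
    return states


# ---------------------------------------------------------------------------
# ideal backbone geometry (NeRF internal-coordinate chain building)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.530
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8
_ANG_N_CA_CB = 110.4


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Next atom position from three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    phi_psi: Sequence[tuple[float, float]], with_cb: bool = True
) -> np.ndarray:
    """Poly-alanine-like backbone from per-residue (φ, ψ) in degrees.

    Returns coordinates of shape ``(n_residues, n_atoms_per_residue, 3)``
    with atoms ordered N, CA, C, O (, CB). ω is fixed at 180°.
    """
    n_res = len(phi_psi)
    per = 5 if with_cb else 4
    coords = np.zeros((n_res, per, 3))
    # seed first three backbone atoms in a plane
    coords[0, 0] = np.array([0.0, 0.0, 0.0])  # N
    coords[0, 1] = np.array([_BOND_N_CA, 0.0, 0.0])  # CA
    ang = math.radians(180.0 - _ANG_N_CA_C)
    coords[0, 2] = coords[0, 1] + _BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            prev_n, prev_ca, prev_c = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
            coords[i, 0] = _place_atom(
                prev_n, prev_ca, prev_c, _BOND_C_N, _ANG_CA_C_N, phi_psi[i - 1][1]
            )
            coords[i, 1] = _place_atom(
                prev_ca, prev_c, coords[i, 0], _BOND_N_CA, _ANG_C_N_CA, 180.0
            )
            coords[i, 2] = _place_atom(
                prev_c, coords[i, 0], coords[i, 1], _BOND_CA_C, _ANG_N_CA_C, phi
            )
        # carbonyl oxygen anti to the next amide nitrogen
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], _BOND_C_O, _ANG_CA_C_O, psi + 180.0
        )
        if with_cb:
            coords[i, 4] = _place_atom(
                coords[i, 2], coords[i, 0], coords[i, 1], _BOND_CA_CB, _ANG_N_CA_CB, 122.6
            )
    return coords


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / points.shape[0]
    _, evecs = np.linalg.eigh(cov)
    return evecs[:, -1]


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any axis perpendicular to u
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, math.pi)
    axis /= s
    return _axis_angle(axis, math.atan2(s, c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    t = 1.0 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def _helix_template(helix_length: int) -> np.ndarray:
    """Ideal α-helix (φ=−57°, ψ=−47°), centered, principal axis exactly +z.

    The pre-rotation makes the backbone-heavy-atom principal eigenvector
    coincide with +z, so a rigid rotation taking +z to a target direction
    plants that direction as the *measured* helix axis exactly.
    """
    coords = build_backbone([(-57.0, -47.0)] * helix_length)
    flat = coords.reshape(-1, 3)
    backbone = coords[:, :4].reshape(-1, 3)
    axis = _principal_axis(backbone)
    seq_dir = coords[-1, 1] - coords[0, 1]  # last CA − first CA
    if axis @ seq_dir < 0:
        axis = -axis
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    flat = (flat - backbone.mean(axis=0)) @ rot.T
    return flat.reshape(coords.shape)


def _linker_template(linker_length: int) -> np.ndarray:
    """Extended chain (φ=−120°, ψ=120°) centered with main axis +z."""
    coords = build_backbone([(-120.0, 120.0)] * linker_length)
    flat = coords.reshape(-1, 3)
    backbone = coords[:, :4].reshape(-1, 3)
    axis = _principal_axis(backbone)
    if axis @ (coords[-1, 1] - coords[0, 1]) < 0:
        axis = -axis
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    flat = (flat - backbone.mean(axis=0)) @ rot.T
    return flat.reshape(coords.shape)


# ---------------------------------------------------------------------------
# planted-state direction solving


def _helix_labels(n_helices: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n_helices)]


def _normalize_pairs(
    state: Mapping[tuple[str, str], float]
) -> dict[tuple[str, str], float]:
    out = {}
    for (a, b), angle in state.items():
        key = (a, b) if a < b else (b, a)
        out[key] = float(angle)
    return out


def _solve_directions(
    labels: Sequence[str],
    base_dirs: Mapping[str, np.ndarray],
    constraints: Mapping[tuple[str, str], float],
) -> dict[str, np.ndarray]:
    """Unit helix directions realizing the constrained pair angles.

    Helices are placed in label order; each may be constrained against at
    most two already-placed helices (a cone, or a cone intersection). The
    free parameter is resolved toward the base direction, keeping the
    bundle geometry recognizable.
    """
    dirs: dict[str, np.ndarray] = {}
    for label in labels:
        cons = [
            (other, ang)
            for (a, b), ang in constraints.items()
            for other in ((b,) if a == label else (a,) if b == label else ())
            if other in dirs
        ]
        base = base_dirs[label]
        if len(cons) == 0:
            dirs[label] = base.copy()
        elif len(cons) == 1:
            other, ang = cons[0]
            u = dirs[other]
            w = base - (base @ u) * u
            if np.linalg.norm(w) < 1e-9:
                w = np.array([1.0, 0.0, 0.0])
                w = w - (w @ u) * u
                if np.linalg.norm(w) < 1e-9:
                    w = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ u) * u
            w /= np.linalg.norm(w)
            theta = math.radians(ang)
            dirs[label] = math.cos(theta) * u + math.sin(theta) * w
        elif len(cons) == 2:
            (o1, a1), (o2, a2) = cons
            u1, u2 = dirs[o1], dirs[o2]
            c1, c2 = math.cos(math.radians(a1)), math.cos(math.radians(a2))
            u12 = float(u1 @ u2)
            det = 1.0 - u12 * u12
            if det < 1e-12:
                raise GenerationError(
                    f"helix {label}: reference helices {o1}, {o2} are parallel; "
                    "cone intersection is degenerate"
                )
            alpha = (c1 - c2 * u12) / det
            beta = (c2 - c1 * u12) / det
            w = np.cross(u1, u2)
            w /= np.linalg.norm(w)
            gamma_sq = 1.0 - (alpha**2 + beta**2 + 2.0 * alpha * beta * u12)
            if gamma_sq < -1e-9:
                raise GenerationError(
                    f"helix {label}: angles {a1}° to {o1} and {a2}° to {o2} "
                    "are not simultaneously realizable"
                )
            gamma = math.sqrt(max(gamma_sq, 0.0))
            if base @ w < 0:
                gamma = -gamma
            dirs[label] = alpha * u1 + beta * u2 + gamma * w
        else:
            raise GenerationError(
                f"helix {label}: over-constrained ({len(cons)} angle constraints "
                "to already-placed helices; at most 2 supported)"
            )
        dirs[label] /= np.linalg.norm(dirs[label])
    return dirs


# ---------------------------------------------------------------------------
# ground truth container


@dataclasses.dataclass
class GroundTruth:
    """Planted truth for one synthetic study."""

    frame_state: np.ndarray
    residue_domain: np.ndarray  # 0/1 per lobe; -1 = linker (unconstrained)
    helices: tuple[HelixDefinition, ...]
    state_angles: list[dict[str, float]]  # realized angle per "X-Y" pair, per state
    water_counts: np.ndarray | None = None
    complex_contacts: dict[str, list[int]] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# ensemble generation


def _random_rotation(rng: np.random.Generator, scale_deg: float) -> np.ndarray:
    if scale_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.normal(0.0, scale_deg))
    return _axis_angle(axis, angle)


def generate_ensemble(config: SyntheticConfig) -> tuple[Ensemble, GroundTruth]:
    """Two-lobe helix-bundle ensemble with planted discrete states.

    Per frame a planted state is drawn (i.i.d. from ``state_weights`` or by
    the Markov chain), each helix is rigidly rotated to realize that
    state's target interhelical angles, each lobe receives an independent
    random reorientation of scale ``lobe_wobble_deg``, the linker is laid
    between the lobes, and isotropic Gaussian noise of ``coord_noise_sd``
    is added. Identical configs and seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_per_lobe = config.n_helices_per_lobe
    n_helices = 2 * n_per_lobe
    labels = _helix_labels(n_helices)
    hl = config.helix_length

    template = _helix_template(hl)

    # bundle layout: within-lobe 2-column grid, lobes separated along +x
    grid = [(0.0, 0.0), (11.0, 0.0), (0.0, 11.0), (11.0, 11.0)]
    offsets, base_dirs = {}, {}
    for h, label in enumerate(labels):
        lobe = h // n_per_lobe
        pos = h % n_per_lobe
        gx, gy = grid[pos % 4]
        extra = 11.0 * (pos // 4)
        offsets[label] = np.array([gx + 40.0 * lobe, gy + extra, 0.0])
        base_dirs[label] = np.array([0.0, 0.0, 1.0 if pos % 2 == 0 else -1.0])

    # per-state helix directions and precomputed helix coordinates
    state_dirs = []
    state_helix_coords = []
    for state in config.planted_states:
        dirs = _solve_directions(labels, base_dirs, _normalize_pairs(state))
        state_dirs.append(dirs)
        coords = {}
        for label in labels:
            rot = _rotation_between(np.array([0.0, 0.0, 1.0]), dirs[label])
            coords[label] = template.reshape(-1, 3) @ rot.T + offsets[label]
        state_helix_coords.append(coords)

    realized = []
    for dirs in state_dirs:
        table = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                cosang = float(np.clip(dirs[a] @ dirs[b], -1.0, 1.0))
                table[f"{a}-{b}"] = math.degrees(math.acos(cosang))
        realized.append(table)

    # frame state sequence
    n_states = config.n_states
    if config.transition_matrix is not None:
        frame_state = generate_label_sequence(
            config.transition_matrix,
            config.n_frames,
            seed=int(rng.integers(2**31)),
        )
    else:
        weights = (
            np.full(n_states, 1.0 / n_states)
            if config.state_weights is None
            else np.asarray(config.state_weights, dtype=float)
        )
        frame_state = rng.choice(n_states, size=config.n_frames, p=weights)

    # topology
    atoms = []
    atom_names = ("N", "CA", "C", "O", "CB")
    elements = ("N", "C", "C", "O", "C")
    serial = 1
    n_res = config.n_residues
    for r in range(n_res):
        resname = (
            config.sequence[r]
            if config.sequence is not None
            else "ALA"
        )
        for name, elem in zip(atom_names, elements):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=elem,
                    residue_name=resname,
                    residue_seq=r + 1,
                    chain="A",
                )
            )
            serial += 1
    topology = Topology(atoms)

    # residue bookkeeping: lobe-1 helices, linker, lobe-2 helices
    lobe1_res = n_per_lobe * hl
    residue_domain = np.empty(n_res, dtype=int)
    residue_domain[:lobe1_res] = 0
    residue_domain[lobe1_res : lobe1_res + config.linker_length] = -1
    residue_domain[lobe1_res + config.linker_length :] = 1

    helices = []
    res_start = 1
    for h, label in enumerate(labels):
        if h == n_per_lobe:
            res_start += config.linker_length
        helices.append(HelixDefinition(label, "A", res_start, res_start + hl - 1))
        res_start += hl

    # static linker halves: each rigidly attached to (and wobbling with)
    # its lobe, mirroring a flexible-linker break at the midpoint
    half1_len = (config.linker_length + 1) // 2
    half2_len = config.linker_length - half1_len
    to_x = _rotation_between(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    half1_xyz = half2_xyz = None
    if half1_len > 0:
        t1 = _linker_template(half1_len).reshape(-1, 3) @ to_x.T
        half1_xyz = t1 - t1.min(axis=0) + np.array([16.0, 4.0, 0.0])
    if half2_len > 0:
        t2 = _linker_template(half2_len).reshape(-1, 3) @ to_x.T
        half2_xyz = t2 - t2.max(axis=0) + np.array([36.0, 8.0, 0.0])

    # frames
    coords_out = np.empty((config.n_frames, n_res * 5, 3))
    lobe1_atoms = slice(0, lobe1_res * 5)
    half1_atoms = slice(lobe1_res * 5, (lobe1_res + half1_len) * 5)
    half2_atoms = slice(
        (lobe1_res + half1_len) * 5, (lobe1_res + config.linker_length) * 5
    )
    lobe2_atoms = slice((lobe1_res + config.linker_length) * 5, n_res * 5)
    for f in range(config.n_frames):
        s = frame_state[f]
        helix_xyz = state_helix_coords[s]
        lobe1 = np.concatenate([helix_xyz[l] for l in labels[:n_per_lobe]])
        lobe2 = np.concatenate([helix_xyz[l] for l in labels[n_per_lobe:]])
        r1 = _random_rotation(rng, config.lobe_wobble_deg)
        r2 = _random_rotation(rng, config.lobe_wobble_deg)
        c1 = lobe1.mean(axis=0)
        c2 = lobe2.mean(axis=0)
        coords_out[f, lobe1_atoms] = (lobe1 - c1) @ r1.T + c1
        coords_out[f, lobe2_atoms] = (lobe2 - c2) @ r2.T + c2
        if half1_len > 0:
            coords_out[f, half1_atoms] = (half1_xyz - c1) @ r1.T + c1
        if half2_len > 0:
            coords_out[f, half2_atoms] = (half2_xyz - c2) @ r2.T + c2
        if config.coord_noise_sd > 0:
            coords_out[f] += rng.normal(0.0, config.coord_noise_sd, coords_out[f].shape)

    truth = GroundTruth(
        frame_state=np.asarray(frame_state, dtype=int),
        residue_domain=residue_domain,
        helices=tuple(helices),
        state_angles=realized,
    )
    return Ensemble(topology, coords_out), truth


# ---------------------------------------------------------------------------
# water shell


def _burial_for_state(mask_spec, state: int, n_res: int) -> np.ndarray:
    if mask_spec is None:
        return np.ones(n_res)
    if isinstance(mask_spec, Mapping):
        return np.asarray(mask_spec[state], dtype=float)
    return np.asarray(mask_spec, dtype=float)


def generate_water_shell(
    ensemble: Ensemble,
    config: SyntheticConfig,
    frame_state: np.ndarray | None = None,
    ground_truth: GroundTruth | None = None,
) -> Ensemble:
    """Append water oxygens on a jittered grid shell around each frame.

    Candidate waters within ``[min_dist, max_dist]`` of the nearest protein
    heavy atom survive with probability ``burial_mask[r]`` where r is
    their nearest residue (per-state masks use ``frame_state``). The
    ensemble keeps a fixed atom count: unoccupied water slots are parked
    on a far shelf (>400 Å away), outside every distance cutoff used in
    the analysis. Per-frame water counts are recorded in the ground truth
    when one is passed.
    """
    shell = config.water_shell
    rng = np.random.default_rng(config.seed + 1)
    top = ensemble.topology
    heavy = np.flatnonzero(top.is_heavy & ~top.is_water)
    res_of_heavy = top.atom_residue_indices[heavy]
    n_res = top.n_residues
    if frame_state is None:
        if isinstance(shell.burial_mask, Mapping):
            raise ValueError("per-state burial_mask requires frame_state")
        frame_state = np.zeros(ensemble.n_frames, dtype=int)

    per_frame_waters = []
    for f in range(ensemble.n_frames):
        coords = ensemble.coordinates[f][heavy]
        lo = coords.min(axis=0) - shell.max_dist
        hi = coords.max(axis=0) + shell.max_dist
        axes = [np.arange(lo[d], hi[d] + shell.spacing, shell.spacing) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        grid = grid + rng.uniform(-0.15, 0.15, grid.shape) * shell.spacing
        tree = cKDTree(coords)
        dist, nearest = tree.query(grid)
        keep = (dist >= shell.min_dist) & (dist <= shell.max_dist)
        pts = grid[keep]
        nearest_res = res_of_heavy[nearest[keep]]
        mask = _burial_for_state(shell.burial_mask, int(frame_state[f]), n_res)
        survive = rng.random(pts.shape[0]) < mask[nearest_res]
        per_frame_waters.append(pts[survive])

    n_slots = max(w.shape[0] for w in per_frame_waters)
    center = ensemble.coordinates[:, heavy].mean(axis=(0, 1))
    shelf = center + np.array([500.0, 0.0, 0.0])

    atoms = list(top.atoms)
    serial = len(atoms) + 1
    for slot in range(n_slots):
        atoms.append(
            AtomRecord(
                serial=serial,
                name="O",
                element="O",
                residue_name="HOH",
                residue_seq=slot + 1,
                chain="W",
            )
        )
        serial += 1
    new_top = Topology(atoms)

    coords_out = np.empty((ensemble.n_frames, len(atoms), 3))
    coords_out[:, : top.n_atoms] = ensemble.coordinates
    for f, waters in enumerate(per_frame_waters):
        block = coords_out[f, top.n_atoms :]
        block[: waters.shape[0]] = waters
        n_park = n_slots - waters.shape[0]
        if n_park:
            park = np.tile(shelf, (n_park, 1))
            park[:, 1] += 5.0 * np.arange(n_park)  # avoid coincident atoms
            block[waters.shape[0] :] = park
    counts = np.array([w.shape[0] for w in per_frame_waters])
    if ground_truth is not None:
        ground_truth.water_counts = counts
    return Ensemble(new_top, coords_out, frame_interval=ensemble.frame_interval)


# ---------------------------------------------------------------------------
# toy complexes

_NEAR_R, _FAR_R = 3.95, 9.0  # contact (< 4.0 Å) and released (> 6.0 Å) radii

_FIB_DIRS = None


def _sphere_directions() -> list[np.ndarray]:
    """128 deterministic quasi-uniform unit vectors (Fibonacci sphere)."""
    global _FIB_DIRS
    if _FIB_DIRS is None:
        golden = math.pi * (3.0 - math.sqrt(5.0))
        dirs = []
        for i in range(128):
            z = 1.0 - 2.0 * (i + 0.5) / 128
            rho = math.sqrt(1.0 - z * z)
            dirs.append(
                np.array([rho * math.cos(golden * i), rho * math.sin(golden * i), z])
            )
        _FIB_DIRS = dirs
    return _FIB_DIRS


def _best_placement(coords, heavy, res_of_heavy, centroid, r, rng):
    """Anchor atom and direction maximizing clearance from other residues.

    The peptide contact atom sits ``_NEAR_R`` from the anchor; the released
    position sits ``_FAR_R`` out along the same direction. The score is the
    smallest distance from either position to any atom of another residue
    (and from the released position to the residue itself); above 6 Å the
    planted contact contract is satisfiable.
    """
    own = heavy[res_of_heavy == r]
    other = heavy[res_of_heavy != r]
    other_xyz = coords[other]
    anchor = own[np.argmax(np.linalg.norm(coords[own] - centroid, axis=1))]
    a = coords[anchor]
    outward = a - centroid
    outward /= np.linalg.norm(outward)
    def clearance(d):
        near = a + _NEAR_R * d
        far = a + _FAR_R * d
        return min(
            np.min(np.linalg.norm(other_xyz - near, axis=1)),
            np.min(np.linalg.norm(other_xyz - far, axis=1)),
            np.min(np.linalg.norm(coords[own] - far, axis=1)),
        )

    candidates = (
        [outward]
        + _sphere_directions()
        + [v / np.linalg.norm(v) for v in rng.normal(size=(500, 3))]
    )
    best_dir, best_score = None, -np.inf
    for d in candidates:
        score = clearance(d)
        if score > best_score:
            best_score, best_dir = score, d
    # local hill climb: the feasible cone can be narrow
    step = 0.4
    for _ in range(120):
        trial = best_dir + step * rng.normal(size=3)
        trial /= np.linalg.norm(trial)
        score = clearance(trial)
        if score > best_score:
            best_score, best_dir = score, trial
        else:
            step = max(step * 0.97, 0.05)
    return a, best_dir, best_score


def feasible_contact_residues(
    frame: Ensemble, candidates: Sequence[int], seed: int = 0
) -> list[int]:
    """Subset of candidate residue numbers where a planted contact is
    geometrically realizable (clearance above the 6 Å release radius)."""
    if frame.n_frames != 1:
        raise ValueError("expects a single-frame ensemble")
    top = frame.topology
    coords = frame.coordinates[0]
    rng = np.random.default_rng(seed)
    heavy = np.flatnonzero(top.is_heavy & ~top.is_water)
    res_of_heavy = top.atom_residue_indices[heavy]
    centroid = coords[heavy].mean(axis=0)
    seq_to_res = {seq: r for r, (_c, seq, _n) in enumerate(top.residues)}
    out = []
    for seq in candidates:
        r = seq_to_res[seq]
        _a, _d, score = _best_placement(coords, heavy, res_of_heavy, centroid, r, rng)
        if score > 6.1:
            out.append(seq)
    return out


def generate_complex(
    frame: Ensemble,
    contact_residues: Sequence[int],
    n_models: int,
    contact_fraction: float,
    seed: int,
    peptide_names: Sequence[str] | None = None,
) -> Ensemble:
    """Toy protein–peptide complex with a planted CaM-side contact set.

    For each designated residue, one peptide heavy atom lies within 4.0 Å
    of a residue heavy atom in exactly ``ceil(contact_fraction * n_models)``
    models and beyond 6.0 Å in the rest; non-designated residues never see
    a peptide atom within 6.0 Å. The peptide chain (id ``B``) has 5-15
    residues, one CA-like heavy atom each.
    """
    if frame.n_frames != 1:
        raise ValueError("generate_complex expects a single-frame ensemble")
    top = frame.topology
    coords = frame.coordinates[0]
    rng = np.random.default_rng(seed)

    seq_to_res = {}
    for r, (chain, seq, _name) in enumerate(top.residues):
        seq_to_res[seq] = r
    try:
        contact_res_idx = [seq_to_res[s] for s in contact_residues]
    except KeyError as exc:
        raise ValueError(f"contact residue {exc} not in topology") from None
    if len(contact_res_idx) > 15:
        raise ValueError("at most 15 contact residues supported (peptide length cap)")

    heavy = np.flatnonzero(top.is_heavy & ~top.is_water)
    res_of_heavy = top.atom_residue_indices[heavy]
    centroid = coords[heavy].mean(axis=0)

    n_contact_models = math.ceil(contact_fraction * n_models)
    n_pep = min(15, max(5, len(contact_res_idx) + 2))
    pep_names = (
        list(peptide_names)
        if peptide_names is not None
        else ["GLY"] * n_pep
    )
    if len(pep_names) < n_pep:
        pep_names = (pep_names * n_pep)[:n_pep]

    # choose an anchor atom and clearance-maximizing direction per contact
    placements = []
    for r in contact_res_idx:
        a, best_dir, best_score = _best_placement(
            coords, heavy, res_of_heavy, centroid, r, rng
        )
        if best_score <= 6.0:
            raise GenerationError(
                f"cannot place a peptide atom near residue {top.residues[r]} "
                "without touching other residues; residue too buried"
            )
        placements.append((a, best_dir))

    # peptide coordinates per model
    models = np.empty((n_models, n_pep, 3))
    spare_base = centroid + np.array([0.0, 0.0, 60.0])
    for m in range(n_models):
        in_contact = m < n_contact_models
        for p in range(n_pep):
            if p < len(placements):
                a, d = placements[p]
                models[m, p] = a + (_NEAR_R if in_contact else _FAR_R) * d
            else:
                models[m, p] = spare_base + np.array([4.0 * p, 0.0, 0.0])

    # verification of the planted contract
    for m in range(n_models):
        pep = models[m]
        for j, r in enumerate(contact_res_idx):
            own_xyz = coords[heavy[res_of_heavy == r]]
            dmin = np.min(
                np.linalg.norm(own_xyz[:, None, :] - pep[None, :, :], axis=2)
            )
            if m < n_contact_models and dmin >= 4.0:
                raise GenerationError(f"model {m}: contact residue {r} not in contact")
            if m >= n_contact_models and dmin <= 6.0:
                raise GenerationError(f"model {m}: residue {r} not released")
        for r in set(res_of_heavy) - set(contact_res_idx):
            own_xyz = coords[heavy[res_of_heavy == r]]
            dmin = np.min(
                np.linalg.norm(own_xyz[:, None, :] - pep[None, :, :], axis=2)
            )
            if dmin <= 6.0:
                raise GenerationError(
                    f"model {m}: non-designated residue {top.residues[r]} within "
                    f"6 Å of the peptide ({dmin:.2f} Å)"
                )

    atoms = list(top.atoms)
    serial = len(atoms) + 1
    for p in range(n_pep):
        atoms.append(
            AtomRecord(
                serial=serial,
                name="CA",
                element="C",
                residue_name=pep_names[p],
                residue_seq=p + 1,
                chain="B",
            )
        )
        serial += 1
    new_top = Topology(atoms)
    out = np.empty((n_models, len(atoms), 3))
    out[:, : top.n_atoms] = coords[None, :, :]
    out[:, top.n_atoms :] = models
    return Ensemble(new_top, out)


# ---------------------------------------------------------------------------
# Markov label sequences


def generate_label_sequence(
    transition_matrix: np.ndarray,
    n_frames: int,
    seed: int,
    start_state: int = 0,
) -> np.ndarray:
    """Markov-chain state labels, deterministic per seed."""
    t = np.asarray(transition_matrix, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must sum to 1 (within 1e-9)")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_frames, dtype=int)
    labels[0] = start_state
    n = t.shape[0]
    # draw all uniforms up front; invert the per-row CDF
    cdf = np.cumsum(t, axis=1)
    u = rng.random(n_frames - 1)
    for i in range(1, n_frames):
        labels[i] = np.searchsorted(cdf[labels[i - 1]], u[i - 1], side="right")
        if labels[i] >= n:  # guard against rounding at the top of the CDF
            labels[i] = n - 1
    return labels
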