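"""Conformational-selection scoring against complex structures.

If binding proceeds by conformational selection, the residues a target
peptide contacts in the complex should already be solvent-exposed in the
unbound state that binds. Each complex k yields a binary contact vector
m^(k) over CaM residues (heavy atom within 4.5 Å of any target-chain atom;
for multi-model structures, in at least 70% of the models). The matching
score of state i against complex k sums the state's relative solvent
exposures over the contact residues,

    S_i(k) = Σ_j s_j^(i) · m_j^(k),

and is normalized over states into a per-complex distribution. Complexes
with similar distributions are grouped into binding-mode classes with the
same spectral engine used for state clustering; each class reports its
mean distribution ± std and the residue-type composition (apolar / polar /
charged) of its contacts. Depth labels (deep / intermediate / shallow) are
user-supplied annotations on the automatic classes, never inferred.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .state_clustering import spectral_cluster_distance_matrix
from .structure_io import Ensemble

__all__ = [
    "ContactVector",
    "MatchingDistribution",
    "BindingClassModel",
    "DEFAULT_RESIDUE_TYPES",
    "contact_vector",
    "matching_scores",
    "classify_binding_modes",
    "contact_residue_types",
]

#: Three-way residue-type table over the 20 standard amino acids.
#: GLY counts as apolar, HIS as polar; override per analysis if needed.
DEFAULT_RESIDUE_TYPES: Mapping[str, str] = {
    **{r: "apolar" for r in ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY")},
    **{r: "polar" for r in ("SER", "THR", "CYS", "TYR", "ASN", "GLN", "HIS")},
    **{r: "charged" for r in ("ASP", "GLU", "LYS", "ARG")},
}

_TYPE_ORDER = ("apolar", "polar", "charged")


@dataclasses.dataclass
class ContactVector:
    """Binary per-CaM-residue contact indicator for one complex."""

    complex_id: str
    residue_seqs: np.ndarray  # reference numbering after residue_map
    residue_names: np.ndarray
    m: np.ndarray
    contact_cutoff: float = 4.5
    ensemble_fraction: float = 0.7

    @property
    def contact_seqs(self) -> np.ndarray:
        return self.residue_seqs[self.m.astype(bool)]


@dataclasses.dataclass
class MatchingDistribution:
    """Raw and state-normalized matching scores for one complex."""

    complex_id: str
    raw: np.ndarray
    normalized: np.ndarray
    states: np.ndarray


@dataclasses.dataclass
class BindingClassModel:
    """Automatic binding-mode classes over a set of complexes."""

    complex_ids: list[str]
    labels: np.ndarray
    k: int
    eigenvalues: np.ndarray
    class_mean: np.ndarray  # (k, n_states)
    class_std: np.ndarray
    type_mean: np.ndarray | None = None  # (k, 3) apolar/polar/charged
    type_std: np.ndarray | None = None


def contact_vector(
    complex_ensemble: Ensemble,
    cam_chain: str,
    target_chain: str,
    cutoff: float = 4.5,
    fraction: float = 0.7,
    residue_map: Mapping[int, int] | None = None,
    complex_id: str = "",
) -> ContactVector:
    """Contact vector m^(k) of one complex structure.

    Per model, CaM residue j is in contact when any of its heavy atoms
    lies strictly within ``cutoff`` of any atom of the target chain; for
    multi-model input, m_j = 1 when the contact holds in at least
    ``fraction`` of the models. ``residue_map`` translates the complex's
    author numbering into the reference numbering of the exposure
    profiles.
    """
    top = complex_ensemble.topology
    chains = top.chains.astype(str)
    cam_atoms = np.flatnonzero((chains == cam_chain) & top.is_heavy & ~top.is_water)
    target_atoms = np.flatnonzero(chains == target_chain)
    if cam_atoms.size == 0:
        raise ValueError(f"chain {cam_chain!r} not found or has no heavy atoms")
    if target_atoms.size == 0:
        raise ValueError(f"target chain {target_chain!r} not found")

    res_of = top.atom_residue_indices
    cam_res = sorted(set(res_of[cam_atoms]))
    seqs = np.array([top.residues[r][1] for r in cam_res])
    names = np.array([top.residues[r][2] for r in cam_res])
    if residue_map is not None:
        unmapped = [int(s) for s in seqs if int(s) not in residue_map]
        if unmapped:
            raise ValueError(f"unmappable complex residues: {unmapped}")
        seqs = np.array([residue_map[int(s)] for s in seqs])

    n_models = complex_ensemble.n_frames
    hits = np.zeros((n_models, len(cam_res)), dtype=bool)
    for f in range(n_models):
        coords = complex_ensemble.coordinates[f]
        tcoords = coords[target_atoms]
        for ri, r in enumerate(cam_res):
            atoms = [a for a in cam_atoms if res_of[a] == r]
            d = np.linalg.norm(
                coords[atoms][:, None, :] - tcoords[None, :, :], axis=2
            )
            hits[f, ri] = bool(np.any(d < cutoff))
    m = (hits.mean(axis=0) >= fraction - 1e-12).astype(int)
    return ContactVector(
        complex_id=complex_id or "complex",
        residue_seqs=seqs,
        residue_names=names,
        m=m,
        contact_cutoff=cutoff,
        ensemble_fraction=fraction,
    )


def matching_scores(
    relative_exposure: pd.DataFrame, contacts: ContactVector
) -> MatchingDistribution:
    """Matching score S_i(k) = Σ_j s_j^(i) m_j^(k), normalized over states.

    ``relative_exposure`` has one row per state and one column per
    reference residue number.
    """
    s = relative_exposure
    contact_seqs = contacts.contact_seqs
    missing = [int(q) for q in contact_seqs if q not in s.columns]
    if missing:
        raise ValueError(
            f"contact residues absent from the exposure profile: {missing}"
        )
    raw = s[list(contact_seqs)].sum(axis=1).to_numpy(dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            f"complex {contacts.complex_id}: no exposed contact residues "
            "(all matching scores are zero)"
        )
    return MatchingDistribution(
        complex_id=contacts.complex_id,
        raw=raw,
        normalized=raw / total,
        states=np.asarray(s.index),
    )


def classify_binding_modes(
    distributions: Sequence[MatchingDistribution],
    k: int | None = None,
    seed: int = 0,
    k_range: tuple[int, int] = (2, 6),
    type_fractions: Sequence[np.ndarray] | None = None,
) -> BindingClassModel:
    """Cluster per-complex score distributions into binding-mode classes.

    The pairwise distance is the Euclidean norm between normalized
    distributions; the spectral engine (Gaussian kernel with the
    average-nearest-neighbour σ, normalized spectrum, eigengap when
    ``k`` is None, spherical k-means) does the grouping. Identical
    distributions collapse to a single class.
    """
    if len(distributions) < 2:
        raise ValueError("need at least 2 complexes to classify")
    n_states = distributions[0].normalized.size
    for d in distributions:
        if d.normalized.size != n_states:
            raise ValueError("distributions have differing state counts")
    if k is not None and k > len(distributions):
        raise ValueError(f"k={k} exceeds the number of complexes")
    x = np.vstack([d.normalized for d in distributions])
    diff = x[:, None, :] - x[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    model = spectral_cluster_distance_matrix(dist, k=k, seed=seed, k_range=k_range)
    labels = model.labels
    kk = model.k
    class_mean = np.vstack([x[labels == c].mean(axis=0) for c in range(kk)])
    class_std = np.vstack([x[labels == c].std(axis=0) for c in range(kk)])
    type_mean = type_std = None
    if type_fractions is not None:
        tf = np.vstack(type_fractions)
        type_mean = np.vstack([tf[labels == c].mean(axis=0) for c in range(kk)])
        type_std = np.vstack([tf[labels == c].std(axis=0) for c in range(kk)])
    return BindingClassModel(
        complex_ids=[d.complex_id for d in distributions],
        labels=labels,
        k=kk,
        eigenvalues=model.eigenvalues,
        class_mean=class_mean,
        class_std=class_std,
        type_mean=type_mean,
        type_std=type_std,
    )


def contact_residue_types(
    contacts: ContactVector,
    types: Mapping[str, str] = DEFAULT_RESIDUE_TYPES,
) -> np.ndarray:
    """Fractions of (apolar, polar, charged) among the contact residues."""
    names = contacts.residue_names[contacts.m.astype(bool)]
    if names.size == 0:
        raise ValueError(
            f"complex {contacts.complex_id}: empty contact vector, "
            "no residue types to count"
        )
    counts = dict.fromkeys(_TYPE_ORDER, 0)
    for name in names:
        if name not in types:
            raise ValueError(f"residue {name!r} has no type mapping")
        counts[types[name]] += 1
    total = names.size
    return np.array([counts[t] / total for t in _TYPE_ORDER])
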