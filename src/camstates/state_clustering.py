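"""Spectral clustering of conformations on the iiad-cmap metric.

Frames are featurized as contact maps of inverse inter-atomic distances
(iiad-cmap): every retained atom pair contributes 1/r in Å⁻¹, so distant
pairs contribute little without needing a hard cutoff, and no structural
alignment is required. Frame dissimilarity is the Euclidean norm between
feature vectors. The dissimilarities enter a Gaussian kernel

    A_ij = exp(-d_ij² / (2 σ²)),

with σ the average nearest-neighbour distance between frames. The
symmetrically normalized matrix L = D^{-1/2} A D^{-1/2} (D the diagonal
degree matrix) is diagonalized; the number of states k is chosen at the
maximum eigengap of its descending spectrum; the top-k eigenvector rows
are normalized onto the unit k-sphere and clustered with spherical
k-means (centers re-projected onto the sphere after every update). Each
state is summarized by the member frame with smallest mean RMSD to the
other members after optimal superposition.

The same kernel/eigengap/spherical-k-means engine is reused by
:mod:`camstates.rigid_domains` (on residue fluctuation similarities) and
:mod:`camstates.binding_analysis` (on matching-score distributions).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import Ensemble

__all__ = [
    "FeatureMatrix",
    "FrameDistanceMatrix",
    "SpectralModel",
    "StateAssignment",
    "iiad_featurize",
    "frame_distance_matrix",
    "estimate_sigma",
    "adjacency",
    "random_walk_matrix",
    "choose_k",
    "spectral_embed",
    "cluster_states",
    "spherical_kmeans",
    "representative_frame",
    "spectral_cluster_distance_matrix",
    "kabsch_rmsd",
    "DegenerateSpectrumWarning",
]


class DegenerateSpectrumWarning(UserWarning):
    """Spectrum carries no cluster structure; model selection fell back."""


@dataclasses.dataclass
class FeatureMatrix:
    """n_frames × n_pairs inverse inter-atomic distances (Å⁻¹)."""

    values: np.ndarray
    atom_indices: np.ndarray
    pair_list: np.ndarray  # (n_pairs, 2) indices into atom_indices' atoms

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class FrameDistanceMatrix:
    """Symmetric frame-to-frame dissimilarities (Euclidean in feature space)."""

    values: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class SpectralModel:
    sigma: float
    adjacency: np.ndarray
    eigenvalues: np.ndarray
    embedding: np.ndarray
    k: int
    labels: np.ndarray
    seed: int


@dataclasses.dataclass
class StateAssignment:
    labels: np.ndarray
    representative_frame: np.ndarray  # per-state frame index
    state_sizes: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.state_sizes)


# ---------------------------------------------------------------------------
# featurization


def iiad_featurize(
    ensemble: Ensemble,
    atom_selection,
    pair_stride: int = 1,
) -> FeatureMatrix:
    """Inverse inter-atomic distances for every retained atom pair.

    Pairs follow the canonical i<j ordering over the selection;
    ``pair_stride`` keeps every ``pair_stride``-th pair (stride 1 keeps
    all). Coincident atoms raise, naming the frame and pair.
    """
    sel = np.asarray(list(atom_selection), dtype=int)
    if sel.size == 0:
        raise ValueError("atom selection is empty")
    if pair_stride < 1:
        raise ValueError("pair_stride must be >= 1")
    n = sel.size
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)[::pair_stride]
    coords = ensemble.coordinates[:, sel, :]
    diff = coords[:, pairs[:, 0], :] - coords[:, pairs[:, 1], :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r == 0.0):
        f, p = np.argwhere(r == 0.0)[0]
        raise FloatingPointError(
            f"coincident atoms in frame {f}, pair "
            f"({sel[pairs[p, 0]]}, {sel[pairs[p, 1]]}): distance is zero"
        )
    return FeatureMatrix(values=1.0 / r, atom_indices=sel, pair_list=pairs)


def frame_distance_matrix(
    features: FeatureMatrix, block_size: int = 256
) -> FrameDistanceMatrix:
    """Pairwise Euclidean distances between frame feature vectors.

    Computed in row blocks so peak memory stays O(n_frames² + block).
    """
    x = features.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    n = x.shape[0]
    sq = np.einsum("ij,ij->i", x, x)
    d2 = np.empty((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        g = x[start:stop] @ x.T
        d2[start:stop] = sq[start:stop, None] + sq[None, :] - 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return FrameDistanceMatrix(values=d)


# ---------------------------------------------------------------------------
# spectral engine


def estimate_sigma(d: FrameDistanceMatrix | np.ndarray) -> float:
    """Average nearest-neighbour distance between configurations."""
    values = d.values if isinstance(d, FrameDistanceMatrix) else np.asarray(d)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to estimate sigma")
    off = values + np.diag(np.full(n, np.inf))
    nn = off.min(axis=1)
    sigma = float(nn.mean())
    if sigma == 0.0:
        raise ValueError(
            "sigma is zero: duplicate frames dominate; deduplicate frames first"
        )
    return sigma


def adjacency(d: FrameDistanceMatrix | np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-kernel edge weights A_ij = exp(-d_ij²/(2σ²)); A_ii = 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    values = d.values if isinstance(d, FrameDistanceMatrix) else np.asarray(d)
    a = np.exp(-(values**2) / (2.0 * sigma**2))
    np.fill_diagonal(a, 1.0)
    return a


def random_walk_matrix(a: np.ndarray):
    """Normalized matrix L = D^{-1/2} A D^{-1/2} and its eigendecomposition.

    Returns ``(L, eigenvalues, eigenvectors)`` with eigenpairs sorted by
    descending eigenvalue. All eigenvalues lie in [-1, 1]; the largest is 1
    for a connected graph.
    """
    a = np.asarray(a, dtype=float)
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero row sum: isolated node in similarity graph")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lmat = a * inv_sqrt[:, None] * inv_sqrt[None, :]
    lmat = 0.5 * (lmat + lmat.T)
    evals, evecs = np.linalg.eigh(lmat)
    order = np.argsort(evals)[::-1]
    return lmat, evals[order], evecs[:, order]


def choose_k(eigenvalues, k_range: tuple[int, int] = (2, 10)) -> int:
    """Cluster count at the maximum eigengap λ_k − λ_{k+1} (1-based, λ descending).

    Ties resolve to the smallest k.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    k_min, k_max = k_range
    k_max = min(k_max, lam.size - 1)
    if k_min > k_max:
        raise ValueError(f"empty k range ({k_min}, {k_max})")
    gaps = lam[k_min - 1 : k_max] - lam[k_min : k_max + 1]
    return int(k_min + np.argmax(gaps))


def spectral_embed(eigenvectors: np.ndarray, k: int) -> np.ndarray:
    """Rows of the top-k eigenvectors projected onto the unit k-sphere.

    Eigenvector signs are canonicalized (largest-magnitude entry positive)
    so the embedding — and downstream labels — do not depend on the
    arbitrary sign returned by the eigensolver.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    u = np.array(eigenvectors[:, :k], dtype=float)
    for j in range(k):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms == 0.0):
        raise FloatingPointError("zero embedding row; cannot project onto sphere")
    return u / norms[:, None]


def spherical_kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> np.ndarray:
    """k-means on the unit sphere with centers renormalized every update.

    Initialization is k-means++-style but runs on a lexicographically
    sorted copy of the points, so relabeling/permuting the input permutes
    the output identically under the same seed. The best of ``n_init``
    restarts by within-cluster cosine dispersion wins.
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    order = np.lexsort(x.T[::-1])  # canonical row order
    xs = x[order]
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, np.inf
    for _ in range(n_init):
        centers = _kmeanspp_sphere(xs, k, rng)
        labels = None
        for _ in range(max_iter):
            sims = xs @ centers.T
            new_labels = np.argmax(sims, axis=1)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            ok = True
            for c in range(k):
                members = xs[labels == c]
                if members.shape[0] == 0:
                    ok = False
                    break
                m = members.sum(axis=0)
                norm = np.linalg.norm(m)
                if norm == 0.0:
                    ok = False
                    break
                centers[c] = m / norm
            if not ok:
                labels = None
                break
        if labels is None:
            continue
        obj = float(np.sum(1.0 - (xs @ centers.T)[np.arange(n), labels]))
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_labels = labels
    if best_labels is None:
        raise RuntimeError("spherical k-means failed: empty cluster in every restart")
    out = np.empty(n, dtype=int)
    out[order] = _canonical_relabel(best_labels)
    return out


def _kmeanspp_sphere(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.maximum(0.0, 1.0 - x @ centers[0])  # cosine distance
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c] = x[rng.integers(n)]
        else:
            centers[c] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.maximum(0.0, 1.0 - x @ centers[c]))
    return centers


def _canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_states(
    embedding: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Cluster k-sphere embedding rows into k states (spherical k-means)."""
    return spherical_kmeans(embedding, k, seed=seed, n_init=n_init)


# ---------------------------------------------------------------------------
# representatives


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = s.copy()
    s[-1] *= d
    n = p.shape[0]
    msd = (np.sum(pc**2) + np.sum(qc**2) - 2.0 * np.sum(s)) / n
    return float(np.sqrt(max(msd, 0.0)))


def representative_frame(
    ensemble: Ensemble, labels: np.ndarray, atom_selection
) -> np.ndarray:
    """Per-state frame minimizing mean pairwise RMSD to the other members.

    RMSD is computed on ``atom_selection`` after optimal rigid
    superposition; ties resolve to the smallest frame index.
    """
    labels = np.asarray(labels)
    sel = np.asarray(list(atom_selection), dtype=int)
    states = np.unique(labels)
    reps = np.empty(states.size, dtype=int)
    for s in states:
        frames = np.flatnonzero(labels == s)
        if frames.size == 1:
            reps[s] = frames[0]
            continue
        coords = ensemble.coordinates[np.ix_(frames, sel)]
        m = frames.size
        total = np.zeros(m)
        for i in range(m):
            for j in range(i + 1, m):
                r = kabsch_rmsd(coords[i], coords[j])
                total[i] += r
                total[j] += r
        reps[s] = frames[int(np.argmin(total))]  # argmin takes first on ties
    return reps


# ---------------------------------------------------------------------------
# one-call engine over a precomputed distance matrix


def spectral_cluster_distance_matrix(
    d: np.ndarray,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_init: int = 10,
) -> SpectralModel:
    """Full spectral pipeline on a precomputed symmetric distance matrix.

    With ``k=None`` the cluster count is selected by the maximum eigengap
    in ``k_range``. A distance matrix that is numerically all-zero carries
    no structure; it yields a single cluster with a warning.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if np.allclose(d, 0.0, atol=1e-12):
        warnings.warn(
            "all pairwise distances are zero; returning a single cluster",
            DegenerateSpectrumWarning,
            stacklevel=2,
        )
        return SpectralModel(
            sigma=0.0,
            adjacency=np.ones_like(d),
            eigenvalues=np.concatenate([[1.0], np.zeros(n - 1)]),
            embedding=np.ones((n, 1)),
            k=1,
            labels=np.zeros(n, dtype=int),
            seed=seed,
        )
    # duplicates (zero-distance groups) would force sigma to 0; collapse
    # them to unique representatives and broadcast the labels back
    zero = d <= 1e-12
    np.fill_diagonal(zero, True)
    if zero.sum() > n:
        from scipy.sparse.csgraph import connected_components

        n_groups, group = connected_components(zero, directed=False)
        if n_groups < n:
            reps = np.array([np.flatnonzero(group == g)[0] for g in range(n_groups)])
            sub = d[np.ix_(reps, reps)]
            if n_groups < 2:
                return SpectralModel(
                    sigma=0.0,
                    adjacency=np.ones_like(d),
                    eigenvalues=np.concatenate([[1.0], np.zeros(n - 1)]),
                    embedding=np.ones((n, 1)),
                    k=1,
                    labels=np.zeros(n, dtype=int),
                    seed=seed,
                )
            k_range = (min(k_range[0], n_groups - 1), min(k_range[1], n_groups - 1))
            sub_model = spectral_cluster_distance_matrix(
                sub,
                k=None if k is None else min(k, n_groups),
                k_range=k_range,
                seed=seed,
                n_init=n_init,
            )
            return SpectralModel(
                sigma=sub_model.sigma,
                adjacency=sub_model.adjacency,
                eigenvalues=sub_model.eigenvalues,
                embedding=sub_model.embedding,
                k=sub_model.k,
                labels=sub_model.labels[group],
                seed=seed,
            )
    sigma = estimate_sigma(d)
    a = adjacency(d, sigma)
    _, evals, evecs = random_walk_matrix(a)
    if k is None:
        # degenerate spectrum: no gap structure beyond the trivial eigenvalue
        gaps = evals[:-1] - evals[1:]
        if n > 2 and np.allclose(gaps[1:], gaps[1], atol=1e-12):
            warnings.warn(
                "eigengap spectrum is flat beyond the leading eigenvalue; "
                "no cluster structure, returning a single cluster",
                DegenerateSpectrumWarning,
                stacklevel=2,
            )
            return SpectralModel(
                sigma=sigma,
                adjacency=a,
                eigenvalues=evals,
                embedding=np.ones((n, 1)),
                k=1,
                labels=np.zeros(n, dtype=int),
                seed=seed,
            )
        k = choose_k(evals, k_range)
    emb = spectral_embed(evecs, k)
    labels = cluster_states(emb, k, seed=seed, n_init=n_init)
    return SpectralModel(
        sigma=sigma,
        adjacency=a,
        eigenvalues=evals,
        embedding=emb,
        k=k,
        labels=labels,
        seed=seed,
    )


def assign_states(
    ensemble: Ensemble,
    atom_selection,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
    pair_stride: int = 1,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[StateAssignment, SpectralModel]:
    """Featurize → distances → spectral model → states → representatives."""
    feats = iiad_featurize(ensemble, atom_selection, pair_stride=pair_stride)
    d = frame_distance_matrix(feats)
    model = spectral_cluster_distance_matrix(
        d.values, k=k, k_range=k_range, seed=seed, n_init=n_init
    )
    reps = representative_frame(ensemble, model.labels, atom_selection)
    sizes = np.bincount(model.labels, minlength=model.k)
    return StateAssignment(model.labels, reps, sizes), model
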