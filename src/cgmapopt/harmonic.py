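"""Harmonic network models: bead-spring chains and Gaussian Network Models.

A harmonic system is defined by a connectivity (Kirchhoff) matrix ``Gamma``
with energy ``u(x) = 1/2 * dx^T Gamma dx`` where ``dx = x - x0``.  Sampling
follows the Boltzmann weight ``exp(-beta * u)``, so the equilibrium
covariance of the displacements is ``Gamma^+ / beta`` (pseudo-inverse over
the non-zero modes; the zero mode is rigid translation and is excluded).

The Gaussian Network Model convention is isotropic: one scalar coordinate
per node.  Three-dimensional observables factorize into ``d`` identical
copies of the scalar problem, so nothing is lost for mapping comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ConnectivityError,
    FormatError,
    InvalidSystemError,
    ParameterError,
)

__all__ = [
    "HarmonicSystem",
    "SpectralDecomposition",
    "build_chain",
    "build_gnm",
    "spectral_decompose",
    "equilibrium_covariance",
    "synthetic_structure",
    "demo_structure",
    "read_calpha",
    "read_coordinate_table",
]

#: seed of the 40-residue synthetic structure shipped as the pinned test
#: fixture for the network-model experiments.
DEMO_STRUCTURE_SEED = 7

_ROW_SUM_TOL = 1e-10


@dataclass(frozen=True)
class HarmonicSystem:
    """Harmonic network with connectivity matrix ``gamma_matrix``.

    Parameters
    ----------
    gamma_matrix
        Symmetric positive-semidefinite n x n connectivity matrix with zero
        row sums (graph-Laplacian structure), units energy / length^2.
    reference_coords
        Reference configuration ``x0``; one scalar per node (GNM convention).
    beta
        Inverse temperature, 1 / energy.
    friction
        Friction coefficient of the overdamped Langevin dynamics,
        time * energy / length^2.
    """

    gamma_matrix: np.ndarray
    reference_coords: np.ndarray
    beta: float = 1.0
    friction: float = 1.0

    def __post_init__(self):
        gamma = np.asarray(self.gamma_matrix, dtype=float)
        x0 = np.asarray(self.reference_coords, dtype=float).ravel()
        object.__setattr__(self, "gamma_matrix", gamma)
        object.__setattr__(self, "reference_coords", x0)
        if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
            raise ParameterError("gamma_matrix must be square")
        if x0.shape[0] != gamma.shape[0]:
            raise ParameterError(
                f"reference_coords length {x0.shape[0]} does not match "
                f"gamma_matrix size {gamma.shape[0]}"
            )
        if not (self.beta > 0 or np.isinf(self.beta)):
            raise ParameterError("beta must be positive")
        if not self.friction > 0:
            raise ParameterError("friction must be positive")
        scale = max(np.abs(gamma).max(), 1.0)
        if not np.allclose(gamma, gamma.T, atol=1e-9 * scale):
            raise InvalidSystemError("gamma_matrix is not symmetric")
        rows = np.abs(gamma.sum(axis=1)).max()
        if rows > _ROW_SUM_TOL * scale:
            raise InvalidSystemError(
                f"gamma_matrix row sums deviate from zero by {rows:g}"
            )

    @property
    def n(self) -> int:
        """Number of nodes."""
        return self.gamma_matrix.shape[0]


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigendecomposition of a connectivity matrix with zero-mode bookkeeping.

    ``eigenvalues`` are sorted ascending, ``eigenvectors[:, i]`` is the
    orthonormal mode belonging to ``eigenvalues[i]``.  The first
    ``zero_mode_count`` modes are classified as rigid (zero) modes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    zero_mode_count: int

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.zero_mode_count :]

    @property
    def nonzero_modes(self) -> np.ndarray:
        return self.eigenvectors[:, self.zero_mode_count :]


def build_chain(n, spring_constants, beta=1.0, friction=1.0) -> HarmonicSystem:
    """Linear bead-spring chain with springs ``k_i`` between beads i, i+1.

    The resulting connectivity matrix is tridiagonal with off-diagonal
    entries ``-k_i`` and degree-weighted diagonals (zero row sums).
    Reference positions are ``0, 1, ..., n-1``.
    """
    if n < 2:
        raise ParameterError(f"need at least 2 beads, got n={n}")
    k = np.asarray(spring_constants, dtype=float).ravel()
    if k.shape[0] != n - 1:
        raise ParameterError(
            f"expected {n - 1} spring constants for n={n}, got {k.shape[0]}"
        )
    if np.any(k <= 0):
        raise ParameterError("all spring constants must be positive")
    gamma = np.zeros((n, n))
    idx = np.arange(n - 1)
    gamma[idx, idx + 1] = -k
    gamma[idx + 1, idx] = -k
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    return HarmonicSystem(gamma, np.arange(n, dtype=float), beta, friction)


def build_gnm(coords, cutoff, beta=1.0, friction=1.0) -> HarmonicSystem:
    """Gaussian Network Model: unit springs between nodes within ``cutoff``.

    ``coords`` is an (m, 3) array of positions (e.g. C-alpha atoms).  The
    off-diagonal connectivity is -1 for pairs within the cutoff distance and
    the diagonal holds the node degrees.  Raises
    :class:`~cgmapopt.errors.ConnectivityError` if the contact graph is
    disconnected, naming the components.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    m = pts.shape[0]
    if m < 2:
        raise ParameterError("need at least 2 points")
    if not cutoff > 0:
        raise ParameterError("cutoff must be positive")
    dist = squareform(pdist(pts))
    adjacency = (dist <= cutoff) & ~np.eye(m, dtype=bool)
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise ConnectivityError(
            f"contact graph at cutoff {cutoff} splits into {n_comp} "
            f"components: {comps}",
            components=comps,
        )
    gamma = -adjacency.astype(float)
    np.fill_diagonal(gamma, adjacency.sum(axis=1))
    # isotropic convention: scalar coordinate per node, reference at zero
    return HarmonicSystem(gamma, np.zeros(m), beta, friction)


def spectral_decompose(system: HarmonicSystem, zero_tolerance: float = 1e-10):
    """Eigendecomposition of ``gamma_matrix`` with zero-mode classification.

    Eigenvalues below ``zero_tolerance`` times the largest eigenvalue are
    classified as rigid modes.  A negative eigenvalue beyond that tolerance
    raises :class:`~cgmapopt.errors.InvalidSystemError`.
    """
    lam, vec = np.linalg.eigh(system.gamma_matrix)
    lam_max = max(lam[-1], 0.0)
    cut = zero_tolerance * max(lam_max, np.finfo(float).tiny)
    if lam[0] < -cut:
        raise InvalidSystemError(
            f"negative eigenvalue {lam[0]:g} beyond tolerance {cut:g}"
        )
    n_zero = int(np.sum(np.abs(lam) <= cut))
    lam = lam.copy()
    lam[:n_zero] = 0.0
    return SpectralDecomposition(lam, vec, n_zero)


def equilibrium_covariance(system: HarmonicSystem) -> np.ndarray:
    """Equilibrium covariance ``c00 = Gamma^+ / beta`` over non-zero modes.

    The pseudo-inverse annihilates the rigid translation (uniform) vector,
    i.e. the distribution is that of a system with pinned centre of mass.
    """
    spec = spectral_decompose(system)
    if spec.zero_mode_count == spec.eigenvalues.shape[0]:
        raise InvalidSystemError("system has no non-zero modes")
    u = spec.nonzero_modes
    lam = spec.nonzero_eigenvalues
    return (u / (system.beta * lam)) @ u.T


def synthetic_structure(m: int, seed: int) -> np.ndarray:
    """Synthetic C-alpha-like trace: self-avoiding random walk in 3-space.

    Consecutive points are a fixed 3.8 length units apart (the C-alpha
    virtual bond length) and any step landing closer than 3.0 units to a
    previous point is rejected and redrawn.  Deterministic given ``seed``;
    the resulting 10-unit-cutoff network is connected by construction
    (consecutive points are always within the cutoff).
    """
    if m < 2:
        raise ParameterError("need at least 2 points")
    rng = np.random.default_rng(seed)
    pts = np.zeros((m, 3))
    step, clash = 3.8, 3.0
    for i in range(1, m):
        for _ in range(10_000):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pts[i - 1] + step * v
            if i < 2 or np.min(np.linalg.norm(pts[: i - 1] - cand, axis=1)) >= clash:
                pts[i] = cand
                break
        else:  # pragma: no cover - astronomically unlikely at these sizes
            raise RuntimeError("self-avoiding walk stalled")
    return pts


def demo_structure() -> np.ndarray:
    """The pinned 40-residue synthetic structure used by the shipped demos."""
    return synthetic_structure(40, DEMO_STRUCTURE_SEED)


def read_calpha(structure_file, chain=None):
    """C-alpha coordinates and residue labels from a PDB file.

    Reads the first model; keeps the first chain unless ``chain`` is given.
    Alternate locations are resolved by highest occupancy and
    insertion-coded duplicate residues are skipped (first occurrence kept).

    Returns
    -------
    coords : (m, 3) float array
    labels : list of residue identifiers ``(res_id, res_name)``
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(structure_file))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except OSError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {structure_file!r} as PDB: {exc}") from exc
    mask = atoms.atom_name == "CA"
    if chain is None:
        chains = atoms.chain_id[mask]
        if chains.size == 0:
            raise FormatError(f"no C-alpha atoms in {structure_file!r}")
        chain = chains[0]
    mask &= atoms.chain_id == chain
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise FormatError(f"no C-alpha atoms in chain {chain!r}")
    coords, labels, seen = [], [], set()
    for i in range(ca.array_length()):
        res = int(ca.res_id[i])
        if res in seen:
            continue  # insertion-coded or duplicate residue: keep first
        seen.add(res)
        coords.append(ca.coord[i])
        labels.append((res, str(ca.res_name[i])))
    return np.asarray(coords, dtype=float), labels


def read_coordinate_table(path) -> np.ndarray:
    """Plain-text coordinate table: one ``x y z`` row per atom."""
    try:
        pts = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse coordinate table {path!r}: {exc}") from exc
    if pts.shape[1] != 3:
        raise FormatError(
            f"coordinate table {path!r} has {pts.shape[1]} columns, expected 3"
        )
    return pts
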