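"""Closed-form mapping scores for harmonic systems.

For a harmonic system with connectivity matrix ``Gamma`` and a linear CG
map ``M``, the thermodynamically consistent CG model is again Gaussian.
Everything needed to score the map follows from two matrices:

* ``c00 = Gamma^+ / beta`` -- the fine-grained equilibrium covariance;
* ``Omega_tau = sum_i exp(-lambda_i tau / gamma) / (beta lambda_i) u_i u_i^T``
  -- the lag-``tau`` covariance of the overdamped Langevin dynamics, where
  ``lambda_i, u_i`` run over the non-zero eigenpairs of ``Gamma``.

The CG covariance and time-lagged covariance are the mapped matrices
``M c00 M^T`` and ``M Omega_tau M^T`` projected by ``Q = 1_N - J J^T / N``
onto the translation-free subspace (the uniform CG vector is the image of
the rigid translation).  On that subspace:

* VAMP-2 score: squared Frobenius norm of the whitened Koopman matrix
  ``C00^{-1/2} C0tau C00^{-1/2}``;
* implied timescales: ``t_i = -tau / ln nu_i`` from its eigenvalues;
* mapping entropy (mapping-dependent part):
  ``(ln T_K - ln t_Gamma) / 2`` with ``t_Gamma, T_K`` the products of
  non-zero eigenvalues of ``Gamma`` and of the effective CG matrix ``K``;
* vibrational power: ``trace(M c00 M^T)`` (uniform masses);
* Gaussian reconstruction error: residual variance of the conditional-mean
  decoder, ``trace(c00 - c00 M^T (M c00 M^T)^+ M c00) / n`` -- a lower
  bound for any trained decoder on the same system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMappingError, ParameterError
from .harmonic import (
    HarmonicSystem,
    SpectralDecomposition,
    equilibrium_covariance,
    spectral_decompose,
)
from .mappings import LinearMapping

__all__ = [
    "CGModel",
    "MetricSet",
    "cg_projector",
    "effective_cg_matrix",
    "omega_tau",
    "time_lagged_covariance_analytic",
    "vamp_score",
    "koopman_eigenvalues",
    "mapping_entropy",
    "mapping_entropy_full",
    "vibrational_power",
    "reconstruction_error_gaussian",
    "analytic_timescales",
    "default_lag_time",
    "score_mapping",
    "AnalyticScorer",
]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class CGModel:
    """Thermodynamically consistent Gaussian CG model for one mapping.

    ``cg_covariance`` is the translation-projected CG covariance
    ``C00 = Q (M c00 M^T) Q`` and satisfies ``C00 = K^+`` (pseudo-inverse)
    with the effective CG matrix ``K``; ``mapped_covariance`` is the raw
    ``M c00 M^T`` (what a sample covariance of mapped coordinates of a
    centre-of-mass-pinned trajectory estimates).
    """

    effective_K: np.ndarray
    cg_covariance: np.ndarray
    mapped_covariance: np.ndarray
    reference: np.ndarray


@dataclass(frozen=True)
class MetricSet:
    """Scores of one mapping on one system at one lag time."""

    vamp: float
    smap: float
    vibrational_power: float
    reconstruction_error: float
    lag_time: float


def cg_projector(N: int) -> np.ndarray:
    """``Q = 1_N - J J^T / N``: removes the uniform (translation) component."""
    return np.eye(N) - np.full((N, N), 1.0 / N)


def _psd_pinv(mat, rank_tolerance=_RANK_TOL, return_spectrum=False):
    s, u = np.linalg.eigh(mat)
    cut = rank_tolerance * max(s[-1], np.finfo(float).tiny)
    keep = s > cut
    pinv = (u[:, keep] / s[keep]) @ u[:, keep].T
    if return_spectrum:
        return pinv, s[keep], u[:, keep]
    return pinv


def effective_cg_matrix(system: HarmonicSystem, mapping: LinearMapping) -> CGModel:
    """Effective CG matrix ``K`` and CG covariances for one mapping.

    Raises :class:`~cgmapopt.errors.DegenerateMappingError` if the projected
    mapped covariance loses more than the single translation mode.
    """
    if mapping.n_atoms != system.n:
        raise ParameterError(
            f"mapping is over {mapping.n_atoms} atoms, system has {system.n}"
        )
    c00 = equilibrium_covariance(system)
    m = mapping.matrix
    mapped = m @ c00 @ m.T
    N = mapping.n_beads
    q = cg_projector(N)
    projected = q @ mapped @ q
    projected = 0.5 * (projected + projected.T)
    k_pinv, s, u = _psd_pinv(projected, return_spectrum=True)
    if s.shape[0] < N - 1:
        raise DegenerateMappingError(
            f"mapped covariance of {mapping.label!r} has rank {s.shape[0]} "
            f"< N-1 = {N - 1}"
        )
    effective_k = k_pinv / system.beta
    return CGModel(effective_k, projected, mapped, mapping.apply(system.reference_coords))


def omega_tau(
    spec: SpectralDecomposition, tau: float, friction: float, beta: float
) -> np.ndarray:
    """Lag-``tau`` covariance of the overdamped harmonic dynamics.

    ``Omega_tau = sum_{lambda_i > 0} exp(-lambda_i tau / gamma)
    / (beta lambda_i) u_i u_i^T``; equals the equilibrium covariance at
    ``tau = 0`` and decays to zero for large lags.
    """
    if tau < 0:
        raise ParameterError(f"lag time must be non-negative, got {tau}")
    lam = spec.nonzero_eigenvalues
    u = spec.nonzero_modes
    w = np.exp(-lam * tau / friction) / (beta * lam)
    return (u * w) @ u.T


def time_lagged_covariance_analytic(
    system: HarmonicSystem, mapping: LinearMapping, tau: float
) -> np.ndarray:
    """Projected CG time-lagged covariance ``C0tau = Q M Omega_tau M^T Q``."""
    spec = spectral_decompose(system)
    om = omega_tau(spec, tau, system.friction, system.beta)
    m = mapping.matrix
    q = cg_projector(mapping.n_beads)
    c0t = q @ m @ om @ m.T @ q
    return 0.5 * (c0t + c0t.T)


def _whiten(c00, rank_tolerance):
    s, u = np.linalg.eigh(c00)
    if s[-1] <= 0:
        raise ParameterError("covariance has no positive eigenvalue")
    cut = rank_tolerance * s[-1]
    if s[0] < -cut:
        raise ParameterError(
            f"covariance indefinite: smallest eigenvalue {s[0]:g}"
        )
    keep = s > cut
    return u[:, keep] / np.sqrt(s[keep])


def koopman_eigenvalues(c00, c0tau, rank_tolerance=_RANK_TOL) -> np.ndarray:
    """Eigenvalues of the whitened Koopman matrix, sorted descending.

    The Koopman matrix is ``W^T C0tau W`` with ``W`` the pseudo-inverse
    square root of ``C00`` restricted to its numerical range.
    """
    c00 = np.asarray(c00, dtype=float)
    c0tau = np.asarray(c0tau, dtype=float)
    if c00.shape != c0tau.shape:
        raise ParameterError(
            f"shape mismatch: C00 {c00.shape} vs C0tau {c0tau.shape}"
        )
    w = _whiten(c00, rank_tolerance)
    t = w.T @ c0tau @ w
    t = 0.5 * (t + t.T)
    nu = np.linalg.eigvalsh(t)
    return nu[::-1]


def vamp_score(c00, c0tau, rank_tolerance=_RANK_TOL) -> float:
    """VAMP-2 score: sum of squared whitened Koopman eigenvalues.

    Lies in ``[0, rank(C00)]``; equals the rank at ``tau = 0`` and measures
    how much slow-process variance the coordinates retain at larger lags.
    """
    nu = koopman_eigenvalues(c00, c0tau, rank_tolerance)
    return float(np.sum(nu**2))


def mapping_entropy(system: HarmonicSystem, mapping: LinearMapping) -> float:
    """Mapping-dependent part of the mapping entropy, ``(ln T_K - ln t_G)/2``.

    ``t_G`` and ``T_K`` are the products of non-zero eigenvalues of the
    connectivity matrix and of the effective CG matrix.  The
    model-independent constants (volume term and dimensionality constant)
    are dropped: they cancel in any comparison at fixed resolution, which
    is the only use of the score.  The identity map returns exactly 0 (no
    information lost); see :func:`mapping_entropy_full` for the constants.
    """
    spec = spectral_decompose(system)
    model = effective_cg_matrix(system, mapping)
    s = np.linalg.eigvalsh(model.cg_covariance)
    keep = s > _RANK_TOL * s[-1]
    # K eigenvalues are 1 / (beta * s) on the kept subspace
    ln_tk = -float(np.sum(np.log(system.beta * s[keep])))
    ln_tg = float(np.sum(np.log(spec.nonzero_eigenvalues)))
    return 0.5 * (ln_tk - ln_tg)


def mapping_entropy_full(
    system: HarmonicSystem, mapping: LinearMapping, volume: float = 100.0
) -> float:
    """Mapping entropy with the excess-entropy constants restored.

    Each of the ``n - N`` discarded degrees of freedom contributes
    ``(1/2) ln(2 pi e / beta) - ln V`` where ``V`` is the confinement
    volume per coordinate used in the excess entropy.  The result is the
    difference between the excess configurational entropy of the
    fine-grained model and the one perceived through the CG map; it is
    non-positive whenever the box is large compared with the thermal
    fluctuations, and zero for the identity map.
    """
    if volume <= 0:
        raise ParameterError("volume must be positive")
    dropped = (system.n - 1) - (mapping.n_beads - 1)
    const = dropped * (0.5 * np.log(2 * np.pi * np.e / system.beta) - np.log(volume))
    return mapping_entropy(system, mapping) + const


def vibrational_power(system: HarmonicSystem, mapping: LinearMapping) -> float:
    """Trace of the (uniform-mass) CG covariance ``M c00 M^T``."""
    c00 = equilibrium_covariance(system)
    m = mapping.matrix
    return float(np.trace(m @ c00 @ m.T))


def reconstruction_error_gaussian(
    system: HarmonicSystem, mapping: LinearMapping
) -> float:
    """Mean-square error of the optimal (conditional-mean) decoder.

    ``RE = trace(c00 - c00 M^T (M c00 M^T)^+ M c00) / n``; this is the
    residual variance per atom left after the best possible reconstruction
    of the fine-grained coordinates from the CG ones, and lower-bounds the
    held-out MSE of any decoder trained on trajectories of the system.
    """
    c00 = equilibrium_covariance(system)
    m = mapping.matrix
    mapped = m @ c00 @ m.T
    pinv = _psd_pinv(0.5 * (mapped + mapped.T))
    resid = c00 - c00 @ m.T @ pinv @ m @ c00
    return float(np.trace(resid)) / system.n


def default_lag_time(system: HarmonicSystem) -> float:
    """Default scoring lag: ten times the fastest relaxation time.

    ``tau = 10 gamma / lambda_max`` sits between the fastest and slowest
    relaxation times for the systems of interest; rankings are insensitive
    to the choice over about a decade (see the test suite).
    """
    spec = spectral_decompose(system)
    return 10.0 * system.friction / float(spec.nonzero_eigenvalues[-1])


def analytic_timescales(
    system: HarmonicSystem,
    mapping: LinearMapping,
    tau: float | None = None,
    count: int | None = None,
) -> np.ndarray:
    """Implied timescales ``t_i = -tau / ln nu_i`` of the mapped dynamics.

    ``nu_i`` are the whitened Koopman eigenvalues at lag ``tau``.  For the
    identity map these are exactly ``gamma / lambda_i``.  Eigenvalues
    outside (0, 1) (beyond tolerance) are dropped with a warning.  Sorted
    descending; at most ``N - 1`` values exist.
    """
    if tau is None:
        tau = default_lag_time(system)
    model = effective_cg_matrix(system, mapping)
    c0t = time_lagged_covariance_analytic(system, mapping, tau)
    nu = koopman_eigenvalues(model.cg_covariance, c0t)
    valid = (nu > 0.0) & (nu < 1.0 - 1e-12)
    if not np.all(valid):
        warnings.warn(
            f"dropped {int(np.sum(~valid))} Koopman eigenvalues outside (0, 1)",
            stacklevel=2,
        )
    times = -tau / np.log(nu[valid])
    times = np.sort(times)[::-1]
    if count is not None:
        if count > times.shape[0]:
            raise ParameterError(
                f"requested {count} timescales, only {times.shape[0]} available"
            )
        times = times[:count]
    return times


def score_mapping(
    system: HarmonicSystem, mapping: LinearMapping, tau: float | None = None
) -> MetricSet:
    """All four analytic scores of one mapping at one lag time."""
    return AnalyticScorer(system, tau).score(mapping)


class AnalyticScorer:
    """Precomputed scoring context for sweeping many mappings on one system.

    Caches the spectral decomposition, ``c00`` and ``Omega_tau`` so that a
    sweep over tens of thousands of candidate maps only pays the N x N
    algebra per candidate.
    """

    def __init__(self, system: HarmonicSystem, tau: float | None = None):
        self.system = system
        self.spec = spectral_decompose(system)
        self.tau = float(tau) if tau is not None else default_lag_time(system)
        self.c00 = equilibrium_covariance(system)
        self.omega = omega_tau(self.spec, self.tau, system.friction, system.beta)
        self._ln_tg = float(np.sum(np.log(self.spec.nonzero_eigenvalues)))

    def _projected(self, mapping):
        m = mapping.matrix
        q = cg_projector(mapping.n_beads)
        a = m @ self.c00 @ m.T
        b = m @ self.omega @ m.T
        c00 = q @ a @ q
        c0t = q @ b @ q
        return a, 0.5 * (c00 + c00.T), 0.5 * (c0t + c0t.T)

    def score(self, mapping: LinearMapping, timescale_count: int | None = None):
        mapped, c00, c0t = self._projected(mapping)
        s = np.linalg.eigvalsh(c00)
        keep = s > _RANK_TOL * s[-1]
        if int(np.sum(keep)) < mapping.n_beads - 1:
            raise DegenerateMappingError(
                f"mapped covariance of {mapping.label!r} is rank-deficient"
            )
        nu = koopman_eigenvalues(c00, c0t)
        vamp = float(np.sum(nu**2))
        smap = 0.5 * (-float(np.sum(np.log(self.system.beta * s[keep]))) - self._ln_tg)
        vp = float(np.trace(mapped))
        c00f = self.c00
        m = mapping.matrix
        pinv = _psd_pinv(0.5 * (mapped + mapped.T))
        re = float(np.trace(c00f - c00f @ m.T @ pinv @ m @ c00f)) / self.system.n
        metrics = MetricSet(vamp, smap, vp, re, self.tau)
        if timescale_count is None:
            return metrics
        valid = (nu > 0.0) & (nu < 1.0 - 1e-12)
        times = np.sort(-self.tau / np.log(nu[valid]))[::-1][:timescale_count]
        return metrics, times

    def timescales(self, mapping: LinearMapping, count: int | None = None):
        return analytic_timescales(self.system, mapping, self.tau, count)
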