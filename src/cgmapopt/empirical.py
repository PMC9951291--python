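"""Trajectory-based estimators of the mapping scores.

Everything the analytic module computes in closed form for harmonic
systems is re-estimated here from equilibrium trajectories: covariance and
time-lagged covariance matrices, the VAMP-2 score, TICA implied
timescales, and the reconstruction error of a decoder trained with the CG
map as its (fixed) encoder.  For nonlinear systems such as the model
protein these estimators are the only route to the scores.

The reversible (symmetrized) covariance estimator is the default: the
instantaneous covariance averages the head and tail segments and the
lagged covariance is symmetrized, which guarantees real whitened Koopman
eigenvalues.  Finite samples still produce eigenvalues outside (0, 1);
those are truncated with a warning, never an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import analytic
from .errors import DataError, ParameterError
from .mappings import LinearMapping
from .simulate import Trajectory

__all__ = [
    "CovariancePair",
    "featurize",
    "remove_cg_translation",
    "estimate_covariances",
    "vamp_score_empirical",
    "tica_timescales",
    "LinearDecoder",
    "MLPDecoder",
    "train_decoder",
    "reconstruction_error_empirical",
    "vibrational_power_empirical",
    "score_candidates_empirical",
]


@dataclass(frozen=True)
class CovariancePair:
    """Instantaneous and time-lagged feature covariance estimates."""

    c00_hat: np.ndarray
    c0tau_hat: np.ndarray
    lag_frames: int
    n_pairs: int
    feature_kind: str = ""
    reversible: bool = True


def featurize(
    trajectory: Trajectory, mapping: LinearMapping, feature_kind: str = "cg_coordinates"
) -> np.ndarray:
    """Per-frame feature vectors of the mapped trajectory.

    ``cg_coordinates``: the CG bead coordinates ``M x`` per spatial
    dimension, concatenated to (T, N*d).  ``cg_pair_distances``: all
    N(N-1)/2 Euclidean distances between CG bead positions per frame
    (translation and rotation invariant; the choice used for the model
    protein).
    """
    if mapping.n_atoms != trajectory.n_atoms:
        raise ParameterError(
            f"mapping is over {mapping.n_atoms} atoms, trajectory has "
            f"{trajectory.n_atoms}"
        )
    cg = np.einsum("Na,tad->tNd", mapping.matrix, trajectory.frames)
    if feature_kind == "cg_coordinates":
        return cg.reshape(cg.shape[0], -1)
    if feature_kind == "cg_pair_distances":
        n = mapping.n_beads
        if n < 2:
            raise ParameterError("pair distances need at least 2 beads")
        iu, ju = np.triu_indices(n, k=1)
        diff = cg[:, iu, :] - cg[:, ju, :]
        return np.sqrt(np.sum(diff**2, axis=-1))
    raise ParameterError(f"unknown feature kind {feature_kind!r}")


def remove_cg_translation(features: np.ndarray, n_beads: int) -> np.ndarray:
    """Project out the uniform (rigid-translation) component per frame.

    Applies ``Q = 1 - J J^T / N`` across the bead axis for each spatial
    dimension of concatenated ``cg_coordinates`` features, making the
    empirical covariances comparable to the translation-projected analytic
    ``C00`` and ``C0tau``.
    """
    t, f = features.shape
    if f % n_beads:
        raise ParameterError(
            f"feature width {f} is not a multiple of n_beads={n_beads}"
        )
    d = f // n_beads
    cg = features.reshape(t, n_beads, d)
    return (cg - cg.mean(axis=1, keepdims=True)).reshape(t, f)


def estimate_covariances(
    features: np.ndarray, lag_frames: int, reversible: bool = True
) -> CovariancePair:
    """Mean-free covariance and time-lagged covariance over all (t, t+lag)
    pairs.

    In reversible mode the mean and the instantaneous covariance average
    the head and tail segments and the lagged covariance is symmetrized.
    Denominators are the number of pairs (no Bessel correction; documented
    choice, irrelevant at the trajectory lengths used for scoring).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"features must be 2-D, got shape {x.shape}")
    if lag_frames < 0:
        raise ParameterError("lag_frames must be >= 0")
    n_pairs = x.shape[0] - lag_frames
    if n_pairs < 2:
        raise DataError(
            f"series of {x.shape[0]} frames too short for lag {lag_frames}"
        )
    head = x[: x.shape[0] - lag_frames]
    tail = x[lag_frames:]
    if reversible:
        mean = 0.5 * (head.mean(axis=0) + tail.mean(axis=0))
    else:
        mean = head.mean(axis=0)
    h = head - mean
    t = tail - mean
    c0t = h.T @ t / n_pairs
    if reversible:
        c00 = 0.5 * (h.T @ h + t.T @ t) / n_pairs
        c0t = 0.5 * (c0t + c0t.T)
    else:
        c00 = h.T @ h / n_pairs
    c00 = 0.5 * (c00 + c00.T)
    return CovariancePair(c00, c0t, lag_frames, n_pairs, reversible=reversible)


def vamp_score_empirical(cov: CovariancePair, rank_tolerance: float = 1e-6) -> float:
    """VAMP-2 score of estimated covariances (same formula as the analytic
    score, pseudo-inverse whitening at ``rank_tolerance``)."""
    if not np.any(np.linalg.eigvalsh(cov.c00_hat) > 0):
        raise DataError("estimated covariance has rank zero")
    return analytic.vamp_score(cov.c00_hat, cov.c0tau_hat, rank_tolerance)


def tica_timescales(
    cov: CovariancePair,
    physical_lag_time: float,
    count: int | None = None,
    rank_tolerance: float = 1e-6,
) -> np.ndarray:
    """Implied timescales ``-tau / ln nu_i`` from estimated covariances.

    ``nu_i`` are the whitened (TICA / Koopman) eigenvalues; estimates
    outside (0, 1) are dropped with a warning, as finite-sample noise
    routinely produces them.
    """
    nu = analytic.koopman_eigenvalues(cov.c00_hat, cov.c0tau_hat, rank_tolerance)
    valid = (nu > 0.0) & (nu < 1.0)
    if not np.all(valid):
        warnings.warn(
            f"dropped {int(np.sum(~valid))} estimated eigenvalues outside (0, 1)",
            stacklevel=2,
        )
    times = np.sort(-physical_lag_time / np.log(nu[valid]))[::-1]
    if count is not None:
        if count > times.shape[0]:
            raise ParameterError(
                f"requested {count} timescales, only {times.shape[0]} available"
            )
        times = times[:count]
    return times


class LinearDecoder:
    """Closed-form least-squares reconstruction ``x_hat = A X + b``.

    The exact ridge-free solution; for Gaussian data this converges to the
    conditional-mean decoder, whose error the analytic Gaussian
    reconstruction error states in closed form.
    """

    def __init__(self, weights: np.ndarray, intercept: np.ndarray, train_span, source):
        self.weights = weights
        self.intercept = intercept
        self.train_span = train_span  # (start, stop) frame range used
        self.source = source  # id of the training trajectory

    def predict(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights.T + self.intercept


class MLPDecoder:
    """Small feed-forward decoder (two hidden layers of width 64).

    A documented, reproducible default: fixed architecture, seed and epoch
    budget.  Trained on the same MSE loss the reconstruction error reports.
    """

    def __init__(self, model, train_span, source):
        self.model = model
        self.train_span = train_span
        self.source = source

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(features)


def _flat_frames(trajectory: Trajectory) -> np.ndarray:
    return trajectory.frames.reshape(trajectory.n_frames, -1)


def train_decoder(
    trajectory: Trajectory,
    mapping: LinearMapping,
    decoder_kind: str = "linear",
    seed: int = 0,
    budget: int = 200,
    train_fraction: float = 0.8,
):
    """Train a decoder from CG features back to fine-grained coordinates.

    The encoder is fixed to the CG map; training uses the first
    ``train_fraction`` of the frames as one contiguous block (no random
    split, to avoid temporal leakage into held-out evaluation).
    """
    x = _flat_frames(trajectory)
    feats = featurize(trajectory, mapping, "cg_coordinates")
    stop = int(trajectory.n_frames * train_fraction)
    if stop < 2:
        raise DataError("not enough frames to train a decoder")
    span = (0, stop)
    source = id(trajectory)
    xt, ft = x[:stop], feats[:stop]
    if decoder_kind == "linear":
        fm = ft.mean(axis=0)
        xm = xt.mean(axis=0)
        w, *_ = np.linalg.lstsq(ft - fm, xt - xm, rcond=None)
        return LinearDecoder(w.T, xm - fm @ w, span, source)
    if decoder_kind == "nonlinear":
        if budget < 1:
            raise ParameterError("nonlinear decoder needs a positive epoch budget")
        from sklearn.neural_network import MLPRegressor

        model = MLPRegressor(
            hidden_layer_sizes=(64, 64),
            activation="relu",
            solver="adam",
            max_iter=budget,
            random_state=seed,
            tol=0.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at fixed budget
            model.fit(ft, xt)
        return MLPDecoder(model, span, source)
    raise ParameterError(f"unknown decoder kind {decoder_kind!r}")


def reconstruction_error_empirical(
    decoder,
    held_out_trajectory: Trajectory,
    mapping: LinearMapping,
    frame_range=None,
) -> float:
    """Held-out mean-square reconstruction error per atom.

    Mean over frames and atoms of the squared deviation between original
    and reconstructed coordinates (summed over spatial dimensions).  If the
    evaluation frames come from the decoder's own training trajectory, they
    must not overlap the training block.
    """
    t = held_out_trajectory.n_frames
    if frame_range is None:
        if id(held_out_trajectory) == decoder.source:
            frame_range = (decoder.train_span[1], t)
        else:
            frame_range = (0, t)
    start, stop = frame_range
    if id(held_out_trajectory) == decoder.source:
        if start < decoder.train_span[1] and stop > decoder.train_span[0]:
            raise DataError(
                f"evaluation frames [{start}, {stop}) overlap the training "
                f"block {decoder.train_span}"
            )
    if stop - start < 1:
        raise DataError("empty evaluation frame range")
    x = _flat_frames(held_out_trajectory)[start:stop]
    feats = featurize(held_out_trajectory, mapping, "cg_coordinates")[start:stop]
    resid = x - decoder.predict(feats)
    # mean over frames and atoms; squared residual summed over dimensions
    return float(np.mean(np.sum(resid**2, axis=1)) / held_out_trajectory.n_atoms)


def vibrational_power_empirical(
    trajectory: Trajectory, mapping: LinearMapping
) -> float:
    """Sum of per-bead sample variances of the mapped coordinates."""
    feats = featurize(trajectory, mapping, "cg_coordinates")
    return float(np.sum(np.var(feats, axis=0)))


def score_candidates_empirical(
    trajectory: Trajectory,
    candidates,
    lag_frames: int,
    feature_kind: str = "cg_coordinates",
    reversible: bool = True,
):
    """VAMP-2 score and vibrational power of each candidate mapping.

    For ``cg_coordinates`` the VAMP covariances are computed on
    translation-projected features so they estimate the analytic projected
    ``C00``/``C0tau``; the vibrational power uses the raw mapped
    coordinates.  Returns a list of ``(mapping, vamp, vp)`` rows in
    candidate order.
    """
    rows = []
    for mapping in candidates:
        feats = featurize(trajectory, mapping, feature_kind)
        vp = vibrational_power_empirical(trajectory, mapping)
        if feature_kind == "cg_coordinates":
            proj = remove_cg_translation(feats, mapping.n_beads)
        else:
            proj = feats
        cov = estimate_covariances(proj, lag_frames, reversible)
        rows.append((mapping, vamp_score_empirical(cov), vp))
    return rows
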