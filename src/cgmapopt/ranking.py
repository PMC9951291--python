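"""Sweep candidate mapping spaces, report optima and timescale recovery.

The sweep streams through a candidate iterator, scores every mapping with
the requested metrics (analytic on a harmonic system, or empirical on a
trajectory), tracks per-metric optima with deterministic tie-breaking, and
optionally writes rows to a tab-separated table as it goes so that sweeps
over tens of thousands of candidates run in constant memory.

Optimization direction: VAMP-2, mapping entropy and vibrational power are
maximized; the reconstruction error is minimized.  Ties within a relative
tolerance of 1e-9 are broken toward the lexicographically first mapping
(several of the 4-bead optima are exact analytic ties, e.g. slicing the
first two versus the last two beads of a symmetric chain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import AnalyticScorer, analytic_timescales, default_lag_time
from .errors import ConfigurationError, ParameterError
from .harmonic import HarmonicSystem
from .mappings import block_map, identity_map  # noqa: F401  (block_map re-exported)
from .simulate import Trajectory

__all__ = [
    "ScoreReport",
    "sweep",
    "timescale_comparison",
    "block_map",
    "read_score_table",
]

#: metrics maximized (True) or minimized (False) by "optimal"
_DIRECTIONS = {"vamp": True, "smap": True, "vp": True, "re": False}
_TIE_RTOL = 1e-9


@dataclass
class ScoreReport:
    """Result of a sweep: one row per mapping plus per-metric optima.

    ``rows`` is a list of dicts with keys ``mapping`` (canonical label),
    ``groups``, the metric values and ``t1..tk`` implied timescales when
    requested.  ``optima`` maps metric name to ``(label, value)``;
    ``provenance`` records enough settings to re-run the sweep.
    """

    rows: list = field(default_factory=list)
    optima: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    n_candidates: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def best(self, metric: str) -> str:
        """Canonical label of the optimal mapping for ``metric``."""
        return self.optima[metric][0]

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = str(path) + ".provenance.json"
        with open(sidecar, "w") as handle:
            json.dump(
                {"provenance": self.provenance, "optima": self.optima}, handle, indent=1
            )

    def summary(self) -> str:
        lines = [f"swept {self.n_candidates} candidate mappings"]
        for metric, (label, value) in sorted(self.optima.items()):
            direction = "max" if _DIRECTIONS[metric] else "min"
            lines.append(f"  {metric:>4s} ({direction}): {label}  value={value:.6g}")
        return "\n".join(lines)


def read_score_table(path) -> pd.DataFrame:
    """Re-read a sweep table written by :meth:`ScoreReport.write_tsv`."""
    return pd.read_csv(path, sep="\t")


class _Optimum:
    def __init__(self, maximize):
        self.maximize = maximize
        self.value = None
        self.groups = None
        self.label = None

    def offer(self, value, groups, label):
        if self.value is None:
            better = True
        else:
            tol = _TIE_RTOL * max(abs(value), abs(self.value), 1e-300)
            delta = value - self.value if self.maximize else self.value - value
            if delta > tol:
                better = True
            elif delta >= -tol:  # tie: lexicographically first mapping wins
                better = groups < self.groups
            else:
                better = False
        if better:
            self.value, self.groups, self.label = value, groups, label


def sweep(
    candidates,
    system: HarmonicSystem | None = None,
    trajectory: Trajectory | None = None,
    metrics=("vamp", "smap", "vp", "re"),
    tau: float | None = None,
    lag_frames: int | None = None,
    timescale_count: int | None = None,
    out=None,
    keep_rows: bool = True,
    feature_kind: str = "cg_coordinates",
) -> ScoreReport:
    """Score every candidate mapping and record per-metric optima.

    Analytic metrics (all four) need ``system``; empirical scoring needs
    ``trajectory`` and ``lag_frames`` and supports ``vamp`` and ``vp``.
    With ``out`` set, rows stream to a TSV file as they are computed; with
    ``keep_rows=False`` they are not retained in memory, so arbitrarily
    large candidate spaces sweep in constant memory.
    """
    metrics = tuple(metrics)
    unknown = set(metrics) - set(_DIRECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown metrics {sorted(unknown)}")
    if (system is None) == (trajectory is None):
        raise ConfigurationError("provide exactly one of system or trajectory")
    if trajectory is not None:
        bad = set(metrics) - {"vamp", "vp"}
        if bad:
            raise ConfigurationError(
                f"metrics {sorted(bad)} need an analytic system, not a trajectory"
            )
        if lag_frames is None:
            raise ConfigurationError("empirical sweep needs lag_frames")

    report = ScoreReport()
    optima = {m: _Optimum(_DIRECTIONS[m]) for m in metrics}
    handle = open(out, "w") if out is not None else None
    wrote_header = False
    scorer = AnalyticScorer(system, tau) if system is not None else None
    try:
        for mapping in candidates:
            row = {"mapping": mapping.label, "groups": str(mapping.groups)}
            if scorer is not None:
                if timescale_count is not None:
                    ms, times = scorer.score(mapping, timescale_count)
                    for i, t in enumerate(times, 1):
                        row[f"t{i}"] = t
                else:
                    ms = scorer.score(mapping)
                values = {
                    "vamp": ms.vamp,
                    "smap": ms.smap,
                    "vp": ms.vibrational_power,
                    "re": ms.reconstruction_error,
                }
            else:
                from .empirical import score_candidates_empirical

                (_m, vamp, vp), = score_candidates_empirical(
                    trajectory, [mapping], lag_frames, feature_kind
                )
                values = {"vamp": vamp, "vp": vp}
            for m in metrics:
                row[m] = values[m]
                optima[m].offer(values[m], mapping.groups, mapping.label)
            report.n_candidates += 1
            if handle is not None:
                if not wrote_header:
                    handle.write("\t".join(row) + "\n")
                    wrote_header = True
                handle.write(
                    "\t".join(
                        f"{v:.12g}" if isinstance(v, float) else str(v)
                        for v in row.values()
                    )
                    + "\n"
                )
            if keep_rows:
                report.rows.append(row)
    finally:
        if handle is not None:
            handle.close()
    report.optima = {m: (o.label, o.value) for m, o in optima.items()}
    report.provenance = {
        "metrics": list(metrics),
        "tau": scorer.tau if scorer is not None else None,
        "lag_frames": lag_frames,
        "n_candidates": report.n_candidates,
        "input": "system" if system is not None else "trajectory",
        "tie_breaking": f"lexicographic within rtol {_TIE_RTOL}",
    }
    return report


def timescale_comparison(
    system: HarmonicSystem,
    mappings,
    count: int,
    tau: float | None = None,
) -> pd.DataFrame:
    """Slowest implied timescales of each mapping against the full model.

    Returns a tidy frame with one row per (mapping, timescale index):
    the CG estimate, the full-resolution reference ``gamma / lambda_i``
    and the relative error.  ``count`` may not exceed ``N - 1`` for
    N-bead mappings (a CG model with N beads has N - 1 relaxation modes).
    """
    if tau is None:
        tau = default_lag_time(system)
    mappings = list(mappings)
    for m in mappings:
        if count > m.n_beads - 1:
            raise ParameterError(
                f"count={count} exceeds N-1={m.n_beads - 1} for mapping "
                f"{m.label!r}: an N-bead CG model has at most N-1 timescales"
            )
    reference = analytic_timescales(system, identity_map(system.n), tau, count)
    records = []
    for m in mappings:
        times = analytic_timescales(system, m, tau, count)
        for i in range(count):
            records.append(
                {
                    "mapping": m.label,
                    "index": i + 1,
                    "timescale": times[i],
                    "reference": reference[i],
                    "rel_error": abs(times[i] - reference[i]) / reference[i],
                }
            )
    return pd.DataFrame(records)
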