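"""Pulling-work analysis: binned work/PMF profiles, barriers, rate factors.

An ensemble of steered-pulling work traces is reduced to a binned profile
W(z) of the restraint-center coordinate with three estimators per bin:

* ``mean_work`` — ⟨W⟩ with its standard error;
* ``jarzynski`` — the exponential-average free-energy estimate
  −kB·T·ln⟨e^(−W/kB·T)⟩, a lower bound on ⟨W⟩ by Jensen's inequality;
* ``cumulant2`` — the second-order cumulant expansion ⟨W⟩ − β·Var(W)/2,
  exact for Gaussian work distributions.

Work is binned by restraint center (the protocol variable), traces are
anchored to zero at the first bin they cover, and barrier differences can be
converted to Boltzmann rate-slowdown factors e^(−ΔΔW/kB·T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB, DEFAULT_TEMPERATURE, kt as _kt
from .exceptions import ProfileGapError, QtrapError, TableParseError
from .io_tables import WorkTrace

__all__ = [
    "PmfProfile",
    "BarrierEstimate",
    "recompute_work",
    "work_profile",
    "barrier_delta",
    "rate_slowdown",
    "PullingWorkModel",
    "WorkProfileResults",
]

ESTIMATORS = ("mean_work", "jarzynski", "cumulant2")


@dataclass
class PmfProfile:
    """A binned work/PMF profile over the restraint-center coordinate."""

    bin_centers: np.ndarray          # Å, uniform spacing
    mean_work: np.ndarray            # kcal/mol
    jarzynski: np.ndarray            # kcal/mol
    cumulant2: np.ndarray            # kcal/mol
    sem_mean: np.ndarray             # standard error of mean_work, kcal/mol
    n_contributing: np.ndarray       # traces per bin
    temperature: float               # K used for β
    bin_width: float                 # Å

    def estimator(self, name: str) -> np.ndarray:
        if name not in ESTIMATORS:
            raise QtrapError(f"unknown estimator {name!r}; choose from {ESTIMATORS}")
        return getattr(self, name)

    def in_kt(self, name: str, temperature: float | None = None) -> np.ndarray:
        """Profile in thermal units at *temperature* (default: profile's own)."""
        return self.estimator(name) / _kt(temperature or self.temperature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_A": self.bin_centers,
                "mean_work_kcal": self.mean_work,
                "jarzynski_kcal": self.jarzynski,
                "cumulant2_kcal": self.cumulant2,
                "sem_mean_kcal": self.sem_mean,
                "n_contributing": self.n_contributing,
            }
        )


@dataclass
class BarrierEstimate:
    """A (difference of) barrier height(s) over a coordinate interval."""

    interval: tuple[float, float]    # Å
    delta_w_kcal: float
    delta_w_kt: float
    estimator: str
    temperature: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def recompute_work(trace: WorkTrace, spring_k: float,
                   deviation_tol: float = 0.02) -> WorkTrace:
    """Recompute accumulated work from the stored schedule and coordinate.

    Uses the stiff-spring rule W_i = W_{i−1} + k·(c_i − x_{i−1})·(c_i − c_{i−1})
    (position from before each restraint step), the same bookkeeping as the
    synthetic pulling simulator.  Warns if the recomputed endpoint deviates
    from the stored work column by more than *deviation_tol* (relative).
    """
    c = trace.restraint_center
    if np.any(np.diff(c) < 0):
        raise TableParseError(f"trace {trace.traj_id!r}: non-monotone schedule")
    x = trace.coordinate
    dc = np.diff(c)
    increments = spring_k * (c[1:] - x[:-1]) * dc
    w = np.concatenate([[0.0], np.cumsum(increments)])
    stored_end = trace.accumulated_work[-1]
    scale = max(abs(stored_end), abs(w[-1]), 1e-12)
    if abs(w[-1] - stored_end) / scale > deviation_tol:
        warnings.warn(
            f"trace {trace.traj_id!r}: recomputed endpoint work {w[-1]:.6g} "
            f"deviates from stored {stored_end:.6g} by more than "
            f"{deviation_tol:.0%}",
            stacklevel=2,
        )
    return WorkTrace(trace.traj_id, trace.time.copy(), c.copy(), x.copy(), w)


def _strictly_increasing(c: np.ndarray, w: np.ndarray):
    """Collapse flat schedule segments, keeping the last sample of each."""
    keep = np.concatenate([c[1:] > c[:-1], [True]])
    return c[keep], w[keep]


def work_profile(traces: Sequence[WorkTrace], bin_width: float = 0.1,
                 temperature: float = DEFAULT_TEMPERATURE) -> PmfProfile:
    """Bin an ensemble of work traces by restraint center.

    Each trace's work curve is interpolated onto a uniform grid of bin
    centers (spacing *bin_width*, default 0.1 Å) and anchored to zero at the
    first bin it covers; per-bin statistics are then taken across traces.
    Raises :class:`ProfileGapError` if an interior bin receives no data.
    """
    if not traces:
        raise QtrapError("work_profile needs at least one trace")
    beta = 1.0 / _kt(temperature)
    c_lo = min(tr.restraint_center[0] for tr in traces)
    c_hi = max(tr.restraint_center[-1] for tr in traces)
    n_bins = int(np.floor((c_hi - c_lo) / bin_width + 1e-9)) + 1
    centers = c_lo + bin_width * np.arange(n_bins)

    values = np.full((len(traces), n_bins), np.nan)
    for i, tr in enumerate(traces):
        c, w = _strictly_increasing(tr.restraint_center, tr.accumulated_work)
        lo, hi = tr.restraint_center[0], tr.restraint_center[-1]
        covered = (centers >= lo - 1e-9) & (centers <= hi + 1e-9)
        if not covered.any():
            continue
        interp = np.interp(centers[covered], c, w)
        values[i, covered] = interp - interp[0]  # per-trace anchoring

    n_contrib = np.sum(~np.isnan(values), axis=0)
    if n_contrib[0] == 0 or n_contrib[-1] == 0:
        # trim empty edge bins introduced by rounding
        good = np.nonzero(n_contrib)[0]
        centers = centers[good[0]:good[-1] + 1]
        values = values[:, good[0]:good[-1] + 1]
        n_contrib = n_contrib[good[0]:good[-1] + 1]
    empty = np.nonzero(n_contrib == 0)[0]
    if empty.size:
        raise ProfileGapError(
            f"interior bins with no contributing trace at centers "
            f"{centers[empty][:10].round(4).tolist()}",
            bins=centers[empty],
        )

    mean = np.nanmean(values, axis=0)
    var = np.zeros_like(mean)
    sem = np.zeros_like(mean)
    jarz = np.empty_like(mean)
    for j in range(values.shape[1]):
        col = values[~np.isnan(values[:, j]), j]
        if col.size > 1:
            var[j] = np.var(col, ddof=1)
            sem[j] = np.sqrt(var[j] / col.size)
        jarz[j] = -(logsumexp(-beta * col) - np.log(col.size)) / beta
    cum2 = mean - beta * var / 2.0
    return PmfProfile(centers, mean, jarz, cum2, sem, n_contrib,
                      temperature, bin_width)


def _span(profile: PmfProfile, interval: tuple[float, float],
          estimator: str) -> float:
    z_lo, z_hi = interval
    if z_lo >= z_hi:
        raise QtrapError(f"interval must have z_lo < z_hi, got {interval}")
    c = profile.bin_centers
    if z_lo < c[0] - 1e-9 or z_hi > c[-1] + 1e-9:
        raise QtrapError(
            f"interval {interval} outside profile range ({c[0]:.4g}, {c[-1]:.4g})"
        )
    sel = (c >= z_lo - 1e-9) & (c <= z_hi + 1e-9)
    vals = profile.estimator(estimator)[sel]
    return float(vals.max() - vals.min())


def barrier_delta(profile_a: PmfProfile, profile_b: PmfProfile,
                  interval: tuple[float, float], estimator: str = "mean_work",
                  temperature: float | None = None) -> BarrierEstimate:
    """Barrier-height difference ΔΔW = span_b − span_a over *interval*.

    ``span`` is max − min of the chosen estimator within the interval.
    Reported in kcal/mol and in kT at *temperature* (default: profile_a's
    simulation temperature; pass 298 to quote "room temperature" kT).
    """
    temp = temperature or profile_a.temperature
    delta = _span(profile_b, interval, estimator) - _span(profile_a, interval, estimator)
    return BarrierEstimate(tuple(interval), delta, delta / _kt(temp),
                           estimator, temp)


def rate_slowdown(delta_barrier_kt: float) -> float:
    """Boltzmann rate factor e^(−ΔΔW) for a barrier difference given in kT.

    A 20 kT extra barrier gives ≈ 2.06 × 10⁻⁹; 0 maps to exactly 1.
    """
    if not np.isfinite(delta_barrier_kt):
        raise QtrapError(f"barrier difference must be finite, got {delta_barrier_kt}")
    return float(np.exp(-delta_barrier_kt))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class PullingWorkModel:
    """Work-profile model over an ensemble of pulling trajectories.

    Parameters
    ----------
    traces : sequence of WorkTrace
    temperature : K, used for β in the Jarzynski and cumulant estimators.
    spring_k : optional restraint stiffness; when given, every trace's work
        column is validated (and replaced) by :func:`recompute_work` before
        fitting.
    """

    def __init__(self, traces: Iterable[WorkTrace],
                 temperature: float = DEFAULT_TEMPERATURE,
                 spring_k: float | None = None):
        traces = list(traces)
        if spring_k is not None:
            traces = [recompute_work(tr, spring_k) for tr in traces]
        self.traces = traces
        self.temperature = temperature

    def fit(self, bin_width: float = 0.1) -> "WorkProfileResults":
        profile = work_profile(self.traces, bin_width=bin_width,
                               temperature=self.temperature)
        return WorkProfileResults(self, profile)


class WorkProfileResults:
    """Fitted work profile with barrier and rate diagnostics."""

    def __init__(self, model: PullingWorkModel, profile: PmfProfile):
        self.model = model
        self.profile = profile

    def barrier(self, interval: tuple[float, float],
                estimator: str = "mean_work",
                temperature: float | None = None) -> BarrierEstimate:
        """Barrier height (max − min of *estimator*) within *interval*."""
        temp = temperature or self.profile.temperature
        span = _span(self.profile, interval, estimator)
        return BarrierEstimate(tuple(interval), span, span / _kt(temp),
                               estimator, temp)

    def barrier_delta_vs(self, other: "WorkProfileResults",
                         interval: tuple[float, float],
                         estimator: str = "mean_work",
                         temperature: float | None = None) -> BarrierEstimate:
        """ΔΔW of *other* relative to this profile over *interval*."""
        return barrier_delta(self.profile, other.profile, interval,
                             estimator, temperature)

    def to_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary(self) -> str:
        p = self.profile
        lines = [
            "Pulling work profile",
            "====================",
            f"traces:        {len(self.model.traces)}",
            f"bins:          {len(p.bin_centers)} × {p.bin_width:g} Å "
            f"({p.bin_centers[0]:.3f} – {p.bin_centers[-1]:.3f} Å)",
            f"temperature:   {p.temperature:g} K (kT = {_kt(p.temperature):.4f} kcal/mol)",
            "",
            "endpoint estimates (kcal/mol | kT):",
        ]
        for name in ESTIMATORS:
            v = p.estimator(name)[-1]
            lines.append(f"  {name:<10s} {v:10.4f} | {v / _kt(p.temperature):8.3f}")
        se = p.sem_mean[-1]
        lines.append(f"  sem(mean)  {se:10.4f}")
        return "\n".join(lines)
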