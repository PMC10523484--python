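"""Alchemical free-energy estimation and thermodynamic-cycle composition.

Per-window free energies are estimated with Bennett's acceptance ratio
(BAR), the minimum-variance two-state estimator, defined by the
self-consistent condition

    Σ_F f(β(ΔU_F − C)) = Σ_R f(β(C − ΔU_R)),   f(x) = 1/(1 + e^x),

where ΔU = U(λ_to) − U(λ_from) in both ensembles (one sign convention), and
ΔG = C + kB·T·ln(n_F/n_R).  The equation's left side is strictly increasing
and its right side strictly decreasing in C, so a bracketed bisection always
converges.  One-sided exponential averaging (Zwanzig) is provided as the
fallback/cross-check estimator.

Window estimates compose across the λ schedule into leg totals, two legs
(mutation with the ligand unbound / bound) close the relative-binding
thermodynamic cycle ΔΔG_bind = ΔG_mut^unbound − ΔG_mut^bound, and frozen
endpoint ensembles are corrected with a k-nearest-neighbor configurational
density estimate (fourth neighbor by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln, logsumexp

from .constants import KB, DEFAULT_TEMPERATURE, kt as _kt
from .exceptions import LambdaCoverageError, QtrapError
from .io_tables import FepWindowSamples

__all__ = [
    "BarEstimate",
    "ComposedFreeEnergy",
    "CycleResult",
    "KnnCorrection",
    "zwanzig_dg",
    "bar_dg",
    "compose_windows",
    "ddg_cycle",
    "knn_density",
    "knn_correction",
    "AlchemicalCycleModel",
    "CycleResults",
]


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class BarEstimate:
    """BAR estimate for one window."""

    delta_g: float               # kcal/mol
    stderr: float                # kcal/mol, asymptotic
    iterations: int
    converged: bool
    lambda_from: float | None = None
    lambda_to: float | None = None


@dataclass
class ComposedFreeEnergy:
    """A leg total: summed window ΔGs with quadrature stderr."""

    delta_g: float
    stderr: float
    hysteresis: float | None     # |forward-only − reverse-only| composition
    per_window: list[BarEstimate] = field(default_factory=list)


@dataclass
class CycleResult:
    """The composed relative-binding thermodynamic cycle.

    Sign convention: positive ``ddg_bind`` means the mutant binds the ligand
    less strongly than the wild type.
    """

    dg_mut_unbound: float
    dg_mut_bound: float
    ddg_bind: float
    stderr: float = 0.0
    hysteresis_unbound: float | None = None
    hysteresis_bound: float | None = None
    per_window_unbound: list[dict] = field(default_factory=list)
    per_window_bound: list[dict] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "CycleResult":
        return cls(**d)


@dataclass
class KnnCorrection:
    """Frozen-endpoint density correction from k-nearest-neighbor distances."""

    k: int
    dimension: int
    density_a: float
    density_b: float
    correction: float            # kcal/mol, −kB·T·ln(ρ̂_a/ρ̂_b)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def zwanzig_dg(samples: Sequence[float],
               temperature: float = DEFAULT_TEMPERATURE) -> float:
    """One-sided exponential-averaging estimate −kB·T·ln⟨e^(−βΔU)⟩."""
    du = np.asarray(samples, dtype=float)
    if du.size == 0:
        raise QtrapError("zwanzig_dg needs at least one sample")
    kt = _kt(temperature)
    return float(-kt * (logsumexp(-du / kt) - math.log(du.size)))


def _reverse_zwanzig_dg(reverse_du: np.ndarray, temperature: float) -> float:
    """ΔG(from→to) estimated from the λ_to ensemble: +kB·T·ln⟨e^(+βΔU)⟩."""
    kt = _kt(temperature)
    return float(kt * (logsumexp(reverse_du / kt) - math.log(len(reverse_du))))


def bar_dg(window: FepWindowSamples, temperature: float = DEFAULT_TEMPERATURE,
           tolerance: float = 1e-8, max_iter: int = 1000) -> BarEstimate:
    """Bennett acceptance-ratio estimate for one window.

    Bisection on the self-consistent equation, bracketed by the forward and
    reverse Zwanzig estimates and expanded geometrically until the residual
    changes sign.  The asymptotic standard error uses Bennett's variance
    expression; when the two ensembles share no overlap the variance
    diverges and the estimate is returned with ``converged=False``.
    """
    fwd = np.asarray(window.forward_du, dtype=float)
    rev = np.asarray(window.reverse_du, dtype=float)
    if fwd.size == 0:
        raise QtrapError("bar_dg needs forward samples")
    if rev.size == 0:
        raise QtrapError(
            "bar_dg needs reverse samples; use zwanzig_dg for one-sided data"
        )
    kt = _kt(temperature)
    beta = 1.0 / kt
    n_f, n_r = fwd.size, rev.size
    log_ratio = math.log(n_f / n_r)

    def residual(c: float) -> float:
        # increasing in c: expit(-x) = 1/(1+e^x)
        return float(
            expit(-beta * (fwd - c)).sum() - expit(-beta * (c - rev)).sum()
        )

    g_f = zwanzig_dg(fwd, temperature)
    g_r = _reverse_zwanzig_dg(rev, temperature)
    lo, hi = min(g_f, g_r) - kt, max(g_f, g_r) + kt
    span = hi - lo
    iterations = 0
    while residual(lo) > 0 and iterations < max_iter:
        lo -= span
        span *= 2.0
        iterations += 1
    while residual(hi) < 0 and iterations < max_iter:
        hi += span
        span *= 2.0
        iterations += 1
    while hi - lo > tolerance and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
        iterations += 1
    c = 0.5 * (lo + hi)
    delta_g = c + kt * log_ratio
    converged = (hi - lo) <= tolerance

    f_f = expit(-beta * (fwd - c))
    f_r = expit(-beta * (c - rev))
    with np.errstate(divide="ignore", invalid="ignore"):
        var = kt ** 2 * (
            (np.mean(f_f ** 2) / np.mean(f_f) ** 2 - 1.0) / n_f
            + (np.mean(f_r ** 2) / np.mean(f_r) ** 2 - 1.0) / n_r
        )
    # mean Fermi weight at the solution ≈ the ensemble-overlap integral;
    # ~1e-1 for usable windows, collapses to ~0 for disjoint distributions
    overlap = 0.5 * (float(np.mean(f_f)) + float(np.mean(f_r)))
    if not np.isfinite(var) or overlap < 1e-6:
        warnings.warn(
            f"window ({window.lambda_from}, {window.lambda_to}): no forward/"
            "reverse overlap, BAR variance diverges", stacklevel=2,
        )
        return BarEstimate(delta_g, float("inf"), iterations, False,
                           window.lambda_from, window.lambda_to)
    return BarEstimate(delta_g, float(math.sqrt(max(var, 0.0))), iterations,
                       converged, window.lambda_from, window.lambda_to)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _check_tiling(windows: Sequence[FepWindowSamples], tol: float = 1e-9):
    ordered = sorted(windows, key=lambda w: w.lambda_from)
    if abs(ordered[0].lambda_from) > tol:
        raise LambdaCoverageError(
            f"λ coverage gap: (0, {ordered[0].lambda_from}) is uncovered"
        )
    for a, b in zip(ordered, ordered[1:]):
        if abs(a.lambda_to - b.lambda_from) > tol:
            kind = "gap" if a.lambda_to < b.lambda_from else "overlap"
            raise LambdaCoverageError(
                f"λ coverage {kind}: ({a.lambda_to}, {b.lambda_from})"
            )
    if abs(ordered[-1].lambda_to - 1.0) > tol:
        raise LambdaCoverageError(
            f"λ coverage gap: ({ordered[-1].lambda_to}, 1) is uncovered"
        )
    return ordered


def compose_windows(estimates: Sequence[BarEstimate],
                    windows: Sequence[FepWindowSamples],
                    temperature: float = DEFAULT_TEMPERATURE,
                    ) -> ComposedFreeEnergy:
    """Sum per-window estimates into a leg total.

    The windows must tile [0, 1] without gap or overlap.  Standard errors
    combine in quadrature.  When every window carries both directions, the
    hysteresis |ΔG(forward-only) − ΔG(reverse-only)| of the one-sided
    compositions is reported as a convergence diagnostic.
    """
    if len(estimates) != len(windows):
        raise QtrapError(
            f"{len(estimates)} estimates for {len(windows)} windows"
        )
    ordered = _check_tiling(windows)
    est_sorted = sorted(estimates, key=lambda e: (e.lambda_from if e.lambda_from
                                                  is not None else 0.0))
    total = float(sum(e.delta_g for e in est_sorted))
    stderr = float(math.sqrt(sum(e.stderr ** 2 for e in est_sorted)))
    hysteresis = None
    if all(w.reverse_du.size for w in ordered):
        fwd_total = sum(zwanzig_dg(w.forward_du, temperature) for w in ordered)
        rev_total = sum(_reverse_zwanzig_dg(w.reverse_du, temperature)
                        for w in ordered)
        hysteresis = abs(fwd_total - rev_total)
    return ComposedFreeEnergy(total, stderr, hysteresis, list(est_sorted))


def ddg_cycle(dg_mut_unbound: float, dg_mut_bound: float,
              stderr_unbound: float = 0.0, stderr_bound: float = 0.0,
              hysteresis_unbound: float | None = None,
              hysteresis_bound: float | None = None,
              per_window_unbound: Sequence[dict] = (),
              per_window_bound: Sequence[dict] = ()) -> CycleResult:
    """Close the thermodynamic cycle: ΔΔG_bind = ΔG_mut^unbound − ΔG_mut^bound.

    Positive ΔΔG_bind means the mutant binds the ligand less strongly.
    """
    for leg, name in ((dg_mut_unbound, "dg_mut_unbound"),
                      (dg_mut_bound, "dg_mut_bound")):
        if not np.isfinite(leg):
            raise QtrapError(f"{name} must be finite, got {leg}")
    return CycleResult(
        dg_mut_unbound=float(dg_mut_unbound),
        dg_mut_bound=float(dg_mut_bound),
        ddg_bind=float(dg_mut_unbound - dg_mut_bound),
        stderr=float(math.hypot(stderr_unbound, stderr_bound)),
        hysteresis_unbound=hysteresis_unbound,
        hysteresis_bound=hysteresis_bound,
        per_window_unbound=list(per_window_unbound),
        per_window_bound=list(per_window_bound),
    )


# ---------------------------------------------------------------------------
# kNN endpoint corrections
# ---------------------------------------------------------------------------

def _log_ball_volume(dimension: int) -> float:
    """ln of the unit d-ball volume π^(d/2)/Γ(d/2 + 1)."""
    return 0.5 * dimension * math.log(math.pi) - gammaln(dimension / 2.0 + 1.0)


def knn_density(distances: Sequence[float], k: int = 4, *,
                dimension: int) -> float:
    """Configurational density at a reference point from k-NN distances.

    *distances* are the scalar distances of n sampled configurations from
    the reference structure.  The estimate uses the k-th smallest distance
    r_k and the d-ball volume, with the log-unbiased normalization
    ρ̂ = e^{ψ(k)} / (n · V_d(r_k)), ψ the digamma function — the estimator
    whose logarithm is asymptotically unbiased, appropriate because the
    correction enters as −kB·T·ln ρ̂.
    """
    r = np.asarray(distances, dtype=float)
    if k < 1:
        raise QtrapError(f"k must be ≥ 1, got {k}")
    if r.size <= k:
        raise QtrapError(f"need more than k={k} samples, got {r.size}")
    if np.any(r < 0):
        raise QtrapError("distances must be nonnegative")
    r_k = float(np.partition(r, k - 1)[k - 1])
    if r_k == 0.0:
        raise QtrapError("k-th neighbor distance is zero (duplicate reference samples)")
    log_rho = (digamma(k) - math.log(r.size)
               - _log_ball_volume(dimension) - dimension * math.log(r_k))
    return float(math.exp(log_rho))


def knn_correction(endpoint_a_distances: Sequence[float],
                   endpoint_b_distances: Sequence[float], k: int = 4, *,
                   dimension: int,
                   temperature: float = DEFAULT_TEMPERATURE) -> KnnCorrection:
    """Free-energy correction −kB·T·ln(ρ̂_a/ρ̂_b) between two frozen endpoints.

    Each argument holds distances-from-frozen-reference of one endpoint
    ensemble.  The default k = 4 uses the fourth nearest neighbor.  The
    normalization constant cancels in the ratio, so the correction is
    exactly 0 for identical sample lists.
    """
    rho_a = knn_density(endpoint_a_distances, k=k, dimension=dimension)
    rho_b = knn_density(endpoint_b_distances, k=k, dimension=dimension)
    corr = -_kt(temperature) * math.log(rho_a / rho_b)
    if not np.isfinite(corr):
        raise QtrapError("kNN correction is not finite")
    return KnnCorrection(k, dimension, rho_a, rho_b, float(corr))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class AlchemicalCycleModel:
    """Relative-binding cycle built from two alchemical legs.

    Parameters
    ----------
    unbound_windows, bound_windows : window samples for the mutation leg
        with the ligand absent / present.
    temperature : K.
    correction_unbound, correction_bound : additive endpoint corrections
        (kcal/mol) for each leg, e.g. from :func:`knn_correction`.
    """

    def __init__(self, unbound_windows: Sequence[FepWindowSamples],
                 bound_windows: Sequence[FepWindowSamples],
                 temperature: float = DEFAULT_TEMPERATURE,
                 correction_unbound: float = 0.0,
                 correction_bound: float = 0.0):
        self.unbound_windows = list(unbound_windows)
        self.bound_windows = list(bound_windows)
        self.temperature = temperature
        self.correction_unbound = correction_unbound
        self.correction_bound = correction_bound

    def _fit_leg(self, windows):
        estimates = [bar_dg(w, self.temperature) for w in windows]
        return compose_windows(estimates, windows, self.temperature)

    def fit(self) -> "CycleResults":
        leg_u = self._fit_leg(self.unbound_windows)
        leg_b = self._fit_leg(self.bound_windows)
        record = ddg_cycle(
            leg_u.delta_g + self.correction_unbound,
            leg_b.delta_g + self.correction_bound,
            leg_u.stderr, leg_b.stderr,
            leg_u.hysteresis, leg_b.hysteresis,
            per_window_unbound=[
                {"lambda_from": e.lambda_from, "lambda_to": e.lambda_to,
                 "delta_g": e.delta_g, "stderr": e.stderr}
                for e in leg_u.per_window
            ],
            per_window_bound=[
                {"lambda_from": e.lambda_from, "lambda_to": e.lambda_to,
                 "delta_g": e.delta_g, "stderr": e.stderr}
                for e in leg_b.per_window
            ],
        )
        return CycleResults(self, leg_u, leg_b, record)


class CycleResults:
    """Fitted thermodynamic cycle: leg totals, ΔΔG_bind, diagnostics."""

    def __init__(self, model: AlchemicalCycleModel, leg_unbound: ComposedFreeEnergy,
                 leg_bound: ComposedFreeEnergy, record: CycleResult):
        self.model = model
        self.leg_unbound = leg_unbound
        self.leg_bound = leg_bound
        self.record = record

    @property
    def ddg_bind(self) -> float:
        return self.record.ddg_bind

    @property
    def stderr(self) -> float:
        return self.record.stderr

    def summary(self) -> str:
        r = self.record
        lines = [
            "Relative binding free energy (thermodynamic cycle)",
            "==================================================",
            f"temperature:        {self.model.temperature:g} K",
            f"ΔG_mut (unbound):   {r.dg_mut_unbound:8.3f} ± {self.leg_unbound.stderr:.3f} kcal/mol",
            f"ΔG_mut (bound):     {r.dg_mut_bound:8.3f} ± {self.leg_bound.stderr:.3f} kcal/mol",
            f"ΔΔG_bind:           {r.ddg_bind:8.3f} ± {r.stderr:.3f} kcal/mol",
            "(positive ΔΔG_bind: mutant binds less strongly)",
        ]
        if r.hysteresis_unbound is not None:
            lines.append(f"hysteresis (unbound leg): {r.hysteresis_unbound:.3f} kcal/mol")
        if r.hysteresis_bound is not None:
            lines.append(f"hysteresis (bound leg):   {r.hysteresis_bound:.3f} kcal/mol")
        lines.append("")
        lines.append("per-window ΔG (kcal/mol):")
        lines.append("  λ_from   λ_to    unbound     bound")
        for eu, eb in zip(r.per_window_unbound, r.per_window_bound):
            lines.append(
                f"  {eu['lambda_from']:.5f} {eu['lambda_to']:.5f} "
                f"{eu['delta_g']:9.4f} {eb['delta_g']:9.4f}"
            )
        return "\n".join(lines)
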