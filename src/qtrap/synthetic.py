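"""Synthetic data generators with known ground truth.

The analysis layer of this package consumes three kinds of input: pulling
work traces, per-window alchemical ΔU samples, and donor–acceptor distance
series.  This module produces all three from models whose answers are known
in closed form, so that every estimator downstream has a parameter-recovery
test that needs no external trajectory data:

* :func:`simulate_pulling` integrates overdamped (Brownian) Langevin dynamics
  of a single coordinate in a model potential under a moving harmonic
  restraint, accumulating external work with the stiff-spring bookkeeping
  used by SMD engines;
* :func:`generate_fep_samples` draws forward/reverse ΔU pairs that satisfy
  the Crooks fluctuation relation exactly for a prescribed true ΔG, making
  the Bennett acceptance-ratio estimator asymptotically unbiased by
  construction;
* :func:`generate_distance_mixture` draws Gaussian-mixture distance samples
  emulating the unimodal (wild-type-like) and bimodal (mutant-like)
  headgroup–N2 distance distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE, LAMBDA_SCHEDULE
from .exceptions import QtrapError, UnstableTimestepError
from .io_tables import DistanceSeries, FepWindowSamples, WorkTrace

__all__ = [
    "ModelPotential",
    "FlatPotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "TabulatedPotential",
    "make_potential",
    "LangevinSpec",
    "MixtureSpec",
    "simulate_pulling",
    "generate_fep_samples",
    "generate_distance_mixture",
    "CycleDataset",
    "generate_cycle_dataset",
]


# ---------------------------------------------------------------------------
# model potentials
# ---------------------------------------------------------------------------

class ModelPotential:
    """A 1-D potential U(x) with analytic gradient.

    Subclasses implement :meth:`energy` and :meth:`grad`; for the analytic
    kinds the free-energy difference between two points of the bare
    coordinate is simply U(x1) − U(x0).
    """

    kind: str = "abstract"

    def energy(self, x):
        raise NotImplementedError

    def grad(self, x):
        raise NotImplementedError

    def delta_pmf(self, x0: float, x1: float) -> float:
        """Bare-potential free-energy difference U(x1) − U(x0)."""
        return float(self.energy(np.asarray(x1)) - self.energy(np.asarray(x0)))


class FlatPotential(ModelPotential):
    kind = "flat"

    def energy(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def grad(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


class HarmonicPotential(ModelPotential):
    """U(x) = ½·κ·(x − x0)²."""

    kind = "harmonic"

    def __init__(self, x0: float = 0.0, kappa: float = 1.0):
        if kappa < 0:
            raise QtrapError(f"harmonic stiffness must be ≥ 0, got {kappa}")
        self.x0 = float(x0)
        self.kappa = float(kappa)

    def energy(self, x):
        return 0.5 * self.kappa * (np.asarray(x, dtype=float) - self.x0) ** 2

    def grad(self, x):
        return self.kappa * (np.asarray(x, dtype=float) - self.x0)


class DoubleWellPotential(ModelPotential):
    """Symmetric quartic double well.

    Wells at ``well_left`` and ``well_right`` (U = 0), barrier of height
    ``barrier`` (kcal/mol) at the midpoint:
    U(x) = barrier · ((x − m)² − d²)² / d⁴ with m the midpoint and d the
    half-separation.
    """

    kind = "double_well"

    def __init__(self, well_left: float, well_right: float, barrier: float):
        if well_right <= well_left:
            raise QtrapError("well_right must exceed well_left")
        if barrier <= 0:
            raise QtrapError(f"barrier must be positive, got {barrier}")
        self.well_left = float(well_left)
        self.well_right = float(well_right)
        self.barrier = float(barrier)
        self._m = 0.5 * (well_left + well_right)
        self._d = 0.5 * (well_right - well_left)

    def energy(self, x):
        u = (np.asarray(x, dtype=float) - self._m) ** 2 - self._d ** 2
        return self.barrier * u ** 2 / self._d ** 4

    def grad(self, x):
        x = np.asarray(x, dtype=float)
        u = (x - self._m) ** 2 - self._d ** 2
        return 4.0 * self.barrier * u * (x - self._m) / self._d ** 4

    @property
    def max_curvature(self) -> float:
        # |U''| is largest at the wells: U''(well) = 8·barrier/d²
        return 8.0 * self.barrier / self._d ** 2


class TabulatedPotential(ModelPotential):
    """Potential interpolated linearly from a (x, U) table."""

    kind = "tabulated"

    def __init__(self, x: Sequence[float], u: Sequence[float]):
        self.x = np.asarray(x, dtype=float)
        self.u = np.asarray(u, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.u.shape or len(self.x) < 2:
            raise QtrapError("tabulated potential needs matching 1-D x and u, n ≥ 2")
        if not np.all(np.diff(self.x) > 0):
            raise QtrapError("tabulated potential x must be strictly increasing")
        self._du = np.gradient(self.u, self.x)

    def energy(self, x):
        return np.interp(np.asarray(x, dtype=float), self.x, self.u)

    def grad(self, x):
        return np.interp(np.asarray(x, dtype=float), self.x, self._du)


def make_potential(kind: str, **params) -> ModelPotential:
    """Factory: ``flat``, ``harmonic``, ``double_well`` or ``tabulated``."""
    kinds = {
        "flat": FlatPotential,
        "harmonic": HarmonicPotential,
        "double_well": DoubleWellPotential,
        "tabulated": TabulatedPotential,
    }
    if kind not in kinds:
        raise QtrapError(f"unknown potential kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](**params)


# ---------------------------------------------------------------------------
# pulling simulation
# ---------------------------------------------------------------------------

@dataclass
class LangevinSpec:
    """Protocol for an overdamped pulling simulation.

    Attributes
    ----------
    temperature : K
    friction : kcal·ns/mol/Å² — drag coefficient γ (diffusion D = kT/γ).
    timestep : ns — must satisfy Δt < 0.1·γ/k_spring.
    spring_k : kcal/mol/Å² — moving-restraint stiffness (default 2, the
        study's pulling restraint).
    schedule : (center_start Å, center_end Å, duration ns) — the restraint
        center moves linearly; the default mirrors the study's extraction
        protocol, 10 → 58 Å over 3 ns ("fast"; the 10×-slower variant uses
        30 ns).
    n_traj : number of trajectories.
    seed : RNG seed; identical seeds give identical traces.
    equil_time : ns spent equilibrating at the start center before pulling
        (work is not accumulated during equilibration).
    """

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    timestep: float = 1e-3
    spring_k: float = 2.0
    schedule: tuple[float, float, float] = (10.0, 58.0, 3.0)
    n_traj: int = 10
    seed: int = 0
    equil_time: float = 0.0

    def validate(self):
        if self.temperature < 0:
            raise QtrapError("temperature must be ≥ 0")
        if self.friction <= 0:
            raise QtrapError("friction must be positive")
        if self.schedule[2] <= 0:
            raise QtrapError("schedule duration must be positive")
        if self.n_traj < 1:
            raise QtrapError("n_traj must be ≥ 1")
        if self.spring_k > 0 and self.timestep >= 0.1 * self.friction / self.spring_k:
            raise UnstableTimestepError(
                f"timestep {self.timestep} ns ≥ 0.1·γ/k = "
                f"{0.1 * self.friction / self.spring_k:.3g} ns; reduce Δt"
            )


def simulate_pulling(potential: ModelPotential, spec: LangevinSpec,
                     output_every: int = 1) -> list[WorkTrace]:
    """Pull a Brownian particle through *potential* with a moving restraint.

    The overdamped update is
    ``x ← x − Δt·(U′(x) + k·(x − c))/γ + sqrt(2·kB·T·Δt/γ)·ξ`` with
    unit-normal ξ, and the external work is accumulated per restraint step as
    ``W ← W + k·(c_new − x)·Δc`` using the position from before the step —
    the stiff-spring bookkeeping of SMD engines, which makes
    :func:`qtrap.smd.recompute_work` an exact inverse when every step is
    stored (``output_every=1``).

    Returns ``spec.n_traj`` :class:`~qtrap.io_tables.WorkTrace` objects,
    reproducible from ``spec.seed``.
    """
    spec.validate()
    c_start, c_end, duration = spec.schedule
    n_steps = max(1, int(round(duration / spec.timestep)))
    dt = duration / n_steps
    n = spec.n_traj
    gamma = spec.friction
    k = spec.spring_k
    noise_amp = math.sqrt(2.0 * KB * spec.temperature * dt / gamma)
    rng = np.random.default_rng(spec.seed)

    x = np.full(n, c_start, dtype=float)
    n_equil = int(round(spec.equil_time / dt))
    for _ in range(n_equil):
        force = -(potential.grad(x) + k * (x - c_start))
        x += dt * force / gamma + noise_amp * rng.standard_normal(n)

    centers = c_start + (c_end - c_start) * np.arange(n_steps + 1) / n_steps
    work = np.zeros(n)
    n_out = n_steps // output_every + 1
    t_out = np.empty(n_out)
    c_out = np.empty(n_out)
    x_out = np.empty((n_out, n))
    w_out = np.empty((n_out, n))
    t_out[0], c_out[0] = 0.0, c_start
    x_out[0], w_out[0] = x, 0.0
    j_out = 1
    c_old = c_start
    for j in range(1, n_steps + 1):
        c_new = centers[j]
        dc = c_new - c_old
        work = work + k * (c_new - x) * dc
        force = -(potential.grad(x) + k * (x - c_new))
        x = x + dt * force / gamma + noise_amp * rng.standard_normal(n)
        if j % output_every == 0:
            t_out[j_out] = j * dt
            c_out[j_out] = c_new
            x_out[j_out] = x
            w_out[j_out] = work
            j_out += 1
        c_old = c_new

    width = len(str(n - 1))
    return [
        WorkTrace(
            traj_id=f"traj{i:0{width}d}",
            time=t_out[:j_out].copy(),
            restraint_center=c_out[:j_out].copy(),
            coordinate=x_out[:j_out, i].copy(),
            accumulated_work=w_out[:j_out, i].copy(),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# alchemical samples
# ---------------------------------------------------------------------------

def generate_fep_samples(true_dg_per_window: Sequence[float], sigma: float,
                         n: int, temperature: float = DEFAULT_TEMPERATURE,
                         seed: int = 0,
                         lambdas: Sequence[float] | None = None,
                         ) -> list[FepWindowSamples]:
    """Draw Crooks-consistent forward/reverse ΔU samples per window.

    For each window with true free-energy change ΔG the draws are

    * forward:  ΔU ~ Normal(ΔG + σ²/(2·kB·T), σ²)  (λ_from ensemble)
    * reverse:  ΔU ~ Normal(ΔG − σ²/(2·kB·T), σ²)  (λ_to ensemble)

    which satisfies p_F(ΔU)/p_R(ΔU) = e^{β(ΔU − ΔG)} exactly, so BAR is
    asymptotically unbiased for ΔG.  With 10 windows the study's λ schedule
    is used unless *lambdas* overrides it.
    """
    if sigma < 0:
        raise QtrapError(f"sigma must be ≥ 0, got {sigma}")
    if n < 1:
        raise QtrapError(f"n must be ≥ 1, got {n}")
    m = len(true_dg_per_window)
    if lambdas is None:
        lambdas = LAMBDA_SCHEDULE if m == 10 else tuple(np.linspace(0.0, 1.0, m + 1))
    if len(lambdas) != m + 1:
        raise QtrapError(f"need {m + 1} λ values for {m} windows, got {len(lambdas)}")
    shift = sigma ** 2 / (2.0 * KB * temperature)
    rng = np.random.default_rng(seed)
    windows = []
    for i, dg in enumerate(true_dg_per_window):
        fwd = dg + shift + sigma * rng.standard_normal(n)
        rev = dg - shift + sigma * rng.standard_normal(n)
        windows.append(FepWindowSamples(lambdas[i], lambdas[i + 1], fwd, rev))
    return windows


# ---------------------------------------------------------------------------
# distance mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """A Gaussian mixture of donor–acceptor distances.

    ``components`` is a list of (weight, mean Å, sd Å); weights must be
    positive and sum to 1 within 1e-12.
    """

    components: list[tuple[float, float, float]]
    n: int
    seed: int = 0
    label: str = ""
    #: sampling cadence for the synthetic time column, ns (500 fs).
    dt: float = 5e-4

    def validate(self):
        if not self.components:
            raise QtrapError("mixture needs at least one component")
        w = np.array([c[0] for c in self.components], dtype=float)
        if np.any(w <= 0):
            raise QtrapError("mixture weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise QtrapError(f"mixture weights sum to {w.sum()!r}, expected 1")
        if any(c[2] <= 0 for c in self.components):
            raise QtrapError("mixture sds must be positive")
        if self.n < 1:
            raise QtrapError("n must be ≥ 1")


def generate_distance_mixture(spec: MixtureSpec, return_components: bool = False):
    """Sample a :class:`~qtrap.io_tables.DistanceSeries` from *spec*.

    With ``return_components=True`` also returns the component index of each
    sample (ground-truth provenance for mode-recovery tests).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w = np.array([c[0] for c in spec.components])
    means = np.array([c[1] for c in spec.components])
    sds = np.array([c[2] for c in spec.components])
    comp = rng.choice(len(w), size=spec.n, p=w)
    dist = means[comp] + sds[comp] * rng.standard_normal(spec.n)
    if np.any(dist <= 0):
        raise QtrapError(
            "mixture produced non-positive distances; means/sds are "
            "unphysical for a distance distribution"
        )
    series = DistanceSeries(np.arange(spec.n) * spec.dt, dist, label=spec.label)
    if return_components:
        return series, comp
    return series


# ---------------------------------------------------------------------------
# thermodynamic-cycle dataset
# ---------------------------------------------------------------------------

@dataclass
class CycleDataset:
    """Two alchemical legs (mutation with ligand unbound / bound) plus truth."""

    unbound: list[FepWindowSamples]
    bound: list[FepWindowSamples]
    true_dg_unbound: float
    true_dg_bound: float

    @property
    def true_ddg(self) -> float:
        return self.true_dg_unbound - self.true_dg_bound


def generate_cycle_dataset(dg_unbound: float, dg_bound: float, sigma: float,
                           n: int, seed: int = 0,
                           temperature: float = DEFAULT_TEMPERATURE,
                           n_windows: int = 10) -> CycleDataset:
    """Generate both legs of a relative-binding thermodynamic cycle.

    Each leg's true ΔG is split evenly across its λ windows; the recoverable
    ground truth is ΔΔG_bind = dg_unbound − dg_bound.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    unbound = generate_fep_samples(
        [dg_unbound / n_windows] * n_windows, sigma, n, temperature,
        seed=ss[0].generate_state(1)[0] % (2 ** 31),
    )
    bound = generate_fep_samples(
        [dg_bound / n_windows] * n_windows, sigma, n, temperature,
        seed=ss[1].generate_state(1)[0] % (2 ** 31),
    )
    return CycleDataset(unbound, bound, dg_unbound, dg_bound)
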