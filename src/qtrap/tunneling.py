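"""Distance-distribution modes and electron-tunneling rate ratios.

The electron donor–acceptor distance R (here, center of the terminal 4Fe-4S
cluster N2 to the center of the CoQ10 quinone headgroup) controls the
nonadiabatic electron-transfer rate through the electronic coupling,
|H(R)|² ∝ e^(−β·R) with distance-decay constant β (Å⁻¹).  This module

* locates the modes of a sampled distance distribution by Gaussian kernel
  density estimation (the wild type is unimodal near 14.1 Å; the A52T
  mutant is bimodal with a more prominent peak near 13.5 Å);
* converts mode positions, or whole distance ensembles, into tunneling-rate
  ratios; and
* evaluates the full Marcus nonadiabatic rate expression (up to the ℏ
  prefactor — ratios are the supported use).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .constants import DEFAULT_TEMPERATURE, kt as _kt
from .exceptions import QtrapError
from .io_tables import DistanceSeries

__all__ = [
    "ModeList",
    "EtParams",
    "find_modes",
    "rate_ratio_peaks",
    "rate_ratio_ensemble",
    "marcus_rate",
    "silverman_bandwidth",
    "fit_two_gaussians",
    "DistanceDistributionModel",
    "ModeResults",
]

#: Default electronic-coupling distance-decay constant, Å⁻¹.  Typical of
#: protein-mediated tunneling; at the 14.1 → 13.5 Å peak shift it gives a
#: rate factor e^(1.8·0.6) ≈ 2.9, i.e. "a factor of 3" to one significant
#: figure.
DEFAULT_BETA_DECAY: float = 1.8

_GRID_STEP = 0.01  # Å


@dataclass
class ModeList:
    """Density modes of a distance distribution, sorted by descending height."""

    modes: list[tuple[float, float]]   # (position Å, density height)
    bandwidth: float                   # Å

    @property
    def positions(self) -> list[float]:
        return [m[0] for m in self.modes]

    @property
    def primary(self) -> float:
        return self.modes[0][0]

    def __len__(self) -> int:
        return len(self.modes)


@dataclass
class EtParams:
    """Parameters of the nonadiabatic (Marcus) electron-transfer rate.

    beta_decay : Å⁻¹ — exponential decay of |H|² with distance.
    coupling_h0 : electronic coupling at the reference distance ``r_ref``
        (arbitrary energy units; only ratios are meaningful downstream).
    reorganization_lambda : kcal/mol.
    driving_dg0 : kcal/mol, reaction driving force ΔG°.
    r_ref : Å, distance at which H = coupling_h0.
    """

    beta_decay: float = DEFAULT_BETA_DECAY
    coupling_h0: float | None = None
    reorganization_lambda: float | None = None
    driving_dg0: float | None = None
    r_ref: float = 0.0

    def __post_init__(self):
        if self.beta_decay <= 0:
            raise QtrapError(f"beta_decay must be positive, got {self.beta_decay}")
        if self.reorganization_lambda is not None and self.reorganization_lambda <= 0:
            raise QtrapError("reorganization_lambda must be positive when supplied")


# ---------------------------------------------------------------------------
# mode detection
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9·min(σ̂, IQR/1.34)·n^(−1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    if a == 0:
        raise QtrapError("cannot choose a bandwidth for a constant series")
    return 0.9 * a * len(x) ** (-0.2)


def find_modes(series: DistanceSeries, bandwidth: float | str = "auto",
               min_height_frac: float = 0.01) -> ModeList:
    """Locate density modes of a distance series by Gaussian KDE.

    The density is evaluated on a 0.01 Å grid; modes are strict local maxima,
    and modes closer than one bandwidth are merged (keeping the higher).
    Local maxima below *min_height_frac* of the tallest mode are discarded as
    kernel noise in sparsely sampled tails.  Automatic bandwidth uses
    Silverman's rule and requires ≥ 100 samples.  Returned modes are sorted
    by descending density height (prominence).
    """
    x = np.asarray(series.distance, dtype=float)
    if np.ptp(x) == 0:
        raise QtrapError(f"series {series.label!r} is constant; no density modes")
    if bandwidth == "auto":
        if x.size < 100:
            raise QtrapError(
                f"automatic bandwidth needs ≥ 100 samples, got {x.size}"
            )
        h = silverman_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise QtrapError(f"bandwidth must be positive, got {h}")

    kde = gaussian_kde(x, bw_method=h / np.std(x, ddof=1))
    grid = np.arange(x.min() - 3 * h, x.max() + 3 * h + _GRID_STEP, _GRID_STEP)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:  # monotone density: take the global maximum
        idx = np.array([int(np.argmax(dens))])
    candidates = sorted(
        ((float(grid[i]), float(dens[i])) for i in idx),
        key=lambda m: -m[1],
    )
    floor = min_height_frac * candidates[0][1]
    kept: list[tuple[float, float]] = []
    for pos, height in candidates:
        if height < floor:
            break
        if all(abs(pos - p) >= h for p, _ in kept):
            kept.append((pos, height))
    return ModeList(kept, bandwidth=h)


# ---------------------------------------------------------------------------
# rate ratios
# ---------------------------------------------------------------------------

def rate_ratio_peaks(d_ref: float, d_alt: float,
                     beta_decay: float = DEFAULT_BETA_DECAY) -> float:
    """Tunneling-rate ratio k(d_alt)/k(d_ref) = e^(β·(d_ref − d_alt)).

    The square-barrier / nonadiabatic coupling-squared distance dependence:
    moving the acceptor 0.6 Å closer at β = 1.8 Å⁻¹ speeds the rate by
    e^1.08 ≈ 2.9.
    """
    if d_ref <= 0 or d_alt <= 0:
        raise QtrapError("distances must be positive")
    if beta_decay <= 0:
        raise QtrapError(f"beta_decay must be positive, got {beta_decay}")
    return float(math.exp(beta_decay * (d_ref - d_alt)))


def rate_ratio_ensemble(series_ref: DistanceSeries, series_alt: DistanceSeries,
                        beta_decay: float = DEFAULT_BETA_DECAY) -> float:
    """Ensemble-averaged rate ratio ⟨e^(−βR)⟩_alt / ⟨e^(−βR)⟩_ref.

    Averages the distance-dependent coupling over each ensemble instead of
    evaluating it at single peak positions; invariant under reordering and
    duplication of either series.
    """
    if beta_decay <= 0:
        raise QtrapError(f"beta_decay must be positive, got {beta_decay}")
    r_ref = np.asarray(series_ref.distance, dtype=float)
    r_alt = np.asarray(series_alt.distance, dtype=float)
    if r_ref.size == 0 or r_alt.size == 0:
        raise QtrapError("both series must be nonempty")
    log_ratio = (
        logsumexp(-beta_decay * r_alt) - math.log(r_alt.size)
        - logsumexp(-beta_decay * r_ref) + math.log(r_ref.size)
    )
    return float(math.exp(log_ratio))


def marcus_rate(params: EtParams, distance: float,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Nonadiabatic electron-transfer rate, up to the 2π/ℏ prefactor.

    k ∝ |H(R)|² · (4π·λ·kB·T)^(−1/2) · e^(−(ΔG° + λ)²/(4·λ·kB·T)) with
    H(R) = H₀·e^(−β·(R − R₀)/2).  Absolute units are not resolved; use
    ratios.  The rate is maximal at the activationless point ΔG° = −λ and
    scales with |H₀|².
    """
    if params.coupling_h0 is None or params.reorganization_lambda is None:
        raise QtrapError("marcus_rate requires coupling_h0 and reorganization_lambda")
    lam = params.reorganization_lambda
    dg0 = params.driving_dg0 if params.driving_dg0 is not None else 0.0
    kt = _kt(temperature)
    h = params.coupling_h0 * math.exp(-params.beta_decay * (distance - params.r_ref) / 2.0)
    return float(
        h ** 2 / math.sqrt(4.0 * math.pi * lam * kt)
        * math.exp(-((dg0 + lam) ** 2) / (4.0 * lam * kt))
    )


# ---------------------------------------------------------------------------
# EM cross-check
# ---------------------------------------------------------------------------

def fit_two_gaussians(series: DistanceSeries, seed: int = 0):
    """Two-component Gaussian-mixture fit (EM) as a cross-check on KDE modes.

    Returns (means, sds, weights), sorted by descending weight.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(series.distance, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(-weights)
    return means[order], sds[order], weights[order]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class DistanceDistributionModel:
    """Density model of a donor–acceptor distance series."""

    def __init__(self, series: DistanceSeries):
        self.series = series

    def fit(self, bandwidth: float | str = "auto") -> "ModeResults":
        modes = find_modes(self.series, bandwidth=bandwidth)
        return ModeResults(self, modes)


class ModeResults:
    """Detected distance-distribution modes with rate-ratio helpers."""

    def __init__(self, model: DistanceDistributionModel, mode_list: ModeList):
        self.model = model
        self.mode_list = mode_list

    @property
    def modes(self) -> list[tuple[float, float]]:
        return self.mode_list.modes

    @property
    def primary_mode(self) -> float:
        return self.mode_list.primary

    def rate_ratio_vs(self, reference: "ModeResults",
                      beta_decay: float = DEFAULT_BETA_DECAY,
                      ensemble: bool = False) -> float:
        """Tunneling-rate ratio of this system relative to *reference*.

        Peak-based by default (primary modes); ``ensemble=True`` averages
        e^(−βR) over the full series instead.
        """
        if ensemble:
            return rate_ratio_ensemble(reference.model.series,
                                       self.model.series, beta_decay)
        return rate_ratio_peaks(reference.primary_mode, self.primary_mode,
                                beta_decay)

    def summary(self) -> str:
        lines = [
            f"Distance-distribution modes ({self.model.series.label or 'unlabeled'})",
            "=" * 40,
            f"samples:    {len(self.model.series)}",
            f"bandwidth:  {self.mode_list.bandwidth:.4f} Å",
            "modes (by prominence):",
        ]
        for pos, height in self.modes:
            lines.append(f"  {pos:8.3f} Å   density {height:.4f}")
        return "\n".join(lines)
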