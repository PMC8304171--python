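"""Mixture model of four-corner and random striking strategies.

Each stroke is struck under one of two pure strategies: with probability
gamma the striker plays a "four-corner" pattern (uniform over the corner
zones 1, 4, 9, 12) and with probability 1 - gamma a fully random pattern
(uniform over all 12 zones).  Marginally, each corner zone then carries
probability

    p4c  = gamma/4 + (1 - gamma)/12 = (1 + 2 gamma) / 12

and each non-corner zone

    pn4c = (1 - gamma)/12,

so 4 p4c + 8 pn4c = 1 and the standard entropy of the mixed distribution is
available in closed form:

    H(gamma) = -[4 p4c ln(p4c) + 8 pn4c ln(pn4c)] / ln(12),

a strictly decreasing curve from H(0) = 1 down to H(1) = ln(4)/ln(12).

The Monte Carlo side simulates stroke-by-stroke zone sequences at match
lengths L_i, scores each replicate with the plug-in standard entropy, and
averages -- the finite-L counterpart of the analytic curve.  ``fit_gamma``
inverts an observed mean entropy onto the gamma grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .entropy import LN_N_ZONES, N_ZONES, normalized_entropy
from .errors import InvalidInputError

CORNER_ZONES_ARRAY = np.array([1, 4, 9, 12])
_NONCORNER_COUNT = N_ZONES - len(CORNER_ZONES_ARRAY)

#: Entropy floor of the mixture: the pure four-corner limit, ln(4)/ln(12).
H_MIN = math.log(4) / LN_N_ZONES


def _check_gamma(gamma: float) -> float:
    if not (0.0 <= gamma <= 1.0):
        raise InvalidInputError(f"gamma must be in [0, 1], got {gamma}")
    return float(gamma)


def corner_probability(gamma: float) -> float:
    """Marginal probability of striking from one given corner zone, (1+2g)/12."""
    return (1.0 + 2.0 * _check_gamma(gamma)) / 12.0


def noncorner_probability(gamma: float) -> float:
    """Marginal probability of striking from one given non-corner zone, (1-g)/12."""
    return (1.0 - _check_gamma(gamma)) / 12.0


def analytic_entropy(gamma: float) -> float:
    """Closed-form standard entropy of the mixture, strictly decreasing in gamma."""
    p4c = corner_probability(gamma)
    pn4c = noncorner_probability(gamma)
    h = 4.0 * p4c * math.log(p4c)
    if pn4c > 0.0:  # 0 ln 0 = 0 at gamma = 1
        h += _NONCORNER_COUNT * pn4c * math.log(pn4c)
    return -h / LN_N_ZONES


def _simulate_zone_block(L: int, gamma: float, rng: np.random.Generator, n_reps: int = 1) -> np.ndarray:
    """(n_reps, L) zone indices via the two-draw scheme, vectorized.

    Draw 1 selects the strategy (corner pattern iff ran1 <= gamma); draw 2
    selects the zone, by quartiles of [0, 1] over the corner zones or by
    twelfths over all 12 zones.  Boundary hits (probability zero) resolve
    toward the lower zone.
    """
    ran1 = rng.random((n_reps, L))
    ran2 = rng.random((n_reps, L))
    corner_idx = np.minimum(np.ceil(ran2 * 4.0).astype(np.int64), 4) - 1
    corner_idx = np.maximum(corner_idx, 0)
    random_zone = np.minimum(np.ceil(ran2 * N_ZONES).astype(np.int64), N_ZONES)
    random_zone = np.maximum(random_zone, 1)
    return np.where(ran1 <= gamma, CORNER_ZONES_ARRAY[corner_idx], random_zone)


def simulate_match_zones(L: int, gamma: float, seed=None) -> np.ndarray:
    """Simulate the zone sequence of one match of L strokes at mixing weight gamma."""
    _check_gamma(gamma)
    if L < 1:
        raise InvalidInputError(f"match length must be >= 1, got {L}")
    rng = np.random.default_rng(seed)
    return _simulate_zone_block(L, gamma, rng)[0]


@dataclass(frozen=True)
class MixtureConfig:
    """Settings for Monte Carlo mixture simulations and gamma sweeps."""

    gamma: float = 0.5
    delta_gamma: float = 0.01
    n_reps: int = 100
    match_lengths: Sequence[int] = field(default_factory=lambda: (842,))
    seed: int = 0

    def __post_init__(self) -> None:
        _check_gamma(self.gamma)
        if not self.delta_gamma > 0:
            raise InvalidInputError("delta_gamma must be positive")
        if self.n_reps < 1:
            raise InvalidInputError("n_reps must be >= 1")
        if len(self.match_lengths) == 0 or any(L < 1 for L in self.match_lengths):
            raise InvalidInputError("match_lengths must be non-empty with all L >= 1")


@dataclass(frozen=True)
class MonteCarloResult:
    """Per-match entropy summaries of one Monte Carlo run at fixed gamma."""

    gamma: float
    per_match_mean: np.ndarray  # mean H over replicates, per match
    per_match_std: np.ndarray  # std of H over replicates, per match
    grand_mean: float
    all_values: np.ndarray  # shape (n_matches, n_reps)


def _entropy_of_zone_block(zones: np.ndarray) -> np.ndarray:
    """Plug-in standard entropy of each row of an (n_reps, L) zone array."""
    n_reps, L = zones.shape
    counts = np.zeros((n_reps, N_ZONES), dtype=np.int64)
    rows = np.repeat(np.arange(n_reps), L)
    np.add.at(counts, (rows, zones.ravel() - 1), 1)
    p = counts / L
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1) / LN_N_ZONES


def monte_carlo_entropy(config: MixtureConfig, gamma: float | None = None) -> MonteCarloResult:
    """Simulate n_reps zone sequences per match length and score each with H.

    Returns per-match replicate means/stds and the grand mean over matches,
    mirroring the boxplot summaries of a gamma sweep at one grid point.
    """
    g = _check_gamma(config.gamma if gamma is None else gamma)
    ss = np.random.SeedSequence(config.seed).spawn(len(config.match_lengths))
    values = np.empty((len(config.match_lengths), config.n_reps))
    for m, (L, child) in enumerate(zip(config.match_lengths, ss)):
        rng = np.random.default_rng(child)
        zones = _simulate_zone_block(int(L), g, rng, n_reps=config.n_reps)
        values[m] = _entropy_of_zone_block(zones)
    return MonteCarloResult(
        gamma=g,
        per_match_mean=values.mean(axis=1),
        per_match_std=values.std(axis=1, ddof=1) if config.n_reps > 1 else np.zeros(len(config.match_lengths)),
        grand_mean=float(values.mean()),
        all_values=values,
    )


@dataclass(frozen=True)
class SweepResult:
    """Entropy distributions over the full gamma grid."""

    gammas: np.ndarray
    mean_H: np.ndarray  # grand mean per gamma
    std_H: np.ndarray  # std of per-match means per gamma
    quartiles: np.ndarray  # shape (len(gammas), 3): 25th, 50th, 75th percentiles
    analytic_H: np.ndarray  # closed-form curve on the same grid


def gamma_grid(delta_gamma: float = 0.01) -> np.ndarray:
    n = int(round(1.0 / delta_gamma))
    return np.linspace(0.0, 1.0, n + 1)


def sweep_gamma(config: MixtureConfig) -> SweepResult:
    """Monte Carlo entropy across the whole gamma grid [0, 1] at step delta_gamma.

    Each grid point gets its own seed substream, so results are independent
    of sweep order and reproducible from ``config.seed`` alone.
    """
    grid = gamma_grid(config.delta_gamma)
    seeds = np.random.SeedSequence(config.seed).spawn(len(grid))
    mean_H = np.empty(len(grid))
    std_H = np.empty(len(grid))
    quartiles = np.empty((len(grid), 3))
    for k, (g, child) in enumerate(zip(grid, seeds)):
        sub = MixtureConfig(
            gamma=float(g),
            delta_gamma=config.delta_gamma,
            n_reps=config.n_reps,
            match_lengths=config.match_lengths,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        res = monte_carlo_entropy(sub)
        mean_H[k] = res.grand_mean
        std_H[k] = res.per_match_mean.std(ddof=1) if len(res.per_match_mean) > 1 else 0.0
        quartiles[k] = np.percentile(res.all_values, [25, 50, 75])
    return SweepResult(
        gammas=grid,
        mean_H=mean_H,
        std_H=std_H,
        quartiles=quartiles,
        analytic_H=np.array([analytic_entropy(g) for g in grid]),
    )


@dataclass(frozen=True)
class GammaFit:
    """Grid inversion of an observed entropy onto the mixture curve."""

    H_obs: float
    gamma_hat: float
    residual: float


def fit_gamma(
    H_obs: float, delta_gamma: float = 0.01, sweep: SweepResult | None = None
) -> GammaFit:
    """Find the grid gamma whose mixture entropy is closest to an observed H.

    By default the inversion uses the analytic curve (deterministic); pass a
    ``sweep`` to match against Monte Carlo means instead, as when reading
    the closest simulated box off a sweep figure.

    Raises
    ------
    InvalidInputError
        If H_obs lies outside the attainable range (ln 4 / ln 12, 1].
    """
    if not (H_MIN < H_obs <= 1.0):
        raise InvalidInputError(
            f"observed entropy {H_obs} outside the attainable range ({H_MIN:.4f}, 1]"
        )
    if sweep is None:
        grid = gamma_grid(delta_gamma)
        curve = np.array([analytic_entropy(g) for g in grid])
    else:
        grid = sweep.gammas
        curve = sweep.mean_H
    k = int(np.argmin(np.abs(curve - H_obs)))
    return GammaFit(H_obs=float(H_obs), gamma_hat=float(grid[k]), residual=float(abs(curve[k] - H_obs)))
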