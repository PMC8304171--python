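"""Normalized Shannon entropy of zone distributions and receiving-zone entropy.

The standard entropy of a strike distribution over the 12 court zones is the
Shannon entropy divided by its maximum, ln(12):

    H = -sum_i p_i ln(p_i) / ln(12),     0 <= H <= 1,

with the 0 * ln 0 = 0 convention for empty zones.  H = 0 means every stroke
came from a single zone; H = 1 means no positional preference at all.

The receiving entropy asks a conditional question: given that a stroke was
hit *from* zone i, how unpredictable is the zone of the very next stroke of
the rally (the position where it is received and returned)?  For each origin
zone the destination-zone distribution over consecutive stroke pairs is
collected and scored with the same normalized entropy, so per-origin values
are directly comparable to the standard entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .court import Match, StrokeRecord
from .errors import EmptyInputError

N_ZONES = 12
LN_N_ZONES = math.log(N_ZONES)


@dataclass(frozen=True)
class ZoneDistribution:
    """Counts and probabilities of strokes over the 12 zones."""

    counts: np.ndarray  # shape (12,), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_ZONES,):
            raise EmptyInputError(f"expected {N_ZONES} zone counts, got shape {counts.shape}")
        if (counts < 0).any():
            raise EmptyInputError("zone counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise EmptyInputError("cannot normalize an all-zero zone distribution")
        return self.counts / self.total

    @classmethod
    def from_zones(cls, zones: Iterable[int]) -> "ZoneDistribution":
        zones = np.asarray(list(zones) if not isinstance(zones, np.ndarray) else zones)
        if zones.size == 0:
            raise EmptyInputError("no strokes to tally")
        return cls(counts=np.bincount(zones - 1, minlength=N_ZONES))


@dataclass(frozen=True)
class EntropyValue:
    """A normalized entropy in [0, 1] with the number of events behind it."""

    H: float
    n_events: int


def zone_distribution(strokes: Sequence[StrokeRecord]) -> ZoneDistribution:
    """Tally a stroke sequence into per-zone counts."""
    if not strokes:
        raise EmptyInputError("no strokes to tally")
    return ZoneDistribution.from_zones([s.zone for s in strokes])


def normalized_entropy(probabilities: np.ndarray) -> float:
    """-sum p ln p / ln 12 with 0 ln 0 = 0; input must sum to 1."""
    p = np.asarray(probabilities, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / LN_N_ZONES)


def standard_entropy(dist: ZoneDistribution) -> EntropyValue:
    """Normalized Shannon entropy of a zone distribution.

    Raises
    ------
    EmptyInputError
        If the distribution has zero total count.
    """
    p = dist.probabilities
    return EntropyValue(H=normalized_entropy(p), n_events=dist.total)


def receiving_pairs(match: Match) -> np.ndarray:
    """Count consecutive (origin zone -> destination zone) pairs of a match.

    Every consecutive stroke pair within a rally contributes one transition
    event; the final stroke of a rally contributes none, so a match with L
    strokes in R rallies yields exactly L - R pairs.

    Returns
    -------
    ndarray of shape (12, 12)
        ``pairs[i, j]`` counts strokes hit from zone i+1 whose successor in
        the rally was hit from zone j+1.
    """
    pairs = np.zeros((N_ZONES, N_ZONES), dtype=np.int64)
    for rally in match.rallies:
        zones = [s.zone for s in rally.strokes]
        for a, b in zip(zones, zones[1:]):
            pairs[a - 1, b - 1] += 1
    return pairs


@dataclass(frozen=True)
class ReceivingProfile:
    """Per-origin-zone transition entropies of a match.

    ``H[i]`` is the normalized entropy of the destination-zone distribution
    conditional on the origin zone i+1, or NaN when that zone produced no
    outgoing pair (never struck from, or only as a rally-ending stroke) --
    an undefined value, deliberately distinct from 0, which would claim the
    destination was fully predictable.
    """

    H: np.ndarray  # shape (12,), NaN where undefined
    pair_counts: np.ndarray  # shape (12,), outgoing pairs per origin zone

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.H)


def receiving_entropy(
    match: Match | None = None, *, pairs: np.ndarray | None = None
) -> ReceivingProfile:
    """Normalized entropy of the receiving zone, per origin zone.

    Either a match or a precomputed 12x12 pair-count matrix may be given.
    """
    if pairs is None:
        if match is None:
            raise EmptyInputError("need a match or a pair-count matrix")
        pairs = receiving_pairs(match)
    pairs = np.asarray(pairs, dtype=np.int64)
    out = np.full(N_ZONES, np.nan)
    totals = pairs.sum(axis=1)
    for i in range(N_ZONES):
        if totals[i] > 0:
            out[i] = normalized_entropy(pairs[i] / totals[i])
    return ReceivingProfile(H=out, pair_counts=totals)
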