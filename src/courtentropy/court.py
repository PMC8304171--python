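"""Domain model for badminton half-courts, zones, strokes, rallies and matches.

The half court (one player's side, net to baseline) is partitioned into a
grid of ``n_rows`` x ``n_cols`` rectangular zones -- 3 rows from the net to
the baseline and 4 columns across the width in the standard coaching
partition, giving 12 zones.  Zones are numbered row-major: row 1 is adjacent
to the net, column 1 at the left sideline, so the front corners are zones 1
and 4, the back corners 9 and 12, and the central back cells 10 and 11.

Coordinates live in the striker's own half-court frame: the origin sits at
the net / left-sideline intersection, ``x`` grows toward the right sideline
and ``y`` from the net toward the baseline, both in meters.

The module also reads and writes the stroke-log CSV format (one row per
stroke) and reconstructs rallies and matches from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, ValidationError

#: Zone indices of the four court corners (front-left, front-right,
#: back-left, back-right) in the 4 x 3 partition.
CORNER_ZONES = (1, 4, 9, 12)

#: Columns of the stroke-log CSV, in order.
LOG_COLUMNS = [
    "match_id",
    "set",
    "point",
    "stroke_no",
    "player",
    "zone",
    "x",
    "y",
    "score_p1",
    "score_p2",
    "winner",
]

#: Columns that must be present in any readable stroke log.  ``zone`` may be
#: absent (derived from x, y) and ``winner`` may be absent (inferred from
#: score deltas).
REQUIRED_COLUMNS = [
    "match_id",
    "set",
    "point",
    "stroke_no",
    "player",
    "x",
    "y",
    "score_p1",
    "score_p2",
]


@dataclass(frozen=True)
class CourtGeometry:
    """Rectangular half court with a regular zone grid.

    Parameters
    ----------
    width : float
        Sideline-to-sideline extent of one player's half, meters.  The
        default is the singles court width, 5.18 m.
    depth : float
        Net-to-baseline extent, meters.  The default is half the 13.4 m
        court length, 6.7 m.
    n_cols, n_rows : int
        Zone grid shape: columns across the width, rows from net to
        baseline.  4 x 3 gives the standard 12-zone partition.
    """

    width: float = 5.18
    depth: float = 6.7
    n_cols: int = 4
    n_rows: int = 3

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.depth > 0):
            raise InvalidInputError("court width and depth must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise InvalidInputError("zone grid must have at least one cell")

    @property
    def n_zones(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def area(self) -> float:
        """Half-court area in square meters, the window area for spatial entropy."""
        return self.width * self.depth

    def zone_bounds(self, zone: int) -> tuple[float, float, float, float]:
        """Return ``(x_min, x_max, y_min, y_max)`` of a zone cell."""
        if not 1 <= zone <= self.n_zones:
            raise InvalidInputError(f"zone must be in 1..{self.n_zones}, got {zone}")
        row, col = divmod(zone - 1, self.n_cols)
        cw = self.width / self.n_cols
        ch = self.depth / self.n_rows
        return (col * cw, (col + 1) * cw, row * ch, (row + 1) * ch)

    def zone_center(self, zone: int) -> tuple[float, float]:
        x0, x1, y0, y1 = self.zone_bounds(zone)
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def assign_zone(x: float, y: float, geom: CourtGeometry | None = None) -> int:
    """Map a strike coordinate to its zone index (1-based, row-major).

    Coordinates outside the court rectangle are clamped to the border row or
    column: players do hit from behind the baseline, and the zone partition
    is a full discretization of striking positions, not an in/out call.

    Raises
    ------
    InvalidInputError
        If either coordinate is not finite.
    """
    if geom is None:
        geom = CourtGeometry()
    if not (math.isfinite(x) and math.isfinite(y)):
        raise InvalidInputError(f"coordinates must be finite, got ({x}, {y})")
    col = min(max(int(x / geom.width * geom.n_cols), 0), geom.n_cols - 1)
    row = min(max(int(y / geom.depth * geom.n_rows), 0), geom.n_rows - 1)
    return row * geom.n_cols + col + 1


def assign_zones(x: np.ndarray, y: np.ndarray, geom: CourtGeometry | None = None) -> np.ndarray:
    """Vectorized :func:`assign_zone` over coordinate arrays."""
    if geom is None:
        geom = CourtGeometry()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("coordinates must be finite")
    col = np.clip((x / geom.width * geom.n_cols).astype(int), 0, geom.n_cols - 1)
    row = np.clip((y / geom.depth * geom.n_rows).astype(int), 0, geom.n_rows - 1)
    return row * geom.n_cols + col + 1


@dataclass(frozen=True)
class StrokeRecord:
    """One hit of the shuttlecock: who struck, from where, at what score."""

    set_index: int
    point_index: int
    stroke_number: int
    player_id: str
    zone: int
    x: float
    y: float
    score_p1: int
    score_p2: int


@dataclass
class Rally:
    """One point: an alternating sequence of strokes and the point's winner."""

    strokes: list[StrokeRecord]
    winner_id: str
    score_before: tuple[int, int]

    def validate(self, players: Sequence[str] | None = None) -> None:
        if not self.strokes:
            raise ValidationError("rally has no strokes")
        for k, s in enumerate(self.strokes, start=1):
            if s.stroke_number != k:
                raise ValidationError(
                    f"rally (set {self.strokes[0].set_index}, point "
                    f"{self.strokes[0].point_index}): stroke numbers not consecutive"
                )
        for a, b in zip(self.strokes, self.strokes[1:]):
            if a.player_id == b.player_id:
                raise ValidationError(
                    f"rally (set {a.set_index}, point {a.point_index}): "
                    f"consecutive strokes by the same player {a.player_id!r}"
                )
        if players is not None and self.winner_id not in players:
            raise ValidationError(f"winner {self.winner_id!r} is not one of the players")


@dataclass
class Match:
    """An ordered sequence of rallies between two players."""

    match_id: str
    players: tuple[str, str]
    rallies: list[Rally] = field(default_factory=list)

    @property
    def L(self) -> int:
        """Total stroke count of the match."""
        return sum(len(r.strokes) for r in self.rallies)

    def strokes(self) -> Iterable[StrokeRecord]:
        for rally in self.rallies:
            yield from rally.strokes

    def validate(self) -> None:
        if not self.rallies:
            raise ValidationError(f"match {self.match_id!r} has no rallies")
        for rally in self.rallies:
            rally.validate(self.players)


def match_to_frame(match: Match) -> pd.DataFrame:
    """Flatten a match to one stroke-log row per stroke."""
    rows = []
    for rally in match.rallies:
        for s in rally.strokes:
            rows.append(
                (
                    match.match_id,
                    s.set_index,
                    s.point_index,
                    s.stroke_number,
                    s.player_id,
                    s.zone,
                    s.x,
                    s.y,
                    s.score_p1,
                    s.score_p2,
                    rally.winner_id,
                )
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_stroke_log(matches: Sequence[Match], path) -> None:
    """Write matches as stroke-log CSV (header always present).

    The inverse of :func:`read_stroke_log`: a written corpus reads back
    field-for-field identical.
    """
    if matches:
        frame = pd.concat([match_to_frame(m) for m in matches], ignore_index=True)
    else:
        frame = pd.DataFrame(columns=LOG_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.6f")


def _infer_winner(
    score_before: tuple[int, int],
    score_after: tuple[int, int] | None,
    players: tuple[str, str],
    match_id: str,
    set_index: int,
    point_index: int,
) -> str:
    if score_after is not None and score_after[0] != score_before[0]:
        return players[0]
    if score_after is not None and score_after[1] != score_before[1]:
        return players[1]
    if score_after is None:
        # Last rally of a set: the winner is whoever stood at game point.
        p1_gp = score_before[0] > score_before[1]
        p2_gp = score_before[1] > score_before[0]
        if p1_gp:
            return players[0]
        if p2_gp:
            return players[1]
    raise ValidationError(
        f"match {match_id!r}, set {set_index}, point {point_index}: "
        "cannot infer the point winner from score deltas; "
        "provide an explicit 'winner' column"
    )


def read_stroke_log(source, geom: CourtGeometry | None = None) -> list[Match]:
    """Read a stroke-log CSV into validated :class:`Match` objects.

    Rallies are reconstructed by grouping on ``(set, point)`` within each
    match, ordered by stroke number.  Point winners come from the ``winner``
    column when present, otherwise from the score change at the next rally
    of the same set; the last rally of a set is attributed to the player who
    stood at game point, which is ambiguous (and raises) when that rally
    started level -- files written by :func:`write_stroke_log` always carry
    the explicit column.  When the ``zone`` column is absent, zones are
    derived from the coordinates via :func:`assign_zone`.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If a rally violates the alternation or stroke-numbering invariants.
    """
    if geom is None:
        geom = CourtGeometry()
    frame = pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"stroke log is missing required column(s): {', '.join(missing)}")
    if "zone" not in frame.columns:
        frame["zone"] = assign_zones(frame["x"].to_numpy(), frame["y"].to_numpy(), geom)
    has_winner = "winner" in frame.columns

    matches: list[Match] = []
    for match_id, mf in frame.groupby("match_id", sort=False):
        players_seen = list(dict.fromkeys(mf["player"].astype(str)))
        if len(players_seen) != 2:
            raise ValidationError(
                f"match {match_id!r}: expected exactly 2 players, found {players_seen}"
            )
        players = (players_seen[0], players_seen[1])
        rallies: list[Rally] = []
        groups = list(mf.groupby(["set", "point"], sort=True))
        for gi, ((set_idx, point_idx), rf) in enumerate(groups):
            rf = rf.sort_values("stroke_no")
            strokes = [
                StrokeRecord(
                    set_index=int(r["set"]),
                    point_index=int(r["point"]),
                    stroke_number=int(r["stroke_no"]),
                    player_id=str(r["player"]),
                    zone=int(r["zone"]),
                    x=float(r["x"]),
                    y=float(r["y"]),
                    score_p1=int(r["score_p1"]),
                    score_p2=int(r["score_p2"]),
                )
                for _, r in rf.iterrows()
            ]
            score_before = (strokes[0].score_p1, strokes[0].score_p2)
            if has_winner:
                winner = str(rf["winner"].iloc[0])
            else:
                nxt = groups[gi + 1][1] if gi + 1 < len(groups) else None
                same_set = nxt is not None and int(nxt["set"].iloc[0]) == int(set_idx)
                score_after = (
                    (int(nxt["score_p1"].iloc[0]), int(nxt["score_p2"].iloc[0]))
                    if same_set
                    else None
                )
                winner = _infer_winner(
                    score_before, score_after, players, str(match_id), int(set_idx), int(point_idx)
                )
            rallies.append(Rally(strokes=strokes, winner_id=winner, score_before=score_before))
        match = Match(match_id=str(match_id), players=players, rallies=rallies)
        match.validate()
        matches.append(match)
    return matches
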