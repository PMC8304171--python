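"""Court geometry, zone assignment, and stroke-log round-tripping."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from courtentropy import (
    CORNER_ZONES,
    CourtGeometry,
    assign_zone,
    assign_zones,
    read_stroke_log,
    write_stroke_log,
)
from courtentropy.court import LOG_COLUMNS, match_to_frame
from courtentropy.errors import FormatError, InvalidInputError, ValidationError
from courtentropy.synthetic import SyntheticConfig, generate_corpus


class TestAssignZone:
    @pytest.mark.parametrize(
        "x, y, zone",
        [
            (0.5, 1.0, 1),  # front-left cell
            (5.0, 6.5, 12),  # back-right cell
            (2.0, 7.5, 10),  # behind the baseline: clamped to back row
            (-1.0, 1.0, 1),  # left of the sideline: clamped to column 1
            (2.0, 3.0, 6),  # middle row, second column
        ],
    )
    def test_examples(self, x, y, zone, geom):
        assert assign_zone(x, y, geom) == zone

    def test_cell_centers_row_major(self, geom):
        zones = [assign_zone(*geom.zone_center(z), geom) for z in range(1, 13)]
        assert zones == list(range(1, 13))

    def test_corner_cells_are_the_corner_zones(self, geom):
        eps = 1e-6
        corners = [
            (eps, eps),
            (geom.width - eps, eps),
            (eps, geom.depth - eps),
            (geom.width - eps, geom.depth - eps),
        ]
        assert sorted(assign_zone(x, y, geom) for x, y in corners) == sorted(CORNER_ZONES)

    def test_nonfinite_rejected(self, geom):
        with pytest.raises(InvalidInputError):
            assign_zone(float("nan"), 1.0, geom)
        with pytest.raises(InvalidInputError):
            assign_zone(1.0, float("inf"), geom)

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.floats(min_value=-2.0, max_value=8.0, allow_nan=False),
        y=st.floats(min_value=-2.0, max_value=9.0, allow_nan=False),
    )
    def test_every_coordinate_maps_to_exactly_one_zone(self, x, y):
        geom = CourtGeometry()
        z = assign_zone(x, y, geom)
        assert 1 <= z <= 12
        # in-bounds points land in the cell whose bounds contain them
        if 0 <= x < geom.width and 0 <= y < geom.depth:
            x0, x1, y0, y1 = geom.zone_bounds(z)
            assert x0 <= x < x1 + 1e-12 and y0 <= y < y1 + 1e-12

    def test_vectorized_matches_scalar(self, geom):
        rng = np.random.default_rng(0)
        xs = rng.uniform(-1, 6, 200)
        ys = rng.uniform(-1, 8, 200)
        vec = assign_zones(xs, ys, geom)
        assert [assign_zone(x, y, geom) for x, y in zip(xs, ys)] == vec.tolist()


class TestStrokeLogIO:
    def test_round_trip_is_lossless(self, tmp_path):
        ds = generate_corpus(SyntheticConfig(n_matches=2, seed=42))
        path = tmp_path / "corpus.csv"
        write_stroke_log(ds.matches, path)
        back = read_stroke_log(path)
        assert len(back) == 2
        for m0, m1 in zip(ds.matches, back):
            assert m0.match_id == m1.match_id
            assert m0.L == m1.L
            for r0, r1 in zip(m0.rallies, m1.rallies):
                assert r0.winner_id == r1.winner_id
                assert r0.score_before == r1.score_before
                for s0, s1 in zip(r0.strokes, r1.strokes):
                    assert (s0.zone, s0.player_id, s0.stroke_number) == (
                        s1.zone,
                        s1.player_id,
                        s1.stroke_number,
                    )
                    assert s0.x == pytest.approx(s1.x, abs=1e-5)
                    assert s0.y == pytest.approx(s1.y, abs=1e-5)

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_stroke_log([], path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == LOG_COLUMNS
        assert len(frame) == 0

    def test_missing_required_column_named_in_error(self, tmp_path):
        ds = generate_corpus(SyntheticConfig(n_matches=1, seed=3))
        frame = match_to_frame(ds.matches[0]).drop(columns=["player"])
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(FormatError, match="player"):
            read_stroke_log(path)

    def test_zone_column_derived_from_coordinates(self, tmp_path):
        ds = generate_corpus(SyntheticConfig(n_matches=1, seed=3))
        frame = match_to_frame(ds.matches[0]).drop(columns=["zone"])
        path = tmp_path / "nozone.csv"
        frame.to_csv(path, index=False)
        back = read_stroke_log(path)
        expect = [s.zone for s in ds.matches[0].strokes()]
        assert [s.zone for s in back[0].strokes()] == expect

    def test_winner_inferred_from_score_deltas(self):
        rows = [
            # set, point, stroke_no, player, zone, x, y, s1, s2
            (1, 1, 1, "a", 1, 0.5, 0.5, 0, 0),
            (1, 1, 2, "b", 2, 1.5, 0.5, 0, 0),
            (1, 2, 1, "b", 3, 2.6, 0.5, 0, 1),  # b's score moved: b won point 1
            (1, 2, 2, "a", 4, 4.0, 0.5, 0, 1),
        ]
        frame = pd.DataFrame(
            [("m1", *r) for r in rows],
            columns=[c for c in LOG_COLUMNS if c != "winner"],
        )
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        (match,) = read_stroke_log(buf)
        assert match.rallies[0].winner_id == "b"
        # last rally of the set: attributed to the player at game point
        assert match.rallies[1].winner_id == "b"

    def test_nonconsecutive_stroke_numbers_rejected(self):
        rows = [
            ("m1", 1, 1, 1, "a", 1, 0.5, 0.5, 0, 0, "a"),
            ("m1", 1, 1, 3, "b", 2, 1.5, 0.5, 0, 0, "a"),
        ]
        frame = pd.DataFrame(rows, columns=LOG_COLUMNS)
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(ValidationError, match="not consecutive"):
            read_stroke_log(buf)

    def test_non_alternating_strikers_rejected(self):
        rows = [
            ("m1", 1, 1, 1, "a", 1, 0.5, 0.5, 0, 0, "a"),
            ("m1", 1, 1, 2, "a", 2, 1.5, 0.5, 0, 0, "a"),
            ("m1", 1, 2, 1, "b", 2, 1.5, 0.5, 1, 0, "a"),
        ]
        frame = pd.DataFrame(rows, columns=LOG_COLUMNS)
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(ValidationError, match="same player"):
            read_stroke_log(buf)
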