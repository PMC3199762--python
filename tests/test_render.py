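"""Scene geometry, tick ladder, color assignment, and deterministic export."""

import hashlib
import xml.etree.ElementTree as ET

import numpy as np
import pytest
from PIL import Image

from syntenyviz import (
    CanvasSpec,
    Interval,
    SyntenyRecord,
    Viewport,
    build_dataset,
    export_png,
    export_svg,
    initial_state,
    render_figure,
    ruler_ticks,
    scene_to_svg,
    to_canvas_x,
    visible_records,
)
from syntenyviz.colors import PALETTE, resolve_color, sequential
from syntenyviz.render import (
    assign_colors,
    layout_synteny,
    ribbon_is_crossed,
    tick_step,
    to_bp,
)
from syntenyviz.viewmodel import record_sides


def _flat_canvas():
    # margin 0 and a bare width make the linear map easy to check by hand
    return CanvasSpec(width_px=800, height_px=400, margin=0)


class TestCanvasTransform:
    def test_left_edge_of_first_base_is_zero(self):
        vp = Viewport("s", 1, 1000)
        assert to_canvas_x(1, vp, _flat_canvas()) == 0.0

    def test_midpoint_maps_linearly(self):
        vp = Viewport("s", 1, 1000)
        assert to_canvas_x(501, vp, _flat_canvas()) == pytest.approx(400.0)

    def test_round_trip_inverse(self):
        vp = Viewport("s", 37, 4111)
        canvas = CanvasSpec()
        for pos in (37, 38, 1000, 4111):
            x = to_canvas_x(pos, vp, canvas)
            assert to_bp(x, vp, canvas) == pytest.approx(pos)

    def test_positions_outside_viewport_extrapolate(self):
        vp = Viewport("s", 101, 200)
        assert to_canvas_x(1, vp, _flat_canvas()) < 0


def _brute_force_step(start, end, max_ticks):
    candidates = sorted(m * 10 ** k for k in range(13) for m in (1, 2, 5))
    for step in candidates:
        if end // step - (start - 1) // step <= max_ticks:
            return step
    raise AssertionError("no step")


class TestRulerTicks:
    def test_span_1000_max_11_steps_by_100(self):
        ticks = ruler_ticks(Viewport("s", 1, 1000), max_ticks=11)
        assert [pos for pos, _ in ticks] == list(range(100, 1001, 100))

    def test_tiny_span_steps_by_1(self):
        ticks = ruler_ticks(Viewport("s", 4, 10), max_ticks=10)
        assert [pos for pos, _ in ticks] == list(range(4, 11))

    def test_matches_brute_force_ladder_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            start = int(rng.integers(1, 10**7))
            end = start + int(rng.integers(1, 10**7))
            max_ticks = int(rng.integers(2, 20))
            assert tick_step(start, end, max_ticks) == _brute_force_step(
                start, end, max_ticks
            )
            ticks = ruler_ticks(Viewport("s", start, end), max_ticks)
            assert len(ticks) <= max_ticks

    def test_labels_use_unit_suffix_and_separators(self):
        ticks = ruler_ticks(Viewport("s", 1, 10_000_000), max_ticks=6)
        assert all(label.endswith("Mb") for _, label in ticks)
        ticks = ruler_ticks(Viewport("s", 1, 100_000), max_ticks=6)
        assert all(label.endswith("kb") for _, label in ticks)
        # bp-scale steps at high coordinates get thousands separators
        ticks = ruler_ticks(Viewport("s", 999_000, 1_000_000), max_ticks=6)
        assert all(label.endswith("bp") and "," in label for _, label in ticks)


class TestColors:
    def test_categorical_cycles_palette(self):
        recs = [
            SyntenyRecord("A", Interval(1, 10), "B", Interval(1, 10), {})
            for _ in range(14)
        ]
        colors = assign_colors(recs, "categorical")
        assert colors[:2] == [PALETTE[0], PALETTE[1]]
        assert colors[12] == PALETTE[0]

    def test_attribute_scheme_minmax_normalizes(self):
        recs = [
            SyntenyRecord("A", Interval(1, 10), "B", Interval(1, 10), {"score": v})
            for v in (0.0, 50.0, 100.0)
        ]
        colors = assign_colors(recs, "attribute:score")
        assert colors == [sequential(0.0), sequential(0.5), sequential(1.0)]

    def test_constant_attribute_gets_midpoint(self):
        recs = [
            SyntenyRecord("A", Interval(1, 10), "B", Interval(1, 10), {"score": 5.0})
            for _ in range(3)
        ]
        assert set(assign_colors(recs, "attribute:score")) == {sequential(0.5)}

    def test_named_colors_resolve_to_hex(self):
        assert resolve_color("blue") == "#0000ff"
        assert resolve_color("#A1B2C3") == "#a1b2c3"


class TestSyntenyLayout:
    def test_ribbon_corners_match_linear_transform(self, demo_dataset, demo_state):
        canvas = CanvasSpec()
        scene = render_figure(demo_dataset, demo_state, canvas)
        ribbons = [g for g in scene.glyphs if g.kind == "ribbon"]
        visible = visible_records(demo_dataset, demo_state)
        assert len(ribbons) == len(visible)
        for glyph in ribbons:
            rec = glyph.source
            iv_a, iv_b = record_sides(rec, demo_state.pair)
            xa = [to_canvas_x(p, demo_state.viewport_a, canvas)
                  for p in (iv_a.start, iv_a.end)]
            xb = [to_canvas_x(p, demo_state.viewport_b, canvas)
                  for p in (iv_b.start, iv_b.end)]
            got_top = [glyph.points[0][0], glyph.points[1][0]]
            got_bottom = sorted([glyph.points[2][0], glyph.points[3][0]])
            assert got_top == pytest.approx(xa, abs=1e-6)
            assert got_bottom == pytest.approx(sorted(xb), abs=1e-6)

    def test_only_inverted_records_self_cross(self, demo_dataset, demo_state):
        scene = render_figure(demo_dataset, demo_state)
        ribbons = [g for g in scene.glyphs if g.kind == "ribbon"]
        assert any(r.source.is_inverted for r in ribbons)
        assert any(not r.source.is_inverted for r in ribbons)
        for glyph in ribbons:
            assert ribbon_is_crossed(glyph) == glyph.source.is_inverted

    def test_lines_mode_one_segment_per_record(self, demo_dataset, demo_state):
        demo_state.display_mode = "lines"
        scene = render_figure(demo_dataset, demo_state)
        segments = [g for g in scene.glyphs if g.kind == "segment"]
        assert len(segments) == len(visible_records(demo_dataset, demo_state))
        assert not any(g.kind == "ribbon" for g in scene.glyphs)

    def test_glyphs_clipped_to_canvas(self, demo_dataset, demo_state):
        # zoom far in so most ribbons extend past the window edges
        demo_state.viewport_a = Viewport(demo_state.pair[0], 200_000, 210_000)
        demo_state.viewport_b = Viewport(demo_state.pair[1], 1, 5_000)
        scene = render_figure(demo_dataset, demo_state)
        c = scene.canvas
        for g in scene.glyphs:
            for x, y in g.points:
                assert -1e-9 <= x <= c.width_px
                assert -1e-9 <= y <= c.height_px


class TestTrackLayout:
    def test_hidden_track_produces_no_glyphs(self, demo_dataset, demo_state):
        scene = render_figure(demo_dataset, demo_state)
        b_tracks = [
            g for g in scene.glyphs
            if g.source is not None and getattr(g.source, "track", None) == "transposon"
            and g.source.seq == demo_state.pair[1]
        ]
        assert b_tracks == []
        a_tracks = [
            g for g in scene.glyphs
            if g.source is not None and getattr(g.source, "track", None) == "transposon"
            and g.source.seq == demo_state.pair[0]
        ]
        assert a_tracks  # still drawn on panel A

    def test_per_track_glyph_count_equals_overlapping_features(
        self, demo_dataset, demo_state
    ):
        scene = render_figure(demo_dataset, demo_state)
        for track in ("gene", "expression"):
            drawn = [
                g for g in scene.glyphs
                if getattr(g.source, "track", None) == track
                and g.source.seq == demo_state.pair[0]
            ]
            expected = [
                f for f in demo_dataset.features
                if f.seq == demo_state.pair[0] and f.track == track
                and f.interval.overlaps(
                    demo_state.viewport_a.start, demo_state.viewport_a.end
                )
            ]
            assert len(drawn) == len(expected)

    def test_style_override_changes_shape_and_color(self, demo_dataset, demo_state):
        demo_state.tracks.style_override["gene"] = ("box", "red")
        scene = render_figure(demo_dataset, demo_state)
        gene_glyphs = [
            g for g in scene.glyphs if getattr(g.source, "track", None) == "gene"
        ]
        assert gene_glyphs
        assert all(g.kind == "box" and g.fill == "#ff0000" for g in gene_glyphs)

    def test_swapping_track_order_swaps_lane_y(self, demo_dataset, demo_state):
        def lane_ys(state):
            scene = render_figure(demo_dataset, state)
            ys = {}
            for g in scene.glyphs:
                track = getattr(g.source, "track", None)
                if track and g.source.seq == state.pair[0]:
                    ys.setdefault(track, set()).update(round(y) for _, y in g.points)
            return ys

        ys1 = lane_ys(demo_state)
        demo_state.tracks.order_a = ["expression", "gene", "transposon"]
        ys2 = lane_ys(demo_state)
        assert ys1["transposon"] == ys2["transposon"]
        assert ys1["gene"] != ys2["gene"]

    def test_dot_strand_arrow_falls_back_to_box(self):
        from syntenyviz import AnnotationFeature

        feats = [
            AnnotationFeature("A", Interval(10, 90), "gene", "arrow", "blue", "."),
            AnnotationFeature("A", Interval(200, 290), "gene", "arrow", "blue", "+"),
        ]
        records = [SyntenyRecord("A", Interval(1, 1000), "B", Interval(1, 1000), {})]
        ds = build_dataset(records, feats)
        scene = render_figure(ds, initial_state(ds))
        kinds = {g.source.strand: g.kind for g in scene.glyphs if g.source in feats}
        assert kinds == {".": "box", "+": "arrow"}


class TestExport:
    def test_empty_dataset_scene_has_rulers_and_ticks_only(self):
        records = [SyntenyRecord("A", Interval(1, 1000), "B", Interval(1, 1000), {})]
        ds = build_dataset(records)
        state = initial_state(ds)
        state.filters = []
        ds.records = []  # nothing to draw between the rulers
        scene = render_figure(ds, state)
        kinds = {g.kind for g in scene.glyphs}
        assert kinds == {"ruler", "tick", "tick_label", "text"}
        assert sum(g.kind == "ruler" for g in scene.glyphs) == 2

    def test_svg_bytes_identical_across_runs(self, demo_dataset, demo_state, tmp_path):
        digests = set()
        for i in range(3):
            scene = render_figure(demo_dataset, demo_state)
            path = export_svg(scene, tmp_path / f"fig{i}.svg")
            digests.add(hashlib.sha256(path.read_bytes()).hexdigest())
        assert len(digests) == 1

    def test_svg_element_count_equals_glyphs_plus_chrome(
        self, demo_dataset, demo_state
    ):
        scene = render_figure(demo_dataset, demo_state)
        root = ET.fromstring(scene_to_svg(scene))
        drawable = [el for el in root if not el.tag.endswith("}rect")]
        assert len(drawable) == len(scene.glyphs)

    def test_svg_is_well_formed_with_expected_size(self, demo_dataset, demo_state):
        scene = render_figure(demo_dataset, demo_state)
        root = ET.fromstring(scene_to_svg(scene))
        assert root.get("width") == str(scene.canvas.width_px)
        assert root.get("height") == str(scene.canvas.height_px)

    def test_png_dimensions_follow_dpi(self, demo_dataset, demo_state, tmp_path):
        scene = render_figure(demo_dataset, demo_state)
        p96 = export_png(scene, tmp_path / "fig.png", dpi=96)
        with Image.open(p96) as img:
            assert img.size == (scene.canvas.width_px, scene.canvas.height_px)
        p192 = export_png(scene, tmp_path / "fig2.png", dpi=192)
        with Image.open(p192) as img:
            assert img.size == (scene.canvas.width_px * 2, scene.canvas.height_px * 2)
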