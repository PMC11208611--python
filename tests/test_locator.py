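"""Cell locator: segmentation, gates, position lists, longitudinal matching."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotfm import locator, phantom
from cardiotfm.fields import ImagingConfig
from cardiotfm.locator import CellRecord, GateSpec, PositionList


def survey_imaging(shape=(1000, 1120)):
    return ImagingConfig(px_size=0.9, fps=1.0, frame_shape=shape,
                         crop_window_um=(shape[0] * 0.9 - 1, shape[1] * 0.9 - 1))


def twenty_cell_specs(seed=5):
    """20 cells on a ~200 µm pitch grid with varied morphology."""
    rng = np.random.default_rng(seed)
    specs = []
    for gy in range(4):
        for gx in range(5):
            specs.append(((150 + gx * 200.0, 130 + gy * 230.0),
                          rng.uniform(400, 2500), rng.uniform(1.5, 8),
                          rng.uniform(0, 180)))
    return specs


def record(area, ar, x=0.0, y=0.0, cid="c"):
    return CellRecord(cell_id=cid, stage_x_um=x, stage_y_um=y,
                      area_um2=area, aspect_ratio=ar)


class TestSegmentSurvey:
    def test_twenty_cell_phantom_measured_accurately(self):
        imaging = survey_imaging()
        img, truth = phantom.make_survey_phantom(twenty_cell_specs(), imaging, seed=3)
        records = locator.segment_survey(img, 0.9)
        assert len(records) == 20
        det_x = np.array([r.stage_x_um for r in records])
        det_y = np.array([r.stage_y_um for r in records])
        for _, row in truth.iterrows():
            j = int(np.argmin(np.hypot(det_x - row.x_um, det_y - row.y_um)))
            assert records[j].area_um2 == pytest.approx(row.area_um2, rel=0.10)
            assert records[j].aspect_ratio == pytest.approx(row.aspect_ratio, rel=0.15)

    def test_detection_count_exact_across_seeds(self):
        """Well-separated phantoms segment without merges or splits."""
        imaging = survey_imaging()
        for seed in range(5):
            img, truth = phantom.make_survey_phantom(twenty_cell_specs(seed + 10),
                                                     imaging, seed=seed)
            assert len(locator.segment_survey(img, 0.9)) == len(truth)

    def test_blank_tile_gives_empty_list(self):
        with pytest.warns(UserWarning, match="blank|uniform"):
            assert locator.segment_survey(np.full((300, 300), 1200, np.uint16), 0.9) == []

    def test_known_pattern_geometry(self):
        """A single 2500 µm², 7:1 cell is measured near its design values."""
        imaging = survey_imaging((800, 800))
        img, _ = phantom.make_survey_phantom([((360.0, 360.0), 2500.0, 7.0, 25.0)],
                                             imaging, seed=1)
        records = locator.segment_survey(img, 0.9)
        assert len(records) == 1
        assert records[0].area_um2 == pytest.approx(2500.0, rel=0.10)
        assert records[0].aspect_ratio == pytest.approx(7.0, rel=0.15)


class TestGates:
    @pytest.mark.parametrize("area,ar,selected", [
        (700.0, 4.0, True),        # typical micropatterned cardiomyocyte
        (250.0, 4.0, False),       # below the area gate
        (300.0, 1.5, True),        # inclusive lower bounds
        (3500.0, 12.0, True),      # inclusive upper bounds
        (3500.1, 4.0, False),
        (700.0, 12.5, False),
    ])
    def test_boundary_rules(self, area, ar, selected):
        sel, rej = locator.apply_gates([record(area, ar)])
        assert (len(sel) == 1) == selected
        assert len(sel) + len(rej) == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(1, 5000), st.floats(1, 20)), max_size=30))
    def test_partition_is_exhaustive_and_disjoint(self, pairs):
        records = [record(a, r, cid=f"c{i}") for i, (a, r) in enumerate(pairs)]
        sel, rej = locator.apply_gates(records)
        assert len(sel) + len(rej) == len(records)
        assert {id(r) for r in sel}.isdisjoint({id(r) for r in rej})

    def test_quadrant_assignment(self):
        out = locator.quadrant_gate(
            [record(900, 5.0), record(704, 3.88), record(500, 5.0),
             record(500, 2.0), record(900, 2.0)],
            median_area_um2=704.0, median_ar=3.88)
        assert [r.quadrant for r in out] == ["I", "I", "II", "III", "IV"]

    def test_quadrant_median_split_property(self):
        rng = np.random.default_rng(4)
        recs = [record(a, r, cid=f"c{i}") for i, (a, r) in
                enumerate(zip(rng.uniform(300, 3000, 51), rng.uniform(1.5, 10, 51)))]
        med_a = float(np.median([r.area_um2 for r in recs]))
        med_r = float(np.median([r.aspect_ratio for r in recs]))
        out = locator.quadrant_gate(recs, med_a, med_r)
        big = sum(r.area_um2 >= med_a for r in out)
        assert abs(big - len(out) / 2) <= 1


class TestPositionLists:
    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        plist = PositionList(
            positions=[(f"cell-{i:03d}", float(x), float(y), float(z))
                       for i, (x, y, z) in enumerate(rng.uniform(0, 5000, (200, 3)))],
            device="dev-A", day=20, px_size=0.9)
        path = tmp_path / "positions.json"
        locator.write_position_list(plist, path)
        back = locator.read_position_list(path)
        assert back.positions == plist.positions
        assert back.device == "dev-A" and back.day == 20

    def test_empty_list_valid(self, tmp_path):
        path = tmp_path / "empty.json"
        locator.write_position_list(PositionList(positions=[]), path)
        assert locator.read_position_list(path).positions == []

    def test_micromanager_dialect_import(self, tmp_path):
        """Synthetic Micro-Manager 1.4 `.pos` document imports exactly."""
        doc = {"VERSION": 3, "ID": "Micro-Manager XY-position list",
               "POSITIONS": [
                   {"LABEL": "Pos0", "DEVICES": [
                       {"DEVICE": "XYStage", "AXES": 2, "X": 1234.5, "Y": -87.25},
                       {"DEVICE": "ZStage", "AXES": 1, "X": 3001.125}]},
                   {"LABEL": "Pos1", "DEVICES": [
                       {"DEVICE": "XYStage", "AXES": 2, "X": -15.0, "Y": 42.0},
                       {"DEVICE": "ZStage", "AXES": 1, "X": 3002.0}]},
               ]}
        path = tmp_path / "mm.pos"
        path.write_text(json.dumps(doc))
        plist = locator.read_position_list(path)
        assert plist.positions == [("Pos0", 1234.5, -87.25, 3001.125),
                                   ("Pos1", -15.0, 42.0, 3002.0)]

    def test_malformed_json_diagnostics(self, tmp_path):
        path = tmp_path / "broken.pos"
        path.write_text('{"POSITIONS": [\n  {"LABEL": }\n]}')
        with pytest.raises(ValueError, match="line 2"):
            locator.read_position_list(path)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PositionList(positions=[("a", 0, 0, 0), ("a", 1, 1, 0)])


class TestLongitudinalMatching:
    def _grid_list(self, prefix, n=30, shift=(0.0, 0.0), drop=()):
        pos = []
        k = 0
        for gy in range(5):
            for gx in range(6):
                if k not in drop:
                    pos.append((f"{prefix}{k}", 100.0 + gx * 200 + shift[0],
                                80.0 + gy * 200 + shift[1], 0.0))
                k += 1
        return PositionList(positions=pos)

    def test_identical_lists_fully_matched(self):
        a = self._grid_list("a")
        res = locator.match_longitudinal(a, self._grid_list("b"))
        assert res.offset_um == (0.0, 0.0)
        assert len(res.pairs) == 30 and not res.lost and not res.new

    def test_shift_with_attrition(self):
        """(30, -12) µm drift and 10% attrition: offset within 1 µm, all
        survivors re-identified, the removed cells reported lost."""
        a = self._grid_list("a")
        b = self._grid_list("b", shift=(30.0, -12.0), drop=(4, 11, 27))
        res = locator.match_longitudinal(a, b)
        assert res.offset_um[0] == pytest.approx(30.0, abs=1.0)
        assert res.offset_um[1] == pytest.approx(-12.0, abs=1.0)
        assert len(res.pairs) == 27
        assert sorted(res.lost) == ["a11", "a27", "a4"]

    def test_symmetry(self):
        a = self._grid_list("a")
        b = self._grid_list("b", shift=(18.0, 7.0))
        fwd = locator.match_longitudinal(a, b)
        bwd = locator.match_longitudinal(b, a)
        assert fwd.offset_um[0] == pytest.approx(-bwd.offset_um[0], abs=1e-9)
        assert fwd.offset_um[1] == pytest.approx(-bwd.offset_um[1], abs=1e-9)
        assert sorted((y, x) for x, y in fwd.pairs) == sorted(bwd.pairs)

    def test_ambiguous_contenders_dropped(self):
        a = PositionList(positions=[("a0", 0.0, 0.0, 0.0), ("a1", 20.0, 0.0, 0.0),
                                    ("a2", 500.0, 0.0, 0.0)])
        b = PositionList(positions=[("b0", 10.0, 0.0, 0.0), ("b2", 500.0, 0.0, 0.0)])
        with pytest.warns(UserWarning, match="multiple candidates"):
            res = locator.match_longitudinal(a, b, tolerance_um=50.0)
        assert ("a2", "b2") in res.pairs
        assert not any(x in ("a0", "a1") for x, _ in res.pairs)
        assert "a0" in res.lost and "a1" in res.lost
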