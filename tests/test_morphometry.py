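"""Cephalometric distances and angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwaymorph.landmarks import RAW, MissingLandmarkError
from airwaymorph.morphometry import (ANGLE_KEYS, MEASURE_KEYS, ap_shift,
                                     compute_measures, distance, fma_angle,
                                     horizontal_offset, vertex_angle,
                                     vertical_offset)
from airwaymorph.reorient import apply_transform, compute_reorientation
from airwaymorph.synthetic import TEMPLATE_POINTS, random_rigid

#: published adult ranges (min, max) for every measure
PUBLISHED_RANGES = {
    "Na-B": (77.1, 118), "Na-A": (47.3, 67.0), "AB-shift": (-12.1, 13.9),
    "S-Na": (58.6, 77.9), "BEP-A": (75.0, 102), "BEP-TUV": (15.5, 43.8),
    "SNPg": (68.7, 93.4), "FMA": (18.2, 48.1), "HSP": (11.1, 34.9),
    "Me-rGo": (57.5, 95.8), "C3-H": (25.8, 45.2), "H-S-Ba": (25.6, 54.7),
    "H-Na-S": (46.8, 68.6), "S-H": (77.9, 122), "Me-H": (27.7, 51.7),
    "H-PNS": (44.2, 76.0), "TUV-PNS": (27.1, 44.9), "rTb-lTb": (41.7, 58.3),
    "Na-ANS": (42.2, 60.5), "rCN-lCN": (12.9, 54.4), "SNA": (72.8, 92.2),
    "SNB": (66.6, 96.5), "Ba-Tph": (11.3, 38.9), "VSP": (26.6, 49.0),
    "rGo-lGo": (78.8, 107),
}


def brute_force_measures(pts: dict) -> dict:
    """Independent per-measure computation straight from the definitions."""
    p = {k: np.asarray(v, dtype=float) for k, v in pts.items()}

    def d(a, b):
        return float(np.sqrt(np.sum((p[a] - p[b]) ** 2)))

    def ang(a, v, b):
        u, w = p[a] - p[v], p[b] - p[v]
        return float(np.degrees(np.arccos(
            np.dot(u, w) / np.sqrt(np.dot(u, u) * np.dot(w, w)))))

    fh = (p["rOr"] - p["rPo"])[[0, 2]]
    mand = (p["rGo"] - p["Me"])[[0, 2]]
    cosv = abs(np.dot(fh, mand)) / np.sqrt(np.dot(fh, fh) * np.dot(mand, mand))
    return {
        "Me-rGo": d("Me", "rGo"), "rGo-lGo": d("rGo", "lGo"),
        "Na-B": d("Na", "B"), "Na-A": d("Na", "A"),
        "AB-shift": float(p["A"][0] - p["B"][0]), "S-Na": d("S", "Na"),
        "C3-H": d("C3", "H"), "Me-H": d("Me", "H"), "H-PNS": d("H", "PNS"),
        "S-H": d("S", "H"), "rTb-lTb": d("rTb", "lTb"),
        "rCN-lCN": d("rCN", "lCN"), "Na-ANS": d("Na", "ANS"),
        "BEP-A": d("BEP", "A"), "BEP-TUV": d("BEP", "TUV"),
        "HSP": float(abs(p["PNS"][0] - p["LP"][0])),
        "TUV-PNS": d("TUV", "PNS"), "Ba-Tph": d("Ba", "Tph"),
        "VSP": float(abs(p["PNS"][2] - p["TUV"][2])),
        "SNA": ang("S", "Na", "A"), "SNB": ang("S", "Na", "B"),
        "SNPg": ang("S", "Na", "Pg"),
        "FMA": float(np.degrees(np.arccos(cosv))),
        "H-S-Ba": ang("H", "S", "Ba"), "H-Na-S": ang("H", "Na", "S"),
    }


class TestPrimitives:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1, 1, 1), (1, 1, 1), 0.0),
    ])
    def test_distance(self, a, b, expected):
        assert distance(a, b) == pytest.approx(expected)

    def test_distance_symmetry(self, rng):
        a, b = rng.normal(size=(2, 3))
        assert distance(a, b) == pytest.approx(distance(b, a), abs=1e-12)
        assert distance(a, b) == pytest.approx(
            np.sqrt(np.sum((a - b) ** 2)), abs=1e-12)

    @pytest.mark.parametrize("a,v,b,expected", [
        ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (0, 0, 0), (-1, 0, 0), 180.0),
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
    ])
    def test_vertex_angle(self, a, v, b, expected):
        assert vertex_angle(a, v, b) == pytest.approx(expected)
        assert vertex_angle(b, v, a) == pytest.approx(expected)

    def test_vertex_angle_zero_arm(self):
        with pytest.raises(ValueError):
            vertex_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_ap_shift(self):
        assert ap_shift((10, 1, 5), (6, -2, 30)) == pytest.approx(4.0)
        assert ap_shift((1, 2, 3), (1, 2, 3)) == 0.0
        assert ap_shift((0, 0, 0), (5, 0, 0)) < 0  # protrusive mandible

    def test_soft_palate_offsets(self):
        assert horizontal_offset((-40, 0, 20), (-55, 0, 12)) == pytest.approx(15.0)
        assert horizontal_offset((-40, 0, 20), (-40, 3, -10)) == 0.0
        assert vertical_offset((0, 0, 20), (5, 0, -16)) == pytest.approx(36.0)
        assert vertical_offset((0, 0, 7), (9, 9, 7)) == 0.0

    def test_fma(self):
        # mandibular line parallel to FH
        assert fma_angle((0, 0, 0), (10, 0, 0), (5, 0, -40),
                         (-5, 0, -40)) == pytest.approx(0.0)
        # direction (1,0,1) against (1,0,0)
        assert fma_angle((0, 0, 0), (10, 0, 0), (0, 0, 0),
                         (1, 0, 1)) == pytest.approx(45.0)


class TestComputeMeasures:
    def test_template_matches_brute_force(self, template):
        got = compute_measures(template)
        expected = brute_force_measures(TEMPLATE_POINTS)
        assert set(got) == set(MEASURE_KEYS)
        for key in MEASURE_KEYS:
            assert got[key] == pytest.approx(expected[key], abs=1e-9), key

    def test_template_inside_published_ranges(self, template_vals):
        for key, (lo, hi) in PUBLISHED_RANGES.items():
            assert lo <= template_vals[key] <= hi, key

    def test_rigid_invariance(self, template, template_vals, rng):
        """Measures are unchanged by any rigid pose applied before reorientation."""
        for _ in range(25):
            pose = random_rigid(rng, 20, 30)
            posed = apply_transform(template, pose).replace(frame=RAW)
            reo = apply_transform(posed, compute_reorientation(posed))
            got = compute_measures(reo)
            for key in MEASURE_KEYS:
                assert got[key] == pytest.approx(template_vals[key],
                                                 abs=1e-6), key

    def test_mirror_invariance(self, template, template_vals):
        """Reflecting the subject across the midsagittal plane changes nothing."""
        mirrored = {}
        for name, p in template.points.items():
            q = p * np.array([1.0, -1.0, 1.0])
            mirrored[name] = q
        # a mirrored subject has left/right labels swapped
        for r, l in (("rOr", "lOr"), ("rGo", "lGo"), ("rTb", "lTb"),
                     ("rCN", "lCN")):
            mirrored[r], mirrored[l] = mirrored[l], mirrored[r]
        got = compute_measures(template.replace(points=mirrored))
        for key in MEASURE_KEYS:
            assert got[key] == pytest.approx(template_vals[key], abs=1e-9), key

    def test_angles_within_bounds(self, template_vals):
        for key in ANGLE_KEYS:
            assert 0.0 < template_vals[key] < 180.0

    def test_raw_frame_rejected(self, template):
        with pytest.raises(ValueError, match="reoriented"):
            compute_measures(template.replace(frame=RAW))

    def test_missing_lp_flags_hsp_absent(self, template):
        noLP = template.replace(points={k: v for k, v in template.points.items()
                                        if k != "LP"})
        got = compute_measures(noLP)
        assert np.isnan(got["HSP"])
        assert np.isfinite(got["VSP"])

    def test_missing_required_landmark_is_named(self, template):
        broken = template.replace(points={k: v for k, v in template.points.items()
                                          if k != "Ba"})
        with pytest.raises(MissingLandmarkError, match="Ba"):
            compute_measures(broken)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sna_exceeds_snb_when_a_anterior(self, dx, dz):
        """With A anterior to B at equal depth below Na, SNA > SNB."""
        S, Na = np.array([0, 0, 0.0]), np.array([65, 0, 9.0])
        B = Na + np.array([dx, 0, -60 + dz])
        A = B + np.array([4.0, 0, 0])  # strictly anterior, same depth
        sna = vertex_angle(S, Na, A)
        snb = vertex_angle(S, Na, B)
        assert sna > snb
        assert ap_shift(A, B) > 0
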