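"""The 6 cephalometric angles and 19 distances, from a reoriented landmark set.

Most measures are plain Euclidean distances or vertex angles and are
invariant to rigid motion.  Four measures are *defined in the reoriented
frame* (anteroposterior A–B shift, horizontal and vertical soft-palate
offsets, FMA): they project onto the anatomical axes and therefore require
``frame == "reoriented"`` input — they are still invariant to rigid
pre-transforms of the raw data because reorientation normalises the pose.

Measure keys (columns of the measurement table):

========== ==============================================================
key        definition
========== ==============================================================
Me-rGo     mandible length, menton to right gonion
rGo-lGo    mandible width between gonia
Na-B       anteroposterior position of the mandible
Na-A       anteroposterior position of the maxilla
AB-shift   signed anteroposterior shift x_A − x_B (positive: A anterior)
S-Na       cranial-base length
C3-H       hyoid to third cervical vertebra
Me-H       hyoid to menton
H-PNS      hyoid to posterior nasal spine
S-H        hyoid to sella
rTb-lTb    maxilla width between tuberosities
rCN-lCN    nasal-cavity width
Na-ANS     nasal-cavity height
BEP-A      tongue height, epiglottis base to A point
BEP-TUV    tongue width, epiglottis base to uvula tip
HSP        horizontal soft palate |x_PNS − x_LP|
TUV-PNS    soft-palate length (Euclidean)
Ba-Tph     pharyngeal soft-tissue thickness, basion to Tph
VSP        vertical soft palate |z_PNS − z_TUV|
SNA        maxillary prognathism angle S–Na–A
SNB        mandibular prognathism angle S–Na–B
SNPg       facial angle S–Na–Pg
FMA        Frankfort–mandibular-plane angle (sagittal projection)
H-S-Ba     hyoid angle at sella
H-Na-S     hyoid angle at nasion
========== ==============================================================
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .landmarks import REORIENTED, LandmarkSet, MissingLandmarkError

#: distance measures as (key, landmark a, landmark b)
DISTANCE_PAIRS = (
    ("Me-rGo", "Me", "rGo"),
    ("rGo-lGo", "rGo", "lGo"),
    ("Na-B", "Na", "B"),
    ("Na-A", "Na", "A"),
    ("S-Na", "S", "Na"),
    ("C3-H", "C3", "H"),
    ("Me-H", "Me", "H"),
    ("H-PNS", "H", "PNS"),
    ("S-H", "S", "H"),
    ("rTb-lTb", "rTb", "lTb"),
    ("rCN-lCN", "rCN", "lCN"),
    ("Na-ANS", "Na", "ANS"),
    ("BEP-A", "BEP", "A"),
    ("BEP-TUV", "BEP", "TUV"),
    ("TUV-PNS", "TUV", "PNS"),
    ("Ba-Tph", "Ba", "Tph"),
)

#: vertex angles as (key, a, vertex, b)
ANGLE_TRIPLES = (
    ("SNA", "S", "Na", "A"),
    ("SNB", "S", "Na", "B"),
    ("SNPg", "S", "Na", "Pg"),
    ("H-S-Ba", "H", "S", "Ba"),
    ("H-Na-S", "H", "Na", "S"),
)

MEASURE_KEYS: tuple[str, ...] = tuple(
    [k for k, *_ in DISTANCE_PAIRS]
    + ["AB-shift", "HSP", "VSP", "FMA"]
    + [k for k, *_ in ANGLE_TRIPLES]
)

ANGLE_KEYS = ("SNA", "SNB", "SNPg", "FMA", "H-S-Ba", "H-Na-S")

#: landmarks needed for every measure except HSP (which needs LP and is
#: reported as missing rather than failing the whole vector)
REQUIRED_LANDMARKS = tuple(sorted({
    n for _, a, b in DISTANCE_PAIRS for n in (a, b)
} | {n for _, a, v, b in ANGLE_TRIPLES for n in (a, v, b)}
  | {"rPo", "rOr", "Me", "rGo", "PNS", "TUV", "A", "B"}))


def distance(a, b) -> float:
    """Euclidean distance in mm."""
    return float(np.linalg.norm(np.asarray(b, dtype=float) - np.asarray(a, dtype=float)))


def vertex_angle(a, v, b) -> float:
    """Angle ∠(a, v, b) at vertex v, in degrees."""
    u = np.asarray(a, dtype=float) - np.asarray(v, dtype=float)
    w = np.asarray(b, dtype=float) - np.asarray(v, dtype=float)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise ValueError("vertex angle undefined: zero-length arm")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(math.degrees(math.acos(c)))


def _require_reoriented(landmarks: LandmarkSet) -> None:
    if landmarks.frame != REORIENTED:
        raise ValueError(
            "measure is defined in the reoriented frame; got frame="
            f"{landmarks.frame!r} (run reorient.compute_reorientation first)")


def ap_shift(A, B) -> float:
    """Signed anteroposterior shift x_A − x_B of the FH-plane projections (mm).

    Positive when the A point is anterior to the B point; negative for a
    protrusive mandible.
    """
    return float(np.asarray(A, dtype=float)[0] - np.asarray(B, dtype=float)[0])


def horizontal_offset(PNS, LP) -> float:
    """Horizontal soft palate (HSP): |x_PNS − x_LP| in mm."""
    return float(abs(np.asarray(PNS, dtype=float)[0] - np.asarray(LP, dtype=float)[0]))


def vertical_offset(PNS, TUV) -> float:
    """Vertical soft palate (VSP): |z_PNS − z_TUV| in mm."""
    return float(abs(np.asarray(PNS, dtype=float)[2] - np.asarray(TUV, dtype=float)[2]))


def fma_angle(rPo, rOr, Me, rGo) -> float:
    """Frankfort–mandibular-plane angle in degrees, in (0°, 90°].

    Both line directions (rPo→rOr and Me→rGo) are projected onto the
    midsagittal x–z plane before taking the acute angle between them.
    """
    u = (np.asarray(rOr, dtype=float) - np.asarray(rPo, dtype=float))[[0, 2]]
    w = (np.asarray(rGo, dtype=float) - np.asarray(Me, dtype=float))[[0, 2]]
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise ValueError("FMA undefined: degenerate sagittal projection")
    c = np.clip(abs(np.dot(u, w)) / (nu * nw), 0.0, 1.0)
    return float(math.degrees(math.acos(c)))


def compute_measures(landmarks: LandmarkSet, age: float | None = None,
                     sex: str | float | None = None) -> dict[str, float]:
    """All 25 measures from a reoriented landmark set.

    ``age``/``sex`` are passed through as covariate columns.  A missing LP
    landmark yields ``HSP = nan`` (measure flagged absent); any other
    missing landmark raises :class:`MissingLandmarkError` naming it, which
    mirrors the study's non-inclusion rule for incomplete landmark sets.
    """
    _require_reoriented(landmarks)
    landmarks.require(REQUIRED_LANDMARKS)

    out: dict[str, float] = {}
    for key, a, b in DISTANCE_PAIRS:
        out[key] = distance(landmarks[a], landmarks[b])
    out["AB-shift"] = ap_shift(landmarks["A"], landmarks["B"])
    try:
        out["HSP"] = horizontal_offset(landmarks["PNS"], landmarks["LP"])
    except MissingLandmarkError:
        out["HSP"] = float("nan")
    out["VSP"] = vertical_offset(landmarks["PNS"], landmarks["TUV"])
    out["FMA"] = fma_angle(landmarks["rPo"], landmarks["rOr"],
                           landmarks["Me"], landmarks["rGo"])
    for key, a, v, b in ANGLE_TRIPLES:
        out[key] = vertex_angle(landmarks[a], landmarks[v], landmarks[b])

    out = {k: out[k] for k in MEASURE_KEYS}  # canonical column order
    if age is not None:
        out["age"] = float(age)
    if sex is not None:
        out["sex"] = float(sex) if not isinstance(sex, str) else float(sex == "F")
    return out


def measurement_table(landmark_sets, ages=None, sexes=None) -> pd.DataFrame:
    """Measurement table: one row per subject, canonical measure columns."""
    rows, index = [], []
    for i, lm in enumerate(landmark_sets):
        age = None if ages is None else ages[i]
        sex = None if sexes is None else sexes[i]
        rows.append(compute_measures(lm, age=age, sex=sex))
        index.append(lm.subject_id or str(i))
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
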