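"""Named 3D anatomical landmarks and their on-disk formats.

A :class:`LandmarkSet` maps landmark names (e.g. ``"Na"``, ``"PNS"``) to
3D coordinates in millimetres.  The ``frame`` tag records whether the set
is in the scanner/raw frame or has been reoriented to the anatomical
reference frame (+X anterior, +Y subject-left, +Z superior, origin at
sella); downstream measures that are defined in the reoriented frame
refuse raw input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The 24 landmarks of the craniofacial protocol plus LP, the most
#: posterior point of the soft-palate contour (needed by the horizontal
#: soft-palate measure).
LANDMARK_NAMES: tuple[str, ...] = (
    "A", "ANS", "B", "Ba", "BEP", "C3", "H", "lCN", "lGo", "lOr", "lTb",
    "MGNM", "Me", "Na", "Pg", "PNS", "rCN", "rGo", "rOr", "rPo", "rTb",
    "S", "Tph", "TUV", "LP",
)

RAW = "raw"
REORIENTED = "reoriented"


class MissingLandmarkError(KeyError):
    """A required anatomical landmark is absent from the set."""

    def __init__(self, names: Iterable[str]):
        self.missing = tuple(names)
        super().__init__(f"missing landmark(s): {', '.join(self.missing)}")


@dataclass
class LandmarkSet:
    """Named 3D points in mm for one subject."""

    points: dict[str, np.ndarray]
    frame: str = RAW
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.points = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()
        }
        for name, p in self.points.items():
            if not np.all(np.isfinite(p)):
                raise ValueError(f"non-finite coordinates for landmark {name!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError([name]) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def require(self, names: Iterable[str]) -> None:
        """Raise :class:`MissingLandmarkError` listing every absent name."""
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing)

    def as_array(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = tuple(names) if names is not None else self.names()
        return np.array([self[n] for n in names], dtype=float)

    def replace(self, points: Mapping[str, np.ndarray] | None = None,
                frame: str | None = None) -> "LandmarkSet":
        return LandmarkSet(
            points=dict(points if points is not None else self.points),
            frame=frame if frame is not None else self.frame,
            subject_id=self.subject_id,
        )

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": self.subject_id, "landmark": n,
             "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for n, p in self.points.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "subject_id": self.subject_id,
            "frame": self.frame,
            "landmarks": {n: list(map(float, p)) for n, p in self.points.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(points={n: np.array(p) for n, p in payload["landmarks"].items()},
                   frame=payload.get("frame", RAW),
                   subject_id=payload.get("subject_id", ""))


def cohort_to_csv(sets: Iterable[LandmarkSet], path) -> None:
    """Write landmark sets as long-format CSV (subject_id, landmark, x_mm, y_mm, z_mm)."""
    pd.concat([s.to_frame() for s in sets], ignore_index=True).to_csv(path, index=False)


def cohort_from_csv(path, frame: str = RAW) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        pts = {r.landmark: np.array([r.x_mm, r.y_mm, r.z_mm]) for r in grp.itertuples()}
        out.append(LandmarkSet(points=pts, frame=frame, subject_id=str(sid)))
    return out
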