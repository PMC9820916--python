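"""Synthetic cohorts of craniofacial landmark sets and airway voxel grids.

Because the study cohort (60 adult CBCT examinations) is not publicly
deposited, every downstream stage is exercised on synthetic subjects with
known ground truth.  A subject is built from a hand-crafted landmark
template in the canonical anatomical frame (+X anterior, +Y subject-left,
+Z superior, origin at sella), calibrated so that all 25 morphometric
measures fall within the ranges published for real adults:

* per-landmark isotropic Gaussian jitter creates between-subject shape
  variation (and hence measure variation),
* a random rigid pose (rotation, translation) simulates head position in
  the scanner — landmarks are delivered "raw" and must be reoriented,
* airway volume and minimal cross-sectional area are drawn from a planted
  linear model on the subject's own soft-palate, tongue and mandible
  measures (negative coefficient on the horizontal soft palate), and a
  voxelized tube with a cosine-modulated elliptical cross-section is
  constructed to realise exactly those targets.

The planted model is the recoverable ground truth for the statistics and
symbolic-regression stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarks import RAW, REORIENTED, LandmarkSet
from .morphometry import compute_measures
from .airway import VoxelGrid

#: Canonical landmark template (mm).  Hand-built so that every derived
#: measure lies inside published adult ranges; midline landmarks at y = 0,
#: the Frankfort landmarks (rPo, rOr, lOr) share z, origin at sella.
TEMPLATE_POINTS: dict[str, tuple[float, float, float]] = {
    "S":    (0.0, 0.0, 0.0),
    "Na":   (65.5, 0.0, 9.0),
    "A":    (65.1, 0.0, -48.1),
    "ANS":  (68.0, 0.0, -41.0),
    "PNS":  (18.0, 0.0, -42.0),
    "B":    (58.2, 0.0, -85.3),
    "Pg":   (59.7, 0.0, -94.8),
    "Me":   (55.0, 0.0, -100.0),
    "rGo":  (-2.8, -46.0, -62.1),
    "lGo":  (-2.8, 46.0, -62.1),
    "Ba":   (-25.0, 0.0, -40.0),
    "MGNM": (-35.0, 0.0, -50.0),
    "H":    (18.0, 0.0, -95.0),
    "C3":   (-12.0, 0.0, -85.0),
    "TUV":  (13.3, 0.0, -78.2),
    "LP":   (-1.1, 0.0, -60.0),
    "BEP":  (8.0, 0.0, -110.0),
    "Tph":  (-8.0, 0.0, -45.0),
    "rTb":  (25.0, -24.5, -45.0),
    "lTb":  (25.0, 24.5, -45.0),
    "rCN":  (45.0, -10.25, -20.0),
    "lCN":  (45.0, 10.25, -20.0),
    "rPo":  (-38.0, -58.0, -24.0),
    "rOr":  (55.0, -33.0, -24.0),
    "lOr":  (55.0, 33.0, -24.0),
}


def template_landmarks() -> LandmarkSet:
    """The canonical template as a reoriented-frame landmark set."""
    return LandmarkSet(points={k: np.array(v) for k, v in TEMPLATE_POINTS.items()},
                       frame=REORIENTED, subject_id="template")


def template_measures() -> dict[str, float]:
    return compute_measures(template_landmarks())

# Cohort-level calibration targets (means of the emulated population).
VOL_MEAN_MM3 = 14_460.0
CSA_MEAN_MM2 = 206.0
#: anteroposterior/lateral aspect ratio of the airway cross-section,
#: calibrated from published mean CSAmin extents (Ap 10.2 / Lat 27.0 mm)
AIRWAY_ASPECT = 10.2 / 27.0


def _default_vol_beta() -> dict[str, float]:
    # Vol = const + b1*HSP + b2*(BEP-A) + b3*(Na-B); b1 < 0 so a longer
    # horizontal soft palate shrinks the airway.  const calibrated so the
    # template subject sits at the population mean volume.
    tm = template_measures()
    b = {"HSP": -900.0, "BEP-A": 400.0, "Na-B": 300.0}
    b["const"] = VOL_MEAN_MM3 - sum(c * tm[k] for k, c in b.items())
    return b


def _default_csa_beta() -> dict[str, float]:
    tm = template_measures()
    b = {"HSP": -15.0, "BEP-TUV": -3.0}
    b["const"] = CSA_MEAN_MM2 - sum(c * tm[k] for k, c in b.items())
    return b


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Defaults emulate the study conditions: n = 60 adults, 0.3 mm voxels
    (the scanner resolution), landmark jitter of a few mm, free head pose
    within ±20°/±30 mm.
    """

    n: int = 60
    seed: int = 0
    vol_beta: dict[str, float] = field(default_factory=_default_vol_beta)
    csa_beta: dict[str, float] = field(default_factory=_default_csa_beta)
    vol_noise_sd: float = 6000.0    # residual SD of the planted Vol model, mm^3
    csa_noise_sd: float = 80.0      # residual SD of the planted CSAmin model, mm^2
    vol_csa_noise_corr: float = 0.6  # residual correlation (a wide airway has both)
    landmark_noise_sd: float = 2.5  # per-landmark jitter SD, mm
    rotation_range_deg: float = 20.0
    translation_range_mm: float = 30.0
    voxel_mm: float = 0.3
    with_grids: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if min(self.landmark_noise_sd, self.vol_noise_sd, self.csa_noise_sd) < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class SyntheticSubject:
    """One generated subject with full ground truth."""

    subject_id: str
    canonical: LandmarkSet      # jittered template, anatomical frame
    posed: LandmarkSet          # same points under a random rigid pose (raw frame)
    true_measures: dict[str, float]
    true_volume_mm3: float
    true_csa_min_mm2: float
    age: float
    sex: str
    grid: VoxelGrid | None = None


def random_rigid(rng: np.random.Generator, rot_deg: float, trans_mm: float):
    """Random rotation (uniform Euler angles within ±rot_deg) and translation."""
    from .reorient import RigidTransform  # deferred: reorient imports airway

    ax, ay, az = np.radians(rng.uniform(-rot_deg, rot_deg, size=3))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    t = rng.uniform(-trans_mm, trans_mm, size=3)
    return RigidTransform(Rz @ Ry @ Rx, t)


def _planted(beta: dict[str, float], measures: dict[str, float]) -> float:
    return beta.get("const", 0.0) + sum(
        c * measures[k] for k, c in beta.items() if k != "const")


def generate_airway_grid(vol_target: float, csa_min_target: float,
                         z_sup: float, z_inf: float, voxel: float,
                         aspect: float = AIRWAY_ASPECT,
                         waist_frac: float = 0.5,
                         margin_mm: float = 0.0,
                         center_xy: tuple[float, float] = (5.0, 0.0)) -> VoxelGrid:
    """Voxelize a vertical airway tube realising (Vol, CSAmin) analytically.

    The axial cross-section is an ellipse (x-semi-axis : y-semi-axis =
    ``aspect``) whose area follows a one-period cosine along z,

        A(t) = Ā − (Ā − CSAmin)·cos(2π(t − t_w)),   t ∈ [0, 1],

    with Ā = Vol / height, so the integral between the planes is exactly
    ``vol_target`` and the single interior minimum at ``t_w`` equals
    ``csa_min_target``.  ``margin_mm`` extends the tube beyond both planes
    (constant end area) so that slightly misplaced cropping planes still
    see airway on both sides.
    """
    if vol_target <= 0 or csa_min_target <= 0:
        raise ValueError("volume and CSAmin targets must be positive")
    if z_sup <= z_inf:
        raise ValueError("z_sup must exceed z_inf")
    height = z_sup - z_inf
    a_mean = vol_target / height
    if csa_min_target > a_mean:
        raise ValueError(
            f"incompatible targets: CSAmin*height = {csa_min_target * height:.0f} "
            f"exceeds volume {vol_target:.0f}")
    if not 0.0 < waist_frac < 1.0:
        raise ValueError("waist must lie strictly between the planes")
    b = a_mean - csa_min_target
    a_max = a_mean + b

    by_max = np.sqrt(a_max / (np.pi * aspect))  # largest y semi-axis
    ax_max = aspect * by_max
    cx, cy = center_xy
    v = float(voxel)

    # voxel-center lattice covering the tube plus margins
    def centers(lo, hi):
        n = int(np.ceil((hi - lo) / v)) + 1
        return lo + np.arange(n) * v

    xs = centers(cx - ax_max - v, cx + ax_max + v)
    ys = centers(cy - by_max - v, cy + by_max + v)
    # z slices at z_inf + (k + 1/2) v tile [z_inf, z_sup] (midpoint rule);
    # the margin adds whole slices below/beyond
    n_in = int(round(height / v))
    n_m = int(np.ceil(margin_mm / v))
    ks = np.arange(-n_m, n_in + n_m)
    zs = z_inf + (ks + 0.5) * v

    t = np.clip((zs - z_inf) / height, 0.0, 1.0)  # clamp profile in the margins
    area = a_mean - b * np.cos(2 * np.pi * (t - waist_frac))
    by = np.sqrt(np.maximum(area, 1e-12) / (np.pi * aspect))
    ax = aspect * by

    dx2 = ((xs - cx) ** 2)[:, None]
    dy2 = ((ys - cy) ** 2)[None, :]
    data = np.zeros((xs.size, ys.size, zs.size), dtype=np.uint8)
    for k in range(zs.size):
        data[:, :, k] = (dx2 / ax[k] ** 2 + dy2 / by[k] ** 2) <= 1.0
    return VoxelGrid(data=data, voxel_mm=v,
                     origin_mm=np.array([xs[0], ys[0], zs[0]]),
                     frame=REORIENTED)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate a cohort of synthetic subjects; deterministic under the seed."""
    from .reorient import apply_transform
    from .airway import bounding_planes

    rng = np.random.default_rng(spec.seed)
    template = template_landmarks()
    subjects: list[SyntheticSubject] = []
    for i in range(spec.n):
        jitter = {
            name: p + rng.normal(0.0, spec.landmark_noise_sd, size=3)
            for name, p in template.points.items()
        }
        canonical = LandmarkSet(points=jitter, frame=REORIENTED,
                                subject_id=f"synthetic-{i:03d}")
        pose = random_rigid(rng, spec.rotation_range_deg, spec.translation_range_mm)
        posed = apply_transform(canonical, pose).replace(frame=RAW)

        age = float(np.clip(rng.normal(39.9, 13.5), 22.0, 72.0))
        sex = "F" if rng.uniform() < 0.7 else "M"
        measures = compute_measures(canonical, age=age, sex=sex)

        rho = spec.vol_csa_noise_corr
        zv, zc_ind = rng.normal(size=2)
        zc = rho * zv + np.sqrt(1.0 - rho ** 2) * zc_ind
        vol = _planted(spec.vol_beta, measures) + spec.vol_noise_sd * zv
        csa = _planted(spec.csa_beta, measures) + spec.csa_noise_sd * zc

        grid = None
        with warnings.catch_warnings():
            # jitter alone can push |z_PNS - z_ANS| past the QC threshold;
            # the generator's planes are ground truth, so no QC warning here
            warnings.simplefilter("ignore")
            z_sup, z_inf = bounding_planes(canonical)
        height = z_sup - z_inf
        # keep the airway geometrically realisable (waist below mean area,
        # positive floor); only the noise tails are affected
        vol = float(np.clip(vol, 2500.0, 40_000.0))
        csa = float(np.clip(csa, 46.0, min(600.0, 0.95 * vol / height)))
        if spec.with_grids:
            grid = generate_airway_grid(
                vol, csa, z_sup, z_inf, spec.voxel_mm,
                waist_frac=float(rng.uniform(0.35, 0.65)), margin_mm=6.0)

        subjects.append(SyntheticSubject(
            subject_id=canonical.subject_id, canonical=canonical, posed=posed,
            true_measures=measures, true_volume_mm3=vol, true_csa_min_mm2=csa,
            age=age, sex=sex, grid=grid))
    return subjects


def generate_repeat_session(subject: SyntheticSubject, placement_sd: float,
                            seed: int) -> LandmarkSet:
    """Second measuring session: the subject's raw landmarks re-placed with
    independent Gaussian error of SD ``placement_sd`` mm per coordinate."""
    if placement_sd < 0:
        raise ValueError("placement SD must be nonnegative")
    rng = np.random.default_rng(seed)
    pts = {n: p + rng.normal(0.0, placement_sd, size=3)
           for n, p in subject.posed.points.items()}
    return LandmarkSet(points=pts, frame=RAW,
                       subject_id=subject.subject_id + "-session2")
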