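"""End-to-end orchestration: simulate → reorient → measure → airway →
stats → symbolic regression, with a run manifest and deterministic seeds.

Every stage reads/writes documented plain formats (CSV, JSON, NIfTI,
PNG), so each stage can also be run standalone; all randomness derives
from the single root seed in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .airway import analyze_airway
from .landmarks import LandmarkSet, cohort_to_csv
from .morphometry import compute_measures
from .reorient import apply_transform, compute_reorientation, midsagittal_residual
from .stats import describe, icc_table, kendall_matrix, pca, shapiro_flags
from .symreg import SRConfig, run_experiments
from .synthetic import CohortSpec, generate_cohort, generate_repeat_session

log = logging.getLogger("airwaymorph")

#: columns never offered to the SR engine as predictors of an airway target
AIRWAY_COLUMNS = ("Vol", "CSAmin", "Ap", "Lat")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort analysis."""

    out_dir: Path
    seed: int = 0
    cohort: CohortSpec | None = None          # None: default spec with this seed
    sr: SRConfig = field(default_factory=SRConfig)
    sr_targets: tuple[str, ...] = ("Vol", "CSAmin")
    repeat_placement_sd: float = 1.0          # mm, second-session landmark error
    make_plots: bool = True

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.cohort is None:
            self.cohort = CohortSpec(seed=self.seed)


def measure_cohort(subjects, *, session_seed: int | None = None,
                   placement_sd: float = 0.0) -> pd.DataFrame:
    """Reorient each subject's raw landmarks and compute the full
    measurement vector plus airway metrics.

    With ``session_seed`` the landmarks are first re-placed with Gaussian
    error (a repeat measuring session); otherwise the posed landmarks are
    measured as-is.
    """
    rows, index = [], []
    n_plane_warnings = 0
    for i, subj in enumerate(subjects):
        lm: LandmarkSet = subj.posed
        if session_seed is not None:
            lm = generate_repeat_session(subj, placement_sd,
                                         seed=session_seed + i)
        t = compute_reorientation(lm)
        reo = apply_transform(lm, t)
        row = compute_measures(reo, age=subj.age, sex=subj.sex)
        row["midsagittal_residual_mm"] = midsagittal_residual(reo)
        if subj.grid is not None:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                metrics = analyze_airway(subj.grid, reo)
                n_plane_warnings += sum(
                    "palatal plane" in str(w.message) for w in caught)
            row.update(metrics.as_dict())
        rows.append(row)
        index.append(subj.subject_id)
    if n_plane_warnings:
        log.info("palatal plane poorly defined (|z_PNS - z_ANS| > 3 mm) for "
                 "%d/%d subjects", n_plane_warnings, len(subjects))
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline and write all artifacts under ``out_dir``.

    Returns a name → path map of everything written.  Outputs are
    byte-identical across reruns with the same configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_csv(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, float_format="%.10g")
        artifacts[name] = p

    log.info("simulating cohort (n=%d, seed=%d)", config.cohort.n,
             config.cohort.seed)
    subjects = generate_cohort(config.cohort)
    cohort_to_csv([s.posed for s in subjects], out / "landmarks_raw.csv")
    artifacts["landmarks_raw"] = out / "landmarks_raw.csv"

    log.info("reorienting and measuring")
    measures = measure_cohort(subjects)
    save_csv("measurements", measures)

    # analysis table: the 25 measures + covariates + airway metrics
    table = measures.drop(columns=["midsagittal_residual_mm"])
    if table["HSP"].isna().all():
        log.warning("LP landmark absent: HSP excluded from all analyses")
        table = table.drop(columns=["HSP"])

    save_csv("descriptives", describe(table))
    save_csv("shapiro_flags", shapiro_flags(table).to_frame())

    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        log.warning("constant column(s) excluded from correlation/PCA/SR: %s",
                    constant)
        table = table.drop(columns=constant)

    log.info("repeat session for reliability (placement SD %.2f mm)",
             config.repeat_placement_sd)
    session2 = measure_cohort(subjects, session_seed=config.seed + 10_000,
                              placement_sd=config.repeat_placement_sd)
    icc = icc_table(measures.drop(columns=["midsagittal_residual_mm"]),
                    session2.drop(columns=["midsagittal_residual_mm"]))
    save_csv("icc", icc)

    log.info("Kendall correlation matrix")
    corr = kendall_matrix(table)
    save_csv("kendall_tau", corr.tau)
    save_csv("kendall_p", corr.p)

    log.info("PCA")
    pca_res = pca(table.dropna(axis=1))
    save_csv("pca_coords", pca_res.coords)
    save_csv("pca_cos2", pca_res.cos2)
    pd.DataFrame({"eigenvalue": pca_res.eigenvalues,
                  "pct_variance": pca_res.pct_variance}).to_csv(
        out / "pca_variance.csv", index_label="dim")
    artifacts["pca_variance"] = out / "pca_variance.csv"

    if config.make_plots:
        from .plots import plot_correlation_matrix, plot_importance, plot_pca_circle
        plot_correlation_matrix(corr, out / "correlation_matrix.png")
        plot_pca_circle(pca_res, out / "pca_circle.png")
        artifacts["correlation_plot"] = out / "correlation_matrix.png"
        artifacts["pca_plot"] = out / "pca_circle.png"

    sr_seeds = {}
    for i, target in enumerate(config.sr_targets):
        if target not in table.columns:
            log.warning("SR target %s absent; skipped", target)
            continue
        cfg = SRConfig(**{**config.sr.__dict__, "target": target,
                          "seed": config.seed + 20_000 + i})
        drop = [c for c in AIRWAY_COLUMNS if c in table.columns]
        features = tuple(c for c in table.columns if c not in drop)
        cfg.features = features
        log.info("symbolic regression on %s (%d runs)", target, cfg.runs)
        exp = run_experiments(table, target, cfg)
        sr_seeds[target] = cfg.seed
        save_csv(f"sr_importance_{target}", exp.importance.to_frame())
        save_csv(f"sr_sensitivity_{target}", exp.sensitivity)
        exp.save_models(out / f"sr_models_{target}.json")
        artifacts[f"sr_models_{target}"] = out / f"sr_models_{target}.json"
        if config.make_plots:
            from .plots import plot_importance
            plot_importance(exp.importance, out / f"sr_importance_{target}.png",
                            title=f"target: {target}")

    manifest = {
        "airwaymorph_version": __version__,
        "seed": config.seed,
        "cohort": {k: v for k, v in config.cohort.__dict__.items()
                   if not isinstance(v, dict)},
        "sr_seeds": sr_seeds,
        "numpy_version": np.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
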