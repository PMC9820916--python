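"""Run the whole analysis in one call and list the written artifacts.

Equivalent to ``airwaymorph all --n 60 --seed 1 --out out/`` on the
command line.  Uses a small cohort and search budget so it finishes in
about a minute.
"""

from airwaymorph import RunConfig, run_full_analysis
from airwaymorph.symreg import SRConfig
from airwaymorph.synthetic import CohortSpec

config = RunConfig(
    out_dir="out/demo",
    seed=1,
    cohort=CohortSpec(n=20, seed=1, voxel_mm=0.6),
    sr=SRConfig(population_size=150, generations=30, runs=3),
    sr_targets=("Vol",),
)
artifacts = run_full_analysis(config)
for name, path in artifacts.items():
    print(f"{name:22s} {path}")
# measurements.csv holds one row per subject; descriptives/icc/kendall/pca
# are the classical statistics; sr_* hold the evolved models, importance
# ranking and sensitivity; manifest.json records seeds and versions.
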