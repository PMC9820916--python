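"""Intra-observer reliability, correlations and PCA on a synthetic cohort.

A second measuring session is simulated by re-placing every landmark with
1 mm Gaussian error; the ICC quantifies how reproducible each measure is.
"""

from airwaymorph import CohortSpec, generate_cohort, kendall_matrix, pca
from airwaymorph.pipeline import measure_cohort
from airwaymorph.stats import icc_table

subjects = generate_cohort(CohortSpec(n=30, seed=3))
session1 = measure_cohort(subjects)
session2 = measure_cohort(subjects, session_seed=99, placement_sd=1.0)

icc = icc_table(session1.drop(columns="midsagittal_residual_mm"),
                session2.drop(columns="midsagittal_residual_mm"))
print("least reproducible measures (ICC, 95% CI):")
for var, row in icc.nsmallest(3, "icc").iterrows():
    print(f"  {var:9s} {row.icc:.2f} [{row.ci_low:.2f}; {row.ci_high:.2f}]")

table = session1.drop(columns="midsagittal_residual_mm")
table = table.loc[:, table.nunique() > 1]
corr = kendall_matrix(table)
print(f"\nKendall tau(Vol, HSP) = {corr.tau.loc['Vol', 'HSP']:+.2f} "
      f"(p = {corr.p.loc['Vol', 'HSP']:.2g})")

res = pca(table)
print(f"PCA: dim1 {res.pct_variance[0]:.1f}%, dim2 {res.pct_variance[1]:.1f}%")
# A negative Vol-HSP correlation is the planted soft-palate effect; ICC
# near 1 means landmark placement error barely affects that measure.
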