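"""Reorient a posed subject and compute the 25 cephalometric measures.

The subject's raw landmarks arrive in an arbitrary scanner pose; the
reorientation aligns the Frankfort horizontal plane with the horizontal
and the midsagittal plane with x-z, after which distances, angles and the
frame-dependent measures (A-B shift, HSP, VSP, FMA) are computed.
"""

from airwaymorph import (CohortSpec, apply_transform, compute_measures,
                         compute_reorientation, generate_cohort)

subject = generate_cohort(CohortSpec(n=2, seed=7, with_grids=False))[0]
raw = subject.posed

transform = compute_reorientation(raw)
reoriented = apply_transform(raw, transform)
measures = compute_measures(reoriented, age=subject.age, sex=subject.sex)

print(f"rotation determinant: {__import__('numpy').linalg.det(transform.rotation):.6f}")
for key in ("S-Na", "Na-A", "Na-B", "AB-shift", "SNA", "SNB", "FMA", "HSP", "VSP"):
    print(f"{key:9s} {measures[key]:7.2f}")
# SNA/SNB describe maxillary/mandibular position relative to the cranial
# base; HSP/VSP locate the soft palate; all are in mm or degrees and fall
# in published adult ranges.
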