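"""Does white-matter integrity mediate the age effect on working memory?

Derives the FWE-significant negative-age-effect mask, runs the voxelwise
Sobel test within it (age -> FA -> manipulation score, sex partialled
out), and quantifies how much of the age effect the peak voxel's FA
absorbs.
"""

from skelstats import (
    CohortParams, DesignMatrix, age_effect_mask, change_in_effect,
    generate_cohort, generate_metric_stack, voxelwise_mediation,
)
from skelstats.validation import block_space

params = CohortParams(n_subjects=200, seed=3)  # planted paths a=-0.4, b=0.3
table = generate_cohort(params)
space = block_space(2000, (13, 13, 13))
stack = generate_metric_stack(table, space, params.mediation, seed=4)

mask, _ = age_effect_mask(stack, table, n_perm=500, seed=5)
print(f"age-effect mask: {mask.sum()} voxels with FWE-significant FA decline with age")

med = voxelwise_mediation(
    stack, table["age"].to_numpy(float), table["wm_manipulation"].to_numpy(float),
    DesignMatrix.from_table(table, ["sex"]), mask, n_perm=500, seed=6,
)
sig = med.significant(0.05)
peak = space.column_to_voxel(med.peak_column)
print(f"{sig.sum()} voxels carry a significant indirect (mediated) effect; "
      f"peak at voxel {tuple(int(i) for i in peak)}")
print(f"peak paths: a = {med.a[med.peak_column]:.3f} (age->FA), "
      f"b = {med.b[med.peak_column]:.3f} (FA->WM | age), "
      f"Sobel z = {med.z_map.values[med.peak_column]:.2f}")

change = change_in_effect(table["age"], table["sex"],
                          stack.data[:, med.peak_column], table["wm_manipulation"])
print(f"\nage-coefficient t: {change.age_t_before:.2f} -> {change.age_t_after:.2f} "
      f"after adding peak-voxel FA")
print(f"age unique variance drops by {-100 * change.age_attenuation:.1f}% "
      f"(r^2 rises {change.r2_before:.3f} -> {change.r2_after:.3f}: the mediator "
      f"absorbs age-related variance rather than adding none)")
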