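"""Agreement statistics on the bundled reference tables.

The package ships the per-video reference-vs-video RR tables of a
two-stage validation study (RGB stage: one sheep, four videos x four
thorax regions; NIR stage: five sheep, 36 observations).  This script
recomputes the agreement statistics a validation report would quote.
"""

from sheeprr import agreement, bland_altman, pearson
from sheeprr.datasets import nir_pairs, rgb_pairs, study_coverage

print("RGB stage (4 videos, mean of four expert counts as reference)")
for region in ("total", "r1", "r2", "r3"):
    summ = agreement(rgb_pairs(region))
    print(f"  {region:>5}: MAE {summ.mean_abs_err:.2f} bpm, "
          f"MRE {summ.mean_rel_err_pct:.2f} %, r {pearson(rgb_pairs(region)):.3f}")

pairs = nir_pairs()
summ = agreement(pairs)
ba = bland_altman(pairs)
print(f"\nNIR stage ({len(pairs)} observations, one expert)")
print(f"  MAE {summ.mean_abs_err:.2f} bpm, MRE {summ.mean_rel_err_pct:.2f} %, "
      f"r {pearson(pairs):.3f}")
print(f"  Bland-Altman: mean diff {ba.mean_diff:.2f} bpm, "
      f"limits [{ba.loa_low:.2f}, {ba.loa_high:.2f}] bpm")

cov = study_coverage()
print(f"\nrest coverage: {cov.coverage_pct:.2f}% "
      f"({cov.rest_duration_s} of {cov.total_duration_s} s usable)")
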