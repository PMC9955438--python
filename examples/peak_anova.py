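"""Peak-level group comparison at the 11 reference serum wavenumbers.

Extracts per-sample peak intensities (local maximum within +/- 8 cm^-1)
and runs a one-way ANOVA across the three diagnostic groups per peak.
"""

import sersdx
from sersdx import CohortConfig, anova_peaks, generate_cohort, preprocess_pipeline

ORDER = [sersdx.HEALTHY, sersdx.STONE, sersdx.POLYP]

sset, _ = generate_cohort(CohortConfig(seed=1))
pset = preprocess_pipeline(sset)

table = anova_peaks(pset, class_order=ORDER)
show = table[["wavenumber", "assignment", "F", "p", "significant"]].copy()
show["wavenumber"] = show.wavenumber.astype(int)
show["F"] = show.F.round(1)
show["p"] = show.p.map(lambda v: f"{v:.2g}")
print(show.to_string(index=False))

sig = table.loc[table.significant, "wavenumber"].tolist()
print(f"\nsignificant at alpha=0.05: {sig}")
# The generator injects class effects at 637, 722, 888, 1134, 1203, 1432
# and 1652 cm^-1 and none at 1003 cm^-1 (phenylalanine), so the
# significant set should match the former and exclude the latter.
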