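"""Stratify marker abundances over FBG quartiles (heat-map matrix).

Samples are binned by fasting-blood-glucose quartiles (Q1 = lowest);
each marker's mean abundance per bin is min-max normalised to [0, 1], so
every row shows where along the FBG range that marker peaks.  Markers
enriched in cases should peak in the high-FBG bins; rows are annotated
with their Kruskal-Wallis case/control significance class.
"""

import numpy as np

from micromarkers import CohortConfig, generate_cohort, stratify

profile, metadata, truth = generate_cohort(CohortConfig(seed=1))
markers = [profile.feature_ids[j] for j in truth.marker_indices]
marker_profile = profile.subset_features(markers)
fbg = np.array([m.covariates["fbg"] for m in metadata])
labels = np.array([m.label for m in metadata])

strat = stratify(marker_profile, fbg, labels)
print("FBG quartile boundaries (mmol/L):",
      ", ".join(f"{b:.2f}" for b in strat.boundaries))
print("\nmarker      Q1    Q2    Q3    Q4    significance")
for fid in strat.feature_ids[:15]:
    row = strat.matrix.loc[fid]
    sig = strat.significance.loc[fid, "significance"]
    cells = "  ".join(f"{v:.2f}" for v in row)
    print(f"{fid:<10}  {cells}  {sig}")
print("\nEach row is scaled to [0, 1]: 1.00 marks the FBG interval where "
      "that marker's mean abundance peaks.")
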