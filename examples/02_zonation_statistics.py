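"""Map single-shape proteomes onto the portal-to-central axis and test zonation.

Simulates a zonated section, bins cells into 20 equidistant classes of
relative distance r = d_PV / (d_PV + d_CV), and runs the moderated
one-way ANOVA across bins plus the Shapiro-Wilk flatness screen.
"""

import numpy as np

import hepazone as hz
from hepazone import qc, zonation
from hepazone.config import SimulatorConfig

sim = SimulatorConfig()  # defaults: 400 cells, 200 proteins, 40% zonated
truth = hz.simulate_lobule(sim.n_cells, sim, seed=7)
matrix = hz.simulate_proteome(truth, sim)
normalized, norm_set = qc.median_normalize(matrix, completeness_fallback=0.95)
print(f"median normalisation set: {len(norm_set)} proteins")

r = zonation.relative_distance(truth.cells["d_pv"].to_numpy(),
                               truth.cells["d_cv"].to_numpy())
bins = zonation.assign_bins(r, 20)
result = zonation.zonation_anova(normalized, bins, completeness_min=0.5, moderate=True)

tested = result["tested"]
zonated = (result["fdr"] < 0.05) & tested
n_true = sum(p.shape_kind != "flat" for p in truth.profiles)
print(f"tested {int(tested.sum())} proteins (>=50% complete); "
      f"{int(zonated.sum())} zonated at FDR<0.05 "
      f"({100 * zonated.sum() / tested.sum():.0f}% of tested; "
      f"{n_true} truly zonated by construction)")
# The excess over the constructed 40% comes from median normalisation: with a
# small protein panel the complete-set median itself carries residual zonation,
# which the test then (correctly) detects in every protein.  See docs/methods.md.

flat = zonation.flatness_test(normalized)
print(f"flat by the normality screen: {int((flat['flat'] == 1.0).sum())} proteins")

profile = zonation.bin_profile(normalized, bins, 20)
top = result.loc[tested].sort_values("F", ascending=False).index[0]
peak_bin = int(np.nanargmax(profile.loc[top].to_numpy())) + 1
print(f"strongest zonation: {top} (F={result.loc[top, 'F']:.1f}), "
      f"expression peaks in bin {peak_bin} of 20")
# Bin 1 touches the portal vein, bin 20 the central vein; the fraction of
# zonated proteins echoes how strongly position shapes the hepatocyte proteome.
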