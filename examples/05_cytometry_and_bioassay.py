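"""Absolute cell densities from bead-spiked cytometry, and metabolite
concentrations from a yield-based bioassay standard curve."""

from crossfeed import bioassay_concentration, cytometry_densities, fit_standard_curve
from crossfeed.synth import NoiseSpec, gen_bioassay_curve, gen_cytometry_events

# --- bead-calibrated flow cytometry ---------------------------------------
sample, truth = gen_cytometry_events(true_live=5.0e6, true_dead=5.0e5, seed=0)
live, dead = cytometry_densities(sample)
print(f"events: {sample.fluorescent_cell_events} live cells, "
      f"{sample.nonfluorescent_cell_events} dead cells, {sample.bead_events} beads")
print(f"live density : {live:.3e} /ml (truth {truth['live_per_ml']:.3e})")
print(f"dead density : {dead:.3e} /ml (truth {truth['dead_per_ml']:.3e})")
# The bead spike of known density converts event ratios into absolute
# densities, independent of how much sample the instrument acquires.

# --- yield-based bioassay ---------------------------------------------------
curve_tab, samples, _ = gen_bioassay_curve(noise=NoiseSpec(0.02, seed=1), spiked=(10.0, 30.0))
curve = fit_standard_curve(list(zip(curve_tab["conc_uM"], curve_tab["turbidity"])))
print(f"\nstandard curve: turbidity = {curve.intercept:.3f} + {curve.slope:.4f} * conc")
for _, row in samples.iterrows():
    res = bioassay_concentration(curve, row["turbidity"])
    print(f"turbidity {row['turbidity']:.3f} -> {res.value:5.2f} uM "
          f"(truth {row['true_conc_uM']:.1f} uM)")
# A tester auxotroph grows until the assayed metabolite is exhausted, so its
# final turbidity reads out the metabolite concentration linearly.
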