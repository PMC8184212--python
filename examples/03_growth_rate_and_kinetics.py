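"""Growth rates from fluorescence time courses and a growth-law fit.

Emulates a microscopy assay: intensity series at several nutrient
concentrations, growth rate = maximal sliding-window log-slope, then a
saturating (Hill-type) growth-law fit b(L) = b_max L^n / (K^n + L^n)
across concentrations.
"""

import numpy as np

from crossfeed import MoserParams, fit_moser, growth_rate_from_timeseries, moser_rate
from crossfeed.synth import NoiseSpec, gen_microscopy_series

truth = MoserParams(b_max=0.44, K=2.0, n=2.0)
concs = [0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0]

points = []
for i, L in enumerate(concs):
    rate = moser_rate(L, truth)
    table, _ = gen_microscopy_series(rate, noise=NoiseSpec(0.03, seed=i))
    est = growth_rate_from_timeseries(table["time_hr"], table["value"], window=4)
    points.append((L, est.rate))
    print(f"L = {L:5.1f} uM : true rate {rate:.3f} /hr, estimated {est.rate:.3f} /hr")

fit = fit_moser(points)
p = fit.params
print(f"\nfitted b_max = {p.b_max:.3f} /hr (truth {truth.b_max})")
print(f"fitted K     = {p.K:.3f} uM  (truth {truth.K})")
print(f"fitted n     = {p.n:.3f}     (truth {truth.n})")
# The half-saturation concentration K and cooperativity n characterize how
# sharply growth shuts down as the partner-supplied nutrient runs out.
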