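"""Posterior inference on balanced accuracy from a confusion matrix.

Sensitivity and specificity receive independent Beta posteriors from the
confusion counts; balanced accuracy is their average.  A model is better
than chance when at least 95% of the posterior mass exceeds BAC = 0.5.
The counts below correspond to a clinical model that detects 18 of 38 bad
outcomes and clears 50 of 56 good ones.
"""

from negprog import ConfusionCounts, point_metrics, posterior_bac

counts = ConfusionCounts(tp=18, fp=6, tn=50, fn=20)
point = point_metrics(counts)
post = posterior_bac(counts, method="grid_convolution")
mc = posterior_bac(counts, method="monte_carlo", n_draws=1_000_000, seed=0)

print(f"point estimates: SE {point.sensitivity:.3f}  SP {point.specificity:.3f}  "
      f"PPV {point.ppv:.3f}  NPV {point.npv:.3f}  BAC {point.bac:.3f}")
print(f"posterior BAC (grid):        mean {post.mean:.3f}  "
      f"95% CI [{post.ci_low:.3f}, {post.ci_high:.3f}]")
print(f"posterior BAC (Monte Carlo): mean {mc.mean:.3f}  "
      f"95% CI [{mc.ci_low:.3f}, {mc.ci_high:.3f}]")
print(f"P(BAC > 0.5) = {post.mass_above_chance:.4f}  ->  "
      f"{'significant' if post.significant else 'not significant'}")
# The two computational routes agree to ~1e-3; the point BAC of 0.68 is well
# above chance, and the posterior criterion confirms it.
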