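"""Used-available resource selection with demographic-class interactions.

Runs the telemetry stage end to end on synthetic data whose subadult
males avoid high-rainfall habitat while every other class selects it,
then shows that the mixed model recovers the coefficients and the
likelihood-ratio test keeps the precipitation-by-class interaction.
"""

from habsel.rsf import odds_ratios
from habsel.validation import telemetry_recovery_trial

out = telemetry_recovery_trial(seed=1)

print(f"design: {out['n_obs']} used+available points (1:4 ratio)")
print("fixed-effect recovery (adult-female slopes, design z-scale):")
for name, truth in out["truth"].items():
    est, se = out["beta_hat"][name], out["se"][name]
    print(f"  {name:>13}: est {est:+.2f} +- {se:.2f}, truth {truth:+.2f}")

print(f"precipitation x subadult male: est {out['interaction_hat']:+.2f} "
      f"+- {out['interaction_se']:.2f}, truth {out['interaction_truth']:+.2f}")
print(f"likelihood-ratio test of the interaction: chi2(3) = "
      f"{out['interaction_chi2']:.1f}, p = {out['interaction_p']:.2g} "
      "(p < 0.05 keeps the term: classes differ in their rainfall response)")

ors = odds_ratios([out["interaction_hat"]], [out["interaction_se"]]).iloc[0]
print(f"as an odds ratio: {ors['or']:.2f} "
      f"({ors['ci_low']:.2f}-{ors['ci_high']:.2f}) per SD of precipitation")
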