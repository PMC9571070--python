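"""FRET-FLIM pipeline: decay fitting and the ternary-complex decision.

Simulates TCSPC bundles for the donor-only, two binary and the ternary
co-expression conditions, fits every decay by iterative reconvolution, and
asks whether the ternary condition quenches the donor beyond the binary
limit — the excess quenching only a ternary complex can produce.
"""

import numpy as np

from trifret import (
    efficiency_from_lifetimes,
    fit_decay,
    make_scenario,
    simulate_decay,
    ternary_excess_quenching,
)

hist = simulate_decay([3.99], n_photons=500_000, seed=3)
fit = fit_decay(hist)
print(f"single decay, true tau = 3.99 ns, {hist.total_counts} photons:")
print(f"  fitted tau = {fit.tau_avg:.3f} ns (reduced deviance {fit.fit_quality:.2f})")


def lifetimes(preset, seed):
    bundle = make_scenario(preset, n_roi=20, seed=seed)
    return [fit_decay(d).tau_avg for d in bundle.decays]


donor = lifetimes("donor_only", 40)
b1 = lifetimes("donor_A1", 41)
b2 = lifetimes("donor_A2", 42)
ternary = lifetimes("ternary_cascade", 43)
decision = ternary_excess_quenching(ternary, b1, b2, donor)

print("\ncondition means over 20 ROIs each:")
print(f"  donor only:      {decision.donor_mean:.3f} ns")
print(f"  binary limit:    {decision.binary_limit:.3f} ns  (strongest heterodimer)")
print(f"  ternary:         {decision.ternary_mean:.3f} ns")
print(f"  excess quenching Delta = {decision.excess_quenching:.3f} ns "
      f"-> ternary complex {'SUPPORTED' if decision.supported else 'not supported'}")
print(f"  lifetime-derived efficiencies: ternary {decision.efficiency_ternary:.3f}, "
      f"binary {decision.efficiency_binary_limit:.3f}")
# A ternary mean below the binary limit (3.40 < 3.54 ns; E 0.148 vs 0.113)
# requires an additional FRET pathway: heterodimers alone cannot explain it.

negative = lifetimes("donor_A1_uncoupledA2", 44)
neg = ternary_excess_quenching(negative, b1, b2, donor)
print(f"\nuncoupled bystander control: Delta = {neg.excess_quenching:+.3f} ns "
      f"-> {'SUPPORTED' if neg.supported else 'not supported'}")
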