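"""Range extension by an intermediate acceptor in a three-fluorophore cascade.

Shows how inserting an intermediate between donor and terminal acceptor
extends the 10%-efficiency working distance from 7.4 nm (direct pair) to
12.4 nm (equidistant) or 11.1 nm (randomly placed intermediate).
"""

from trifret import (
    CascadeGeometry,
    cascade_efficiencies,
    cascade_range,
    distance_at_efficiency,
)

R0 = (5.7, 5.2, 5.1)  # donor/A1, A1/A2, donor/A2 Förster radii in nm

direct = distance_at_efficiency(0.1, R0[2])
midpoint = cascade_range(R0, "midpoint", 0.1)
random = cascade_range(R0, "random", 0.1, n_samples=1000, seed=7)
print(f"direct donor->terminal r10%:            {direct:.1f} nm")
print(f"cascade r10%, equidistant intermediate: {midpoint:.1f} nm")
print(f"cascade r10%, random 1-D placement:     {random:.1f} nm")
# The intermediate relays energy across distances the direct pair cannot
# bridge; random placement averages over unknown complex geometry and
# still extends the detection range by ~50%.

print("\npathway decomposition at the extended range (12.4 nm, equidistant):")
res = cascade_efficiencies(CascadeGeometry(12.4, 6.2, *R0))
print(f"  donor -> intermediate:       {res.e_to_a1:.3f}")
print(f"  donor -> terminal (direct):  {res.e_direct_to_a2:.3f}")
print(f"  total reaching terminal:     {res.e_total_to_a2:.3f}")
# Nearly all terminal-acceptor signal at long range arrives via the
# sequential hop; the direct pathway is negligible beyond ~9 nm.
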