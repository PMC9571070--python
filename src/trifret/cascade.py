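"""Three-fluorophore energy-flow model along a donor → A1 → A2 cascade.

A donor D can hand its excitation either to an intermediate acceptor A1 or
directly to the terminal acceptor A2; the two transfer channels compete with
the donor's intrinsic decay. With collinear placement (A1 at distance x from
D on the D–A2 axis of length r) the relative rates are

    u1 = (R0_DA1 / x)⁶,   u2 = (R0_DA2 / r)⁶

so a donor excitation reaches A1 with probability u1/(1+u1+u2) and A2
directly with u2/(1+u1+u2). A quantum on A1 hops on with the ordinary pair
efficiency v/(1+v), v = (R0_A1A2 / (r−x))⁶. No back-transfer and no photon
re-absorption — standard Förster kinetics.

The practical payoff is the effective 10 %-efficiency range: inserting an
intermediate extends the detectable D–A2 separation well beyond any binary
pair's r10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .forster import distance_at_efficiency

__all__ = ["CascadeGeometry", "CascadeResult", "cascade_efficiencies", "cascade_range"]


@dataclass(frozen=True)
class CascadeGeometry:
    """Collinear D–A1–A2 arrangement plus the three pairwise Förster radii (nm)."""

    r_da2: float  # donor -> terminal acceptor distance
    x_a1: float  # intermediate position, distance from donor along the axis
    r0_da1: float
    r0_a1a2: float
    r0_da2: float

    def __post_init__(self) -> None:
        if not self.r_da2 > 0:
            raise ValueError("donor–terminal distance must be positive")
        if not 0 < self.x_a1 < self.r_da2:
            raise ValueError(
                "intermediate must lie strictly between donor and terminal acceptor "
                f"(got x={self.x_a1}, r={self.r_da2}); endpoint placement is singular"
            )
        if min(self.r0_da1, self.r0_a1a2, self.r0_da2) < 0:
            raise ValueError("Förster radii must be non-negative")


@dataclass(frozen=True)
class CascadeResult:
    """Fate of a donor excitation in the three-fluorophore arrangement."""

    e_total_to_a2: float  # fraction of donor excitations reaching A2 (either path)
    e_to_a1: float  # fraction handed to the intermediate
    e_direct_to_a2: float  # fraction transferred directly D -> A2
    donor_retained: float  # fraction decaying on the donor itself


def _total_efficiency(r, x, r0_da1, r0_a1a2, r0_da2):
    """Vectorized fraction of donor excitations reaching A2; r, x broadcastable."""
    u1 = (r0_da1 / x) ** 6
    u2 = (r0_da2 / r) ** 6
    denom = 1.0 + u1 + u2
    e_a1 = u1 / denom
    e_direct = u2 / denom
    v = (r0_a1a2 / (r - x)) ** 6
    e_hop = v / (1.0 + v)
    return e_direct + e_a1 * e_hop


def cascade_efficiencies(geom: CascadeGeometry) -> CascadeResult:
    """Resolve the competing direct and sequential pathways for one geometry."""
    u1 = (geom.r0_da1 / geom.x_a1) ** 6
    u2 = (geom.r0_da2 / geom.r_da2) ** 6
    denom = 1.0 + u1 + u2
    e_a1 = u1 / denom
    e_direct = u2 / denom
    v = (geom.r0_a1a2 / (geom.r_da2 - geom.x_a1)) ** 6
    e_hop = v / (1.0 + v)
    return CascadeResult(
        e_total_to_a2=float(e_direct + e_a1 * e_hop),
        e_to_a1=float(e_a1),
        e_direct_to_a2=float(e_direct),
        donor_retained=float(1.0 / denom),
    )


def cascade_range(
    r0_triple: tuple[float, float, float],
    placement: str = "midpoint",
    e_target: float = 0.1,
    n_samples: int = 1000,
    seed: int | None = None,
) -> float:
    """Effective D–A2 distance (nm) at which cascade transfer hits ``e_target``.

    Parameters
    ----------
    r0_triple
        (R0_DA1, R0_A1A2, R0_DA2) in nm.
    placement
        ``"midpoint"`` fixes A1 at r/2; ``"random"`` averages the total
        efficiency over ``n_samples`` uniform 1-D positions x ~ U(0, r) on
        the D–A2 segment; ``"random3d"`` instead samples A1 uniformly in the
        ball having the D–A2 segment as diameter (off-axis variant, not used
        for the headline numbers).
    e_target
        Target total efficiency in (0, 1); 0.1 is the operational FRET
        detection limit.
    n_samples, seed
        Monte-Carlo settings for the random placements. The same uniform
        fractions are reused at every root-search iterate (common random
        numbers), keeping the objective monotone in r.

    Notes
    -----
    Solved by bracketing root search on r ∈ [0.5, 50] nm to 1e-4 nm. If A1
    is uncoupled (R0_DA1 = 0) the result collapses to the binary-pair
    r = R0_DA2 · ((1−E)/E)^(1/6).
    """
    r0_da1, r0_a1a2, r0_da2 = (float(v) for v in r0_triple)
    if not 0.0 < e_target < 1.0:
        raise ValueError(f"target efficiency must lie in (0, 1), got {e_target}")
    if placement not in ("midpoint", "random", "random3d"):
        raise ValueError(f"unknown placement {placement!r}")

    if placement == "midpoint":
        def mean_eff(r: float) -> float:
            return _total_efficiency(r, 0.5 * r, r0_da1, r0_a1a2, r0_da2)
    else:
        if seed is None:
            raise ValueError("random placement requires a seed")
        if n_samples < 1:
            raise ValueError("need at least one placement sample")
        rng = np.random.default_rng(seed)
        if placement == "random":
            # uniform fractional positions on the open segment
            frac = np.clip(rng.random(n_samples), 1e-9, 1.0 - 1e-9)

            def mean_eff(r: float) -> float:
                x = frac * r
                return float(np.mean(_total_efficiency(r, x, r0_da1, r0_a1a2, r0_da2)))
        else:
            # uniform in the unit-diameter ball centred on the segment midpoint
            direction = rng.standard_normal((n_samples, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            radius_frac = 0.5 * rng.random(n_samples) ** (1.0 / 3.0)
            pts = radius_frac[:, None] * direction  # in units of r, midpoint at origin

            def mean_eff(r: float) -> float:
                p = pts * r
                d = np.array([-0.5 * r, 0.0, 0.0])
                a2 = np.array([0.5 * r, 0.0, 0.0])
                d_da1 = np.maximum(np.linalg.norm(p - d, axis=1), 1e-9)
                d_a1a2 = np.maximum(np.linalg.norm(p - a2, axis=1), 1e-9)
                u1 = (r0_da1 / d_da1) ** 6
                u2 = (r0_da2 / r) ** 6
                denom = 1.0 + u1 + u2
                v = (r0_a1a2 / d_a1a2) ** 6
                return float(np.mean(u2 / denom + (u1 / denom) * v / (1.0 + v)))

    if r0_da1 == 0.0 and r0_da2 > 0.0:
        return distance_at_efficiency(e_target, r0_da2)

    lo, hi = 0.5, 50.0
    f_lo, f_hi = mean_eff(lo) - e_target, mean_eff(hi) - e_target
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            f"target efficiency {e_target} not bracketed on r ∈ [{lo}, {hi}] nm "
            f"(efficiency spans [{f_hi + e_target:.3g}, {f_lo + e_target:.3g}])"
        )
    return float(brentq(lambda r: mean_eff(r) - e_target, lo, hi, xtol=1e-4))
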