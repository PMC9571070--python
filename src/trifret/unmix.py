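"""Linear spectral unmixing and ratio-matched FRET comparison.

A measured λ-stack is decomposed into a non-negative combination of binned
reference spectra (plus an optional flat background), giving the relative
proportion each fluorophore contributes to the recorded emission. Because
cross-excitation and bleed-through scale with expression level, FRET can
only be read off by comparing conditions at matched donor-to-acceptor
protein ratios — estimated from sequential single-line channel images after
inverting the bleed-through response matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectra_sim import DetectorDialect, band_integral_binned, bin_spectrum

__all__ = [
    "UnmixResult",
    "RatioTaggedSample",
    "ComparisonSummary",
    "SensitizedEmissionReport",
    "unmix",
    "reference_stacks",
    "donor_acceptor_ratio",
    "ratio_matched_compare",
    "sensitized_emission_flag",
]


@dataclass(frozen=True)
class UnmixResult:
    """Non-negative least-squares decomposition of one λ-stack."""

    coefficients: np.ndarray  # weight per reference, a.u.
    background: float  # flat offset, a.u. (0 when not fitted)
    residual_rms: float
    proportions: np.ndarray  # coefficients / sum(coefficients)
    reference_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class RatioTaggedSample:
    """An unmixed spectrum tagged with its donor-to-acceptor protein ratio."""

    unmix: UnmixResult
    da_ratio: float
    label: str

    def __post_init__(self) -> None:
        if not self.da_ratio > 0:
            raise ValueError("donor-to-acceptor ratio must be positive")


@dataclass(frozen=True)
class ComparisonSummary:
    """Ratio-matched comparison of an acceptor proportion between two groups."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    difference: float  # mean_a - mean_b
    n_a: int
    n_b: int
    ratio_band: tuple[float, float]
    values_a: np.ndarray  # raw per-sample proportions, for external significance testing
    values_b: np.ndarray


def reference_stacks(records, dialect: DetectorDialect) -> np.ndarray:
    """(n_refs, n_bins) binned unit-area emission shapes, the unmixing basis.

    References are binned on the same dialect as the measured stacks — never
    the un-binned continuum — so binning bias cancels in the fit.
    """
    return np.array([bin_spectrum((rec.wavelengths, rec.emission), dialect) for rec in records])


def unmix(stack, references, fit_background: bool = True, reference_names=()) -> UnmixResult:
    """Decompose a λ-stack into non-negative reference weights.

    Parameters
    ----------
    stack
        Binned intensities, one value per dialect bin.
    references
        (n_refs, n_bins) array (rows are binned reference spectra) or a list
        of such rows. Must be linearly independent on the bin grid.
    fit_background
        Add a flat non-negative offset column modelling cellular background.
    """
    stack = np.asarray(stack, dtype=float)
    refs = np.atleast_2d(np.asarray(references, dtype=float))
    if refs.shape[0] < 1:
        raise ValueError("need at least one reference spectrum")
    if refs.shape[1] != stack.shape[0]:
        raise ValueError(
            f"references have {refs.shape[1]} bins but the stack has {stack.shape[0]}"
        )
    names = tuple(reference_names) or tuple(f"ref{i}" for i in range(refs.shape[0]))

    norms = np.linalg.norm(refs, axis=1)
    if np.any(norms == 0):
        raise ValueError("a reference spectrum is identically zero on the dialect grid")
    unit = refs / norms[:, None]
    gram = unit @ unit.T
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            if abs(gram[i, j]) > 1.0 - 1e-10:
                raise ValueError(f"collinear reference pair: {names[i]} and {names[j]}")
    if np.linalg.matrix_rank(refs) < refs.shape[0]:
        raise ValueError("reference set is rank deficient")

    design = refs.T
    if fit_background:
        design = np.column_stack([design, np.ones(len(stack))])
    solution, _ = nnls(design, stack)
    coeffs = solution[: refs.shape[0]]
    background = float(solution[-1]) if fit_background else 0.0
    residual = stack - design @ solution
    total = coeffs.sum()
    proportions = coeffs / total if total > 0 else np.zeros_like(coeffs)
    return UnmixResult(
        coefficients=coeffs,
        background=background,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        proportions=proportions,
        reference_names=names,
    )


def donor_acceptor_ratio(
    channel_values,
    response,
    donor_index: int = 0,
    acceptor_index: int = 1,
) -> float:
    """Donor-to-acceptor abundance ratio from sequential-excitation channels.

    Solves ``response @ abundances = channel_values`` — the bleed-through
    correction — then returns donor/acceptor. Negative solved abundances are
    clamped to zero with a warning; a zero acceptor abundance is reported as
    the sentinel ``inf`` rather than raising, so degenerate ROIs can be
    filtered downstream.
    """
    c = np.asarray(channel_values, dtype=float)
    m = np.asarray(response, dtype=float)
    if np.any(c < 0):
        raise ValueError("channel intensities must be non-negative")
    if m.shape[0] != m.shape[1]:
        raise ValueError("response matrix must be square (one channel per member)")
    if abs(np.linalg.det(m)) < 1e-300 or np.linalg.cond(m) > 1e12:
        raise ValueError("bleed-through response matrix is not invertible")
    abundances = np.linalg.solve(m, c)
    if np.any(abundances < -1e-9 * max(abs(abundances).max(), 1.0)):
        warnings.warn("negative solved abundance clamped to 0", stacklevel=2)
    abundances = np.clip(abundances, 0.0, None)
    if abundances[acceptor_index] == 0.0:
        return math.inf
    return float(abundances[donor_index] / abundances[acceptor_index])


def ratio_matched_compare(
    samples,
    group_a: str,
    group_b: str,
    ratio_tolerance: float = 0.25,
    acceptor_index: int = 1,
) -> ComparisonSummary:
    """Compare an acceptor's unmixed proportion between two conditions at matched ratios.

    Only samples whose donor-to-acceptor ratio falls inside the band common
    to both groups (the overlap of the per-group ratio ranges, widened by the
    relative tolerance) enter the comparison; at least 3 samples per group
    must survive. Significance testing on the returned raw arrays is
    delegated to standard statistical routines.
    """
    a = [s for s in samples if s.label == group_a and math.isfinite(s.da_ratio)]
    b = [s for s in samples if s.label == group_b and math.isfinite(s.da_ratio)]
    if not a or not b:
        raise ValueError("both groups need at least one finite-ratio sample")
    lo = max(min(s.da_ratio for s in a), min(s.da_ratio for s in b))
    hi = min(max(s.da_ratio for s in a), max(s.da_ratio for s in b))
    band = (lo / (1.0 + ratio_tolerance), hi * (1.0 + ratio_tolerance))
    if band[0] > band[1]:
        raise ValueError(
            f"no overlapping donor-to-acceptor ratio band between {group_a!r} and "
            f"{group_b!r} at tolerance {ratio_tolerance}"
        )
    sel_a = [s for s in a if band[0] <= s.da_ratio <= band[1]]
    sel_b = [s for s in b if band[0] <= s.da_ratio <= band[1]]
    if len(sel_a) < 3 or len(sel_b) < 3:
        raise ValueError(
            f"need >=3 ratio-matched samples per group, got {len(sel_a)}/{len(sel_b)}"
        )
    va = np.array([s.unmix.proportions[acceptor_index] for s in sel_a])
    vb = np.array([s.unmix.proportions[acceptor_index] for s in sel_b])
    return ComparisonSummary(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        difference=float(va.mean() - vb.mean()),
        n_a=len(sel_a),
        n_b=len(sel_b),
        ratio_band=band,
        values_a=va,
        values_b=vb,
    )


@dataclass(frozen=True)
class SensitizedEmissionReport:
    """Per-condition sensitized-emission indicators against the donor-only baseline."""

    label: str
    terminal_band_excess: float  # baseline-subtracted terminal-acceptor band, fraction of total
    intermediate_band_change: float  # drop vs the donor+intermediate reference, fraction of total
    terminal_sensitized: bool
    cascade_signature: bool  # terminal band up AND intermediate band down


def sensitized_emission_flag(
    stacks: dict,
    dialect: DetectorDialect,
    baseline_label: str,
    intermediate_reference_label: str | None = None,
    terminal_band=(600.0, 625.0),
    intermediate_band=(515.0, 535.0),
    terminal_threshold: float = 0.003,
    intermediate_threshold: float = 0.005,
) -> dict[str, SensitizedEmissionReport]:
    """Flag terminal-acceptor sensitized emission and the three-chromophore signature.

    Each λ-stack is normalized to unit total so conditions compare shape-wise.
    A condition shows sensitized terminal emission when its terminal band
    exceeds the donor-only baseline by more than ``terminal_threshold`` of
    the total intensity. The full cascade signature additionally requires the
    intermediate band to drop by ``intermediate_threshold`` relative to the
    donor+intermediate reference condition (energy leaving the intermediate
    toward the terminal acceptor). Thresholds are fractions of total
    intensity, sized for condition-averaged stacks (see docs).
    """
    if baseline_label not in stacks:
        raise ValueError(f"donor-only baseline {baseline_label!r} missing from stacks")

    def norm_band(stack, band) -> float:
        stack = np.asarray(stack, dtype=float)
        total = band_integral_binned(stack, dialect, (dialect.grid.start, dialect.grid.stop))
        if total <= 0:
            return 0.0
        return band_integral_binned(stack, dialect, band) / total

    base_term = norm_band(stacks[baseline_label], terminal_band)
    ref_inter = (
        norm_band(stacks[intermediate_reference_label], intermediate_band)
        if intermediate_reference_label is not None
        else None
    )
    out: dict[str, SensitizedEmissionReport] = {}
    for label, stack in stacks.items():
        term_excess = norm_band(stack, terminal_band) - base_term
        inter_change = (ref_inter - norm_band(stack, intermediate_band)) if ref_inter is not None else 0.0
        sensitized = term_excess > terminal_threshold
        out[label] = SensitizedEmissionReport(
            label=label,
            terminal_band_excess=float(term_excess),
            intermediate_band_change=float(inter_change),
            terminal_sensitized=bool(sensitized),
            cascade_signature=bool(
                sensitized
                and ref_inter is not None
                and label != intermediate_reference_label
                and inter_change > intermediate_threshold
            ),
        )
    return out
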