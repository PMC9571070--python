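"""Forward simulation of emission spectra under single-line excitation.

Models what a spectral detector sees for a mixture of fluorophores: each
member is excited in proportion to abundance · ε(λ_ex) (cross-excitation
falls out naturally for acceptors absorbing at the donor's line), excited
quanta are redistributed along the pairwise FRET matrix, and every member
emits its remaining quanta with its quantum yield into its emission band
(bleed-through between detection bands likewise falls out naturally).

Intensities are arbitrary units with a single global gain; absolute
radiometry is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cascade import CascadeGeometry, cascade_efficiencies
from .forster import fret_efficiency
from .spectra_core import WORKING_GRID, FluorophoreRecord, WavelengthGrid

__all__ = [
    "SpectralScene",
    "DetectorDialect",
    "EmissionSpectrum",
    "LEICA",
    "ZEISS",
    "simulate_emission",
    "stoichiometry_series",
    "bin_spectrum",
    "channel_intensities",
    "response_matrix",
    "band_integral_binned",
]


@dataclass(frozen=True)
class DetectorDialect:
    """λ-stack binning grid plus the sequential excitation/detection channels."""

    name: str
    grid: WavelengthGrid
    channels: tuple[tuple[float, tuple[float, float]], ...]  # (excitation nm, (band lo, hi))

    def __post_init__(self) -> None:
        for _, (lo, hi) in self.channels:
            if not lo < hi:
                raise ValueError(f"{self.name}: malformed detection band ({lo}, {hi})")
        bands = sorted(band for _, band in self.channels)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(bands, bands[1:]):
            if b_lo < a_hi:
                raise ValueError(f"{self.name}: detection bands overlap")

    @property
    def n_bins(self) -> int:
        # bins are [start, start+step); the grid stop closes the last bin
        return int(np.floor((self.grid.stop - self.grid.start) / self.grid.step))

    def bin_edges(self) -> np.ndarray:
        return self.grid.start + self.grid.step * np.arange(self.n_bins + 1)


#: 460–625 nm λ-stack at Δ7.5 nm (22 bins); 458/514/561 nm lines with
#: 465–505 / 525–565 / 605–650 nm detection bands.
LEICA = DetectorDialect(
    name="leica",
    grid=WavelengthGrid(460.0, 625.0, 7.5),
    channels=((458.0, (465.0, 505.0)), (514.0, (525.0, 565.0)), (561.0, (605.0, 650.0))),
)

#: 460–650 nm at Δ4.5 nm, single 485 nm line variant.
ZEISS = DetectorDialect(
    name="zeiss",
    grid=WavelengthGrid(460.0, 650.0, 4.5),
    channels=((485.0, (495.0, 550.0)), (561.0, (565.0, 650.0))),
)


@dataclass(frozen=True)
class SpectralScene:
    """Fluorophore amounts, pairwise transfer efficiencies and the excitation line.

    ``transfer[i, j]`` is the probability that an excited member i hands its
    quantum to member j; rows must sum to ≤ 1 and transfer is only allowed
    downhill in energy (toward redder emitters).
    """

    members: tuple[tuple[FluorophoreRecord, float], ...]
    transfer: np.ndarray
    excitation_nm: float
    relay_cross_excitation: bool = True  # directly excited non-donor members may relay onward

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.transfer, dtype=float))
        n = len(self.members)
        if t.shape != (n, n):
            raise ValueError(f"transfer matrix must be {n}x{n}, got {t.shape}")
        if np.any(t < 0) or np.any(t.sum(axis=1) > 1.0 + 1e-12):
            raise ValueError("transfer efficiencies must be >= 0 with row sums <= 1")
        peaks = [rec.emission_peak_nm for rec, _ in self.members]
        for i in range(n):
            for j in range(n):
                if t[i, j] > 0 and peaks[j] <= peaks[i]:
                    raise ValueError(
                        "uphill transfer forbidden: "
                        f"{self.members[i][0].name} -> {self.members[j][0].name}"
                    )
        for rec, amount in self.members:
            if amount < 0:
                raise ValueError(f"{rec.name}: abundance must be non-negative")
        object.__setattr__(self, "transfer", t)

    def with_abundances(self, abundances) -> "SpectralScene":
        if len(abundances) != len(self.members):
            raise ValueError("one abundance per member required")
        members = tuple((rec, float(a)) for (rec, _), a in zip(self.members, abundances))
        return replace(self, members=members)

    @classmethod
    def from_cascade(
        cls,
        donor: FluorophoreRecord,
        intermediate: FluorophoreRecord,
        terminal: FluorophoreRecord,
        geometry: CascadeGeometry,
        abundances=(1.0, 1.0, 1.0),
        excitation_nm: float = 458.0,
        relay_cross_excitation: bool = True,
    ) -> "SpectralScene":
        """Build the D/A1/A2 transfer matrix from a collinear cascade geometry."""
        res = cascade_efficiencies(geometry)
        e_hop = fret_efficiency(geometry.r_da2 - geometry.x_a1, geometry.r0_a1a2)
        transfer = np.array(
            [
                [0.0, res.e_to_a1, res.e_direct_to_a2],
                [0.0, 0.0, e_hop],
                [0.0, 0.0, 0.0],
            ]
        )
        return cls(
            members=tuple(
                (rec, float(a)) for rec, a in zip((donor, intermediate, terminal), abundances)
            ),
            transfer=transfer,
            excitation_nm=excitation_nm,
            relay_cross_excitation=relay_cross_excitation,
        )


@dataclass(frozen=True)
class EmissionSpectrum:
    """Total simulated spectrum plus its per-member component decomposition."""

    wavelengths: np.ndarray
    components: np.ndarray  # (n_members, n_wavelengths)
    member_names: tuple[str, ...]
    excited: np.ndarray  # quanta absorbed per member (direct + received)
    emitted: np.ndarray  # quanta emitted per member
    transferred_out: np.ndarray  # quanta handed onward per member

    @property
    def total(self) -> np.ndarray:
        return self.components.sum(axis=0)


def simulate_emission(
    scene: SpectralScene,
    grid: WavelengthGrid = WORKING_GRID,
    gain: float = 1.0,
) -> EmissionSpectrum:
    """Simulate the emission spectrum of a scene under its excitation line.

    Excitation of member i is abundance_i · ε_i(λ_ex). Quanta then flow along
    the transfer matrix in energy order; each member emits
    (absorbed − transferred-out) · Q into its unit-area emission density.
    With ``relay_cross_excitation=False``, directly excited quanta of
    non-primary members emit without relaying (only FRET-received quanta hop
    onward) — a sensitivity switch for the cross-excitation → relay pathway.
    """
    n = len(scene.members)
    direct = np.array(
        [amount * rec.extinction_at(scene.excitation_nm) for rec, amount in scene.members]
    )
    if np.all(direct == 0):
        warnings.warn(
            f"excitation at {scene.excitation_nm} nm is outside every member's "
            "extinction support; spectrum is all-zero",
            stacklevel=2,
        )

    order = np.argsort([rec.emission_peak_nm for rec, _ in scene.members])
    primary = order[0]  # bluest member drives the cascade
    received = np.zeros(n)
    transferred_out = np.zeros(n)
    for i in order:
        relay_pool = received[i] + (
            direct[i] if (scene.relay_cross_excitation or i == primary) else 0.0
        )
        out_frac = scene.transfer[i].sum()
        transferred_out[i] = relay_pool * out_frac
        if out_frac > 0:
            received += relay_pool * scene.transfer[i]

    excited = direct + received
    emitted = (excited - transferred_out) * np.array(
        [rec.quantum_yield for rec, _ in scene.members]
    )
    wl = grid.points()
    components = gain * emitted[:, None] * np.array(
        [rec.emission_at(wl) for rec, _ in scene.members]
    )
    return EmissionSpectrum(
        wavelengths=wl,
        components=components,
        member_names=tuple(rec.name for rec, _ in scene.members),
        excited=excited,
        emitted=emitted,
        transferred_out=transferred_out,
    )


def stoichiometry_series(scene: SpectralScene, ratios) -> list[EmissionSpectrum]:
    """Simulate the scene at a series of abundance vectors (e.g. 1:2, 1:3, 1:4)."""
    ratios = list(ratios)
    if not ratios:
        raise ValueError("empty ratio list")
    return [simulate_emission(scene.with_abundances(r)) for r in ratios]


def _band_integral(wavelengths: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    """Exact integral of the piecewise-linear spectrum over [lo, hi]."""
    lo = max(lo, wavelengths[0])
    hi = min(hi, wavelengths[-1])
    if hi <= lo:
        return 0.0
    inner = wavelengths[(wavelengths > lo) & (wavelengths < hi)]
    xs = np.concatenate(([lo], inner, [hi]))
    ys = np.interp(xs, wavelengths, values)
    return float(np.trapezoid(ys, xs))


def bin_spectrum(spectrum, dialect: DetectorDialect) -> np.ndarray:
    """Bin a spectrum into the dialect's λ-stack (integral per [start, start+Δ) bin)."""
    if isinstance(spectrum, EmissionSpectrum):
        wl, y = spectrum.wavelengths, spectrum.total
    else:
        wl, y = (np.asarray(a, dtype=float) for a in spectrum)
    edges = dialect.bin_edges()
    return np.array([_band_integral(wl, y, a, b) for a, b in zip(edges, edges[1:])])


def band_integral_binned(stack: np.ndarray, dialect: DetectorDialect, band) -> float:
    """Integral of a binned λ-stack over a wavelength band (partial-bin overlap weighted)."""
    lo, hi = band
    edges = dialect.bin_edges()
    total = 0.0
    for value, (a, b) in zip(stack, zip(edges, edges[1:])):
        overlap = max(0.0, min(b, hi) - max(a, lo))
        total += value * overlap / (b - a)
    return float(total)


def channel_intensities(scene: SpectralScene, dialect: DetectorDialect) -> np.ndarray:
    """Per-channel intensities under sequential single-line excitation.

    For each channel the scene is re-simulated at that channel's excitation
    line and the total spectrum integrated over its detection band, so
    cross-excitation and bleed-through of every member are included.
    """
    return channel_components(scene, dialect).sum(axis=0)


def channel_components(scene: SpectralScene, dialect: DetectorDialect) -> np.ndarray:
    """(n_members, n_channels) per-member contributions to each channel."""
    out = np.zeros((len(scene.members), len(dialect.channels)))
    for c, (ex, (lo, hi)) in enumerate(dialect.channels):
        spec = simulate_emission(replace(scene, excitation_nm=ex))
        for m in range(len(scene.members)):
            out[m, c] = _band_integral(spec.wavelengths, spec.components[m], lo, hi)
    return out


def response_matrix(records, dialect: DetectorDialect) -> np.ndarray:
    """(n_channels, n_members) response of each pure unit-abundance member.

    Column j is what member j alone contributes to each sequential channel —
    the matrix inverted by bleed-through correction when estimating
    abundances from channel images.
    """
    n = len(records)
    cols = []
    for rec in records:
        scene = SpectralScene(
            members=((rec, 1.0),),
            transfer=np.zeros((1, 1)),
            excitation_nm=dialect.channels[0][0],
        )
        cols.append(channel_intensities(scene, dialect))
    return np.column_stack(cols)
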