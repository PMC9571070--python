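"""Named ground-truth scenarios emulating the measured inputs end to end.

Each preset describes one co-expression condition of the membrane receptor
study this package models — donor alone, donor plus one acceptor, the full
donor→intermediate→terminal cascade, and negative controls with an
uncoupled bystander — and generates everything a real acquisition would
produce: noisy 8-bit λ-stacks, sequential-excitation channel intensities
and TCSPC decay histograms, together with a ground-truth manifest.

The defaults are the study's conditions: 1:1:1 stoichiometry with the
7 nm equidistant cascade arrangement for the ternary preset, donor
lifetimes of 3.99 ns (unquenched), 3.54 ns (binary heteromer) and 3.40 ns
(ternary complex), 2 % spectral noise with 8-bit saturation, and a
5×10⁵-photon budget per decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeGeometry, cascade_efficiencies
from .flim import DecayHistogram, simulate_decay
from .forster import fret_efficiency
from .spectra_core import synthetic_fluorophores
from .spectra_sim import (
    LEICA,
    DetectorDialect,
    SpectralScene,
    bin_spectrum,
    channel_intensities,
    simulate_emission,
)

__all__ = ["ScenarioPreset", "ScenarioBundle", "PRESETS", "make_scenario", "write_bundle"]

#: Pairwise Förster radii (nm) of the donor/intermediate/terminal triple.
R0_TRIPLE = (5.7, 5.2, 5.1)

#: Equidistant cascade arrangement used for ground truth: 7 nm spacings.
TERNARY_GEOMETRY = CascadeGeometry(14.0, 7.0, *R0_TRIPLE)


@dataclass(frozen=True)
class ScenarioPreset:
    """Ground truth for one co-expression condition."""

    name: str
    members: tuple[str, ...]  # subset of {mTRQ2, mVEN, mRFP}
    transfer: np.ndarray  # pairwise efficiencies on the member list
    abundances: tuple[float, ...]
    donor_lifetime_ns: float  # ground-truth donor lifetime under this condition
    lifetime_sd_ns: float = 0.05  # ROI-to-ROI biological spread
    spectra_noise: float = 0.02  # additive Gaussian sigma, fraction of stack peak
    photon_budget: int = 500_000
    abundance_jitter: float = 0.1  # lognormal sigma on per-ROI expression levels
    geometry: CascadeGeometry | None = None


def _binary_transfer(e: float) -> np.ndarray:
    return np.array([[0.0, e], [0.0, 0.0]])


def _presets() -> dict[str, ScenarioPreset]:
    e_da1 = fret_efficiency(7.0, R0_TRIPLE[0])  # donor -> intermediate at 7 nm
    res = cascade_efficiencies(TERNARY_GEOMETRY)
    e_hop = fret_efficiency(7.0, R0_TRIPLE[1])
    cascade_t = np.array(
        [
            [0.0, res.e_to_a1, res.e_direct_to_a2],
            [0.0, 0.0, e_hop],
            [0.0, 0.0, 0.0],
        ]
    )
    uncoupled_t = np.array(
        [
            [0.0, e_da1, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
        ]
    )
    presets = [
        ScenarioPreset(
            name="donor_only",
            members=("mTRQ2",),
            transfer=np.zeros((1, 1)),
            abundances=(1.0,),
            donor_lifetime_ns=3.99,
        ),
        ScenarioPreset(
            name="donor_A1",
            members=("mTRQ2", "mVEN"),
            transfer=_binary_transfer(e_da1),
            abundances=(1.0, 1.0),
            donor_lifetime_ns=3.54,
        ),
        ScenarioPreset(
            name="donor_A2",
            members=("mTRQ2", "mRFP"),
            transfer=_binary_transfer(fret_efficiency(7.0, R0_TRIPLE[2])),
            abundances=(1.0, 1.0),
            donor_lifetime_ns=3.54,
        ),
        ScenarioPreset(
            name="donor_A1_uncoupledA2",
            members=("mTRQ2", "mVEN", "mRFP"),
            transfer=uncoupled_t,
            abundances=(1.0, 1.0, 1.0),
            donor_lifetime_ns=3.60,
        ),
        ScenarioPreset(
            name="ternary_cascade",
            members=("mTRQ2", "mVEN", "mRFP"),
            transfer=cascade_t,
            abundances=(1.0, 1.0, 1.0),
            donor_lifetime_ns=3.40,
            geometry=TERNARY_GEOMETRY,
        ),
        # Non-interacting bystander intermediate: cross-excitation and
        # bleed-through present, no energy transfer at all.
        ScenarioPreset(
            name="negative_control_FLS2like",
            members=("mTRQ2", "mVEN"),
            transfer=np.zeros((2, 2)),
            abundances=(1.0, 1.0),
            donor_lifetime_ns=3.70,
        ),
    ]
    return {p.name: p for p in presets}


PRESETS: dict[str, ScenarioPreset] = _presets()


@dataclass(frozen=True)
class ScenarioBundle:
    """n_roi noisy realizations of one preset plus the generating truth."""

    preset: ScenarioPreset
    dialect: DetectorDialect
    stacks: np.ndarray  # (n_roi, n_bins) 8-bit λ-stacks, a.u.
    channel_values: np.ndarray  # (n_roi, n_channels) 8-bit channel intensities
    decays: tuple[DecayHistogram, ...]
    roi_lifetimes_ns: np.ndarray  # per-ROI true donor lifetimes
    truth: dict

    def mean_stack(self) -> np.ndarray:
        return self.stacks.mean(axis=0)


def _quantize_8bit(values: np.ndarray, scale: float) -> np.ndarray:
    """Scale to 8-bit a.u. and saturate, as the detector's channel images do."""
    return np.clip(np.round(values * scale), 0, 255)


def make_scenario(
    preset: str | ScenarioPreset,
    n_roi: int = 20,
    seed: int | None = None,
    dialect: DetectorDialect = LEICA,
    excitation_nm: float = 458.0,
) -> ScenarioBundle:
    """Generate a deterministic synthetic dataset bundle for one preset.

    Per ROI: expression levels are jittered lognormally around the preset
    abundances, the emission spectrum is forward-simulated and binned to the
    dialect, Gaussian noise (``spectra_noise`` × clean peak) is added and
    the stack quantized to 8 bits with the clean peak mapped to 200 a.u.;
    channel intensities get the same treatment. The donor decay is drawn
    with a per-ROI lifetime (truth ± ``lifetime_sd_ns``) at the preset's
    photon budget. Identical preset + seed ⇒ identical bundle.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        preset = PRESETS[preset]
    if seed is None:
        raise ValueError("a seed is required; bundles must be reproducible")
    if n_roi < 1:
        raise ValueError("need at least one ROI")

    rng = np.random.default_rng(seed)
    records = synthetic_fluorophores()
    members = [records[name] for name in preset.members]

    stacks, channels, decays, lifetimes = [], [], [], []
    for _ in range(n_roi):
        amounts = np.asarray(preset.abundances) * rng.lognormal(
            0.0, preset.abundance_jitter, size=len(members)
        )
        scene = SpectralScene(
            members=tuple(zip(members, amounts)),
            transfer=preset.transfer,
            excitation_nm=excitation_nm,
        )
        clean = bin_spectrum(simulate_emission(scene), dialect)
        peak = clean.max()
        scale = 200.0 / peak if peak > 0 else 1.0
        noisy = clean + rng.normal(0.0, preset.spectra_noise * peak, size=clean.shape)
        stacks.append(_quantize_8bit(noisy, scale))

        ch_clean = channel_intensities(scene, dialect)
        ch_scale = 200.0 / ch_clean.max() if ch_clean.max() > 0 else 1.0
        ch_noisy = ch_clean + rng.normal(
            0.0, preset.spectra_noise * ch_clean.max(), size=ch_clean.shape
        )
        channels.append(_quantize_8bit(ch_noisy, ch_scale))

        tau = max(rng.normal(preset.donor_lifetime_ns, preset.lifetime_sd_ns), 0.1)
        lifetimes.append(tau)
        decays.append(
            simulate_decay(
                [tau],
                n_photons=preset.photon_budget,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )

    truth = {
        "preset": preset.name,
        "members": list(preset.members),
        "abundances": list(preset.abundances),
        "transfer": np.asarray(preset.transfer).tolist(),
        "donor_lifetime_ns": preset.donor_lifetime_ns,
        "lifetime_sd_ns": preset.lifetime_sd_ns,
        "spectra_noise": preset.spectra_noise,
        "photon_budget": preset.photon_budget,
        "n_roi": n_roi,
        "seed": seed,
        "dialect": dialect.name,
        "excitation_nm": excitation_nm,
    }
    return ScenarioBundle(
        preset=preset,
        dialect=dialect,
        stacks=np.array(stacks),
        channel_values=np.array(channels),
        decays=tuple(decays),
        roi_lifetimes_ns=np.array(lifetimes),
        truth=truth,
    )


def write_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> Path:
    """Write a bundle as plain-text CSV/JSON files (one λ-stack CSV per ROI)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = bundle.dialect.bin_edges()[:-1]
    for i, stack in enumerate(bundle.stacks):
        pd.DataFrame({"bin_start_nm": edges, "intensity": stack}).to_csv(
            out / f"stack_roi{i:03d}.csv", index=False
        )
    pd.DataFrame(
        bundle.channel_values,
        columns=[f"ex{int(ex)}nm" for ex, _ in bundle.dialect.channels],
    ).to_csv(out / "channels.csv", index=False)
    for i, decay in enumerate(bundle.decays):
        pd.DataFrame(
            {"time_ns": decay.bin_times, "counts": decay.counts, "irf": decay.irf}
        ).to_csv(out / f"decay_roi{i:03d}.csv", index=False)
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
    return out
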