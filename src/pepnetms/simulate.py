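"""Seeded simulation of singly protonated linear-peptide MS/MS spectra.

The generator stands in for raw LC-MS/MS data: it renders a peptide's
theoretical ion set with ion-kind-dependent base intensities, perturbs every
m/z with zero-mean Gaussian ppm error (defaults emulate the few-ppm accuracy
of high-resolution QTOF product-ion tables), applies multiplicative
lognormal intensity jitter, and adds a Poisson number of low-intensity noise
peaks.  Identical (peptide, config, seed) always yields an identical
spectrum, and the ground-truth ion-to-peak map is retained for testing.

Real product-ion intensities for this compound class are unpublished, so the
intensity model is rank-free and arbitrary-but-fixed; nothing downstream
asserts intensity values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .fragments import FragmentationConfig, IonSpecies, theoretical_ions
from .peptides import LinearPeptide, precursor_mz
from .spectrum import Peak, Spectrum

__all__ = [
    "SimulationConfig",
    "SimulatedSpectrum",
    "simulate_spectrum",
    "derive_subseed",
]

#: Relative base intensity per ion kind (arbitrary units).
_DEFAULT_KIND_INTENSITY: Mapping[str, float] = MappingProxyType(
    {
        "y": 1.0,
        "b": 0.8,
        "precursor": 0.7,
        "immonium": 0.6,
        "internal_b": 0.5,
        "a": 0.4,
        "internal_a": 0.3,
    }
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; ``seed`` is required for reproducibility."""

    seed: int
    kind_intensity: Mapping[str, float] = field(
        default_factory=lambda: _DEFAULT_KIND_INTENSITY
    )
    loss_factor: float = 0.3                # per neutral loss, multiplicative
    mass_error_ppm_sigma: float = 3.0
    intensity_jitter_sigma: float = 0.2     # lognormal sigma; 0 disables
    noise_peak_mean: float = 5.0            # Poisson mean; 0 disables
    noise_intensity_max_frac: float = 0.05  # of the base (signal) peak
    noise_low_mz: float = 50.0
    noise_upper_margin: float = 20.0        # noise stays this far below precursor
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)

    def __post_init__(self):
        if self.mass_error_ppm_sigma < 0 or self.intensity_jitter_sigma < 0:
            raise ValueError("noise widths must be non-negative")
        if any(v <= 0 for v in self.kind_intensity.values()):
            raise ValueError("relative intensities must be positive")


@dataclass(frozen=True)
class SimulatedSpectrum:
    """A spectrum plus its generation ground truth."""

    spectrum: Spectrum
    peptide: LinearPeptide
    #: (ion, index into ``spectrum.peaks``) for every rendered signal ion
    ion_peaks: tuple[tuple[IonSpecies, int], ...]

    @property
    def ions(self) -> tuple[IonSpecies, ...]:
        return tuple(ion for ion, _ in self.ion_peaks)


def simulate_spectrum(
    p: LinearPeptide, cfg: SimulationConfig, spectrum_id: str | None = None
) -> SimulatedSpectrum:
    rng = np.random.default_rng(cfg.seed)
    ions = theoretical_ions(p, cfg.fragmentation)

    def jitter_mz(mz: float) -> float:
        if cfg.mass_error_ppm_sigma == 0:
            return mz
        return mz * (1 + rng.normal(0.0, cfg.mass_error_ppm_sigma) * 1e-6)

    # draws happen in a fixed order: precursor first, then ions sorted as
    # enumerated, then noise — so the stream is stable for a fixed config
    prec = jitter_mz(precursor_mz(p))

    entries: list[tuple[float, float, IonSpecies | None]] = []
    for ion in ions:
        base = cfg.kind_intensity.get(ion.kind)
        if base is None:
            continue
        intensity = base * cfg.loss_factor ** len(ion.losses)
        if cfg.intensity_jitter_sigma > 0:
            intensity *= float(np.exp(rng.normal(0.0, cfg.intensity_jitter_sigma)))
        entries.append((jitter_mz(ion.mz), intensity, ion))

    if cfg.noise_peak_mean > 0 and entries:
        base_int = max(e[1] for e in entries)
        high = prec - cfg.noise_upper_margin
        n_noise = int(rng.poisson(cfg.noise_peak_mean))
        for _ in range(n_noise):
            mz = float(rng.uniform(cfg.noise_low_mz, high))
            intensity = float(rng.uniform(0.0, cfg.noise_intensity_max_frac)) * base_int
            if intensity <= 0.0:
                intensity = 1e-9 * base_int
            entries.append((mz, intensity, None))

    order = sorted(range(len(entries)), key=lambda k: entries[k][0])
    peaks = tuple(Peak(entries[k][0], entries[k][1]) for k in order)
    spectrum = Spectrum(
        id=spectrum_id or (p.name or "simulated"),
        precursor_mz=prec,
        precursor_charge=1,
        peaks=peaks,
    )
    # map ions to post-sort peak indices (merging of sub-1e-6 Da collisions
    # is possible in principle; map onto the merged peak by nearest m/z)
    mz_list = [pk.mz for pk in spectrum.peaks]
    ion_peaks = []
    for k in order:
        ion = entries[k][2]
        if ion is None:
            continue
        mz = entries[k][0]
        idx = min(range(len(mz_list)), key=lambda i: abs(mz_list[i] - mz))
        ion_peaks.append((ion, idx))
    return SimulatedSpectrum(spectrum, p, tuple(ion_peaks))


def derive_subseed(master_seed: int, name: str) -> int:
    """Stable per-compound sub-seed (< 2**31): adding a compound never
    perturbs the spectra of the others."""
    return (int(master_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31)
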