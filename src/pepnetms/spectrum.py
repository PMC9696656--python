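"""Observed-data carriers: peaks and spectra."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Peak", "Spectrum", "SpectrumError"]


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise SpectrumError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise SpectrumError("peak intensity must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """Precursor info plus a peak list kept sorted ascending in m/z.

    Peaks closer than 1e-6 Da are merged (intensities summed) on
    construction so that every stored m/z is unique.
    """

    id: str
    precursor_mz: float
    precursor_charge: int = 1
    retention_time: float | None = None
    peaks: tuple[Peak, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise SpectrumError("precursor m/z must be positive")
        if self.precursor_charge < 1:
            raise SpectrumError("precursor charge must be >= 1")
        merged: list[Peak] = []
        for p in sorted(self.peaks, key=lambda p: p.mz):
            if merged and p.mz - merged[-1].mz < 1e-6:
                merged[-1] = Peak(merged[-1].mz, merged[-1].intensity + p.intensity)
            else:
                merged.append(p)
        object.__setattr__(self, "peaks", tuple(merged))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def scaled(self, factor: float) -> "Spectrum":
        """Spectrum with all intensities multiplied by ``factor``."""
        return replace(
            self,
            peaks=tuple(Peak(p.mz, p.intensity * factor) for p in self.peaks),
        )
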