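"""ssNMR spectrum utilities: region normalization and difference spectra.

Solid-state 13C spectra of treated and control lignin are compared after
scaling each spectrum so that the integral over a reference region (the
aliphatic 10-60 ppm and O-aliphatic 60-110 ppm carbons, which the treatment
leaves unchanged) is one; the pointwise difference then isolates
treatment-induced intensity changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Spectrum", "normalize_spectrum_to_region", "difference_spectrum"]

ALIPHATIC_REGION = (10.0, 60.0)
O_ALIPHATIC_REGION = (60.0, 110.0)


@dataclass(frozen=True)
class Spectrum:
    """A 1-D NMR spectrum: ppm axis (strictly monotone) and intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    nucleus: str = "13C"

    def __post_init__(self):
        ppm = np.asarray(self.ppm, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or y.shape != ppm.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", y)

    def region_integral(self, region: tuple[float, float]) -> float:
        lo, hi = sorted(region)
        ppm, y = self.ppm, self.intensity
        if ppm[0] > ppm[-1]:  # descending axis: integrate on the reversed copy
            ppm, y = ppm[::-1], y[::-1]
        if hi < ppm[0] or lo > ppm[-1]:
            raise ValueError(f"region {region} does not overlap the axis")
        mask = (ppm >= lo) & (ppm <= hi)
        if mask.sum() < 2:
            raise ValueError(f"region {region} covers fewer than two points")
        return float(np.trapezoid(y[mask], ppm[mask]))


def normalize_spectrum_to_region(
    spec: Spectrum, region: tuple[float, float] | list[tuple[float, float]]
) -> Spectrum:
    """Scale intensities so the integral over ``region`` equals 1.

    ``region`` may be a single (lo, hi) ppm interval or a list of intervals
    whose integrals are summed (e.g. aliphatic plus O-aliphatic carbons).
    """
    regions = region if isinstance(region, list) else [region]
    total = sum(spec.region_integral(r) for r in regions)
    if total == 0:
        raise ValueError("zero integral over the normalization region")
    return replace(spec, intensity=spec.intensity / total)


def difference_spectrum(a: Spectrum, b: Spectrum, interpolate: bool = False) -> Spectrum:
    """Pointwise a - b on a shared ppm axis.

    The axes must be equal unless ``interpolate`` is set, in which case b is
    linearly interpolated onto a's axis.
    """
    if a.ppm.shape == b.ppm.shape and np.allclose(a.ppm, b.ppm):
        return replace(a, intensity=a.intensity - b.intensity)
    if not interpolate:
        raise ValueError("ppm axes differ; pass interpolate=True to resample b")
    asc = a.ppm[0] < a.ppm[-1]
    bp, bi = (b.ppm, b.intensity) if b.ppm[0] < b.ppm[-1] else (b.ppm[::-1], b.intensity[::-1])
    target = a.ppm if asc else a.ppm[::-1]
    resampled = np.interp(target, bp, bi)
    if not asc:
        resampled = resampled[::-1]
    return replace(a, intensity=a.intensity - resampled)
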