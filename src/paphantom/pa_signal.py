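"""Photoacoustic A-line processing and peak-to-peak spectroscopy.

An A-line is the time-resolved pressure signal recorded after one laser
pulse. The spectroscopic validation currency is the peak-to-peak (P2P)
amplitude of the denoised, pulse-energy-normalised A-line as a function of
the illumination wavelength; comparing a candidate phantom spectrum with an
ensemble of tissue spectra (mean, sd, min/max envelope) is the final
validation computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt

__all__ = [
    "PAAline",
    "PASpectrum",
    "SpectrumEnsemble",
    "DenoiseConfig",
    "denoise",
    "p2p_spectrum",
    "compare_spectra",
]


@dataclass(frozen=True)
class PAAline:
    """One photoacoustic trace at a single wavelength.

    ``photodiode_value`` is the per-pulse energy proxy used for
    normalisation; must be strictly positive.
    """

    trace: np.ndarray
    sampling_rate: float
    wavelength_nm: float
    photodiode_value: float = 1.0
    n_averages: int = 512

    def __post_init__(self):
        tr = np.asarray(self.trace, dtype=float)
        if not np.all(np.isfinite(tr)):
            raise ValueError("trace contains non-finite samples")
        if self.photodiode_value <= 0:
            raise ValueError(
                f"photodiode_value must be > 0, got {self.photodiode_value}")
        object.__setattr__(self, "trace", tr)


@dataclass(frozen=True)
class PASpectrum:
    """Wavelength-indexed normalised peak-to-peak amplitudes."""

    wavelengths_nm: np.ndarray
    p2p: np.ndarray
    gate: tuple[float, float] | None = None

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        p = np.asarray(self.p2p, dtype=float)
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("p2p amplitudes must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "p2p", p)

    def peak_normalised(self) -> "PASpectrum":
        peak = self.p2p.max()
        if peak == 0:
            raise ValueError("cannot peak-normalise an all-zero spectrum")
        return replace(self, p2p=self.p2p / peak)


@dataclass(frozen=True)
class SpectrumEnsemble:
    """A set of spectra on a common grid with mean, sd and min/max envelope."""

    wavelengths_nm: np.ndarray
    members: np.ndarray   # shape (n_members, n_wavelengths)

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        m = np.atleast_2d(np.asarray(self.members, dtype=float))
        if m.shape[1] != w.size:
            raise ValueError("member spectra do not match the wavelength grid")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "members", m)

    @classmethod
    def from_spectra(cls, spectra, normalise: bool = True) -> "SpectrumEnsemble":
        grid = spectra[0].wavelengths_nm
        rows = []
        for s in spectra:
            if not np.array_equal(s.wavelengths_nm, grid):
                raise ValueError("ensemble members must share a wavelength grid")
            rows.append(s.peak_normalised().p2p if normalise else s.p2p)
        return cls(wavelengths_nm=grid, members=np.array(rows))

    @property
    def mean(self):
        return self.members.mean(axis=0)

    @property
    def sd(self):
        if self.members.shape[0] < 2:
            return np.zeros(self.members.shape[1])
        return self.members.std(axis=0, ddof=1)

    @property
    def envelope(self):
        return self.members.min(axis=0), self.members.max(axis=0)


@dataclass(frozen=True)
class DenoiseConfig:
    """Wavelet shrinkage settings.

    Daubechies-8 with soft universal thresholding; the threshold is the
    universal sigma*sqrt(2 ln N) with sigma estimated from the median
    absolute deviation of the finest detail level. Level defaults to
    min(5, log2(N) - 3).
    """

    wavelet: str = "db8"
    level: int | None = None
    mode: str = "soft"


def _decomposition_level(n: int, level: int | None) -> int:
    auto = max(1, min(5, int(np.floor(np.log2(n))) - 3))
    return auto if level is None else level


def denoise(aline: PAAline, config: DenoiseConfig | None = None) -> PAAline:
    """Wavelet-shrinkage denoising of a single A-line.

    Output has the same length as the input; an all-zero trace maps to
    itself (the estimated noise level is zero).
    """
    config = config or DenoiseConfig()
    x = aline.trace
    level = _decomposition_level(len(x), config.level)
    if len(x) < 2**level:
        raise ValueError(
            f"trace of {len(x)} samples too short for decomposition level {level}")
    coeffs = pywt.wavedec(x, config.wavelet, level=level)
    detail_fine = coeffs[-1]
    sigma = np.median(np.abs(detail_fine - np.median(detail_fine))) / 0.6745
    if sigma == 0:   # noise-free (e.g. all-zero) trace: nothing to shrink
        return replace(aline, trace=x.copy())
    threshold = sigma * np.sqrt(2.0 * np.log(len(x)))
    denoised = [coeffs[0]] + [
        pywt.threshold(c, threshold, mode=config.mode) for c in coeffs[1:]
    ]
    y = pywt.waverec(denoised, config.wavelet)[: len(x)]
    return replace(aline, trace=y)


def _gate_mask(n: int, sampling_rate: float,
               gate: tuple[float, float] | None) -> np.ndarray:
    if gate is None:
        return np.ones(n, dtype=bool)
    t = np.arange(n) / sampling_rate
    mask = (t >= gate[0]) & (t < gate[1])
    if not np.any(mask):
        raise ValueError(f"gate {gate} selects no samples")
    return mask


def p2p_spectrum(alines, gate: tuple[float, float] | None = None,
                 denoise_config: DenoiseConfig | None = None,
                 apply_denoise: bool = True) -> PASpectrum:
    """Peak-to-peak spectrum of a set of A-lines (one per wavelength).

    p2p(lambda) = (max - min) of the denoised, gated trace, divided by the
    photodiode value at that wavelength. The gate defaults to the full trace.
    """
    if not alines:
        raise ValueError("empty A-line set")
    items = sorted(alines, key=lambda a: a.wavelength_nm)
    wavelengths, p2p = [], []
    for aline in items:
        processed = denoise(aline, denoise_config) if apply_denoise else aline
        mask = _gate_mask(len(processed.trace), processed.sampling_rate, gate)
        seg = processed.trace[mask]
        wavelengths.append(aline.wavelength_nm)
        p2p.append((seg.max() - seg.min()) / aline.photodiode_value)
    return PASpectrum(wavelengths_nm=np.array(wavelengths),
                      p2p=np.array(p2p), gate=gate)


def compare_spectra(candidate: PASpectrum, ensemble: SpectrumEnsemble,
                    normalisation: str = "peak") -> dict:
    """Compare a candidate P2P spectrum against a tissue ensemble.

    With the default peak normalisation both sides are scaled to a unit
    maximum first, making the report invariant to global amplitude scaling.
    Returns pointwise z-scores against the ensemble mean/sd, the fraction of
    wavelengths inside mean +/- 1 sd, and inside the min/max envelope.
    """
    if normalisation not in ("peak", "none"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    if not np.array_equal(candidate.wavelengths_nm, ensemble.wavelengths_nm):
        raise ValueError(
            "candidate and ensemble wavelength grids differ; resample first")
    cand = candidate.peak_normalised().p2p if normalisation == "peak" else candidate.p2p
    mean, sd = ensemble.mean, ensemble.sd
    lo, hi = ensemble.envelope
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (cand - mean) / sd, np.where(cand == mean, 0.0, np.inf))
    inside_sd = (cand >= mean - sd) & (cand <= mean + sd)
    inside_env = (cand >= lo) & (cand <= hi)
    return {
        "wavelengths_nm": ensemble.wavelengths_nm,
        "z_scores": z,
        "fraction_within_1sd": float(inside_sd.mean()),
        "fraction_within_envelope": float(inside_env.mean()),
    }
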