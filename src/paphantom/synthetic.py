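"""Seeded generators for every input the characterisation pipeline consumes.

Each generator is an exact inverse of its analysis stage in the noiseless
limit — that is the module's core contract and what the round-trip tests
assert: optical tables regenerate the law parameters under the nonlinear
fits; waveform pairs regenerate the injected sound speed and attenuation
power law; calorimetry records regenerate the injected heat capacity;
photoacoustic A-line sets regenerate the injected absorption spectrum shape.

Noise defaults follow the bench repeatability: ~1.3% CV on optical
coefficients, 0.1 deg C thermocouple scatter, 0.1 mg mass scatter, and an
additive white noise floor on waveforms controlled by an SNR in dB.
All randomness flows from the single ``seed`` in :class:`GeneratorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .laws import (
    AbsorptionLawParams,
    AttenuationLawParams,
    PhantomComposition,
    ScatteringLawParams,
    absorption_coefficient,
    reduced_scattering,
)
from .measurement import CalorimetryRecord, WaterModel, WaveformPair
from .pa_signal import PAAline

__all__ = [
    "GeneratorConfig",
    "gen_optical_dataset",
    "gen_waveform_pair",
    "gen_calorimetry",
    "gen_pa_alines",
]

# bench measurement grids
ABSORPTION_CONCENTRATIONS = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0)   # % w/w
SCATTERING_CONCENTRATIONS = (0.25, 0.35, 0.5, 0.65, 1.0)             # mg/mL
ABSORPTION_WAVELENGTHS = tuple(np.linspace(490.0, 835.0, 15))        # nm
SCATTERING_WAVELENGTHS = tuple(np.arange(590.0, 816.0, 25.0))        # nm


@dataclass(frozen=True)
class GeneratorConfig:
    """Truth parameters, grids and noise levels for all generators.

    Noise defaults mirror the bench repeatability figures; set them to zero
    for the exact (noiseless) inverses. The waveform sampling rate defaults
    to the full 4 GSa/s digitiser rate; ``waveform_fs`` may be reduced (any
    rate whose Nyquist frequency clears the 15-40 MHz analysis band, e.g.
    1 GSa/s) for faster runs without touching the analysis band.
    """

    seed: int = 0
    optical_cv: float = 0.0128            # relative sd on mu_a / mu_s'
    waveform_snr_db: float | None = None  # None = noiseless
    thermocouple_sd: float = 0.1          # deg C
    mass_sd: float = 1e-7                 # kg
    absorption_law: AbsorptionLawParams = field(default_factory=AbsorptionLawParams)
    scattering_law: ScatteringLawParams = field(default_factory=ScatteringLawParams)
    attenuation_law: AttenuationLawParams = field(default_factory=AttenuationLawParams)
    waveform_fs: float = 4e9              # Hz
    waveform_duration: float = 2e-6       # s
    pulse_centre_mhz: float = 25.0
    pulse_fractional_bw: float = 1.2      # covers the 15-40 MHz band

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_optical_dataset(cfg: GeneratorConfig | None = None,
                        noiseless: bool = False) -> pd.DataFrame:
    """Optical coefficient table over the bench concentration/wavelength grids.

    Columns: c_agarose_pct, c_tio2_mg_ml, lambda_nm, mu_a_cm1,
    mu_s_prime_cm1 (NaN outside each law's own grid). Values are
    law(C, lambda) * (1 + eps) with eps ~ Normal(0, optical_cv).
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    cv = 0.0 if noiseless else cfg.optical_cv
    rows = []
    for c_ag in ABSORPTION_CONCENTRATIONS:
        comp = PhantomComposition(c_agarose=c_ag)
        for lam in ABSORPTION_WAVELENGTHS:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                mu = absorption_coefficient(comp, lam, cfg.absorption_law)
            rows.append({"c_agarose_pct": c_ag, "c_tio2_mg_ml": 0.0,
                         "lambda_nm": lam,
                         "mu_a_cm1": mu * (1.0 + cv * rng.standard_normal()),
                         "mu_s_prime_cm1": np.nan})
    for c_ti in SCATTERING_CONCENTRATIONS:
        comp = PhantomComposition(c_tio2=c_ti)
        for lam in SCATTERING_WAVELENGTHS:
            mu = reduced_scattering(comp, lam, cfg.scattering_law)
            rows.append({"c_agarose_pct": 1.0, "c_tio2_mg_ml": c_ti,
                         "lambda_nm": lam, "mu_a_cm1": np.nan,
                         "mu_s_prime_cm1": mu * (1.0 + cv * rng.standard_normal())})
    return pd.DataFrame(rows)


def _gaussian_pulse(t, centre_s, fc_hz, fractional_bw):
    """Gaussian-modulated sinusoid with the stated -6 dB fractional bandwidth."""
    bw = fractional_bw * fc_hz
    sigma_f = bw / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    tau = t - centre_s
    return np.exp(-(tau**2) / (2.0 * sigma_t**2)) * np.cos(2.0 * np.pi * fc_hz * tau)


def gen_waveform_pair(cs_true: float, alpha_law, h: float,
                      cfg: GeneratorConfig | None = None,
                      water: WaterModel | None = None,
                      T_water: float = 19.9) -> WaveformPair:
    """Through-transmission reference/sample pair with known truth.

    The reference trace is a Gaussian-modulated sinusoid through water; the
    sample trace is the reference delayed by dt = h*(1/cs_true - 1/cw) and
    filtered in the frequency domain by 10^(-(alpha(f) - alpha_w(f))*h_cm/20),
    with ``alpha_law`` a callable f_MHz -> dB/cm. Additive white noise at
    ``cfg.waveform_snr_db`` (None = noiseless).
    """
    if h <= 0:
        raise ValueError(f"sample height must be > 0, got {h}")
    cfg = cfg or GeneratorConfig()
    water = water or WaterModel()
    cw = water.sound_speed(T_water)
    n = int(round(cfg.waveform_duration * cfg.waveform_fs))
    t = np.arange(n) / cfg.waveform_fs
    centre = cfg.waveform_duration / 2.0
    ref = _gaussian_pulse(t, centre, cfg.pulse_centre_mhz * 1e6,
                          cfg.pulse_fractional_bw)
    dt = h * (1.0 / cs_true - 1.0 / cw)
    f_hz = np.fft.rfftfreq(n, d=1.0 / cfg.waveform_fs)
    f_mhz = f_hz / 1e6
    excess_db_per_cm = np.asarray(alpha_law(f_mhz), dtype=float) \
        - water.attenuation(f_mhz)
    h_cm = h * 100.0
    transfer = 10.0 ** (-excess_db_per_cm * h_cm / 20.0) \
        * np.exp(-2j * np.pi * f_hz * dt)
    sample = np.fft.irfft(np.fft.rfft(ref) * transfer, n=n)
    if cfg.waveform_snr_db is not None:
        rng = cfg.rng()
        p_sig = np.mean(ref**2)
        sigma = np.sqrt(p_sig / 10.0 ** (cfg.waveform_snr_db / 10.0))
        ref = ref + sigma * rng.standard_normal(n)
        sample = sample + sigma * rng.standard_normal(n)
    return WaveformPair(reference_trace=ref, sample_trace=sample,
                        sampling_rate=cfg.waveform_fs, h=h, T_water=T_water)


def gen_calorimetry(cp_true: float, m_water: float = 0.2,
                    m_phantom: float = 0.05, T_water: float = 20.9,
                    T_phantom: float = 2.5, C_calo: float = 100.0,
                    cfg: GeneratorConfig | None = None,
                    noiseless: bool = False) -> CalorimetryRecord:
    """Calorimetry record whose energy balance inverts to ``cp_true``.

    T_eq is the heat-capacity-weighted mean of the two subsystem
    temperatures; thermocouple noise (sd ``cfg.thermocouple_sd``) is added
    to the three recorded temperatures unless ``noiseless``.
    """
    if cp_true <= 0:
        raise ValueError("cp_true must be strictly positive")
    cfg = cfg or GeneratorConfig()
    c_water = 4180.0
    heat_w = C_calo + m_water * c_water
    heat_p = m_phantom * cp_true
    T_eq = (heat_w * T_water + heat_p * T_phantom) / (heat_w + heat_p)
    if noiseless:
        tw, tp, te = T_water, T_phantom, T_eq
        mw, mp = m_water, m_phantom
    else:
        rng = cfg.rng()
        tw, tp, te = (T_water + cfg.thermocouple_sd * rng.standard_normal(),
                      T_phantom + cfg.thermocouple_sd * rng.standard_normal(),
                      T_eq + cfg.thermocouple_sd * rng.standard_normal())
        mw = m_water + cfg.mass_sd * rng.standard_normal()
        mp = m_phantom + cfg.mass_sd * rng.standard_normal()
    return CalorimetryRecord(m_water=mw, m_phantom=mp, T_water=tw,
                             T_phantom=tp, T_eq=te, C_calo=C_calo,
                             c_water=c_water, u_T=cfg.thermocouple_sd or 0.1,
                             u_m=cfg.mass_sd or 1e-7)


def _bipolar_pulse(t, centre_s, width_s):
    """Bipolar (first-derivative-of-Gaussian) pressure pulse, unit peak."""
    tau = (t - centre_s) / width_s
    pulse = -tau * np.exp(0.5) * np.exp(-0.5 * tau**2)
    return pulse


def gen_pa_alines(mu_a_spectrum, Gamma: float = 0.12,
                  cfg: GeneratorConfig | None = None,
                  wavelengths_nm=None,
                  sampling_rate: float = 2.5e8,
                  n_samples: int = 2048,
                  photodiode_values=None,
                  noise_sd: float = 0.0) -> list[PAAline]:
    """Photoacoustic A-line set over the spectroscopy grid (700-900 nm, 5 nm).

    The source is a bipolar pulse whose amplitude is proportional to
    Gamma * mu_a(lambda) * photodiode_value(lambda); ``mu_a_spectrum`` is a
    callable lambda_nm -> cm^-1 or an array on the grid. Seeded white noise
    of absolute sd ``noise_sd`` is added per trace.
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(700.0, 901.0, 5.0)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if callable(mu_a_spectrum):
        mu_a = np.asarray([mu_a_spectrum(w) for w in wavelengths_nm], dtype=float)
    else:
        mu_a = np.asarray(mu_a_spectrum, dtype=float)
        if mu_a.size != wavelengths_nm.size:
            raise ValueError("mu_a_spectrum array does not match the grid")
    if photodiode_values is None:
        photodiode = np.ones_like(wavelengths_nm)
    else:
        photodiode = np.asarray(photodiode_values, dtype=float)
    t = np.arange(n_samples) / sampling_rate
    centre = t[n_samples // 2]
    width = 20.0 / sampling_rate
    base = _bipolar_pulse(t, centre, width)
    alines = []
    for w, mu, pd_val in zip(wavelengths_nm, mu_a, photodiode):
        amp = Gamma * mu * pd_val
        trace = amp * base
        if noise_sd > 0:
            trace = trace + noise_sd * rng.standard_normal(n_samples)
        alines.append(PAAline(trace=trace, sampling_rate=sampling_rate,
                              wavelength_nm=w, photodiode_value=pd_val))
    return alines
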