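"""Bench-measurement computations for the phantom characterisation pipeline.

Covers every processing step between a raw record and a fitted law:

* Dewar calorimetry — isobaric heat capacity from the equilibrium temperature
  of a phantom dropped into water, with first-order (GUM Type B) uncertainty
  propagation over the five measured inputs;
* through-transmission substitution acoustics — time-of-flight sound speed
  from the cross-correlation delay between reference (water-only) and sample
  traces, temperature-corrected to a common reference day; FFT amplitude-ratio
  attenuation spectra and their power-law fits;
* nonlinear least-squares fits of the optical constitutive laws;
* impedance and interface-transmission arithmetic;
* the Monte-Carlo uncertainty scheme for pluggable inversion algorithms, and
  plain coefficient-of-variation repeatability summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .laws import (
    AbsorptionLawParams,
    AttenuationLawParams,
    ScatteringLawParams,
)

logger = logging.getLogger("paphantom")

__all__ = [
    "DB_PER_NEPER",
    "CalorimetryRecord",
    "WaveformPair",
    "AmplitudeSpectrum",
    "PowerLawFit",
    "WaterModel",
    "UncertaintyBudget",
    "FitFailureError",
    "calorimeter_cp",
    "cross_correlation_delay",
    "speed_of_sound",
    "amplitude_spectrum",
    "attenuation_spectrum",
    "fit_power_law",
    "fit_absorption_model",
    "fit_scattering_model",
    "impedance_and_transmission",
    "montecarlo_uncertainty",
    "coefficient_of_variation",
    "cv_summary",
]

DB_PER_NEPER = 8.685889638


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge; carries the residual diagnostics."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalorimetryRecord:
    """One Dewar-calorimeter run: masses in kg, temperatures in deg C.

    ``C_calo`` is the calibrated heat capacity of the calorimeter itself
    (J/K); ``u_T`` and ``u_m`` the standard uncertainties of the thermocouple
    and the precision scale.
    """

    m_water: float
    m_phantom: float
    T_water: float
    T_phantom: float
    T_eq: float
    C_calo: float
    c_water: float = 4180.0      # J K^-1 kg^-1
    u_T: float = 0.1             # deg C
    u_m: float = 1e-7            # kg

    def __post_init__(self):
        if self.m_water <= 0 or self.m_phantom <= 0:
            raise ValueError("masses must be strictly positive")
        lo, hi = sorted((self.T_phantom, self.T_water))
        if not lo < self.T_eq < hi:
            raise ValueError(
                f"T_eq={self.T_eq} must lie strictly between T_phantom="
                f"{self.T_phantom} and T_water={self.T_water}"
            )


@dataclass(frozen=True)
class WaveformPair:
    """Reference (water-only) and sample through-transmission traces.

    ``h`` is the sample height in metres (caliper, standard uncertainty
    ``u_h``); both traces share the sampling rate.
    """

    reference_trace: np.ndarray
    sample_trace: np.ndarray
    sampling_rate: float = 4e9   # Hz
    h: float = 0.019             # m
    u_h: float = 20e-6           # m
    T_water: float = 20.0        # deg C

    def __post_init__(self):
        ref = np.asarray(self.reference_trace, dtype=float)
        sam = np.asarray(self.sample_trace, dtype=float)
        if ref.shape != sam.shape:
            raise ValueError("reference and sample traces must have equal length")
        if self.h <= 0:
            raise ValueError(f"sample height must be > 0, got {self.h}")
        object.__setattr__(self, "reference_trace", ref)
        object.__setattr__(self, "sample_trace", sam)


@dataclass(frozen=True)
class AmplitudeSpectrum:
    f_mhz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.f_mhz, dtype=float)
        mag = np.asarray(self.magnitude, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(mag < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "f_mhz", f)
        object.__setattr__(self, "magnitude", mag)


@dataclass(frozen=True)
class PowerLawFit:
    """alpha = a0 * f^n over ``band`` (MHz); r2 in log-log space."""

    a0: float
    n: float
    r2: float
    band: tuple[float, float]
    a0_se: float = float("nan")
    n_se: float = float("nan")

    def __post_init__(self):
        if self.a0 <= 0:
            raise ValueError(f"power-law prefactor must be > 0, got {self.a0}")

    def __call__(self, f_mhz):
        return self.a0 * np.asarray(f_mhz, dtype=float) ** self.n


# Marczak (1997) pure-water sound speed polynomial, 0-95 deg C, m/s
_WATER_CS_COEFFS = (
    1.402385e3, 5.038813, -5.799136e-2, 3.287156e-4, -1.398845e-6, 2.787860e-9,
)


@dataclass(frozen=True)
class WaterModel:
    """Reference properties of the coupling water.

    ``cs_poly`` are polynomial coefficients of cw(T) in ascending powers of
    the temperature in deg C; ``k_atten`` the quadratic attenuation
    coefficient so that alpha_w(f) = k*f^2 in dB/cm (0.85 dB/cm at 20 MHz).
    """

    cs_poly: tuple = _WATER_CS_COEFFS
    k_atten: float = 0.85 / 400.0   # dB cm^-1 MHz^-2

    def sound_speed(self, temperature_c):
        t = np.asarray(temperature_c, dtype=float)
        cw = sum(c * t**i for i, c in enumerate(self.cs_poly))
        return cw if np.shape(cw) else float(cw)

    def attenuation(self, f_mhz):
        a = self.k_atten * np.asarray(f_mhz, dtype=float) ** 2
        return a if a.shape else float(a)


@dataclass(frozen=True)
class UncertaintyBudget:
    """GUM-style budget: per-input standard uncertainties times sensitivities.

    ``components`` maps an input name to its contribution |dy/dx|*u(x);
    the combined u is the quadrature sum, the expanded U = k*u.
    """

    components: dict = field(default_factory=dict)
    coverage_factor: float = 1.96

    @property
    def combined(self) -> float:
        return float(np.sqrt(sum(v**2 for v in self.components.values())))

    @property
    def expanded(self) -> float:
        return self.coverage_factor * self.combined


# ---------------------------------------------------------------------------
# Calorimetry
# ---------------------------------------------------------------------------

def calorimeter_cp(rec: CalorimetryRecord):
    """Isobaric heat capacity (J K^-1 kg^-1) from an equilibrium record.

    cp = [C_calo*(Tw - Teq) + m_w*c_w*(Tw - Teq)] / [m_p*(Teq - Tp)],
    with a Type-B budget propagated to first order over the three measured
    temperatures and the two masses (treated as independent).
    """
    dT_w = rec.T_water - rec.T_eq
    dT_p = rec.T_eq - rec.T_phantom
    num = (rec.C_calo + rec.m_water * rec.c_water) * dT_w
    den = rec.m_phantom * dT_p
    cp = num / den
    if cp <= 0:
        raise ValueError(
            f"computed cp = {cp:.1f} <= 0: temperature signs are inconsistent "
            f"(dT_water={dT_w}, dT_phantom={dT_p})"
        )
    heat = rec.C_calo + rec.m_water * rec.c_water
    d_Tw = heat / den
    d_Teq = (-heat * den - num * rec.m_phantom) / den**2
    d_Tp = num * rec.m_phantom / den**2
    d_mw = rec.c_water * dT_w / den
    d_mp = -num / (rec.m_phantom**2 * dT_p)
    budget = UncertaintyBudget(components={
        "T_water": abs(d_Tw) * rec.u_T,
        "T_eq": abs(d_Teq) * rec.u_T,
        "T_phantom": abs(d_Tp) * rec.u_T,
        "m_water": abs(d_mw) * rec.u_m,
        "m_phantom": abs(d_mp) * rec.u_m,
    })
    return cp, budget


# ---------------------------------------------------------------------------
# Speed of sound
# ---------------------------------------------------------------------------

def cross_correlation_delay(pair: WaveformPair) -> float:
    """Arrival-time shift of the sample trace relative to the reference (s).

    Peak of the full cross-correlation with parabolic three-point sub-sample
    interpolation. Negative when the sample pulse arrives earlier (sample
    faster than water).
    """
    ref = pair.reference_trace
    sam = pair.sample_trace
    xc = signal.correlate(sam, ref, mode="full")
    lags = signal.correlation_lags(len(sam), len(ref), mode="full")
    k = int(np.argmax(xc))
    lag = float(lags[k])
    if 0 < k < len(xc) - 1:
        y0, y1, y2 = xc[k - 1], xc[k], xc[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * (y0 - y2) / denom
    return lag / pair.sampling_rate


def speed_of_sound(pair: WaveformPair, water: WaterModel | None = None,
                   reference_T: float = 19.9):
    """Time-of-flight sound speed (m/s), temperature-corrected.

    cs = cw / (1 + dt*cw/h) with cw evaluated at the recorded water
    temperature, then corrected to ``reference_T`` with the agar-gel
    temperature slope of 0.6 m s^-1 per deg C. The budget carries the
    caliper, thermocouple and sampling-resolution contributions.
    """
    water = water or WaterModel()
    cw = water.sound_speed(pair.T_water)
    dt = cross_correlation_delay(pair)
    denom = 1.0 + dt * cw / pair.h
    if abs(denom) < 1e-6:
        raise ValueError(
            f"1 + dt*cw/h = {denom:.2e}: delay inconsistent with geometry"
        )
    cs_raw = cw / denom
    cs = cs_raw - 0.6 * (pair.T_water - reference_T)
    # first-order sensitivities of cs_raw = cw/(1 + dt*cw/h)
    d_h = cs_raw**2 * dt / pair.h**2            # dcs/dh
    d_dt = -cs_raw**2 / pair.h                  # dcs/d(dt)
    d_cw = 1.0 / denom**2                       # dcs/dcw
    dcw_dT = (water.sound_speed(pair.T_water + 0.05)
              - water.sound_speed(pair.T_water - 0.05)) / 0.1
    u_dt = 1.0 / (pair.sampling_rate * np.sqrt(12.0))
    budget = UncertaintyBudget(components={
        "h": abs(d_h) * pair.u_h,
        "dt": abs(d_dt) * u_dt,
        "T_water": abs(d_cw * dcw_dT) * 0.1,
    })
    return cs, budget


# ---------------------------------------------------------------------------
# Attenuation spectroscopy
# ---------------------------------------------------------------------------

def amplitude_spectrum(trace, sampling_rate: float,
                       gate: tuple[float, float] | None = None) -> AmplitudeSpectrum:
    """Magnitude of the DFT (rectangular window) of a gated trace.

    ``gate`` is a (start_s, stop_s) interval; default is the full trace.
    """
    x = np.asarray(trace, dtype=float)
    if gate is not None:
        t = np.arange(len(x)) / sampling_rate
        mask = (t >= gate[0]) & (t < gate[1])
        if not np.any(mask):
            raise ValueError(f"gate {gate} selects no samples")
        x = x[mask]
    mag = np.abs(np.fft.rfft(x))
    f_mhz = np.fft.rfftfreq(len(x), d=1.0 / sampling_rate) / 1e6
    # rfftfreq starts at 0 which breaks the strict-increase invariant only if
    # duplicated; keep the DC bin, grid is strictly increasing by construction
    return AmplitudeSpectrum(f_mhz=f_mhz, magnitude=mag)


def attenuation_spectrum(pair: WaveformPair, water: WaterModel | None = None,
                         band: tuple[float, float] = (15.0, 40.0),
                         gate: tuple[float, float] | None = None):
    """Attenuation spectrum alpha(f) in dB/cm over ``band`` (MHz).

    alpha(f) = -(20/h_cm)*log10(A_sample/A_reference) + alpha_water(f),
    assuming total transmission at the water/sample interfaces.
    Returns ``(f_mhz, alpha)`` arrays on the DFT grid restricted to the band.
    """
    water = water or WaterModel()
    spec_ref = amplitude_spectrum(pair.reference_trace, pair.sampling_rate, gate)
    spec_sam = amplitude_spectrum(pair.sample_trace, pair.sampling_rate, gate)
    f = spec_ref.f_mhz
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} MHz outside the spectral grid")
    a_ref = spec_ref.magnitude[mask]
    a_sam = spec_sam.magnitude[mask]
    if np.any(a_ref == 0):
        raise ZeroDivisionError("reference spectrum vanishes inside the band")
    h_cm = pair.h * 100.0
    alpha = -(20.0 / h_cm) * np.log10(a_sam / a_ref) + water.attenuation(f[mask])
    return f[mask], alpha


def fit_power_law(f_mhz, alpha, band: tuple[float, float] | None = None) -> PowerLawFit:
    """Fit alpha = a0 * f^n by least squares in log-log space.

    Exact recovery on noiseless power-law input; standard errors from the
    linear-regression covariance.
    """
    f = np.asarray(f_mhz, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if band is not None:
        mask = (f >= band[0]) & (f <= band[1])
        f, a = f[mask], a[mask]
    if len(f) < 3:
        raise ValueError("need at least 3 frequency points")
    if np.any(a <= 0) or np.any(f <= 0):
        raise ValueError("power-law fit requires strictly positive f and alpha")
    lx, ly = np.log(f), np.log(a)
    design = np.column_stack([np.ones_like(lx), lx])
    coef, res_ss, *_ = np.linalg.lstsq(design, ly, rcond=None)
    pred = design @ coef
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = len(f) - 2
    if dof > 0:
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        n_se = float(np.sqrt(cov[1, 1]))
        a0_se = float(np.exp(coef[0]) * np.sqrt(cov[0, 0]))
    else:
        n_se = a0_se = float("nan")
    return PowerLawFit(a0=float(np.exp(coef[0])), n=float(coef[1]), r2=r2,
                       band=(float(f.min()), float(f.max())),
                       a0_se=a0_se, n_se=n_se)


# ---------------------------------------------------------------------------
# Optical law fits
# ---------------------------------------------------------------------------

_FIT_KW = dict(method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000)


def fit_absorption_model(c_agarose, lambda_nm, mu_a) -> AbsorptionLawParams:
    """Joint nonlinear fit of the Lorentzian absorption law over (C, lambda).

    Model: mu_a = (a*C + b)*c / (c^2 + (lambda - 500)^2). Needs at least two
    concentrations and five wavelengths; raises :class:`FitFailureError`
    with the residuals when the optimiser does not converge.
    """
    c_arr = np.asarray(c_agarose, dtype=float)
    lam = np.asarray(lambda_nm, dtype=float)
    mu = np.asarray(mu_a, dtype=float)
    if len(np.unique(c_arr)) < 2 or len(np.unique(lam)) < 5:
        raise ValueError("need >= 2 concentrations and >= 5 wavelengths")

    def model(params):
        a, b, c = params
        return (a * c_arr + b) * c / (c**2 + (lam - 500.0) ** 2)

    def residuals(params):
        return model(params) - mu

    # amplitude initialised from the data scale, width from the band span
    amp0 = float(np.max(mu) * 200.0)
    result = optimize.least_squares(
        residuals, x0=[amp0, 0.0, 200.0],
        bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]), **_FIT_KW)
    if not result.success:
        raise FitFailureError(
            f"absorption fit did not converge: {result.message}",
            residuals=result.fun)
    se = _least_squares_se(result)
    return AbsorptionLawParams(a=result.x[0], b=result.x[1], c=result.x[2],
                               a_se=se[0], b_se=se[1], c_se=se[2])


def _least_squares_se(result):
    """Standard errors from the Jacobian of a scipy least_squares result."""
    _, s, vt = np.linalg.svd(result.jac, full_matrices=False)
    s = s[s > s[0] * np.finfo(float).eps * max(result.jac.shape)]
    vt = vt[: s.size]
    dof = max(result.fun.size - result.x.size, 1)
    sigma2 = 2.0 * result.cost / dof
    cov = (vt.T / s**2) @ vt * sigma2
    return np.sqrt(np.diag(cov))


def fit_scattering_model(c_tio2, lambda_nm, mu_s_prime,
                         pooling: str = "two-stage") -> ScatteringLawParams:
    """Fit the Rayleigh/Mie scattering mixture over (C_TiO2, lambda).

    Per-concentration model (initial values (a, x, y) = (0.5, 5, 2)):
    mu_s' = x_C*(a*(lam/1000)^-4 + (1-a)*(lam/1000)^-y). ``pooling`` selects
    how the concentrations are combined: ``"two-stage"`` (default) runs the
    per-concentration fits first — reporting a Rayleigh-component warning if
    a pins at a bound with a large residual — and then refits the pooled
    proportional model jointly; ``"simultaneous"`` fits the pooled model
    directly. On Mie-dominated data a converges to 0 and the law collapses to
    mu_s' = C * x * (lam/1000)^-y.
    """
    c_arr = np.asarray(c_tio2, dtype=float)
    lam = np.asarray(lambda_nm, dtype=float)
    mu = np.asarray(mu_s_prime, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("c_tio2 must be non-negative")
    if pooling not in ("two-stage", "simultaneous"):
        raise ValueError(f"unknown pooling mode {pooling!r}")

    lam_rel = lam / 1000.0

    def pooled_residuals(params):
        a_rm, x, y = params
        shape = a_rm * lam_rel**-4.0 + (1.0 - a_rm) * lam_rel**-y
        return c_arr * x * shape - mu

    x0 = [0.5, 5.0, 2.0]
    if pooling == "two-stage":
        stage1 = []
        for c_val in np.unique(c_arr):
            m = c_arr == c_val
            lr, mm = lam_rel[m], mu[m]

            def res_c(p, lr=lr, mm=mm):
                a_rm, xc, y = p
                return xc * (a_rm * lr**-4.0 + (1 - a_rm) * lr**-y) - mm

            r = optimize.least_squares(
                res_c, x0=[0.5, 5.0, 2.0],
                bounds=([0.0, 1e-9, 0.0], [1.0, np.inf, 6.0]), **_FIT_KW)
            if not r.success:
                raise FitFailureError(
                    f"per-concentration scattering fit failed at C={c_val}: "
                    f"{r.message}", residuals=r.fun)
            rms = float(np.sqrt(np.mean(r.fun**2)))
            if min(r.x[0], 1.0 - r.x[0]) < 1e-6 and rms > 0.05 * np.mean(mm):
                logger.warning(
                    "Rayleigh-to-Mie weight pinned at %.3g with RMS residual "
                    "%.3g at C=%.3g mg/mL", r.x[0], rms, c_val)
            stage1.append((c_val, *r.x))
        # pool: initialise the joint proportional fit from the stage-1 medians
        arr = np.array(stage1)
        x0 = [float(np.median(arr[:, 1])),
              float(np.median(arr[:, 2] / arr[:, 0])),
              float(np.median(arr[:, 3]))]
        x0[0] = min(max(x0[0], 0.0), 1.0)

    result = optimize.least_squares(
        pooled_residuals, x0=x0,
        bounds=([0.0, 1e-9, 0.0], [1.0, np.inf, 6.0]), **_FIT_KW)
    if not result.success:
        raise FitFailureError(
            f"pooled scattering fit did not converge: {result.message}",
            residuals=result.fun)
    se = _least_squares_se(result)
    return ScatteringLawParams(x=result.x[1], y=result.x[2], a_rm=result.x[0],
                               x_se=se[1], y_se=se[2], a_rm_se=se[0])


# ---------------------------------------------------------------------------
# Impedance / transmission, Monte-Carlo, repeatability
# ---------------------------------------------------------------------------

def impedance_and_transmission(rho: float, cs: float, Z_ref: float = 1.48):
    """Acoustic impedance (MRayl) and pressure-amplitude transmission.

    Z = rho*cs*1e-6; T = 2*Z_ref/(Z_ref + Z) for the sample -> reference
    (water) direction; T = 1 at impedance match.
    """
    if rho <= 0 or cs <= 0 or Z_ref <= 0:
        raise ValueError("rho, cs and Z_ref must be strictly positive")
    Z = rho * cs * 1e-6
    T = 2.0 * Z_ref / (Z_ref + Z)
    return Z, T


def montecarlo_uncertainty(inversion, nominal, n_trials: int = 5000,
                           half_width: float | np.ndarray = 0.0,
                           seed: int = 0):
    """Monte-Carlo repeatability of a pluggable inversion algorithm.

    Every scalar input is perturbed independently with a uniform law centred
    on its nominal value, half-width ``half_width`` (scalar or per-input).
    Returns the per-output coefficient of variation sd/mean over
    ``n_trials`` evaluations. Deterministic for a fixed ``seed``.
    """
    nominal = np.atleast_1d(np.asarray(nominal, dtype=float))
    hw = np.broadcast_to(np.asarray(half_width, dtype=float), nominal.shape)
    rng = np.random.default_rng(seed)
    draws = nominal + rng.uniform(-1.0, 1.0, size=(n_trials, nominal.size)) * hw
    outputs = np.array([np.atleast_1d(np.asarray(inversion(d), dtype=float))
                        for d in draws])
    means = outputs.mean(axis=0)
    if np.any(means == 0):
        raise ZeroDivisionError("inversion output has zero mean: CV undefined")
    cv = outputs.std(axis=0, ddof=1) / np.abs(means)
    return cv if cv.size > 1 else float(cv[0])


def coefficient_of_variation(replicates) -> float:
    """CV = sample sd / mean (n-1 denominator) of a replicate set."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = x.mean()
    if mean == 0:
        raise ZeroDivisionError("replicate mean is zero: CV undefined")
    return float(x.std(ddof=1) / abs(mean))


def cv_summary(groups):
    """Mean +/- sd of per-group CVs (the repeatability summary statistic)."""
    cvs = np.array([coefficient_of_variation(g) for g in groups])
    sd = float(cvs.std(ddof=1)) if cvs.size > 1 else 0.0
    return float(cvs.mean()), sd
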