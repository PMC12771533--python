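"""Empirical constitutive laws for TiO2-doped agarose hydrogel phantoms.

Forward evaluation of the laws linking the two tunable components of the
phantom recipe — the agarose mass fraction (% w/w), which sets the optical
absorption and the mechanical/acoustic backbone, and the TiO2 concentration
(mg/mL), which sets the optical scattering and trims the heat capacity — to
the full multiphysics property set a photoacoustic experiment cares about:

* optical absorption ``mu_a(C_agarose, lambda)`` — Lorentzian in wavelength,
  peaked at 500 nm, with concentration-linear amplitude;
* reduced scattering ``mu_s'(C_TiO2, lambda)`` — power law in wavelength,
  proportional to the TiO2 load (Mie-dominated: the Rayleigh mixing weight
  fitted to the bench data converges to zero);
* acoustic attenuation ``alpha(C_agarose, f)`` — frequency power law whose
  prefactor and exponent both depend on the agarose content;
* density, sound speed and isobaric heat capacity — linear laws anchored to
  the characterised range endpoints;
* the Grueneisen parameter ``Gamma = beta * cs**2 / cp`` coupling them all.

Internal convention: SI units for thermo-mechanics (cp in J K^-1 kg^-1, cs in
m s^-1, rho in kg m^-3); spectra keep the bench units (cm^-1, nm, MHz,
dB cm^-1). Conversions happen only at type boundaries.

Evaluating a law outside its characterised domain is permitted (the laws
extrapolate well within reason) but always raises :class:`ExtrapolationWarning`
— never silently accepted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("paphantom")

__all__ = [
    "ExtrapolationWarning",
    "InvalidParameterError",
    "PhantomComposition",
    "AbsorptionLawParams",
    "ScatteringLawParams",
    "AttenuationLawParams",
    "LinearLaw",
    "GrueneisenInputs",
    "BiphasicModel",
    "MieGrid",
    "MieAnisotropyResult",
    "PropertySheet",
    "absorption_coefficient",
    "absorption_uncertainty",
    "reduced_scattering",
    "scattering_uncertainty",
    "attenuation_law",
    "attenuation_uncertainty",
    "evaluate_linear_law",
    "gruneisen",
    "biphasic_spectra",
    "tio2_refractive_index",
    "mie_coefficients",
    "mie_asymmetry",
    "mie_anisotropy",
    "DENSITY_LAW",
    "SOUND_SPEED_LAW",
    "HEAT_CAPACITY_LAW",
    "ABSORPTION_LAMBDA_DOMAIN",
    "SCATTERING_LAMBDA_DOMAIN",
    "ATTENUATION_F_DOMAIN",
]

# Characterised domains of the bench campaign (nm, MHz, % w/w, mg/mL)
ABSORPTION_LAMBDA_DOMAIN = (490.0, 835.0)
ABSORPTION_C_DOMAIN = (0.5, 2.0)
SCATTERING_LAMBDA_DOMAIN = (590.0, 815.0)
SCATTERING_C_DOMAIN = (0.25, 1.0)
ATTENUATION_F_DOMAIN = (15.0, 35.0)
ATTENUATION_C_DOMAIN = (0.75, 4.0)


class ExtrapolationWarning(UserWarning):
    """A constitutive law was evaluated outside its characterised domain."""


class InvalidParameterError(ValueError):
    """A law parameter violates a structural constraint (e.g. c <= 0)."""


def _flag_extrapolation(name: str, value, domain: tuple[float, float]) -> bool:
    value = np.asarray(value, dtype=float)
    outside = (value < domain[0]) | (value > domain[1])
    if np.any(outside):
        msg = (
            f"{name}={np.atleast_1d(value)[np.atleast_1d(outside)][:3]} outside "
            f"characterised domain [{domain[0]}, {domain[1]}]; extrapolating"
        )
        warnings.warn(msg, ExtrapolationWarning, stacklevel=3)
        logger.info("extrapolation: %s", msg)
        return True
    return False


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomComposition:
    """Recipe of one phantom: agarose % w/w and TiO2 mg/mL."""

    c_agarose: float = 0.0
    c_tio2: float = 0.0

    def __post_init__(self):
        if self.c_agarose < 0 or self.c_tio2 < 0:
            raise ValueError(
                f"concentrations must be non-negative, got "
                f"({self.c_agarose}, {self.c_tio2})"
            )


@dataclass(frozen=True)
class AbsorptionLawParams:
    """Lorentzian absorption law mu_a = (a*C + b)*c / (c^2 + (lambda-500)^2).

    a: nm cm^-1 (% w/w)^-1, b: nm cm^-1, c: nm (half-width at half maximum).
    Defaults are the bench-fit values with their standard errors.
    """

    a: float = 67.731
    b: float = 0.099
    c: float = 207.0
    a_se: float = 0.426
    b_se: float = 0.588
    c_se: float = 5.0

    def __post_init__(self):
        if self.c <= 0:
            raise InvalidParameterError(f"Lorentzian width c must be > 0, got {self.c}")


@dataclass(frozen=True)
class ScatteringLawParams:
    """Scattering power law mu_s' = C * x * (a_rm*(lam/1000)^-4 + (1-a_rm)*(lam/1000)^-y).

    x: cm^-1 mL mg^-1, y: dimensionless spectral exponent, a_rm: Rayleigh-to-Mie
    mixing weight in [0, 1] (zero on the bench data: Mie-dominated).
    """

    x: float = 9.629
    y: float = 0.775
    a_rm: float = 0.0
    x_se: float = 0.365
    y_se: float = 0.057
    a_rm_se: float = 0.0

    def __post_init__(self):
        if self.x <= 0:
            raise InvalidParameterError(f"scattering amplitude x must be > 0, got {self.x}")
        if not 0.0 <= self.a_rm <= 1.0:
            raise InvalidParameterError(f"a_rm must lie in [0, 1], got {self.a_rm}")


@dataclass(frozen=True)
class AttenuationLawParams:
    """Attenuation law alpha = (a2*C^a3 + a1) * f^(b2*C + b1), f in MHz, alpha in dB/cm."""

    a1: float = 0.0072
    a2: float = 0.0026
    a3: float = 2.636
    b1: float = 1.897
    b2: float = -0.132
    a1_se: float = 0.0010
    a2_se: float = 0.0005
    a3_se: float = 0.145
    b1_se: float = 0.039
    b2_se: float = 0.019

    def __post_init__(self):
        # the frequency exponent must stay physical over the characterised range
        lo, hi = ATTENUATION_C_DOMAIN
        for c_ag in (lo, hi):
            exp = self.b2 * c_ag + self.b1
            if not 0.0 < exp <= 3.0:
                raise InvalidParameterError(
                    f"frequency exponent b2*C+b1 = {exp:.3f} at C={c_ag} "
                    f"outside (0, 3]"
                )


@dataclass(frozen=True)
class LinearLaw:
    """slope*value + intercept with an explicit validity interval.

    Houses the density/sound-speed/heat-capacity regressions, which are
    reconstructed from the published range endpoints (the fitted coefficients
    themselves were not released); anchors are therefore overridable.
    """

    slope: float
    intercept: float
    valid_domain: tuple[float, float]
    regressor_name: str = "c_agarose"
    units: str = ""

    @classmethod
    def from_anchors(cls, x0, y0, x1, y1, regressor_name="c_agarose", units=""):
        slope = (y1 - y0) / (x1 - x0)
        return cls(slope, y0 - slope * x0, (min(x0, x1), max(x0, x1)),
                   regressor_name, units)


# Default linear laws anchored to the characterised range endpoints.
DENSITY_LAW = LinearLaw.from_anchors(0.5, 1000.0, 3.0, 1018.0,
                                     "c_agarose", "kg m^-3")
SOUND_SPEED_LAW = LinearLaw.from_anchors(0.5, 1482.0, 3.0, 1493.0,
                                         "c_agarose", "m s^-1")
HEAT_CAPACITY_LAW = LinearLaw.from_anchors(0.0, 4100.0, 1.0, 3870.0,
                                           "c_tio2", "J K^-1 kg^-1")


@dataclass(frozen=True)
class GrueneisenInputs:
    """beta (K^-1), cs (m/s), cp (J K^-1 kg^-1) — strictly SI."""

    beta: float
    cs: float
    cp: float

    def __post_init__(self):
        if self.cs <= 0 or self.cp <= 0:
            raise InvalidParameterError(
                f"cs and cp must be strictly positive, got cs={self.cs}, cp={self.cp}"
            )


@dataclass(frozen=True)
class BiphasicModel:
    """Idealised two-phase (water + collagen) tissue optical model.

    mu_a mixes as a convex combination weighted by the water volume fraction;
    mu_s' is carried by the collagen phase alone.
    """

    phi_water: float
    wavelengths_nm: np.ndarray
    water_mu_a: np.ndarray
    collagen_mu_a: np.ndarray
    collagen_mu_s_prime: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.phi_water <= 1.0:
            raise ValueError(f"phi_water must lie in [0, 1], got {self.phi_water}")
        n = len(self.wavelengths_nm)
        for name in ("water_mu_a", "collagen_mu_a", "collagen_mu_s_prime"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(
                    f"{name} has {len(arr)} samples but the wavelength grid has {n}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")


# TiO2 dispersion relation constants: n^2 = A + B / (lambda_um^2 - C)
_TIO2_DISPERSION = (5.913, 0.2441, 0.0803)


@dataclass(frozen=True)
class MieGrid:
    """Radius x wavelength grid for the anisotropy computation.

    Defaults reproduce the bench estimate: TiO2 spheres of 125-250 nm radius
    (10 nm steps) in an agarose host of index 1.335, 590-830 nm (1 nm steps).
    """

    radii_nm: np.ndarray = field(
        default_factory=lambda: np.arange(125.0, 251.0, 10.0))
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(590.0, 831.0, 1.0))
    n_host: float = 1.335
    dispersion: tuple[float, float, float] = _TIO2_DISPERSION

    def __post_init__(self):
        if np.any(np.asarray(self.radii_nm) <= 0):
            raise ValueError("radii must be strictly positive")
        lam_um = np.asarray(self.wavelengths_nm, dtype=float) / 1000.0
        if np.any(lam_um**2 <= self.dispersion[2]):
            raise ValueError(
                "wavelengths too close to the dispersion-relation pole "
                f"(lambda_um^2 must exceed {self.dispersion[2]})"
            )


@dataclass(frozen=True)
class MieAnisotropyResult:
    g: np.ndarray          # shape (n_radii, n_wavelengths)
    mean: float
    sd: float
    radii_nm: np.ndarray
    wavelengths_nm: np.ndarray


@dataclass
class PropertySheet:
    """Full multiphysics property set for one composition at stated lambda/f/T.

    Spectral quantities in bench units (cm^-1, dB cm^-1), thermo-mechanics in
    SI, impedance in MRayl. ``uncertainties`` holds first-order propagated
    standard uncertainties where available; ``extrapolated`` names the fields
    whose law was evaluated outside its characterised domain.
    """

    composition: PhantomComposition
    lambda_nm: float
    f_mhz: float
    temperature_c: float = 20.0
    mu_a: float | None = None            # cm^-1
    mu_s_prime: float | None = None      # cm^-1
    g: float | None = None               # dimensionless
    rho: float | None = None             # kg m^-3
    cp: float | None = None              # J K^-1 kg^-1
    cs: float | None = None              # m s^-1
    alpha: float | None = None           # dB cm^-1 at f_mhz
    Z: float | None = None               # MRayl
    Gamma: float | None = None           # dimensionless
    Gamma_range: tuple[float, float] | None = None
    uncertainties: dict = field(default_factory=dict)
    extrapolated: list = field(default_factory=list)

    def validate(self) -> None:
        """Check internal consistency (Z = rho*cs, positivity)."""
        for name in ("mu_a", "mu_s_prime", "rho", "cp", "cs", "alpha", "Z", "Gamma"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} = {v} is negative")
        if self.Z is not None and self.rho is not None and self.cs is not None:
            z_check = self.rho * self.cs * 1e-6
            if not math.isclose(self.Z, z_check, rel_tol=1e-9):
                raise ValueError(f"Z = {self.Z} inconsistent with rho*cs = {z_check}")


# ---------------------------------------------------------------------------
# Law evaluation
# ---------------------------------------------------------------------------

def absorption_coefficient(comp, lambda_nm,
                           params: AbsorptionLawParams | None = None):
    """Optical absorption mu_a (cm^-1) of the agarose matrix.

    Lorentzian in wavelength, peaked at 500 nm with half-width ``c``; the
    amplitude is linear in the agarose mass fraction. TiO2 is treated as a
    pure scatterer and does not enter.
    """
    params = params or AbsorptionLawParams()
    if params.c <= 0:
        raise InvalidParameterError("Lorentzian width c must be > 0")
    c_ag = comp.c_agarose if isinstance(comp, PhantomComposition) else float(comp)
    if c_ag < 0:
        raise ValueError("c_agarose must be non-negative")
    lam = np.asarray(lambda_nm, dtype=float)
    _flag_extrapolation("lambda_nm", lam, ABSORPTION_LAMBDA_DOMAIN)
    _flag_extrapolation("c_agarose", c_ag, ABSORPTION_C_DOMAIN)
    mu_a = (params.a * c_ag + params.b) * params.c / (
        params.c**2 + (lam - 500.0) ** 2)
    return mu_a if mu_a.shape else float(mu_a)


def absorption_uncertainty(comp, lambda_nm,
                           params: AbsorptionLawParams | None = None):
    """First-order (delta-method) standard uncertainty of mu_a.

    Parameter standard errors are treated as independent (covariances were
    not published), which is conservative-approximate.
    """
    params = params or AbsorptionLawParams()
    c_ag = comp.c_agarose if isinstance(comp, PhantomComposition) else float(comp)
    lam = np.asarray(lambda_nm, dtype=float)
    d2 = params.c**2 + (lam - 500.0) ** 2
    amp = params.a * c_ag + params.b
    dmu_da = c_ag * params.c / d2
    dmu_db = params.c / d2
    dmu_dc = amp * (d2 - 2 * params.c**2) / d2**2
    var = (dmu_da * params.a_se) ** 2 + (dmu_db * params.b_se) ** 2 \
        + (dmu_dc * params.c_se) ** 2
    u = np.sqrt(var)
    return u if u.shape else float(u)


def reduced_scattering(comp, lambda_nm,
                       params: ScatteringLawParams | None = None):
    """Reduced scattering mu_s' (cm^-1), proportional to the TiO2 load.

    Wavelength dependence is a Rayleigh/Mie mixture; with the default
    ``a_rm = 0`` it reduces to the pure Mie power law C*x*(lambda/1000)^-y.
    """
    params = params or ScatteringLawParams()
    c_tio2 = comp.c_tio2 if isinstance(comp, PhantomComposition) else float(comp)
    if c_tio2 < 0:
        raise ValueError(f"c_tio2 must be non-negative, got {c_tio2}")
    lam = np.asarray(lambda_nm, dtype=float)
    _flag_extrapolation("lambda_nm", lam, SCATTERING_LAMBDA_DOMAIN)
    if c_tio2 > 0:
        _flag_extrapolation("c_tio2", c_tio2, SCATTERING_C_DOMAIN)
    lam_rel = lam / 1000.0
    shape = params.a_rm * lam_rel**-4.0 + (1.0 - params.a_rm) * lam_rel**-params.y
    mu = c_tio2 * params.x * shape
    return mu if mu.shape else float(mu)


def scattering_uncertainty(comp, lambda_nm,
                           params: ScatteringLawParams | None = None):
    """Delta-method standard uncertainty of mu_s' (independent x, y errors)."""
    params = params or ScatteringLawParams()
    c_tio2 = comp.c_tio2 if isinstance(comp, PhantomComposition) else float(comp)
    lam_rel = np.asarray(lambda_nm, dtype=float) / 1000.0
    mie = lam_rel**-params.y
    dmu_dx = c_tio2 * ((1 - params.a_rm) * mie + params.a_rm * lam_rel**-4.0)
    dmu_dy = -c_tio2 * params.x * (1 - params.a_rm) * mie * np.log(lam_rel)
    u = np.sqrt((dmu_dx * params.x_se) ** 2 + (dmu_dy * params.y_se) ** 2)
    return u if u.shape else float(u)


def attenuation_law(comp, f_mhz, params: AttenuationLawParams | None = None):
    """Acoustic attenuation alpha (dB cm^-1) at frequency f (MHz).

    Power law in frequency; both the prefactor (a2*C^a3 + a1) and the
    exponent (b2*C + b1) depend on the agarose mass fraction.
    """
    params = params or AttenuationLawParams()
    c_ag = comp.c_agarose if isinstance(comp, PhantomComposition) else float(comp)
    if c_ag < 0:
        raise ValueError("c_agarose must be non-negative")
    f = np.asarray(f_mhz, dtype=float)
    _flag_extrapolation("f_mhz", f, ATTENUATION_F_DOMAIN)
    _flag_extrapolation("c_agarose", c_ag, ATTENUATION_C_DOMAIN)
    alpha = (params.a2 * c_ag**params.a3 + params.a1) * f ** (
        params.b2 * c_ag + params.b1)
    return alpha if alpha.shape else float(alpha)


def attenuation_uncertainty(comp, f_mhz,
                            params: AttenuationLawParams | None = None):
    """Delta-method standard uncertainty of alpha over the five law parameters."""
    params = params or AttenuationLawParams()
    c_ag = comp.c_agarose if isinstance(comp, PhantomComposition) else float(comp)
    f = np.asarray(f_mhz, dtype=float)
    pref = params.a2 * c_ag**params.a3 + params.a1
    expo = params.b2 * c_ag + params.b1
    fe = f**expo
    logf = np.log(f)
    logc = np.log(c_ag) if c_ag > 0 else 0.0
    grads = [
        (fe, params.a1_se),
        (c_ag**params.a3 * fe, params.a2_se),
        (params.a2 * c_ag**params.a3 * logc * fe, params.a3_se),
        (pref * fe * logf, params.b1_se),
        (pref * fe * logf * c_ag, params.b2_se),
    ]
    var = sum((g * se) ** 2 for g, se in grads)
    u = np.sqrt(var)
    return u if np.shape(u) else float(u)


def evaluate_linear_law(law: LinearLaw, value):
    """Evaluate slope*value + intercept, flagging out-of-domain regressors."""
    v = np.asarray(value, dtype=float)
    _flag_extrapolation(law.regressor_name, v, law.valid_domain)
    out = law.slope * v + law.intercept
    return out if out.shape else float(out)


def gruneisen(inputs: GrueneisenInputs) -> float:
    """Photoacoustic efficiency Gamma = beta * cs^2 / cp (SI units in)."""
    return inputs.beta * inputs.cs**2 / inputs.cp


def biphasic_spectra(model: BiphasicModel):
    """Idealised water+collagen tissue spectra.

    Returns ``(mu_a, mu_s_prime)`` on the model grid:
    mu_a = phi*mu_a_water + (1-phi)*mu_a_collagen (convex combination),
    mu_s' = (1-phi)*mu_s'_collagen.
    """
    phi = model.phi_water
    mu_a = phi * np.asarray(model.water_mu_a, float) \
        + (1.0 - phi) * np.asarray(model.collagen_mu_a, float)
    mu_s = (1.0 - phi) * np.asarray(model.collagen_mu_s_prime, float)
    return mu_a, mu_s


# ---------------------------------------------------------------------------
# Mie scattering anisotropy of the TiO2 particles
# ---------------------------------------------------------------------------

def tio2_refractive_index(lambda_um, dispersion=_TIO2_DISPERSION):
    """Refractive index of TiO2 from its single-pole dispersion relation.

    n^2 = 5.913 + 0.2441 / (lambda^2 - 0.0803), lambda in micrometres.
    """
    a_const, b_const, c_pole = dispersion
    lam2 = np.asarray(lambda_um, dtype=float) ** 2
    if np.any(lam2 <= c_pole):
        raise ValueError(
            f"lambda_um^2 must exceed the dispersion pole {c_pole}"
        )
    n = np.sqrt(a_const + b_const / (lam2 - c_pole))
    return n if n.shape else float(n)


# series truncation: standard Wiscombe-style term count
def _mie_nmax(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(m: complex, x: float):
    """Mie scattering coefficients (a_n, b_n) for relative index m, size x.

    The logarithmic derivative of the internal field is computed by downward
    recurrence (stable for all m*x); the Riccati-Bessel functions of the real
    argument x by upward recurrence. Truncation at n = x + 4x^(1/3) + 2.
    """
    if x <= 0:
        raise ValueError(f"size parameter must be > 0, got {x}")
    nmax = _mie_nmax(x)
    mx = m * x
    nstart = nmax + 15
    d = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    if not np.all(np.isfinite(d[: nmax + 1])):
        raise ArithmeticError(
            f"Mie logarithmic-derivative recurrence diverged (m={m}, x={x})"
        )
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_prev, psi_cur = math.cos(x), math.sin(x)    # psi_{-1}, psi_0
    chi_prev, chi_cur = -math.sin(x), math.cos(x)   # chi_{-1}, chi_0
    psi[0], chi[0] = psi_cur, chi_cur
    for k in range(1, nmax + 1):
        psi_next = (2 * k - 1) / x * psi_cur - psi_prev
        chi_next = (2 * k - 1) / x * chi_cur - chi_prev
        psi_prev, psi_cur = psi_cur, psi_next
        chi_prev, chi_cur = chi_cur, chi_next
        psi[k] = psi_next
        chi[k] = chi_next
    xi = psi + 1j * chi
    n = np.arange(1, nmax + 1)
    dn = d[1: nmax + 1]
    ta = dn / m + n / x
    tb = dn * m + n / x
    a = (ta * psi[1:] - psi[:-1]) / (ta * xi[1:] - xi[:-1])
    b = (tb * psi[1:] - psi[:-1]) / (tb * xi[1:] - xi[:-1])
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ArithmeticError(f"Mie series not convergent for m={m}, x={x}")
    return a, b


def mie_asymmetry(m: complex, x: float) -> float:
    """Asymmetry parameter g = <cos theta> for a single sphere."""
    a, b = mie_coefficients(m, x)
    n = np.arange(1, len(a) + 1, dtype=float)
    qsca_sum = np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    if qsca_sum == 0:
        return 0.0
    cross = n[:-1] * (n[:-1] + 2.0) / (n[:-1] + 1.0) * np.real(
        a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    same = (2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b))
    return float((2.0 * (cross.sum() + same.sum())) / qsca_sum)


def mie_anisotropy(grid: MieGrid | None = None,
                   weights: np.ndarray | None = None) -> MieAnisotropyResult:
    """Anisotropy factor g of the TiO2 particles over a radius x wavelength grid.

    Size parameter x = 2*pi*r*n_host/lambda_vac, relative index
    m = n_TiO2(lambda)/n_host. The summary mean is unweighted by default
    (the particle size distribution is unknown); pass per-radius ``weights``
    to average against a known distribution instead.
    """
    grid = grid or MieGrid()
    radii = np.asarray(grid.radii_nm, dtype=float)
    lams = np.asarray(grid.wavelengths_nm, dtype=float)
    g = np.empty((radii.size, lams.size))
    for j, lam in enumerate(lams):
        m = tio2_refractive_index(lam / 1000.0, grid.dispersion) / grid.n_host
        for i, r in enumerate(radii):
            x = 2.0 * np.pi * r * grid.n_host / lam
            g[i, j] = mie_asymmetry(m, x)
    if np.any((g <= -1) | (g >= 1)):
        raise ArithmeticError("asymmetry parameter outside (-1, 1): series failure")
    if weights is None:
        mean = float(g.mean())
        sd = float(g.std(ddof=1))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        per_lam = w @ g               # weighted over radii, per wavelength
        mean = float(per_lam.mean())
        sd = float(per_lam.std(ddof=1))
    return MieAnisotropyResult(g=g, mean=mean, sd=sd,
                               radii_nm=radii, wavelengths_nm=lams)
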