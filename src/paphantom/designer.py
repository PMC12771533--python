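"""Inverse phantom design and feasibility reporting.

Forward direction: :func:`predict_properties` composes every constitutive law
into a single :class:`~paphantom.laws.PropertySheet` for a candidate recipe.
Inverse direction: :func:`design_phantom` solves the laws for the
(C_agarose, C_TiO2) pair that realises a set of target properties — in
closed form when only one optical target constrains each concentration,
otherwise by bounded least squares in log-property space.
:func:`feasibility_report` grades a property sheet against bundled tissue
reference envelopes (healthy-disc optical targets, annulus fibrosus
measurements, soft-tissue mechanics).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import optimize

from .laws import (
    ABSORPTION_C_DOMAIN,
    ABSORPTION_LAMBDA_DOMAIN,
    ATTENUATION_C_DOMAIN,
    SCATTERING_C_DOMAIN,
    AbsorptionLawParams,
    AttenuationLawParams,
    DENSITY_LAW,
    ExtrapolationWarning,
    GrueneisenInputs,
    HEAT_CAPACITY_LAW,
    LinearLaw,
    PhantomComposition,
    PropertySheet,
    SOUND_SPEED_LAW,
    ScatteringLawParams,
    absorption_coefficient,
    absorption_uncertainty,
    attenuation_law,
    attenuation_uncertainty,
    evaluate_linear_law,
    gruneisen,
    reduced_scattering,
    scattering_uncertainty,
)

__all__ = [
    "BETA_GEL_INTERVAL",
    "TissueReference",
    "DesignTarget",
    "DesignResult",
    "LawSet",
    "load_references",
    "predict_properties",
    "design_phantom",
    "feasibility_report",
    "reference_envelope",
]

# Volumetric thermal expansion of gelatin hydrogels at 20 deg C (K^-1):
# the phantom's own beta was not measured, so Gamma always carries the
# interval-induced range.
BETA_GEL_INTERVAL = (0.207e-3, 0.231e-3)


@dataclass(frozen=True)
class LawSet:
    """The full set of constitutive laws a design run evaluates against."""

    absorption: AbsorptionLawParams = field(default_factory=AbsorptionLawParams)
    scattering: ScatteringLawParams = field(default_factory=ScatteringLawParams)
    attenuation: AttenuationLawParams = field(default_factory=AttenuationLawParams)
    density: LinearLaw = DENSITY_LAW
    sound_speed: LinearLaw = SOUND_SPEED_LAW
    heat_capacity: LinearLaw = HEAT_CAPACITY_LAW


@dataclass(frozen=True)
class TissueReference:
    """Reference property intervals for one tissue, with source tags.

    ``entries`` maps a property name (mu_a, mu_s_prime, cp, rho, cs, Z,
    alpha) to a dict with ``lo``, ``hi``, ``units`` and ``source``.
    """

    name: str
    entries: dict

    def __post_init__(self):
        for prop, e in self.entries.items():
            if e["lo"] > e["hi"]:
                raise ValueError(f"{self.name}/{prop}: interval lower > upper")
            if not e.get("source"):
                raise ValueError(f"{self.name}/{prop}: missing source tag")


@dataclass(frozen=True)
class DesignTarget:
    """Desired property values at a stated wavelength/frequency.

    ``targets`` maps property names to desired values; ``tolerances`` to
    acceptable absolute deviations (defaults to 1% of the target).
    At least one optical target (mu_a or mu_s_prime) is required.
    """

    wavelength_nm: float
    targets: dict
    f_mhz: float = 20.0
    tolerances: dict = field(default_factory=dict)

    def __post_init__(self):
        known = {"mu_a", "mu_s_prime", "cp", "rho", "cs", "alpha"}
        unknown = set(self.targets) - known
        if unknown:
            raise ValueError(f"unknown target properties: {sorted(unknown)}")
        if not ({"mu_a", "mu_s_prime"} & set(self.targets)):
            raise ValueError("at least one optical target (mu_a or mu_s_prime) required")
        for prop, tol in self.tolerances.items():
            if tol <= 0:
                raise ValueError(f"tolerance for {prop} must be > 0")

    def tolerance(self, prop: str) -> float:
        return self.tolerances.get(prop, 0.01 * abs(self.targets[prop]))


@dataclass
class DesignResult:
    composition: PhantomComposition
    predicted: PropertySheet
    residuals: dict
    in_domain: bool
    extrapolated: bool
    infeasible: bool


def load_references() -> dict[str, TissueReference]:
    """Bundled tissue reference tables (versioned JSON with source tags)."""
    text = resources.files("paphantom.data").joinpath(
        "tissue_references.json").read_text()
    raw = json.loads(text)
    return {name: TissueReference(name=name, entries=entries)
            for name, entries in raw["tissues"].items()}


# ---------------------------------------------------------------------------
# Forward prediction
# ---------------------------------------------------------------------------

def predict_properties(comp: PhantomComposition, lambda_nm: float,
                       f_mhz: float = 20.0, temperature_c: float = 20.0,
                       beta: float | tuple[float, float] | None = None,
                       laws: LawSet | None = None) -> PropertySheet:
    """Full property sheet for one recipe at stated wavelength/frequency.

    ``beta`` may be a scalar, an (lo, hi) interval, or None (the bundled
    gelatin-hydrogel interval). Gamma is computed at the interval midpoint
    and reported with its interval-induced range. Every law evaluated
    outside its characterised domain is recorded in ``sheet.extrapolated``.
    """
    laws = laws or LawSet()
    if beta is None:
        beta_lo, beta_hi = BETA_GEL_INTERVAL
    elif np.isscalar(beta):
        beta_lo = beta_hi = float(beta)
    else:
        beta_lo, beta_hi = float(beta[0]), float(beta[1])

    sheet = PropertySheet(composition=comp, lambda_nm=lambda_nm, f_mhz=f_mhz,
                          temperature_c=temperature_c)

    def eval_flagged(name, fn):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ExtrapolationWarning)
            value = fn()
        if any(issubclass(w.category, ExtrapolationWarning) for w in caught):
            sheet.extrapolated.append(name)
        return value

    sheet.mu_a = eval_flagged(
        "mu_a", lambda: absorption_coefficient(comp, lambda_nm, laws.absorption))
    sheet.uncertainties["mu_a"] = absorption_uncertainty(
        comp, lambda_nm, laws.absorption)
    sheet.mu_s_prime = eval_flagged(
        "mu_s_prime", lambda: reduced_scattering(comp, lambda_nm, laws.scattering))
    sheet.uncertainties["mu_s_prime"] = scattering_uncertainty(
        comp, lambda_nm, laws.scattering)
    sheet.alpha = eval_flagged(
        "alpha", lambda: attenuation_law(comp, f_mhz, laws.attenuation))
    sheet.uncertainties["alpha"] = attenuation_uncertainty(
        comp, f_mhz, laws.attenuation)
    sheet.rho = eval_flagged(
        "rho", lambda: evaluate_linear_law(laws.density, comp.c_agarose))
    sheet.cs = eval_flagged(
        "cs", lambda: evaluate_linear_law(laws.sound_speed, comp.c_agarose))
    sheet.cp = eval_flagged(
        "cp", lambda: evaluate_linear_law(laws.heat_capacity, comp.c_tio2))
    sheet.Z = sheet.rho * sheet.cs * 1e-6
    g_lo = gruneisen(GrueneisenInputs(beta=beta_lo, cs=sheet.cs, cp=sheet.cp))
    g_hi = gruneisen(GrueneisenInputs(beta=beta_hi, cs=sheet.cs, cp=sheet.cp))
    sheet.Gamma = 0.5 * (g_lo + g_hi)
    sheet.Gamma_range = (g_lo, g_hi)
    sheet.validate()
    return sheet


# ---------------------------------------------------------------------------
# Inverse design
# ---------------------------------------------------------------------------

def _invert_mu_s_prime(target, lambda_nm, params: ScatteringLawParams):
    lam_rel = lambda_nm / 1000.0
    shape = params.a_rm * lam_rel**-4 + (1 - params.a_rm) * lam_rel**-params.y
    return target / (params.x * shape)


def _invert_mu_a(target, lambda_nm, params: AbsorptionLawParams):
    d2 = params.c**2 + (lambda_nm - 500.0) ** 2
    return (target * d2 / params.c - params.b) / params.a


def design_phantom(target: DesignTarget, laws: LawSet | None = None,
                   allow_extrapolation: bool = False) -> DesignResult:
    """Solve the constitutive laws for the recipe realising ``target``.

    A pure optical target is inverted in closed form (each optical property
    constrains exactly one concentration); any other combination is solved by
    bounded least squares over both concentrations, in log-property space so
    that properties spanning orders of magnitude weigh equally. Targets the
    laws cannot reach inside the admissible region are flagged infeasible and
    the nearest-achievable recipe is reported with its residuals.
    """
    laws = laws or LawSet()
    prop_names = sorted(target.targets)

    # concentration bounds: intersection of the characterised domains of the
    # laws actually targeted, per regressor
    ag_domains = {"mu_a": ABSORPTION_C_DOMAIN, "alpha": ATTENUATION_C_DOMAIN,
                  "rho": laws.density.valid_domain,
                  "cs": laws.sound_speed.valid_domain}
    tio2_domains = {"mu_s_prime": SCATTERING_C_DOMAIN,
                    "cp": laws.heat_capacity.valid_domain}
    ag_lo = max((ag_domains[p][0] for p in prop_names if p in ag_domains),
                default=ABSORPTION_C_DOMAIN[0])
    ag_hi = min((ag_domains[p][1] for p in prop_names if p in ag_domains),
                default=ABSORPTION_C_DOMAIN[1])
    ti_lo = max((tio2_domains[p][0] for p in prop_names if p in tio2_domains),
                default=0.0)
    ti_hi = min((tio2_domains[p][1] for p in prop_names if p in tio2_domains),
                default=SCATTERING_C_DOMAIN[1])
    if allow_extrapolation:
        ag_lo, ag_hi, ti_lo, ti_hi = 0.0, 10.0, 0.0, 5.0

    closed_form = set(prop_names) <= {"mu_a", "mu_s_prime"}
    if closed_form:
        c_ag = (_invert_mu_a(target.targets["mu_a"], target.wavelength_nm,
                             laws.absorption)
                if "mu_a" in target.targets else ag_lo)
        c_ti = (_invert_mu_s_prime(target.targets["mu_s_prime"],
                                   target.wavelength_nm, laws.scattering)
                if "mu_s_prime" in target.targets else 0.0)
    else:
        def predict_vec(c):
            comp = PhantomComposition(max(c[0], 0.0), max(c[1], 0.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                sheet = predict_properties(comp, target.wavelength_nm,
                                           target.f_mhz, laws=laws)
            return np.array([getattr(sheet, p) for p in prop_names])

        goal = np.array([target.targets[p] for p in prop_names])

        def residuals(c):
            pred = predict_vec(c)
            # log-space residuals; guard non-positive predictions
            return np.log(np.maximum(pred, 1e-12)) - np.log(np.maximum(goal, 1e-12))

        sol = optimize.least_squares(
            residuals, x0=[0.5 * (ag_lo + ag_hi), 0.5 * (ti_lo + ti_hi)],
            bounds=([ag_lo, ti_lo], [ag_hi, ti_hi]),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        c_ag, c_ti = sol.x

    clamped_ag = float(np.clip(c_ag, ag_lo, ag_hi))
    clamped_ti = float(np.clip(c_ti, ti_lo, ti_hi))
    infeasible = not (np.isclose(clamped_ag, c_ag, rtol=0, atol=1e-9)
                      and np.isclose(clamped_ti, c_ti, rtol=0, atol=1e-9))
    comp = PhantomComposition(clamped_ag, clamped_ti)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        sheet = predict_properties(comp, target.wavelength_nm, target.f_mhz,
                                   laws=laws)
    residuals_out = {p: getattr(sheet, p) - target.targets[p] for p in prop_names}
    if not infeasible:
        infeasible = any(abs(residuals_out[p]) > target.tolerance(p)
                         for p in prop_names)
    return DesignResult(
        composition=comp,
        predicted=sheet,
        residuals=residuals_out,
        in_domain=not sheet.extrapolated,
        extrapolated=bool(sheet.extrapolated),
        infeasible=infeasible,
    )


# ---------------------------------------------------------------------------
# Feasibility / envelopes
# ---------------------------------------------------------------------------

def feasibility_report(sheet: PropertySheet, ref: TissueReference) -> dict:
    """Label each sheet property against a tissue reference interval.

    Closed intervals: a value exactly at a bound is "within". Outside values
    carry the relative difference to the nearest bound. Properties missing
    from the reference are skipped with a warning entry.
    """
    report = {}
    for prop in ("mu_a", "mu_s_prime", "cp", "rho", "cs", "Z", "alpha"):
        value = getattr(sheet, prop, None)
        if value is None:
            continue
        entry = ref.entries.get(prop)
        if entry is None:
            report[prop] = {"status": "skipped", "reason": "no reference entry"}
            continue
        lo, hi = entry["lo"], entry["hi"]
        if lo <= value <= hi:
            status, rel = "within", 0.0
        elif value < lo:
            status, rel = "below", (lo - value) / lo
        else:
            status, rel = "above", (value - hi) / hi
        report[prop] = {"status": status, "relative_difference": rel,
                        "reference": (lo, hi), "value": value,
                        "units": entry.get("units", "")}
    return report


def reference_envelope(spectra: dict, exclusions=()):
    """Pointwise min/max envelope of a named set of spectra on a shared grid.

    ``spectra`` maps name -> array; ``exclusions`` names removed before the
    envelope is taken (e.g. blood-stained outliers).
    """
    kept = {k: np.asarray(v, dtype=float)
            for k, v in spectra.items() if k not in set(exclusions)}
    if not kept:
        raise ValueError("no spectra left after exclusions")
    lengths = {v.size for v in kept.values()}
    if len(lengths) != 1:
        raise ValueError("spectra must share a common wavelength grid")
    stack = np.vstack(list(kept.values()))
    return stack.min(axis=0), stack.max(axis=0)
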