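"""Binding thermodynamics: one-site ITC isotherms and NMR CSP titrations.

The ITC forward model is the closed-form 1:1 (one-site) isotherm. With total
macromolecule concentration Mt (cell), total ligand Xt, stoichiometry n,
dissociation constant Kd and molar enthalpy dH, the cumulative heat after
reaching (Mt, Xt) in cell volume V0 is

    Q = n*Mt*dH*V0 * (b - sqrt(b^2 - 4*Xt/(n*Mt))) / 2,
    b = 1 + Xt/(n*Mt) + Kd/(n*Mt)

and per-injection heats are finite differences of Q with the standard
displaced-volume correction. CSP titrations use the single-site
ligand-depletion (quadratic) binding model in the fast-exchange limit.

Kd is fitted in log space throughout to enforce positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ITCParams",
    "Isotherm",
    "ShiftPair",
    "TitrationSeries",
    "ITCFitResult",
    "TitrationFitResult",
    "one_site_total_heat",
    "predicted_injection_heats",
    "fit_itc",
    "thermo_decompose",
    "check_thermo_consistency",
    "combined_csp",
    "fraction_bound",
    "fit_titration_kd",
    "kd_fold_change",
    "UnidentifiableFitError",
]

# kcal/(mol K)
GAS_CONSTANT_KCAL = 1.987e-3

DEFAULT_TEMPERATURE = 313.0  # K
ALPHA_N = 0.15
ALPHA_C = 0.25


class UnidentifiableFitError(RuntimeError):
    """Raised when the data carry no binding signal to fit."""


@dataclass(frozen=True)
class ITCParams:
    """One-site binding parameters: Kd (M), dH (kcal/mol), stoichiometry n."""

    kd: float
    dh: float
    n: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry n must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class Isotherm:
    """Injection geometry plus integrated heats.

    Volumes in litres, concentrations molar; ``heats`` in kcal per mole of
    injectant when ``per_mole`` (the instrument-normalised convention) or
    total kcal per injection otherwise.
    """

    v0: float
    injection_volumes: tuple
    cell_conc: float
    syringe_conc: float
    heats: tuple
    per_mole: bool = True
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("injection_volumes and heats must have equal length")
        if self.v0 <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if not all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")


@dataclass(frozen=True)
class ShiftPair:
    """Free/bound chemical shifts for one residue (ppm)."""

    residue: str
    h_free: float
    h_bound: float
    x_free: float
    x_bound: float
    nucleus: str = "amide-N"  # or "carbonyl-C"

    def __post_init__(self) -> None:
        if self.nucleus not in ("amide-N", "carbonyl-C"):
            raise ValueError(f"unknown nucleus class {self.nucleus!r}")
        for value in (self.h_free, self.h_bound, self.x_free, self.x_bound):
            if not np.isfinite(value):
                raise ValueError("shifts must be finite")


@dataclass(frozen=True)
class TitrationSeries:
    """Per-residue CSPs (ppm) across ligand additions at fixed protein conc."""

    p0: float
    ligand_concs: tuple
    csp: np.ndarray  # shape (n_residues, n_points)
    residues: tuple = ()

    def __post_init__(self) -> None:
        csp = np.asarray(self.csp, dtype=float)
        object.__setattr__(self, "csp", csp)
        if csp.ndim != 2 or csp.shape[1] != len(self.ligand_concs):
            raise ValueError("csp must be (n_residues, n_points)")
        if np.any(np.diff(self.ligand_concs) < 0):
            raise ValueError("ligand concentrations must be non-decreasing")
        if np.any(csp < 0) or not np.all(np.isfinite(csp)):
            raise ValueError("CSPs must be finite and non-negative")


def one_site_total_heat(params: ITCParams, mt, xt, v0: float):
    """Cumulative heat Q (kcal) at total concentrations (mt, xt) in cell v0."""
    mt = np.asarray(mt, dtype=float)
    xt = np.asarray(xt, dtype=float)
    if np.any(mt < 0) or np.any(xt < 0):
        raise ValueError("concentrations must be non-negative")
    nmt = params.n * mt
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(nmt > 0, xt / np.where(nmt > 0, nmt, 1.0), 0.0)
        rk = np.where(nmt > 0, params.kd / np.where(nmt > 0, nmt, 1.0), 0.0)
        b = 1.0 + r + rk
        disc = b * b - 4.0 * r
        if np.any(disc < -1e-12):
            raise ValueError("negative discriminant in one-site model")
        frac = (b - np.sqrt(np.clip(disc, 0.0, None))) / 2.0
    q = params.n * mt * params.dh * v0 * frac
    return q if q.ndim else float(q)


def predicted_injection_heats(
    params: ITCParams,
    v0: float,
    injection_volumes,
    cell_conc: float,
    syringe_conc: float,
    per_mole: bool = True,
):
    """Per-injection heats for the one-site model with dilution tracking.

    Concentrations after cumulative injected volume v follow the standard
    displaced-volume bookkeeping Mt = M0(1-v/2V0)/(1+v/2V0) and
    Xt = X0(v/V0)/(1+v/2V0); injection heats are
    dQ_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2.
    """
    dv = np.asarray(injection_volumes, dtype=float)
    if np.any(dv <= 0):
        raise ValueError("injection volumes must be positive")
    if np.any(dv >= v0):
        raise ValueError("injection volume must be smaller than the cell volume")
    vcum = np.cumsum(dv)
    d = vcum / (2.0 * v0)
    mt = cell_conc * (1.0 - d) / (1.0 + d)
    xt = syringe_conc * (vcum / v0) / (1.0 + d)
    q = one_site_total_heat(params, mt, xt, v0)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    if per_mole:
        dq = dq / (syringe_conc * dv)
    return dq


def _itc_residuals(theta, iso: Isotherm, mask):
    log_kd, dh, n = theta
    params = ITCParams(np.exp(log_kd), dh, n, iso.temperature)
    pred = predicted_injection_heats(
        params,
        iso.v0,
        np.asarray(iso.injection_volumes),
        iso.cell_conc,
        iso.syringe_conc,
        per_mole=iso.per_mole,
    )
    return (pred - np.asarray(iso.heats))[mask]


@dataclass(frozen=True)
class ITCFitResult:
    params: ITCParams
    stderr: dict
    residuals: np.ndarray
    c_value: float
    identifiable: bool = True
    message: str = ""


def fit_itc(
    iso: Isotherm,
    init: ITCParams | None = None,
    exclude_first: bool = True,
) -> ITCFitResult:
    """Fit (Kd, dH, n) to an isotherm by least squares on (log Kd, dH, n).

    The first injection is excluded by default (syringe diffusion artifact
    convention). Auto-initialisation takes n from the molar ratio at the
    steepest heat change, dH from the earliest retained injection, and
    Kd from a c ~ 10 guess. A c-value (n*M0/Kd) outside [1, 1000] triggers
    an identifiability warning.
    """
    heats = np.asarray(iso.heats, dtype=float)
    n_inj = len(heats)
    mask = np.ones(n_inj, dtype=bool)
    if exclude_first and n_inj > 1:
        mask[0] = False
    if mask.sum() < 8:
        raise ValueError("need at least 8 informative injections to fit")
    if np.max(np.abs(heats[mask])) < 1e-9:
        return ITCFitResult(
            params=ITCParams(1.0, 0.0, 1.0, iso.temperature),
            stderr={},
            residuals=heats[mask],
            c_value=np.nan,
            identifiable=False,
            message="no heat signal; dH ~ 0, parameters unidentifiable",
        )

    if init is None:
        dv = np.asarray(iso.injection_volumes)
        vcum = np.cumsum(dv)
        ratio = (iso.syringe_conc * vcum / iso.v0) / iso.cell_conc
        visible = np.where(mask)[0]
        slopes = np.abs(np.diff(heats[visible]))
        inflection = visible[np.argmax(slopes)] if len(slopes) else visible[0]
        n0 = float(np.clip(ratio[inflection], 0.2, 5.0))
        dh0 = float(heats[visible[0]])
        if not iso.per_mole:
            dh0 = dh0 / (iso.syringe_conc * dv[visible[0]])
        kd0 = max(n0 * iso.cell_conc / 10.0, 1e-12)
        init = ITCParams(kd0, dh0 if dh0 != 0 else -1.0, n0, iso.temperature)

    theta0 = np.array([np.log(init.kd), init.dh, init.n])
    result = optimize.least_squares(
        _itc_residuals,
        theta0,
        args=(iso, mask),
        bounds=([np.log(1e-12), -1e4, 1e-3], [np.log(1.0), 1e4, 10.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=500 * 3,
    )
    if not result.success:
        raise RuntimeError(f"ITC fit did not converge: {result.message}")
    log_kd, dh, n = result.x
    fitted = ITCParams(float(np.exp(log_kd)), float(dh), float(n), iso.temperature)

    # asymptotic standard errors from the Jacobian (delta method for Kd)
    dof = max(mask.sum() - 3, 1)
    s2 = float(result.cost * 2.0 / dof)
    jtj = result.jac.T @ result.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stderr = {"kd": fitted.kd * se[0], "dh": se[1], "n": se[2]}
    except np.linalg.LinAlgError:
        stderr = {"kd": np.nan, "dh": np.nan, "n": np.nan}

    c_value = fitted.n * iso.cell_conc / fitted.kd
    message = ""
    if not 1.0 <= c_value <= 1000.0:
        message = f"c-value {c_value:.3g} outside [1, 1000]; Kd poorly constrained"
        warnings.warn(message, stacklevel=2)
    return ITCFitResult(
        params=fitted,
        stderr=stderr,
        residuals=result.fun,
        c_value=float(c_value),
        identifiable=True,
        message=message,
    )


def thermo_decompose(kd: float, dh: float, temperature: float = DEFAULT_TEMPERATURE):
    """(dG, -T*dS) in kcal/mol from Kd (M) and dH via dG = RT ln Kd."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("Kd and temperature must be positive")
    dg = GAS_CONSTANT_KCAL * temperature * np.log(kd)
    return float(dg), float(dg - dh)


def combined_csp(pair: ShiftPair, alpha_n: float = ALPHA_N, alpha_c: float = ALPHA_C) -> float:
    """Combined CSP (ppm): sqrt(dH^2 + (aN*dX)^2) for amides, aC*|dC'| for carbonyls."""
    dh = pair.h_bound - pair.h_free
    dx = pair.x_bound - pair.x_free
    if pair.nucleus == "amide-N":
        return float(np.sqrt(dh * dh + (alpha_n * dx) ** 2))
    return float(alpha_c * abs(dx))


def fraction_bound(p_total, l_total, kd):
    """Fraction of protein bound under ligand depletion (quadratic root).

    fb = ((P+L+Kd) - sqrt((P+L+Kd)^2 - 4PL)) / (2P).
    """
    p = np.asarray(p_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    s = p + l + kd
    fb = (s - np.sqrt(s * s - 4.0 * p * l)) / (2.0 * p)
    return fb if fb.ndim else float(fb)


@dataclass(frozen=True)
class TitrationFitResult:
    kd: float
    dmax: np.ndarray
    residues: tuple
    saturation: float
    rss: float
    warning: str = ""


def fit_titration_kd(series: TitrationSeries, noise_floor: float = 1e-4) -> TitrationFitResult:
    """Global fast-exchange fit: shared Kd, residue-specific saturation CSPs.

    For a candidate Kd the per-residue amplitude is the linear least-squares
    solution dmax_r = sum(fb*d_obs)/sum(fb^2), so only log Kd is profiled
    numerically. Requires >= 4 titration points and at least one residue
    whose largest CSP exceeds ``noise_floor``; warns when the final point
    is below 50% saturation (upper bound only).
    """
    csp = series.csp
    ligand = np.asarray(series.ligand_concs, dtype=float)
    if len(ligand) < 4:
        raise ValueError("need at least 4 titration points")
    if np.max(csp) <= noise_floor:
        raise UnidentifiableFitError("no CSP above the noise floor: no binding signal")

    def profiled_rss(log_kd: float) -> float:
        fb = fraction_bound(series.p0, ligand, np.exp(log_kd))
        denom = float(fb @ fb)
        if denom == 0:
            return float(np.sum(csp**2))
        amp = (csp @ fb) / denom
        resid = csp - amp[:, None] * fb[None, :]
        return float(np.sum(resid**2))

    bracket = (np.log(1e-9), np.log(1e-1))
    res = optimize.minimize_scalar(
        profiled_rss, bounds=bracket, method="bounded",
        options={"xatol": 1e-12},
    )
    kd = float(np.exp(res.x))
    fb = fraction_bound(series.p0, ligand, kd)
    dmax = (csp @ fb) / float(fb @ fb)
    saturation = float(fb[-1])
    warning = ""
    if saturation < 0.5:
        warning = (
            f"final titration point only {saturation:.0%} saturated; "
            "fitted Kd is an upper bound"
        )
        warnings.warn(warning, stacklevel=2)
    return TitrationFitResult(
        kd=kd,
        dmax=np.asarray(dmax),
        residues=series.residues,
        saturation=saturation,
        rss=float(res.fun),
        warning=warning,
    )


def check_thermo_consistency(
    kd: float,
    dh: float,
    minus_tds: float,
    temperature: float = DEFAULT_TEMPERATURE,
    tol_kcal: float = 1.0,
) -> bool:
    """True when a reported (Kd, dH, -TdS) triple satisfies dG = dH + (-TdS)
    with dG = RT ln Kd to within ``tol_kcal``.

    Published thermodynamic decompositions are not always self-consistent
    with the reported Kd; Kd is treated as ground truth and inconsistent
    decompositions are flagged (a warning) rather than propagated.
    """
    dg, _ = thermo_decompose(kd, dh, temperature)
    consistent = abs(dg - (dh + minus_tds)) <= tol_kcal
    if not consistent:
        warnings.warn(
            f"thermodynamic decomposition inconsistent: RT ln Kd = {dg:.2f} "
            f"kcal/mol but dH + (-TdS) = {dh + minus_tds:.2f} kcal/mol",
            stacklevel=2,
        )
    return consistent


def kd_fold_change(kd_a: float, kd_b: float) -> float:
    """Affinity fold change kd_a / kd_b (dimensionless)."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("Kd values must be positive")
    return kd_a / kd_b
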