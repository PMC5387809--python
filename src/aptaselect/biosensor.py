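"""Biosensor analytics: QCM mass conversion and SPR Langmuir kinetics.

QCM
    A quartz crystal microbalance reports binding as a drop in the crystal's
    resonance frequency.  For a rigid adlayer the Sauerbrey relation is
    linear::

        delta_f = -2 f0^2 delta_m / (A sqrt(mu rho))

    with f0 the fundamental resonant frequency (Hz), A the electrode area
    (cm^2), rho the crystal density (g/cm^3) and mu the quartz shear modulus
    (g cm^-1 s^-2).  A frequency *decrease* corresponds to adsorbed mass.
    Replicate frequency changes are summarized as mean +/- sample standard
    deviation, and candidate aptamers are compared as fold changes over a
    benchmark aptamer.

SPR
    A surface plasmon resonance sensorgram records response versus time
    through an association phase (analyte at concentration C flowing over
    immobilized aptamer) and a dissociation phase (buffer only).  Under 1:1
    first-order Langmuir kinetics::

        association:   R(t)   = Req (1 - exp(-(ka C + kd) t)),
                       Req    = Rmax ka C / (ka C + kd)
        dissociation:  R(t)   = R0 exp(-kd (t - t0))

    with R0 the response at the start of dissociation (continuity at the
    phase boundary).  Global least-squares fitting of both phases yields the
    association rate ka (M^-1 s^-1), dissociation rate kd (s^-1) and binding
    affinity KA = ka/kd (M^-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError, ParameterError

#: Typical fundamental frequency (Hz) for the 8 MHz-class crystals used with
#: electrochemical QCM instruments; f0 must always be passed explicitly.
TYPICAL_F0_HZ = 7.995e6

ASSOCIATION = "association"
DISSOCIATION = "dissociation"


@dataclass(frozen=True)
class SauerbreyParams:
    """Crystal constants for the Sauerbrey conversion.

    Defaults are the published constants of the instrument class: gold disk
    area 0.196 cm^2, quartz density 2.684 g/cm^3, shear modulus
    2.947e11 g/(cm s^2).  f0 is instrument-specific and has no default.
    """

    f0: float
    area: float = 0.196
    density: float = 2.684
    shear_modulus: float = 2.947e11

    def __post_init__(self) -> None:
        for name in ("f0", "area", "density", "shear_modulus"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")


def sauerbrey_mass(delta_f: float, p: SauerbreyParams) -> float:
    """Mass change (g) from a frequency change (Hz).

    A negative delta_f (frequency drop) maps to positive adsorbed mass.
    """
    return -delta_f * p.area * math.sqrt(p.shear_modulus * p.density) / (
        2.0 * p.f0**2
    )


def sauerbrey_mass_ng(delta_f: float, p: SauerbreyParams) -> float:
    return sauerbrey_mass(delta_f, p) * 1e9


def sauerbrey_freq(delta_m: float, p: SauerbreyParams) -> float:
    """Frequency change (Hz) from a mass change (g); inverse of
    :func:`sauerbrey_mass`."""
    return -2.0 * p.f0**2 * delta_m / (
        p.area * math.sqrt(p.shear_modulus * p.density)
    )


def qcm_summary(replicates) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of replicate |delta f| values."""
    arr = np.asarray(replicates, dtype=float)
    if arr.size < 2:
        raise InputError("need at least two replicates for a summary")
    return float(arr.mean()), float(arr.std(ddof=1))


def fold_change(value: float, reference: float) -> float:
    """Signal ratio relative to a benchmark (e.g. candidate vs control Δf)."""
    if reference <= 0:
        raise InputError("reference must be strictly positive")
    return value / reference


def molar_concentration(mass_conc_ng_per_ml: float, molecular_weight: float) -> float:
    """Molarity (M) of an analyte given ng/ml and molar mass (g/mol)."""
    if mass_conc_ng_per_ml < 0 or molecular_weight <= 0:
        raise ParameterError("concentration must be >= 0 and MW > 0")
    grams_per_liter = mass_conc_ng_per_ml * 1e-6
    return grams_per_liter / molecular_weight


@dataclass(frozen=True)
class KineticParams:
    """1:1 Langmuir rate constants; KA = ka/kd by definition."""

    ka: float  # M^-1 s^-1
    kd: float  # s^-1
    rmax: float = 1.0  # response units

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0:
            raise ParameterError("ka and kd must be strictly positive")
        if self.rmax <= 0:
            raise ParameterError("Rmax must be strictly positive")

    @property
    def KA(self) -> float:
        return self.ka / self.kd


def binding_affinity(ka: float, kd: float) -> float:
    """Equilibrium association constant KA = ka/kd (M^-1)."""
    if kd <= 0:
        raise ParameterError("kd must be strictly positive")
    return ka / kd


@dataclass(frozen=True)
class Sensorgram:
    """An SPR time series with per-point phase labels.

    time is strictly increasing (seconds); phase holds 'association' or
    'dissociation' per point, association first; concentration is the molar
    analyte concentration during association.
    """

    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray
    concentration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        ph = np.asarray(self.phase)
        if not (len(t) == len(r) == len(ph)):
            raise InputError("time/response/phase lengths differ")
        if np.any(np.diff(t) <= 0):
            raise InputError("time must be strictly increasing")
        labels = set(ph.tolist())
        if not labels <= {ASSOCIATION, DISSOCIATION}:
            raise InputError(f"unknown phase labels: {labels}")
        is_d = ph == DISSOCIATION
        if is_d.any() and not is_d[np.argmax(is_d):].all():
            raise InputError("association must precede dissociation")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "phase", np.asarray(ph))
        if self.concentration <= 0:
            raise ParameterError("analyte concentration must be positive")

    @property
    def t_dissoc_start(self) -> float | None:
        mask = self.phase == DISSOCIATION
        if not mask.any():
            return None
        return float(self.time[np.argmax(mask)])


def langmuir_response(
    t,
    kp: KineticParams,
    concentration: float,
    t_dissoc_start: float | None = None,
) -> np.ndarray:
    """Evaluate the two-phase 1:1 Langmuir model at times ``t``.

    Times before ``t_dissoc_start`` follow the association solution from
    R(0)=0; later times decay exponentially from the association value at
    the boundary, so the curve is continuous there.  ``t_dissoc_start=None``
    means association-only.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("times must be non-negative")
    kobs = kp.ka * concentration + kp.kd
    req = kp.rmax * kp.ka * concentration / kobs
    assoc = req * (1.0 - np.exp(-kobs * t))
    if t_dissoc_start is None:
        return assoc
    r0 = req * (1.0 - math.exp(-kobs * t_dissoc_start))
    dissoc = r0 * np.exp(-kp.kd * (t - t_dissoc_start))
    return np.where(t < t_dissoc_start, assoc, dissoc)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a global sensorgram fit."""

    params: KineticParams
    KA: float
    stderr: dict[str, float]
    condition_number: float
    poorly_identified: bool
    cost: float
    n_points: int
    message: str


def _fit_residuals(log10_theta, sg: Sensorgram):
    ka, kd, rmax = 10.0 ** np.asarray(log10_theta)
    kp = KineticParams(ka, kd, rmax)
    model = langmuir_response(
        sg.time, kp, sg.concentration, sg.t_dissoc_start
    )
    return model - sg.response


def fit_sensorgram(
    sg: Sensorgram,
    init: KineticParams | None = None,
    bounds: tuple[tuple[float, float], ...] | None = None,
) -> FitResult:
    """Global bounded least-squares fit of (ka, kd, Rmax) over both phases.

    The fit runs in log10 parameter space (rates span decades) from three
    log-spaced multi-starts — or from ``init`` alone when provided — and the
    best converged solution wins.  Parameter standard errors come from the
    local curvature (Gauss-Newton J^T J) at the optimum.  When ka*C << kd
    the association phase barely constrains ka and Rmax separately; such
    fits are flagged ``poorly_identified`` with the Jacobian condition
    number as the diagnostic.
    """
    for label in (ASSOCIATION, DISSOCIATION):
        if int((sg.phase == label).sum()) < 10:
            raise InputError(
                f"sensorgram needs >= 10 points in the {label} phase"
            )
    if bounds is None:
        bounds = ((1e0, 1e9), (1e-7, 1e1), (1e-6, 1e9))
    lo = np.log10([b[0] for b in bounds])
    hi = np.log10([b[1] for b in bounds])

    if init is not None:
        starts = [np.log10([init.ka, init.kd, init.rmax])]
    else:
        rmax_guess = max(float(np.max(sg.response)), 1e-12)
        starts = []
        for ka0, kd0 in ((1e3, 1e-2), (1e5, 1e-3), (1e7, 1e-4)):
            starts.append(np.log10([ka0, kd0, rmax_guess * 2.0]))
    starts = [np.clip(s, lo, hi) for s in starts]

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                _fit_residuals,
                x0,
                args=(sg,),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except (ValueError, ParameterError):
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("sensorgram fit did not converge from any start")

    ka, kd, rmax = 10.0**best.x
    params = KineticParams(ka, kd, rmax)
    jac = best.jac
    jtj = jac.T @ jac
    try:
        cond = float(np.linalg.cond(jtj))
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = float("inf")
    dof = max(len(sg.time) - 3, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov_log = s2 * np.linalg.pinv(jtj)
        log_se = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        log_se = np.full(3, np.nan)
    # delta method: se(p) = ln(10) * p * se(log10 p)
    se = math.log(10.0) * np.array([ka, kd, rmax]) * log_se
    poorly = params.ka * sg.concentration < 0.01 * params.kd or cond > 1e12
    if poorly:
        warnings.warn(
            "ka*C << kd or ill-conditioned Jacobian: ka and Rmax are nearly "
            "unidentifiable from a single analyte concentration",
            stacklevel=2,
        )
    return FitResult(
        params=params,
        KA=params.KA,
        stderr={"ka": float(se[0]), "kd": float(se[1]), "rmax": float(se[2])},
        condition_number=cond,
        poorly_identified=bool(poorly),
        cost=float(best.cost),
        n_points=len(sg.time),
        message=best.message,
    )


def fit_dissociation_rate(sg: Sensorgram) -> float:
    """kd from log-linear regression on the dissociation phase only.

    Closed-form check on the nonlinear fit: ln R(t) is linear in t with
    slope -kd during dissociation (for strictly positive responses).
    """
    mask = sg.phase == DISSOCIATION
    t = sg.time[mask]
    r = sg.response[mask]
    if len(t) < 2:
        raise InputError("need at least two dissociation points")
    if np.any(r <= 0):
        raise InputError("log-linear estimate requires positive responses")
    slope = np.polyfit(t, np.log(r), 1)[0]
    return float(-slope)
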