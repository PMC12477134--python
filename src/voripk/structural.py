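"""One-compartment oral steady-state kernel with allometric scaling.

The disposition model is a single central compartment with first-order
absorption (rate constant ``ka``) and first-order elimination, parameterized
by apparent clearance CL/F and apparent volume V/F (F == 1 convention, as
only oral data are observed).  Body weight enters through fixed-exponent
allometry referenced to 70 kg: CL scales with (WT/70)**0.75 and V with
(WT/70)**1.  Inter-individual variability acts multiplicatively on CL via
exp(eta), eta ~ N(0, omega2_cl); no random effect is carried on V.

All kernels accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataError",
    "ConfigError",
    "ResidualSpec",
    "PopPKParams",
    "typical_params",
    "individual_params",
    "ss_trough",
    "residual_variance",
]

#: lower limit of quantitation of the trough assay, mg/L
LLOQ = 0.25

#: relative |ka - ke| below which the flip-flop-safe limit branch is used
_KA_KE_SWITCH = 1e-6


class DataError(ValueError):
    """Invalid observed/simulated data passed to a kernel."""


class ConfigError(ValueError):
    """Invalid configuration or parameter specification."""


@dataclass(frozen=True)
class ResidualSpec:
    """Residual (within-subject) error model on the concentration scale.

    kind
        ``proportional`` — var = (cv_prop * pred)**2;
        ``additive``     — var = sd_add**2;
        ``combined``     — sum of both.
    cv_prop
        coefficient of variation (fraction) of the proportional component.
    sd_add
        standard deviation (mg/L) of the additive component.
    """

    kind: str = "proportional"
    cv_prop: float = 0.25
    sd_add: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ConfigError(f"unknown residual error kind: {self.kind!r}")
        if self.kind == "proportional":
            if self.cv_prop <= 0 or self.sd_add != 0:
                raise ConfigError("proportional error needs cv_prop>0, sd_add=0")
        elif self.kind == "additive":
            if self.sd_add <= 0 or self.cv_prop != 0:
                raise ConfigError("additive error needs sd_add>0, cv_prop=0")
        else:
            if self.cv_prop <= 0 or self.sd_add <= 0:
                raise ConfigError("combined error needs cv_prop>0 and sd_add>0")

    def variance(self, pred):
        pred = np.asarray(pred, dtype=float)
        if self.kind == "proportional":
            return (self.cv_prop * pred) ** 2
        if self.kind == "additive":
            return np.full_like(pred, self.sd_add**2)
        return (self.cv_prop * pred) ** 2 + self.sd_add**2


@dataclass(frozen=True)
class PopPKParams:
    """Fixed and random effect parameters of the population model.

    Defaults are the final published model for this population:
    CL/F = 17.9 L/h/70kg, V/F = 788 L/70kg, Ka fixed at 1.19 /h,
    omega2_cl = 0.674 on the log scale (SD ~0.821).
    """

    theta_cl: float = 17.9
    theta_v: float = 788.0
    ka: float = 1.19
    exp_cl: float = 0.75
    exp_v: float = 1.0
    ref_wt: float = 70.0
    omega2_cl: float = 0.674
    sigma: ResidualSpec = field(default_factory=ResidualSpec)

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v", "ka", "ref_wt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.omega2_cl < 0:
            raise ConfigError("omega2_cl must be >= 0")


def typical_params(params: PopPKParams, weight):
    """Typical-value (CL, V) at a body weight, by fixed-exponent allometry.

    CL = theta_cl * (WT/ref)**exp_cl ; V = theta_v * (WT/ref)**exp_v.
    """
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise DataError("weight must be > 0")
    frac = weight / params.ref_wt
    return params.theta_cl * frac**params.exp_cl, params.theta_v * frac**params.exp_v


def individual_params(typical, eta_cl):
    """Individual (CL_i, V_i) from typical values and the subject's eta.

    The random effect is exponential on CL only; V carries no IIV in the
    final model (shrinkage >90% under trough-only sampling).
    """
    cl, v = typical
    eta_cl = np.asarray(eta_cl, dtype=float)
    return np.asarray(cl, dtype=float) * np.exp(eta_cl), np.asarray(v, dtype=float) + 0.0 * eta_cl


def ss_trough(dose, tau, cl, v, ka):
    """Steady-state trough concentration (mg/L) just before the next dose.

    C(tau) = (D*ka)/(V*(ka-ke)) * [ e^(-ke*tau)/(1-e^(-ke*tau))
                                    - e^(-ka*tau)/(1-e^(-ka*tau)) ],  ke = CL/V.

    Near ka == ke (flip-flop degeneracy) the analytic limit
    (D*ka*tau/V) * e^(-km*tau)/(1-e^(-km*tau))**2, km = (ka+ke)/2,
    is used so the surface stays continuous.
    """
    dose, tau, cl, v, ka = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (dose, tau, cl, v, ka))
    )
    if np.any(dose < 0):
        raise DataError("dose must be >= 0")
    if np.any(tau <= 0) or np.any(cl <= 0) or np.any(v <= 0) or np.any(ka <= 0):
        raise DataError("tau, CL, V, ka must be > 0")
    ke = cl / v
    near = np.abs(ka - ke) < _KA_KE_SWITCH * ke

    def _accum(x):
        # e^(-x*tau) / (1 - e^(-x*tau)) without overflow for large x*tau
        ex = np.exp(-x * tau)
        return ex / (1.0 - ex)

    with np.errstate(divide="ignore", invalid="ignore"):
        general = dose * ka / (v * (ka - ke)) * (_accum(ke) - _accum(ka))
    km = 0.5 * (ka + ke)
    exm = np.exp(-km * tau)
    limit = dose * ka * tau / v * exm / (1.0 - exm) ** 2
    out = np.where(near, limit, general)
    return out if out.ndim else float(out)


def residual_variance(pred, spec: ResidualSpec):
    """Residual error variance ((mg/L)^2) at a model prediction."""
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise DataError("pred must be >= 0")
    out = spec.variance(pred)
    return out if out.ndim else float(out)
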