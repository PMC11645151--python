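"""ROI-level one-tissue compartment model fitting.

``OneTissueModel`` is a statsmodels-style model object built from a
measured time-activity curve and an arterial input function; ``fit()``
performs bounded weighted nonlinear least squares against the exact
analytic forward model and returns a ``OneTissueResults`` carrying the
estimates, residual diagnostics and a ``summary()`` table.
``fit_linearized()`` solves the operational linear form used by the
voxel-wise mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .simulate import simulate_tac
from .types import FrameSchedule, InputFunction, PKParameters, TimeActivityCurve

DEFAULT_INIT = (0.1, 0.1, 0.05)            # K1, k2, vb
DEFAULT_BOUNDS = ((0.0, 0.0, 0.0), (5.0, 5.0, 1.0))


@dataclass
class OneTissueResults:
    """Estimates and diagnostics from a one-tissue model fit."""

    params: PKParameters
    residual_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    fitted_curve: np.ndarray | None = None
    method: str = "nls"

    @property
    def K1(self) -> float:
        return self.params.K1

    @property
    def k2(self) -> float:
        return self.params.k2

    @property
    def vb(self) -> float:
        return self.params.vb

    @property
    def flow(self) -> float:
        """Blood flow F = K1 / extraction fraction (mL/min/mL tissue)."""
        return self.params.F

    def as_dict(self) -> dict:
        return {
            "K1": self.K1, "k2": self.k2, "vb": self.vb, "F": self.flow,
            "residual_norm": self.residual_norm, "converged": self.converged,
            "flags": list(self.flags), "method": self.method,
        }

    def summary(self) -> str:
        lines = [
            "One-tissue compartment model fit",
            "================================",
            f"  method          : {self.method}",
            f"  K1  (mL/min/mL) : {self.K1:.5f}",
            f"  k2  (1/min)     : {self.k2:.5f}",
            f"  vb  (fraction)  : {self.vb:.5f}",
            f"  F   (mL/min/mL) : {self.flow:.5f}  "
            f"(extraction fraction {self.params.extraction_fraction})",
            f"  residual norm   : {self.residual_norm:.4g}",
            f"  converged       : {self.converged}",
        ]
        if self.flags:
            lines.append(f"  flags           : {', '.join(self.flags)}")
        return "\n".join(lines)


class OneTissueModel:
    """One-tissue compartment model for a measured ROI time-activity curve.

    Parameters
    ----------
    tac : TimeActivityCurve
        Measured tissue curve (kBq/mL per frame).
    input_fn : InputFunction
        Calibrated, metabolite-corrected arterial input.
    weights : array, optional
        Per-frame weights in the least-squares objective; default is
        proportional to frame duration (approximates count-variance
        weighting without calibration data).
    """

    def __init__(self, tac: TimeActivityCurve, input_fn: InputFunction,
                 weights=None):
        self.tac = tac
        self.input_fn = input_fn
        self.schedule: FrameSchedule = tac.schedule
        if self.schedule.n_frames < 4:
            raise ValueError("at least 4 frames are required")
        if weights is None:
            weights = self.schedule.durations
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != self.tac.activity.shape or np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative, one per frame")
        if not np.any(self.input_fn.parent_activity > 0):
            if not np.any(self.tac.activity != 0):
                raise ValueError("cannot calibrate fit: degenerate input "
                                 "(zero input and zero observed curve)")
            raise ValueError("input function is identically zero")

    # ---- forward model -------------------------------------------------
    def predict(self, params: PKParameters) -> np.ndarray:
        return simulate_tac(params, self.input_fn, self.schedule).activity

    # ---- nonlinear fit -------------------------------------------------
    def fit(self, init: PKParameters | tuple = DEFAULT_INIT,
            bounds=DEFAULT_BOUNDS, fix_vb: float | None = None) -> OneTissueResults:
        """Bounded trust-region weighted nonlinear least squares.

        Minimizes sum_i w_i (C_obs,i - C_model,i)^2.  ``fix_vb`` freezes
        the blood volume fraction at the given value.
        """
        obs = self.tac.activity
        sw = np.sqrt(self.weights)
        ef = init.extraction_fraction if isinstance(init, PKParameters) else 0.52
        if isinstance(init, PKParameters):
            x0 = [init.K1, init.k2, init.vb]
        else:
            x0 = list(init)
        lo, hi = (np.asarray(bounds[0], float), np.asarray(bounds[1], float))

        if not np.any(obs != 0):
            # no signal: K1 = 0 fits exactly; k2 carries no information
            params = PKParameters(0.0, 0.0, 0.0, ef)
            return OneTissueResults(params, 0.0, True,
                                    flags=["unidentifiable k2"],
                                    fitted_curve=np.zeros_like(obs))

        if fix_vb is None:
            def residuals(x):
                p = PKParameters(x[0], x[1], x[2], ef)
                return sw * (self.predict(p) - obs)
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
            k1, k2, vb = sol.x
        else:
            def residuals(x):
                p = PKParameters(x[0], x[1], fix_vb, ef)
                return sw * (self.predict(p) - obs)
            sol = least_squares(residuals, x0[:2], bounds=(lo[:2], hi[:2]),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
            k1, k2, vb = sol.x[0], sol.x[1], fix_vb

        params = PKParameters(float(k1), float(k2), float(vb), ef)
        fitted = self.predict(params)
        rnorm = float(np.sqrt(np.sum(self.weights * (fitted - obs) ** 2)))
        flags = [] if sol.success else ["non-convergence: best iterate returned"]
        return OneTissueResults(params, rnorm, bool(sol.success), flags=flags,
                                fitted_curve=fitted)

    # ---- linearized fit ------------------------------------------------
    def fit_linearized(self, bounds=DEFAULT_BOUNDS) -> OneTissueResults:
        """Ordinary least squares on the linear operational form.

        C_PET(t) = th1 * int C_a + th2 * int C_PET + th3 * C_a(t),
        with vb = th3, k2 = -th2, K1 = (th1 + th2*th3) / (1 - th3).
        Integrals use the trapezoid rule on frame mid-times.  Estimates
        outside the bounds are clipped and flagged.
        """
        X, y = self._linear_design()
        theta, flags = _solve_linear(X, y)
        params, clip_flags = _theta_to_params(theta, bounds)
        fitted = X @ theta
        rnorm = float(np.linalg.norm(fitted - y))
        return OneTissueResults(params, rnorm, True, flags=flags + clip_flags,
                                fitted_curve=fitted, method="linearized-ols")

    def _linear_design(self):
        mids = self.schedule.mid_times
        y = self.tac.activity
        ca = self.input_fn(mids)
        t_aug = np.concatenate([[0.0], mids])
        int_ca = np.cumsum(np.diff(t_aug) * 0.5
                           * (np.concatenate([[0.0], ca])[:-1] + ca))
        int_cp = np.cumsum(np.diff(t_aug) * 0.5
                           * (np.concatenate([[0.0], y])[:-1] + y))
        X = np.column_stack([int_ca, int_cp, ca])
        return X, y


def _solve_linear(X: np.ndarray, y: np.ndarray):
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design: curves carry no kinetic information")
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return theta, []


def _theta_to_params(theta, bounds, extraction_fraction: float = 0.52):
    th1, th2, th3 = (float(v) for v in theta)
    vb = th3
    k2 = -th2
    denom = 1.0 - vb
    K1 = (th1 + th2 * th3) / denom if abs(denom) > 1e-12 else np.inf
    lo, hi = (np.asarray(bounds[0], float), np.asarray(bounds[1], float))
    raw = np.array([K1, k2, vb])
    clipped = np.clip(raw, lo, hi)
    flags = ["clipped"] if not np.allclose(raw, clipped, atol=0.0) else []
    params = PKParameters(float(clipped[0]), float(clipped[1]), float(clipped[2]),
                          extraction_fraction)
    return params, flags


# ---- functional façades ------------------------------------------------

def fit_roi(tac: TimeActivityCurve, input_fn: InputFunction,
            init=DEFAULT_INIT, bounds=DEFAULT_BOUNDS, weights=None,
            fix_vb: float | None = None) -> OneTissueResults:
    """Fit the one-tissue model to an ROI curve by weighted NLS."""
    return OneTissueModel(tac, input_fn, weights=weights).fit(
        init=init, bounds=bounds, fix_vb=fix_vb)


def linearized_fit(tac: TimeActivityCurve, input_fn: InputFunction,
                   bounds=DEFAULT_BOUNDS) -> OneTissueResults:
    """Fit the one-tissue model by the OLS linear operational form."""
    return OneTissueModel(tac, input_fn).fit_linearized(bounds=bounds)
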