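"""Age-dependent normative distributions: the LMS method under the
Yeo-Johnson transformation.

The model assumes that, at each age t, the (normalized) volume y becomes
standard normal after a Yeo-Johnson power transform with an age-dependent
exponent L(t), location mu(t) and scale sigma(t):

    z = ( psi_{L(t)}(y / s0) - mu(t) - b_s * sex - b_h * (height - 170) ) / sigma(t)

Each of L, mu and log sigma is a natural cubic regression spline in age
with ``delta`` degrees of freedom (delta = 2 is exactly linear in age);
b_s and b_h are additive covariate effects on the transformed-scale
location.  All parameters are estimated jointly by maximizing the exact
log-likelihood, including the Jacobian of the transformation.  s0 is the
training-sample median volume; normalizing by it keeps the optimization
well conditioned without changing the model family to first order.

From a fitted model one obtains z-scores for new subjects and
iso-z-score curves (the centile-like volume-vs-age lines at constant z).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy import optimize

log = logging.getLogger("normvol")

LAMBDA_BOUND = 3.0  # |L(t)| is smoothly constrained below this


class FitError(RuntimeError):
    """Raised when normative fitting cannot produce a usable model."""


class DomainError(ValueError):
    """Raised when a value lies outside the image of the YJ transform."""


class ExtrapolationError(ValueError):
    """Raised when a model is evaluated outside its fitted age domain."""


# ---------------------------------------------------------------------------
# Yeo-Johnson transform


def yeo_johnson(y, lam):
    """Yeo-Johnson power transform, elementwise; ``lam`` may be an array.

    Strictly increasing in ``y`` and continuous in ``lam`` for every real
    input.
    """
    scalar = np.ndim(y) == 0 and np.ndim(lam) == 0
    y = np.atleast_1d(np.asarray(y, dtype=float))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), y.shape).copy()
    out = np.empty_like(y)

    # expm1/log1p formulation: accurate and continuous as lam -> 0 / 2
    pos = y >= 0
    lam_p = lam[pos]
    yp = y[pos]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out_p = np.where(
            np.abs(lam_p) > 1e-12,
            np.expm1(lam_p * np.log1p(yp)) / np.where(np.abs(lam_p) > 1e-12, lam_p, 1.0),
            np.log1p(yp),
        )
    out[pos] = out_p

    neg = ~pos
    lam_n = lam[neg]
    yn = y[neg]
    two_m = 2.0 - lam_n
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out_n = np.where(
            np.abs(two_m) > 1e-12,
            -np.expm1(two_m * np.log1p(-yn)) / np.where(np.abs(two_m) > 1e-12, two_m, 1.0),
            -np.log1p(-yn),
        )
    out[neg] = out_n
    return float(out[0]) if scalar else out


def yeo_johnson_inverse(x, lam):
    """Inverse of :func:`yeo_johnson`; raises :class:`DomainError` when a
    value lies outside the image of the transform for the given lambda
    (e.g. x <= -1/lam for lam > 0)."""
    scalar = np.ndim(x) == 0 and np.ndim(lam) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), x.shape).copy()
    out = np.empty_like(x)

    pos = x >= 0
    lam_p = lam[pos]
    xp = x[pos]
    lam_nonzero = np.abs(lam_p) > 1e-12
    arg = lam_p * xp + 1.0
    if np.any(arg[lam_nonzero] <= 0.0):
        raise DomainError("value outside the image of the Yeo-Johnson transform "
                          "(lam * x + 1 <= 0 on the non-negative branch)")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out_p = np.where(
            lam_nonzero,
            np.expm1(np.log(np.where(lam_nonzero, arg, 1.0))
                     / np.where(lam_nonzero, lam_p, 1.0)),
            np.expm1(xp),
        )
    out[pos] = out_p

    neg = ~pos
    lam_n = lam[neg]
    xn = x[neg]
    two_m = 2.0 - lam_n
    two_nonzero = np.abs(two_m) > 1e-12
    arg_n = 1.0 - two_m * xn
    if np.any(arg_n[two_nonzero] <= 0.0):
        raise DomainError("value outside the image of the Yeo-Johnson transform "
                          "(1 - (2 - lam) * x <= 0 on the negative branch)")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out_n = np.where(
            two_nonzero,
            -np.expm1(np.log(np.where(two_nonzero, arg_n, 1.0))
                      / np.where(two_nonzero, two_m, 1.0)),
            -np.expm1(-xn),
        )
    out[neg] = out_n
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Natural cubic spline basis


def natural_spline_basis(t, knots):
    """Design matrix of a natural cubic spline with the given knots.

    ``K = len(knots)`` basis columns (intercept, linear, and K-2 curvature
    terms), so the fitted curve has K degrees of freedom; with K = 2 the
    basis is exactly {1, t}.  ``K = 1`` degenerates to the intercept only.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K == 1:
        return np.ones((t.size, 1))
    B = np.empty((t.size, K))
    B[:, 0] = 1.0
    B[:, 1] = t
    if K > 2:
        xi_K = knots[-1]
        xi_Km1 = knots[-2]

        def d(xi):
            return (np.clip(t - xi, 0.0, None) ** 3 - np.clip(t - xi_K, 0.0, None) ** 3) / (xi_K - xi)

        dK1 = d(xi_Km1)
        for j in range(K - 2):
            B[:, 2 + j] = d(knots[j]) - dK1
    return B


# ---------------------------------------------------------------------------
# Model containers


@dataclasses.dataclass
class LMSCurves:
    """Fitted spline curves of one normative model.

    Ages are internally standardized as s = (age - age_center) / age_scale;
    knots and coefficients live on that standardized axis.  ``coef_l``
    parameterizes the raw lambda curve before the smooth [-3, 3] bound.
    """

    knots: np.ndarray
    coef_l: np.ndarray
    coef_mu: np.ndarray
    coef_logsigma: np.ndarray
    delta: int
    age_domain: tuple[float, float]
    age_center: float
    age_scale: float

    def _basis(self, age):
        s = (np.asarray(age, dtype=float) - self.age_center) / self.age_scale
        return natural_spline_basis(s, self.knots)

    def lambda_at(self, age):
        raw = self._basis(age) @ self.coef_l
        return LAMBDA_BOUND * np.tanh(raw / LAMBDA_BOUND)

    def mu_at(self, age):
        return self._basis(age) @ self.coef_mu

    def sigma_at(self, age):
        return np.exp(self._basis(age) @ self.coef_logsigma)


@dataclasses.dataclass
class NormativeModel:
    """A fitted normative distribution for one (method, region)."""

    method: str
    region: str
    curves: LMSCurves
    beta_sex: float
    beta_height: float
    volume_scale: float  # s0: training median volume, mm^3
    ref_sex: int = 1
    ref_height: float = 170.0
    diagnostics: dict = dataclasses.field(default_factory=dict)
    provenance: dict = dataclasses.field(default_factory=dict)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        c = self.curves
        return {
            "method": self.method,
            "region": self.region,
            "delta": c.delta,
            "knots": c.knots.tolist(),
            "coef_l": c.coef_l.tolist(),
            "coef_mu": c.coef_mu.tolist(),
            "coef_logsigma": c.coef_logsigma.tolist(),
            "age_domain": list(c.age_domain),
            "age_center": c.age_center,
            "age_scale": c.age_scale,
            "beta_sex": self.beta_sex,
            "beta_height": self.beta_height,
            "volume_scale": self.volume_scale,
            "ref_sex": self.ref_sex,
            "ref_height": self.ref_height,
            "diagnostics": self.diagnostics,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        curves = LMSCurves(
            knots=np.asarray(d["knots"], dtype=float),
            coef_l=np.asarray(d["coef_l"], dtype=float),
            coef_mu=np.asarray(d["coef_mu"], dtype=float),
            coef_logsigma=np.asarray(d["coef_logsigma"], dtype=float),
            delta=int(d["delta"]),
            age_domain=tuple(d["age_domain"]),
            age_center=float(d["age_center"]),
            age_scale=float(d["age_scale"]),
        )
        return cls(
            method=d["method"], region=d["region"], curves=curves,
            beta_sex=float(d["beta_sex"]), beta_height=float(d["beta_height"]),
            volume_scale=float(d["volume_scale"]),
            ref_sex=int(d["ref_sex"]), ref_height=float(d["ref_height"]),
            diagnostics=d.get("diagnostics", {}), provenance=d.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "NormativeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def _check_domain(self, age, allow_extrapolation: bool) -> None:
        lo, hi = self.curves.age_domain
        age = np.asarray(age, dtype=float)
        if not allow_extrapolation and (np.any(age < lo) or np.any(age > hi)):
            raise ExtrapolationError(
                f"age outside fitted domain [{lo:.2f}, {hi:.2f}] "
                f"(pass allow_extrapolation=True to override)"
            )


# ---------------------------------------------------------------------------
# Fitting


def _negloglik(theta, B, w, sex, dheight, K):
    """Mean negative log-likelihood of the LMS/YJ model (Jacobian included)."""
    coef_l = theta[:K]
    coef_mu = theta[K:2 * K]
    coef_ls = theta[2 * K:3 * K]
    beta_s, beta_h = theta[3 * K], theta[3 * K + 1]

    lam = LAMBDA_BOUND * np.tanh((B @ coef_l) / LAMBDA_BOUND)
    mu = B @ coef_mu
    logsigma = B @ coef_ls
    if np.any(logsigma > 50.0) or np.any(logsigma < -50.0):
        return 1e10
    sigma = np.exp(logsigma)

    # positive branch only: normalized volumes are > 0
    lam_safe = np.where(np.abs(lam) > 1e-12, lam, 1e-12)
    u = np.expm1(lam * np.log1p(w)) / lam_safe
    u = np.where(np.abs(lam) > 1e-12, u, np.log1p(w))

    z = (u - mu - beta_s * sex - beta_h * dheight) / sigma
    # log-Jacobian of the YJ transform on the positive branch
    logjac = (lam - 1.0) * np.log1p(w)
    nll = np.mean(0.5 * z * z + logsigma - logjac)
    if not np.isfinite(nll):
        return 1e10
    return nll


def fit_lms(ages, volumes, sex, height, delta: int = 2,
            ref_covariates: tuple[int, float] = (1, 170.0),
            min_n: int = 50, method: str = "", region: str = "",
            max_iter: int = 500) -> NormativeModel:
    """Fit an age-dependent normative distribution by maximum likelihood.

    Parameters
    ----------
    ages, volumes, sex, height : array-like
        Training observations (one reference subject each); volumes in mm^3.
    delta : int
        Degrees of freedom of each curve (L, mu, log sigma).  delta = 2 is
        linear in age; delta >= 3 adds interior knots at age quantiles.
    ref_covariates : (sex, height)
        Covariate values at which curves are displayed (default male,
        170 cm).
    min_n : int
        Minimum number of observations (fitting refused below it).

    Returns
    -------
    NormativeModel
        With fit diagnostics: converged flag, log-likelihood, n, and the
        mean/SD of the training z-scores (recorded, not enforced).
    """
    ages = np.asarray(ages, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    sex = np.asarray(sex, dtype=float)
    height = np.asarray(height, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(volumes) & np.isfinite(sex) & np.isfinite(height)
    ages, volumes, sex, height = ages[ok], volumes[ok], sex[ok], height[ok]
    n = ages.size
    if n < max(min_n, 2):
        raise FitError(f"{method}/{region}: {n} observations < required {max(min_n, 2)}")
    if np.std(volumes) == 0.0:
        raise FitError(f"{method}/{region}: degenerate (constant) volumes")
    if delta < 1:
        raise FitError("delta must be >= 1")

    s0 = float(np.median(volumes))
    if s0 <= 0:
        raise FitError(f"{method}/{region}: non-positive median volume")
    w = volumes / s0
    ref_sex, ref_height = ref_covariates
    dheight = height - ref_height

    age_lo, age_hi = float(np.min(ages)), float(np.max(ages))
    center = 0.5 * (age_lo + age_hi)
    scale = max(0.5 * (age_hi - age_lo), 1e-8)
    s_ages = (ages - center) / scale
    K = delta
    if K == 1:
        knots = np.array([0.0])
    else:
        knots = np.quantile(np.unique(s_ages), np.linspace(0.0, 1.0, K))
        knots = np.unique(knots)
        K = len(knots)
    B = natural_spline_basis(s_ages, knots)

    # init at the identity transform (lambda = 1): least squares for mu,
    # residual SD for sigma, betas at zero
    theta0 = np.zeros(3 * K + 2)
    theta0[0] = LAMBDA_BOUND * np.arctanh(min(1.0 / LAMBDA_BOUND, 0.999))
    coef_mu0, *_ = np.linalg.lstsq(B, w, rcond=None)
    theta0[K:2 * K] = coef_mu0
    resid = w - B @ coef_mu0
    theta0[2 * K] = np.log(max(np.std(resid), 1e-6))

    nll0 = _negloglik(theta0, B, w, sex, dheight, K)
    res = optimize.minimize(
        _negloglik, theta0, args=(B, w, sex, dheight, K),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e9:
        raise FitError(f"{method}/{region}: optimization diverged ({res.message})")
    if res.fun > nll0 + 1e-9:
        raise FitError(f"{method}/{region}: optimizer made no progress ({res.message})")

    theta = res.x
    curves = LMSCurves(
        knots=knots,
        coef_l=theta[:K].copy(),
        coef_mu=theta[K:2 * K].copy(),
        coef_logsigma=theta[2 * K:3 * K].copy(),
        delta=delta,
        age_domain=(age_lo, age_hi),
        age_center=center,
        age_scale=scale,
    )
    model = NormativeModel(
        method=method, region=region, curves=curves,
        beta_sex=float(theta[3 * K]), beta_height=float(theta[3 * K + 1]),
        volume_scale=s0, ref_sex=int(ref_sex), ref_height=float(ref_height),
    )
    z_train = z_score(model, ages, sex, height, volumes)
    model.diagnostics = {
        "converged": bool(res.success),
        "message": str(res.message),
        "n_iter": int(res.nit),
        "loglik": float(-res.fun * n),
        "n": int(n),
        "train_z_mean": float(np.mean(z_train)),
        "train_z_sd": float(np.std(z_train, ddof=1)),
    }
    if not res.success:
        log.warning("fit %s/%s: optimizer stopped without clean convergence (%s)",
                    method, region, res.message)
    return model


# ---------------------------------------------------------------------------
# Evaluation


def z_score(model: NormativeModel, age, sex, height, volume,
            allow_extrapolation: bool = False):
    """z-score of a volume against the model's normative distribution.

    Strictly increasing in volume at fixed covariates.  Evaluating outside
    the fitted age domain raises :class:`ExtrapolationError` unless
    overridden.
    """
    model._check_domain(age, allow_extrapolation)
    c = model.curves
    scalar = np.ndim(age) == 0 and np.ndim(volume) == 0
    age = np.atleast_1d(np.asarray(age, dtype=float))
    lam = c.lambda_at(age)
    u = yeo_johnson(np.atleast_1d(np.asarray(volume, dtype=float)) / model.volume_scale, lam)
    loc = (c.mu_at(age) + model.beta_sex * np.asarray(sex, dtype=float)
           + model.beta_height * (np.asarray(height, dtype=float) - model.ref_height))
    z = (u - loc) / c.sigma_at(age)
    return float(z[0]) if scalar else z


def iso_curve(model: NormativeModel, z: float, age_grid, sex: int | None = None,
              height: float | None = None, allow_extrapolation: bool = False):
    """Volume-vs-age curve at constant z (the centile-like display lines).

    With z = 0 this is the covariate-adjusted median curve.  Raises
    :class:`DomainError` (naming the age) if the requested z falls outside
    the image of the transform somewhere on the grid.
    """
    sex = model.ref_sex if sex is None else sex
    height = model.ref_height if height is None else height
    model._check_domain(age_grid, allow_extrapolation)
    c = model.curves
    age_grid = np.atleast_1d(np.asarray(age_grid, dtype=float))
    lam = c.lambda_at(age_grid)
    x = (c.mu_at(age_grid) + model.beta_sex * sex
         + model.beta_height * (height - model.ref_height) + z * c.sigma_at(age_grid))
    out = np.empty_like(x)
    for i, (xi, li) in enumerate(zip(x, lam)):
        try:
            out[i] = yeo_johnson_inverse(xi, li)
        except DomainError:
            raise DomainError(
                f"iso-curve at z={z} leaves the transform's image at age "
                f"{age_grid[i]:.2f} (lambda={li:.3f})"
            ) from None
    return out * model.volume_scale
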