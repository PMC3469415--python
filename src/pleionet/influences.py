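"""Reparametrize interaction coefficients as directed influences.

The interaction coefficient b12_j of a pair is recast, jointly across
eigentraits, in terms of two phenotype-independent activity changes
(delta_1, delta_2): the inferred change in each variant's activity when
the partner variant is present, weighted per phenotype by that variant's
main effect,

    b12_j = delta_1 * b1_j + delta_2 * b2_j.                 (activity model)

With two eigentraits the 2x2 main-effect matrix B is inverted exactly;
with more, the system is solved by least squares (pseudoinverse) and the
residual norm is reported as a goodness-of-fit diagnostic for the posited
phenotype independence of delta.

The activity changes are then expressed as directed influence
coefficients: writing each variant's change in activity as an influence
coefficient times the partner's total activity (baseline 1 plus its own
change),

    delta_1 = g_{1<-2} (1 + delta_2),   delta_2 = g_{2<-1} (1 + delta_1),

so  g_{1<-2} = delta_1 / (1 + delta_2)  and  g_{2<-1} = delta_2 / (1 + delta_1).

Negative influences are suppression, positive are enhancement.
Uncertainties are propagated from the regression coefficient covariance
by the delta method with analytic Jacobians; a generic finite-difference
`propagate_variance` is provided for arbitrary derived quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivityChange",
    "InfluencePair",
    "solve_activity_changes",
    "influence_coefficients",
    "propagate_variance",
    "gamma_from_delta",
    "delta_from_gamma",
    "interaction_from_activity",
    "batched_influence_stats",
]

#: condition-number bound on the main-effect matrix beyond which the
#: activity solve is flagged invalid (matrix inversion would amplify noise)
COND_MAX = 1e8
#: |1 + delta| tolerance below which an influence direction is undefined
DENOM_TOL = 1e-8
_TINY = np.finfo(float).tiny


def gamma_from_delta(d1: float, d2: float, tol: float = DENOM_TOL):
    """Influence coefficients from activity changes; NaN where undefined."""
    g1 = d1 / (1 + d2) if abs(1 + d2) > tol else np.nan
    g2 = d2 / (1 + d1) if abs(1 + d1) > tol else np.nan
    return g1, g2


def delta_from_gamma(g12: float, g21: float, tol: float = DENOM_TOL):
    """Forward map: activity changes implied by a pair of influences.

    Solves the coupled relations d1 = g12 (1 + d2), d2 = g21 (1 + d1):

        d1 = g12 (1 + g21) / (1 - g12 g21),
        d2 = g21 (1 + g12) / (1 - g12 g21).

    Returns NaN for the degenerate case g12 * g21 = 1.
    """
    det = 1.0 - g12 * g21
    if abs(det) <= tol:
        return np.nan, np.nan
    return g12 * (1 + g21) / det, g21 * (1 + g12) / det


def interaction_from_activity(delta, beta_main):
    """Interaction coefficients implied by activity changes (forward map).

    ``delta`` = (d1, d2); ``beta_main`` is (k, 2) with columns (b1_j, b2_j).
    Returns b12_j = d1 b1_j + d2 b2_j, shape (k,).
    """
    return np.asarray(beta_main, dtype=float) @ np.asarray(delta, dtype=float)


@dataclass
class ActivityChange:
    """Solved activity changes for one pair, with propagated covariance."""

    pair: tuple
    delta: np.ndarray          # (2,)
    cov_delta: np.ndarray      # (2, 2)
    solve_mode: str            # "exact" (k=2) | "least-squares" (k>2)
    residual_norm: float       # ||b12 - B delta||, 0 for exact solve
    condition: float           # condition number of the main-effect matrix
    valid: bool
    jac: np.ndarray = None     # (k, 2, 3) d delta / d (b1_j, b2_j, b12_j)
    cov3: np.ndarray = None    # (k, 3, 3) coefficient covariance blocks


@dataclass
class InfluencePair:
    """Directed influence coefficients between two variants.

    ``gamma[0]`` is the influence of locus 2 on locus 1 (g_{1<-2}) and
    ``gamma[1]`` the influence of locus 1 on locus 2 (g_{2<-1});
    negative = suppression, positive = enhancement.
    """

    pair: tuple
    gamma: np.ndarray          # (2,)
    se: np.ndarray             # (2,)
    stat: np.ndarray           # (2,) |gamma|/SE
    valid: np.ndarray          # (2,) bool
    p_raw: np.ndarray = None
    p_adj: np.ndarray = None


def _influence_core(beta1, beta2, beta12, cov3, cond_max, denom_tol):
    """Vectorized activity solve + influence map over a batch.

    Inputs are (P, k) coefficient arrays and (P, k, 3, 3) covariance
    blocks.  Returns a dict of batched delta, gamma, variances, Jacobians
    and validity masks.  The least-squares solve through the normal
    equations G = B'B coincides with the exact solve at k = 2; its
    Jacobian uses the pseudoinverse differential
    d delta = B+ (db - dB delta) + G^-1 dB' r with residual r.
    """
    P, k = beta1.shape
    B = np.stack([beta1, beta2], axis=2)              # (P, k, 2)
    b = beta12                                        # (P, k)

    s = np.linalg.svd(B, compute_uv=False)            # (P, 2)
    cond = s[:, 0] / np.maximum(s[:, 1], _TINY)
    valid_solve = (cond < cond_max) & np.isfinite(cond) & (s[:, 1] > 0)

    G = np.einsum("pki,pkj->pij", B, B)               # (P, 2, 2)
    detG = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
    safe_det = np.where(np.abs(detG) > _TINY, detG, 1.0)
    Ginv = np.empty_like(G)
    Ginv[:, 0, 0] = G[:, 1, 1] / safe_det
    Ginv[:, 1, 1] = G[:, 0, 0] / safe_det
    Ginv[:, 0, 1] = -G[:, 0, 1] / safe_det
    Ginv[:, 1, 0] = -G[:, 1, 0] / safe_det

    Btb = np.einsum("pki,pk->pi", B, b)
    delta = np.einsum("pij,pj->pi", Ginv, Btb)        # (P, 2)
    r = b - np.einsum("pki,pi->pk", B, delta)         # (P, k)
    resid_norm = np.linalg.norm(r, axis=1)

    # Jacobian of delta w.r.t. each eigentrait's (b1_j, b2_j, b12_j)
    W = np.einsum("pij,pkj->pki", Ginv, B)            # (P, k, 2): G^-1 B_j'
    J = np.empty((P, k, 2, 3))
    J[..., 0] = -delta[:, None, 0:1] * W + r[:, :, None] * Ginv[:, None, :, 0]
    J[..., 1] = -delta[:, None, 1:2] * W + r[:, :, None] * Ginv[:, None, :, 1]
    J[..., 2] = W
    cov_delta = np.einsum("pkat,pktu,pkbu->pab", J, cov3, J)

    d1, d2 = delta[:, 0], delta[:, 1]
    den1, den2 = 1 + d2, 1 + d1
    ok1 = valid_solve & (np.abs(den1) > denom_tol)
    ok2 = valid_solve & (np.abs(den2) > denom_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.stack([d1 / den1, d2 / den2], axis=1)
        # gradient of gamma w.r.t. delta
        Ggrad = np.empty((P, 2, 2))
        Ggrad[:, 0, 0] = 1 / den1
        Ggrad[:, 0, 1] = -d1 / den1**2
        Ggrad[:, 1, 0] = -d2 / den2**2
        Ggrad[:, 1, 1] = 1 / den2
        var_gamma = np.einsum("pai,pij,paj->pa", Ggrad, cov_delta, Ggrad)
    var_gamma = np.where(var_gamma < 0, 0.0, var_gamma)
    gamma_valid = np.stack([ok1, ok2], axis=1)
    gamma = np.where(gamma_valid, gamma, np.nan)
    se_gamma = np.where(gamma_valid, np.sqrt(var_gamma), np.nan)

    return {
        "delta": delta, "cov_delta": cov_delta, "resid_norm": resid_norm,
        "cond": cond, "valid_solve": valid_solve, "jac": J,
        "gamma": gamma, "se_gamma": se_gamma, "gamma_valid": gamma_valid,
    }


def batched_influence_stats(beta1, beta2, beta12, cov3,
                            cond_max=COND_MAX, denom_tol=DENOM_TOL):
    """Influence |gamma|/SE statistics for a batch of (permuted) fits.

    Returns (stat (P, 2), gamma (P, 2), valid (P, 2)); invalid entries NaN.
    """
    core = _influence_core(np.asarray(beta1, float), np.asarray(beta2, float),
                           np.asarray(beta12, float), np.asarray(cov3, float),
                           cond_max, denom_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(core["gamma"]) / core["se_gamma"]
    return stat, core["gamma"], core["gamma_valid"]


def solve_activity_changes(fit, cond_max: float = COND_MAX) -> ActivityChange:
    """Solve the activity model B delta = b12 for one pairwise fit.

    Exact for two eigentraits, least squares for more.  A near-singular
    main-effect matrix (condition number >= ``cond_max``) flags the
    result invalid instead of returning noise-amplified values.
    """
    if not fit.estimable:
        nan2 = np.full(2, np.nan)
        return ActivityChange(fit.pair, nan2, np.full((2, 2), np.nan),
                              "exact", np.nan, np.inf, False)
    core = _influence_core(fit.beta1[None], fit.beta2[None], fit.beta12[None],
                           fit.cov3[None], cond_max, DENOM_TOL)
    mode = "exact" if fit.k == 2 else "least-squares"
    return ActivityChange(
        fit.pair, core["delta"][0], core["cov_delta"][0], mode,
        float(core["resid_norm"][0]), float(core["cond"][0]),
        bool(core["valid_solve"][0]), core["jac"][0], fit.cov3,
    )


def influence_coefficients(ac: ActivityChange, denom_tol: float = DENOM_TOL) -> InfluencePair:
    """Directed influences (and SEs) from solved activity changes."""
    d1, d2 = ac.delta
    den1, den2 = 1 + d2, 1 + d1
    ok = np.array([
        ac.valid and abs(den1) > denom_tol,
        ac.valid and abs(den2) > denom_tol,
    ])
    gamma = np.full(2, np.nan)
    se = np.full(2, np.nan)
    if ok[0]:
        g = np.array([1 / den1, -d1 / den1**2])
        var = max(float(g @ ac.cov_delta @ g), 0.0)
        gamma[0], se[0] = d1 / den1, np.sqrt(var)
    if ok[1]:
        g = np.array([-d2 / den2**2, 1 / den2])
        var = max(float(g @ ac.cov_delta @ g), 0.0)
        gamma[1], se[1] = d2 / den2, np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(gamma) / se
    return InfluencePair(ac.pair, gamma, se, stat, ok)


def propagate_variance(theta, cov, func, rel_step: float = 1e-6) -> float:
    """Delta-method variance of a scalar function of regression coefficients.

    Computes grad f' Sigma grad f with the gradient by central finite
    differences (relative step ``rel_step``); exact for linear maps up to
    rounding.  A numerically negative result is clamped to zero with a
    warning.
    """
    theta = np.asarray(theta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    grad = np.empty_like(theta)
    for i in range(theta.size):
        h = rel_step * max(abs(theta[i]), 1.0)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (func(up) - func(dn)) / (2 * h)
    var = float(grad @ cov @ grad)
    if var < 0:
        warnings.warn("negative delta-method variance clamped to 0", stacklevel=2)
        var = 0.0
    return var
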