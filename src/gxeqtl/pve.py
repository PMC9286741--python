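"""Variance decomposition: total and environment-conditional PVE.

The proportion of phenotypic variance explained by genetics (PVE) is
VarG / VarY where both terms come from the expectation of the sample
variance of Y under the fitted mixed model.  With W_e = Z_e Z_e',

    VarG = rho2 (tr(K)/N - sum(K)/N^2)
         + sum_e Omega_ee (tr(K o W_e)/N - sum(K o W_e)/N^2)
    VarY = VarG + fixed-effect variance of mu + tr(Theta) (N-1)/N^2

and the conditional-on-environment version restricts every trace and sum
through Hadamard products with W_e.  Under EMMA the decomposition reduces
to a single genetic term plus homoscedastic noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.stats

from .gxemm import (VarianceComponents, _as_matrix, _pack, _nll_and_grad,
                    build_covariance)
from .data_io import logger


@dataclass
class PVEEstimate:
    pve: float
    var_G: float
    var_Y: float
    model: str = "gxemm"
    environment: Optional[str] = None
    se: float = np.nan
    age: Optional[int] = None

    def clipped(self) -> float:
        """PVE clipped to [0, 1] for reporting (raw value stays in .pve)."""
        return float(min(max(self.pve, 0.0), 1.0))


def _gen_terms(K, Z):
    """Per-environment genetic coefficients tr(K o W_e)/N - sum(K o W_e)/N^2."""
    Kmat = _as_matrix(K)
    N = Kmat.shape[0]
    diag = np.diag(Kmat)
    out = []
    for e in range(Z.shape[1]):
        z = Z[:, e]
        out.append(float(diag @ z) / N - float(z @ Kmat @ z) / N ** 2)
    return np.array(out)


def _fixed_effect_var(mu, weights=None):
    mu = np.asarray(mu, dtype=float)
    if weights is None:
        N = len(mu)
        return float((mu ** 2).sum()) / N - float(mu.sum()) ** 2 / N ** 2
    Ne = weights.sum()
    return float((mu ** 2) @ weights) / Ne - (float(mu @ weights) / Ne) ** 2


def pve_total(vc: VarianceComponents, K, Z, mu) -> PVEEstimate:
    """Total PVE over the whole sample under the GxEMM decomposition."""
    Kmat = _as_matrix(K)
    Z = np.asarray(Z, dtype=float)
    N = Kmat.shape[0]
    trK = float(np.trace(Kmat))
    sumK = float(Kmat.sum())
    var_G = vc.rho2 * (trK / N - sumK / N ** 2)
    var_G += float(vc.omega @ _gen_terms(K, Z))
    theta = Z @ vc.sigma2
    var_Y = var_G + _fixed_effect_var(mu) + float(theta.sum()) * (N - 1) / N ** 2
    return PVEEstimate(pve=var_G / var_Y, var_G=var_G, var_Y=var_Y, model="gxemm")


def pve_env(vc: VarianceComponents, K, Z, mu, e: int,
            label: Optional[str] = None) -> PVEEstimate:
    """PVE conditional on membership in environment column e."""
    Kmat = _as_matrix(K)
    Z = np.asarray(Z, dtype=float)
    ze = Z[:, e]
    Ne = float(ze.sum())
    if Ne < 2:
        raise ValueError(f"environment {e} has fewer than 2 members")
    diag = np.diag(Kmat)
    var_G = vc.rho2 * (float(diag @ ze) / Ne - float(ze @ Kmat @ ze) / Ne ** 2)
    for ep in range(Z.shape[1]):
        zz = ze * Z[:, ep]
        var_G += vc.omega[ep] * (float(diag @ zz) / Ne
                                 - float(zz @ Kmat @ zz) / Ne ** 2)
    theta = Z @ vc.sigma2
    var_Y = var_G + _fixed_effect_var(mu, weights=ze) \
        + float(theta @ ze) * (Ne - 1) / Ne ** 2
    return PVEEstimate(pve=var_G / var_Y, var_G=var_G, var_Y=var_Y,
                       model="gxemm", environment=label)


def pve_emma(vc: VarianceComponents, K, mu) -> PVEEstimate:
    """PVE under the EMMA reduction (single genetic variance, tied noise)."""
    Kmat = _as_matrix(K)
    N = Kmat.shape[0]
    var_G = vc.rho2 * (float(np.trace(Kmat)) / N - float(Kmat.sum()) / N ** 2)
    theta2 = float(vc.sigma2[0])
    # residual term is tr(theta2 I)(N-1)/N^2, matching the general decomposition
    var_Y = var_G + _fixed_effect_var(mu) + N * theta2 * (N - 1) / N ** 2
    return PVEEstimate(pve=var_G / var_Y, var_G=var_G, var_Y=var_Y, model="emma")


# ---------------------------------------------------------------------------
# uncertainty
# ---------------------------------------------------------------------------

def _observed_information(vc, Y, X, K, Z, h=1e-5):
    """Numerical Hessian of the negative profile log likelihood via central
    differences of the analytic gradient."""
    Kmat = _as_matrix(K)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(Y):
        X = X.T
    theta0 = _pack(vc.sigma2, vc.rho2, vc.omega)
    scale = np.maximum(np.abs(theta0), 1e-3)
    p = len(theta0)
    H = np.zeros((p, p))
    for i in range(p):
        step = h * scale[i]
        tp, tm = theta0.copy(), theta0.copy()
        tp[i] += step
        tm[i] -= step
        _, gp = _nll_and_grad(tp, np.asarray(Y, float), X, Kmat, np.asarray(Z, float))
        _, gm = _nll_and_grad(tm, np.asarray(Y, float), X, Kmat, np.asarray(Z, float))
        H[i] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def pve_standard_error(vc: VarianceComponents, Y, X, K, Z, mu,
                       environment: Optional[int] = None,
                       model: str = "gxemm") -> float:
    """Delta-method standard error of a PVE estimate.

    Propagates the inverse observed information of (sigma2, rho2, Omega)
    through the PVE algebra; the PVE gradient is taken numerically since the
    decomposition is cheap closed-form algebra.  Returns NaN with a warning
    when the information matrix is singular.
    """
    Z = np.asarray(Z, dtype=float)
    E = Z.shape[1]
    info = _observed_information(vc, Y, X, K, Z)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        logger.warning("singular observed information; PVE SE reported missing")
        return np.nan

    def pve_of(theta):
        v = VarianceComponents(vc.alpha, float(theta[E]), theta[E + 1:],
                               theta[:E], constrained=False)
        if model == "emma":
            return pve_emma(v, K, mu).pve
        if environment is None:
            return pve_total(v, K, Z, mu).pve
        return pve_env(v, K, Z, mu, environment).pve

    theta0 = _pack(vc.sigma2, vc.rho2, vc.omega)
    g = np.zeros_like(theta0)
    for i in range(len(theta0)):
        step = 1e-5 * max(abs(theta0[i]), 1e-3)
        tp, tm = theta0.copy(), theta0.copy()
        tp[i] += step
        tm[i] -= step
        g[i] = (pve_of(tp) - pve_of(tm)) / (2 * step)
    var = float(g @ cov @ g)
    if var < 0:
        logger.warning("negative delta-method variance; PVE SE reported missing")
        return np.nan
    return float(np.sqrt(var))


def pve_bootstrap_se(vc, K, Z, mu, n_boot: int = 100, seed: int = 0,
                     model: str = "gxemm") -> float:
    """Parametric-bootstrap alternative to the delta-method SE (slow)."""
    from .gxemm import fit_gxemm, fit_emma

    rng = np.random.default_rng(seed)
    Lam = build_covariance(vc, K, Z)
    L = np.linalg.cholesky(Lam)
    X = np.ones((Lam.shape[0], 1))
    vals = []
    for _ in range(n_boot):
        Yb = np.asarray(mu) + L @ rng.standard_normal(Lam.shape[0])
        if model == "emma":
            vb = fit_emma(Yb, X, K, n_starts=1, seed=int(rng.integers(2 ** 31)))
            vals.append(pve_emma(vb, K, mu).pve)
        else:
            vb = fit_gxemm(Yb, X, K, Z, n_starts=1, seed=int(rng.integers(2 ** 31)))
            vals.append(pve_total(vb, K, Z, mu).pve)
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# kinship-covariance diagnostic
# ---------------------------------------------------------------------------

def kinship_covariance_diagnostic(weights, K, diet_labels, threshold: float = 0.2
                                  ) -> dict:
    """Within-diet separation of phenotypic pair similarity by kinship.

    For each diet, every pair of mice gets the product of the two mice's
    deviations from the diet-mean weight (a pairwise covariance statistic);
    pairs are partitioned into high kinship (K_mn > threshold) and low
    kinship, and the two distributions are compared with a two-sided
    Mann-Whitney U test (normal approximation, tie-corrected).  AUC is the
    standard transform U / (n1 n2).

    Returns {diet: {"p": .., "auc": .., "n_high": .., "n_low": ..}}; diets
    with an empty kinship group are skipped with a warning.
    """
    weights = np.asarray(weights, dtype=float)
    Kmat = _as_matrix(K)
    diet_labels = np.asarray(diet_labels)
    out = {}
    for diet in pd_unique_preserve(diet_labels):
        idx = np.flatnonzero(diet_labels == diet)
        dev = weights[idx] - weights[idx].mean()
        iu, ju = np.triu_indices(len(idx), k=1)
        stat = dev[iu] * dev[ju]
        kin = Kmat[np.ix_(idx, idx)][iu, ju]
        high = stat[kin > threshold]
        low = stat[kin <= threshold]
        if len(high) < 2 or len(low) < 2:
            logger.warning("diet %s: empty/undersized kinship group; diagnostic skipped",
                           diet)
            continue
        res = scipy.stats.mannwhitneyu(high, low, alternative="two-sided",
                                       method="asymptotic")
        out[str(diet)] = {
            "p": float(res.pvalue),
            "auc": float(res.statistic) / (len(high) * len(low)),
            "n_high": int(len(high)),
            "n_low": int(len(low)),
        }
    return out


def pd_unique_preserve(values):
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
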