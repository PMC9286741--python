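"""Gene x environment mixed model (GxEMM) and the EMMA special case.

The phenotype vector ``Y`` over N mice is modelled as

    Y = X alpha + sum_v G_v beta_v + sum_{v,e} G_v Z_e gamma_ve + eps

with normal priors ``beta_v ~ N(0, rho2 / V)`` on environment-independent
polygenic effects, ``gamma_v. ~ N(0, Omega / V)`` (diagonal Omega) on
polygenic genotype-environment interaction effects, and heteroscedastic
noise ``eps ~ N(0, Theta)`` with ``Theta_nn = sum_e Z_ne sigma2_e``.
Integrating out the random effects gives

    Y ~ N(mu, Lambda),
    mu     = X alpha,
    Lambda = Theta + rho2 K + sum_e Omega_ee (K o Z_e Z_e^T),

where K is the kinship matrix and ``o`` the Hadamard product.  EMMA is the
special case with a single environment column of ones and Omega fixed at
zero (homoscedastic noise, one genetic variance).

Fixed effects are profiled out by generalised least squares and the profile
likelihood is maximised over the variance components by bounded
quasi-Newton ascent with analytic gradients.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize

logger = logging.getLogger("gxeqtl")

#: Canonical diversity-outbred founder letter code A-H.
FOUNDERS = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
N_FOUNDERS = len(FOUNDERS)


# ---------------------------------------------------------------------------
# genotype containers
# ---------------------------------------------------------------------------

@dataclass
class FounderProbMatrix:
    """Founder-of-origin probabilities, one 8-vector per mouse per marker.

    ``probs`` has shape (N, V, 8); each (mouse, marker) slice sums to one
    (the probability that the two alleles at the marker descend from each
    of the eight DO founder lines).  ``marker_map`` carries marker_id,
    chrom and pos_bp columns, one row per marker, in column order of
    ``probs``.
    """

    probs: np.ndarray
    marker_map: pd.DataFrame
    mouse_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != N_FOUNDERS:
            raise ValueError("probs must have shape (N, V, 8)")
        if len(self.marker_map) != self.probs.shape[1]:
            raise ValueError("marker_map length does not match marker count")

    @property
    def n_mice(self) -> int:
        return self.probs.shape[0]

    @property
    def n_markers(self) -> int:
        return self.probs.shape[1]

    def subset_markers(self, mask: np.ndarray) -> "FounderProbMatrix":
        return FounderProbMatrix(
            self.probs[:, mask, :],
            self.marker_map.loc[np.asarray(mask)].reset_index(drop=True),
            self.mouse_ids,
        )


@dataclass
class DosageMatrix:
    """Expected minor/alternate allele counts in [0, 2], mice x variants."""

    dosages: np.ndarray
    marker_map: pd.DataFrame
    mouse_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (mice x variants)")
        if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
            self.dosages, initial=0.0
        ) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_mice(self) -> int:
        return self.dosages.shape[0]


@dataclass
class KinshipMatrix:
    """N x N genetic similarity between mice.

    In ``founder_prob`` mode ``K_mn = (1/V) sum_v G_mv . G_nv`` over
    founder-probability 8-vectors, so diagonal entries lie in [1/8, 1].
    In ``dosage`` mode it is the usual standardized-dosage cross product.
    ``excluded_chrom`` records a leave-one-chromosome-out (LOCO) kinship.
    """

    K: np.ndarray
    mode: str
    excluded_chrom: Optional[str] = None

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")


def compute_kinship(G, mode: Optional[str] = None,
                    exclude_chrom: Optional[str] = None) -> KinshipMatrix:
    """Kinship from founder probabilities or allele dosages.

    Parameters
    ----------
    G : FounderProbMatrix or DosageMatrix
    mode : "founder_prob" | "dosage", inferred from the type of G if None.
    exclude_chrom : drop every marker on this chromosome (LOCO kinship).
    """
    if mode is None:
        mode = "founder_prob" if isinstance(G, FounderProbMatrix) else "dosage"
    keep = np.ones(len(G.marker_map), dtype=bool)
    if exclude_chrom is not None:
        keep = (G.marker_map["chrom"].astype(str) != str(exclude_chrom)).to_numpy()
    if keep.sum() == 0:
        raise ValueError(
            f"excluding chromosome {exclude_chrom!r} leaves no markers"
        )
    if mode == "founder_prob":
        P = G.probs[:, keep, :]
        V = P.shape[1]
        K = np.tensordot(P, P, axes=([1, 2], [1, 2])) / V
    elif mode == "dosage":
        D = G.dosages[:, keep]
        # per-marker allele-frequency centering and unit-variance scaling
        mean = D.mean(axis=0)
        sd = D.std(axis=0)
        poly = sd > 0
        if poly.sum() == 0:
            raise ValueError("no polymorphic markers for dosage kinship")
        Ds = (D[:, poly] - mean[poly]) / sd[poly]
        K = Ds @ Ds.T / poly.sum()
    else:
        raise ValueError(f"unknown kinship mode {mode!r}")
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, mode=mode, excluded_chrom=exclude_chrom)


# ---------------------------------------------------------------------------
# variance components and model covariance
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Fitted (or specified) parameters of the mixed model.

    alpha : fixed-effect coefficients (grams), in the column order of X
    rho2 : environment-independent polygenic variance
    omega : per-environment interaction variances, diag(Omega)
    sigma2 : per-environment residual noise variances
    """

    alpha: np.ndarray
    rho2: float
    omega: np.ndarray
    sigma2: np.ndarray
    constrained: bool = True
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0
    message: str = ""

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if self.constrained:
            if self.rho2 < -1e-12 or (self.omega < -1e-12).any() or (
                self.sigma2 < -1e-12
            ).any():
                raise ValueError("constrained components must be non-negative")


def build_covariance(vc: VarianceComponents, K, Z) -> np.ndarray:
    """Marginal phenotype covariance Lambda = Theta + rho2 K + sum_e O_ee K o W_e."""
    K = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    Z = np.asarray(Z, dtype=float)
    theta = Z @ vc.sigma2
    Lam = vc.rho2 * K
    for e in range(Z.shape[1]):
        if vc.omega[e] != 0.0:
            Lam = Lam + vc.omega[e] * (K * np.outer(Z[:, e], Z[:, e]))
    Lam = Lam + np.diag(theta)
    return Lam


def _as_matrix(K):
    return K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _profile_pieces(Lam, Y, X):
    """Cholesky-based GLS pieces for the profile likelihood.

    Returns (cho_factor, logdet, alpha_hat, cov_alpha, PY, yPy).
    Raises np.linalg.LinAlgError if Lambda is not positive definite and
    ValueError if the fixed-effect design is collinear.
    """
    c, low = sla.cho_factor(Lam, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Li_Y = sla.cho_solve((c, low), Y, check_finite=False)
    Li_X = sla.cho_solve((c, low), X, check_finite=False)
    XtLiX = X.T @ Li_X
    XtLiY = X.T @ Li_Y
    try:
        cov_alpha = np.linalg.inv(XtLiX)
    except np.linalg.LinAlgError as err:
        raise ValueError("collinear fixed-effect design (X' Lambda^-1 X singular)") from err
    alpha = cov_alpha @ XtLiY
    PY = Li_Y - Li_X @ alpha
    yPy = float(Y @ PY)
    return (c, low), logdet, alpha, cov_alpha, PY, yPy


def neg_log_likelihood(vc: VarianceComponents, Y, X, K, Z) -> float:
    """Negative profile log likelihood -L_alpha_hat at the given components."""
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != Y.shape[0]:
        X = X.T
    Lam = build_covariance(vc, K, Z)
    _, logdet, _, _, _, yPy = _profile_pieces(Lam, Y, X)
    N = Y.shape[0]
    ll = -0.5 * N * np.log(2 * np.pi) - 0.5 * logdet - 0.5 * yPy
    return -ll


def gls_fixed_effects(vc: VarianceComponents, Y, X, K, Z):
    """GLS estimate of the fixed effects and its covariance at fixed components.

    Returns (alpha_hat, cov_alpha) where cov_alpha = (X' Lambda^-1 X)^-1.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Lam = build_covariance(vc, K, Z)
    _, _, alpha, cov_alpha, _, _ = _profile_pieces(Lam, Y, X)
    return alpha, cov_alpha


def _pack(sigma2, rho2, omega):
    return np.concatenate([np.atleast_1d(sigma2), [rho2], np.atleast_1d(omega)])


def _unpack(theta, E):
    return theta[:E], theta[E], theta[E + 1:]


def _nll_and_grad(theta, Y, X, Kmat, Z, penalty=1e10):
    """Negative profile log likelihood and its gradient in one pass.

    Gradient components follow the trace/quadratic-form identities for the
    profile likelihood: d L / d v = -1/2 tr(Lambda^-1 dLambda) + 1/2 Y' P dLambda P Y.
    """
    E = Z.shape[1]
    sigma2, rho2, omega = _unpack(theta, E)
    vc = VarianceComponents(np.zeros(X.shape[1]), rho2, omega, sigma2,
                            constrained=False)
    Lam = build_covariance(vc, Kmat, Z)
    N = Y.shape[0]
    try:
        (c, low), logdet, alpha, cov_alpha, PY, yPy = _profile_pieces(Lam, Y, X)
    except (np.linalg.LinAlgError, ValueError):
        return penalty, np.zeros_like(theta)
    nll = 0.5 * (N * np.log(2 * np.pi) + logdet + yPy)

    # explicit inverse needed once per evaluation for the trace terms
    Linv = sla.cho_solve((c, low), np.eye(N), check_finite=False)
    M = Linv * Kmat  # elementwise; sum over rows/cols gives the traces below
    grad = np.empty_like(theta)
    # d/d sigma2_e : tr(Lambda^-1 I_Ze) and (PY)' I_Ze (PY)
    diagL = np.diag(Linv)
    PY2 = PY ** 2
    for e in range(E):
        z = Z[:, e]
        grad[e] = -(-0.5 * float(diagL @ z) + 0.5 * float(PY2 @ z))
    # d/d rho2 : tr(Lambda^-1 K) = sum(Lambda^-1 o K) by symmetry
    grad[E] = -(-0.5 * float(M.sum()) + 0.5 * float(PY @ (Kmat @ PY)))
    # d/d Omega_ee : tr(Lambda^-1 K_e) = Ze' (Lambda^-1 o K) Ze
    for e in range(E):
        z = Z[:, e]
        tr_e = float(z @ (M @ z))
        zPY = z * PY
        quad_e = float(zPY @ (Kmat @ zPY))
        grad[E + 1 + e] = -(-0.5 * tr_e + 0.5 * quad_e)
    return nll, grad


def _initial_points(Y, X, E, n_starts, rng):
    """Heuristic plus randomized starting points for the variance scale."""
    resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
    v = max(float(np.var(resid)), 1e-8)
    starts = [_pack(np.full(E, 0.5 * v), 0.25 * v, np.full(E, 0.25 * v))]
    for _ in range(n_starts - 1):
        scales = rng.uniform(0.05, 2.0, size=2 * E + 1)
        starts.append(_pack(np.full(E, v), 0.5 * v, np.full(E, 0.5 * v)) * scales)
    return starts


def fit_gxemm(Y, X, K, Z, constrained: bool = True, seed: int = 0,
              n_starts: int = 3, fix_omega_zero: bool = False,
              gtol: float = 1e-6, max_iter: int = 500) -> VarianceComponents:
    """Maximum profile likelihood fit of the GxEMM variance components.

    Parameters
    ----------
    Y, X : phenotype vector and fixed-effect design (N and N x C)
    K : kinship (KinshipMatrix or array)
    Z : N x E binary environment design
    constrained : bound all variance components below by zero
    seed, n_starts : multi-start control; the best likelihood is kept
    fix_omega_zero : pin all interaction variances at zero (EMMA-style)

    Non-convergence is flagged on the returned components rather than
    raised, with the optimizer message attached.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != Y.shape[0]:
        X = X.T
    Z = np.asarray(Z, dtype=float)
    Kmat = _as_matrix(K)
    N, E = Z.shape
    if N <= X.shape[1]:
        raise ValueError("need more samples than fixed effects")
    rng = np.random.default_rng(seed)

    lo = 0.0 if constrained else -np.inf
    bounds = [(1e-9, None)] * E + [(lo, None)] + [(lo, None)] * E
    if fix_omega_zero:
        bounds[E + 1:] = [(0.0, 0.0)] * E

    best = None
    for x0 in _initial_points(Y, X, E, n_starts, rng):
        if fix_omega_zero:
            x0 = x0.copy()
            x0[E + 1:] = 0.0
        res = scipy.optimize.minimize(
            _nll_and_grad, x0, args=(Y, X, Kmat, Z), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    sigma2, rho2, omega = _unpack(best.x, E)
    # clip the tiny positive floor on sigma2 back to an exact zero boundary
    sigma2 = np.where(sigma2 <= 2e-9, 0.0, sigma2)
    vc = VarianceComponents(
        alpha=np.zeros(X.shape[1]), rho2=float(rho2), omega=omega,
        sigma2=sigma2, constrained=constrained, loglik=-float(best.fun),
        converged=bool(best.success), n_iter=int(best.nit),
        message=str(best.message),
    )
    if (sigma2 > 0).any():
        alpha, _ = gls_fixed_effects(vc, Y, X, K, Z)
        vc.alpha = alpha
    if not vc.converged:
        logger.warning("fit_gxemm did not converge: %s", vc.message)
    return vc


def gradients(vc: VarianceComponents, Y, X, K, Z) -> dict:
    """Analytic gradients of the profile log likelihood L_alpha_hat.

    Returns a dict with keys "sigma2" (length E), "rho2" (scalar) and
    "omega" (length E), the partial derivatives with respect to the noise
    variances, the shared genetic variance, and the interaction variances.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != Y.shape[0]:
        X = X.T
    Z = np.asarray(Z, dtype=float)
    Kmat = _as_matrix(K)
    theta = _pack(vc.sigma2, vc.rho2, vc.omega)
    nll, grad = _nll_and_grad(theta, Y, X, Kmat, Z)
    if nll >= 1e10:
        raise np.linalg.LinAlgError("Lambda not positive definite at vc")
    g = -grad  # gradient of the log likelihood itself
    E = Z.shape[1]
    return {"sigma2": g[:E], "rho2": float(g[E]), "omega": g[E + 1:]}


def fit_emma(Y, X, K, constrained: bool = True, seed: int = 0,
             n_starts: int = 3) -> VarianceComponents:
    """EMMA fit: single genetic variance rho2 and homoscedastic noise theta2.

    Implemented as the E = 1 special case of the GxEMM likelihood with the
    interaction variance pinned at zero, so Lambda = theta2 I + rho2 K.
    """
    N = np.asarray(Y).shape[0]
    Z1 = np.ones((N, 1))
    return fit_gxemm(Y, X, K, Z1, constrained=constrained, seed=seed,
                     n_starts=n_starts, fix_omega_zero=True)
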