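"""Genome-wide additive and genotype-diet interaction scans.

For each focal variant s the additive test compares

    H1: Y ~ N(X alpha + phi_s G_s, Lambda_s)   vs   H0: phi_s = 0,

and the interaction test additionally frees per-diet effects chi_se of the
focal variant (phi_s free in both models), where Lambda_s uses the
leave-one-chromosome-out (LOCO) kinship of the focal variant's chromosome.
The statistic is the natural-log likelihood ratio Phi; LOD = Phi / ln 10.
Founder-of-origin genotypes enter as 8 founder columns under a sum-to-zero
contrast so the intercept stays identifiable.

By default the variance components are estimated once per (age, chromosome)
under the no-focal-variant model and held fixed while the focal fixed
effects are profiled across variants; ``refit_per_variant=True`` re-fits
them for every variant (exact but slow).

Significance comes from sequential permutations: permute phenotype labels,
recompute Phi, and stop once C_stop exceedances are seen (or M_max
permutations are spent); the p-value is drawn uniformly from
[C/M, (C+1)/(M+1)].  Genome-wide thresholds divide alpha by the effective
number of tests, the count of top LD-matrix eigenvalues explaining a target
fraction of marker variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .gxemm import (FounderProbMatrix, N_FOUNDERS, _as_matrix,
                    build_covariance, compute_kinship, fit_gxemm)

LN10 = math.log(10.0)

#: Sum-to-zero contrast (8 founders -> 7 columns): founder f vs the mean.
_CONTRAST = sla.helmert(N_FOUNDERS).T  # shape (8, 7), columns sum to zero


@dataclass
class AssociationResult:
    variant_id: str
    chrom: str
    pos: int
    age: Optional[int]
    test: str                      # "additive" | "interaction"
    llr: float                     # Phi, natural log
    lod: float                     # Phi / ln 10
    phi: np.ndarray                # founder (or allele) effects, grams
    chi: Optional[np.ndarray] = None  # per-diet interaction effects
    p_value: float = np.nan
    exceed_count: int = 0          # C_s
    perm_count: int = 0            # M_s
    monomorphic: bool = False


@dataclass
class SignificanceThresholds:
    alpha: float
    meff_90: int
    meff_995: int
    suggestive: float    # interaction tests only
    significant: float
    stringent: float

    def __post_init__(self):
        if not (self.stringent <= self.significant <= self.suggestive):
            raise ValueError("thresholds must be ordered stringent<=significant<=suggestive")


def founder_contrast(probs_v: np.ndarray) -> np.ndarray:
    """Encode an (N, 8) founder-probability slice as N x 7 sum-to-zero columns."""
    return probs_v @ _CONTRAST


def variant_columns(G, v: int) -> np.ndarray:
    """Fixed-effect columns for variant v: founder contrasts or a dosage column."""
    if isinstance(G, FounderProbMatrix):
        return founder_contrast(G.probs[:, v, :])
    return np.asarray(G.dosages[:, v: v + 1], dtype=float)


def _is_monomorphic(cols: np.ndarray, tol: float = 1e-10) -> bool:
    return bool((cols.std(axis=0) < tol).all())


class _GLSWorkspace:
    """Profile-likelihood evaluations at fixed covariance Lambda.

    With Lambda fixed, max_alpha log L for design W differs from the null
    design only through b' (W' Lambda^-1 W)^-1 b with b = W' Lambda^-1 Y, so
    likelihood ratios over nested fixed-effect designs need no further
    factorizations per variant.
    """

    def __init__(self, Lam: np.ndarray):
        self.chol = sla.cho_factor(Lam, lower=True, check_finite=False)

    def solve(self, B: np.ndarray) -> np.ndarray:
        return sla.cho_solve(self.chol, B, check_finite=False)

    def quad_form_gain(self, Y, W) -> tuple[float, np.ndarray, np.ndarray]:
        """Returns (b' A^-1 b, coefficients, cov) for design W."""
        LiW = self.solve(W)
        A = W.T @ LiW
        b = LiW.T @ Y
        Ainv = np.linalg.pinv(A)
        coef = Ainv @ b
        return float(b @ coef), coef, Ainv


def _loglik_ratio(ws: _GLSWorkspace, Y, X_null: np.ndarray, X_alt: np.ndarray):
    q0, _, _ = ws.quad_form_gain(Y, X_null)
    q1, coef, cov = ws.quad_form_gain(Y, X_alt)
    llr = max(0.5 * (q1 - q0), 0.0)
    return llr, coef, cov


def _fit_null_vc(Y, X, K, Z, seed, n_starts=2, vc=None):
    if vc is not None:
        return vc
    return fit_gxemm(Y, X, K, Z, seed=seed, n_starts=n_starts)


def _loco_covariance(G, Y, X, Z, chrom, vc=None, K_loco=None, seed=0):
    K = K_loco if K_loco is not None else compute_kinship(G, exclude_chrom=chrom)
    vc = _fit_null_vc(Y, X, K, Z, seed=seed, vc=vc)
    Lam = build_covariance(vc, K, Z)
    return vc, _GLSWorkspace(Lam)


def scan_additive(Y, G, X, Z, age: Optional[int] = None,
                  K_loco: Optional[dict] = None,
                  vc_by_chrom: Optional[dict] = None,
                  refit_per_variant: bool = False,
                  seed: int = 0) -> list[AssociationResult]:
    """Additive association scan across all variants in G.

    K_loco maps chromosome name -> LOCO KinshipMatrix (computed from G if
    absent); vc_by_chrom maps chromosome -> pre-fit VarianceComponents
    (fitted under the no-focal-variant model if absent).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(Y):
        X = X.T
    Z = np.asarray(Z, dtype=float)
    results = []
    chroms = G.marker_map["chrom"].astype(str)
    for chrom in chroms.unique():
        vc0 = (vc_by_chrom or {}).get(chrom)
        Kc = (K_loco or {}).get(chrom)
        vc, ws = _loco_covariance(G, Y, X, Z, chrom, vc=vc0, K_loco=Kc, seed=seed)
        for v in np.flatnonzero((chroms == chrom).to_numpy()):
            mk = G.marker_map.iloc[v]
            cols = variant_columns(G, v)
            if _is_monomorphic(cols):
                results.append(AssociationResult(
                    str(mk["marker_id"]) if "marker_id" in mk else f"v{v}",
                    chrom, int(mk["pos_bp"] if "pos_bp" in mk else mk["pos"]),
                    age, "additive", 0.0, 0.0,
                    np.zeros(cols.shape[1]), monomorphic=True))
                continue
            if refit_per_variant:
                llr, coef, cov = _refit_llr(Y, X, np.hstack([X, cols]),
                                            Kc or compute_kinship(G, exclude_chrom=chrom),
                                            Z, seed)
            else:
                llr, coef, cov = _loglik_ratio(ws, Y, X, np.hstack([X, cols]))
            phi = coef[X.shape[1]:]
            results.append(AssociationResult(
                str(mk["marker_id"]) if "marker_id" in mk else f"v{v}",
                chrom, int(mk["pos_bp"] if "pos_bp" in mk else mk["pos"]),
                age, "additive", llr, llr / LN10, phi))
    return results


def _refit_llr(Y, X_null, X_alt, K, Z, seed):
    fit0 = fit_gxemm(Y, X_null, K, Z, seed=seed, n_starts=1)
    fit1 = fit_gxemm(Y, X_alt, K, Z, seed=seed, n_starts=1)
    llr = max(fit1.loglik - fit0.loglik, 0.0)
    from .gxemm import gls_fixed_effects
    coef, cov = gls_fixed_effects(fit1, Y, X_alt, K, Z)
    return llr, coef, cov


def interaction_columns(cols: np.ndarray, Z_diet: np.ndarray) -> np.ndarray:
    """Focal-variant x diet interaction columns, first diet as reference."""
    parts = [cols * Z_diet[:, e:e + 1] for e in range(1, Z_diet.shape[1])]
    return np.hstack(parts)


def scan_interaction(Y, G, X, Z, Z_diet, age: Optional[int] = None,
                     K_loco: Optional[dict] = None,
                     vc_by_chrom: Optional[dict] = None,
                     refit_per_variant: bool = False,
                     seed: int = 0) -> list[AssociationResult]:
    """Genotype-diet interaction scan: chi_se free vs chi_se = 0, phi_s free.

    Z_diet holds the diet columns only (the environments of interest);
    generations stay in the random effects through Z.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(Y):
        X = X.T
    Z = np.asarray(Z, dtype=float)
    Z_diet = np.asarray(Z_diet, dtype=float)
    results = []
    chroms = G.marker_map["chrom"].astype(str)
    for chrom in chroms.unique():
        vc0 = (vc_by_chrom or {}).get(chrom)
        Kc = (K_loco or {}).get(chrom)
        vc, ws = _loco_covariance(G, Y, X, Z, chrom, vc=vc0, K_loco=Kc, seed=seed)
        for v in np.flatnonzero((chroms == chrom).to_numpy()):
            mk = G.marker_map.iloc[v]
            vid = str(mk["marker_id"]) if "marker_id" in mk else f"v{v}"
            pos = int(mk["pos_bp"] if "pos_bp" in mk else mk["pos"])
            cols = variant_columns(G, v)
            if _is_monomorphic(cols):
                results.append(AssociationResult(
                    vid, chrom, pos, age, "interaction", 0.0, 0.0,
                    np.zeros(cols.shape[1]), monomorphic=True))
                continue
            inter = interaction_columns(cols, Z_diet)
            X_null = np.hstack([X, cols])
            X_alt = np.hstack([X, cols, inter])
            if refit_per_variant:
                llr, coef, cov = _refit_llr(Y, X_null, X_alt,
                                            Kc or compute_kinship(G, exclude_chrom=chrom),
                                            Z, seed)
            else:
                llr, coef, cov = _loglik_ratio(ws, Y, X_null, X_alt)
            k = X.shape[1]
            phi = coef[k:k + cols.shape[1]]
            chi = coef[k + cols.shape[1]:]
            results.append(AssociationResult(vid, chrom, pos, age, "interaction",
                                             llr, llr / LN10, phi, chi=chi))
    return results


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def permutation_statistics(Y, X_null, X_alt, ws: _GLSWorkspace, rng,
                           scheme: str = "literal", strata=None,
                           batch: int = 256):
    """Infinite stream of permutation likelihood-ratio statistics.

    Phenotype labels are permuted (unrestricted by default, matching the
    exchangeability assumption; scheme="within" permutes within the given
    strata to respect the design) and Phi is recomputed at the fixed null
    covariance.  Only O(N x columns) work per permutation is needed because
    Lambda^-1 X_null / X_alt are precomputed.
    """
    Y = np.asarray(Y, dtype=float)
    N = len(Y)
    Li0 = ws.solve(X_null)
    Li1 = ws.solve(X_alt)
    A0inv = np.linalg.pinv(X_null.T @ Li0)
    A1inv = np.linalg.pinv(X_alt.T @ Li1)
    if scheme == "within":
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
    while True:
        Yp = np.empty((batch, N))
        for b in range(batch):
            if scheme == "literal":
                Yp[b] = Y[rng.permutation(N)]
            elif scheme == "within":
                row = Y.copy()
                for g in groups:
                    row[g] = row[g[rng.permutation(len(g))]]
                Yp[b] = row
            else:
                raise ValueError(f"unknown permutation scheme {scheme!r}")
        B0 = Yp @ Li0  # batch x k0
        B1 = Yp @ Li1
        q0 = np.einsum("bi,ij,bj->b", B0, A0inv, B0)
        q1 = np.einsum("bi,ij,bj->b", B1, A1inv, B1)
        for phi in np.maximum(0.5 * (q1 - q0), 0.0):
            yield float(phi)


def sequential_permutation_p(phi_obs: float, perm_stats: Iterable,
                             c_stop: int = 10, m_max: int = 10 ** 8,
                             seed: Optional[int] = None, rng=None,
                             fixed_m: Optional[int] = None,
                             method: str = "beta"):
    """Sequential permutation p-value for an observed statistic.

    Draw permutation statistics until ``c_stop`` of them meet or exceed
    phi_obs (ties count as exceedances) or ``m_max`` permutations are
    spent.  On early stopping the randomized p-value is, by default
    (``method="beta"``), a draw from Beta(C, M - C + 1) - the exact
    construction whose null distribution is uniform under negative-binomial
    stopping; ``method="interval"`` draws uniformly from the approximating
    interval [C/M, (C+1)/(M+1)] instead.  When the permutation budget is
    exhausted (and in fixed-M mode) the p-value is the standard
    (C+1)/(M+1).  Returns (p, C, M).
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    if method not in ("beta", "interval"):
        raise ValueError(f"unknown p-value method {method!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    it = iter(perm_stats)
    C = 0
    M = 0
    limit = fixed_m if fixed_m is not None else m_max
    while M < limit:
        stat = next(it)
        M += 1
        if stat >= phi_obs:
            C += 1
            if fixed_m is None and C >= c_stop:
                if method == "beta":
                    p = float(rng.beta(C, M - C + 1))
                else:
                    p = float(rng.uniform(C / M, (C + 1) / (M + 1)))
                return max(p, 1e-300), C, M
    p = (C + 1) / (M + 1)
    return float(p), C, M


# ---------------------------------------------------------------------------
# genome-wide significance thresholds
# ---------------------------------------------------------------------------

def _marker_matrix(G) -> tuple[np.ndarray, np.ndarray]:
    """Flatten genotypes to an observations x markers matrix plus chrom labels."""
    chroms = G.marker_map["chrom"].astype(str).to_numpy()
    if isinstance(G, FounderProbMatrix):
        N, V, F = G.probs.shape
        M = G.probs.transpose(0, 2, 1).reshape(N * F, V)
    else:
        M = np.asarray(G.dosages, dtype=float)
    return M, chroms


def effective_tests(G, variance_fraction: float) -> int:
    """Effective number of tests: count of top LD-matrix eigenvalues whose
    sum reaches the given fraction of total marker variance (per-chromosome
    eigenvalues pooled genome-wide)."""
    if len(G.marker_map) < 2:
        raise ValueError("need >= 2 markers")
    M, chroms = _marker_matrix(G)
    eigs = []
    for c in pd.unique(chroms):
        block = M[:, chroms == c]
        sd = block.std(axis=0)
        block = block[:, sd > 1e-12]
        if block.shape[1] == 0:
            continue
        R = np.corrcoef(block, rowvar=False)
        R = np.atleast_2d(R)
        w = np.linalg.eigvalsh(R)
        eigs.append(np.clip(w, 0.0, None))
    if not eigs:
        return 1  # all markers degenerate
    w = np.sort(np.concatenate(eigs))[::-1]
    total = w.sum()
    csum = np.cumsum(w)
    return int(np.searchsorted(csum, variance_fraction * total - 1e-12) + 1)


def effective_tests_threshold(G, alpha: float = 0.05) -> SignificanceThresholds:
    """Bonferroni thresholds from the effective number of tests.

    'significant' divides alpha by the eigenvalue count explaining 90% of
    marker variance, 'stringent' by the count explaining 99.5%; the
    suggestive tier (interaction tests only) is 10x the significant cutoff.
    """
    meff_90 = effective_tests(G, 0.90)
    meff_995 = effective_tests(G, 0.995)
    significant = alpha / meff_90
    stringent = alpha / meff_995
    return SignificanceThresholds(alpha=alpha, meff_90=meff_90,
                                  meff_995=meff_995,
                                  suggestive=10 * significant,
                                  significant=significant,
                                  stringent=stringent)


def classify_significance(p_value: float, test: str,
                          thresholds: SignificanceThresholds) -> str:
    """Tier labels: '***' stringent, '**' significant, '*' suggestive.

    The suggestive tier is applied to interaction tests only."""
    if p_value <= thresholds.stringent:
        return "***"
    if p_value <= thresholds.significant:
        return "**"
    if test == "interaction" and p_value <= thresholds.suggestive:
        return "*"
    return ""


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "age": r.age, "test": r.test, "llr": r.llr, "lod": r.lod,
            "p_value": r.p_value, "C": r.exceed_count, "M": r.perm_count,
            "monomorphic": r.monomorphic,
        })
    return pd.DataFrame(rows)
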