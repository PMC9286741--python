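"""Synthetic diversity-outbred data with exact target per-environment PVE.

The generator stands in for the real study data so that every stage of the
pipeline is testable without downloads.  It emulates:

* 8-founder mosaic genomes with local linkage: per mouse and chromosome a
  first-order Markov chain over the founders along markers (switch
  probability per marker), emitted as one-hot founder probabilities with
  dosages derived from random biallelic founder alleles;
* the kinship such mosaics imply;
* a binary environment design (two study environments, or generation +
  diet columns);
* phenotypes drawn from the zero-mean multivariate normal implied by the
  mixed model, with the interaction variances solved in closed form so the
  conditional PVE in each environment hits its target exactly (shared
  genetic variance rho2 = 0 in protocol mode);
* optional injected QTLs (founder allele pattern, additive and per-diet
  effects) added to the phenotype mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gxemm import (FOUNDERS, N_FOUNDERS, DosageMatrix, FounderProbMatrix,
                    KinshipMatrix, VarianceComponents, build_covariance,
                    compute_kinship, fit_emma, fit_gxemm)
from .pve import pve_emma, pve_env, pve_total


@dataclass
class InjectedQTL:
    """A causal variant added to the phenotype mean."""

    chrom: str
    marker_index: int            # index within the chromosome's markers
    fap: tuple                   # founder names carrying the minor allele
    effect: float                # grams per minor-allele dose
    diet_effects: Optional[dict] = None  # diet name -> extra grams per dose


@dataclass
class SimulationConfig:
    """Study conditions for the simulation protocol.

    Defaults are desk-scale study conditions: N = 500 mice, two chromosomes
    of 250 markers with founder-switch probability 0.05 per marker, two
    environments with equal allocation, unit noise variance in each.
    """

    n_mice: int = 500
    n_markers: int = 250          # per chromosome
    n_chromosomes: int = 2
    switch_rate: float = 0.05
    allocation: tuple = (0.5, 0.5)
    pve_e: tuple = (0.5, 0.5)
    sigma2_e: tuple = (1.0, 1.0)
    qtls: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.switch_rate <= 1:
            raise ValueError("switch rate must lie in [0, 1]")
        if any(not (0 <= p < 1) for p in self.pve_e):
            raise ValueError("target pve_e must lie in [0, 1)")
        if any(s <= 0 for s in self.sigma2_e):
            raise ValueError("sigma2_e must be positive")
        if abs(sum(self.allocation) - 1) > 1e-9:
            raise ValueError("allocation proportions must sum to 1")


def simulate_mosaics(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[FounderProbMatrix, DosageMatrix, np.ndarray]:
    """Founder mosaics, one-hot probabilities, dosages and founder alleles.

    Returns (founder probabilities, dosage matrix, founder ALT counts with
    shape (V_total, 8) in {0, 2}).  Both alleles of a mouse at a marker
    descend from the mosaic founder (one-hot rows), so dosages are twice
    the founder's allele indicator.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    N, V, C = config.n_mice, config.n_markers, config.n_chromosomes
    r = config.switch_rate
    states = np.empty((N, C * V), dtype=np.int64)
    for c in range(C):
        col = rng.integers(N_FOUNDERS, size=N)
        states[:, c * V] = col
        for v in range(1, V):
            switch = rng.random(N) < r
            col = np.where(switch, rng.integers(N_FOUNDERS, size=N), col)
            states[:, c * V + v] = col
    probs = np.zeros((N, C * V, N_FOUNDERS))
    np.put_along_axis(probs, states[:, :, None], 1.0, axis=2)
    # biallelic founder alleles: each founder homozygous, pattern non-monomorphic
    alt = rng.random((C * V, N_FOUNDERS)) < 0.5
    mono = alt.all(axis=1) | (~alt).all(axis=1)
    while mono.any():
        alt[mono] = rng.random((int(mono.sum()), N_FOUNDERS)) < 0.5
        mono = alt.all(axis=1) | (~alt).all(axis=1)
    counts = 2 * alt.astype(int)  # (V_total, 8)
    dosages = counts[np.arange(C * V)[None, :], states].astype(float)
    marker_map = pd.DataFrame({
        "marker_id": [f"c{c + 1}m{v + 1}" for c in range(C) for v in range(V)],
        "chrom": [f"chr{c + 1}" for c in range(C) for v in range(V)],
        "pos_bp": [int(1e5 * (v + 1)) for c in range(C) for v in range(V)],
    })
    mice = [f"DO{i:04d}" for i in range(N)]
    fp = FounderProbMatrix(probs, marker_map, mice)
    dm = DosageMatrix(dosages, marker_map.copy(), mice)
    return fp, dm, counts


def assign_environments(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Random assignment of mice to environments at the configured ratio."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    N = config.n_mice
    E = len(config.allocation)
    sizes = np.floor(np.asarray(config.allocation) * N).astype(int)
    sizes[0] += N - sizes.sum()
    labels = np.repeat(np.arange(E), sizes)
    labels = labels[rng.permutation(N)]
    Z = np.zeros((N, E), dtype=int)
    Z[np.arange(N), labels] = 1
    return Z


def solve_components_for_pve(pve_targets, sigma2_e, K, Z) -> VarianceComponents:
    """Interaction variances giving exactly the target conditional PVE.

    With rho2 = 0 and zero mean, the conditional decomposition gives a
    linear system A Omega = b with A[e, e'] the genetic coefficient of
    Omega_e'e' in Var_G|e and b[e] = pve_e/(1-pve_e) times the residual
    term of Var_Y|e.  Raises if a genetic coefficient is non-positive
    (degenerate kinship) or the solved Omega is negative.
    """
    K = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    Z = np.asarray(Z, dtype=float)
    p = np.atleast_1d(np.asarray(pve_targets, dtype=float))
    s2 = np.atleast_1d(np.asarray(sigma2_e, dtype=float))
    E = Z.shape[1]
    diag = np.diag(K)
    A = np.zeros((E, E))
    b = np.zeros(E)
    theta = Z @ s2
    for e in range(E):
        z = Z[:, e]
        Ne = z.sum()
        for ep in range(E):
            zz = z * Z[:, ep]
            A[e, ep] = float(diag @ zz) / Ne - float(zz @ K @ zz) / Ne ** 2
        if A[e, e] <= 0:
            raise ValueError(f"degenerate kinship: genetic coefficient <= 0 in env {e}")
        resid = float(theta @ z) * (Ne - 1) / Ne ** 2
        b[e] = p[e] / (1 - p[e]) * resid
    omega = np.linalg.solve(A, b)
    if (omega < -1e-12).any():
        raise ValueError("targets imply negative interaction variance")
    return VarianceComponents(alpha=np.zeros(1), rho2=0.0,
                              omega=np.clip(omega, 0.0, None), sigma2=s2)


def simulate_phenotypes(vc: VarianceComponents, K, Z, mu,
                        rng: Optional[np.random.Generator] = None,
                        seed: int = 0, size: int = 1) -> np.ndarray:
    """Draws from N(mu, Lambda) via Cholesky; shape (size, N) (squeezed)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    Lam = build_covariance(vc, K, Z)
    try:
        L = np.linalg.cholesky(Lam)
    except np.linalg.LinAlgError:
        wmin = float(np.linalg.eigvalsh(Lam).min())
        raise np.linalg.LinAlgError(
            f"model covariance not positive definite (min eigenvalue {wmin:.3e})"
        )
    mu = np.zeros(Lam.shape[0]) if mu is None else np.asarray(mu, dtype=float)
    draws = mu + rng.standard_normal((size, Lam.shape[0])) @ L.T
    return draws[0] if size == 1 else draws


def qtl_mean(qtl: InjectedQTL, config: SimulationConfig, counts: np.ndarray,
             fp: FounderProbMatrix, Z_diet=None, diet_names=None) -> np.ndarray:
    """Phenotype-mean contribution G_s phi (+ sum_e G_s Z_e chi_e) of a QTL.

    The variant's minor allele is carried (homozygous) by the founders of
    the QTL's FAP; its dosage in each mouse follows from the mosaic.
    """
    chrom_ids = fp.marker_map["chrom"].astype(str).to_numpy()
    idx = np.flatnonzero(chrom_ids == qtl.chrom)[qtl.marker_index]
    carriers = np.array([f in qtl.fap for f in FOUNDERS], dtype=float)
    dosage = 2.0 * (fp.probs[:, idx, :] @ carriers)
    mu = qtl.effect * dosage
    if qtl.diet_effects:
        for d, chi in qtl.diet_effects.items():
            e = list(diet_names).index(d)
            mu = mu + chi * dosage * Z_diet[:, e]
    return mu


def protocol_grid() -> list[dict]:
    """The simulation-protocol grid: 114 (pve_e1, pve_e2, allocation) settings."""
    pve_e1 = (0.2, 0.5, 0.8)
    pve_e2 = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
    settings = []
    for ratio, alloc in (("1:1", (0.5, 0.5)), ("4:1", (0.8, 0.2))):
        for p1 in pve_e1:
            for p2 in pve_e2:
                settings.append({"pve_e1": p1, "pve_e2": p2, "ratio": ratio,
                                 "allocation": alloc})
    return settings


def run_simulation_study(settings: Sequence[dict], n_replicates: int = 50,
                         seed: int = 0, config: Optional[SimulationConfig] = None,
                         fit_models: tuple = ("gxemm", "emma"),
                         n_starts: int = 1) -> pd.DataFrame:
    """Replicated PVE recovery across a grid of simulation settings.

    One mosaic kinship is simulated per study (as the real study uses one
    observed kinship); each replicate redraws the environment assignment
    and the phenotype vector.  Returns a tidy frame with true and estimated
    total and per-environment PVE per replicate and model.
    """
    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    fp, _, _ = simulate_mosaics(base, rng)
    K = compute_kinship(fp)
    N = base.n_mice
    X = np.ones((N, 1))
    rows = []
    for setting in settings:
        cfg = SimulationConfig(
            n_mice=base.n_mice, n_markers=base.n_markers,
            n_chromosomes=base.n_chromosomes, switch_rate=base.switch_rate,
            allocation=tuple(setting.get("allocation", base.allocation)),
            pve_e=(setting["pve_e1"], setting["pve_e2"]),
            sigma2_e=tuple(setting.get("sigma2_e", base.sigma2_e)),
            seed=base.seed,
        )
        for rep in range(n_replicates):
            Z = assign_environments(cfg, rng)
            vc_true = solve_components_for_pve(cfg.pve_e, cfg.sigma2_e, K, Z)
            Y = simulate_phenotypes(vc_true, K, Z, None, rng=rng)
            row = {**{k: v for k, v in setting.items() if k != "allocation"},
                   "replicate": rep}
            truth_tot = pve_total(vc_true, K, Z, np.zeros(N)).pve
            row["pve_tot_true"] = truth_tot
            if "gxemm" in fit_models:
                fit = fit_gxemm(Y, X, K, Z, seed=int(rng.integers(2 ** 31)),
                                n_starts=n_starts)
                row["gxemm_pve_tot"] = pve_total(fit, K, Z, X @ fit.alpha).pve
                for e in range(Z.shape[1]):
                    row[f"gxemm_pve_e{e + 1}"] = pve_env(
                        fit, K, Z, X @ fit.alpha, e).pve
            if "emma" in fit_models:
                fit = fit_emma(Y, X, K, seed=int(rng.integers(2 ** 31)),
                               n_starts=n_starts)
                row["emma_pve_tot"] = pve_emma(fit, K, X @ fit.alpha).pve
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_study(results: pd.DataFrame, value: str, by: Sequence[str]
                    ) -> pd.DataFrame:
    """Median and 95% interquantile band of an estimate per grid setting."""
    g = results.groupby(list(by))[value]
    out = g.median().rename("median").to_frame()
    out["q2.5"] = g.quantile(0.025)
    out["q97.5"] = g.quantile(0.975)
    return out.reset_index()
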