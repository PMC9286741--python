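"""Nonlinearity of effect-size trends across age.

Estimated per-age effects phi_hat_t with standard errors psi_hat_t are
modelled as phi_hat_t ~ N(phi_t, psi_hat_t); the trend phi_t is compared
between a cubic alternative and a linear null,

    H_nl: phi_t = a0 + a1 t + a2 t^2 + a3 t^3      H_l: phi_t = a0 + a1 t,

by weighted least squares with known per-age weights 1/psi_hat^2.  Twice
the log likelihood ratio equals the drop in weighted residual sum of
squares and is referred to a chi-squared distribution with 2 degrees of
freedom.  Ages are affinely mapped to [-1, 1] before polynomial fitting
for conditioning; the statistic is invariant to that reparameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .gxemm import FOUNDERS
from .data_io import DIETS
from .finemap import EffectProfile

#: Bonferroni-style cutoffs per tier (rounded-down powers of ten for the
#: 112 diet-independent and 760 diet-dependent tests of the full design).
TIER_CUTOFFS = {"diet_independent": 1e-4, "diet_dependent": 1e-5}

DF = 2  # the two freed coefficients (quadratic and cubic)


@dataclass
class NonlinearityResult:
    locus_id: str
    level: str
    coef_cubic: np.ndarray   # a0..a3 on the scaled age axis
    coef_linear: np.ndarray  # a0, a1 on the scaled age axis
    statistic: float
    p_value: float
    tier: str = "diet_independent"
    significant: bool = False


def _wls(T: np.ndarray, y: np.ndarray, w: np.ndarray):
    Tw = T * w[:, None]
    coef, *_ = np.linalg.lstsq(Tw.T @ T, Tw.T @ y, rcond=None)
    resid = y - T @ coef
    return coef, float(w @ resid ** 2)


def nonlinearity_test(profile: EffectProfile,
                      tier: str = "diet_independent") -> NonlinearityResult:
    """Cubic-vs-linear weighted LRT on one effect-size trajectory."""
    ok = np.isfinite(profile.effect) & np.isfinite(profile.se) & (profile.se > 0)
    t, y, s = profile.ages[ok], profile.effect[ok], profile.se[ok]
    if len(t) < 5:
        raise ValueError("need >= 5 ages with finite effect and SE")
    if len(np.unique(t)) < 4:
        raise ValueError("cubic fit needs >= 4 distinct ages")
    # affine map to [-1, 1] for conditioning; the LRT is invariant to it
    ts = 2 * (t - t.min()) / (t.max() - t.min()) - 1
    w = 1.0 / s ** 2
    T_cubic = np.vander(ts, 4, increasing=True)
    T_lin = T_cubic[:, :2]
    coef_c, rss_c = _wls(T_cubic, y, w)
    coef_l, rss_l = _wls(T_lin, y, w)
    stat = max(rss_l - rss_c, 0.0)
    p = float(scipy.stats.chi2.sf(stat, DF))
    return NonlinearityResult(profile.locus_id, profile.level, coef_c, coef_l,
                              stat, p, tier=tier,
                              significant=p < TIER_CUTOFFS[tier])


def nonlinearity_sweep(loci: Sequence[tuple],
                       profile_getter: Callable[..., Optional[EffectProfile]]
                       ) -> tuple[pd.DataFrame, dict]:
    """Run the test over every founder (and diet) at each locus.

    ``loci`` is a sequence of (locus_id, tier) with tier in
    {"diet_independent", "diet_dependent"}.  Diet-independent loci get one
    test per founder allele (8); diet-dependent loci one per
    (founder, diet) pair (40).  ``profile_getter(locus_id, founder, diet)``
    (diet None for the independent tier) returns the EffectProfile or None
    to skip.  Returns the tidy results plus the executed test count per tier.
    """
    rows = []
    counts = {"diet_independent": 0, "diet_dependent": 0}
    for locus_id, tier in loci:
        diets = (None,) if tier == "diet_independent" else DIETS
        for founder in FOUNDERS:
            for diet in diets:
                profile = profile_getter(locus_id, founder, diet)
                if profile is None:
                    continue
                res = nonlinearity_test(profile, tier=tier)
                counts[tier] += 1
                rows.append({
                    "locus_id": locus_id, "tier": tier, "founder": founder,
                    "diet": diet, "statistic": res.statistic,
                    "p_value": res.p_value, "significant": res.significant,
                })
    return pd.DataFrame(rows), counts
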