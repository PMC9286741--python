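"""Fine-mapping: imputation, founder allele patterns, annotation, effects.

Candidate loci from the genome scans are refined by (i) imputing
founder-strain variants onto the DO mice from the founder-of-origin
probabilities of flanking typed markers, (ii) grouping significant variants
by their founder allele pattern (FAP) - the subset of founders carrying the
minor allele - with a group LOD equal to the best member LOD, (iii)
overlapping member variants with gene models and open-chromatin intervals,
and (iv) extracting age/diet effect-size profiles for lead variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .gxemm import (FOUNDERS, N_FOUNDERS, DosageMatrix, FounderProbMatrix,
                    VarianceComponents, build_covariance)
from .data_io import AnnotationSet, FounderGenotypes, logger
from .scan import _GLSWorkspace


@dataclass
class FAPGroup:
    """Variants sharing one founder bipartition at a locus."""

    fap_label: str
    minor_founders: tuple
    members: pd.DataFrame        # variant rows with a per-variant "lod" column
    group_lod: float
    rank: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return int(self.members["pos"].min()), int(self.members["pos"].max())


@dataclass
class EffectProfile:
    """Per-age effect (grams) and standard error for one locus/level."""

    locus_id: str
    level: str                    # e.g. "founder:AJ", "minor", "minor:diet=40"
    ages: np.ndarray
    effect: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.ages.shape == self.effect.shape == self.se.shape):
            raise ValueError("ages/effect/se must be equal length")


# ---------------------------------------------------------------------------
# imputation of untyped variants
# ---------------------------------------------------------------------------

def impute_dosages(founder_probs: FounderProbMatrix,
                   founder_geno: FounderGenotypes) -> tuple[DosageMatrix, int]:
    """Expected allele dosages of untyped founder variants in each DO mouse.

    The founder-of-origin probability vector at an untyped position is
    linearly interpolated (in physical position) between the two flanking
    typed markers on the same chromosome; the expected dosage is then
    sum_f p_f * alt_count_f.  Variants outside the typed-marker span (or on
    chromosomes without typed markers) are skipped; the skipped count is
    returned alongside the dosage matrix.
    """
    mm = founder_probs.marker_map
    kept_rows = []
    dosages = []
    skipped = 0
    for chrom, vdf in founder_geno.variants.groupby("chrom", sort=False):
        on = (mm["chrom"].astype(str) == str(chrom)).to_numpy()
        if on.sum() < 2:
            skipped += len(vdf)
            continue
        idx = np.flatnonzero(on)
        pos = mm.loc[on, "pos_bp"].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos = pos[order]
        probs = founder_probs.probs[:, idx[order], :]  # N x Vc x 8
        for row in vdf.itertuples():
            if not (pos[0] <= row.pos <= pos[-1]):
                skipped += 1
                continue
            j = np.searchsorted(pos, row.pos, side="right") - 1
            j = min(j, len(pos) - 2)
            span = pos[j + 1] - pos[j]
            w = 0.0 if span == 0 else (row.pos - pos[j]) / span
            p = (1 - w) * probs[:, j, :] + w * probs[:, j + 1, :]
            counts = founder_geno.counts[row.Index].astype(float)
            if (counts < 0).any():
                skipped += 1  # missing founder call
                continue
            dosages.append(p @ counts)
            kept_rows.append(row.Index)
    if not dosages:
        raise ValueError("no variants inside the typed-marker span")
    variants = founder_geno.variants.loc[kept_rows].reset_index()
    marker_map = pd.DataFrame({
        "marker_id": [f"{c}:{p}" for c, p in zip(variants["chrom"], variants["pos"])],
        "chrom": variants["chrom"],
        "pos_bp": variants["pos"],
    })
    D = np.clip(np.column_stack(dosages), 0.0, 2.0)
    return DosageMatrix(D, marker_map, founder_probs.mouse_ids), skipped


# ---------------------------------------------------------------------------
# founder allele patterns
# ---------------------------------------------------------------------------

def assign_fap(counts8) -> Optional[str]:
    """Founder allele pattern of a biallelic variant from founder ALT counts.

    Founders must be homozygous (counts 0 or 2); a heterozygous or missing
    founder call excludes the variant (returns None), as does a variant
    monomorphic across the founders.  The minor allele is the one carried by
    fewer founders; on a 4/4 tie the side containing the earliest founder in
    canonical order (AJ) is labelled.  The label joins carrier names in
    canonical founder order.
    """
    counts = np.asarray(counts8)
    if counts.shape != (N_FOUNDERS,):
        raise ValueError("expected 8 founder allele counts")
    if not np.isin(counts, (0, 2)).all():
        return None  # heterozygous or missing founder call
    alt = np.flatnonzero(counts == 2)
    ref = np.flatnonzero(counts == 0)
    if len(alt) == 0 or len(ref) == 0:
        return None  # monomorphic across founders
    if len(alt) < len(ref):
        minor = alt
    elif len(ref) < len(alt):
        minor = ref
    else:  # 4/4 tie: label the side containing founder index 0 (AJ)
        minor = alt if 0 in alt else ref
    return "/".join(FOUNDERS[i] for i in sorted(minor))


def minor_founders_of(label: str) -> tuple:
    return tuple(label.split("/"))


def group_and_rank_faps(variants: pd.DataFrame) -> list[FAPGroup]:
    """Partition significant variants by FAP and rank groups by best LOD.

    ``variants`` needs columns fap, lod, pos (and may carry any others);
    rows with fap None/NaN are dropped.  Groups are ranked descending by
    group LOD; ties break by larger member count, then label order.
    """
    df = variants.dropna(subset=["fap"])
    groups = []
    for label, g in df.groupby("fap", sort=False):
        groups.append(FAPGroup(
            fap_label=str(label),
            minor_founders=minor_founders_of(str(label)),
            members=g.reset_index(drop=True),
            group_lod=float(g["lod"].max()),
        ))
    groups.sort(key=lambda fg: (-fg.group_lod, -len(fg.members), fg.fap_label))
    for i, fg in enumerate(groups):
        fg.rank = i + 1
    return groups


# ---------------------------------------------------------------------------
# annotation overlap
# ---------------------------------------------------------------------------

def annotate_variants(variants: pd.DataFrame, annotations: AnnotationSet
                      ) -> pd.DataFrame:
    """Flag gene and regulatory-element overlap for point variants.

    Membership is point-in-interval under the 0-based half-open convention
    ([start, end): position end does not hit).  Raises if variant
    chromosome names are absent from the annotation set entirely.
    """
    from intervaltree import IntervalTree

    known = annotations.chroms()
    unmatched = sorted(set(variants["chrom"].astype(str)) - known)
    if known and unmatched:
        raise ValueError(f"chromosome name(s) not in annotations: {unmatched}")
    gene_trees: dict[str, IntervalTree] = {}
    reg_trees: dict[str, IntervalTree] = {}
    for iv in annotations.genes:
        if iv.start < iv.end:
            gene_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    for iv in annotations.regulatory:
        if iv.start < iv.end:
            reg_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    genes, in_gene, tissues, in_reg = [], [], [], []
    for row in variants.itertuples():
        chrom, pos = str(row.chrom), int(row.pos)
        hits = sorted(h.data.name for h in gene_trees.get(chrom, IntervalTree())[pos])
        rhits = sorted({h.data.tissue for h in reg_trees.get(chrom, IntervalTree())[pos]})
        genes.append(";".join(hits))
        in_gene.append(bool(hits))
        tissues.append(";".join(rhits))
        in_reg.append(bool(rhits))
    out = variants.copy()
    out["genes"] = genes
    out["in_gene"] = in_gene
    out["regulatory_tissues"] = tissues
    out["in_regulatory"] = in_reg
    return out


# ---------------------------------------------------------------------------
# effect-size profiles across age
# ---------------------------------------------------------------------------

def effect_at_age(Y, X, vc: VarianceComponents, K, Z, focal: np.ndarray,
                  combination: Optional[np.ndarray] = None
                  ) -> tuple[float, float]:
    """GLS effect estimate and SE of focal fixed-effect column(s) at one age.

    ``focal`` is N x k; the reported effect is the (default: first) linear
    combination of the focal coefficients, e.g. phi + chi_diet for a
    diet-level profile, with SE from the GLS coefficient covariance.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(Y):
        X = X.T
    focal = np.atleast_2d(np.asarray(focal, dtype=float))
    if focal.shape[0] != len(Y):
        focal = focal.T
    W = np.hstack([X, focal])
    Lam = build_covariance(vc, K, Z)
    ws = _GLSWorkspace(Lam)
    _, coef, cov = ws.quad_form_gain(Y, W)
    k = X.shape[1]
    if combination is None:
        combination = np.zeros(focal.shape[1])
        combination[0] = 1.0
    c = np.zeros(W.shape[1])
    c[k:] = combination
    eff = float(c @ coef)
    se = float(np.sqrt(c @ cov @ c))
    return eff, se


def effect_profile(locus_id: str, ages: Sequence[int],
                   per_age: Callable[[int], Optional[tuple]],
                   level: str = "minor") -> EffectProfile:
    """Assemble an effect-size trajectory across the analysis age grid.

    ``per_age(age)`` returns (Y, X, vc, K, Z, focal, combination) for that
    age, or None when the fit is unavailable; unavailable or non-converged
    ages are logged and skipped.
    """
    out_ages, effs, ses = [], [], []
    for age in ages:
        data = per_age(age)
        if data is None:
            logger.warning("locus %s: no fit at age %s; skipped", locus_id, age)
            continue
        Y, X, vc, K, Z, focal, comb = data
        if not vc.converged:
            logger.warning("locus %s: non-converged fit at age %s; skipped",
                           locus_id, age)
            continue
        eff, se = effect_at_age(Y, X, vc, K, Z, focal, comb)
        out_ages.append(age)
        effs.append(eff)
        ses.append(se)
    return EffectProfile(locus_id, level, np.array(out_ages),
                         np.array(effs), np.array(ses))
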