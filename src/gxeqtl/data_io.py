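"""Readers, writers and study-design containers.

All downstream modules consume only the domain types defined here and in
:mod:`gxeqtl.gxemm`.  Internal genomic coordinates are 0-based half-open
everywhere; GFF (1-based closed) is converted at the boundary, BED is taken
as already 0-based half-open.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gxemm import FOUNDERS, N_FOUNDERS, FounderProbMatrix

logger = logging.getLogger("gxeqtl")
if not logger.handlers:  # log to stderr once, with a plain format
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing columns...)."""


class ValidationError(ValueError):
    """A file parses but its contents violate an invariant."""


# study-design constants ----------------------------------------------------

#: Age (days) at which dietary intervention is imposed.
INTERVENTION_AGE = 180

#: Diet groups: ad libitum, 20%/40% daily calorie restriction, 1- or
#: 2-day-per-week intermittent fasting.
DIETS = ("AL", "20", "40", "1D", "2D")

#: Average daily food intake (grams) of a female DO mouse, the baseline
#: from which the calorie-restricted rations are computed.
BASELINE_INTAKE_G = 3.43

#: Fraction of the baseline intake offered under each diet; fasting diets
#: feed ad libitum on non-fasting days.
DIET_INTAKE_FRACTION = {"AL": 1.0, "20": 0.8, "40": 0.6, "1D": 1.0, "2D": 1.0}


def ration_g_per_day(diet: str) -> float:
    """Daily ration in grams per mouse implied by the diet's intake fraction."""
    if diet not in DIET_INTAKE_FRACTION:
        raise ValidationError(f"unknown diet label {diet!r}")
    return BASELINE_INTAKE_G * DIET_INTAKE_FRACTION[diet]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSeries:
    """One mouse's body-weight series: ages in days, weights in grams."""

    mouse_id: str
    ages: np.ndarray
    weights: np.ndarray
    source: str = "raw"  # "raw" | "trend_filtered"

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.ages.shape != self.weights.shape:
            raise ValidationError(f"{self.mouse_id}: ages/weights length mismatch")
        if len(self.ages) and (np.diff(self.ages) <= 0).any():
            raise ValidationError(f"{self.mouse_id}: ages must be strictly increasing")
        if not np.isfinite(self.weights).all() or (self.weights <= 0).any():
            raise ValidationError(f"{self.mouse_id}: weights must be finite and > 0")


def read_phenotypes(path) -> list[PhenotypeSeries]:
    """Read a mouse x age body-weight CSV (mouse_id, age_days, weight_g)."""
    df = pd.read_csv(path)
    required = {"mouse_id", "age_days", "weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype CSV missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["mouse_id", "age_days"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate measurement for mouse {row.mouse_id!r} at age {row.age_days}"
        )
    bad = ~(df["weight_g"] > 0) | ~np.isfinite(df["weight_g"])
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"non-positive weight in row {idx}: {df.iloc[idx].to_dict()}")
    out = []
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("age_days")
        out.append(PhenotypeSeries(str(mouse_id), grp["age_days"].to_numpy(),
                                   grp["weight_g"].to_numpy()))
    return out


def measurement_completeness(series: Sequence[PhenotypeSeries], ages) -> dict:
    """Percentage of mice whose measurement span covers each query age.

    Mice exit the study on death, so the fraction of series reaching an age
    summarizes measurement completeness at that age.
    """
    out = {}
    for age in ages:
        n = sum(1 for s in series if s.ages[0] <= age <= s.ages[-1])
        out[int(age)] = 100.0 * n / len(series)
    return out


def write_phenotypes(series: Sequence[PhenotypeSeries], path) -> None:
    """Write the canonical phenotype CSV (sorted by mouse then age)."""
    rows = []
    for s in sorted(series, key=lambda s: s.mouse_id):
        for a, w in zip(s.ages, s.weights):
            rows.append((s.mouse_id, int(a), float(w)))
    pd.DataFrame(rows, columns=["mouse_id", "age_days", "weight_g"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# environment design
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentDesign:
    """N x E binary membership over generation cohorts and diet groups.

    Before the intervention age only generation columns apply (each mouse
    in exactly one); at and after it, diet columns are appended (each mouse
    additionally in exactly one diet).
    """

    Z: np.ndarray
    env_labels: list  # [(kind in {"generation", "diet"}, name), ...]
    mouse_ids: list
    intervention_age: int = INTERVENTION_AGE

    def __post_init__(self):
        self.Z = np.asarray(self.Z)
        if not np.isin(self.Z, (0, 1)).all():
            raise ValidationError("Z entries must be 0/1")
        kinds = [k for k, _ in self.env_labels]
        gen = self.Z[:, [i for i, k in enumerate(kinds) if k == "generation"]]
        if gen.size and not (gen.sum(axis=1) == 1).all():
            raise ValidationError("each mouse must be in exactly one generation")
        diet = self.Z[:, [i for i, k in enumerate(kinds) if k == "diet"]]
        if diet.size and not (diet.sum(axis=1) == 1).all():
            raise ValidationError("each mouse must be in exactly one diet")

    @property
    def n_env(self) -> int:
        return self.Z.shape[1]

    def columns(self, kind: str) -> np.ndarray:
        idx = [i for i, (k, _) in enumerate(self.env_labels) if k == kind]
        return self.Z[:, idx]

    def for_age(self, age: int) -> "EnvironmentDesign":
        """Design applicable at the given age: drop diet columns pre-intervention."""
        if age >= self.intervention_age:
            return self
        keep = [i for i, (k, _) in enumerate(self.env_labels) if k == "generation"]
        return EnvironmentDesign(self.Z[:, keep],
                                 [self.env_labels[i] for i in keep],
                                 self.mouse_ids, self.intervention_age)

    def diet_labels(self) -> np.ndarray:
        """Per-mouse diet name (requires diet columns)."""
        idx = [i for i, (k, _) in enumerate(self.env_labels) if k == "diet"]
        names = np.array([self.env_labels[i][1] for i in idx])
        return names[np.argmax(self.Z[:, idx], axis=1)]


def read_environments(path, intervention_age: int = INTERVENTION_AGE
                      ) -> EnvironmentDesign:
    """Read the covariate CSV (mouse_id, generation, diet) into a design."""
    df = pd.read_csv(path, dtype=str)
    required = {"mouse_id", "generation", "diet"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"covariate CSV missing columns: {sorted(missing)}")
    unknown = set(df["diet"]) - set(DIETS)
    if unknown:
        raise ValidationError(f"unknown diet label(s): {sorted(unknown)}")
    generations = sorted(df["generation"].unique())
    diets = [d for d in DIETS if d in set(df["diet"])]
    labels = [("generation", g) for g in generations] + [("diet", d) for d in diets]
    Z = np.zeros((len(df), len(labels)), dtype=int)
    for j, (kind, name) in enumerate(labels):
        col = "generation" if kind == "generation" else "diet"
        Z[:, j] = (df[col] == name).to_numpy().astype(int)
    return EnvironmentDesign(Z, labels, df["mouse_id"].tolist(), intervention_age)


# ---------------------------------------------------------------------------
# founder probabilities (package dialect) and founder genotypes
# ---------------------------------------------------------------------------

_PROB_COLS = ["mouse_id", "marker_id", "chrom", "pos_bp", *FOUNDERS]


def read_founder_probs(path) -> FounderProbMatrix:
    """Read founder-of-origin probabilities from the package's long CSV dialect.

    Columns: mouse_id, marker_id, chrom, pos_bp, then one column per founder
    (AJ..WSB).  Each row's founder block must sum to 1 within 1e-3 and is
    renormalized to exact unit L1 norm.
    """
    df = pd.read_csv(path)
    missing = set(_PROB_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"founder-probability CSV missing columns: {sorted(missing)}")
    P = df[list(FOUNDERS)].to_numpy(dtype=float)
    sums = P.sum(axis=1)
    bad = (sums < 1 - 1e-3) | (sums > 1 + 1e-3)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"founder probabilities in row {idx} sum to {sums[idx]:.6f}, not 1"
        )
    df = df.copy()
    df[list(FOUNDERS)] = P / sums[:, None]
    mice = sorted(df["mouse_id"].astype(str).unique())
    markers = df.drop_duplicates("marker_id")[["marker_id", "chrom", "pos_bp"]]
    markers = markers.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    marker_pos = {m: i for i, m in enumerate(markers["marker_id"])}
    mouse_pos = {m: i for i, m in enumerate(mice)}
    probs = np.zeros((len(mice), len(markers), N_FOUNDERS))
    i = df["mouse_id"].astype(str).map(mouse_pos).to_numpy()
    j = df["marker_id"].map(marker_pos).to_numpy()
    probs[i, j, :] = df[list(FOUNDERS)].to_numpy()
    return FounderProbMatrix(probs, markers, mice)


def write_founder_probs(fp: FounderProbMatrix, path) -> None:
    """Write founder probabilities in the package's long CSV dialect."""
    mice = fp.mouse_ids or [f"m{i}" for i in range(fp.n_mice)]
    rows = []
    for i, m in enumerate(mice):
        for j in range(fp.n_markers):
            mk = fp.marker_map.iloc[j]
            rows.append((m, mk["marker_id"], mk["chrom"], mk["pos_bp"],
                         *fp.probs[i, j, :]))
    pd.DataFrame(rows, columns=_PROB_COLS).to_csv(path, index=False)


def convert_qtl2_probs(path):  # pragma: no cover - documented stub
    """Convert a qtl2-style founder-probability export to the package dialect.

    The upstream study deposited founder-probability arrays without a stated
    file dialect; this converter is a stub documenting where such support
    would plug in.  Export qtl2 probabilities to the long CSV dialect of
    :func:`read_founder_probs` instead.
    """
    raise NotImplementedError(
        "export qtl2 genoprobs to the long CSV dialect (see read_founder_probs)"
    )


@dataclass
class FounderGenotypes:
    """Biallelic founder-strain genotypes for imputation onto DO mice.

    ``counts`` holds the ALT allele count (0/1/2) per variant per founder in
    canonical founder order; shape (n_variants, 8).
    """

    variants: pd.DataFrame  # chrom, pos (0-based), ref, alt
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.variants), N_FOUNDERS):
            raise ValidationError("counts must be (n_variants, 8)")


def read_founder_genotypes(vcf_path) -> FounderGenotypes:
    """Read founder genotypes from a VCF whose 8 samples are the founder names."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if set(samples) != set(FOUNDERS):
        raise FormatError(
            f"VCF samples must be the 8 founder strains, got {samples}"
        )
    order = [samples.index(f) for f in FOUNDERS]
    rows, counts = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # biallelic only
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        cnt = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=-1)
        rows.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        counts.append(cnt[order])
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return FounderGenotypes(variants, np.array(counts, dtype=int))


# ---------------------------------------------------------------------------
# annotations (GFF genes + BED regulatory elements)
# ---------------------------------------------------------------------------

@dataclass
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."
    tissue: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class AnnotationSet:
    """Gene models (from GFF) and regulatory elements (from BED)."""

    genes: list = field(default_factory=list)
    regulatory: list = field(default_factory=list)

    def chroms(self) -> set:
        return {iv.chrom for iv in self.genes} | {iv.chrom for iv in self.regulatory}


def read_annotations(gff_path=None, bed_path=None) -> AnnotationSet:
    """Read gene models (GFF3, converted to 0-based half-open) and open-chromatin
    intervals (BED, already 0-based half-open)."""
    genes: list[GenomicInterval] = []
    if gff_path is not None:
        import gffutils

        db = gffutils.create_db(str(gff_path), dbfn=":memory:",
                                merge_strategy="create_unique", keep_order=True)
        for feat in db.features_of_type("gene"):
            name = feat.attributes.get("Name", feat.attributes.get("ID", [""]))[0]
            # GFF is 1-based closed: [start, end] -> [start-1, end)
            genes.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                         name=name, strand=feat.strand))
    regulatory: list[GenomicInterval] = []
    if bed_path is not None:
        bed = pd.read_csv(bed_path, sep=r"\s+", header=None, comment="#")
        if bed.shape[1] < 3:
            raise FormatError("BED requires at least chrom, start, end columns")
        for row in bed.itertuples(index=False):
            tissue = str(row[3]) if len(row) > 3 else ""
            regulatory.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]),
                                              name=tissue, tissue=tissue))
    return AnnotationSet(genes=genes, regulatory=regulatory)
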