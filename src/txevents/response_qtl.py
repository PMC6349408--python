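"""Response-QTL classification and colocalisation filtering.

A QTL detected in a stimulated condition is a *response* QTL when its
effect size differs between the stimulated and the paired naive
condition.  Two complementary statistics decide this:

* an interaction likelihood-ratio test comparing the mixed models
  ``phenotype ~ genotype + condition + (1|donor)`` (H0) and
  ``phenotype ~ genotype + condition + condition:genotype + (1|donor)``
  (H1), both fitted by ML, with a chi-square(1) reference for the
  two-condition contrast; and
* a random-effects variance decomposition
  ``phenotype ~ (1|genotype) + (1|condition) + (1|condition:genotype)``
  with genotype entering as an unordered three-level factor, from which
  sigma2_relative = sigma2_interaction / (sigma2_interaction +
  sigma2_genotype) quantifies how much of the genetic variance the
  interaction explains.

A candidate is classified as a response QTL iff its interaction-test BH
FDR < 10% and sigma2_relative > 0.5.

The module also filters externally computed colocalisation posteriors
by the posterior-probability, MHC-region and GWAS-significance rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GenomicInterval
from .lmm import fit_random_intercept, fit_variance_components
from .qtl_mapping import bh_fdr

__all__ = [
    "LongPhenotypeTable",
    "ResponseClassification",
    "ColocRecord",
    "MHC_REGION",
    "interaction_lrt",
    "variance_components",
    "classify_response",
    "filter_colocalisations",
    "coloc_candidate_regions",
]

#: GRCh38 MHC region excluded from colocalisation results (1-based inclusive).
MHC_REGION = ("6", 28_510_120, 33_480_577)


@dataclass
class LongPhenotypeTable:
    """Long-format phenotype observations across conditions.

    One row per (donor, condition) sample with the donor's genotype
    dosage and the phenotype value.  Dosage must be constant within a
    donor and non-constant across donors; at least two conditions are
    required and at least three donors must be observed in more than
    one condition (otherwise the donor random effect and the
    interaction are confounded).
    """

    data: pd.DataFrame  # columns: donor, sample, condition, dosage, phenotype

    def __post_init__(self) -> None:
        required = {"donor", "condition", "dosage", "phenotype"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        d = self.data
        if d["dosage"].groupby(d["donor"]).nunique().gt(1).any():
            raise ValueError("dosage varies within a donor")
        if d["condition"].nunique() < 2:
            raise ValueError("at least two conditions are required")
        if d["dosage"].nunique() < 2:
            raise ValueError("genotype dosage is constant")
        multi = d.groupby("donor")["condition"].nunique().ge(2).sum()
        if multi < 3:
            raise ValueError(
                "need >=3 donors observed in more than one condition"
            )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())


def _design_matrices(t: LongPhenotypeTable):
    d = t.data
    cond_levels = t.conditions
    cond_dummies = np.column_stack(
        [(d["condition"] == c).to_numpy(float) for c in cond_levels[1:]]
    )
    g = d["dosage"].to_numpy(float)
    X0 = np.column_stack([np.ones(len(d)), g, cond_dummies])
    X1 = np.column_stack([X0, cond_dummies * g[:, None]])
    y = d["phenotype"].to_numpy(float)
    donors = d["donor"].to_numpy()
    return y, X0, X1, donors, len(cond_levels)


def interaction_lrt(t: LongPhenotypeTable) -> float:
    """Genotype-by-condition interaction likelihood-ratio p-value.

    Both models carry a donor random intercept and are fitted by ML;
    the test statistic 2 (ll1 - ll0) is referred to chi-square with
    (number of conditions - 1) degrees of freedom — one, for the usual
    stimulated-versus-naive contrast.
    """
    y, X0, X1, donors, n_cond = _design_matrices(t)
    fit0 = fit_random_intercept(y, X0, donors)
    fit1 = fit_random_intercept(y, X1, donors)
    lr = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    return float(stats.chi2.sf(lr, df=n_cond - 1))


def variance_components(
    t: LongPhenotypeTable, genotype_as_factor: bool = True
) -> dict[str, float]:
    """Random-effects decomposition of the phenotype.

    Fits ``phenotype ~ (1|genotype) + (1|condition) +
    (1|condition:genotype)`` by ML, with genotype as an unordered
    factor of rounded dosage levels (an additive-dosage alternative —
    ``genotype_as_factor=False`` — replaces the genotype component's
    levels with the raw dosage values, for sensitivity analysis).
    Returns the named variances plus ``sigma2_relative =
    sigma2_interaction / (sigma2_interaction + sigma2_genotype)``.
    """
    d = t.data
    y = d["phenotype"].to_numpy(float)
    geno_levels = (
        np.round(d["dosage"]).astype(int).to_numpy()
        if genotype_as_factor
        else d["dosage"].to_numpy()
    )
    cond = d["condition"].astype(str).to_numpy()
    inter = np.char.add(np.char.add(cond, ":"), geno_levels.astype(str))
    fit = fit_variance_components(
        y, {"genotype": geno_levels, "condition": cond, "interaction": inter}
    )
    comps = fit.components
    denom = comps["interaction"] + comps["genotype"]
    rel = comps["interaction"] / denom if denom > 0 else 0.0
    return {
        "sigma2_genotype": comps["genotype"],
        "sigma2_condition": comps["condition"],
        "sigma2_interaction": comps["interaction"],
        "sigma2_residual": comps["residual"],
        "sigma2_relative": float(rel),
    }


@dataclass
class ResponseClassification:
    feature_id: str
    lrt_p: float
    fdr: float
    sigma2_genotype: float
    sigma2_interaction: float
    sigma2_relative: float
    is_response: bool


def classify_response(
    tables: dict[str, LongPhenotypeTable],
    fdr_threshold: float = 0.10,
    sigma2_relative_threshold: float = 0.5,
) -> list[ResponseClassification]:
    """Classify candidate QTLs of one stimulated condition.

    ``tables`` maps feature id to its long phenotype table (naive +
    stimulated observations).  Candidates are assumed pre-selected
    (significant at FDR < 10% in the stimulated condition).  BH FDR is
    applied across the candidates' interaction LRT p-values; a
    candidate is a response QTL iff its FDR is below the threshold and
    sigma2_relative exceeds 0.5.
    """
    feature_ids = sorted(tables)
    lrt_ps = np.array([interaction_lrt(tables[f]) for f in feature_ids])
    fdrs = bh_fdr(lrt_ps) if len(lrt_ps) else np.array([])
    out = []
    for f, p, q in zip(feature_ids, lrt_ps, fdrs):
        vc = variance_components(tables[f])
        out.append(
            ResponseClassification(
                feature_id=f,
                lrt_p=float(p),
                fdr=float(q),
                sigma2_genotype=vc["sigma2_genotype"],
                sigma2_interaction=vc["sigma2_interaction"],
                sigma2_relative=vc["sigma2_relative"],
                is_response=bool(
                    q < fdr_threshold
                    and vc["sigma2_relative"] > sigma2_relative_threshold
                ),
            )
        )
    return out


@dataclass
class ColocRecord:
    """One externally computed colocalisation result."""

    feature_id: str
    lead_variant: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    gwas_min_p: float
    region: GenomicInterval

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{self.feature_id}: posterior probabilities sum to {total}"
            )


def _overlaps_mhc(region: GenomicInterval) -> bool:
    chrom, lo, hi = MHC_REGION
    return (
        region.chrom.removeprefix("chr") == chrom
        # region is half-open; the MHC bounds are 1-based inclusive
        and region.start < hi
        and lo - 1 < region.end
    )


def filter_colocalisations(records: list[ColocRecord]) -> list[ColocRecord]:
    """Keep stringent colocalisations; order-preserving and idempotent.

    A record survives iff PP3+PP4 >= 0.8 (power filter), PP4/(PP3+PP4)
    > 0.9 (single shared causal variant strongly preferred), its region
    does not overlap the MHC (GRCh38 6:28,510,120-33,480,577), and the
    minimal GWAS p-value in the region is < 1e-6.
    """
    kept = []
    for rec in records:
        power = rec.pp3 + rec.pp4
        if power < 0.8:
            continue
        if rec.pp4 / power <= 0.9:
            continue
        if _overlaps_mhc(rec.region):
            continue
        if not rec.gwas_min_p < 1e-6:
            continue
        kept.append(rec)
    return kept


def coloc_candidate_regions(
    leads: pd.DataFrame,
    gwas: pd.DataFrame,
    region_size: int = 400_000,
    max_distance: int = 100_000,
    gwas_p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Candidate colocalisation regions around lead QTL variants.

    A lead variant qualifies when at least one GWAS variant with
    nominal p below ``gwas_p_threshold`` lies within ``max_distance``
    on the same chromosome; the candidate region is ``region_size``
    centered on the lead.  ``leads`` needs columns ``lead_variant``,
    ``chrom``, ``pos``; ``gwas`` needs ``chrom``, ``pos``, ``p``.
    """
    for col in ("lead_variant", "chrom", "pos"):
        if col not in leads.columns:
            raise ValueError(f"lead table missing column {col!r}")
    for col in ("chrom", "pos", "p"):
        if col not in gwas.columns:
            raise ValueError(f"gwas table missing column {col!r}")
    half = region_size // 2
    strong = gwas[gwas["p"] < gwas_p_threshold]
    rows = []
    for _, row in leads.iterrows():
        near = strong[
            (strong["chrom"].astype(str) == str(row["chrom"]))
            & ((strong["pos"] - row["pos"]).abs() <= max_distance)
        ]
        if len(near) == 0:
            continue
        rows.append(
            {
                "lead_variant": row["lead_variant"],
                "chrom": row["chrom"],
                "start": int(row["pos"]) - half,
                "end": int(row["pos"]) + half,
            }
        )
    return pd.DataFrame(rows, columns=["lead_variant", "chrom", "start", "end"])
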