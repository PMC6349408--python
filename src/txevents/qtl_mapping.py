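"""cis usage-QTL mapping: nominal scan, permutation pass, FDR, replication.

The association scheme mirrors the standard cis-QTL two-stage design:
a nominal pass tests every variant in a +/-500 kb window around a
feature with ordinary least squares (optionally adjusting for
covariates such as phenotype principal components), and a permutation
pass estimates, per gene x event-type scope, an empirical p-value for
the minimum nominal p over all (variant, feature) pairs in a +/-100 kb
window, by jointly permuting sample labels of the scope's phenotypes.
Permutation p-values are then corrected with Benjamini-Hochberg FDR.
Cross-method replication is measured as the fraction of query lead
variants in high LD (r^2 > 0.8) with the reference method's lead for
the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "QtlAssociation",
    "PermutationResult",
    "read_dosage_matrix",
    "nominal_scan",
    "permutation_pass",
    "permutation_scan_table",
    "bh_fdr",
    "ld_r2",
    "gene_level_leads",
    "replication_fraction",
]


@dataclass
class GenotypeMatrix:
    """Bi-allelic variant dosages (variants x samples, values in [0, 2]).

    MAF filtering is assumed to have happened upstream; helper
    :meth:`maf` is provided for callers that want to enforce it.
    """

    variant_ids: list[str]
    positions: pd.DataFrame  # indexed by variant id: chrom, pos, ref, alt
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.variant_ids), len(self.samples)):
            raise ValueError("dosage shape does not match variant/sample ids")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        self.positions = self.positions.loc[self.variant_ids]

    def maf(self) -> np.ndarray:
        p = self.dosage.mean(axis=1) / 2.0
        return np.minimum(p, 1 - p)

    def dosage_for(self, variant_id: str) -> np.ndarray:
        return self.dosage[self.variant_ids.index(variant_id)]

    def subset_window(self, chrom: str, center: int, window: int) -> "GenotypeMatrix":
        pos = self.positions
        keep = (pos["chrom"].astype(str) == str(chrom)) & (
            (pos["pos"] - center).abs() <= window
        )
        idx = np.flatnonzero(keep.to_numpy())
        return GenotypeMatrix(
            variant_ids=[self.variant_ids[i] for i in idx],
            positions=pos.iloc[idx],
            samples=self.samples,
            dosage=self.dosage[idx],
        )

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise ValueError(f"samples absent from genotypes: {missing}")
        idx = [lookup[s] for s in samples]
        return GenotypeMatrix(
            variant_ids=list(self.variant_ids),
            positions=self.positions,
            samples=list(samples),
            dosage=self.dosage[:, idx],
        )


def read_dosage_matrix(path: str) -> GenotypeMatrix:
    """Read a plain tab-separated dosage matrix.

    Expected header: ``variant_id chrom pos ref alt <sample...>``.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in tab.columns]
    if missing:
        raise ValueError(f"dosage matrix missing columns {missing}")
    tab = tab.set_index("variant_id")
    samples = [c for c in tab.columns if c not in meta_cols]
    return GenotypeMatrix(
        variant_ids=list(tab.index),
        positions=tab[["chrom", "pos", "ref", "alt"]],
        samples=samples,
        dosage=tab[samples].to_numpy(dtype=float),
    )


@dataclass
class QtlAssociation:
    feature_id: str
    variant_id: str
    beta: float
    se: float
    p_nominal: float


@dataclass
class PermutationResult:
    """Empirical p for one gene x event-type scope."""

    p_empirical: float
    p_nominal_min: float
    lead_variant: str
    lead_feature: str
    n_perm: int
    n_variants: int
    n_features: int


def _residualize(mat: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Remove intercept + covariates; returns residuals and model rank."""
    n = mat.shape[0]
    design = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.hstack([design, cov])
    q, r = np.linalg.qr(design)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))).sum())
    resid = mat - q @ (q.T @ mat)
    return resid, rank


def nominal_scan(
    pheno: pd.Series,
    geno: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    anchor: tuple[str, int] | None = None,
    window: int = 500_000,
) -> list[QtlAssociation]:
    """OLS of one phenotype on each variant's dosage (plus covariates).

    ``anchor`` = (chrom, position) restricts variants to the cis window;
    pass ``None`` when ``geno`` is already windowed.  Samples with
    undefined phenotype are dropped.  Returns per-variant effect sizes
    (per alt allele, on the phenotype scale), standard errors and
    two-sided t-test p-values.
    """
    if anchor is not None:
        geno = geno.subset_window(anchor[0], anchor[1], window)
    pheno = pheno.loc[geno.samples]
    ok = pheno.notna().to_numpy()
    y = pheno.to_numpy(dtype=float)[ok]
    G = geno.dosage[:, ok].T  # n x v
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[ok]
    n = y.size
    n_cov = 0 if cov is None else cov.shape[1]
    if n < n_cov + 3:
        raise ValueError(f"too few samples ({n}) for {n_cov} covariates")
    yr, rank = _residualize(y[:, None], cov)
    Gr, _ = _residualize(G, cov)
    df = n - rank - 1
    gss = (Gr**2).sum(axis=0)
    scale = (G**2).sum(axis=0) + 1.0
    deficient = gss < 1e-10 * scale
    if deficient.any():
        bad = [geno.variant_ids[i] for i in np.flatnonzero(deficient)]
        raise np.linalg.LinAlgError(
            f"dosage collinear with covariates (rank deficiency): {bad}"
        )
    beta = (Gr * yr).sum(axis=0) / gss
    rss = (yr**2).sum() - beta**2 * gss
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gss)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(tval), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return [
        QtlAssociation(pheno.name or "", vid, float(b), float(s), float(pv))
        for vid, b, s, pv in zip(geno.variant_ids, beta, se, p)
    ]


def _corr_columns(mat: np.ndarray) -> np.ndarray:
    """Unit-normalise centred columns; all-zero columns become zero."""
    norms = np.sqrt((mat**2).sum(axis=0))
    norms[norms == 0] = np.inf
    return mat / norms


def permutation_pass(
    phenos: pd.DataFrame,
    geno: GenotypeMatrix,
    n_perm: int = 10_000,
    covariates: np.ndarray | None = None,
    anchor: tuple[str, int] | None = None,
    window: int = 100_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult | None:
    """Scope-level empirical p-value by joint sample-label permutation.

    ``phenos`` holds all features of one scope (rows features, columns
    samples): for event-level analyses a scope is one gene x event type,
    pooling the two construction groups, so the correction accounts for
    the number of alternative events tested.  The observed statistic is
    the minimum nominal p over (variants in the window) x (features);
    permutations shuffle sample labels of all phenotypes jointly, which
    preserves inter-feature correlation.  The empirical p-value uses the
    pseudo-count estimator ``(1 + #{perm <= obs}) / (n_perm + 1)`` and
    can never fall below ``1 / (n_perm + 1)``.

    Returns ``None`` when no variant lies in the window (caller logs
    the skipped scope).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low; empirical p is coarse")
    if anchor is not None:
        geno = geno.subset_window(anchor[0], anchor[1], window)
    if len(geno.variant_ids) == 0:
        return None
    phenos = phenos[geno.samples]
    ok = phenos.notna().all(axis=0).to_numpy()
    Y = phenos.to_numpy(dtype=float)[:, ok].T  # n x f
    G = geno.dosage[:, ok].T  # n x v
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[ok]
    n = Y.shape[0]
    Yr, rank = _residualize(Y, cov)
    Gr, _ = _residualize(G, cov)
    df = n - rank - 1
    Yn = _corr_columns(Yr)
    Gn = _corr_columns(Gr)

    obs_r = np.abs(Gn.T @ Yn)  # v x f
    i, j = np.unravel_index(np.argmax(obs_r), obs_r.shape)
    r_obs = obs_r[i, j]
    # tie-break lead variant: smallest position, then lexicographic id
    vmax = np.flatnonzero(np.isclose(obs_r.max(axis=1), r_obs, rtol=0, atol=1e-12))
    lead_order = sorted(
        vmax,
        key=lambda k: (geno.positions["pos"].iloc[k], geno.variant_ids[k]),
    )
    i = lead_order[0]
    j = int(np.argmax(obs_r[i]))

    # vectorised permutations in chunks: row k of idx is one shuffled
    # sample order applied jointly to every feature of the scope
    count = 0
    remaining = n_perm
    while remaining > 0:
        m = min(remaining, 512)
        idx = np.argsort(rng.random((m, n)), axis=1)
        chunk_max = np.zeros(m)
        for j in range(Yn.shape[1]):
            r = np.abs(Yn[idx, j] @ Gn)  # m x v
            np.maximum(chunk_max, r.max(axis=1), out=chunk_max)
        count += int((chunk_max >= r_obs - 1e-15).sum())
        remaining -= m
    p_emp = (1 + count) / (n_perm + 1)

    r2 = min(r_obs**2, 1.0 - 1e-15)
    t_obs = r_obs * np.sqrt(df / (1.0 - r2))
    p_min = float(np.clip(2 * stats.t.sf(t_obs, df), np.finfo(float).tiny, 1.0))
    return PermutationResult(
        p_empirical=float(p_emp),
        p_nominal_min=p_min,
        lead_variant=geno.variant_ids[i],
        lead_feature=str(phenos.index[j]),
        n_perm=n_perm,
        n_variants=len(geno.variant_ids),
        n_features=Y.shape[1],
    )


def permutation_scan_table(
    pheno: pd.DataFrame,
    feature_meta: pd.DataFrame,
    anchors: dict[str, tuple[str, int]],
    geno: GenotypeMatrix,
    n_perm: int = 10_000,
    covariates: np.ndarray | None = None,
    window: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation pass over all gene x event-type scopes, plus BH FDR.

    ``feature_meta`` (indexed like ``pheno``) must carry ``gene_id`` and
    ``event_type``; construction groups of the same gene and type are
    pooled into one scope.  ``anchors`` maps gene id to its cis-window
    anchor (chrom, 5'-most exon position).  Returns one row per scope
    with the empirical p, lead variant/feature and BH q-value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    meta = feature_meta.loc[pheno.index]
    for (gene_id, ev_type), idx in meta.groupby(
        ["gene_id", "event_type"], sort=True
    ).groups.items():
        res = permutation_pass(
            pheno.loc[idx],
            geno,
            n_perm=n_perm,
            covariates=covariates,
            anchor=anchors[gene_id],
            window=window,
            rng=rng,
        )
        if res is None:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "event_type": ev_type,
                "lead_feature": res.lead_feature,
                "lead_variant": res.lead_variant,
                "p_nominal_min": res.p_nominal_min,
                "p_empirical": res.p_empirical,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "event_type",
            "lead_feature",
            "lead_variant",
            "p_nominal_min",
            "p_empirical",
        ],
    )
    if len(out):
        out["fdr"] = bh_fdr(out["p_empirical"].to_numpy())
    else:
        out["fdr"] = []
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Returns NaN when either vector is constant (undefined LD).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors of different length")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def gene_level_leads(leads: pd.DataFrame) -> pd.DataFrame:
    """Collapse event-level leads to one lead per gene (smallest p).

    Ties break to the lexicographically smallest variant id, then
    feature id, making the collapse deterministic.
    """
    cols = ["gene_id", "lead_variant", "p_empirical"]
    missing = [c for c in cols if c not in leads.columns]
    if missing:
        raise ValueError(f"lead table missing columns {missing}")
    sort_cols = ["gene_id", "p_empirical", "lead_variant"]
    if "lead_feature" in leads.columns:
        sort_cols.append("lead_feature")
    ordered = leads.sort_values(sort_cols, kind="mergesort")
    return ordered.groupby("gene_id", sort=True).head(1).reset_index(drop=True)


def replication_fraction(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_threshold: float = 0.8,
    count_missing_reference: bool = True,
) -> float:
    """Fraction of query gene leads in high LD with the reference lead.

    ``query`` and ``reference`` are gene-level lead tables (columns
    ``gene_id``, ``lead_variant``); the query is expected to be
    pre-filtered to its significant set (e.g. FDR < 0.01).  Genes with
    no reference lead count as non-replicated by default (conservative
    reading; set ``count_missing_reference=False`` to drop them from the
    denominator).  The measure is asymmetric between methods.
    """
    if len(query) == 0:
        return float("nan")
    ref_lead = dict(zip(reference["gene_id"], reference["lead_variant"]))
    hits = 0
    denom = 0
    for _, row in query.iterrows():
        ref_var = ref_lead.get(row["gene_id"])
        if ref_var is None:
            if count_missing_reference:
                denom += 1
            continue
        denom += 1
        r2 = ld_r2(geno.dosage_for(row["lead_variant"]), geno.dosage_for(ref_var))
        if np.isfinite(r2) and r2 > r2_threshold:
            hits += 1
    if denom == 0:
        return float("nan")
    return hits / denom
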