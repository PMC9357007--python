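"""Matrisome temporal-proteomics pipeline.

Operates on a raw-intensity proteins x samples matrix with a 2-tissue
(healthy / tumour) x 3-stage (early / mid / late) design: presence
filtering, log2 median-centred transformation, multi-sample ANOVA and
two-group volcano statistics with Benjamini-Hochberg FDR control,
agglomerative temporal clustering of condition-median z-profiles into
four canonical clusters, Fisher-exact matrisome-category enrichment, and
a PCA summary. Missing values are never imputed: proteins that cannot be
tested are flagged untestable rather than significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

TISSUES = ("healthy", "tumour")
STAGES = ("early", "mid", "late")

MATRISOME_DIVISIONS = {
    "core matrisome": ("collagens", "ECM glycoproteins", "proteoglycans"),
    "matrisome-associated": ("ECM regulators", "ECM-affiliated proteins",
                             "secreted factors"),
}


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the sample table covers exactly the six tissue x stage groups."""
    missing = {"tissue", "stage"} - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    bad_t = set(design["tissue"]) - set(TISSUES)
    bad_s = set(design["stage"]) - set(STAGES)
    if bad_t or bad_s:
        raise ValueError(f"unknown tissue/stage labels: {bad_t | bad_s}")
    groups = design.groupby(["tissue", "stage"], observed=True).size()
    if len(groups) != 6:
        raise ValueError("design must contain all six tissue x stage groups")
    return design


def filter_presence(matrix: pd.DataFrame, min_frac: float = 0.70) -> pd.DataFrame:
    """Keep proteins present (non-missing) in at least ``min_frac`` of all
    samples. Raises if nothing survives."""
    present = matrix.notna().mean(axis=1)
    kept = matrix.loc[present >= min_frac]
    if kept.empty:
        raise ValueError("presence filter removed every protein")
    return kept


def transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and per-sample median-centre a raw-intensity matrix."""
    if (matrix <= 0).any().any():
        raise ValueError("raw intensities must be positive")
    logm = np.log2(matrix)
    return logm - logm.median(axis=0)


def condition_medians(transformed: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Median over replicates per tissue x stage condition (six columns,
    healthy early..late then tumour early..late)."""
    cols = []
    out = {}
    for t in TISSUES:
        for s in STAGES:
            samples = design.index[(design["tissue"] == t) & (design["stage"] == s)]
            name = f"{t}_{s}"
            cols.append(name)
            out[name] = transformed[samples].median(axis=1)
    return pd.DataFrame(out, columns=cols)


def zscore_profiles(medians: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score of the condition-median profile. Proteins with
    any fully-missing condition, or zero profile variance, are dropped."""
    complete = medians.dropna()
    mu = complete.mean(axis=1)
    sd = complete.std(axis=1, ddof=1)
    keep = sd > 0
    return complete.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # columns F, p, q, significant, testable
    fdr: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def multi_sample_anova(
    transformed: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.05,
    min_per_group: int = 2,
) -> AnovaResult:
    """One-way ANOVA across the six tissue x stage groups, per protein,
    with Benjamini-Hochberg q-values at the given FDR.

    A protein is testable when at least two groups have at least
    ``min_per_group`` non-missing observations and there is non-zero
    within-group variance; untestable or degenerate proteins are flagged
    and never counted significant.
    """
    validate_design(design)
    group_cols = [
        design.index[(design["tissue"] == t) & (design["stage"] == s)].tolist()
        for t in TISSUES for s in STAGES
    ]
    F = np.full(len(transformed), np.nan)
    p = np.full(len(transformed), np.nan)
    testable = np.zeros(len(transformed), dtype=bool)
    values = [transformed[cols].to_numpy() for cols in group_cols]
    for i in range(len(transformed)):
        groups = []
        for v in values:
            obs = v[i][~np.isnan(v[i])]
            if obs.size >= min_per_group:
                groups.append(obs)
        if len(groups) < 2:
            continue
        if all(np.ptp(g) == 0 for g in groups):
            continue  # zero within-group variance everywhere: degenerate
        res = stats.f_oneway(*groups)
        if np.isfinite(res.pvalue):
            F[i], p[i] = res.statistic, res.pvalue
            testable[i] = True
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = _bh_qvalues(p[testable])
    table = pd.DataFrame({
        "F": F, "p": p, "q": q,
        "significant": testable & (q <= fdr),
        "testable": testable,
    }, index=transformed.index)
    return AnovaResult(table, fdr)


def two_group_volcano(
    transformed: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    fdr: float = 0.05,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Welch t-test of tumour vs healthy at one stage.

    Returns per-protein ``log2fc`` (tumour minus healthy group mean of
    transformed values), ``t``, ``p``, ``q`` and ``significant``.
    """
    validate_design(design)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    h_cols = design.index[(design["tissue"] == "healthy") & (design["stage"] == stage)]
    t_cols = design.index[(design["tissue"] == "tumour") & (design["stage"] == stage)]
    hv = transformed[h_cols].to_numpy()
    tv = transformed[t_cols].to_numpy()
    n = len(transformed)
    lfc = np.full(n, np.nan)
    tstat = np.full(n, np.nan)
    p = np.full(n, np.nan)
    testable = np.zeros(n, dtype=bool)
    for i in range(n):
        a = tv[i][~np.isnan(tv[i])]
        b = hv[i][~np.isnan(hv[i])]
        if a.size < min_per_group or b.size < min_per_group:
            continue
        lfc[i] = a.mean() - b.mean()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        if np.isfinite(res.pvalue):
            tstat[i], p[i] = res.statistic, res.pvalue
            testable[i] = True
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = _bh_qvalues(p[testable])
    return pd.DataFrame({
        "log2fc": lfc, "t": tstat, "p": p, "q": q,
        "significant": testable & (q <= fdr), "testable": testable,
    }, index=transformed.index)


@dataclass
class TemporalClusterResult:
    labels: pd.Series            # 'C1'..'Ck' per clustered protein
    cluster_medians: pd.DataFrame  # per-cluster median z-profile
    linkage_matrix: np.ndarray
    excluded: list[str]          # proteins dropped for incomplete profiles


def temporal_cluster(
    z_profiles: pd.DataFrame,
    k: int = 4,
    linkage: str = "average",
) -> TemporalClusterResult:
    """Agglomerative clustering of condition-median z-profiles.

    Euclidean distance, configurable linkage; the tree is cut at ``k``
    clusters and labels are renumbered canonically by descending mean
    tumour-late z so 'C1' is always the most tumour-late-elevated
    cluster, independent of input order.
    """
    complete = z_profiles.dropna()
    excluded = [p for p in z_profiles.index if p not in complete.index]
    if k > len(complete):
        raise ValueError(f"k={k} exceeds the {len(complete)} clusterable proteins")
    Z = hierarchy.linkage(complete.to_numpy(), method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    tumour_late = complete["tumour_late"]
    order = sorted(
        np.unique(raw),
        key=lambda c: -tumour_late[raw == c].mean(),
    )
    rename = {c: f"C{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=complete.index, name="cluster")
    medians = complete.groupby(labels).median()
    return TemporalClusterResult(labels, medians, Z, excluded)


def category_enrichment(
    labels: pd.Series,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher exact association of matrisome categories with clusters.

    ``annotation`` maps protein -> division / category. For each
    (cluster, category) pair a 2x2 table (in-cluster x in-category over
    the clustered proteins) is tested two-sided; q-values are BH over all
    pairs.
    """
    missing = [p for p in labels.index if p not in annotation.index]
    if missing:
        raise ValueError(f"{len(missing)} clustered proteins lack annotation")
    cats = annotation.loc[labels.index, "category"]
    rows = []
    for cl in sorted(labels.unique()):
        in_cl = labels == cl
        for cat in sorted(cats.unique()):
            in_cat = cats == cat
            if not in_cat.any():
                raise ValueError(f"category {cat!r} absent from the data")
            a = int((in_cl & in_cat).sum())
            b = int((in_cl & ~in_cat).sum())
            c = int((~in_cl & in_cat).sum())
            d = int((~in_cl & ~in_cat).sum())
            _, pval = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"cluster": cl, "category": cat,
                         "a": a, "b": b, "c": c, "d": d, "p": pval})
    out = pd.DataFrame(rows)
    out["q"] = _bh_qvalues(out["p"].to_numpy())
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x PCs
    loadings: pd.DataFrame      # proteins x PCs
    variance_ratio: np.ndarray
    top_loadings: dict[str, list[str]]


def pca_summary(
    transformed: pd.DataFrame,
    n_components: int = 2,
    n_top: int = 10,
) -> PCAResult:
    """SVD-based PCA of samples over the complete-protein subset.

    Only proteins present in every sample enter (no imputation). Scores
    are per sample, loadings per protein; the proteins with the largest
    absolute loadings are reported per component.
    """
    complete = transformed.dropna()
    X = complete.to_numpy().T  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("need at least two samples for PCA")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2 / (X.shape[0] - 1)
    ratio = var / var.sum()
    ncomp = min(n_components, len(S))
    pcs = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(U[:, :ncomp] * S[:ncomp], index=transformed.columns,
                          columns=pcs)
    loadings = pd.DataFrame(Vt[:ncomp].T, index=complete.index, columns=pcs)
    top = {pc: loadings[pc].abs().nlargest(n_top).index.tolist() for pc in pcs}
    return PCAResult(scores, loadings, ratio[:ncomp], top)


def run_matrisome_pipeline(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    min_presence: float = 0.70,
    fdr: float = 0.05,
    k: int = 4,
    linkage: str = "average",
) -> dict:
    """Full pipeline: presence filter -> transform -> ANOVA -> clustering
    (significant proteins only) -> optional category enrichment -> PCA."""
    validate_design(design)
    filtered = filter_presence(matrix, min_presence)
    logm = transform(filtered)
    anova = multi_sample_anova(logm, design, fdr=fdr)
    medians = condition_medians(logm, design)
    sig = anova.table.index[anova.table["significant"]]
    z = zscore_profiles(medians.loc[medians.index.intersection(sig)])
    out = {
        "n_input": len(matrix), "n_filtered": len(filtered),
        "transformed": logm, "anova": anova, "medians": medians,
    }
    if len(z) >= k:
        clusters = temporal_cluster(z, k=k, linkage=linkage)
        out["clusters"] = clusters
        if annotation is not None:
            out["enrichment"] = category_enrichment(clusters.labels, annotation)
    out["pca"] = pca_summary(logm)
    return out
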