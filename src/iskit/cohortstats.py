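"""Cross-sample statistics for integration-site cohorts.

Covers the outcome-group summaries, per-gene differential integration
between outcome groups (presence/absence Fisher exact tests with
Benjamini–Hochberg control and a pseudocounted log2 enrichment), Pearson
covariate correlations stratified by vector class, two-sample t-tests, and
sample-level PCA of normalized gene-integration matrices.

The per-gene differential test uses presence/absence rather than counts:
with cohort sizes around n ≈ 28 a 2×2 exact test is robust to the heavy
PCR skew of per-sample event counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "vector_class", "car_target", "disease", "gender",
    "cd4_pct", "cd8_pct", "transduction_eff_pct", "vcn",
]
OUTCOME_COLUMNS = ["sample_id", "response", "crs", "hlh"]


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    for col in ("cd4_pct", "cd8_pct", "transduction_eff_pct"):
        bad = df[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            raise ValueError(f"{col} outside [0, 100] for samples {list(bad.sample_id)}")
    if (df["vcn"] < 0).any():
        raise ValueError("vcn must be non-negative")
    return df


def load_example_outcomes() -> pd.DataFrame:
    """Packaged example clinical-outcomes table.

    Synthetic sample ids carrying the outcome composition of a 28-product
    CD22 CAR T-cell cohort: 23 objective responders (OR) / 5 non-responders
    (NR); 4 high-grade vs 24 low-grade cytokine release syndrome; 13 with and
    15 without carHLH-like toxicity.
    """
    with importlib.resources.files("iskit.data").joinpath("cohort_outcomes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def group_summary(meta: pd.DataFrame, field: str) -> pd.DataFrame:
    """Counts and percentages per category of one outcome/covariate column.

    Percentages are 100 × count / total over non-missing values, rounded to
    one decimal for reporting.
    """
    if field not in meta.columns:
        raise KeyError(f"field {field!r} not in table")
    vals = meta[field].dropna()
    counts = vals.value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.values,
            "percent": np.round(100.0 * counts.values / total, 1),
        }
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return q


@dataclass
class DiffIntResult:
    gene_id: str
    n_with_a: int
    n_a: int
    n_with_b: int
    n_b: int
    log2_enrichment: float
    p_value: float
    q_value: float


def differential_integration(
    presence: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> list[DiffIntResult]:
    """Per-gene differential integration between two sample groups.

    ``presence`` is a gene × sample boolean matrix. Each gene contributes a
    2×2 table (with event / without) × (group A / group B) tested two-sided
    by Fisher's exact test; q-values are BH over the tested genes. The
    enrichment is log2 of the pseudocounted prevalence ratio
    ((n_with_A + 0.5)/(n_A + 1)) / ((n_with_B + 0.5)/(n_B + 1)), positive
    when group A is more often hit. Genes with no event in either group are
    excluded.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    n_a, n_b = len(group_a), len(group_b)
    rows = []
    for gene in presence.index:
        wa = int(presence.loc[gene, group_a].sum())
        wb = int(presence.loc[gene, group_b].sum())
        if wa == 0 and wb == 0:
            continue
        p = fisher_exact_2x2(wa, n_a - wa, wb, n_b - wb)
        enr = np.log2(((wa + 0.5) / (n_a + 1)) / ((wb + 0.5) / (n_b + 1)))
        rows.append((gene, wa, wb, p, enr))
    if not rows:
        return []
    qvals = bh_adjust([r[3] for r in rows])
    return [
        DiffIntResult(gene, wa, n_a, wb, n_b, float(enr), float(p), float(q))
        for (gene, wa, wb, p, enr), q in zip(rows, qvals)
    ]


def diffint_frame(results: Sequence[DiffIntResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.n_with_a, r.n_a, r.n_with_b, r.n_b, r.log2_enrichment, r.p_value, r.q_value)
            for r in results
        ],
        columns=["gene_id", "n_with_A", "n_A", "n_with_B", "n_B", "log2_enrichment", "p_value", "q_value"],
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment r with the two-tailed t-distribution p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ttest_two_sample(a: Sequence[float], b: Sequence[float], equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class PcaResult:
    scores: np.ndarray  # samples × components
    loadings: np.ndarray  # features × components
    pct_variance: np.ndarray  # per component, sums to 100
    sample_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca_samples(matrix: pd.DataFrame) -> PcaResult:
    """PCA of a samples × genes matrix via SVD of the column-centered data."""
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    pct = 100.0 * var / total if total > 0 else np.zeros_like(var)
    return PcaResult(scores=u * s, loadings=vt.T, pct_variance=pct, sample_ids=list(matrix.index))


def covariate_scan(
    coverage: pd.DataFrame, meta: pd.DataFrame, covariate: str
) -> pd.DataFrame:
    """Pearson r between feature-coverage percentages and one covariate,
    per vector-class stratum and feature class.

    ``coverage`` has columns sample_id, feature_class, percent. Strata with
    fewer than 3 samples are reported with r/p = NaN (not computable).
    """
    if covariate not in meta.columns:
        raise KeyError(f"covariate {covariate!r} not in metadata")
    coverage = coverage.drop(columns=["vector_class"], errors="ignore")
    merged = coverage.merge(meta[["sample_id", "vector_class", covariate]], on="sample_id")
    rows = []
    for (vclass, fclass), sub in merged.groupby(["vector_class", "feature_class"], sort=True):
        sub = sub.dropna(subset=[covariate])
        n = len(sub)
        if n < 3 or sub["percent"].std() == 0 or sub[covariate].std() == 0:
            rows.append((fclass, vclass, covariate, n, np.nan, np.nan))
            continue
        r, p = pearson_corr(sub["percent"], sub[covariate])
        rows.append((fclass, vclass, covariate, n, r, p))
    return pd.DataFrame(rows, columns=["feature_class", "vector_class", "covariate", "n", "r", "p"])
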