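"""Group comparisons and correlation analyses.

Nonparametric throughout: two-sided Mann-Whitney U for two groups,
Kruskal-Wallis followed by Dunn's pairwise z-tests for three or more, and
Spearman correlation for metric-vs-expression associations. Multiple-testing
control is Benjamini-Hochberg, applied within explicitly labelled families.
Groups below the minimum sample size produce not-testable results with a
reason code rather than being dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_MIN_SAMPLES = 3

#: Largest combined sample size at which the exact Mann-Whitney null
#: distribution is used (only when there are no ties).
EXACT_MW_MAX_N = 20


@dataclass
class ComparisonResult:
    metric: str
    locus: str
    grouping: str
    test: str  # mann-whitney | kruskal-wallis | dunn
    statistic: float = float("nan")
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    group_n: dict = field(default_factory=dict)
    group_median: dict = field(default_factory=dict)
    family: str = ""
    testable: bool = True
    reason: str = ""


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    stratum: str  # LSP | HSP | all
    rho: float = float("nan")
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    n: int = 0
    family: str = ""
    testable: bool = True
    reason: str = ""


@dataclass
class SignatureScore:
    signature: str
    sample_id: str
    score: float
    coverage: float  # fraction of the gene set found in the matrix


def log2p1(values) -> np.ndarray:
    """Element-wise log2(value + 1); rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("log2p1 requires non-negative values")
    return np.log2(arr + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def mann_whitney(
    group_a,
    group_b,
    metric: str = "",
    locus: str = "",
    grouping: str = "",
    labels: tuple[str, str] = ("A", "B"),
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test with missing-value exclusion.

    Uses the exact null distribution for small tie-free samples (combined
    n <= 20), otherwise the normal approximation with tie correction.
    """
    a, b = _clean(group_a), _clean(group_b)
    result = ComparisonResult(
        metric=metric, locus=locus, grouping=grouping, test="mann-whitney",
        group_n={labels[0]: len(a), labels[1]: len(b)},
        group_median={
            labels[0]: float(np.median(a)) if len(a) else float("nan"),
            labels[1]: float(np.median(b)) if len(b) else float("nan"),
        },
    )
    if len(a) < min_samples or len(b) < min_samples:
        result.testable = False
        result.reason = f"group below min_samples={min_samples}"
        return result
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and len(combined) <= EXACT_MW_MAX_N:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    result.statistic = float(res.statistic)
    result.p_raw = float(min(res.pvalue, 1.0))
    return result


def _dunn_pairwise(
    groups: Mapping[str, np.ndarray]
) -> list[tuple[str, str, float, float]]:
    """Dunn's z-tests on pooled midranks with tie correction.

    Returns (label_i, label_j, z, two-sided p) for every pair.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        size = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + size].mean())
        sizes[g] = size
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    variance_unit = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            se = np.sqrt(variance_unit * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[gi] - mean_ranks[gj]) / se
                p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
            out.append((gi, gj, float(z), p))
    return out


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    metric: str = "",
    locus: str = "",
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> list[ComparisonResult]:
    """Kruskal-Wallis omnibus test plus BH-adjusted Dunn pairwise tests.

    Requires at least three groups meeting ``min_samples``; with fewer, use
    :func:`mann_whitney`.
    """
    cleaned = {g: _clean(v) for g, v in groups.items()}
    eligible = {g: v for g, v in cleaned.items() if len(v) >= min_samples}
    if len(eligible) < 3:
        raise ValueError(
            f"kruskal_dunn needs >= 3 groups with >= {min_samples} values "
            f"(got {len(eligible)}); use mann_whitney for two groups"
        )
    family = f"dunn:{metric}:{locus}" if metric or locus else "dunn"
    arrays = list(eligible.values())
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        h_stat, p_omni = 0.0, 1.0  # identical groups: no evidence, H = 0
    else:
        h_stat, p_omni = sps.kruskal(*arrays)
    omnibus = ComparisonResult(
        metric=metric, locus=locus, grouping="omnibus", test="kruskal-wallis",
        statistic=float(h_stat), p_raw=float(p_omni), p_adj=float(p_omni),
        group_n={g: len(v) for g, v in eligible.items()},
        group_median={g: float(np.median(v)) for g, v in eligible.items()},
        family=family,
    )
    results = [omnibus]
    pairs = _dunn_pairwise(eligible)
    adj = bh_adjust([p for (_, _, _, p) in pairs])
    for (gi, gj, z, p), p_adj in zip(pairs, adj):
        results.append(
            ComparisonResult(
                metric=metric, locus=locus, grouping=f"{gi}-vs-{gj}", test="dunn",
                statistic=z, p_raw=p, p_adj=float(p_adj),
                group_n={gi: len(eligible[gi]), gj: len(eligible[gj])},
                group_median={
                    gi: float(np.median(eligible[gi])),
                    gj: float(np.median(eligible[gj])),
                },
                family=family,
            )
        )
    for g, v in cleaned.items():
        if g not in eligible:
            results.append(
                ComparisonResult(
                    metric=metric, locus=locus, grouping=g, test="dunn",
                    group_n={g: len(v)}, family=family,
                    testable=False, reason=f"group below min_samples={min_samples}",
                )
            )
    return results


def spearman_matrix(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    strata: pd.Series,
    metric_columns: Sequence[str] = ("abundance", "entropy"),
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Spearman correlations of per-locus chain metrics against covariates.

    ``metrics`` is the long per-(sample, locus) metrics table; ``covariates``
    is sample-indexed with one column per marker gene or signature;
    ``strata`` maps sample_id -> phenotype label. Correlations are computed
    per stratum and pooled ("all"), excluding missing values pairwise, and
    BH-adjusted within each (stratum, locus, metric) family.
    """
    samples = sorted(
        set(metrics["sample_id"]) & set(covariates.index) & set(strata.index)
    )
    if not samples:
        raise ValueError("no overlapping samples between metrics and covariates")
    strata = strata.loc[samples]
    stratum_samples = {"all": samples}
    for label in sorted(strata.unique()):
        stratum_samples[label] = [s for s in samples if strata[s] == label]

    results: list[CorrelationResult] = []
    wide = metrics.pivot_table(
        index="sample_id", columns="locus", values=list(metric_columns)
    )
    for stratum, sset in stratum_samples.items():
        for metric_col in metric_columns:
            for locus in sorted(metrics["locus"].unique()):
                if (metric_col, locus) not in wide.columns:
                    continue
                family = f"{stratum}:{metric_col}:{locus}"
                family_results: list[CorrelationResult] = []
                x_full = wide[(metric_col, locus)].reindex(sset)
                for cov in covariates.columns:
                    y_full = covariates[cov].reindex(sset)
                    mask = x_full.notna() & y_full.notna()
                    x, y = x_full[mask].to_numpy(), y_full[mask].to_numpy()
                    res = CorrelationResult(
                        x_name=f"{locus}:{metric_col}", y_name=cov,
                        stratum=stratum, n=int(mask.sum()), family=family,
                    )
                    if len(x) < min_n:
                        res.testable, res.reason = False, f"n < {min_n}"
                    elif np.ptp(x) == 0 or np.ptp(y) == 0:
                        res.testable, res.reason = False, "zero variance"
                    else:
                        rho, p = sps.spearmanr(x, y)
                        res.rho, res.p_raw = float(rho), float(min(max(p, 0.0), 1.0))
                    family_results.append(res)
                testable = [r for r in family_results if r.testable]
                if testable:
                    adj = bh_adjust([max(r.p_raw, np.nextafter(0, 1)) for r in testable])
                    for r, p_adj in zip(testable, adj):
                        r.p_adj = float(p_adj)
                results.extend(family_results)
    return results


def signature_score(
    expr: pd.DataFrame, gene_set: Sequence[str], name: str = "signature"
) -> list[SignatureScore]:
    """Mean log2(TPM+1) over the gene set's present genes, per sample."""
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError(
            f"none of the genes in set {name!r} found in matrix: {sorted(gene_set)}"
        )
    coverage = len(present) / len(gene_set)
    means = expr.loc[present].mean(axis=0)
    return [
        SignatureScore(signature=name, sample_id=str(s), score=float(v), coverage=coverage)
        for s, v in means.items()
    ]


def read_gene_sets(path) -> dict[str, list[str]]:
    """Parse a gene-set file: one set per line, ``name<TAB>gene,gene,...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, genes = line.partition("\t")
            sets[name] = [g.strip() for g in genes.split(",") if g.strip()]
    return sets


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric, "locus": r.locus, "grouping": r.grouping,
                "test": r.test, "statistic": r.statistic,
                "p_raw": r.p_raw, "p_adj": r.p_adj, "family": r.family,
                "group_n": ";".join(f"{k}={v}" for k, v in r.group_n.items()),
                "group_median": ";".join(f"{k}={v:.6g}" for k, v in r.group_median.items()),
                "testable": r.testable, "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": r.x_name, "y": r.y_name, "stratum": r.stratum,
                "rho": r.rho, "p_raw": r.p_raw, "p_adj": r.p_adj, "n": r.n,
                "family": r.family, "testable": r.testable, "reason": r.reason,
            }
            for r in results
        ]
    )
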