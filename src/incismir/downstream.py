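"""Clinical association scans, survival, miRNA-mRNA correlation, screen hits.

Replicated in-cis miRNAs are scanned for differential expression across
clinical and molecular subgroups (Wilcoxon rank-sum for two-level
variables, Kruskal-Wallis for histological grade), BH-adjusted per variable
per cohort; relapse-free survival is compared between median-split
expression groups with a log-rank test; candidate miRNAs are correlated to
mRNA expression (Spearman |rho| > 0.3, cross-cohort sign-consistent); and
functional-screen endpoints are called significant at |0.2| (log2
viability) or |z| > 1.96 (lysate-array z-scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .incis import bh_adjust, rank_sum_test, spearman
from .matrix import LocusSampleMatrix

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "sample_id", "er", "her2", "grade", "tp53", "subtype", "rfs_time", "rfs_event",
]

#: two-level clinical variables and their (reference, comparison) levels
TWO_LEVEL_VARIABLES = {
    "er": ("neg", "pos"),
    "her2": ("neg", "pos"),
    "tp53": ("wildtype", "mutant"),
    "subtype": ("basal", "luminal"),
}


@dataclass
class AssociationResult:
    locus_id: str
    variable: str
    test: str  # wilcoxon | kruskal_wallis
    p: float
    q: float = np.nan
    direction: str = ""
    significant: bool = False


@dataclass
class ScreenMeasurement:
    cell_line: str
    mirna: str
    endpoint: str  # viability | ki67 | cparp | pakt
    normalized_value: float
    z: float = np.nan
    hit: bool = False


@dataclass
class SurvivalSplitResult:
    locus_id: str
    low_samples: tuple
    high_samples: tuple
    statistic: float = np.nan
    p: float = np.nan
    testable: bool = False


def read_clinical(path) -> pd.DataFrame:
    """Read the tab-separated clinical table; empty fields become missing."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=[""])
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    return df.set_index("sample_id", drop=False)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def association_scan(
    expression: LocusSampleMatrix,
    clinical: pd.DataFrame,
    variable: str,
    min_group_size: int = 3,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Differential-expression scan of one clinical variable across loci.

    Two-level variables use the Wilcoxon rank-sum test; ``grade`` uses
    Kruskal-Wallis (tie-corrected, chi-square p).  BH adjustment across
    loci; direction is described from group medians (grade direction from
    the Spearman sign of expression vs grade).
    """
    shared = [s for s in expression.data.columns if s in clinical.index]
    values = clinical.loc[shared, variable]
    groups = values.dropna()
    levels = sorted(groups.unique(), key=str)
    usable_levels = [
        lv for lv in levels if (groups == lv).sum() >= min_group_size
    ]
    if len(usable_levels) < 2:
        log.warning("variable %r has <2 usable levels; scan skipped", variable)
        return []
    results = []
    for locus_id, row in expression.data[shared].iterrows():
        by_level = [
            row[groups.index[groups == lv]].dropna().to_numpy() for lv in usable_levels
        ]
        if any(len(g) < min_group_size for g in by_level):
            continue
        if variable == "grade" and len(usable_levels) > 2:
            try:
                h, p = sps.kruskal(*by_level)
            except ValueError:
                h, p = 0.0, 1.0
            if not np.isfinite(p):  # degenerate tie correction: identical values
                h, p = 0.0, 1.0
            rho = spearman(
                row[groups.index].to_numpy(), groups.astype(float).to_numpy()
            )
            direction = (
                "increasing with grade" if rho > 0 else "decreasing with grade"
            )
            results.append(
                AssociationResult(locus_id, variable, "kruskal_wallis", float(p), direction=direction)
            )
        else:
            ref, cmp_ = by_level[0], by_level[-1]
            _, p = rank_sum_test(cmp_, ref)
            direction = (
                f"up in {usable_levels[-1]}"
                if np.median(cmp_) > np.median(ref)
                else f"up in {usable_levels[0]}"
            )
            results.append(
                AssociationResult(locus_id, variable, "wilcoxon", float(p), direction=direction)
            )
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
            r.significant = q < alpha
    return results


def consistent_associations(
    results_a: list[AssociationResult],
    results_b: list[AssociationResult],
    alpha: float = 0.05,
) -> list[tuple[AssociationResult, AssociationResult]]:
    """Associations significant in both cohorts with concordant direction."""
    index_b = {(r.locus_id, r.variable): r for r in results_b}
    out = []
    for ra in results_a:
        rb = index_b.get((ra.locus_id, ra.variable))
        if rb is None:
            continue
        if ra.q < alpha and rb.q < alpha and ra.direction == rb.direction:
            out.append((ra, rb))
    return out


def survival_median_split(
    expression_row: pd.Series, clinical: pd.DataFrame
) -> SurvivalSplitResult:
    """Log-rank comparison of relapse-free survival between expression halves.

    Samples with expression strictly below the median form the low group;
    samples exactly at the median join the low group; the rest are high.
    Requires at least two events overall; tied event times use the standard
    hypergeometric variance.
    """
    locus_id = str(expression_row.name)
    surv = clinical[["rfs_time", "rfs_event"]].dropna()
    shared = [s for s in expression_row.index if s in surv.index]
    expr = expression_row[shared].dropna()
    if expr.empty:
        return SurvivalSplitResult(locus_id, (), ())
    med = float(expr.median())
    low = tuple(expr.index[expr <= med])
    high = tuple(expr.index[expr > med])
    events = surv.loc[list(expr.index), "rfs_event"].sum()
    if events < 2 or not low or not high:
        return SurvivalSplitResult(locus_id, low, high)
    res = logrank_test(
        surv.loc[list(low), "rfs_time"],
        surv.loc[list(high), "rfs_time"],
        event_observed_A=surv.loc[list(low), "rfs_event"],
        event_observed_B=surv.loc[list(high), "rfs_event"],
    )
    return SurvivalSplitResult(
        locus_id, low, high, float(res.test_statistic), float(res.p_value), True
    )


def mirna_mrna_correlation(
    mirna: LocusSampleMatrix,
    mrna: LocusSampleMatrix,
    rho_threshold: float = 0.3,
) -> pd.DataFrame:
    """Spearman rho for every (miRNA, gene) pair over shared samples.

    Returns a long DataFrame (mirna, gene, rho, n, selected) where selected
    means |rho| > threshold.  Pairs with fewer than 3 complete observations
    are skipped.
    """
    shared = [s for s in mirna.data.columns if s in mrna.data.columns]
    rows = []
    mrna_sub = mrna.data[shared]
    for mir_id, mrow in mirna.data[shared].iterrows():
        x = mrow.to_numpy(dtype=float)
        for gene, grow in mrna_sub.iterrows():
            y = grow.to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            rho = spearman(x[ok], y[ok])
            rows.append(
                {
                    "mirna": mir_id,
                    "gene": gene,
                    "rho": rho,
                    "n": int(ok.sum()),
                    "selected": bool(abs(rho) > rho_threshold),
                }
            )
    return pd.DataFrame(rows, columns=["mirna", "gene", "rho", "n", "selected"])


def consistent_correlations(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Pairs selected in both cohorts with the same correlation sign."""
    merged = table_a.merge(table_b, on=["mirna", "gene"], suffixes=("_a", "_b"))
    keep = (
        merged["selected_a"]
        & merged["selected_b"]
        & (np.sign(merged["rho_a"]) == np.sign(merged["rho_b"]))
    )
    return merged.loc[keep, ["mirna", "gene", "rho_a", "rho_b"]].reset_index(drop=True)


VIABILITY_THRESHOLD = 0.2
ZSCORE_THRESHOLD = 1.96


def screen_hit_call(measurements: pd.DataFrame) -> list[ScreenMeasurement]:
    """Call functional-screen hits per endpoint.

    Viability values (already plate-normalized, log2): hit iff
    |value| > 0.2.  Lysate-array endpoints (ki67, cparp, pakt): values are
    standardized against the whole screen's mean and SD and hit iff
    |z| > 1.96.  A zero screen SD is an error.
    """
    out: list[ScreenMeasurement] = []
    for endpoint, sub in measurements.groupby("endpoint", sort=True):
        vals = sub["normalized_value"].to_numpy(dtype=float)
        if endpoint == "viability":
            for r, v in zip(sub.itertuples(), vals):
                out.append(
                    ScreenMeasurement(
                        r.cell_line, r.mirna, endpoint, float(v),
                        hit=bool(abs(v) > VIABILITY_THRESHOLD),
                    )
                )
        else:
            sd = float(np.std(vals, ddof=1))
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"endpoint {endpoint!r}: zero screen SD")
            mean = float(np.mean(vals))
            for r, v in zip(sub.itertuples(), vals):
                z = (v - mean) / sd
                out.append(
                    ScreenMeasurement(
                        r.cell_line, r.mirna, endpoint, float(v), z=float(z),
                        hit=bool(abs(z) > ZSCORE_THRESHOLD),
                    )
                )
    return out


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in results],
            "variable": [r.variable for r in results],
            "test": [r.test for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )
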