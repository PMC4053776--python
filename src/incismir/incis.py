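"""The in-cis discovery machine.

For every miRNA locus, patients are split into 'altered' and 'non-altered'
groups under two scenarios (activating: gain/hypomethylation raising
expression; silencing: loss/hypermethylation lowering it) and three test
categories (copy number alone, methylation alone, or both combined), and a
Wilcoxon rank-sum test asks whether expression differs between the groups.
P-values are Benjamini-Hochberg adjusted within each (scenario, category)
test family; FDR < 0.05 together with the expected correlation sign
(positive copy-number/expression, negative methylation/expression) declares
a locus in-cis.  Candidates are then re-tested in an independent cohort at
uncorrected p < 0.05 with matching aberration type, and multi-locus seed
families are scored for complementary activating aberrations across
patients.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .aberration import AberrationMatrix
from .matrix import LocusSampleMatrix

log = logging.getLogger(__name__)

SCENARIOS = ("activating", "silencing")
CATEGORIES = ("copy_number", "methylation", "combined")


@dataclass(frozen=True)
class TestSpec:
    scenario: str
    category: str

    def __post_init__(self):
        if self.scenario not in SCENARIOS or self.category not in CATEGORIES:
            raise ValueError(f"invalid test spec {self.scenario}/{self.category}")


TestSpec.__test__ = False  # not a pytest class

ALL_SPECS = tuple(
    TestSpec(s, c) for s, c in itertools.product(SCENARIOS, CATEGORIES)
)

#: aberration states counted as 'altered' per scenario and axis
_CN_TARGET = {"activating": "gain", "silencing": "loss"}
_METH_TARGET = {"activating": "hypo", "silencing": "hyper"}


@dataclass
class InCisConfig:
    fdr_alpha: float = 0.05
    replication_alpha: float = 0.05
    min_group_size: int = 3

    def __post_init__(self):
        for a in (self.fdr_alpha, self.replication_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError(f"alpha must be in (0,1), got {a}")


@dataclass
class InCisResult:
    locus_id: str
    spec: TestSpec
    n_altered: int
    n_ref: int
    W: float = np.nan
    p: float = np.nan
    q: float = np.nan
    rho_cn: float = np.nan
    rho_meth: float = np.nan
    passes_direction: bool = False
    testable: bool = False
    significant: bool = False


@dataclass
class InCisMirna:
    locus_id: str
    effect: str  # activating | silencing | both
    driver_class: str  # copy_number | methylation | combination


@dataclass
class FamilyAberrationProfile:
    family_id: str
    locus_ids: tuple
    member_state: pd.DataFrame  # member loci x samples, activating aberration flag
    overall: pd.Series = field(default=None)  # OR across members
    fraction_altered: float = np.nan

    def __post_init__(self):
        self.overall = self.member_state.any(axis=0)
        self.fraction_altered = float(self.overall.mean()) if len(self.overall) else np.nan


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the mid-rank sum of the first group.  The p-value is exact
    (permutation enumeration of the rank-sum distribution) when the pooled
    size is <= 20 with no cross-group ties, otherwise a tie-corrected normal
    approximation with a continuity correction toward the null mean is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n1].sum())
    _, counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(counts > 1))
    if n1 + n2 <= 20 and not has_ties:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        return W, min(1.0, p)
    N = n1 + n2
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return W, 1.0  # all observations identical
    mean_w = n1 * (N + 1) / 2.0
    d = W - mean_w
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return W, min(1.0, float(2.0 * sps.norm.sf(abs(z))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> float:
    """Spearman rho over complete pairs (mid-ranks for ties); NaN if < 3 pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return np.nan
    res = sps.spearmanr(x[ok], y[ok])
    return float(res.statistic)


# ---------------------------------------------------------------------------
# Group construction and direction filtering
# ---------------------------------------------------------------------------

def build_groups(
    locus_id: str, aberrations: AberrationMatrix, spec: TestSpec
) -> tuple[list, list]:
    """Partition samples into (altered, reference) for one locus and test spec.

    Single-axis categories: altered = samples in the scenario's target state
    on that axis; reference = every other sample with a non-missing state on
    that axis (so e.g. losses sit in the reference group of an activating
    copy-number test).  Combined: altered = target state on either axis;
    reference = samples with no aberration at all on both axes.
    """
    cn = aberrations.cn_state.loc[locus_id]
    meth = aberrations.meth_state.loc[locus_id]
    cn_t, meth_t = _CN_TARGET[spec.scenario], _METH_TARGET[spec.scenario]
    if spec.category == "copy_number":
        altered = cn.index[cn == cn_t]
        ref = cn.index[(cn != cn_t) & (cn != "missing")]
    elif spec.category == "methylation":
        altered = meth.index[meth == meth_t]
        ref = meth.index[(meth != meth_t) & (meth != "missing")]
    else:
        altered = cn.index[(cn == cn_t) | (meth == meth_t)]
        ref = cn.index[
            (cn == "neutral") & (meth == "normal")
        ]
    return list(altered), list(ref)


@dataclass
class DirectionCheck:
    rho_cn: float
    rho_meth: float
    passes: bool
    testable: bool


def direction_check(
    expression,
    locus_cn,
    locus_beta,
    spec: TestSpec,
    cn_contributes: bool = True,
    meth_contributes: bool = True,
) -> DirectionCheck:
    """In-cis sign filter on Spearman correlations with expression.

    Copy-number category passes iff rho(cn, expr) > 0; methylation iff
    rho(beta, expr) < 0; combined requires every axis that contributed an
    altered sample to pass.  Fewer than 3 complete pairs on a required axis
    marks the check untestable.
    """
    rho_cn = spearman(locus_cn, expression) if locus_cn is not None else np.nan
    rho_meth = spearman(locus_beta, expression) if locus_beta is not None else np.nan
    if spec.category == "copy_number":
        need = [("cn", rho_cn)]
    elif spec.category == "methylation":
        need = [("meth", rho_meth)]
    else:
        need = []
        if cn_contributes:
            need.append(("cn", rho_cn))
        if meth_contributes:
            need.append(("meth", rho_meth))
    if not need or any(np.isnan(r) for _, r in need):
        return DirectionCheck(rho_cn, rho_meth, passes=False, testable=False)
    passes = all((r > 0) if axis == "cn" else (r < 0) for axis, r in need)
    return DirectionCheck(rho_cn, rho_meth, passes=passes, testable=True)


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------

def _classify_driver(sig_specs: set) -> str:
    cn_sig = any(s.category == "copy_number" for s in sig_specs)
    meth_sig = any(s.category == "methylation" for s in sig_specs)
    if cn_sig and not meth_sig:
        return "copy_number"
    if meth_sig and not cn_sig:
        return "methylation"
    return "combination"


def detect_incis(
    expression: LocusSampleMatrix,
    locus_cn: LocusSampleMatrix,
    locus_beta: LocusSampleMatrix,
    aberrations: AberrationMatrix,
    config: InCisConfig | None = None,
) -> tuple[list[InCisResult], list[InCisMirna]]:
    """Run all six scenario x category tests per locus and call in-cis miRNAs.

    BH adjustment is applied within each (scenario, category) family across
    testable loci; a result is significant when q < fdr_alpha AND the
    correlation-sign filter passes; a locus is in-cis when significant under
    any spec.  Returns every per-spec result plus the in-cis call list with
    effect (activating/silencing/both) and driver class.
    """
    config = config or InCisConfig()
    loci = [l for l in aberrations.loci if l in expression.data.index]
    if not loci:
        log.warning("no loci shared between expression matrix and aberration matrix")
        return [], []
    samples = [s for s in aberrations.samples if s in expression.data.columns]
    results: list[InCisResult] = []
    for spec in ALL_SPECS:
        spec_results = []
        for locus_id in loci:
            altered, ref = build_groups(locus_id, aberrations, spec)
            altered = [s for s in altered if s in samples]
            ref = [s for s in ref if s in samples]
            res = InCisResult(locus_id, spec, len(altered), len(ref))
            expr_row = expression.data.loc[locus_id]
            x = expr_row[altered].dropna()
            y = expr_row[ref].dropna()
            if len(x) >= config.min_group_size and len(y) >= config.min_group_size:
                res.W, res.p = rank_sum_test(x.to_numpy(), y.to_numpy())
                res.testable = True
                cn_row = (
                    locus_cn.data.loc[locus_id, samples]
                    if locus_cn is not None and locus_id in locus_cn.data.index
                    else None
                )
                beta_row = (
                    locus_beta.data.loc[locus_id, samples]
                    if locus_beta is not None and locus_id in locus_beta.data.index
                    else None
                )
                cn_contrib, meth_contrib = _combined_contributions(
                    locus_id, aberrations, spec, altered
                )
                check = direction_check(
                    expr_row[samples], cn_row, beta_row, spec, cn_contrib, meth_contrib
                )
                res.rho_cn, res.rho_meth = check.rho_cn, check.rho_meth
                res.passes_direction = check.passes and check.testable
            else:
                log.debug(
                    "locus %s %s/%s untestable (groups %d vs %d)",
                    locus_id, spec.scenario, spec.category, len(altered), len(ref),
                )
            spec_results.append(res)
        testable = [r for r in spec_results if r.testable]
        if testable:
            qs = bh_adjust([r.p for r in testable])
            for r, q in zip(testable, qs):
                r.q = float(q)
                r.significant = q < config.fdr_alpha and r.passes_direction
        results.extend(spec_results)

    incis = []
    by_locus: dict = {}
    for r in results:
        if r.significant:
            by_locus.setdefault(r.locus_id, set()).add(r.spec)
    for locus_id in loci:
        sig = by_locus.get(locus_id)
        if not sig:
            continue
        scen = {s.scenario for s in sig}
        effect = "both" if scen == {"activating", "silencing"} else scen.pop()
        incis.append(InCisMirna(locus_id, effect, _classify_driver(sig)))
    return results, incis


def _combined_contributions(locus_id, aberrations, spec, altered):
    """Which axes contributed altered samples (drives the combined direction rule)."""
    if spec.category == "copy_number":
        return True, False
    if spec.category == "methylation":
        return False, True
    cn = aberrations.cn_state.loc[locus_id, altered]
    meth = aberrations.meth_state.loc[locus_id, altered]
    return bool((cn == _CN_TARGET[spec.scenario]).any()), bool(
        (meth == _METH_TARGET[spec.scenario]).any()
    )


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationData:
    """Replication-cohort inputs.

    Copy number is typically genome-wide while methylation is assayed only
    for selected loci; absent layers are simply None.  ``paired_meth_states``
    maps a locus to alternative per-CpG methylation state layers (one
    pd.Series of states per assay) when two CpG assays cover one promoter;
    each assay is then tested separately and the larger p-value is reported.
    """

    expression: LocusSampleMatrix
    aberrations: AberrationMatrix
    locus_cn: LocusSampleMatrix | None = None
    locus_beta: LocusSampleMatrix | None = None
    paired_meth_states: dict | None = None


@dataclass
class ReplicationOutcome:
    locus_id: str
    spec: TestSpec
    p: float
    replicated: bool
    assessable: bool
    note: str = ""


def _test_with_states(expr_row, cn_states, meth_states, spec, min_group_size):
    """Rank-sum p for one locus given explicit state Series on both axes."""
    cn_t, meth_t = _CN_TARGET[spec.scenario], _METH_TARGET[spec.scenario]
    if spec.category == "copy_number":
        altered = cn_states.index[cn_states == cn_t]
        ref = cn_states.index[(cn_states != cn_t) & (cn_states != "missing")]
    elif spec.category == "methylation":
        altered = meth_states.index[meth_states == meth_t]
        ref = meth_states.index[(meth_states != meth_t) & (meth_states != "missing")]
    else:
        altered = cn_states.index[(cn_states == cn_t) | (meth_states == meth_t)]
        ref = cn_states.index[(cn_states == "neutral") & (meth_states == "normal")]
    x = expr_row[[s for s in altered if s in expr_row.index]].dropna()
    y = expr_row[[s for s in ref if s in expr_row.index]].dropna()
    if len(x) < min_group_size or len(y) < min_group_size:
        return np.nan
    _, p = rank_sum_test(x.to_numpy(), y.to_numpy())
    return p


def replicate_incis(
    candidates: list[InCisMirna],
    discovery_results: list[InCisResult],
    repl: ReplicationData,
    config: InCisConfig | None = None,
) -> list[ReplicationOutcome]:
    """Re-test discovery candidates in an independent cohort.

    For each candidate, the scenario/category tests significant in discovery
    are re-run on the replication cohort when the axis is measured there;
    uncorrected p < replication_alpha with passing direction check means
    replicated.  When a locus has paired CpG assays, the methylation test is
    run once per assay and the larger p is reported.  Candidates missing
    from the replication expression matrix are dropped from the denominator
    (assessable=False).
    """
    config = config or InCisConfig()
    sig_by_locus: dict = {}
    for r in discovery_results:
        if r.significant:
            sig_by_locus.setdefault(r.locus_id, []).append(r.spec)
    paired = repl.paired_meth_states or {}
    outcomes: list[ReplicationOutcome] = []
    for cand in candidates:
        specs = sig_by_locus.get(cand.locus_id, [])
        if cand.locus_id not in repl.expression.data.index:
            outcomes.append(
                ReplicationOutcome(
                    cand.locus_id, specs[0] if specs else TestSpec("activating", "copy_number"),
                    np.nan, False, False, "not expressed in replication cohort",
                )
            )
            continue
        expr_row = repl.expression.data.loc[cand.locus_id]
        in_ab = cand.locus_id in repl.aberrations.cn_state.index
        for spec in specs:
            has_cn = in_ab and (
                repl.aberrations.cn_state.loc[cand.locus_id] != "missing"
            ).any()
            has_meth = (
                in_ab
                and (repl.aberrations.meth_state.loc[cand.locus_id] != "missing").any()
            ) or cand.locus_id in paired
            if spec.category == "copy_number" and not has_cn:
                outcomes.append(ReplicationOutcome(cand.locus_id, spec, np.nan, False, False, "copy number not measured"))
                continue
            if spec.category == "methylation" and not has_meth:
                outcomes.append(ReplicationOutcome(cand.locus_id, spec, np.nan, False, False, "methylation not assayed"))
                continue
            if spec.category == "combined" and not (has_cn and has_meth):
                outcomes.append(ReplicationOutcome(cand.locus_id, spec, np.nan, False, False, "combined axes not both measured"))
                continue
            cn_states = (
                repl.aberrations.cn_state.loc[cand.locus_id]
                if in_ab
                else pd.Series("missing", index=repl.aberrations.samples)
            )
            if spec.category == "methylation" and cand.locus_id in paired:
                ps = [
                    _test_with_states(expr_row, cn_states, assay_states, spec, config.min_group_size)
                    for assay_states in paired[cand.locus_id]
                ]
                ps = [p for p in ps if np.isfinite(p)]
                p = max(ps) if ps else np.nan
                note = "paired CpG assays: max p reported" if len(ps) > 1 else ""
            else:
                meth_states = (
                    repl.aberrations.meth_state.loc[cand.locus_id]
                    if in_ab
                    else pd.Series("missing", index=repl.aberrations.samples)
                )
                p = _test_with_states(expr_row, cn_states, meth_states, spec, config.min_group_size)
                note = ""
            if not np.isfinite(p):
                outcomes.append(ReplicationOutcome(cand.locus_id, spec, np.nan, False, False, note or "groups below minimum size"))
                continue
            samples = list(repl.expression.data.columns)
            cn_row = (
                repl.locus_cn.data.loc[cand.locus_id, samples]
                if repl.locus_cn is not None and cand.locus_id in repl.locus_cn.data.index
                else None
            )
            beta_row = (
                repl.locus_beta.data.loc[cand.locus_id, samples]
                if repl.locus_beta is not None and cand.locus_id in repl.locus_beta.data.index
                else None
            )
            check = direction_check(expr_row[samples], cn_row, beta_row, spec)
            ok = p < config.replication_alpha and check.passes and check.testable
            outcomes.append(ReplicationOutcome(cand.locus_id, spec, float(p), ok, True, note))
    return outcomes


def replicated_set(outcomes: list[ReplicationOutcome]) -> set:
    """Loci with at least one replicated scenario/category test."""
    return {o.locus_id for o in outcomes if o.replicated}


# ---------------------------------------------------------------------------
# Family complementarity
# ---------------------------------------------------------------------------

def family_complementarity(
    families: dict,
    aberrations: AberrationMatrix,
    incis: list[InCisMirna],
) -> list[FamilyAberrationProfile]:
    """Score multi-locus in-cis families for complementary activating aberrations.

    Per family per sample, a member's activating state is gain OR
    hypomethylation at that member's locus; the family's overall state is
    the OR across members.  Families with fewer than two in-cis members are
    skipped.
    """
    incis_loci = {m.locus_id for m in incis}
    profiles = []
    for family_id in sorted(families):
        members = sorted(
            set(families[family_id]) & incis_loci & set(aberrations.cn_state.index)
        )
        if len(members) < 2:
            continue
        state = (aberrations.cn_state.loc[members] == "gain") | (
            aberrations.meth_state.loc[members] == "hypo"
        )
        profiles.append(FamilyAberrationProfile(family_id, tuple(members), state))
    return profiles


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def results_table(results: list[InCisResult]) -> pd.DataFrame:
    """Flat per-(locus, spec) results table."""
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in results],
            "scenario": [r.spec.scenario for r in results],
            "category": [r.spec.category for r in results],
            "n_altered": [r.n_altered for r in results],
            "n_ref": [r.n_ref for r in results],
            "W": [r.W for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "rho_cn": [r.rho_cn for r in results],
            "rho_meth": [r.rho_meth for r in results],
            "passes_direction": [r.passes_direction for r in results],
            "testable": [r.testable for r in results],
            "significant": [r.significant for r in results],
        }
    )


def incis_summary_table(
    incis: list[InCisMirna], results: list[InCisResult], annotations: list
) -> pd.DataFrame:
    """Per in-cis locus summary: location, best correlations, driver class."""
    ann_by_locus = {a.locus_id: a for a in annotations}
    best_rho: dict = {}
    for r in results:
        if r.testable and r.locus_id in {m.locus_id for m in incis}:
            cur = best_rho.setdefault(r.locus_id, [np.nan, np.nan])
            if np.isfinite(r.rho_cn) and (np.isnan(cur[0]) or abs(r.rho_cn) > abs(cur[0])):
                cur[0] = r.rho_cn
            if np.isfinite(r.rho_meth) and (np.isnan(cur[1]) or abs(r.rho_meth) > abs(cur[1])):
                cur[1] = r.rho_meth
    rows = []
    for m in incis:
        ann = ann_by_locus.get(m.locus_id)
        rho = best_rho.get(m.locus_id, [np.nan, np.nan])
        rows.append(
            {
                "locus_id": m.locus_id,
                "mature_id": ann.mature_id if ann else "",
                "mimat_id": ann.mimat_id if ann else "",
                "location": f"{ann.interval.chrom}:{ann.interval.start}-{ann.interval.end}"
                if ann
                else "",
                "rho_cn": rho[0],
                "rho_meth": rho[1],
                "effect": m.effect,
                "driver_class": m.driver_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "mature_id", "mimat_id", "location",
            "rho_cn", "rho_meth", "effect", "driver_class",
        ],
    )
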