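"""Group construction, rank-sum/BH/Spearman oracles, detection and replication."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from incismir.aberration import AberrationMatrix
from incismir.incis import (
    InCisConfig,
    InCisMirna,
    ReplicationData,
    TestSpec,
    bh_adjust,
    build_groups,
    detect_incis,
    direction_check,
    family_complementarity,
    rank_sum_test,
    replicate_incis,
    spearman,
)
from incismir.matrix import BETA, CN_LOGRATIO, EXPRESSION, LocusSampleMatrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def exact_ranksum_p(x, y):
    """Enumerate all C(n+m, n) group assignments of the pooled sample and
    compute the two-sided tail probability of the observed rank sum."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    ws = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n)]
    ws = np.asarray(ws)
    total = len(ws)
    p = 2 * min((ws <= w_obs + 1e-9).sum(), (ws >= w_obs - 1e-9).sum()) / total
    return min(1.0, p)


def naive_bh(p):
    """Quadratic-time textbook BH: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_pos, m)
        ]
        q[idx] = min(candidates)
    return q


def midrank_spearman(x, y):
    """Rank both vectors with mid-ranks, then Pearson."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


# ---------------------------------------------------------------------------
# rank_sum_test
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_most_extreme_small_case(self):
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_groups_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_groups(self, rng):
        for _ in range(40):
            n, m = rng.integers(3, 9, size=2)
            x, y = rng.normal(size=int(n)), rng.normal(size=int(m))
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_symmetric_in_group_order(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=14)
        assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])

    def test_ties_use_midranks(self):
        w, _ = rank_sum_test([1.0, 2.0], [2.0, 3.0])
        assert w == 1.0 + 2.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_naive_definition(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_bounds_and_monotonicity(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q <= 1.0).all() and (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_tie_heavy_matches_midrank_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=30).astype(float)
            y = rng.integers(0, 4, size=30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(midrank_spearman(x, y), abs=1e-12)

    def test_too_few_pairs_is_nan(self):
        assert np.isnan(spearman([1, 2, np.nan], [1, np.nan, 3]))


# ---------------------------------------------------------------------------
# build_groups
# ---------------------------------------------------------------------------

def _ab(cn_row, meth_row, samples=None):
    samples = samples or [f"s{i}" for i in range(len(cn_row))]
    return AberrationMatrix(
        cn_state=pd.DataFrame([cn_row], index=["L"], columns=samples),
        meth_state=pd.DataFrame([meth_row], index=["L"], columns=samples),
    )


class TestBuildGroups:
    def test_combined_activating_partition(self):
        ab = _ab(
            ["gain", "neutral", "gain", "neutral"],
            ["normal", "hypo", "hypo", "normal"],
            ["gain_only", "hypo_only", "both", "neither"],
        )
        altered, ref = build_groups("L", ab, TestSpec("activating", "combined"))
        assert set(altered) == {"gain_only", "hypo_only", "both"}
        assert set(ref) == {"neither"}

    def test_no_gains_gives_empty_altered(self):
        ab = _ab(["neutral", "loss"], ["normal", "normal"])
        altered, ref = build_groups("L", ab, TestSpec("activating", "copy_number"))
        assert altered == []
        assert set(ref) == {"s0", "s1"}  # losses stay in the reference group

    def test_matches_set_comprehension_oracle(self, rng):
        cn_states = rng.choice(["loss", "neutral", "gain", "missing"], size=40)
        meth_states = rng.choice(["hypo", "normal", "hyper", "missing"], size=40)
        ab = _ab(list(cn_states), list(meth_states))
        samples = ab.samples
        for spec in [TestSpec(s, c) for s in ("activating", "silencing")
                     for c in ("copy_number", "methylation", "combined")]:
            altered, ref = build_groups("L", ab, spec)
            cn_t = "gain" if spec.scenario == "activating" else "loss"
            meth_t = "hypo" if spec.scenario == "activating" else "hyper"
            if spec.category == "copy_number":
                exp_alt = {s for s, v in zip(samples, cn_states) if v == cn_t}
                exp_ref = {s for s, v in zip(samples, cn_states) if v not in (cn_t, "missing")}
            elif spec.category == "methylation":
                exp_alt = {s for s, v in zip(samples, meth_states) if v == meth_t}
                exp_ref = {s for s, v in zip(samples, meth_states) if v not in (meth_t, "missing")}
            else:
                exp_alt = {
                    s for s, c, m in zip(samples, cn_states, meth_states)
                    if c == cn_t or m == meth_t
                }
                exp_ref = {
                    s for s, c, m in zip(samples, cn_states, meth_states)
                    if c == "neutral" and m == "normal"
                }
            assert set(altered) == exp_alt and set(ref) == exp_ref


class TestDirectionCheck:
    def test_positive_cn_correlation_passes(self, rng):
        cn = rng.normal(size=30)
        expr = cn + rng.normal(0, 0.5, 30)
        chk = direction_check(expr, cn, None, TestSpec("activating", "copy_number"))
        assert chk.passes and chk.rho_cn > 0

    def test_positive_meth_correlation_fails_any_scenario(self, rng):
        beta = rng.uniform(0, 1, 30)
        expr = beta + rng.normal(0, 0.1, 30)  # positively correlated: wrong sign
        for scenario in ("activating", "silencing"):
            chk = direction_check(expr, None, beta, TestSpec(scenario, "methylation"))
            assert not chk.passes and chk.rho_meth > 0

    def test_combined_requires_all_contributing_axes(self, rng):
        cn = rng.normal(size=40)
        beta = rng.uniform(size=40)
        expr = cn - 2 * beta + rng.normal(0, 0.2, 40)
        spec = TestSpec("activating", "combined")
        both = direction_check(expr, cn, beta, spec, True, True)
        assert both.passes
        bad_expr = cn + 2 * beta  # methylation correlates positively
        assert not direction_check(bad_expr, cn, beta, spec, True, True).passes
        # ...but passes when only copy number contributed altered samples
        assert direction_check(bad_expr, cn, beta, spec, True, False).passes

    def test_too_few_pairs_untestable(self):
        chk = direction_check(
            pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]), None,
            TestSpec("activating", "copy_number"),
        )
        assert not chk.testable


# ---------------------------------------------------------------------------
# detect_incis on constructed cohorts
# ---------------------------------------------------------------------------

def _cohort(n=60, planted_shift=2.0, seed=5):
    """40-locus toy cohort with one gain-driven and one hyper-driven locus."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    loci = [f"L{i}" for i in range(40)]
    cn = pd.DataFrame("neutral", index=loci, columns=samples)
    meth = pd.DataFrame("normal", index=loci, columns=samples)
    cn_vals = pd.DataFrame(rng.normal(0, 0.02, (40, n)), index=loci, columns=samples)
    beta_vals = pd.DataFrame(rng.uniform(0.4, 0.5, (40, n)), index=loci, columns=samples)
    expr = pd.DataFrame(rng.normal(0, 0.5, (40, n)), index=loci, columns=samples)
    gain_samples = samples[: n // 3]
    cn.loc["L0", gain_samples] = "gain"
    cn_vals.loc["L0", gain_samples] += 0.35
    expr.loc["L0", gain_samples] += planted_shift
    hyper_samples = samples[n // 3 : n // 2]
    meth.loc["L1", hyper_samples] = "hyper"
    beta_vals.loc["L1", hyper_samples] += 0.3
    expr.loc["L1", hyper_samples] -= planted_shift
    return (
        LocusSampleMatrix(expr, EXPRESSION),
        LocusSampleMatrix(cn_vals, CN_LOGRATIO),
        LocusSampleMatrix(np.clip(beta_vals, 0, 1), BETA),
        AberrationMatrix(cn_state=cn, meth_state=meth),
    )


class TestDetectIncis:
    def test_recovers_planted_loci_with_correct_labels(self):
        expr, cn, beta, ab = _cohort()
        results, incis = detect_incis(expr, cn, beta, ab)
        by_locus = {m.locus_id: m for m in incis}
        assert set(by_locus) == {"L0", "L1"}
        assert by_locus["L0"].effect == "activating"
        assert by_locus["L0"].driver_class == "copy_number"
        assert by_locus["L1"].effect == "silencing"
        assert by_locus["L1"].driver_class == "methylation"

    def test_zero_aberrations_zero_incis(self):
        expr, cn, beta, _ = _cohort()
        loci, samples = expr.row_ids, expr.col_ids
        ab = AberrationMatrix(
            cn_state=pd.DataFrame("neutral", index=loci, columns=samples),
            meth_state=pd.DataFrame("normal", index=loci, columns=samples),
        )
        _, incis = detect_incis(expr, cn, beta, ab)
        assert incis == []

    def test_q_never_below_p(self):
        expr, cn, beta, ab = _cohort()
        results, _ = detect_incis(expr, cn, beta, ab)
        for r in results:
            if r.testable:
                assert r.q >= r.p - 1e-12


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

class TestReplication:
    def _discovery(self):
        expr, cn, beta, ab = _cohort()
        results, incis = detect_incis(expr, cn, beta, ab)
        return expr, cn, beta, ab, results, incis

    def test_strong_effect_replicates_weak_does_not(self):
        expr, cn, beta, ab, results, incis = self._discovery()
        # replication cohort with the same planted structure replicates...
        r_expr, r_cn, r_beta, r_ab = _cohort(seed=11)
        repl = ReplicationData(r_expr, r_ab, r_cn, r_beta)
        outcomes = replicate_incis(incis, results, repl)
        assert {o.locus_id for o in outcomes if o.replicated} == {"L0", "L1"}
        # ...a null replication cohort does not
        n_expr, n_cn, n_beta, n_ab = _cohort(seed=12, planted_shift=0.0)
        outcomes = replicate_incis(incis, results, ReplicationData(n_expr, n_ab, n_cn, n_beta))
        assert not any(o.replicated for o in outcomes)

    def test_candidate_absent_from_replication_not_assessable(self):
        expr, cn, beta, ab, results, incis = self._discovery()
        r_expr, r_cn, r_beta, r_ab = _cohort(seed=11)
        r_expr = LocusSampleMatrix(r_expr.data.drop(index="L0"), EXPRESSION)
        outcomes = replicate_incis(incis, results, ReplicationData(r_expr, r_ab, r_cn, r_beta))
        l0 = [o for o in outcomes if o.locus_id == "L0"]
        assert len(l0) == 1 and not l0[0].assessable

    def test_paired_cpg_assays_report_larger_p(self):
        """Two CpG assays covering one promoter: each is tested separately
        and the larger of the two p-values is the reported one."""
        expr, cn, beta, ab, results, incis = self._discovery()
        r_expr, r_cn, r_beta, r_ab = _cohort(seed=11)
        samples = r_ab.samples
        strong = r_ab.meth_state.loc["L1"]
        # second assay with weaker aberration overlap -> larger p
        weak = strong.copy()
        hyper_idx = [s for s in samples if strong[s] == "hyper"]
        weak[hyper_idx[: len(hyper_idx) // 2]] = "normal"
        weak[[s for s in samples if strong[s] == "normal"][:4]] = "hyper"
        paired = {"L1": [strong, weak]}
        repl = ReplicationData(r_expr, r_ab, r_cn, r_beta, paired_meth_states=paired)
        outcomes = replicate_incis(incis, results, repl)
        meth_l1 = [
            o for o in outcomes if o.locus_id == "L1" and o.spec.category == "methylation"
        ]
        assert len(meth_l1) == 1
        p_strong = _p_for_states(r_expr.data.loc["L1"], strong)
        p_weak = _p_for_states(r_expr.data.loc["L1"], weak)
        assert meth_l1[0].p == pytest.approx(max(p_strong, p_weak))


def _p_for_states(expr_row, states):
    x = expr_row[states.index[states == "hyper"]].dropna().to_numpy()
    y = expr_row[states.index[(states != "hyper") & (states != "missing")]].dropna().to_numpy()
    return rank_sum_test(x, y)[1]


# ---------------------------------------------------------------------------
# Family complementarity
# ---------------------------------------------------------------------------

class TestFamilyComplementarity:
    def _ab(self, rng, loci, samples):
        return AberrationMatrix(
            cn_state=pd.DataFrame(
                rng.choice(["loss", "neutral", "gain"], size=(len(loci), len(samples))),
                index=loci, columns=samples,
            ),
            meth_state=pd.DataFrame(
                rng.choice(["hypo", "normal", "hyper"], size=(len(loci), len(samples))),
                index=loci, columns=samples,
            ),
        )

    def test_overall_state_is_member_or(self, rng):
        loci = [f"L{i}" for i in range(4)]
        samples = [f"s{j}" for j in range(25)]
        ab = self._ab(rng, loci, samples)
        incis = [InCisMirna(l, "activating", "copy_number") for l in loci]
        (profile,) = family_complementarity({"fam": set(loci)}, ab, incis)
        oracle = (
            (ab.cn_state.loc[loci] == "gain") | (ab.meth_state.loc[loci] == "hypo")
        ).any(axis=0)
        assert (profile.overall == oracle).all()
        assert profile.fraction_altered == pytest.approx(oracle.mean())

    def test_single_member_families_skipped(self, rng):
        ab = self._ab(rng, ["L0", "L1"], ["s0", "s1"])
        incis = [InCisMirna("L0", "activating", "copy_number")]
        assert family_complementarity({"fam": {"L0", "L1"}}, ab, incis) == []

    def test_gain_plus_normal_is_altered_all_neutral_is_not(self):
        cn = pd.DataFrame(
            [["gain", "neutral"], ["neutral", "neutral"]],
            index=["A", "B"], columns=["p1", "p2"],
        )
        meth = pd.DataFrame(
            [["normal", "normal"], ["normal", "normal"]],
            index=["A", "B"], columns=["p1", "p2"],
        )
        ab = AberrationMatrix(cn_state=cn, meth_state=meth)
        incis = [InCisMirna("A", "activating", "copy_number"),
                 InCisMirna("B", "activating", "copy_number")]
        (profile,) = family_complementarity({"f": {"A", "B"}}, ab, incis)
        assert bool(profile.overall["p1"]) is True
        assert bool(profile.overall["p2"]) is False
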