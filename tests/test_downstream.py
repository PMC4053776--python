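"""Clinical scans, survival median split, mRNA correlation, screen hit calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from incismir.downstream import (
    association_scan,
    consistent_associations,
    consistent_correlations,
    mirna_mrna_correlation,
    screen_hit_call,
    survival_median_split,
)
from incismir.matrix import EXPRESSION, LocusSampleMatrix


def _expr(values, rows=None, cols=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    rows = rows or [f"L{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    return LocusSampleMatrix(pd.DataFrame(values, index=rows, columns=cols), EXPRESSION)


def _clinical(n, **overrides):
    df = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "er": ["pos"] * n,
            "her2": ["neg"] * n,
            "grade": [2] * n,
            "tp53": ["wildtype"] * n,
            "subtype": ["luminal"] * n,
            "rfs_time": [5.0] * n,
            "rfs_event": [0] * n,
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df.set_index("sample_id", drop=False)


def kruskal_oracle(groups):
    """Brute-force H: mid-ranks, between-group rank-sum statistic, tie correction."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (N**3 - N)
    return h / correction


class TestAssociationScan:
    def test_identical_constant_groups_h_zero_p_one(self):
        clin = _clinical(9, grade=[1, 1, 1, 2, 2, 2, 3, 3, 3])
        res = association_scan(_expr([[1.0] * 9]), clin, "grade")
        assert res[0].test == "kruskal_wallis"
        assert res[0].p == pytest.approx(1.0)

    def test_kruskal_matches_brute_force_oracle(self, rng):
        grades = [1] * 5 + [2] * 5 + [3] * 5
        vals = rng.normal(size=15)
        clin = _clinical(15, grade=grades)
        res = association_scan(_expr([vals]), clin, "grade")
        groups = [vals[:5], vals[5:10], vals[10:]]
        h = kruskal_oracle(groups)
        # independently recompute p from the chi-square null of H
        assert res[0].p == pytest.approx(float(sps.chi2.sf(h, 2)), abs=1e-12)

    def test_planted_tp53_effect_detected_in_both_cohorts(self, rng):
        """Hypomethylation-style planted effect: expression up in mutant
        samples, recovered at q < 0.05 in two independent cohorts."""
        for seed in (1, 2):
            r = np.random.default_rng(seed)
            tp53 = np.where(r.random(60) < 0.4, "mutant", "wildtype")
            vals = r.normal(0, 0.5, size=(20, 60))
            vals[0] += 1.5 * (tp53 == "mutant")
            clin = _clinical(60, tp53=tp53)
            res = association_scan(_expr(vals), clin, "tp53")
            hit = {x.locus_id: x for x in res}["L0"]
            assert hit.q < 0.05
            assert hit.direction == "up in mutant"

    def test_degenerate_variable_skipped(self):
        clin = _clinical(6)  # er all "pos": single level
        assert association_scan(_expr([[1, 2, 3, 4, 5, 6]]), clin, "er") == []


class TestConsistentAssociations:
    def _mk(self, q, direction="up in pos"):
        from incismir.downstream import AssociationResult

        return AssociationResult("L0", "er", "wilcoxon", p=q / 2, q=q, direction=direction)

    def test_requires_significance_in_both(self):
        assert consistent_associations([self._mk(0.01)], [self._mk(0.20)]) == []
        assert len(consistent_associations([self._mk(0.01)], [self._mk(0.03)])) == 1

    def test_opposite_directions_excluded(self):
        out = consistent_associations(
            [self._mk(0.01, "up in pos")], [self._mk(0.01, "up in neg")]
        )
        assert out == []


class TestSurvivalMedianSplit:
    def test_identical_curves_statistic_zero(self):
        # expression splits 3/3; both groups share identical survival data
        clin = _clinical(
            6,
            rfs_time=[1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            rfs_event=[1, 1, 0, 1, 1, 0],
        )
        row = pd.Series([1, 2, 3, 10, 11, 12.0], index=clin.index, name="L0")
        res = survival_median_split(row, clin)
        assert res.testable
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_even_unique_values_split_in_half(self, rng):
        n = 86
        clin = _clinical(n, rfs_time=rng.uniform(1, 10, n), rfs_event=[1] * n)
        row = pd.Series(rng.permutation(np.arange(n, dtype=float)), index=clin.index, name="L")
        res = survival_median_split(row, clin)
        assert len(res.low_samples) == 43 and len(res.high_samples) == 43

    def test_median_ties_go_to_low_group(self):
        clin = _clinical(5, rfs_time=[1, 2, 3, 4, 5.0], rfs_event=[1, 1, 1, 1, 1])
        row = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0], index=clin.index, name="L")
        res = survival_median_split(row, clin)
        assert set(res.low_samples) == {"s0", "s1", "s2"}

    def test_matches_hand_computed_observed_expected(self):
        """Six-sample toy: log-rank statistic equals the manual O-E table."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 0]
        clin = _clinical(6, rfs_time=times, rfs_event=events)
        row = pd.Series([0.0, 1.0, 2.0, 10.0, 11.0, 12.0], index=clin.index, name="L")
        res = survival_median_split(row, clin)
        in_low = np.array([1, 1, 1, 0, 0, 0])
        order = np.argsort(times)
        o_minus_e, var = 0.0, 0.0
        for k, idx in enumerate(order):
            if not events[idx]:
                continue
            at_risk = order[k:]
            n_tot = len(at_risk)
            n_low = int(in_low[at_risk].sum())
            o_minus_e += in_low[idx] - n_low / n_tot
            # single event per time: hypergeometric variance reduces to p(1-p)
            var += (n_low / n_tot) * (1 - n_low / n_tot)
        expected = o_minus_e**2 / var
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_no_events_untestable(self):
        clin = _clinical(6, rfs_event=[0] * 6)
        row = pd.Series(np.arange(6.0), index=clin.index, name="L")
        assert not survival_median_split(row, clin).testable


class TestMirnaMrnaCorrelation:
    def test_selection_threshold_and_consistency(self, rng):
        n = 50
        mir = rng.normal(size=n)
        genes = {
            "POS": 0.9 * mir + rng.normal(0, 0.3, n),
            "NULL": rng.normal(size=n),
        }
        mirna = _expr([mir], rows=["miR-x"])
        mrna = _expr(np.vstack(list(genes.values())), rows=list(genes))
        tab = mirna_mrna_correlation(mirna, mrna, rho_threshold=0.3)
        sel = dict(zip(tab["gene"], tab["selected"]))
        assert sel["POS"] and not sel["NULL"]

    @pytest.mark.parametrize(
        "rho_a,rho_b,expected",
        [(0.35, 0.41, True), (0.35, 0.10, False), (0.35, -0.45, False)],
    )
    def test_cross_cohort_consistency_rules(self, rho_a, rho_b, expected):
        def tab(rho):
            return pd.DataFrame(
                {"mirna": ["m"], "gene": ["g"], "rho": [rho], "n": [50],
                 "selected": [abs(rho) > 0.3]}
            )

        out = consistent_correlations(tab(rho_a), tab(rho_b))
        assert (len(out) == 1) is expected

    def test_symmetric_in_cohort_order(self, rng):
        a = pd.DataFrame(
            {"mirna": ["m"] * 3, "gene": ["g1", "g2", "g3"],
             "rho": [0.5, -0.4, 0.2], "n": [30] * 3,
             "selected": [True, True, False]}
        )
        b = pd.DataFrame(
            {"mirna": ["m"] * 3, "gene": ["g1", "g2", "g3"],
             "rho": [0.6, 0.5, 0.9], "n": [30] * 3,
             "selected": [True, True, True]}
        )
        ab = consistent_correlations(a, b)[["mirna", "gene"]]
        ba = consistent_correlations(b, a)[["mirna", "gene"]]
        pd.testing.assert_frame_equal(ab, ba)


class TestScreenHitCall:
    def test_viability_threshold(self):
        df = pd.DataFrame(
            {
                "cell_line": ["KPL4"] * 3,
                "mirna": ["a", "b", "c"],
                "endpoint": ["viability"] * 3,
                "normalized_value": [-0.25, 0.1, 0.2],
            }
        )
        calls = screen_hit_call(df)
        assert [c.hit for c in calls] == [True, False, False]  # strict at |0.2|

    def test_lysate_zscore_threshold(self, rng):
        vals = rng.normal(0, 1, 200)
        vals[0] = vals.mean() + 3 * vals.std(ddof=1)
        df = pd.DataFrame(
            {
                "cell_line": "MCF7",
                "mirna": [f"m{i}" for i in range(200)],
                "endpoint": "ki67",
                "normalized_value": vals,
            }
        )
        calls = screen_hit_call(df)
        assert calls[0].hit and abs(calls[0].z) > 1.96
        hits = [c for c in calls if c.hit]
        assert all(abs(c.z) > 1.96 for c in hits)

    def test_zero_screen_sd_is_error(self):
        df = pd.DataFrame(
            {"cell_line": "x", "mirna": ["a", "b"], "endpoint": "pakt",
             "normalized_value": [1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="zero screen SD"):
            screen_hit_call(df)


def test_label_permuted_scan_yields_uniform_pvalues(rng):
    """Expression independent of a permuted two-level label: the scan's
    p-value distribution should be near-uniform (Kolmogorov distance < 0.1)."""
    n, n_loci = 80, 250
    ps = []
    for seed in range(3):
        r = np.random.default_rng(seed)
        er = r.permutation(np.array(["pos"] * 40 + ["neg"] * 40))
        clin = _clinical(n, er=er)
        vals = r.normal(size=(n_loci, n))
        res = association_scan(_expr(vals), clin, "er")
        ps.extend([x.p for x in res])
    ps = np.sort(ps)
    grid = (np.arange(1, len(ps) + 1)) / len(ps)
    assert np.max(np.abs(ps - grid)) < 0.1
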