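"""Isoform fractions, switch scores, DAS/DE calling, UTR association."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from splicescape.isoform_quant import (
    call_das,
    call_de,
    compute_dif,
    isoform_fractions,
    switch_score,
    utr5_expression_association,
)
from splicescape.models_io import ExpressionMatrix
from splicescape.synthetic_data import generate_expression

from conftest import make_gene


def _expr(rows: dict, conditions: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows).T, conditions)


def two_isoform_gene(gid="g1"):
    return make_gene(gid, [[(0, 100)], [(200, 300)]])


class TestFractions:
    def test_basic_percentages(self):
        g = two_isoform_gene()
        expr = _expr(
            {"g1.t1": {"s1": 80.0}, "g1.t2": {"s1": 20.0}}, {"s1": "c1"}
        )
        table = isoform_fractions(expr, [g])
        assert table.loc["g1.t1", "c1"] == pytest.approx(80.0)
        assert table.loc["g1.t2", "c1"] == pytest.approx(20.0)

    def test_single_isoform_is_100(self):
        g = make_gene("g1", [[(0, 100)]])
        expr = _expr({"g1.t1": {"s1": 3.0}}, {"s1": "c1"})
        assert isoform_fractions(expr, [g]).loc["g1.t1", "c1"] == 100.0

    def test_three_way_split(self):
        g = make_gene("g1", [[(0, 10)], [(20, 30)], [(40, 50)]])
        expr = _expr(
            {f"g1.t{i}": {"s1": v} for i, v in zip((1, 2, 3), (1.0, 1.0, 2.0))},
            {"s1": "c1"},
        )
        t = isoform_fractions(expr, [g])
        assert list(t["s1" if "s1" in t else "c1"]) == [25.0, 25.0, 50.0]

    def test_zero_gene_fpkm_is_nan_not_zero(self):
        g = two_isoform_gene()
        expr = _expr(
            {"g1.t1": {"s1": 0.0}, "g1.t2": {"s1": 0.0}}, {"s1": "c1"}
        )
        t = isoform_fractions(expr, [g])
        assert t["c1"].isna().all()

    def test_if_sums_to_100_per_gene(self, noiseless):
        ds = noiseless
        table = isoform_fractions(ds.expression, ds.genes)
        for _, sub in table.groupby("gene_id"):
            for c in sub.columns[1:]:
                assert sub[c].sum() == pytest.approx(100.0, abs=1e-6)


class TestDif:
    def test_sign_and_magnitude(self):
        g = two_isoform_gene()
        expr = _expr(
            {
                "g1.t1": {"s1": 80.0, "s2": 20.0},
                "g1.t2": {"s1": 20.0, "s2": 80.0},
            },
            {"s1": "c1", "s2": "c2"},
        )
        table = isoform_fractions(expr, [g])
        dif = compute_dif(table, ("c1", "c2"))
        assert dif["g1.t1"] == pytest.approx(-60.0)
        assert dif["g1.t2"] == pytest.approx(60.0)

    def test_identical_conditions_zero(self):
        g = two_isoform_gene()
        expr = _expr(
            {"g1.t1": {"s1": 5.0, "s2": 5.0}, "g1.t2": {"s1": 1.0, "s2": 1.0}},
            {"s1": "c1", "s2": "c2"},
        )
        dif = compute_dif(isoform_fractions(expr, [g]), ("c1", "c2"))
        assert (dif.abs() < 1e-9).all()

    def test_gene_dif_sums_to_zero(self, noiseless):
        ds = noiseless
        table = isoform_fractions(ds.expression, ds.genes)
        conds = ds.expression.condition_names
        dif = compute_dif(table, (conds[0], conds[1]))
        sums = dif.groupby(table["gene_id"]).sum()
        assert np.allclose(sums, 0.0, atol=1e-6)


class TestSwitchScore:
    @staticmethod
    def jsd_oracle(p, q):
        """Direct entropy-formula evaluation (independent of scipy)."""
        p = np.asarray(p) / np.sum(p)
        q = np.asarray(q) / np.sum(q)
        m = (p + q) / 2

        def h(v):
            return -sum(x * math.log2(x) for x in v if x > 0)

        return math.sqrt(h(m) - (h(p) + h(q)) / 2)

    def test_equal_distributions_zero(self):
        assert switch_score([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_support_is_one(self):
        assert switch_score([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        # H(0.75, 0.25) - 0.5*H(0.5, 0.5) = 0.311278; sqrt = 0.55792
        val = switch_score([0.5, 0.5], [1.0, 0.0])
        assert val == pytest.approx(0.55792, abs=1e-5)
        assert val == pytest.approx(self.jsd_oracle([0.5, 0.5], [1, 0]), abs=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 5)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            a, b = switch_score(p, q), switch_score(q, p)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 1.0
            assert a == pytest.approx(self.jsd_oracle(p, q), abs=1e-9)

    def test_unnormalised_inputs_renormalised(self):
        assert switch_score([50, 50], [100, 0]) == pytest.approx(0.55792, abs=1e-5)


class TestCallDas:
    def _switch_expr(self, reps=3):
        g = two_isoform_gene()
        rows = {}
        for r in range(reps):
            rows[f"c1_rep{r + 1}"] = {"g1.t1": 90.0, "g1.t2": 10.0}
        for r in range(reps):
            rows[f"c2_rep{r + 1}"] = {"g1.t1": 10.0, "g1.t2": 90.0}
        values = pd.DataFrame(rows)
        conds = {c: c.split("_")[0] for c in values.columns}
        return g, ExpressionMatrix(values, conds)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """The label-permutation p equals an independent enumeration oracle.

        With 3+3 identical replicates the observed labelling and its
        mirror are the only assignments reaching the observed sqrt-JSD,
        so the exhaustive p is exactly 2/C(6,3).
        """
        g, expr = self._switch_expr(reps=3)
        res = call_das(expr, [g], ("c1", "c2"))
        # independent oracle: enumerate all C(6,3) label assignments
        cols = expr.values.to_numpy()
        obs = None
        stats = []
        for comb in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(comb)] = True
            p = cols[:, mask].mean(axis=1)
            q = cols[:, ~mask].mean(axis=1)
            stats.append(switch_score(p, q))
            if comb == (0, 1, 2):
                obs = stats[-1]
        oracle_p = np.mean([s >= obs - 1e-12 for s in stats])
        assert oracle_p == pytest.approx(2 / 20)
        assert res.genes.loc["g1", "pvalue"] == pytest.approx(oracle_p)
        assert res.genes.loc["g1", "max_abs_dif"] == pytest.approx(80.0)

    def test_threshold_only_mode_flags_switch(self):
        g, expr = self._switch_expr(reps=1)
        res = call_das(expr, [g], ("c1", "c2"))
        assert res.significance == "none"
        assert bool(res.genes.loc["g1", "das"])
        assert res.isoforms["das"].all()

    def test_small_dif_never_called(self):
        g = two_isoform_gene()
        expr = _expr(
            {
                "g1.t1": {"s1": 57.5, "s2": 42.5},
                "g1.t2": {"s1": 42.5, "s2": 57.5},
            },
            {"s1": "c1", "s2": "c2"},
        )
        res = call_das(expr, [g], ("c1", "c2"))  # dIF = 15
        assert not res.genes["das"].any()

    def test_type_i_error_on_null_genes(self):
        """Permutation test rejection rate on 500 null genes stays near 0.05."""
        rng = np.random.default_rng(42)
        n_genes, reps = 500, 5
        genes = []
        rows = {}
        for i in range(n_genes):
            gid = f"n{i:03d}"
            genes.append(make_gene(gid, [[(0, 10)], [(20, 30)]]))
            base = rng.uniform(0.3, 0.7)
            for r in range(reps):
                for c in ("c1", "c2"):
                    noise = rng.lognormal(0, 0.25, 2)
                    rows.setdefault(f"{c}_rep{r + 1}", {})[f"{gid}.t1"] = (
                        10 * base * noise[0]
                    )
                    rows[f"{c}_rep{r + 1}"][f"{gid}.t2"] = 10 * (1 - base) * noise[1]
        values = pd.DataFrame(rows)
        expr = ExpressionMatrix(values, {c: c.split("_")[0] for c in values})
        res = call_das(expr, genes, ("c1", "c2"), seed=0)
        rate = float((res.genes["pvalue"] < 0.05).mean())
        se = math.sqrt(0.05 * 0.95 / n_genes)
        assert rate <= 0.05 + 2 * se
        # and no DAS calls at all on null data after dIF + BH filtering
        assert not res.genes["das"].any()


class TestCallDe:
    def _gene_expr(self, fpkm1, fpkm2):
        g = make_gene("g1", [[(0, 100)]])
        expr = _expr(
            {"g1.t1": {"s1": fpkm1, "s2": fpkm2}}, {"s1": "c1", "s2": "c2"}
        )
        return g, expr

    @pytest.mark.parametrize(
        "f1,f2,expected",
        [
            (10.0, 2.0, False),   # |log2 0.2| = 2.32 > 2 -> DE (down)
            (4.0, 2.0, False),    # |log2 0.5| = 1 -> not DE
            (0.0, 1.0, True),     # clamped to 0.2 vs 1 -> |log2 5| > 2 -> DE up
        ],
    )
    def test_fold_change_rule(self, f1, f2, expected):
        g, expr = self._gene_expr(f1, f2)
        de = call_de(expr, [g], ("c1", "c2"))
        if f1 == 10.0:
            assert bool(de.loc["g1", "de"]) and de.loc["g1", "direction"] == "down"
        elif f1 == 4.0:
            assert not bool(de.loc["g1", "de"])
        else:
            assert bool(de.loc["g1", "de"]) == expected
            assert de.loc["g1", "direction"] == "up"

    def test_below_floor_in_both_conditions_excluded(self):
        g, expr = self._gene_expr(0.05, 0.1)
        de = call_de(expr, [g], ("c1", "c2"))
        assert "g1" not in de.index

    def test_planted_de_recovered(self, noiseless):
        ds = noiseless
        conds = ds.expression.condition_names
        de = call_de(ds.expression, ds.genes, (conds[0], conds[1]))
        called = set(de.index[de["de"]])
        assert called == set(ds.ground_truth.de_genes)


class TestUtr5Association:
    def test_planted_negative_association(self):
        from splicescape.synthetic_data import generate_genome_and_genes

        events = {"alt_tss": 20}
        ds = generate_genome_and_genes(
            n_genes=22, events_per_type=events, n_u12_genes=0,
            n_extra_isoform_genes=0, seed=9,
        )
        generate_expression(ds, noise_cv=0.0, utr5_association=True, seed=10)
        utr5 = {t: rec["utr5"] for t, rec in ds.ground_truth.orfs.items()}
        # restrict to genes whose isoforms all have known UTRs (ATSS genes)
        multi = {
            t: u
            for g in ds.genes
            if len(g.transcripts) >= 2
            and all(x.transcript_id in utr5 for x in g.transcripts)
            for t, u in utr5.items()
            if t.rsplit(".", 1)[0] == g.gene_id
        }
        cond = ds.expression.condition_names[0]
        rho, p = utr5_expression_association(multi, ds.expression, cond, seed=0)
        assert rho < 0

    def test_constant_fpkm_gives_zero_rho(self):
        g = make_gene("g1", [[(0, 10)], [(20, 30)], [(40, 50)]])
        expr = _expr(
            {f"g1.t{i}": {"s1": 5.0} for i in (1, 2, 3)}, {"s1": "c1"}
        )
        rho, p = utr5_expression_association(
            {"g1.t1": 10, "g1.t2": 50, "g1.t3": 90}, expr, "c1"
        )
        assert rho == 0.0 and p == 1.0

    def test_too_few_points_undefined(self):
        g = two_isoform_gene()
        expr = _expr(
            {"g1.t1": {"s1": 5.0}, "g1.t2": {"s1": 2.0}}, {"s1": "c1"}
        )
        rho, p = utr5_expression_association(
            {"g1.t1": 10, "g1.t2": 50}, expr, "c1"
        )
        assert math.isnan(rho) and math.isnan(p)

    def test_null_permutation_p_not_extreme(self):
        rng = np.random.default_rng(3)
        tids = [f"g.t{i}" for i in range(30)]
        expr = _expr(
            {t: {"s1": float(v)} for t, v in zip(tids, rng.lognormal(1, 1, 30))},
            {"s1": "c1"},
        )
        utr5 = {t: int(u) for t, u in zip(tids, rng.integers(10, 500, 30))}
        rho, p = utr5_expression_association(utr5, expr, "c1", seed=1)
        assert abs(rho) < 0.5 and p > 0.01
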