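"""Duplex alignment, lncRNA filters, site context, enrichment, correlation."""

import math

import numpy as np
import pytest

from splicescape.as_events import catalogue_junctions
from splicescape.lnc_interactome import (
    PairingScoreScheme,
    align_duplex,
    classify_cis_nat,
    classify_site,
    common_site_fraction,
    correlate_pairs,
    filter_lncrna_candidates,
    fisher_two_sided,
    junction_enrichment,
    odds_ratio_haldane,
    spearman_permutation,
)
from splicescape.models_io import (
    ExpressionMatrix,
    TranscriptModel,
    premrna_sequence,
    reverse_complement,
    spliced_sequence,
)
from splicescape.as_events import build_pre_mrna
from splicescape.synthetic_data import (
    generate_genome_and_genes,
    generate_lncrnas,
)

from conftest import make_gene

import pandas as pd


# ---------------------------------------------------------------------------
# Independent textbook Gotoh DP (explicit per-cell loops, no vectorisation)
# ---------------------------------------------------------------------------

def gotoh_oracle(x: str, y: str, scheme: PairingScoreScheme) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    mat = scheme.matrix()
    n, m = len(x), len(y)
    NEG = -1e12
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    open_cost = scheme.gap_open + scheme.gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[idx[x[i - 1]], idx[y[j - 1]]]
            M[i][j] = s + max(
                0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]
            )
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - scheme.gap_extend)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - scheme.gap_extend)
            best = max(best, M[i][j])
    return best


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAlignDuplex:
    def test_oracle_equivalence_200_random_pairs(self):
        rng = np.random.default_rng(2024)
        scheme = PairingScoreScheme()
        for _ in range(200):
            x = rand_seq(rng, int(rng.integers(10, 61)))
            y = rand_seq(rng, int(rng.integers(10, 61)))
            expected = gotoh_oracle(x, y, scheme)
            got = align_duplex(
                x, y, scheme, min_score=1, min_len=1, convention="parallel"
            )
            if expected < 1:
                assert got == []
            else:
                assert got[0].score == pytest.approx(expected)

    def test_antiparallel_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            x = rand_seq(rng, 40)
            y = rand_seq(rng, 50)
            a = align_duplex(x, y, min_score=1, min_len=1)
            b = align_duplex(x[::-1], y[::-1], min_score=1, min_len=1)
            sa = a[0].score if a else 0
            sb = b[0].score if b else 0
            assert sa == pytest.approx(sb)

    def test_perfect_gc_window_scores_exactly_4l(self):
        rng = np.random.default_rng(1)
        for L in (25, 40):
            win = "".join("GC"[i] for i in rng.integers(0, 2, L))
            target = "A" * 30 + win + "A" * 30
            lnc = reverse_complement(win)  # no flanks: nothing can extend
            (site,) = align_duplex(lnc, target, min_score=4 * L, min_len=L)
            assert site.score == 4 * L
            assert site.target_interval == (30, 30 + L)
            assert site.lnc_interval == (0, L)

    def test_polya_never_pairs(self):
        assert align_duplex("A" * 50, "A" * 50, min_score=5, min_len=3) == []

    def test_wobble_only_segment_threshold_behaviour(self):
        # 10 G:U wobbles score 10: below the default threshold, reported
        # only when the threshold is lowered
        assert align_duplex("G" * 10, "T" * 10) == []
        sites = align_duplex("G" * 10, "T" * 10, min_score=10, min_len=5)
        assert sites and sites[0].score == 10

    def test_multiple_sites_non_overlapping(self):
        rng = np.random.default_rng(4)
        w1 = "".join("GC"[i] for i in rng.integers(0, 2, 30))
        w2 = "".join("GC"[i] for i in rng.integers(0, 2, 30))
        target = "A" * 20 + w1 + "A" * 40 + w2 + "A" * 20
        lnc = (
            "A" * 10
            + reverse_complement(w2)
            + "A" * 15
            + reverse_complement(w1)
            + "A" * 10
        )
        sites = align_duplex(lnc, target, min_score=100, min_len=25)
        assert len(sites) == 2
        ivs = sorted(s.target_interval for s in sites)
        assert ivs[0][1] <= ivs[1][0]

    def test_empty_sequence_empty_result(self):
        assert align_duplex("", "ACGT") == []

    def test_planted_sites_with_wobbles_recovered(self):
        ds = generate_genome_and_genes(seed=21)
        generate_lncrnas(ds, wobble_frac=0.10, seed=22)
        gene_by_id = {g.gene_id: g for g in ds.genes}
        for spec in ds.ground_truth.lnc_sites:
            lnc = next(
                t for t in ds.lncrnas if t.transcript_id == spec["lncrna_id"]
            )
            sites = align_duplex(
                spliced_sequence(lnc, ds.genome),
                premrna_sequence(gene_by_id[spec["target_gene"]], ds.genome),
            )
            assert sites, spec["lncrna_id"]
            ts, te = spec["target_interval"]
            bs, be = sites[0].target_interval
            overlap = max(0, min(te, be) - max(ts, bs)) / (te - ts)
            assert overlap >= 0.9


class TestCandidateFilters:
    def _tx(self, tid, length, seq=None, start=0):
        t = TranscriptModel(tid, f"{tid}.locus", "chrT", "+",
                           [(start, start + length)])
        t.sequence = seq if seq is not None else "C" * length
        return t

    def _expr(self, rows):
        values = pd.DataFrame({"s1": rows})
        return ExpressionMatrix(values, {"s1": "c1"})

    def test_short_candidate_rejected(self):
        t = self._tx("lnc1", 150)
        kept = filter_lncrna_candidates([t], None, {"lnc1": "u"})
        assert kept == []

    def test_long_orf_rejected(self):
        seq = "C" * 50 + "ATG" + "GCT" * 300 + "TAA" + "C" * 50
        t = self._tx("lnc1", len(seq), seq=seq)
        assert filter_lncrna_candidates([t], None, {"lnc1": "u"}) == []

    def test_fpkm_threshold(self):
        t1, t2 = self._tx("lo", 500), self._tx("hi", 500)
        expr = self._expr({"lo": 0.4, "hi": 0.6})
        kept = filter_lncrna_candidates(
            [t1, t2], expr, {"lo": "u", "hi": "u"}
        )
        assert [t.transcript_id for t in kept] == ["hi"]

    def test_annotated_class_code_rejected(self):
        t = self._tx("lnc1", 500)
        assert filter_lncrna_candidates([t], None, {"lnc1": "="}) == []

    def test_cis_nat_classification(self):
        host = make_gene("host", [[(100, 200), (300, 400)]])
        anti = TranscriptModel("nat", "nat.locus", "chrT", "-", [(250, 280)])
        far = TranscriptModel("far", "far.locus", "chrT", "+", [(5000, 5400)])
        same = TranscriptModel("same", "same.locus", "chrT", "+", [(150, 450)])
        out = classify_cis_nat([anti, far, same], [host])
        assert out["nat"] == ("cis_NAT", ["host"])
        assert out["far"] == ("intergenic", [])
        assert out["same"][0] == "same_strand_overlap"


class TestSiteContext:
    def _gene(self):
        # pre-mRNA axis: exon (0,100), intron (100,200), exon (200,300);
        # second isoform retains the intron
        return make_gene(
            "g", [[(0, 100), (200, 300)], [(0, 300)]], reference="g.t1"
        )

    def _site(self, ts, te):
        from splicescape.lnc_interactome import InteractionSite

        return InteractionSite(
            "lnc", "g.premrna", (0, te - ts), (ts, te), 100.0, te - ts
        )

    def test_exonic_and_retained_intron_junction_classes(self):
        g = self._gene()
        pm = build_pre_mrna(g)
        junctions = catalogue_junctions(g)
        assert classify_site(self._site(10, 60), pm, junctions).site_class == "exonic"
        # (100,200) is retained by the second isoform, so the union keeps
        # it exonic; its boundaries are still junction boundaries
        assert (
            classify_site(self._site(120, 180), pm, junctions).site_class
            == "exonic"
        )
        s = classify_site(self._site(80, 130), pm, junctions)
        assert s.site_class == "junction_spanning"
        # the retained intron's boundaries are alternative
        assert s.spans_alternative_junction

    def test_intronic_site_in_constitutive_intron(self):
        g = make_gene(
            "g", [[(0, 100), (200, 300)], [(0, 100), (200, 320)]]
        )
        pm = build_pre_mrna(g)
        junctions = catalogue_junctions(g)
        s = classify_site(self._site(120, 180), pm, junctions)
        assert s.site_class == "intronic"
        assert not s.spans_alternative_junction

    def test_constitutive_junction_not_flagged_alternative(self):
        g = make_gene(
            "g",
            [[(0, 100), (200, 300), (350, 400)],
             [(0, 100), (200, 300), (350, 420)]],
        )
        pm = build_pre_mrna(g)
        junctions = catalogue_junctions(g)
        s = classify_site(self._site(80, 130), pm, junctions)
        assert s.site_class == "junction_spanning"
        assert not s.spans_alternative_junction


class TestFisher:
    @staticmethod
    def enumeration_oracle(table):
        """Two-sided exact p by summing hypergeometric table probabilities."""
        (a, b), (c, d) = table
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2

        def pmf(k):
            return (
                math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
            )

        support = range(max(0, c1 - r2), min(r1, c1) + 1)
        p_obs = pmf(a)
        return sum(p for k in support if (p := pmf(k)) <= p_obs * (1 + 1e-9))

    def test_balanced_table(self):
        assert fisher_two_sided([[10, 10], [10, 10]]) == pytest.approx(1.0)
        assert odds_ratio_haldane([[10, 10], [10, 10]]) == pytest.approx(1.0)

    def test_strong_association_hand_value(self):
        # 2 * (C(10,9)C(10,1) + C(10,10)C(10,0)) / C(20,10) = 202/184756
        p = fisher_two_sided([[9, 1], [1, 9]])
        assert p == pytest.approx(202 / 184756)
        assert p == pytest.approx(self.enumeration_oracle([[9, 1], [1, 9]]))

    def test_enumeration_equivalence_all_small_tables(self):
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        assert fisher_two_sided(t) == pytest.approx(
                            self.enumeration_oracle(t), rel=1e-9, abs=1e-12
                        ), t

    def test_haldane_correction_on_zero_cell(self):
        assert odds_ratio_haldane([[5, 0], [2, 7]]) == pytest.approx(
            (5.5 * 7.5) / (0.5 * 2.5)
        )

    def test_planted_alternative_junction_enrichment(self):
        ds = generate_genome_and_genes(seed=31)
        generate_lncrnas(ds, seed=32)
        from splicescape.models_io import extract_sequences

        extract_sequences(ds.genes, ds.genome)
        gene_by_id = {g.gene_id: g for g in ds.genes}
        targets = sorted({s["target_gene"] for s in ds.ground_truth.lnc_sites})
        premrna_by_gene = {}
        gene_of_target = {}
        all_junctions = []
        sites = []
        for g in ds.genes:
            all_junctions.extend(catalogue_junctions(g))
            premrna_by_gene[g.gene_id] = build_pre_mrna(g)
            gene_of_target[f"{g.gene_id}.premrna"] = g.gene_id
        for gid in targets:
            g = gene_by_id[gid]
            tseq = premrna_sequence(g, ds.genome)
            for lnc in ds.lncrnas:
                if lnc.transcript_id.startswith("lncNAT"):
                    continue
                sites.extend(
                    align_duplex(
                        spliced_sequence(lnc, ds.genome), tseq,
                        lncrna_id=lnc.transcript_id,
                        target_id=f"{gid}.premrna",
                    )
                )
        odds, p, table = junction_enrichment(
            sites, all_junctions, premrna_by_gene, gene_of_target
        )
        assert odds > 1.0
        assert p < 0.05


class TestCorrelation:
    def _expr(self, lnc_vals, target_vals):
        values = pd.DataFrame(
            {f"s{i}": [l, t] for i, (l, t) in enumerate(zip(lnc_vals, target_vals))},
            index=["lnc1", "g1"],
        )
        return ExpressionMatrix(values, {c: c for c in values.columns})

    def _sites(self):
        from splicescape.lnc_interactome import InteractionSite

        return [InteractionSite("lnc1", "g1", (0, 30), (0, 30), 120.0, 30)]

    def test_identical_order_rho_one(self):
        expr = self._expr([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        (rec,) = correlate_pairs(self._sites(), expr)
        assert rec["rho"] == pytest.approx(1.0)
        assert rec["pvalue"] == pytest.approx(1 / math.factorial(6))
        assert rec["coregulated"]

    def test_reversed_order_rho_minus_one(self):
        expr = self._expr([1, 2, 3, 4, 5, 6], [60, 50, 40, 30, 20, 10])
        (rec,) = correlate_pairs(self._sites(), expr)
        assert rec["rho"] == pytest.approx(-1.0)
        assert not rec["coregulated"]

    def test_three_samples_p_floor_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="splicescape.lnc_interactome"):
            rho, p = spearman_permutation([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 6)
        assert any("cannot fall below" in r.message for r in caplog.records)

    def test_constant_vector_undefined(self):
        rho, p = spearman_permutation([1, 2, 3, 4], [5, 5, 5, 5])
        assert math.isnan(rho)

    def test_planted_coregulated_pairs_recovered(self, dataset):
        ds = dataset
        from splicescape.lnc_interactome import InteractionSite

        sites = [
            InteractionSite(
                p["lncrna_id"], p["target_gene"], (0, 10), (0, 10), 100.0, 10
            )
            for p in ds.ground_truth.coregulated_pairs
        ]
        # correlate against the summed gene expression rows
        expr = ds.expression
        tx_by_gene = {
            g.gene_id: [t.transcript_id for t in g.transcripts]
            for g in ds.genes
        }
        values = expr.values.copy()
        for gid, tids in tx_by_gene.items():
            values.loc[gid] = values.loc[tids].sum(axis=0)
        expr2 = ExpressionMatrix(values, expr.conditions)
        recs = correlate_pairs(sites, expr2)
        assert recs
        for rec in recs:
            assert rec["rho"] > 0.8 and rec["coregulated"]


class TestCommonSites:
    def test_identical_sets(self):
        a = [("l", "g", (0, 30))]
        frac, *_ = common_site_fraction(a, a)
        assert frac == 1.0

    def test_disjoint_sets(self):
        a = [("l", "g", (0, 30))]
        b = [("l", "g", (100, 130))]
        frac, *_ = common_site_fraction(a, b)
        assert frac == 0.0

    def test_one_of_four_shared(self):
        ref = [("l", "g", (0, 30)), ("l", "g", (100, 130))]
        alt = [("l", "g", (10, 40)), ("l", "g2", (0, 30)), ("l2", "g", (0, 30))]
        frac, shared, ref_only, alt_only = common_site_fraction(ref, alt)
        assert (shared, ref_only, alt_only) == (1, 1, 2)
        assert frac == pytest.approx(0.25)
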