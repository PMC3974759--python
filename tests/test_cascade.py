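import itertools

import numpy as np
import pandas as pd
import pytest

import omicascade as oc
from omicascade import (
    AlignmentError,
    CascadeConfig,
    ConfigError,
    ExpressionMatrix,
    Triad,
    join_triads,
    run_cascade,
    summarize_unique,
)


def brute_force_join(conc, g1, m2, s3, s4, s5, s6):
    """Exhaustive cross-product enumeration with all six membership checks."""
    snps = {s for s, _ in s4} | {s for s, _ in s5} | set(s6)
    genes = set(g1) | {g for _, g in s4} | {g for g, _ in s3}
    mirnas = set(m2) | {m for _, m in s5} | {m for _, m in s3}
    out = set()
    for s, m, g in itertools.product(snps, mirnas, genes):
        if (
            g in g1 and m in m2 and (g, m) in s3
            and (s, g) in s4 and (s, m) in s5 and s in s6
        ):
            out.add((s, m, g))
    return out


class TestJoinTriads:
    def test_minimal_join_yields_single_triad(self):
        tri = join_triads(
            10.0,
            {"g1": 0.01}, {"m1": 0.02}, {("g1", "m1"): (-0.5, 1e-5)},
            {("s1", "g1"): 2e-5}, {("s1", "m1"): 0.03}, {"s1": 5e-5},
        )
        assert len(tri) == 1
        t = tri[0]
        assert t.key == ("s1", "m1", "g1")
        assert (t.p_s1, t.p_s2, t.p_s3, t.p_s4, t.p_s5, t.p_s6) == (
            0.01, 0.02, 1e-5, 2e-5, 0.03, 5e-5
        )
        assert t.r_s3 == -0.5

    def test_missing_step5_membership_kills_triad(self):
        tri = join_triads(
            10.0,
            {"g1": 0.01}, {"m1": 0.02}, {("g1", "m1"): (-0.5, 1e-5)},
            {("s1", "g1"): 2e-5}, {}, {"s1": 5e-5},
        )
        assert tri == []

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            snps = [f"s{i}" for i in range(rng.integers(1, 6))]
            genes = [f"g{i}" for i in range(rng.integers(1, 6))]
            mirnas = [f"m{i}" for i in range(rng.integers(1, 6))]
            pick = lambda pool, p: {x for x in pool if rng.random() < p}
            g1 = {g: 0.01 for g in pick(genes, 0.7)}
            m2 = {m: 0.01 for m in pick(mirnas, 0.7)}
            s3 = {
                (g, m): (-0.4, 1e-5)
                for g, m in itertools.product(genes, mirnas)
                if rng.random() < 0.4
            }
            s4 = {
                (s, g): 1e-5
                for s, g in itertools.product(snps, genes)
                if rng.random() < 0.4
            }
            s5 = {
                (s, m): 0.01
                for s, m in itertools.product(snps, mirnas)
                if rng.random() < 0.4
            }
            s6 = {s: 1e-5 for s in pick(snps, 0.7)}
            got = {t.key for t in join_triads(5.0, g1, m2, s3, s4, s5, s6)}
            assert got == brute_force_join(5.0, g1, m2, s3, s4, s5, s6)


class TestSummarizeUnique:
    def test_same_triad_at_two_doses_counted_once(self):
        mk = lambda conc: Triad(
            "s1", "m1", "g1", conc, 0.01, 0.01, 1e-5, 1e-5, 0.01, 1e-5, -0.4
        )
        out = summarize_unique([mk(5.0), mk(7.0)])
        assert out["n_unique_triads"] == 1

    def test_counts_by_entity(self):
        t1 = Triad("s1", "m1", "g1", 5.0, *[1e-3] * 6, -0.4)
        t2 = Triad("s1", "m2", "g1", 5.0, *[1e-3] * 6, -0.4)
        out = summarize_unique([t1, t2])
        assert out == {
            "n_unique_triads": 2, "n_snps": 1, "n_mirnas": 2, "n_genes": 1,
        }

    def test_matches_set_oracle_with_duplicates(self):
        rng = np.random.default_rng(5)
        triads = []
        for _ in range(20):
            s, m, g = (
                f"s{rng.integers(3)}", f"m{rng.integers(3)}",
                f"g{rng.integers(3)}",
            )
            triads.append(
                Triad(s, m, g, float(rng.choice([3, 5])), *[1e-3] * 6, -0.1)
            )
        out = summarize_unique(triads)
        keys = {(t.snp_id, t.mirna_id, t.gene_id) for t in triads}
        assert out["n_unique_triads"] == len(keys)
        assert out["n_snps"] == len({k[0] for k in keys})


class TestConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError, match="alpha_strict"):
            CascadeConfig(alpha_loose=1e-5, alpha_strict=1e-3).validate()


class TestStepSemantics:
    def test_step1_survivors_are_exactly_sub_threshold_genes(
        self, small_null_cohort
    ):
        c = small_null_cohort
        cfg = CascadeConfig()
        s1 = oc.step1_pheno_gene(c.phenotypes, c.gene_expr, cfg)
        conc = 10.0
        y = c.phenotypes.log_pheno[conc].to_numpy()
        expect = set()
        for g in c.gene_expr.feature_ids:
            rec = oc.fit_slope(c.gene_expr.values[g].to_numpy(), y)
            if rec.p < cfg.alpha_loose:
                expect.add(g)
        got = set(s1.loc[s1["concentration"] == conc, "feature_id"])
        assert got == expect

    def test_loose_gate_uses_strict_inequality(self, small_null_cohort):
        # a feature with p exactly re-threshold must not survive; verified
        # indirectly: no surviving p is >= alpha_loose
        c = small_null_cohort
        cfg = CascadeConfig()
        s2 = oc.step2_pheno_mirna(c.phenotypes, c.mirna_expr, cfg)
        if len(s2):
            assert (s2["p"] < cfg.alpha_loose).all()

    def test_vacuous_propagation_with_tiny_alpha(self, small_null_cohort):
        c = small_null_cohort
        cfg = CascadeConfig(alpha_loose=1e-6, alpha_strict=1e-8)
        res = run_cascade(
            c.genotypes, c.gene_expr, c.mirna_expr, c.phenotypes, cfg
        )
        assert res.triads == []
        assert all(len(df) == 0 for df in res.steps.values())

    def test_step3_sign_gate_rejects_positive_pairs(self, single_triad_cohort):
        c = single_triad_cohort
        cfg = CascadeConfig()
        s1 = oc.step1_pheno_gene(c.phenotypes, c.gene_expr, cfg)
        s2 = oc.step2_pheno_mirna(c.phenotypes, c.mirna_expr, cfg)
        s3 = oc.step3_negative_pairs(s1, s2, c.gene_expr, c.mirna_expr, cfg)
        assert (s3["r"] < 0).all()
        assert (s3["p"] <= cfg.alpha_strict).all()


class TestCascadeEndToEnd:
    def test_planted_triad_recovered_at_high_doses(self, single_triad_cohort):
        c = single_triad_cohort
        res = run_cascade(c.genotypes, c.gene_expr, c.mirna_expr, c.phenotypes)
        truth = c.truth[0]
        found = {
            (t.snp_id, t.mirna_id, t.gene_id)
            for t in res.triads
            if t.concentration == 10.0
        }
        assert (truth.snp_id, truth.mirna_id, truth.gene_id) in found

    def test_survivor_sets_are_nested(self, single_triad_cohort):
        c = single_triad_cohort
        res = run_cascade(c.genotypes, c.gene_expr, c.mirna_expr, c.phenotypes)
        s = res.steps
        for conc in c.phenotypes.concentrations:
            sel = lambda k: s[k][s[k]["concentration"] == conc]
            g1 = set(sel("S1")["feature_id"])
            m2 = set(sel("S2")["feature_id"])
            assert set(sel("S3")["gene_id"]) <= g1
            assert set(sel("S3")["mirna_id"]) <= m2
            assert set(sel("S4")["gene_id"]) <= set(sel("S3")["gene_id"])
            assert set(sel("S5")["snp_id"]) <= set(sel("S4")["snp_id"])
            assert set(sel("S5")["mirna_id"]) <= set(sel("S3")["mirna_id"])
            assert set(sel("S6")["snp_id"]) <= set(sel("S5")["snp_id"])

    def test_triad_pvalues_satisfy_thresholds(self, single_triad_cohort):
        c = single_triad_cohort
        cfg = CascadeConfig()
        res = run_cascade(
            c.genotypes, c.gene_expr, c.mirna_expr, c.phenotypes, cfg
        )
        assert res.triads, "expected at least one triad in planted cohort"
        for t in res.triads:
            assert t.p_s1 < cfg.alpha_loose
            assert t.p_s2 < cfg.alpha_loose
            assert t.p_s5 < cfg.alpha_loose
            assert t.p_s3 <= cfg.alpha_strict
            assert t.p_s4 <= cfg.alpha_strict
            assert t.p_s6 <= cfg.alpha_strict
            assert t.r_s3 < 0

    def test_roster_mismatch_raises_alignment_error(self, small_null_cohort):
        c = small_null_cohort
        bad = ExpressionMatrix(
            c.gene_expr.values.rename(index={c.gene_expr.samples[0]: "ALIEN"})
        )
        with pytest.raises(AlignmentError, match="ALIEN"):
            run_cascade(c.genotypes, bad, c.mirna_expr, c.phenotypes)

    def test_shuffled_sample_rows_give_identical_triads(
        self, single_triad_cohort
    ):
        # alignment is by identifier, never by position
        c = single_triad_cohort
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(c.gene_expr.samples))
        shuffled = ExpressionMatrix(c.gene_expr.values.iloc[perm])
        a = run_cascade(c.genotypes, c.gene_expr, c.mirna_expr, c.phenotypes)
        b = run_cascade(c.genotypes, shuffled, c.mirna_expr, c.phenotypes)
        keys = lambda res: sorted((t.concentration,) + t.key for t in res.triads)
        assert keys(a) == keys(b)
        pa = {(t.concentration,) + t.key: t.p_s1 for t in a.triads}
        pb = {(t.concentration,) + t.key: t.p_s1 for t in b.triads}
        for k in pa:
            assert pa[k] == pytest.approx(pb[k], rel=1e-10)
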