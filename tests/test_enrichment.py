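import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import _oracles
from seedmod.enrichment import (
    ContingencyTable,
    PhenotypeAnnotation,
    bootstrap_rates,
    build_contingency,
    cadd_filter,
    classify_functional,
    classify_variants,
    cnv_hits_module,
    cnv_overlap_enrichment,
    fisher_test,
    gene_group_rate_comparison,
    permutation_test,
    phenotype_enrichment_score,
)
from seedmod.errors import InputError
from seedmod.simulate import SimConfig, simulate_cnvs, simulate_networks, simulate_variants


def make_vt(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "group", "cohort", "gene", "functional_class", "cadd"])
    return classify_variants(df)


class TestClassification:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("stop-gained", "LOF"),
            ("frameshift", "LOF"),
            ("splice_donor", "LOF"),
            ("stop-gained-near-splice", "LOF"),
            ("stop-lost", "LOF"),
            ("missense-near-splice", "missense"),
            ("Missense", "missense"),
            ("synonymous", "synonymous"),
            ("intergenic", "other"),
            ("frobnicated", "other"),
        ],
    )
    def test_vocabulary(self, label, expected):
        assert classify_functional(label) == expected

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                ["stop-gained", "missense", "synonymous", "intron", "frameshift", "weird"]
            ),
            min_size=1,
            max_size=50,
        )
    )
    def test_classification_conserves_records(self, labels):
        rows = [(f"s{i}", "case", "ASD", "G1", lab, 10.0) for i, lab in enumerate(labels)]
        out = make_vt(rows)
        counts = out["mut_class"].value_counts()
        assert counts.sum() == len(labels)
        assert set(counts.index) <= {"LOF", "missense", "synonymous", "other"}


class TestCaddFilter:
    def test_threshold_and_scope(self):
        rows = [
            ("s1", "case", "ASD", "G1", "missense", 20.0),
            ("s2", "case", "ASD", "G1", "missense", 10.0),
            ("s3", "case", "ASD", "G1", "missense", np.nan),
            ("s4", "case", "ASD", "G1", "stop-gained", 3.0),
            ("s5", "case", "ASD", "G1", "synonymous", 1.0),
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "group", "cohort", "gene", "functional_class", "cadd"])
        out = cadd_filter(df, threshold=15)
        kept = set(out["sample_id"])
        assert kept == {"s1", "s4", "s5"}

    def test_empty_table(self):
        df = pd.DataFrame(columns=["sample_id", "group", "cohort", "gene", "functional_class", "cadd"])
        assert len(cadd_filter(df)) == 0


class TestContingency:
    def test_hand_tally(self):
        rows = [
            ("s1", "case", "ASD", "A", "missense", 20.0),
            ("s1", "case", "ASD", "B", "stop-gained", 30.0),
            ("s2", "case", "ASD", "C", "missense", 20.0),
            ("s3", "control", "control", "A", "missense", 20.0),
            ("s4", "control", "control", "C", "synonymous", 5.0),
        ]
        ct = build_contingency({"A", "B"}, make_vt(rows))
        assert (ct.a, ct.b, ct.c, ct.d) == (2, 1, 1, 0)

    def test_module_with_all_genes(self):
        rows = [
            ("s1", "case", "ASD", "A", "missense", 20.0),
            ("s2", "control", "control", "A", "missense", 20.0),
        ]
        ct = build_contingency({"A"}, make_vt(rows))
        assert ct.b == 0 and ct.d == 0

    def test_all_zero_table_surfaces_downstream(self):
        rows = [("s1", "case", "EPI", "A", "missense", 20.0)]
        ct = build_contingency({"A"}, make_vt(rows), case_cohorts={"SCZ"})
        with pytest.raises(InputError):
            fisher_test(ct)


class TestFisher:
    def test_example_table(self):
        ct = ContingencyTable(10, 90, 5, 195)
        res = fisher_test(ct, alternative="greater")
        assert res.odds_ratio == pytest.approx((10 * 195) / (90 * 5))
        assert res.fisher_p == pytest.approx(
            _oracles.fisher_greater_exact(10, 90, 5, 195), abs=1e-12
        )

    def test_symmetric_table(self):
        res = fisher_test(ContingencyTable(4, 7, 4, 7), alternative="two-sided")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_infinite_odds_ratio(self):
        res = fisher_test(ContingencyTable(3, 0, 0, 3), alternative="greater")
        assert np.isinf(res.odds_ratio)
        assert res.fisher_p == pytest.approx(
            _oracles.fisher_greater_exact(3, 0, 0, 3), abs=1e-12
        )

    def test_agrees_with_scipy_fisher_exact(self, rng):
        """Independent cross-check against the reference implementation."""
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            ct = ContingencyTable(a, b, c, d)
            for alt in ("greater", "two-sided"):
                ours = fisher_test(ct, alternative=alt).fisher_p
                ref = stats.fisher_exact([[a, b], [c, d]], alternative=alt)[1]
                assert ours == pytest.approx(ref, abs=1e-9)


class TestPermutation:
    def _null_table(self, rng_seed=0):
        cfg = SimConfig(
            n_genes=100, planted_size=10, n_cases=100, n_controls=100,
            enrichment_factor=1.0, rng_seed=rng_seed,
        )
        _, _, _, truth = simulate_networks(cfg)
        return classify_variants(simulate_variants(cfg, truth)), truth

    def test_no_module_mutations_gives_p_one(self):
        vt, truth = self._null_table()
        p = permutation_test(vt, {"NOT_A_GENE"}, n_iter=99, rng_seed=1).perm_p
        assert p == pytest.approx(1.0)

    def test_planted_enrichment_detected(self):
        cfg = SimConfig(rng_seed=11)  # defaults: factor 5, 1000+1000
        _, _, _, truth = simulate_networks(cfg)
        vt = classify_variants(simulate_variants(cfg, truth))
        res = permutation_test(vt, set(truth.planted), n_iter=999, rng_seed=2)
        assert res.perm_p <= 0.01

    def test_deterministic(self):
        vt, truth = self._null_table(3)
        p1 = permutation_test(vt, set(truth.planted), n_iter=199, rng_seed=5).perm_p
        p2 = permutation_test(vt, set(truth.planted), n_iter=199, rng_seed=5).perm_p
        assert p1 == p2

    def test_p_bounded_below(self):
        vt, truth = self._null_table(4)
        res = permutation_test(vt, set(truth.planted), n_iter=49, rng_seed=5)
        assert 1 / 50 <= res.perm_p <= 1.0


class TestBootstrap:
    def test_zero_variance_ci(self):
        rows = [(f"p{i}", "case", "ASD", "A", "missense", 20.0) for i in range(10)]
        rows += [(f"c{i}", "control", "control", "A", "missense", 20.0) for i in range(10)]
        out = bootstrap_rates(make_vt(rows), {"A"}, n_iter=200, rng_seed=1)
        assert out["case"]["ci"] == (1.0, 1.0)
        assert out["control"]["mean"] == 1.0

    def test_deterministic(self):
        cfg = SimConfig(n_genes=50, planted_size=5, n_cases=80, n_controls=80, rng_seed=2)
        _, _, _, truth = simulate_networks(cfg)
        vt = classify_variants(simulate_variants(cfg, truth))
        b1 = bootstrap_rates(vt, set(truth.planted), n_iter=500, rng_seed=9)
        b2 = bootstrap_rates(vt, set(truth.planted), n_iter=500, rng_seed=9)
        assert b1 == b2

    def test_poisson_coverage(self):
        """Percentile bootstrap CI covers the true mean in ~95% of replicates."""
        lam, n, covered = 0.1, 2000, 0
        reps = 60
        master = np.random.default_rng(123)
        for r in range(reps):
            counts = master.poisson(lam, n)
            rows = [(f"p{i}", "case", "ASD", "A", "missense", 20.0)
                    for i, c in enumerate(counts) for _ in range(c)]
            rows += [("c0", "control", "control", "A", "missense", 20.0)]
            vt = make_vt(rows)
            out = bootstrap_rates(
                vt, {"A"}, n_iter=400, rng_seed=r,
                samples={"case": [f"p{i}" for i in range(n)], "control": ["c0"]},
            )
            lo, hi = out["case"]["ci"]
            covered += lo <= lam <= hi
        assert covered / reps >= 0.85

    def test_empty_arm_errors(self):
        rows = [("p1", "case", "ASD", "A", "missense", 20.0)]
        with pytest.raises(InputError):
            bootstrap_rates(make_vt(rows), {"A"}, n_iter=10, rng_seed=0)


class TestRateComparison:
    def test_null_rates_near_one(self):
        cfg = SimConfig(enrichment_factor=1.0, rng_seed=21)
        _, _, _, truth = simulate_networks(cfg)
        vt = classify_variants(simulate_variants(cfg, truth))
        out = gene_group_rate_comparison(vt, {"planted": set(truth.planted)})
        row = out[(out["group"] == "planted") & (out["mut_class"] == "non-synonymous")].iloc[0]
        assert 0.5 < row["rate_ratio"] < 2.0
        assert row["p_value"] > 0.05

    def test_enriched_group_detected_and_synonymous_flat(self):
        cfg = SimConfig(enrichment_factor=3.0, rng_seed=22)
        _, _, _, truth = simulate_networks(cfg)
        vt = classify_variants(simulate_variants(cfg, truth))
        out = gene_group_rate_comparison(vt, {"planted": set(truth.planted)})
        nsyn = out[(out["mut_class"] == "non-synonymous")].iloc[0]
        syn = out[(out["mut_class"] == "synonymous")].iloc[0]
        assert 2.0 < nsyn["rate_ratio"] < 4.5
        assert nsyn["p_value"] < 0.05
        assert syn["p_value"] > 0.05

    def test_empty_group_skipped(self, caplog):
        rows = [("s1", "case", "ASD", "A", "missense", 20.0),
                ("c1", "control", "control", "A", "missense", 20.0)]
        with caplog.at_level("WARNING"):
            out = gene_group_rate_comparison(make_vt(rows), {"empty": set(), "ok": {"A"}})
        assert set(out["group"]) == {"ok"}


class TestPhenotypeScore:
    def test_printed_formula_example(self):
        anno = PhenotypeAnnotation({"NDD": {f"P{i}" for i in range(500)}}, genome_total=19_986)
        module = {f"P{i}" for i in range(10)} | {f"X{i}" for i in range(40)}
        score = phenotype_enrichment_score(module, anno, "NDD")
        assert score == pytest.approx((10 / 40) / (500 / 19_486))
        assert score == pytest.approx(9.743, abs=5e-4)

    def test_zero_and_saturated(self):
        anno = PhenotypeAnnotation({"NDD": {"P1", "P2"}}, genome_total=100)
        assert phenotype_enrichment_score({"X1", "X2"}, anno, "NDD") == 0.0
        assert np.isinf(phenotype_enrichment_score({"P1", "P2"}, anno, "NDD"))

    def test_null_calibration_equals_one(self):
        # module annotated at exactly the genome-wide fraction
        anno = PhenotypeAnnotation({"P": {f"A{i}" for i in range(100)}}, genome_total=500)
        module = {f"A{i}" for i in range(8)} | {f"B{i}" for i in range(32)}
        assert phenotype_enrichment_score(module, anno, "P") == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 400))
    def test_scale_consistency(self, m_p, m_pc, g_p):
        """Doubling both annotated and unannotated module counts keeps the score."""
        anno = PhenotypeAnnotation({"P": {f"A{i}" for i in range(g_p)}}, genome_total=1000)
        mod1 = {f"A{i}" for i in range(m_p)} | {f"B{i}" for i in range(m_pc)}
        mod2 = ({f"A{i}" for i in range(min(2 * m_p, g_p))}
                | {f"B{i}" for i in range(2 * m_pc)})
        s1 = phenotype_enrichment_score(mod1, anno, "P")
        if 2 * m_p <= g_p:
            s2 = phenotype_enrichment_score(mod2, anno, "P")
            assert s2 == pytest.approx(s1)


class TestCnv:
    def test_half_open_boundary(self):
        iv = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [150, 200], "end": [160, 210],
             "gene": ["IN", "OUT"]}
        )
        cnvs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200],
             "sample_id": ["s1"], "group": ["case"], "type": ["del"]}
        )
        assert cnv_hits_module(cnvs, iv, {"IN"}).tolist() == [True]
        assert cnv_hits_module(cnvs, iv, {"OUT"}).tolist() == [False]

    def test_saturated_module_hits_every_genic_cnv(self):
        cfg = SimConfig(n_genes=50, planted_size=5, n_cases=60, n_controls=60, rng_seed=6)
        _, _, _, truth = simulate_networks(cfg)
        cnvs, iv = simulate_cnvs(cfg, truth)
        hits = cnv_hits_module(cnvs, iv, set(iv["gene"]))
        assert hits.all()

    def test_planted_bias_detected(self):
        cfg = SimConfig(rng_seed=13)  # defaults: bias 4, 1000+1000
        _, _, _, truth = simulate_networks(cfg)
        cnvs, iv = simulate_cnvs(cfg, truth)
        res = cnv_overlap_enrichment(cnvs, iv, set(truth.planted), n_perm=500, rng_seed=3)
        assert res.odds_ratio > 1.0
        assert res.perm_p <= 0.05

    def test_empty_cnvs_error(self):
        iv = pd.DataFrame({"chrom": [], "start": [], "end": [], "gene": []})
        cnvs = pd.DataFrame(columns=["chrom", "start", "end", "sample_id", "group", "type"])
        with pytest.raises(InputError):
            cnv_overlap_enrichment(cnvs, iv, {"A"}, n_perm=10, rng_seed=0)
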