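"""Counting, normalization, NB Wald testing, BH, Fisher and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phasetally as pt


def make_cm(arr, genotypes):
    genes = [f"g{i}" for i in range(arr.shape[0])]
    libs = [f"{g}_{i}" for i, g in enumerate(genotypes)]
    counts = pd.DataFrame(arr, index=genes, columns=libs)
    meta = pd.DataFrame({"genotype": genotypes}, index=libs)
    return pt.CountMatrix(counts, meta)


class TestCounting:
    @pytest.fixture()
    def features(self):
        return pd.DataFrame(
            [
                {"gene_id": "A", "chrom": "chr1", "start": 100, "end": 200,
                 "type": "miRNA_target"},
                {"gene_id": "B", "chrom": "chr1", "start": 200, "end": 300,
                 "type": "protein_coding"},
                {"gene_id": "I1", "chrom": "chr1", "start": 0, "end": 100,
                 "type": "intergenic"},
                {"gene_id": "I2", "chrom": "chr1", "start": 300, "end": 400,
                 "type": "intergenic"},
            ]
        )

    def _write_sam(self, path, rows, chrom_len=400, chrom="chr1"):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for name, start, length in rows:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "A" * length
                a.reference_id = 0
                a.reference_start = start
                a.cigartuples = [(0, length)]
                a.mapping_quality = 255
                out.write(a)

    def test_inside_ambiguous_and_conservation(self, features, tmp_path):
        path = tmp_path / "lib.sam"
        rows = [
            ("in_A", 150, 21),        # fully inside A
            ("ambig", 190, 21),       # spans A and B equally -> unassigned
            ("in_B", 250, 24),
            ("in_I1", 10, 22),
        ]
        self._write_sam(path, rows)
        cm = pt.assign_reads_to_features({"wt_1": path}, features)
        assert cm.counts.loc["A", "wt_1"] == 1
        assert cm.counts.loc["B", "wt_1"] == 1
        assert cm.counts.loc["I1", "wt_1"] == 1
        assert cm.unassigned["wt_1"] == 1
        assert cm.counts["wt_1"].sum() + cm.unassigned["wt_1"] == len(rows)

    def test_empty_alignment_file_gives_zero_matrix(self, features, tmp_path):
        path = tmp_path / "empty.sam"
        self._write_sam(path, [])
        cm = pt.assign_reads_to_features({"wt_1": path}, features)
        assert (cm.counts["wt_1"] == 0).all()

    def test_unknown_chromosome_raises_with_name(self, features, tmp_path):
        path = tmp_path / "badchrom.sam"
        self._write_sam(path, [("r", 5, 21)], chrom="chrX")
        with pytest.raises(ValueError, match="chrX"):
            pt.assign_reads_to_features({"wt_1": path}, features)


class TestNormalization:
    def test_rpm_and_rp10m(self):
        counts = pd.DataFrame({"lib": [5, 999_995]})
        assert pt.normalize_rpm(counts, "RPM").iloc[0, 0] == pytest.approx(5.0)
        assert pt.normalize_rpm(counts, "RP10M").iloc[0, 0] == pytest.approx(50.0)

    def test_doubling_counts_and_total_preserves_rpm(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"lib": rng.integers(1, 100, 50)})
        doubled = counts * 2
        assert np.allclose(pt.normalize_rpm(counts), pt.normalize_rpm(doubled))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero library total"):
            pt.normalize_rpm(pd.DataFrame({"lib": [0, 0]}))


class TestSizeFactors:
    def test_identical_libraries_factor_one(self):
        counts = pd.DataFrame({"a": [10, 30, 7], "b": [10, 30, 7]})
        assert np.allclose(pt.size_factors(counts), 1.0)

    def test_doubled_library_median_of_ratios(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
        sf = pt.size_factors(counts)
        assert sf["A"] == pytest.approx(1 / math.sqrt(2))
        assert sf["B"] == pytest.approx(math.sqrt(2))

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 3)),
                              columns=list("abc"))
        perm = counts.sample(frac=1, random_state=1)
        assert np.allclose(pt.size_factors(counts), pt.size_factors(perm))

    def test_no_common_nonzero_gene_suggests_pseudocount(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            pt.size_factors(counts)
        assert (pt.size_factors(counts, pseudocount=0.5) > 0).all()


class TestNBWald:
    def test_poisson_limit_matches_poisson_glm(self):
        """At dispersion -> 0 the Wald p agrees with a Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        arr = rng.poisson(60, size=(40, 6))
        cm = make_cm(arr, ["wt"] * 3 + ["mut"] * 3)
        sf = pt.size_factors(cm.counts)
        res = pt.nb_wald_test(cm, ("mut", "wt"), dispersion=0.0, sf=sf)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        for gene in res.index[:10]:
            fit = sm.GLM(cm.counts.loc[gene].to_numpy(), X,
                         family=sm.families.Poisson(),
                         offset=np.log(sf.to_numpy())).fit()
            p_ref = 2 * stats.norm.sf(abs(fit.params[1] / fit.bse[1]))
            assert res.loc[gene, "pvalue"] == pytest.approx(p_ref, abs=1e-3)

    def test_invariant_to_replicate_relabeling(self):
        rng = np.random.default_rng(6)
        arr = rng.negative_binomial(10, 0.1, size=(30, 6))
        cm1 = make_cm(arr, ["wt", "wt", "wt", "mut", "mut", "mut"])
        shuffled = arr[:, [2, 0, 1, 5, 3, 4]]
        cm2 = make_cm(shuffled, ["wt", "wt", "wt", "mut", "mut", "mut"])
        r1 = pt.nb_wald_test(cm1, ("mut", "wt"))
        r2 = pt.nb_wald_test(cm2, ("mut", "wt"))
        assert np.allclose(r1["pvalue"], r2["pvalue"], equal_nan=True)

    def test_single_replicate_group_refused(self):
        arr = np.ones((5, 3), dtype=int)
        cm = make_cm(arr, ["wt", "wt", "mut"])
        with pytest.raises(ValueError, match="at least 2"):
            pt.nb_wald_test(cm, ("mut", "wt"))

    def test_all_zero_genes_excluded_and_flagged(self):
        arr = np.array([[10, 12, 9, 50, 55, 60], [0, 0, 0, 0, 0, 0]])
        cm = make_cm(arr, ["wt"] * 3 + ["mut"] * 3)
        res = pt.nb_wald_test(cm, ("mut", "wt"), dispersion=0.1)
        assert "g1" not in res.index
        assert res.attrs["all_zero"] == ["g1"]

    def test_recovers_large_fold_change_direction(self):
        cfg = pt.SimConfig(seed=40, nb_params=pt.NBParams(
            genotypes={"wt": 3, "mutant": 3}, n_genes=300, mean=100.0,
            dispersion=0.05,
            lfc={"mutant": np.r_[np.full(30, 2.0), np.zeros(270)]}))
        cm = pt.simulate_count_matrix(cfg)
        res = pt.nb_wald_test(cm, ("mutant", "wt"), dispersion="pooled")
        changed = res.loc[[f"GENE{i+1}" for i in range(30)]]
        assert (changed["padj"] < 0.05).mean() > 0.9
        assert changed["log2FC"].median() == pytest.approx(2.0, abs=0.35)

    def test_agrees_with_deseq2_reference_on_small_matrix(self):
        """Independent cross-check against pydeseq2 on simulated counts."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = pt.SimConfig(seed=41, nb_params=pt.NBParams(
            genotypes={"wt": 4, "mutant": 4}, n_genes=120, mean=200.0,
            dispersion=0.05,
            lfc={"mutant": np.r_[np.full(20, 1.5), np.zeros(100)]}))
        cm = pt.simulate_count_matrix(cfg)
        res = pt.nb_wald_test(cm, ("mutant", "wt"), dispersion="pooled")
        meta = cm.libraries.rename(columns={"genotype": "condition"})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=cm.counts.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "mutant", "wt"],
                            quiet=True)
            ds.summary()
        ref = ds.results_df.loc[res.index]
        r = np.corrcoef(res["log2FC"], ref["log2FoldChange"])[0, 1]
        assert r > 0.98
        # same gene calls at padj < 0.05 for the strongly changed block
        ours = set(res.index[res["padj"] < 0.05])
        theirs = set(ref.index[ref["padj"] < 0.05])
        jaccard = len(ours & theirs) / max(1, len(ours | theirs))
        assert jaccard > 0.8


class TestBHAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(
            pt.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_and_degenerate_inputs(self):
        assert pt.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        assert np.allclose(pt.bh_adjust(np.ones(5)), 1.0)

    def test_nan_propagates_without_entering_ranking(self):
        p = np.array([0.01, np.nan, 0.02])
        adj = pt.bh_adjust(p)
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], pt.bh_adjust(np.array([0.01, 0.02])))

    def test_monotone_nondecreasing_in_p_rank(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        adj = pt.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFisherEnrichment:
    def test_complete_overlap_hand_value(self):
        universe = set(range(10))
        targets = set(range(5))
        _, p = pt.fisher_enrichment(targets, universe, targets)
        assert p == pytest.approx(1 / 252)

    def test_targets_equal_universe_p_one(self):
        u = set(range(8))
        _, p = pt.fisher_enrichment(set(range(3)), u, u)
        assert p == pytest.approx(1.0)

    def test_super_uniform_under_null(self):
        rng = np.random.default_rng(8)
        universe = set(range(50))
        targets = set(range(10))
        ps = []
        for _ in range(300):
            de = set(rng.choice(50, size=15, replace=False))
            ps.append(pt.fisher_enrichment(de, universe, targets)[1])
        ps = np.array(ps)
        for a in (0.05, 0.1, 0.25):
            assert (ps <= a).mean() <= a + 3 * np.sqrt(a * (1 - a) / 300)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pt.fisher_enrichment(set(), set(), set())


class TestSummaries:
    def test_size_class_profile_hand_fixture(self):
        read_table = pd.DataFrame(
            {"library": ["wt_1"] * 4 + ["wt_2"] * 2,
             "gene_id": ["A", "A", "B", "A", "A", "B"],
             "length": [21, 21, 24, 22, 21, 24]}
        )
        libs = pd.DataFrame({"genotype": ["wt", "wt"]}, index=["wt_1", "wt_2"])
        gene_types = {"A": "miRNA_target", "B": "transposable_element"}
        totals = {"wt_1": 4, "wt_2": 2}
        out = pt.size_class_profile(read_table, libs, gene_types, totals)
        row = out[(out["type"] == "miRNA_target") & (out["length"] == 21)]
        # wt_1: 2/4*1e6 = 5e5 ; wt_2: 1/2*1e6 = 5e5 -> mean 5e5, sem 0
        assert row["mean_rpm"].iloc[0] == pytest.approx(5e5)
        assert row["sem"].iloc[0] == pytest.approx(0.0)

    def test_identical_replicates_sem_zero(self):
        read_table = pd.DataFrame(
            {"library": ["a", "b"], "gene_id": ["A", "A"], "length": [21, 21]}
        )
        libs = pd.DataFrame({"genotype": ["wt", "wt"]}, index=["a", "b"])
        out = pt.size_class_profile(read_table, libs, {"A": "miRNA_target"},
                                    {"a": 1, "b": 1})
        assert (out["sem"] == 0).all()

    def test_zscore_population_sd_convention(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["wt", "m1", "m2"])
        z, flags = pt.target_zscore_matrix(mat)
        assert np.allclose(z.iloc[0], [-1.224744871, 0, 1.224744871])
        assert not flags.iloc[0]

    def test_constant_row_zero_and_flagged(self):
        mat = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                           columns=["a", "b", "c"])
        z, flags = pt.target_zscore_matrix(mat)
        assert (z.iloc[0] == 0).all()
        assert flags.iloc[0] and not flags.iloc[1]

    def test_row_zscores_sum_to_zero(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.random((10, 4)))
        z, _ = pt.target_zscore_matrix(mat)
        assert np.allclose(z.sum(axis=1), 0.0, atol=1e-12)
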