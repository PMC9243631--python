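"""Feature-length, overlap, QC and colocalization statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import tribe_edit as te
from tribe_edit.pileup_io import GeneModel, GenomicInterval


def gene_of_length(gene_id, length, biotype="protein_coding"):
    return GeneModel(
        gene_id, gene_id, biotype, "2L", "+",
        exons=[GenomicInterval("2L", 0, int(length))],
    )


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(first):
        rest = list(pooled)
        for v in first:
            rest.remove(v)
        return sum(1 for a in first for b in rest if a > b) + 0.5 * sum(
            1 for a in first for b in rest if a == b
        )

    observed = u_stat(list(x))
    mean_u = n1 * (len(y)) / 2
    us = [u_stat(list(c)) for c in itertools.combinations(pooled, n1)]
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12)
    return extreme / len(us)


class TestBiotypeBreakdown:
    def test_all_coding(self):
        models = [gene_of_length(f"g{i}", 100) for i in range(3)]
        assert te.biotype_breakdown([g.gene_id for g in models], models) == {"protein_coding": 1.0}

    def test_mixed_fractions(self):
        models = [gene_of_length(f"g{i}", 100) for i in range(99)]
        models.append(gene_of_length("nc1", 100, biotype="ncRNA"))
        out = te.biotype_breakdown([g.gene_id for g in models], models)
        assert out == {"ncRNA": pytest.approx(0.01), "protein_coding": pytest.approx(0.99)}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            te.biotype_breakdown([], [gene_of_length("g1", 100)])

    def test_unknown_gene_excluded_with_warning(self):
        models = [gene_of_length("g1", 100)]
        with pytest.warns(UserWarning, match="missing"):
            out = te.biotype_breakdown(["g1", "mystery"], models)
        assert out == {"protein_coding": 1.0}


class TestLengthComparison:
    def make_models(self, lengths_in, lengths_out):
        models = {}
        set_in, set_out = [], []
        for i, L in enumerate(lengths_in):
            g = gene_of_length(f"in{i}", L)
            models[g.gene_id] = g
            set_in.append(g.gene_id)
        for i, L in enumerate(lengths_out):
            g = gene_of_length(f"out{i}", L)
            models[g.gene_id] = g
            set_out.append(g.gene_id)
        return set_in, set_out, models

    def test_fully_separated_small_sample_exact_p(self):
        set_in, set_out, models = self.make_models([1, 2, 3], [4, 5, 6])
        out = te.length_comparison(set_in, set_out, models)
        assert out["U"] == 0.0
        assert out["p_value"] == pytest.approx(0.1)
        assert out["method"] == "exact"

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5), (6, 4)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        x = rng.permutation(100)[:n1] + 1  # tie-free integers
        y = rng.permutation(100)[50 : 50 + n2] + 101
        y = rng.permutation(np.concatenate([x * 3 + 1, y]))[:n2]  # interleave
        if len(np.unique(np.concatenate([x, y]))) < n1 + n2:
            y = y + np.arange(n2) * 0.01 + 0.001
        set_in, set_out, models = self.make_models(x, y)
        out = te.length_comparison(set_in, set_out, models)
        assert out["p_value"] == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-9)

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(8)
        lengths = rng.integers(500, 5000, size=400)
        set_in, set_out, models = self.make_models(lengths[:200], lengths[200:])
        out = te.length_comparison(set_in, set_out, models)
        assert out["median_ratio"] == pytest.approx(1.0, rel=0.15)
        assert out["p_value"] > 0.05

    def test_recovers_simulated_length_shift(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(np.log(2000), 0.4, size=500)
        longer = rng.lognormal(np.log(2000 * 1.3), 0.4, size=500)
        set_in, set_out, models = self.make_models(longer, base)
        out = te.length_comparison(set_in, set_out, models)
        assert 1.2 <= out["median_ratio"] <= 1.4
        assert out["p_value"] < 0.001

    def test_utr_feature_excludes_noncoding_genes(self):
        coding = GeneModel(
            "c1", "c1", "protein_coding", "2L", "+",
            exons=[GenomicInterval("2L", 0, 100)],
            cds=[GenomicInterval("2L", 20, 80)],
        )
        nc = gene_of_length("nc1", 100, biotype="ncRNA")
        with pytest.raises(ValueError):
            te.length_comparison(["nc1"], ["c1"], {"c1": coding, "nc1": nc}, feature="utr5")


class TestHypergeometricOverlap:
    def test_counted_example_against_enumeration(self):
        universe = [f"u{i}" for i in range(10)]
        a, b = universe[:5], universe[:4]
        k, frac, p = te.hypergeometric_overlap(a, b, universe)
        assert (k, frac) == (4, 0.8)
        assert p == pytest.approx(5 / 210)  # C(5,4)C(5,0)/C(10,4)

    def test_maximum_overlap_is_single_tail_term(self):
        universe = [f"u{i}" for i in range(10)]
        a = universe[:4]
        k, _, p = te.hypergeometric_overlap(a, a, universe)
        assert k == 4
        assert p == pytest.approx(1 / math.comb(10, 4))

    def test_zero_overlap_with_large_expectation_is_uninteresting(self):
        universe = [f"u{i}" for i in range(20)]
        _, _, p = te.hypergeometric_overlap(universe[:10], universe[10:], universe)
        assert p > 0.99

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            te.hypergeometric_overlap(["x"], ["u0"], ["u0", "u1"])


class TestReplicateQc:
    def freq_table(self, matrix, samples):
        rows = []
        for gi, row in enumerate(matrix):
            for s, v in zip(samples, row):
                rows.append((f"g{gi}", s, v))
        return pd.DataFrame(rows, columns=["gene_id", "sample_id", "editing_freq"])

    def test_duplicated_sample_perfectly_correlated(self):
        tab = self.freq_table([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]], ["s1", "s2"])
        out = te.replicate_qc(tab)
        assert out["correlation"].loc["s1", "s2"] == pytest.approx(1.0)
        assert out["distance"].loc["s1", "s2"] == pytest.approx(0.0)

    def test_opposite_patterns_anticorrelated(self):
        tab = self.freq_table([[1.0, -1.0], [-1.0, 1.0], [1.0, -1.0]], ["s1", "s2"])
        assert te.replicate_qc(tab)["correlation"].loc["s1", "s2"] == pytest.approx(-1.0)

    def test_distance_satisfies_triangle_inequality(self):
        rng = np.random.default_rng(4)
        tab = self.freq_table(rng.random((20, 3)), ["s1", "s2", "s3"])
        d = te.replicate_qc(tab)["distance"]
        for a, b, c in itertools.permutations(["s1", "s2", "s3"]):
            assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-12

    def test_replicates_cluster_on_default_simulation(self, default_run):
        freq = te.per_sample_gene_frequencies(default_run.sites)
        out = te.replicate_qc(freq)
        corr = out["correlation"]
        ars = [s for s in corr.columns if s.startswith("arsenite")]
        basal = [s for s in corr.columns if s.startswith("schneiders")]
        within = np.mean([corr.loc[a, b] for a in ars for b in ars if a != b])
        across = np.mean([corr.loc[a, b] for a in ars for b in basal])
        assert within > across


class TestIntronEditing:
    def test_exon_only_editing_leaves_introns_flat(self, default_run):
        out = te.intron_editing_report(default_run.variants)
        assert out["n_intronic_sites"] == 0
        assert not out["ag_dominant"]

    def test_injected_intronic_editing_detected(self):
        cfg = te.SimConfig(
            n_genes=60, positions_per_gene=40, edited_sites_per_gene=3,
            intron_positions_per_gene=40, intron_edited_sites_per_gene=3,
            frac_sg_genes=1.0, intron_depth_factor=1.0, rng_seed=17,
        )
        counts, _, _ = te.simulate_bulk_counts(cfg)
        variants = te.call_variant_positions(counts)
        out = te.intron_editing_report(variants, counts=counts)
        assert out["n_intronic_sites"] > 0
        assert out["ag_dominant"]
        assert out["arsenite_exceeds_basal"]

    def test_no_intron_annotation_is_empty_not_error(self, default_run):
        out = te.intron_editing_report(default_run.variants.iloc[:0])
        assert out["n_intronic_sites"] == 0


class TestSmfishColocalization:
    square = "POLYGON ((0 0, 0.5 0, 0.5 0.5, 0 0.5, 0 0))"

    def spots(self, coords, gene="g1", cell="c1"):
        return pd.DataFrame([(gene, cell, x, y) for x, y in coords], columns=["gene_id", "cell_id", "x", "y"])

    def granules(self, cell="c1", wkt=None):
        return pd.DataFrame([(cell, wkt or self.square)], columns=["cell_id", "granule_wkt"])

    def test_all_inside(self):
        out = te.smfish_colocalization(self.spots([(0.1, 0.1), (0.2, 0.3)]), self.granules())
        assert out["fraction_in_granule"].item() == 1.0

    def test_no_granules_means_zero(self):
        out = te.smfish_colocalization(self.spots([(0.1, 0.1)]), self.granules(cell="other"))
        assert out["fraction_in_granule"].item() == 0.0

    def test_boundary_points_count_inside(self):
        out = te.smfish_colocalization(self.spots([(0.5, 0.25), (0.0, 0.0)]), self.granules())
        assert out["fraction_in_granule"].item() == 1.0

    def test_invariant_under_rigid_translation(self):
        rng = np.random.default_rng(6)
        coords = [(x, y) for x, y in rng.random((50, 2))]
        base = te.smfish_colocalization(self.spots(coords), self.granules())
        shifted = [(x + 10, y - 3) for x, y in coords]
        wkt = "POLYGON ((10 -3, 10.5 -3, 10.5 -2.5, 10 -2.5, 10 -3))"
        moved = te.smfish_colocalization(self.spots(shifted), self.granules(wkt=wkt))
        assert base["fraction_in_granule"].item() == moved["fraction_in_granule"].item()


class TestEditingLocalizationRegression:
    def test_perfect_linear_relation(self):
        fc = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        frac = 0.1 + 0.2 * fc
        out = te.editing_localization_regression(fc, frac)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.2)

    def test_independent_noise_has_no_signal(self):
        rng = np.random.default_rng(2)
        fc = pd.Series(rng.uniform(1, 10, 500))
        frac = pd.Series(rng.uniform(0, 1, 500))
        assert te.editing_localization_regression(fc, frac)["r_squared"] < 0.02

    def test_infinite_fold_changes_excluded_by_default(self):
        fc = pd.Series([1.0, 2.0, np.inf, 4.0], index=list("abcd"))
        frac = pd.Series([0.1, 0.2, 0.9, 0.4], index=list("abcd"))
        out = te.editing_localization_regression(fc, frac)
        assert out["n"] == 3 and out["n_excluded_infinite"] == 1

    def test_winsorize_keeps_group3_genes(self):
        fc = pd.Series([1.0, 2.0, np.inf, 4.0], index=list("abcd"))
        frac = pd.Series([0.1, 0.2, 0.9, 0.4], index=list("abcd"))
        out = te.editing_localization_regression(fc, frac, infinite_policy="winsorize")
        assert out["n"] == 4

    def test_logistic_recruitment_recovered_from_simulation(self, sc_panel):
        spots, granules = te.simulate_smfish(
            sc_panel.truth, n_cells_imaged=10, granule_area_fraction=0.1, rng_seed=5
        )
        coloc = te.smfish_colocalization(spots, granules).set_index("gene_id")
        per_gene = sc_panel.truth.sites.groupby("gene_id")[["rate_schneiders", "rate_arsenite"]].mean()
        fc = per_gene["rate_arsenite"] / per_gene["rate_schneiders"].replace(0.0, np.nan)
        fc = fc.fillna(np.inf)
        out = te.editing_localization_regression(fc, coloc["fraction_in_granule"], log_fold=True)
        assert out["r_squared"] > 0.5
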