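"""Feature/CGI/state annotation, enrichment, metagene, overlaps."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oxbspipe as ox
from oxbspipe.context import (
    annotate_positions,
    enrichment_vs_background,
    gene_body_summary,
    metagene_profile,
    overlap_hypergeometric,
)
from oxbspipe.datamodel import ValidationError

from oracles import fisher_two_sided, hypergeom_upper_tail, overlap_permutation_p


def _probes(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions},
                        index=[f"cg{i:05d}" for i in range(len(positions))])


class TestAnnotatePositions:
    def test_feature_precedence_and_windows(self, tiny_annotation):
        # geneA: + strand, TSS 10_000, exons [10k,12k) [15k,17k) [19k,20k)
        probes = _probes([
            9_500,    # 500 bp upstream of TSS -> promoter
            10_300,   # inside first exon but also inside +500 promoter window -> promoter
            11_000,   # exon
            13_000,   # intron
            30_000,   # intergenic
            58_500,   # geneB (- strand) exon
            60_300,   # 300 bp upstream of geneB TSS (- strand) -> promoter
        ])
        ann = annotate_positions(probes, tiny_annotation)
        assert ann["feature"].tolist() == [
            "promoter", "promoter", "exon", "intron", "intergenic", "exon", "promoter"]

    def test_cgi_context_distance_cutoffs(self, tiny_annotation):
        # CGI spans [9500, 10500)
        probes = _probes([10_000, 12_000, 13_500, 15_500])
        ann = annotate_positions(probes, tiny_annotation)
        assert ann["cgi_context"].tolist() == ["island", "shore", "shelf", "open_sea"]

    def test_nearest_gene_signed_distance(self, tiny_annotation):
        probes = _probes([9_000, 10_500, 61_000])
        ann = annotate_positions(probes, tiny_annotation)
        assert ann["nearest_gene"].tolist() == ["geneA", "geneA", "geneB"]
        # upstream of TSS is negative in gene orientation, on both strands
        assert ann["tss_distance"].tolist() == [-1000, 500, -1000]

    def test_chrom_state_lookup(self, tiny_annotation):
        ann = annotate_positions(_probes([5_000, 12_000, 50_000]), tiny_annotation)
        assert ann["chrom_state"].tolist() == ["Promoter", "Txn Elongation", "Heterochromatin"]

    def test_unknown_chromosome_rejected(self, tiny_annotation):
        with pytest.raises(ValidationError, match="chrM"):
            annotate_positions(_probes([100], chrom="chrM"), tiny_annotation)

    def test_features_partition_default_probes(self, default_bundle):
        ctx = default_bundle["probe_context"]
        counts = ctx["feature"].value_counts()
        assert counts.sum() == len(ctx)
        assert set(counts.index) <= {"promoter", "exon", "intron", "intergenic"}


class TestEnrichment:
    def test_odds_ratio_arithmetic(self):
        fg = [f"f{i}" for i in range(100)]
        rest = [f"r{i}" for i in range(100)]
        cats = pd.Series({p: ("intron" if i < 30 else "other") for i, p in enumerate(fg)} |
                         {p: ("intron" if i < 10 else "other") for i, p in enumerate(rest)})
        result = enrichment_vs_background(fg, fg + rest, cats)
        assert result.loc["intron", "odds_ratio"] == pytest.approx((30 * 90) / (70 * 10))

    def test_background_vs_itself_neutral(self):
        ids = [f"p{i}" for i in range(60)]
        cats = pd.Series(np.where(np.arange(60) % 3 == 0, "a", "b"), index=ids)
        result = enrichment_vs_background(ids, ids, cats)
        # foreground == background: neutral by definition
        assert np.allclose(result["odds_ratio"], 1.0)
        assert np.allclose(result["p"], 1.0)

    def test_fisher_p_matches_enumeration(self):
        fg = [f"f{i}" for i in range(5)]
        rest = [f"r{i}" for i in range(5)]
        cats = pd.Series({p: ("x" if i < 3 else "y") for i, p in enumerate(fg)} |
                         {p: ("x" if i < 1 else "y") for i, p in enumerate(rest)})
        result = enrichment_vs_background(fg, fg + rest, cats)
        assert result.loc["x", "p"] == pytest.approx(fisher_two_sided(3, 2, 1, 4), abs=1e-12)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_vs_background([], ["a"], pd.Series({"a": "x"}))


class TestMetagene:
    def test_constant_signal_flat_profile(self, tiny_annotation):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(8_000, 22_000), size=60, replace=False))
        probes = _probes(pos)
        signal = pd.Series(0.5, index=probes.index)
        profiles = metagene_profile(signal, probes, tiny_annotation)
        prof = profiles["up"]
        filled = prof[prof["count"] > 0]
        assert len(filled) > 10
        assert np.allclose(filled["mean"], 0.5)

    def test_strand_mirror_genes_reverse_profiles(self):
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [10_000, 40_000], "end": [20_000, 50_000],
            "strand": ["+", "-"], "tss": [10_000, 50_000],
        }, index=pd.Index(["plus", "minus"], name="gene_id"))
        ann = ox.GenomeAnnotation(
            chrom_sizes={"chr1": 100_000}, genes=genes,
            exons={"plus": [(10_000, 20_000)], "minus": [(40_000, 50_000)]},
            cgis=pd.DataFrame(columns=["chrom", "start", "end"]),
            chrom_states=pd.DataFrame(columns=["chrom", "start", "end", "state"]),
            gene_sets=pd.Series({"plus": "up", "minus": "down"}))
        offsets = np.arange(250, 10_000, 500)
        probes = _probes(np.concatenate([10_000 + offsets, 40_000 + offsets]))
        # signal linear in the chromosome coordinate within each gene span
        values = np.concatenate([offsets / 10_000, offsets / 10_000])
        signal = pd.Series(values, index=probes.index)
        profiles = metagene_profile(signal, probes, ann, flank=0, flank_bins=1, body_bins=20)
        plus_body = profiles["up"]["mean"].to_numpy()[1:-1]
        minus_body = profiles["down"]["mean"].to_numpy()[1:-1]
        assert np.allclose(plus_body, minus_body[::-1], atol=1e-12, equal_nan=True)

    def test_binning_conserves_probe_mass(self, tiny_annotation):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(7_000, 63_000), size=120, replace=False))
        probes = _probes(pos)
        signal = pd.Series(rng.uniform(size=len(probes)), index=probes.index)
        profiles = metagene_profile(signal, probes, tiny_annotation, flank=2000)
        for gs, gene in (("up", "geneA"), ("down", "geneB")):
            row = tiny_annotation.genes.loc[gene]
            lo, hi = row["start"] - 2000, row["end"] + 2000
            expected = int(((pos >= lo) & (pos < hi)).sum())
            assert profiles[gs]["n_assigned"].sum() == expected


class TestGeneBodySummary:
    def test_flat_truth_reports_exact_percent(self, tiny_annotation):
        probes = _probes([11_000, 13_000, 16_000, 53_000, 55_000])
        pairs = pd.DataFrame({"condition": ["differentiating"] * 2, "culture": ["c1", "c2"]},
                             index=pd.Index(["differentiating:c1", "differentiating:c2"], name="pair_id"))
        h = pd.DataFrame(0.04, index=probes.index, columns=pairs.index)
        m = pd.DataFrame(0.50, index=probes.index, columns=pairs.index)
        est = ox.MethylomeEstimate(m_hat=m, h_hat=h, na_mask=h.isna(), probes=probes, pairs=pairs)
        summary, _ = gene_body_summary(est, tiny_annotation)
        assert summary.loc["differentiating", "mean_h_pct"] == pytest.approx(4.0)

    def test_default_simulation_direction_and_significance(self, default_bundle):
        summary = default_bundle["gene_body_summary"]
        tests = default_bundle["gene_body_tests"]
        assert summary.loc["proliferative", "mean_h_pct"] < summary.loc["differentiating", "mean_h_pct"]
        row = tests[(tests["contrast"].str.contains("proliferative"))
                    & (tests["contrast"].str.contains("differentiating"))
                    & (tests["signal"] == "h")]
        assert row["p"].iloc[0] < 0.01

    def test_up_gene_bodies_exceed_down_in_metagene(self, default_bundle):
        for seed_bundle in [default_bundle]:
            prof = seed_bundle["metagene"]["differentiating"]
            body = slice(5, 25)
            up = np.nanmean(prof["up"]["mean"].to_numpy()[body])
            down = np.nanmean(prof["down"]["mean"].to_numpy()[body])
            assert up > down


class TestOverlapHypergeometric:
    def test_exact_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        a, b = universe[:10], universe[5:15]
        result = overlap_hypergeometric(a, b, universe)
        assert result["overlap"] == 5
        assert result["expected"] == pytest.approx(1.0)
        assert result["fold"] == pytest.approx(5.0)
        assert result["p"] == pytest.approx(hypergeom_upper_tail(5, 100, 10, 10), rel=1e-12)

    def test_full_overlap_neutral(self):
        u = [f"g{i}" for i in range(20)]
        result = overlap_hypergeometric(u, u, u)
        assert result["overlap"] == 20
        assert result["fold"] == pytest.approx(1.0)
        assert result["p"] == pytest.approx(1.0)

    def test_disjoint_small_sets_p_near_one(self):
        u = [f"g{i}" for i in range(1000)]
        result = overlap_hypergeometric(u[:5], u[5:10], u)
        assert result["p"] > 0.97

    def test_agrees_with_permutation_on_small_universe(self):
        result = overlap_hypergeometric([f"g{i}" for i in range(12)],
                                        [f"g{i}" for i in range(8, 20)],
                                        [f"g{i}" for i in range(40)])
        mc = overlap_permutation_p(result["overlap"], 40, 12, 12, n_draws=20_000, seed=1)
        assert result["p"] == pytest.approx(mc, abs=0.02)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_hypergeometric([], [], [])
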