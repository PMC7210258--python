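"""Moderated testing, BH, region clustering, rank-sum comparisons."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oxbspipe.datamodel import ValidationError
from oxbspipe.differential import (
    adjust_bh,
    call_positions,
    call_regions,
    compare_groups_wilcoxon,
    differential_positions,
    fit_group_model,
    moderate_ebayes,
    stouffer_combine,
    trigamma_inverse,
)

from oracles import bh_stepup, mannwhitney_exact


def _two_group(n_probes, n1=3, n2=3, seed=0, shift=None):
    rng = np.random.default_rng(seed)
    data = rng.normal(0.5, 0.1, size=(n_probes, n1 + n2))
    if shift is not None:
        data[:, :n1] += shift
    cols = [f"t{i}" for i in range(n1)] + [f"r{i}" for i in range(n2)]
    values = pd.DataFrame(data, columns=cols,
                          index=[f"cg{i:05d}" for i in range(n_probes)])
    design = pd.Series(["target"] * n1 + ["reference"] * n2, index=cols)
    return values, design


class TestFitGroupModel:
    def test_exact_small_case(self):
        values = pd.DataFrame({"t1": [0.6], "t2": [0.6], "r1": [0.4], "r2": [0.4]})
        design = pd.Series({"t1": "a", "t2": "a", "r1": "b", "r2": "b"})
        fit = fit_group_model(values, design, ("a", "b"))
        assert fit["estimate"].iloc[0] == pytest.approx(0.2)
        assert fit["s2"].iloc[0] == pytest.approx(0.0)
        assert fit["df"].iloc[0] == 2

    def test_matches_hand_rolled_two_sample_formula(self):
        values, design = _two_group(50, seed=3)
        fit = fit_group_model(values, design, ("target", "reference"))
        for pid in values.index[:10]:
            a = values.loc[pid, design == "target"].to_numpy()
            b = values.loc[pid, design == "reference"].to_numpy()
            delta = a.mean() - b.mean()
            s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
            assert fit.loc[pid, "estimate"] == pytest.approx(delta, abs=1e-12)
            assert fit.loc[pid, "s2"] == pytest.approx(s2, abs=1e-12)

    def test_na_handling_flags_untestable(self):
        values, design = _two_group(3)
        values.iloc[0, [0, 1]] = np.nan  # one target replicate left
        fit = fit_group_model(values, design, ("target", "reference"))
        assert not fit["testable"].iloc[0]
        assert fit["testable"].iloc[1:].all()

    def test_unknown_contrast_condition_rejected(self):
        values, design = _two_group(3)
        with pytest.raises(ValidationError, match="ghost"):
            fit_group_model(values, design, ("ghost", "reference"))


class TestModerateEbayes:
    def test_prior_df_zero_recovers_classical_t(self):
        values, design = _two_group(200, seed=1)
        fit = fit_group_model(values, design, ("target", "reference"))
        mod = moderate_ebayes(fit, prior_df=0)
        for pid in values.index[:20]:
            a = values.loc[pid, design == "target"]
            b = values.loc[pid, design == "reference"]
            t_classic = stats.ttest_ind(a, b).statistic
            assert mod.loc[pid, "t_mod"] == pytest.approx(t_classic, abs=1e-10)

    def test_constant_variance_ensemble_shrinks_completely(self):
        values, design = _two_group(100, seed=2)
        fit = fit_group_model(values, design, ("target", "reference"))
        fit["s2"] = 0.01  # artificially identical residual variances
        mod = moderate_ebayes(fit)
        assert np.isinf(mod.attrs["d0"])
        assert np.allclose(mod["s2_post"], mod["s2_post"].iloc[0])

    def test_infinite_prior_gives_common_variance_z_statistic(self):
        values, design = _two_group(300, seed=4)
        fit = fit_group_model(values, design, ("target", "reference"))
        mod = moderate_ebayes(fit, prior_df=np.inf)
        expected = fit["estimate"] / (np.sqrt(mod.attrs["s0_2"]) * fit["stdev_unscaled"])
        assert np.allclose(mod["t_mod"], expected)
        assert np.isinf(mod["df_total"]).all()

    def test_all_zero_variance_rejected(self):
        values, design = _two_group(20)
        fit = fit_group_model(values, design, ("target", "reference"))
        fit["s2"] = 0.0
        with pytest.raises(ValidationError, match="replicates|jitter"):
            moderate_ebayes(fit)

    def test_null_type_i_error_calibrated(self):
        """Empirical size of the moderated test at nominal 0.05, df = 4."""
        rejections, total = 0, 0
        for seed in range(5):
            values, design = _two_group(5000, seed=seed + 10)
            fit = fit_group_model(values, design, ("target", "reference"))
            mod = moderate_ebayes(fit)
            rejections += int((mod["p"] < 0.05).sum())
            total += len(mod)
        assert 0.035 <= rejections / total <= 0.065

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (1e-5, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_agrees_with_limma_reference(self, tmp_path):
        """Independent cross-check against the Bioconductor reference
        implementation of the moderated t (limma), via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        values, design = _two_group(40, seed=6)
        fit = fit_group_model(values, design, ("target", "reference"))
        mod = moderate_ebayes(fit)
        values.to_csv(tmp_path / "values.csv")
        script = tmp_path / "limma_check.R"
        script.write_text("""
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
x <- as.matrix(read.csv(args[1], row.names=1))
design <- cbind(Intercept=1, target=c(rep(1,3), rep(0,3)))
fit <- eBayes(lmFit(x, design))
out <- data.frame(t=fit$t[,"target"], p=fit$p.value[,"target"],
                  d0=fit$df.prior, s02=fit$s2.prior)
write.csv(out, args[2])
""")
        subprocess.run(["Rscript", str(script), str(tmp_path / "values.csv"),
                        str(tmp_path / "out.csv")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert mod.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert mod.attrs["s0_2"] == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        assert np.allclose(mod["t_mod"], ref["t"], atol=1e-6)
        assert np.allclose(mod["p"], ref["p"], atol=1e-8)


class TestAdjustBh:
    def test_hand_worked_example(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p,expected", [([0.5], [0.5]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])])
    def test_degenerate_inputs(self, p, expected):
        assert adjust_bh(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_permutation_invariant(self, p):
        result = adjust_bh(p)
        assert result == pytest.approx(bh_stepup(p), abs=1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        permuted = adjust_bh(np.asarray(p)[perm])
        assert permuted == pytest.approx(np.asarray(result)[perm], abs=1e-12)


class TestCallPositions:
    @pytest.mark.parametrize("delta,fdr,expected", [
        (0.25, 0.01, True),
        (0.15, 0.001, False),   # below delta threshold despite tiny FDR
        (0.25, 0.05, False),    # FDR boundary is strict
        (-0.25, 0.01, True),    # magnitude, not sign
    ])
    def test_threshold_logic(self, delta, fdr, expected):
        diff = pd.DataFrame({"delta_beta": [delta], "fdr": [fdr]})
        got = call_positions(diff, delta_min=0.20, alpha=0.05)
        assert (len(got) == 1) is expected


class TestCallRegions:
    def _positions(self, pos, significant, p=None, delta=None):
        n = len(pos)
        return pd.DataFrame({
            "chrom": "chr1", "pos": pos,
            "p": p if p is not None else [1e-4] * n,
            "delta_beta": delta if delta is not None else [0.3] * n,
            "significant": significant,
        }, index=[f"cg{i:05d}" for i in range(n)])

    def test_cluster_span_and_membership(self):
        pos = self._positions([100, 500, 900, 5000], [True] * 4)
        regions = call_regions(pos, maxgap=1000, min_cpgs=3)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start"], r["end"], r["n_cpgs"]) == (100, 901, 3)
        assert "cg00003" not in r["probe_ids"]

    def test_too_few_cpgs_no_region(self):
        pos = self._positions([100, 500], [True, True])
        assert len(call_regions(pos)) == 0

    def test_stouffer_value(self):
        z = stouffer_combine([2.0, 2.0, 2.0])
        assert z == pytest.approx(6 / np.sqrt(3), abs=1e-12)
        p_each = 2 * stats.norm.sf(2.0)
        pos = self._positions([100, 200, 300], [True] * 3, p=[p_each] * 3)
        regions = call_regions(pos)
        assert regions["stouffer_z"].iloc[0] == pytest.approx(3.4641016, abs=1e-6)

    def test_unsorted_input_rejected(self):
        pos = self._positions([500, 100, 900], [True] * 3)
        with pytest.raises(ValidationError, match="sorted"):
            call_regions(pos)

    def test_regions_disjoint_and_cover_qualifying_cpgs(self):
        rng = np.random.default_rng(5)
        pos_values = np.sort(rng.choice(200_000, size=300, replace=False))
        sig = rng.uniform(size=300) < 0.4
        pos = self._positions(pos_values, sig)
        regions = call_regions(pos, maxgap=1000, min_cpgs=3)
        covered = [pid for ids in regions["probe_ids"] for pid in ids]
        assert len(covered) == len(set(covered))
        spans = regions.sort_values("start")
        assert (spans["start"].to_numpy()[1:] >= spans["end"].to_numpy()[:-1]).all()
        # every significant CpG in a qualifying cluster is covered
        sig_pos = pos_values[sig]
        gaps = np.diff(sig_pos) > 1000
        clusters = np.split(sig_pos, np.where(gaps)[0] + 1)
        expected = sum(len(c) for c in clusters if len(c) >= 3)
        assert len(covered) == expected


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        _, p = compare_groups_wilcoxon([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact(self):
        u, p = compare_groups_wilcoxon([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=5), rng.normal(size=4)
        _, p1 = compare_groups_wilcoxon(a, b)
        _, p2 = compare_groups_wilcoxon(b, a)
        assert p1 == pytest.approx(p2)

    def test_degenerate_constant_input_warns(self):
        with pytest.warns(UserWarning):
            _, p = compare_groups_wilcoxon([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.uniform(size=rng.integers(3, 6))
            b = rng.uniform(size=rng.integers(3, 6))
            u, p = compare_groups_wilcoxon(a, b)
            u_ref, p_ref = mannwhitney_exact(a, b)
            # scipy's U counts wins of the first sample, as does the oracle
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestEndToEndDifferential:
    def test_planted_blocks_detected(self):
        from oxbspipe.synthetic import simulate_differential_blocks
        from oxbspipe.hmc import estimate_methylome

        bs, oxbs, sheet, blocks = simulate_differential_blocks(seed=0)
        est = estimate_methylome(bs, oxbs, sheet)
        design = est.pairs["condition"]
        diff = differential_positions(est.h_hat, design, ("target", "reference"),
                                      delta_min=0.10)
        diff.insert(0, "chrom", est.probes["chrom"])
        diff.insert(1, "pos", est.probes["pos"])
        regions = call_regions(diff, maxgap=1000, min_cpgs=3)
        for _, block in blocks.iterrows():
            overlap = regions[(regions["start"] < block["end"]) & (regions["end"] > block["start"])]
            assert len(overlap) == 1, f"planted block {block['block']} not recovered"
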