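"""Differential analysis: filtering, TMM, tests, FDR, imputation, glog."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pandas.testing import assert_frame_equal
from scipy import stats

import driftomics as d
from driftomics.differential import (
    bh_fdr,
    compare_signatures,
    de_genes,
    de_metabolites,
    filter_expressed,
    glog_transform,
    impute_min,
    tmm_factors,
)


def _meta(groups):
    return pd.DataFrame({"sample": [f"s{i}" for i in range(len(groups))],
                         "group": groups})


class TestFilterExpressed:
    def test_cpm_above_one_in_half_samples_kept(self):
        # filler makes each library ~1e6, so counts read as CPM:
        # the borderline gene clears CPM>1 in exactly 3 of 6 samples
        counts = pd.DataFrame(
            [[2, 2, 2, 0, 0, 0], [1_000_000 - 2] * 6],
            index=["g_borderline", "g_filler"],
            columns=[f"s{j}" for j in range(6)],
        )
        assert "g_borderline" in filter_expressed(counts).index

    def test_all_zero_gene_dropped(self):
        counts = pd.DataFrame(
            {"s0": [0, 10], "s1": [0, 12]}, index=["dead", "alive"]
        )
        assert "dead" not in filter_expressed(counts).index

    def test_cpm_exactly_one_everywhere_dropped(self):
        # one gene at exactly CPM 1 (strictly-greater rule)
        counts = pd.DataFrame(
            {"s0": [1, 999_999], "s1": [1, 999_999]}, index=["unit", "big"]
        )
        assert "unit" not in filter_expressed(counts).index
        assert "big" in filter_expressed(counts).index

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [5, 5], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            filter_expressed(counts)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [200], [3000]], (1, 4)),
                              columns=list("abcd"))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (200, 6)))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_brute_force(self, rng):
        """Reference TMM recomputed from the definition with plain loops."""
        counts = pd.DataFrame(rng.poisson(rng.uniform(5, 500, 80)[:, None]
                                          * rng.uniform(0.5, 2, 6)[None, :]))
        mine = tmm_factors(counts).to_numpy()

        x = counts.to_numpy(float)
        lib = x.sum(axis=0)
        f75 = np.array([np.quantile(x[:, k] / lib[k], 0.75) for k in range(6)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        raw = []
        for k in range(x.shape[1]):
            pairs = [(o, r) for o, r in zip(x[:, k], x[:, ref]) if o > 0 and r > 0]
            m = [math.log2((o / lib[k]) / (r / lib[ref])) for o, r in pairs]
            a = [0.5 * math.log2((o / lib[k]) * (r / lib[ref])) for o, r in pairs]
            w = [1.0 / ((lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r))
                 for o, r in pairs]
            n = len(m)
            lo_l, hi_l = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
            lo_s, hi_s = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
            rm, ra = stats.rankdata(m), stats.rankdata(a)
            keep = [(lo_l <= rm[i] <= hi_l) and (lo_s <= ra[i] <= hi_s)
                    for i in range(n)]
            num = sum(w[i] * m[i] for i in range(n) if keep[i])
            den = sum(w[i] for i in range(n) if keep[i])
            raw.append(2.0 ** (num / den))
        raw = np.array(raw)
        raw /= np.exp(np.mean(np.log(raw)))
        assert np.allclose(mine, raw, atol=1e-8)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_edger_reference(self, tmp_path, rng):
        counts = pd.DataFrame(
            rng.poisson(np.exp(rng.normal(4, 1, 60))[:, None]
                        * rng.uniform(0.5, 2, 4)[None, :]),
            index=[f"g{i}" for i in range(60)], columns=list("wxyz"),
        )
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR)); '
            f'x <- as.matrix(read.delim("{path}", row.names=1)); '
            'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, timeout=120)
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
        theirs = np.array([float(v) for v in proc.stdout.split()])
        assert np.allclose(tmm_factors(counts).to_numpy(), theirs, atol=1e-8)

    def test_spiked_two_sample_ratio(self):
        """One library doubled except for 5 spike genes: the trimmed mean
        must recover the doubling, not the spikes."""
        base = np.arange(10, 130, 4, dtype=float)  # 30 genes
        col_a = base.copy()
        col_b = base * 2
        col_b[:5] = base[:5]  # spikes unchanged in absolute counts
        counts = pd.DataFrame({"a": col_a, "b": col_b}).astype(int)
        f = tmm_factors(counts)
        # doubled counts but also doubled library: M-values ~0 for the
        # bulk, so factors stay near 1 while the spikes are trimmed away
        assert f["b"] / f["a"] == pytest.approx(1.0, abs=0.05)


class TestBhFdr:
    def test_step_up_oracle(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_empty_vector(self):
        assert bh_fdr([]).size == 0

    def test_matches_brute_force_step_up(self, rng):
        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            mine = bh_fdr(p)
            assert np.allclose(mine, brute(p), atol=1e-12)
            assert (mine <= 1).all() and (mine >= p - 1e-12).all()

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_in_p_rank(self, pvals):
        adj = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDeGenes:
    def test_significance_rule_is_strict(self, small_dataset):
        counts = filter_expressed(small_dataset.counts)
        res = de_genes(counts, tmm_factors(counts), small_dataset.metadata,
                       ("old", "young"))
        recomputed = (res["fdr"] < 0.05) & (res["log2fc"].abs() > 0.3)
        assert (res["significant"] == recomputed).all()

    def test_planted_strong_gene_detected_with_sign(self):
        cfg = d.SynthConfig(n_genes=500, frac_aging_genes=0.2, seed=11)
        counts, _, truth = d.generate_transcriptome(cfg)
        meta = d.generate_metadata(cfg)
        filtered = filter_expressed(counts)
        res = de_genes(filtered, tmm_factors(filtered), meta, ("old", "young"))
        strong = truth.gene_log2fc[truth.gene_log2fc.abs() > 1.5]
        # restrict to decently expressed genes, where the log2(CPM+1)
        # fold estimate is not attenuated by the +1 offset
        expressed = counts.mean(axis=1) >= 20
        strong = strong[strong.index.isin(res.index[expressed.reindex(res.index)])]
        assert len(strong) > 0
        hits = res.loc[strong.index]
        assert (hits["p"] < 0.01).all()
        assert hits["significant"].mean() >= 0.8
        assert (np.sign(hits["log2fc"]) == np.sign(strong)).all()

    def test_null_yields_few_calls(self):
        sig_counts = []
        for seed in range(5):
            cfg = d.SynthConfig(n_genes=2000, frac_aging_genes=0.0, seed=seed)
            counts, _, _ = d.generate_transcriptome(cfg)
            meta = d.generate_metadata(cfg)
            filtered = filter_expressed(counts)
            res = de_genes(filtered, tmm_factors(filtered), meta, ("old", "young"))
            sig_counts.append(res["significant"].sum())
        assert np.mean(sig_counts) < 10

    def test_sample_order_invariance(self, small_dataset, rng):
        counts = filter_expressed(small_dataset.counts)
        meta = small_dataset.metadata
        res1 = de_genes(counts, tmm_factors(counts), meta, ("old", "young"))
        perm = rng.permutation(counts.columns)
        counts2 = counts[perm]
        meta2 = meta.set_index("sample").loc[perm].reset_index()
        res2 = de_genes(counts2, tmm_factors(counts2), meta2, ("old", "young"))
        assert_frame_equal(res1, res2)

    def test_power_monotone_in_effect_size(self):
        powers = []
        for lfc in (0.3, 0.6, 1.2):
            hits = []
            for seed in range(8):
                rng = np.random.default_rng([seed, 99])
                n_genes, n_aff = 1000, 100
                base = np.exp(rng.normal(4.5, 1, n_genes))
                mult = np.ones((n_genes, 12))
                mult[:n_aff, 6:] = 2.0 ** lfc
                counts = pd.DataFrame(
                    rng.poisson(base[:, None] * mult),
                    index=[f"g{i}" for i in range(n_genes)],
                    columns=[f"s{i}" for i in range(12)],
                )
                meta = _meta(["young"] * 6 + ["old"] * 6)
                filt = filter_expressed(counts)
                res = de_genes(filt, tmm_factors(filt), meta, ("old", "young"))
                planted = [g for g in counts.index[:n_aff] if g in res.index]
                hits.append(res.loc[planted, "significant"].mean())
            powers.append(np.mean(hits))
        assert powers[0] < powers[1] < powers[2]


class TestImputeGlog:
    def test_min_imputation_rule(self):
        m = pd.DataFrame([[2.0, np.nan, 4.0]], index=["x"], columns=list("abc"))
        out = impute_min(m)
        assert out.loc["x"].tolist() == [2.0, 2.0, 4.0]

    def test_identity_without_missing(self, rng):
        m = pd.DataFrame(rng.lognormal(3, 1, (5, 4)))
        assert_frame_equal(impute_min(m), m)

    def test_idempotent_and_min_preserving(self, rng):
        m = pd.DataFrame(rng.lognormal(3, 1, (8, 6)))
        m[m < m.quantile(0.2, axis=1).to_numpy()[:, None]] = np.nan
        once = impute_min(m)
        assert not once.isna().any().any()
        assert_frame_equal(impute_min(once), once)
        assert np.allclose(once.min(axis=1), m.min(axis=1))

    def test_all_missing_metabolite_errors(self):
        m = pd.DataFrame([[np.nan, np.nan]], index=["ghost"])
        with pytest.raises(ValueError, match="ghost"):
            impute_min(m)

    def test_glog_limits_and_values(self):
        m = pd.DataFrame([[10.0]])
        assert glog_transform(m, lam=1e-12).iloc[0, 0] == pytest.approx(
            math.log(10.0), abs=1e-6
        )
        z = pd.DataFrame([[0.0]])
        assert glog_transform(z, lam=2.0).iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_glog_monotone(self):
        grid = pd.DataFrame([np.linspace(0, 50, 200)])
        out = glog_transform(grid, lam=3.0).to_numpy().ravel()
        assert (np.diff(out) > 0).all()

    def test_glog_rejects_bad_lambda(self, rng):
        m = pd.DataFrame(rng.lognormal(0, 1, (3, 3)))
        with pytest.raises(ValueError, match="lambda"):
            glog_transform(m, lam=-1.0)


class TestDeMetabolites:
    def test_null_raw_p_near_uniform(self):
        fracs = []
        for seed in range(20):
            cfg = d.SynthConfig(n_metabolites=40, metabolite_fold_table={},
                                hub_metabolite="none", seed=seed)
            table, _ = d.generate_metabolome(cfg)
            meta = d.generate_metadata(cfg)
            res = de_metabolites(impute_min(table), meta, ("old", "young"))
            fracs.append((res["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.03

    def test_zero_effect_metabolite_unbiased(self):
        lfcs = []
        for seed in range(20):
            cfg = d.SynthConfig(seed=seed)
            table, _ = d.generate_metabolome(cfg)
            meta = d.generate_metadata(cfg)
            res = de_metabolites(impute_min(table), meta, ("old", "young"))
            lfcs.append(res.loc["met_0000", "log2fc"])
        assert abs(np.median(lfcs)) < 0.1

    def test_unimputed_input_rejected(self, toy_metadata):
        m = pd.DataFrame([[1.0, np.nan, 2, 3, 4, 5]],
                         columns=toy_metadata["sample"])
        with pytest.raises(ValueError, match="impute"):
            de_metabolites(m, toy_metadata, ("old", "young"))


class TestCompareSignatures:
    def _result(self, lfc, sig):
        idx = [f"f{i}" for i in range(len(lfc))]
        return pd.DataFrame({"log2fc": lfc, "p": 0.01, "fdr": 0.01,
                             "significant": sig, "contrast": "a vs b"}, index=idx)

    def test_self_comparison_is_identity(self, rng):
        lfc = rng.normal(0, 1, 10)
        res = self._result(lfc, [True] * 10)
        comp = compare_signatures(res, res)
        assert comp.shared == frozenset(res.index)
        assert comp.unique_to_a == frozenset()
        assert comp.r_shared == pytest.approx(1.0)

    def test_negated_folds_give_minus_one(self, rng):
        lfc = rng.normal(0, 1, 10)
        comp = compare_signatures(self._result(lfc, [True] * 10),
                                  self._result(-lfc, [True] * 10))
        assert comp.r_shared == pytest.approx(-1.0)

    def test_small_partition_correlation_undefined(self, rng):
        lfc = rng.normal(0, 1, 5)
        comp = compare_signatures(self._result(lfc, [True, True, False, False, False]),
                                  self._result(lfc, [True, True, False, False, False]))
        assert comp.r_shared is None  # only 2 shared features

    def test_venn_counts_match_set_algebra(self, rng):
        for _ in range(50):
            n = 30
            sig_a = rng.random(n) < 0.4
            sig_b = rng.random(n) < 0.4
            res_a = self._result(rng.normal(0, 1, n), sig_a)
            res_b = self._result(rng.normal(0, 1, n), sig_b)
            comp = compare_signatures(res_a, res_b)
            a = {f"f{i}" for i in range(n) if sig_a[i]}
            b = {f"f{i}" for i in range(n) if sig_b[i]}
            assert comp.shared == a & b
            assert comp.unique_to_a == a - b
            assert comp.unique_to_b == b - a
            assert comp.shared | comp.unique_to_a == a
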