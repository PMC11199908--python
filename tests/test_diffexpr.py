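"""Size factors, BH adjustment, and the moderated NB contrast test."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import toxconcord as tc
from toxconcord.containers import CountMatrix

from conftest import contrast_arms, two_group_design


def _cm(arr, sample_ids=None):
    arr = np.asarray(arr)
    ids = sample_ids or [f"s{i}" for i in range(arr.shape[1])]
    probes = pd.Index([f"p{i}" for i in range(arr.shape[0])],
                      name="probe_id")
    return CountMatrix(
        pd.DataFrame(arr, index=probes, columns=ids),
        pd.DataFrame({"gene_symbol": [f"g{i}" for i in range(arr.shape[0])]},
                     index=probes))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        sf = tc.estimate_size_factors(pd.DataFrame({"a": [5, 10, 20],
                                                    "b": [5, 10, 20]}))
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_pair(self):
        counts = pd.DataFrame({"a": [10, 100, 50], "b": [20, 200, 100]})
        sf = tc.estimate_size_factors(counts)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_all_zero_probe_rows_ignored(self):
        base = pd.DataFrame({"a": [10, 100, 50], "b": [20, 200, 100]})
        withzero = pd.concat(
            [base, pd.DataFrame({"a": [0], "b": [0]})], ignore_index=True)
        assert np.allclose(tc.estimate_size_factors(base).to_numpy(),
                           tc.estimate_size_factors(withzero).to_numpy())

    def test_no_common_probe_raises(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            tc.estimate_size_factors(counts)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (200, 4)),
                              columns=list("abcd"))
        sf0 = tc.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        sf1 = tc.estimate_size_factors(scaled)
        # ratio of c's factor to the others rises threefold
        assert (sf1["c"] / sf1["a"]) == pytest.approx(
            3 * sf0["c"] / sf0["a"], rel=1e-6)


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
        ([0.5], [0.5]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ([0.04, 0.01, 0.02], [0.04, 0.03, 0.03]),
    ])
    def test_hand_computed_step_up(self, p, expected):
        assert np.allclose(tc.bh_adjust(p), expected)

    def test_nan_passthrough_not_counted(self):
        out = tc.bh_adjust([0.01, np.nan, 0.02, 0.04, np.nan])
        assert np.isnan(out[1]) and np.isnan(out[4])
        assert np.allclose(out[[0, 2, 3]], [0.03, 0.03, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tc.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        adj = tc.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestContrast:
    def _null_study(self, seed, n_genes=250, reps=4):
        spec = two_group_design(n_genes, reps, seed=seed,
                                probes_per_gene=(2, 2))
        sheet = tc.generate_design(spec)
        truth = tc.generate_truth(spec, sheet, null_only=True)
        counts = tc.simulate_counts(sheet, truth)
        sf = tc.estimate_size_factors(counts.counts)
        return counts, sheet, sf

    def test_identical_data_permuted_labels_has_no_deps(self):
        """Group columns are exact copies of the control columns: every
        log2FC is 0 and nothing can be a DEP."""
        counts, sheet, sf = self._null_study(0)
        grp, ctl = contrast_arms(sheet, 500.0)
        dup = counts.counts[ctl].copy()
        dup.columns = [f"dup{i}" for i in range(len(ctl))]
        both = CountMatrix(pd.concat([counts.counts[ctl], dup], axis=1),
                           counts.probes)
        sf2 = pd.Series(1.0, index=both.sample_ids)
        res = tc.NBContrastModel(both, sf2, list(dup.columns), ctl).fit()
        assert np.allclose(res.table["log2fc"].dropna(), 0.0)
        assert res.n_dep() == 0

    def test_simulated_null_rarely_yields_deps(self):
        """Independent null draws: the chance of any DEP per seed is the
        BH family floor (~10% at 500 probes); seeds with hits stay rare."""
        hits = 0
        for seed in range(20):
            counts, sheet, sf = self._null_study(seed)
            grp, ctl = contrast_arms(sheet, 500.0)
            res = tc.NBContrastModel(counts, sf, grp, ctl).fit()
            hits += res.n_dep() > 0
        assert hits <= 4

    def test_planted_induction_flagged_up(self):
        """4-fold planted induction, baseline ~200, n=4 vs 4: flagged as
        an upregulated DEP in >=95% of seeds."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            counts, sheet, sf = self._null_study(seed + 1000, n_genes=200)
            # plant the effect directly into the drawn counts' generating
            # mean by rescaling one probe's treated columns
            rng = np.random.default_rng(seed)
            probe = counts.counts.index[7]
            grp, ctl = contrast_arms(sheet, 500.0)
            base = 200
            alpha = 0.05
            r = 1 / alpha
            mu_c, mu_t = base, base * 4
            counts.counts.loc[probe, ctl] = rng.negative_binomial(
                r, r / (r + mu_c), len(ctl))
            counts.counts.loc[probe, grp] = rng.negative_binomial(
                r, r / (r + mu_t), len(grp))
            res = tc.NBContrastModel(counts, sf, grp, ctl).fit()
            row = res.table.set_index("probe_id").loc[probe]
            ok += bool(row["dep"]) and row["direction"] == "up"
        assert ok / n_seeds >= 0.95

    def test_all_zero_probe_excluded_from_testing_and_fdr(self):
        counts, sheet, sf = self._null_study(3, n_genes=100)
        probe = counts.counts.index[0]
        counts.counts.loc[probe] = 0
        grp, ctl = contrast_arms(sheet, 500.0)
        res = tc.NBContrastModel(counts, sf, grp, ctl).fit()
        t = res.table.set_index("probe_id")
        assert np.isnan(t.loc[probe, "p"])
        assert pd.isna(t.loc[probe, "dep"])
        # BH m excludes the NA probe: smallest padj unchanged vs re-running
        # adjustment on the non-NA subset
        sub = t["p"].dropna()
        assert np.allclose(
            tc.bh_adjust(sub.to_numpy()),
            t.loc[sub.index, "padj"].to_numpy())

    def test_insufficient_replicates_rejected(self):
        counts, sheet, sf = self._null_study(4, n_genes=50)
        grp, ctl = contrast_arms(sheet, 500.0)
        with pytest.raises(ValueError):
            tc.NBContrastModel(counts, sf, grp[:1], ctl)

    def test_deg_iff_any_probe_dep_and_representative_rule(self):
        counts, sheet, sf = self._null_study(5, n_genes=150)
        grp, ctl = contrast_arms(sheet, 500.0)
        res = tc.NBContrastModel(counts, sf, grp, ctl).fit()
        t = res.table
        for _, row in res.genes.iterrows():
            probes = t[t.gene.eq(row.gene)]
            any_dep = probes["dep"].astype("boolean").fillna(False).any()
            assert row["deg"] == any_dep
            best = probes["padj"].min()
            assert (row["padj"] == best) or (
                np.isnan(best) and np.isnan(row["padj"]))


class TestCountDeps:
    def test_empty_results_all_zero(self):
        out = tc.count_deps(pd.DataFrame())
        assert out.empty

    def test_planted_up_deps_counted(self, tiny_qc):
        filtered, _, sheet_qc, sf = tiny_qc
        de = tc.run_all_contrasts(filtered, sheet_qc, sf)
        grid = tc.count_deps(de)
        tested = de[~de.skipped]
        total_dep = (tested["dep"].astype("boolean").fillna(False)).sum()
        assert grid.n_up.sum() + grid.n_down.sum() == total_dep
        probes_per_cell = tested.groupby(
            ["genotype", "chemical", "concentration", "timepoint_h"]).size()
        merged = grid.set_index(
            ["genotype", "chemical", "concentration", "timepoint_h"])
        assert ((merged.n_up + merged.n_down)
                <= probes_per_cell.loc[merged.index]).all()
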