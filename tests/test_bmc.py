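"""Dose-response fitting, BMC estimation, filters, pathway summaries."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import toxconcord as tc
from toxconcord.bmc import (DoseResponseFit, _f_hill, compute_bmc,
                            prefilter_trend)
from toxconcord.containers import GeneSetCollection


def hill_fit(a=10.0, s=4.0, e=10.0, h=1.0):
    return DoseResponseFit(family="hill",
                           params=np.array([a, s, e, h]), cov=None,
                           chi2=0.0, df=1, aic=8.0, fit_p=1.0, fun=_f_hill)


CONC = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])


class TestClosedFormBMC:
    def test_hill_inversion(self):
        """f(c) = 10 + 4c/(10+c), control SD 1, BMR factor 1:
        4c/(10+c) = 1 -> c = 10/3."""
        est = compute_bmc(hill_fit(), bmr=1.0, conc=CONC)
        assert est.bmc == pytest.approx(10.0 / 3.0, abs=1e-6)

    def test_zero_span_flags_above_range(self):
        est = compute_bmc(hill_fit(s=0.0), bmr=1.0, conc=CONC)
        assert np.isnan(est.bmc) and "above-range" in est.flags

    def test_concentration_scale_equivariance(self):
        """Doubling all concentrations (EC50 included) doubles the BMC."""
        e1 = compute_bmc(hill_fit(e=10.0), bmr=1.0, conc=CONC)
        e2 = compute_bmc(hill_fit(e=20.0), bmr=1.0, conc=CONC * 2)
        assert e2.bmc == pytest.approx(2 * e1.bmc, rel=1e-9)

    def test_negative_bmr_rejected(self):
        with pytest.raises(ValueError):
            compute_bmc(hill_fit(), bmr=-1.0, conc=CONC)


class TestModelSelection:
    def test_exact_line_linear_beats_poly2_by_aic(self):
        conc = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        y = 2.0 + 0.1 * conc
        res = tc.DoseResponseModel(conc, y, np.full(5, 0.05)).fit(
            families=["linear", "poly2"])
        assert res.winner.family == "linear"

    def test_hill_generated_data_recovers_hill_shape(self):
        """Hill data (a=10, span 4, EC50=10, h=1, sigma=0.05): the winning
        model reproduces the curve and its BMC, whatever family label wins
        under the AIC parsimony penalty."""
        rng = np.random.default_rng(12)
        conc = np.array([0.0, 1.0, 5.0, 25.0, 125.0])
        ok = 0
        n_seeds = 50
        for _ in range(n_seeds):
            y = _f_hill(conc, 10, 4, 10, 1) + rng.normal(0, 0.05, 5)
            res = tc.DoseResponseModel(conc, y, np.full(5, 0.05)).fit()
            est = res.bmc(control_sd=1.0)
            ok += (np.isfinite(est.bmc)
                   and abs(np.log10(est.bmc / (10 / 3))) < 0.25)
        assert ok / n_seeds >= 0.9

    def test_pure_noise_low_fit_p_is_rare(self):
        """White-noise probes still fit well (fit p >= .1) in roughly the
        type-I proportion; they are meant to be caught by the prefilter."""
        rng = np.random.default_rng(3)
        lowp = 0
        n = 100
        for _ in range(n):
            y = rng.normal(5.0, 0.1, 5)
            res = tc.DoseResponseModel(CONC, y, np.full(5, 0.1)).fit()
            if res.winner is not None and res.winner.fit_p < 0.1:
                lowp += 1
        assert lowp / n < 0.25


class TestPrefilter:
    def _expr(self, effect, n_probes, reps=4, sigma=0.1, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.repeat(np.arange(5), reps)
        base = rng.normal(6, 0.5, n_probes)[:, None]
        shift = effect * (groups == 4)
        return base + shift + rng.normal(0, sigma,
                                         (n_probes, groups.size)), groups

    def test_flat_probes_pass_at_alpha_rate(self):
        x, g = self._expr(0.0, 2000)
        keep = prefilter_trend(x, g, alpha=0.05)
        assert keep.mean() == pytest.approx(0.05, abs=0.02)

    def test_planted_effect_retained(self):
        x, g = self._expr(2.0, 200)
        keep = prefilter_trend(x, g, alpha=0.05)
        assert keep.mean() >= 0.95

    def test_alpha_one_keeps_finite_variance_probes(self):
        x, g = self._expr(0.0, 100)
        assert prefilter_trend(x, g, alpha=1.0 + 1e-9).all()

    def test_zero_variance_probe_excluded(self):
        x, g = self._expr(0.0, 10)
        x[0] = 3.0
        assert not prefilter_trend(x, g, alpha=0.05)[0]


class TestFilters:
    def _row(self, **kw):
        base = dict(winner="hill", fit_p=0.5, bmc=5.0, bmcl=3.0, bmcu=8.0)
        base.update(kw)
        return pd.DataFrame([base])

    @pytest.mark.parametrize("kw, rule", [
        (dict(bmc=0.005), "below-range"),          # < lowest/10 = 0.01
        (dict(bmc=600.0, bmcl=400, bmcu=900), "above-range"),
        (dict(bmc=1.0, bmcl=0.04, bmcu=2.0), "ratio-bmc-bmcl"),  # 25 > 20
        (dict(bmc=1.0, bmcl=0.9, bmcu=25.0), "ratio-bmcu-bmc"),
        (dict(fit_p=0.05), "gof-fail"),
        (dict(winner="none"), "fit-fail"),
    ])
    def test_each_rule_fires_alone(self, kw, rule):
        out = tc.apply_bmc_filters(self._row(**kw),
                                   conc_ladder=[0.1, 1, 10, 100, 500])
        assert rule in out.failed_rules.iloc[0]
        assert not out.retained.iloc[0]

    def test_bmcu_bmcl_ratio_rule(self):
        out = tc.apply_bmc_filters(
            self._row(bmc=1.0, bmcl=0.06, bmcu=3.0),
            conc_ladder=[0.1, 1, 10, 100, 500])
        # 3/0.06 = 50 > 40 while the pairwise 20x rules both pass
        assert out.failed_rules.iloc[0] == "ratio-bmcu-bmcl"

    def test_clean_row_retained_with_no_rules(self):
        out = tc.apply_bmc_filters(self._row(),
                                   conc_ladder=[0.1, 1, 10, 100, 500])
        assert out.retained.iloc[0]
        assert out.failed_rules.iloc[0] == ""


def fisher_two_tail_exact(a, b, c, d) -> float:
    """Two-tailed Fisher by enumeration over tables with fixed margins:
    sum the probabilities of all tables no more probable than observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


class TestPathwaySummaries:
    def test_fisher_two_tail_worked_example(self):
        # in-set responsive 3 / in-set not 2 / out responsive 2 / out not 13
        assert tc.fisher_exact_2x2(3, 2, 2, 13) == pytest.approx(
            fisher_two_tail_exact(3, 2, 2, 13), abs=1e-12)

    def test_fisher_matches_enumeration_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            a, b, c, d = rng.integers(0, 9, 4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert tc.fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_two_tail_exact(a, b, c, d), abs=1e-10)

    def test_median_bmc_of_uniform_set(self):
        probe_table = pd.DataFrame({
            "probe_id": ["p1", "p2", "p3"],
            "gene": ["g1", "g2", "g3"],
            "winner": "hill", "fit_p": 0.5,
            "bmc": [2.0, 2.0, 2.0], "bmcl": 1.0, "bmcu": 4.0,
            "retained": True, "failed_rules": ""})
        coll = GeneSetCollection({"s": ["g1", "g2", "g3"]})
        out = tc.pathway_bmc(probe_table, coll,
                             universe_genes=[f"g{i}" for i in range(1, 21)])
        assert out.median_bmc.iloc[0] == pytest.approx(2.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            tc.pathway_bmc(pd.DataFrame(), GeneSetCollection(), ["g1"])

    def test_accumulation_is_sorted_cumulative(self):
        acc = tc.accumulation_data([3.0, 1.0, np.nan, 2.0])
        assert acc.value.tolist() == [1.0, 2.0, 3.0]
        assert acc.cumulative_count.tolist() == [1, 2, 3]


class TestFilterSoundness:
    def test_retained_rows_pass_all_rules(self, tiny_qc):
        filtered, _, sheet_qc, sf = tiny_qc
        tab = tc.bmc_analysis(filtered, sheet_qc, sf, "WT", "HFPO-DA",
                              24.0, seed=0)
        ladder = [0.1, 5.0, 50.0, 500.0]
        ret = tab[tab.retained]
        assert (ret.fit_p >= 0.1).all()
        assert (ret.bmc >= ladder[0] / 10).all()
        assert (ret.bmc <= ladder[-1]).all()
        assert (ret.bmc / ret.bmcl <= 20).all()
        assert (ret.bmcu / ret.bmc <= 20).all()
        assert (ret.bmcu / ret.bmcl <= 40).all()
        assert (ret.bmcl <= ret.bmc).all() and (ret.bmc <= ret.bmcu).all()
        removed = tab[~tab.retained]
        assert (removed.failed_rules != "").all()
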