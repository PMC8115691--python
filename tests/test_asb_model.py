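import math

import numpy as np
import pytest
from scipy import stats

from asbkit.asb_model import (FitTable, NbMixtureFit, NegBinMixtureModel,
                              asb_pvalues, collect_cells, effect_size,
                              fit_cell, mixture_pmf, rmsea, score_calls)
from asbkit.variant_io import SnvCall


def draw_truncated_mixture(rng, r, w, p, size):
    """Model draws rejected below the truncation bound (test oracle)."""
    out = []
    while len(out) < size:
        if rng.random() < w:
            x = rng.negative_binomial(r, p)       # success prob 1-p... see below
        else:
            x = rng.negative_binomial(r, 1 - p)
        if x >= 5:
            out.append(int(x))
    return out


class TestMixturePmf:
    def test_symmetric_at_bad_one_pmf_independent_of_w(self):
        xs = np.arange(5, 60)
        fits = [NbMixtureFit(1.0, "alt", 10, r=12.0, w=w) for w in (0.0, 0.3, 1.0)]
        base = fits[0].pmf(xs)
        for fit in fits[1:]:
            np.testing.assert_allclose(fit.pmf(xs), base, rtol=1e-12)

    @pytest.mark.parametrize("bad,r,w", [(1.0, 10.0, 1.0), (2.0, 7.5, 0.3),
                                         (6.0, 40.0, 0.0)])
    def test_normalisation(self, bad, r, w):
        fit = NbMixtureFit(bad, "alt", 10, r=r, w=w)
        xs = np.arange(5, 20000)
        assert fit.pmf(xs).sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_component_closed_form(self):
        # w=1 picks the NB(r, 1-p) component: pmf C(x+r-1,x) p^r (1-p)^x / A
        r, bad = 10, 2.0
        p = 1.0 / (bad + 1.0)
        fit = NbMixtureFit(bad, "alt", 10, r=float(r), w=1.0)
        norm = 1.0 - sum(math.comb(x + r - 1, x) * p**r * (1 - p)**x
                         for x in range(5))
        for x in (5, 12, 30):
            direct = math.comb(x + r - 1, x) * p**r * (1 - p)**x / norm
            assert mixture_pmf(x, fit) == pytest.approx(direct, rel=1e-10)

    def test_below_truncation_rejected(self):
        fit = NbMixtureFit(1.0, "alt", 10, r=10.0, w=1.0)
        with pytest.raises(ValueError):
            mixture_pmf(4, fit)


class TestFitCell:
    def test_parameter_recovery_from_model_draws(self, rng):
        r_true, w_true, bad, m = 18.0, 0.4, 2.0, 20
        p = 1.0 / (bad + 1.0)
        comp = [stats.nbinom(r_true, 1 - p), stats.nbinom(r_true, p)]
        draws = []
        while len(draws) < 5000:
            c = comp[rng.random() < w_true]
            x = int(c.rvs(random_state=rng))
            if x >= 5:
                draws.append(x)
        fit = fit_cell(draws, bad=bad, m=m)
        assert fit.status == "fitted"
        assert fit.r == pytest.approx(r_true, rel=0.15)
        assert fit.w == pytest.approx(w_true, abs=0.1)

    def test_off_family_data_falls_back(self, rng):
        # far-separated point masses cannot be approximated by the mixture
        draws = np.concatenate([np.full(400, 5), np.full(400, 200)])
        fit = fit_cell(draws, bad=1.0, m=20)
        assert fit.status == "fallback"
        assert fit.r == 20.0 and fit.w == 1.0

    def test_small_cell_falls_back_immediately(self):
        fit = fit_cell([8] * 10, bad=1.0, m=10, min_obs=50)
        assert fit.status == "fallback" and fit.n_obs == 10

    def test_reference_bias_inflates_r_for_ref_scoring(self, rng):
        # reference-mapping bias shifts reads toward the reference allele;
        # the maximum-likelihood r conditioning on the alt count (scoring
        # ref) must then exceed r of the mirrored fit at the same m.
        # Totals vary NB-like and the split is beta-binomial, as in real
        # reads; the RMSEA gate is disabled to examine the MLE itself.
        bias = 1.3
        p_ref = bias * 0.5 / (bias * 0.5 + 0.5)
        r_cov = 1.0 / 0.3
        totals = rng.negative_binomial(r_cov, r_cov / (r_cov + 40.0),
                                       size=40000) + 1
        conc = (1 - 0.02) / 0.02
        c_ref = rng.binomial(totals, rng.beta(p_ref * conc,
                                              (1 - p_ref) * conc, 40000))
        c_alt = totals - c_ref
        keep = (c_ref >= 5) & (c_alt >= 5)
        c_ref, c_alt = c_ref[keep], c_alt[keep]
        wins = 0
        for m in (12, 15, 18):
            ref_counts = c_ref[c_alt == m]   # distribution of ref reads
            alt_counts = c_alt[c_ref == m]   # distribution of alt reads
            fit_ref = NegBinMixtureModel(ref_counts, 1.0, m, "alt").fit(
                min_obs=30, rmsea_gate=np.inf)
            fit_alt = NegBinMixtureModel(alt_counts, 1.0, m, "ref").fit(
                min_obs=30, rmsea_gate=np.inf)
            assert fit_ref.status == "fitted" and fit_alt.status == "fitted"
            wins += fit_ref.r > fit_alt.r
        assert wins == 3


class TestRmsea:
    def test_perfect_histogram_scores_zero(self):
        fit = NbMixtureFit(1.0, "alt", 10, r=10.0, w=1.0)
        n = 5000
        xs = np.arange(5, 200)
        hist = {int(x): float(p) * n for x, p in zip(xs, fit.pmf(xs))}
        assert rmsea(hist, fit) == pytest.approx(0.0, abs=1e-9)

    def test_calibration_under_the_model(self, rng):
        fit = NbMixtureFit(2.0, "alt", 15, r=15.0, w=0.5)
        xs = np.arange(5, 400)
        probs = fit.pmf(xs)
        probs = probs / probs.sum()
        ok = 0
        n_rep = 40
        for _ in range(n_rep):
            draws = rng.choice(xs, p=probs, size=5000)
            if rmsea(draws, fit) < 0.05:
                ok += 1
        assert ok / n_rep >= 0.95

    def test_shifted_histogram_fails_the_gate(self):
        fit = NbMixtureFit(1.0, "alt", 10, r=10.0, w=1.0)
        draws = np.full(2000, 40)  # mass far from the model mode
        assert rmsea(draws, fit) > 0.05

    def test_undefined_when_too_few_bins(self):
        fit = NbMixtureFit(1.0, "alt", 200, r=200.0, w=1.0)
        # all mass near 200 -> single pooled bin at these observations
        assert rmsea({5: 3}, fit) is None


def _snv(c_ref, c_alt, pos=1000):
    return SnvCall("chr1", pos, "A", "G", c_ref, c_alt, "het", "rs1", "d1")


class TestPvalues:
    def test_minimum_count_gives_p_one(self):
        fits = FitTable()
        p_ref, _ = asb_pvalues(_snv(5, 10), 1.0, fits)
        assert p_ref == 1.0

    def test_brute_force_tail_oracle(self):
        # fallback at BAD=1, c_alt=10: truncated NB(r=10, p=1/2) upper tail
        fits = FitTable()
        p_ref, _ = asb_pvalues(_snv(25, 10), 1.0, fits)
        r, p = 10, 0.5
        pmf = [math.comb(x + r - 1, x) * p**r * (1 - p)**x for x in range(4000)]
        norm = sum(pmf[5:])
        brute = sum(pmf[25:]) / norm
        assert p_ref == pytest.approx(brute, rel=1e-9)

    def test_monotone_in_observed_count(self):
        fits = FitTable()
        pvals = [asb_pvalues(_snv(c, 12), 2.0, fits)[0] for c in range(5, 80)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_null_pvalues_are_conservative(self, rng):
        fit = NbMixtureFit.fallback(1.0, "alt", 10)
        xs = np.arange(5, 500)
        probs = fit.pmf(xs)
        draws = rng.choice(xs, p=probs / probs.sum(), size=10000)
        pvals = fit.sf_trunc(draws)
        grid = np.linspace(0, 1, 501)[1:]
        ecdf = np.searchsorted(np.sort(pvals), grid, side="right") / len(pvals)
        d_plus = float(np.max(ecdf - grid))
        # one-sided KS bound at alpha=0.01
        assert d_plus <= math.sqrt(math.log(1 / 0.01) / (2 * len(pvals)))


class TestEffectSize:
    def test_bad_one_fallback_near_log_ratio(self):
        fits = FitTable()
        es_ref, _ = effect_size(_snv(20, 10), 1.0, fits)
        assert es_ref == pytest.approx(1.0, abs=0.1)

    def test_zero_at_model_expectation(self):
        fits = FitTable()
        fit = fits.get(1.0, "alt", 10)
        expected = fit.expectation_trunc()
        snv = _snv(int(round(expected)), 10)
        es_ref, _ = effect_size(snv, 1.0, fits)
        assert es_ref == pytest.approx(math.log2(round(expected) / expected),
                                       abs=1e-12)

    def test_bad_two_bracket(self):
        # ES_ref must lie between log2(c_ref*BAD/c_alt) and
        # log2(c_ref/(BAD*c_alt)) (order depends on the haplotype weights)
        fits = FitTable()
        fits.add(NbMixtureFit(2.0, "alt", 10, r=10.0, w=0.5))
        snv = _snv(30, 10)
        es_ref, _ = effect_size(snv, 2.0, fits)
        lo, hi = sorted([math.log2(30 * 2 / 10), math.log2(30 / (2 * 10))])
        assert lo - 0.1 <= es_ref <= hi + 0.1


class TestFitTable:
    def test_roundtrip_through_frame(self):
        table = FitTable([NbMixtureFit(2.0, "alt", 10, r=8.5, w=0.4,
                                       rmsea=0.01, status="fitted", n_obs=100),
                          NbMixtureFit.fallback(1.0, "ref", 7, n_obs=3)])
        back = FitTable.from_frame(table.to_frame())
        assert len(back) == 2
        fit = back.get(2.0, "alt", 10)
        assert (fit.r, fit.w, fit.status) == (8.5, 0.4, "fitted")

    def test_missing_cell_resolves_to_fallback(self):
        fit = FitTable().get(3.0, "ref", 42)
        assert fit.status == "fallback" and fit.r == 42.0 and fit.w == 1.0

    def test_collect_cells_groups_both_direction(self):
        calls = [_snv(12, 8), _snv(20, 8, pos=2000)]
        cells = collect_cells(calls, badmap=None)
        assert sorted(cells[(1.0, "alt", 8)]) == [12, 20]
        assert cells[(1.0, "ref", 12)] == [8]

    def test_score_calls_matches_scalar_path(self):
        fits = FitTable()
        calls = [_snv(12, 8), _snv(25, 10, pos=2000), _snv(5, 30, pos=3000)]
        df = score_calls(calls, None, fits)
        for row, c in zip(df.itertuples(), calls):
            p_ref, p_alt = asb_pvalues(c, 1.0, fits)
            es_ref, es_alt = effect_size(c, 1.0, fits)
            assert row.p_ref == pytest.approx(p_ref, rel=1e-12)
            assert row.p_alt == pytest.approx(p_alt, rel=1e-12)
            assert row.es_ref == pytest.approx(es_ref, rel=1e-12)
            assert row.es_alt == pytest.approx(es_alt, rel=1e-12)
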