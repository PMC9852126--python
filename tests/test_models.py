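"""PP model / PPV statistic, CVP decomposition, section comparison."""

import numpy as np
import pandas as pd
import pytest

import hemogam as hg
from hemogam.exceptions import TooFewObservationsError, WrongModelError


def make_cvp_table(cfg):
    wave, ann, truth = hg.gen_cvp_wave(cfg)
    seg = hg.WaveformSegment.from_frame(wave)
    tab = hg.build_cvp_table(seg, ann["qrs_times"], ann["insp_starts"],
                             pr_interval=cfg.pr_interval)
    return tab, truth


def resp_smooth_on_grid(fit, grid):
    term = next(t for t in fit.design.terms if t.label == "respiration")
    sl = fit.term_slices["respiration"]
    f = term.basis.design(grid) @ fit.coefficients[sl]
    se = np.sqrt(np.maximum(np.einsum(
        "ij,jk,ik->i", term.basis.design(grid),
        fit.posterior_covariance[sl, sl], term.basis.design(grid)), 0))
    return f, se


def cardiac_smooth_on_grid(fit, grid, label="cardiac"):
    term = next(t for t in fit.design.terms if t.label == label)
    sl = fit.term_slices[label]
    return term.basis.design(grid) @ fit.coefficients[sl]


class TestPPModel:
    def test_alpha_is_mean_pp(self, pp_beats):
        beats, _ = pp_beats
        fit = hg.fit_pp_model(beats)
        alpha = fit.coefficients[fit.term_slices["intercept"]][0]
        assert alpha == pytest.approx(beats["pulse_pressure"].mean(),
                                      abs=1e-6)

    def test_respiratory_smooth_recovers_modulation(self, pp_beats):
        beats, truth = pp_beats
        fit = hg.fit_pp_model(beats)
        grid = np.linspace(0, 1, 256, endpoint=False)
        f, _ = resp_smooth_on_grid(fit, grid)
        target = truth["resp_effect"](grid)
        rmse = np.sqrt(np.mean(((f - f.mean()) - (target - target.mean()))**2))
        assert rmse < 0.1

    def test_null_modulation_within_noise(self):
        beats, _ = hg.gen_pp_series(hg.PPGeneratorConfig(
            resp_effect=("sinusoid", 0.0), seed=13))
        fit = hg.fit_pp_model(beats)
        grid = np.linspace(0, 1, 256, endpoint=False)
        f, se = resp_smooth_on_grid(fit, grid)
        assert f.max() - f.min() < 2.0 * se.max()

    def test_sparse_beats_per_cycle_still_recover(self):
        """Pooling cycles reveals the modulation even at HR:RR near 2:1."""
        beats, truth = hg.gen_pp_series(hg.PPGeneratorConfig(
            heart_rate=52.0, resp_rate=24.0, seed=14))
        fit = hg.fit_pp_model(beats)
        grid = np.linspace(0, 1, 256, endpoint=False)
        f, _ = resp_smooth_on_grid(fit, grid)
        target = truth["resp_effect"](grid)
        rmse = np.sqrt(np.mean(((f - f.mean()) - (target - target.mean()))**2))
        assert rmse < 0.15

    def test_too_few_beats_rejected(self):
        beats, _ = hg.gen_pp_series(hg.PPGeneratorConfig(n_beats=5, seed=0))
        with pytest.raises(TooFewObservationsError):
            hg.fit_pp_model(beats)


class TestPPV:
    def test_flat_smooth_gives_zero(self):
        beats, _ = hg.gen_pp_series(hg.PPGeneratorConfig(
            resp_effect=("sinusoid", 0.0), noise_sd=0.0,
            trend=("linear", 0.5), seed=1))
        fit = hg.fit_pp_model(beats)
        res = hg.compute_ppv(fit, n_draws=2000, seed=0)
        assert res.ppv == pytest.approx(0.0, abs=0.05)

    def test_converges_to_closed_form_on_dense_noiseless_beats(self):
        cfg = hg.PPGeneratorConfig(n_beats=600, heart_rate=600.0,
                                   resp_rate=12.0, noise_sd=0.0, seed=0)
        beats, _ = hg.gen_pp_series(cfg)
        res = hg.compute_ppv(hg.fit_pp_model(beats), n_draws=2000, seed=0)
        assert res.ppv == pytest.approx(15.0, abs=0.1)
        assert res.alpha == pytest.approx(8.0, abs=1e-6)

    def test_matches_classic_formula_on_dense_data(self):
        """GAM PPV vs per-cycle (PPmax-PPmin)/mean from the generator."""
        cfg = hg.PPGeneratorConfig(n_beats=600, heart_rate=600.0,
                                   resp_rate=12.0, noise_sd=0.0, seed=0)
        beats, _ = hg.gen_pp_series(cfg)
        cyc = np.floor(beats["time_s"].to_numpy() / 5.0).astype(int)
        classic = []
        for c in np.unique(cyc)[:-1]:
            pp = beats.loc[cyc == c, "pulse_pressure"]
            classic.append(100.0 * (pp.max() - pp.min())
                           / ((pp.max() + pp.min()) / 2.0))
        res = hg.compute_ppv(hg.fit_pp_model(beats), n_draws=2000, seed=0)
        assert res.ppv == pytest.approx(np.mean(classic), abs=0.2)

    def test_recovery_within_one_point(self, pp_beats):
        beats, truth = pp_beats
        res = hg.compute_ppv(hg.fit_pp_model(beats), n_draws=5000, seed=0)
        assert abs(res.ppv - truth["ppv_true"]) < 1.0
        assert res.ci_low <= res.ppv <= res.ci_high

    def test_seed_reproducibility(self, pp_beats):
        beats, _ = pp_beats
        fit = hg.fit_pp_model(beats)
        a = hg.compute_ppv(fit, n_draws=2000, seed=3)
        b = hg.compute_ppv(fit, n_draws=2000, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_rejects_non_pp_fit(self, cvp_dataset):
        tab, _ = cvp_dataset
        fit = hg.fit_cvp_additive(tab.iloc[:2000], ar1="off")
        with pytest.raises(WrongModelError):
            hg.compute_ppv(fit)


class TestCVPModels:
    def test_additive_recovers_cardiac_template_without_interaction(self):
        tab, truth = make_cvp_table(hg.CVPGeneratorConfig(
            seed=15, interaction_gain=0.0))
        fit = hg.fit_cvp_additive(tab)
        cg = np.linspace(0.0, tab["cardiac_position"].quantile(0.99), 150)
        f = cardiac_smooth_on_grid(fit, cg)
        target = truth["cardiac_template"](cg)
        rmse = np.sqrt(np.mean(
            ((f - f.mean()) - (target - target.mean())) ** 2))
        assert rmse < 0.15

    def test_interaction_reduces_residuals_when_present(self, cvp_dataset):
        tab, _ = cvp_dataset
        fa = hg.fit_cvp_additive(tab)
        fi = hg.fit_cvp_interaction(tab)
        assert np.std(fi.residuals) < np.std(fa.residuals)
        assert fi.rss <= fa.rss + 1e-8  # nested models

    def test_no_interaction_no_residual_gap(self):
        tab, _ = make_cvp_table(hg.CVPGeneratorConfig(
            seed=16, interaction_gain=0.0))
        fa = hg.fit_cvp_additive(tab)
        fi = hg.fit_cvp_interaction(tab)
        sd_a, sd_i = np.std(fa.residuals), np.std(fi.residuals)
        assert abs(sd_a - sd_i) < 0.05 * sd_a

    def test_interaction_surface_correlates_with_truth(self, cvp_dataset):
        tab, truth = cvp_dataset
        fit = hg.fit_cvp_interaction(tab)
        term = next(t for t in fit.design.terms if t.label == "interaction")
        sl = fit.term_slices["interaction"]
        cc, rr = np.meshgrid(
            np.linspace(0.02, tab["cardiac_position"].quantile(0.98), 30),
            np.linspace(0, 1, 30, endpoint=False), indexing="ij")
        XY = np.column_stack([cc.ravel(), rr.ravel()])
        fhat = term.basis.design(XY) @ fit.coefficients[sl]
        ftrue = truth["interaction"](cc.ravel(), rr.ravel())
        assert np.corrcoef(fhat, ftrue)[0, 1] > 0.8

    def test_null_interaction_term_shrinks(self):
        tab, _ = make_cvp_table(hg.CVPGeneratorConfig(
            seed=17, interaction_gain=0.0, duration_s=20))
        fit = hg.fit_cvp_interaction(tab)
        term = next(t for t in fit.design.terms if t.label == "interaction")
        sl = fit.term_slices["interaction"]
        cc, rr = np.meshgrid(
            np.linspace(0.05, tab["cardiac_position"].quantile(0.95), 20),
            np.linspace(0, 1, 20, endpoint=False), indexing="ij")
        XY = np.column_stack([cc.ravel(), rr.ravel()])
        G = term.basis.design(XY)
        f = G @ fit.coefficients[sl]
        se = np.sqrt(np.maximum(np.einsum(
            "ij,jk,ik->i", G, fit.posterior_covariance[sl, sl], G), 0))
        assert np.abs(f).max() < 2.0 * se.max()
        assert fit.edf["interaction"] < 0.15 * (sl.stop - sl.start)

    @pytest.mark.parametrize("seed", [18, 19, 20])
    def test_null_respiratory_modulation_within_noise(self, seed):
        """With zero respiratory amplitude the fitted respiratory smooth is
        negligible: amplitude far below the noise floor, and inside the
        pointwise 2-SE band at nearly all grid points (the band is
        pointwise, so isolated small excursions are expected)."""
        tab, _ = make_cvp_table(hg.CVPGeneratorConfig(
            seed=seed, resp_effect=("sinusoid", 0.0)))
        fit = hg.fit_cvp_additive(tab)
        grid = np.linspace(0, 1, 128, endpoint=False)
        f, se = resp_smooth_on_grid(fit, grid)
        assert np.abs(f).max() < 0.1  # mmHg; true modulation would be ~2
        assert np.mean(np.abs(f) <= 2.0 * se) >= 0.85


class TestSectionComparison:
    @staticmethod
    def section_pair(cfg_pre, cfg_post, gap=40.0):
        tab1, tr1 = make_cvp_table(cfg_pre)
        tab1["section"] = "pre"
        wave, ann, tr2 = hg.gen_cvp_wave(cfg_post)
        wave = wave.assign(time_s=wave["time_s"] + gap)
        seg = hg.WaveformSegment.from_frame(wave)
        tab2 = hg.build_cvp_table(seg, ann["qrs_times"] + gap,
                                  ann["insp_starts"] + gap,
                                  pr_interval=cfg_post.pr_interval,
                                  section="post")
        return tab1, tab2, tr1, tr2

    def test_constant_shift_recovered(self):
        pre, post, *_ = self.section_pair(
            hg.CVPGeneratorConfig(seed=11, interaction_gain=0.4),
            hg.CVPGeneratorConfig(seed=12, interaction_gain=0.4,
                                  mean_cvp=10.0))
        comp = hg.compare_sections(pre, post)
        assert 1.8 <= comp.beta_s <= 2.2
        assert comp.fit.coefficients[
            comp.fit.term_slices["section(section)"]].shape == (1,)

    def test_identical_sections_agree(self):
        pre, post, *_ = self.section_pair(
            hg.CVPGeneratorConfig(seed=21, duration_s=20),
            hg.CVPGeneratorConfig(seed=22, duration_s=20))
        comp = hg.compare_sections(pre, post)
        fit = comp.fit
        grid = np.linspace(0, 1, 128, endpoint=False)
        for stem, xs in (("respiration", grid),
                         ("cardiac", np.linspace(0.0, 0.6, 100))):
            fs, ses = [], []
            for lab in ("pre", "post"):
                term = next(t for t in fit.design.terms
                            if t.label == f"{stem}[{lab}]")
                sl = fit.term_slices[term.label]
                G = term.basis.design(xs)
                fs.append(G @ fit.coefficients[sl])
                ses.append(np.sqrt(np.maximum(np.einsum(
                    "ij,jk,ik->i", G, fit.posterior_covariance[sl, sl], G),
                    0)))
            gap = np.abs(fs[0] - fs[1])
            comb = np.sqrt(ses[0] ** 2 + ses[1] ** 2)
            assert np.all(gap <= 2.0 * comb + 0.05)
        assert abs(comp.beta_s) <= 2.0 * comp.beta_s_se + 0.05

    def test_more_cardiac_less_respiratory_after_fluid(self):
        """Post section built with a taller cardiac template and a smaller
        respiratory swing; the fitted per-section ranges must reproduce
        both orderings."""
        taller = tuple((c, w, 1.4 * a)
                       for c, w, a in hg.synth._DEFAULT_TEMPLATE)
        pre, post, *_ = self.section_pair(
            hg.CVPGeneratorConfig(seed=23, duration_s=20),
            hg.CVPGeneratorConfig(seed=24, duration_s=20,
                                  cardiac_template=taller,
                                  resp_effect=("plateau", 1.0)))
        comp = hg.compare_sections(pre, post)
        r = comp.smooth_ranges
        assert r["post"]["cardiac"] > r["pre"]["cardiac"]
        assert r["post"]["respiration"] < r["pre"]["respiration"]

    def test_overlapping_sections_rejected(self, cvp_dataset):
        tab, _ = cvp_dataset
        a = tab.copy()
        a["section"] = "pre"
        b = tab.copy()
        b["section"] = "post"
        with pytest.raises(ValueError, match="overlap"):
            hg.compare_sections(a, b)

    def test_cycle_curves_cover_both_phases(self):
        pre, post, *_ = self.section_pair(
            hg.CVPGeneratorConfig(seed=25, duration_s=15),
            hg.CVPGeneratorConfig(seed=26, duration_s=15))
        comp = hg.compare_sections(pre, post)
        got = set(map(tuple, comp.cycle_curves[["section", "phase"]]
                      .drop_duplicates().to_numpy()))
        assert got == {("pre", "end_inspiration"), ("pre", "end_expiration"),
                       ("post", "end_inspiration"),
                       ("post", "end_expiration")}


class TestExports:
    def test_summary_dict_round_trips_json(self, pp_beats):
        import json

        beats, _ = pp_beats
        fit = hg.fit_pp_model(beats)
        ppv = hg.compute_ppv(fit, n_draws=1000, seed=0)
        s = hg.summary_dict(fit, ppv=ppv)
        text = json.dumps(s)
        back = json.loads(text)
        assert back["ppv"]["ppv"] == pytest.approx(ppv.ppv)
        assert set(back["edf"]) == {"intercept", "respiration", "trend"}

    def test_term_grid_frame_long_format(self, pp_beats):
        beats, _ = pp_beats
        fit = hg.fit_pp_model(beats)
        grid = pd.DataFrame({
            "resp_position": np.linspace(0, 1, 50, endpoint=False),
            "time_s": np.full(50, 100.0)})
        frame = hg.term_grid_frame(fit, grid)
        assert set(frame["term"]) == {"intercept", "respiration", "trend"}
        assert {"contribution", "se"}.issubset(frame.columns)
        assert len(frame) == 150
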