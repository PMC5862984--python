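"""REML engine vs dense/grid oracles, LRT behaviour, fast approximations."""

import numpy as np
import pytest

from hhmap import grm as grm_mod
from hhmap import simulate, varcomp
from hhmap.grm import GenotypeView
from hhmap.varcomp import (
    MixedModelSpec,
    VarCompFit,
    VarKernel,
    fast_scan_then_refit,
    fit_reml,
    grammar_residuals,
    lrt,
    regional_heritability,
)

from conftest import make_panel


def dense_reml_loglik(y, X, V):
    """Independent dense evaluation of the restricted log-likelihood."""
    n, p = X.shape
    sign, ld = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    _, ld2 = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (ld + ld2 + y @ P @ y + (n - p) * np.log(2 * np.pi))


@pytest.fixture(scope="module")
def fixture40():
    """40-individual panel with regional + whole-genome kernels and phenotype."""
    rng = np.random.default_rng(99)
    haps = rng.integers(0, 2, size=(40, 2, 30), dtype=np.int8)
    panel = make_panel(haps)
    gv = GenotypeView.from_panel(panel)
    Kr = grm_mod.snp_regional_grm(gv, slice(0, 5))
    Kw = grm_mod.whole_genome_grm(gv)
    g_r = np.sqrt(0.3) * Kr.loadings @ rng.standard_normal(Kr.loadings.shape[1])
    g_w = np.sqrt(0.3) * Kw.loadings @ rng.standard_normal(Kw.loadings.shape[1])
    y = g_r + g_w + np.sqrt(0.6) * rng.standard_normal(40)
    return y, Kr, Kw


class TestFitReml:
    def test_identity_kernel_rejected(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        spec = MixedModelSpec(y=y, K_w=np.eye(30))
        with pytest.raises(ValueError, match="component matrix equals identity"):
            fit_reml(spec, components=("whole_genome",))

    def test_loglik_matches_dense_oracle_at_estimates(self, fixture40):
        y, Kr, Kw = fixture40
        fit = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        V = (
            fit.variances["regional"] * Kr.matrix
            + fit.variances["whole_genome"] * Kw.matrix
            + fit.variances["residual"] * np.eye(40)
        )
        dense = dense_reml_loglik(y, np.ones((40, 1)), V)
        assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_grid_search_oracle(self, fixture40):
        y, Kr, Kw = fixture40
        fit = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        X = np.ones((40, 1))
        best = -np.inf
        grids = [
            np.linspace(max(v, 1e-4) * 0.5, max(v, 1e-4) * 1.6, 7)
            for v in (fit.variances["regional"], fit.variances["whole_genome"],
                      fit.variances["residual"])
        ]
        for a in grids[0]:
            for b in grids[1]:
                for c in grids[2]:
                    V = a * Kr.matrix + b * Kw.matrix + c * np.eye(40)
                    best = max(best, dense_reml_loglik(y, X, V))
        assert fit.loglik >= best - 1e-3

    def test_permutation_equivariance(self, fixture40):
        y, Kr, Kw = fixture40
        fit = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        perm = np.random.default_rng(1).permutation(40)
        Kr2 = grm_mod.RegionalGRM(
            [Kr.individual_ids[i] for i in perm], Kr.matrix[np.ix_(perm, perm)],
            Kr.n_markers, "snp", loadings=Kr.loadings[perm],
        )
        Kw2 = grm_mod.RegionalGRM(
            [Kw.individual_ids[i] for i in perm], Kw.matrix[np.ix_(perm, perm)],
            Kw.n_markers, "whole_genome", loadings=Kw.loadings[perm],
        )
        fit2 = fit_reml(MixedModelSpec(y=y[perm], K_r=Kr2, K_w=Kw2))
        for k in fit.variances:
            assert fit.variances[k] == pytest.approx(fit2.variances[k], abs=1e-8)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_scale_equivariance(self, fixture40):
        y, Kr, Kw = fixture40
        f1 = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        f3 = fit_reml(MixedModelSpec(y=3.0 * y, K_r=Kr, K_w=Kw))
        for k in f1.variances:
            assert f3.variances[k] == pytest.approx(9.0 * f1.variances[k], rel=1e-4)
        n1 = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
        n3 = fit_reml(MixedModelSpec(y=3.0 * y, K_w=Kw), components=("whole_genome",))
        assert lrt(f1, n1).value == pytest.approx(lrt(f3, n3).value, abs=1e-6)
        assert regional_heritability(f1) == pytest.approx(regional_heritability(f3), abs=1e-6)

    def test_dense_kernel_path_matches_loadings_path(self, fixture40):
        y, Kr, Kw = fixture40
        f_load = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        Kr_dense = grm_mod.RegionalGRM(Kr.individual_ids, Kr.matrix, Kr.n_markers, "snp")
        Kw_dense = grm_mod.RegionalGRM(Kw.individual_ids, Kw.matrix, Kw.n_markers, "snp")
        f_dense = fit_reml(MixedModelSpec(y=y, K_r=Kr_dense, K_w=Kw_dense))
        for k in f_load.variances:
            assert f_load.variances[k] == pytest.approx(f_dense.variances[k], abs=1e-6)

    def test_adding_component_never_decreases_loglik(self, fixture40):
        y, Kr, Kw = fixture40
        full = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        null = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
        assert full.loglik >= null.loglik - 1e-6
        assert lrt(full, null).value >= 0.0

    def test_parameter_recovery(self, recovery_cohort):
        panel, gmap, blocks = recovery_cohort
        gv = GenotypeView.from_panel(panel)
        win = max(blocks, key=lambda w: w.n_snps)
        Kr = grm_mod.haplotype_regional_grm(grm_mod.enumerate_haplotypes(panel, win))
        Kw_load = grm_mod.whole_genome_loadings(
            gv, exclude=range(win.abs_start, win.abs_stop)
        )
        Kw = VarKernel(Kw_load, name="whole_genome")
        truth = np.array([0.05, 0.25, 0.70])
        rng = np.random.default_rng(17)
        est = []
        for _ in range(20):
            g_r = np.sqrt(truth[0]) * Kr.loadings @ rng.standard_normal(Kr.loadings.shape[1])
            g_w = np.sqrt(truth[1]) * Kw_load @ rng.standard_normal(Kw_load.shape[1])
            y = g_r + g_w + np.sqrt(truth[2]) * rng.standard_normal(panel.n_individuals)
            fit = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
            est.append([fit.variances["regional"], fit.variances["whole_genome"],
                        fit.variances["residual"]])
        est = np.array(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert (np.abs(est.mean(axis=0) - truth) < 2 * se + 0.01).all()


class TestLrt:
    def test_zero_when_equal(self, fixture40):
        y, Kr, Kw = fixture40
        full = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        null = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
        stat = lrt(full, null)
        assert stat.value == 2 * max(0.0, full.loglik - null.loglik) or stat.value == 0.0

    def test_mismatched_specs_error(self, fixture40):
        y, Kr, Kw = fixture40
        full = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        with pytest.raises(ValueError):
            lrt(full, full)

    def test_threshold_flag(self, fixture40):
        y, Kr, Kw = fixture40
        full = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
        null = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
        assert lrt(full, null, threshold=1e9).significant is False

    def test_null_data_zero_fraction_near_half(self):
        # boundary mixture 0.5*chi2_0 + 0.5*chi2_1: about half the LRTs are 0
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(80, 2, 40), dtype=np.int8)
        panel = make_panel(haps)
        gv = GenotypeView.from_panel(panel)
        Kr = grm_mod.snp_regional_grm(gv, slice(0, 4))
        Kw_load = grm_mod.whole_genome_loadings(gv, exclude=range(0, 4))
        Kw = VarKernel(Kw_load, name="whole_genome")
        zeros = 0
        n_rep = 200
        for _ in range(n_rep):
            g_w = np.sqrt(0.3) * Kw_load @ rng.standard_normal(Kw_load.shape[1])
            y = g_w + np.sqrt(0.7) * rng.standard_normal(80)
            full = fit_reml(MixedModelSpec(y=y, K_r=Kr, K_w=Kw))
            null = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
            if lrt(full, null).value == 0.0:
                zeros += 1
        frac = zeros / n_rep
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_rep) + 0.02


class TestRegionalHeritability:
    def _fit(self, r, w, e):
        return VarCompFit(
            variances={"regional": r, "whole_genome": w, "residual": e},
            loglik=0.0, iterations=1, converged=True, se={}, n=10,
            components=("regional", "whole_genome"), beta=np.zeros(1),
        )

    def test_partition_value(self):
        assert regional_heritability(self._fit(0.05, 0.25, 0.70)) == pytest.approx(0.05)

    def test_zero_regional(self):
        assert regional_heritability(self._fit(0.0, 0.3, 0.7)) == 0.0

    def test_arithmetic(self):
        assert regional_heritability(self._fit(1, 1, 2)) == pytest.approx(0.25)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total variance"):
            regional_heritability(self._fit(0.0, 0.0, 0.0))

    def test_missing_component_errors(self):
        fit = VarCompFit(
            variances={"whole_genome": 1.0, "residual": 1.0}, loglik=0.0,
            iterations=1, converged=True, se={}, n=10,
            components=("whole_genome",), beta=np.zeros(1),
        )
        with pytest.raises(ValueError):
            regional_heritability(fit)


class TestGrammarResiduals:
    def test_zero_mean(self, fixture40):
        y, Kr, Kw = fixture40
        resid = grammar_residuals(MixedModelSpec(y=y, K_w=Kw))
        assert abs(resid.mean()) < 1e-10

    def test_ols_limit_when_no_genetic_signal(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(150)  # no structure: sigma_w -> 0
        haps = rng.integers(0, 2, size=(150, 2, 20), dtype=np.int8)
        Kw = grm_mod.whole_genome_grm(GenotypeView.from_panel(make_panel(haps)))
        resid = grammar_residuals(MixedModelSpec(y=y, K_w=Kw))
        assert np.abs(resid - (y - y.mean())).max() < 1e-4

    def test_regional_fit_on_residuals_ranks_causal_first(self, small_cohort):
        panel, gmap, blocks = small_cohort
        gv = GenotypeView.from_panel(panel)
        usable = [w for w in blocks if len(np.unique(panel.haplotypes[:, :, w.abs_start:w.abs_stop].reshape(panel.n_individuals * 2, -1), axis=0)) > 1][:10]
        causal = usable[3]
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            pheno = simulate.simulate_phenotypes(
                panel, blocks, causal,
                simulate.SimConfig("AllHap", h2_region=0.10, seed=(100, rep)),
            )
            Kw = grm_mod.whole_genome_grm(gv, exclude=range(causal.abs_start, causal.abs_stop))
            resid = grammar_residuals(MixedModelSpec(y=pheno.y, K_w=Kw))
            lrts = []
            for w in usable:
                try:
                    Kr = grm_mod.haplotype_regional_grm(grm_mod.enumerate_haplotypes(panel, w))
                except grm_mod.WindowSkipped:
                    lrts.append(-1.0)
                    continue
                fit = fit_reml(MixedModelSpec(y=resid, K_r=Kr), components=("regional",))
                null = fit_reml(MixedModelSpec(y=resid), components=())
                lrts.append(lrt(fit, null).value)
            if int(np.argmax(lrts)) == 3:
                wins += 1
        assert wins > n_rep / 2


@pytest.fixture(scope="module")
def scan_setup(small_cohort):
    panel, gmap, blocks = small_cohort
    gv = GenotypeView.from_panel(panel)
    kernels = []
    for w in blocks[:10]:
        try:
            kernels.append(grm_mod.snp_regional_grm(gv, w))
        except grm_mod.WindowSkipped:
            pass
    causal = blocks[3]
    pheno = simulate.simulate_phenotypes(
        panel, blocks, causal, simulate.SimConfig("AllSNP", h2_region=0.10, seed=55)
    )
    Kw = grm_mod.whole_genome_grm(gv)
    return pheno.y, kernels, Kw


class TestFastScan:
    def test_top_fraction_one_equals_full_scan(self, scan_setup):
        y, kernels, Kw = scan_setup
        fast = fast_scan_then_refit(y, None, Kw, kernels, top_fraction=1.0)
        null = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
        for rec in fast:
            assert not rec["approximate"]
            full = fit_reml(MixedModelSpec(y=y, K_r=kernels[rec["window"]], K_w=Kw))
            assert rec["lrt"] == pytest.approx(lrt(full, null).value, abs=1e-6)

    def test_single_window_always_refitted(self, scan_setup):
        y, kernels, Kw = scan_setup
        out = fast_scan_then_refit(y, None, Kw, kernels[:1], top_fraction=0.01)
        assert len(out) == 1 and not out[0]["approximate"]

    def test_refitted_causal_matches_full_model(self, scan_setup):
        y, kernels, Kw = scan_setup
        fast = fast_scan_then_refit(y, None, Kw, kernels, top_fraction=0.2)
        null = fit_reml(MixedModelSpec(y=y, K_w=Kw), components=("whole_genome",))
        refit = [r for r in fast if not r["approximate"]]
        assert refit
        for rec in refit:
            full = fit_reml(MixedModelSpec(y=y, K_r=kernels[rec["window"]], K_w=Kw))
            assert rec["lrt"] == pytest.approx(lrt(full, null).value, abs=1e-6)

    def test_empty_window_list_errors(self, scan_setup):
        y, _, Kw = scan_setup
        with pytest.raises(ValueError, match="empty window list"):
            fast_scan_then_refit(y, None, Kw, [], top_fraction=0.5)
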