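"""NB likelihood kernel, dispersion estimation, and the gene-level MLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import screenpulse as sp
from screenpulse.beta import ALPHA_MIN
from screenpulse.errors import ConfigError, FitError

from oracles import grid_beta_mle, nb_logpmf


def _design(n_base, n_cond, cond="DMSO_D2"):
    samples = ([f"REP1_BASE_D0" if n_base == 1 else f"REP{i+1}_BASE_D0"
                for i in range(n_base)] +
               [f"REP{i+1}_DMSO_D2" for i in range(n_cond)])
    d = pd.DataFrame({cond: [0] * n_base + [1] * n_cond}, index=samples)
    return d, samples


class TestNbLoglik:
    def test_closed_form_k0(self):
        # k=0, mu=1, alpha=1: log(1/(1+mu*alpha))^(1/alpha) = -ln 2
        assert sp.nb_loglik(0, 1.0, 1.0) == pytest.approx(-np.log(2), abs=1e-12)

    def test_poisson_limit_k0(self):
        assert sp.nb_loglik(0, 1.0, 0.0) == pytest.approx(-1.0, abs=1e-12)

    def test_poisson_limit_k2(self):
        # Poisson(2): log pmf at k=2 is -2 + ln 2
        assert sp.nb_loglik(2, 2.0, 1e-8) == pytest.approx(-2 + np.log(2), abs=1e-4)

    def test_matches_scipy_parameterization(self):
        k = np.arange(0, 50)
        got = sp.nb_loglik(k, 7.3, 0.4)
        assert np.allclose(got, nb_logpmf(k, 7.3, 0.4), atol=1e-10)

    @given(mu=st.floats(0.1, 100), alpha=st.floats(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_pmf_sums_to_one(self, mu, alpha):
        k = np.arange(0, 8000)
        total = np.exp(sp.nb_loglik(k, mu, alpha)).sum()
        assert abs(total - 1.0) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sp.nb_loglik(1, 0.0, 0.1)
        with pytest.raises(ValueError):
            sp.nb_loglik(1, 1.0, -0.1)


class TestDispersion:
    def _cm(self, rows, samples):
        counts = pd.DataFrame(
            dict(zip(samples, np.asarray(rows, dtype=np.int64).T)),
            index=pd.Index([f"sg{i}" for i in range(len(rows))], name="sgRNA"))
        return sp.CountMatrix.from_samples(counts)

    def test_zero_variance_floors(self):
        cm = self._cm([[100, 100]], ["REP1_DMSO_D2", "REP2_DMSO_D2"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        assert sp.estimate_dispersion(cm, sf).iloc[0] == ALPHA_MIN

    def test_moments_arithmetic(self):
        # [50, 150]: m=100, s2=5000 -> alpha = (5000-100)/100^2 = 0.49
        cm = self._cm([[50, 150]], ["REP1_DMSO_D2", "REP2_DMSO_D2"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        assert sp.estimate_dispersion(cm, sf).iloc[0] == pytest.approx(0.49, rel=1e-12)

    def test_poisson_counts_hit_floor(self):
        rng = np.random.default_rng(0)
        n_sg, n_rep = 300, 100
        rows = rng.poisson(500.0, size=(n_sg, n_rep))
        samples = [f"REP{i+1}_DMSO_D2" for i in range(n_rep)]
        cm = self._cm(rows, samples)
        sf = pd.Series(1.0, index=cm.counts.columns)
        alpha = sp.estimate_dispersion(cm, sf)
        assert (alpha <= ALPHA_MIN + 1e-12).mean() > 0.9

    def test_no_replicates_warns_and_floors(self):
        cm = self._cm([[10, 20]], ["REP1_DMSO_D2", "REP1_DAC_D2"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        with pytest.warns(UserWarning, match="replicate group"):
            alpha = sp.estimate_dispersion(cm, sf)
        assert (alpha == ALPHA_MIN).all()


class TestFitGene:
    def test_single_guide_poisson_log_ratio(self):
        design, samples = _design(1, 1)
        gc = pd.DataFrame([[100, 800]], index=["sg1"], columns=samples)
        fit = sp.fit_gene(gc, design, pd.Series(1.0, index=samples),
                          pd.Series(1e-8, index=["sg1"]))
        assert fit.beta.iloc[0] == pytest.approx(np.log(8), abs=1e-3)
        assert fit.converged

    def test_two_guides_pooled_log_ratio(self):
        design, samples = _design(1, 1)
        gc = pd.DataFrame([[100, 400], [100, 100]], index=["sg1", "sg2"],
                          columns=samples)
        fit = sp.fit_gene(gc, design, pd.Series(1.0, index=samples),
                          pd.Series(1e-8, index=gc.index))
        assert fit.beta.iloc[0] == pytest.approx(np.log(500 / 200), abs=1e-3)

    def test_identity_case(self):
        design, samples = _design(1, 1)
        gc = pd.DataFrame([[123, 123]], index=["sg1"], columns=samples)
        fit = sp.fit_gene(gc, design, pd.Series(1.0, index=samples),
                          pd.Series(0.05, index=["sg1"]))
        assert abs(fit.beta.iloc[0]) < 1e-6

    def test_swap_baseline_condition_negates(self):
        design, samples = _design(1, 1)
        sf = pd.Series(1.0, index=samples)
        disp = pd.Series(1e-8, index=["sg1"])
        gc = pd.DataFrame([[100, 700]], index=["sg1"], columns=samples)
        b1 = sp.fit_gene(gc, design, sf, disp).beta.iloc[0]
        gc2 = pd.DataFrame([[700, 100]], index=["sg1"], columns=samples)
        b2 = sp.fit_gene(gc2, design, sf, disp).beta.iloc[0]
        assert b1 == pytest.approx(-b2, abs=1e-5)

    def test_size_factor_constant_absorbed(self):
        design, samples = _design(2, 2)
        gc = pd.DataFrame([[100, 90, 400, 350], [80, 70, 120, 140]],
                          index=["sg1", "sg2"], columns=samples)
        disp = pd.Series(0.05, index=gc.index)
        sf = pd.Series([1.0, 1.2, 0.8, 1.1], index=samples)
        b1 = sp.fit_gene(gc, design, sf, disp).beta
        b2 = sp.fit_gene(gc, design, sf * 3.7, disp).beta
        assert np.allclose(b1, b2, atol=1e-6)

    def test_all_zero_gene_raises(self):
        design, samples = _design(1, 1)
        gc = pd.DataFrame([[0, 0]], index=["sg1"], columns=samples)
        with pytest.raises(FitError):
            sp.fit_gene(gc, design, pd.Series(1.0, index=samples),
                        pd.Series(0.05, index=["sg1"]))

    def test_matches_grid_oracle(self):
        # random toy instances against the exhaustive-grid oracle
        rng = np.random.default_rng(21)
        for _ in range(8):
            n_i = int(rng.integers(1, 5))
            K = rng.integers(0, 2001, size=(n_i, 4)).astype(float)
            K[K.sum(axis=1) == 0, 0] = 1
            if K[:, 2:].sum() == 0:
                K[0, 2] = 1
            design, samples = _design(2, 2)
            s = rng.uniform(0.5, 2.0, 4)
            alpha = rng.uniform(0.01, 1.0, n_i)
            gc = pd.DataFrame(K, index=[f"sg{i}" for i in range(n_i)],
                              columns=samples)
            fit = sp.fit_gene(gc, design, pd.Series(s, index=samples),
                              pd.Series(alpha, index=gc.index))
            oracle = grid_beta_mle(K, s, np.array([0, 0, 1, 1.0]), alpha)
            assert fit.beta.iloc[0] == pytest.approx(oracle, abs=2e-3)


class TestFitScreen:
    def test_replicates_of_identical_counts_identical_tables(self, small_screen):
        lib, _, _, cm = small_screen
        # duplicate replicate 1 as replicate 2
        rep1 = [n for n in cm.sample_names if n.startswith("REP1_")]
        dup = cm.counts[rep1].copy()
        dup.columns = [n.replace("REP1_", "REP2_") for n in rep1]
        both = pd.concat([cm.counts[rep1], dup], axis=1)
        cm2 = sp.CountMatrix.from_samples(both, genes=cm.genes)
        fits = sp.fit_screen(cm2, lib)
        pd.testing.assert_frame_equal(fits[1].table, fits[2].table)

    def test_recovery_of_planted_effect(self, small_screen):
        lib, truth, cfg, cm = small_screen
        fits = sp.fit_screen(cm, lib)
        diffs = [sp.differential_beta_from_table(fits[r]) for r in fits]
        avg = sp.average_replicates(diffs)
        # truth-model prediction: delta beta ~ e * mean(w) * t / tau
        day = 10
        for gene in truth.effects.index[truth.effects["treatment_effect"] > 0][:3]:
            w = truth.guides.loc[truth.guides["unit"] == gene, "w"].mean()
            pred = 1.0 * w * day / cfg.tau_days
            assert avg.loc[gene, day] == pytest.approx(pred, abs=0.35 * pred + 0.8)
        # planted direction separates cleanly from the bulk
        pos = truth.effects.index[truth.effects["treatment_effect"] > 0]
        neg = truth.effects.index[truth.effects["treatment_effect"] < 0]
        null = truth.effects.index[(truth.effects["treatment_effect"] == 0)
                                   & truth.effects.index.isin(avg.index)]
        assert avg.loc[pos, day].min() > avg.loc[null, day].quantile(0.95)
        assert avg.loc[neg, day].max() < avg.loc[null, day].quantile(0.05)


class TestCellCycleNormalize:
    def _bt(self, betas, conds=("DMSO_D6", "DAC_D6")):
        rows = []
        for (gene, cond), b in betas.items():
            rows.append((gene, cond, b, 1.0, b, True))
        return sp.BetaTable(pd.DataFrame(
            rows, columns=["gene", "condition", "beta", "se", "z", "converged"]))

    def test_scaling_arithmetic(self):
        bt = self._bt({("g1", "DMSO_D6"): 2.0, ("g2", "DMSO_D6"): -2.0,
                       ("g3", "DMSO_D6"): -3.0})
        out = sp.cellcycle_normalize(bt, reference_genes=["g1", "g2"])
        assert out.metadata["kappa"]["DMSO_D6"] == 2.0
        got = out.table.set_index("gene")["beta"]
        assert got["g3"] == pytest.approx(-1.5)

    def test_reference_medians_become_one(self):
        bt = self._bt({("g1", "DMSO_D6"): 1.0, ("g2", "DMSO_D6"): -1.0,
                       ("g1", "DAC_D6"): 2.0, ("g2", "DAC_D6"): -2.0})
        out = sp.cellcycle_normalize(bt)
        for cond in ("DMSO_D6", "DAC_D6"):
            sub = out.table[out.table["condition"] == cond]
            assert sub["beta"].abs().median() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_scale_preserves_ordering(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        bt = self._bt({(g, "DAC_D6"): float(rng.normal()) for g in genes})
        out = sp.cellcycle_normalize(bt)
        a = bt.table.set_index("gene")["beta"].rank()
        b = out.table.set_index("gene")["beta"].rank()
        pd.testing.assert_series_equal(a, b)

    def test_empty_reference_is_error(self):
        bt = self._bt({("g1", "DAC_D6"): 1.0})
        with pytest.raises(ConfigError):
            sp.cellcycle_normalize(bt, reference_genes=[])
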