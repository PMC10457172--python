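"""Wright-Fisher engine limits and gamma-DFE fitting behavior."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from haplosel import dfe
from haplosel.config import GroundTruth, N_REF
from haplosel.sfs import FoldedSFS
from haplosel.simulate import simulate_fsfs_pair
from haplosel.wright_fisher import expected_folded_sfs, neutral_folded_shape


class TestEngine:
    def test_neutral_equilibrium_matches_coalescent(self):
        e = expected_folded_sfs(16, s=0.0)[1:]
        shape = e / e.sum()
        assert np.abs(shape / neutral_folded_shape(16) - 1).max() < 0.01

    def test_weak_selection_converges_to_neutral(self):
        e0 = expected_folded_sfs(16, s=0.0)[1:]
        e_eps = expected_folded_sfs(16, s=-1e-6 / N_REF)[1:]
        assert np.abs(e_eps / e0 - 1).max() < 1e-3

    def test_strong_selection_suppresses_segregation(self):
        neutral = expected_folded_sfs(16, s=0.0)[1:].sum()
        strong = expected_folded_sfs(16, s=-1000.0 / N_REF)[1:].sum()
        assert strong < 0.01 * neutral

    def test_zero_epoch_ignores_n2(self):
        eq = expected_folded_sfs(16, 0.0, 1.0, 0.0)
        assert np.allclose(expected_folded_sfs(16, 0.0, 3.0, 0.0), eq)

    def test_expansion_inflates_rare_classes(self):
        eq = expected_folded_sfs(16, 0.0, 1.0, 0.0)[1:]
        ex = expected_folded_sfs(16, 0.0, 2.0, 100.0)[1:]
        assert ex[0] / ex.sum() > eq[0] / eq.sum()

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            expected_folded_sfs(1)
        with pytest.raises(ValueError):
            expected_folded_sfs(16, n2_ratio=0.0)
        with pytest.raises(ValueError):
            expected_folded_sfs(16, t2=-1.0)


class TestClassProportions:
    def test_exponential_closed_form(self):
        props = dfe.nes_class_proportions((1.0, 1.0 / N_REF), N_REF)
        assert props["0-1"] == pytest.approx(1 - np.exp(-1), abs=1e-9)
        assert props[">100"] == pytest.approx(np.exp(-100), abs=1e-9)

    def test_sum_to_one(self, rng):
        for _ in range(50):
            beta = float(rng.uniform(0.05, 5.0))
            es = float(rng.uniform(1e-4, 10.0))
            props = dfe.nes_class_proportions((beta, es), N_REF)
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in props.values())

    def test_strong_mean_pushes_mass_above_100(self):
        props = dfe.nes_class_proportions((1.0, 1e6 / N_REF), N_REF)
        assert props[">100"] > 0.999

    def test_matches_numerical_integration(self):
        beta, mean = 0.37, 22.0
        props = dfe.nes_class_proportions((beta, mean / N_REF), N_REF)
        rv = gamma_dist(a=beta, scale=mean / beta)
        for lab, (lo, hi) in zip(
            dfe.NES_CLASS_LABELS, [(0, 1), (1, 10), (10, 100), (100, np.inf)]
        ):
            num, _ = integrate.quad(rv.pdf, lo, min(hi, 1e5), limit=200)
            assert props[lab] == pytest.approx(num, abs=1e-6)

    def test_gamma_weights_cover_unit_mass(self):
        grid = dfe.nes_grid(64)
        w = dfe.gamma_weights(0.5, 50.0, grid)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestLikelihood:
    def test_profile_u_closed_form(self):
        seg = np.array([30.0, 10.0, 5.0])
        e = np.array([3.0, 1.0, 0.5])
        u = dfe._profile_u(seg, 1000, e)
        assert u == pytest.approx(45 / (1000 * 4.5))

    def test_scale_invariance_of_profiled_fit(self):
        """Scaling all bins and the site total together leaves the profiled
        influx and the likelihood ordering of parameter points unchanged."""
        seg = np.array([300.0, 120.0, 60.0, 30.0, 20.0, 15.0, 12.0, 6.0])
        e_a = neutral_folded_shape(16)
        e_b = np.linspace(1.0, 0.2, 8)
        for c in (1.0, 7.0):
            u_a = dfe._profile_u(c * seg, int(c * 10000), e_a)
            assert u_a == pytest.approx(dfe._profile_u(seg, 10000, e_a))
            d1 = dfe._loglik(seg, 10000 - int(seg.sum()), e_a,
                             dfe._profile_u(seg, 10000, e_a), 10000)
            d2 = dfe._loglik(seg, 10000 - int(seg.sum()), e_b,
                             dfe._profile_u(seg, 10000, e_b), 10000)
            s1 = dfe._loglik(c * seg, int(c * (10000 - seg.sum())), e_a, u_a,
                             int(c * 10000))
            s2 = dfe._loglik(c * seg, int(c * (10000 - seg.sum())), e_b,
                             dfe._profile_u(c * seg, int(c * 10000), e_b),
                             int(c * 10000))
            assert (d1 > d2) == (s1 > s2)


class TestNeutralFit:
    def test_equilibrium_recovered(self):
        truth = GroundTruth(true_Es=0.0)
        _, f4 = simulate_fsfs_pair(truth, 1000, 100_000, 16, seed=12)
        fit = dfe.fit_neutral(f4)
        assert fit.converged
        assert fit.n2_ratio == pytest.approx(1.0)
        assert fit.t2 == 0.0

    def test_expansion_detected_and_beats_equilibrium(self):
        truth = GroundTruth(true_Es=0.0, true_N2_ratio=2.0, true_t2=100.0)
        _, f4 = simulate_fsfs_pair(truth, 1000, 200_000, 16, seed=5)
        fit = dfe.fit_neutral(f4)
        assert fit.n2_ratio > 1.2
        assert fit.t2 > 0

    def test_no_segregating_sites_flagged(self):
        fit = dfe.fit_neutral(FoldedSFS(n=16, bins=[100] + [0] * 8))
        assert not fit.converged


class TestSelectedFit:
    def test_neutral_data_mass_in_nearly_neutral_class(self):
        truth = GroundTruth(true_Es=0.0)
        f0, f4 = simulate_fsfs_pair(truth, 100_000, 100_000, 16, seed=31)
        g = dfe.fit_selected(f0, dfe.fit_neutral(f4))
        assert g.class_proportions()["0-1"] > 0.95

    def test_same_data_both_classes_looks_neutral(self):
        truth = GroundTruth(true_Es=0.0)
        _, f4 = simulate_fsfs_pair(truth, 1000, 100_000, 16, seed=8)
        dem = dfe.fit_neutral(f4)
        g = dfe.fit_selected(f4, dem)
        assert g.class_proportions()["0-1"] > 0.9

    def test_deterministic_given_inputs(self):
        truth = GroundTruth(true_beta=0.5, true_Es=0.3)
        f0, f4 = simulate_fsfs_pair(truth, 50_000, 50_000, 16, seed=17)
        dem = dfe.fit_neutral(f4)
        a = dfe.fit_selected(f0, dem)
        b = dfe.fit_selected(f0, dem)
        assert a.beta == b.beta and a.es == b.es


class TestRunReplicates:
    def test_table_shape_and_determinism(self):
        truth = GroundTruth(true_beta=0.5, true_Es=0.3)
        pairs = [
            simulate_fsfs_pair(truth, 30_000, 30_000, 16, seed=s)
            for s in range(3)
        ]
        fits_a = dfe.run_replicates(pairs, gene_set="mg")
        fits_b = dfe.run_replicates(pairs, gene_set="mg")
        assert len(fits_a) == 3
        assert (fits_a["beta"] == fits_b["beta"]).all()
        summary = dfe.summarize_replicates(fits_a)
        assert summary.iloc[0]["n_converged"] == 3
        props = [summary.iloc[0][f"p_{k}_mean"] for k in dfe.NES_CLASS_LABELS]
        assert sum(props) == pytest.approx(1.0, abs=1e-9)
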