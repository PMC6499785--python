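"""Sampler law, estimation, goodness of fit, and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from senet.ergm import (DegeneracyError, FitOptions, MultilevelERGM,
                        MultilevelERGMResults, compare_models_mahalanobis)
from senet.statistics import ERGMSpec

from conftest import make_actors, make_network, random_graph, random_multilevel

EDGE = ERGMSpec.from_names("edge_density")


def edge_model(n, p, seed=0):
    rng = np.random.default_rng(seed)
    net = make_network(random_graph(rng, n, p))
    return MultilevelERGM(net, None, EDGE)


def manual_results(model, theta):
    names = model.spec.names
    return MultilevelERGMResults(
        model=model, params=pd.Series(theta, index=names),
        bse=pd.Series(np.ones(len(names)), index=names),
        conv_ratios=pd.Series(np.zeros(len(names)), index=names),
        cov_stats=pd.DataFrame(np.eye(len(names)), index=names, columns=names),
        converged=True, near_singular=False)


class TestSimulate:
    def test_density_half_at_zero_parameters(self):
        model = edge_model(20, 0.3)
        Z, _ = model.simulate([0.0], n_samples=300, seed=1)
        dens = Z[:, 0] / model.n_dyads
        mc_se = dens.std(ddof=1) / np.sqrt(len(dens))
        assert abs(dens.mean() - 0.5) < 3 * max(mc_se, 1e-3)

    def test_density_matches_logit_inverse(self):
        model = edge_model(30, 0.3)
        Z, _ = model.simulate([logit(0.2)], n_samples=300, seed=2)
        dens = Z[:, 0] / model.n_dyads
        mc_se = dens.std(ddof=1) / np.sqrt(len(dens))
        assert abs(dens.mean() - 0.2) < 3 * max(mc_se, 1e-3)

    def test_same_seed_identical_samples(self, rng):
        net = random_multilevel(rng, n=15)
        actors = make_actors(15, rng)
        spec = ERGMSpec.from_names("edge_density,alt_triangle,se_closure")
        model = MultilevelERGM(net, actors, spec)
        theta = [-2.0, 0.2, 0.1]
        Z1, N1 = model.simulate(theta, n_samples=20, seed=99,
                                return_networks=True)
        Z2, N2 = model.simulate(theta, n_samples=20, seed=99,
                                return_networks=True)
        assert np.array_equal(Z1, Z2)
        assert all(np.array_equal(a, b) for a, b in zip(N1, N2))

    def test_nonfinite_theta_rejected(self):
        model = edge_model(10, 0.3)
        with pytest.raises(ValueError, match="non-finite"):
            model.simulate([np.nan], n_samples=1)

    def test_burn_in_thinning_validated(self):
        model = edge_model(10, 0.3)
        with pytest.raises(ValueError, match="burn_in"):
            model.simulate([0.0], n_samples=1, burn_in=0)


class TestEstimate:
    def test_edge_only_recovers_logit_density(self):
        model = edge_model(30, 0.15, seed=4)
        res = model.fit(seed=11, phase3_samples=800)
        p_obs = model.z_obs[0] / model.n_dyads
        assert abs(res.params["edge_density"] - logit(p_obs)) < 0.1
        assert res.converged

    def test_empty_observed_network_degenerate(self):
        net = make_network(np.zeros((10, 10)))
        with pytest.raises(DegeneracyError, match="boundary"):
            MultilevelERGM(net, None, EDGE).fit(seed=0)

    def test_same_seed_reproducible_fit(self):
        model = edge_model(15, 0.25, seed=5)
        opts = dict(phase3_samples=200, subphase_iterations=30)
        r1 = model.fit(seed=7, **opts)
        r2 = model.fit(seed=7, **opts)
        assert (r1.params == r2.params).all()
        assert (r1.conv_ratios == r2.conv_ratios).all()

    def test_trace_and_summary(self):
        model = edge_model(15, 0.25, seed=5)
        res = model.fit(seed=7, phase3_samples=200, subphase_iterations=30)
        assert len(res.trace) == 1 + res.options.subphases
        text = res.summary()
        assert "edge_density" in text and "converged" in text


class TestGof:
    def test_modeled_statistics_consistent_at_truth(self):
        """Networks simulated from the model fit it: small modeled t-ratios."""
        model = edge_model(25, 0.2, seed=6)
        Z, nets = model.simulate([logit(0.2)], n_samples=1, seed=3,
                                 return_networks=True)
        obs_model = MultilevelERGM(make_network(nets[0]), None, EDGE)
        res = manual_results(obs_model, [logit(0.2)])
        report = res.gof(n_sim=300, seed=8)
        assert abs(report.t_ratios[0]) < 3  # edge stat drawn from same law

    def test_auxiliary_adequacy_rate_under_self_simulation(self):
        """Aux |t| < 2 holds at roughly the nominal rate when the model
        simulated its own data."""
        model = edge_model(25, 0.2, seed=6)
        theta = [logit(0.2)]
        checks = []
        for rep in range(15):
            _, nets = model.simulate(theta, n_samples=1, seed=100 + rep,
                                     return_networks=True)
            obs_model = MultilevelERGM(make_network(nets[0]), None, EDGE)
            report = manual_results(obs_model, theta).gof(n_sim=120,
                                                          seed=200 + rep)
            checks.extend(abs(t) < 2 for t in report.t_ratios[1:]
                          if np.isfinite(t))
        assert np.mean(checks) >= 0.85

    def test_constant_statistic_flagged_undefined(self, rng):
        # X is all-zero, so the closure statistic is constant at 0
        net = make_network(random_graph(rng, 12, 0.3),
                           X=np.zeros((12, 3), dtype=np.int8))
        spec = ERGMSpec.from_names("edge_density,se_closure")
        model = MultilevelERGM(net, None, spec)
        res = manual_results(model, [-1.0, 0.0])
        report = res.gof(n_sim=50, seed=1)
        k = report.names.index("se_closure")
        assert np.isnan(report.t_ratios[k])
        assert np.isfinite(report.mahalanobis)

    def test_identical_reports_tie(self):
        model = edge_model(15, 0.25)
        res = manual_results(model, [-1.0])
        rep = res.gof(n_sim=50, seed=5)
        cmp = compare_models_mahalanobis(rep, rep)
        assert cmp.tie

    def test_mismatched_aux_sets_rejected(self):
        model = edge_model(15, 0.25)
        res = manual_results(model, [-1.0])
        r1 = res.gof(n_sim=30, seed=5)
        r2 = res.gof(aux_stats=("degree_sd",), n_sim=30, seed=5)
        with pytest.raises(ValueError, match="auxiliary"):
            compare_models_mahalanobis(r1, r2)

    def test_closure_model_preferred_on_closure_data(self, rng):
        """With a true cross-level closure effect, the with-closure model
        wins the Mahalanobis comparison in a majority of replicates."""
        n, m = 40, 8
        X = (rng.random((n, m)) < 0.35).astype(np.int8)
        net0 = make_network(np.zeros((n, n)), X=X)
        spec_with = ERGMSpec.from_names("edge_density,se_closure")
        spec_without = ERGMSpec.from_names("edge_density")
        gen = MultilevelERGM(net0, None, spec_with)
        wins = 0
        reps = 5
        for rep in range(reps):
            _, nets = gen.simulate([-3.5, 0.6], n_samples=1, seed=50 + rep,
                                   return_networks=True)
            obs = make_network(nets[0], X=X)
            fit_w = MultilevelERGM(obs, None, spec_with).fit(
                seed=rep, phase3_samples=300, subphase_iterations=50)
            fit_wo = MultilevelERGM(obs, None, spec_without).fit(
                seed=rep, phase3_samples=300, subphase_iterations=50)
            cmp = compare_models_mahalanobis(
                fit_w.gof(n_sim=150, seed=70 + rep),
                fit_wo.gof(n_sim=150, seed=70 + rep))
            wins += cmp.preferred == "with"
        assert wins > reps / 2


class TestResidualScreen:
    def _site_net(self, rng, boost_site=None):
        n = 40
        actors = make_actors(n, rng, sites=("a", "b", "c"))
        sites = actors["landing_site"].to_numpy()
        P = np.full((n, n), 0.06)
        if boost_site is not None:
            members = sites == boost_site
            P[np.ix_(members, members)] = 0.5
            P[np.ix_(members, ~members)] = 0.25
            P[np.ix_(~members, members)] = 0.25
        A = (rng.random((n, n)) < P).astype(np.int8)
        A = np.triu(A, 1)
        net = make_network(A + A.T)
        return net, actors

    def test_hyperactive_site_flagged(self, rng):
        net, actors = self._site_net(rng, boost_site="a")
        model = MultilevelERGM(net, actors, EDGE)
        res = model.fit(seed=3, phase3_samples=300, subphase_iterations=40)
        flagged = res.residual_site_activity_screen(n_sim=150, seed=9)
        assert "a" in flagged

    def test_homogeneous_network_unflagged(self, rng):
        net, actors = self._site_net(rng)
        model = MultilevelERGM(net, actors, EDGE)
        res = model.fit(seed=3, phase3_samples=300, subphase_iterations=40)
        assert res.residual_site_activity_screen(n_sim=150, seed=9) == []

    def test_single_site_community_empty(self, rng):
        net, actors = self._site_net(rng)
        actors["landing_site"] = "only"
        model = MultilevelERGM(net, actors, EDGE)
        res = manual_results(model, [-2.0])
        assert res.residual_site_activity_screen(n_sim=30, seed=1) == []
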