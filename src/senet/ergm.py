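"""Multilevel ERGM: simulation, Robbins-Monro MCMC-MLE, GOF, model comparison.

Only social ties are random; the cross-level incidence and the trophic web
are exogenous.  Estimation solves the method-of-moments condition
``E_theta[z] = z_obs`` (the maximum-likelihood condition for this
exponential family) by three-phase Robbins-Monro stochastic approximation:

* phase 1 — a short simulation at the initial parameters scales the
  updates by the statistic variances;
* phase 2 — subphases of stochastic updates
  ``theta <- theta - a * D^{-1} (z_sim - z_obs)`` with the gain ``a``
  halved per subphase and iterate averaging at the end of each;
* phase 3 — a long run at the final parameters yields convergence
  t-ratios ``(mean z_sim - z_obs)/sd(z_sim)``, the simulated statistic
  covariance ``Sigma_z`` (the Fisher information of an exponential family),
  and standard errors ``sqrt(diag(Sigma_z^{-1}))``.

A fit is flagged converged when every |t-ratio| < 0.1; goodness of fit
labels auxiliary statistics adequate at |t| < 2 (both conventional
thresholds for this estimation style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _engine
from .network import MultilevelNetwork
from .statistics import ERGMSpec, EncodedModel, encode_model, statistics_from_adjacency

__all__ = [
    "MultilevelERGM",
    "MultilevelERGMResults",
    "FitOptions",
    "GofReport",
    "ModelComparison",
    "DegeneracyError",
    "simulate_networks",
    "estimate",
    "goodness_of_fit",
    "compare_models_mahalanobis",
    "residual_site_activity_screen",
    "AUX_STATS",
]

_SE_RCOND = 1e-10


class DegeneracyError(RuntimeError):
    """The sampler collapsed to an empty/complete graph or a statistic sat
    at its extreme bound; carries the estimation trace for diagnosis."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


def _degree_sd(A: np.ndarray) -> float:
    d = A.sum(axis=1)
    return float(d.std(ddof=0))


def _transitivity(A: np.ndarray) -> float:
    Af = A.astype(np.float64)
    d = Af.sum(axis=1)
    triples = (d * (d - 1)).sum()
    if triples == 0:
        return 0.0
    closed = np.trace(Af @ Af @ Af)
    return float(closed / triples)


def _isolates(A: np.ndarray) -> float:
    return float((A.sum(axis=1) == 0).sum())


#: Auxiliary (non-modeled) statistics used for goodness of fit.
AUX_STATS = {
    "degree_sd": _degree_sd,
    "global_clustering": _transitivity,
    "isolates": _isolates,
}


@dataclass
class FitOptions:
    """Robbins-Monro tuning knobs (all sizes in samples or proposal steps).

    Defaults follow common stochastic-approximation practice for ERGMs:
    five gain-halving subphases starting at gain 0.1, iterate averaging,
    and a phase-3 run long enough to measure convergence t-ratios.
    ``None`` values are resolved against the network size at fit time
    (thinning defaults to the number of dyads).
    """

    gain: float = 0.1
    subphases: int = 5
    subphase_iterations: int = 100     # doubled each subphase
    phase2_steps: int | None = None    # chain proposals per theta update
    phase1_samples: int = 100
    phase3_samples: int = 1000
    burn_in: int | None = None
    thinning: int | None = None
    max_step: float = 0.5              # per-component theta update clamp
    conv_tol: float = 0.1


@dataclass
class GofReport:
    """Simulation-based goodness of fit at fitted parameters.

    ``t_ratios`` are (observed - simulated mean)/simulated sd per statistic
    (NaN where the simulated sd is zero); ``mahalanobis`` is the distance of
    the observed statistic vector under the simulated covariance
    (pseudo-inverse when near-singular).
    """

    names: list[str]
    observed: np.ndarray
    mean_sim: np.ndarray
    sd_sim: np.ndarray
    t_ratios: np.ndarray
    mahalanobis: float
    n_sim: int
    seed: int | None = None
    aux_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed": self.observed, "mean_sim": self.mean_sim,
            "sd_sim": self.sd_sim, "t_ratio": self.t_ratios,
            "adequate": np.abs(self.t_ratios) < 2,
        }, index=self.names)

    def plot(self, ax=None):
        """Bar chart of GOF t-ratios with the |t| = 2 adequacy band."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.names) + 2, 3.5))
        ax.bar(self.names, self.t_ratios, color="steelblue")
        ax.axhline(2, ls="--", c="grey")
        ax.axhline(-2, ls="--", c="grey")
        ax.set_ylabel("GOF t-ratio")
        ax.tick_params(axis="x", rotation=45)
        return ax

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "observed": self.observed.tolist(),
            "mean_sim": self.mean_sim.tolist(),
            "sd_sim": self.sd_sim.tolist(),
            "t_ratios": [None if not np.isfinite(t) else float(t)
                         for t in self.t_ratios],
            "mahalanobis": float(self.mahalanobis),
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


@dataclass
class ModelComparison:
    distance_with: float
    distance_without: float
    preferred: str  # "with" | "without" | "tie"

    @property
    def tie(self) -> bool:
        return self.preferred == "tie"


class MultilevelERGM:
    """Exponential random graph model over the social level of a
    multilevel network, with exogenous cross-level and ecological ties.

    Parameters
    ----------
    network
        Observed :class:`~senet.network.MultilevelNetwork`; only ``A`` is
        modeled, ``X`` enters through the cross-level closure statistic.
    actors
        Actor attribute table aligned with the network's actor registry
        (needed for attribute-bound statistics).
    spec
        :class:`~senet.statistics.ERGMSpec` listing the model statistics.
    """

    def __init__(self, network: MultilevelNetwork,
                 actors: pd.DataFrame | None = None,
                 spec: ERGMSpec | None = None):
        if spec is None:
            spec = ERGMSpec.from_names("edge_density")
        self.network = network
        self.actors = actors
        self.spec = spec
        self.encoded: EncodedModel = encode_model(network, actors, spec)
        self.n = network.n_actors
        self.n_dyads = self.n * (self.n - 1) // 2
        self.z_obs = statistics_from_adjacency(network.A, self.encoded)

    # -- simulation --------------------------------------------------------

    def simulate(self, theta, n_samples: int = 100, burn_in: int | None = None,
                 thinning: int | None = None, seed: int | None = None,
                 start: np.ndarray | None = None, return_networks: bool = False):
        """Draw thinned MH samples of the social network at ``theta``.

        Returns ``(Z, nets)`` where ``Z`` is the ``(n_samples, p)`` statistic
        matrix and ``nets`` a list of adjacency matrices (empty unless
        ``return_networks``).
        """
        theta = np.asarray(theta, dtype=np.float64)
        if not np.all(np.isfinite(theta)):
            raise ValueError(f"non-finite parameters: {theta}")
        if theta.shape != (len(self.spec),):
            raise ValueError("theta length does not match spec")
        burn_in = 10 * self.n_dyads if burn_in is None else int(burn_in)
        thinning = self.n_dyads if thinning is None else int(thinning)
        if burn_in < 1 or thinning < 1:
            raise ValueError("burn_in and thinning must be >= 1")
        if seed is not None:
            _engine.seed(int(seed) % (2 ** 31))
        A = (self.network.A.copy() if start is None
             else np.asarray(start, dtype=np.int8).copy())
        deg = A.sum(axis=1).astype(np.int64)
        z = statistics_from_adjacency(A, self.encoded)
        e = self.encoded
        _engine.run_chain(A, deg, theta, e.kinds, e.lams, e.asite,
                          e.leader, e.site, e.m, burn_in, z)
        Z = np.empty((n_samples, len(self.spec)), dtype=np.float64)
        nets: list[np.ndarray] = []
        for s in range(n_samples):
            _engine.run_chain(A, deg, theta, e.kinds, e.lams, e.asite,
                              e.leader, e.site, e.m, thinning, z)
            Z[s] = z
            if return_networks:
                nets.append(A.copy())
        return Z, nets

    # -- estimation --------------------------------------------------------

    def _theta0(self) -> np.ndarray:
        theta = np.zeros(len(self.spec))
        try:
            k = self.spec.index("edge_density")
        except KeyError:
            return theta
        dens = self.z_obs[k] / self.n_dyads
        dens = min(max(dens, 1.0 / (self.n_dyads + 1)), 1 - 1.0 / (self.n_dyads + 1))
        theta[k] = np.log(dens / (1 - dens))
        return theta

    def fit(self, seed: int | None = None,
            options: FitOptions | None = None, **kwargs) -> "MultilevelERGMResults":
        """Robbins-Monro method-of-moments fit (the MCMC-MLE).

        Raises :class:`DegeneracyError` when the observed statistics sit at
        an extreme bound or the chain collapses during estimation.
        """
        opts = options or FitOptions(**kwargs)
        edges_obs = int(self.network.A.sum()) // 2
        if edges_obs == 0 or edges_obs == self.n_dyads:
            raise DegeneracyError(
                f"observed network at boundary (edges={edges_obs} of "
                f"{self.n_dyads}); statistics are at their extreme bound")
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        chain_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        _engine.seed(chain_seed)

        e = self.encoded
        burn_in = 10 * self.n_dyads if opts.burn_in is None else opts.burn_in
        thinning = self.n_dyads if opts.thinning is None else opts.thinning
        phase2_steps = (max(2 * self.n, self.n_dyads // 4)
                        if opts.phase2_steps is None else opts.phase2_steps)
        p = len(self.spec)
        theta = self._theta0()
        A = self.network.A.copy()
        deg = A.sum(axis=1).astype(np.int64)
        z = self.z_obs.copy()

        def advance(steps: int) -> None:
            _engine.run_chain(A, deg, theta, e.kinds, e.lams, e.asite,
                              e.leader, e.site, e.m, steps, z)

        # phase 1: scale factors from short-run statistic variances
        advance(burn_in)
        Z1 = np.empty((opts.phase1_samples, p))
        thin1 = max(self.n, thinning // 5)
        for s in range(opts.phase1_samples):
            advance(thin1)
            Z1[s] = z
        D = Z1.var(axis=0, ddof=1)
        D = np.maximum(D, 1e-8 * max(D.max(), 1.0))

        trace: list[np.ndarray] = [theta.copy()]
        # phase 2: gain-halved stochastic updates with iterate averaging
        for r in range(opts.subphases):
            a = opts.gain / (2 ** r)
            iters = opts.subphase_iterations * (2 ** r)
            thetas = np.empty((iters, p))
            for it in range(iters):
                advance(phase2_steps)
                step = a * (z - self.z_obs) / D
                step = np.clip(step, -opts.max_step, opts.max_step)
                theta = theta - step
                thetas[it] = theta
            theta = thetas[iters // 2:].mean(axis=0)
            trace.append(theta.copy())
            edges_now = int(A.sum()) // 2
            if edges_now == 0 or edges_now == self.n_dyads:
                raise DegeneracyError(
                    f"chain collapsed to {'empty' if edges_now == 0 else 'complete'} "
                    f"graph in subphase {r + 1}", trace)

        # phase 3: convergence diagnostics and standard errors
        advance(burn_in)
        Z3 = np.empty((opts.phase3_samples, p))
        for s in range(opts.phase3_samples):
            advance(thinning)
            Z3[s] = z
        mean3 = Z3.mean(axis=0)
        sd3 = Z3.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ratios = (mean3 - self.z_obs) / sd3
        t_ratios = np.where(sd3 > 0, t_ratios,
                            np.where(mean3 == self.z_obs, 0.0, np.inf))
        cov = np.cov(Z3, rowvar=False).reshape(p, p)
        near_singular = False
        try:
            info_inv = np.linalg.inv(cov)
            if np.linalg.cond(cov) > 1 / _SE_RCOND:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(cov, rcond=_SE_RCOND)
            near_singular = True
            warnings.warn("simulated statistic covariance near-singular; "
                          "standard errors use a pseudo-inverse")
        se = np.sqrt(np.abs(np.diag(info_inv)))
        converged = bool(np.max(np.abs(t_ratios)) < opts.conv_tol)
        return MultilevelERGMResults(
            model=self, params=pd.Series(theta, index=self.spec.names),
            bse=pd.Series(se, index=self.spec.names),
            conv_ratios=pd.Series(t_ratios, index=self.spec.names),
            cov_stats=pd.DataFrame(cov, index=self.spec.names,
                                   columns=self.spec.names),
            converged=converged, near_singular=near_singular,
            trace=trace, seed=seed, options=opts)


@dataclass
class MultilevelERGMResults:
    """Parameter estimates with uncertainties and convergence diagnostics."""

    model: MultilevelERGM
    params: pd.Series
    bse: pd.Series
    conv_ratios: pd.Series
    cov_stats: pd.DataFrame
    converged: bool
    near_singular: bool
    trace: list = field(default_factory=list)
    seed: int | None = None
    options: FitOptions | None = None

    @property
    def tvalues(self) -> pd.Series:
        """Wald z = estimate / SE per parameter."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * sps.norm.sf(np.abs(self.tvalues.to_numpy())),
                         index=self.params.index)

    def significant(self, factor: float = 2.0) -> pd.Series:
        """Wald significance rule |estimate| > factor * SE."""
        return self.params.abs() > factor * self.bse

    def summary(self) -> str:
        lines = [
            "Multilevel ERGM (Robbins-Monro MCMC-MLE)",
            f"  actors: {self.model.n}   dyads: {self.model.n_dyads}   "
            f"converged: {self.converged}",
            f"{'statistic':<22}{'estimate':>10}{'SE':>9}{'conv t':>9}  sig",
        ]
        sig = self.significant()
        for name in self.params.index:
            star = "*" if sig[name] else ""
            lines.append(f"{name:<22}{self.params[name]:>10.3f}"
                         f"{self.bse[name]:>9.3f}"
                         f"{self.conv_ratios[name]:>9.3f}  {star}")
        lines.append("  * |estimate| > 2 SE (Wald P < 0.05)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": self.model.spec.names,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "conv_ratios": {k: (None if not np.isfinite(v) else float(v))
                            for k, v in self.conv_ratios.items()},
            "converged": self.converged,
            "near_singular": self.near_singular,
            "seed": self.seed,
        }

    # -- goodness of fit ---------------------------------------------------

    def gof(self, aux_stats: tuple[str, ...] = ("degree_sd", "global_clustering",
                                                "isolates"),
            n_sim: int = 200, seed: int | None = None) -> GofReport:
        """Simulate at the fitted parameters and compare modeled plus
        auxiliary statistics with the observation."""
        for a in aux_stats:
            if a not in AUX_STATS:
                raise KeyError(f"unknown auxiliary statistic {a!r}")
        Z, nets = self.model.simulate(self.params.to_numpy(), n_samples=n_sim,
                                      seed=seed, return_networks=True)
        aux_sim = np.array([[AUX_STATS[a](A) for a in aux_stats] for A in nets])
        S = np.hstack([Z, aux_sim])
        obs_aux = np.array([AUX_STATS[a](self.model.network.A) for a in aux_stats])
        obs = np.concatenate([self.model.z_obs, obs_aux])
        names = self.model.spec.names + list(aux_stats)
        mean = S.mean(axis=0)
        sd = S.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, (obs - mean) / sd, np.nan)
        diff = obs - mean
        cov = np.cov(S, rowvar=False).reshape(len(names), len(names))
        maha = float(np.sqrt(max(diff @ np.linalg.pinv(cov, rcond=_SE_RCOND) @ diff,
                                 0.0)))
        return GofReport(names, obs, mean, sd, t, maha, n_sim, seed,
                         aux_names=list(aux_stats))

    def residual_site_activity_screen(self, n_sim: int = 200,
                                      seed: int | None = None,
                                      threshold: float = 2.0) -> list[str]:
        """Landing sites whose tie activity exceeds the model's expectation.

        For each landing site ``a`` present among the actors, the activity
        statistic (sum of degrees over that site's actors) is compared with
        its simulated distribution under this fit; sites with GOF t-ratio
        above ``threshold`` are returned for inclusion as controls.  Sites
        covering all actors are skipped (the statistic degenerates to twice
        the edge count).
        """
        enc = self.model.encoded
        if not enc.site_categories:
            return []
        _, nets = self.model.simulate(self.params.to_numpy(), n_samples=n_sim,
                                      seed=seed, return_networks=True)
        flagged = []
        for code, label in enumerate(enc.site_categories):
            members = enc.site == code
            if members.all() or not members.any():
                continue
            obs = float(self.model.network.A.sum(axis=1)[members].sum())
            sims = np.array([float(A.sum(axis=1)[members].sum()) for A in nets])
            sd = sims.std(ddof=1)
            if sd == 0:
                continue
            if (obs - sims.mean()) / sd > threshold:
                flagged.append(label)
        return flagged


# ---------------------------------------------------------------------------
# Functional wrappers mirroring the operation-style surface
# ---------------------------------------------------------------------------

def simulate_networks(net0: MultilevelNetwork, actors, spec: ERGMSpec, theta,
                      n_samples: int, burn_in: int | None = None,
                      thinning: int | None = None, seed: int | None = None,
                      return_networks: bool = True):
    model = MultilevelERGM(net0, actors, spec)
    return model.simulate(theta, n_samples=n_samples, burn_in=burn_in,
                          thinning=thinning, seed=seed,
                          return_networks=return_networks)


def estimate(net_obs: MultilevelNetwork, actors, spec: ERGMSpec,
             seed: int | None = None,
             options: FitOptions | None = None, **kwargs) -> MultilevelERGMResults:
    return MultilevelERGM(net_obs, actors, spec).fit(seed=seed, options=options,
                                                     **kwargs)


def goodness_of_fit(fit: MultilevelERGMResults,
                    aux_stats: tuple[str, ...] = ("degree_sd",
                                                  "global_clustering",
                                                  "isolates"),
                    n_sim: int = 200, seed: int | None = None) -> GofReport:
    return fit.gof(aux_stats=aux_stats, n_sim=n_sim, seed=seed)


def residual_site_activity_screen(fit: MultilevelERGMResults, n_sim: int = 200,
                                  seed: int | None = None) -> list[str]:
    return fit.residual_site_activity_screen(n_sim=n_sim, seed=seed)


def compare_models_mahalanobis(report_with: GofReport,
                               report_without: GofReport) -> ModelComparison:
    """Prefer the model whose observed statistics lie closer (Mahalanobis)
    to its simulated distribution; statistic sets must be comparable."""
    if report_with.aux_names != report_without.aux_names:
        raise ValueError("goodness-of-fit reports use different auxiliary "
                         "statistic sets")
    shared_with = [n for n in report_with.names if n in report_without.names]
    shared_without = [n for n in report_without.names if n in report_with.names]
    if not shared_with or shared_with != shared_without:
        raise ValueError("goodness-of-fit reports have mismatched statistic sets")
    dw, dwo = report_with.mahalanobis, report_without.mahalanobis
    if np.isclose(dw, dwo, rtol=0, atol=1e-12):
        preferred = "tie"
    else:
        preferred = "with" if dw < dwo else "without"
    return ModelComparison(dw, dwo, preferred)
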