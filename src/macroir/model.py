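"""Model/Results front-end tying the likelihood engine to the sampler.

``IntervalCurrentModel`` owns the data (a segmented trace), a kinetic
scheme, the prior, and the likelihood method; ``fit()`` runs the
parallel-tempering ensemble sampler and returns an
``IntervalCurrentResults`` carrying posterior draws, evidence,
diagnostics and the posterior analyses.

Example
-------
>>> model = IntervalCurrentModel(trace, scheme, prior, obs_base, method="macroir")
>>> res = model.fit(n_rungs=8, n_walkers=16, n_steps=400, seed=1)
>>> res.summary()          # doctest: +SKIP
>>> res.log_evidence       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .infer import (
    EvidenceEstimate,
    PriorSpec,
    PTResult,
    PTSettings,
    convergence_diagnostics,
    relabel_symmetry,
    run_pt_mcmc,
)
from .kinetics import KineticScheme
from .likelihood import macroinr_loglik, macroir_loglik
from .segmentation import Protocol, SegmentedTrace
from .simulate import ObservationParams

__all__ = ["IntervalCurrentModel", "IntervalCurrentResults"]

_OBS_FIELDS = tuple(ObservationParams.__dataclass_fields__)


class IntervalCurrentModel:
    """Bayesian model of a time-averaged macroscopic current trace.

    Parameters named in ``prior`` are sampled; names matching fields of the
    kinetic scheme update the scheme, names matching observation fields
    (gamma, R_gamma, rho_leak, i0, N_ch, k_inact, eps2, nu2) update the
    measurement layer; everything else in ``obs_base`` stays fixed.
    ``method`` selects the recursive interval likelihood (``"macroir"``)
    or the non-recursive midpoint control (``"macroinr"``).
    """

    def __init__(
        self,
        trace: SegmentedTrace,
        scheme: KineticScheme,
        prior: PriorSpec,
        obs_base: ObservationParams,
        method: str = "macroir",
        target_qdelta: float = 0.05,
    ) -> None:
        if method not in ("macroir", "macroinr"):
            raise ValueError("method must be 'macroir' or 'macroinr'")
        self.trace = trace
        self.scheme = scheme
        self.prior = prior
        self.obs_base = obs_base
        self.method = method
        self.target_qdelta = target_qdelta
        scheme_keys = set(scheme.params)
        self._scheme_names = [n for n in prior.names if n in scheme_keys]
        self._obs_names = [n for n in prior.names if n in _OBS_FIELDS]
        unknown = set(prior.names) - set(self._scheme_names) - set(self._obs_names)
        if unknown:
            raise ValueError(f"prior parameter(s) {sorted(unknown)} match neither "
                             "scheme parameters nor observation fields")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        scheme: KineticScheme,
        prior: PriorSpec,
        obs_base: ObservationParams,
        **kwargs,
    ) -> "IntervalCurrentModel":
        """Construct from a segmented-trace table (t0_s, width_s, y_avg_pA, conc_uM)."""
        return cls(SegmentedTrace.from_frame(df), scheme, prior, obs_base, **kwargs)

    # ---------------------------------------------------------------- mapping
    def _bind(self, natural: dict[str, np.ndarray]):
        scheme = self.scheme
        if self._scheme_names:
            scheme = scheme.with_params({n: natural[n] for n in self._scheme_names})
        obs = self.obs_base
        if self._obs_names:
            obs = replace(obs, **{n: natural[n] for n in self._obs_names})
        return scheme, obs

    def loglike(self, params) -> float | np.ndarray:
        """Log-likelihood at natural-scale parameters (dict or vector in
        prior order); vectors may be stacked into an (M, d) batch."""
        if isinstance(params, dict):
            natural = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        else:
            arr = np.atleast_2d(np.asarray(params, dtype=float))
            natural = {n: arr[:, j] for j, n in enumerate(self.prior.names)}
        scheme, obs = self._bind(natural)
        fn = macroir_loglik if self.method == "macroir" else macroinr_loglik
        kwargs = {"target_qdelta": self.target_qdelta} if self.method == "macroir" else {}
        out = fn(self.trace, scheme, obs, **kwargs)
        out = np.atleast_1d(out)
        return float(out[0]) if out.size == 1 else out

    def _loglik_z(self, Z: np.ndarray) -> np.ndarray:
        natural = self.prior.to_natural(np.atleast_2d(Z))
        scheme, obs = self._bind(natural)
        fn = macroir_loglik if self.method == "macroir" else macroinr_loglik
        kwargs = {"target_qdelta": self.target_qdelta} if self.method == "macroir" else {}
        out = np.atleast_1d(fn(self.trace, scheme, obs, **kwargs))
        out[~np.isfinite(out)] = -np.inf
        return out

    # ---------------------------------------------------------------- fitting
    def fit(
        self,
        n_rungs: int = 8,
        n_walkers: int | None = None,
        n_steps: int = 500,
        n_burn: int | None = None,
        thin: int = 1,
        seed: int = 0,
        checkpoint: str | None = None,
        **kwargs,
    ) -> "IntervalCurrentResults":
        d = self.prior.dim
        settings = PTSettings(
            n_rungs=n_rungs,
            n_walkers=n_walkers if n_walkers is not None else max(2 * d, 10),
            n_steps=n_steps,
            n_burn=n_burn if n_burn is not None else n_steps // 2,
            thin=thin,
            seed=seed,
            checkpoint=checkpoint,
            **kwargs,
        )
        pt = run_pt_mcmc(self._loglik_z, self.prior, settings, vectorized=True)
        return IntervalCurrentResults(self, pt)


class IntervalCurrentResults:
    """Posterior draws, evidence and diagnostics of a fitted model."""

    def __init__(self, model: IntervalCurrentModel, pt: PTResult) -> None:
        self.model = model
        self.pt = pt
        self._evidence: EvidenceEstimate | None = None

    # ---------------------------------------------------------------- access
    @property
    def posterior(self) -> pd.DataFrame:
        """Flattened posterior draws (beta = 1 rung) on the natural scale."""
        return self.pt.posterior_samples(self.model.prior)

    @property
    def log_evidence(self) -> EvidenceEstimate:
        if self._evidence is None:
            self._evidence = self.pt.evidence()
        return self._evidence

    def diagnostics(self, demix: bool = False) -> pd.DataFrame:
        """Per-parameter split-R-hat, ESS and posterior concentration factor."""
        chains = np.transpose(self.pt.chains[-1], (1, 0, 2))  # walkers as chains
        return convergence_diagnostics(chains, self.model.prior, demix=demix)

    def relabeled_posterior(self) -> pd.DataFrame:
        """Posterior with the A/B coupling label-switching resolved."""
        return relabel_symmetry(self.posterior)

    # ---------------------------------------------------------------- summary
    def summary(self, demix: bool = False) -> pd.DataFrame:
        post = self.relabeled_posterior() if demix else self.posterior
        diag = self.diagnostics(demix=demix)
        rows = []
        for name in self.model.prior.names:
            x = post[name].to_numpy()
            rows.append(
                {
                    "parameter": name,
                    "median": np.median(x),
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "q05": np.quantile(x, 0.05),
                    "q95": np.quantile(x, 0.95),
                    "rhat": diag.loc[name, "rhat"],
                    "ess": diag.loc[name, "ess"],
                    "pcf": diag.loc[name, "pcf"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # ---------------------------------------------------------------- science
    def conductance_fractions(self) -> pd.DataFrame:
        from .analyze import conductance_fractions

        post = self.posterior
        for col, fallback in (("R_gamma", self.model.obs_base.R_gamma),
                              ("rho_leak", self.model.obs_base.rho_leak)):
            if col not in post.columns:
                post[col] = fallback
        return conductance_fractions(post)

    def coupling_report(self, tau0: float = 1e-6, **kwargs) -> pd.DataFrame:
        from .analyze import coupling_report

        return coupling_report(self.relabeled_posterior(), tau0=tau0, **kwargs)

    def variance_partition(self) -> pd.DataFrame:
        from .analyze import variance_partition

        med = {n: float(np.median(self.posterior[n])) for n in self.model.prior.names}
        scheme, obs = self.model._bind({k: np.asarray(v) for k, v in med.items()})
        return variance_partition(self.model.trace, scheme, obs)

    def posterior_predictive(
        self, protocol: Protocol, n_rep: int = 20, seed: int = 0
    ):
        from .analyze import posterior_predictive_trace

        return posterior_predictive_trace(
            self.posterior, self.model.scheme, protocol, n_rep, seed,
            obs_base=self.model.obs_base,
        )
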