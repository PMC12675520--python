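"""Priors, affine-invariant parallel-tempering MCMC, thermodynamic
integration, and convergence / identifiability diagnostics.

The sampler runs an ensemble of stretch-move walkers on every rung of an
inverse-temperature ladder (geometric betas plus beta = 0, whose rung
samples the prior), with adjacent-rung walker swaps every sweep.  The
log-evidence is the thermodynamic integral of the per-rung mean
log-likelihood over beta, with an autocorrelation-aware standard error
computed on the per-sweep quadrature series.

Log-likelihood callables may be *vectorised*: ``loglik_fn(Theta)`` with
``Theta`` of shape (M, d) returning (M,).  All proposals of a half-sweep
across every rung are then scored in a single call, which is what makes
moment-recursion likelihoods affordable inside the ensemble sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PriorParam",
    "PriorSpec",
    "PTSettings",
    "TemperedEnsemble",
    "EvidenceEstimate",
    "PTResult",
    "stretch_step",
    "pt_swap_step",
    "run_pt_mcmc",
    "thermo_evidence",
    "relabel_symmetry",
    "convergence_diagnostics",
    "geometric_ladder",
]

_COUPLING_TRIPLETS = (("RB", "BR"), ("RB_bon", "BR_bon"), ("RB_ron", "BR_ron"))


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorParam:
    """One parameter's prior: a (truncated) normal on the sampling scale.

    ``transform='log'`` samples ``ln(x)`` (natural log), appropriate for
    rates and multiplicative coupling factors; ``'identity'`` samples the
    raw value.  ``loc``/``scale`` and the hard bounds are given on the
    *natural* scale and converted internally.
    """

    name: str
    loc: float
    scale: float
    transform: str = "log"
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.transform not in ("log", "identity"):
            raise ValueError("transform must be 'log' or 'identity'")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.transform == "log" and self.loc <= 0:
            raise ValueError("log-transformed parameters need a positive loc")

    # sampling-scale representation
    @property
    def z_loc(self) -> float:
        return np.log(self.loc) if self.transform == "log" else self.loc

    @property
    def z_scale(self) -> float:
        return self.scale

    @property
    def z_lower(self) -> float:
        if self.transform == "log":
            # lower <= 0 (incl. the -inf default) is unbounded on the log scale
            return -np.inf if self.lower <= 0 else np.log(self.lower)
        return self.lower

    @property
    def z_upper(self) -> float:
        if self.transform == "log":
            return np.inf if np.isinf(self.upper) else np.log(self.upper)
        return self.upper

    def _dist(self):
        a = (self.z_lower - self.z_loc) / self.z_scale
        b = (self.z_upper - self.z_loc) / self.z_scale
        return stats.truncnorm(a, b, loc=self.z_loc, scale=self.z_scale)

    def to_natural(self, z):
        return np.exp(z) if self.transform == "log" else z

    def from_natural(self, x):
        return np.log(x) if self.transform == "log" else x


@dataclass
class PriorSpec:
    """An ordered collection of :class:`PriorParam`; the parameter vector
    sampled by MCMC lives on the concatenated sampling scales."""

    params: list[PriorParam]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in prior")
        # cached sampling-scale arrays for fast vectorised density/sampling
        self._locs = np.array([p.z_loc for p in self.params])
        self._scales = np.array([p.z_scale for p in self.params])
        self._los = np.array([p.z_lower for p in self.params])
        self._his = np.array([p.z_upper for p in self.params])
        a = (self._los - self._locs) / self._scales
        b = (self._his - self._locs) / self._scales
        self._cdf_lo = stats.norm.cdf(a)
        self._cdf_hi = stats.norm.cdf(b)
        self._log_trunc = np.log(self._cdf_hi - self._cdf_lo)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def dim(self) -> int:
        return len(self.params)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n prior samples on the sampling scale, shape (n, d)."""
        from scipy.special import ndtri

        u = rng.uniform(size=(n, self.dim))
        q = self._cdf_lo + u * (self._cdf_hi - self._cdf_lo)
        return self._locs + self._scales * ndtri(q)

    def logpdf(self, Z: np.ndarray) -> np.ndarray:
        """Normalised prior log-density on the sampling scale, batched."""
        Z = np.atleast_2d(Z)
        t = (Z - self._locs) / self._scales
        terms = -0.5 * t**2 - np.log(self._scales) - 0.5 * np.log(2 * np.pi)
        terms = terms - self._log_trunc
        out = terms.sum(axis=1)
        inside = np.all((Z >= self._los) & (Z <= self._his), axis=1)
        return np.where(inside, out, -np.inf)

    def to_natural(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        Z = np.atleast_2d(Z)
        return {p.name: p.to_natural(Z[:, j]) for j, p in enumerate(self.params)}

    def from_natural(self, values: dict) -> np.ndarray:
        return np.array([p.from_natural(np.asarray(values[p.name], dtype=float))
                         for p in self.params]).T

    def width90(self) -> np.ndarray:
        """Prior 90% equal-tailed interval width per parameter (sampling scale)."""
        return np.array([p._dist().ppf(0.95) - p._dist().ppf(0.05) for p in self.params])


# --------------------------------------------------------------------------
# tempered ensemble
# --------------------------------------------------------------------------

def geometric_ladder(n_rungs: int, beta_min: float = 1e-2) -> np.ndarray:
    """Inverse-temperature ladder: beta = 0 plus a geometric grid up to 1."""
    if n_rungs < 2:
        raise ValueError("need at least 2 rungs")
    return np.concatenate([[0.0], np.geomspace(beta_min, 1.0, n_rungs - 1)])


@dataclass
class TemperedEnsemble:
    """Walker populations across the inverse-temperature ladder."""

    betas: np.ndarray            # (R,), strictly increasing in [0, 1]
    walkers: np.ndarray          # (R, W, d)
    logliks: np.ndarray          # (R, W)
    logpriors: np.ndarray        # (R, W)
    rng: np.random.Generator

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if np.any(np.diff(b) <= 0) or b[0] < 0 or b[-1] > 1:
            raise ValueError("betas must be strictly increasing within [0, 1]")
        if self.walkers.shape[1] < 2 * self.walkers.shape[2]:
            raise ValueError("need at least 2*d walkers per rung")


@dataclass
class EvidenceEstimate:
    """Thermodynamic-integration log-evidence with its standard error and
    the per-rung mean log-likelihoods it integrates."""

    log_evidence: float
    std_error: float
    betas: np.ndarray
    mean_logliks: np.ndarray

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("std_error must be >= 0")


# --------------------------------------------------------------------------
# moves
# --------------------------------------------------------------------------

def _draw_z(rng: np.random.Generator, a: float, size) -> np.ndarray:
    """Stretch-move scale draws with density proportional to 1/sqrt(z) on [1/a, a]."""
    u = rng.uniform(size=size)
    return (u * (np.sqrt(a) - np.sqrt(1.0 / a)) + np.sqrt(1.0 / a)) ** 2


def stretch_step(
    coords: np.ndarray,
    logpdf: Callable[[np.ndarray], np.ndarray],
    a: float,
    rng: np.random.Generator,
    logp_current: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One affine-invariant stretch sweep over a single walker ensemble.

    Each walker draws a partner from the complementary half and proposes
    ``x' = x_p + z (x - x_p)`` with ``z ~ 1/sqrt(z)`` on ``[1/a, a]``,
    accepted with probability ``min(1, z^(d-1) exp(dlogpdf))``.  Returns
    (coords, logp, accepted_mask).
    """
    if a <= 1:
        raise ValueError("stretch scale a must exceed 1")
    W, d = coords.shape
    if W < 2:
        raise ValueError("need at least 2 walkers")
    coords = coords.copy()
    logp = logpdf(coords) if logp_current is None else logp_current.copy()
    accepted = np.zeros(W, dtype=bool)
    half = W // 2
    sets = (np.arange(half), np.arange(half, W))
    for active, other in (sets, sets[::-1]):
        partners = other[rng.integers(0, len(other), size=len(active))]
        z = _draw_z(rng, a, len(active))
        prop = coords[partners] + z[:, None] * (coords[active] - coords[partners])
        logp_prop = logpdf(prop)
        log_r = (d - 1) * np.log(z) + logp_prop - logp[active]
        acc = np.log(rng.uniform(size=len(active))) < log_r
        coords[active[acc]] = prop[acc]
        logp[active[acc]] = logp_prop[acc]
        accepted[active[acc]] = True
    return coords, logp, accepted


def pt_swap_step(ensemble: TemperedEnsemble, rng: np.random.Generator | None = None,
                 parity: int = 0) -> float:
    """Attempt walker swaps between adjacent rungs (in place).

    Swap of walker w between rungs i < j is accepted with probability
    ``min(1, exp((beta_i - beta_j)(loglik_j - loglik_i)))``.  Returns the
    acceptance fraction.
    """
    rng = rng if rng is not None else ensemble.rng
    R, W, _ = ensemble.walkers.shape
    n_acc = 0
    n_try = 0
    for i in range(parity % 2, R - 1, 2):
        j = i + 1
        dlog = (ensemble.betas[i] - ensemble.betas[j]) * (
            ensemble.logliks[j] - ensemble.logliks[i]
        )
        acc = np.log(rng.uniform(size=W)) < dlog
        n_acc += int(acc.sum())
        n_try += W
        for arr in (ensemble.walkers, ensemble.logliks, ensemble.logpriors):
            tmp = arr[i][acc].copy()
            arr[i][acc] = arr[j][acc]
            arr[j][acc] = tmp
    return n_acc / max(n_try, 1)


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PTSettings:
    n_rungs: int = 8
    n_walkers: int = 16
    n_steps: int = 500
    n_burn: int = 200
    thin: int = 1
    a: float = 2.0
    beta_min: float = 1e-2
    seed: int = 0
    checkpoint: str | None = None
    checkpoint_every: int = 200


@dataclass
class PTResult:
    """Thinned post-burn-in chains per rung plus the final ensemble.

    ``chains``: (R, n_kept, W, d) on the sampling scale; ``logliks``:
    (R, n_kept, W); rung -1 (beta = 1) is the posterior.
    """

    chains: np.ndarray
    logliks: np.ndarray
    betas: np.ndarray
    names: list[str]
    ensemble: TemperedEnsemble
    swap_acceptance: float
    move_acceptance: float

    def posterior_samples(self, prior: PriorSpec) -> pd.DataFrame:
        """Flattened posterior draws (beta = 1 rung) on the natural scale."""
        flat = self.chains[-1].reshape(-1, self.chains.shape[-1])
        return pd.DataFrame(prior.to_natural(flat))

    def evidence(self) -> EvidenceEstimate:
        # per-sweep walker means keep the time ordering batch-means needs
        return thermo_evidence(self.betas, self.logliks.mean(axis=2))


def _eval_loglik(loglik_fn, Theta: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        return np.asarray(loglik_fn(Theta), dtype=float)
    return np.array([float(loglik_fn(t)) for t in Theta])


def run_pt_mcmc(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    prior: PriorSpec,
    settings: PTSettings,
    vectorized: bool = True,
) -> PTResult:
    """Affine-invariant parallel-tempering MCMC over the tempered posteriors.

    ``loglik_fn`` maps parameter vectors on the sampling scale to data
    log-likelihoods (vectorised over rows unless ``vectorized=False``).
    The run is deterministic given ``settings.seed``; with a checkpoint
    path, interrupting and resuming reproduces the uninterrupted run
    bit-exactly.
    """
    d = prior.dim
    R, W = settings.n_rungs, settings.n_walkers
    if W < 2 * d:
        raise ValueError(f"need n_walkers >= 2*dim = {2*d}")
    betas = geometric_ladder(R, settings.beta_min)

    state = _load_checkpoint(settings.checkpoint, betas, W, d) if settings.checkpoint else None
    if state is None:
        rng = np.random.default_rng(settings.seed)
        walkers = np.stack([prior.sample(rng, W) for _ in range(R)])
        logpriors = np.stack([prior.logpdf(walkers[r]) for r in range(R)])
        logliks = _eval_loglik(loglik_fn, walkers.reshape(R * W, d), vectorized).reshape(R, W)
        retry = 0
        while not np.all(np.isfinite(logliks)) and retry < 50:
            bad = ~np.isfinite(logliks)
            for r in range(R):
                nb = int(bad[r].sum())
                if nb:
                    walkers[r][bad[r]] = prior.sample(rng, nb)
                    logpriors[r][bad[r]] = prior.logpdf(walkers[r][bad[r]])
            logliks = _eval_loglik(loglik_fn, walkers.reshape(R * W, d), vectorized).reshape(R, W)
            retry += 1
        if not np.all(np.isfinite(logliks)):
            raise RuntimeError("non-finite log-likelihood at initialization after retries")
        start_sweep = 0
        kept_chains: list[np.ndarray] = []
        kept_logliks: list[np.ndarray] = []
        n_swap_acc = n_swap_try = n_move_acc = n_move_try = 0
    else:
        (rng, walkers, logliks, logpriors, start_sweep, kept_chains, kept_logliks,
         n_swap_acc, n_swap_try, n_move_acc, n_move_try) = state

    ens = TemperedEnsemble(betas=betas, walkers=walkers, logliks=logliks,
                           logpriors=logpriors, rng=rng)

    half = W // 2
    sets = (np.arange(half), np.arange(half, W))
    for sweep in range(start_sweep, settings.n_steps):
        for active, other in (sets, sets[::-1]):
            nA = len(active)
            partners = other[rng.integers(0, len(other), size=(R, nA))]
            z = _draw_z(rng, settings.a, (R, nA))
            cur = walkers[:, active, :]
            par = np.take_along_axis(walkers, partners[:, :, None], axis=1)
            prop = par + z[:, :, None] * (cur - par)
            lp_prop = np.stack([prior.logpdf(prop[r]) for r in range(R)])
            finite = np.isfinite(lp_prop)
            ll_prop = np.full((R, nA), -np.inf)
            if finite.any():
                ll_prop[finite] = _eval_loglik(loglik_fn, prop[finite], vectorized)
            log_r = (
                (d - 1) * np.log(z)
                + betas[:, None] * (ll_prop - logliks[:, active])
                + lp_prop
                - logpriors[:, active]
            )
            log_r = np.where(np.isfinite(lp_prop), log_r, -np.inf)
            acc = np.log(rng.uniform(size=(R, nA))) < log_r
            for r in range(R):
                ai = active[acc[r]]
                walkers[r, ai] = prop[r, acc[r]]
                logliks[r, ai] = ll_prop[r, acc[r]]
                logpriors[r, ai] = lp_prop[r, acc[r]]
            n_move_acc += int(acc.sum())
            n_move_try += acc.size
        n_pairs = len(range(sweep % 2, R - 1, 2))
        frac = pt_swap_step(ens, rng, parity=sweep % 2)
        n_swap_acc += int(round(frac * n_pairs * W))
        n_swap_try += n_pairs * W
        if sweep >= settings.n_burn and (sweep - settings.n_burn) % settings.thin == 0:
            kept_chains.append(walkers.copy())
            kept_logliks.append(logliks.copy())
        if settings.checkpoint and (sweep + 1) % settings.checkpoint_every == 0:
            _save_checkpoint(settings.checkpoint, rng, walkers, logliks, logpriors,
                             sweep + 1, kept_chains, kept_logliks,
                             n_swap_acc, n_swap_try, n_move_acc, n_move_try)

    if settings.checkpoint:
        _save_checkpoint(settings.checkpoint, rng, walkers, logliks, logpriors,
                         settings.n_steps, kept_chains, kept_logliks,
                         n_swap_acc, n_swap_try, n_move_acc, n_move_try)

    chains = np.stack(kept_chains, axis=1) if kept_chains else np.empty((R, 0, W, d))
    lls = np.stack(kept_logliks, axis=1) if kept_logliks else np.empty((R, 0, W))
    return PTResult(
        chains=chains,
        logliks=lls,
        betas=betas,
        names=prior.names,
        ensemble=ens,
        swap_acceptance=n_swap_acc / max(n_swap_try, 1),
        move_acceptance=n_move_acc / max(n_move_try, 1),
    )


def _save_checkpoint(path, rng, walkers, logliks, logpriors, sweep,
                     kept_chains, kept_logliks, *counters) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sweep"] = sweep
        f.attrs["rng_state"] = json.dumps(rng.bit_generator.state)
        f.attrs["counters"] = np.array(counters, dtype=np.int64)
        f.create_dataset("walkers", data=walkers)
        f.create_dataset("logliks", data=logliks)
        f.create_dataset("logpriors", data=logpriors)
        if kept_chains:
            f.create_dataset("kept_chains", data=np.stack(kept_chains))
            f.create_dataset("kept_logliks", data=np.stack(kept_logliks))


def _load_checkpoint(path, betas, W, d):
    import os

    import h5py

    if not path or not os.path.exists(path):
        return None
    with h5py.File(path, "r") as f:
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        walkers = f["walkers"][:]
        logliks = f["logliks"][:]
        logpriors = f["logpriors"][:]
        sweep = int(f.attrs["sweep"])
        counters = tuple(int(x) for x in f.attrs["counters"])
        kept_chains = list(f["kept_chains"][:]) if "kept_chains" in f else []
        kept_logliks = list(f["kept_logliks"][:]) if "kept_logliks" in f else []
    if walkers.shape != (len(betas), W, d):
        raise ValueError("checkpoint shape does not match settings")
    return (rng, walkers, logliks, logpriors, sweep, kept_chains, kept_logliks, *counters)


# --------------------------------------------------------------------------
# evidence
# --------------------------------------------------------------------------

def _integrated_autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time by Geyer's initial-positive-sequence
    truncation; 1.0 for (near-)iid series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    v = x.var()
    if n < 8 or v == 0:
        return 1.0
    xc = x - x.mean()
    acf = np.correlate(xc, xc, "full")[n - 1:] / (v * n)
    tau = 1.0
    m = 1
    while m + 1 < n // 2:
        pair = acf[m] + acf[m + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        m += 2
    return max(tau, 1.0)


def thermo_evidence(betas: np.ndarray, loglik_traces: Sequence[np.ndarray]) -> EvidenceEstimate:
    """Thermodynamic-integration log-evidence from per-rung log-likelihood traces.

    ``log Z = int_0^1 E_beta[log L] d_beta`` by trapezoid quadrature over
    the ladder; the standard error propagates each rung trace's variance
    of the mean (inflated by its integrated autocorrelation time) through
    the quadrature weights.
    """
    betas = np.asarray(betas, dtype=float)
    if len(betas) < 2:
        raise ValueError("need at least 2 rungs")
    if betas[0] != 0.0 or betas[-1] != 1.0:
        raise ValueError("ladder must include beta = 0 and beta = 1")
    means = np.array([np.mean(tr) for tr in loglik_traces])
    # trapezoid weights
    w = np.zeros_like(betas)
    db = np.diff(betas)
    w[:-1] += db / 2
    w[1:] += db / 2
    logz = float(np.sum(w * means))
    lengths = {len(np.asarray(tr).ravel()) for tr in loglik_traces}
    if len(lengths) == 1 and lengths.pop() > 1:
        # per-sweep quadrature series: captures cross-rung covariance
        # (swaps couple the rungs) as well as serial autocorrelation
        T = np.stack([np.asarray(tr, dtype=float).ravel() for tr in loglik_traces])
        series = w @ T
        tau = _integrated_autocorr_time(series)
        var = series.var(ddof=1) * tau / len(series)
    else:
        var = 0.0
        for r, tr in enumerate(loglik_traces):
            tr = np.asarray(tr, dtype=float).ravel()
            if len(tr) > 1:
                tau = _integrated_autocorr_time(tr)
                var += w[r] ** 2 * tr.var(ddof=1) * tau / len(tr)
    return EvidenceEstimate(
        log_evidence=logz, std_error=float(np.sqrt(var)), betas=betas, mean_logliks=means
    )


# --------------------------------------------------------------------------
# posterior post-processing
# --------------------------------------------------------------------------

def relabel_symmetry(samples: pd.DataFrame) -> pd.DataFrame:
    """Resolve the A/B label-switching degeneracy of the coupling factors.

    For every draw with ``RB < BR`` the pairs (RB, BR), (RB_bon, BR_bon)
    and (RB_ron, BR_ron) are swapped so the stronger equilibrium coupling
    is always carried by the A-side label; ties are left unchanged.
    """
    cols = [c for pair in _COUPLING_TRIPLETS for c in pair]
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise ValueError(f"missing coupling coordinate(s): {missing}")
    out = samples.copy()
    swap = out["RB"].to_numpy() < out["BR"].to_numpy()
    for a, b in _COUPLING_TRIPLETS:
        va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
        out.loc[swap, a] = vb[swap]
        out.loc[swap, b] = va[swap]
    return out


def convergence_diagnostics(
    chains: np.ndarray,
    prior: PriorSpec,
    demix: bool = False,
) -> pd.DataFrame:
    """Split-R-hat, effective sample size, and the posterior concentration
    factor (prior 90% equal-tailed width / posterior 90% width) for chains
    of shape (n_chains, n_samples, d) on the sampling scale.

    With ``demix=True`` the label-switching relabeling is applied before
    widths are computed (requires the six coupling coordinates).
    """
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3:
        raise ValueError("chains must have shape (n_chains, n_samples, d)")
    if chains.shape[1] < 4:
        raise ValueError("chains too short for diagnostics")
    names = prior.names
    flat = chains.reshape(-1, chains.shape[-1])
    if demix:
        nat = pd.DataFrame(prior.to_natural(flat))
        nat = relabel_symmetry(nat)
        flat = prior.from_natural({c: nat[c].to_numpy() for c in names})
    ds = az.convert_to_dataset({n: chains[:, :, j] for j, n in enumerate(names)})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    pw = prior.width90()
    rows = []
    for j, n in enumerate(names):
        post_w = np.quantile(flat[:, j], 0.95) - np.quantile(flat[:, j], 0.05)
        rows.append(
            {
                "parameter": n,
                "rhat": float(rhat[n].values),
                "ess": float(ess[n].values),
                "pcf": float(pw[j] / post_w) if post_w > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
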