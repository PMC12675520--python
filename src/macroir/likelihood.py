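"""Interval-averaged Gaussian likelihoods for macroscopic currents.

The recursive engine (``macroir_loglik``) propagates the ensemble mean and
covariance of channel-state occupancies jointly with the running time
integral of the gating current through each measurement interval, and
conditions the end-of-interval state on each observed interval average by
Gaussian conditioning.  This treats every data point as what it physically
is — a time average over a finite window — and remains valid when windows
exceed the kinetic relaxation times.

The non-recursive control (``macroinr_loglik``) evolves mean occupancies
deterministically and scores each interval with an instantaneous Gaussian
at the interval midpoint, ignoring both time averaging and the information
an observation carries about the boundary state.

All heavy routines accept batched parameters: if the scheme's parameters
and the observation parameters are length-K arrays, a single call scores
all K parameter vectors (the moment recursion is vectorised over the
batch), which is what makes ensemble MCMC affordable.

Numerics: each interval of width ``Delta`` is split into ``n_sub``
substeps with ``max|Q_ii| * Delta/n_sub <= target_qdelta`` (default 0.05,
minimum 2 substeps); the per-substep transition matrix is the exact
``exp(Q * delta)`` and the integral is accumulated at the left endpoint,
so the propagated moments are exact for the discretised chain and
converge to the continuous-time moments as the substep count grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .kinetics import KineticScheme, conductance_vector, stationary_distribution
from .segmentation import SegmentedTrace, instrument_noise_variance
from .simulate import ObservationParams

__all__ = [
    "MomentState",
    "IntervalJointMoments",
    "propagate_interval_moments",
    "measurement_update",
    "macroir_loglik",
    "macroinr_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class MomentState:
    """Gaussian moment-closure state of the channel ensemble: mean counts
    ``mu`` (length S), count covariance ``sigma`` (S x S), running total
    log-likelihood."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik: float = 0.0


@dataclass
class IntervalJointMoments:
    """Joint second-order moments of the end-of-interval state and the
    interval-averaged gating current."""

    end_mu: np.ndarray
    end_sigma: np.ndarray
    avg_mean: float
    avg_var: float
    cross: np.ndarray


# --------------------------------------------------------------------------
# batched primitives
# --------------------------------------------------------------------------

def _batched_expm(Q: np.ndarray, dt: float) -> np.ndarray:
    """exp(Q*dt) for a (..., S, S) stack via eigendecomposition, with a
    scipy fallback for defective matrices; rows are cleaned to be a valid
    stochastic matrix."""
    Q = np.asarray(Q, dtype=float)
    single = Q.ndim == 2
    Qb = Q[None] if single else Q
    K, S, _ = Qb.shape
    P = np.empty_like(Qb)
    try:
        w, V = np.linalg.eig(Qb)
        Vinv = np.linalg.inv(V)
        P[:] = np.real(np.einsum("kij,kj,kjl->kil", V, np.exp(w * dt), Vinv))
        bad = ~np.all(np.isfinite(P), axis=(1, 2))
        bad |= np.abs(P.sum(axis=2) - 1.0).max(axis=1) > 1e-6
    except np.linalg.LinAlgError:
        bad = np.ones(K, dtype=bool)
    for k in np.nonzero(bad)[0]:
        P[k] = expm(Qb[k] * dt)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P[0] if single else P


def _n_substeps(Q: np.ndarray, delta: float, target_qdelta: float, n_min: int = 2,
                n_max: int = 4000) -> int:
    qmax = float(np.max(np.abs(np.diagonal(Q, axis1=-2, axis2=-1))))
    n = int(np.ceil(qmax * delta / target_qdelta)) if qmax > 0 else n_min
    return int(np.clip(n, n_min, n_max))


def _propagate_batch(mu, sigma, P, g, dsub, n_sub):
    """Advance (mu, sigma) and the joint moments of the running integral A
    over ``n_sub`` substeps of width ``dsub`` with one-step matrix ``P``.

    Shapes: mu (K,S), sigma (K,S,S), P (K,S,S), g (K,S).  Returns
    (mu_end, sigma_end, mA, vA, cross) with mA/vA the mean/variance of A
    and cross (K,S) the covariance of (x_end, A).
    """
    K, S = mu.shape
    mA = np.zeros(K)
    vA = np.zeros(K)
    cross = np.zeros((K, S))
    PT = np.ascontiguousarray(np.swapaxes(P, -1, -2))
    idx = np.arange(S)
    gc = g[:, :, None]
    for _ in range(n_sub):
        # accumulate A += dsub * g.x (left endpoint)
        sg = (sigma @ gc)[:, :, 0]
        mA += dsub * (g * mu).sum(axis=1)
        vA += 2.0 * dsub * (g * cross).sum(axis=1) + dsub**2 * (g * sg).sum(axis=1)
        cross = cross + dsub * sg
        # advance the chain one substep; jump noise = diag(mu') - P^T diag(mu) P
        mu_new = (PT @ mu[:, :, None])[:, :, 0]
        E = PT @ (mu[:, :, None] * P)
        sigma = PT @ sigma @ P
        sigma[:, idx, idx] += mu_new
        sigma -= E
        cross = (PT @ cross[:, :, None])[:, :, 0]
        mu = mu_new
    return mu, sigma, mA, vA, cross


def _project_batch(mu, sigma, total):
    """Clip negative means, rescale to the conserved total, symmetrise the
    covariance and floor its negative eigenvalues at zero."""
    mu = np.clip(mu, 0.0, None)
    s = mu.sum(axis=1, keepdims=True)
    mu = np.where(s > 0, mu * (total[:, None] / np.where(s > 0, s, 1.0)), mu)
    sigma = 0.5 * (sigma + np.swapaxes(sigma, -1, -2))
    w, V = np.linalg.eigh(sigma)
    if np.any(w < 0):
        w = np.clip(w, 0.0, None)
        sigma = np.einsum("kij,kj,klj->kil", V, w, V)
    return mu, sigma


# --------------------------------------------------------------------------
# public single-instance operations
# --------------------------------------------------------------------------

def propagate_interval_moments(
    state: MomentState,
    Q: np.ndarray,
    g: np.ndarray,
    delta: float,
    n_sub: int | None = None,
    target_qdelta: float = 0.05,
) -> IntervalJointMoments:
    """Propagate boundary-conditioned moments through one interval.

    Treats the running integral ``A = int g.x dt`` as an auxiliary
    coordinate; returns the joint moments of the end state and the
    interval average ``A / delta``.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite generator")
    if delta <= 0:
        raise ValueError("interval width must be positive")
    if n_sub is None:
        n_sub = _n_substeps(Q, delta, target_qdelta)
    dsub = delta / n_sub
    P = _batched_expm(Q[None], dsub)
    mu, sigma, mA, vA, cross = _propagate_batch(
        state.mu[None].astype(float),
        state.sigma[None].astype(float),
        P,
        np.asarray(g, dtype=float)[None],
        dsub,
        n_sub,
    )
    return IntervalJointMoments(
        end_mu=mu[0],
        end_sigma=sigma[0],
        avg_mean=float(mA[0] / delta),
        avg_var=float(max(vA[0], 0.0) / delta**2),
        cross=cross[0] / delta,
    )


def measurement_update(
    joint: IntervalJointMoments,
    y_obs: float,
    i_0: float,
    sigma_inst2: float,
) -> tuple[MomentState, float]:
    """Score one observed interval average and condition the end state on it.

    The predictive density is ``N(y; i_0 + avg_mean, avg_var +
    sigma_inst2)``; the posterior end-state moments follow from joint
    Gaussian conditioning through the state/average cross-covariance, then
    the mean is projected back to the conserved-total simplex and the
    covariance is symmetrised with negative eigenvalues floored.
    """
    if sigma_inst2 <= 0:
        raise ValueError("instrument variance must be positive")
    v = joint.avg_var + sigma_inst2
    if v <= 0:
        raise ValueError("non-positive predictive variance")
    resid = y_obs - i_0 - joint.avg_mean
    increment = -0.5 * (_LOG2PI + np.log(v)) - 0.5 * resid**2 / v
    mu = joint.end_mu + joint.cross * resid / v
    sigma = joint.end_sigma - np.outer(joint.cross, joint.cross) / v
    total = np.array([joint.end_mu.sum()])
    mu_p, sigma_p = _project_batch(mu[None], sigma[None], total)
    return MomentState(mu=mu_p[0], sigma=sigma_p[0]), float(increment)


# --------------------------------------------------------------------------
# trace likelihoods (batched)
# --------------------------------------------------------------------------

def _prepare(trace, scheme, obs, params):
    if params is not None:
        scheme = scheme.with_params(params if isinstance(params, dict) else
                                    {k: getattr(params, k) for k in params.__dataclass_fields__})
    g = np.atleast_2d(conductance_vector(scheme, obs))
    S = scheme.n_states
    Qprobe = scheme.generator(float(trace.concentration[0]))
    K = max(g.shape[0], 1 if Qprobe.ndim == 2 else Qprobe.shape[0])
    g = np.broadcast_to(g, (K, S)).astype(float)

    def as_batch(x):
        return np.broadcast_to(np.asarray(x, dtype=float), (K,)).astype(float)

    i0 = as_batch(obs.i0)
    eps2 = as_batch(obs.eps2)
    nu2 = as_batch(obs.nu2)
    N_ch = as_batch(obs.N_ch)
    k_inact = as_batch(obs.k_inact)

    qcache: dict[float, np.ndarray] = {}

    def Q_of(c: float) -> np.ndarray:
        if c not in qcache:
            Q = scheme.generator(c)
            qcache[c] = np.broadcast_to(Q, (K, S, S)) if Q.ndim == 2 else Q
        return qcache[c]

    return scheme, g, K, S, i0, eps2, nu2, N_ch, k_inact, Q_of


def macroir_loglik(
    trace: SegmentedTrace,
    scheme: KineticScheme,
    obs: ObservationParams,
    params=None,
    target_qdelta: float = 0.05,
    details: bool = False,
):
    """Total recursive interval-averaged log-likelihood of a segmented trace.

    The initial ensemble state is stationary at the first interval's
    concentration with multinomial covariance ``N_ch (diag(pi) - pi pi^T)``.
    Batched: array-valued scheme/observation parameters of length K return
    a length-K vector; scalars return a float.  With ``details=True`` also
    returns a dict of per-interval predictive means/variances and variance
    components.
    """
    scheme, g, K, S, i0, eps2, nu2, N_ch, k_inact, Q_of = _prepare(trace, scheme, obs, params)
    scalar_out = g.shape[0] == 1 and np.asarray(obs.gamma).ndim == 0

    Q0 = Q_of(float(trace.concentration[0]))
    mu = np.empty((K, S))
    sigma = np.empty((K, S, S))
    for k in range(K):
        pi = stationary_distribution(Q0[k])
        mu[k] = N_ch[k] * pi
        sigma[k] = N_ch[k] * (np.diag(pi) - np.outer(pi, pi))
    total = N_ch.copy()

    loglik = np.zeros(K)
    pcache: dict[tuple, tuple[np.ndarray, float, int]] = {}
    n_int = len(trace)
    if details:
        det = {
            "pred_mean": np.empty((K, n_int)),
            "pred_var": np.empty((K, n_int)),
            "gating_var": np.empty((K, n_int)),
            "white_var": np.empty((K, n_int)),
            "pink_var": np.empty((K, n_int)),
            "increment": np.empty((K, n_int)),
        }

    for i in range(n_int):
        delta = float(trace.width[i])
        conc = float(trace.concentration[i])
        y = float(trace.y_avg[i])
        Q = Q_of(conc)
        key = (conc, delta)
        if key not in pcache:
            n_sub = _n_substeps(Q, delta, target_qdelta)
            dsub = delta / n_sub
            pcache[key] = (_batched_expm(Q, dsub), dsub, n_sub)
        P, dsub, n_sub = pcache[key]

        # deterministic inactivation envelope over this interval
        decay = np.exp(-k_inact * delta)
        mu *= decay[:, None]
        sigma *= (decay**2)[:, None, None]
        total *= decay

        mu, sigma, mA, vA, cross = _propagate_batch(mu, sigma, P, g, dsub, n_sub)
        avg_mean = mA / delta
        avg_var = np.clip(vA, 0.0, None) / delta**2
        inst = eps2 / delta + nu2
        v = avg_var + inst
        resid = y - i0 - avg_mean
        inc = -0.5 * (_LOG2PI + np.log(v)) - 0.5 * resid**2 / v
        loglik += inc
        cross_d = cross / delta
        mu = mu + cross_d * (resid / v)[:, None]
        sigma = sigma - np.einsum("ki,kj->kij", cross_d, cross_d) / v[:, None, None]
        mu, sigma = _project_batch(mu, sigma, total)

        if details:
            det["pred_mean"][:, i] = i0 + avg_mean
            det["pred_var"][:, i] = v
            det["gating_var"][:, i] = avg_var
            det["white_var"][:, i] = eps2 / delta
            det["pink_var"][:, i] = nu2
            det["increment"][:, i] = inc

    if details:
        if scalar_out:
            det = {k: v[0] for k, v in det.items()}
        return (float(loglik[0]) if scalar_out else loglik), det
    return float(loglik[0]) if scalar_out else loglik


def macroinr_loglik(
    trace: SegmentedTrace,
    scheme: KineticScheme,
    obs: ObservationParams,
    params=None,
):
    """Non-recursive control likelihood (single-pass, midpoint emission).

    Mean occupancies evolve deterministically (no conditioning on the
    data); each interval contributes a Gaussian log-density with mean
    ``i0 + g . mu(t_mid)`` and variance equal to the instantaneous
    multinomial gating variance at the midpoint plus instrument noise.
    """
    scheme, g, K, S, i0, eps2, nu2, N_ch, k_inact, Q_of = _prepare(trace, scheme, obs, params)
    scalar_out = g.shape[0] == 1 and np.asarray(obs.gamma).ndim == 0

    Q0 = Q_of(float(trace.concentration[0]))
    mu = np.empty((K, S))
    for k in range(K):
        mu[k] = N_ch[k] * stationary_distribution(Q0[k])
    total = N_ch.copy()

    loglik = np.zeros(K)
    pcache: dict[tuple, np.ndarray] = {}
    for i in range(len(trace)):
        delta = float(trace.width[i])
        conc = float(trace.concentration[i])
        y = float(trace.y_avg[i])
        Q = Q_of(conc)
        key = (conc, delta)
        if key not in pcache:
            pcache[key] = _batched_expm(Q, delta / 2.0)
        Ph = pcache[key]

        decay = np.exp(-k_inact * delta)
        mu *= decay[:, None]
        total *= decay

        mu_mid = np.einsum("kij,ki->kj", Ph, mu)
        mean = i0 + np.einsum("ks,ks->k", g, mu_mid)
        gate_var = np.einsum("ks,ks->k", g**2, mu_mid) - np.einsum(
            "ks,ks->k", g, mu_mid
        ) ** 2 / np.where(total > 0, total, 1.0)
        gate_var = np.clip(gate_var, 0.0, None)
        v = gate_var + eps2 / delta + nu2
        loglik += -0.5 * (_LOG2PI + np.log(v)) - 0.5 * (y - mean) ** 2 / v
        mu = np.einsum("kij,ki->kj", Ph, mu_mid)

    return float(loglik[0]) if scalar_out else loglik
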