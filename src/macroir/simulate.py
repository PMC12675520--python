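"""Stochastic macropatch simulator and synthetic-dataset generator.

Simulates the summed current of ``N_ch`` independent channels evolved by
exact event-driven (Gillespie) simulation under a piecewise-constant
agonist protocol, with a deterministic exponential inactivation envelope,
white instrument noise of power ``eps2`` (pA^2 s) and 1/f ("pink")
baseline noise of power ``nu2`` (pA^2) synthesised spectrally.  Default
protocol designs emulate brief (0.2 ms) agonist pulses over a
concentration series plus longer (10 ms) monitor pulses, at a reduced
desk scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .kinetics import KineticScheme, conductance_vector, stationary_distribution
from .segmentation import Epoch, Protocol

__all__ = [
    "ObservationParams",
    "ProtocolDesign",
    "SyntheticDataset",
    "p_bind",
    "pink_noise_series",
    "simulate_channel_occupancy",
    "simulate_ensemble_trace",
    "make_synthetic_dataset",
]


@dataclass(frozen=True)
class ObservationParams:
    """Measurement-layer parameters linking channel states to recorded current.

    gamma: unitary current of the fully rotated channel (pA); R_gamma:
    per-missing-rotation conductance factor; rho_leak: closed-channel leak
    ratio in [0, 1]; i0: baseline current (pA); N_ch: number of active
    channels; k_inact: rate (1/s) of the deterministic inactivation
    envelope; eps2: white-noise power (pA^2 s); nu2: pink-noise power (pA^2).
    """

    gamma: float
    R_gamma: float = 1.0
    rho_leak: float = 0.0
    i0: float = 0.0
    N_ch: int = 1
    k_inact: float = 0.0
    eps2: float = 0.0
    nu2: float = 0.0

    def __post_init__(self) -> None:
        if not (np.asarray(self.gamma) > 0).all() or not (np.asarray(self.N_ch) > 0).all():
            raise ValueError("gamma and N_ch must be positive")
        leak = np.asarray(self.rho_leak)
        if (leak < 0).any() or (leak > 1).any():
            raise ValueError("rho_leak must lie in [0, 1]")
        for name in ("eps2", "nu2", "k_inact"):
            if (np.asarray(getattr(self, name)) < 0).any():
                raise ValueError(f"{name} must be >= 0")


def p_bind(k_on: float, c: float, t: float) -> float:
    """Pre-equilibrium pocket occupancy probability ``1 - exp(-k_on*c*t)``.

    ``k_on`` in uM^-1 s^-1, ``c`` in uM, ``t`` in s.
    """
    if k_on < 0 or c < 0 or t < 0:
        raise ValueError("p_bind arguments must be >= 0")
    return -np.expm1(-k_on * c * t)


def pink_noise_series(
    n: int, f_s: float, nu2: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Zero-mean series with 1/f power spectral density between ``f_s/n``
    and ``f_s/2``, scaled so the total sample variance equals ``nu2``."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    if nu2 < 0:
        raise ValueError("nu2 must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / f_s)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    spec = amp * phases
    series = np.fft.irfft(spec, n=n)
    if nu2 == 0:
        return np.zeros(n)
    sd = series.std()
    if sd > 0:
        series *= np.sqrt(nu2) / sd
    return series


def simulate_channel_occupancy(
    scheme: KineticScheme,
    protocol: Protocol,
    n_channels: int,
    rng: np.random.Generator,
    p0: np.ndarray | None = None,
) -> np.ndarray:
    """Exact event-driven simulation of independent channels.

    Returns an integer array of shape ``(n_samples, S)`` with the channel
    count per state at each sample time (sample ``k`` reports the state at
    ``t0 + k/f_s``).  Initial states are drawn from ``p0`` (default: the
    stationary distribution at the first epoch's concentration).
    """
    fs = protocol.sampling_rate
    n_samples = int(round((protocol.t_end - protocol.epochs[0].t_start) * fs))
    S = scheme.n_states
    if p0 is None:
        p0 = stationary_distribution(scheme.generator(protocol.epochs[0].concentration))
    counts = np.zeros((n_samples, S), dtype=np.int64)
    t_origin = protocol.epochs[0].t_start

    states = rng.choice(S, size=n_channels, p=p0)
    for ch in range(n_channels):
        s = states[ch]
        t = t_origin
        for epoch in protocol.epochs:
            Q = scheme.generator(epoch.concentration)
            exit_rate = -np.diag(Q)
            jump_p = Q / np.where(exit_rate[:, None] > 0, exit_rate[:, None], 1.0)
            np.fill_diagonal(jump_p, 0.0)
            t = max(t, epoch.t_start)
            while t < epoch.t_end:
                lam = exit_rate[s]
                dwell = np.inf if lam <= 0 else rng.exponential(1.0 / lam)
                t_next = min(t + dwell, epoch.t_end)
                i0 = int(np.ceil((t - t_origin) * fs - 1e-9))
                i1 = int(np.ceil((t_next - t_origin) * fs - 1e-9))
                i0 = max(i0, 0)
                i1 = min(i1, n_samples)
                if i1 > i0:
                    counts[i0:i1, s] += 1
                if t + dwell >= epoch.t_end:
                    break
                s = rng.choice(S, p=jump_p[s])
                t = t + dwell
    return counts


def simulate_ensemble_trace(
    scheme: KineticScheme,
    obs: ObservationParams,
    protocol: Protocol,
    seed: int | np.random.Generator,
    p0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a raw macroscopic current trace.

    Per-sample current ``i0 + exp(-k_inact t) * sum_ch g(state) + white +
    pink``; white noise has per-sample variance ``eps2 * f_s`` and the pink
    series carries total power ``nu2``.  Returns ``(time, current)``;
    identical seeds give bit-identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = protocol.sampling_rate
    t0 = protocol.epochs[0].t_start
    n_samples = int(round((protocol.t_end - t0) * fs))
    time = t0 + np.arange(n_samples) / fs
    g = conductance_vector(scheme, obs)
    if obs.N_ch > 0:
        counts = simulate_channel_occupancy(scheme, protocol, int(obs.N_ch), rng, p0=p0)
        gating = counts @ g
    else:
        gating = np.zeros(n_samples)
    envelope = np.exp(-obs.k_inact * (time - t0))
    current = obs.i0 + envelope * gating
    if obs.eps2 > 0:
        current = current + rng.standard_normal(n_samples) * np.sqrt(obs.eps2 * fs)
    if obs.nu2 > 0:
        current = current + pink_noise_series(n_samples, fs, obs.nu2, rng)
    return time, current


@dataclass(frozen=True)
class ProtocolDesign:
    """Shape of the synthetic stimulation protocol (desk-scale defaults).

    Emulates brief agonist pulses over a concentration series plus longer
    monitor pulses at a fixed concentration, with shrunk baselines.
    Concentrations in uM.
    """

    concentrations: tuple[float, ...] = (100.0, 200.0, 500.0, 1000.0, 2000.0, 10000.0)
    pulse_width: float = 0.2e-3      # s
    monitor_concentration: float = 1000.0
    monitor_width: float = 10e-3     # s
    baseline: float = 0.1            # s before each pulse
    tail: float = 0.2                # s of decay after each pulse
    sampling_rate: float = 50e3      # Hz
    n_replicates: int = 1

    def protocols(self) -> list[Protocol]:
        protos = []
        for c in self.concentrations:
            protos.append(
                Protocol(
                    epochs=(
                        Epoch(0.0, self.baseline, 0.0),
                        Epoch(self.baseline, self.pulse_width, c),
                        Epoch(self.baseline + self.pulse_width, self.tail, 0.0),
                    ),
                    sampling_rate=self.sampling_rate,
                )
            )
        protos.append(
            Protocol(
                epochs=(
                    Epoch(0.0, self.baseline, 0.0),
                    Epoch(self.baseline, self.monitor_width, self.monitor_concentration),
                    Epoch(self.baseline + self.monitor_width, self.tail, 0.0),
                ),
                sampling_rate=self.sampling_rate,
            )
        )
        return protos


@dataclass
class SyntheticDataset:
    """Simulated raw traces with embedded ground truth and seed."""

    traces: list[tuple[np.ndarray, np.ndarray]]
    protocols: list[Protocol]
    ground_truth: dict
    seed: int

    def __iter__(self):
        return iter(zip(self.traces, self.protocols))


def make_synthetic_dataset(
    scheme: KineticScheme,
    obs: ObservationParams,
    design: ProtocolDesign = ProtocolDesign(),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a synthetic dataset over the design's protocol family.

    One trace per protocol per replicate; every trace uses an independent
    child seed spawned from ``seed`` so regeneration is bit-identical.
    """
    protos = design.protocols() * design.n_replicates
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(protos))
    traces = []
    for child, proto in zip(children, protos):
        rng = np.random.default_rng(child)
        traces.append(simulate_ensemble_trace(scheme, obs, proto, rng))
    ground_truth = {
        "scheme_params": {k: float(np.asarray(v)) for k, v in scheme.params.items()},
        "observation": asdict(obs),
        "design": asdict(design),
    }
    return SyntheticDataset(traces=traces, protocols=protos, ground_truth=ground_truth, seed=seed)
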