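"""Stimulation protocols and multi-resolution trace segmentation.

Raw macropatch recordings are reduced to an ordered sequence of
time-averaged intervals at several resolutions: coarse baseline windows
(default 13.7 ms) plus a handful of fine windows (default 0.02 ms) that
jointly identify white and pink instrument noise, raw unit-sample
intervals through each agonist pulse (and a short pre-onset margin),
and logarithmically widening bins through the post-pulse decay
(default 10 per time decade).  The interval-averaged likelihood engine
consumes exactly this structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "Protocol",
    "SegmentationPlan",
    "SegmentedTrace",
    "segment_trace",
    "steady_state_response",
    "instrument_noise_variance",
    "log_bin_edges",
]


@dataclass(frozen=True)
class Epoch:
    t_start: float       # s
    duration: float      # s
    concentration: float  # uM

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass(frozen=True)
class Protocol:
    """A pulse protocol: ordered, non-overlapping epochs of constant agonist.

    Concentration is treated as a step function (instantaneous solution
    exchange), appropriate for sub-millisecond square pulses.
    """

    epochs: tuple[Epoch, ...]
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.t_start)
        for e in eps:
            if e.duration <= 0 or e.concentration < 0:
                raise ValueError("epochs need positive duration and concentration >= 0")
        for a, b in zip(eps, eps[1:]):
            if a.t_end > b.t_start + 1e-12:
                raise ValueError(f"overlapping epochs at t={b.t_start}")
        object.__setattr__(self, "epochs", tuple(eps))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def t_end(self) -> float:
        return self.epochs[-1].t_end

    def concentration_at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        for e in self.epochs:
            c = np.where((t >= e.t_start) & (t < e.t_end), e.concentration, c)
        return c

    def pulse_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.concentration > 0]


@dataclass(frozen=True)
class SegmentationPlan:
    """Settings of the multi-resolution segmenter (defaults match the
    two-tier baseline / raw-pulse / log-decay design)."""

    coarse_width: float = 13.7e-3   # s, baseline averaging window
    n_fine: int = 10                # number of fine baseline windows
    fine_width: float = 0.02e-3     # s
    pre_onset: float = 0.24e-3      # s of raw samples kept before pulse onset
    per_decade: int = 10            # decay bins per time decade
    decay_start: float | None = None  # s after pulse end; default 1 sample


@dataclass
class SegmentedTrace:
    """Ordered intervals ``(t0, width, y_avg, concentration, n_raw)`` plus
    optional steady-state points ``(concentration, current)``."""

    t0: np.ndarray
    width: np.ndarray
    y_avg: np.ndarray
    concentration: np.ndarray
    n_raw: np.ndarray
    steady_state_points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t0 = np.asarray(self.t0, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.y_avg = np.asarray(self.y_avg, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.n_raw = np.asarray(self.n_raw, dtype=int)
        if np.any(self.width <= 0):
            raise ValueError("interval widths must be positive")
        if np.any(np.diff(self.t0) <= 0):
            raise ValueError("intervals must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.t0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t0_s": self.t0,
                "width_s": self.width,
                "y_avg_pA": self.y_avg,
                "conc_uM": self.concentration,
                "n_raw": self.n_raw,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentedTrace":
        return cls(
            t0=df["t0_s"].to_numpy(),
            width=df["width_s"].to_numpy(),
            y_avg=df["y_avg_pA"].to_numpy(),
            concentration=df["conc_uM"].to_numpy(),
            n_raw=df.get("n_raw", pd.Series(np.ones(len(df)))).to_numpy(),
        )


def log_bin_edges(t_lo: float, t_hi: float, per_decade: int) -> np.ndarray:
    """Logarithmically spaced bin edges from ``t_lo`` to ``t_hi`` at
    ``per_decade`` bins per time decade (e.g. 1 ms -> 1 s at 10 per decade
    gives 30 bins)."""
    if t_lo <= 0 or t_hi <= t_lo:
        raise ValueError("need 0 < t_lo < t_hi")
    n = int(round(per_decade * np.log10(t_hi / t_lo)))
    n = max(n, 1)
    return np.geomspace(t_lo, t_hi, n + 1)


def segment_trace(
    time: np.ndarray,
    current: np.ndarray,
    protocol: Protocol,
    plan: SegmentationPlan = SegmentationPlan(),
) -> SegmentedTrace:
    """Convert a uniformly sampled trace into the multi-resolution interval set.

    Before the first pulse: fine windows sit immediately before the retained
    raw pre-onset region; coarse windows fill the remaining baseline from
    the pulse side backwards, and the incomplete remainder at the very start
    of the trace is trimmed (not merged).  During each pulse (plus
    ``plan.pre_onset`` before it) raw samples are kept as unit intervals.
    After each pulse the decay is binned with ``plan.per_decade``
    log-spaced widths per decade, snapped to the sample grid.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    fs = protocol.sampling_rate
    dt = 1.0 / fs
    n = len(time)
    if n != len(current):
        raise ValueError("time and current must have equal length")
    if time[-1] + dt < protocol.t_end - 1e-9:
        raise ValueError("trace is shorter than the protocol span")
    if plan.fine_width * fs < 1 - 1e-9:
        raise ValueError("sampling too coarse for the fine baseline windows")

    t0_trace = time[0]

    def idx_of(t: float) -> int:
        return int(np.clip(round((t - t0_trace) * fs), 0, n))

    pulses = protocol.pulse_epochs()
    # sample-index breakpoints: list of (i_start, i_end, kind)
    segments: list[tuple[int, int]] = []

    def add_span(i0: int, i1: int) -> None:
        if i1 > i0:
            segments.append((i0, i1))

    def add_raw(i0: int, i1: int) -> None:
        for k in range(i0, i1):
            add_span(k, k + 1)

    def add_decay(i0: int, i1: int) -> None:
        if i1 <= i0:
            return
        t_lo = plan.decay_start if plan.decay_start is not None else dt
        span = (i1 - i0) * dt
        if span <= t_lo:
            add_span(i0, i1)
            return
        edges = log_bin_edges(t_lo, span, plan.per_decade)
        cuts = [i0] + [i0 + int(round(e * fs)) for e in edges]
        cuts = sorted(set(min(c, i1) for c in cuts)) + [i1]
        cuts = sorted(set(cuts))
        for a, b in zip(cuts, cuts[1:]):
            add_span(a, b)

    def add_baseline(i0: int, i1: int) -> None:
        """Fine windows at the end, coarse before, remainder trimmed at start."""
        n_fine_samp = int(round(plan.fine_width * fs))
        fine_start = i1 - plan.n_fine * n_fine_samp
        n_coarse_samp = int(round(plan.coarse_width * fs))
        avail = max(fine_start - i0, 0)
        n_coarse = avail // n_coarse_samp if n_coarse_samp > 0 else 0
        coarse_start = fine_start - n_coarse * n_coarse_samp
        for k in range(n_coarse):
            add_span(coarse_start + k * n_coarse_samp, coarse_start + (k + 1) * n_coarse_samp)
        for k in range(plan.n_fine):
            add_span(fine_start + k * n_fine_samp, fine_start + (k + 1) * n_fine_samp)

    prev_end = 0
    for k, pulse in enumerate(pulses):
        i_raw0 = idx_of(pulse.t_start - plan.pre_onset)
        i_raw1 = idx_of(pulse.t_end)
        if k == 0:
            add_baseline(prev_end, i_raw0)
        else:
            add_decay(prev_end, i_raw0)
        add_raw(max(i_raw0, prev_end), i_raw1)
        prev_end = i_raw1
    add_decay(prev_end, n)

    segments.sort()
    t0s, widths, yavgs, concs, nraws = [], [], [], [], []
    for i0, i1 in segments:
        t0 = t0_trace + i0 * dt
        w = (i1 - i0) * dt
        t0s.append(t0)
        widths.append(w)
        yavgs.append(float(current[i0:i1].mean()))
        concs.append(float(protocol.concentration_at(t0 + w / 2)))
        nraws.append(i1 - i0)

    # steady-state points from long (monitor) pulses
    ss = []
    for pulse in pulses:
        if pulse.duration * fs >= 2:
            half = steady_state_response(time, current, pulse)
            ss.append((pulse.concentration, half))

    return SegmentedTrace(
        t0=np.array(t0s),
        width=np.array(widths),
        y_avg=np.array(yavgs),
        concentration=np.array(concs),
        n_raw=np.array(nraws),
        steady_state_points=ss,
    )


def steady_state_response(time: np.ndarray, current: np.ndarray, epoch: Epoch) -> float:
    """Mean current over the final half of a pulse epoch (steady-state proxy)."""
    if epoch.duration <= 0:
        raise ValueError("epoch duration must be positive")
    time = np.asarray(time, dtype=float)
    mask = (time >= epoch.t_start + epoch.duration / 2) & (time < epoch.t_end)
    if not mask.any():
        raise ValueError("no samples in the final half of the epoch")
    return float(np.asarray(current, dtype=float)[mask].mean())


def instrument_noise_variance(delta: float | np.ndarray, obs) -> float | np.ndarray:
    """Variance (pA^2) of instrument noise averaged over a window of width
    ``delta`` (s): white power ``eps2`` contributes ``eps2/delta`` and pink
    power ``nu2`` a width-independent floor."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("interval width must be positive")
    out = np.asarray(obs.eps2, dtype=float) / delta + np.asarray(obs.nu2, dtype=float)
    return float(out) if out.ndim == 0 else out
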