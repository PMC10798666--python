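"""Synaptic conductance synthesis and trace statistics.

Spike trains are converted into sampled conductance waveforms by linear
superposition of a biexponential unitary kernel

    k(t) = A * N * (exp(-t / tau_decay) - exp(-t / tau_rise)),   t >= 0

peak-normalised so that ``max_t k(t) = A`` (the stated unitary amplitude),
the standard conductance-clamp convention.  Defaults: inhibitory PC kernel
tau_rise = 0.1 ms, tau_decay = 2.5 ms; excitatory mossy-fiber kernel
tau_rise = 0.28 ms, tau_decay = 1.06 ms, A = 0.4 nS (reflecting
depression).  Excitation is a single aggregate Poisson event stream at the
printed total events-per-second rate.

The mean of a shot-noise trace obeys Campbell's theorem,
``mean = sum_i A_i * rate_i * integral(k)``, which the tests use as a
closed-form oracle; the trace CV (sd/mean) is the fluctuation measure that
drives model-neuron firing.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import oaconvolve

from .synthetic_inputs import InputPopulation, SpikeTrain

__all__ = [
    "Kernel",
    "ConductanceTrace",
    "TraceStats",
    "unitary_kernel",
    "inhibitory_kernel",
    "excitatory_kernel",
    "conductance_from_train",
    "conductance_from_events",
    "total_inhibitory_conductance",
    "excitatory_conductance",
    "trace_stats",
    "spike_triggered_average",
    "write_trace_csv",
    "read_trace_csv",
    "DEFAULT_DT",
    "SIZE_CLASS_EDGES",
]

#: Default sampling step, seconds (0.02 ms <= tau_rise/5 of the 0.1 ms rise).
DEFAULT_DT = 2e-5

#: Amplitude edges (nS) splitting inputs into small/medium/large components.
SIZE_CLASS_EDGES = (6.0, 20.0)

#: Kernel support truncation, in multiples of tau_decay.  At 10*tau_decay
#: the discarded tail is < 1e-4 of the kernel integral.
KERNEL_SUPPORT_FACTOR = 10.0


@dataclass(frozen=True)
class Kernel:
    """Peak-normalised biexponential unitary conductance kernel."""

    tau_rise: float  # ms
    tau_decay: float  # ms
    amplitude: float  # nS (peak value)

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum, ms: (tr*td/(td-tr)) * ln(td/tr)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm(self) -> float:
        """Normalisation constant making the peak equal the amplitude."""
        tp = self.peak_time
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))

    @property
    def integral(self) -> float:
        """Time integral of the kernel in nS*s: A*N*(td - tr) (tau in ms)."""
        return self.amplitude * self.norm * (self.tau_decay - self.tau_rise) * 1e-3

    @property
    def support(self) -> float:
        """Truncation support in seconds."""
        return KERNEL_SUPPORT_FACTOR * self.tau_decay * 1e-3

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate k(t) for t in seconds; zero for t < 0."""
        t_ms = np.asarray(t, dtype=float) * 1e3
        out = self.amplitude * self.norm * (
            np.exp(-t_ms / self.tau_decay) - np.exp(-t_ms / self.tau_rise)
        )
        return np.where(t_ms < 0, 0.0, out)

    def sample(self, dt: float) -> np.ndarray:
        """Kernel sampled on the dt grid over its truncated support."""
        n = int(round(self.support / dt)) + 1
        return np.asarray(self(np.arange(n) * dt))


def unitary_kernel(tau_rise: float, tau_decay: float, amplitude: float) -> Kernel:
    """Biexponential kernel with time constants in ms, peak amplitude in nS."""
    return Kernel(tau_rise, tau_decay, amplitude)


def inhibitory_kernel(amplitude: float = 1.0) -> Kernel:
    """Unitary PC (GABAergic) kernel: 0.1 ms rise, 2.5 ms decay."""
    return Kernel(0.1, 2.5, amplitude)


def excitatory_kernel(amplitude: float = 0.4) -> Kernel:
    """Unitary mossy-fiber AMPA kernel: 0.28 ms rise, 1.06 ms decay, 0.4 nS."""
    return Kernel(0.28, 1.06, amplitude)


@dataclass
class ConductanceTrace:
    """Uniformly sampled conductance (nS) starting at ``t0``.

    ``components`` optionally decomposes the total by input size class; the
    components sum to the total within floating tolerance.
    """

    dt: float  # s
    values: np.ndarray  # nS
    t0: float = 0.0
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    @classmethod
    def constant(cls, value: float, dt: float, duration: float) -> "ConductanceTrace":
        n = int(round(duration / dt))
        return cls(dt=dt, values=np.full(n, float(value)))

    def __add__(self, other: "ConductanceTrace") -> "ConductanceTrace":
        if other.dt != self.dt or other.t0 != self.t0:
            raise ValueError("traces must share dt and t0")
        n = min(self.values.size, other.values.size)
        return ConductanceTrace(self.dt, self.values[:n] + other.values[:n], self.t0)


@dataclass(frozen=True)
class TraceStats:
    """Mean/sd/CV of a conductance trace after a burn-in period."""

    mean: float
    sd: float
    cv: float  # NaN when the mean is zero
    burn_in: float


def _binned_events(
    times: np.ndarray,
    weights: np.ndarray | float,
    t0: float,
    n: int,
    dt: float,
    lookback: float,
) -> tuple[np.ndarray, int]:
    """Weighted event counts on an extended grid covering [t0-lookback, t0+n*dt).

    Returns the extended bin array and the sample offset of t0 within it.
    """
    pad = int(math.ceil(lookback / dt))
    lo, hi = t0 - pad * dt, t0 + n * dt
    sel = (times >= lo) & (times < hi)
    idx = np.floor((times[sel] - lo) / dt).astype(np.int64)
    idx = np.clip(idx, 0, pad + n - 1)
    w = weights[sel] if isinstance(weights, np.ndarray) else None
    bins = np.bincount(idx, weights=w, minlength=pad + n).astype(float)
    if w is None and not isinstance(weights, np.ndarray):
        bins *= float(weights)
    return bins, pad


def conductance_from_events(
    times: np.ndarray,
    weights: np.ndarray | float,
    kernel: Kernel,
    dt: float,
    duration: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Superpose unit kernels (scaled by per-event weights) at event times.

    Events earlier than ``t0`` within the kernel support still contribute,
    which makes chunked synthesis exact.  The kernel amplitude multiplies the
    weights, so pass a unit-amplitude kernel with amplitude weights, or a
    sized kernel with unit weights.
    """
    n = int(round(duration / dt))
    bins, pad = _binned_events(np.asarray(times, float), weights, t0, n, dt,
                               kernel.support)
    k = kernel.sample(dt)
    if bins.sum() == 0:
        return np.zeros(n)
    full = oaconvolve(bins, k)
    return full[pad:pad + n]


def conductance_from_train(
    train: SpikeTrain,
    kernel: Kernel,
    dt: float = DEFAULT_DT,
    duration: float | None = None,
) -> ConductanceTrace:
    """Convolve one spike train with a unitary kernel.

    Warns if ``dt`` exceeds half the kernel rise time (undersampled rise).
    """
    if dt > kernel.tau_rise * 1e-3 / 2:
        warnings.warn(
            f"dt={dt} s undersamples the {kernel.tau_rise} ms kernel rise "
            "(require dt <= tau_rise/2)",
            stacklevel=2,
        )
    dur = train.duration if duration is None else duration
    values = conductance_from_events(train.times, 1.0, kernel, dt, dur)
    return ConductanceTrace(dt=dt, values=values)


def _size_class(amplitude: float) -> str:
    lo, hi = SIZE_CLASS_EDGES
    if amplitude < lo:
        return "small"
    return "medium" if amplitude <= hi else "large"


def total_inhibitory_conductance(
    pop: InputPopulation,
    trains: Mapping[str, SpikeTrain],
    dt: float = DEFAULT_DT,
    duration: float | None = None,
    tau_rise: float = 0.1,
    tau_decay: float = 2.5,
    components: bool = True,
) -> ConductanceTrace:
    """Total inhibitory conductance of a population, one train per sync group.

    Each input contributes its group's spike train scaled by its amplitude;
    the result optionally carries small/medium/large size-class components
    that sum to the total.
    """
    groups = pop.sync_groups()
    missing = [g for g in groups if g not in trains]
    if missing:
        raise ValueError(f"missing spike train for sync group(s) {missing}")
    if duration is None:
        duration = max((trains[g].duration for g in groups), default=0.0)
    kernel = Kernel(tau_rise, tau_decay, 1.0)
    n = int(round(duration / dt))
    # Merge weighted events per size class so each class needs one convolution.
    events: dict[str, list[tuple[np.ndarray, float]]] = {}
    for g, members in groups.items():
        tr = trains[g]
        for cls in ("small", "medium", "large"):
            amp = sum(
                pop.inputs[i].amplitude
                for i in members
                if _size_class(pop.inputs[i].amplitude) == cls
            )
            if amp > 0:
                events.setdefault(cls, []).append((tr.times, amp))
    by_class: dict[str, np.ndarray] = {}
    for cls, parts in events.items():
        times = np.concatenate([t for t, _ in parts])
        weights = np.concatenate([np.full(t.size, a) for t, a in parts])
        order = np.argsort(times, kind="stable")
        by_class[cls] = conductance_from_events(
            times[order], weights[order], kernel, dt, duration
        )
    total = sum(by_class.values(), np.zeros(n))
    return ConductanceTrace(
        dt=dt, values=total, components=by_class if components else {}
    )


def excitatory_conductance(
    events_per_second: float,
    dt: float = DEFAULT_DT,
    duration: float = 1.0,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    kernel: Kernel | None = None,
) -> ConductanceTrace:
    """Aggregate mossy-fiber drive: Poisson events through the AMPA kernel."""
    if events_per_second < 0:
        raise ValueError("event rate must be non-negative")
    rng = np.random.default_rng(seed)
    kernel = kernel or excitatory_kernel()
    n_events = rng.poisson(events_per_second * duration)
    times = np.sort(rng.random(n_events) * duration)
    values = conductance_from_events(times, 1.0, kernel, dt, duration)
    return ConductanceTrace(dt=dt, values=values)


def trace_stats(trace: ConductanceTrace, burn_in: float = 1.0) -> TraceStats:
    """Mean, sd and CV of a trace over ``t >= burn_in``."""
    if trace.duration <= burn_in:
        raise ValueError("trace must be longer than the burn-in period")
    start = int(round(burn_in / trace.dt))
    v = trace.values[start:]
    mean = float(v.mean())
    sd = float(v.std())
    cv = sd / mean if mean > 0 else float("nan")
    return TraceStats(mean=mean, sd=sd, cv=cv, burn_in=burn_in)


def spike_triggered_average(
    trace: ConductanceTrace,
    ref: SpikeTrain,
    window: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average of trace segments aligned to reference spikes.

    ``window`` is the half-width in ms; returns ``(lags_ms, sta_ns)``.
    Reference spikes closer than the window to either trace edge are dropped.
    """
    half = int(round(window * 1e-3 / trace.dt))
    idx = np.round((ref.times - trace.t0) / trace.dt).astype(np.int64)
    idx = idx[(idx >= half) & (idx + half < trace.values.size)]
    if idx.size == 0:
        raise ValueError("no reference spikes far enough from the trace edges")
    offsets = np.arange(-half, half + 1)
    sta = trace.values[idx[:, None] + offsets[None, :]].mean(axis=0)
    return offsets * trace.dt * 1e3, sta


def write_trace_csv(path: str | Path, trace: ConductanceTrace) -> None:
    """Write a trace as CSV with a ``t0/dt/unit`` metadata header (lossless)."""
    with open(path, "w") as fh:
        fh.write(f"# t0={trace.t0!r} dt={trace.dt!r} unit=nS\n")
        fh.write("g_ns\n")
        for v in trace.values:
            fh.write(f"{float(v)!r}\n")


def read_trace_csv(path: str | Path) -> ConductanceTrace:
    """Read a trace written by :func:`write_trace_csv`."""
    lines = Path(path).read_text().splitlines()
    meta = dict(p.split("=", 1) for p in lines[0][1:].split() if "=" in p)
    values = np.array([float(x) for x in lines[2:] if x.strip()])
    return ConductanceTrace(dt=float(meta["dt"]), values=values, t0=float(meta["t0"]))
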