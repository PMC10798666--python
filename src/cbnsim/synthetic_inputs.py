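"""Synthetic Purkinje-cell (PC) input generation.

Purkinje cells converge onto cerebellar nuclei (CbN) projection neurons with
highly variable unitary strengths.  This module builds the synthetic side of
that picture:

* interspike-interval (ISI) models for PC firing — a lognormal family whose
  standard deviation follows an empirical linear function of the mean ISI,
  plus a memoryless (exponential/Poisson) control without refractory
  structure;
* spike-train sampling from those models;
* the unitary-conductance size distribution measured in juvenile animals
  (right-skewed, raw mean 52.9 nS, CV 1.0), with the static corrections for
  synaptic depression (x 0.4) and the high-chloride recording internal
  (/ 2.3);
* input populations drawn from that distribution until a target total
  inhibitory conductance is reached, the simplified fixed-size populations
  used for spike-triggered averaging, synchrony grouping ("synchronised
  inputs share one spike train"), and brief pause manipulations.
"""

from __future__ import annotations

import io
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DEPRESSION_FACTOR",
    "CHLORIDE_DIVISOR",
    "RAW_MEAN_NS",
    "RAW_CV",
    "MAX_LOGNORMAL_RATE",
    "ISIModel",
    "SpikeTrain",
    "UnitaryInput",
    "InputPopulation",
    "SizeDistributionModel",
    "isi_lognormal_model",
    "isi_poisson_model",
    "sample_spike_train",
    "correct_conductance",
    "draw_input_population",
    "simplified_population",
    "apply_synchrony",
    "synchronize_largest",
    "apply_pauses",
    "write_spike_trains",
    "read_spike_trains",
    "read_conductance_csv",
    "population_to_yaml",
    "population_from_yaml",
]

# Static correction factors applied to raw measured unitary conductances:
# steady-state synaptic depression at physiological rates, and the gain of
# the high-chloride internal used for the voltage-clamp measurements.
DEPRESSION_FACTOR = 0.4
CHLORIDE_DIVISOR = 2.3

# Calibration of the raw juvenile unitary-conductance distribution.
RAW_MEAN_NS = 52.9
RAW_CV = 1.0

# Coefficients of the empirical linear relation between the mean and sd of
# lognormal ISI fits to in vivo PC firing: sd = SD_INTERCEPT + SD_SLOPE*mean.
SD_INTERCEPT = -0.00154
SD_SLOPE = 0.583

#: Largest firing rate (spikes/s) for which the linear mean-sd relation
#: yields a positive sd; the lognormal ISI model is undefined above this.
MAX_LOGNORMAL_RATE = SD_SLOPE / -SD_INTERCEPT  # ~378.57 spikes/s


# ---------------------------------------------------------------------------
# ISI models and spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ISIModel:
    """Interspike-interval distribution of one presynaptic input.

    Parameters
    ----------
    kind
        ``"lognormal"`` (refractory-like structure arises from the low mass
        near zero) or ``"exponential"`` (memoryless Poisson control).
    mean_isi
        Mean interspike interval in seconds.
    sd_isi
        ISI standard deviation in seconds (lognormal only).
    mu, sigma
        Location/scale of the underlying normal (lognormal only), set by
        moment matching so that ``exp(mu + sigma**2/2) == mean_isi`` and
        ``(exp(sigma**2) - 1) * mean_isi**2 == sd_isi**2``.
    """

    kind: str
    mean_isi: float
    sd_isi: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "exponential"):
            raise ValueError(f"unknown ISI model kind {self.kind!r}")
        if not self.mean_isi > 0:
            raise ValueError("mean_isi must be positive")
        if self.kind == "lognormal" and not (self.sd_isi or 0) > 0:
            raise ValueError("lognormal ISI model requires sd_isi > 0")

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return 1.0 / self.mean_isi

    def sample_isis(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. interspike intervals (seconds)."""
        if self.kind == "lognormal":
            return rng.lognormal(self.mu, self.sigma, size=n)
        return rng.exponential(self.mean_isi, size=n)


def isi_lognormal_model(rate: float) -> ISIModel:
    """Lognormal ISI model at a given mean firing rate.

    The sd is tied to the mean ISI through the empirical linear relation
    ``sd = -0.00154 + 0.583 * mean`` (seconds), and the lognormal shape
    parameters are set by moment matching.

    Parameters
    ----------
    rate
        Mean firing rate in spikes/s; must lie in ``(0, ~378.57)`` — above
        ``0.583/0.00154`` spikes/s the sd relation turns non-positive.
    """
    if not 0 < rate < MAX_LOGNORMAL_RATE:
        raise ValueError(
            f"rate must be in (0, {MAX_LOGNORMAL_RATE:.2f}) spikes/s: the "
            f"ISI sd relation sd = {SD_INTERCEPT} + {SD_SLOPE}*mean is "
            f"non-positive at rate {rate}"
        )
    mean_isi = 1.0 / rate
    sd_isi = SD_INTERCEPT + SD_SLOPE * mean_isi
    sigma2 = math.log1p((sd_isi / mean_isi) ** 2)
    mu = math.log(mean_isi) - sigma2 / 2.0
    return ISIModel(
        kind="lognormal",
        mean_isi=mean_isi,
        sd_isi=sd_isi,
        mu=mu,
        sigma=math.sqrt(sigma2),
    )


def isi_poisson_model(rate: float) -> ISIModel:
    """Exponential (Poisson) ISI model without refractory structure."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    return ISIModel(kind="exponential", mean_isi=1.0 / rate)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one input (or one synchrony group).

    Times are in seconds, strictly increasing, in ``[0, duration)``.
    """

    times: np.ndarray
    duration: float
    source_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Empirical firing rate in spikes/s."""
        return len(self) / self.duration if self.duration > 0 else 0.0


def sample_spike_train(
    model: ISIModel,
    duration: float,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    source_id: str = "",
) -> SpikeTrain:
    """Sample a spike train by cumulatively summing i.i.d. ISI draws.

    The first spike time is itself one ISI draw from time zero; the train is
    truncated at ``duration``.  Identical seeds give identical trains.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    if duration == 0:
        return SpikeTrain(np.empty(0), 0.0, source_id)
    chunks: list[np.ndarray] = []
    t = 0.0
    # Draw in batches sized from the expected count until past `duration`.
    batch = max(64, int(duration / model.mean_isi * 1.1) + 32)
    while t < duration:
        isis = model.sample_isis(batch, rng)
        times = t + np.cumsum(isis)
        chunks.append(times)
        t = times[-1]
        batch = max(64, int((duration - t) / model.mean_isi * 1.1) + 32)
    times = np.concatenate(chunks)
    return SpikeTrain(times[times < duration], duration, source_id)


# ---------------------------------------------------------------------------
# Unitary conductance sizes
# ---------------------------------------------------------------------------

def correct_conductance(raw: float | np.ndarray) -> float | np.ndarray:
    """Apply the depression (x 0.4) and chloride (/ 2.3) corrections."""
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw conductance must be non-negative")
    out = arr * DEPRESSION_FACTOR / CHLORIDE_DIVISOR
    return float(out) if np.isscalar(raw) or out.ndim == 0 else out


@dataclass(frozen=True)
class SizeDistributionModel:
    """Model of the raw (uncorrected) unitary-conductance distribution.

    The default family is a lognormal calibrated so that the raw analytic
    mean is 52.9 nS and the raw analytic CV is 1.0, matching the right skew
    of the measured juvenile distribution.  Alternatively a user-supplied
    empirical multiset of raw conductances (nS) can be used, in which case
    draws resample it with replacement and the "analytic" moments are the
    multiset's.
    """

    family: str = "lognormal"
    mean: float = RAW_MEAN_NS
    cv: float = RAW_CV
    values: np.ndarray | None = None  # empirical multiset, raw nS
    depression_factor: float = DEPRESSION_FACTOR
    chloride_divisor: float = CHLORIDE_DIVISOR

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "empirical"):
            raise ValueError(f"unknown size-distribution family {self.family!r}")
        if self.family == "empirical":
            vals = np.asarray(self.values, dtype=float)
            if vals.size == 0:
                raise ValueError("empirical model requires at least one value")
            if np.any(vals <= 0):
                raise ValueError("empirical conductances must be positive")
            object.__setattr__(self, "values", vals)
        elif not (self.mean > 0 and self.cv > 0):
            raise ValueError("mean and cv must be positive")

    # Closed-form moments of the raw model ---------------------------------
    @property
    def raw_mean(self) -> float:
        """Analytic mean of the raw distribution, nS."""
        if self.family == "empirical":
            return float(np.mean(self.values))
        return self.mean

    @property
    def raw_cv(self) -> float:
        """Analytic coefficient of variation of the raw distribution."""
        if self.family == "empirical":
            m = np.mean(self.values)
            return float(np.std(self.values) / m)
        return self.cv

    @property
    def corrected_mean(self) -> float:
        """Mean unitary conductance after depression/chloride correction."""
        return self.raw_mean * self.depression_factor / self.chloride_divisor

    @property
    def _lognormal_params(self) -> tuple[float, float]:
        sigma2 = math.log1p(self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    # Sampling --------------------------------------------------------------
    def sample_raw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` raw (uncorrected) unitary conductances in nS."""
        if self.family == "empirical":
            return rng.choice(self.values, size=n, replace=True)
        mu, sigma = self._lognormal_params
        return rng.lognormal(mu, sigma, size=n)

    def sample_corrected(
        self, n: int, rng: np.random.Generator, scale: float = 1.0
    ) -> np.ndarray:
        """Draw corrected amplitudes: raw x 0.4 / 2.3, optionally rescaled."""
        raw = self.sample_raw(n, rng)
        return raw * (self.depression_factor / self.chloride_divisor) * scale

    @classmethod
    def juvenile(cls) -> "SizeDistributionModel":
        """The packaged juvenile model (lognormal, 52.9 nS mean, CV 1.0)."""
        return cls()

    @classmethod
    def from_csv(cls, path: str | Path) -> "SizeDistributionModel":
        """Empirical model from a CSV of raw conductances, one nS value per
        row; a non-numeric first row is treated as a header."""
        values = read_conductance_csv(path)
        return cls(family="empirical", values=values)


def read_conductance_csv(path: str | Path) -> np.ndarray:
    """Read one raw conductance (nS) per row; header row optional."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"empty conductance file: {path}")
    try:
        float(lines[0].split(",")[0])
    except ValueError:
        lines = lines[1:]
    return np.array([float(ln.split(",")[0]) for ln in lines if ln.strip()])


# ---------------------------------------------------------------------------
# Input populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitaryInput:
    """One PC input: corrected amplitude, firing model, synchrony label.

    Inputs sharing a ``sync_group`` label share one spike train.
    """

    amplitude: float  # nS, post-correction
    rate_model: ISIModel
    sync_group: str

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class InputPopulation:
    """A set of converging PC inputs onto one model CbN neuron."""

    inputs: tuple[UnitaryInput, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([u.amplitude for u in self.inputs])

    @property
    def total_conductance(self) -> float:
        """Sum of member amplitudes, nS."""
        return float(self.amplitudes.sum())

    def sync_groups(self) -> dict[str, list[int]]:
        """Mapping sync-group label -> member input indices (ordered)."""
        groups: dict[str, list[int]] = {}
        for i, u in enumerate(self.inputs):
            groups.setdefault(u.sync_group, []).append(i)
        return groups

    def with_rate(self, index: int, model: ISIModel) -> "InputPopulation":
        """Copy with input ``index`` given a new firing model (or silenced
        by a model of ``None`` — handled by the experiment layer)."""
        inputs = list(self.inputs)
        inputs[index] = replace(inputs[index], rate_model=model)
        return replace(self, inputs=tuple(inputs))


def _default_isi(rate: float, kind: str) -> ISIModel:
    if kind == "lognormal":
        return isi_lognormal_model(rate)
    return isi_poisson_model(rate)


def draw_input_population(
    model: SizeDistributionModel,
    total_target: float = 200.0,
    rate: float = 80.0,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    scale: float = 1.0,
    isi_kind: str = "lognormal",
    provenance: str = "empirical-draw",
) -> InputPopulation:
    """Draw corrected input sizes until the total conductance reaches target.

    Amplitudes are drawn one at a time from the corrected (and optionally
    rescaled) size distribution until the running total reaches
    ``total_target`` nS; the overshooting draw is kept, so the realised
    total is >= the target.  Every input receives its own ISI model at
    ``rate`` and a singleton synchrony group.
    """
    if not total_target > 0:
        raise ValueError("total_target must be positive")
    if not scale > 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    amps: list[float] = []
    total = 0.0
    while total < total_target:
        a = float(model.sample_corrected(1, rng, scale=scale)[0])
        if not a > 0:
            raise ValueError("size distribution produced a non-positive draw")
        amps.append(a)
        total += a
    inputs = tuple(
        UnitaryInput(a, _default_isi(rate, isi_kind), sync_group=f"g{i}")
        for i, a in enumerate(amps)
    )
    return InputPopulation(inputs, provenance=provenance)


#: Simplified population recipes: (amplitude nS, count) per size class,
#: with the ISI model used in the corresponding protocol.
_SIMPLIFIED: dict[str, tuple[list[tuple[float, int]], float, str]] = {
    # 16 small (3 nS), 10 medium (10 nS), 2 large (30 nS); 83 Hz lognormal.
    "fig2": ([(3.0, 16), (10.0, 10), (30.0, 2)], 83.0, "lognormal"),
    # Medium class re-sized (8 x 12 nS) to ease 25/50% synchrony subsets.
    "fig6": ([(3.0, 16), (12.0, 8), (30.0, 2)], 80.0, "lognormal"),
    "uniform40": ([(5.0, 40)], 80.0, "lognormal"),
    # Rate-matched uniform 20 nS sets for spike-triggered averaging.
    "fig3-49": ([(20.0, 12)], 49.0, "lognormal"),
    "fig3-83": ([(20.0, 9)], 83.0, "lognormal"),
    "fig3-122": ([(20.0, 6)], 122.0, "lognormal"),
    "fig3-poisson": ([(20.0, 9)], 80.0, "exponential"),
}


def simplified_population(variant: str, rate: float | None = None) -> InputPopulation:
    """One of the fixed simplified input populations.

    Variants: ``fig2`` (16x3 + 10x10 + 2x30 nS at 83 Hz), ``fig6``
    (16x3 + 8x12 + 2x30 nS at 80 Hz), ``uniform40`` (40x5 nS at 80 Hz), and
    the rate-matched 20 nS sets ``fig3-49 | fig3-83 | fig3-122 |
    fig3-poisson``.  ``rate`` overrides the variant's default firing rate.
    """
    if variant not in _SIMPLIFIED:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(_SIMPLIFIED)}"
        )
    recipe, default_rate, kind = _SIMPLIFIED[variant]
    r = default_rate if rate is None else rate
    inputs = []
    i = 0
    for amp, count in recipe:
        for _ in range(count):
            inputs.append(UnitaryInput(amp, _default_isi(r, kind), f"g{i}"))
            i += 1
    return InputPopulation(tuple(inputs), provenance=f"simplified-{variant}")


# ---------------------------------------------------------------------------
# Synchrony and pauses
# ---------------------------------------------------------------------------

def apply_synchrony(
    pop: InputPopulation, groups: Mapping[int, str] | Sequence[str]
) -> InputPopulation:
    """Assign synchrony-group labels; grouped inputs share one spike train.

    ``groups`` maps input index -> label (a sequence is taken as one label
    per input, in order).  Every input must receive exactly one label.
    Amplitudes, input count and total conductance are unchanged: fully
    synchronising k inputs is equivalent to one input of their summed
    amplitude.
    """
    if isinstance(groups, Mapping):
        labels = [groups.get(i) for i in range(len(pop))]
    else:
        labels = list(groups)
    if len(labels) != len(pop) or any(g is None for g in labels):
        raise ValueError("every input must be assigned to exactly one group")
    inputs = tuple(
        replace(u, sync_group=str(g)) for u, g in zip(pop.inputs, labels)
    )
    return replace(pop, inputs=inputs)


def synchronize_largest(pop: InputPopulation, n: int, label: str = "sync") -> InputPopulation:
    """Merge the ``n`` largest-amplitude inputs into one synchrony group."""
    order = np.argsort(pop.amplitudes)[::-1][:n]
    labels = [u.sync_group for u in pop.inputs]
    for i in order:
        labels[int(i)] = label
    return apply_synchrony(pop, labels)


def apply_pauses(
    train: SpikeTrain, onsets: Sequence[float], width: float
) -> SpikeTrain:
    """Delete spikes falling in ``[onset, onset + width)`` windows.

    Remaining spikes are untouched (no re-drawing of subsequent ISIs).
    Overlapping windows are merged.
    """
    if not width > 0:
        raise ValueError("pause width must be positive")
    onsets_arr = np.sort(np.asarray(onsets, dtype=float))
    if onsets_arr.size == 0 or len(train) == 0:
        return train
    if onsets_arr[0] < 0 or onsets_arr[-1] >= train.duration:
        raise ValueError("pause onsets must lie in [0, duration)")
    # Merge overlapping [onset, onset+width) windows.
    starts, ends = [onsets_arr[0]], [onsets_arr[0] + width]
    for t in onsets_arr[1:]:
        if t <= ends[-1]:
            ends[-1] = max(ends[-1], t + width)
        else:
            starts.append(t)
            ends.append(t + width)
    starts_a, ends_a = np.array(starts), np.array(ends)
    idx = np.searchsorted(starts_a, train.times, side="right") - 1
    in_window = (idx >= 0) & (train.times < ends_a[np.clip(idx, 0, None)])
    return replace(train, times=train.times[~in_window])


# ---------------------------------------------------------------------------
# Plain-text interfaces
# ---------------------------------------------------------------------------

def write_spike_trains(path: str | Path, trains: Sequence[SpikeTrain]) -> None:
    """Write trains as CSV ``source_id,time_s`` (microsecond precision)."""
    with open(path, "w") as fh:
        for tr in trains:
            fh.write(f"# duration_s={tr.duration!r} source_id={tr.source_id}\n")
        fh.write("source_id,time_s\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.source_id},{t:.6f}\n")


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    """Read trains written by :func:`write_spike_trains`."""
    durations: dict[str, float] = {}
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = dict(p.split("=", 1) for p in line[1:].split() if "=" in p)
            sid = parts.get("source_id", "")
            durations[sid] = float(parts["duration_s"])
            if sid not in order:
                order.append(sid)
                rows[sid] = []
            continue
        if line.startswith("source_id"):
            continue
        sid, t = line.split(",")
        if sid not in rows:
            order.append(sid)
            rows[sid] = []
        rows[sid].append(float(t))
    out = []
    for sid in order:
        times = np.array(rows[sid])
        dur = durations.get(sid, float(times[-1]) + 1e-6 if times.size else 0.0)
        out.append(SpikeTrain(times, dur, sid))
    return out


def population_to_yaml(pop: InputPopulation, path: str | Path | None = None) -> str:
    """Serialise a population description (amplitudes, rates, sync groups)."""
    doc = {
        "provenance": pop.provenance,
        "inputs": [
            {
                "amplitude_ns": float(u.amplitude),
                "isi_kind": u.rate_model.kind,
                "rate_hz": float(u.rate_model.rate),
                "sync_group": u.sync_group,
            }
            for u in pop.inputs
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def population_from_yaml(source: str | Path) -> InputPopulation:
    """Inverse of :func:`population_to_yaml` (accepts a path or YAML text)."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    doc = yaml.safe_load(io.StringIO(text))
    inputs = tuple(
        UnitaryInput(
            d["amplitude_ns"],
            _default_isi(d["rate_hz"], d.get("isi_kind", "lognormal")),
            d["sync_group"],
        )
        for d in doc["inputs"]
    )
    return InputPopulation(inputs, provenance=doc.get("provenance", ""))
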