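"""Conductance-based integrate-and-fire model of a CbN projection neuron.

The membrane equation is

    Cm dV/dt = gE(t) (VE - V) + gI(t) (VI - V) + gL (VL - V)

with excitatory and inhibitory reversal potentials VE = 0 mV and
VI = -75 mV, a constant leak (gL, VL), a spike threshold theta, a reset
potential Vr, and an absolute refractory period t_ref during which the
neuron is held inactive at Vr.  There are no intrinsic spike-generating
conductances: firing is driven entirely by the mean and fluctuations of the
synaptic conductances, which is the point of the model.

Integration uses a per-step exponential update toward the instantaneous
equilibrium potential, which is exact for piecewise-constant conductances
and removes the stiffness error at the 0.1 ms synaptic rise time.  In the
constant-conductance limit the firing rate has a closed form
(:func:`constant_conductance_rate`) used as an independent oracle.

Units at the interface: mV, nS, pF, ms; trace sampling steps in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

from .conductance import DEFAULT_DT, ConductanceTrace

__all__ = [
    "NeuronParams",
    "SimResult",
    "Preset",
    "PRESETS",
    "preset",
    "simulate",
    "constant_conductance_rate",
    "firing_rate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Passive membrane, threshold and reset parameters."""

    Cm: float  # pF
    gL: float  # nS
    VL: float  # mV
    theta: float = -50.0  # mV, spike threshold
    Vr: float = -60.0  # mV, reset
    t_ref: float = 2.0  # ms, absolute refractory period
    VE: float = 0.0  # mV
    VI: float = -75.0  # mV

    def __post_init__(self) -> None:
        if not (self.Cm > 0 and self.gL > 0):
            raise ValueError("Cm and gL must be positive")
        if not self.Vr < self.theta:
            raise ValueError("reset must be below threshold")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


class Preset(NamedTuple):
    """Per-protocol neuron parameters plus the aggregate excitatory rate."""

    neuron: NeuronParams
    exc_events_per_second: float


#: Named parameter sets for the per-figure protocols.  ``fig4`` is shared by
#: the rate-code (fig5) and synchrony (fig6) protocols; ``fig8-uniform``
#: differs from ``fig8`` only in its excitatory drive.
PRESETS: dict[str, Preset] = {
    "fig2": Preset(NeuronParams(Cm=50.0, gL=8.8, VL=-40.0), 20_000.0),
    "fig4": Preset(NeuronParams(Cm=200.0, gL=5.0, VL=-10.0), 23_650.0),
    "fig8": Preset(NeuronParams(Cm=70.0, gL=20.0, VL=-49.9, t_ref=1.0), 23_650.0),
    "fig8-uniform": Preset(
        NeuronParams(Cm=70.0, gL=20.0, VL=-49.9, t_ref=1.0), 25_000.0
    ),
}
PRESETS["fig5"] = PRESETS["fig4"]
PRESETS["fig6"] = PRESETS["fig4"]


def preset(name: str) -> Preset:
    """Look up a named preset (``fig2 | fig4 | fig5 | fig6 | fig8 |
    fig8-uniform``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
        ) from None


@dataclass
class SimResult:
    """Spike times (s) and optional voltage trace (mV) of one simulation."""

    spike_times: np.ndarray
    duration: float
    dt: float
    params: NeuronParams
    voltage: np.ndarray | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return int(self.spike_times.size)


@njit(cache=True)
def _integrate_core(
    gE, gI, dt, Cm, gL, VL, VE, VI, theta, Vr, ref_steps, v0, ref0, record
):  # pragma: no cover - exercised via simulate()
    n = gE.size
    max_spikes = n // (ref_steps + 1) + 1
    spikes = np.empty(max_spikes, np.int64)
    vtrace = np.empty(n if record else 0, np.float64)
    k = 0
    v = v0
    ref = ref0
    # nS/pF = 1/ms; traces step in seconds, hence the 1e3 factor.
    inv_cm = 1e3 / Cm
    for i in range(n):
        if ref > 0:
            ref -= 1
            v = Vr
        else:
            gtot = gL + gE[i] + gI[i]
            vinf = (gL * VL + gE[i] * VE + gI[i] * VI) / gtot
            v = vinf + (v - vinf) * math.exp(-gtot * inv_cm * dt)
            if v >= theta:
                spikes[k] = i
                k += 1
                v = Vr
                ref = ref_steps
        if record:
            vtrace[i] = v
    return spikes[:k], v, ref, vtrace


def _resample(values: np.ndarray, from_dt: float, to_dt: float) -> np.ndarray:
    """Integer up/down-sampling of a piecewise-constant trace."""
    if math.isclose(from_dt, to_dt, rel_tol=1e-9):
        return values
    ratio = from_dt / to_dt
    if ratio > 1 and math.isclose(ratio, round(ratio), rel_tol=1e-9):
        return np.repeat(values, int(round(ratio)))
    ratio = to_dt / from_dt
    if ratio > 1 and math.isclose(ratio, round(ratio), rel_tol=1e-9):
        return values[:: int(round(ratio))]
    raise ValueError(
        f"trace dt {from_dt} not an integer multiple/divisor of sim dt {to_dt}"
    )


def simulate(
    params: NeuronParams,
    gE: ConductanceTrace | float,
    gI: ConductanceTrace | float,
    dt: float = DEFAULT_DT,
    duration: float | None = None,
    record_voltage: bool = False,
    v0: float | None = None,
    _state: tuple[float, int] | None = None,
    _t0: float = 0.0,
) -> SimResult:
    """Integrate the membrane equation and report threshold crossings.

    ``gE``/``gI`` may be :class:`ConductanceTrace` objects (resampled to the
    simulation ``dt`` by integer factors if needed) or constants in nS.  A
    spike is emitted on an upward threshold crossing, after which the
    voltage is clamped at ``Vr`` for ``t_ref`` and integration resumes.

    ``_state``/``_t0`` carry (voltage, remaining refractory steps) across
    chunked simulations and offset the reported spike times; they are
    internal plumbing for the experiment runner.
    """
    if duration is None:
        for g in (gE, gI):
            if isinstance(g, ConductanceTrace):
                duration = g.duration
                break
        else:
            raise ValueError("duration required with constant conductances")
    n = int(round(duration / dt))

    def as_array(g):
        if isinstance(g, ConductanceTrace):
            vals = _resample(g.values, g.dt, dt)
            if vals.size < n:
                raise ValueError("conductance trace shorter than the simulation")
            return np.ascontiguousarray(vals[:n])
        return np.full(n, float(g))

    gE_arr, gI_arr = as_array(gE), as_array(gI)
    ref_steps = int(round(params.t_ref * 1e-3 / dt))
    if _state is not None:
        v_start, ref_start = _state
    else:
        v_start, ref_start = (params.Vr if v0 is None else v0), 0
    idx, v_end, ref_end, vtrace = _integrate_core(
        gE_arr, gI_arr, dt,
        params.Cm, params.gL, params.VL, params.VE, params.VI,
        params.theta, params.Vr, ref_steps,
        v_start, ref_start, record_voltage,
    )
    result = SimResult(
        spike_times=_t0 + (idx + 1) * dt,
        duration=duration,
        dt=dt,
        params=params,
        voltage=vtrace if record_voltage else None,
    )
    result._end_state = (v_end, ref_end)  # type: ignore[attr-defined]
    return result


def constant_conductance_rate(
    params: NeuronParams, gE0: float = 0.0, gI0: float = 0.0
) -> float:
    """Closed-form firing rate for constant conductances (spikes/s).

    With total conductance g = gL + gE0 + gI0 the voltage relaxes toward
    V_inf = (gL VL + gE0 VE + gI0 VI) / g with time constant tau = Cm/g.
    If V_inf <= theta the neuron is silent; otherwise the ISI is
    ``tau * ln((V_inf - Vr)/(V_inf - theta)) + t_ref``.
    """
    if gE0 < 0 or gI0 < 0:
        raise ValueError("conductances must be non-negative")
    g = params.gL + gE0 + gI0
    vinf = (params.gL * params.VL + gE0 * params.VE + gI0 * params.VI) / g
    if vinf <= params.theta:
        return 0.0
    tau_s = params.Cm / g * 1e-3
    isi = tau_s * math.log((vinf - params.Vr) / (vinf - params.theta))
    return 1.0 / (isi + params.t_ref * 1e-3)


def firing_rate(result: SimResult, burn_in: float = 1.0) -> float:
    """Spike count after ``burn_in`` divided by the remaining duration."""
    if result.duration <= burn_in:
        raise ValueError("duration must exceed the burn-in period")
    n = int(np.count_nonzero(result.spike_times >= burn_in))
    return n / (result.duration - burn_in)
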