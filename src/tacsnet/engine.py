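"""Forward integration of the multi-region aeif network.

The integrator advances the adaptive exponential integrate-and-fire membrane
equation with conductance-based alpha synapses, per-neuron Poisson background
drive, delayed spike delivery, and an optional sinusoidal stimulation current
with per-neuron amplitudes (the in-silico tACS drive).

Numerics
--------
Fixed-step forward Euler at dt = 0.1 ms (default).  The membrane potential is
clamped at the spike-detection threshold inside the exponential argument, the
standard aeif guard against overflow.  Synaptic conductances follow the alpha
kernel ``g(s) = g_max (s/tau) exp(-(s-tau)/tau)`` advanced by the exact
two-state linear update (impulse ``g_max * e / tau`` onto the auxiliary state
per presynaptic spike), not by event summation.  Spike delivery times are
quantized to the simulation grid.  The local field potential of a region is
the signed sum of all synaptic currents (AMPA + GABA, background excluded) of
its neurons.

Determinism: (model, stimulus, duration, dt, seed) fully determine the
output; the background Poisson stream is drawn from the kernel RNG seeded
once per run, so a run with stimulation scaling V = 0 is bit-identical to an
unstimulated run with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .efield import NormalComponentDistribution
from .network import NetworkModel

__all__ = [
    "StimulusSpec",
    "SimulationResult",
    "IntegrationError",
    "assign_stimulus",
    "simulate",
    "compute_lfp",
    "alpha_kernel",
    "save_result",
    "load_result",
]

DEFAULT_DT_MS = 0.1
DEFAULT_TRANSIENT_S = 4.0


class IntegrationError(RuntimeError):
    """State became non-finite during integration."""

    def __init__(self, time_s: float):
        super().__init__(f"integration failure (non-finite state) at t = {time_s:.4f} s")
        self.time_s = time_s


@dataclass
class StimulusSpec:
    """Sinusoidal stimulation: neuron i of the stimulated network receives
    ``I_ext,i(t) = A_i * V * sin(2 pi f t)`` pA.

    ``amplitudes`` are dimensionless per-neuron factors A_i (negative values
    encode anti-phase drive); ``V`` converts them to pA.  V = 0 switches the
    stimulation off exactly.
    """

    frequency_hz: float
    V: float
    amplitudes: np.ndarray  # (n_neurons,)
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.frequency_hz <= 0:
            raise ValueError("stimulation frequency must be positive")

    def currents_pa(self) -> np.ndarray:
        """Per-neuron peak currents A_i * V (pA)."""
        return self.amplitudes * self.V


@dataclass
class SimulationResult:
    """Spikes and local field potentials of one run.

    ``lfp`` has one row per region at the simulation resolution, with the
    initial transient removed.  Spike times are in seconds from simulation
    onset (transient included) so refractory and delay bookkeeping stay
    inspectable.
    """

    spike_neurons: np.ndarray  # (n_spikes,) neuron index
    spike_times_s: np.ndarray  # (n_spikes,) seconds
    lfp: np.ndarray  # (n_regions, n_kept_steps) pA
    dt_ms: float
    duration_s: float
    transient_cut_s: float
    region_ids: list
    n_per_region: int
    currents: np.ndarray | None = None  # optional (n_neurons, n_kept_steps) I_syn
    conductances_ampa: np.ndarray | None = None  # optional (n_neurons, n_kept_steps)

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.spike_times_s[self.spike_neurons == neuron]

    def firing_rates_hz(self) -> np.ndarray:
        """Mean rate per neuron over the post-transient window."""
        n_neurons = len(self.region_ids) * self.n_per_region
        window = self.duration_s - self.transient_cut_s
        keep = self.spike_times_s >= self.transient_cut_s
        counts = np.bincount(self.spike_neurons[keep], minlength=n_neurons)
        return counts / window


def assign_stimulus(
    dist: NormalComponentDistribution | np.ndarray,
    V: float,
    f: float,
    seed: int = 0,
    n_neurons: int = 100,
) -> StimulusSpec:
    """Draw one amplitude per neuron i.i.d. from the empirical distribution
    (inverse-CDF over the stored samples) and wrap it with the scaling V and
    frequency f."""
    samples = dist.samples if isinstance(dist, NormalComponentDistribution) else np.asarray(dist, float)
    if samples.size == 0:
        raise ValueError("cannot sample amplitudes from an empty distribution")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling over the empirical distribution == uniform draw
    # with replacement from the sample set
    amps = samples[rng.integers(0, samples.size, size=n_neurons)]
    return StimulusSpec(frequency_hz=f, V=V, amplitudes=amps, seed=seed)


def alpha_kernel(lag_ms: np.ndarray, g_max: float, tau_ms: float) -> np.ndarray:
    """Closed-form alpha conductance: peaks at exactly g_max at lag tau."""
    lag = np.asarray(lag_ms, dtype=float)
    out = np.where(lag > 0, g_max * (lag / tau_ms) * np.exp(-(lag - tau_ms) / tau_ms), 0.0)
    return out


@njit(cache=False)
def _integrate(
    n_regions, n_per, n_exc,
    C, gL, EL, dT, vth, vreset, a_, b_, tauw, Ib, tref_steps, is_exc,
    gA_max, gG_max, gN_max, EA, EG, tauA, tauG,
    inter_g, delay_steps,
    amp, two_pi_f,
    n_steps, dt, lam, seed,
    record_traces,
):  # pragma: no cover - exercised via simulate()
    np.random.seed(seed)
    N = n_regions * n_per
    v_peak = 0.0

    L = int(delay_steps.max()) + 1
    buf_e = np.zeros((n_regions, L), dtype=np.int32)
    buf_i = np.zeros((n_regions, L), dtype=np.int32)
    own = np.zeros((N, L), dtype=np.uint8)

    v = EL.copy()
    w = np.zeros(N)
    xA = np.zeros(N)
    gA = np.zeros(N)
    xG = np.zeros(N)
    gG = np.zeros(N)
    xN = np.zeros(N)
    gN = np.zeros(N)
    refrac_until = np.full(N, -1, dtype=np.int64)

    decA = math.exp(-dt / tauA)
    decG = math.exp(-dt / tauG)
    impA_unit = math.e / tauA
    impG_unit = math.e / tauG

    cap = N * n_steps // 50 + 4096  # generous: ~200 Hz at dt=0.1 ms
    spike_i = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap, dtype=np.int64)
    n_spk = 0

    lfp = np.zeros((n_regions, n_steps))
    if record_traces:
        cur = np.zeros((N, n_steps))
        gAr = np.zeros((N, n_steps))
    else:
        cur = np.zeros((1, 1))
        gAr = np.zeros((1, 1))

    cE = np.zeros(n_regions)
    cI = np.zeros(n_regions)
    inter_imp = np.zeros(n_regions)
    new_cE = np.zeros(n_regions, dtype=np.int32)
    new_cI = np.zeros(n_regions, dtype=np.int32)
    own_new = np.zeros(N, dtype=np.uint8)
    fail_step = -1

    for t in range(n_steps):
        sin_t = math.sin(two_pi_f * t * dt * 1e-3)
        slot_w = t % L
        for k in range(n_regions):
            d_in = delay_steps[k, k]
            if t >= d_in:
                s = (t - d_in) % L
                cE[k] = buf_e[k, s]
                cI[k] = buf_i[k, s]
            else:
                cE[k] = 0.0
                cI[k] = 0.0
            acc = 0.0
            for k2 in range(n_regions):
                if k2 != k and inter_g[k, k2] > 0.0:
                    d = delay_steps[k, k2]
                    if t >= d:
                        acc += inter_g[k, k2] * buf_e[k2, (t - d) % L]
            inter_imp[k] = acc
            new_cE[k] = 0
            new_cI[k] = 0

        for i in range(N):
            k = i // n_per
            d_in = delay_steps[k, k]
            own_d = 0.0
            if t >= d_in:
                own_d = own[i, (t - d_in) % L]
            if is_exc[i]:
                impA = gA_max * (cE[k] - own_d) + inter_imp[k]
                impG = gG_max * cI[k]
            else:
                impA = gA_max * cE[k] + inter_imp[k]
                impG = gG_max * (cI[k] - own_d)
            impN = gN_max * np.random.poisson(lam)

            # exact two-state alpha update, impulse applied post-decay
            gA[i] = (gA[i] + dt * xA[i]) * decA
            xA[i] = xA[i] * decA + impA * impA_unit
            gG[i] = (gG[i] + dt * xG[i]) * decG
            xG[i] = xG[i] * decG + impG * impG_unit
            gN[i] = (gN[i] + dt * xN[i]) * decA
            xN[i] = xN[i] * decA + impN * impA_unit

            vi = v[i]
            Isyn = gA[i] * (vi - EA) + gG[i] * (vi - EG)
            lfp[k, t] += Isyn
            if record_traces:
                cur[i, t] = Isyn
                gAr[i, t] = gA[i]

            if t >= refrac_until[i]:
                vc = vi if vi < v_peak else v_peak
                Iion = (
                    -gL[i] * (vi - EL[i])
                    + gL[i] * dT[i] * math.exp((vc - vth[i]) / dT[i])
                    - w[i]
                    + Ib[i]
                    - Isyn
                    - gN[i] * (vi - EA)
                    + amp[i] * sin_t
                )
                v[i] = vi + dt * Iion / C[i]
                w[i] += dt * (a_[i] * (vi - EL[i]) - w[i]) / tauw[i]
            else:
                v[i] = vreset[i]
                w[i] += dt * (a_[i] * (vreset[i] - EL[i]) - w[i]) / tauw[i]

            own_new[i] = 0
            if v[i] > v_peak:
                if n_spk < cap:
                    spike_i[n_spk] = i
                    spike_t[n_spk] = t
                    n_spk += 1
                v[i] = vreset[i]
                w[i] += b_[i]
                refrac_until[i] = t + 1 + tref_steps[i]
                own_new[i] = 1
                if is_exc[i]:
                    new_cE[k] += 1
                else:
                    new_cI[k] += 1
            if v[i] != v[i] or w[i] != w[i]:
                fail_step = t
                break

        if fail_step >= 0:
            break
        for k in range(n_regions):
            buf_e[k, slot_w] = new_cE[k]
            buf_i[k, slot_w] = new_cI[k]
        for i in range(N):
            own[i, slot_w] = own_new[i]

    return spike_i[:n_spk], spike_t[:n_spk], lfp, cur, gAr, fail_step


def simulate(
    model: NetworkModel,
    stim: StimulusSpec | None,
    duration_s: float,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
    transient_cut_s: float = DEFAULT_TRANSIENT_S,
    record_traces: bool = False,
    extra_bias: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration_s`` seconds.

    ``stim=None`` and a stimulus with V = 0 produce bit-identical output for
    the same seed.  ``extra_bias`` adds a constant per-neuron current (pA), a
    hook for single-neuron protocols such as rheobase location.
    """
    if duration_s <= transient_cut_s:
        raise ValueError("duration must exceed the transient cut")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")

    R, n_per, n_exc = model.n_regions, model.n_per_region, model.n_exc
    N = R * n_per
    ep, ip, sp = model.exc_params, model.inh_params, model.synapses

    def per_neuron(attr):
        e = getattr(ep, attr)
        i = getattr(ip, attr)
        row = np.concatenate([np.full(model.n_exc, e), np.full(model.n_inh, i)])
        return np.tile(row, R)

    C = per_neuron("C")
    gL = per_neuron("g_L")
    EL = per_neuron("E_L")
    dT = per_neuron("delta_T")
    vth = per_neuron("v_th")
    vreset = per_neuron("v_reset")
    a_ = per_neuron("a")
    b_ = per_neuron("b")
    tauw = per_neuron("tau_w")
    Ib = per_neuron("I")
    if extra_bias is not None:
        Ib = Ib + np.asarray(extra_bias, dtype=float)
    tref = np.round(per_neuron("t_ref") / dt_ms).astype(np.int64)
    is_exc = np.tile(
        np.concatenate([np.ones(model.n_exc, bool), np.zeros(model.n_inh, bool)]), R
    )

    delay_steps = np.maximum(np.round(model.delays_ms / dt_ms).astype(np.int64), 1)

    if stim is None:
        amp = np.zeros(N)
        two_pi_f = 0.0
    else:
        if stim.amplitudes.size != N:
            raise ValueError(
                f"stimulus has {stim.amplitudes.size} amplitudes for {N} neurons"
            )
        amp = stim.currents_pa()
        two_pi_f = 2.0 * np.pi * stim.frequency_hz

    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    lam = model.background_rate_hz * dt_ms * 1e-3

    spike_i, spike_t, lfp, cur, gAr, fail_step = _integrate(
        R, n_per, n_exc,
        C, gL, EL, dT, vth, vreset, a_, b_, tauw, Ib, tref, is_exc,
        sp.g_AMPA, sp.g_GABA, sp.g_noise, sp.E_AMPA, sp.E_GABA,
        sp.tau_AMPA, sp.tau_GABA,
        model.inter_g, delay_steps,
        amp, two_pi_f,
        n_steps, dt_ms, lam, int(seed) % (2**31),
        record_traces,
    )
    if fail_step >= 0:
        raise IntegrationError(fail_step * dt_ms * 1e-3)

    cut_steps = int(round(transient_cut_s * 1000.0 / dt_ms))
    return SimulationResult(
        spike_neurons=np.asarray(spike_i),
        spike_times_s=np.asarray(spike_t) * dt_ms * 1e-3,
        lfp=lfp[:, cut_steps:],
        dt_ms=dt_ms,
        duration_s=duration_s,
        transient_cut_s=transient_cut_s,
        region_ids=list(model.region_ids),
        n_per_region=n_per,
        currents=cur[:, cut_steps:] if record_traces else None,
        conductances_ampa=gAr[:, cut_steps:] if record_traces else None,
    )


def compute_lfp(result: SimulationResult, region) -> np.ndarray:
    """The region's local field potential: signed sum of its neurons'
    synaptic currents at each retained time step."""
    try:
        idx = list(result.region_ids).index(region)
    except ValueError:
        raise ValueError(f"unknown region {region!r}") from None
    return result.lfp[idx]


def save_result(result: SimulationResult, path: str) -> None:
    """HDF5 archive: /spikes (neuron, time), /lfp (region x time) + attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes/neuron", data=result.spike_neurons)
        f.create_dataset("spikes/time_s", data=result.spike_times_s)
        f.create_dataset("lfp", data=result.lfp)
        f.attrs["dt_ms"] = result.dt_ms
        f.attrs["duration_s"] = result.duration_s
        f.attrs["transient_cut_s"] = result.transient_cut_s
        f.attrs["n_per_region"] = result.n_per_region
        f.attrs["region_ids"] = [str(r) for r in result.region_ids]


def load_result(path: str) -> SimulationResult:
    with h5py.File(path, "r") as f:
        return SimulationResult(
            spike_neurons=f["spikes/neuron"][...],
            spike_times_s=f["spikes/time_s"][...],
            lfp=f["lfp"][...],
            dt_ms=float(f.attrs["dt_ms"]),
            duration_s=float(f.attrs["duration_s"]),
            transient_cut_s=float(f.attrs["transient_cut_s"]),
            region_ids=list(f.attrs["region_ids"]),
            n_per_region=int(f.attrs["n_per_region"]),
        )
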