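"""Multi-region spiking network construction.

Each brain region is a balanced, fully connected population of 80 excitatory
and 20 inhibitory adaptive exponential integrate-and-fire (aeif) neurons.
Within a region both AMPA (excitatory) and GABA_A (inhibitory) synapses are
present; long-range projections between regions are excitatory only, with
conduction delays set by fiber length over conduction speed and strengths
scaled by the normalized connectome weight times a global coupling factor.

Neuron parameters default to regular-spiking pyramidal-cell values for the
excitatory class and fast-spiking interneuron values for the inhibitory
class.  The constant bias currents and maximum synaptic conductances are
model-level degrees of freedom; the shipped defaults were frozen from a grid
search selecting an unstimulated single-region local field potential with a
spectral peak inside the alpha band (8-12 Hz) and physiological firing rates
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .fixtures import Connectome

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "NetworkModel",
    "EXC_PARAMS",
    "INH_PARAMS",
    "DEFAULT_SYNAPSES",
    "N_EXC",
    "N_INH",
    "INTRA_DELAY_MS",
    "DEFAULT_CONDUCTION_SPEED",
    "build_population",
    "build_network",
    "save_model",
    "load_model",
]

N_EXC = 80
N_INH = 20
INTRA_DELAY_MS = 1.0
BACKGROUND_RATE_HZ = 2400.0  # per-neuron Poisson background, spikes/s
DEFAULT_CONDUCTION_SPEED = 3.9  # m/s; 15-180 mm tracts give ~4-46 ms delays


@dataclass(frozen=True)
class NeuronParams:
    """aeif membrane parameters for one neuron class.

    Units: C pF, voltages mV, conductances nS, currents pA, times ms.
    ``a`` is the subthreshold adaptation conductance, ``b`` the
    spike-triggered adaptation increment, ``delta_T`` the spike-initiation
    slope factor, ``I`` a constant bias current.
    """

    C: float
    v_reset: float
    E_L: float
    g_L: float
    a: float
    b: float
    delta_T: float
    tau_w: float
    v_th: float
    v_peak: float = 0.0
    t_ref: float = 2.0
    I: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0 or self.tau_w <= 0 or self.delta_T <= 0:
            raise ValueError("C, g_L, tau_w and delta_T must be positive")
        if self.v_reset >= self.v_peak:
            raise ValueError("v_reset must be below the spike-detection threshold")


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-based alpha-synapse parameters shared by a model.

    The alpha kernel ``g(dt) = g_max * (dt/tau) * exp(-(dt-tau)/tau)`` peaks
    at exactly ``g_max`` a lag ``tau`` after the presynaptic spike.
    """

    g_AMPA: float
    g_GABA: float
    g_noise: float
    E_AMPA: float = 0.0
    E_GABA: float = -85.0
    tau_AMPA: float = 3.0
    tau_GABA: float = 3.2

    def __post_init__(self) -> None:
        if min(self.g_AMPA, self.g_GABA, self.g_noise) < 0:
            raise ValueError("maximum conductances must be >= 0")
        if self.E_GABA >= self.E_AMPA:
            raise ValueError("E_GABA must lie below E_AMPA")
        if self.tau_AMPA <= 0 or self.tau_GABA <= 0:
            raise ValueError("synaptic time constants must be positive")


# Regular-spiking pyramidal cell (excitatory) and fast-spiking interneuron
# (inhibitory) membrane parameters.  Bias currents frozen from the alpha-band
# tuning sweep.
EXC_PARAMS = NeuronParams(
    C=104.0, v_reset=-53.0, E_L=-65.0, g_L=4.3, a=-0.8, b=65.0,
    delta_T=0.8, tau_w=88.0, v_th=-52.0, I=60.0,
)
INH_PARAMS = NeuronParams(
    C=59.0, v_reset=-54.0, E_L=-62.0, g_L=2.9, a=1.8, b=61.0,
    delta_T=3.0, tau_w=16.0, v_th=-42.0, I=10.0,
)
DEFAULT_SYNAPSES = SynapseParams(g_AMPA=0.01, g_GABA=0.4, g_noise=0.03)


@dataclass
class NetworkModel:
    """A multi-region spiking network ready for simulation.

    ``inter_g[k, k']`` is the maximum AMPA conductance (nS) of every synapse
    from an excitatory neuron of region k' onto any neuron of region k;
    ``delays_ms[k, k']`` the corresponding conduction delay.  Intra-regional
    wiring is all-to-all without self-connections, at fixed delay
    ``INTRA_DELAY_MS``.
    """

    region_ids: list
    exc_params: NeuronParams
    inh_params: NeuronParams
    synapses: SynapseParams
    inter_g: np.ndarray  # (R, R) nS, zero diagonal
    delays_ms: np.ndarray  # (R, R) ms, diagonal = INTRA_DELAY_MS
    coupling: float = 0.0
    background_rate_hz: float = BACKGROUND_RATE_HZ
    n_exc: int = N_EXC
    n_inh: int = N_INH

    def __post_init__(self) -> None:
        self.inter_g = np.asarray(self.inter_g, dtype=float)
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        off = ~np.eye(self.n_regions, dtype=bool)
        if self.n_regions > 1 and np.any(self.delays_ms[off & (self.inter_g > 0)] <= 0):
            raise ValueError("inter-regional delays must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_per_region(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def n_neurons(self) -> int:
        return self.n_regions * self.n_per_region

    def intra_edge_counts(self) -> tuple[int, int]:
        """Directed intra-regional (excitatory, inhibitory) synapse counts:
        all-to-all without autapses."""
        n = self.n_per_region
        return self.n_exc * (n - 1), self.n_inh * (n - 1)


def build_population(
    exc_params: NeuronParams = EXC_PARAMS,
    inh_params: NeuronParams = INH_PARAMS,
    syn: SynapseParams = DEFAULT_SYNAPSES,
) -> NetworkModel:
    """Single-region model: 80 E + 20 I, all-to-all intra wiring (no
    autapses), E->all AMPA, I->all GABA, 1 ms intra delay."""
    return NetworkModel(
        region_ids=[0],
        exc_params=exc_params,
        inh_params=inh_params,
        synapses=syn,
        inter_g=np.zeros((1, 1)),
        delays_ms=np.array([[INTRA_DELAY_MS]]),
        coupling=0.0,
    )


def build_network(
    connectome: Connectome,
    coupling: float,
    conduction_speed: float = DEFAULT_CONDUCTION_SPEED,
    exc_params: NeuronParams = EXC_PARAMS,
    inh_params: NeuronParams = INH_PARAMS,
    syn: SynapseParams = DEFAULT_SYNAPSES,
) -> NetworkModel:
    """Wire one population per connectome region.

    Per-pair inter conductance is ``coupling * w_kk' / max(w) * g_AMPA``;
    every excitatory neuron of the source region projects to every neuron of
    the target region with that conductance.  Delays are
    ``length_kk' (mm) / conduction_speed (m/s)`` in ms; the diagonal carries
    the 1 ms intra delay.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    if conduction_speed <= 0:
        raise ValueError("conduction_speed must be positive")
    if not np.allclose(connectome.weights, connectome.weights.T):
        raise ValueError("connectome weights must be symmetric")

    w = connectome.weights
    wmax = w.max()
    inter_g = np.zeros_like(w) if wmax == 0 else coupling * syn.g_AMPA * (w / wmax)
    np.fill_diagonal(inter_g, 0.0)
    # length (mm) / speed (m/s) = length/speed ms
    with np.errstate(divide="ignore", invalid="ignore"):
        delays = connectome.lengths / conduction_speed
    np.fill_diagonal(delays, INTRA_DELAY_MS)
    return NetworkModel(
        region_ids=list(connectome.region_ids),
        exc_params=exc_params,
        inh_params=inh_params,
        synapses=syn,
        inter_g=inter_g,
        delays_ms=delays,
        coupling=coupling,
    )


def save_model(model: NetworkModel, path: str) -> None:
    """Serialize the model to an .npz archive of matrices and parameters."""
    np.savez(
        path,
        inter_g=model.inter_g,
        delays_ms=model.delays_ms,
        region_ids=np.array([str(r) for r in model.region_ids]),
        coupling=model.coupling,
        background_rate_hz=model.background_rate_hz,
        n_exc=model.n_exc,
        n_inh=model.n_inh,
        exc_params=np.array(list(asdict(model.exc_params).items()), dtype=object),
        inh_params=np.array(list(asdict(model.inh_params).items()), dtype=object),
        synapses=np.array(list(asdict(model.synapses).items()), dtype=object),
    )


def load_model(path: str) -> NetworkModel:
    with np.load(path, allow_pickle=True) as z:
        def params(key, cls):
            return cls(**{k: float(v) for k, v in z[key]})

        return NetworkModel(
            region_ids=list(z["region_ids"]),
            exc_params=params("exc_params", NeuronParams),
            inh_params=params("inh_params", NeuronParams),
            synapses=params("synapses", SynapseParams),
            inter_g=z["inter_g"],
            delays_ms=z["delays_ms"],
            coupling=float(z["coupling"]),
            background_rate_hz=float(z["background_rate_hz"]),
            n_exc=int(z["n_exc"]),
            n_inh=int(z["n_inh"]),
        )
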