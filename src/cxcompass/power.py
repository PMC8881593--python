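"""Neuromorphic power estimation from network structure and spike records.

Energy is accounted per published per-operation figures for digital
neuromorphic hardware: a fixed cost per neuron update per timestep, a cost
per synaptic spike operation (each spike visits every structurally present
outgoing synapse), and a cost per plastic-synapse update applied every
``delta_p`` timesteps.  Power assumes 1000 timesteps of simulated dynamics
per wall-clock second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnergyConstants",
    "PowerReport",
    "neuron_power",
    "comm_power",
    "plasticity_power",
    "total_power",
]

_PJ_PER_STEP_TO_UW = 1e-12 * 1000.0 * 1e6  # pJ/step -> W at 1000 steps/s -> uW


@dataclass(frozen=True)
class EnergyConstants:
    """Per-operation energies (picojoules) and timing assumptions."""

    neuron_update_pj: float = 81.0
    spike_op_pj: float = 1.7
    synaptic_update_pj: float = 120.0
    delta_p: int = 63           # timesteps between plastic-synapse updates
    steps_per_second: float = 1000.0

    def __post_init__(self):
        if min(
            self.neuron_update_pj, self.spike_op_pj, self.synaptic_update_pj,
            self.delta_p, self.steps_per_second,
        ) <= 0:
            raise ValueError("all energy constants must be positive")

    @property
    def _uw_per_pj_per_step(self) -> float:
        return 1e-12 * self.steps_per_second * 1e6


@dataclass(frozen=True)
class PowerReport:
    """Estimated power in microwatts, by component."""

    neuron_uw: float
    comm_uw: float
    plasticity_uw: float

    @property
    def total_uw(self) -> float:
        return self.neuron_uw + self.comm_uw + self.plasticity_uw

    def to_dict(self) -> dict:
        return {
            "neuron_uw": self.neuron_uw,
            "comm_uw": self.comm_uw,
            "plasticity_uw": self.plasticity_uw,
            "total_uw": self.total_uw,
        }

    def summary(self) -> str:
        return (
            "Neuromorphic power estimate\n"
            f"  neuron updates : {self.neuron_uw:8.2f} uW\n"
            f"  communication  : {self.comm_uw:8.2f} uW\n"
            f"  plasticity     : {self.plasticity_uw:8.2f} uW\n"
            f"  total          : {self.total_uw:8.2f} uW"
        )


def neuron_power(n_neurons: int, k: EnergyConstants = EnergyConstants()) -> float:
    """Neuron-update power (uW): every neuron is updated every timestep."""
    if n_neurons < 0:
        raise ValueError("neuron count must be non-negative")
    return n_neurons * k.neuron_update_pj * k._uw_per_pj_per_step


def comm_power(
    spike_record: np.ndarray,
    connectivity_mask: np.ndarray,
    k: EnergyConstants = EnergyConstants(),
) -> float:
    """Spike-communication power (uW) from a (T, N) binary spike record and
    an (N, N) structural mask (1 where a synapse i->j exists): the mean
    per-timestep spike fanout times the per-spike-op energy."""
    y = np.asarray(spike_record, dtype=float)
    m = np.asarray(connectivity_mask, dtype=float)
    if y.ndim != 2 or m.shape != (y.shape[1], y.shape[1]):
        raise ValueError("spike record (T, N) and mask (N, N) must agree")
    fanout = m.sum(axis=1)
    mean_ops = float(y.mean(axis=0) @ fanout)
    return mean_ops * k.spike_op_pj * k._uw_per_pj_per_step


def comm_power_from_counts(
    total_spike_fanout_ops: float, n_steps: int, k: EnergyConstants = EnergyConstants()
) -> float:
    """Spike-communication power from an accumulated spike-fanout count
    (sum over timesteps and spiking neurons of outgoing-synapse counts),
    avoiding storage of the full raster."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    return (total_spike_fanout_ops / n_steps) * k.spike_op_pj * k._uw_per_pj_per_step


def plasticity_power(
    n_plastic_synapses: int, k: EnergyConstants = EnergyConstants()
) -> float:
    """Plasticity power (uW): each plastic synapse is updated every
    ``delta_p`` timesteps."""
    if n_plastic_synapses < 0:
        raise ValueError("synapse count must be non-negative")
    return (
        n_plastic_synapses * k.synaptic_update_pj / k.delta_p
    ) * k._uw_per_pj_per_step


def total_power(
    neuron_uw: float, comm_uw: float, plasticity_uw: float
) -> PowerReport:
    """Assemble a report; total is the sum of the three components."""
    return PowerReport(
        neuron_uw=float(neuron_uw),
        comm_uw=float(comm_uw),
        plasticity_uw=float(plasticity_uw),
    )
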