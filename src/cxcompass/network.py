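"""Spiking core: population layout, fixed connectome, and batched
leaky integrate-and-fire dynamics at 1 ms resolution.

The network is the insect central-complex heading circuit: 81 visually
tuned ring neurons, 18 E-PG ("compass") neurons whose activity bump is the
heading estimate, 16 P-EN neurons carrying angular velocity, 16 P-EG
neurons closing a recurrent excitatory loop, and 10 inhibitory PIntr
(Delta7) neurons -- 141 neurons in total.  All fixed weights among the 60
non-ring neurons follow the block values 20 (excitatory), -15 (PIntr onto
excitatory) and -20 (PIntr onto PIntr); PIntr never inhibit E-PG directly.

The simulator is batched: every state array carries a leading batch axis
so that independent random seeds run as one vectorized simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationLayout",
    "FixedConnectome",
    "LIFParams",
    "NetworkState",
    "build_layout",
    "build_connectome",
    "lif_rate",
    "lif_current_for_rate",
    "lif_step",
    "step_network",
    "init_bump",
]

# Global neuron index ranges (fixed by the layout).
N_RING, N_EPG, N_PEN, N_PEG, N_PINTR = 81, 18, 16, 16, 10
N_TOTAL = N_RING + N_EPG + N_PEN + N_PEG + N_PINTR  # 141
N_GLOM = 9  # glomeruli per hemisphere


class PopulationLayout:
    """Populations, hemisphere tags, glomerulus indices, preferred angles.

    Slices index into the global 141-neuron vector in the fixed order
    ring, E-PG, P-EN, P-EG, PIntr.  Within E-PG/P-EN/P-EG the right
    hemisphere comes first; E-PG have 9 glomeruli per hemisphere, P-EN and
    P-EG 8 (one fewer, per the anatomical pattern).  E-PG preferred angles
    are 9 values uniformly spanning 2*pi (40 deg spacing), identical across
    hemispheres.
    """

    ring = slice(0, N_RING)
    epg = slice(N_RING, N_RING + N_EPG)
    pen = slice(N_RING + N_EPG, N_RING + N_EPG + N_PEN)
    peg = slice(N_RING + N_EPG + N_PEN, N_RING + N_EPG + N_PEN + N_PEG)
    pintr = slice(N_TOTAL - N_PINTR, N_TOTAL)

    @property
    def n_total(self) -> int:
        return N_TOTAL

    @property
    def counts(self) -> dict[str, int]:
        return {
            "ring": N_RING, "epg": N_EPG, "pen": N_PEN,
            "peg": N_PEG, "pintr": N_PINTR,
        }

    @property
    def epg_glomerulus(self) -> np.ndarray:
        """Glomerulus index (0..8) per E-PG neuron, right then left."""
        return np.concatenate([np.arange(N_GLOM), np.arange(N_GLOM)])

    @property
    def epg_position(self) -> np.ndarray:
        """Functional ring position (0..7) per E-PG neuron: the ninth
        glomerulus duplicates the first (the first and last anatomical
        wedges overlap in the ellipsoid body), closing the ring with 8
        distinct positions covered by 8 P-EN/P-EG per hemisphere."""
        base = np.concatenate([np.arange(8), [0]])
        return np.concatenate([base, base])

    @property
    def epg_hemisphere(self) -> np.ndarray:
        """'R'/'L' per E-PG neuron."""
        return np.array(["R"] * N_GLOM + ["L"] * N_GLOM)

    @property
    def pen_glomerulus(self) -> np.ndarray:
        """Ring position per P-EN/P-EG neuron: both hemispheres cover
        positions 0..7."""
        return np.concatenate([np.arange(8), np.arange(8)])

    @property
    def pen_hemisphere(self) -> np.ndarray:
        return np.array(["R"] * 8 + ["L"] * 8)

    @property
    def preferred_angles(self) -> np.ndarray:
        """Preferred heading per E-PG neuron (radians): 8 distinct values
        at 2*pi/8 spacing (the duplicated endpoint glomerulus shares the
        first position's angle), identical across hemispheres."""
        from ._angles import wrap_rad

        return wrap_rad(self.epg_position * (2.0 * np.pi / 8.0))

    @property
    def decoder_weights(self) -> np.ndarray:
        """Per-E-PG decoder weight 1/multiplicity of its ring position, so
        the duplicated endpoint position carries the same population-vector
        mass as every other position."""
        pos = self.epg_position
        counts = np.bincount(pos, minlength=8)[pos]
        return 1.0 / counts


def build_layout() -> PopulationLayout:
    """The five-population layout of the 141-neuron circuit."""
    return PopulationLayout()


@dataclass(frozen=True)
class FixedConnectome:
    """Signed fixed weights among the 60 non-ring neurons, embedded in a
    141 x 141 matrix (ring rows/columns zero; plastic ring->E-PG weights
    live elsewhere).  ``weights[i, j]`` is the weight from neuron i to j.
    """

    weights: np.ndarray

    def __post_init__(self):
        if self.weights.shape != (N_TOTAL, N_TOTAL):
            raise ValueError("connectome must be 141 x 141")

    def mask(self) -> np.ndarray:
        """Binary structural mask (1 where a nonzero weight exists)."""
        return (self.weights != 0.0).astype(np.int8)


# Block weight values (model units; threshold = 1).
W_EXC = 20.0
W_INH = -15.0
W_PINTR_PINTR = -20.0


def build_connectome(layout: PopulationLayout) -> FixedConnectome:
    """Glomerular wiring of the fixed circuit.

    The functional ring has 8 positions at 2*pi/8 spacing; the ninth E-PG
    glomerulus per hemisphere duplicates position 0 (the first and last
    ellipsoid-body wedges overlap), so the 8 P-EN and 8 P-EG per
    hemisphere cover every position symmetrically in both rotation
    directions.

    - E-PG at ring position p excites the hemisphere-matched P-EN and
      P-EG at p, and every PIntr neuron.
    - P-EG at p excites all E-PG at p (both hemispheres, including the
      duplicate glomerulus at position 0) -- the sustaining loop.
    - P-EN at p excites E-PG at p+1 mod 8 (right hemisphere,
      counter-clockwise shift) or p-1 mod 8 (left, clockwise).
    - PIntr pool activity from all E-PG (+20) and inhibit the P-EN and
      P-EG at their output position (-15) and each other (-20), so
      inhibition everywhere tracks total bump activity (stabilizing rate
      and enforcing a single winner) while E-PG are never inhibited
      directly.
    """
    W = np.zeros((N_TOTAL, N_TOTAL))
    epg0 = layout.epg.start
    epg_pos = np.concatenate([np.arange(8), [0]])  # glomerulus -> position

    for hemi in range(2):  # 0 = right, 1 = left
        eoff = epg0 + hemi * N_GLOM
        noff = layout.pen.start + hemi * 8
        goff = layout.peg.start + hemi * 8
        for p in range(8):
            # One E-PG source per P-EN/P-EG: the duplicate pair at
            # position 0 is split across hemispheres (right sourced by
            # glomerulus 0, left by glomerulus 8) so no position gets a
            # doubled recurrent drive.
            src = 8 if (p == 0 and hemi == 1) else p
            W[eoff + src, noff + p] = W_EXC
            W[eoff + src, goff + p] = W_EXC
            # P-EG at p -> all E-PG at p (both hemispheres, incl. the
            # duplicate glomerulus); P-EN at p -> all E-PG one position
            # over (CCW for right hemisphere, CW for left).
            shift = 1 if hemi == 0 else -1
            tgt_gloms = np.flatnonzero(epg_pos == (p + shift) % 8)
            own_gloms = np.flatnonzero(epg_pos == p)
            for h2 in range(2):
                for g in own_gloms:
                    W[goff + p, epg0 + h2 * N_GLOM + g] = W_EXC
                for g in tgt_gloms:
                    W[noff + p, epg0 + h2 * N_GLOM + g] = W_EXC

    # PIntr: global input pooling; outputs tile alternating ring
    # positions (PIntr k inhibits the four positions of parity k mod 2,
    # echoing the alternating-glomerulus innervation of Delta7 axons).
    # Every position receives exactly five PIntr inputs, so inhibition is
    # spatially even and tracks total bump activity -- stabilizing the
    # firing rate and suppressing competing bumps without ever touching
    # E-PG directly.
    pintr0 = layout.pintr.start
    for k in range(N_PINTR):
        W[layout.epg, pintr0 + k] = W_EXC
        for p in range(k % 2, 8, 2):
            for hemi in range(2):
                noff = layout.pen.start + hemi * 8
                goff = layout.peg.start + hemi * 8
                W[pintr0 + k, noff + p] = W_INH
                W[pintr0 + k, goff + p] = W_INH
    # PIntr -> PIntr: mutual inhibition (no self-connections).
    blk = np.full((N_PINTR, N_PINTR), W_PINTR_PINTR)
    np.fill_diagonal(blk, 0.0)
    W[layout.pintr.start:layout.pintr.stop, layout.pintr] = blk
    return FixedConnectome(weights=W)


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters shared by all populations.

    Membrane: tau * dV/dt = -V + I, threshold 1, reset 0, refractory 2 ms,
    integrated by exponential Euler at dt = 1 ms.  Zero-mean Gaussian state
    noise (sigma = 0.1, current units) enters the P-EG and PIntr input
    currents each step.  Activation traces (the r and c signals used by
    learning and decoding) are exponential low-passes of the spike trains,
    scaled to estimate firing rate in Hz, with time constant tau_trace.

    Synaptic transmission: each fixed connection delivers a current
    ``syn_gain * weight * (presynaptic spike trace)``, where the synaptic
    trace is a faster low-pass (tau_syn) of the spike train in Hz, and
    ``syn_gain`` is the single free scalar mapping weight x rate to
    current units (calibrated so the attractor operates; the printed
    connectome weights are dimensionless ratios).
    """

    tau: float = 20e-3
    dt: float = 1e-3
    t_ref: float = 2e-3
    v_th: float = 1.0
    v_reset: float = 0.0
    state_noise_sigma: float = 0.1
    tau_trace: float = 50e-3
    tau_syn: float = 10e-3
    tau_syn_pen: float = 50e-3
    syn_gain: float = 2.0e-3
    pen_epg_gain: float = 2.0
    peg_epg_gain: float = 0.4
    epg_pen_gain: float = 1.0
    pintr_out_gain: float = 0.2

    def __post_init__(self):
        if self.dt > self.tau:
            raise ValueError("dt must not exceed the membrane time constant")
        if self.t_ref < 0:
            raise ValueError("refractory period must be non-negative")

    @property
    def decay(self) -> float:
        return float(np.exp(-self.dt / self.tau))

    @property
    def trace_decay(self) -> float:
        return float(np.exp(-self.dt / self.tau_trace))

    @property
    def syn_decay(self) -> np.ndarray:
        """Per-neuron synaptic-trace decay: P-EN outputs use the slower
        tau_syn_pen (averaging spiking shot noise out of the velocity
        pathway), everything else tau_syn."""
        tau = np.full(N_TOTAL, self.tau_syn)
        tau[N_RING + N_EPG : N_RING + N_EPG + N_PEN] = self.tau_syn_pen
        return np.exp(-self.dt / tau)

    @property
    def ref_steps(self) -> int:
        return int(round(self.t_ref / self.dt))


def lif_rate(current, p: LIFParams = LIFParams()) -> np.ndarray:
    """Closed-form steady-state LIF firing rate (Hz) for constant current.

    rate = 1 / (t_ref + tau * ln(I / (I - v_th))) above threshold, 0 below.
    """
    I = np.asarray(current, dtype=float)
    out = np.zeros_like(I)
    supra = I > p.v_th
    with np.errstate(divide="ignore"):
        isi = p.t_ref + p.tau * np.log(I[supra] / (I[supra] - p.v_th))
    out[supra] = 1.0 / isi
    return out if out.ndim else float(out)


def lif_current_for_rate(rate_hz: float, p: LIFParams = LIFParams()) -> float:
    """Constant current whose continuous-time steady-state LIF rate is
    ``rate_hz`` (inverse of :func:`lif_rate`)."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    isi = 1.0 / rate_hz
    if isi <= p.t_ref:
        raise ValueError("requested rate exceeds the refractory limit")
    x = np.exp((isi - p.t_ref) / p.tau)  # = I / (I - v_th)
    return float(p.v_th * x / (x - 1.0))


def lif_rate_discrete(current, p: LIFParams = LIFParams()) -> np.ndarray:
    """Steady-state firing rate of the *simulated* (exponential-Euler,
    integer-step) LIF neuron: inter-spike intervals quantize to whole
    timesteps, so the rate is 1 / ((ref_steps + k) * dt) with k the first
    step at which I*(1 - decay^k) crosses threshold."""
    I = np.asarray(current, dtype=float)
    out = np.zeros_like(I)
    supra = I > p.v_th
    frac = np.log1p(-p.v_th / I[supra]) / np.log(p.decay)
    k = np.ceil(frac - 1e-12)
    out[supra] = 1.0 / ((p.ref_steps + k) * p.dt)
    return out if out.ndim else float(out)


def lif_current_for_rate_discrete(rate_hz: float, p: LIFParams = LIFParams()) -> float:
    """Smallest constant current whose simulated steady-state rate is at
    least ``rate_hz``, accounting for timestep quantization (inverse of
    :func:`lif_rate_discrete`; sits just above the threshold boundary)."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    n_steps = int(round(1.0 / (rate_hz * p.dt)))
    k = n_steps - p.ref_steps
    if k < 1:
        raise ValueError("requested rate exceeds the refractory limit")
    return float(p.v_th / (1.0 - p.decay**k) * (1.0 + 1e-9))


@dataclass
class NetworkState:
    """Batched dynamical state: membrane potentials, refractory timers,
    last-step spikes, and rate-scaled activation traces (Hz)."""

    v: np.ndarray          # (B, 141) membrane potentials
    refrac: np.ndarray     # (B, 141) remaining refractory steps
    spikes: np.ndarray     # (B, 141) boolean, spikes emitted this step
    trace: np.ndarray      # (B, 141) slow low-pass spike trace, Hz units
    syn: np.ndarray        # (B, 141) fast synaptic spike trace, Hz units

    @classmethod
    def zeros(cls, n_batch: int) -> "NetworkState":
        return cls(
            v=np.zeros((n_batch, N_TOTAL)),
            refrac=np.zeros((n_batch, N_TOTAL), dtype=np.int32),
            spikes=np.zeros((n_batch, N_TOTAL), dtype=bool),
            trace=np.zeros((n_batch, N_TOTAL)),
            syn=np.zeros((n_batch, N_TOTAL)),
        )

    @property
    def n_batch(self) -> int:
        return self.v.shape[0]


def lif_step(
    state: NetworkState,
    currents: np.ndarray,
    params: LIFParams,
    rng: np.random.Generator | None = None,
    noise_sigma_per_neuron: np.ndarray | None = None,
) -> NetworkState:
    """Advance all neurons one timestep (in place) given input currents.

    Exponential-Euler membrane update; threshold crossing emits a spike,
    resets the potential and starts the refractory clock.  Optional
    per-neuron Gaussian current noise (used for P-EG/PIntr).  Traces are
    updated as rate-scaled exponential low-passes of the spike trains.
    """
    I = np.asarray(currents, dtype=float)
    if I.shape != state.v.shape:
        raise ValueError(f"currents must have shape {state.v.shape}, got {I.shape}")
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite input currents")
    if noise_sigma_per_neuron is not None and rng is not None:
        I = I + rng.standard_normal(I.shape) * noise_sigma_per_neuron

    decay = params.decay
    v = state.v * decay + I * (1.0 - decay)
    refractory = state.refrac > 0
    v[refractory] = params.v_reset
    spikes = v >= params.v_th
    v[spikes] = params.v_reset
    state.refrac[refractory] -= 1
    state.refrac[spikes] = params.ref_steps
    state.v = v
    state.spikes = spikes
    a = params.trace_decay
    state.trace = state.trace * a + spikes * ((1.0 - a) / params.dt)
    s = params.syn_decay
    state.syn = state.syn * s + spikes * ((1.0 - s) / params.dt)
    return state


_eff_cache: dict[tuple[int, float], np.ndarray] = {}


def _effective_weights(connectome: FixedConnectome, params: LIFParams) -> np.ndarray:
    """Connectome weights with the calibrated pathway gains applied to
    the two inputs of E-PG: pen_epg_gain on the P-EN -> E-PG shift
    pathway (closed-loop bump-speed calibration) and peg_epg_gain on the
    P-EG -> E-PG sustaining loop (keeps the bump core below the
    refractory ceiling so the velocity differential can act); cached."""
    gains = (
        params.pen_epg_gain, params.peg_epg_gain,
        params.epg_pen_gain, params.pintr_out_gain,
    )
    if gains == (1.0, 1.0, 1.0, 1.0):
        return connectome.weights
    key = (id(connectome), *gains)
    if key not in _eff_cache:
        W = connectome.weights.copy()
        epg = slice(N_RING, N_RING + N_EPG)
        pen = slice(N_RING + N_EPG, N_RING + N_EPG + N_PEN)
        peg = slice(N_RING + N_EPG + N_PEN, N_RING + N_EPG + N_PEN + N_PEG)
        pintr = slice(N_TOTAL - N_PINTR, N_TOTAL)
        W[pen, epg] *= params.pen_epg_gain
        W[peg, epg] *= params.peg_epg_gain
        W[epg, pen] *= params.epg_pen_gain
        W[pintr, pen] *= params.pintr_out_gain
        W[pintr, peg] *= params.pintr_out_gain
        _eff_cache[key] = W
    return _eff_cache[key]


def step_network(
    state: NetworkState,
    visual_drive: np.ndarray,
    av_drive: np.ndarray,
    W_rc: np.ndarray | None,
    ring_rates: np.ndarray | None,
    connectome: FixedConnectome,
    layout: PopulationLayout,
    params: LIFParams,
    rng: np.random.Generator,
    epg_bias: float = 0.0,
    extra_epg_current: np.ndarray | None = None,
) -> NetworkState:
    """Compose all per-step currents and advance the network one step.

    - ring neurons receive ``visual_drive`` (B, 81) directly;
    - P-EN neurons receive recurrent current plus ``av_drive`` (B, 16);
    - E-PG neurons receive recurrent current, a constant bias, and the
      visual term ``ring_rates @ W_rc.T`` where ``ring_rates`` (B, 81, Hz)
      is the ring activation (analytic in rate mode, spike trace in
      spiking mode) and ``W_rc`` (B, 18, 81) is non-positive, acting by
      disinhibition against the bias;
    - P-EG and PIntr receive recurrent current plus state noise.
    """
    B = state.n_batch
    # Recurrent: filtered presynaptic spike trains (Hz) through the signed
    # weights, scaled by the global synaptic gain (with the calibrated
    # extra gain on the P-EN -> E-PG shift pathway).
    I = params.syn_gain * (state.syn @ _effective_weights(connectome, params))
    I[:, layout.ring] += visual_drive
    I[:, layout.pen] += av_drive
    I[:, layout.epg] += epg_bias
    if W_rc is not None and ring_rates is not None:
        I[:, layout.epg] += np.einsum("bm,bnm->bn", ring_rates, W_rc)
    if extra_epg_current is not None:
        I[:, layout.epg] += extra_epg_current
    sigma = np.zeros(N_TOTAL)
    sigma[layout.peg] = params.state_noise_sigma
    sigma[layout.pintr] = params.state_noise_sigma
    return lif_step(state, I, params, rng=rng, noise_sigma_per_neuron=sigma)


def init_bump(
    state: NetworkState,
    heading: float,
    layout: PopulationLayout,
    connectome: FixedConnectome,
    params: LIFParams,
    rng: np.random.Generator,
    epg_bias: float = 0.0,
    duration: float = 0.1,
    amplitude: float = 2.0,
    width: float = 2.0 * np.pi / 9.0,
) -> NetworkState:
    """Seed the attractor with a bump at ``heading`` by pulsing a Gaussian
    current profile (over preferred angles) into the E-PG population for
    ``duration`` seconds, with the rest of the network running normally."""
    from ._angles import wrap_rad

    theta = layout.preferred_angles
    profile = amplitude * np.exp(
        -0.5 * (wrap_rad(theta - heading) / width) ** 2
    )
    pulse = np.broadcast_to(profile, (state.n_batch, N_EPG)).copy()
    zeros_v = np.zeros((state.n_batch, N_RING))
    zeros_a = np.zeros((state.n_batch, N_PEN))
    for _ in range(int(round(duration / params.dt))):
        step_network(
            state, zeros_v, zeros_a, None, None, connectome, layout, params,
            rng, epg_bias=epg_bias, extra_epg_current=pulse,
        )
    return state
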