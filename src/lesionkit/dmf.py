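"""Reduced dynamic mean-field (DMF) network model.

Each region holds one excitatory and one inhibitory population described by
average synaptic gating variables S_E, S_I in [0, 1]. Excitatory currents
combine a constant external drive, local recurrence, long-range excitation
through the structural connectome scaled by the global coupling G, and local
feedback inhibition with per-region weight J_i:

    I_E_i = w_E*I0 + w_plus*J_N*S_E_i + G*J_N*sum_j C_ij S_E_j - J_i*S_I_i
    I_I_i = w_I*I0 + J_N*S_E_i - w_II*S_I_i

Population rates follow the sigmoidal-linear transfer r = (aI-b)/(1-exp(-d(aI-b)))
and the gating variables evolve as Ito SDEs integrated with Euler-Maruyama
(step dt, default 1 ms), with additive noise sigma*nu(t) on both populations
and clipping to [0, 1] after each step.

``step`` is the transparent one-step reference; ``simulate`` runs the same
update in a numba-compiled loop (tests assert exact agreement on shared
noise streams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .connectome import Connectome

__all__ = [
    "DMFParams",
    "DMFState",
    "SimulationResult",
    "NumericalBlowupError",
    "transfer_rate",
    "step",
    "simulate",
]


class NumericalBlowupError(RuntimeError):
    pass


@dataclass(frozen=True)
class DMFParams:
    """Model constants. Currents in nA, rates in Hz, times in ms.

    Defaults are the canonical reduced mean-field parameter set used
    throughout the feedback-inhibition-control literature. ``G`` has no
    universal default in that literature (it is fitted to empirical FC per
    cohort); 1.4 is the largest value on a 0.05 grid for which the
    balanced state remains stable — FIC converges and fresh simulations
    keep every region inside the homeostatic firing band — across a
    validation sweep of synthetic cohorts normalised to unit maximum nodal
    strength, and is used when no fit is run.
    """

    w_E: float = 1.0
    w_I: float = 0.7
    I_0: float = 0.382          # nA
    w_plus: float = 1.4
    J_N: float = 0.15           # nA
    w_II: float = 1.0
    G: float = 1.4
    a_E: float = 310.0          # nC^-1
    b_E: float = 125.0          # Hz
    d_E: float = 0.16           # s
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 100.0        # ms (NMDA)
    tau_I: float = 10.0         # ms (GABA)
    gamma: float = 0.641
    sigma: float = 0.01         # nA
    dt: float = 1.0             # ms
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "d_E", "d_I", "a_E", "a_I", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def with_(self, **kw) -> "DMFParams":
        return replace(self, **kw)


@dataclass
class DMFState:
    """Per-region synaptic gating and local inhibitory weights."""

    S_E: np.ndarray
    S_I: np.ndarray
    J: np.ndarray

    @classmethod
    def initial(cls, n_regions: int, J: np.ndarray | float = 1.0) -> "DMFState":
        j = np.full(n_regions, float(J)) if np.isscalar(J) else np.asarray(J, dtype=float).copy()
        return cls(S_E=np.full(n_regions, 0.1), S_I=np.full(n_regions, 0.1), J=j)


@dataclass
class SimulationResult:
    r_E: np.ndarray             # per-region mean excitatory rate, Hz
    r_I: np.ndarray
    I_E: np.ndarray             # per-region mean excitatory current, nA
    duration: float             # s
    transient: float            # s
    seed: int | None
    S_E_trace: np.ndarray | None = None   # (time, region), includes transient
    trace_dt: float | None = None         # s between recorded samples


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------

def transfer_rate(I, a: float, b: float, d: float):
    """Firing rate (aI-b)/(1-exp(-d(aI-b))), continuous at aI-b=0 (value 1/d)."""
    x = a * np.asarray(I, dtype=float) - b
    y = d * x
    small = np.abs(y) < 1e-6
    # same operation order as the compiled kernel's scalar version, so the
    # two integration paths agree bit-for-bit
    denom = 1.0 - np.exp(-np.clip(y, -700.0, None))
    r = np.where(small, 1.0 / d + x / 2.0 + d * x * x / 12.0,
                 x / np.where(small, 1.0, denom))
    if np.ndim(I) == 0:
        return float(r)
    return r


@njit(cache=True)
def _phi(I: float, a: float, b: float, d: float) -> float:
    x = a * I - b
    y = d * x
    if abs(y) < 1e-6:
        return 1.0 / d + x / 2.0 + d * x * x / 12.0
    if y < -700.0:
        y = -700.0
    return x / (1.0 - math.exp(-y))


# ---------------------------------------------------------------------------
# One Euler-Maruyama step (reference implementation)
# ---------------------------------------------------------------------------

def _currents(S_E: np.ndarray, S_I: np.ndarray, J: np.ndarray,
              weights: np.ndarray, p: DMFParams) -> tuple[np.ndarray, np.ndarray]:
    # scalar prefactors and the scaled matvec mirror the compiled kernel
    coupling = (p.G * p.J_N * weights) @ S_E
    I_E = (p.w_E * p.I_0) + (p.w_plus * p.J_N) * S_E + coupling - J * S_I
    I_I = (p.w_I * p.I_0) + p.J_N * S_E - p.w_II * S_I
    return I_E, I_I


def step(state: DMFState, c: Connectome, p: DMFParams,
         rng: np.random.Generator | None = None,
         noise: tuple[np.ndarray, np.ndarray] | None = None) -> DMFState:
    """One Euler-Maruyama update of all gating variables.

    ``noise`` supplies the pair of standard-normal increment vectors
    (excitatory, inhibitory); otherwise they are drawn from ``rng``.
    Results are clipped to [0, 1].
    """
    n = c.n_regions
    if state.S_E.shape != (n,):
        raise ValueError(f"state has {state.S_E.shape[0]} regions, connectome has {n}")
    if noise is None:
        if p.sigma > 0:
            if rng is None:
                raise ValueError("rng required when sigma > 0 and no noise is given")
            eta_E = rng.standard_normal(n)
            eta_I = rng.standard_normal(n)
        else:
            eta_E = eta_I = np.zeros(n)
    else:
        eta_E, eta_I = noise
    dt_s = p.dt / 1000.0
    sq = p.sigma * math.sqrt(dt_s)
    inv_te = 1000.0 / p.tau_E
    inv_ti = 1000.0 / p.tau_I
    I_E, I_I = _currents(state.S_E, state.S_I, state.J, c.weights, p)
    r_E = transfer_rate(I_E, p.a_E, p.b_E, p.d_E)
    r_I = transfer_rate(I_I, p.a_I, p.b_I, p.d_I)
    S_E = state.S_E + dt_s * (-state.S_E * inv_te
                              + (1.0 - state.S_E) * p.gamma * r_E) + sq * eta_E
    S_I = state.S_I + dt_s * (-state.S_I * inv_ti + r_I) + sq * eta_I
    return DMFState(S_E=np.clip(S_E, 0.0, 1.0), S_I=np.clip(S_I, 0.0, 1.0), J=state.J)


# ---------------------------------------------------------------------------
# Compiled multi-step loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dmf_chunk(S_E, S_I, J, Wg, w_e_i0, wp_jn, w_i_i0, j_n, w_ii,
               a_e, b_e, d_e, a_i, b_i, d_i, inv_te, inv_ti, gamma,
               dt_s, sq_sigma, eta_E, eta_I,
               offset, accum_start, sum_rE, sum_rI, sum_IE,
               rec, rec_stride, rec_count):
    n = S_E.shape[0]
    m = eta_E.shape[0]
    for t in range(m):
        coupling = np.dot(Wg, S_E)
        g = offset + t
        for i in range(n):
            ie = w_e_i0 + wp_jn * S_E[i] + coupling[i] - J[i] * S_I[i]
            ii = w_i_i0 + j_n * S_E[i] - w_ii * S_I[i]
            re = _phi(ie, a_e, b_e, d_e)
            ri = _phi(ii, a_i, b_i, d_i)
            if g >= accum_start:
                sum_rE[i] += re
                sum_rI[i] += ri
                sum_IE[i] += ie
            se = S_E[i] + dt_s * (-S_E[i] * inv_te + (1.0 - S_E[i]) * gamma * re) \
                + sq_sigma * eta_E[t, i]
            si = S_I[i] + dt_s * (-S_I[i] * inv_ti + ri) + sq_sigma * eta_I[t, i]
            S_E[i] = min(max(se, 0.0), 1.0)
            S_I[i] = min(max(si, 0.0), 1.0)
        if rec_stride > 0 and (g + 1) % rec_stride == 0:
            for i in range(n):
                rec[rec_count, i] = S_E[i]
            rec_count += 1
    return rec_count


class NetworkIntegrator:
    """Stateful Euler-Maruyama integrator over a fixed connectome.

    Holds (S_E, S_I, J) across calls so the feedback-inhibition loop can
    simulate consecutive windows without state resets.
    """

    _CHUNK = 4000

    def __init__(self, c: Connectome, p: DMFParams, J: np.ndarray | float = 1.0,
                 state: DMFState | None = None):
        self.p = p
        self.n = c.n_regions
        self.Wg = np.ascontiguousarray(p.G * p.J_N * c.weights)
        self.state = state if state is not None else DMFState.initial(self.n, J)
        self.steps_done = 0

    def run(self, n_steps: int, rng: np.random.Generator,
            accum_start: int = 0, record_stride: int = 0
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
        """Advance ``n_steps``; return per-region means of r_E, r_I, I_E over
        steps >= ``accum_start`` (index local to this call) and the recorded
        S_E trace (every ``record_stride`` steps) if requested."""
        p = self.p
        dt_s = p.dt / 1000.0
        sq = p.sigma * math.sqrt(dt_s)
        n = self.n
        sum_rE = np.zeros(n)
        sum_rI = np.zeros(n)
        sum_IE = np.zeros(n)
        n_rec = n_steps // record_stride if record_stride > 0 else 0
        rec = np.empty((max(n_rec, 1), n)) if record_stride > 0 else np.empty((1, n))
        rec_count = 0
        S_E, S_I, J = self.state.S_E, self.state.S_I, np.asarray(self.state.J, dtype=float)
        done = 0
        while done < n_steps:
            m = min(self._CHUNK, n_steps - done)
            if p.sigma > 0:
                eta_E = rng.standard_normal((m, n))
                eta_I = rng.standard_normal((m, n))
            else:
                eta_E = np.zeros((m, n))
                eta_I = np.zeros((m, n))
            rec_count = _dmf_chunk(
                S_E, S_I, J, self.Wg,
                p.w_E * p.I_0, p.w_plus * p.J_N, p.w_I * p.I_0, p.J_N, p.w_II,
                p.a_E, p.b_E, p.d_E, p.a_I, p.b_I, p.d_I,
                1000.0 / p.tau_E, 1000.0 / p.tau_I, p.gamma,
                dt_s, sq, eta_E, eta_I,
                done, accum_start, sum_rE, sum_rI, sum_IE,
                rec, record_stride, rec_count)
            done += m
            if not np.all(np.isfinite(S_E)) or not np.all(np.isfinite(S_I)):
                raise NumericalBlowupError(
                    f"non-finite gating state by step {self.steps_done + done}")
        self.steps_done += n_steps
        n_acc = max(n_steps - accum_start, 1)
        trace = rec[:rec_count] if record_stride > 0 else None
        return sum_rE / n_acc, sum_rI / n_acc, sum_IE / n_acc, trace


def simulate(c: Connectome, p: DMFParams, J: np.ndarray | float = 1.0,
             duration: float = 600.0, transient: float = 120.0,
             record_stride: int = 0, seed: int | None = None,
             rng: np.random.Generator | None = None) -> SimulationResult:
    """Simulate the network for ``duration`` seconds; averages discard the
    first ``transient`` seconds. ``record_stride`` > 0 stores S_E every that
    many integration steps (including the transient, for the hemodynamic
    stage which applies its own transient removal)."""
    if duration <= transient:
        raise ValueError("duration must exceed transient")
    if rng is None:
        rng = np.random.default_rng(p.seed if seed is None else seed)
    steps = int(round(duration * 1000.0 / p.dt))
    accum_start = int(round(transient * 1000.0 / p.dt))
    integ = NetworkIntegrator(c, p, J)
    r_E, r_I, I_E, trace = integ.run(steps, rng, accum_start=accum_start,
                                     record_stride=record_stride)
    return SimulationResult(
        r_E=r_E, r_I=r_I, I_E=I_E, duration=duration, transient=transient,
        seed=seed if seed is not None else p.seed,
        S_E_trace=trace,
        trace_dt=record_stride * p.dt / 1000.0 if record_stride else None)
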