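"""Feedback inhibition control (FIC): homeostatic tuning of local inhibition.

Each region's feedback inhibitory weight J_i is adjusted recursively so that
its window-averaged excitatory input current sits at the homeostatic working
point I* = b_E/a_E - 0.026 nA (within +/- 0.005 nA). Through the excitatory
transfer function this current band maps exactly onto a mean excitatory
firing band of 2.63-3.55 Hz around the ~3 Hz set point, i.e. the balanced
excitation-inhibition state of the resting cortex.

The loop simulates consecutive windows (default 10 s) without state resets:
after each window, regions whose mean current is above the band get more
inhibition (J up), regions below get less (J down), with a per-region
additive step that halves whenever the region's deviation changes sign
(oscillation around the band). Tuning ends on the first window in which
every region is inside the band, or when the window budget is exhausted.

The re-adjustment time RT_i is window_length times the index (1-based) of
the last window in which region i violated the band; a region that is
in band from the start has RT_i = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import Connectome
from .dmf import DMFParams, NetworkIntegrator, transfer_rate

__all__ = [
    "FICResult",
    "WeightChange",
    "target_current",
    "default_J_init",
    "run_fic",
    "weight_change",
    "CURRENT_OFFSET",
    "CURRENT_TOL",
]

logger = logging.getLogger(__name__)

CURRENT_OFFSET = -0.026   # nA below the excitatory transfer threshold b_E/a_E
CURRENT_TOL = 0.005       # nA half-width of the homeostatic band
J_FLOOR = 0.001           # nA lower bound on inhibitory weights


def target_current(p: DMFParams) -> float:
    """Homeostatic set point for the mean excitatory input current (nA)."""
    return p.b_E / p.a_E + CURRENT_OFFSET


def firing_band(p: DMFParams) -> tuple[float, float]:
    """Excitatory firing-rate band implied by the current band (Hz)."""
    t = target_current(p)
    return (transfer_rate(t - CURRENT_TOL, p.a_E, p.b_E, p.d_E),
            transfer_rate(t + CURRENT_TOL, p.a_E, p.b_E, p.d_E))


def balanced_gating(p: DMFParams) -> tuple[float, float, float]:
    """Gating values (S_E*, S_I*) and isolated-node weight J* at the set point.

    At the homeostatic current target the excitatory rate and hence S_E*
    follow in closed form; S_I* solves the scalar inhibitory fixed point
    S_I = tau_I * r_I(w_I*I_0 + J_N*S_E* - w_II*S_I); J* then balances the
    excitatory current of a decoupled region exactly.
    """
    from scipy.optimize import brentq

    t = target_current(p)
    r_e = transfer_rate(t, p.a_E, p.b_E, p.d_E)
    tau_e = p.tau_E / 1000.0
    tau_i = p.tau_I / 1000.0
    s_e = p.gamma * r_e * tau_e / (1.0 + p.gamma * r_e * tau_e)

    def f(s_i: float) -> float:
        i_i = p.w_I * p.I_0 + p.J_N * s_e - p.w_II * s_i
        return tau_i * transfer_rate(i_i, p.a_I, p.b_I, p.d_I) - s_i

    s_i = brentq(f, 1e-9, 1.0)
    j_iso = (p.w_E * p.I_0 + p.w_plus * p.J_N * s_e - t) / s_i
    return s_e, s_i, j_iso


def default_J_init(c: Connectome, p: DMFParams) -> np.ndarray:
    """Balanced-state initial guess for the inhibitory weights.

    Assumes every region sits at the homeostatic gating point, which makes
    the required weight affine in nodal strength:
    J_i = J* + (G*J_N*S_E*/S_I*) * strength_i. The recursion then only has
    to absorb network fluctuations around that point.
    """
    s_e, s_i, j_iso = balanced_gating(p)
    return j_iso + (p.G * p.J_N * s_e / s_i) * c.weights.sum(axis=1)


@dataclass
class FICResult:
    J_final: np.ndarray        # nA
    RT: np.ndarray             # s, per-region re-adjustment time
    converged: np.ndarray      # bool per region
    firing: np.ndarray         # Hz, mean excitatory rate in the final window
    I_E: np.ndarray            # nA, mean excitatory current in the final window
    n_windows: int
    window_length: float       # s


@dataclass
class WeightChange:
    """Signed inhibitory-weight change dJJ = J' - J; lesioned entry is NaN."""

    dJJ: np.ndarray
    abs_dJJ: np.ndarray
    lesion: int | None


def run_fic(c: Connectome, p: DMFParams, J_init: np.ndarray | None = None,
            window_length: float = 10.0, max_windows: int = 200,
            step: float = 0.05, tol: float = CURRENT_TOL,
            seed: int | None = None,
            rng: np.random.Generator | None = None) -> FICResult:
    """Tune per-region inhibitory weights to the homeostatic current band.

    Parameters
    ----------
    J_init
        Starting weights (> 0). Defaults to the strength heuristic
        ``default_J_init``; post-lesion re-tuning should pass the healthy
        run's final weights.
    window_length, max_windows
        Seconds per tuning window and the window budget.
    step
        Initial additive weight update (nA); halves per region on
        oscillation, never below 1e-4.
    """
    n = c.n_regions
    if J_init is None:
        J = default_J_init(c, p)
    else:
        J = np.asarray(J_init, dtype=float).copy()
        if J.shape != (n,):
            raise ValueError(f"J_init has shape {J.shape}, expected ({n},)")
        if np.any(J <= 0):
            raise ValueError("J_init must be positive")
    if rng is None:
        rng = np.random.default_rng(p.seed if seed is None else seed)

    target = target_current(p)
    window_steps = int(round(window_length * 1000.0 / p.dt))
    integ = NetworkIntegrator(c, p, J)
    delta = np.full(n, float(step))
    last_dir = np.zeros(n)
    last_violation = np.zeros(n, dtype=int)
    r_E = np.zeros(n)
    I_E = np.full(n, target)
    in_band = np.zeros(n, dtype=bool)
    w = 0
    for w in range(1, max_windows + 1):
        integ.state.J = J
        r_E, _, I_E, _ = integ.run(window_steps, rng)
        dev = I_E - target
        viol = np.abs(dev) > tol
        in_band = ~viol
        if not np.any(viol):
            break
        last_violation[viol] = w
        direction = np.sign(dev)
        flipped = viol & (last_dir != 0) & (direction != last_dir)
        delta[flipped] = np.maximum(delta[flipped] * 0.5, 1e-4)
        J = J.copy()
        J[viol] = np.maximum(J[viol] + direction[viol] * delta[viol], J_FLOOR)
        last_dir[viol] = direction[viol]
    else:
        warnings.warn(
            f"FIC budget of {max_windows} windows exhausted; "
            f"{int(np.sum(~in_band))} region(s) unconverged",
            RuntimeWarning, stacklevel=2)
        logger.warning("FIC unconverged regions: %s", np.nonzero(~in_band)[0])

    return FICResult(
        J_final=J, RT=window_length * last_violation.astype(float),
        converged=in_band, firing=r_E, I_E=I_E,
        n_windows=w, window_length=window_length)


def weight_change(J_healthy: np.ndarray, J_lesioned: np.ndarray,
                  lesion: int | None = None) -> WeightChange:
    """Per-region inhibitory weight change dJJ = J' - J, lesioned entry NaN."""
    a = np.asarray(J_healthy, dtype=float)
    b = np.asarray(J_lesioned, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = b - a
    if lesion is not None:
        d = d.copy()
        d[lesion] = np.nan
    return WeightChange(dJJ=d, abs_dJJ=np.abs(d), lesion=lesion)
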