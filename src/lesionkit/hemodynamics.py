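"""Forward hemodynamic model (Balloon-Windkessel) and FC construction.

Regional synaptic activity drives a four-state vasodilatory cascade per
region — vasodilatory signal s, normalised blood inflow f, venous volume v
and deoxyhemoglobin content q:

    ds/dt = z - kappa*s - gamma_f*(f - 1)
    df/dt = s
    tau dv/dt = f - v**(1/alpha)
    tau dq/dt = f*(1 - (1-rho)**(1/f))/rho - v**(1/alpha) * q/v

with the BOLD percent signal change read out as
100 * V0 * (k1*(1-q) + k2*(1-q/v) + k3*(1-v)), k1 = 7*rho, k2 = 2,
k3 = 2*rho - 0.2. At zero drive the system rests at s=0, f=v=q=1 and the
readout is exactly 0%. The drive should therefore be zero-centred activity
(the pipeline subtracts each region's temporal mean of S_E).

Functional connectivity is the Pearson correlation matrix of the per-region
z-scored BOLD series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BalloonParams",
    "BOLDSeries",
    "FCMatrix",
    "bold_from_activity",
    "fc_from_bold",
]


@dataclass(frozen=True)
class BalloonParams:
    """Standard Balloon-Windkessel constants (times in s)."""

    kappa: float = 0.65      # signal decay rate, s^-1
    gamma_f: float = 0.41    # flow-dependent elimination, s^-1
    tau: float = 0.98        # hemodynamic transit time, s
    alpha: float = 0.32      # Grubb vessel stiffness exponent
    rho: float = 0.34        # resting oxygen extraction fraction
    V0: float = 0.02         # resting venous blood volume fraction


@dataclass
class BOLDSeries:
    samples: np.ndarray      # (region, time), % signal change
    TR: float                # s
    duration: float          # s covered by the samples


@dataclass
class FCMatrix:
    values: np.ndarray       # (region, region) Pearson correlations
    condition: str = "healthy"

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def bold_from_activity(activity: np.ndarray, dt: float, TR: float = 2.0,
                       p: BalloonParams = BalloonParams(),
                       transient: float = 0.0) -> BOLDSeries:
    """Integrate the Balloon-Windkessel system driven by ``activity``.

    Parameters
    ----------
    activity
        Zero-centred neural drive, shape (region, time) or (time, region)
        resolved by ``dt`` x length; internally (region, time).
    dt
        Sampling interval of ``activity`` in seconds (also the Euler step).
    TR
        Output sampling interval (s).
    transient
        Initial seconds to discard from the output.
    """
    z = np.asarray(activity, dtype=float)
    if z.ndim != 2:
        raise ValueError("activity must be 2-D (region x time)")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in activity")
    n, T = z.shape
    if n > T:  # assume (time, region) orientation
        z = z.T
        n, T = z.shape

    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    k1 = 7.0 * p.rho
    k2 = 2.0
    k3 = 2.0 * p.rho - 0.2

    stride = max(int(round(TR / dt)), 1)
    n_out = T // stride
    out = np.empty((n, n_out))
    j = 0
    for t in range(T):
        fv = v ** (1.0 / p.alpha)
        E = 1.0 - (1.0 - p.rho) ** (1.0 / f)
        ds = z[:, t] - p.kappa * s - p.gamma_f * (f - 1.0)
        df = s
        dv = (f - fv) / p.tau
        dq = (f * E / p.rho - fv * q / v) / p.tau
        s = s + dt * ds
        f = np.maximum(f + dt * df, 1e-6)
        v = np.maximum(v + dt * dv, 1e-6)
        q = np.maximum(q + dt * dq, 1e-6)
        if (t + 1) % stride == 0:
            out[:, j] = 100.0 * p.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
            j += 1
    out = out[:, :j]
    drop = int(round(transient / TR))
    out = out[:, drop:]
    return BOLDSeries(samples=out, TR=TR, duration=out.shape[1] * TR)


def fc_from_bold(b: BOLDSeries, condition: str = "healthy") -> FCMatrix:
    """Pearson FC of per-region z-scored BOLD; zero-variance regions get 0."""
    x = b.samples
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time points for FC")
    sd = x.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} region(s) with zero BOLD variance; their FC is 0",
            RuntimeWarning, stacklevel=2)
    xs = (x - x.mean(axis=1, keepdims=True)) / np.where(flat, 1.0, sd)[:, None]
    fc = (xs @ xs.T) / x.shape[1]
    fc[flat, :] = 0.0
    fc[:, flat] = 0.0
    np.fill_diagonal(fc, 1.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    return FCMatrix(values=fc, condition=condition)
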