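"""1-D heat conduction in skin under a contact thermode.

The skin is modelled as a homogeneous half-space with thermal diffusivity
``alpha``: dT/dt = alpha * d2T/dx2, with a Dirichlet surface boundary equal to
the thermode setpoint program (perfect thermal contact), a uniform initial
condition at the neutral temperature, and a fixed far boundary several
millimetres deep.  The quantity of interest is the temperature history at
nociceptor depth (default 150 µm, with a 100 µm alternative preset) and the
first time it crosses a transduction threshold — e.g. 43 °C for heat
(TRPV1-like) — which sets the thermal-lag component of first-spike latency.

The solver is a Crank–Nicolson scheme (unconditionally stable, second order);
closed-form erfc/Duhamel solutions for step and ramp-and-hold boundaries are
provided as independent verification oracles.  ``calibrate_diffusivity`` fits
the single free scalar so that the hot protocol's 43 °C crossing at 150 µm
matches a target latency; the cold prediction is then parameter-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky_banded, cho_solve_banded
from scipy.optimize import brentq
from scipy.special import erfc

from .protocols import ThermalProtocol

__all__ = [
    "SkinThermalParams",
    "TemperatureField",
    "solve_skin_temperature",
    "analytic_step_response",
    "analytic_ramp_hold_response",
    "threshold_crossing_latency",
    "calibrate_diffusivity",
    "NO_CROSSING",
    "DEFAULT_DIFFUSIVITY",
    "NOCICEPTOR_DEPTH",
    "ALT_NOCICEPTOR_DEPTH",
    "HEAT_THRESHOLD",
    "COLD_TARGET_TEMP",
]

#: diffusivity (m²/s) calibrated so the 52 °C / 300 °C/s protocol reaches
#: 43 °C at 150 µm in 470 ms (see analysis/01_calibrate_thermal.py); within
#: the epidermal literature range of order 1e-7 m²/s.
DEFAULT_DIFFUSIVITY = 9.0008012162746e-08
NOCICEPTOR_DEPTH = 150e-6
ALT_NOCICEPTOR_DEPTH = 100e-6
HEAT_THRESHOLD = 43.0
COLD_TARGET_TEMP = 18.0

#: sentinel returned when the depth trace never crosses the threshold
NO_CROSSING = math.nan


class ResolutionError(ValueError):
    """Grid too coarse to resolve the nociceptor depth."""


@dataclass(frozen=True)
class SkinThermalParams:
    diffusivity: float = DEFAULT_DIFFUSIVITY
    nociceptor_depth: float = NOCICEPTOR_DEPTH
    initial_temp: float = 30.0
    domain_depth: float = 5e-3
    far_boundary_temp: float = 30.0

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if not 0 < self.nociceptor_depth < self.domain_depth:
            raise ValueError("need 0 < nociceptor_depth < domain_depth")


@dataclass(frozen=True)
class TemperatureField:
    """Temperature as a function of depth and time under one protocol."""

    depth_grid: np.ndarray
    time_grid: np.ndarray
    temperatures: np.ndarray  # (time, depth)
    protocol: ThermalProtocol = field(compare=False)
    params: SkinThermalParams = field(compare=False, default=None)

    def depth_trace(self, depth: float) -> np.ndarray:
        """Temperature history at ``depth``, linearly interpolated between nodes."""
        if not self.depth_grid[0] <= depth <= self.depth_grid[-1]:
            raise ValueError("depth outside the solved domain")
        j = np.searchsorted(self.depth_grid, depth)
        if j == 0 or math.isclose(self.depth_grid[j], depth):
            return self.temperatures[:, j].copy()
        x0, x1 = self.depth_grid[j - 1], self.depth_grid[j]
        w = (depth - x0) / (x1 - x0)
        return (1 - w) * self.temperatures[:, j - 1] + w * self.temperatures[:, j]


def solve_skin_temperature(
    p: ThermalProtocol,
    sp: SkinThermalParams | None = None,
    dt: float = 1e-3,
    dx: float = 10e-6,
    t_end: float | None = None,
) -> TemperatureField:
    """Crank–Nicolson solution of the diffusion problem under protocol ``p``.

    The surface node follows the setpoint exactly; the far node is pinned at
    ``far_boundary_temp``.  Raises :class:`ResolutionError` when fewer than 3
    nodes lie at or above the nociceptor depth.
    """
    sp = sp or SkinThermalParams()
    if dt <= 0 or dx <= 0:
        raise ValueError("dt and dx must be positive")
    if t_end is None:
        t_end = p.total_duration
    nx = int(round(sp.domain_depth / dx)) + 1
    depth = np.linspace(0.0, sp.domain_depth, nx)
    if np.sum(depth <= sp.nociceptor_depth + 1e-15) < 3:
        raise ResolutionError("fewer than 3 nodes above the nociceptor depth")
    nt = int(math.floor(t_end / dt + 1e-9)) + 1
    time = np.arange(nt) * dt
    lam = sp.diffusivity * dt / dx**2

    # interior system (I - lam/2 * L) T^{n+1} = (I + lam/2 * L) T^n + bc terms;
    # the matrix is constant, SPD and tridiagonal -> factor once.
    n_int = nx - 2
    ab = np.zeros((2, n_int))
    ab[0, 1:] = -lam / 2.0
    ab[1, :] = 1.0 + lam
    cb = cholesky_banded(ab)

    surface = p.temperature(np.minimum(time, p.total_duration))
    temps = np.empty((nt, nx))
    temps[0] = sp.initial_temp
    temps[0, 0] = surface[0]
    temps[0, -1] = sp.far_boundary_temp

    u = temps[0, 1:-1].copy()
    for n in range(1, nt):
        rhs = (1.0 - lam) * u
        rhs[1:] += (lam / 2.0) * u[:-1]
        rhs[:-1] += (lam / 2.0) * u[1:]
        rhs[0] += (lam / 2.0) * (surface[n - 1] + surface[n])
        rhs[-1] += lam * sp.far_boundary_temp
        u = cho_solve_banded((cb, False), rhs)
        temps[n, 1:-1] = u
        temps[n, 0] = surface[n]
        temps[n, -1] = sp.far_boundary_temp
    return TemperatureField(depth_grid=depth, time_grid=time, temperatures=temps,
                            protocol=p, params=sp)


# -- closed-form oracles ---------------------------------------------------

def analytic_step_response(sp: SkinThermalParams, depth: float, delta: float, t):
    """Semi-infinite step solution: T = T0 + delta * erfc(x / (2 sqrt(alpha t)))."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, sp.initial_temp, dtype=float)
    pos = t > 0
    if depth == 0:
        out[pos] = sp.initial_temp + delta
    else:
        arg = depth / (2.0 * np.sqrt(sp.diffusivity * t[pos]))
        out[pos] = sp.initial_temp + delta * erfc(arg)
    return float(out) if out.ndim == 0 else out


def _i2erfc(eta: np.ndarray) -> np.ndarray:
    """Second repeated integral of erfc (i²erfc)."""
    return 0.25 * ((1.0 + 2.0 * eta**2) * erfc(eta)
                   - 2.0 * eta / math.sqrt(math.pi) * np.exp(-(eta**2)))


def analytic_ramp_hold_response(
    sp: SkinThermalParams, depth: float, rate: float, t_ramp_end: float, t
):
    """Duhamel solution for a surface ramp at ``rate`` starting at t=0 and
    frozen at ``t_ramp_end`` (ramp-and-hold boundary)."""

    def ramp_term(tt: np.ndarray) -> np.ndarray:
        out = np.zeros_like(tt)
        pos = tt > 0
        if depth == 0:
            out[pos] = tt[pos]
        else:
            eta = depth / (2.0 * np.sqrt(sp.diffusivity * tt[pos]))
            out[pos] = 4.0 * tt[pos] * _i2erfc(eta)
        return out

    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    resp = sp.initial_temp + rate * (ramp_term(t) - ramp_term(t - t_ramp_end))
    return float(resp[0]) if scalar else resp


def threshold_crossing_latency(
    f: TemperatureField, depth: float, threshold: float, direction: str
) -> float:
    """First time the depth trace crosses ``threshold`` in the stated direction,
    linearly interpolated between time samples; NaN when never crossed."""
    if direction not in ("heating", "cooling"):
        raise ValueError("direction must be 'heating' or 'cooling'")
    trace = f.depth_trace(depth)
    if direction == "heating":
        hit = trace >= threshold
    else:
        hit = trace <= threshold
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return NO_CROSSING
    i = idx[0]
    if i == 0:
        return 0.0
    t0, t1 = f.time_grid[i - 1], f.time_grid[i]
    y0, y1 = trace[i - 1], trace[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def calibrate_diffusivity(
    protocol: ThermalProtocol,
    target_latency: float,
    threshold: float = HEAT_THRESHOLD,
    depth: float = NOCICEPTOR_DEPTH,
    direction: str = "heating",
    sp: SkinThermalParams | None = None,
    bounds: tuple[float, float] = (2e-8, 5e-7),
    dt: float = 1e-3,
    dx: float = 10e-6,
) -> float:
    """Find the diffusivity at which the protocol's threshold crossing at
    ``depth`` equals ``target_latency`` (root-finding on the solver itself)."""
    sp = sp or SkinThermalParams()

    def residual(alpha: float) -> float:
        f = solve_skin_temperature(protocol, replace(sp, diffusivity=alpha), dt=dt, dx=dx)
        lat = threshold_crossing_latency(f, depth, threshold, direction)
        if math.isnan(lat):
            return 1e3  # no crossing: alpha far too small
        return lat - target_latency

    return brentq(residual, *bounds, xtol=1e-13)
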