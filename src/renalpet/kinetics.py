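"""Irreversible two-tissue-compartment (2TCM) kinetics for FDG.

Model
-----
With plasma input Cp(t), free (unphosphorylated) tracer Cf and trapped
(phosphorylated) tracer Ct obey

    dCf/dt = K1*Cp - (k2 + k3)*Cf,      dCt/dt = k3*Cf,      k4 = 0,

and the measured tissue concentration includes a fractional blood volume Vb:

    C_T(t) = (1 - Vb)*(Cf + Ct) + Vb*Cp(t).

The net influx macro-parameter is Ki = K1*k3/(k2+k3) (mL cm^-3 min^-1).

Numerics
--------
Cp is represented as a piecewise-linear curve on a time grid.  On every grid
interval the convolution states

    z(t) = int_0^t Cp,          y(t) = int_0^t e^{-beta (t-s)} Cp(s) ds,

(beta = k2 + k3, per second) have closed forms, as do their interval
integrals, so both point values of C_T and *exact* frame-interval averages of
C_T are computed without quadrature error for the piecewise-linear input.
The stabilised exponential kernels

    phi1(x) = (1 - e^-x)/x,  phi2(x) = (e^-x - 1 + x)/x^2,
    phi3(x) = (x^2/2 - x + 1 - e^-x)/x^3,

are evaluated by series for small x to avoid cancellation.

Rate constants are per minute at every public interface and converted to per
second internally (frame times are in seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError
from .frames import FramingSchedule, TimeActivityCurve
from .input_function import InputFunctionParams, eval_input_function

__all__ = [
    "KineticParams",
    "FitDiagnostics",
    "ki_macro",
    "simulate_tissue",
    "simulate_tissue_framed",
    "fit_2tcm",
]


@dataclass(frozen=True)
class KineticParams:
    """2TCM rate constants (per minute) and fractional blood volume.

    ``K1`` is the plasma-to-tissue transfer constant (mL cm^-3 min^-1), ``k2``
    the efflux and ``k3`` the phosphorylation/trapping rate (min^-1); ``k4``
    is fixed at 0 (irreversible trapping over a 40-min scan); ``Vb`` is the
    dimensionless fractional blood volume in [0, 1).
    """

    K1: float
    k2: float
    k3: float
    Vb: float = 0.0
    k4: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.K1, self.k2, self.k3, self.Vb, self.k4)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("kinetic parameters must be finite")
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise InvalidParameterError("rate constants must be non-negative")
        if self.k4 != 0.0:
            raise InvalidParameterError("the model is irreversible: k4 must be 0")
        if not (0.0 <= self.Vb < 1.0):
            raise InvalidParameterError("Vb must lie in [0, 1)")

    @property
    def ki(self) -> float:
        return ki_macro(self)


@dataclass(frozen=True)
class FitDiagnostics:
    """Convergence bookkeeping for a 2TCM fit."""

    residual_sum_squares: float
    iterations: int
    converged: bool
    covariance_ok: bool

    def __post_init__(self) -> None:
        if self.residual_sum_squares < 0:
            raise InvalidParameterError("residual_sum_squares must be >= 0")
        if self.converged and self.iterations < 1:
            raise InvalidParameterError("a converged fit implies >= 1 iteration")


def ki_macro(kp: KineticParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) (mL cm^-3 min^-1); 0 when k2+k3 == 0."""
    denom = kp.k2 + kp.k3
    if denom <= 0.0:
        return 0.0
    return kp.K1 * kp.k3 / denom


# ---------------------------------------------------------------------------
# stabilised exponential kernels
# ---------------------------------------------------------------------------

def _phi123(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    small = x < 0.03
    xl = np.where(small, 1.0, x)  # dummy 1.0 avoids 0/0 in the closed forms
    em = np.exp(-xl)
    p1_l = (1.0 - em) / xl
    p2_l = (em - 1.0 + xl) / xl**2
    p3_l = (0.5 * xl**2 - xl + 1.0 - em) / xl**3
    xs = np.where(small, x, 0.0)
    p1_s = 1.0 - xs / 2 + xs**2 / 6 - xs**3 / 24 + xs**4 / 120
    p2_s = 0.5 - xs / 6 + xs**2 / 24 - xs**3 / 120 + xs**4 / 720
    p3_s = 1.0 / 6 - xs / 24 + xs**2 / 120 - xs**3 / 720 + xs**4 / 5040
    return (
        np.where(small, p1_s, p1_l),
        np.where(small, p2_s, p2_l),
        np.where(small, p3_s, p3_l),
    )


class _Forward(NamedTuple):
    """Node values and per-interval integrals of the forward model."""

    ct: np.ndarray        # C_T at nodes
    int_ct: np.ndarray    # integral of C_T over each interval
    free: np.ndarray      # free-compartment concentration Cf at nodes
    int_cp: np.ndarray    # integral of Cp over each interval


def _forward(t: np.ndarray, cp: np.ndarray, kp: KineticParams) -> _Forward:
    """Exact 2TCM response to the piecewise-linear input (t, cp)."""
    h = np.diff(t)
    if np.any(h <= 0):
        raise InvalidParameterError("time grid must be strictly increasing")
    c0 = cp[:-1]
    m = np.diff(cp) / h

    k1s, k2s, k3s = kp.K1 / 60.0, kp.k2 / 60.0, kp.k3 / 60.0
    beta = k2s + k3s

    int_cp = 0.5 * (cp[:-1] + cp[1:]) * h
    z = np.concatenate([[0.0], np.cumsum(int_cp)])
    int_z = z[:-1] * h + c0 * h**2 / 2 + m * h**3 / 6

    if beta > 0.0:
        x = beta * h
        p1, p2, p3 = _phi123(x)
        decay = np.exp(-x)
        push = c0 * h * p1 + m * h**2 * p2
        y = np.empty_like(t)
        y[0] = 0.0
        for i in range(h.size):  # short scan; exact per-interval update
            y[i + 1] = y[i] * decay[i] + push[i]
        int_y = y[:-1] * h * p1 + c0 * h**2 * p2 + m * h**3 * p3
        conv = k1s * (k3s * z + k2s * y) / beta
        int_conv = k1s * (k3s * int_z + k2s * int_y) / beta
        free = k1s * y
    else:  # k2 = k3 = 0: pure irreversible delivery into the free compartment
        conv = k1s * z
        int_conv = k1s * int_z
        free = k1s * z

    ct = (1.0 - kp.Vb) * conv + kp.Vb * cp
    int_ct = (1.0 - kp.Vb) * int_conv + kp.Vb * int_cp
    return _Forward(ct=ct, int_ct=int_ct, free=free, int_cp=int_cp)


def simulate_tissue(
    p_in: InputFunctionParams, kp: KineticParams, t_grid: Sequence[float]
) -> np.ndarray:
    """Tissue concentration C_T (kBq/mL) at the points of ``t_grid`` (seconds).

    ``t_grid`` must be strictly increasing and start at 0.  The input function
    is evaluated at the grid nodes and treated as piecewise linear in between,
    so a finer grid gives a more faithful response to the bolus curvature.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidParameterError("t_grid must contain at least two points")
    if t[0] != 0.0:
        raise InvalidParameterError("t_grid must start at 0")
    cp = np.asarray(eval_input_function(p_in, t), dtype=float)
    return _forward(t, cp, kp).ct


def _framed_from_nodes(
    t_nodes: np.ndarray,
    cp_nodes: np.ndarray,
    frame_of_interval: np.ndarray,
    durations: np.ndarray,
    kp: KineticParams,
) -> tuple[np.ndarray, _Forward]:
    fwd = _forward(t_nodes, cp_nodes, kp)
    n_frames = durations.size
    means = np.bincount(frame_of_interval, weights=fwd.int_ct, minlength=n_frames) / durations
    return means, fwd


def simulate_tissue_framed(
    p_in: InputFunctionParams,
    kp: KineticParams,
    schedule: FramingSchedule,
    max_step: float = 0.5,
    region: str = "",
) -> TimeActivityCurve:
    """Frame-interval averages of C_T on ``schedule`` (not midpoint samples).

    Frames of mixed length (1 s and 30 s) coexist, so each frame mean is the
    exact integral of the model over the frame divided by its duration; the
    internal grid refines every frame to steps of at most ``max_step`` seconds
    to resolve the bolus curvature.
    """
    nodes, frame_idx = schedule.refined(max_step)
    cp = np.asarray(eval_input_function(p_in, nodes), dtype=float)
    means, _ = _framed_from_nodes(nodes, cp, frame_idx, schedule.duration, kp)
    return TimeActivityCurve(schedule, means, region=region)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = ((1e-6, 0.0, 0.0, 0.0), (5.0, 10.0, 5.0, 0.9))
_ACTIVITY_FLOOR_FRAC = 0.01  # weight floor: 1% of the curve peak


def _cp_node_representation(input_tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Continuous (piecewise-linear) plasma curve through the frame midpoints."""
    mids = input_tac.schedule.mid
    vals = input_tac.values
    t = np.concatenate([[input_tac.schedule.start[0]], mids, [input_tac.schedule.end[-1]]])
    # constant extrapolation at both ends of the sampled mid-times
    v = np.concatenate([[vals[0]], vals, [vals[-1]]])
    return t, v


def fit_2tcm(
    tac: TimeActivityCurve,
    input_tac: TimeActivityCurve,
    init: KineticParams | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    weighting: str = "frame-duration",
    t_max: float | None = None,
) -> tuple[KineticParams, FitDiagnostics]:
    """Weighted least-squares 2TCM fit of a tissue curve against a plasma curve.

    Model predictions are frame-interval averages (matching how the data were
    framed), residuals are weighted by ``sqrt(dt_k / max(C_k, floor))``
    mirroring count statistics (``weighting="uniform"`` disables this), and a
    bounded trust-region optimiser with three deterministic restarts handles
    the shallow k2/k3 trade-off.  Returns fitted parameters (Ki populated via
    the macro formula) plus diagnostics; non-convergence is reported in the
    diagnostics, not raised.
    """
    if not tac.schedule.same_as(input_tac.schedule):
        raise InvalidParameterError("tissue and input curves must share one schedule")
    if weighting not in ("frame-duration", "uniform"):
        raise InvalidParameterError(f"unknown weighting scheme: {weighting!r}")

    obs = tac.values
    cp_obs = input_tac.values
    if not np.any(obs > 0):
        raise DegenerateInputError("tissue curve is identically zero")
    if not np.any(cp_obs > 0):
        raise DegenerateInputError("input curve is identically zero")
    n_active = int(np.sum(obs > _ACTIVITY_FLOOR_FRAC * np.max(obs)))
    if n_active < 10:
        raise InsufficientDataError("need >= 10 frames with activity above threshold")

    schedule = tac.schedule
    keep = np.ones(schedule.n_frames, dtype=bool)
    if t_max is not None:
        keep = schedule.end <= t_max + 1e-9
        if np.sum(keep) < 10:
            raise InsufficientDataError("fit interval leaves fewer than 10 frames")

    cp_t, cp_v = _cp_node_representation(input_tac)
    # analysis grid: frame boundaries plus midpoints keeps the Cp kinks exact
    edges = np.concatenate([[schedule.start[0]], schedule.end])
    nodes = np.sort(np.unique(np.concatenate([edges, schedule.mid])))
    cp_nodes = np.interp(nodes, cp_t, cp_v)
    frame_idx = np.searchsorted(schedule.end, nodes[:-1], side="right")
    durations = schedule.duration

    if weighting == "frame-duration":
        floor = _ACTIVITY_FLOOR_FRAC * np.max(obs)
        w = durations / np.maximum(obs, floor)
    else:
        w = np.ones_like(obs)
    w = w * keep
    sw = np.sqrt(w / np.mean(w[keep]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        kp = KineticParams(K1=theta[0], k2=theta[1], k3=theta[2], Vb=theta[3])
        pred, _ = _framed_from_nodes(nodes, cp_nodes, frame_idx, durations, kp)
        return sw * (pred - obs)

    if init is None:
        init = KineticParams(K1=0.3, k2=1.0, k3=0.05, Vb=0.1)
    lo, hi = bounds if bounds is not None else _DEFAULT_BOUNDS
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    x0 = np.clip([init.K1, init.k2, init.k3, init.Vb], lo + 1e-12, hi - 1e-12)

    starts = [x0]
    best = None
    for attempt, x_start in enumerate(starts):
        res = least_squares(
            residuals, x_start, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.success and attempt == 0:
            break
        if attempt == 0 and not res.success:
            # deterministic restarts around the initial guess
            starts.append(np.clip(x0 * np.array([0.5, 0.5, 2.0, 1.0]), lo + 1e-12, hi - 1e-12))
            starts.append(np.clip(x0 * np.array([2.0, 2.0, 0.5, 1.0]), lo + 1e-12, hi - 1e-12))

    assert best is not None
    kp_fit = KineticParams(K1=best.x[0], k2=best.x[1], k3=best.x[2], Vb=best.x[3])
    pred, _ = _framed_from_nodes(nodes, cp_nodes, frame_idx, durations, kp_fit)
    rss = float(np.sum(((pred - obs) * keep) ** 2))
    jtj = best.jac.T @ best.jac
    cov_ok = bool(np.all(np.isfinite(jtj)) and np.linalg.matrix_rank(jtj) == jtj.shape[0])
    diag = FitDiagnostics(
        residual_sum_squares=rss,
        iterations=int(best.nfev),
        converged=bool(best.success),
        covariance_ok=cov_ok,
    )
    return kp_fit, diag
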