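"""Derived quantities reported from transport simulations.

Covers the summary numbers a delivery experiment is judged by: how long
the phantom takes to reach steady state, the average solute flux across
the nanoporous interface, how deep the solute front has penetrated, and
normalized (dimensionless) concentration profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import TransportResult

__all__ = [
    "SteadyStateReport",
    "FluxReport",
    "steady_state_time",
    "interface_flux",
    "penetration_depth",
    "normalize_profile",
]


@dataclass(frozen=True)
class SteadyStateReport:
    """Earliest output time satisfying the steady-state criterion."""

    time: float  # s; lower bound if not converged within the horizon
    rel_tol: float
    converged: bool
    final_profile: np.ndarray
    criterion: str = "relative L-inf distance to the long-horizon profile"


@dataclass(frozen=True)
class FluxReport:
    """Interface flux series (μM·μm/s) and its averages.

    Three averaging conventions are reported because the convention behind
    a single printed "average flux" is rarely stated: the time average
    over the approach to steady state (``mean_flux``, default window), the
    final/steady instantaneous value, and the whole-run time average.
    """

    times: np.ndarray
    series: np.ndarray
    mean_flux: float
    steady_flux: float
    whole_run_mean: float
    window: tuple[float, float]


def steady_state_time(result: TransportResult, rel_tol: float = 0.05) -> SteadyStateReport:
    """Earliest output time within ``rel_tol`` (L∞, relative to the peak of
    the converged profile) of the long-horizon profile.

    The last output profile serves as the converged reference c_∞; if the
    penultimate profile is not itself within tolerance of the last one the
    horizon is flagged as too short and the reported time is a lower bound.
    """
    if not 0.0 < rel_tol < 1.0:
        raise ValueError("rel_tol must lie in (0, 1)")
    if len(result.times) < 3:
        raise ValueError("need at least 3 output times to assess steadiness")
    c_inf = result.concentrations[-1]
    scale = float(np.max(np.abs(c_inf)))
    if scale == 0.0:
        return SteadyStateReport(0.0, rel_tol, True, c_inf)
    dist = np.max(np.abs(result.concentrations - c_inf), axis=1) / scale
    converged = bool(dist[-2] <= rel_tol)
    below = np.nonzero(dist <= rel_tol)[0]
    if below.size == 0:  # horizon too short: lower bound only
        return SteadyStateReport(float(result.times[-1]), rel_tol, False, c_inf)
    # earliest time after which the criterion holds at all later outputs
    idx = below[0]
    for k in below:
        if np.all(dist[k:] <= rel_tol):
            idx = k
            break
    return SteadyStateReport(
        time=float(result.times[idx]),
        rel_tol=rel_tol,
        converged=converged,
        final_profile=c_inf,
    )


def interface_flux(
    result: TransportResult, window: tuple[float, float] | None = None
) -> FluxReport:
    """Average the recorded membrane-interface flux series.

    ``window`` defaults to (0, steady-state time). Averages are trapezoidal
    in time over the densely recorded step series.
    """
    t = result.step_times
    J = result.interface_flux
    if window is None:
        window = (0.0, steady_state_time(result).time)
    t0, t1 = window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t1 <= t0:
        raise ValueError(f"window {window} outside recorded times [{t[0]}, {t[-1]}]")
    mask = (t >= t0) & (t <= t1)
    mean = float(np.trapezoid(J[mask], t[mask]) / (t[mask][-1] - t[mask][0]))
    whole = float(np.trapezoid(J, t) / (t[-1] - t[0])) if t[-1] > t[0] else float(J[-1])
    return FluxReport(
        times=t,
        series=J,
        mean_flux=mean,
        steady_flux=float(J[-1]),
        whole_run_mean=whole,
        window=window,
    )


def penetration_depth(
    positions: np.ndarray, profile: np.ndarray, threshold: float = 0.1
) -> float:
    """Distance (μm) from the source face at which the concentration first
    falls below ``threshold`` × its face value, with linear sub-cell
    interpolation. A profile already below threshold at the face gives 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    x = np.asarray(positions, dtype=float)
    c = np.asarray(profile, dtype=float)
    face_value = c[0]
    if face_value <= 0.0:
        return 0.0
    target = threshold * face_value
    below = np.nonzero(c < target)[0]
    if below.size == 0:
        return float(x[-1] - x[0])
    i = below[0]
    if i == 0:
        return 0.0
    frac = (c[i - 1] - target) / (c[i - 1] - c[i])
    return float(x[i - 1] + frac * (x[i] - x[i - 1]) - x[0])


def normalize_profile(profile: np.ndarray, reference: float) -> np.ndarray:
    """Elementwise division by the reference (source) concentration."""
    if reference <= 0.0:
        raise ValueError("reference concentration must be positive")
    return np.asarray(profile, dtype=float) / reference
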