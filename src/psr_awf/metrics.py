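"""Reconstruction metrics and convergence-curve utilities.

Intensity-only measurements are blind to a global phase factor, so all
field-level errors are computed after removing the optimal global phase
rotation, which has the closed form ``phi* = -arg <x_true, x_hat>``.
"""

from __future__ import annotations

import numpy as np

from .containers import ComplexField, InvalidParameterError, PhaseTargetSpec

__all__ = [
    "aligned_rmse",
    "phase_from_height",
    "iterations_to_threshold",
    "NOT_REACHED",
]

#: Sentinel returned by :func:`iterations_to_threshold` when the metric never
#: crosses the threshold.
NOT_REACHED = None


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ComplexField) else np.asarray(x, dtype=np.complex128)


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Map phase differences to the principal branch (-pi, pi]."""
    return np.angle(np.exp(1j * phi))


def aligned_rmse(x_hat, x_true, border: int = 0) -> dict:
    """Global-phase-invariant root-mean-square errors.

    Removes the optimal global phase from ``x_hat`` before comparing, then
    reports::

        rmse_complex : ||x_hat e^{i phi*} - x_true|| / sqrt(n)
        rmse_amp     : RMSE of the moduli (phase-free)
        rmse_phase   : RMSE of the wrapped, aligned phase difference

    ``border`` excludes that many pixels on every edge (wrap-around region of
    the circular propagation model).  Amplitude scale is NOT aligned: the
    forward model fixes the scale through the data.
    """
    a = _values(x_hat)
    b = _values(x_true)
    if a.shape != b.shape:
        raise InvalidParameterError(f"grid mismatch: {a.shape} vs {b.shape}")
    if border > 0:
        if 2 * border >= min(a.shape):
            raise InvalidParameterError("border margin swallows the whole grid")
        a = a[border:-border, border:-border]
        b = b[border:-border, border:-border]
    inner = np.vdot(b, a)  # <x_true, x_hat> with conjugation on x_true
    phi_star = -np.angle(inner) if inner != 0 else 0.0
    a_rot = a * np.exp(1j * phi_star)
    n = a.size
    rmse_complex = float(np.linalg.norm(a_rot - b) / np.sqrt(n))
    rmse_amp = float(np.linalg.norm(np.abs(a) - np.abs(b)) / np.sqrt(n))
    dphi = _wrap_phase(np.angle(a_rot) - np.angle(b))
    rmse_phase = float(np.linalg.norm(dphi) / np.sqrt(n))
    return {
        "rmse_amp": rmse_amp,
        "rmse_phase": rmse_phase,
        "rmse_complex": rmse_complex,
        "phi_star": float(phi_star),
    }


def phase_from_height(spec: PhaseTargetSpec) -> float:
    """Phase delay (radians) of a structure of height h and refractive index
    RI in air, at wavelength w: 2*pi*h*(RI-1)/w."""
    return 2.0 * np.pi * spec.h * (spec.RI - 1.0) / spec.w


def iterations_to_threshold(history, metric: str, threshold: float):
    """First iteration at which ``metric <= threshold``.

    ``history`` is the per-iteration DataFrame of a ReconResult (must contain
    an ``iter`` column and the requested metric column).  Returns the
    iteration number, or :data:`NOT_REACHED` (None) if never crossed.
    """
    if len(history) == 0:
        raise InvalidParameterError("empty history")
    if metric not in history.columns:
        raise InvalidParameterError(f"history has no column {metric!r}")
    hit = history.loc[history[metric] <= threshold, "iter"]
    if len(hit) == 0:
        return NOT_REACHED
    return int(hit.iloc[0])
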