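"""Melting-temperature estimation from thermal-denaturation curves.

Supports dye-based DSF (single fluorescence channel) and label-free nanoDSF
(intrinsic fluorescence at 330 and 350 nm, analyzed as the 350/330 ratio).
Tm is the midpoint of a Boltzmann sigmoid fit, or the extremum of a smoothed
first derivative.  Ligand-dose thermal-shift profiles report dTm relative to
the apo protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class MeltFit:
    """Result of a melting-curve analysis."""

    tm: float
    slope: float
    pre_level: float
    post_level: float
    method: str
    converged: bool
    message: str = ""


def boltzmann(t, pre, post, tm, slope):
    """Two-state sigmoid ``pre + (post - pre) / (1 + exp((tm - t)/slope))``.

    ``slope`` (degC) is positive; a falling transition is encoded by
    ``post < pre``.
    """
    t = np.asarray(t, dtype=float)
    return pre + (post - pre) / (1.0 + np.exp((tm - t) / slope))


def _is_flat(signal: np.ndarray, flat_rel: float = 0.01) -> bool:
    span = float(np.max(signal) - np.min(signal))
    scale = max(float(np.max(np.abs(signal))), 1e-30)
    return span < flat_rel * scale


def fit_boltzmann(
    temperatures,
    signal,
    min_points: int = 10,
    flat_rel: float = 0.01,
) -> MeltFit:
    """Least-squares Boltzmann fit of a single-channel melt curve.

    Requires at least ``min_points`` temperatures.  Curves whose total signal
    span is below ``flat_rel`` of the signal magnitude are flagged flat and
    returned unconverged.  Tm is invariant to affine transforms of the signal.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size != y.size:
        raise ValueError("temperature and signal lengths differ")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} temperature points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")

    if _is_flat(y, flat_rel):
        return MeltFit(
            tm=np.nan, slope=np.nan, pre_level=float(y[0]), post_level=float(y[-1]),
            method="boltzmann", converged=False, message="flat curve",
        )

    pre0, post0 = float(y[:3].mean()), float(y[-3:].mean())
    half = 0.5 * (pre0 + post0)
    tm0 = float(t[np.argmin(np.abs(y - half))])
    span = float(t[-1] - t[0])
    try:
        popt, _ = curve_fit(
            boltzmann, t, y,
            p0=[pre0, post0, tm0, 1.0],
            bounds=([-np.inf, -np.inf, t[0], 0.01], [np.inf, np.inf, t[-1], span]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as err:
        return MeltFit(
            tm=np.nan, slope=np.nan, pre_level=np.nan, post_level=np.nan,
            method="boltzmann", converged=False, message=f"optimizer failed: {err}",
        )
    pre, post, tm, slope = popt
    return MeltFit(
        tm=float(tm), slope=float(slope), pre_level=float(pre),
        post_level=float(post), method="boltzmann", converged=True,
    )


def _derivative_tm(t: np.ndarray, y: np.ndarray, window: int = 5) -> float:
    """Temperature of the extremum of a smoothed first derivative.

    A centered moving average of fixed ``window`` points precedes
    differentiation; the peak location is refined by a parabola through the
    three points around the discrete maximum.
    """
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    smooth = np.convolve(ypad, kernel, mode="valid")
    dy = np.gradient(smooth, t)
    mag = np.abs(dy)
    i = int(np.argmax(mag))
    if 0 < i < t.size - 1:
        # parabolic refinement on the derivative magnitude
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(t[i] + delta * (t[min(i + 1, t.size - 1)] - t[i]))
    return float(t[i])


def ratio_tm(
    temperatures,
    f330,
    f350,
    method: str = "boltzmann",
    smoothing_window: int = 5,
) -> MeltFit:
    """Tm from the nanoDSF 350/330 fluorescence ratio.

    The pointwise ratio ``r(T) = F350 / F330`` is analyzed either by a
    Boltzmann sigmoid fit or by the extremum of a smoothed first derivative.
    The result is invariant to common rescaling of both channels.
    """
    t = np.asarray(temperatures, dtype=float)
    a330 = np.asarray(f330, dtype=float)
    a350 = np.asarray(f350, dtype=float)
    if np.any(a330 <= 0):
        raise ValueError("330 nm channel must be positive")
    r = a350 / a330

    if method == "boltzmann":
        fit = fit_boltzmann(t, r)
        return MeltFit(**{**fit.__dict__, "method": "ratio-boltzmann"})
    if method == "derivative":
        if _is_flat(r):
            return MeltFit(
                tm=np.nan, slope=np.nan, pre_level=float(r[0]), post_level=float(r[-1]),
                method="ratio-derivative", converged=False, message="flat curve",
            )
        tm = _derivative_tm(t, r, smoothing_window)
        return MeltFit(
            tm=tm, slope=np.nan, pre_level=float(r[0]), post_level=float(r[-1]),
            method="ratio-derivative", converged=True,
        )
    raise ValueError("method must be 'boltzmann' or 'derivative'")


def thermal_shift_profile(
    fits: list[tuple[float, MeltFit]],
    reference: MeltFit,
) -> tuple[pd.DataFrame, bool]:
    """Ligand-dose thermal-shift table ``dTm = Tm(ligand) - Tm(apo)``.

    ``fits`` pairs each ligand concentration with its converged MeltFit;
    ``reference`` is the apo-protein fit.  Returns the table ordered by
    concentration and a flag that is True when dTm is non-decreasing in
    concentration (the saturating-binding expectation).
    """
    if reference is None or not reference.converged:
        raise ValueError("missing or unconverged apo reference fit")
    for conc, fit in fits:
        if not fit.converged:
            raise ValueError(f"unconverged fit at concentration {conc}")
    rows = sorted(((float(c), f.tm - reference.tm) for c, f in fits), key=lambda x: x[0])
    df = pd.DataFrame(rows, columns=["concentration", "delta_tm"])
    monotone = bool(np.all(np.diff(df["delta_tm"].to_numpy()) >= -1e-9)) if len(df) > 1 else True
    return df, monotone
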