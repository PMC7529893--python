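"""TR-FRET signal computation, plate normalization, Z'-factor QC and 4PL fitting.

The TR-FRET readout of a well is the emission ratio ``10000 x 520nm / 490nm``.
Per-plate controls — DMSO wells (0% inhibition, "negative" control) and DMSO
wells lacking the donor-tagged protein (100% inhibition, "positive" control) —
normalize compound signals to percent inhibition and yield the Z'-factor
plate-quality statistic.  Dose-response series are fit with a four-parameter
logistic (bottom, top, IC50, Hill slope) in log-concentration space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

ROLE_COMPOUND = "compound"
ROLE_NEG = "neg_ctrl"   # DMSO, full binding signal, 0% inhibition
ROLE_POS = "pos_ctrl"   # DMSO without donor protein, 100% inhibition


def fret_signal(channel_520, channel_490):
    """TR-FRET emission ratio ``10000 x 520 / 490``.

    Accepts scalars or arrays.  Raises on non-positive 490 counts for scalar
    input; array input returns NaN at such wells so they can be flagged and
    excluded downstream.
    """
    ch520 = np.asarray(channel_520, dtype=float)
    ch490 = np.asarray(channel_490, dtype=float)
    if ch490.ndim == 0:
        if ch490 <= 0:
            raise ValueError("channel_490 must be positive for ratio computation")
        return float(10000.0 * ch520 / ch490)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ch490 > 0, 10000.0 * ch520 / ch490, np.nan)
    return out


@dataclass
class PlateControls:
    """Per-plate control statistics feeding percent-inhibition and Z'."""

    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    n_neg: int
    n_pos: int

    def __post_init__(self) -> None:
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("need at least 2 wells per control group")
        if self.sd_neg < 0 or self.sd_pos < 0:
            raise ValueError("control SDs must be non-negative")

    @classmethod
    def from_signals(cls, neg_signals, pos_signals) -> "PlateControls":
        neg = np.asarray(neg_signals, dtype=float)
        pos = np.asarray(pos_signals, dtype=float)
        neg = neg[~np.isnan(neg)]
        pos = pos[~np.isnan(pos)]
        return cls(
            mean_neg=float(neg.mean()),
            sd_neg=float(neg.std(ddof=1)),
            mean_pos=float(pos.mean()),
            sd_pos=float(pos.std(ddof=1)),
            n_neg=int(neg.size),
            n_pos=int(pos.size),
        )


def percent_inhibition(signal, controls: PlateControls):
    """Normalize a TR-FRET signal to percent inhibition.

    ``%Inh = 100 - 100 * (signal - mean_pos) / (mean_neg - mean_pos)``

    where ``mean_pos`` is the 100%-inhibition control (no donor protein) and
    ``mean_neg`` the 0%-inhibition DMSO control.  Affine-invariant: rescaling
    all signals and controls by a common positive factor leaves %Inh
    unchanged.
    """
    if controls.mean_neg == controls.mean_pos:
        raise ValueError("degenerate controls: equal means")
    signal = np.asarray(signal, dtype=float)
    inh = 100.0 - 100.0 * (signal - controls.mean_pos) / (controls.mean_neg - controls.mean_pos)
    return float(inh) if inh.ndim == 0 else inh


def zprime(controls: PlateControls) -> float:
    """Z'-factor: ``1 - 3(sd_neg + sd_pos) / |mean_neg - mean_pos|``.

    A plate passes QC when Z' > 0.5.  Symmetric under swapping the control
    labels (absolute separation in the denominator).
    """
    sep = abs(controls.mean_neg - controls.mean_pos)
    if sep == 0:
        raise ValueError("degenerate controls: equal means")
    return 1.0 - 3.0 * (controls.sd_neg + controls.sd_pos) / sep


def passes_qc(controls: PlateControls, min_zprime: float = 0.5) -> bool:
    return zprime(controls) > min_zprime


def design_dilution_series(top: float, factor: float, levels: int) -> np.ndarray:
    """Descending serial-dilution concentrations ``top / factor**(i-1)``, i=1..levels."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if levels < 2:
        raise ValueError("need at least 2 levels")
    return top / factor ** np.arange(levels, dtype=float)


def four_param_logistic(x, bottom, top, ic50, hill):
    """4PL response: ``bottom + (top - bottom) / (1 + (ic50 / x)**hill)``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit with convergence diagnostics."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""


def fit_dose_response(
    conc,
    response,
    top_bounds: tuple[float, float] | None = None,
    bottom_bounds: tuple[float, float] | None = None,
    hill_bounds: tuple[float, float] = (0.2, 5.0),
    min_span: float = 5.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of (concentration, response) points.

    Replicate wells at the same concentration are averaged before fitting.
    The optimizer works on log10(IC50) with the Hill slope bounded to
    ``hill_bounds``; initial values are taken from response quartiles
    (top/bottom), the concentration nearest half-maximal response (IC50) and
    hill = 1.  A curve whose response span is below ``min_span`` is flagged
    flat and returned unconverged.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have the same length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    # average replicates per concentration
    df = pd.DataFrame({"conc": conc, "response": response}).groupby("conc", as_index=False).mean()
    x = df["conc"].to_numpy()
    y = df["response"].to_numpy()
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 distinct concentrations")

    span = float(y.max() - y.min())
    if span < min_span:
        return DoseResponseFit(
            ic50=np.nan, hill=np.nan, top=float(y.max()), bottom=float(y.min()),
            rss=float(np.sum((y - y.mean()) ** 2)), converged=False, n_points=n,
            message="flat response (span below minimum)",
        )

    b0 = float(np.percentile(y, 25))
    t0 = float(np.percentile(y, 75))
    half = 0.5 * (y.min() + y.max())
    ic0 = float(x[np.argmin(np.abs(y - half))])
    logx = np.log10(x)

    def model(lx, bottom, top, logic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((logic50 - lx) * hill))

    def widen(bounds):
        # allow fixing a plateau by passing an (almost) degenerate interval
        lo, hi = bounds
        if lo >= hi:
            eps = 1e-9 * (abs(lo) + 1.0)
            lo, hi = lo - eps, lo + eps
        return lo, hi

    lo_b, hi_b = widen(bottom_bounds) if bottom_bounds else (-np.inf, np.inf)
    lo_t, hi_t = widen(top_bounds) if top_bounds else (-np.inf, np.inf)
    bounds = (
        [lo_b, lo_t, logx.min() - 3.0, hill_bounds[0]],
        [hi_b, hi_t, logx.max() + 3.0, hill_bounds[1]],
    )
    p0 = [
        np.clip(b0, *[bounds[0][0], bounds[1][0]]),
        np.clip(t0, *[bounds[0][1], bounds[1][1]]),
        np.clip(np.log10(ic0), bounds[0][2], bounds[1][2]),
        1.0,
    ]
    try:
        popt, _ = curve_fit(model, logx, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as err:
        return DoseResponseFit(
            ic50=np.nan, hill=np.nan, top=np.nan, bottom=np.nan, rss=np.nan,
            converged=False, n_points=n, message=f"optimizer failed: {err}",
        )
    bottom, top, logic50, hill = popt
    resid = y - model(logx, *popt)
    if bottom > top:  # canonicalize so bottom <= top
        bottom, top = top, bottom
    return DoseResponseFit(
        ic50=float(10.0 ** logic50), hill=float(hill), top=float(top),
        bottom=float(bottom), rss=float(np.sum(resid ** 2)), converged=True,
        n_points=n,
    )


def plate_controls(plate: pd.DataFrame) -> PlateControls:
    """Control statistics of a single-plate well table (columns per the plate CSV)."""
    sig = fret_signal(plate["channel_520"].to_numpy(), plate["channel_490"].to_numpy())
    roles = plate["role"].to_numpy()
    return PlateControls.from_signals(sig[roles == ROLE_NEG], sig[roles == ROLE_POS])


def process_screen(wells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plate normalization of a multi-plate screen well table.

    Returns the compound-well table with added ``signal`` and
    ``pct_inhibition`` columns (wells with unusable 490 counts are dropped
    and counted in the QC table) and a per-plate QC report with control
    statistics, Z' and pass/fail.
    """
    out_rows = []
    qc_rows = []
    for plate_id, plate in wells.groupby("plate_id", sort=False):
        sig = fret_signal(plate["channel_520"].to_numpy(), plate["channel_490"].to_numpy())
        plate = plate.assign(signal=sig)
        controls = PlateControls.from_signals(
            plate.loc[plate["role"] == ROLE_NEG, "signal"],
            plate.loc[plate["role"] == ROLE_POS, "signal"],
        )
        z = zprime(controls)
        compounds = plate[plate["role"] == ROLE_COMPOUND]
        n_flagged = int(compounds["signal"].isna().sum())
        compounds = compounds.dropna(subset=["signal"]).copy()
        compounds["pct_inhibition"] = percent_inhibition(
            compounds["signal"].to_numpy(), controls
        )
        out_rows.append(compounds)
        qc_rows.append(
            {
                "plate_id": plate_id,
                "mean_neg": controls.mean_neg, "sd_neg": controls.sd_neg,
                "mean_pos": controls.mean_pos, "sd_pos": controls.sd_pos,
                "n_neg": controls.n_neg, "n_pos": controls.n_pos,
                "zprime": z, "pass_qc": z > 0.5, "n_flagged_wells": n_flagged,
            }
        )
    results = pd.concat(out_rows, ignore_index=True) if out_rows else pd.DataFrame()
    return results, pd.DataFrame(qc_rows)
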