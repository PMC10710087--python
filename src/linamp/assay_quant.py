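"""Quantification formulas for the viability, dose-response and qPCR assays.

Implements the plate-reader alamarBlue reduction score and its derived
relative growth, the fluorescence viability ratio, four-parameter
log-logistic IC50 fitting, relative/real gene copy number from qPCR Ct
values (the E^(-ddCt) method against a reference gene of known genomic copy
number), and the mCherry/BFP ratio that serves as an inverse reporter of
free active TetR.

All formula operations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ExtinctionCoefficients",
    "DoseResponseFitResult",
    "QpcrResult",
    "TetrActivityResult",
    "alamar_score",
    "relative_growth",
    "viability_ratio",
    "four_param_logistic",
    "fit_ic50",
    "qpcr_copy_number",
    "htetr_activity_ratio",
]

# Manufacturer-protocol molar extinction coefficients of oxidized
# resazurin-based reagent at 570 and 600 nm.  Config defaults, overridable.
DEFAULT_O1 = 80586.0
DEFAULT_O2 = 117216.0


@dataclass(frozen=True)
class ExtinctionCoefficients:
    """Molar extinction of the oxidized reagent at 570 nm (O1) and 600 nm (O2)."""

    O1: float = DEFAULT_O1
    O2: float = DEFAULT_O2

    def __post_init__(self) -> None:
        if self.O1 <= 0 or self.O2 <= 0:
            raise ValueError("extinction coefficients must be > 0")


def alamar_score(
    A570: float, A600: float, coeffs: ExtinctionCoefficients | None = None
) -> float:
    """Reduction score S = O2*A570 - O1*A600 from blank-subtracted absorbances."""
    if A570 is None or A600 is None:
        raise ValueError("both A570 and A600 channels are required")
    c = coeffs or ExtinctionCoefficients()
    return c.O2 * A570 - c.O1 * A600


def relative_growth(
    test_scores: Sequence[float], control_scores: Sequence[float]
) -> float:
    """Fold change of mean test score over mean control score."""
    test = np.asarray(test_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if test.size == 0 or control.size == 0:
        raise ValueError("score lists must be non-empty")
    denom = control.mean()
    if denom == 0:
        raise ValueError("mean control score is zero; fold change undefined")
    return float(test.mean() / denom)


def viability_ratio(test_FI590: float, control_FI590: float, blank: float = 0.0) -> float:
    """Relative viability R = (test - blank) / (control - blank)."""
    denom = control_FI590 - blank
    if denom <= 0:
        raise ValueError("blank-subtracted control fluorescence must be > 0")
    return (test_FI590 - blank) / denom


# ---------------------------------------------------------------------------
# IC50 fitting

def four_param_logistic(
    x: np.ndarray, bottom: float, top: float, ic50: float, hill: float
) -> np.ndarray:
    """4PL response: bottom + (top - bottom) / (1 + (x / ic50)^hill).

    With ``hill > 0`` and ``top > bottom`` this decreases with dose and
    crosses the midpoint of the top-bottom span exactly at ``ic50``.
    """
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


@dataclass
class DoseResponseFitResult:
    ic50: float
    hill_slope: float
    top: float
    bottom: float
    sse: float
    converged: bool


_HILL_STARTS = (0.5, 1.0, 2.0)


def fit_ic50(
    concentrations: Sequence[float],
    percent_growth: Sequence[float],
    n_ic50_starts: int = 7,
) -> DoseResponseFitResult:
    """Four-parameter log-logistic fit of percent growth versus dose.

    Least squares over (bottom, top, log ic50, log hill) from a documented
    deterministic multi-start grid: ic50 starts on a geometric grid spanning
    the dosed range crossed with Hill slopes {0.5, 1, 2}; the lowest-SSE
    solution wins.  Flat (degenerate) responses come back with
    ``converged=False``.  Because the start grid is built from the dose
    values, the fit is equivariant under rescaling all concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(percent_growth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and percent_growth must have equal length")
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0 (log-dose model)")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    lo, hi = float(x.min()), float(x.max())
    ic50_starts = np.geomspace(lo, hi, n_ic50_starts)
    y_lo, y_hi = float(y.min()), float(y.max())
    span = max(y_hi - y_lo, 1e-9)

    def residuals(theta: np.ndarray) -> np.ndarray:
        bottom, top, log_ic50, log_hill = theta
        return four_param_logistic(x, bottom, top, np.exp(log_ic50), np.exp(log_hill)) - y

    best = None
    for ic50_0 in ic50_starts:
        for hill_0 in _HILL_STARTS:
            theta0 = np.array([y_lo, y_hi, np.log(ic50_0), np.log(hill_0)])
            try:
                sol = least_squares(
                    residuals,
                    theta0,
                    bounds=(
                        [-np.inf, -np.inf, np.log(lo) - 7.0, np.log(0.05)],
                        [np.inf, np.inf, np.log(hi) + 7.0, np.log(20.0)],
                    ),
                    method="trf",
                )
            except Exception:
                continue
            sse = float(2.0 * sol.cost)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, sol)
    if best is None:
        return DoseResponseFitResult(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    sse, sol = best
    bottom, top, log_ic50, log_hill = sol.x
    fitted_span = abs(top - bottom)
    degenerate = fitted_span < 1e-6 * max(1.0, abs(top)) or span < 1e-9
    converged = bool(sol.success) and not degenerate
    return DoseResponseFitResult(
        ic50=float(np.exp(log_ic50)),
        hill_slope=float(np.exp(log_hill)),
        top=float(top),
        bottom=float(bottom),
        sse=sse,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# qPCR copy number

@dataclass
class QpcrResult:
    """Relative (vs calibrator) and real (per genome) copy numbers."""

    relative: float
    real_copies: float
    delta_delta_ct: float
    calibrator_copies: float
    efficiency: float


def _mean_ct(table: pd.DataFrame, sample: str, gene: str) -> float:
    sel = table[(table["sample"] == sample) & (table["gene"] == gene)]
    if sel.empty:
        raise KeyError(f"missing qPCR wells for sample={sample!r}, gene={gene!r}")
    ct = sel["ct"].astype(float)
    if (ct <= 0).any():
        raise ValueError(f"non-positive Ct for sample={sample!r}, gene={gene!r}")
    return float(ct.mean())


def qpcr_copy_number(
    table: pd.DataFrame,
    sample: str,
    target_gene: str,
    calibrator_sample: str,
    reference_gene: str = "Vinculin",
    reference_copies: float = 2.0,
    efficiency: float | None = None,
) -> QpcrResult:
    """Relative and real copy number of ``target_gene`` in ``sample``.

    ``table`` is tidy with columns ``sample``, ``gene``, ``ct`` (technical
    replicates as extra rows; Ct values are averaged).  The relative copy
    number is ``E^(-ddCt)`` with

        ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator

    and the real copy number anchors the calibrator to the known genomic
    copy number of the reference gene:
    ``real = relative * E^(-dCt_calibrator) * reference_copies``.

    ``efficiency`` defaults to the table's ``efficiency`` column for the
    target gene if present, else 2.0 (perfect doubling).  Valid range
    ``1 < E <= 2``.  Missing wells raise ``KeyError`` naming them.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    if efficiency is None:
        if "efficiency" in table.columns:
            sel = table[table["gene"] == target_gene]["efficiency"].dropna()
            efficiency = float(sel.iloc[0]) if len(sel) else 2.0
        else:
            efficiency = 2.0
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"amplification efficiency must lie in (1, 2], got {efficiency}")

    missing = []
    cts = {}
    for s, g in [
        (sample, target_gene),
        (sample, reference_gene),
        (calibrator_sample, target_gene),
        (calibrator_sample, reference_gene),
    ]:
        try:
            cts[(s, g)] = _mean_ct(table, s, g)
        except KeyError:
            missing.append((s, g))
    if missing:
        raise KeyError(f"missing qPCR wells: {missing}")

    d_ct_sample = cts[(sample, target_gene)] - cts[(sample, reference_gene)]
    d_ct_cal = cts[(calibrator_sample, target_gene)] - cts[(calibrator_sample, reference_gene)]
    dd_ct = d_ct_sample - d_ct_cal
    relative = efficiency ** (-dd_ct)
    calibrator_copies = efficiency ** (-d_ct_cal) * reference_copies
    return QpcrResult(
        relative=float(relative),
        real_copies=float(relative * calibrator_copies),
        delta_delta_ct=float(dd_ct),
        calibrator_copies=float(calibrator_copies),
        efficiency=float(efficiency),
    )


# ---------------------------------------------------------------------------
# TetR activity sensor

@dataclass
class TetrActivityResult:
    """Per-cell mCherry/BFP ratios (inverse readout of free active TetR)."""

    ratios: np.ndarray
    mean: float
    cv: float
    n_retained: int
    n_total: int
    threshold: float


def htetr_activity_ratio(
    mcherry_per_cell: Sequence[float],
    bfp_per_cell: Sequence[float],
    control_bfp: Sequence[float] | None = None,
    threshold: float | None = None,
    floor: float = 100.0,
) -> TetrActivityResult:
    """mCherry/BFP ratio per BFP-positive cell, with population mean and CV.

    BFP (the constitutive plasmid copy-number reference) gates transfected
    cells: the positivity threshold is, in order of precedence, the explicit
    ``threshold``, the 99th percentile of an untransfected ``control_bfp``
    population, or the fixed ``floor``.  A higher mean ratio means less free
    active TetR.
    """
    mcherry = np.asarray(mcherry_per_cell, dtype=float)
    bfp = np.asarray(bfp_per_cell, dtype=float)
    if mcherry.shape != bfp.shape:
        raise ValueError("mcherry and bfp arrays must have equal length")
    if threshold is None:
        if control_bfp is not None:
            threshold = float(np.percentile(np.asarray(control_bfp, dtype=float), 99.0))
        else:
            threshold = floor
    keep = bfp > threshold
    n_retained = int(keep.sum())
    if n_retained == 0:
        raise ValueError(f"no cells exceed the BFP positivity threshold ({threshold})")
    ratios = mcherry[keep] / bfp[keep]
    mean = float(ratios.mean())
    cv = float(ratios.std(ddof=1) / mean) if n_retained > 1 and mean != 0 else 0.0
    return TetrActivityResult(
        ratios=ratios,
        mean=mean,
        cv=cv,
        n_retained=n_retained,
        n_total=int(bfp.size),
        threshold=float(threshold),
    )
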