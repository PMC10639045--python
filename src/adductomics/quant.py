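"""Isotope-dilution absolute quantification.

A fixed amount of stable-isotope-labeled internal standard (IS) is
co-injected with each sample. Calibration samples with known analyte
concentrations give the response factor as the slope of the std/IS
area ratio versus concentration (through the origin by default, since
only the slope is reported for the assay); an unknown's concentration
is then its area ratio divided by the response factor. Canonical
nucleosides are quantified from the in-line UV signal the same way
(slope of UV area versus concentration), and adduct amounts are
normalized to the total canonical nucleotides to give lesions per
10^9 nucleotides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class CalibrationModel:
    """A fitted response factor: ratio (or UV area) per concentration unit."""

    analyte: str
    response_factor: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def valid(self) -> bool:
        return self.response_factor > 0 and self.n_points >= 3


def fit_response_factor(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    fit_intercept: bool = False,
) -> CalibrationModel:
    """Least-squares calibration slope.

    ``points`` are (concentration, std/IS area ratio) pairs — or
    (concentration, UV area) for canonical nucleosides. The default is
    a through-origin fit; ``fit_intercept=True`` fits an affine line.
    R^2 is reported against the fitted model.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 calibration points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.any(x > 0):
        raise ValueError("calibration concentrations are all zero")
    if fit_intercept:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(np.sum(y**2))  # uncentered: through-origin model
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    model = CalibrationModel(
        analyte=analyte,
        response_factor=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=len(x),
    )
    if model.response_factor <= 0:
        warnings.warn(f"non-positive response factor for {analyte!r}; curve invalid")
    return model


def quantify_isotope_dilution(
    analyte_area: float, is_area: float, model: CalibrationModel
) -> float:
    """Amount of analyte from its area ratio to the internal standard.

    Returns the amount in the calibration's concentration unit:
    ``(analyte_area / is_area - intercept) / response_factor``.
    """
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive (IS failure)")
    if not model.valid:
        raise ValueError(f"calibration model for {model.analyte!r} is invalid")
    ratio = analyte_area / is_area
    return (ratio - model.intercept) / model.response_factor


def lesions_per_1e9(amount_fmol: float, nt_total_mol: float) -> float:
    """Convert an on-column adduct amount to lesions per 10^9 nucleotides.

    ``nt_total_mol`` is the total canonical nucleotides co-injected,
    in mol (UV-quantified). The result is (mol adduct / mol nt) x 1e9.
    """
    if nt_total_mol <= 0:
        raise ValueError("total nucleotide amount must be positive")
    if amount_fmol < 0:
        raise ValueError("adduct amount cannot be negative")
    return amount_fmol * 1e-15 / nt_total_mol * 1e9


def implied_nt_total(amount_fmol: float, per_billion_nt: float) -> float:
    """Total nucleotides (mol) implied by a (fmol, per-1e9-nt) pair —
    the inverse of :func:`lesions_per_1e9`."""
    if per_billion_nt <= 0:
        raise ValueError("per-1e9 value must be positive")
    return amount_fmol * 1e-15 * 1e9 / per_billion_nt


def estimate_loq(
    levels: Sequence[float],
    replicate_signals: Sequence[Sequence[float]],
    blank_noise: float,
    min_snr: float = 10.0,
    max_cv: float = 0.20,
) -> float:
    """Limit of quantification from replicate calibration injections.

    The LOQ is the lowest calibration level whose mean signal is at
    least ``min_snr`` times the blank noise and whose replicate CV is
    at most ``max_cv``. Returns ``inf`` (with a warning) when no level
    qualifies. These thresholds are rough operating bounds, not a
    statistical detection-limit model.
    """
    if len(levels) != len(replicate_signals):
        raise ValueError("levels and replicate_signals must align")
    order = np.argsort(levels)
    for i in order:
        level = levels[i]
        if level <= 0:
            continue
        sig = np.asarray(replicate_signals[i], dtype=float)
        mean = sig.mean()
        if mean < min_snr * blank_noise:
            continue
        cv = sig.std(ddof=1) / mean if len(sig) > 1 and mean > 0 else 0.0
        if cv <= max_cv:
            return float(level)
    warnings.warn("no calibration level met the LOQ criteria")
    return math.inf
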