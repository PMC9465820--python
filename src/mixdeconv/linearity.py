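"""MS-signal linearity QC and the biological-origin ion filter.

Spike-in series (known amounts of pure standards added to cell extracts)
establish, per ion and sample matrix, whether measured intensity responds
linearly to concentration and where the detector/ionization saturation
limit lies. Before deconvolution, ions are additionally filtered to those
whose intensity scales with the number of cells extracted -- i.e. signals
of likely biological origin -- using a stacked regression with cell-line
specific slopes and a single shared intercept pinned by cell-free blanks,
at a Bonferroni-adjusted significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LinearFitResult",
    "SaturationResult",
    "bonferroni_threshold",
    "detect_saturation_limit",
    "fit_base_model",
    "cross_matrix_r2",
    "biological_origin_filter",
]


@dataclass(frozen=True)
class SaturationResult:
    """Detected saturation limit for one ion's spike-in series."""

    limit: float  # intensity; inf when the response never saturates
    first_saturated_index: int | None
    nonresponsive: bool

    @property
    def bounded(self) -> bool:
        return np.isfinite(self.limit)


@dataclass(frozen=True)
class LinearFitResult:
    """OLS fit of intensity against spiked amount (or cell number)."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_points_used: int
    saturation_limit: float = np.inf


def detect_saturation_limit(
    spike_amounts,
    intensities,
    rel_slope_cutoff: float = 0.1,
    init_points: int = 3,
) -> SaturationResult:
    """Locate the intensity above which the response stops increasing.

    The local slope between successive spike levels is normalized by the
    initial-region slope (OLS over the first ``init_points`` points); the
    limit is the intensity at the first point from which every subsequent
    local slope stays below ``rel_slope_cutoff`` (default 0.1). Series
    whose initial slope is <= 0 are flagged non-responsive.
    """
    x = np.asarray(spike_amounts, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 points to assess saturation")
    if np.any(np.diff(x) <= 0):
        raise ValueError("spike amounts must be strictly increasing")
    s0 = stats.linregress(x[:init_points], y[:init_points]).slope
    if s0 <= 0:
        return SaturationResult(np.nan, None, True)
    local = np.diff(y) / np.diff(x)
    rel = local / s0
    # smallest j such that every interval from j onward is flat
    flat_from = len(rel)
    for j in range(len(rel) - 1, -1, -1):
        if rel[j] < rel_slope_cutoff:
            flat_from = j
        else:
            break
    if flat_from >= len(rel):
        return SaturationResult(np.inf, None, False)
    return SaturationResult(float(y[flat_from]), int(flat_from), False)


def fit_base_model(
    spike_amounts,
    intensities,
    saturation_limit: float = np.inf,
) -> LinearFitResult:
    """Fit the base linear model intensity ~ spiked amount by OLS.

    Points at or above the saturation limit are excluded; at least 3
    unsaturated points with >= 2 distinct spike amounts are required. The
    slope carries a two-sided p-value; the intercept is the basal
    abundance of the metabolite in the unspiked extract.
    """
    x = np.asarray(spike_amounts, dtype=float)
    y = np.asarray(intensities, dtype=float)
    keep = y < saturation_limit
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("fewer than 3 unsaturated points; fit refused")
    if np.unique(x).size < 2:
        raise ValueError("rank-deficient design: all spike amounts identical")
    res = stats.linregress(x, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n_points_used=len(x),
        saturation_limit=float(saturation_limit),
    )


def cross_matrix_r2(base: LinearFitResult, spike_amounts, intensities) -> float:
    """Goodness of fit of the base model's slope on another sample matrix.

    The intercept is refit to the other matrix by least squares (matrices
    differ in basal metabolite abundance) while the slope stays fixed;
    returns ``1 - SS_resid/SS_total``, which may be negative when the
    fixed slope fits worse than a constant. NaN when the other matrix has
    zero total variance.
    """
    if not np.isfinite(base.slope):
        raise ValueError("base model has no valid slope")
    x = np.asarray(spike_amounts, dtype=float)
    y = np.asarray(intensities, dtype=float)
    keep = y < base.saturation_limit
    x, y = x[keep], y[keep]
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    intercept = np.mean(y - base.slope * x)
    ss_res = np.sum((y - intercept - base.slope * x) ** 2)
    return float(1.0 - ss_res / ss_tot)


def bonferroni_threshold(alpha_fw: float = 0.05, n_ions: int = 1, n_cell_lines: int = 1) -> float:
    """Family-wise threshold ``alpha_fw / (n_ions * n_cell_lines)``."""
    if alpha_fw <= 0 or n_ions < 1 or n_cell_lines < 1:
        raise ValueError("invalid Bonferroni inputs")
    return alpha_fw / (n_ions * n_cell_lines)


def biological_origin_filter(
    cell_counts: dict[str, np.ndarray],
    intensities: dict[str, pd.DataFrame],
    blanks: pd.DataFrame,
    alpha_fw: float = 0.05,
    n_ions: int | None = None,
) -> pd.DataFrame:
    """Retain ions whose intensity scales with the number of cells extracted.

    Per ion, a single stacked regression fits one slope per cell line and
    one shared intercept across all cell lines; blank (cell-free) samples
    enter as rows with zero cells and pin the intercept to the MS
    background. An ion is retained when its smallest slope p-value across
    cell lines falls below the Bonferroni threshold
    ``alpha_fw / (n_ions * n_cell_lines)`` -- i.e. a significant
    cell-number dependence in at least one cell line.

    Parameters
    ----------
    cell_counts:
        Per cell line, the number of cells extracted in each sample
        (>= 3 biomass levels).
    intensities:
        Per cell line, a samples x ions table aligned with the counts.
    blanks:
        Samples x ions table of cell-free blanks (required).
    n_ions:
        Ion count for the Bonferroni adjustment; defaults to the number
        of ion columns.

    Returns
    -------
    Per-ion DataFrame: ``retained, best_p_value, bonferroni_threshold``
    plus one ``p_<cell_line>`` and ``slope_<cell_line>`` column each.
    """
    if blanks is None or len(blanks) == 0:
        raise ValueError("blank samples are required to pin the shared intercept")
    lines = list(cell_counts)
    ions = list(blanks.columns)
    for line in lines:
        if len(cell_counts[line]) < 3:
            raise ValueError(f"cell line {line}: need >= 3 biomass levels")
        if list(intensities[line].columns) != ions:
            raise ValueError("ion columns must match across tables")

    # stacked design: one slope column per cell line + shared intercept
    n_rows = sum(len(cell_counts[line]) for line in lines) + len(blanks)
    X = np.zeros((n_rows, len(lines)))
    Y = np.empty((n_rows, len(ions)))
    r = 0
    for k, line in enumerate(lines):
        counts = np.asarray(cell_counts[line], dtype=float)
        X[r : r + len(counts), k] = counts
        Y[r : r + len(counts)] = intensities[line].to_numpy(dtype=float)
        r += len(counts)
    Y[r:] = blanks.to_numpy(dtype=float)  # zero-cell rows
    Xc = sm.add_constant(X, prepend=False)

    threshold = bonferroni_threshold(alpha_fw, n_ions or len(ions), len(lines))
    records = []
    for j, ion in enumerate(ions):
        fit = sm.OLS(Y[:, j], Xc).fit()
        pvals = fit.pvalues[: len(lines)]
        rec = {
            "ion": ion,
            "best_p_value": float(np.min(pvals)),
            "bonferroni_threshold": threshold,
            "retained": bool(np.min(pvals) < threshold),
        }
        for k, line in enumerate(lines):
            rec[f"slope_{line}"] = float(fit.params[k])
            rec[f"p_{line}"] = float(pvals[k])
        records.append(rec)
    return pd.DataFrame(records).set_index("ion")
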