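"""Constrained mixture regression: designs, fits, bootstrap errors, purification.

The measurement model for a mixed-extract sample is

    I_mix = alpha_P * N_P * V_P + alpha_Q * N_Q * V_Q + beta

where ``alpha`` is the per-cell metabolite abundance of the proliferating
(P) or quiescent (Q) subpopulation, ``N`` the subpopulation cell count in
the sample, ``V`` the (relative) cell volume and ``beta`` the ion-specific
instrument background. Across a series of samples mixed at known ratios
the alphas are identifiable and are fitted per ion by non-negative least
squares; condition blocks (cell line x stimulus) are independent because
the stacked design matrix is block diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import spearmanr

__all__ = [
    "MIX_FRACTIONS",
    "POPULATIONS",
    "DeconvolutionFit",
    "build_mix_design",
    "build_design_matrix",
    "fit_alphas",
    "bootstrap_errors",
    "purify_intensities",
    "compare_to_reference",
]

#: Mixing ratios of the 8-h extract (mostly proliferating cells) into the
#: 96-h extract (mostly quiescent cells): 100, 85, 70, 55, 40, 25, 10, 0 %.
MIX_FRACTIONS: tuple[float, ...] = (1.00, 0.85, 0.70, 0.55, 0.40, 0.25, 0.10, 0.00)

#: Column/population order within each condition block: proliferating
#: (non-G0) first, quiescent (G0) second.
POPULATIONS: tuple[str, str] = ("P", "Q")

CONDITION_COLS = ["cell_line", "stimulus"]


def _as_condition_value(value, condition) -> float:
    """Resolve a scalar-or-dict parameter for one (cell_line, stimulus)."""
    if isinstance(value, dict):
        return float(value[condition])
    return float(value)


def build_mix_design(
    totals: float,
    fractions: Sequence[float] = MIX_FRACTIONS,
    g0_fraction_8h: float | dict = 0.1,
    g0_fraction_96h: float | dict = 0.8,
    conditions: Sequence[tuple[str, str]] = (("cellline1", "stimulus1"),),
    replicates: int = 3,
    v_p: float = 1.0,
    v_q: float = 1.0,
) -> pd.DataFrame:
    """Build the per-sample subpopulation cell counts of a mixing design.

    A mix with fraction ``f`` of the 8-h extract carries

        N_Q = totals * (f * g0_8h + (1 - f) * g0_96h),   N_P = totals - N_Q

    so the total cell number is constant across mixes while the G0 count
    interpolates between the two end-point G0 fractions (measured by flow
    cytometry at 8 and 96 h).

    Parameters
    ----------
    totals:
        Total number of cells represented in each mixed sample.
    fractions:
        Mixing fractions of the 8-h extract, each in [0, 1].
    g0_fraction_8h, g0_fraction_96h:
        G0 fractions of the two end-point extracts; scalars or dicts keyed
        by ``(cell_line, stimulus)``.
    conditions:
        ``(cell_line, stimulus)`` keys; one block of rows per condition.
    replicates:
        Independent replicate series per condition.
    v_p, v_q:
        Relative cell volumes (default 1, the equal-volume assumption).

    Returns
    -------
    DataFrame with one row per sample and columns
    ``cell_line, stimulus, mix, replicate, fraction, n_p, n_q, v_p, v_q``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("mixing fractions must lie in [0, 1]")
    if totals <= 0:
        raise ValueError("totals must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rows = []
    for condition in conditions:
        g0_8h = _as_condition_value(g0_fraction_8h, condition)
        g0_96h = _as_condition_value(g0_fraction_96h, condition)
        for g0 in (g0_8h, g0_96h):
            if not 0.0 <= g0 <= 1.0:
                raise ValueError("G0 fractions must lie in [0, 1]")
        if g0_8h == g0_96h:
            raise ValueError(
                f"condition {condition}: identical G0 fractions at 8 h and 96 h "
                "make all mixes identical (rank-deficient design)"
            )
        for rep in range(1, replicates + 1):
            for m, f in enumerate(fractions, start=1):
                n_q = totals * (f * g0_8h + (1.0 - f) * g0_96h)
                rows.append(
                    {
                        "cell_line": condition[0],
                        "stimulus": condition[1],
                        "mix": m,
                        "replicate": rep,
                        "fraction": f,
                        "n_p": totals - n_q,
                        "n_q": n_q,
                        "v_p": v_p,
                        "v_q": v_q,
                    }
                )
    return pd.DataFrame(rows)


def build_design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Assemble the block-diagonal design matrix over all conditions.

    For K conditions the matrix is (n_samples x 2K); the row of a sample in
    condition k has ``N_P*V_P`` and ``N_Q*V_Q`` in columns ``2k`` and
    ``2k+1`` and zeros elsewhere, matching a coefficient vector ordered as
    ``(alpha_c1_P, alpha_c1_Q, alpha_c2_P, alpha_c2_Q, ...)``.
    """
    conditions = list(
        dict.fromkeys(zip(design["cell_line"], design["stimulus"]))
    )
    index = {c: k for k, c in enumerate(conditions)}
    X = np.zeros((len(design), 2 * len(conditions)))
    for i, row in enumerate(design.itertuples(index=False)):
        k = index[(row.cell_line, row.stimulus)]
        X[i, 2 * k] = row.n_p * row.v_p
        X[i, 2 * k + 1] = row.n_q * row.v_q
    return X, conditions


@dataclass
class DeconvolutionFit:
    """State of a fitted mixture regression, one NNLS problem per ion x condition.

    ``profile`` holds the tidy coefficient table (``ion, cell_line,
    stimulus, population, alpha, sd, n_bootstrap, identifiable``);
    ``residuals`` and ``fitted`` are sample x ion matrices aligned with
    ``design`` and feed the residual bootstrap.
    """

    design: pd.DataFrame
    conditions: list[tuple[str, str]]
    profile: pd.DataFrame
    fitted: pd.DataFrame
    residuals: pd.DataFrame
    background: pd.Series
    block_rows: dict = field(repr=False, default_factory=dict)
    block_X: dict = field(repr=False, default_factory=dict)

    def alphas_wide(self) -> pd.DataFrame:
        """Pivot to one row per ion, columns (cell_line, stimulus, population)."""
        return self.profile.pivot_table(
            index="ion",
            columns=CONDITION_COLS + ["population"],
            values="alpha",
            sort=False,
        )


def _background_series(background, ions) -> pd.Series:
    if background is None:
        return pd.Series(0.0, index=ions)
    if np.isscalar(background):
        return pd.Series(float(background), index=ions)
    bg = pd.Series(background).reindex(ions)
    if bg.isna().any():
        raise ValueError("background missing for some ions")
    if (bg < 0).any():
        raise ValueError("background must be >= 0")
    return bg.astype(float)


def fit_alphas(
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    background: pd.Series | float | None = None,
) -> DeconvolutionFit:
    """Fit per-cell abundance coefficients by non-negative least squares.

    Solves, per ion, ``min || (I_mix - beta) - X alpha ||^2 s.t. alpha >= 0``
    over all conditions at once; the block-diagonal structure makes this
    equivalent to independent per-condition solves, which is how it is
    executed. Negative background-corrected intensities are kept as-is
    (the constraint acts on the coefficients, not the data).

    Parameters
    ----------
    intensities:
        Samples x ions table; rows aligned with ``design`` rows.
    design:
        Output of :func:`build_mix_design` (or equivalent).
    background:
        Per-ion instrument background ``beta`` (scalar, Series, or None
        for zero), typically the mean of cell-free blank samples.

    Rank-deficient condition blocks are flagged ``identifiable=False`` with
    NaN coefficients rather than silently zeroed.
    """
    if len(intensities) != len(design):
        raise ValueError("intensities and design must have the same number of rows")
    ions = list(intensities.columns)
    bg = _background_series(background, ions)
    Y = intensities.to_numpy(dtype=float) - bg.to_numpy()

    conditions = list(dict.fromkeys(zip(design["cell_line"], design["stimulus"])))
    fitted = np.zeros_like(Y)
    records = []
    block_rows: dict = {}
    block_X: dict = {}
    for cond in conditions:
        mask = (
            (design["cell_line"] == cond[0]) & (design["stimulus"] == cond[1])
        ).to_numpy()
        rows = np.flatnonzero(mask)
        sub = design.iloc[rows]
        X = np.column_stack(
            [sub["n_p"].to_numpy() * sub["v_p"].to_numpy(),
             sub["n_q"].to_numpy() * sub["v_q"].to_numpy()]
        )
        block_rows[cond] = rows
        block_X[cond] = X
        identifiable = np.linalg.matrix_rank(X) >= 2
        for j, ion in enumerate(ions):
            if identifiable:
                coef, _ = nnls(X, Y[rows, j])
                fitted[rows, j] = X @ coef
            else:
                coef = np.array([np.nan, np.nan])
            for p, pop in enumerate(POPULATIONS):
                records.append(
                    {
                        "ion": ion,
                        "cell_line": cond[0],
                        "stimulus": cond[1],
                        "population": pop,
                        "alpha": coef[p],
                        "sd": np.nan,
                        "n_bootstrap": 0,
                        "identifiable": identifiable,
                    }
                )
    profile = pd.DataFrame(records)
    fitted_df = pd.DataFrame(fitted, index=intensities.index, columns=ions)
    residuals = pd.DataFrame(Y, index=intensities.index, columns=ions) - fitted_df
    return DeconvolutionFit(
        design=design.reset_index(drop=True),
        conditions=conditions,
        profile=profile,
        fitted=fitted_df,
        residuals=residuals,
        background=bg,
        block_rows=block_rows,
        block_X=block_X,
    )


def bootstrap_errors(
    fit: DeconvolutionFit,
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
) -> DeconvolutionFit:
    """Residual-bootstrap standard deviations for the fitted coefficients.

    Per repetition the model residuals are resampled with replacement
    within each condition block (the design is fixed by construction),
    added to the fitted values, and the constrained model refit; the
    coefficient SD over ``n_reps`` repetitions (default 100) becomes the
    coefficient error. Zero-residual fits yield sd = 0.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ions = list(fit.fitted.columns)
    profile = fit.profile.set_index(CONDITION_COLS + ["population", "ion"])
    fitted = fit.fitted.to_numpy()
    resid = fit.residuals.to_numpy()

    for cond in fit.conditions:
        rows = fit.block_rows[cond]
        X = fit.block_X[cond]
        if np.linalg.matrix_rank(X) < 2:
            continue
        nb = len(rows)
        draws = np.empty((n_reps, 2, len(ions)))
        for r in range(n_reps):
            for j in range(len(ions)):
                idx = rng.integers(0, nb, nb)
                y_star = fitted[rows, j] + resid[rows, j][idx]
                draws[r, :, j], _ = nnls(X, y_star)
        sds = draws.std(axis=0, ddof=0)
        for p, pop in enumerate(POPULATIONS):
            for j, ion in enumerate(ions):
                profile.loc[(cond[0], cond[1], pop, ion), "sd"] = sds[p, j]
                profile.loc[(cond[0], cond[1], pop, ion), "n_bootstrap"] = n_reps
    fit.profile = profile.reset_index()[fit.profile.columns]
    return fit


def purify_intensities(
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    profile: pd.DataFrame,
    endpoint: str,
    background: pd.Series | float | None = None,
) -> pd.DataFrame:
    """Reconstruct single-subpopulation intensity profiles at an end point.

    For the 96-h sample (mostly G0 cells) the contribution of the other
    subpopulation is subtracted, ``I_G0 = I_mix - alpha_P * N_P * V_P``,
    and the result divided by the G0 cell count ``N_Q``; the 8-h sample is
    treated symmetrically with the roles swapped. Negative purified values
    are floored at 0 and flagged. If a per-ion ``background`` is given it
    is subtracted before normalization, so noise-free per-cell values equal
    the focal population's alpha exactly.

    Returns a tidy DataFrame with one row per (sample, ion):
    ``sample, ion, purified, per_cell, floored``.
    """
    if endpoint not in {"8h", "96h"}:
        raise ValueError("endpoint must be '8h' or '96h'")
    other_pop, focal_pop = ("Q", "P") if endpoint == "8h" else ("P", "Q")
    other_cols = ("n_q", "v_q") if endpoint == "8h" else ("n_p", "v_p")
    focal_count = "n_p" if endpoint == "8h" else "n_q"
    if len(intensities) != len(design):
        raise ValueError("intensities and design must have the same number of rows")

    ions = list(intensities.columns)
    bg = _background_series(background, ions)
    alpha = (
        profile[profile["population"] == other_pop]
        .set_index(["ion"] + CONDITION_COLS)["alpha"]
    )

    out = []
    for i, row in enumerate(design.itertuples(index=False)):
        cond = (row.cell_line, row.stimulus)
        n_focal = getattr(row, focal_count)
        if n_focal <= 0:
            raise ValueError(
                f"sample {intensities.index[i]!r}: focal population ({focal_pop}) "
                "count is 0, per-cell normalization undefined"
            )
        n_other = getattr(row, other_cols[0]) * getattr(row, other_cols[1])
        for ion in ions:
            a_other = alpha[(ion, *cond)]
            contribution = 0.0 if n_other == 0 else a_other * n_other
            purified = intensities.iloc[i][ion] - contribution - bg[ion]
            floored = purified < 0
            purified = max(purified, 0.0)
            out.append(
                {
                    "sample": intensities.index[i],
                    "ion": ion,
                    "cell_line": row.cell_line,
                    "stimulus": row.stimulus,
                    "purified": purified,
                    "per_cell": purified / n_focal,
                    "floored": bool(floored),
                }
            )
    return pd.DataFrame(out)


def compare_to_reference(
    profile: pd.DataFrame,
    reference: pd.DataFrame,
    errors: pd.DataFrame | None = None,
    error_multiplier: float = 3.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Validate deconvolved profiles against independent per-cell-line data.

    Characteristic ions are those whose variation across cell lines exceeds
    ``error_multiplier`` times the typical (median) per-cell-line error of
    the reference estimates; for each such ion a Spearman correlation
    across the shared cell lines compares the deconvolved and reference
    abundance rankings. A null distribution is built by scrambling the
    cell-line labels of the reference and recomputing the correlations.

    Parameters
    ----------
    profile, reference:
        Ion x cell-line abundance tables (wide; shared ions and >= 3
        shared cell-line columns required).
    errors:
        Per-ion, per-cell-line errors of the reference estimates; if None
        every ion is treated as characteristic.

    Returns
    -------
    (per-ion DataFrame with ``spearman_r``; flat array of null correlations)
    """
    shared_lines = [c for c in reference.columns if c in profile.columns]
    if len(shared_lines) < 3:
        raise ValueError("need >= 3 shared cell lines for a rank correlation")
    shared_ions = reference.index.intersection(profile.index)

    ref = reference.loc[shared_ions, shared_lines]
    prof = profile.loc[shared_ions, shared_lines]
    if errors is not None:
        typical = np.nanmedian(errors.loc[shared_ions, shared_lines].to_numpy())
        characteristic = ref.std(axis=1, ddof=1) > error_multiplier * typical
    else:
        characteristic = pd.Series(True, index=shared_ions)
    ions = shared_ions[characteristic]

    rows = []
    for ion in ions:
        r = spearmanr(prof.loc[ion], ref.loc[ion]).statistic
        rows.append({"ion": ion, "spearman_r": r})
    result = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(ions)))
    ref_arr = ref.loc[ions].to_numpy()
    prof_arr = prof.loc[ions].to_numpy()
    for b in range(n_permutations):
        perm = rng.permutation(len(shared_lines))
        for i in range(len(ions)):
            null[b, i] = spearmanr(prof_arr[i], ref_arr[i, perm]).statistic
    if len(ions) and np.isnan(null).any():
        warnings.warn("ties produced undefined correlations in the permutation null")
    return result, null.ravel()
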