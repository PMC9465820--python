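"""Differential statistics downstream of the deconvolution.

Covers (i) standardized effect sizes between the quiescent (Q) and
proliferating (P) coefficients, ``d = (alpha_Q - alpha_P) / SD_pooled``
with ``SD_pooled = sqrt((SD_P^2 + SD_Q^2)/2)``; (ii) the iterative
effect-size-thresholding hypergeometric test that calls metabolites with
a consistent quiescence-associated pattern across the cell-line x
stimulus grid; (iii) one-way ANOVA across quiescence stimuli; and (iv)
confluence-normalized log2 fold-changes for dynamic treatment profiling.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "effect_size",
    "effect_size_table",
    "g0_association",
    "bh_adjust",
    "stimulus_anova",
    "dynamic_fold_change",
]


def effect_size(alpha_q, alpha_p, sd_q, sd_p):
    """Standardized Q-vs-P difference, ``(alpha_Q - alpha_P)/SD_pooled``.

    ``SD_pooled = sqrt((SD_P**2 + SD_Q**2)/2)``. A negative value means a
    lower abundance in quiescent cells. NaN where the pooled SD is zero
    (undefined; excluded downstream). Accepts scalars or arrays.
    """
    alpha_q = np.asarray(alpha_q, dtype=float)
    alpha_p = np.asarray(alpha_p, dtype=float)
    sd_q = np.asarray(sd_q, dtype=float)
    sd_p = np.asarray(sd_p, dtype=float)
    if np.any(sd_q < 0) or np.any(sd_p < 0):
        raise ValueError("standard deviations must be >= 0")
    pooled = np.sqrt((sd_p**2 + sd_q**2) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, (alpha_q - alpha_p) / pooled, np.nan)
    return d if d.ndim else float(d)


def effect_size_table(profile: pd.DataFrame) -> pd.DataFrame:
    """Per (ion, cell line, stimulus) effect sizes from a coefficient table.

    ``profile`` is the tidy deconvolution output with columns
    ``ion, cell_line, stimulus, population, alpha, sd``.
    """
    wide = profile.pivot_table(
        index=["ion", "cell_line", "stimulus"],
        columns="population",
        values=["alpha", "sd"],
        sort=False,
    )
    d = effect_size(
        wide[("alpha", "Q")], wide[("alpha", "P")],
        wide[("sd", "Q")], wide[("sd", "P")],
    )
    pooled = np.sqrt((wide[("sd", "P")] ** 2 + wide[("sd", "Q")] ** 2) / 2.0)
    out = wide.index.to_frame(index=False)
    out["d"] = np.asarray(d)
    out["pooled_sd"] = pooled.to_numpy()
    return out


def _hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def g0_association(
    effects: pd.DataFrame,
    thresholds: Sequence[float] | None = None,
    draws: str = "conditions",
) -> pd.DataFrame:
    """Call metabolites with a consistent G0-associated abundance pattern.

    For every ion and every integer effect-size threshold ``t`` in the
    grid, the conditions with ``d > +t`` and with ``d < -t`` are counted
    and the sign with the larger count prioritized. Significance of the
    consistent pattern is an upper-tail hypergeometric probability of
    drawing at least that many threshold-passing entries when sampling
    the ion's conditions at random from all same-sign effect sizes pooled
    over the whole table. Per ion the threshold with the smallest
    p-value is reported (tie: the smallest threshold) and
    Benjamini-Hochberg correction is applied across ions at the end.

    Parameters
    ----------
    effects:
        Output of :func:`effect_size_table` (columns ``ion, d``; one row
        per ion x condition). NaN effect sizes are ignored.
    thresholds:
        Threshold grid; default ``3 .. ceil(mean(|d|))`` in steps of 1
        (at least ``[3]``).
    draws:
        ``"conditions"`` (default): the hypergeometric draw count is the
        ion's number of conditions (18 in the full design), truncated to
        the pooled population size. ``"same_sign"``: the ion's number of
        same-sign conditions.

    Returns
    -------
    Per-ion DataFrame: ``direction`` (+1/-1/0), ``n_passing``,
    ``n_conditions``, ``g0_association`` (fraction of conditions
    passing), ``threshold``, ``p_value``, ``p_adjusted``, ``sign_tie``.
    """
    if draws not in {"conditions", "same_sign"}:
        raise ValueError("draws must be 'conditions' or 'same_sign'")
    d_all = effects["d"].to_numpy(dtype=float)
    finite = np.isfinite(d_all)
    pos_pool = d_all[finite & (d_all > 0)]
    neg_pool = -d_all[finite & (d_all < 0)]  # magnitudes of negative effects

    if thresholds is None:
        upper = max(3, math.ceil(np.mean(np.abs(d_all[finite])))) if finite.any() else 3
        thresholds = np.arange(3, upper + 1)
    thresholds = np.asarray(thresholds, dtype=float)

    records = []
    for ion, grp in effects.groupby("ion", sort=False):
        d = grp["d"].to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        n_cond = len(d)
        best = {
            "ion": ion, "direction": 0, "n_passing": 0, "n_conditions": n_cond,
            "g0_association": 0.0, "threshold": np.nan, "p_value": 1.0,
            "sign_tie": False,
        }
        recorded = False
        for t in thresholds:
            k_pos = int(np.sum(d > t))
            k_neg = int(np.sum(d < -t))
            if k_pos == 0 and k_neg == 0:
                continue
            tie = k_pos == k_neg
            if k_pos > k_neg:
                sign = 1
            elif k_neg > k_pos:
                sign = -1
            else:  # tie: the sign carrying the larger summed magnitude
                sign = 1 if np.sum(d[d > t]) >= np.sum(-d[d < -t]) else -1
            pool = pos_pool if sign > 0 else neg_pool
            k = k_pos if sign > 0 else k_neg
            N = len(pool)
            if N == 0:
                continue  # p undefined for this sign at this threshold
            K = int(np.sum(pool > t))
            if draws == "conditions":
                n = min(n_cond, N)
            else:
                n = min(int(np.sum(d > 0) if sign > 0 else np.sum(d < 0)), N)
            p = max(_hypergeom_sf(k, N, K, n), np.finfo(float).tiny)
            if not recorded or p < best["p_value"] - 1e-15:
                best.update(
                    direction=sign, n_passing=k,
                    g0_association=k / n_cond if n_cond else 0.0,
                    threshold=float(t), p_value=p, sign_tie=tie,
                )
                recorded = True
        records.append(best)
    out = pd.DataFrame(records)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN inputs are excluded from the family size and propagated as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if np.any((p[ok] <= 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def stimulus_anova(values: pd.DataFrame, min_per_group: int = 2) -> pd.DataFrame:
    """One-way ANOVA per ion across stimulus groups, BH-corrected.

    ``values`` is tidy with columns ``ion, stimulus, value`` (e.g. one
    coefficient or effect size per cell line per stimulus). Requires >= 2
    groups with >= ``min_per_group`` observations each; ions violating
    this get NaN.
    """
    records = []
    for ion, grp in values.groupby("ion", sort=False):
        groups = [g["value"].to_numpy(dtype=float) for _, g in grp.groupby("stimulus")]
        groups = [g[np.isfinite(g)] for g in groups]
        groups = [g for g in groups if len(g) >= min_per_group]
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups):
            records.append({"ion": ion, "f_stat": np.nan, "p_value": np.nan})
            continue
        f, p = stats.f_oneway(*groups)
        records.append({"ion": ion, "f_stat": float(f), "p_value": float(p)})
    out = pd.DataFrame(records)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def dynamic_fold_change(
    measured: pd.DataFrame,
    measured_confluence,
    steady: pd.DataFrame,
    steady_confluence,
    groups=None,
    unperturbed=None,
) -> pd.DataFrame:
    """Confluence-normalized log2 fold-changes of a treatment time course.

    Per ion, a linear regression of abundance against cell confluence on
    steady-state (unperturbed growth) samples predicts the expected
    abundance at each time-course sample's confluence;
    ``log2FC = log2(measured / expected)``. Samples whose confluence lies
    outside the steady-state range are flagged ``extrapolated``; ions with
    an expected abundance <= 0 are flagged ``undefined`` with NaN.

    With ``groups`` (a label per measured sample, e.g. time point) and
    ``unperturbed`` (boolean mask over measured samples), each perturbed
    group is tested per ion by an unpaired t-test of its log2FC values
    against all unperturbed samples, BH-corrected across ions within the
    group; per-group results are returned in a second set of columns via
    the ``summary`` attribute-free tidy output (``group`` rows).

    Returns a tidy DataFrame with one row per (sample, ion):
    ``sample, ion, group, log2fc, expected, extrapolated, undefined`` and,
    when tests are run, per-(group, ion) columns ``p_value, p_adjusted``
    merged in.
    """
    mc = np.asarray(measured_confluence, dtype=float)
    sc = np.asarray(steady_confluence, dtype=float)
    if len(mc) != len(measured) or len(sc) != len(steady):
        raise ValueError("confluence vectors must match table rows")
    lo, hi = sc.min(), sc.max()
    ions = list(measured.columns)

    rows = []
    for ion in ions:
        fit = stats.linregress(sc, steady[ion].to_numpy(dtype=float))
        expected = fit.intercept + fit.slope * mc
        meas = measured[ion].to_numpy(dtype=float)
        for i, sample in enumerate(measured.index):
            undefined = expected[i] <= 0 or meas[i] <= 0
            rows.append(
                {
                    "sample": sample,
                    "ion": ion,
                    "group": None if groups is None else groups[i],
                    "log2fc": np.nan if undefined else np.log2(meas[i] / expected[i]),
                    "expected": expected[i],
                    "extrapolated": bool(mc[i] < lo or mc[i] > hi),
                    "undefined": bool(undefined),
                }
            )
    out = pd.DataFrame(rows)
    if groups is None or unperturbed is None:
        return out

    unperturbed = np.asarray(unperturbed, dtype=bool)
    sample_flags = dict(zip(measured.index, unperturbed))
    out["unperturbed"] = out["sample"].map(sample_flags)
    tests = []
    for grp_label, sub in out[~out["unperturbed"]].groupby("group", sort=False):
        for ion, ion_sub in sub.groupby("ion", sort=False):
            ref = out[(out["unperturbed"]) & (out["ion"] == ion)]["log2fc"].dropna()
            vals = ion_sub["log2fc"].dropna()
            if len(vals) < 2 or len(ref) < 2:
                p = np.nan
            else:
                p = float(stats.ttest_ind(vals, ref).pvalue)
            tests.append({"group": grp_label, "ion": ion, "p_value": p})
    tests = pd.DataFrame(tests)
    tests["p_adjusted"] = np.nan
    for grp_label, sub in tests.groupby("group", sort=False):
        tests.loc[sub.index, "p_adjusted"] = bh_adjust(sub["p_value"].to_numpy())
    return out.merge(tests, on=["group", "ion"], how="left")
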