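"""Cell-cycle gating from DNA/RNA co-staining cytometry events.

Events are stratified by DNA content (Hoechst channel) into 2n and 4n
windows around histogram peaks, with S phase in between, and the 2n
window is split by RNA content (Pyronin-Y channel): cells with 2n DNA and
an RNA content below the proliferating (S and G2/M) phases are classified
as G0. Gates derived on a reference sample (the 8-h sample of each cell
line, which contains all cycle phases) can be reused on later samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "GatingError",
    "GateParams",
    "CellCycleFractions",
    "pick_dna_peaks",
    "derive_gates",
    "classify_phases",
]

PHASES = ("G0", "G1", "S", "G2M")


class GatingError(RuntimeError):
    """Raised when gates cannot be derived from the provided events."""


@dataclass(frozen=True)
class GateParams:
    """Gate geometry: DNA peak locations, window half-widths, RNA split."""

    g1_peak: float
    g2m_peak: float
    g1_halfwidth: float
    g2m_halfwidth: float
    rna_threshold: float
    fallback_g2m: bool = False  # True when 4n peak was imputed as 2 x 2n


@dataclass
class CellCycleFractions:
    """Phase fractions over classified events plus the gates used."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_unclassified: int
    gates: GateParams
    labels: pd.Series  # per-event assignment incl. "unclassified"


def _check_events(events: pd.DataFrame, min_events: int) -> None:
    for col in ("dna", "rna"):
        if col not in events.columns:
            raise ValueError(f"event table lacks a '{col}' column")
        vals = events[col].to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{col} intensities must be finite and >= 0")
    if len(events) < min_events:
        raise GatingError(
            f"only {len(events)} events; gating requires >= {min_events}"
        )


def pick_dna_peaks(
    events: pd.DataFrame,
    ratio_band: tuple[float, float] = (1.7, 2.3),
    min_events: int = 1000,
) -> tuple[float, float, bool]:
    """Pick the 2n (G1) and 4n (G2/M) peaks from the DNA-content histogram.

    The histogram uses Freedman-Diaconis bins, is smoothed with a short
    moving average, and peaks are ranked by prominence; the returned pair
    is the most prominent pair whose location ratio falls in
    ``ratio_band`` (default [1.7, 2.3], around the expected 2x). If only
    one peak is found -- e.g. an all-G0 sample -- the 4n peak is imputed
    as twice the 2n peak and the fallback flag set.

    Returns ``(g1_peak, g2m_peak, fallback)``.
    """
    _check_events(events, min_events)
    dna = events["dna"].to_numpy(dtype=float)
    iqr = np.subtract(*np.percentile(dna, [75, 25]))
    span = dna.max() - dna.min()
    if span <= 0:
        raise GatingError("no detectable peak: DNA channel is constant")
    width = 2 * iqr / len(dna) ** (1 / 3)
    if width <= 0:
        width = span / 100
    n_bins = max(10, int(np.ceil(span / width)))
    counts, edges = np.histogram(dna, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")

    idx, props = find_peaks(smooth, prominence=0.02 * smooth.max())
    if len(idx) == 0:
        raise GatingError("no detectable peak in the DNA channel")
    order = np.argsort(props["prominences"])[::-1]
    locs = centers[idx][order]
    proms = props["prominences"][order]

    best, best_score = None, -np.inf
    for i in range(len(locs)):
        for j in range(len(locs)):
            lo, hi = sorted((locs[i], locs[j]))
            if i != j and ratio_band[0] <= hi / lo <= ratio_band[1]:
                score = proms[i] + proms[j]
                if score > best_score:
                    best, best_score = (lo, hi), score
    if best is not None:
        return best[0], best[1], False
    g1 = locs[0]
    return g1, 2.0 * g1, True


def derive_gates(
    events: pd.DataFrame,
    dna_halfwidth_k: float = 2.5,
    rna_quantile: float = 5.0,
    ratio_band: tuple[float, float] = (1.7, 2.3),
    min_events: int = 1000,
    min_proliferating_fraction: float = 0.02,
) -> GateParams:
    """Derive gate parameters from a reference event table.

    DNA window half-widths are ``k`` robust SDs (1.4826 x MAD) of the 2n
    mode (default k = 2.5), with the 4n half-width scaled by the peak
    ratio (constant coefficient of variation). The RNA threshold
    separating G0 from G1 is the ``rna_quantile``-th percentile (default
    5) of RNA intensity among events in the S and G2/M DNA windows -- a
    robust lower envelope of the proliferating RNA distribution.
    """
    g1, g2m, fallback = pick_dna_peaks(events, ratio_band, min_events)
    dna = events["dna"].to_numpy(dtype=float)
    near_g1 = np.abs(dna - g1) < 0.5 * (g2m - g1)
    mad = np.median(np.abs(dna[near_g1] - g1))
    robust_sd = 1.4826 * mad
    if robust_sd <= 0:
        robust_sd = 0.01 * g1
    hw1 = dna_halfwidth_k * robust_sd
    hw2 = hw1 * g2m / g1

    proliferating = dna > g1 + hw1
    proliferating &= dna <= g2m + hw2
    # a pure-2n sample leaks a small lognormal tail past the G1 window;
    # require a real S/G2M presence before trusting its RNA percentile
    if proliferating.mean() < min_proliferating_fraction:
        raise GatingError(
            "RNA threshold underivable: too few events in the S/G2M DNA "
            "windows of the reference sample"
        )
    rna_thr = float(np.percentile(events["rna"].to_numpy()[proliferating], rna_quantile))
    return GateParams(g1, g2m, hw1, hw2, rna_thr, fallback)


def classify_phases(
    events: pd.DataFrame,
    gates: GateParams | str = "derive",
    min_events: int = 1000,
    **derive_kwargs,
) -> CellCycleFractions:
    """Assign events to G0/G1/S/G2M and return subpopulation fractions.

    Events inside the 2n DNA window with RNA below the threshold are G0,
    inside the 2n window above the threshold G1, between the windows S,
    inside the 4n window G2/M. Events outside all windows are counted as
    unclassified and excluded from the fractions.

    Pass ``gates="derive"`` to derive gates from these events, or a
    :class:`GateParams` from a reference sample to reuse its gates.
    """
    _check_events(events, min_events)
    if isinstance(gates, str):
        if gates != "derive":
            raise ValueError("gates must be 'derive' or a GateParams")
        gates = derive_gates(events, min_events=min_events, **derive_kwargs)

    dna = events["dna"].to_numpy(dtype=float)
    rna = events["rna"].to_numpy(dtype=float)
    in_2n = np.abs(dna - gates.g1_peak) <= gates.g1_halfwidth
    in_4n = np.abs(dna - gates.g2m_peak) <= gates.g2m_halfwidth
    between = (dna > gates.g1_peak + gates.g1_halfwidth) & (
        dna < gates.g2m_peak - gates.g2m_halfwidth
    )

    labels = np.full(len(events), "unclassified", dtype=object)
    labels[in_4n] = "G2M"
    labels[between] = "S"
    labels[in_2n & (rna >= gates.rna_threshold)] = "G1"
    labels[in_2n & (rna < gates.rna_threshold)] = "G0"

    label_s = pd.Series(labels, index=events.index, name="phase")
    counts = {p: int((labels == p).sum()) for p in PHASES}
    n_classified = sum(counts.values())
    if n_classified == 0:
        raise GatingError("no events fall inside any gate window")
    fractions = {p: counts[p] / n_classified for p in PHASES}
    return CellCycleFractions(
        fractions=fractions,
        counts=counts,
        n_unclassified=int(len(events) - n_classified),
        gates=gates,
        labels=label_s,
    )
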