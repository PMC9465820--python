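"""Synthetic experiments with known ground truth for every pipeline stage.

Generates (i) mixed-extract ion-intensity tables following the linear
mixing model ``I = alpha_P*N_P*V_P + alpha_Q*N_Q*V_Q + beta + noise``
across the 8-point mixing design, (ii) spike-in linearity series with
detector saturation, (iii) DNA/RNA cytometry event clouds with a low-RNA
G0 mode, and (iv) exponential confluence curves with growth lags.

Noise model: the instrument error is multiplicative log-normal (mean-one,
parameterized by a coefficient of variation) plus an additive Gaussian
floor near the detection limit; both default to zero so the noise-free
limit is exact and bit-reproducible. Saturation is a hard clip by default,
with an optional soft (exponential-approach) variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mixdeconv.deconvolve import MIX_FRACTIONS, build_mix_design

__all__ = [
    "MeasurementModel",
    "SyntheticExperiment",
    "make_truth",
    "simulate_mix_experiment",
    "simulate_spikein_series",
    "simulate_cytometry_events",
    "simulate_confluence_curve",
    "three_decade_spikes",
]

PHASES = ("G0", "G1", "S", "G2M")

#: Default per-phase RNA-stain clouds (log-normal location and sigma).
#: The G0 location sits far below the proliferating phases, whose clouds
#: overlap each other, so a lower-envelope threshold of the S/G2M RNA
#: distribution lands in the gap between G0 and G1.
DEFAULT_RNA_PARAMS: dict[str, tuple[float, float]] = {
    "G0": (35.0, 0.18),
    "G1": (150.0, 0.15),
    "S": (140.0, 0.15),
    "G2M": (160.0, 0.15),
}


@dataclass(frozen=True)
class MeasurementModel:
    """Instrument model shared by the intensity simulators.

    Parameters
    ----------
    background:
        Ion-specific MS measurement background ``beta`` (scalar or per-ion
        array), >= 0.
    noise_cv:
        Coefficient of variation of the mean-one multiplicative log-normal
        noise (0 disables it).
    noise_floor_sd:
        SD of the additive Gaussian noise floor (0 disables it).
    saturation:
        Ion abundance above which further concentration increases yield no
        intensity increase; ``inf`` for unbounded.
    seed:
        Seed for the noise generator; noise-free output ignores it.
    soft_saturation:
        If True, intensities approach the limit as ``sat*(1-exp(-I/sat))``
        instead of a hard clip.
    """

    background: float | np.ndarray = 0.0
    noise_cv: float = 0.0
    noise_floor_sd: float = 0.0
    saturation: float | np.ndarray = np.inf
    seed: int | None = None
    soft_saturation: bool = False

    def __post_init__(self):
        if np.any(np.asarray(self.background) < 0):
            raise ValueError("background must be >= 0 for every ion")
        if self.noise_cv < 0 or self.noise_floor_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if np.any(np.asarray(self.saturation) < np.asarray(self.background)):
            raise ValueError("saturation must be >= background")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Add noise and apply the saturation limit to noise-free intensities."""
        out = np.asarray(clean, dtype=float)
        if self.noise_cv > 0:
            # mean-one log-normal: E[exp(s Z - s^2/2)] = 1, CV = sqrt(e^{s^2}-1)
            s = np.sqrt(np.log1p(self.noise_cv**2))
            out = out * np.exp(rng.normal(-0.5 * s * s, s, size=out.shape))
        if self.noise_floor_sd > 0:
            out = out + rng.normal(0.0, self.noise_floor_sd, size=out.shape)
        if self.soft_saturation and np.any(np.isfinite(self.saturation)):
            sat = np.broadcast_to(np.asarray(self.saturation, dtype=float), out.shape)
            finite = np.isfinite(sat)
            out = np.where(finite, np.where(sat > 0, sat, 1) * -np.expm1(-out / np.where(sat > 0, sat, 1)), out)
        else:
            out = np.minimum(out, self.saturation)
        return np.maximum(out, 0.0)


@dataclass
class SyntheticExperiment:
    """A simulated mixing experiment bundled with its ground truth."""

    truth: pd.DataFrame
    design: pd.DataFrame
    intensities: pd.DataFrame
    model: MeasurementModel
    g0_fractions: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write intensities/design as TSV and the ground truth as JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.intensities.to_csv(out / "intensities.tsv", sep="\t", index_label="sample")
        self.design.to_csv(out / "design.tsv", sep="\t", index=False)
        truth = {
            "alphas": {
                f"{r.cell_line}|{r.stimulus}|{r.population}|{r.ion}": r.alpha
                for r in self.truth.itertuples(index=False)
            },
            "g0_fractions": self.g0_fractions,
            "background": np.asarray(self.model.background).tolist(),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def make_truth(
    n_ions: int,
    conditions: Sequence[tuple[str, str]] = (("cellline1", "stimulus1"),),
    alpha_scale: float = 20.0,
    alpha_sigma: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ground-truth per-cell abundances, log-normal across ions.

    Per-cell ion intensities in FIA-TOFMS span orders of magnitude; a
    log-normal with median ``alpha_scale`` (intensity units per cell) and
    log-SD ``alpha_sigma`` is drawn independently for the P and Q
    populations of each condition.
    """
    rng = np.random.default_rng(seed)
    ions = [f"ion{i:04d}" for i in range(n_ions)]
    rows = []
    for cl, st in conditions:
        for pop in ("P", "Q"):
            alphas = alpha_scale * rng.lognormal(0.0, alpha_sigma, n_ions)
            for ion, a in zip(ions, alphas):
                rows.append(
                    {"cell_line": cl, "stimulus": st, "population": pop,
                     "ion": ion, "alpha": a}
                )
    return pd.DataFrame(rows)


def _truth_matrix(truth: pd.DataFrame, cond: tuple[str, str], ions) -> tuple[np.ndarray, np.ndarray]:
    sub = truth[(truth["cell_line"] == cond[0]) & (truth["stimulus"] == cond[1])]
    a_p = sub[sub["population"] == "P"].set_index("ion")["alpha"].reindex(ions)
    a_q = sub[sub["population"] == "Q"].set_index("ion")["alpha"].reindex(ions)
    if a_p.isna().any() or a_q.isna().any():
        raise ValueError(f"truth incomplete for condition {cond}")
    return a_p.to_numpy(), a_q.to_numpy()


def simulate_mix_experiment(
    truth: pd.DataFrame,
    totals: float = 1e4,
    fractions: Sequence[float] = MIX_FRACTIONS,
    g0_at_8h: float = 0.1,
    g0_at_96h: float = 0.8,
    model: MeasurementModel = MeasurementModel(),
    replicates: int = 3,
) -> SyntheticExperiment:
    """Simulate a mixed-extract intensity table over the mixing design.

    Subpopulation counts follow the design rule
    ``N_Q = totals*(f*g0_8h + (1-f)*g0_96h)``, ``N_P = totals - N_Q``; each
    sample's per-ion intensity is ``alpha_P*N_P*V_P + alpha_Q*N_Q*V_Q +
    beta`` passed through the measurement model's noise and saturation.
    Replicates are generated independently; output is reproducible under a
    fixed ``model.seed``.
    """
    if (truth["alpha"] < 0).any():
        raise ValueError("ground-truth abundances must be >= 0")
    conditions = list(dict.fromkeys(zip(truth["cell_line"], truth["stimulus"])))
    design = build_mix_design(
        totals=totals,
        fractions=fractions,
        g0_fraction_8h=g0_at_8h,
        g0_fraction_96h=g0_at_96h,
        conditions=conditions,
        replicates=replicates,
    )
    ions = list(dict.fromkeys(truth["ion"]))
    rng = model.rng()
    clean = np.empty((len(design), len(ions)))
    for cond in conditions:
        mask = (
            (design["cell_line"] == cond[0]) & (design["stimulus"] == cond[1])
        ).to_numpy()
        a_p, a_q = _truth_matrix(truth, cond, ions)
        sub = design[mask]
        np_v = (sub["n_p"] * sub["v_p"]).to_numpy()[:, None]
        nq_v = (sub["n_q"] * sub["v_q"]).to_numpy()[:, None]
        clean[mask] = np_v * a_p[None, :] + nq_v * a_q[None, :] + np.asarray(model.background)
    intensities = pd.DataFrame(
        model.apply(clean, rng),
        columns=ions,
        index=[f"s{i:03d}" for i in range(len(design))],
    )
    return SyntheticExperiment(
        truth=truth,
        design=design,
        intensities=intensities,
        model=model,
        g0_fractions={"8h": g0_at_8h, "96h": g0_at_96h},
    )


def three_decade_spikes(n: int = 7, low_pmol: float = 3.0, high_pmol: float = 3000.0) -> np.ndarray:
    """Spike amount grid spanning three decades (3 pmol to 3 nmol by default)."""
    return np.geomspace(low_pmol, high_pmol, n)


def simulate_spikein_series(
    base_extract_levels: Sequence[float],
    spike_amounts: Sequence[float],
    response_slopes: Sequence[float],
    model: MeasurementModel = MeasurementModel(),
    replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a spike-in linearity series for one sample matrix.

    Per ion, ``intensity = min(saturation, base + slope*spike + noise)``;
    the intercept equals the basal abundance of the metabolite in the
    unspiked extract. Spike amounts must be strictly increasing and >= 0.

    Returns a DataFrame with ``spike_amount`` and ``replicate`` columns
    plus one column per ion.
    """
    spikes = np.asarray(spike_amounts, dtype=float)
    if np.any(spikes < 0) or np.any(np.diff(spikes) <= 0):
        raise ValueError("spike amounts must be strictly increasing and >= 0")
    base = np.asarray(base_extract_levels, dtype=float)
    slopes = np.asarray(response_slopes, dtype=float)
    if base.shape != slopes.shape:
        raise ValueError("base levels and slopes must have matching shapes")

    rng = model.rng()
    rows, meta = [], []
    for rep in range(1, replicates + 1):
        for s in spikes:
            clean = base + slopes * s + np.asarray(model.background)
            rows.append(model.apply(clean, rng))
            meta.append({"spike_amount": s, "replicate": rep})
    table = pd.DataFrame(rows, columns=[f"ion{i:04d}" for i in range(len(base))])
    return pd.concat([pd.DataFrame(meta), table], axis=1)


def simulate_cytometry_events(
    n_events: int,
    phase_fractions: Mapping[str, float],
    dna_peak_g1: float = 100.0,
    rna_params: Mapping[str, tuple[float, float]] | None = None,
    dna_cv: float = 0.04,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate DNA/RNA co-staining event clouds with ground-truth labels.

    G0 and G1 events are log-normal around the 2n DNA peak, G2/M around
    the 4n peak (2x), and S-phase DNA is uniform between the two modes.
    The RNA channel is log-normal per phase with the G0 location strictly
    below the proliferating phases, emulating Hoechst/Pyronin-Y staining.

    Returns a DataFrame with columns ``dna, rna, label``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    fracs = np.array([phase_fractions.get(p, 0.0) for p in PHASES], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("phase fractions must sum to 1")
    if np.any(fracs < 0):
        raise ValueError("phase fractions must be >= 0")
    rna = dict(DEFAULT_RNA_PARAMS, **(rna_params or {}))
    for phase, (loc, scale) in rna.items():
        if loc <= 0 or scale <= 0:
            raise ValueError(f"degenerate RNA parameters for {phase}")
    if dna_cv <= 0 or dna_peak_g1 <= 0:
        raise ValueError("dna_peak_g1 and dna_cv must be > 0")
    prolif_locs = [rna[p][0] for p in ("G1", "S", "G2M") if fracs[PHASES.index(p)] > 0]
    if prolif_locs and rna["G0"][0] >= min(prolif_locs):
        raise ValueError("G0 RNA location must lie below proliferating phases")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, fracs)
    s_dna = np.sqrt(np.log1p(dna_cv**2))
    dna_parts, rna_parts, labels = [], [], []
    for phase, count in zip(PHASES, counts):
        if count == 0:
            continue
        if phase in ("G0", "G1"):
            dna = dna_peak_g1 * rng.lognormal(0.0, s_dna, count)
        elif phase == "G2M":
            dna = 2.0 * dna_peak_g1 * rng.lognormal(0.0, s_dna, count)
        else:  # S: uniform between the well-separated flanks of the two modes
            dna = rng.uniform(1.25 * dna_peak_g1, 1.75 * dna_peak_g1, count)
        loc, scale = rna[phase]
        rna_vals = loc * rng.lognormal(0.0, scale, count)
        dna_parts.append(dna)
        rna_parts.append(rna_vals)
        labels.extend([phase] * count)
    events = pd.DataFrame(
        {
            "dna": np.concatenate(dna_parts),
            "rna": np.concatenate(rna_parts),
            "label": labels,
        }
    )
    return events.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


def simulate_confluence_curve(
    c0: float,
    rate: float,
    lag: float = 0.0,
    t_max: float = 96.0,
    dt: float = 1.5,
    noise_sd: float = 0.0,
    plateau: float = 1.0,
    seed: int | None = None,
    replicate: int = 1,
) -> pd.DataFrame:
    """Simulate a lagged exponential confluence time series.

    Confluence stays at ``c0`` until ``lag`` hours, then grows as
    ``c0 * 10**(rate*(t-lag))`` (rate in log10 units per hour) capped at
    ``plateau``; Gaussian noise is added on top and the result clipped to
    (0, 1]. Sampled on the regular ``dt`` grid from 0 to ``t_max``.
    """
    if not 0 < c0 < plateau <= 1:
        raise ValueError("require 0 < c0 < plateau <= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, t_max + dt / 2, dt)
    c = np.where(t < lag, c0, c0 * 10.0 ** (rate * (t - lag)))
    c = np.minimum(c, plateau)
    if noise_sd > 0:
        c = c + np.random.default_rng(seed).normal(0.0, noise_sd, c.shape)
        c = np.clip(c, 1e-6, 1.0)
    return pd.DataFrame({"time_h": t, "confluence": c, "replicate": replicate})
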