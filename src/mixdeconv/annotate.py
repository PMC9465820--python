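"""Putative metabolite annotation by accurate-mass matching.

Measured m/z features are matched against reference monoisotopic masses
computed from elemental formulas, within a configurable mass tolerance
(default 0.003 m/z, strict). Because alpha-keto acids are stabilized with
phenylhydrazine during extraction, their phenylhydrazone derivatives
(formula shifted by +C6H8N2 -H2O, identifiers prefixed ``PHderiv_``) are
added to the reference list before matching.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "formula_mass",
    "parse_formula",
    "combine_formulas",
    "derivatize_keto_acids",
    "annotate_ions",
    "load_reference_list",
]

#: Most-abundant-isotope masses (Da), CODATA/AME-derived standard values.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885271,
    "F": 18.99840320,
    "Se": 79.91652,
}

#: Mass of a proton; [M-H]- ions appear at M - this value.
PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
PHENYLHYDRAZONE_SHIFT = ("C6H8N2", "H2O")  # added, removed


def parse_formula(formula: str, masses: dict[str, float] | None = None) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    masses = masses or MONOISOTOPIC_MASSES
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in masses:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def formula_mass(formula: str | dict, masses: dict[str, float] | None = None) -> float:
    """Neutral monoisotopic mass (Da) of an elemental formula.

    The empty formula has mass 0.
    """
    masses = masses or MONOISOTOPIC_MASSES
    counts = parse_formula(formula, masses) if isinstance(formula, str) else formula
    return float(sum(masses[el] * n for el, n in counts.items()))


def combine_formulas(base: str, add: str = "", remove: str = "") -> str:
    """Element bookkeeping ``base + add - remove``, in Hill order.

    Refuses combinations that would need a negative element count.
    """
    counts = parse_formula(base)
    for el, n in parse_formula(add).items() if add else ():
        counts[el] = counts.get(el, 0) + n
    for el, n in parse_formula(remove).items() if remove else ():
        counts[el] = counts.get(el, 0) - n
        if counts[el] < 0:
            raise ValueError(
                f"removing {remove} from {base}+{add} yields negative {el} count"
            )
    counts = {el: n for el, n in counts.items() if n > 0}
    ordered = [el for el in ("C", "H") if el in counts]
    ordered += sorted(el for el in counts if el not in ("C", "H"))
    return "".join(f"{el}{counts[el] if counts[el] > 1 else ''}" for el in ordered)


def derivatize_keto_acids(references: pd.DataFrame) -> pd.DataFrame:
    """Append phenylhydrazone derivative entries for flagged alpha-keto acids.

    For each entry with ``keto_acid == True`` a derivative row is added
    with formula ``+C6H8N2 -H2O``, identifier prefixed ``PHderiv_`` and
    ``derivative = True``; all other rows pass through unchanged.
    """
    required = {"id", "name", "formula"}
    if not required.issubset(references.columns):
        raise ValueError(f"reference list needs columns {sorted(required)}")
    out = references.copy()
    if "derivative" not in out.columns:
        out["derivative"] = False
    if "keto_acid" not in out.columns:
        return out
    add, remove = PHENYLHYDRAZONE_SHIFT
    rows = []
    for row in out[out["keto_acid"].astype(bool)].itertuples(index=False):
        rec = row._asdict()
        rec["id"] = f"PHderiv_{rec['id']}"
        rec["name"] = f"phenylhydrazone of {rec['name']}"
        rec["formula"] = combine_formulas(rec["formula"], add=add, remove=remove)
        rec["derivative"] = True
        if "mass" in rec:
            rec["mass"] = formula_mass(rec["formula"])
        rows.append(rec)
    return pd.concat([out, pd.DataFrame(rows)], ignore_index=True) if rows else out


def annotate_ions(
    mz_values,
    references: pd.DataFrame,
    tolerance: float = 0.003,
    adduct: str = "M-H",
    inclusive: bool = False,
) -> pd.DataFrame:
    """Match measured m/z values against a reference mass list.

    Expected m/z per reference entry follows the adduct rule: ``"M-H"``
    (deprotonation, the default for negative-mode flow injection),
    ``"M+H"``, or ``"neutral"``. Every reference within the tolerance is
    reported (closest first, never collapsed); unmatched ions appear with
    an empty match. The tolerance comparison is strict unless
    ``inclusive``.

    Returns a tidy DataFrame: ``mz, id, name, expected_mz, mass_error,
    adduct`` with NaN/None fields for unmatched ions.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    refs = references.copy()
    if "mass" not in refs.columns:
        refs["mass"] = [formula_mass(f) for f in refs["formula"]]
    if adduct == "M-H":
        refs["expected_mz"] = refs["mass"] - PROTON_MASS
    elif adduct == "M+H":
        refs["expected_mz"] = refs["mass"] + PROTON_MASS
    elif adduct == "neutral":
        refs["expected_mz"] = refs["mass"]
    else:
        raise ValueError(f"unknown adduct rule {adduct!r}")

    rows = []
    expected = refs["expected_mz"].to_numpy(dtype=float)
    for mz in np.asarray(mz_values, dtype=float):
        err = mz - expected
        # inclusive gets a 1e-12 Da guard so an exactly-at-boundary match
        # survives floating-point representation of the tolerance
        hit = np.abs(err) <= tolerance + 1e-12 if inclusive else np.abs(err) < tolerance
        if not hit.any():
            rows.append(
                {"mz": mz, "id": None, "name": None,
                 "expected_mz": np.nan, "mass_error": np.nan, "adduct": adduct}
            )
            continue
        order = np.argsort(np.abs(err[hit]), kind="stable")
        sub = refs[hit].iloc[order]
        for _, ref in sub.iterrows():
            rows.append(
                {
                    "mz": mz,
                    "id": ref["id"],
                    "name": ref["name"],
                    "expected_mz": float(ref["expected_mz"]),
                    "mass_error": float(mz - ref["expected_mz"]),
                    "adduct": adduct,
                }
            )
    return pd.DataFrame(rows)


def load_reference_list(derivatize: bool = True) -> pd.DataFrame:
    """Load the bundled reference metabolite list (small curated set).

    Masses are computed from the formulas at load time; with
    ``derivatize=True`` phenylhydrazone entries for the flagged alpha-keto
    acids are appended.
    """
    with resources.files("mixdeconv").joinpath("data/reference_metabolites.tsv").open() as fh:
        refs = pd.read_csv(fh, sep="\t")
    refs["keto_acid"] = refs["keto_acid"].astype(bool)
    if derivatize:
        refs = derivatize_keto_acids(refs)
    refs["mass"] = [formula_mass(f) for f in refs["formula"]]
    return refs
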