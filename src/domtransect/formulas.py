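"""Molecular-formula descriptors and van Krevelen compound classification.

Ultrahigh-resolution mass spectrometry of dissolved organic matter (DOM)
yields thousands of elemental formulas (CHNOSP) per sample, each with a
relative signal intensity.  This module derives the standard elemental
descriptors used to place formulas in van Krevelen space (H/C vs O/C),
the double-bond equivalents (DBE) and the modified aromaticity index
(AImod), and classifies every formula into the compound groups commonly
reported for DOM (saturated, saccharide-like, unsaturated, highly
unsaturated, aromatic, polycyclic aromatic) plus the three
sulfur-containing groups that track combustion-derived "dissolved black
sulfur", its degradation products, and abiotic sulfurization in sulfidic
(mangrove porewater) environments.

Definitions
-----------
DBE   = 1 + C - H/2 + N/2 + P/2
AImod = (1 + C - O/2 - S - H/2) / (C - O/2 - S - N - P)

AImod is clamped to 0 whenever its numerator or denominator is <= 0
(the standard convention: such formulas cannot be aromatic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics.mass import Composition
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "MolecularFormula",
    "FormulaDescriptors",
    "FormulaTable",
    "parse_formula",
    "compute_descriptors",
    "classify_compound_group",
    "classify_sulfur_group",
    "group_relative_abundances",
    "intensity_weighted_parameter",
    "COMPOUND_GROUPS",
    "SULFUR_GROUPS",
    "DEFAULT_PRECEDENCE",
]

ALLOWED_ELEMENTS = ("C", "H", "N", "O", "S", "P")

COMPOUND_GROUPS = (
    "saturated",
    "saccharide",
    "unsaturated",
    "highly_unsaturated",
    "aromatic",
    "PAC",
    "other",
)

SULFUR_GROUPS = (
    "dissolved_black_sulfur",
    "highly_unsaturated_S",
    "sulfurized_aliphatic",
    "other_S",
    "not_S",
)

#: Order in which overlapping compound-group rules are evaluated.  The
#: printed threshold rules overlap (glucose satisfies both the saccharide
#: and the unsaturated rule); the first matching rule wins.
DEFAULT_PRECEDENCE = (
    "saturated",
    "saccharide",
    "unsaturated",
    "PAC",
    "aromatic",
    "highly_unsaturated",
)


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition restricted to C, H, N, O, S, P."""

    c: int
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"element count {name!r} must be a nonnegative integer, got {v!r}")

    def __str__(self) -> str:
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("N", self.n),
                           ("O", self.o), ("S", self.s), ("P", self.p)):
            if count == 1:
                parts.append(sym)
            elif count > 1:
                parts.append(f"{sym}{count}")
        return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C20H18O11"``.

    Implicit counts of 1 are allowed (``"CH4"``).  Elements outside
    C, H, N, O, S, P are rejected.
    """
    if not isinstance(text, str) or not text or not re.fullmatch(r"[A-Za-z0-9]+", text):
        raise ValueError(f"malformed formula string: {text!r}")
    try:
        comp = Composition(formula=text)
    except PyteomicsError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed formula string: {text!r}") from exc
    extra = set(comp) - set(ALLOWED_ELEMENTS)
    if extra:
        raise ValueError(f"unsupported element(s) {sorted(extra)} in {text!r}")
    return MolecularFormula(
        c=comp.get("C", 0), h=comp.get("H", 0), n=comp.get("N", 0),
        o=comp.get("O", 0), s=comp.get("S", 0), p=comp.get("P", 0),
    )


@dataclass(frozen=True)
class FormulaDescriptors:
    h_to_c: float
    o_to_c: float
    dbe: float
    aimod: float
    contains_sulfur: bool


def compute_descriptors(f: MolecularFormula) -> FormulaDescriptors:
    """Elemental ratios, DBE and (clamped) modified aromaticity index."""
    if f.c < 1:
        raise ValueError("descriptor computation requires at least one carbon")
    dbe = 1.0 + f.c - f.h / 2.0 + f.n / 2.0 + f.p / 2.0
    numer = 1.0 + f.c - f.o / 2.0 - f.s - f.h / 2.0
    denom = f.c - f.o / 2.0 - f.s - f.n - f.p
    aimod = 0.0 if (numer <= 0.0 or denom <= 0.0) else numer / denom
    return FormulaDescriptors(
        h_to_c=f.h / f.c,
        o_to_c=f.o / f.c,
        dbe=dbe,
        aimod=aimod,
        contains_sulfur=f.s > 0,
    )


def _rule_matches(group: str, d: FormulaDescriptors) -> bool:
    if group == "saturated":
        return d.dbe == 0.0
    if group == "saccharide":
        return d.o_to_c >= 0.7 and 1.7 <= d.h_to_c < 2.2
    if group == "unsaturated":
        return 1.5 <= d.h_to_c <= 2.0
    if group == "highly_unsaturated":
        return d.aimod <= 0.50 and d.h_to_c < 1.5
    if group == "aromatic":
        return 0.5 < d.aimod <= 0.67
    if group == "PAC":
        return d.aimod > 0.67
    raise KeyError(group)


def classify_compound_group(
    d: FormulaDescriptors, precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
) -> str:
    """Assign exactly one compound-group label.

    The threshold rules are evaluated in ``precedence`` order and the
    first match wins; formulas matching no rule get ``"other"``.
    """
    for group in precedence:
        if _rule_matches(group, d):
            return group
    return "other"


def classify_sulfur_group(d: FormulaDescriptors) -> str:
    """Assign one of the three sulfur van Krevelen boxes (strict bounds).

    Sulfur-free formulas map to ``not_S``; sulfur-containing formulas
    falling in none of the boxes map to ``other_S``.
    """
    if not d.contains_sulfur:
        return "not_S"
    hc, oc = d.h_to_c, d.o_to_c
    if hc < 0.6 and oc < 0.3:
        return "dissolved_black_sulfur"
    if 0.6 < hc < 1.0 and oc < 0.3:
        return "highly_unsaturated_S"
    if 1.0 < hc < 1.5 and 0.4 < oc < 0.7:
        return "sulfurized_aliphatic"
    return "other_S"


class FormulaTable:
    """Formulas x samples relative-intensity matrix with derived descriptors.

    Parameters
    ----------
    formulas:
        Molecular formulas (one per row), or formula strings.
    intensities:
        DataFrame of nonnegative relative intensities; rows must align with
        ``formulas`` and columns are sample identifiers.  Every sample
        column must have a positive sum.
    """

    def __init__(self, formulas, intensities: pd.DataFrame):
        formulas = [
            f if isinstance(f, MolecularFormula) else parse_formula(f) for f in formulas
        ]
        intensities = pd.DataFrame(intensities).astype(float)
        if len(formulas) != len(intensities):
            raise ValueError("formulas and intensity rows differ in length")
        if (intensities.values < 0).any():
            raise ValueError("intensities must be nonnegative")
        colsums = intensities.sum(axis=0)
        if (colsums <= 0).any():
            bad = list(colsums.index[colsums <= 0])
            raise ValueError(f"sample(s) with zero total intensity: {bad}")
        self.formulas = list(formulas)
        self.intensities = intensities.reset_index(drop=True)
        self.sample_ids = list(intensities.columns)

    def __len__(self) -> int:
        return len(self.formulas)

    def descriptor_frame(self) -> pd.DataFrame:
        """Per-formula descriptors and group labels as a DataFrame."""
        rows = []
        for f in self.formulas:
            d = compute_descriptors(f)
            rows.append(
                {
                    "formula": str(f),
                    "C": f.c, "H": f.h, "N": f.n, "O": f.o, "S": f.s, "P": f.p,
                    "h_to_c": d.h_to_c,
                    "o_to_c": d.o_to_c,
                    "dbe": d.dbe,
                    "aimod": d.aimod,
                    "group": classify_compound_group(d),
                    "sulfur_group": classify_sulfur_group(d),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        out = self.descriptor_frame()[["formula"]].join(self.intensities)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FormulaTable":
        df = pd.read_csv(path, sep="\t")
        if "formula" not in df.columns:
            raise ValueError("formula table needs a 'formula' column")
        return cls(df["formula"].tolist(), df.drop(columns=["formula"]))


def group_relative_abundances(table: FormulaTable, grouping: str = "compound") -> pd.DataFrame:
    """Per-sample percentage of total intensity carried by each group.

    ``grouping`` is ``"compound"`` (Table-style compound groups) or
    ``"sulfur"`` (the three sulfur boxes plus other_S/not_S).  Including
    the residual label, percentages sum to 100 per sample.
    """
    desc = table.descriptor_frame()
    if grouping == "compound":
        labels, order = desc["group"], COMPOUND_GROUPS
    elif grouping == "sulfur":
        labels, order = desc["sulfur_group"], SULFUR_GROUPS
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    totals = table.intensities.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-intensity sample")
    grouped = table.intensities.groupby(labels.values).sum()
    grouped = grouped.reindex(order, fill_value=0.0)
    return (100.0 * grouped / totals).T  # samples x groups


def intensity_weighted_parameter(table: FormulaTable, descriptor: str) -> pd.Series:
    """Per-sample intensity-weighted mean of a descriptor column.

    ``descriptor`` is any numeric column of :meth:`FormulaTable.descriptor_frame`
    (e.g. ``"o_to_c"``, ``"aimod"``, ``"S"``).
    """
    desc = table.descriptor_frame()
    if descriptor not in desc.columns:
        raise KeyError(descriptor)
    d = desc[descriptor].to_numpy(dtype=float)
    w = table.intensities.to_numpy(dtype=float)
    totals = w.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero total weight in a sample")
    return pd.Series((d @ w) / totals, index=table.sample_ids, name=descriptor)
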