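"""Chemical-formula arithmetic and adduct-aware accurate-mass annotation.

An ESI source does not yield the neutral molecule M but an adduct ion
([M+H]+, [M+Na]+, [M-H]-, ...), so annotating a molecular feature means
reconciling its observed m/z with ``(monoisotopic_mass(M) + delta)/z`` for
some adduct rule of the matching polarity, within a ppm tolerance. Hits at
this level are annotation level 3 (accurate mass only, no MS/MS evidence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "AdductRule",
    "ADDUCT_REGISTRY",
    "default_adducts",
    "adduct_mz",
    "AnnotationHit",
    "match_features",
    "distinct_compounds",
]

# Masses of the most abundant isotope of each element, in Da.
# Values follow the CODATA/AME tabulation used by accurate-mass software.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Mg": 23.9850417,
    "Si": 27.9769265347,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637064864,
    "Ca": 39.9625909,
    "Fe": 55.9349363,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.9044719,
}

PROTON_MASS = 1.00727646677  # H minus one electron
ELECTRON_MASS = 0.00054857990907
_WATER = 2 * MONOISOTOPIC_MASSES["H"] + MONOISOTOPIC_MASSES["O"]
_FORMATE = (
    MONOISOTOPIC_MASSES["H"] + MONOISOTOPIC_MASSES["C"] + 2 * MONOISOTOPIC_MASSES["O"]
)


class FormulaError(ValueError):
    """Raised for a molecular formula the grammar cannot accept."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(s: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula like ``C2H7NO3S``.

    Returns an element -> count mapping. Repeated element symbols are
    accumulated. Raises :class:`FormulaError` (with the offending position)
    for empty input, unknown element symbols, or an explicit zero count.
    """
    if not isinstance(s, str) or not s.strip():
        raise FormulaError("empty formula")
    s = s.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"cannot parse formula {s!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASSES:
            raise FormulaError(
                f"unknown element symbol {element!r} in {s!r} at position {pos}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {element!r} in {s!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Format counts in Hill order (C, H, then alphabetical)."""
    parts = []
    for el in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        if el in counts and counts[el] > 0:
            n = counts[el]
            parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def monoisotopic_mass(counts: Mapping[str, int] | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da of a formula."""
    if isinstance(counts, str):
        counts = parse_formula(counts)
    total = 0.0
    for element, n in counts.items():
        try:
            total += MONOISOTOPIC_MASSES[element] * n
        except KeyError:
            raise FormulaError(f"no atomic mass tabulated for element {element!r}")
    return total


@dataclass(frozen=True)
class AdductRule:
    """An ESI adduct: observed m/z = (neutral mass + delta)/charge."""

    name: str
    polarity: str  # "pos" | "neg"
    delta: float  # Da, includes electron correction
    charge: int = 1

    def __post_init__(self):
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be pos|neg, got {self.polarity!r}")


# Minimal registry reconciling serum Q-TOF features: protonation, sodiation
# and in-source water loss in positive mode; deprotonation, formate adduct
# (formic-acid mobile phase) and water loss in negative mode.
ADDUCT_REGISTRY: dict[str, AdductRule] = {
    r.name: r
    for r in [
        AdductRule("[M+H]+", "pos", PROTON_MASS),
        AdductRule("[M+Na]+", "pos", MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS),
        AdductRule("[M+H-H2O]+", "pos", PROTON_MASS - _WATER),
        AdductRule("[M-H]-", "neg", -PROTON_MASS),
        AdductRule("[M+HCOO]-", "neg", _FORMATE + ELECTRON_MASS),
        AdductRule("[M-H-H2O]-", "neg", -PROTON_MASS - _WATER),
    ]
}


def default_adducts(polarity: str | None = None) -> list[AdductRule]:
    """Default adduct rules, optionally restricted to one polarity."""
    rules = list(ADDUCT_REGISTRY.values())
    if polarity is not None:
        rules = [r for r in rules if r.polarity == polarity]
    return rules


def adduct_mz(neutral_mass: float, rule: AdductRule) -> float:
    """m/z of the ion formed from a neutral monoisotopic mass by ``rule``."""
    mz = (neutral_mass + rule.delta) / rule.charge
    if mz <= 0:
        raise ValueError(
            f"adduct {rule.name} of mass {neutral_mass} gives non-positive m/z"
        )
    return mz


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    mz: float
    polarity: str
    compound: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm: float  # signed, observed vs theoretical
    best: bool = False


def match_features(
    features,
    library,
    adducts: Sequence[AdductRule] | None = None,
    tol_ppm: float = 20.0,
) -> list[AnnotationHit]:
    """Match features against a compound library by adduct arithmetic.

    Parameters
    ----------
    features
        DataFrame with columns ``feature_id``, ``mz``, ``polarity``
        (plus anything else, ignored), or an iterable of
        ``(feature_id, mz, polarity)`` tuples.
    library
        A :class:`~oametab.io.CompoundLibrary`.
    adducts
        Adduct rules to try; defaults to the full registry (each feature
        only sees rules of its own polarity).
    tol_ppm
        Accept |1e6*(observed-theoretical)/theoretical| <= tol_ppm.

    Returns hits sorted by |ppm|, with the best hit per feature flagged.
    """
    if adducts is None:
        adducts = default_adducts()
    if isinstance(features, pd.DataFrame):
        rows = list(
            features[["feature_id", "mz", "polarity"]].itertuples(index=False)
        )
    else:
        rows = [tuple(r) for r in features]

    hits: list[AnnotationHit] = []
    for feature_id, mz, polarity in rows:
        for rec in library.records:
            mass = rec.monoisotopic_mass
            for rule in adducts:
                if rule.polarity != polarity:
                    continue
                theo = adduct_mz(mass, rule)
                ppm = 1e6 * (mz - theo) / theo
                if abs(ppm) <= tol_ppm:
                    hits.append(
                        AnnotationHit(
                            feature_id=str(feature_id),
                            mz=float(mz),
                            polarity=polarity,
                            compound=rec.name,
                            formula=rec.formula,
                            adduct=rule.name,
                            theoretical_mz=theo,
                            ppm=ppm,
                        )
                    )
    hits.sort(key=lambda h: (abs(h.ppm), h.feature_id, h.compound, h.adduct))
    seen: set[str] = set()
    flagged = []
    for h in hits:
        if h.feature_id not in seen:
            seen.add(h.feature_id)
            h = AnnotationHit(**{**h.__dict__, "best": True})
        flagged.append(h)
    return flagged


def distinct_compounds(
    hits: Iterable[AnnotationHit], best_only: bool = True
) -> dict[str, list[str]]:
    """Group hits by compound: name -> sorted list of supporting feature ids.

    By default only each feature's best (smallest |ppm|) assignment counts,
    mirroring the one-identity-per-variable reading of an identification
    table; pass ``best_only=False`` to group every retained hit.
    """
    groups: dict[str, set[str]] = {}
    for h in hits:
        if best_only and not h.best:
            continue
        groups.setdefault(h.compound, set()).add(h.feature_id)
    return {name: sorted(feats) for name, feats in sorted(groups.items())}


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Annotation hits as a DataFrame (TSV-ready schema)."""
    cols = [
        "feature_id",
        "mz",
        "polarity",
        "compound",
        "formula",
        "adduct",
        "theoretical_mz",
        "ppm",
        "best",
    ]
    if not hits:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([h.__dict__ for h in hits])[cols]
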