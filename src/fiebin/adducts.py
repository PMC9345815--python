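"""Electrospray ionisation-product prediction and accurate-m/z matching.

Given a neutral molecule M with monoisotopic mass computed from its
molecular formula, each adduct rule describes a charged species

    m/z = (nmer * M + delta) / |z|

where ``nmer`` is the number of molecules in the ion (1 or 2), ``z``
its charge and ``delta`` the mass change relative to ``nmer * M`` —
protons gained or lost, attached cations/anions, and the electron
bookkeeping: a cation's m/z is short ``z`` electron masses, an anion's
carries ``z`` extra.  At Orbitrap resolving power the 0.00055 Da
electron mass matters at low m/z, so it is folded into every delta
explicitly.

Twelve common ESI adducts are registered: six positive
([M+H]1+, [M+K]1+, [M+41K]1+, [M+Na]1+, [2M+H]1+, [M+2H]2+) and six
negative ([M-H]1-, [M+Cl]1-, [M+37Cl]1-, [M+K-2H]1-, [2M-H]1-,
[M-2H]2-).  [M+41K]1+ and [M+37Cl]1- are the minor-isotope potassium
and chloride adducts.

Predicted products are matched against the consensus accurate m/z of
fully-occupied spectral bins within a ppm tolerance (default 10 ppm).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ADDUCT_RULES",
    "AdductRule",
    "IonisationProduct",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "predict_products",
    "ppm_error",
    "match_products",
]

# Monoisotopic atomic masses in Da (unified scale, 12C = 12 exactly).
# Principal isotope per element; minor isotopes keyed with a mass-number
# prefix.  Values: IUPAC/CIAAW 2021 atomic mass evaluation, >= 6 dp.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "2H": 2.01410177785,
    "C": 12.0,
    "13C": 13.00335483507,
    "N": 14.00307400443,
    "15N": 15.00010889888,
    "O": 15.99491461957,
    "18O": 17.99915961286,
    "F": 18.99840316273,
    "Na": 22.98976928196,
    "Mg": 23.985041697,
    "Si": 27.97692653465,
    "P": 30.97376199842,
    "S": 31.9720711744,
    "34S": 33.967867004,
    "Cl": 34.968852682,
    "37Cl": 36.965902602,
    "K": 38.9637064864,
    "41K": 40.96182525792,
    "Ca": 39.962590863,
    "Fe": 55.93493633,
    "Cu": 62.92959772,
    "Zn": 63.92914201,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.9044719,
}

PROTON_MASS = 1.007276466621  # Da, CODATA
ELECTRON_MASS = 0.000548579909  # Da, CODATA

_H = MONOISOTOPIC_MASSES["H"]

_FORMULA_TOKEN = re.compile(r"(?:\[(\d+)([A-Z][a-z]?)\]|([A-Z][a-z]?))(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into an element->count map.

    Isotopes are written with a bracketed mass-number prefix, e.g.
    ``[13C]C6H12O6`` for one 13C; the returned keys then carry the mass
    number (``"13C"``).  Unknown element symbols and malformed input
    raise ``ValueError`` naming the offending token.

    >>> parse_formula("C7H15NO3")
    {'C': 7, 'H': 15, 'N': 1, 'O': 3}
    """
    if not text or not text.strip():
        raise ValueError("empty molecular formula")
    text = text.strip()
    comp: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(0):
            raise ValueError(f"malformed formula {text!r} at {text[pos:]!r}")
        isotope, iso_sym, sym, count = m.groups()
        symbol = f"{isotope}{iso_sym}" if iso_sym else sym
        if symbol not in MONOISOTOPIC_MASSES:
            raise ValueError(f"unknown element {symbol!r} in formula {text!r}")
        n = int(count) if count else 1
        if n < 1:
            raise ValueError(f"invalid count for {symbol!r} in formula {text!r}")
        comp[symbol] = comp.get(symbol, 0) + n
        pos = m.end()
    return comp


def monoisotopic_mass(composition: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a composition or formula string."""
    if isinstance(composition, str):
        composition = parse_formula(composition)
    return sum(MONOISOTOPIC_MASSES[el] * n for el, n in composition.items())


@dataclass(frozen=True)
class AdductRule:
    """An ionisation rule: m/z = (nmer * M + delta) / charge.

    ``delta`` is the total mass change of the ion relative to
    ``nmer * M`` in Da, electron bookkeeping included.
    """

    name: str
    polarity: str  # "positive" | "negative"
    nmer: int
    charge: int
    delta: float


def _cation(mass: float) -> float:
    return mass - ELECTRON_MASS


def _anion(mass: float) -> float:
    return mass + ELECTRON_MASS


ADDUCT_RULES: tuple[AdductRule, ...] = (
    AdductRule("[M+H]1+", "positive", 1, 1, PROTON_MASS),
    AdductRule("[M+K]1+", "positive", 1, 1, _cation(MONOISOTOPIC_MASSES["K"])),
    AdductRule("[M+41K]1+", "positive", 1, 1, _cation(MONOISOTOPIC_MASSES["41K"])),
    AdductRule("[M+Na]1+", "positive", 1, 1, _cation(MONOISOTOPIC_MASSES["Na"])),
    AdductRule("[2M+H]1+", "positive", 2, 1, PROTON_MASS),
    AdductRule("[M+2H]2+", "positive", 1, 2, 2 * PROTON_MASS),
    AdductRule("[M-H]1-", "negative", 1, 1, -PROTON_MASS),
    AdductRule("[M+Cl]1-", "negative", 1, 1, _anion(MONOISOTOPIC_MASSES["Cl"])),
    AdductRule("[M+37Cl]1-", "negative", 1, 1, _anion(MONOISOTOPIC_MASSES["37Cl"])),
    AdductRule(
        "[M+K-2H]1-", "negative", 1, 1, _anion(MONOISOTOPIC_MASSES["K"] - 2 * _H)
    ),
    AdductRule("[2M-H]1-", "negative", 2, 1, -PROTON_MASS),
    AdductRule("[M-2H]2-", "negative", 1, 2, -2 * PROTON_MASS),
)

_RULES_BY_NAME = {r.name: r for r in ADDUCT_RULES}


def rule(name: str) -> AdductRule:
    """Look up a registered adduct rule by name (ASCII hyphen-minus)."""
    try:
        return _RULES_BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown adduct rule {name!r}") from None


def adduct_mz(M: float, rule: AdductRule) -> float:
    """Theoretical m/z of the ionisation product of a neutral mass ``M``."""
    if M <= 0:
        raise ValueError("neutral monoisotopic mass must be positive")
    return (rule.nmer * M + rule.delta) / rule.charge


@dataclass(frozen=True)
class IonisationProduct:
    """A (compound, adduct rule) pair with its theoretical m/z."""

    compound: str
    formula: str
    rule: AdductRule
    theoretical_mz: float


def predict_products(
    compounds: Iterable[tuple[str, str]],
    rules: Sequence[AdductRule] = ADDUCT_RULES,
    applicable: Callable[[str, Mapping[str, int], AdductRule], bool] | None = None,
) -> list[IonisationProduct]:
    """Enumerate ionisation products of compounds under a set of rules.

    Parameters
    ----------
    compounds : iterable of (name, formula)
    rules : adduct rules to apply (default: all twelve registered).
    applicable : optional predicate (name, composition, rule) -> bool
        Hook for structure-dependent applicability filtering; the
        default applies every rule to every compound.
    """
    products = []
    for name, formula in compounds:
        comp = parse_formula(formula)
        M = monoisotopic_mass(comp)
        for r in rules:
            if applicable is not None and not applicable(name, comp, r):
                continue
            products.append(IonisationProduct(name, formula, r, adduct_mz(M, r)))
    return products


def ppm_error(theoretical: float, measured: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (measured - theoretical) / theoretical


def match_products(
    products: Sequence[IonisationProduct],
    bin_table: pd.DataFrame,
    tol_ppm: float = 10.0,
    occupancy_min: float = 1.0,
) -> pd.DataFrame:
    """Match predicted products to binned accurate m/z.

    A product matches a bin when their polarities agree, the bin's
    occupancy is at least ``occupancy_min`` (default: fully occupied),
    and the absolute ppm error between the product's theoretical m/z and
    the bin's consensus accurate m/z is within ``tol_ppm``.  All
    qualifying bins are reported; per product, the nearest match is
    flagged.

    Parameters
    ----------
    products : predicted ionisation products.
    bin_table : DataFrame indexed by bin name with at least columns
        ``polarity``, ``accurate_mz`` and ``occupancy`` (as produced by
        :func:`fiebin.binning.bin_sample_set`).

    Returns
    -------
    DataFrame with one row per match: compound, formula, adduct,
    theoretical_mz, bin, measured_mz, ppm_error (signed), nearest (bool),
    plus any extra bin_table columns (purity, centrality, ...).
    """
    extra = [
        c for c in ("purity", "centrality") if c in bin_table.columns
    ]
    eligible = bin_table[bin_table["occupancy"] >= occupancy_min]
    rows = []
    for prod in products:
        cand = eligible[eligible["polarity"] == prod.rule.polarity]
        if cand.empty:
            continue
        errs = cand["accurate_mz"].map(
            lambda m, t=prod.theoretical_mz: ppm_error(t, m)
        )
        hits = errs[errs.abs() <= tol_ppm]
        if hits.empty:
            continue
        nearest = hits.abs().idxmin()
        for name, err in hits.items():
            row = {
                "compound": prod.compound,
                "formula": prod.formula,
                "adduct": prod.rule.name,
                "theoretical_mz": prod.theoretical_mz,
                "bin": name,
                "measured_mz": bin_table.at[name, "accurate_mz"],
                "ppm_error": err,
                "nearest": name == nearest,
            }
            for c in extra:
                row[c] = bin_table.at[name, c]
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "formula",
            "adduct",
            "theoretical_mz",
            "bin",
            "measured_mz",
            "ppm_error",
            "nearest",
            *extra,
        ],
    )
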