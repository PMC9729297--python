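"""Bundled sum-composition lipid library.

A compact, editable annotation surface built from elemental-formula rules:
free fatty acids C12-C24 with 0-3 double bonds, optionally hydroxylated, plus
glycerophospholipid and glycosyldiacylglycerol species (PE, PG, PC, MGDG,
DGDG, lysyl-PG) over a grid of even total acyl carbons, and the six spiked
internal standards.  Formulas follow the usual sum-composition arithmetic:
a diacyl species with C total acyl carbons and d double bonds is the glycerol
backbone plus two acyls minus the esterification waters, so e.g. a diacyl-PE
C:d is C(C+5) H(2C+10-2d) N O8 P.
"""
from __future__ import annotations

from .masses import monoisotopic_mass
from .model import LipidRecord


def ffa_formula(carbons: int, double_bonds: int, hydroxyl: bool = False) -> str:
    """Free fatty acid CnH(2n-2d)O2, +O if hydroxylated."""
    h = 2 * carbons - 2 * double_bonds
    o = 3 if hydroxyl else 2
    return f"C{carbons}H{h}O{o}"


def pe_formula(c: int, d: int) -> str:
    return f"C{c + 5}H{2 * c + 10 - 2 * d}NO8P"


def pg_formula(c: int, d: int) -> str:
    return f"C{c + 6}H{2 * c + 11 - 2 * d}O10P"


def pc_formula(c: int, d: int) -> str:
    return f"C{c + 8}H{2 * c + 16 - 2 * d}NO8P"


def ps_formula(c: int, d: int) -> str:
    return f"C{c + 6}H{2 * c + 10 - 2 * d}NO10P"


def lpc_formula(c: int, d: int) -> str:
    """Mono-acyl (lyso) PC."""
    return f"C{c + 8}H{2 * c + 18 - 2 * d}NO7P"


def mgdg_formula(c: int, d: int) -> str:
    """Diacylglycerol plus one hexose."""
    return f"C{c + 9}H{2 * c + 14 - 2 * d}O10"


def dgdg_formula(c: int, d: int) -> str:
    """Diacylglycerol plus two hexoses."""
    return f"C{c + 15}H{2 * c + 24 - 2 * d}O15"


def lpg_formula(c: int, d: int) -> str:
    """Lysyl-PG: PG esterified with lysine (+C6H12N2O)."""
    return f"C{c + 12}H{2 * c + 23 - 2 * d}N2O11P"


def _record(name: str, subclass: str, formula: str) -> LipidRecord:
    return LipidRecord(name, subclass, formula, monoisotopic_mass(formula))


def internal_standards() -> list[LipidRecord]:
    """The six spiked internal standards, carried for QC only (never used for
    normalization).  PS and LPC species fall under subclass 'other' because
    the annotation rule table does not cover their classes."""
    return [
        _record("IS LPC 13:0", "other", lpc_formula(13, 0)),
        _record("IS PC 19:0/19:0", "PC", pc_formula(38, 0)),
        _record("IS PC 14:0/14:0", "PC", pc_formula(28, 0)),
        _record("IS PS 12:0/12:0", "other", ps_formula(24, 0)),
        _record("IS PG 15:0/15:0", "PG", pg_formula(30, 0)),
        _record("IS PE 17:0/17:0", "PE", pe_formula(34, 0)),
    ]


def default_library(include_standards: bool = True) -> list[LipidRecord]:
    """Build the bundled library.

    FFAs: C12-C24, 0-3 double bonds, with and without a hydroxyl.
    Diacyl classes: even total carbons 26-40, 0-3 double bonds.
    """
    records: list[LipidRecord] = []
    for c in range(12, 25):
        for d in range(0, 4):
            records.append(_record(f"FFA {c}:{d}", "FFA", ffa_formula(c, d)))
            records.append(_record(f"FFA {c}:{d}(OH)", "FFA", ffa_formula(c, d, True)))
    diacyl = {
        "PE": pe_formula,
        "PG": pg_formula,
        "PC": pc_formula,
        "MGDG": mgdg_formula,
        "DGDG": dgdg_formula,
        "LPG": lpg_formula,
    }
    for subclass, builder in diacyl.items():
        for c in range(26, 41, 2):
            for d in range(0, 4):
                records.append(_record(f"{subclass} {c}:{d}", subclass, builder(c, d)))
    if include_standards:
        records.extend(internal_standards())
    return records
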