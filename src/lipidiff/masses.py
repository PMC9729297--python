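"""Exact-mass arithmetic: monoisotopic masses, adduct m/z, ppm error.

Singly charged electrospray adducts only. The charge carrier is the proton;
the electron mass is folded into the 1.007276 Da proton constant, as is
standard in accurate-mass work.
"""
from __future__ import annotations

from pyteomics.auxiliary import PyteomicsError
from pyteomics.mass import calculate_mass

#: Mass of a proton (charge carrier), Da. Electron mass already removed.
PROTON = 1.007276

#: m/z shift of each supported singly charged adduct relative to the neutral
#: monoisotopic mass M.  FA is formic acid; [M+FA-H]- is the formate adduct.
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": +1.007276,
    "[M+NH4]+": +18.033823,
    "[M-H]-": -1.007276,
    "[M+FA-H]-": +44.998203,
}

_UNICODE_MINUS = "−"


def canonical_adduct(name: str) -> str:
    """Normalize an adduct name (unicode minus, stray spaces) to the ASCII form."""
    return name.replace(_UNICODE_MINUS, "-").replace(" ", "")


def adduct_polarity(adduct: str) -> str:
    """Ionization polarity implied by an adduct name ('positive' or 'negative')."""
    adduct = canonical_adduct(adduct)
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_SHIFTS)}"
        )
    return "positive" if adduct.endswith("+") else "negative"


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula such as 'C16H32O2'.

    Raises ``ValueError`` for formulas with unknown element symbols.
    """
    try:
        return float(calculate_mass(formula=formula))
    except PyteomicsError as exc:  # unknown element / malformed formula
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct of a neutral molecule of the given mass."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    adduct = canonical_adduct(adduct)
    try:
        shift = ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_SHIFTS)}"
        ) from None
    return neutral_mass + shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error |observed - theoretical| / theoretical * 1e6."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return abs(observed - theoretical) / theoretical * 1e6
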