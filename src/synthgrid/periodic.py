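"""Small per-element lookup tables shared across the package.

Covalent radii follow Cordero et al.; van der Waals radii follow Bondi
(with Rowland/Taylor updates). Both tables cover the elements that occur
in organic molecular crystals plus the alkali/halide ions used by the
toy-structure generators. Values in Angstrom.
"""

from __future__ import annotations

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "I": 1.39, "Xe": 1.40,
}

VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "He": 1.40,
    "Li": 1.81, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Zn": 1.39, "Br": 1.85, "Kr": 2.02,
    "Rb": 3.03, "I": 1.98, "Xe": 2.16,
}

#: fallback vdW radius for elements missing from the table
DEFAULT_VDW_RADIUS = 1.70


def normalize_element(symbol: str) -> str:
    """Strip charges/digits from a CIF type symbol: 'O2-' -> 'O', 'Ca2+' -> 'Ca'."""
    s = "".join(ch for ch in symbol if ch.isalpha())
    if not s:
        raise ValueError(f"cannot extract an element symbol from {symbol!r}")
    return s[0].upper() + s[1:].lower()


def is_known_element(symbol: str) -> bool:
    return symbol in COVALENT_RADII


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None


def vdw_radius(symbol: str) -> float:
    return VDW_RADII.get(symbol, DEFAULT_VDW_RADIUS)
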