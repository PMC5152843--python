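"""Compound-key parsing and monoisotopic mass arithmetic for heparin chains.

A glycosaminoglycan chain composition is the 5-tuple
``[dHexA, HexA, GlcN, Ac, SO3]`` — residue counts for the unsaturated
uronic acid at the non-reducing end, interior hexuronic acids and
hexosamines, plus N-acetyl and sulfo substituent counts.  The bracketed
tuple is the unit of comparison throughout the toolkit; masses are only
needed by the hypothesis enumerator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "Composition",
    "MassConstants",
    "MASS",
    "KEY_PROFILES",
    "KeyError_",
    "extract_key",
    "parse_composition",
    "composition_mass",
    "adducted_mass",
]


class KeyError_(ValueError):
    """Raised when a compound-key cell cannot be parsed."""


# Lazy match: shortest span from the first "[" to the next "]".  Anything
# outside the brackets (e.g. an adduct annotation such as "2NH3") is opaque
# text and is discarded.
_BRACKET_RE = re.compile(r"\[.*?\]")

_INT_RE = re.compile(r"-?\d+")


def extract_key(cell: str) -> str:
    """Extract the first bracket-delimited composition key from a cell.

    Matching is lazy: the shortest span from the first ``[`` to the next
    ``]`` wins, so ``"[1,4,5,2,7] 2NH3"`` and ``"[1,5,6,0,14][extra]"``
    both yield the first bracketed group.  Whitespace inside the brackets
    is removed so the result is canonical interchange text.

    Raises
    ------
    KeyError_
        If the cell contains no bracketed span.
    """
    m = _BRACKET_RE.search(cell)
    if m is None:
        raise KeyError_(f"no bracketed compound key in cell {cell!r}")
    return re.sub(r"\s+", "", m.group(0))


# Positional field orders for the bracketed tuple.  "default" is the
# enoxaparin intact-chain order; "pnp" is the synthesized-standard dialect
# [HexA, GlcN, PNP, SO3, Ac] where the third field is a para-nitrophenyl
# aglycone flag that must be 1 and carries no residue count here.
KEY_PROFILES: dict[str, tuple[str, ...]] = {
    "default": ("dhexa", "hexa", "glcn", "ac", "so3"),
    "pnp": ("hexa", "glcn", "pnp", "so3", "ac"),
}


@dataclass(frozen=True, order=True)
class Composition:
    """Canonical chain composition: residue and substituent counts."""

    dhexa: int
    hexa: int
    glcn: int
    ac: int
    so3: int
    anhydro: bool = False

    def __post_init__(self) -> None:
        for name in ("dhexa", "hexa", "glcn", "ac", "so3"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.dhexa not in (0, 1):
            raise ValueError(f"dhexa must be 0 or 1, got {self.dhexa}")
        if self.dp < 1:
            raise ValueError("composition must contain at least one residue")
        if self.anhydro and self.dhexa != 1:
            raise ValueError("1,6-anhydro variant requires dhexa == 1")

    @property
    def dp(self) -> int:
        """Degree of polymerization: number of monosaccharide units."""
        return self.dhexa + self.hexa + self.glcn

    @property
    def key(self) -> str:
        """Canonical interchange text ``[dhexa,hexa,glcn,ac,so3]``."""
        return f"[{self.dhexa},{self.hexa},{self.glcn},{self.ac},{self.so3}]"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def parse_composition(
    key: str, anhydro: bool = False, profile: str = "default"
) -> Composition:
    """Parse canonical key text ``[i,i,i,i,i]`` into a :class:`Composition`.

    ``profile`` selects the positional field order (see ``KEY_PROFILES``).
    The anhydro flag is table-level metadata — the 5-tuple is identical for
    both reducing-end variants — so it is passed in, never inferred.
    """
    try:
        order = KEY_PROFILES[profile]
    except KeyError:
        raise KeyError_(f"unknown key profile {profile!r}") from None
    stripped = key.strip()
    if not (stripped.startswith("[") and stripped.endswith("]")):
        raise KeyError_(f"key must be bracketed, got {key!r}")
    parts = [p.strip() for p in stripped[1:-1].split(",")]
    if len(parts) != 5:
        raise KeyError_(f"key must have 5 fields, got {len(parts)} in {key!r}")
    values: dict[str, int] = {}
    for name, text in zip(order, parts):
        if not _INT_RE.fullmatch(text):
            raise KeyError_(f"non-integer field {text!r} in {key!r}")
        n = int(text)
        if n < 0:
            raise KeyError_(f"negative field {n} in {key!r}")
        values[name] = n
    if profile == "pnp":
        if values.pop("pnp") != 1:
            raise KeyError_(f"PNP flag must be 1 in {key!r}")
        values["dhexa"] = 0
    return Composition(anhydro=anhydro, **values)


@dataclass(frozen=True)
class MassConstants:
    """Residue and increment monoisotopic masses (Da).

    Hard-coded from standard atomic monoisotopic masses; the derivation is
    reproducible with ``scripts/derive_masses.py``.  The anhydro variant of
    the terminal unsaturated uronic acid (C6H4O4 instead of C6H6O5) is one
    water lighter, reflecting the extra dehydration at the reducing end.
    """

    m_dhexa: float = 158.02152329042  # C6H6O5
    m_dhexa_anhydro: float = 140.01095860668  # C6H4O4
    m_hexa: float = 176.03208797416  # C6H8O6
    m_glcn: float = 161.06880783597  # C6H11NO4, free-amine hexosamine
    m_ac: float = 42.01056468374  # C2H2O increment
    m_so3: float = 79.9568148588  # SO3 increment
    m_h2o: float = 18.01056468374
    m_nh3: float = 17.02654910101

    def __post_init__(self) -> None:
        if abs(self.m_dhexa - self.m_dhexa_anhydro - self.m_h2o) > 1e-9:
            raise ValueError("anhydro residue must be exactly one H2O lighter")
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


MASS = MassConstants()


def composition_mass(c: Composition, consts: MassConstants = MASS) -> float:
    """Neutral monoisotopic mass of a chain (Da): residue sum + one H2O."""
    m_terminal = consts.m_dhexa_anhydro if c.anhydro else consts.m_dhexa
    return (
        c.dhexa * m_terminal
        + c.hexa * consts.m_hexa
        + c.glcn * consts.m_glcn
        + c.ac * consts.m_ac
        + c.so3 * consts.m_so3
        + consts.m_h2o
    )


def adducted_mass(
    mass: float, n_nh3: int, consts: MassConstants = MASS, n_max: int = 14
) -> float:
    """Mass shifted by ``n_nh3`` ammonium adducts."""
    if not 0 <= n_nh3 <= n_max:
        raise ValueError(f"adduct count {n_nh3} outside [0, {n_max}]")
    return mass + n_nh3 * consts.m_nh3
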