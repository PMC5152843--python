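"""Enumerate the enoxaparin intact-chain composition hypothesis.

The search space couples the five counts: with A unsaturated terminal
residues, B interior uronic acids and C hexosamines, the hexosamine count
is constrained to A+B-1 .. A+B+1 (alternating backbone), acetylation to at
most min(3, C) amines, and sulfation to B .. A+B+2C+1-D available
positions.  Each composition is expanded over ammonium adduct states and
windowed on its unadducted molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import (
    MASS,
    Composition,
    MassConstants,
    adducted_mass,
    composition_mass,
)

__all__ = ["HypothesisParams", "HypothesisEntry", "enumerate_hypothesis", "match_mass"]


@dataclass(frozen=True)
class HypothesisParams:
    """Bounds of the composition/adduct search space.

    Defaults reproduce the standard enoxaparin hypothesis: MW window
    500-6000 Da, up to dp 18, ammonium adducts 0-14, 5 ppm match error.
    """

    dhexa_choices: frozenset[int] = frozenset({0, 1})
    hexa_max: int = 9
    ac_max: int = 3
    nh3_max: int = 14
    mw_min: float = 500.0
    mw_max: float = 6000.0
    dp_max: int = 18
    match_error_ppm: float = 5.0
    anhydro: bool = False
    #: when True the MW window is applied to the adducted mass instead of
    #: the bare chain mass
    mw_bounds_on_adducted: bool = False

    def __post_init__(self) -> None:
        if not self.dhexa_choices <= {0, 1}:
            raise ValueError("dhexa_choices must be a subset of {0, 1}")
        if self.anhydro and 1 not in self.dhexa_choices:
            raise ValueError("anhydro hypothesis requires dhexa = 1")
        # equality is allowed: a degenerate window selects only chains whose
        # unadducted mass equals the bound exactly
        if self.mw_min > self.mw_max:
            raise ValueError("mw_min must be <= mw_max")
        for name in ("hexa_max", "ac_max", "nh3_max", "dp_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mw_min < 0 or self.match_error_ppm <= 0:
            raise ValueError("bounds must be non-negative, ppm positive")


@dataclass(frozen=True)
class HypothesisEntry:
    composition: Composition
    n_nh3: int
    theoretical_mass: float


def enumerate_hypothesis(
    p: HypothesisParams, consts: MassConstants = MASS
) -> list[HypothesisEntry]:
    """Generate all (composition, adduct count) entries satisfying ``p``.

    Output is deterministic — lexicographic in (dhexa, hexa, glcn, ac,
    so3, n_nh3) — and duplicate-free by construction.  The anhydro
    variant, when requested, forces dhexa = 1 and uses the dehydrated
    terminal residue mass.
    """
    entries: list[HypothesisEntry] = []
    dhexa_values = [d for d in (0, 1) if d in p.dhexa_choices]
    if p.anhydro:
        dhexa_values = [1]
    for a in dhexa_values:
        for b in range(p.hexa_max + 1):
            c_lo = max(0, a + b - 1)
            for c in range(c_lo, a + b + 2):
                if a + b + c > p.dp_max or a + b + c < 1:
                    continue
                for d in range(min(p.ac_max, c) + 1):
                    e_hi = a + b + 2 * c + 1 - d
                    for e in range(b, e_hi + 1):
                        comp = Composition(a, b, c, d, e, anhydro=p.anhydro)
                        m0 = composition_mass(comp, consts)
                        for n in range(p.nh3_max + 1):
                            m = adducted_mass(m0, n, consts, n_max=p.nh3_max)
                            bounded = m if p.mw_bounds_on_adducted else m0
                            if p.mw_min <= bounded <= p.mw_max:
                                entries.append(HypothesisEntry(comp, n, m))
    return entries


def match_mass(
    observed: float, entries: list[HypothesisEntry], ppm: float = 5.0
) -> list[HypothesisEntry]:
    """All entries within ``ppm`` of an observed mass, best match first.

    One observed mass can hit several adduct states of different
    compositions — the ambiguity that replicate-presence filtering is
    designed to resolve.
    """
    if observed <= 0 or ppm <= 0:
        raise ValueError("observed mass and ppm tolerance must be positive")

    def ppm_error(entry: HypothesisEntry) -> float:
        return abs(observed - entry.theoretical_mass) / entry.theoretical_mass * 1e6

    hits = [e for e in entries if ppm_error(e) <= ppm]
    hits.sort(key=lambda e: (ppm_error(e), _entry_order(e)))
    return hits


def _entry_order(e: HypothesisEntry) -> tuple:
    c = e.composition
    return (c.dhexa, c.hexa, c.glcn, c.ac, c.so3, e.n_nh3)
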