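"""Independent brute-force oracles used to check the production code.

Everything here is deliberately naive and kept separate from the package:
element-sum mass computation, quintuple-loop hypothesis enumeration, a
set-intersection + group-by comparator, and a literal row-loop simulator
of the spreadsheet merging procedure.
"""

from __future__ import annotations

import re
from collections import defaultdict

ATOMS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}


def element_sum_mass(
    dhexa: int, hexa: int, glcn: int, ac: int, so3: int, anhydro: bool = False
) -> float:
    """Assemble the full molecular formula, then sum atomic masses."""
    counts: dict[str, int] = defaultdict(int)

    def add(formula: dict[str, int], times: int = 1) -> None:
        for el, n in formula.items():
            counts[el] += n * times

    terminal = {"C": 6, "H": 4, "O": 4} if anhydro else {"C": 6, "H": 6, "O": 5}
    add(terminal, dhexa)
    add({"C": 6, "H": 8, "O": 6}, hexa)
    add({"C": 6, "H": 11, "N": 1, "O": 4}, glcn)
    add({"C": 2, "H": 2, "O": 1}, ac)
    add({"S": 1, "O": 3}, so3)
    add({"H": 2, "O": 1})  # terminal water
    return sum(ATOMS[el] * n for el, n in counts.items())


def brute_force_hypothesis(
    dhexa_choices: set[int],
    hexa_max: int,
    ac_max: int,
    nh3_max: int,
    mw_min: float,
    mw_max: float,
    dp_max: int,
    anhydro: bool = False,
) -> set[tuple[int, int, int, int, int, int]]:
    """Quintuple loop over wide ranges; filter by every constraint."""
    nh3 = ATOMS["N"] + 3 * ATOMS["H"]
    out = set()
    for a in range(0, 2):
        for b in range(0, hexa_max + 1):
            for c in range(0, hexa_max + 3):
                for d in range(0, ac_max + 1):
                    for e in range(0, 2 * (hexa_max + 3) + hexa_max + 3):
                        for n in range(0, nh3_max + 1):
                            if a not in dhexa_choices:
                                continue
                            if anhydro and a != 1:
                                continue
                            if not (max(0, a + b - 1) <= c <= a + b + 1):
                                continue
                            if d > c:
                                continue
                            if not (b <= e <= a + b + 2 * c + 1 - d):
                                continue
                            if not (1 <= a + b + c <= dp_max):
                                continue
                            m0 = element_sum_mass(a, b, c, d, e, anhydro)
                            if not (mw_min <= m0 <= mw_max):
                                continue
                            out.add((a, b, c, d, e, n))
    return out


def naive_compare(rows, labels):
    """Set-intersection + group-by oracle.

    ``rows`` are (label, raw_key_cell, score, volume) tuples.  Returns
    {key: {label: (max_score, summed_volume)}} for keys present in every
    label.
    """
    def key_of(cell):
        return re.sub(r"\s+", "", re.search(r"\[.*?\]", cell).group(0))

    keys_by_label = defaultdict(set)
    for label, cell, _, _ in rows:
        keys_by_label[label].add(key_of(cell))
    common = set.intersection(*(keys_by_label[l] for l in labels)) if labels else set()
    out = {}
    for label, cell, score, volume in rows:
        k = key_of(cell)
        if k not in common:
            continue
        group = out.setdefault(k, {}).setdefault(label, [0.0, 0.0, False])
        if not group[2] or score > group[0]:
            group[0] = score
        group[2] = True
        group[1] += volume
    return {
        k: {l: (s[0], s[1]) for l, s in by_label.items()}
        for k, by_label in out.items()
    }


def table1_simulator(rows):
    """Literal bottom-up row-loop simulator of the merging pseudocode.

    ``rows`` are (label, key, score, volume) with keys already extracted
    and the all-presence screen already applied; they are stable-sorted by
    key (pooled order preserved inside ties, so each label's rows stay
    contiguous within a key).  Returns {(key, label): (score, volume)} of
    the surviving rows.
    """
    rows = sorted(rows, key=lambda r: r[1])  # stable: by key only
    rows = [list(r) for r in rows]
    i = len(rows) - 1
    j = i - 1
    while j >= 0:
        ri, rj = rows[i], rows[j]
        if ri[1] == rj[1] and ri[0] == rj[0]:
            if ri[2] <= rj[2]:
                rj[3] = rj[3] + ri[3]
                del rows[i]
                i = j
            else:
                ri[3] = ri[3] + rj[3]
                del rows[j]
                i = j  # row above removed: survivor shifts up one slot
        else:
            i = j
        j = i - 1
    return {(r[1], r[0]): (r[2], r[3]) for r in rows}
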