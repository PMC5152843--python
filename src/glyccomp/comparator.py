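"""All-presence screening across samples and per-sample adduct merging.

This is the core computation: a composition is kept only if its extracted
compound key is observed in every sample being compared (anything else is
treated as noise), and the rows that survive are collapsed per
(key, sample) — one merged entry holding the maximum score and the summed
total volume of the adduct-split rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .composition import Composition, extract_key, parse_composition
from .glycresoft_io import (
    MatchRecord,
    SampleTable,
    concat_tables,
    drop_empty_keys,
    read_table,
)

__all__ = [
    "SampleStats",
    "ComparisonResult",
    "all_presence_filter",
    "merge_adduct_groups",
    "compare",
    "compare_tables",
    "write_comparison",
    "read_comparison",
    "sort_key",
]

log = logging.getLogger("glyccomp")


@dataclass(frozen=True)
class SampleStats:
    """Merged per-sample statistics for one composition."""

    score: float  # maximum over the merged rows
    total_volume: float  # sum over the merged rows
    extras: Mapping[str, str] = field(default_factory=dict)


@dataclass
class ComparisonResult:
    """One composition that survived the all-presence filter."""

    key: str
    per_sample: dict[str, SampleStats]
    anhydro: bool = False
    profile: str = "default"  # key dialect, see composition.KEY_PROFILES

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    @property
    def composition(self) -> Composition:
        return parse_composition(self.key, anhydro=self.anhydro, profile=self.profile)

    @property
    def dp(self) -> int:
        return self.composition.dp


def sort_key(key: str, profile: str = "default") -> tuple:
    """Report ordering for canonical keys: by dp, then the tuple itself."""
    c = parse_composition(key, profile=profile)
    return (c.dp, (c.dhexa, c.hexa, c.glcn, c.ac, c.so3))


def all_presence_filter(
    records: Sequence[MatchRecord], labels: set[str]
) -> list[MatchRecord]:
    """Retain records whose key occurs in at least one record of every label.

    Rows whose extracted key is missing from any of the ``labels`` samples
    are deleted as noise.  Relative order is preserved.  Requires K >= 2
    samples and records with non-empty keys.
    """
    if len(labels) < 2:
        raise ValueError("all-presence filtering needs at least 2 sample labels")
    keys = [extract_key(r.compound_key_raw) for r in records]
    for r in records:
        if r.sample_label not in labels:
            raise ValueError(
                f"record labeled {r.sample_label!r} is outside the declared "
                f"sample set {sorted(labels)}"
            )
    seen: dict[str, set[str]] = {}
    for k, r in zip(keys, records):
        seen.setdefault(k, set()).add(r.sample_label)
    return [r for k, r in zip(keys, records) if seen[k] == labels]


def merge_adduct_groups(
    records: Sequence[MatchRecord],
    profile: str = "default",
) -> list[ComparisonResult]:
    """Collapse adduct-split rows: one result per key, one entry per sample.

    Within each (key, sample) group the surviving score is the group
    maximum and the volume is the exact sum (``math.fsum`` over rows in
    pooled order); the extras of the first maximum-score row are kept.
    Results are sorted by (dp, key tuple).  Every key must carry the same
    sample set — guaranteed when input passed ``all_presence_filter``.
    """
    groups: dict[str, dict[str, list[MatchRecord]]] = {}
    for r in records:
        k = extract_key(r.compound_key_raw)
        groups.setdefault(k, {}).setdefault(r.sample_label, []).append(r)

    label_sets = {frozenset(by_label) for by_label in groups.values()}
    if len(label_sets) > 1:
        raise RuntimeError(
            "inconsistent sample coverage across keys; "
            "input has not passed the all-presence filter"
        )

    results: list[ComparisonResult] = []
    for k in sorted(groups, key=lambda key: sort_key(key, profile)):
        per_sample: dict[str, SampleStats] = {}
        for label in sorted(groups[k]):
            rows = groups[k][label]
            best = max(rows, key=lambda r: r.score)  # first max on ties
            per_sample[label] = SampleStats(
                score=best.score,
                total_volume=math.fsum(r.total_volume for r in rows),
                extras=dict(best.extras),
            )
        results.append(
            ComparisonResult(key=k, per_sample=per_sample, profile=profile)
        )
    return results


def compare_tables(
    tables: Sequence[SampleTable],
    min_score: float | None = None,
    anhydro: bool = False,
    profile: str = "default",
) -> list[ComparisonResult]:
    """Run the screening pipeline on already-loaded tables."""
    n_raw = sum(len(t) for t in tables)
    cleaned = [drop_empty_keys(t) for t in tables]
    n_keyed = sum(len(t) for t in cleaned)
    pooled = concat_tables(cleaned)
    if min_score is not None:
        pooled = [r for r in pooled if r.score >= min_score]
    labels = {t.label for t in tables}
    retained = all_presence_filter(pooled, labels)
    results = merge_adduct_groups(retained, profile=profile)
    for r in results:
        r.anhydro = anhydro
    log.info(
        "compare: %d raw rows -> %d with keys -> %d pooled -> %d retained "
        "-> %d merged components",
        n_raw,
        n_keyed,
        len(pooled),
        len(retained),
        len(results),
    )
    return results


def compare(
    paths: Sequence[str | Path],
    labels: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    min_score: float | None = None,
    anhydro: bool = False,
    profile: str = "default",
) -> list[ComparisonResult]:
    """Read K >= 2 sample tables and compare them end to end.

    Pipeline: read -> drop empty keys -> pool -> (optional score
    pre-filter) -> all-presence filter -> adduct merging.  Per-stage row
    counts are logged.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 input files to compare")
    if labels is not None and len(labels) != len(paths):
        raise ValueError("labels must match the number of input files")
    tables = [
        read_table(
            p,
            label=(labels[i] if labels is not None else None),
            column_map=column_map,
            delimiter=delimiter,
        )
        for i, p in enumerate(paths)
    ]
    return compare_tables(
        tables, min_score=min_score, anhydro=anhydro, profile=profile
    )


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def write_comparison(
    results: Sequence[ComparisonResult], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write comparison results as delimited text.

    Columns: key, dp, anhydro, then per-sample score and total_volume
    pairs, samples in sorted label order.
    """
    labels = sorted(results[0].per_sample) if results else []
    header = ["key", "dp", "anhydro"]
    for l in labels:
        header += [f"{l}:score", f"{l}:total_volume"]
    lines = [delimiter.join(header)]
    for r in results:
        row = [r.key, str(r.dp), "1" if r.anhydro else "0"]
        for l in labels:
            s = r.per_sample[l]
            row += [_fmt(s.score), _fmt(s.total_volume)]
        lines.append(delimiter.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_comparison(
    path: str | Path, delimiter: str = "\t", profile: str = "default"
) -> list[ComparisonResult]:
    """Read a file produced by :func:`write_comparison`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    header = lines[0].split(delimiter)
    sample_cols: dict[str, dict[str, int]] = {}
    for i, h in enumerate(header):
        if ":" in h:
            label, what = h.rsplit(":", 1)
            sample_cols.setdefault(label, {})[what] = i
    results = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split(delimiter)
        per_sample = {
            label: SampleStats(
                score=float(cells[cols["score"]]),
                total_volume=float(cells[cols["total_volume"]]),
            )
            for label, cols in sample_cols.items()
        }
        results.append(
            ComparisonResult(
                key=cells[0],
                per_sample=per_sample,
                anhydro=cells[2].strip() == "1",
                profile=profile,
            )
        )
    return results
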