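"""Relative quantification and false-positive evaluation of comparisons."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .comparator import ComparisonResult, sort_key
from .composition import parse_composition

__all__ = [
    "TruthSet",
    "FdrResult",
    "top_n_normalize",
    "fdr_evaluate",
    "grouped_report",
    "read_truth",
]


@dataclass(frozen=True)
class TruthSet:
    """Canonical keys confirmed true by manual interpretation."""

    true_keys: frozenset[str]
    source: str = ""
    profile: str = "default"  # key dialect, see composition.KEY_PROFILES

    def __post_init__(self) -> None:
        if not self.true_keys:
            raise ValueError("truth set must be non-empty")
        for k in self.true_keys:
            parse_composition(k, profile=self.profile)  # validates


@dataclass(frozen=True)
class FdrResult:
    retained: int
    false_positive_rate: float | None  # None when retained == 0 (undefined)
    false_negatives: int


def read_truth(path: str | Path, profile: str = "default") -> TruthSet:
    """Read a truth file: one canonical key per line, '#' comments."""
    keys = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            keys.add(line)
    return TruthSet(true_keys=frozenset(keys), source=str(path), profile=profile)


def top_n_normalize(
    results: Sequence[ComparisonResult], n: int = 10
) -> dict[tuple[str, str], float]:
    """Normalize volumes to the summed volume of each sample's top-n keys.

    Per sample, keys are ranked by total_volume descending (ties broken by
    canonical key order); the denominator is the sum of the top-n volumes
    — all keys tied with the rank-n volume are included — or of all keys
    when fewer than n exist.  Every key's abundance is reported, not only
    the top n.
    """
    if not results:
        raise ValueError("no results to normalize")
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = sorted(results[0].per_sample)
    out: dict[tuple[str, str], float] = {}
    for label in labels:
        ranked = sorted(
            results,
            key=lambda r: (
                -r.per_sample[label].total_volume,
                sort_key(r.key, r.profile),
            ),
        )
        top = ranked[:n]
        if len(ranked) > n:
            cutoff = ranked[n - 1].per_sample[label].total_volume
            for r in ranked[n:]:
                if r.per_sample[label].total_volume == cutoff:
                    top.append(r)
                else:
                    break
        denom = math.fsum(r.per_sample[label].total_volume for r in top)
        if denom == 0:
            raise ValueError(f"all volumes are zero in sample {label!r}")
        for r in results:
            out[(r.key, label)] = r.per_sample[label].total_volume / denom
    return out


def fdr_evaluate(results: Sequence[ComparisonResult], truth: TruthSet) -> FdrResult:
    """Score retained keys against a manually annotated truth set.

    false_positive_rate = (retained - |retained ∩ truth|) / retained;
    false_negatives counts truth keys the comparison missed.
    """
    retained_keys = {r.key for r in results}
    retained = len(retained_keys)
    if retained == 0:
        return FdrResult(
            retained=0,
            false_positive_rate=None,
            false_negatives=len(truth.true_keys),
        )
    true_found = len(retained_keys & truth.true_keys)
    return FdrResult(
        retained=retained,
        false_positive_rate=(retained - true_found) / retained,
        false_negatives=len(truth.true_keys - retained_keys),
    )


def grouped_report(
    results: Sequence[ComparisonResult],
    normalized: dict[tuple[str, str], float],
) -> list[list[str]]:
    """Tabulate normalized abundances grouped by anhydro status and dp.

    Returns header + data rows ordered by (anhydro, dp, key); columns are
    key, dp, anhydro, then one normalized-abundance column per sample —
    ready for bar-chart plotting or TSV dumping.
    """
    labels = sorted(results[0].per_sample) if results else []
    header = ["key", "dp", "anhydro", *labels]
    rows = [header]
    ordered = sorted(results, key=lambda r: (r.anhydro, sort_key(r.key, r.profile)))
    for r in ordered:
        rows.append(
            [
                r.key,
                str(r.dp),
                "1" if r.anhydro else "0",
                *(repr(normalized[(r.key, l)]) for l in labels),
            ]
        )
    return rows
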