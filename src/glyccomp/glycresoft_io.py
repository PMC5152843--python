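"""Read, label, clean and write GlycReSoft-style tab-delimited match tables.

Each input file is one sample/replicate: a header row followed by one row
per candidate match.  Three columns matter downstream — the bracketed
compound key, the match score, and the summed ion volume — all remaining
columns are carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MatchRecord",
    "SampleTable",
    "ColumnConfigError",
    "read_table",
    "read_workbook",
    "drop_empty_keys",
    "concat_tables",
    "write_table",
]

#: roles every table must provide, and the header names they match
#: (case-insensitive, surrounding whitespace ignored)
REQUIRED_ROLES = ("compound_key", "score", "total_volume")
_DEFAULT_NAMES = {
    "compound_key": "compound key",
    "score": "score",
    "total_volume": "total volume",
}


class ColumnConfigError(ValueError):
    """A required column role could not be resolved against the header."""


@dataclass
class MatchRecord:
    """One row of a match table."""

    sample_label: str
    compound_key_raw: str
    score: float
    total_volume: float
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score < 0 or self.total_volume < 0:
            raise ValueError("score and total_volume must be non-negative")

    @property
    def has_key(self) -> bool:
        return bool(self.compound_key_raw.strip())


@dataclass
class SampleTable:
    label: str
    records: list[MatchRecord]
    source_path: str = ""

    def __post_init__(self) -> None:
        for r in self.records:
            if r.sample_label != self.label:
                raise ValueError(
                    f"record labeled {r.sample_label!r} in table {self.label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, int]:
    """Map each required role to a header index; raise naming missing roles."""
    lowered = {h.strip().lower(): i for i, h in enumerate(header)}
    wanted = dict(_DEFAULT_NAMES)
    if column_map:
        for role, name in column_map.items():
            if role not in REQUIRED_ROLES:
                raise ColumnConfigError(f"unknown column role {role!r}")
            wanted[role] = name.strip().lower()
    indices: dict[str, int] = {}
    missing: list[str] = []
    for role in REQUIRED_ROLES:
        idx = lowered.get(wanted[role])
        if idx is None:
            missing.append(role)
        else:
            indices[role] = idx
    if missing:
        raise ColumnConfigError(
            "required column(s) not found in header: " + ", ".join(missing)
        )
    return indices


def _parse_number(text: str, role: str, path: str, line_no: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ValueError(
            f"{path}:{line_no}: unparseable {role} value {text!r}"
        ) from None
    return value


def read_table(
    path: str | Path,
    label: str | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> SampleTable:
    """Read one sample's tab-delimited match table.

    ``label`` defaults to the file name stem.  ``column_map`` maps a role
    (``compound_key`` / ``score`` / ``total_volume``) to a nonstandard
    header name.  An empty file yields an empty table.
    """
    path = Path(path)
    label = label if label is not None else path.stem
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        return SampleTable(label=label, records=[], source_path=str(path))
    header = lines[0].split(delimiter)
    indices = _resolve_columns(header, column_map)
    # a "sample_label" column (as written by write_table) restores per-row
    # provenance instead of the file name stem
    label_col = next(
        (i for i, h in enumerate(header) if h.strip().lower() == "sample_label"),
        None,
    )
    role_cols = set(indices.values()) | ({label_col} if label_col is not None else set())
    extra_cols = [
        (i, h.strip()) for i, h in enumerate(header) if i not in role_cols
    ]
    records: list[MatchRecord] = []
    row_labels: set[str] = set()
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(delimiter)
        cells += [""] * (len(header) - len(cells))

        def cell(role: str) -> str:
            return cells[indices[role]]

        row_label = label
        if label_col is not None and cells[label_col].strip():
            row_label = cells[label_col].strip()
        row_labels.add(row_label)
        records.append(
            MatchRecord(
                sample_label=row_label,
                compound_key_raw=cell("compound_key"),
                score=_parse_number(cell("score"), "score", str(path), line_no),
                total_volume=_parse_number(
                    cell("total_volume"), "total_volume", str(path), line_no
                ),
                extras={h: cells[i] for i, h in extra_cols},
            )
        )
    if label_col is not None and len(row_labels) == 1:
        label = next(iter(row_labels))
    return SampleTable(label=label, records=records, source_path=str(path))


def read_workbook(
    path: str | Path,
    sheets: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[SampleTable]:
    """Read a spreadsheet workbook with one match table per sheet.

    Exists to consume replicate data distributed as .xlsx; each selected
    sheet becomes a :class:`SampleTable` labeled with the sheet name.
    """
    from openpyxl import load_workbook

    wb = load_workbook(str(path), read_only=True, data_only=True)
    names = list(sheets) if sheets is not None else wb.sheetnames
    tables: list[SampleTable] = []
    for name in names:
        ws = wb[name]
        rows = [
            ["" if c is None else str(c) for c in row]
            for row in ws.iter_rows(values_only=True)
        ]
        while rows and not any(c.strip() for c in rows[-1]):
            rows.pop()
        if not rows:
            tables.append(SampleTable(label=name, records=[], source_path=str(path)))
            continue
        indices = _resolve_columns(rows[0], column_map)
        role_cols = set(indices.values())
        extra_cols = [
            (i, h.strip()) for i, h in enumerate(rows[0]) if i not in role_cols
        ]
        records = []
        for line_no, cells in enumerate(rows[1:], start=2):
            if not any(c.strip() for c in cells):
                continue
            cells = list(cells) + [""] * (len(rows[0]) - len(cells))
            records.append(
                MatchRecord(
                    sample_label=name,
                    compound_key_raw=cells[indices["compound_key"]],
                    score=_parse_number(
                        cells[indices["score"]], "score", f"{path}#{name}", line_no
                    ),
                    total_volume=_parse_number(
                        cells[indices["total_volume"]],
                        "total_volume",
                        f"{path}#{name}",
                        line_no,
                    ),
                    extras={h: cells[i] for i, h in extra_cols},
                )
            )
        tables.append(SampleTable(label=name, records=records, source_path=str(path)))
    wb.close()
    return tables


def drop_empty_keys(table: SampleTable) -> SampleTable:
    """Remove rows whose compound key is empty after trimming (noise rows)."""
    kept = [r for r in table.records if r.has_key]
    return SampleTable(label=table.label, records=kept, source_path=table.source_path)


def concat_tables(tables: Sequence[SampleTable]) -> list[MatchRecord]:
    """Pool ≥2 labeled tables into one record sequence.

    Labels must be pairwise distinct — each pooled record keeps its
    sample label so provenance survives pooling.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to pool")
    labels = [t.label for t in tables]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate sample labels: {', '.join(dupes)}")
    pooled: list[MatchRecord] = []
    for t in tables:
        pooled.extend(t.records)
    return pooled


def _fmt(x: float) -> str:
    # repr round-trips floats exactly; ints print without trailing noise
    return repr(int(x)) if float(x).is_integer() else repr(x)


def write_table(
    records: Iterable[MatchRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write records as delimited text with a deterministic column order:
    sample_label, compound key, score, total_volume, then extras in
    first-seen order.  ``read_table(write_table(x))`` reproduces ``x``.
    """
    records = list(records)
    extra_names: list[str] = []
    for r in records:
        for name in r.extras:
            if name not in extra_names:
                extra_names.append(name)
    header = ["sample_label", "Compound Key", "Score", "Total Volume", *extra_names]
    lines = [delimiter.join(header)]
    for r in records:
        row = [
            r.sample_label,
            r.compound_key_raw,
            _fmt(r.score),
            _fmt(r.total_volume),
            *(r.extras.get(n, "") for n in extra_names),
        ]
        lines.append(delimiter.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
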