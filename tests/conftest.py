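from __future__ import annotations

import random

import pytest

from glyccomp import MatchRecord, SampleTable


def write_tsv(path, rows, header=("Compound Key", "Score", "Total Volume")):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def make_record(label="s1", key="[1,2,3,0,4]", score=0.5, volume=100.0, extras=None):
    return MatchRecord(
        sample_label=label,
        compound_key_raw=key,
        score=score,
        total_volume=volume,
        extras=extras or {},
    )


def random_instance(rng: random.Random, max_labels=4, max_keys=8, max_rows=40):
    """A random comparison instance with integer volumes (exact sums).

    Returns (rows, labels) where rows are (label, raw_cell, score, volume).
    """
    k = rng.randint(2, max_labels)
    labels = [f"s{i}" for i in range(k)]
    keys = [
        f"[{rng.randint(0, 1)},{rng.randint(0, 3)},{rng.randint(1, 4)},"
        f"{rng.randint(0, 2)},{rng.randint(0, 6)}]"
        for _ in range(rng.randint(1, max_keys))
    ]
    rows = []
    for _ in range(rng.randint(0, max_rows)):
        key = rng.choice(keys)
        decorated = rng.choice([key, f"{key} {rng.randint(0, 14)}NH3", f" {key} "])
        rows.append(
            (
                rng.choice(labels),
                decorated,
                round(rng.random(), 3),
                float(rng.randint(1, 10_000)),
            )
        )
    return rows, labels


def rows_to_tables(rows, labels):
    by_label = {l: [] for l in labels}
    for label, cell, score, volume in rows:
        by_label[label].append(make_record(label, cell, score, volume))
    return [SampleTable(label=l, records=by_label[l]) for l in labels]


@pytest.fixture
def rng():
    return random.Random(20160914)
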