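"""Fixture generator: replicate match tables with planted ground truth.

Emits K tab-delimited files in the reader's dialect, with true components
present in every file (split across several ammonium-adduct rows), decoy
components present in a strict subset of files, and noise rows with empty
compound keys.  Everything derives from a single seeded Mersenne Twister
(``random.Random``), so outputs are byte-identical across runs and
platforms for a given spec.

Row volumes are drawn log-normal (heavy-tailed, like ion volumes) and
rounded to integers so that merged-volume conservation can be asserted
bit-exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .composition import Composition
from .hypothesis import HypothesisParams, enumerate_hypothesis
from .quantify import TruthSet

__all__ = ["SyntheticSpec", "GeneratedDataset", "generate_dataset", "sample_compositions"]


@dataclass(frozen=True)
class SyntheticSpec:
    k_samples: int = 3
    n_true: int = 10
    n_decoy: int = 15
    #: inclusive (lo, hi) number of adduct-split rows per component per sample
    adduct_rows_per_component: tuple[int, int] = (1, 4)
    noise_fraction: float = 0.3
    #: log-normal (mu, sigma) for row volumes, discretized to integers
    volume_model: tuple[float, float] = (9.0, 1.5)
    seed: int = 0
    hypothesis: HypothesisParams = field(default_factory=HypothesisParams)

    def __post_init__(self) -> None:
        if self.k_samples < 2:
            raise ValueError("k_samples must be >= 2")
        if self.n_true < 0 or self.n_decoy < 0:
            raise ValueError("component counts must be >= 0")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        lo, hi = self.adduct_rows_per_component
        if not 1 <= lo <= hi:
            raise ValueError("adduct_rows_per_component must be 1 <= lo <= hi")

    @property
    def labels(self) -> list[str]:
        return [f"rep{i + 1}" for i in range(self.k_samples)]


@dataclass
class GeneratedDataset:
    paths: list[Path]
    truth: TruthSet | None  # None when the spec plants no true components
    #: (key, label) -> (expected merged max score, expected merged volume sum)
    ledger: dict[tuple[str, str], tuple[float, float]]
    decoy_keys: set[str]


def sample_compositions(
    n: int, p: HypothesisParams, seed: int | random.Random
) -> list[Composition]:
    """Draw ``n`` distinct compositions uniformly from the hypothesis space."""
    space = sorted(
        {e.composition for e in enumerate_hypothesis(p)},
        key=lambda c: (c.dhexa, c.hexa, c.glcn, c.ac, c.so3),
    )
    if n > len(space):
        raise ValueError(
            f"requested {n} compositions from a space of {len(space)}"
        )
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    return rng.sample(space, n)


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> GeneratedDataset:
    """Write the replicate files and return the planted ground truth.

    The returned ledger maps (key, label) to the exact expected merged
    score (max of planted rows) and volume (sum of planted rows) for true
    components, enabling bit-exact end-to-end checks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    labels = spec.labels

    comps = sample_compositions(
        spec.n_true + spec.n_decoy, spec.hypothesis, rng
    )
    truths, decoys = comps[: spec.n_true], comps[spec.n_true :]
    lo, hi = spec.adduct_rows_per_component
    if hi > spec.hypothesis.nh3_max + 1:
        raise ValueError(
            "adduct_rows_per_component exceeds the number of distinct adduct states"
        )

    # each decoy lives in a uniformly chosen strict, non-empty subset
    decoy_homes: dict[str, list[str]] = {}
    for comp in decoys:
        size = rng.randint(1, spec.k_samples - 1)
        decoy_homes[comp.key] = sorted(rng.sample(labels, size))

    mu, sigma = spec.volume_model
    rows_by_label: dict[str, list[tuple[str, float, float, int]]] = {
        l: [] for l in labels
    }
    ledger: dict[tuple[str, str], tuple[float, float]] = {}

    def plant(comp: Composition, where: Sequence[str], record: bool) -> None:
        for label in where:
            n_rows = rng.randint(lo, hi)
            adducts = rng.sample(range(spec.hypothesis.nh3_max + 1), n_rows)
            scores, volumes = [], []
            for n_nh3 in adducts:
                score = round(rng.random(), 6)
                volume = float(max(1, round(rng.lognormvariate(mu, sigma))))
                cell = f"{comp.key} {n_nh3}NH3"
                rows_by_label[label].append((cell, score, volume, n_nh3))
                scores.append(score)
                volumes.append(volume)
            if record:
                ledger[(comp.key, label)] = (max(scores), sum(volumes))

    for comp in truths:
        plant(comp, labels, record=True)
    for comp in decoys:
        plant(comp, decoy_homes[comp.key], record=False)

    # noise rows with empty keys: fraction f of the final file row count
    f = spec.noise_fraction
    for label in labels:
        planted = len(rows_by_label[label])
        n_noise = round(planted * f / (1 - f))
        for _ in range(n_noise):
            score = round(rng.random(), 6)
            volume = float(max(1, round(rng.lognormvariate(mu, sigma))))
            rows_by_label[label].append(("", score, volume, 0))
        rng.shuffle(rows_by_label[label])

    paths: list[Path] = []
    for label in labels:
        path = out_dir / f"{label}.txt"
        lines = ["Compound Key\tScore\tTotal Volume\tAdducts"]
        for cell, score, volume, n_nh3 in rows_by_label[label]:
            lines.append(f"{cell}\t{_fmt(score)}\t{_fmt(volume)}\t{n_nh3}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths.append(path)

    truth = None
    if truths:
        truth = TruthSet(
            true_keys=frozenset(c.key for c in truths), source="synthetic"
        )
        truth_path = out_dir / "truth.txt"
        truth_path.write_text(
            "# planted true component keys\n"
            + "\n".join(sorted(truth.true_keys))
            + "\n",
            encoding="utf-8",
        )
    ledger_path = out_dir / "ledger.tsv"
    ledger_lines = ["key\tlabel\texpected_score\texpected_volume"]
    for (key, label), (score, volume) in sorted(ledger.items()):
        ledger_lines.append(f"{key}\t{label}\t{_fmt(score)}\t{_fmt(volume)}")
    ledger_path.write_text("\n".join(ledger_lines) + "\n", encoding="utf-8")

    return GeneratedDataset(
        paths=paths,
        truth=truth,
        ledger=ledger,
        decoy_keys={c.key for c in decoys},
    )
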