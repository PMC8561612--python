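"""Reading, validating and synthesising student score sets.

Scores are percentages in [0, 100].  Input is a plain comma-delimited CSV
whose first column is numeric; any further columns are ignored, and a
single leading non-numeric row is tolerated as a header.  Scores are kept
with duplicates (duplicates shape the cumulative curve) and stored sorted
ascending.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, ValidationError


@dataclass(frozen=True)
class ScoreSet:
    """A validated, ascending-sorted collection of scores in [0, 100]."""

    scores: tuple[float, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValidationError("score set is empty")
        ordered = tuple(sorted(float(s) for s in self.scores))
        for s in ordered:
            if not np.isfinite(s) or not 0.0 <= s <= 100.0:
                raise ValidationError(
                    f"score {s} outside the percentage range [0, 100]")
        object.__setattr__(self, "scores", ordered)

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def minimum(self) -> float:
        return self.scores[0]

    @property
    def maximum(self) -> float:
        return self.scores[-1]

    def distinct(self) -> tuple[float, ...]:
        return tuple(dict.fromkeys(self.scores))


def _parse_cell(cell: str) -> float | None:
    try:
        return float(cell.strip())
    except ValueError:
        return None


def read_scores(path: str | Path, max_rows: int | None = None) -> ScoreSet:
    """Read the first column of a CSV file into a :class:`ScoreSet`.

    Rules: only the first column is read; one leading non-numeric row is
    skipped as a header; any later non-numeric cell is an error reported
    with its row number; sorting is automatic.  ``max_rows`` limits the
    number of data rows read (header excluded).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"score file not found: {path}")
    values: list[float] = []
    try:
        text = path.read_text(encoding="utf-8-sig")
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc

    rows = [r for r in csv.reader(text.splitlines()) if r and any(
        cell.strip() for cell in r)]
    start = 0
    if rows and _parse_cell(rows[0][0]) is None:
        start = 1  # header row
    for row_no, row in enumerate(rows[start:], start=start + 1):
        value = _parse_cell(row[0])
        if value is None:
            raise InputError(
                f"{path} row {row_no}: first column {row[0]!r} is not a number")
        if not 0.0 <= value <= 100.0:
            raise InputError(
                f"{path} row {row_no}: score {value} outside [0, 100]")
        values.append(value)
        if max_rows is not None and len(values) >= max_rows:
            break
    if not values:
        raise InputError(f"{path}: no numeric score rows found")
    return ScoreSet(tuple(values), source_label=str(path))


def generate_synthetic_scores(n: int, low: int = 1, high: int = 100,
                              seed: int = 0) -> ScoreSet:
    """Draw ``n`` integer scores uniformly (with replacement) from [low, high].

    This reproduces the shape of a spreadsheet RANDBETWEEN fixture: the
    default bounds give a flat cohort over 1..100, the hardest realistic
    case for cut-off placement because the cumulative curve is close to a
    straight line.  Identical arguments give identical output.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if low > high:
        raise ValidationError(f"low={low} exceeds high={high}")
    if low < 0 or high > 100:
        raise ValidationError(
            f"bounds [{low}, {high}] must lie within [0, 100]")
    rng = np.random.default_rng(seed)
    draws = rng.integers(low, high + 1, size=n)
    return ScoreSet(tuple(float(v) for v in draws),
                    source_label=f"synthetic uniform[{low},{high}] n={n} seed={seed}")


def write_scores_csv(scores: ScoreSet | Sequence[float] | Iterable[float],
                     path: str | Path, header: str | None = "score") -> Path:
    """Write scores as a single-column CSV (optionally with a header row)."""
    path = Path(path)
    values = scores.scores if isinstance(scores, ScoreSet) else list(scores)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow([header])
        for v in values:
            writer.writerow([f"{v:g}"])
    return path
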