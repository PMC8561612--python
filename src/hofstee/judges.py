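"""Judge-panel collection and aggregation of the four Hofstee parameters.

The Hofstee compromise method starts from each judge's independent answers
to four questions: the lowest and highest score they would accept as the
pass/fail cut-off (c_min, c_max, both on the 0-100 score axis) and the
lowest and highest percentage of the cohort they would accept failing
(f_min, f_max, on the 0-100 percent axis).  The panel's estimates are then
reduced to a single quadruple by taking the arithmetic mean of each
parameter (the classical choice) or the median (a robust alternative some
authors prefer).  Standard deviations are reported alongside so the panel
can see how much the judges disagree.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import ValidationError

PARAMETER_NAMES = ("c_min", "c_max", "f_min", "f_max")

AggregationMethod = Literal["mean", "median"]


def _check_quadruple(c_min: float, c_max: float, f_min: float, f_max: float,
                     label: str) -> None:
    for name, value in zip(PARAMETER_NAMES, (c_min, c_max, f_min, f_max)):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(f"{label}: {name} must be numeric, got {value!r}")
        if not math.isfinite(value):
            raise ValidationError(f"{label}: {name} must be finite, got {value!r}")
        if not 0.0 <= value <= 100.0:
            raise ValidationError(
                f"{label}: {name}={value} outside the percentage range [0, 100]")
    if c_min > c_max:
        raise ValidationError(f"{label}: c_min={c_min} exceeds c_max={c_max}")
    if f_min > f_max:
        raise ValidationError(f"{label}: f_min={f_min} exceeds f_max={f_max}")


@dataclass(frozen=True)
class JudgeEstimate:
    """One judge's quadruple (c_min, c_max, f_min, f_max), all in [0, 100]."""

    judge_id: int
    c_min: float
    c_max: float
    f_min: float
    f_max: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.c_min, self.c_max, self.f_min, self.f_max)


def validate_estimate(estimate: JudgeEstimate) -> JudgeEstimate:
    """Return ``estimate`` unchanged if it satisfies the domain invariants.

    Raises :class:`ValidationError` naming the offending parameter when a
    value is non-numeric, outside [0, 100], or when c_min > c_max or
    f_min > f_max.
    """
    if not isinstance(estimate.judge_id, int) or estimate.judge_id < 1:
        raise ValidationError(
            f"judge_id must be a positive integer, got {estimate.judge_id!r}")
    _check_quadruple(estimate.c_min, estimate.c_max, estimate.f_min,
                     estimate.f_max, f"judge {estimate.judge_id}")
    return estimate


@dataclass(frozen=True)
class HofsteeParameters:
    """The aggregated quadruple that defines line AB.

    ``source`` records provenance: ``"mean"``/``"median"`` when aggregated
    from a panel, ``"direct"`` when the user supplied pre-aggregated values.
    """

    c_min: float
    c_max: float
    f_min: float
    f_max: float
    source: Literal["mean", "median", "direct"] = "direct"

    def __post_init__(self) -> None:
        _check_quadruple(self.c_min, self.c_max, self.f_min, self.f_max,
                         "aggregate parameters")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


@dataclass
class JudgePanel:
    """An ordered panel of validated judge estimates with recomputable stats."""

    estimates: list[JudgeEstimate] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.estimates = [validate_estimate(e) for e in self.estimates]

    @classmethod
    def from_quadruples(
        cls, quads: Iterable[Sequence[float]]
    ) -> "JudgePanel":
        """Build a panel from (c_min, c_max, f_min, f_max) rows, numbering
        judges 1..k in input order."""
        estimates = [
            JudgeEstimate(i, *map(float, q)) for i, q in enumerate(quads, start=1)
        ]
        return cls(estimates)

    def __len__(self) -> int:
        return len(self.estimates)

    def _column(self, name: str) -> list[float]:
        return [getattr(e, name) for e in self.estimates]

    def means(self) -> dict[str, float]:
        self._require_nonempty()
        return {n: statistics.fmean(self._column(n)) for n in PARAMETER_NAMES}

    def medians(self) -> dict[str, float]:
        # even-sized panels: mean of the two middle values
        self._require_nonempty()
        return {n: float(statistics.median(self._column(n)))
                for n in PARAMETER_NAMES}

    def stdevs(self) -> dict[str, float]:
        """Per-parameter sample standard deviation (n-1 denominator);
        0.0 for a single-judge panel."""
        self._require_nonempty()
        if len(self.estimates) == 1:
            return {n: 0.0 for n in PARAMETER_NAMES}
        return {n: statistics.stdev(self._column(n)) for n in PARAMETER_NAMES}

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean, sample SD and median for each of the four parameters."""
        means, sds, medians = self.means(), self.stdevs(), self.medians()
        return {
            n: {"mean": means[n], "sd": sds[n], "median": medians[n]}
            for n in PARAMETER_NAMES
        }

    def _require_nonempty(self) -> None:
        if not self.estimates:
            raise ValidationError("judge panel is empty: at least one "
                                  "judge's parameters are required")


def aggregate_panel(panel: JudgePanel,
                    method: AggregationMethod = "mean") -> HofsteeParameters:
    """Reduce a panel to a single :class:`HofsteeParameters` quadruple.

    ``method`` selects the per-parameter arithmetic mean or median across
    judges.  Because every estimate satisfies c_min <= c_max and
    f_min <= f_max, both aggregates preserve those orderings, so the result
    always validates.
    """
    if method not in ("mean", "median"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    agg = panel.means() if method == "mean" else panel.medians()
    # ordering can only break if an estimate slipped past validation
    assert agg["c_min"] <= agg["c_max"] and agg["f_min"] <= agg["f_max"]
    return HofsteeParameters(agg["c_min"], agg["c_max"], agg["f_min"],
                             agg["f_max"], source=method)
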