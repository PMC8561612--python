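"""Static Hofstee charts (full cohort or detail around the parameter window).

Rendering is a pure sink: it never alters numeric results.  The chart shows
the cumulative polyline, line AB, dashed guide lines at the four
parameters, and — when a cut-off exists — a marker labelled with the 2-dp
cut score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import CutoffResult, LineSegment  # noqa: E402
from .curve import CumulativeCurve  # noqa: E402
from .errors import InputError, ValidationError  # noqa: E402

DETAIL_MARGIN_FRACTION = 0.10


@dataclass(frozen=True)
class ChartSpec:
    mode: Literal["full", "detailed"] = "full"
    path: str | Path = "hofstee_chart.png"
    image_format: Literal["png", "svg"] = "png"
    title: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("full", "detailed"):
            raise ValidationError(f"unknown chart mode {self.mode!r}")
        if self.image_format not in ("png", "svg"):
            raise ValidationError(
                f"unsupported image format {self.image_format!r}")


def detailed_limits(ab: LineSegment) -> tuple[float, float]:
    """X-axis window for the detailed chart: [c_min - m, c_max + m] with a
    margin m of 10% of the parameter span (floor of 1 score point when
    c_min == c_max)."""
    span = ab.x_hi - ab.x_lo
    margin = DETAIL_MARGIN_FRACTION * span if span > 0 else 1.0
    return ab.x_lo - margin, ab.x_hi + margin


def render_chart(curve: CumulativeCurve, ab: LineSegment,
                 result: CutoffResult | None, spec: ChartSpec) -> Path:
    """Render the chart described by ``spec`` and return the written path."""
    fig, ax = plt.subplots(figsize=(8, 6), dpi=150)
    try:
        ax.plot(curve.xs, curve.ys, color="tab:blue", lw=1.8,
                label="cumulative % of students")
        ax.plot([ab.x1, ab.x2], [ab.y1, ab.y2], color="tab:red", lw=1.5,
                label="line AB")
        # dashed guides at the four parameter values
        for x in (ab.x1, ab.x2):
            ax.axvline(x, color="grey", ls="--", lw=0.8)
        for y in (ab.y1, ab.y2):
            ax.axhline(y, color="grey", ls="--", lw=0.8)
        if result is not None:
            ax.plot([result.cutoff_x], [result.cutoff_y], "ko", ms=6,
                    label="cut-off")
            ax.annotate(f"{result.display_cutoff:.2f}",
                        (result.cutoff_x, result.cutoff_y),
                        textcoords="offset points", xytext=(8, 8))
        else:
            ax.annotate("no intersection between AB and the curve",
                        (0.02, 0.95), xycoords="axes fraction",
                        color="tab:red")
        if spec.mode == "detailed":
            ax.set_xlim(*detailed_limits(ab))
        ax.set_xlabel("score (%)")
        ax.set_ylabel("cumulative % of students")
        ax.set_title(spec.title or "Hofstee chart")
        ax.legend(loc="best", fontsize=8)
        path = Path(spec.path)
        try:
            fig.savefig(path, format=spec.image_format)
        except OSError as exc:
            raise InputError(f"cannot write chart to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path
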