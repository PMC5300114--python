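"""Triangular heat-map rendering of scan results.

A scan result is drawn as a tri-variate scatter: x = window midpoint,
y = window length, color = score. With a full grid the marks fill a
triangle (the full-length window has one placement, the shortest ones
many); a length-truncated scan yields a trapezoid. Marks are sized to
fuse into a continuous surface.

Colors come from a "short rainbow" running blue (lowest score) through
green and yellow to red (highest), deliberately avoiding purple, which
the eye confuses with both ends. The hue is traversed at a non-uniform
rate -- the broad band that all reads as "green" is crossed quickly --
so that equal score differences read as roughly equal color differences.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure

from simbal.scan_engine import ScanResult

#: Monotone (t, hue-degrees) control points of the short-rainbow ramp.
#: Hue falls from 240 (blue) to 0 (red); the 90-150 degree green band is
#: compressed into a short t interval because human vision resolves it
#: poorly, while the blue-cyan and yellow-red bands get more of the ramp.
_HUE_KNOTS: tuple[tuple[float, float], ...] = (
    (0.00, 240.0),
    (0.30, 185.0),
    (0.50, 140.0),
    (0.62, 95.0),
    (0.80, 55.0),
    (1.00, 0.0),
)


@dataclass(frozen=True)
class HeatmapSpec:
    """Rendering parameters for one heat map.

    ``score_floor`` maps to blue and defaults to the lowest score in the
    data; ``score_cap`` maps to red, or, when None, the maximum score in
    the data. A fixed floor/cap lets several maps (e.g. a query and its
    paralogs) share one color scale. A degenerate range (cap <= floor,
    as in a flat negative-control scan) renders uniform blue.
    """

    score_floor: float | None = None
    score_cap: float | None = None
    point_size: float | None = None
    title: str | None = None


class HeatPoint(NamedTuple):
    midpoint: float
    length: int
    scaled: float
    hex_color: str


def short_rainbow(t: float) -> tuple[int, int, int]:
    """Map t in [0, 1] to an RGB triple from blue (t=0) to red (t=1).

    Piecewise-linear in hue over the knots above, full saturation and
    value; inputs outside [0, 1] are clamped.
    """
    t = min(1.0, max(0.0, t))
    hue = _HUE_KNOTS[-1][1]
    for (t0, h0), (t1, h1) in zip(_HUE_KNOTS, _HUE_KNOTS[1:]):
        if t <= t1:
            frac = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
            hue = h0 + frac * (h1 - h0)
            break
    r, g, b = colorsys.hsv_to_rgb(hue / 360.0, 1.0, 1.0)
    return round(r * 255), round(g * 255), round(b * 255)


def _scale(score: float, floor: float, cap: float) -> float:
    if cap <= floor:
        return 0.0
    return min(1.0, max(0.0, (score - floor) / (cap - floor)))


def heatmap_points(result: ScanResult, spec: HeatmapSpec | None = None) -> list[HeatPoint]:
    """One colored mark per scored window: (midpoint, length, scaled, hex)."""
    spec = spec or HeatmapSpec()
    if not result.windows:
        raise ValueError("cannot render an empty scan result")
    cap = spec.score_cap
    if cap is None:
        cap = max(w.score for w in result.windows)
    floor = spec.score_floor
    if floor is None:
        floor = min(w.score for w in result.windows)
    points: list[HeatPoint] = []
    for w in result.windows:
        t = _scale(w.score, floor, cap)
        r, g, b = short_rainbow(t)
        points.append(
            HeatPoint(w.midpoint, w.length, t, f"#{r:02x}{g:02x}{b:02x}")
        )
    return points


def write_points_table(points: list[HeatPoint], path: str | Path) -> None:
    """Sidecar TSV of heat-map marks for external plotting."""
    with open(path, "w") as fh:
        fh.write("midpoint\tlength\tscaled_score\thex_color\n")
        for pt in points:
            fh.write(f"{pt.midpoint:.1f}\t{pt.length}\t{pt.scaled:.4f}\t"
                     f"{pt.hex_color}\n")


def render_heatmap(
    result: ScanResult, spec: HeatmapSpec | None = None,
    path: str | Path = "heatmap.png",
) -> None:
    """Render the triangular heat map to ``path`` (PNG or SVG by suffix)."""
    spec = spec or HeatmapSpec()
    points = heatmap_points(result, spec)
    fig = Figure(figsize=(8, 6), dpi=150)
    suffix = Path(path).suffix.lower()
    if suffix == ".svg":
        FigureCanvasSVG(fig)
    elif suffix == ".png":
        FigureCanvasAgg(fig)
    else:
        raise ValueError(f"unsupported output format {suffix!r}; use .png or .svg")
    ax = fig.add_subplot(111)
    size = spec.point_size
    if size is None:
        # large enough that adjacent marks of a full-resolution grid touch
        n_lengths = len({p.length for p in points}) or 1
        size = max(1.0, (6 * 72 / n_lengths) ** 2 / 4)
    ax.scatter(
        [p.midpoint for p in points],
        [p.length for p in points],
        c=[p.hex_color for p in points],
        s=size, marker="s", linewidths=0,
    )
    ax.set_xlim(0, result.query_length + 1)
    ax.set_xlabel("subsequence midpoint (residue)")
    ax.set_ylabel("subsequence length (residues)")
    if spec.title:
        ax.set_title(spec.title)
    fig.savefig(path)
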