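"""Score overlays: one colored dot per segment plus a color bar.

Each segment gets a filled dot at its left edge whose color encodes the
normalized b1 score through a piecewise-linear ramp (default blue → yellow
→ red over [0, threshold]); flagged segments are drawn in the flag color
(green) and insufficient-tissue segments in neutral gray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .grid import FLAGGED, INSUFFICIENT, SegmentRecord

__all__ = ["ColorScale", "render_overlay", "render_colorbar"]

logger = logging.getLogger(__name__)

GRAY = (128, 128, 128)


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear score-to-color map with a reserved flag color.

    Scores between breakpoints interpolate linearly; scores above the last
    breakpoint clamp to ``flag_color``.
    """

    breakpoints: tuple = (
        (0.0, (40, 60, 220)),     # blue: quiet tissue
        (15.0, (235, 220, 50)),   # yellow: elevated contact
        (30.0, (220, 50, 40)),    # red: at threshold
    )
    flag_color: tuple = (0, 255, 0)

    def __post_init__(self) -> None:
        scores = [s for s, _ in self.breakpoints]
        if len(scores) < 2 or any(b <= a for a, b in zip(scores, scores[1:])):
            raise ValueError("breakpoint scores must be strictly increasing")

    def color(self, score: float) -> tuple[int, int, int]:
        pts = self.breakpoints
        if score <= pts[0][0]:
            return tuple(pts[0][1])
        if score > pts[-1][0]:
            return tuple(self.flag_color)
        for (s0, c0), (s1, c1) in zip(pts, pts[1:]):
            if score <= s1:
                t = (score - s0) / (s1 - s0)
                rgb = (1 - t) * np.asarray(c0) + t * np.asarray(c1)
                return tuple(int(round(v)) for v in rgb)
        return tuple(pts[-1][1])  # unreachable


def render_overlay(img: np.ndarray, records: Sequence[SegmentRecord],
                   scale: ColorScale | None = None,
                   dot_radius: int | None = None) -> np.ndarray:
    """Return a copy of ``img`` with one score dot per segment.

    Dots sit at the segment's left edge, vertically centered.  Flagged
    segments use the flag color; insufficient-tissue segments a gray
    marker; all others the ramp color of their normalized score.
    """
    scale = scale or ColorScale()
    out = np.asarray(img).copy()
    if not records:
        return out
    seg_h = records[0].y1 - records[0].y0
    radius = dot_radius if dot_radius is not None else max(2, seg_h // 6)
    if radius < 1:
        raise ValueError("dot_radius must be >= 1")
    if 2 * radius > min(seg_h, records[0].x1 - records[0].x0):
        logger.warning("dot radius %d exceeds segment size; dots are clipped",
                       radius)
    for rec in records:
        if rec.status == FLAGGED:
            color = scale.flag_color
        elif rec.status == INSUFFICIENT:
            color = GRAY
        else:
            color = scale.color(rec.b1_normalized)
        cy = (rec.y0 + rec.y1) / 2
        cx = rec.x0 + radius
        rr, cc = draw_disk((cy, cx), radius, shape=out.shape[:2])
        out[rr, cc] = color
    return out


def render_colorbar(scale: ColorScale | None = None, size: int = 256,
                    width: int = 24) -> np.ndarray:
    """Vertical color-bar strip: flag color at top, ramp minimum at bottom."""
    scale = scale or ColorScale()
    if size < 10:
        raise ValueError("color bar size must be >= 10")
    lo = scale.breakpoints[0][0]
    hi = scale.breakpoints[-1][0]
    span = hi - lo
    bar = np.empty((size, width, 3), dtype=np.uint8)
    for i in range(size):
        if i == 0:
            score = hi + 1.0  # top row: past the clamp, i.e. the flag color
        else:
            score = lo + (1.0 - i / (size - 1)) * span
        bar[i, :] = scale.color(score)
    return bar
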