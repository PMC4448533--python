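"""Segment-grid scoring and flagging of a binarized tile.

The tile is partitioned into a rows x cols grid (default 14 x 14) with
half-open pixel bounds; each segment is scored independently:

* ``b0``, ``b1`` of the foreground restricted to the segment, with holes
  evaluated against the segment's own border;
* the non-blank ratio (tissue fraction) of the segment;
* the normalized score ``b1_normalized = b1 / nonblank_ratio``.

A segment is *flagged* when its normalized score strictly exceeds the
threshold (default 30).  Segments with tissue fraction below ``min_tissue``
are reported as ``insufficient_tissue`` and never flagged: dividing a small
b1 by a near-zero tissue fraction produces spuriously high scores on
almost-blank glass (the numerical-artifact failure mode), and the guard
neutralizes it.  Setting ``min_tissue = 0`` disables the guard and
reproduces the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .homology import betti_numbers

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_TISSUE",
    "SegmentBounds",
    "SegmentRecord",
    "ImageVerdict",
    "make_grid",
    "score_segment",
    "score_image",
    "flag_segments",
    "image_verdict",
]

DEFAULT_GRID = 14
DEFAULT_THRESHOLD = 30.0
DEFAULT_MIN_TISSUE = 0.05

FLAGGED = "flagged"
UNFLAGGED = "unflagged"
INSUFFICIENT = "insufficient_tissue"


@dataclass(frozen=True)
class SegmentBounds:
    """Half-open pixel bounds of one grid cell (0-based)."""

    row: int
    col: int
    x0: int
    x1: int
    y0: int
    y1: int


@dataclass(frozen=True)
class SegmentRecord:
    """Score record for one grid segment."""

    row: int
    col: int
    x0: int
    x1: int
    y0: int
    y1: int
    b0: int
    b1: int
    nonblank_ratio: float
    b1_normalized: float
    status: str


@dataclass(frozen=True)
class ImageVerdict:
    """Image-level screening verdict: positive iff any segment is flagged."""

    positive: bool
    n_flagged: int
    n_insufficient: int


def _partition(extent: int, n: int) -> list[int]:
    # boundary j = round(j * extent / n), half-up
    return [int(math.floor(j * extent / n + 0.5)) for j in range(n + 1)]


def make_grid(width: int, height: int, rows: int = DEFAULT_GRID,
              cols: int = DEFAULT_GRID) -> list[SegmentBounds]:
    """Partition a width x height image into a rows x cols segment grid.

    Column boundary j sits at round(j * width / cols) (likewise rows), so
    the half-open segments tile the image exactly with no gaps or overlaps.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if rows > height or cols > width:
        raise ValueError(
            f"grid {rows}x{cols} does not fit a {height}x{width} image"
        )
    xb = _partition(width, cols)
    yb = _partition(height, rows)
    return [
        SegmentBounds(r, c, xb[c], xb[c + 1], yb[r], yb[r + 1])
        for r in range(rows)
        for c in range(cols)
    ]


def score_segment(fg: np.ndarray, blanks: np.ndarray, bounds: SegmentBounds,
                  min_tissue: float = DEFAULT_MIN_TISSUE) -> SegmentRecord:
    """Score one segment of a binarized tile.

    Betti numbers are computed on the foreground cropped to the segment, so
    complement regions touching the segment border never count as holes.
    When the tissue fraction falls below ``min_tissue`` the segment is
    marked ``insufficient_tissue``: raw b0/b1 are retained but the
    normalized score is reported as 0.
    """
    fg = np.asarray(fg, dtype=bool)
    blanks = np.asarray(blanks, dtype=bool)
    if fg.shape != blanks.shape:
        raise ValueError("foreground and blank masks must share dimensions")
    sub_fg = fg[bounds.y0:bounds.y1, bounds.x0:bounds.x1]
    sub_blank = blanks[bounds.y0:bounds.y1, bounds.x0:bounds.x1]
    if sub_fg.size == 0:
        raise ValueError(f"empty segment bounds: {bounds}")

    pair = betti_numbers(sub_fg)
    ratio = float(1.0 - sub_blank.mean())

    if ratio < min_tissue or ratio == 0.0:
        status = INSUFFICIENT
        normalized = 0.0
    else:
        status = UNFLAGGED
        normalized = pair.b1 / ratio
    return SegmentRecord(
        row=bounds.row, col=bounds.col,
        x0=bounds.x0, x1=bounds.x1, y0=bounds.y0, y1=bounds.y1,
        b0=pair.b0, b1=pair.b1,
        nonblank_ratio=ratio, b1_normalized=normalized, status=status,
    )


def flag_segments(records: Sequence[SegmentRecord],
                  threshold: float = DEFAULT_THRESHOLD) -> list[SegmentRecord]:
    """Mark segments whose normalized score strictly exceeds the threshold.

    ``insufficient_tissue`` records pass through unchanged regardless of
    their raw values.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    out = []
    for rec in records:
        if rec.status == INSUFFICIENT:
            out.append(rec)
        else:
            status = FLAGGED if rec.b1_normalized > threshold else UNFLAGGED
            out.append(replace(rec, status=status))
    return out


def score_image(fg: np.ndarray, blanks: np.ndarray,
                rows: int = DEFAULT_GRID, cols: int = DEFAULT_GRID,
                threshold: float = DEFAULT_THRESHOLD,
                min_tissue: float = DEFAULT_MIN_TISSUE,
                normalize: bool = True) -> list[SegmentRecord]:
    """Grid-score a tile end to end: partition, score, flag.

    With ``normalize=False`` the raw b1 is compared against the threshold
    instead of the tissue-fraction-normalized score.
    """
    fg = np.asarray(fg, dtype=bool)
    h, w = fg.shape
    records = [
        score_segment(fg, blanks, b, min_tissue=min_tissue)
        for b in make_grid(w, h, rows, cols)
    ]
    if not normalize:
        records = [
            rec if rec.status == INSUFFICIENT else replace(rec, b1_normalized=float(rec.b1))
            for rec in records
        ]
    return flag_segments(records, threshold)


def image_verdict(records: Sequence[SegmentRecord]) -> ImageVerdict:
    """Aggregate segment records: positive iff at least one flagged segment."""
    if not records:
        raise ValueError("cannot form a verdict from an empty record list")
    n_flagged = sum(r.status == FLAGGED for r in records)
    n_insufficient = sum(r.status == INSUFFICIENT for r in records)
    return ImageVerdict(n_flagged >= 1, n_flagged, n_insufficient)
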