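"""Segment grid construction, scoring, flagging, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bettiscan.grid import (
    FLAGGED,
    INSUFFICIENT,
    UNFLAGGED,
    SegmentBounds,
    flag_segments,
    image_verdict,
    make_grid,
    score_image,
    score_segment,
)


class TestMakeGrid:
    def test_exact_division(self):
        segs = make_grid(28, 28, 14, 14)
        assert len(segs) == 196
        assert all(s.x1 - s.x0 == 2 and s.y1 - s.y0 == 2 for s in segs)

    def test_even_split_10(self):
        segs = make_grid(10, 10, 2, 2)
        xb = sorted({s.x0 for s in segs} | {s.x1 for s in segs})
        assert xb == [0, 5, 10]

    def test_rounded_boundaries_15_by_4(self):
        segs = make_grid(15, 15, 4, 4)
        xb = sorted({s.x0 for s in segs} | {s.x1 for s in segs})
        assert xb == [0, 4, 8, 11, 15]

    @given(st.integers(1, 300), st.integers(1, 300),
           st.integers(1, 20), st.integers(1, 20))
    @settings(deadline=None, derandomize=True)
    def test_tiles_exactly(self, w, h, rows, cols):
        if rows > h or cols > w:
            with pytest.raises(ValueError):
                make_grid(w, h, rows, cols)
            return
        segs = make_grid(w, h, rows, cols)
        area = np.zeros((h, w), dtype=int)
        for s in segs:
            assert s.x0 < s.x1 and s.y0 < s.y1
            area[s.y0:s.y1, s.x0:s.x1] += 1
        assert (area == 1).all()


def _bounds(x0, x1, y0, y1, row=0, col=0):
    return SegmentBounds(row, col, x0, x1, y0, y1)


class TestScoreSegment:
    def test_full_tissue_normalization_is_identity(self, ring_mask):
        fg = np.zeros((9, 9), bool)
        fg[:3, :3] = ring_mask
        blanks = np.zeros((9, 9), bool)
        rec = score_segment(fg, blanks, _bounds(0, 9, 0, 9))
        assert rec.b1 == 1
        assert rec.nonblank_ratio == 1.0
        assert rec.b1_normalized == rec.b1

    def test_half_blank_doubles_score(self, ring_mask):
        fg = np.zeros((4, 8), bool)
        fg[:3, :3] = ring_mask
        blanks = np.zeros((4, 8), bool)
        blanks[:, 4:] = True
        rec = score_segment(fg, blanks, _bounds(0, 8, 0, 4))
        assert rec.nonblank_ratio == pytest.approx(0.5)
        assert rec.b1_normalized == pytest.approx(2 * rec.b1)

    def test_insufficient_tissue_guard(self):
        fg = np.zeros((10, 10), bool)
        fg[0, 0] = True
        blanks = np.ones((10, 10), bool)
        blanks[0, 0] = False  # ratio 0.01
        rec = score_segment(fg, blanks, _bounds(0, 10, 0, 10), min_tissue=0.05)
        assert rec.status == INSUFFICIENT
        assert rec.b1_normalized == 0.0
        assert rec.b0 == 1  # raw values retained

    def test_holes_evaluated_within_segment_border(self, ring_mask):
        """A ring cut in half by the segment boundary encloses nothing."""
        fg = np.zeros((3, 6), bool)
        fg[:, :3] = ring_mask
        blanks = np.zeros((3, 6), bool)
        left = score_segment(fg, blanks, _bounds(0, 2, 0, 3))
        assert left.b1 == 0

    def test_locality(self, rng, ring_mask):
        """Pixels outside a segment never change its record."""
        fg = np.zeros((20, 20), bool)
        fg[4:7, 4:7] = ring_mask
        blanks = np.zeros((20, 20), bool)
        b = _bounds(0, 10, 0, 10)
        before = score_segment(fg, blanks, b)
        fg2 = fg.copy()
        fg2[:, 10:] = rng.random((20, 10)) < 0.5
        blanks2 = blanks.copy()
        blanks2[:, 10:] = ~fg2[:, 10:]
        assert score_segment(fg2, blanks2, b) == before


class TestFlagging:
    def _rec(self, score, status=UNFLAGGED):
        fg = np.zeros((4, 4), bool)
        blanks = np.zeros((4, 4), bool)
        base = score_segment(fg, blanks, _bounds(0, 4, 0, 4))
        from dataclasses import replace
        return replace(base, b1_normalized=score, status=status)

    def test_strict_inequality_at_threshold(self):
        recs = flag_segments([self._rec(30.0), self._rec(31.0)], threshold=30)
        assert recs[0].status == UNFLAGGED
        assert recs[1].status == FLAGGED

    def test_insufficient_guard_precedence(self):
        rec = self._rec(1e9, status=INSUFFICIENT)
        assert flag_segments([rec], threshold=30)[0].status == INSUFFICIENT

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1,
                    max_size=30),
           st.floats(0, 100), st.floats(0, 100))
    @settings(deadline=None, derandomize=True)
    def test_raising_threshold_never_flags_more(self, scores, t1, t2):
        lo, hi = sorted([t1, t2])
        recs = [self._rec(s) for s in scores]
        n_lo = sum(r.status == FLAGGED for r in flag_segments(recs, lo))
        n_hi = sum(r.status == FLAGGED for r in flag_segments(recs, hi))
        assert n_hi <= n_lo


class TestVerdict:
    def test_negative_without_flags(self):
        recs = flag_segments([TestFlagging()._rec(1.0)])
        v = image_verdict(recs)
        assert not v.positive and v.n_flagged == 0

    def test_counts(self):
        f = TestFlagging()
        recs = [f._rec(50.0)] * 5 + [f._rec(0.0, status=INSUFFICIENT)] * 3
        v = image_verdict(flag_segments(recs))
        assert v.positive and v.n_flagged == 5 and v.n_insufficient == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            image_verdict([])


def test_score_image_normalization_monotonicity(ring_mask):
    """For fixed b1 > 0 the normalized score strictly decreases as the
    tissue fraction grows."""
    fg = np.zeros((6, 6), bool)
    fg[:3, :3] = ring_mask
    scores = []
    for n_blank in (27, 18, 9, 0):
        blanks = np.zeros(36, bool)
        blanks[-n_blank:] = n_blank > 0
        rec = score_segment(fg, blanks.reshape(6, 6), _bounds(0, 6, 0, 6))
        scores.append(rec.b1_normalized)
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_score_image_area_partition(rng):
    fg = rng.random((50, 70)) < 0.3
    blanks = rng.random((50, 70)) < 0.2
    recs = score_image(fg, blanks, rows=7, cols=9)
    assert len(recs) == 63
    total = sum((r.x1 - r.x0) * (r.y1 - r.y0) for r in recs)
    assert total == 50 * 70
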