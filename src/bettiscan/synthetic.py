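"""Seeded synthetic H&E-like tiles and exact binary test patterns.

No public dataset accompanies the colonic screening benchmark, so this
module generates the phenotypes the homology screen discriminates:

* ``normal_mucosa`` — gland rings of well-spaced dark nuclei around white
  lumina on pink stroma; nuclei stay isolated, so segments show high b0 and
  near-zero b1.
* ``adenocarcinoma`` — a compact sheet of crowded, mutually touching nuclei
  whose interstices remain uncovered: a fenestrated sheet with many small
  windows (high b1).  Models the loss of contact inhibition: enlarged,
  pseudo-stratified nuclei fuse into one component and isolated-component
  count converts into window count.
* ``inflammation`` — dense small round cells in aggregates whose packing
  density varies from tile to tile, straddling the flagging threshold: an
  intended benign false-positive phenotype (lymphocyte aggregation).
* ``blank_margin`` — mostly bare glass with a narrow tissue strip and a few
  tiny ring-shaped debris specks; exercises the near-zero tissue-fraction
  normalization artifact.
* ``folded_artifact`` — normal tissue plus a band of doubled-over tissue
  rendered as a dark fenestrated sheet; folded regions score high, another
  benign-positive mode.

All randomness flows from ``SyntheticTissueSpec.seed``; the same spec
object always renders the same tile.  ``generate_pattern`` builds binary
masks whose Betti numbers are known exactly from the construction, for use
as homology test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .homology import BettiPair

__all__ = [
    "PHENOTYPES",
    "SyntheticTissueSpec",
    "BinaryPatternSpec",
    "generate_tile",
    "generate_pattern",
    "generate_cohort",
]

PHENOTYPES = (
    "normal_mucosa",
    "adenocarcinoma",
    "inflammation",
    "blank_margin",
    "folded_artifact",
)

# Stain palette chosen so the default blank level (220) and automatic
# binarization separate glass / stroma / nuclei cleanly.
NUCLEUS_RGB = (64, 32, 128)
STROMA_RGB = (230, 170, 190)
GLASS_RGB = (250, 250, 250)
FOLD_STROMA_RGB = (120, 60, 140)  # doubled-over tissue, hematoxylin-dark


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Parameters of one synthetic tile.

    ``contact_prob`` controls how likely neighboring nuclei are to touch;
    the adenocarcinoma default (0.95) far exceeds the normal-mucosa default
    (0.05), encoding the increased nuclear contact of tumor tissue.
    ``n_nuclei`` is matched across phenotypes by default so that normal and
    tumor tiles differ in arrangement, not in nuclear count.
    """

    phenotype: str = "normal_mucosa"
    width: int = 512
    height: int = 512
    n_nuclei: int = 600
    nucleus_radius_range: tuple[float, float] = (2.5, 3.5)
    contact_prob: float | None = None
    seed: int = 0
    stain_colors: dict = field(default_factory=lambda: {
        "nucleus": NUCLEUS_RGB, "stroma": STROMA_RGB, "background": GLASS_RGB,
    })

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )
        if self.width < 64 or self.height < 64:
            raise ValueError("tile dimensions must be at least 64x64")

    @property
    def effective_contact_prob(self) -> float:
        if self.contact_prob is not None:
            return self.contact_prob
        return {"adenocarcinoma": 0.95, "inflammation": 0.5}.get(self.phenotype, 0.05)


# --------------------------------------------------------------------------
# rendering helpers

def _canvas(spec: SyntheticTissueSpec, rng: np.random.Generator,
            base: tuple[int, int, int]) -> np.ndarray:
    img = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    img[:] = base
    img += rng.normal(0.0, 2.0, size=img.shape)
    return img


def _paint_disk(img: np.ndarray, r: float, c: float, radius: float,
                color: tuple[int, int, int], rng: np.random.Generator) -> None:
    rr, cc = draw_disk((r, c), radius, shape=img.shape[:2])
    img[rr, cc] = np.asarray(color) + rng.normal(0.0, 4.0, size=(rr.size, 3))


def _paint_ellipse(img: np.ndarray, r: float, c: float, a: float, b: float,
                   rot: float, color: tuple[int, int, int],
                   rng: np.random.Generator) -> None:
    rr, cc = draw_ellipse(r, c, a, b, shape=img.shape[:2], rotation=rot)
    img[rr, cc] = np.asarray(color) + rng.normal(0.0, 4.0, size=(rr.size, 3))


def _finalize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _gland_positions(spec_w: int, spec_h: int, spacing: float,
                     rng: np.random.Generator, margin: float) -> Iterator[tuple[float, float]]:
    ny = int((spec_h - 2 * margin) // spacing) + 1
    nx = int((spec_w - 2 * margin) // spacing) + 1
    for iy in range(ny):
        for ix in range(nx):
            yield (
                margin + iy * spacing + rng.uniform(-4, 4),
                margin + ix * spacing + rng.uniform(-4, 4),
            )


def _draw_gland(img: np.ndarray, cy: float, cx: float, n_nuclei: int,
                nucleus_r: float, rng: np.random.Generator,
                lumen_radius: float = 8.0, ring_radius: float = 13.0) -> int:
    """One colonic crypt cross-section: white lumen, ring of spaced nuclei."""
    _paint_disk(img, cy, cx, lumen_radius, GLASS_RGB, rng)
    phase = rng.uniform(0, 2 * np.pi)
    drawn = 0
    for k in range(n_nuclei):
        ang = phase + 2 * np.pi * k / n_nuclei + rng.normal(0, 0.04)
        ny = cy + ring_radius * np.sin(ang)
        nx = cx + ring_radius * np.cos(ang)
        # tangentially oriented elongated nuclei, radially polarized
        _paint_ellipse(img, ny, nx, nucleus_r + 0.8, nucleus_r - 0.6,
                       -ang, NUCLEUS_RGB, rng)
        drawn += 1
    return drawn


def _render_normal(spec: SyntheticTissueSpec, rng: np.random.Generator,
                   region: tuple[int, int, int, int] | None = None,
                   n_nuclei: int | None = None) -> np.ndarray:
    img = _canvas(spec, rng, STROMA_RGB)
    y0, y1, x0, x1 = region or (0, spec.height, 0, spec.width)
    n_target = spec.n_nuclei if n_nuclei is None else n_nuclei
    per_gland = 9
    spacing = max(40.0, np.sqrt((y1 - y0) * (x1 - x0) * per_gland / max(n_target, 1)))
    nucleus_r = float(np.mean(spec.nucleus_radius_range))
    placed = 0
    for cy, cx in _gland_positions(x1 - x0, y1 - y0, spacing, rng, margin=20):
        if placed >= n_target:
            break
        placed += _draw_gland(img, y0 + cy, x0 + cx, per_gland, nucleus_r, rng)
    return img


def _fenestrated_sheet(img: np.ndarray, cy: float, cx: float, half: float,
                       spacing: float, radius: float, jitter: float,
                       rng: np.random.Generator,
                       color: tuple[int, int, int] = NUCLEUS_RGB,
                       n_max: int | None = None) -> int:
    """Crowded nuclei on a jittered lattice: touching disks, open interstices."""
    n = 0
    ny = int(2 * half // spacing)
    nx = int(2 * half // spacing)
    for iy in range(ny):
        for ix in range(nx):
            if n_max is not None and n >= n_max:
                return n
            y = cy - half + (iy + 0.5) * spacing + rng.uniform(-jitter, jitter)
            x = cx - half + (ix + 0.5) * spacing + rng.uniform(-jitter, jitter)
            if (y - cy) ** 2 + (x - cx) ** 2 > half ** 2 * 1.05:
                continue
            _paint_disk(img, y, x, radius, color, rng)
            n += 1
    return n


def _render_adenocarcinoma(spec: SyntheticTissueSpec,
                           rng: np.random.Generator) -> np.ndarray:
    img = _canvas(spec, rng, STROMA_RGB)
    spacing = 5.0
    # sheet sized so the nuclear count matches the normal preset, clamped
    # to fit small canvases
    half = float(np.sqrt(spec.n_nuclei * spacing ** 2) / 2) * 1.2
    half = min(half, min(spec.height, spec.width) / 2 - 12)
    cy = rng.uniform(half + 10, spec.height - half - 10)
    cx = rng.uniform(half + 10, spec.width - half - 10)
    jitter = 1.0 * spec.effective_contact_prob
    _fenestrated_sheet(img, cy, cx, half, spacing,
                       radius=float(np.mean(spec.nucleus_radius_range)),
                       jitter=jitter, rng=rng, n_max=spec.n_nuclei)
    return img


def _render_inflammation(spec: SyntheticTissueSpec,
                         rng: np.random.Generator) -> np.ndarray:
    img = _canvas(spec, rng, STROMA_RGB)
    # aggregate packing density varies tile to tile: scores straddle the
    # flagging threshold, producing an intermediate positive rate
    spacing = rng.uniform(4.4, 6.0)
    n_aggregates = rng.integers(3, 6)
    remaining = spec.n_nuclei
    for _ in range(int(n_aggregates)):
        half = rng.uniform(30, 50)
        cy = rng.uniform(half, spec.height - half)
        cx = rng.uniform(half, spec.width - half)
        drawn = _fenestrated_sheet(img, cy, cx, half, spacing, radius=2.4,
                                   jitter=0.6, rng=rng, n_max=remaining)
        remaining -= drawn
        if remaining <= 0:
            break
    return img


def _render_blank_margin(spec: SyntheticTissueSpec,
                         rng: np.random.Generator) -> np.ndarray:
    img = _canvas(spec, rng, GLASS_RGB)
    # narrow tissue strip on the left edge
    strip_w = int(spec.width * 0.12)
    img[:, :strip_w] = np.asarray(STROMA_RGB) + rng.normal(
        0.0, 2.0, size=(spec.height, strip_w, 3))
    # a handful of gland rings inside the strip
    for cy in np.linspace(30, spec.height - 30, 5):
        _draw_gland(img, float(cy) + rng.uniform(-5, 5),
                    strip_w / 2 + rng.uniform(-3, 3), 9, 3.0, rng)
    # tiny ring-shaped debris specks on otherwise bare glass: with the
    # tissue-fraction guard off these reproduce the normalization artifact
    seg = spec.width / 14.0
    for k in range(4):
        col = 6 + 2 * k
        row = int(rng.integers(2, 12))
        cy = (row + 0.5) * spec.height / 14.0
        cx = (col + 0.5) * seg
        rr, cc = draw_disk((cy, cx), 4.0, shape=img.shape[:2])
        img[rr, cc] = np.asarray(NUCLEUS_RGB) + rng.normal(0, 4, (rr.size, 3))
        rr, cc = draw_disk((cy, cx), 2.4, shape=img.shape[:2])
        img[rr, cc] = np.asarray(GLASS_RGB) + rng.normal(0, 2, (rr.size, 3))
    return img


def _render_folded(spec: SyntheticTissueSpec,
                   rng: np.random.Generator) -> np.ndarray:
    img = _render_normal(spec, rng, n_nuclei=spec.n_nuclei // 2)
    # doubled-over band: hematoxylin-dark sheet with fine interstitial
    # clefts left by the two tissue layers
    band_w = int(spec.width * 0.22)
    x0 = int(rng.uniform(0.15, 0.6) * spec.width)
    band = img[:, x0:x0 + band_w]
    band[:] = np.asarray(FOLD_STROMA_RGB) + rng.normal(0, 4, band.shape)
    for y in np.arange(3.0, spec.height - 3, 6.0):
        for x in np.arange(3.0, band_w - 3, 6.0):
            yy = y + rng.uniform(-0.8, 0.8)
            xx = x + rng.uniform(-0.8, 0.8)
            rr, cc = draw_disk((yy, xx), 1.4, shape=band.shape[:2])
            band[rr, cc] = np.asarray(STROMA_RGB) + rng.normal(0, 3, (rr.size, 3))
    return img


_RENDERERS = {
    "normal_mucosa": _render_normal,
    "adenocarcinoma": _render_adenocarcinoma,
    "inflammation": _render_inflammation,
    "blank_margin": _render_blank_margin,
    "folded_artifact": _render_folded,
}


def generate_tile(spec: SyntheticTissueSpec) -> tuple[np.ndarray, str, bool]:
    """Render one synthetic tile.

    Returns ``(image, condition, roi)`` where ``condition`` is ``"cancer"``
    for adenocarcinoma and ``"benign"`` otherwise, and ``roi`` is True for
    every phenotype except bare-glass ``blank_margin``.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    img = _finalize(_RENDERERS[spec.phenotype](spec, rng))
    condition = "cancer" if spec.phenotype == "adenocarcinoma" else "benign"
    roi = spec.phenotype != "blank_margin"
    return img, condition, roi


def generate_cohort(phenotypes: dict[str, int], seed: int = 0,
                    **spec_kwargs) -> list[tuple[str, np.ndarray, str, bool]]:
    """Render a labeled cohort: ``phenotypes`` maps phenotype -> tile count.

    Tile k of a phenotype uses seed ``seed + k`` offset by a stable
    per-phenotype stride, so cohorts are reproducible and tiles distinct.
    Returns ``(image_id, image, condition, roi)`` tuples.
    """
    out = []
    for p_idx, (phenotype, count) in enumerate(sorted(phenotypes.items())):
        for k in range(count):
            tile_seed = (seed + 7919 * p_idx + k) % (2 ** 31)
            spec = SyntheticTissueSpec(phenotype=phenotype, seed=tile_seed,
                                       **spec_kwargs)
            img, condition, roi = generate_tile(spec)
            out.append((f"{phenotype}_{k:03d}", img, condition, roi))
    return out


# --------------------------------------------------------------------------
# exact binary patterns for homology tests

PATTERN_KINDS = ("disks", "rings", "ring_lattice", "checkerboard", "random")


@dataclass(frozen=True)
class BinaryPatternSpec:
    """A binary mask whose Betti numbers are certain by construction."""

    kind: str = "disks"
    n: int = 3                  # disks/rings: component count; lattice/board: cells per side
    size: int = 96              # canvas side (disks/rings/random)
    cell: int = 6               # lattice / checkerboard cell size
    radius: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.kind in ("rings", "random") and self.radius < 3.5:
            raise ValueError("ring patterns need radius >= 3.5 to stay closed")
        if self.kind in ("ring_lattice", "checkerboard") and self.cell < 2:
            raise ValueError("cell size must be >= 2")


def _place_disjoint(mask_shape: tuple[int, int], rings: list[bool],
                    radius: float, rng: np.random.Generator) -> np.ndarray:
    """Place shapes (disk or ring per flag) with >=3 px center clearance.

    Disjointness is enforced at placement time, never post-hoc, so the
    pattern's Betti numbers are certain.  Raises if the packing is
    infeasible within the attempt budget.
    """
    mask = np.zeros(mask_shape, dtype=bool)
    outer = radius
    if min(mask_shape) < 2 * outer + 6:
        raise ValueError(
            f"infeasible packing: radius {radius} shapes do not fit {mask_shape}")
    centers: list[tuple[float, float]] = []
    attempts = 0
    for is_ring in rings:
        while True:
            attempts += 1
            if attempts > 2000 * len(rings):
                raise ValueError(
                    f"infeasible packing: cannot place {len(rings)} shapes of "
                    f"radius {radius} in {mask_shape}")
            y = rng.uniform(outer + 2, mask_shape[0] - outer - 2)
            x = rng.uniform(outer + 2, mask_shape[1] - outer - 2)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= (2 * outer + 3) ** 2
                   for cy, cx in centers):
                break
        centers.append((y, x))
        rr, cc = draw_disk((y, x), outer, shape=mask_shape)
        mask[rr, cc] = True
        if is_ring:
            rr, cc = draw_disk((y, x), max(outer - 2.0, 1.0), shape=mask_shape)
            mask[rr, cc] = False
    return mask


def _ring_lattice(n: int, cell: int) -> np.ndarray:
    """An n x n grid of fused square rings sharing walls: b0=1, b1=n*n."""
    side = n * cell + 1
    mask = np.zeros((side, side), dtype=bool)
    mask[::cell, :] = True
    mask[:, ::cell] = True
    return mask


def _checkerboard(n: int, cell: int) -> tuple[np.ndarray, BettiPair]:
    board = np.add.outer(np.arange(n), np.arange(n)) % 2 == 0
    mask = np.kron(board, np.ones((cell, cell), dtype=bool))
    # all true cells join through shared corners: exactly one component
    b0 = 1
    # holes: false cells strictly interior to the board (false blocks are
    # 4-disconnected from each other, so each is its own hole)
    if n > 2:
        b1 = int((~board[1:-1, 1:-1]).sum())
    else:
        b1 = 0
    return mask, BettiPair(b0, b1)


def generate_pattern(spec: BinaryPatternSpec) -> tuple[np.ndarray, BettiPair]:
    """Build a binary mask together with its exact expected Betti pair.

    Disjointness of placed shapes is enforced by construction (minimum
    clearance between bounding circles), so the expected values are certain
    without running any homology computation.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.size, spec.size)
    if spec.kind == "disks":
        mask = _place_disjoint(shape, [False] * spec.n, spec.radius, rng)
        return mask, BettiPair(spec.n, 0)
    if spec.kind == "rings":
        mask = _place_disjoint(shape, [True] * spec.n, spec.radius, rng)
        return mask, BettiPair(spec.n, spec.n)
    if spec.kind == "ring_lattice":
        return _ring_lattice(spec.n, spec.cell), BettiPair(1, spec.n * spec.n)
    if spec.kind == "checkerboard":
        return _checkerboard(spec.n, spec.cell)
    # random: a disjoint mixture of disks and rings in random order
    n_rings = int(rng.integers(0, spec.n + 1))
    flags = [True] * n_rings + [False] * (spec.n - n_rings)
    rng.shuffle(flags)
    mask = _place_disjoint(shape, flags, spec.radius, rng)
    return mask, BettiPair(spec.n, n_rings)
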