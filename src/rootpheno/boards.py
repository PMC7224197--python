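"""Synthetic root-board images with analytically known geometry.

Emulates field photographs of storage roots laid out on a green board with
painted reference circles of known diameter.  Roots are drawn as rotated
superellipses (exponent 2 = ellipse; larger exponents approach rectangular,
blockier outlines), circles as disks.  Background, roots and circles occupy
disjoint hue bands so that the hue-threshold segmentation used on real
photographs applies unchanged.

Every drawn object carries analytic ground truth (area, perimeter, maximum
caliper, axes) computed from the generating shape equations rather than from
pixels, so the measurement chain can be validated against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma
from skimage.color import hsv2rgb

__all__ = ["RootShape", "BoardSpec", "BoardImage", "generate_board_image"]


@dataclass(frozen=True)
class RootShape:
    """One root outline: a superellipse with semi-axes in cm.

    ``|x/a|^n + |y/b|^n <= 1`` in the root's own frame, rotated by ``theta``
    radians.  ``exponent`` = 2 gives an ellipse; values in (2, 6] give
    progressively blockier, more cylindrical roots.
    """

    a_cm: float
    b_cm: float
    theta: float = 0.0
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.a_cm <= 0 or self.b_cm <= 0:
            raise ValueError("semi-axes must be positive")
        if self.exponent <= 0:
            raise ValueError("superellipse exponent must be positive")


@dataclass
class BoardSpec:
    """Parameters of one simulated board photograph.

    The physical board is ``board_width_px / px_per_cm`` by
    ``board_height_px / px_per_cm`` cm; the true ``px_per_cm`` is what the
    scale-circle detector must recover downstream.
    """

    board_width_px: int = 1600
    board_height_px: int = 1200
    px_per_cm: float = 10.0
    n_circles: int = 5
    circle_diameter_cm: float = 7.5
    n_roots: int = 6
    root_shape_params: list[RootShape] = field(default_factory=list)
    hue_background: int = 85
    hue_root: int = 20
    hue_circle: int = 180
    margin_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.circle_diameter_cm <= 0:
            raise ValueError("circle_diameter_cm must be positive")
        if self.n_roots < 0:
            raise ValueError("n_roots must be >= 0")
        for h in (self.hue_background, self.hue_root, self.hue_circle):
            if not 0 <= h <= 255:
                raise ValueError("hues must be in [0, 255]")


@dataclass
class BoardImage:
    """An RGB board raster plus identifying metadata."""

    rgb: np.ndarray  # (H, W, 3) uint8
    image_id: str = "board"
    plot_id: str = ""


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all objects."""


def _superellipse_area_cm2(a: float, b: float, n: float) -> float:
    # closed form via the beta/gamma function; n=2 reduces to pi*a*b
    return 4.0 * a * b * gamma(1 + 1 / n) ** 2 / gamma(1 + 2 / n)


def _superellipse_boundary(a: float, b: float, n: float, k: int = 4096) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    c, s = np.cos(t), np.sin(t)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / n)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / n)
    return np.column_stack([x, y])


def _superellipse_perimeter_cm(a: float, b: float, n: float) -> float:
    pts = _superellipse_boundary(a, b, n)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _superellipse_caliper_cm(a: float, b: float, n: float) -> float:
    # centrally symmetric convex body: max caliper = 2 * max radial distance
    pts = _superellipse_boundary(a, b, n)
    return float(2.0 * np.sqrt((pts**2).sum(axis=1).max()))


def default_root_shapes(n_roots: int, rng: np.random.Generator) -> list[RootShape]:
    """Draw realistic cassava-like root outlines.

    Semi-major axes 6-16 cm, aspect ratios 2-5 and exponents 2-4 span the
    conical to irregular/cylindrical outline classes; root areas then fall
    in roughly the 25-350 cm^2 range observed for field-grown storage roots.
    """
    shapes = []
    for _ in range(n_roots):
        a = rng.uniform(6.0, 16.0)
        ar = rng.uniform(2.0, 5.0)
        shapes.append(
            RootShape(
                a_cm=a,
                b_cm=a / ar,
                theta=rng.uniform(0.0, np.pi),
                exponent=rng.uniform(2.0, 4.0),
            )
        )
    return shapes


def _circle_positions(spec: BoardSpec) -> list[tuple[float, float]]:
    """Reference circles along the left and right board edges (alternating)."""
    r = spec.circle_diameter_cm * spec.px_per_cm / 2.0
    pad = r + spec.margin_px + 2.0
    xs = {0: pad, 1: spec.board_width_px - pad}
    n_left = (spec.n_circles + 1) // 2
    n_right = spec.n_circles - n_left
    pos = []
    for side, count in ((0, n_left), (1, n_right)):
        ys = np.linspace(pad, spec.board_height_px - pad, count) if count else []
        pos.extend((xs[side], float(y)) for y in ys)
    return pos


def _rasterize_superellipse(
    shape_mask: np.ndarray,
    cx: float,
    cy: float,
    a_px: float,
    b_px: float,
    theta: float,
    n: float,
) -> int:
    """Fill pixels whose centres lie inside the rotated superellipse."""
    h, w = shape_mask.shape
    rad = int(np.ceil(max(a_px, b_px))) + 2
    x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
    y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx + 0.5) - cx
    dy = (yy + 0.5) - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a_px
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b_px
    inside = np.abs(u) ** n + np.abs(v) ** n <= 1.0
    shape_mask[y0:y1, x0:x1] |= inside
    return int(inside.sum())


def generate_board_image(spec: BoardSpec, max_attempts: int = 2000) -> tuple[BoardImage, pd.DataFrame]:
    """Render one board and return the image plus analytic ground truth.

    Returns
    -------
    image : BoardImage
        8-bit RGB raster; background, roots and circles occupy the disjoint
        hue values given in ``spec``.
    ground_truth : pandas.DataFrame
        One row per drawn object with columns ``object_id, klass, area_cm2,
        perimeter_cm, feret_cm, major_cm, minor_cm, centroid_x_px,
        centroid_y_px``.  Geometry is analytic (shape equations), not pixel
        counting, and therefore independent of ``px_per_cm`` and ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shapes = list(spec.root_shape_params)
    if not shapes and spec.n_roots > 0:
        shapes = default_root_shapes(spec.n_roots, rng)
    if len(shapes) != spec.n_roots:
        raise ValueError(
            f"root_shape_params has {len(shapes)} entries but n_roots={spec.n_roots}"
        )

    h, w = spec.board_height_px, spec.board_width_px
    hue = np.full((h, w), spec.hue_background, dtype=np.uint8)

    records = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius px)

    # reference circles first, at fixed edge positions
    r_px = spec.circle_diameter_cm * spec.px_per_cm / 2.0
    circle_mask = np.zeros((h, w), bool)
    for i, (cx, cy) in enumerate(_circle_positions(spec)):
        _rasterize_superellipse(circle_mask, cx, cy, r_px, r_px, 0.0, 2.0)
        placed.append((cx, cy, r_px))
        d = spec.circle_diameter_cm
        records.append(
            dict(
                object_id=f"circle_{i}",
                klass="circle",
                area_cm2=np.pi * (d / 2) ** 2,
                perimeter_cm=np.pi * d,
                feret_cm=d,
                major_cm=d,
                minor_cm=d,
                centroid_x_px=cx,
                centroid_y_px=cy,
            )
        )
    hue[circle_mask] = spec.hue_circle

    root_mask = np.zeros((h, w), bool)
    for i, shp in enumerate(shapes):
        a_px = shp.a_cm * spec.px_per_cm
        b_px = shp.b_cm * spec.px_per_cm
        bound = max(a_px, b_px)
        pad = bound + spec.margin_px + 2.0
        if 2 * pad >= min(h, w):
            raise PlacementError(
                f"root {i} (bounding radius {bound:.0f} px) cannot fit on a "
                f"{w}x{h} px board"
            )
        for attempt in range(max_attempts):
            cx = rng.uniform(pad, w - pad)
            cy = rng.uniform(pad, h - pad)
            ok = all(
                np.hypot(cx - px, cy - py) > bound + pr + spec.margin_px
                for px, py, pr in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_roots} roots and {spec.n_circles} "
                f"circles on a {w}x{h} px board after {max_attempts} attempts"
            )
        _rasterize_superellipse(root_mask, cx, cy, a_px, b_px, shp.theta, shp.exponent)
        placed.append((cx, cy, bound))
        records.append(
            dict(
                object_id=f"root_{i}",
                klass="root",
                area_cm2=_superellipse_area_cm2(shp.a_cm, shp.b_cm, shp.exponent),
                perimeter_cm=_superellipse_perimeter_cm(shp.a_cm, shp.b_cm, shp.exponent),
                feret_cm=_superellipse_caliper_cm(shp.a_cm, shp.b_cm, shp.exponent),
                major_cm=2 * max(shp.a_cm, shp.b_cm),
                minor_cm=2 * min(shp.a_cm, shp.b_cm),
                centroid_x_px=cx,
                centroid_y_px=cy,
            )
        )
    hue[root_mask] = spec.hue_root

    hsv = np.stack(
        [hue / 255.0, np.full((h, w), 0.80), np.full((h, w), 0.85)], axis=-1
    )
    rgb = np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    gt = pd.DataFrame.from_records(records)
    return BoardImage(rgb=rgb, image_id=f"board_seed{spec.seed}"), gt
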