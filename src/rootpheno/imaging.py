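"""Hue-threshold segmentation and particle measurement for root boards.

The measurement chain mirrors the classic particle-analyzer workflow: an
RGB photograph is reduced to its hue channel, thresholded twice (a roots
pass and a reference-circle pass), contiguous white regions are extracted,
and each particle is summarised by seven size/shape descriptors: area,
perimeter, Feret (maximum caliper), circularity, roundness, solidity and
aspect ratio.  Painted circles of known diameter provide the pixel-to-cm
scaling coefficient ``sqrt(mean circle area in px^2 / circle area in cm^2)``.

Descriptor conventions
----------------------
* perimeter: Crofton 4-direction estimate by default (near-unbiased on
  smooth convex outlines); the Freeman chain-code (1 per axial step,
  sqrt(2) per diagonal) is available via ``perimeter_method="chain"``.
* ellipse axes: from the eigenvalues of the second central moment matrix,
  scaled so a filled ellipse recovers its semi-axes (semi-axis =
  2*sqrt(eigenvalue)).
* circularity = min(1, 4*pi*area/perimeter^2); roundness =
  4*area/(pi*major^2); solidity = area / convex hull area; AR = major/minor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure
from skimage.color import rgb2hsv
from skimage.morphology import convex_hull_image

from .boards import BoardImage

__all__ = [
    "PhenotypingConfig",
    "ScalingResult",
    "ScaleNotDetectedError",
    "rgb_to_hue",
    "binarize",
    "label_particles",
    "measure_particle",
    "detect_scale_circles",
    "phenotype_image",
]

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = [
    "particle_id", "pixel_count", "area", "perimeter", "feret",
    "major_axis", "minor_axis", "circularity", "roundness", "solidity",
    "aspect_ratio", "centroid_x", "centroid_y", "touches_border", "flags",
]


@dataclass
class PhenotypingConfig:
    """Tunable knobs of the measurement chain.

    Hue bounds follow the 0-255 hue convention.  The roots pass spans the
    whole hue range minus a background-exclusion band centred on the board's
    green; the circles pass keeps hue 125-255 as in the original protocol.
    """

    roots_band: tuple[int, int] = (0, 255)
    circles_band: tuple[int, int] = (125, 255)
    background_band: tuple[int, int] = (70, 100)
    min_area_px: int = 500
    circle_diameter_cm: float = 7.5
    circle_min_circularity: float = 0.85
    circle_area_tolerance: float = 0.25
    perimeter_method: str = "crofton"  # or "chain"


@dataclass
class ScalingResult:
    n_circles_used: int
    mean_circle_area_px: float
    scaling_coefficient: float  # px per cm


class ScaleNotDetectedError(RuntimeError):
    pass


@dataclass
class BinaryMask:
    mask: np.ndarray
    provenance: str
    bounds: tuple[int, int]


def rgb_to_hue(image: BoardImage | np.ndarray) -> np.ndarray:
    """Hue channel of an 8-bit RGB image, scaled to integers in [0, 255].

    Saturation and brightness are discarded.  Grey pixels (r = g = b) have
    undefined hue and map to 0 by convention.
    """
    rgb = image.rgb if isinstance(image, BoardImage) else image
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an RGB raster (H, W, 3), got shape {rgb.shape}")
    hue = rgb2hsv(rgb.astype(np.float64) / 255.0)[..., 0]
    return np.round(hue * 255.0).astype(np.uint8)


def binarize(
    hue: np.ndarray,
    lo: int,
    hi: int,
    background_band: tuple[int, int] | None = None,
    provenance: str = "",
) -> BinaryMask:
    """Threshold the hue raster: foreground = lo <= hue <= hi, background band excluded."""
    if lo > hi:
        raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
    fg = (hue >= lo) & (hue <= hi)
    if background_band is not None:
        b_lo, b_hi = background_band
        fg &= ~((hue >= b_lo) & (hue <= b_hi))
    return BinaryMask(mask=fg, provenance=provenance, bounds=(lo, hi))


@dataclass
class Particle:
    label: int
    mask: np.ndarray  # particle-local boolean patch
    offset: tuple[int, int]  # (row, col) of patch origin in the full image
    touches_border: bool


def label_particles(mask: BinaryMask | np.ndarray, min_area_px: int = 500) -> list[Particle]:
    """8-connected components of the binary mask, small specks discarded.

    Components touching the image border are kept in the list but flagged;
    callers exclude them from root tables (roots may not touch the board
    edge, and a clipped particle would be measured wrongly anyway).
    """
    m = mask.mask if isinstance(mask, BinaryMask) else mask
    lab = skmeasure.label(m, connectivity=2)
    h, w = m.shape
    out = []
    for region in skmeasure.regionprops(lab):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        out.append(
            Particle(
                label=region.label,
                mask=region.image.copy(),
                offset=(r0, c0),
                touches_border=touches,
            )
        )
    return out


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour (row, col)."""
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    return np.argwhere(boundary)


def _chain_code_perimeter(mask: np.ndarray) -> float:
    """Freeman chain-code length of the outer boundary (1 axial, sqrt2 diagonal).

    Moore-neighbour tracing of the outer contour of the (single) particle.
    """
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # top-most then left-most pixel
    if len(rows) == 1:
        return 4.0  # lone pixel: unit-square outline
    # clockwise Moore neighbourhood starting north
    nbrs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    weights = [1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)]
    cur = start
    back = 6  # backtrack direction: the background pixel west of the start
    # the walk is a deterministic map on (pixel, backtrack) states, so it is
    # eventually periodic; the outer boundary is the cycle it settles into
    seen: dict[tuple[tuple[int, int], int], float] = {(cur, back): 0.0}
    perim = 0.0
    while True:
        for k in range(1, 9):
            d = (back + k) % 8
            nxt = (cur[0] + nbrs[d][0], cur[1] + nbrs[d][1])
            if padded[nxt]:
                perim += weights[d]
                # backtrack for the next pixel: the last background cell
                # checked, expressed as a direction from `nxt`
                prev_bg = (cur[0] + nbrs[(d - 1) % 8][0], cur[1] + nbrs[(d - 1) % 8][1])
                back = nbrs.index((prev_bg[0] - nxt[0], prev_bg[1] - nxt[1]))
                cur = nxt
                break
        else:  # isolated pixel reached via a spur; outline closed here
            return perim + 4.0
        state = (cur, back)
        if state in seen:
            return perim - seen[state]
        seen[state] = perim


def _perimeter(mask: np.ndarray, method: str) -> float:
    if method == "chain":
        return _chain_code_perimeter(mask)
    if method == "crofton":
        return float(skmeasure.perimeter_crofton(mask, directions=4))
    raise ValueError(f"unknown perimeter method: {method!r}")


def feret_diameter(boundary: np.ndarray) -> float:
    """Maximum caliper: the largest pairwise distance between boundary pixels.

    Computed over the convex-hull vertices of the boundary point set, which
    attains the same maximum as the full all-pairs scan.
    """
    pts = np.asarray(boundary, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force over all of them
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def measure_particle(
    particle: Particle, config: PhenotypingConfig | None = None
) -> dict:
    """Seven size/shape descriptors of one particle, in pixel units."""
    config = config or PhenotypingConfig()
    mask = particle.mask
    area = float(mask.sum())
    perim = _perimeter(mask, config.perimeter_method)
    boundary = _boundary_pixels(mask)
    feret = feret_diameter(boundary)

    rows, cols = np.nonzero(mask)
    r_mean, c_mean = rows.mean(), cols.mean()
    dr, dc = rows - r_mean, cols - c_mean
    cov = np.array(
        [[np.mean(dc * dc), np.mean(dc * dr)], [np.mean(dc * dr), np.mean(dr * dr)]]
    )
    ev = np.linalg.eigvalsh(cov)  # ascending
    semi_minor = 2.0 * np.sqrt(max(ev[0], 0.0))
    semi_major = 2.0 * np.sqrt(max(ev[1], 0.0))
    flags = []
    if semi_minor < 0.5:
        semi_minor = 0.5
        flags.append("degenerate_minor_axis")
        warnings.warn("near-1D particle: minor axis floored at 0.5 px", stacklevel=2)
    major, minor = 2.0 * semi_major, 2.0 * semi_minor

    hull_area = float(convex_hull_image(mask).sum())
    circularity = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 0.0
    roundness = 4.0 * area / (np.pi * major**2) if major > 0 else 0.0
    solidity = min(1.0, area / hull_area) if hull_area > 0 else 0.0

    return dict(
        particle_id=particle.label,
        pixel_count=int(area),
        area=area,
        perimeter=perim,
        feret=feret,
        major_axis=major,
        minor_axis=minor,
        circularity=circularity,
        roundness=roundness,
        solidity=solidity,
        aspect_ratio=major / minor,
        centroid_x=c_mean + particle.offset[1],
        centroid_y=r_mean + particle.offset[0],
        touches_border=particle.touches_border,
        flags=";".join(flags),
    )


def detect_scale_circles(
    image: BoardImage | np.ndarray,
    circle_diameter_cm: float | None = None,
    config: PhenotypingConfig | None = None,
) -> ScalingResult:
    """Find the painted reference circles and derive the px/cm coefficient.

    Candidates come from the circles-pass threshold; they must be close to
    circular (circularity >= 0.85 by default) and mutually consistent in
    area (within 25% of the median candidate).  At least three accepted
    circles are required; the coefficient is
    ``sqrt(mean area px^2 / (pi (d/2)^2 cm^2))``.
    """
    config = config or PhenotypingConfig()
    d = circle_diameter_cm if circle_diameter_cm is not None else config.circle_diameter_cm
    hue = rgb_to_hue(image)
    mask = binarize(hue, *config.circles_band,
                    background_band=config.background_band, provenance="circles-pass")
    particles = [p for p in label_particles(mask, config.min_area_px)
                 if not p.touches_border]
    cands = [measure_particle(p, config) for p in particles]
    cands = [c for c in cands if c["circularity"] >= config.circle_min_circularity]
    if cands:
        med = float(np.median([c["area"] for c in cands]))
        cands = [c for c in cands
                 if abs(c["area"] - med) <= config.circle_area_tolerance * med]
    if len(cands) < 3:
        raise ScaleNotDetectedError(
            f"scale not detected: only {len(cands)} acceptable circle candidates"
        )
    mean_area = float(np.mean([c["area"] for c in cands]))
    coef = float(np.sqrt(mean_area / (np.pi * (d / 2.0) ** 2)))
    logger.info("scale: %d circles, mean area %.1f px^2, %.3f px/cm",
                len(cands), mean_area, coef)
    return ScalingResult(
        n_circles_used=len(cands), mean_circle_area_px=mean_area,
        scaling_coefficient=coef,
    )


def phenotype_image(
    image: BoardImage | np.ndarray,
    config: PhenotypingConfig | None = None,
    image_id: str | None = None,
    plot_id: str | None = None,
) -> pd.DataFrame:
    """Measure every root on one board and convert to cm units.

    Lengths are divided by the scaling coefficient and areas by its square.
    Border-touching particles are excluded (protocol: roots must not touch
    the board edge).  Returns an empty table when no roots are present.
    """
    config = config or PhenotypingConfig()
    if isinstance(image, BoardImage):
        image_id = image_id or image.image_id
        plot_id = plot_id or image.plot_id
    scale = detect_scale_circles(image, config=config)
    s = scale.scaling_coefficient

    hue = rgb_to_hue(image)
    mask = binarize(hue, *config.roots_band,
                    background_band=config.background_band, provenance="roots-pass")
    particles = label_particles(mask, config.min_area_px)
    n_border = sum(p.touches_border for p in particles)
    rows = [measure_particle(p, config) for p in particles if not p.touches_border]
    # the full-range roots pass also picks up the reference circles; drop
    # particles matching the detected circle signature (area and circularity)
    def _is_circle(r: dict) -> bool:
        return (
            r["circularity"] >= config.circle_min_circularity
            and abs(r["area"] - scale.mean_circle_area_px)
            <= config.circle_area_tolerance * scale.mean_circle_area_px
        )

    n_circ = sum(_is_circle(r) for r in rows)
    rows = [r for r in rows if not _is_circle(r)]
    logger.info(
        "image %s: %d roots kept, %d border-touching and %d circle-like dropped",
        image_id, len(rows), n_border, n_circ,
    )
    df = pd.DataFrame(rows, columns=MEASURE_COLUMNS)
    for col in ("perimeter", "feret", "major_axis", "minor_axis"):
        df[col] = df[col] / s
    df["area"] = df["area"] / s**2
    df.insert(0, "image_id", image_id or "")
    df.insert(1, "plot_id", plot_id or "")
    df.attrs["scaling"] = scale
    return df
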