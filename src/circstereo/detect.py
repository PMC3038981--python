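"""Detection of dark circular markers on a light background.

The measurement targets are black circles printed on white; their
perspective images are ellipses.  Detection proceeds in three steps:

1. a global gray-value threshold (Otsu) separates dark blobs,
2. each black/white boundary is traced as a sub-pixel contour
   (marching squares with linear interpolation of the threshold
   crossing),
3. a direct least-squares conic, constrained to an ellipse, is fitted to
   every contour.

Markers whose image is too slim (minor/major axis ratio below 0.2, i.e.
the marker plane nearly contains the viewing direction) or too small are
rejected, because the edge becomes dominated by uncertain gray values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel, find_contours

from .errors import InsufficientDataError, NonEllipseError

__all__ = [
    "ImageEllipse",
    "threshold_and_edges",
    "fit_ellipse",
    "accept_marker",
    "detect_markers",
    "read_image",
    "ellipses_to_frame",
    "frame_to_ellipses",
]

log = logging.getLogger(__name__)

#: minimum number of edge pixels for a usable contour
MIN_EDGE_PIXELS = 20
#: minimum admissible minor/major axis ratio ("slimness" criterion)
MIN_AXES_RATIO = 0.2


@dataclass(frozen=True)
class ImageEllipse:
    """A conic fitted to a marker edge, in pixel coordinates.

    ``orientation`` is the angle of the **major** axis, in ``[0, pi)``.
    ``semi_minor <= semi_major`` always holds.
    """

    centre: np.ndarray
    semi_minor: float
    semi_major: float
    orientation: float
    n_edge_pixels: int = 0
    residual_rms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        if not (0 < self.semi_minor <= self.semi_major):
            raise ValueError("require 0 < semi_minor <= semi_major")
        object.__setattr__(self, "orientation", float(self.orientation) % np.pi)

    @property
    def axes_ratio(self) -> float:
        """Minor-to-major axis ratio in ``(0, 1]``."""
        return self.semi_minor / self.semi_major


def read_image(path) -> np.ndarray:
    """Load an 8/16-bit gray or RGB image as a float gray array."""
    img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # RGB(A) -> luma
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return img


def threshold_and_edges(image: np.ndarray, min_edge_pixels: int = MIN_EDGE_PIXELS):
    """Sub-pixel edge point sets of the dark blobs in a gray image.

    Returns a list of ``(n, 2)`` arrays of ``(x, y)`` points ordered along
    each closed contour.  Blobs touching the image border (open contours)
    are discarded, as are contours shorter than ``min_edge_pixels``.
    A blob-free image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 1 and image.ndim != 2:
        raise ValueError("expected a single-channel image")
    if image.max() == image.min():
        return []
    level = threshold_otsu(image)
    contours = find_contours(image, level)
    out = []
    for c in contours:
        if not np.allclose(c[0], c[-1]):
            continue  # open contour: blob touches the border
        if len(c) < min_edge_pixels:
            log.info("contour with %d points below min_edge_pixels=%d skipped",
                     len(c), min_edge_pixels)
            continue
        pts = c[:-1][:, ::-1]  # drop duplicate endpoint, (row, col) -> (x, y)
        # keep only contours that enclose a *dark* region
        cy, cx = np.mean(c[:-1], axis=0)
        iy = int(round(np.clip(cy, 0, image.shape[0] - 1)))
        ix = int(round(np.clip(cx, 0, image.shape[1] - 1)))
        if image[iy, ix] >= level:
            continue
        out.append(pts)
    return out


def fit_ellipse(edge_points) -> ImageEllipse:
    """Direct least-squares ellipse fit to a set of edge points.

    The fit is performed on centred, isotropically scaled coordinates for
    numerical conditioning and mapped back, so that analytically sampled
    conic points are recovered essentially exactly.

    Raises
    ------
    InsufficientDataError
        Fewer than 6 points, or a collinear point set.
    NonEllipseError
        The best conic through the points is not an ellipse.
    """
    pts = np.asarray(edge_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise InsufficientDataError("need at least 6 edge points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    scale = np.sqrt((centred ** 2).sum(axis=1).mean())
    if scale == 0:
        raise InsufficientDataError("degenerate (coincident) points")
    norm = centred / scale

    with np.errstate(divide="ignore", invalid="ignore"):
        model = EllipseModel.from_estimate(norm)
    if not model:
        raise NonEllipseError("conic fit did not yield an ellipse")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise NonEllipseError("degenerate conic")
    residual = _sampson_rms(norm, xc, yc, a, b, theta) * scale

    centre = np.array([xc, yc]) * scale + centroid
    a, b = a * scale, b * scale
    if a >= b:
        semi_major, semi_minor, orient = a, b, theta
    else:
        semi_major, semi_minor, orient = b, a, theta + np.pi / 2
    return ImageEllipse(
        centre=centre,
        semi_minor=float(semi_minor),
        semi_major=float(semi_major),
        orientation=float(orient % np.pi),
        n_edge_pixels=len(pts),
        residual_rms=residual,
    )


def _sampson_rms(pts, xc, yc, a, b, theta) -> float:
    """First-order geometric (Sampson) RMS distance of points to an ellipse."""
    u = np.array([np.cos(theta), np.sin(theta)])
    v = np.array([-u[1], u[0]])
    d = pts - [xc, yc]
    s = (d @ u) / a
    t = (d @ v) / b
    f = s ** 2 + t ** 2 - 1.0
    gx = 2 * (s[:, None] * u / a + t[:, None] * v / b)
    gnorm = np.linalg.norm(gx, axis=1)
    gnorm[gnorm == 0] = 1.0
    return float(np.sqrt(np.mean((f / gnorm) ** 2)))


def accept_marker(e: ImageEllipse, min_ratio: float = MIN_AXES_RATIO,
                  min_edge_pixels: int = MIN_EDGE_PIXELS) -> bool:
    """Admissibility of a fitted ellipse as a marker observation.

    The boundary is inclusive: ``axes_ratio == min_ratio`` is accepted.
    """
    return e.axes_ratio >= min_ratio and e.n_edge_pixels >= min_edge_pixels


def detect_markers(image: np.ndarray, min_ratio: float = MIN_AXES_RATIO,
                   min_edge_pixels: int = MIN_EDGE_PIXELS) -> list:
    """Full detection: threshold, trace edges, fit and filter ellipses."""
    ellipses = []
    for pts in threshold_and_edges(image, min_edge_pixels):
        try:
            e = fit_ellipse(pts)
        except (InsufficientDataError, NonEllipseError) as exc:
            log.info("contour rejected: %s", exc)
            continue
        if accept_marker(e, min_ratio, min_edge_pixels):
            ellipses.append(e)
    return ellipses


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = ["image_id", "camera_id", "ellipse_id",
            "cx", "cy", "a", "b", "alpha", "n_edge", "ratio"]


def ellipses_to_frame(ellipses, image_id="", camera_id=0) -> pd.DataFrame:
    """Detected ellipses as a tidy table (one row per ellipse)."""
    rows = []
    for k, e in enumerate(ellipses):
        rows.append({
            "image_id": image_id, "camera_id": camera_id, "ellipse_id": k,
            "cx": e.centre[0], "cy": e.centre[1],
            "a": e.semi_minor, "b": e.semi_major, "alpha": e.orientation,
            "n_edge": e.n_edge_pixels, "ratio": e.axes_ratio,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_ellipses(df: pd.DataFrame) -> list:
    return [
        ImageEllipse(centre=np.array([r.cx, r.cy]), semi_minor=r.a,
                     semi_major=r.b, orientation=r.alpha,
                     n_edge_pixels=int(r.n_edge))
        for r in df.itertuples()
    ]
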