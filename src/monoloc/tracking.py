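"""Template tracking of a device marker by normalized cross-correlation.

Manual picking of the working point in every frame is impractical during an
intervention; a radio-opaque marker is instead tracked across the frame
sequence with zero-mean normalized cross-correlation against a template
extracted at the operator-approved initial position, and each tracked pixel
is localized in 3D on the centerline. The template is fixed by default
(no drift); an optional exponential update blends in the current
appearance. Sub-pixel (3-point parabolic) peak refinement is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import match_template

#: default Gaussian prefilter (px) applied to frames before correlation;
#: suppresses pixel noise at scales below the marker size
DEFAULT_PRESMOOTH_PX = 1.0

from .localization import LocalizationResult, localize_sequence
from .geometry import WorkingPoint2D


class TrackingError(ValueError):
    pass


class TrackingLostError(TrackingError):
    """Raised when the search region carries no signal (zero variance)."""


@dataclass(frozen=True)
class TrackState:
    template: np.ndarray
    center_px: tuple[float, float]
    template_size_px: tuple[int, int]
    search_radius_px: int = 20
    #: sub-pixel phase of the initial position relative to the integer grid
    #: the template was extracted on; added back by sub-pixel tracking so
    #: reported positions refer to the operator's original reference point
    template_frac_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        h, w = self.template_size_px
        if h < 3 or w < 3 or h % 2 == 0 or w % 2 == 0:
            raise TrackingError(
                f"template size must be odd and >= 3, got {self.template_size_px}"
            )
        if self.template.shape != (h, w):
            raise TrackingError(
                f"template shape {self.template.shape} != declared size {(h, w)}"
            )
        if self.search_radius_px < 1:
            raise TrackingError("search_radius_px must be >= 1")


def _extract(image: np.ndarray, center: tuple[int, int], size: tuple[int, int]) -> np.ndarray:
    h, w = size
    r, c = center
    r0, c0 = r - h // 2, c - w // 2
    if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise TrackingError(
            f"window {size} at center {center} exceeds image bounds {image.shape}"
        )
    return np.asarray(image, dtype=float)[r0 : r0 + h, c0 : c0 + w].copy()


def _prefilter(image: np.ndarray, sigma: float) -> np.ndarray:
    return gaussian_filter(image, sigma) if sigma > 0 else image


def init_track(
    image,
    center_px: tuple[float, float],
    template_size_px: int | tuple[int, int] = 21,
    search_radius_px: int = 20,
    presmooth_px: float = DEFAULT_PRESMOOTH_PX,
) -> TrackState:
    """Extract the template patch around the initial marker position.

    The frame is Gaussian-prefiltered (``presmooth_px``) before extraction,
    the same filter :func:`track_next` applies to every search window.
    """
    image = _prefilter(np.asarray(image, dtype=float), presmooth_px)
    if isinstance(template_size_px, int):
        template_size_px = (template_size_px, template_size_px)
    center = (int(round(center_px[0])), int(round(center_px[1])))
    tpl = _extract(image, center, template_size_px)
    return TrackState(
        template=tpl,
        center_px=(float(center[0]), float(center[1])),
        template_size_px=tuple(template_size_px),
        search_radius_px=search_radius_px,
        template_frac_px=(
            float(center_px[0]) - center[0],
            float(center_px[1]) - center[1],
        ),
    )


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Vertex of the parabola through (-1, y0), (0, y1), (1, y2); zero when
    the samples carry no convex curvature (flat or saddle)."""
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def track_next(
    state: TrackState,
    image,
    subpixel: bool = False,
    template_update_alpha: float = 0.0,
    presmooth_px: float = DEFAULT_PRESMOOTH_PX,
) -> TrackState:
    """Advance the track by one frame.

    The new center is the argmax of zero-mean normalized cross-correlation
    between the template and the search window around the previous center;
    exact score ties go to the smallest displacement. With
    ``template_update_alpha`` > 0 the template is blended toward the patch
    at the new position (exponential update).
    """
    image = _prefilter(np.asarray(image, dtype=float), presmooth_px)
    h, w = state.template_size_px
    rad = state.search_radius_px
    pr, pc = int(round(state.center_px[0])), int(round(state.center_px[1]))
    r0 = max(pr - rad - h // 2, 0)
    c0 = max(pc - rad - w // 2, 0)
    r1 = min(pr + rad + h // 2 + 1, image.shape[0])
    c1 = min(pc + rad + w // 2 + 1, image.shape[1])
    window = image[r0:r1, c0:c1]
    if window.shape[0] < h or window.shape[1] < w:
        raise TrackingError(
            f"search window {window.shape} smaller than template {(h, w)}"
        )
    if float(window.std()) == 0.0 or float(state.template.std()) == 0.0:
        raise TrackingLostError("flat search region: correlation undefined")

    corr = match_template(window, state.template)  # zero-mean normalized
    best = corr.max()
    peaks = np.argwhere(corr >= best - 1e-12)
    centers = peaks + np.array([h // 2, w // 2]) + np.array([r0, c0])
    disp = np.linalg.norm(centers - np.array([pr, pc]), axis=1)
    order = np.lexsort((centers[:, 1], centers[:, 0], disp))
    pk_r, pk_c = peaks[order[0]]
    new_r, new_c = float(centers[order[0]][0]), float(centers[order[0]][1])

    if subpixel:
        if 0 < pk_r < corr.shape[0] - 1:
            new_r += _parabolic_offset(
                -corr[pk_r - 1, pk_c], -corr[pk_r, pk_c], -corr[pk_r + 1, pk_c]
            )
        if 0 < pk_c < corr.shape[1] - 1:
            new_c += _parabolic_offset(
                -corr[pk_r, pk_c - 1], -corr[pk_r, pk_c], -corr[pk_r, pk_c + 1]
            )
        new_r += state.template_frac_px[0]
        new_c += state.template_frac_px[1]

    template = state.template
    if template_update_alpha > 0:
        patch = _extract(image, (int(round(new_r)), int(round(new_c))), (h, w))
        template = (1 - template_update_alpha) * template + template_update_alpha * patch
    return replace(state, template=template, center_px=(new_r, new_c))


def track_and_localize(
    frames,
    geom_per_frame,
    tree,
    init_px: tuple[float, float],
    window_mm: float = 10.0,
    template_size_px: int = 21,
    search_radius_px: int = 20,
    subpixel: bool = False,
    presmooth_px: float = DEFAULT_PRESMOOTH_PX,
    init: LocalizationResult | None = None,
):
    """Track a marker across frames and localize every tracked pixel in 3D.

    Returns ``(results, track_px, status)``: the per-frame localization
    results, the tracked pixel path, and ``"ok"`` or ``"lost at frame k"``
    when correlation failed mid-sequence (results then cover the frames up
    to the loss).
    """
    frames = list(frames)
    if not frames:
        raise TrackingError("empty frame sequence")
    state = init_track(
        frames[0], init_px, template_size_px,
        search_radius_px=search_radius_px, presmooth_px=presmooth_px,
    )
    first = (
        (state.center_px[0] + state.template_frac_px[0],
         state.center_px[1] + state.template_frac_px[1])
        if subpixel
        else state.center_px
    )
    track = [first]
    status = "ok"
    for k, frame in enumerate(frames[1:], start=1):
        try:
            state = track_next(state, frame, subpixel=subpixel,
                               presmooth_px=presmooth_px)
        except TrackingLostError:
            status = f"lost at frame {k}"
            break
        track.append(state.center_px)
    points2d = [WorkingPoint2D(row_px=r, col_px=c) for r, c in track]
    if isinstance(geom_per_frame, (list, tuple)):
        geoms = list(geom_per_frame)[: len(points2d)]
    else:
        geoms = geom_per_frame
    results = localize_sequence(geoms, points2d, tree, window_mm=window_mm, init=init)
    return results, np.array(track), status
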