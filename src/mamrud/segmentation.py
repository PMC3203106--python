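"""Compartment segmentation of stained sections from manual contours.

The workflow mirrors semi-manual histological practice: the user supplies a
closed contour around the mammary rudiment (MR, plus its neck when present),
a polyline tracing the basement membrane of the surface ectoderm, and the
rudiment centre.  From these the module derives the full compartment label
map used for BrdU tabulation:

- the ectoderm band, refined against the background with a region-based
  (Chan–Vese) active contour and split into dorsal and ventral arms at the
  rudiment attachment;
- the MR core and periphery, split by erosion to a core:whole area ratio of
  1:3 on central sections (the cuboidal-core / columnar-periphery boundary);
- the mammary mesenchyme, a 15 um dilation band around the epithelium;
- a dermal-mesenchyme window between a line through the MR centre parallel
  to the local basement membrane and a second line 65 um deeper.

Every operation returns plain boolean masks;
:func:`label_compartments` composes them into one label map plus a
quality-control overlay image for visual verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage import color, draw, filters, morphology, segmentation as skseg

from mamrud.compartments import Compartment, OVERLAY_COLORS
from mamrud.errors import SegmentationError, ValidationError

__all__ = [
    "AnnotationSet",
    "CompartmentLabeling",
    "CoreSplit",
    "polygon_mask",
    "refine_ectoderm",
    "mammary_mesenchyme_band",
    "erode_to_core",
    "dermal_window",
    "split_ectoderm",
    "split_by_line",
    "label_compartments",
]

#: Default parameters of the compartment geometry (um) and the active
#: contour; all overridable per call.
DEFAULTS = {
    "mammary_band_um": 15.0,
    "dermal_offset_um": 65.0,
    "core_target_ratio": 1.0 / 3.0,
    "active_contour_max_iter": 200,
    "active_contour_tol": 1e-4,
    "membrane_window_um": 100.0,
}


@dataclass(frozen=True)
class AnnotationSet:
    """Manual annotations for one section, in 0-based (row, col) pixels."""

    mr_contour: np.ndarray  # (N, 2) closed polygon
    basement_membrane: np.ndarray  # (M, 2) open polyline, M >= 2
    mr_center: tuple[float, float]
    neck_contour: np.ndarray | None = None
    is_central_section: bool = False
    ventral_left: bool = True

    def __post_init__(self):
        contour = np.asarray(self.mr_contour, dtype=float)
        if contour.ndim != 2 or contour.shape[0] < 3 or contour.shape[1] != 2:
            raise ValidationError("need a closed polygon with >= 3 vertices", field="mr_contour")
        poly = Polygon(contour)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("polygon must be simple with area > 0", field="mr_contour")
        if not poly.contains(Point(self.mr_center)):
            raise ValidationError("mr_center must lie inside mr_contour", field="mr_center")
        membrane = np.asarray(self.basement_membrane, dtype=float)
        if membrane.ndim != 2 or membrane.shape[0] < 2 or membrane.shape[1] != 2:
            raise ValidationError("need a polyline with >= 2 vertices", field="basement_membrane")

    def to_dict(self) -> dict:
        return {
            "mr_contour": np.asarray(self.mr_contour).tolist(),
            "basement_membrane": np.asarray(self.basement_membrane).tolist(),
            "mr_center": list(self.mr_center),
            "neck_contour": None if self.neck_contour is None else np.asarray(self.neck_contour).tolist(),
            "is_central_section": self.is_central_section,
            "ventral_left": self.ventral_left,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSet":
        return cls(
            mr_contour=np.asarray(d["mr_contour"], dtype=float),
            basement_membrane=np.asarray(d["basement_membrane"], dtype=float),
            mr_center=tuple(d["mr_center"]),
            neck_contour=None if d.get("neck_contour") is None else np.asarray(d["neck_contour"], dtype=float),
            is_central_section=bool(d.get("is_central_section", False)),
            ventral_left=bool(d.get("ventral_left", True)),
        )


@dataclass
class CompartmentLabeling:
    """Per-pixel compartment label map for one section."""

    labels: np.ndarray  # (H, W) uint8 of Compartment values
    pixel_size_um: float
    core_split: bool  # whether core/periphery were separated (central sections)
    warnings: list[str] = field(default_factory=list)

    def mask(self, *compartments: Compartment) -> np.ndarray:
        return np.isin(self.labels, [int(c) for c in compartments])


@dataclass
class CoreSplit:
    """Result of the erosion split of the rudiment into core and periphery."""

    core: np.ndarray
    periphery: np.ndarray
    achieved_ratio: float
    erosion_depth_px: int
    warning: bool = False  # True when the mask emptied before a usable ratio


def polygon_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed (row, col) polygon to a boolean mask."""
    contour = np.asarray(contour, dtype=float)
    rr, cc = draw.polygon(contour[:, 0], contour[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _membrane_row_per_col(membrane: np.ndarray, width: int) -> np.ndarray:
    """Basement-membrane row at every image column (edge-extrapolated)."""
    membrane = np.asarray(membrane, dtype=float)
    order = np.argsort(membrane[:, 1])
    cols, rows = membrane[order, 1], membrane[order, 0]
    return np.interp(np.arange(width), cols, rows)


def refine_ectoderm(
    image: np.ndarray,
    basement_membrane: np.ndarray,
    band_prior_um: float = 20.0,
    pixel_size_um: float = 1.0,
    max_iter: int | None = None,
    tol: float | None = None,
) -> np.ndarray:
    """Refine the ectoderm band between the basement membrane and background.

    The basement-membrane polyline fixes the inner (deep) boundary; a
    region-based Chan–Vese active contour separates tissue from the pale
    background to find the outer boundary.  The contour evolves until the
    level-set change drops below ``tol`` or ``max_iter`` iterations, and the
    result is the connected tissue region on the outer side of the membrane.
    With ``max_iter=0`` the prior band (``band_prior_um`` outward of the
    membrane) is returned unchanged.

    Raises :class:`ValidationError` if the polyline leaves the image and
    :class:`SegmentationError` if no tissue region is found.
    """
    max_iter = DEFAULTS["active_contour_max_iter"] if max_iter is None else max_iter
    tol = DEFAULTS["active_contour_tol"] if tol is None else tol
    membrane = np.asarray(basement_membrane, dtype=float)
    H, W = image.shape[:2]
    if membrane.shape[0] < 2:
        raise ValidationError("need >= 2 vertices", field="basement_membrane")
    if (membrane < -0.5).any() or (membrane[:, 0] > H - 0.5).any() or (membrane[:, 1] > W - 0.5).any():
        raise ValidationError("polyline outside image", field="basement_membrane")

    membrane_rows = _membrane_row_per_col(membrane, W)
    rows = np.arange(H)[:, None]
    outer_side = rows < membrane_rows[None, :]
    band_px = max(1, int(round(band_prior_um / pixel_size_um)))
    prior = outer_side & (rows >= (membrane_rows[None, :] - band_px))
    if max_iter == 0:
        return prior

    gray = color.rgb2gray(image) if image.ndim == 3 else image.astype(float)
    # Median-filter with a window larger than one nucleus so stained nuclei
    # collapse onto the surrounding cytoplasm level: the two-phase contour
    # must separate tissue from background, not nuclei from everything else.
    # A median keeps the tissue/background edge sharp where a Gaussian blurs it.
    gray = ndi.median_filter(gray, size=7)
    phase = skseg.chan_vese(gray, mu=0.1, tol=tol, max_num_iter=max_iter, init_level_set="checkerboard")
    if phase.all() or (~phase).all():
        raise SegmentationError("no tissue/background contrast found")
    if abs(gray[phase].mean() - gray[~phase].mean()) < 0.01:
        raise SegmentationError("no tissue/background contrast found")
    tissue = phase if gray[phase].mean() < gray[~phase].mean() else ~phase

    ect = tissue & outer_side
    if not ect.any():
        raise SegmentationError("empty ectoderm region above the basement membrane")
    lab, _ = ndi.label(ect)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def mammary_mesenchyme_band(
    mr_mask: np.ndarray,
    pixel_size_um: float,
    ectoderm_mask: np.ndarray | None = None,
    band_um: float | None = None,
) -> np.ndarray:
    """Mammary-mesenchyme band: a fixed-width dilation around the rudiment.

    ``band = dilate(mr, disk(round(band_um / pixel_size))) \\ mr \\ ectoderm``.
    """
    band_um = DEFAULTS["mammary_band_um"] if band_um is None else band_um
    if not np.any(mr_mask):
        raise ValidationError("empty rudiment mask", field="mr_mask")
    if pixel_size_um <= 0:
        raise ValidationError("must be > 0", field="pixel_size_um")
    radius = int(round(band_um / pixel_size_um))
    if radius < 1:
        raise ValidationError(
            f"band width {band_um} um is below one pixel at {pixel_size_um} um/px", field="pixel_size_um"
        )
    dilated = morphology.dilation(mr_mask, morphology.disk(radius))
    band = dilated & ~mr_mask
    if ectoderm_mask is not None:
        band &= ~ectoderm_mask
    return band


def erode_to_core(
    mr_mask: np.ndarray,
    target_ratio: float | None = None,
    is_central_section: bool = True,
) -> CoreSplit:
    """Split the rudiment into core and periphery by iterative erosion.

    The mask is eroded by successive unit-disk steps (equivalently, by
    thresholding the Euclidean distance transform at depth *k*) and the
    erosion level whose core-area / whole-area ratio is closest to
    ``target_ratio`` is kept; ties break toward the smaller core.  The split
    is only meaningful on central sections, where the cuboidal core and
    columnar periphery actually differ — hence the flag is required.

    If the mask erodes to empty before any level reaches a ratio of at most
    ``2 * target_ratio``, an empty core is returned with ``warning=True``.
    """
    target_ratio = DEFAULTS["core_target_ratio"] if target_ratio is None else target_ratio
    if not is_central_section:
        raise ValidationError("core/periphery split applies to central sections only", field="is_central_section")
    area = int(np.count_nonzero(mr_mask))
    if area == 0:
        raise ValidationError("empty rudiment mask", field="mr_mask")

    edt = ndi.distance_transform_edt(mr_mask)
    best_k, best_core, best_err = 0, None, np.inf
    reached_usable = False
    for k in range(1, int(edt.max()) + 1):
        core = edt >= k
        ratio = core.sum() / area
        if ratio <= 2 * target_ratio:
            reached_usable = True
        err = abs(ratio - target_ratio)
        if err <= best_err:  # <= so ties go to the deeper erosion (smaller core)
            best_k, best_core, best_err = k, core, err
    if not reached_usable or best_core is None:
        empty = np.zeros_like(mr_mask)
        return CoreSplit(empty, mr_mask.copy(), 0.0, 0, warning=True)
    return CoreSplit(
        core=best_core,
        periphery=mr_mask & ~best_core,
        achieved_ratio=float(best_core.sum() / area),
        erosion_depth_px=best_k,
    )


def dermal_window(
    mr_center: tuple[float, float],
    basement_membrane: np.ndarray,
    shape: tuple[int, int],
    pixel_size_um: float = 1.0,
    offset_um: float | None = None,
    exclude: list[np.ndarray] | tuple = (),
    tissue_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Dermal-mesenchyme window below the rudiment centre.

    The window lies between a line through ``mr_center`` parallel to the
    local basement-membrane direction and a second parallel line
    ``offset_um`` deeper.  The local direction is the principal axis of the
    membrane vertices within +-100 um of the rudiment centre (the membrane is
    curved; a single global direction would misplace the window).  Pixels in
    any ``exclude`` mask (rudiment, neck, mammary band) are removed, as are
    pixels above the membrane.  Returns ``(mask, clipped)`` with ``clipped``
    True when the window ran off the image and was truncated.
    """
    offset_um = DEFAULTS["dermal_offset_um"] if offset_um is None else offset_um
    H, W = shape
    r0, c0 = mr_center
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValidationError("centre outside image", field="mr_center")
    membrane = np.asarray(basement_membrane, dtype=float)
    if membrane.shape[0] < 2:
        raise ValidationError("need >= 2 vertices", field="basement_membrane")

    win_px = DEFAULTS["membrane_window_um"] / pixel_size_um
    local = membrane[np.abs(membrane[:, 1] - c0) <= win_px]
    if local.shape[0] < 2:
        local = membrane
    centered = local - local.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(centered.T))
    direction = vecs[:, -1]  # principal axis, (row, col)
    normal = np.array([-direction[1], direction[0]])
    if normal[0] < 0:  # orient the normal downward, into the tissue
        normal = -normal

    rows, cols = np.mgrid[0:H, 0:W]
    d = (rows - r0) * normal[0] + (cols - c0) * normal[1]
    offset_px = offset_um / pixel_size_um
    window = (d >= 0) & (d < offset_px)

    membrane_rows = _membrane_row_per_col(membrane, W)
    window &= rows >= membrane_rows[None, :]
    if tissue_mask is not None:
        window &= tissue_mask
    for mask in exclude:
        window &= ~mask
    clipped = bool(d.max() < offset_px)
    return window, clipped


def split_ectoderm(
    ectoderm_mask: np.ndarray,
    mr_mask: np.ndarray,
    ventral_left: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the ectoderm band into dorsal and ventral arms.

    The attachment zone is the column range where the (slightly dilated)
    rudiment meets the ectoderm; columns strictly left/right of it form the
    two arms, assigned by the ``ventral_left`` orientation flag.  Returns
    ``(dorsal, ventral)``.  Raises :class:`SegmentationError` when the
    rudiment is nowhere adjacent to the ectoderm.
    """
    touch = morphology.dilation(mr_mask, morphology.disk(2)) & ectoderm_mask
    attach_cols = np.where(touch.any(axis=0))[0]
    if attach_cols.size == 0:
        raise SegmentationError("rudiment not adjacent to ectoderm")
    c0, c1 = attach_cols[0], attach_cols[-1]
    cols = np.arange(ectoderm_mask.shape[1])[None, :]
    left = ectoderm_mask & (cols < c0)
    right = ectoderm_mask & (cols > c1)
    return (right, left) if ventral_left else (left, right)


def split_by_line(mask: np.ndarray, line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask into two halves by a manually drawn line.

    Used e.g. to subdivide the mammary-mesenchyme band when one half must be
    scored separately.  ``line`` is a (row, col) polyline; pixels are
    assigned by the side of the (first-to-last vertex) direction they fall
    on.  The two halves partition the mask exactly.
    """
    line = np.asarray(line, dtype=float)
    if line.shape[0] < 2:
        raise ValidationError("need >= 2 vertices", field="line")
    p0, p1 = line[0], line[-1]
    direction = p1 - p0
    rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    cross = (rows - p0[0]) * direction[1] - (cols - p0[1]) * direction[0]
    first = mask & (cross >= 0)
    return first, mask & ~first


def label_compartments(
    image: np.ndarray,
    annotations: AnnotationSet,
    pixel_size_um: float = 1.0,
    params: dict | None = None,
) -> tuple[CompartmentLabeling, np.ndarray]:
    """Compose the full compartment label map and a QC overlay.

    Applies, in order: ectoderm refinement, rudiment/neck rasterization,
    dorsal/ventral split, core/periphery erosion (central sections only),
    the 15 um mammary-mesenchyme band, and the 65 um dermal window.  The
    overlay draws each compartment boundary in its conventional colour for
    visual verification of the segmentation.
    """
    p = dict(DEFAULTS)
    if params:
        p.update(params)
    H, W = image.shape[:2]
    warnings: list[str] = []

    mr = polygon_mask(annotations.mr_contour, (H, W))
    neck = (
        polygon_mask(annotations.neck_contour, (H, W)) & ~mr
        if annotations.neck_contour is not None
        else np.zeros((H, W), dtype=bool)
    )
    epithelium = mr | neck

    ect = refine_ectoderm(
        image,
        annotations.basement_membrane,
        pixel_size_um=pixel_size_um,
        max_iter=p["active_contour_max_iter"],
        tol=p["active_contour_tol"],
    )
    ect &= ~epithelium

    try:
        dorsal, ventral = split_ectoderm(ect, epithelium, annotations.ventral_left)
    except SegmentationError:
        # Deep sections: the rudiment no longer reaches the band; fall back
        # to a split at the annotated centre column.
        warnings.append("rudiment not adjacent to ectoderm; split at centre column")
        cols = np.arange(W)[None, :]
        cc = int(round(annotations.mr_center[1]))
        left, right = ect & (cols < cc), ect & (cols > cc)
        dorsal, ventral = (right, left) if annotations.ventral_left else (left, right)

    if annotations.is_central_section:
        split = erode_to_core(mr, target_ratio=p["core_target_ratio"])
        if split.warning:
            warnings.append("rudiment too small for core/periphery split")
        core, periphery = split.core, split.periphery
        core_split = not split.warning
    else:
        core = np.zeros((H, W), dtype=bool)
        periphery = mr
        core_split = False

    membrane_rows = _membrane_row_per_col(annotations.basement_membrane, W)
    below = np.arange(H)[:, None] >= membrane_rows[None, :]
    mamm = mammary_mesenchyme_band(epithelium, pixel_size_um, ectoderm_mask=ect, band_um=p["mammary_band_um"]) & below

    derm, clipped = dermal_window(
        annotations.mr_center,
        annotations.basement_membrane,
        (H, W),
        pixel_size_um=pixel_size_um,
        offset_um=p["dermal_offset_um"],
        exclude=[epithelium, mamm],
    )
    if clipped:
        warnings.append("dermal window clipped to image bounds")

    labels = np.zeros((H, W), dtype=np.uint8)
    for comp, mask in (
        (Compartment.DERMAL_MESENCHYME, derm),
        (Compartment.MAMMARY_MESENCHYME, mamm),
        (Compartment.DORSAL_ECTODERM, dorsal),
        (Compartment.VENTRAL_ECTODERM, ventral),
        (Compartment.MR_NECK, neck),
        (Compartment.MR_PERIPHERY, periphery),
        (Compartment.MR_CORE, core),
    ):
        labels[mask] = int(comp)

    labeling = CompartmentLabeling(labels, pixel_size_um, core_split, warnings)
    return labeling, qc_overlay(image, labeling)


def qc_overlay(image: np.ndarray, labeling: CompartmentLabeling) -> np.ndarray:
    """Quality-control image: compartment boundaries in the colour key."""
    overlay = image.copy() if image.ndim == 3 else np.stack([image] * 3, axis=-1)
    for comp, rgb in OVERLAY_COLORS.items():
        mask = labeling.mask(comp)
        if mask.any():
            overlay[skseg.find_boundaries(mask, mode="inner")] = rgb
    return overlay
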