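"""Synthetic stained-section phantoms with complete ground truth.

The generator emulates transversal histological sections through an embryonic
flank: a single-layered surface ectoderm band, an embedded dome/bud-shaped
multilayered mammary rudiment (an ellipsoid, optionally with a neck joining
it to the ectoderm), condensing mammary mesenchyme around the rudiment, and
dermal mesenchyme below.  Nuclei are rendered as filled ellipses — BrdU+
nuclei in dark DAB-like brown, BrdU- nuclei in hematoxylin-like blue — on a
pale cytoplasm/background, so that the colour-threshold rules of
:mod:`mamrud.brdu` apply directly.

Every quantity measured downstream has an analytic or recorded ground truth:
per-section compartment label maps, per-nucleus records (position,
compartment, BrdU status), the closed-form rudiment volume, and any applied
inter-section misalignment transforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from mamrud.compartments import Compartment, ECTODERM_COMPARTMENTS, MR_COMPARTMENTS
from mamrud.errors import ValidationError
from mamrud.transform import SimilarityTransform2D, warp_image

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SectionImage",
    "generate_stack",
    "perturb_stack",
    "annotations_from_truth",
    "write_stack",
    "read_stack",
    "BRDU_COLOR",
    "HEMATOXYLIN_COLOR",
    "CYTOPLASM_COLOR",
    "BACKGROUND_COLOR",
]

# Rendered palette (RGB).  BrdU+ nuclei: low-luminance DAB brown; BrdU-
# nuclei: medium-luminance hematoxylin blue; background near-white.
BRDU_COLOR = (70, 45, 25)
HEMATOXYLIN_COLOR = (95, 115, 185)
CYTOPLASM_COLOR = (236, 222, 228)
BACKGROUND_COLOR = (250, 249, 246)

#: Group key used for nucleus radius / BrdU fraction lookup per compartment.
_GROUP_OF = {
    Compartment.DORSAL_ECTODERM: "ectoderm",
    Compartment.VENTRAL_ECTODERM: "ectoderm",
    Compartment.MR_CORE: "core",
    Compartment.MR_PERIPHERY: "periphery",
    Compartment.MR_NECK: "periphery",
    Compartment.MAMMARY_MESENCHYME: "mesenchyme",
    Compartment.DERMAL_MESENCHYME: "mesenchyme",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic serial-section stack.

    Geometry is given in micrometres; images use (row, col) pixel indexing
    with the physical origin at the image top-left and depth of section *i*
    equal to ``i * section_thickness``.  Defaults approximate a bud-stage
    rudiment: an ellipsoid of semi-axes 55 x 45 x 40 um (volume ~4.1e5 um^3,
    the E13.5 scale), a ~18 um ectoderm band, 5 um sections at 1 um/pixel,
    22% BrdU labelling in the ectoderm and 4.5% in the rudiment (the 2 h
    pulse rates), and ~20% in the mesenchyme.
    """

    semi_axes_um: tuple[float, float, float] = (55.0, 45.0, 40.0)  # (col, row, depth)
    neck_um: tuple[float, float] | None = None  # (radius, length)
    ectoderm_thickness_um: float = 18.0
    pixel_size_um: float = 1.0
    section_thickness_um: float = 5.0
    n_sections: int = 17
    image_shape: tuple[int, int] = (190, 256)
    nucleus_radius_um: dict = field(
        default_factory=lambda: {"ectoderm": 2.8, "core": 2.5, "periphery": 2.5, "mesenchyme": 2.8}
    )
    brdu_fraction: dict = field(
        default_factory=lambda: {"ectoderm": 0.22, "core": 0.045, "periphery": 0.045, "mesenchyme": 0.20}
    )
    lost_section_indices: tuple[int, ...] = ()
    misalignment: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (max px, max rad, max scale dev)
    allow_touching: bool = False
    rng_seed: int = 0
    # Layout details (um): top margin above the ectoderm, depth of the
    # rudiment centre below the basement membrane as a fraction of the row
    # semi-axis, mammary-mesenchyme band width, dermal-window offset.
    top_margin_um: float = 12.0
    center_depth_frac: float = 0.75
    mammary_band_um: float = 15.0
    dermal_offset_um: float = 65.0

    def __post_init__(self):
        for name in ("ectoderm_thickness_um", "pixel_size_um", "section_thickness_um"):
            if getattr(self, name) <= 0:
                raise ValidationError("must be > 0", field=name)
        if len(self.semi_axes_um) != 3 or any(a <= 0 for a in self.semi_axes_um):
            raise ValidationError("three positive semi-axes required", field="semi_axes_um")
        if self.neck_um is not None and any(v <= 0 for v in self.neck_um):
            raise ValidationError("neck radius and length must be > 0", field="neck_um")
        if self.n_sections < 3:
            raise ValidationError("need at least 3 sections", field="n_sections")
        for key, val in self.brdu_fraction.items():
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"fraction for {key!r} outside [0, 1]", field="brdu_fraction")
        for key, val in self.nucleus_radius_um.items():
            if val <= 0:
                raise ValidationError(f"radius for {key!r} must be > 0", field="nucleus_radius_um")
        bad = [i for i in self.lost_section_indices if not 0 <= i < self.n_sections]
        if bad:
            raise ValidationError(f"indices {bad} outside 0..{self.n_sections - 1}", field="lost_section_indices")
        if len(set(self.lost_section_indices)) >= self.n_sections:
            raise ValidationError("all sections lost", field="lost_section_indices")
        if any(m < 0 for m in self.misalignment):
            raise ValidationError("magnitudes must be >= 0", field="misalignment")

    # -- derived pixel-scale geometry -----------------------------------
    @property
    def basement_row(self) -> int:
        """Row index of the first pixel below the ectoderm band."""
        px = self.pixel_size_um
        return int(round(self.top_margin_um / px)) + int(round(self.ectoderm_thickness_um / px))

    @property
    def ect_top_row(self) -> int:
        return int(round(self.top_margin_um / self.pixel_size_um))

    @property
    def center_rc(self) -> tuple[float, float]:
        b_row_px = self.semi_axes_um[1] / self.pixel_size_um
        return (self.basement_row + self.center_depth_frac * b_row_px, self.image_shape[1] / 2.0)

    @property
    def center_depth_um(self) -> float:
        return (self.n_sections - 1) * self.section_thickness_um / 2.0

    @property
    def section_depths_um(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.section_thickness_um

    def true_volume_um3(self) -> float:
        """Closed-form rudiment volume: ellipsoid plus optional neck cylinder."""
        a, b, c = self.semi_axes_um
        vol = 4.0 / 3.0 * np.pi * a * b * c
        if self.neck_um is not None:
            r, length = self.neck_um
            vol += np.pi * r**2 * length
        return float(vol)


@dataclass
class SectionImage:
    """One calibrated RGB section."""

    index: int
    image: np.ndarray  # (H, W, 3) uint8
    pixel_size_um: float
    section_thickness_um: float

    @property
    def depth_um(self) -> float:
        return self.index * self.section_thickness_um


@dataclass
class GroundTruth:
    """Complete truth for one generated stack.

    ``labels[i]`` is the compartment label map of section *i* (all nominal
    sections, including lost ones) in the unperturbed frame.  ``transforms``
    map unperturbed coordinates to the rendered image of each section
    (identity unless misalignment was requested).
    """

    spec: PhantomSpec
    labels: np.ndarray  # (n_sections, H, W) uint8 of Compartment values
    nuclei: pd.DataFrame  # section, row, col, depth_um, compartment, brdu, radius_px
    transforms: list[SimilarityTransform2D]
    true_volume_um3: float
    basement_row: int
    central_index: int

    @property
    def lost_sections(self) -> tuple[int, ...]:
        return tuple(self.spec.lost_section_indices)

    def mask(self, index: int, *compartments: Compartment) -> np.ndarray:
        return np.isin(self.labels[index], [int(c) for c in compartments])

    def mr_mask(self, index: int) -> np.ndarray:
        return self.mask(index, *MR_COMPARTMENTS)

    def ectoderm_mask(self, index: int) -> np.ndarray:
        return self.mask(index, *ECTODERM_COMPARTMENTS)

    def mr_areas_um2(self) -> np.ndarray:
        """Per-section rudiment cross-section areas (um^2), lost included."""
        px2 = self.spec.pixel_size_um**2
        return np.array([self.mr_mask(i).sum() * px2 for i in range(self.spec.n_sections)])

    def realized_fraction(self, *compartments: Compartment) -> float:
        """Realized BrdU+ nucleus fraction over the given compartments."""
        names = [Compartment(c).name for c in compartments]
        sub = self.nuclei[self.nuclei["compartment"].isin(names)]
        if len(sub) == 0:
            return float("nan")
        return float(sub["brdu"].mean())


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_mask(shape, center_rc, semi_rc):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center_rc
    sr, sc = semi_rc
    if sr <= 0 or sc <= 0:
        return np.zeros(shape, dtype=bool)
    return ((rr - r0) / sr) ** 2 + ((cc - c0) / sc) ** 2 <= 1.0


def _core_by_depth(mask: np.ndarray, target_ratio: float = 1.0 / 3.0) -> np.ndarray:
    """Inner region holding ~``target_ratio`` of the area.

    The core is the set of pixels deeper than *k* from the rudiment surface
    (Euclidean distance), with *k* chosen so the core-to-whole area ratio is
    closest to the target — the geometric counterpart of the cuboidal core /
    columnar periphery distinction.
    """
    area = mask.sum()
    if area == 0:
        return np.zeros_like(mask)
    edt = ndi.distance_transform_edt(mask)
    best, best_err = np.zeros_like(mask), np.inf
    for k in range(1, int(edt.max()) + 1):
        core = edt >= k
        err = abs(core.sum() / area - target_ratio)
        if err <= best_err:  # ties -> deeper (smaller) core
            best, best_err = core, err
    return best


def _section_geometry(spec: PhantomSpec, index: int) -> dict:
    """Boolean masks of every compartment for one nominal section."""
    H, W = spec.image_shape
    px = spec.pixel_size_um
    a, b, c = spec.semi_axes_um
    z = index * spec.section_thickness_um
    f2 = 1.0 - ((z - spec.center_depth_um) / c) ** 2
    center = spec.center_rc

    rud = np.zeros((H, W), dtype=bool)
    if f2 > 0:
        f = np.sqrt(f2)
        rud = _ellipse_mask((H, W), center, (b * f / px, a * f / px))

    neck = np.zeros((H, W), dtype=bool)
    if spec.neck_um is not None and f2 > 0:
        r_neck, length = spec.neck_um
        if abs(z - spec.center_depth_um) <= r_neck:
            rows = slice(spec.basement_row, min(H, spec.basement_row + int(round(length / px))))
            cols = slice(
                max(0, int(round(center[1] - r_neck / px))),
                min(W, int(round(center[1] + r_neck / px)) + 1),
            )
            neck[rows, cols] = True
            neck &= ~rud

    band_rows = np.zeros((H, W), dtype=bool)
    band_rows[spec.ect_top_row : spec.basement_row, :] = True
    ect = band_rows & ~rud & ~neck

    # Dorsal/ventral split at the rudiment attachment columns (ventral left).
    epi = rud | neck
    attach_cols = np.where((epi & band_rows).any(axis=0))[0]
    if attach_cols.size:
        c0, c1 = attach_cols[0], attach_cols[-1]
    else:
        c0 = c1 = int(round(center[1]))
    cols = np.arange(W)
    ventral = ect & (cols[None, :] < c0)
    dorsal = ect & (cols[None, :] > c1)

    core = _core_by_depth(rud) if f2 > 0 else np.zeros((H, W), dtype=bool)
    periphery = rud & ~core

    # Mammary mesenchyme: within the band width of the rudiment, below the
    # basement membrane, outside the epithelium.
    below = np.zeros((H, W), dtype=bool)
    below[spec.basement_row :, :] = True
    if epi.any():
        dist = ndi.distance_transform_edt(~epi)
        mamm = (dist <= spec.mammary_band_um / px) & below & ~epi
    else:
        mamm = np.zeros((H, W), dtype=bool)

    # Dermal mesenchyme window: between the row through the rudiment centre
    # and a parallel row ``dermal_offset_um`` deeper.
    r0 = int(round(center[0]))
    r1 = min(H, r0 + int(round(spec.dermal_offset_um / px)))
    derm = np.zeros((H, W), dtype=bool)
    derm[r0:r1, :] = True
    derm &= below & ~epi & ~mamm

    return {
        Compartment.DORSAL_ECTODERM: dorsal,
        Compartment.VENTRAL_ECTODERM: ventral,
        Compartment.MR_CORE: core,
        Compartment.MR_PERIPHERY: periphery,
        Compartment.MR_NECK: neck,
        Compartment.MAMMARY_MESENCHYME: mamm,
        Compartment.DERMAL_MESENCHYME: derm,
        "attachment_cols": (int(c0), int(c1)),
        "tissue_rows": (spec.ect_top_row, H),
    }


def _labels_from_masks(masks: dict, shape) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.uint8)
    # Paint lower-priority compartments first; epithelium last so it wins.
    order = [
        Compartment.DERMAL_MESENCHYME,
        Compartment.MAMMARY_MESENCHYME,
        Compartment.DORSAL_ECTODERM,
        Compartment.VENTRAL_ECTODERM,
        Compartment.MR_NECK,
        Compartment.MR_PERIPHERY,
        Compartment.MR_CORE,
    ]
    for comp in order:
        labels[masks[comp]] = int(comp)
    return labels


# ---------------------------------------------------------------------------
# nucleus placement and rendering

def _place_nuclei(mask, radius_px, rng, allow_touching):
    """Jittered-grid nucleus centroids lying wholly inside ``mask``."""
    H, W = mask.shape
    margin = int(np.ceil(radius_px)) + 1
    allowed = ndi.binary_erosion(mask, structure=np.ones((3, 3)), iterations=margin) if margin else mask
    if not allowed.any():
        return np.empty((0, 2))
    gap = -1.0 if allow_touching else 2.0
    spacing = max(3, int(round(2 * radius_px + gap)))
    jitter = 0.45 * spacing if allow_touching else min(0.35 * spacing, max(0.0, (spacing - 2 * radius_px - 1) / 2))
    # Random whole-grid offset per call so nuclei of consecutive sections do
    # not stack into the same (row, col) positions — one nucleus spans a
    # single 5-6 um section, as in real material.
    off_r, off_c = rng.uniform(0, spacing, size=2)
    rows = np.arange(off_r, H, spacing, dtype=float)
    cols = np.arange(off_c, W, spacing, dtype=float)
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
    grid = grid + rng.uniform(-jitter, jitter, size=grid.shape)
    ri = np.clip(np.rint(grid[:, 0]).astype(int), 0, H - 1)
    ci = np.clip(np.rint(grid[:, 1]).astype(int), 0, W - 1)
    return grid[allowed[ri, ci]]


def _draw_nucleus(image, row, col, radius_px, color, rng):
    from skimage.draw import ellipse

    rot = rng.uniform(0, np.pi)
    rr, cc = ellipse(row, col, radius_px, 0.85 * radius_px, shape=image.shape[:2], rotation=rot)
    image[rr, cc] = color


def generate_stack(spec: PhantomSpec) -> tuple[list[SectionImage], GroundTruth]:
    """Render a serial-section phantom and its ground truth.

    Returns the kept sections (lost ones omitted from the image list but
    present in the ground truth) and a :class:`GroundTruth` carrying label
    maps, nucleus records, the analytic rudiment volume and the per-section
    misalignment transforms (identity unless requested in the spec).

    Output is bit-identical for identical spec and seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.image_shape
    labels = np.zeros((spec.n_sections, H, W), dtype=np.uint8)
    records = []
    images = []

    for i in range(spec.n_sections):
        masks = _section_geometry(spec, i)
        labels[i] = _labels_from_masks(masks, (H, W))

        canvas = np.empty((H, W, 3), dtype=np.uint8)
        canvas[:] = BACKGROUND_COLOR
        canvas[masks["tissue_rows"][0] :, :] = CYTOPLASM_COLOR
        noise = rng.integers(-3, 4, size=(H, W, 1))
        canvas = np.clip(canvas.astype(int) + noise, 0, 255).astype(np.uint8)

        for comp in (
            Compartment.DORSAL_ECTODERM,
            Compartment.VENTRAL_ECTODERM,
            Compartment.MR_CORE,
            Compartment.MR_PERIPHERY,
            Compartment.MR_NECK,
            Compartment.MAMMARY_MESENCHYME,
            Compartment.DERMAL_MESENCHYME,
        ):
            group = _GROUP_OF[comp]
            radius_px = spec.nucleus_radius_um.get(group, 2.5) / spec.pixel_size_um
            frac = spec.brdu_fraction.get(group, 0.0)
            centers = _place_nuclei(masks[comp], radius_px, rng, spec.allow_touching)
            for row, col in centers:
                brdu = bool(rng.random() < frac)
                _draw_nucleus(canvas, row, col, radius_px, BRDU_COLOR if brdu else HEMATOXYLIN_COLOR, rng)
                records.append(
                    {
                        "section": i,
                        "row": float(row),
                        "col": float(col),
                        "depth_um": i * spec.section_thickness_um,
                        "compartment": comp.name,
                        "brdu": brdu,
                        "radius_px": float(radius_px),
                    }
                )
        images.append(SectionImage(i, canvas, spec.pixel_size_um, spec.section_thickness_um))

    # Misalignment: section 0 is the reference frame and stays untouched.
    transforms = [SimilarityTransform2D() for _ in range(spec.n_sections)]
    max_shift, max_rot, max_sdev = spec.misalignment
    if max_shift > 0 or max_rot > 0 or max_sdev > 0:
        for i in range(1, spec.n_sections):
            transforms[i] = SimilarityTransform2D(
                scale=1.0 + rng.uniform(-max_sdev, max_sdev),
                rotation=rng.uniform(-max_rot, max_rot),
                translation=(rng.uniform(-max_shift, max_shift), rng.uniform(-max_shift, max_shift)),
            )
            images[i].image = warp_image(images[i].image, transforms[i], cval=float(np.mean(BACKGROUND_COLOR)))

    nuclei = pd.DataFrame.from_records(
        records, columns=["section", "row", "col", "depth_um", "compartment", "brdu", "radius_px"]
    )
    central = int(np.argmin(np.abs(spec.section_depths_um - spec.center_depth_um)))
    truth = GroundTruth(
        spec=spec,
        labels=labels,
        nuclei=nuclei,
        transforms=transforms,
        true_volume_um3=spec.true_volume_um3(),
        basement_row=spec.basement_row,
        central_index=central,
    )
    kept = [s for s in images if s.index not in spec.lost_section_indices]
    return kept, truth


def perturb_stack(
    sections: list[SectionImage],
    max_shift_px: float = 0.0,
    max_rot_rad: float = 0.0,
    max_scale_dev: float = 0.0,
    seed: int = 0,
    transforms: list[SimilarityTransform2D] | None = None,
) -> tuple[list[SectionImage], list[SimilarityTransform2D]]:
    """Apply recorded non-reflective similarity misalignments to a stack.

    The first section is the reference and receives the identity.  Pass
    ``transforms`` to apply a known list instead of sampling; the returned
    list always records exactly what was applied.  Applying the inverse
    transforms restores the original stack up to interpolation error.
    """
    if len(sections) == 0:
        raise ValidationError("empty stack", field="sections")
    rng = np.random.default_rng(seed)
    if transforms is None:
        transforms = [SimilarityTransform2D()]
        for _ in sections[1:]:
            transforms.append(
                SimilarityTransform2D(
                    scale=1.0 + rng.uniform(-max_scale_dev, max_scale_dev),
                    rotation=rng.uniform(-max_rot_rad, max_rot_rad),
                    translation=(
                        rng.uniform(-max_shift_px, max_shift_px),
                        rng.uniform(-max_shift_px, max_shift_px),
                    ),
                )
            )
    if len(transforms) != len(sections):
        raise ValidationError("one transform per section required", field="transforms")
    out = []
    for sec, tf in zip(sections, transforms):
        img = sec.image if tf.is_identity() else warp_image(sec.image, tf, cval=float(np.mean(BACKGROUND_COLOR)))
        out.append(SectionImage(sec.index, img, sec.pixel_size_um, sec.section_thickness_um))
    return out, list(transforms)


def annotations_from_truth(truth: GroundTruth, index: int):
    """Build the manual-annotation set a user would draw, from ground truth.

    Returns an :class:`mamrud.segmentation.AnnotationSet` with the rudiment
    contour (traced around the true epithelial mask), the basement-membrane
    polyline, the rudiment centre and the central-section flag.
    """
    from skimage import measure

    from mamrud.segmentation import AnnotationSet

    epi = truth.mask(index, *MR_COMPARTMENTS)
    if not epi.any():
        raise ValidationError(f"section {index} contains no rudiment", field="index")
    contours = measure.find_contours(epi.astype(float), 0.5)
    mr_contour = max(contours, key=len)[::3]
    com = ndi.center_of_mass(epi)
    W = truth.labels.shape[2]
    membrane_row = truth.basement_row - 0.5
    basement = np.array([[membrane_row, c] for c in np.arange(0, W, 4.0)] + [[membrane_row, W - 1.0]])
    neck_contour = None
    neck = truth.mask(index, Compartment.MR_NECK)
    if neck.any():
        neck_contour = max(measure.find_contours(neck.astype(float), 0.5), key=len)[::3]
    return AnnotationSet(
        mr_contour=np.asarray(mr_contour),
        basement_membrane=basement,
        mr_center=(float(com[0]), float(com[1])),
        neck_contour=None if neck_contour is None else np.asarray(neck_contour),
        is_central_section=(index == truth.central_index),
        ventral_left=True,
    )


# ---------------------------------------------------------------------------
# disk I/O: numbered PNGs plus a JSON ground-truth sidecar

def write_stack(outdir: str | Path, sections: list[SectionImage], truth: GroundTruth | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sec in sections:
        iio.imwrite(outdir / f"section_{sec.index:03d}.png", sec.image)
    if truth is not None:
        for i in range(truth.labels.shape[0]):
            iio.imwrite(outdir / f"labels_{i:03d}.png", truth.labels[i])
        sidecar = {
            "pixel_size_um": truth.spec.pixel_size_um,
            "section_thickness_um": truth.spec.section_thickness_um,
            "n_sections": truth.spec.n_sections,
            "lost_sections": list(truth.lost_sections),
            "true_volume_um3": truth.true_volume_um3,
            "basement_row": truth.basement_row,
            "central_index": truth.central_index,
            "transforms": [t.to_dict() for t in truth.transforms],
            "nuclei": truth.nuclei.to_dict(orient="list"),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(sidecar))
    return outdir


def read_stack(outdir: str | Path) -> tuple[list[SectionImage], dict | None]:
    outdir = Path(outdir)
    sidecar = None
    gt_path = outdir / "ground_truth.json"
    if gt_path.exists():
        sidecar = json.loads(gt_path.read_text())
    px = sidecar["pixel_size_um"] if sidecar else 1.0
    dz = sidecar["section_thickness_um"] if sidecar else 1.0
    sections = []
    for path in sorted(outdir.glob("section_*.png")):
        index = int(path.stem.split("_")[1])
        sections.append(SectionImage(index, iio.imread(path), px, dz))
    return sections, sidecar
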