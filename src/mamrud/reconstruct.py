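"""3D reconstruction of rudiments from aligned serial sections.

Consecutive sections are registered to the first section of the stack with
non-reflective similarity transforms estimated from three control points
(two in the ectoderm plus the rudiment centre).  The aligned stack is
converted to inverted grayscale on [0, 1]; dark BrdU+ nuclei are segmented
with a fixed 0.65 threshold, connected in 3D (26-connectivity, anisotropic
voxels of pixel_size x pixel_size x section_thickness), size-filtered with a
priori knowledge of nuclear size, and touching nuclei are split by a
distance-transform-seeded geodesic partition.  Iso-surface meshes of any
labelled tissue are extracted with marching cubes in physical coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, measure, segmentation as skseg

from mamrud.errors import ValidationError
from mamrud.phantom import SectionImage
from mamrud.transform import SimilarityTransform2D, fit_similarity, warp_image

__all__ = [
    "NucleusSet",
    "SurfaceMesh",
    "align_stack",
    "to_inverted_gray",
    "extract_label_voxels",
    "split_touching",
    "isosurface",
    "fit_similarity",
    "SimilarityTransform2D",
]

#: ITU-R 601 luma weights used for the grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class NucleusSet:
    """Labelled 3D nuclei with anisotropic voxel spacing.

    ``labels`` is a (n_sections, H, W) int array; ``spacing_um`` is
    (section_thickness, pixel_size, pixel_size); ``table`` has one row per
    nucleus: id, centroid in um (z, y, x), voxel count.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    table: pd.DataFrame

    @property
    def count(self) -> int:
        return int(len(self.table))


@dataclass
class SurfaceMesh:
    """Triangulated iso-surface of one tissue in physical um coordinates."""

    vertices: np.ndarray  # (V, 3) um, (z, y, x)
    faces: np.ndarray  # (F, 3) vertex indices
    tissue: str

    def enclosed_volume_um3(self) -> float:
        import trimesh

        mesh = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        return float(abs(mesh.volume))

    def save_ply(self, path) -> None:
        import trimesh

        trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False).export(
            str(path), file_type="ply", encoding="ascii"
        )


def _nucleus_table(labels: np.ndarray, spacing: tuple[float, float, float]) -> pd.DataFrame:
    rows = []
    for region in measure.regionprops(labels):
        cz, cy, cx = region.centroid
        rows.append(
            {
                "id": int(region.label),
                "centroid_z_um": cz * spacing[0],
                "centroid_y_um": cy * spacing[1],
                "centroid_x_um": cx * spacing[2],
                "voxels": int(region.area),
            }
        )
    return pd.DataFrame(rows, columns=["id", "centroid_z_um", "centroid_y_um", "centroid_x_um", "voxels"])


def align_stack(
    sections: list[SectionImage],
    control_points: dict[int, np.ndarray],
    order: int = 1,
    cval: float = 249.0,
) -> tuple[list[SectionImage], list[SimilarityTransform2D | None]]:
    """Register every section into the frame of the first section.

    ``control_points[i]`` holds the three (row, col) landmarks of section
    ``i`` (same anatomical points in every section, e.g. two ectoderm marks
    and the rudiment centre).  For each section the similarity transform
    mapping its landmarks onto those of the first section is estimated and
    the image resampled accordingly (bilinear by default).  Sections without
    control points are passed through unchanged with a warning and a
    ``None`` transform recorded.
    """
    if len(sections) == 0:
        raise ValidationError("empty stack", field="sections")
    if len(sections) == 1:
        return list(sections), [SimilarityTransform2D()]
    ref_index = sections[0].index
    if ref_index not in control_points:
        raise ValidationError("control points for the first section are required", field="control_points")
    ref = np.asarray(control_points[ref_index], dtype=float)

    aligned: list[SectionImage] = []
    transforms: list[SimilarityTransform2D | None] = []
    for sec in sections:
        if sec.index not in control_points:
            warnings.warn(f"section {sec.index}: no control points; left unaligned", RuntimeWarning, stacklevel=2)
            aligned.append(sec)
            transforms.append(None)
            continue
        tform = fit_similarity(np.asarray(control_points[sec.index], dtype=float), ref)
        img = sec.image if tform.is_identity(tol=1e-12) else warp_image(sec.image, tform, order=order, cval=cval)
        aligned.append(SectionImage(sec.index, img, sec.pixel_size_um, sec.section_thickness_um))
        transforms.append(tform)
    return aligned, transforms


def control_point_residual(
    control_points: dict[int, np.ndarray],
    transforms: list[SimilarityTransform2D | None],
    indices: list[int],
) -> float:
    """Mean distance of (transformed) landmarks to the reference landmarks."""
    ref = np.asarray(control_points[indices[0]], dtype=float)
    dists = []
    for idx, tform in zip(indices, transforms):
        pts = np.asarray(control_points[idx], dtype=float)
        if tform is not None:
            pts = tform.apply(pts)
        dists.append(np.linalg.norm(pts - ref, axis=1).mean())
    return float(np.mean(dists))


def to_inverted_gray(image: np.ndarray) -> np.ndarray:
    """Inverted grayscale on [0, 1]: dark stain maps to high values."""
    if image.ndim == 3:
        gray = image[..., :3].astype(float) @ _LUMA
    else:
        gray = image.astype(float)
    return 1.0 - gray / 255.0


def extract_label_voxels(
    sections: list[SectionImage],
    threshold: float = 0.65,
    size_window: tuple[int, int] | None = None,
    expected_nucleus_voxels: float | None = None,
) -> NucleusSet:
    """Segment BrdU+ nuclei in 3D from an aligned stack.

    Pixels whose inverted grayscale exceeds ``threshold`` (default 0.65,
    which isolates the near-black DAB precipitate) are connected in 3D with
    26-connectivity; components outside ``size_window`` voxels are removed
    as noise or artefacts.  When only ``expected_nucleus_voxels`` is given,
    the window defaults to 0.3x-3x that volume.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)", field="threshold")
    if len(sections) == 0:
        raise ValidationError("empty stack", field="sections")
    if size_window is None:
        if expected_nucleus_voxels is not None:
            size_window = (max(1, int(0.3 * expected_nucleus_voxels)), int(3 * expected_nucleus_voxels) + 1)
        else:
            size_window = (1, np.iinfo(np.int64).max)

    stack = np.stack([to_inverted_gray(sec.image) for sec in sections])
    mask = stack >= threshold
    labels, _ = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    counts = np.bincount(labels.ravel())
    lo, hi = size_window
    bad = np.where((counts < lo) | (counts > hi))[0]
    if bad.size:
        labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _ = ndi.label(labels > 0, structure=np.ones((3, 3, 3), dtype=bool))

    sec0 = sections[0]
    spacing = (sec0.section_thickness_um, sec0.pixel_size_um, sec0.pixel_size_um)
    return NucleusSet(labels=labels, spacing_um=spacing, table=_nucleus_table(labels, spacing))


def split_touching(
    nuclei: NucleusSet,
    min_separation_um: float | None = None,
) -> NucleusSet:
    """Split fused nuclei by a distance-transform-seeded geodesic partition.

    Seeds are the local maxima of the anisotropy-aware Euclidean distance
    transform of the foreground; every foreground voxel is assigned to the
    nearest seed by geodesic (within-foreground) distance, implemented as a
    watershed of the negated distance map.  Singleton components are
    unchanged, and the union of the split labels equals the input foreground
    exactly.  ``min_separation_um`` sets the minimum distance between seeds
    (default: one median nucleus diameter estimate from the distance map).
    """
    mask = nuclei.labels > 0
    if not mask.any():
        return nuclei
    spacing = np.asarray(nuclei.spacing_um, dtype=float)
    dist = ndi.distance_transform_edt(mask, sampling=spacing)
    if min_separation_um is None:
        min_separation_um = 2.0 * float(np.median(dist[mask])) + spacing.min()
    # Seed suppression must respect anisotropy: candidate maxima are found
    # with a neighbourhood min_separation_um wide along each *physical*
    # axis (many in-plane pixels, typically a single 5-6 um section in z),
    # then plateau duplicates are removed greedily by physical distance so
    # stacked nuclei in consecutive sections keep separate seeds.
    footprint = np.ones(
        tuple(max(1, 2 * int(min_separation_um / s) + 1) for s in spacing), dtype=bool
    )
    candidates = feature.peak_local_max(
        dist, labels=nuclei.labels, footprint=footprint, exclude_border=False
    )
    values = dist[tuple(candidates.T)]
    physical = candidates * spacing
    kept: list[int] = []
    for i in np.argsort(-values):
        if all(np.linalg.norm(physical[i] - physical[j]) >= min_separation_um for j in kept):
            kept.append(i)
    peaks = candidates[kept]
    markers = np.zeros_like(nuclei.labels)
    for i, (z, y, x) in enumerate(peaks, start=1):
        markers[z, y, x] = i
    if markers.max() == 0:
        return nuclei
    labels = skseg.watershed(-dist, markers=markers, mask=mask)
    return NucleusSet(labels=labels, spacing_um=nuclei.spacing_um, table=_nucleus_table(labels, nuclei.spacing_um))


def isosurface(mask: np.ndarray, spacing_um: tuple[float, float, float], tissue: str) -> SurfaceMesh:
    """Triangulated 0.5-level surface of a binary mask in um coordinates.

    The mask is zero-padded so that surfaces touching the array border are
    closed; for convex solids the resulting mesh is watertight and its
    enclosed volume approximates the voxel volume.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValidationError("3D mask required", field="mask")
    if not mask.any():
        raise ValidationError("empty mask has no surface", field="mask")
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing_um)
    verts -= np.asarray(spacing_um)  # undo the one-voxel pad offset
    return SurfaceMesh(vertices=verts, faces=faces, tissue=tissue)
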