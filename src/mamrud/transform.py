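"""Non-reflective 2D similarity transforms for serial-section registration.

A non-reflective similarity transform is a rotation plus uniform scaling plus
translation; the determinant of its linear part is ``s**2 > 0``, so mirror
images are excluded.  Consecutive sections of a stack are registered to the
first section with such transforms estimated from three manually placed
control points (two in the ectoderm, one at the rudiment centre).

Convention: point arrays everywhere in this package are ``(row, col)`` pixel
coordinates, matching NumPy image indexing.  Internally the transform acts on
``(x, y) = (col, row)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from mamrud.errors import ValidationError

__all__ = ["SimilarityTransform2D", "fit_similarity", "warp_image"]


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Rotation by ``rotation`` rad, uniform ``scale``, then translation.

    ``translation`` is ``(tx, ty)`` in pixel units along (col, row) axes.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValidationError("scale must be finite and > 0", field="scale")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        tx, ty = self.translation
        return np.array(
            [
                [self.scale * c, -self.scale * s, tx],
                [self.scale * s, self.scale * c, ty],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "SimilarityTransform2D":
        matrix = np.asarray(matrix, dtype=float)
        linear = matrix[:2, :2]
        det = np.linalg.det(linear)
        if det <= 0:
            raise ValidationError("reflective transform (det <= 0)", field="matrix")
        scale = float(np.sqrt(det))
        # Uniform-scale check: both columns must have norm == scale.
        norms = np.linalg.norm(linear, axis=0)
        if not np.allclose(norms, scale, rtol=1e-6, atol=1e-9):
            raise ValidationError("matrix is not a similarity", field="matrix")
        rotation = float(np.arctan2(linear[1, 0], linear[0, 0]))
        return cls(scale=scale, rotation=rotation, translation=(float(matrix[0, 2]), float(matrix[1, 2])))

    def apply(self, points_rc: np.ndarray) -> np.ndarray:
        """Map ``(row, col)`` points through the transform."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        xy = pts[:, ::-1]
        out_xy = xy @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        out = out_xy[:, ::-1]
        return out if np.asarray(points_rc).ndim == 2 else out[0]

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """Return the transform applying ``other`` first, then ``self``."""
        return SimilarityTransform2D.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "SimilarityTransform2D":
        return SimilarityTransform2D.from_matrix(np.linalg.inv(self.matrix))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))

    def to_dict(self) -> dict:
        return {
            "scale": float(self.scale),
            "rotation": float(self.rotation),
            "translation": [float(t) for t in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform2D":
        return cls(scale=d["scale"], rotation=d["rotation"], translation=tuple(d["translation"]))


def fit_similarity(src_rc: np.ndarray, dst_rc: np.ndarray) -> SimilarityTransform2D:
    """Least-squares non-reflective similarity transform mapping src to dst.

    Uses the closed-form Umeyama solution (through scikit-image), which
    constrains the linear part to a positive-determinant rotation-scaling.
    Exact when the point sets are truly similarity-related.

    Parameters
    ----------
    src_rc, dst_rc : (N, 2) arrays of matched ``(row, col)`` points, N >= 2
        (N >= 3 for the registration use case).

    Raises
    ------
    ValidationError
        If fewer than two distinct points are given or the source points are
        collinear/duplicate so the problem is degenerate.
    """
    src = np.atleast_2d(np.asarray(src_rc, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_rc, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2 or src.shape[1] != 2:
        raise ValidationError("need matched (N, 2) point arrays with N >= 2", field="control_points")
    centered = src - src.mean(axis=0)
    # Collinear or coincident source points leave rotation/scale unresolved.
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValidationError("control points are collinear or duplicated", field="control_points")
    tform = sktransform.SimilarityTransform.from_estimate(src[:, ::-1], dst[:, ::-1])  # skimage wants (x, y)
    if not tform or not np.all(np.isfinite(tform.params)):
        raise ValidationError("similarity estimation failed", field="control_points")
    return SimilarityTransform2D.from_matrix(tform.params)


def warp_image(
    image: np.ndarray,
    transform: SimilarityTransform2D,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` under ``transform`` (forward mapping of content).

    A feature at point ``p`` in the input appears at ``transform.apply(p)``
    in the output.  ``order=1`` (bilinear) suits intensity images, ``order=0``
    (nearest neighbour) label masks.  Output dtype matches the input.
    """
    inv = sktransform.SimilarityTransform(matrix=transform.inverse().matrix)
    out = sktransform.warp(
        image.astype(float), inverse_map=inv, order=order, cval=cval, preserve_range=True
    )
    if np.issubdtype(image.dtype, np.integer) or image.dtype == bool:
        out = np.rint(out)
        if image.dtype == bool:
            return out > 0.5
        info = np.iinfo(image.dtype)
        return np.clip(out, info.min, info.max).astype(image.dtype)
    return out.astype(image.dtype)
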