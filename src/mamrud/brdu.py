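"""Colour-threshold segmentation and tabulation of BrdU incorporation.

BrdU+ nuclei carry a dark brown DAB precipitate; all nuclei are additionally
marked by the blue hematoxylin counterstain.  Manual colour thresholding
separates the two classes, and the BrdU+ fraction of all nuclear *pixels*
per compartment serves as the proliferation-rate proxy.  Pixel areas rather
than cell counts are quantified because the immuno-precipitate saturates:
both daughters of a labelled cell stain as strongly as their mother, so
pixel area tracks labelled mass.

Fractions over compartments with no nuclear pixels are undefined and
propagate as NaN, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mamrud.compartments import Compartment, ECTODERM_COMPARTMENTS, MR_COMPARTMENTS
from mamrud.errors import ValidationError
from mamrud.segmentation import CompartmentLabeling

__all__ = [
    "ColorRule",
    "ThresholdParams",
    "threshold_nuclei",
    "tabulate",
    "pooled_fraction",
    "dv_difference",
    "ectoderm_mr_ratio",
    "counts_to_csv",
]


@dataclass(frozen=True)
class ColorRule:
    """Conjunction of per-channel windows selecting a stain colour.

    Each bound is an inclusive ``(lo, hi)`` window on the 0-255 channel
    value; ``b_minus_r`` optionally bounds the blue-minus-red difference,
    which separates hematoxylin blue from both brown and pale pink.
    """

    r: tuple[int, int] = (0, 255)
    g: tuple[int, int] = (0, 255)
    b: tuple[int, int] = (0, 255)
    b_minus_r: tuple[int, int] | None = None

    def __post_init__(self):
        for name in ("r", "g", "b"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ValidationError("window must satisfy 0 <= lo <= hi <= 255", field=name)

    def evaluate(self, image: np.ndarray) -> np.ndarray:
        r = image[..., 0].astype(int)
        g = image[..., 1].astype(int)
        b = image[..., 2].astype(int)
        mask = (
            (r >= self.r[0]) & (r <= self.r[1])
            & (g >= self.g[0]) & (g <= self.g[1])
            & (b >= self.b[0]) & (b <= self.b[1])
        )
        if self.b_minus_r is not None:
            lo, hi = self.b_minus_r
            mask &= (b - r >= lo) & (b - r <= hi)
        return mask


# DAB brown: all channels dark.  Hematoxylin blue: strong blue excess over
# red.  Tuned to the phantom palette; real slides need user-set windows.
DAB_RULE = ColorRule(r=(0, 130), g=(0, 115), b=(0, 115), b_minus_r=(-255, 20))
HEMATOXYLIN_RULE = ColorRule(b=(100, 255), b_minus_r=(25, 255))


@dataclass(frozen=True)
class ThresholdParams:
    """Colour rules for BrdU+ pixels and for all stained (nuclear) pixels.

    ``nuclei_rules`` should cover both stains; the BrdU mask is intersected
    with the nuclei mask so that BrdU-selected pixels are always a subset of
    nuclei-selected pixels.
    """

    brdu_rules: tuple[ColorRule, ...] = (DAB_RULE,)
    nuclei_rules: tuple[ColorRule, ...] = (DAB_RULE, HEMATOXYLIN_RULE)


def threshold_nuclei(
    image: np.ndarray, params: ThresholdParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Segment BrdU+ and all-nuclei pixels by colour thresholding.

    Returns ``(brdu_mask, nuclei_mask)`` with ``brdu_mask`` a subset of
    ``nuclei_mask`` by construction.  Requires an RGB image: channel rules
    are meaningless on grayscale input.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValidationError("RGB image required for colour thresholding", field="image")
    params = params or ThresholdParams()
    nuclei = np.zeros(image.shape[:2], dtype=bool)
    for rule in params.nuclei_rules:
        nuclei |= rule.evaluate(image)
    brdu = np.zeros(image.shape[:2], dtype=bool)
    for rule in params.brdu_rules:
        brdu |= rule.evaluate(image)
    return brdu & nuclei, nuclei


def tabulate(
    labeling: CompartmentLabeling,
    brdu_mask: np.ndarray,
    nuclei_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-compartment nuclear and BrdU+ pixel counts and fractions.

    One row per compartment plus aggregate rows ``MR`` (core + periphery +
    neck, exactly additive) and ``ECTODERM`` (dorsal + ventral pooled).
    ``fraction`` is BrdU+ pixels over all nuclear pixels, NaN where a
    compartment holds no nuclear pixels.
    """
    if brdu_mask.shape != labeling.labels.shape or nuclei_mask.shape != labeling.labels.shape:
        raise ValidationError("masks and labeling must share shape", field="brdu_mask")
    rows = []
    for comp in Compartment:
        if comp is Compartment.BACKGROUND:
            continue
        mask = labeling.mask(comp)
        nuc = int(np.count_nonzero(nuclei_mask & mask))
        pos = int(np.count_nonzero(brdu_mask & mask))
        rows.append({"compartment": comp.name, "nuclear_pixels": nuc, "brdu_pixels": pos})
    table = pd.DataFrame(rows).set_index("compartment")
    for name, comps in (("MR", MR_COMPARTMENTS), ("ECTODERM", ECTODERM_COMPARTMENTS)):
        sub = table.loc[[c.name for c in comps]]
        table.loc[name] = sub.sum()
    table["fraction"] = np.where(
        table["nuclear_pixels"] > 0, table["brdu_pixels"] / table["nuclear_pixels"].replace(0, 1), np.nan
    )
    return table


def pooled_fraction(tables: list[pd.DataFrame], compartment: str) -> float:
    """Pixel-pooled BrdU+ fraction of one compartment across sections."""
    nuc = sum(int(t.loc[compartment, "nuclear_pixels"]) for t in tables)
    pos = sum(int(t.loc[compartment, "brdu_pixels"]) for t in tables)
    return pos / nuc if nuc > 0 else float("nan")


def dv_difference(ventral_fraction: float, dorsal_fraction: float) -> float:
    """Signed labelling difference: ventral minus dorsal ectoderm fraction.

    Undefined (NaN) inputs propagate to an undefined result.
    """
    return float(ventral_fraction) - float(dorsal_fraction)


def ectoderm_mr_ratio(ectoderm_fraction: float, mr_fraction: float) -> float:
    """Fold difference of ectodermal over rudiment labelling fraction.

    A zero rudiment fraction yields ``inf`` with a warning rather than an
    exception, mirroring how a ratio table flags such specimens.
    """
    if np.isnan(ectoderm_fraction) or np.isnan(mr_fraction):
        return float("nan")
    if mr_fraction == 0:
        warnings.warn("rudiment fraction is zero; ratio reported as inf", RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(ectoderm_fraction) / float(mr_fraction)


def counts_to_csv(
    path,
    per_section: dict[int, pd.DataFrame],
    specimen: str = "specimen",
) -> pd.DataFrame:
    """Write one row per (specimen, section, compartment) to CSV."""
    frames = []
    for index, table in sorted(per_section.items()):
        frame = table.reset_index()
        frame.insert(0, "section", index)
        frame.insert(0, "specimen", specimen)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    return out
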