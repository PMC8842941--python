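"""H-DAB stain separation by color deconvolution.

Brightfield immunohistochemistry obeys Beer–Lambert absorption: the
optical density of a pixel, OD_c = −log10(I_c / I0_c), is linear in the
per-stain concentrations, OD = c_H·v_H + c_D·v_D (+ residual), where v_H
and v_D are unit vectors in OD space characteristic of hematoxylin (blue
nuclear counterstain) and DAB (the brown chromogen marking α-synuclein).
Deconvolution inverts this linear system per pixel, yielding concentration
maps from which per-slide stain statistics are pooled over the detected
LTS patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Standard H-DAB optical-density triplets (unit-normalized below).
_H_OD = (0.650, 0.704, 0.286)
_DAB_OD = (0.269, 0.568, 0.778)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainModel:
    """Stain-separation basis: unit OD vectors for hematoxylin and DAB.

    The third basis vector is the normalized cross product of the two,
    capturing whatever absorbance the two stains cannot explain.
    """

    od_vector_hematoxylin: tuple = _H_OD
    od_vector_dab: tuple = _DAB_OD
    background_intensity: tuple = (255, 255, 255)

    def __post_init__(self) -> None:
        h = _unit(self.od_vector_hematoxylin)
        d = _unit(self.od_vector_dab)
        if np.linalg.norm(np.cross(h, d)) < 1e-8:
            raise ValidationError("stain vectors are collinear")
        object.__setattr__(self, "od_vector_hematoxylin", tuple(h))
        object.__setattr__(self, "od_vector_dab", tuple(d))

    @property
    def basis(self) -> np.ndarray:
        """3×3 matrix whose rows are the H, DAB and residual unit vectors."""
        h = np.asarray(self.od_vector_hematoxylin)
        d = np.asarray(self.od_vector_dab)
        r = _unit(np.cross(h, d))
        return np.stack([h, d, r])


@dataclass
class StainChannels:
    """Per-pixel stain concentration maps in OD units."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray


def od_transform(rgb: np.ndarray, i0=(255, 255, 255)) -> np.ndarray:
    """Convert an RGB image to optical density: OD_c = −log10(I_c / I0_c).

    Zero intensities are clamped to 1 before the log so fully dark pixels
    map to a large finite density.
    """
    img = np.asarray(rgb, dtype=float)
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), img.shape[-1:])
    n_clamped = int(np.sum(img < 1))
    if n_clamped:
        log.debug("od_transform clamped %d sub-unit intensities", n_clamped)
    img = np.clip(img, 1.0, None)
    return -np.log10(img / i0)


def od_inverse(od: np.ndarray, i0=(255, 255, 255)) -> np.ndarray:
    """Invert :func:`od_transform`: I_c = I0_c · 10^(−OD_c)."""
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), np.asarray(od).shape[-1:])
    return i0 * 10.0 ** (-np.asarray(od, dtype=float))


def deconvolve(od: np.ndarray, model: StainModel | None = None) -> StainChannels:
    """Solve per-pixel concentrations against the stain basis.

    The 3×3 basis (H, DAB, residual) is exactly invertible, so the
    least-squares solution reduces to a linear map; negative concentrations
    are clamped to zero (count logged) since absorbance is non-negative.
    """
    model = model or StainModel()
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValidationError("OD image must have 3 channels")
    inv = np.linalg.inv(model.basis.T)
    conc = od @ inv.T
    n_neg = int(np.sum(conc[..., :2] < -1e-12))
    if n_neg:
        log.debug("deconvolve clamped %d negative concentrations", n_neg)
    conc = np.clip(conc, 0.0, None)
    return StainChannels(conc[..., 0], conc[..., 1], conc[..., 2])


def stain_statistics(channels: StainChannels, grid) -> dict[str, float]:
    """Pooled {sum, mean, median, sd} of H and DAB inside positive cells.

    ``grid`` is a :class:`~ltsq.detector.PatchGrid` aligned to the channel
    maps.  Statistics pool all pixels lying in positive 40×40 cells; the SD
    uses the population denominator n.  An empty grid yields NaN for every
    statistic.
    """
    mask = grid.pixel_mask()
    if mask.shape != channels.hematoxylin.shape:
        raise ValidationError("grid does not align with channel maps")
    out: dict[str, float] = {}
    for name, chan in (("hematoxylin", channels.hematoxylin), ("dab", channels.dab)):
        vals = np.asarray(chan)[mask]
        if vals.size == 0:
            stats = dict.fromkeys(("sum", "mean", "median", "sd"), float("nan"))
        else:
            stats = {
                "sum": float(np.sum(vals)),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "sd": float(np.std(vals)),
            }
        for k, v in stats.items():
            out[f"{name}_{k}"] = v
    return out


def tissue_mask(
    rgb: np.ndarray,
    model: StainModel | None = None,
    threshold: float = 0.05,
    median_size: int = 3,
) -> tuple[np.ndarray, int]:
    """Segment tissue from glass: total OD magnitude ≥ threshold.

    The OD magnitude image is median-smoothed (size ``median_size``) to
    suppress salt noise before thresholding.  Returns the boolean mask and
    the tissue pixel count.
    """
    model = model or StainModel()
    od = od_transform(rgb, model.background_intensity)
    mag = np.linalg.norm(od, axis=-1)
    if median_size > 1:
        mag = ndimage.median_filter(mag, size=median_size)
    mask = mag >= threshold
    return mask, int(mask.sum())
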