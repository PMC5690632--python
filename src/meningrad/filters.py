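"""Filtered image channels: undecimated 3D wavelet subbands and LoG scales.

Texture features are extracted not only from the original volume but from a
bank of filtered channels that emphasize detail at different scales:

* eight subbands of a single-level undecimated (stationary) 3D wavelet
  transform, one per low/high combination along (x, y, z) — labels
  ``LLL`` ... ``HHH`` where the k-th letter is the filter applied along the
  k-th axis;
* ten Laplacian-of-Gaussian responses at sigma = 0.5 ... 5.0 mm in 0.5 mm
  steps, labelled ``LoG1`` ... ``LoG10`` (``LoGk`` <-> sigma = 0.5 k mm).

The wavelet family is Coiflet-1 (orthonormal, single level), the convention
of the radiomics signature literature this feature set follows.  Both
filters use symmetric (mirror) boundary extension, and every channel keeps
the input grid shape.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .imaging import DegenerateInputError, VolumeImage

WAVELET_FAMILY = "coif1"
WAVELET_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
LOG_LABELS = tuple(f"LoG{k}" for k in range(1, 11))
LOG_SIGMAS_MM = {f"LoG{k}": 0.5 * k for k in range(1, 11)}
CHANNEL_LABELS = ("original",) + WAVELET_LABELS + LOG_LABELS


@dataclass
class FilteredChannel:
    label: str
    image: VolumeImage

    def __post_init__(self) -> None:
        if self.label not in CHANNEL_LABELS:
            raise ValueError(f"unknown channel label {self.label!r}")


def _filter_pair() -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(WAVELET_FAMILY)
    return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def wavelet_subbands(img: VolumeImage) -> list[FilteredChannel]:
    """Single-level undecimated 3D wavelet transform, one channel per subband.

    The subband label letter k ('L' low-pass / 'H' high-pass) names the
    filter applied along axis k (x, y, z).  All subbands retain the input
    shape; high-pass of a constant field is identically zero.
    """
    lo, hi = _filter_pair()
    flen = len(lo)
    if min(img.shape) < flen:
        raise DegenerateInputError(
            f"image shape {img.shape} smaller than the wavelet filter length {flen}"
        )
    bank = {"L": lo, "H": hi}
    out = []
    for letters in itertools.product("LH", repeat=3):
        label = "".join(letters)
        res = img.values.astype(np.float64)
        for axis, letter in enumerate(letters):
            res = ndimage.correlate1d(res, bank[letter], axis=axis, mode="mirror")
        out.append(
            FilteredChannel(label, VolumeImage(res, spacing=img.spacing, origin=img.origin))
        )
    order = {lab: i for i, lab in enumerate(WAVELET_LABELS)}
    out.sort(key=lambda ch: order[ch.label])
    return out


def log_filter(img: VolumeImage, sigma_mm: float) -> FilteredChannel:
    """Laplacian-of-Gaussian response at a physical scale sigma (mm).

    sigma is converted to per-axis voxel units through the voxel spacing, so
    the same physical blob produces the same center response on grids of
    different resolution.  The label requires sigma on the 0.5 mm grid.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    k = sigma_mm / 0.5
    if abs(k - round(k)) > 1e-9 or not (1 <= round(k) <= 10):
        raise ValueError(f"sigma_mm={sigma_mm} is not on the 0.5..5.0 mm half-mm grid")
    label = f"LoG{int(round(k))}"
    if sigma_mm < 0.5 * max(img.spacing):
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is under-resolved at voxel spacing {img.spacing}",
            stacklevel=2,
        )
    # second derivatives are taken in physical (mm) units: each axis term is
    # computed in voxel units and divided by spacing^2; a wide truncation
    # keeps the kernel's DC response negligible (zero response on constants)
    vals = img.values.astype(np.float64)
    res = np.zeros_like(vals)
    for axis, sp in enumerate(img.spacing):
        order = [0, 0, 0]
        order[axis] = 2
        res += (
            ndimage.gaussian_filter(
                vals, sigma=[sigma_mm / s for s in img.spacing], order=order,
                mode="mirror", truncate=8.0,
            )
            / sp**2
        )
    return FilteredChannel(label, VolumeImage(res, spacing=img.spacing, origin=img.origin))


def get_channel(img: VolumeImage, label: str) -> FilteredChannel:
    """Compute a single named channel ('original', wavelet subband, or LoG scale)."""
    if label == "original":
        return FilteredChannel("original", img)
    if label in WAVELET_LABELS:
        for ch in wavelet_subbands(img):
            if ch.label == label:
                return ch
    if label in LOG_LABELS:
        return log_filter(img, LOG_SIGMAS_MM[label])
    raise ValueError(f"unknown channel label {label!r}")
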