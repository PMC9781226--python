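"""Shared low-level helpers: CLAHE wrapper, binary morphology, blob picking.

Binary morphology border convention used package-wide:

* opening  = erosion (outside counts as background) then dilation
* closing  = dilation (outside counts as background) then erosion with the
  outside counting as foreground, so closing never eats mask interiors that
  touch the border.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, measure


#: histogram bins used by the CLAHE implementation
_CLAHE_NBINS = 256


def clahe(grid: np.ndarray, clip: float, tiles: tuple[int, int]) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit grid.

    ``clip`` is expressed as a multiple of the uniform histogram bin height
    (so 1 is the gentlest limit, larger values enhance more); an
    unlimited-clip AHE would map each tile's darkest pixel to black, which
    destroys the global darkness ordering that the threshold rules
    downstream depend on.  ``tiles`` is the number of tiles per axis
    (rows, cols).  Returns float64 in [0, 255].
    """
    g = np.asarray(grid, dtype=np.float64) / 255.0
    h, w = g.shape
    kernel = (max(1, h // tiles[0]), max(1, w // tiles[1]))
    enh = exposure.equalize_adapthist(np.clip(g, 0, 1), kernel_size=kernel,
                                      clip_limit=min(1.0, clip / _CLAHE_NBINS))
    return enh * 255.0


def binary_opening(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    er = ndi.binary_erosion(mask, structure=footprint, border_value=0)
    return ndi.binary_dilation(er, structure=footprint, border_value=0)


def binary_closing(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    di = ndi.binary_dilation(mask, structure=footprint, border_value=0)
    return ndi.binary_erosion(di, structure=footprint, border_value=1)


def largest_blob(mask: np.ndarray, intensity: np.ndarray | None = None):
    """Largest 8-connected component of a binary mask.

    Ties on area are broken by brighter mean intensity (when given), then by
    scan order (leftmost-topmost label).  Returns ``(blob_mask, centroid_xy,
    area)`` or ``None`` for an empty mask.
    """
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return None
    props = measure.regionprops(labels, intensity_image=intensity)
    best = None
    for p in props:
        mean = float(p.intensity_mean) if intensity is not None else 0.0
        key = (p.area, mean, -p.label)
        if best is None or key > best[0]:
            best = (key, p)
    p = best[1]
    blob = labels == p.label
    cy, cx = p.centroid
    return blob, (float(cx), float(cy)), int(p.area)
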