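"""Template (prior) image construction.

The template is the artifact-free surrogate of the kV slice: high-density
pixels (M1) keep the source values, while the soft-tissue (M2) and
low-density (M3) regions are filled with their respective regional mean of
the source image.  Because the means are taken over whole regions, streaks
average out and the template's forward projection predicts what the sinogram
should look like without artifacts.  On later iterations the fill means are
recomputed from the current corrected image, which progressively de-biases
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import SliceImage
from .segmentation import TissueMasks

log = logging.getLogger(__name__)


@dataclass
class TemplateImage:
    """Piecewise-filled template: values + the fill means / pixel counts used."""

    image: SliceImage
    mean_m2: float | None
    mean_m3: float | None
    n_m2: int
    n_m3: int
    iteration: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.image.values


def build_template(source: SliceImage, masks: TissueMasks, iteration: int = 0,
                   mean_source: SliceImage | None = None) -> TemplateImage:
    """Fill M2 and M3 with their regional means; copy M1 from ``source``.

    By default the fill means come from ``source`` itself.  The iteration
    loop passes the latest corrected image as ``mean_source`` so that only
    the fill means update across iterations while M1 keeps the original kV
    values.  An empty M2 or M3 skips that fill with a warning (the region
    invariant is vacuously satisfied).
    """
    if masks.m1.shape != source.shape:
        raise ValidationError("masks do not match the source image shape")
    mean_source = source if mean_source is None else mean_source
    if mean_source.shape != source.shape:
        raise ValidationError("mean_source does not match the source image shape")
    values = source.values.copy()
    n_m2 = int(masks.m2.sum())
    n_m3 = int(masks.m3.sum())
    mean_m2 = mean_m3 = None
    if n_m2 > 0:
        mean_m2 = float(mean_source.values[masks.m2].mean())
        values[masks.m2] = mean_m2
    else:
        log.warning("template: M2 is empty, skipping soft-tissue fill")
    if n_m3 > 0:
        mean_m3 = float(mean_source.values[masks.m3].mean())
        values[masks.m3] = mean_m3
    else:
        log.warning("template: M3 is empty, skipping low-density fill")
    image = SliceImage(values, source.pixel_spacing, modality="template")
    return TemplateImage(image, mean_m2, mean_m3, n_m2, n_m3, iteration)
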