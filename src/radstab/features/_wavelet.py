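"""Single-level stationary wavelet decomposition of the analysis frame.

The stationary (undecimated) transform keeps every sub-band at the frame's
size, so the original lesion mask applies directly to each filtered image.
Band names follow the <row filter><column filter> convention: LH is low-pass
along rows (y) and high-pass along columns (x), i.e. it responds to intensity
variation in the x direction.
"""

from __future__ import annotations

import numpy as np
import pywt

BAND_NAMES = ("LL", "LH", "HL", "HH")


def wavelet_variants(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Four same-size sub-band images {LL, LH, HL, HH} of a 2D frame.

    Frames smaller than 8x8 raise ``ValueError`` (the caller is expected to
    skip wavelet families and log).  Odd dimensions are edge-padded to even
    for the transform and cropped back.
    """
    image = np.asarray(image, float)
    if min(image.shape) < 8:
        raise ValueError("frame must be at least 8x8 for the wavelet transform")
    h, w = image.shape
    ph, pw = h % 2, w % 2
    padded = np.pad(image, ((0, ph), (0, pw)), mode="edge")
    (ca, (ch, cv, cd)), = pywt.swt2(padded, wavelet, level=1, norm=True)
    out = {"LL": ca, "LH": cv, "HL": ch, "HH": cd}
    return {k: v[:h, :w] for k, v in out.items()}
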