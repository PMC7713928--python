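"""Acuity-limited rendering of scenes through a viewer's eyes.

A scene image (linear intensity, known physical width and viewing distance) is
taken to the frequency domain, each spatial frequency (in cycles/degree of the
viewer's visual field) is attenuated by a single-parameter modulation transfer
function of the viewer's minimum resolvable angle, and the result is
transformed back.  Frequencies above the viewer's acuity threshold are wiped
out, leaving only the detail the viewer could actually resolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .acuity import subtended_angle

__all__ = [
    "SceneImage",
    "to_linear",
    "to_display",
    "snyder_mtf",
    "acuity_filter",
    "MTF_CONSTANT",
]

#: exponential MTF constant: exp(-3.56) ~ 3%, the contrast threshold at the
#: resolution limit in the underlying psychophysical model
MTF_CONSTANT = 3.56

DISPLAY_GAMMA = 2.2


class SceneStateError(ValueError):
    """Operation applied to an image in the wrong gamma state."""


@dataclass(frozen=True)
class SceneImage:
    """Single-channel intensity raster with physical context.

    ``physical_width`` and ``viewing_distance`` are in cm; ``gamma_state``
    records whether the pixel values are linear intensity or display-encoded.
    """

    data: np.ndarray
    physical_width: float
    viewing_distance: float
    gamma_state: str = "linear"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, float)
        if arr.ndim != 2:
            raise ValueError("scene data must be a 2-D single-channel array")
        if arr.shape[1] < 8:
            raise ValueError("scene must be at least 8 pixels wide")
        if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
            raise ValueError("scene values must be finite and within [0, 1]")
        if self.physical_width <= 0 or self.viewing_distance <= 0:
            raise ValueError("physical_width and viewing_distance must be positive")
        if self.gamma_state not in ("linear", "display"):
            raise ValueError("gamma_state must be 'linear' or 'display'")
        object.__setattr__(self, "data", arr)

    @property
    def scene_angle(self) -> float:
        """Horizontal visual angle subtended by the scene, in degrees."""
        return subtended_angle(self.physical_width, self.viewing_distance)

    # -- PNG I/O ------------------------------------------------------------

    @classmethod
    def from_png(
        cls,
        path: str | Path,
        physical_width: float,
        viewing_distance: float,
        gamma_state: str = "display",
    ) -> "SceneImage":
        """Load a PNG; RGB input is converted to one channel by averaging."""
        from PIL import Image

        img = np.asarray(Image.open(path), dtype=float) / 255.0
        if img.ndim == 3:
            img = img[..., :3].mean(axis=2)
        return cls(img, physical_width, viewing_distance, gamma_state)

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        arr = np.clip(np.round(self.data * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)

    def save_sidecar(self, path: str | Path, mra: float | None = None) -> None:
        meta = {
            "physical_width_cm": float(self.physical_width),
            "viewing_distance_cm": float(self.viewing_distance),
            "gamma_state": self.gamma_state,
        }
        if mra is not None:
            meta["mra_degrees"] = float(mra)
        Path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def to_linear(image: SceneImage, gamma: float = DISPLAY_GAMMA) -> SceneImage:
    """Decode display-encoded pixel values to linear intensity."""
    if image.gamma_state != "display":
        raise SceneStateError("image is already linear")
    return replace(image, data=image.data**gamma, gamma_state="linear")


def to_display(image: SceneImage, gamma: float = DISPLAY_GAMMA) -> SceneImage:
    """Encode linear intensity for display."""
    if image.gamma_state != "linear":
        raise SceneStateError("image is already display-encoded")
    return replace(image, data=image.data ** (1.0 / gamma), gamma_state="display")


def snyder_mtf(frequency, mra: float, constant: float = MTF_CONSTANT):
    """Exponential MTF of the viewer: exp(-c (mra * nu)^2).

    ``frequency`` in cycles/degree, ``mra`` in degrees.  Unit gain at DC; the
    attenuation reaches ~3% (exp(-c)) at the resolution limit nu = 1/mra.
    """
    if mra <= 0:
        raise ValueError("mra must be positive")
    nu = np.asarray(frequency, float)
    if np.any(nu < 0):
        raise ValueError("frequency must be non-negative")
    out = np.exp(-constant * (mra * nu) ** 2)
    return float(out) if np.isscalar(frequency) else out


def acuity_filter(
    image: SceneImage,
    mra: float,
    constant: float = MTF_CONSTANT,
    mirror_pad: bool = False,
) -> SceneImage:
    """Render a scene at the spatial resolution of a viewer with the given MRA.

    The image is Fourier-transformed, each frequency-plane element multiplied
    by the MTF at its radial frequency in cycles/degree (isotropic, using the
    horizontal angular scale for both axes), inverse-transformed and clipped
    back to [0, 1].  The DC term is untouched, so mean intensity is preserved
    up to clipping.  ``mirror_pad`` reflects the image before transforming to
    suppress wrap-around at hard borders.
    """
    if image.gamma_state != "linear":
        raise SceneStateError("acuity_filter requires linear intensity; decode first")
    if mra <= 0:
        raise ValueError("mra must be positive")
    data = image.data
    if mirror_pad:
        data = np.block(
            [
                [data, data[:, ::-1]],
                [data[::-1, :], data[::-1, ::-1]],
            ]
        )
    rows, cols = data.shape
    # degrees per pixel from the horizontal scene angle; isotropic mapping
    deg_per_px = image.scene_angle / image.data.shape[1]
    fx = np.fft.fftfreq(cols, d=deg_per_px)
    fy = np.fft.fftfreq(rows, d=deg_per_px)
    nu = np.hypot(fy[:, None], fx[None, :])
    spectrum = np.fft.fft2(data) * snyder_mtf(nu, mra, constant)
    filtered = np.real(np.fft.ifft2(spectrum))
    if mirror_pad:
        filtered = filtered[: image.data.shape[0], : image.data.shape[1]]
    return replace(image, data=np.clip(filtered, 0.0, 1.0))
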