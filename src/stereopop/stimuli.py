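"""Gaussian-noise random-dot stereograms with exact integer 2D disparity.

Each stimulus is a left/right pair of contrast images (zero mean-luminance
reference, i.i.d. standard-normal pixels).  The right image is the left
image shifted by the stimulus disparity; pixels uncovered by the shift are
filled with fresh, independent noise, so the disparity signal lives purely
in the overlap region.  Anticorrelated pairs invert the contrast of the
right image on the overlap (the uncovered border stays fresh noise, whose
sign is immaterial).

Coordinate convention
---------------------
Arrays are indexed ``[iy, ix]`` with x increasing rightward (axis 1) and
y increasing upward (axis 0); the origin sits at the central pixel of an
odd-sized image.  A feature at position p in the left image appears at
p + (dx, dy) in the right image; equivalently, on the overlap,

    I_R(x, y) = I_L(x - dx, y - dy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CORRELATED = "correlated"
ANTICORRELATED = "anticorrelated"
_POLARITIES = (CORRELATED, ANTICORRELATED)


@dataclass(frozen=True)
class Stereogram:
    """A left/right contrast-image pair with known integer 2D disparity.

    Attributes
    ----------
    left, right : ndarray, shape (height, width)
        Contrast images (unitless, relative to mean luminance).
    dx, dy : int
        Horizontal / vertical disparity in pixels.
    polarity : str
        ``"correlated"`` or ``"anticorrelated"``.
    seed : int or None
        Seed used to generate the pair (None for pairs drawn from a
        shared stream).
    """

    left: np.ndarray
    right: np.ndarray
    dx: int
    dy: int
    polarity: str
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape


def overlap_slices(
    shape: tuple[int, int], dx: int, dy: int
) -> tuple[tuple[slice, slice], tuple[slice, slice]]:
    """Index slices of the overlap region in the right and left images.

    Returns ``(right_sl, left_sl)`` such that
    ``right[right_sl] == left[left_sl]`` for a correlated pair:
    ``right[iy, ix] = left[iy - dy, ix - dx]`` wherever both indices are
    valid.
    """
    h, w = shape
    ry = slice(max(dy, 0), h + min(dy, 0))
    rx = slice(max(dx, 0), w + min(dx, 0))
    ly = slice(max(-dy, 0), h + min(-dy, 0))
    lx = slice(max(-dx, 0), w + min(-dx, 0))
    return (ry, rx), (ly, lx)


def shift_image(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift ``image`` by (dx, dy), leaving uncovered pixels as NaN.

    Used by tests to verify the shift convention; the generator itself
    fills uncovered pixels with fresh noise.
    """
    out = np.full_like(image, np.nan, dtype=float)
    (ry, rx), (ly, lx) = overlap_slices(image.shape, dx, dy)
    out[ry, rx] = image[ly, lx]
    return out


def _check_args(width: int, height: int, dx: int, dy: int, polarity: str) -> None:
    if width < 1 or height < 1:
        raise ValueError(f"image size must be >= 1, got {width}x{height}")
    if abs(dx) >= width or abs(dy) >= height:
        raise ValueError(
            f"disparity ({dx},{dy}) leaves no overlap in a {width}x{height} image"
        )
    if polarity not in _POLARITIES:
        raise ValueError(f"polarity must be one of {_POLARITIES}, got {polarity!r}")


def generate_batch(
    n: int,
    width: int,
    height: int,
    dx: int,
    dy: int,
    polarity: str = CORRELATED,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` stereogram pairs from one stream.

    Returns ``(left, right)`` arrays of shape ``(n, height, width)``.
    The left images are i.i.d. standard normal; each right image is the
    shifted left image (contrast-inverted for anticorrelated polarity)
    with fresh noise in the uncovered border.
    """
    _check_args(width, height, dx, dy, polarity)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    left = rng.standard_normal((n, height, width))
    right = rng.standard_normal((n, height, width))
    (ry, rx), (ly, lx) = overlap_slices((height, width), dx, dy)
    right[:, ry, rx] = left[:, ly, lx]
    if polarity == ANTICORRELATED:
        # negate the whole eye (gap noise stays standard normal), so an
        # anticorrelated pair is the exact sign-flipped twin of the
        # correlated pair drawn with the same stream
        np.negative(right, out=right)
    return left, right


def generate_stereogram(
    width: int = 81,
    height: int = 81,
    dx: int = 0,
    dy: int = 0,
    polarity: str = CORRELATED,
    seed: int | None = None,
) -> Stereogram:
    """Generate one uniform-disparity Gaussian-noise stereogram.

    Deterministic given ``seed``.  Raises ``ValueError`` when the disparity
    magnitude reaches the image extent (no overlap would remain to carry
    the disparity signal).
    """
    left, right = generate_batch(
        1, width, height, dx, dy, polarity, np.random.default_rng(seed)
    )
    return Stereogram(left[0], right[0], dx, dy, polarity, seed)
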