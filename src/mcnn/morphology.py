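"""Flat grayscale morphology with learned-binarized structuring elements.

The first layer of each channel network applies four morphological
operations in parallel to the same input image: erosion, dilation, opening,
and the morphological residual (input minus erosion).  Each operation uses
its own 5x5 binary structuring element, obtained by thresholding a
real-valued filter at the midpoint of its min-max normalization range.

Erosion of an image ``X`` by a binary structuring element ``w`` is the
moving minimum of ``X`` over the active cells of ``w``; dilation is the
moving maximum over the reflected element.  Opening is erosion followed by
dilation, closing is dilation followed by erosion.  All operators are
"flat" (the element carries no heights) and operate on intensities in
[0, 1] with same padding: the pad value is the neutral element of the
reduction (1.0 for a minimum, 0.0 for a maximum) so the border never
creates spurious extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructuringElement",
    "MorphFeatureStack",
    "binarize_filter",
    "erode",
    "dilate",
    "open_",
    "close_",
    "residual",
    "morphological_layer",
]

#: side length of the filters used throughout the model
FILTER_SIZE = 5


@dataclass(frozen=True)
class StructuringElement:
    """A flat binary structuring element (odd square mask of 0/1 entries).

    Attributes
    ----------
    mask
        2-D array with entries in {0, 1}; the active cells define the
        neighborhood of the morphological operation.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValueError(f"structuring element must be square, got shape {mask.shape}")
        if mask.shape[0] % 2 == 0:
            raise ValueError("structuring element side must be odd")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("structuring element entries must be 0 or 1")
        if not mask.any():
            raise ValueError("structuring element must have at least one active cell")
        object.__setattr__(self, "mask", mask.astype(np.uint8))

    @property
    def size(self) -> int:
        return self.mask.shape[0]

    @property
    def active_count(self) -> int:
        """Number of active cells (``n`` in the min/max reductions)."""
        return int(self.mask.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Active-cell offsets relative to the element center, shape (n, 2)."""
        half = self.size // 2
        rows, cols = np.nonzero(self.mask)
        return np.stack([rows - half, cols - half], axis=1)

    def reflect(self) -> "StructuringElement":
        """The element reflected through its center (used by dilation)."""
        return StructuringElement(self.mask[::-1, ::-1])

    @property
    def contains_center(self) -> bool:
        half = self.size // 2
        return bool(self.mask[half, half])

    @classmethod
    def center_only(cls, size: int = FILTER_SIZE) -> "StructuringElement":
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[size // 2, size // 2] = 1
        return cls(mask)

    @classmethod
    def full(cls, size: int = FILTER_SIZE) -> "StructuringElement":
        return cls(np.ones((size, size), dtype=np.uint8))


@dataclass
class MorphFeatureStack:
    """The four parallel feature maps produced by the morphological layer.

    ``maps`` has shape ``(H, W, 4)`` holding, in order: erosion, dilation,
    opening, and the residual ``source - erosion``.  Every map has the same
    height/width as the source image (stride 1, same padding).
    """

    maps: np.ndarray
    source: np.ndarray = field(repr=False)

    #: fixed order of the default layer's operations
    OPERATIONS = ("erosion", "dilation", "opening", "residual")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[..., self.OPERATIONS.index(name)]


def binarize_filter(weights: np.ndarray) -> StructuringElement:
    """Binarize a real-valued 5x5 filter into a structuring element.

    The filter is min-max normalized to [0, 1] and thresholded at 0.5, the
    midpoint between the two extremes of the normalization range: cells with
    normalized value >= 0.5 become active.  A constant filter has no
    normalization range; it degenerates to the center-only element, which
    makes the associated operation the identity.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (FILTER_SIZE, FILTER_SIZE):
        raise ValueError(
            f"filter must be {FILTER_SIZE}x{FILTER_SIZE}, got shape {weights.shape}"
        )
    lo, hi = weights.min(), weights.max()
    if hi == lo:
        return StructuringElement.center_only(FILTER_SIZE)
    normalized = (weights - lo) / (hi - lo)
    return StructuringElement((normalized >= 0.5).astype(np.uint8))


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    return image


def _sliding_extremum(
    stack: np.ndarray, offsets: np.ndarray, pad_value: float, minimum: bool
) -> np.ndarray:
    """Masked moving min/max over a batch of images, shape (N, H, W).

    Computed as an in-place reduction over shifted views of the padded
    batch: one pass per active offset, no window materialization.
    """
    n, h, w = stack.shape
    half_r = int(np.abs(offsets[:, 0]).max(initial=0))
    half_c = int(np.abs(offsets[:, 1]).max(initial=0))
    padded = np.full((n, h + 2 * half_r, w + 2 * half_c), pad_value, dtype=stack.dtype)
    padded[:, half_r : half_r + h, half_c : half_c + w] = stack
    reduce = np.minimum if minimum else np.maximum
    out: np.ndarray | None = None
    for dr, dc in offsets:
        view = padded[:, half_r + dr : half_r + dr + h, half_c + dc : half_c + dc + w]
        if out is None:
            out = view.copy()
        else:
            reduce(out, view, out=out)
    assert out is not None
    return out


def erode_batch(stack: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion of a batch of images, shape (N, H, W): moving minimum with
    1.0 padding (neutral for min on [0, 1] intensities)."""
    return _sliding_extremum(stack, se.offsets, pad_value=1.0, minimum=True)


def dilate_batch(stack: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation of a batch: moving maximum over the reflected element with
    0.0 padding (neutral for max)."""
    return _sliding_extremum(stack, se.reflect().offsets, pad_value=0.0, minimum=False)


def erode(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Flat grayscale erosion: ``out(p) = min_{q in se} image(p + q)``."""
    image = _check_image(image)
    return erode_batch(image[None], se)[0]


def dilate(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Flat grayscale dilation: ``out(p) = max_{q in se} image(p - q)``."""
    image = _check_image(image)
    return dilate_batch(image[None], se)[0]


def open_(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological opening: erosion followed by dilation.

    Idempotent and anti-extensive (``open_(X) <= X`` when the element
    contains its center)."""
    image = _check_image(image)
    return dilate_batch(erode_batch(image[None], se), se)[0]


def close_(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological closing: dilation followed by erosion.

    Idempotent and extensive (``close_(X) >= X`` when the element contains
    its center)."""
    image = _check_image(image)
    return erode_batch(dilate_batch(image[None], se), se)[0]


def residual(image: np.ndarray, op_output: np.ndarray) -> np.ndarray:
    """Morphological residual: the image minus a transform of it.

    Highlights the structures removed by the transform.  Not clipped: the
    residual against a dilation or closing is non-positive.
    """
    image = _check_image(image)
    op_output = np.asarray(op_output, dtype=float)
    if op_output.shape != image.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs operation output {op_output.shape}"
        )
    return image - op_output


def morphological_layer(
    image: np.ndarray, filters: np.ndarray | list[np.ndarray]
) -> MorphFeatureStack:
    """Apply the four-operation morphological layer to one image.

    Parameters
    ----------
    filters
        Four real-valued 5x5 filters, one per operation (erosion, dilation,
        opening, residual-of-erosion).  Each is binarized into its own
        structuring element before use.

    Returns
    -------
    MorphFeatureStack
        Four same-sized feature maps computed in parallel on the same
        input, stacked along the last axis.
    """
    image = _check_image(image)
    maps = morphological_layer_batch(image[None], filters)[0]
    return MorphFeatureStack(maps=maps, source=image)


def morphological_layer_batch(
    stack: np.ndarray, filters: np.ndarray | list[np.ndarray]
) -> np.ndarray:
    """Batched morphological layer: (N, H, W) -> (N, H, W, 4).

    Map order matches :attr:`MorphFeatureStack.OPERATIONS`.
    """
    filters = np.asarray(filters, dtype=float)
    if filters.shape[0] != 4:
        raise ValueError(f"the morphological layer takes exactly 4 filters, got {filters.shape[0]}")
    ses = [binarize_filter(f) for f in filters]
    stack = np.asarray(stack)
    if not np.issubdtype(stack.dtype, np.floating):
        stack = stack.astype(float)
    out = np.empty(stack.shape + (4,), dtype=stack.dtype)
    out[..., 0] = erode_batch(stack, ses[0])
    out[..., 1] = dilate_batch(stack, ses[1])
    out[..., 2] = dilate_batch(erode_batch(stack, ses[2]), ses[2])
    out[..., 3] = stack - erode_batch(stack, ses[3])
    return out
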