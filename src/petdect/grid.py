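"""Image grid description shared by all image-domain objects."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ImageGrid:
    """Uniform 2D pixel grid, pixel-center origin convention, row-major order.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; at least 8 each.
    pixel_size : float
        Pixel side length in cm.
    """

    n_rows: int
    n_cols: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def fov(self) -> tuple[float, float]:
        """Field of view (height, width) in cm."""
        return (self.n_rows * self.pixel_size, self.n_cols * self.pixel_size)
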