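"""Container for one lesion's 4D diffusion-weighted acquisition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bvalues import BValueScheme


@dataclass
class DWIStudy:
    """A 4D diffusion-weighted signal volume plus its b-value scheme.

    ``signal`` is indexed ``(slice, row, column, b_index)`` with one volume
    per b-value, all on a single grid.  Intensities are magnitude-image
    values and therefore non-negative.  ``voxel_size`` is
    (slice, row, column) extent in mm; the default matches a 1.5 T liver
    protocol (7 mm slices + 0.7 mm gap, ~3.4 mm in plane).
    """

    signal: np.ndarray
    scheme: BValueScheme = field(default_factory=BValueScheme)
    voxel_size: tuple[float, float, float] = (7.7, 3.4, 3.4)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(
                f"signal must be 4D (slice, row, col, b), got shape {self.signal.shape}"
            )
        if self.signal.shape[3] != 4:
            raise ValueError(
                f"expected one volume per b-value (4), got {self.signal.shape[3]}"
            )
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_slices(self) -> int:
        return self.signal.shape[0]

    def volume(self, b_index: int) -> np.ndarray:
        """The 3D volume acquired at ``scheme.values[b_index]``."""
        return self.signal[..., b_index]
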