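"""Diffusion-weighting scheme for the four-point simplified IVIM protocol."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BValueScheme:
    """The four b-values (s/mm²) of a simplified IVIM acquisition.

    The protocol acquires one baseline image (b0 = 0) and three
    diffusion-weighted images; the defaults are the clinical liver scheme
    0, 50, 250, 800 s/mm².  b-values must be strictly increasing and the
    first must be zero, because the perfusion-fraction estimators normalise
    against S(0).
    """

    b0: float = 0.0
    b1: float = 50.0
    b2: float = 250.0
    b3: float = 800.0

    def __post_init__(self) -> None:
        if self.b0 != 0.0:
            raise ValueError(f"b0 must be 0 s/mm², got {self.b0}")
        vals = (self.b0, self.b1, self.b2, self.b3)
        if not all(lo < hi for lo, hi in zip(vals, vals[1:])):
            raise ValueError(f"b-values must be strictly increasing, got {vals}")

    @property
    def values(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3], dtype=float)

    @classmethod
    def from_sidecar(cls, text: str) -> "BValueScheme":
        """Parse a plain-text b-value sidecar (whitespace-separated s/mm²)."""
        vals = [float(tok) for tok in text.split()]
        if len(vals) != 4:
            raise ValueError(f"expected 4 b-values in sidecar, got {len(vals)}")
        return cls(*vals)

    def to_sidecar(self) -> str:
        return " ".join(f"{b:g}" for b in self.values) + "\n"
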