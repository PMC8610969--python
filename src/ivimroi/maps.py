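"""Closed-form voxel-wise ADC and simplified-IVIM parameter estimation.

The simplified IVIM approach replaces free bi-exponential fitting with
closed-form estimators built from four b-values (0, 50, 250, 800 s/mm²):

* three log-slope diffusion coefficients
  ``ADC = ADC(0,800)``, ``D1' = ADC(50,800)``, ``D2' = ADC(250,800)``;
* two perfusion fractions
  ``f1' = 1 − S(50)/S(0)·exp(D1'·50)``,
  ``f2' = 1 − S(250)/S(0)·exp(D2'·250)``;
* a pseudo-diffusion coefficient
  ``D*' = −(1/50)·ln[(1/f2')·(S(50)/S(0) − (1−f2')·exp(−D2'·50))]``.

Every estimator is a pure per-voxel function, so maps are independent of
voxel iteration and storage order.  Voxels where a logarithm argument or a
denominator is non-positive carry no defined value; they are marked in a
boolean ``defined`` mask (authoritative) and hold NaN in the value array.
Internal units are mm²/s and unit fractions; scaling to the conventional
report units (coefficients ×10⁻⁶ mm²/s, fractions ×10⁻³) happens only at
reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study import DWIStudy

PARAMETERS = ("adc", "d1", "d2", "f1", "f2", "dstar")

#: multiplicative factor from internal units to the printed report units
REPORT_SCALE = {
    "adc": 1e6,
    "d1": 1e6,
    "d2": 1e6,
    "dstar": 1e6,
    "f1": 1e3,
    "f2": 1e3,
}

#: which parameters are diffusion-sensitive vs perfusion-sensitive
DIFFUSION_PARAMETERS = ("adc", "d1", "d2")
PERFUSION_PARAMETERS = ("f1", "f2", "dstar")


def _as_float(x):
    return np.asarray(x, dtype=float)


def estimate_log_slope(s_a, s_b, b_a: float, b_b: float):
    """Log-slope diffusion coefficient between two b-values.

    Returns ``(ln S_a − ln S_b)/(b_b − b_a)`` in mm²/s together with a
    defined mask; the slope is undefined wherever either signal is ≤ 0
    (flagged, never raised).  Covers ADC(0,800), D1'(50,800), D2'(250,800).
    """
    if not b_b > b_a >= 0:
        raise ValueError(f"require b_b > b_a >= 0, got b_a={b_a}, b_b={b_b}")
    s_a, s_b = _as_float(s_a), _as_float(s_b)
    defined = (s_a > 0) & (s_b > 0)
    slope = (
        np.log(np.where(defined, s_a, 1.0)) - np.log(np.where(defined, s_b, 1.0))
    ) / (b_b - b_a)
    return np.where(defined, slope, np.nan), defined


def estimate_f_prime(s_0, s_b, d_prime, b: float, d_defined=None):
    """Perfusion fraction ``1 − (S_b/S_0)·exp(D'·b)``.

    The fraction measures the relative signal excess of S(0) over the
    mono-exponential diffusion component extrapolated back from higher
    b-values.  Under noise the result may be negative; the value is
    retained and a separate negative flag is exposed downstream.
    Undefined where ``S_0 ≤ 0`` or where D' itself is undefined.
    """
    s_0, s_b, d_prime = _as_float(s_0), _as_float(s_b), _as_float(d_prime)
    if d_defined is None:
        d_defined = np.isfinite(d_prime)
    defined = (s_0 > 0) & np.asarray(d_defined, bool)
    with np.errstate(over="ignore", invalid="ignore"):
        raw = 1.0 - (s_b / np.where(s_0 > 0, s_0, 1.0)) * np.exp(
            np.where(defined, d_prime, 0.0) * b
        )
    return np.where(defined, raw, np.nan), defined


#: perfusion fractions at or below this are treated as "no perfusion
#: compartment" when inverting for D*'; the threshold sits far below any
#: physical fraction but above the rounding floor of the f2' cancellation
#: in the mono-exponential limit
F2_MIN = 1e-12


def estimate_dstar(s_0, s_b1, f2, d2, b1: float = 50.0, defined_in=None):
    """Pseudo-diffusion coefficient from the four-point scheme.

    ``D*' = −(1/b1)·ln[(1/f2')·(S(b1)/S(0) − (1−f2')·exp(−D2'·b1))]``.
    Undefined where f2' ≤ 0 (no perfusion compartment to attribute the
    b1 reading to, tolerance :data:`F2_MIN`) or where the logarithm
    argument is non-positive; those voxels are excluded from ROI
    analysis downstream.
    """
    if not b1 > 0:
        raise ValueError("b1 must be positive")
    s_0, s_b1, f2, d2 = map(_as_float, (s_0, s_b1, f2, d2))
    base = (s_0 > 0) & np.isfinite(f2) & np.isfinite(d2) & (f2 > F2_MIN)
    if defined_in is not None:
        base &= np.asarray(defined_in, bool)
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        ratio = s_b1 / np.where(s_0 > 0, s_0, 1.0)
        f2_safe = np.where(base, f2, 1.0)
        d2_safe = np.where(base, d2, 0.0)
        arg = (ratio - (1.0 - f2_safe) * np.exp(-d2_safe * b1)) / f2_safe
        defined = base & (arg > 0)
        value = -np.log(np.where(defined, arg, 1.0)) / b1
    return np.where(defined, value, np.nan), defined


@dataclass
class ParameterMaps:
    """Voxel-wise parameter maps with per-parameter defined masks.

    Results object of :class:`SimplifiedIVIM`.  Value arrays are in
    internal units (mm²/s, unit fractions) and hold NaN where undefined;
    the boolean ``defined`` mask is authoritative.  ``negative`` flags
    defined-but-negative voxels (noise artefacts) so the alternative
    policy of excluding them is one mask away.
    """

    adc: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    dstar: np.ndarray
    defined: dict[str, np.ndarray] = field(default_factory=dict)
    negative: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (7.7, 3.4, 3.4)

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)

    def defined_mask(self, parameter: str) -> np.ndarray:
        return self.defined[parameter]

    def report_values(self, parameter: str) -> np.ndarray:
        """Values scaled to report units (×10⁻⁶ mm²/s or ×10⁻³)."""
        return self.values(parameter) * REPORT_SCALE[parameter]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.adc.shape

    def summary(self) -> pd.DataFrame:
        """Per-parameter defined/undefined/negative voxel bookkeeping."""
        n = int(np.prod(self.grid_shape))
        rows = []
        for p in PARAMETERS:
            nd = int(self.defined[p].sum())
            rows.append(
                {
                    "parameter": p,
                    "n_voxels": n,
                    "n_defined": nd,
                    "n_undefined": n - nd,
                    "n_negative": int(self.negative[p].sum()),
                }
            )
        return pd.DataFrame(rows)


class SimplifiedIVIM:
    """Closed-form simplified-IVIM model for one 4-b-value DWI study.

    Parameters
    ----------
    study : DWIStudy
        The 4D acquisition; its four volumes must share one grid.

    ``fit()`` evaluates the closed-form estimators voxel-wise (no spatial
    smoothing, no registration, no iteration) and returns the
    :class:`ParameterMaps` results object.
    """

    def __init__(self, study: DWIStudy):
        self.study = study

    def fit(self) -> ParameterMaps:
        sig = self.study.signal
        b = self.study.scheme.values
        s0, s1, s2, s3 = (sig[..., i] for i in range(4))

        adc, adc_def = estimate_log_slope(s0, s3, b[0], b[3])
        d1, d1_def = estimate_log_slope(s1, s3, b[1], b[3])
        d2, d2_def = estimate_log_slope(s2, s3, b[2], b[3])
        f1, f1_def = estimate_f_prime(s0, s1, d1, b[1], d1_def)
        f2, f2_def = estimate_f_prime(s0, s2, d2, b[2], d2_def)
        dstar, ds_def = estimate_dstar(s0, s1, f2, d2, b[1], f2_def & d2_def)

        values = {"adc": adc, "d1": d1, "d2": d2, "f1": f1, "f2": f2, "dstar": dstar}
        defined = {
            "adc": adc_def,
            "d1": d1_def,
            "d2": d2_def,
            "f1": f1_def,
            "f2": f2_def,
            "dstar": ds_def,
        }
        negative = {p: defined[p] & (values[p] < 0) for p in PARAMETERS}
        return ParameterMaps(
            adc=adc,
            d1=d1,
            d2=d2,
            f1=f1,
            f2=f2,
            dstar=dstar,
            defined=defined,
            negative=negative,
            voxel_size=self.study.voxel_size,
        )


def compute_parameter_maps(study: DWIStudy) -> ParameterMaps:
    """Functional shorthand for ``SimplifiedIVIM(study).fit()``."""
    return SimplifiedIVIM(study).fit()
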