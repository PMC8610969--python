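"""Lesion ROI variants and first-order (histogram) summarisation.

A lesion is delineated slice by slice.  The first and last lesion slice
are always labelled "bad" (partial-volume risk) and any slice degraded by
motion, susceptibility or pixel-misalignment artefacts is labelled "bad"
as well; exactly one good slice — the representative central slice — is
flagged as the 2D reference.  Lesions with central necrosis, cystic
components or scars carry an additional mask of those centrally deviating
areas (CDA).

Six ROI variants are analysed per lesion: three extents (2D reference
slice, 3DG = good slices only, 3DA = all slices) crossed with two tissue
modes (including or excluding the CDA voxels).  A summary of a parameter
map within a variant reports the mean plus the histogram metrics median,
SD, percentiles 5/10/25/75/90/95, skewness and kurtosis, computed over
defined voxels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .maps import PARAMETERS, REPORT_SCALE, ParameterMaps

EXTENTS = ("2D", "3DG", "3DA")
TISSUES = ("inclCDA", "exclCDA")

#: summary metrics, in report order; "mean" first, then histogram metrics
METRICS = (
    "mean",
    "median",
    "sd",
    "p5",
    "p10",
    "p25",
    "p75",
    "p90",
    "p95",
    "skewness",
    "kurtosis",
)


@dataclass
class SliceROI:
    """Hand-drawn ROI on one slice: coordinates, quality label, reference flag."""

    slice_index: int
    coords: np.ndarray  # (n, 2) int array of (row, col) within the slice
    quality: str = "good"
    reference: bool = False

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        if self.coords.size and self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2) (row, col) pairs")
        if self.quality not in ("good", "bad"):
            raise ValueError(f"quality must be 'good' or 'bad', got {self.quality!r}")

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {(self.slice_index, int(r), int(c)) for r, c in self.coords}


@dataclass
class LesionROISet:
    """All slice ROIs of one lesion plus its optional CDA voxel set."""

    lesion_id: str
    class_label: str  # "benign" | "malignant"
    slices: list[SliceROI]
    cda_coords: np.ndarray | None = None  # (m, 3) int (slice, row, col)

    def __post_init__(self) -> None:
        if self.class_label not in ("benign", "malignant"):
            raise ValueError(f"class_label must be benign/malignant, got {self.class_label!r}")
        if self.cda_coords is not None:
            self.cda_coords = np.atleast_2d(np.asarray(self.cda_coords, dtype=int))
            if self.cda_coords.size == 0:
                self.cda_coords = None
        self.validate()

    def validate(self) -> None:
        if not self.slices:
            raise ValueError(f"lesion {self.lesion_id}: no slice ROIs")
        refs = [s for s in self.slices if s.reference]
        if len(refs) != 1:
            raise ValueError(
                f"lesion {self.lesion_id}: exactly one reference slice required, got {len(refs)}"
            )
        if refs[0].quality != "good":
            raise ValueError(f"lesion {self.lesion_id}: reference slice must be labelled good")
        order = sorted(self.slices, key=lambda s: s.slice_index)
        if order[0].quality != "bad" or order[-1].quality != "bad":
            raise ValueError(
                f"lesion {self.lesion_id}: first and last lesion slice must be labelled bad"
            )
        if self.cda_coords is not None:
            lesion_voxels = self.voxel_set("3DA")
            cda = {tuple(int(v) for v in row) for row in self.cda_coords}
            if not cda <= lesion_voxels:
                raise ValueError(
                    f"lesion {self.lesion_id}: CDA voxels must lie within the lesion ROI"
                )

    @property
    def has_cda(self) -> bool:
        return self.cda_coords is not None

    @property
    def reference_slice(self) -> SliceROI:
        return next(s for s in self.slices if s.reference)

    def voxel_set(self, extent: str) -> set[tuple[int, int, int]]:
        if extent == "2D":
            chosen = [self.reference_slice]
        elif extent == "3DG":
            chosen = [s for s in self.slices if s.quality == "good"]
            if not chosen:
                raise ValueError(f"lesion {self.lesion_id}: 3DG requested but no good slices")
        elif extent == "3DA":
            chosen = list(self.slices)
        else:
            raise ValueError(f"unknown extent {extent!r}")
        out: set[tuple[int, int, int]] = set()
        for s in chosen:
            out |= s.voxel_set()
        return out


@dataclass(frozen=True)
class ROIVariant:
    """One of the six (extent, tissue) ROI analysis variants."""

    extent: str
    tissue: str

    def __post_init__(self) -> None:
        if self.extent not in EXTENTS:
            raise ValueError(f"extent must be one of {EXTENTS}, got {self.extent!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")

    @classmethod
    def all_variants(cls) -> tuple["ROIVariant", ...]:
        return tuple(cls(e, t) for e, t in product(EXTENTS, TISSUES))

    def __str__(self) -> str:
        return f"{self.extent}-{self.tissue}"


def assemble_roi(lesion: LesionROISet, variant: ROIVariant) -> np.ndarray:
    """Voxel coordinates (n, 3) of one ROI variant, lexicographically sorted.

    2D → reference-slice voxels; 3DG → union of good slices; 3DA → union of
    all slices; the exclCDA tissue mode subtracts the lesion's CDA voxels.
    Raises if the result is empty (e.g. CDA covering the whole reference
    slice), because an empty ROI cannot be analysed.
    """
    voxels = lesion.voxel_set(variant.extent)
    if variant.tissue == "exclCDA" and lesion.cda_coords is not None:
        cda = {tuple(int(v) for v in row) for row in lesion.cda_coords}
        voxels = voxels - cda
    if not voxels:
        raise ValueError(
            f"lesion {lesion.lesion_id}: variant {variant} yields an empty ROI"
        )
    arr = np.array(sorted(voxels), dtype=int)
    return arr


@dataclass
class ROISummary:
    """Mean and histogram metrics of one parameter within one ROI variant.

    ``available`` is False when the ROI holds no defined voxel (e.g. an
    all-undefined pseudo-diffusion map in an unperfused lesion); all
    metrics are then NaN.  Skewness and kurtosis are NaN for degenerate
    (zero-variance) distributions.
    """

    n_voxels: int
    n_defined: int
    mean: float = np.nan
    median: float = np.nan
    sd: float = np.nan
    p5: float = np.nan
    p10: float = np.nan
    p25: float = np.nan
    p75: float = np.nan
    p90: float = np.nan
    p95: float = np.nan
    skewness: float = np.nan
    kurtosis: float = np.nan

    @property
    def available(self) -> bool:
        return self.n_defined > 0

    def as_dict(self) -> dict[str, float]:
        d = {"n_voxels": self.n_voxels, "n_defined": self.n_defined}
        for m in METRICS:
            d[m] = getattr(self, m)
        return d


def summarize_roi(values, defined=None) -> ROISummary:
    """Summarise parameter samples over defined voxels only.

    Percentiles use linear interpolation between order statistics at
    fractional rank ``p·(n−1)`` (0-based); SD uses the n−1 denominator;
    skewness is the adjusted Fisher–Pearson sample skewness and kurtosis
    is excess kurtosis (set ``summarize_roi.excess_kurtosis = False`` for
    the raw convention).
    """
    values = np.asarray(values, dtype=float).ravel()
    if defined is None:
        defined = np.isfinite(values)
    defined = np.asarray(defined, bool).ravel()
    v = values[defined]
    n_vox, n_def = len(values), len(v)
    if n_def == 0:
        return ROISummary(n_voxels=n_vox, n_defined=0)
    p5, p10, p25, med, p75, p90, p95 = np.percentile(v, [5, 10, 25, 50, 75, 90, 95])
    sd = float(np.std(v, ddof=1)) if n_def > 1 else 0.0
    if n_def > 2 and sd > 0:
        with warnings.catch_warnings():
            # noise-free phantom ROIs are near-identical; scipy flags the
            # (expected) precision loss in higher moments
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(stats.skew(v, bias=False))
            kurt = float(
                stats.kurtosis(
                    v, fisher=getattr(summarize_roi, "excess_kurtosis", True), bias=False
                )
            )
    else:
        skew = kurt = np.nan
    return ROISummary(
        n_voxels=n_vox,
        n_defined=n_def,
        mean=float(np.mean(v)),
        median=float(med),
        sd=sd,
        p5=float(p5),
        p10=float(p10),
        p25=float(p25),
        p75=float(p75),
        p90=float(p90),
        p95=float(p95),
        skewness=skew,
        kurtosis=kurt,
    )


#: convention switch: excess (normal → 0) by default
summarize_roi.excess_kurtosis = True


def summarize_all(lesion: LesionROISet, maps: ParameterMaps) -> pd.DataFrame:
    """Summaries of all six parameters in all six variants of one lesion.

    Returns one row per (parameter, variant) in report units
    (coefficients ×10⁻⁶ mm²/s, fractions ×10⁻³).  For CDA-free lesions
    the inclCDA and exclCDA rows are identical by construction.
    """
    rows = []
    for variant in ROIVariant.all_variants():
        coords = assemble_roi(lesion, variant)
        idx = tuple(coords.T)
        for p in PARAMETERS:
            vals = maps.values(p)[idx] * REPORT_SCALE[p]
            summ = summarize_roi(vals, maps.defined_mask(p)[idx])
            rows.append(
                {
                    "lesion": lesion.lesion_id,
                    "class": lesion.class_label,
                    "parameter": p,
                    "extent": variant.extent,
                    "tissue": variant.tissue,
                    **summ.as_dict(),
                }
            )
    return pd.DataFrame(rows)
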