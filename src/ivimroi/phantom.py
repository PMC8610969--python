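"""Synthetic DWI lesion cohorts with known IVIM ground truth.

The generator emulates the clinical material of a 4-b-value liver DWI
study: ellipsoidal lesions of two diagnostic classes embedded in a
liver-like background, optional necrotic/cystic cores (centrally
deviating areas: high diffusion, near-zero perfusion), "bad" slices
degraded by in-plane pixel misalignment of the high-b images, and Rician
magnitude noise.  Per-class lesion-level parameter distributions default
to truncated normals calibrated on the published 1.5 T group statistics
(2D-ROI, CDA excluded): the diffusion coefficient from the D2' column,
the perfusion fraction from f2' and the pseudo-diffusion coefficient
from D*'.

The bi-exponential forward model is
``S(b) = S0·[(1−f)·exp(−b·D) + f·exp(−b·D*)]``
(the perfusion compartment decays with rate D*, the convention the
closed-form pseudo-diffusion estimator inverts).  A switch to the
``exp(−b·(D+D*))`` convention is provided.

All randomness flows from one seed through named substreams (parameter
draws, geometry, noise, artefacts), so identical specs and seeds yield
identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bvalues import BValueScheme
from .roi import LesionROISet, SliceROI
from .study import DWIStudy


@dataclass(frozen=True)
class TissueIVIMParams:
    """IVIM tissue parameters: D, f, D* and the baseline intensity S0."""

    d: float  # diffusion coefficient, mm²/s
    f: float  # perfusion fraction, dimensionless
    dstar: float  # pseudo-diffusion coefficient, mm²/s
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"D must be positive, got {self.d}")
        if not 0 <= self.f < 1:
            raise ValueError(f"f must be in [0, 1), got {self.f}")
        if self.f > 0 and not self.dstar > self.d:
            raise ValueError("D* must exceed D when a perfusion compartment exists")
        if not self.s0 > 0:
            raise ValueError("S0 must be positive")


def ivim_signal(params: TissueIVIMParams, b, compartment_rate: str = "dstar"):
    """Bi-exponential IVIM signal at b-value(s) ``b`` (s/mm²).

    ``compartment_rate="dstar"`` (default) decays the perfusion term as
    exp(−b·D*); ``"d_plus_dstar"`` uses exp(−b·(D+D*)).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    rate = params.dstar if compartment_rate == "dstar" else params.d + params.dstar
    if compartment_rate not in ("dstar", "d_plus_dstar"):
        raise ValueError(f"unknown compartment_rate {compartment_rate!r}")
    return params.s0 * (
        (1.0 - params.f) * np.exp(-b * params.d) + params.f * np.exp(-b * rate)
    )


def add_rician_noise(signal, sigma: float, rng) -> np.ndarray:
    """Magnitude-MRI (Rician) noise: ``√((S+ε₁)² + ε₂²)``, ε ~ N(0, σ²).

    ``rng`` is a seed or a numpy Generator; sigma = 0 returns the input
    unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(rng)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


#: liver-like background tissue surrounding every lesion
BACKGROUND_TISSUE = TissueIVIMParams(d=1.05e-3, f=0.25, dstar=60e-3, s0=800.0)

#: necrotic/cystic-core (CDA) defaults: free-fluid-like high diffusion,
#: near-zero perfusion
CDA_TISSUE = TissueIVIMParams(d=2.75e-3, f=0.01, dstar=10e-3, s0=1200.0)


@dataclass
class LesionSpec:
    """Geometry, tissue and artefact plan of one synthetic lesion."""

    lesion_id: str
    class_label: str  # "benign" | "malignant"
    tissue: TissueIVIMParams
    center: tuple[float, float, float] = (4.0, 15.5, 15.5)  # (slice, row, col)
    semi_axes: tuple[float, float, float] = (3.0, 9.0, 9.0)  # voxels
    cda_tissue: TissueIVIMParams | None = None
    cda_scale: float = 0.5  # CDA core semi-axes relative to the lesion's
    artifact_slices: tuple[int, ...] = ()  # extra bad slices (misalignment)
    grid_shape: tuple[int, int, int] = (9, 32, 32)

    def __post_init__(self) -> None:
        if not 0 < self.cda_scale < 1:
            raise ValueError("cda_scale must lie strictly inside (0, 1)")


def _ellipsoid_mask(grid_shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.indices(grid_shape)
    return (
        ((zz - center[0]) / semi_axes[0]) ** 2
        + ((yy - center[1]) / semi_axes[1]) ** 2
        + ((xx - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def generate_lesion(
    spec: LesionSpec,
    scheme: BValueScheme | None = None,
    sigma: float = 0.0,
    seed=0,
    compartment_rate: str = "dstar",
):
    """Voxelise one lesion and synthesise its 4-b-value study.

    Returns ``(DWIStudy, LesionROISet, truth)`` where ``truth`` records
    the generating tissue parameters.  The first and last lesion slice
    are labelled bad; slices in ``artifact_slices`` are labelled bad and
    their two high-b volumes are translated in plane by one voxel
    (emulating pixel misalignment).  The reference slice is the good
    slice with the largest ROI area (ties → lowest slice index).
    """
    scheme = scheme or BValueScheme()
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(spec.grid_shape, spec.center, spec.semi_axes)
    if not mask.any():
        raise ValueError(f"lesion {spec.lesion_id}: geometry does not intersect the grid")
    lesion_slices = np.flatnonzero(mask.any(axis=(1, 2)))
    if lesion_slices[0] == 0 or lesion_slices[-1] == spec.grid_shape[0] - 1:
        raise ValueError(f"lesion {spec.lesion_id}: lesion touches the grid's slice range")
    if len(lesion_slices) < 3:
        raise ValueError(f"lesion {spec.lesion_id}: needs >= 3 slices for a good interior slice")

    cda_mask = np.zeros_like(mask)
    if spec.cda_tissue is not None:
        cda_mask = _ellipsoid_mask(
            spec.grid_shape,
            spec.center,
            tuple(a * spec.cda_scale for a in spec.semi_axes),
        )
        cda_mask &= mask

    # noise-free signal per b-value
    b = scheme.values
    sig = np.empty(spec.grid_shape + (4,), dtype=float)
    for i, bv in enumerate(b):
        vol = np.full(spec.grid_shape, ivim_signal(BACKGROUND_TISSUE, bv, compartment_rate))
        vol[mask] = ivim_signal(spec.tissue, bv, compartment_rate)
        if spec.cda_tissue is not None:
            vol[cda_mask] = ivim_signal(spec.cda_tissue, bv, compartment_rate)
        sig[..., i] = vol

    # pixel-misalignment artefacts on designated bad slices: shift the
    # high-b images of that slice in plane by one voxel
    for sl in spec.artifact_slices:
        shift = (int(rng.integers(-2, 3)) or 1, int(rng.integers(-2, 3)))
        for i in (2, 3):
            sig[sl, :, :, i] = np.roll(sig[sl, :, :, i], shift, axis=(0, 1))

    sig = add_rician_noise(sig, sigma, rng)
    study = DWIStudy(signal=sig, scheme=scheme)

    # slice ROIs drawn on the lesion outline
    edge = {int(lesion_slices[0]), int(lesion_slices[-1])}
    bad = edge | {int(s) for s in spec.artifact_slices}
    slice_rois = []
    for sl in lesion_slices:
        rows, cols = np.nonzero(mask[sl])
        slice_rois.append(
            SliceROI(
                slice_index=int(sl),
                coords=np.column_stack([rows, cols]),
                quality="bad" if int(sl) in bad else "good",
            )
        )
    good = [s for s in slice_rois if s.quality == "good"]
    if not good:
        raise ValueError(f"lesion {spec.lesion_id}: artefact plan left no good slice")
    ref = max(good, key=lambda s: (s.n_voxels, -s.slice_index))
    ref.reference = True

    cda_coords = np.argwhere(cda_mask) if spec.cda_tissue is not None else None
    roiset = LesionROISet(
        lesion_id=spec.lesion_id,
        class_label=spec.class_label,
        slices=slice_rois,
        cda_coords=cda_coords if cda_coords is not None and len(cda_coords) else None,
    )
    truth = {
        "lesion": spec.lesion_id,
        "class": spec.class_label,
        "d": spec.tissue.d,
        "f": spec.tissue.f,
        "dstar": spec.tissue.dstar,
        "s0": spec.tissue.s0,
        "has_cda": spec.cda_tissue is not None,
        "cda_volume_fraction": float(cda_mask.sum() / mask.sum()),
        "n_slices": len(lesion_slices),
        "n_voxels": int(mask.sum()),
    }
    return study, roiset, truth


@dataclass(frozen=True)
class ClassDistribution:
    """Lesion-level truncated-normal parameter distribution of one class.

    Means/SDs are in mm²/s (d, dstar) and unit fractions (f); bounds are
    physical truncation limits applied to every draw.
    """

    d_mean: float
    d_sd: float
    f_mean: float
    f_sd: float
    dstar_mean: float
    dstar_sd: float
    d_bounds: tuple[float, float] = (0.2e-3, 2.8e-3)
    f_bounds: tuple[float, float] = (0.02, 0.40)
    dstar_bounds: tuple[float, float] = (10e-3, 80e-3)


#: published 1.5 T group statistics (2D-ROI, CDA excluded): malignant
#: D2' 939±250, f2' 141±96 (×10⁻³), D*' 18837±8603 (×10⁻⁶ mm²/s)
MALIGNANT_15T = ClassDistribution(
    d_mean=939e-6, d_sd=250e-6, f_mean=0.141, f_sd=0.096,
    dstar_mean=18837e-6, dstar_sd=8603e-6,
)

#: benign counterpart: D2' 1423±416, f2' 191±104, D*' 21189±13251
BENIGN_15T = ClassDistribution(
    d_mean=1423e-6, d_sd=416e-6, f_mean=0.191, f_sd=0.104,
    dstar_mean=21189e-6, dstar_sd=13251e-6,
)


@dataclass
class CohortSpec:
    """Recipe for a full synthetic cohort.

    Defaults reproduce the 1.5 T study composition: 74 malignant and 35
    benign lesions, of which 36/109 carry a centrally deviating area.
    ``sigma`` is the Rician noise level relative to a lesion S0 of 1000.
    """

    n_malignant: int = 74
    n_benign: int = 35
    malignant: ClassDistribution = field(default_factory=lambda: MALIGNANT_15T)
    benign: ClassDistribution = field(default_factory=lambda: BENIGN_15T)
    cda_fraction: float = 36 / 109
    sigma: float = 15.0
    scheme: BValueScheme = field(default_factory=BValueScheme)
    grid_shape: tuple[int, int, int] = (9, 32, 32)
    artifact_rate: float = 0.15  # per interior slice
    seed: int = 0
    compartment_rate: str = "dstar"

    def __post_init__(self) -> None:
        if self.n_malignant <= 0 or self.n_benign <= 0:
            raise ValueError("cohort class counts must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.cda_fraction <= 1:
            raise ValueError("cda_fraction must be in [0, 1]")


def _truncnorm(mean, sd, bounds, rng, size=None):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_tissue(dist: ClassDistribution, rng) -> TissueIVIMParams:
    d = float(_truncnorm(dist.d_mean, dist.d_sd, dist.d_bounds, rng))
    f = float(_truncnorm(dist.f_mean, dist.f_sd, dist.f_bounds, rng))
    dstar = float(_truncnorm(dist.dstar_mean, dist.dstar_sd, dist.dstar_bounds, rng))
    return TissueIVIMParams(d=d, f=f, dstar=max(dstar, 1.5 * d), s0=1000.0)


def generate_cohort(spec: CohortSpec):
    """Generate a seeded cohort of lesions with ground truth.

    Returns ``(lesions, truth_table)`` where ``lesions`` is a list of
    ``(DWIStudy, LesionROISet, truth_dict)`` triples and ``truth_table``
    a DataFrame with one row per lesion (id, class, D, f, D*, CDA flag).
    CDA lesions get a free-fluid-like core with slightly jittered
    diffusion and a per-lesion core size.
    """
    ss = np.random.SeedSequence(spec.seed)
    draw_child, geom_child, noise_ss = ss.spawn(3)
    draw_rng = np.random.default_rng(draw_child)
    geom_rng = np.random.default_rng(geom_child)
    nz = spec.grid_shape[0]
    labels = ["malignant"] * spec.n_malignant + ["benign"] * spec.n_benign
    lesions = []
    truths = []
    noise_children = noise_ss.spawn(len(labels))
    for i, label in enumerate(labels):
        dist = spec.malignant if label == "malignant" else spec.benign
        tissue = _draw_tissue(dist, draw_rng)
        has_cda = bool(draw_rng.random() < spec.cda_fraction)
        cda_tissue = None
        cda_scale = 0.5
        if has_cda:
            cda_tissue = replace(
                CDA_TISSUE, d=float(geom_rng.uniform(2.5e-3, 3.0e-3))
            )
            cda_scale = float(geom_rng.uniform(0.35, 0.7))
        # geometry: ellipsoid fitting the grid with >= 1 voxel margin
        c_sl = float(geom_rng.uniform(2.4, 3.4))  # spans 5-7 slices around center
        center_sl = (nz - 1) / 2 + float(geom_rng.uniform(-0.5, 0.5))
        semi_r = float(geom_rng.uniform(6.0, 11.0))
        semi_c = float(geom_rng.uniform(6.0, 11.0))
        lesion_spec = LesionSpec(
            lesion_id=f"L{i:03d}",
            class_label=label,
            tissue=tissue,
            center=(center_sl, (spec.grid_shape[1] - 1) / 2, (spec.grid_shape[2] - 1) / 2),
            semi_axes=(c_sl, semi_r, semi_c),
            cda_tissue=cda_tissue,
            cda_scale=cda_scale,
            grid_shape=spec.grid_shape,
        )
        # artefact plan: interior slices only, always keeping one good slice
        mask_slices = np.flatnonzero(
            _ellipsoid_mask(spec.grid_shape, lesion_spec.center, lesion_spec.semi_axes).any(
                axis=(1, 2)
            )
        )
        interior = list(map(int, mask_slices[1:-1]))
        candidates = [s for s in interior if geom_rng.random() < spec.artifact_rate]
        if len(candidates) >= len(interior):  # keep at least one good slice
            candidates = candidates[: len(interior) - 1]
        lesion_spec.artifact_slices = tuple(candidates)
        study, roiset, truth = generate_lesion(
            lesion_spec,
            scheme=spec.scheme,
            sigma=spec.sigma,
            seed=noise_children[i],
            compartment_rate=spec.compartment_rate,
        )
        lesions.append((study, roiset, truth))
        truths.append(truth)
    return lesions, pd.DataFrame(truths)
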