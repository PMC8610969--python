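"""ROC evaluation of lesion summaries and paired AUC comparison (DeLong).

Benign vs malignant discrimination is scored per (parameter, variant,
metric) by the empirical (Mann–Whitney) AUC with ties counted ½.  The
orientation is chosen per marker: "benign-high" (printed ``>``) counts
benign > malignant pairs, "benign-low" (``<``) the reverse, and the
direction with AUC ≥ 0.5 is reported.  Cut-offs maximise Youden's index
J = sensitivity + specificity − 1 over midpoint thresholds, with
malignant as the positive class.  Confidence intervals use the DeLong
structural-components variance with a normal approximation, clipped to
[0, 1]; paired AUCs on the same lesions are compared with the DeLong z
test.  No multiple-testing adjustment is applied (raw p-values, α = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .roi import EXTENTS, METRICS, TISSUES

BENIGN_HIGH = ">"
BENIGN_LOW = "<"


def _score_matrix(benign, malignant, direction: str) -> np.ndarray:
    """Pairwise success scores: 1 if the benign case is ranked on the
    benign side of the malignant case, ½ on ties."""
    b = np.asarray(benign, float)[:, None]
    m = np.asarray(malignant, float)[None, :]
    if direction == BENIGN_HIGH:
        return (b > m) + 0.5 * (b == m)
    if direction == BENIGN_LOW:
        return (b < m) + 0.5 * (b == m)
    raise ValueError(f"direction must be {BENIGN_HIGH!r} or {BENIGN_LOW!r}")


def empirical_auc(benign, malignant, direction: str = BENIGN_HIGH) -> float:
    """Mann–Whitney AUC by pair counting with ties scored ½."""
    benign, malignant = np.asarray(benign, float), np.asarray(malignant, float)
    if benign.size == 0 or malignant.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(_score_matrix(benign, malignant, direction).mean())


def choose_direction(benign, malignant) -> str:
    """Orientation with empirical AUC ≥ 0.5; ties favour benign-high."""
    return BENIGN_HIGH if empirical_auc(benign, malignant, BENIGN_HIGH) >= 0.5 else BENIGN_LOW


def delong_placements(benign, malignant, direction: str = BENIGN_HIGH):
    """DeLong structural components: per-benign and per-malignant placement
    values, whose means equal the AUC."""
    s = _score_matrix(benign, malignant, direction)
    return s.mean(axis=1), s.mean(axis=0)


def delong_variance(benign, malignant, direction: str = BENIGN_HIGH) -> float:
    """Variance of the empirical AUC by the DeLong estimator.

    ``var = var(V_benign)/n_benign + var(V_malignant)/n_malignant`` with
    sample (n−1) variances of the placement components.  Degenerate
    samples (all scores tied, e.g. perfect separation) give 0 with a
    warning.
    """
    vb, vm = delong_placements(benign, malignant, direction)
    if len(vb) < 2 or len(vm) < 2:
        raise ValueError("need at least 2 cases per group for a variance")
    var = float(np.var(vb, ddof=1) / len(vb) + np.var(vm, ddof=1) / len(vm))
    if var == 0.0:
        warnings.warn("degenerate AUC variance (all placement components equal)")
    return var


def delong_covariance(benign_a, malignant_a, benign_b, malignant_b,
                      direction_a: str = BENIGN_HIGH, direction_b: str = BENIGN_HIGH) -> float:
    """Covariance of two paired AUCs measured on the same lesions."""
    if len(benign_a) != len(benign_b) or len(malignant_a) != len(malignant_b):
        raise ValueError("paired AUCs require identical lesion sets")
    vba, vma = delong_placements(benign_a, malignant_a, direction_a)
    vbb, vmb = delong_placements(benign_b, malignant_b, direction_b)
    cov_b = np.cov(vba, vbb, ddof=1)[0, 1] if len(vba) > 1 else 0.0
    cov_m = np.cov(vma, vmb, ddof=1)[0, 1] if len(vma) > 1 else 0.0
    return float(cov_b / len(vba) + cov_m / len(vma))


def auc_confidence_interval(auc: float, variance: float, level: float = 0.95):
    """Normal-approximation CI ``auc ± z·√variance`` clipped to [0, 1]."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def youden_cutoff(benign, malignant, direction: str = BENIGN_HIGH):
    """Optimal cut-off by Youden's index.

    Candidate thresholds are the midpoints of adjacent sorted unique
    pooled values plus ±∞.  Malignant is the positive class: for
    benign-high markers a case is called malignant when its value falls
    below the threshold, for benign-low when above.  Returns
    ``(cutoff, sensitivity, specificity)``; ties in J are broken towards
    the smallest cutoff.
    """
    benign, malignant = np.asarray(benign, float), np.asarray(malignant, float)
    if benign.size == 0 or malignant.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.unique(np.concatenate([benign, malignant]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if len(pooled) > 1 else np.empty(0)
    cands = np.concatenate([[-np.inf], mids, [np.inf]])
    if direction == BENIGN_HIGH:
        sens = (malignant[None, :] < cands[:, None]).mean(axis=1)
        spec = (benign[None, :] > cands[:, None]).mean(axis=1)
    elif direction == BENIGN_LOW:
        sens = (malignant[None, :] > cands[:, None]).mean(axis=1)
        spec = (benign[None, :] < cands[:, None]).mean(axis=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximiser
    return float(cands[best]), float(sens[best]), float(spec[best])


def accuracy(sensitivity: float, specificity: float, n_malignant: int, n_benign: int) -> float:
    """Prevalence-weighted accuracy at a cut-off:
    ``(sens·n_malignant + spec·n_benign) / (n_malignant + n_benign)``."""
    if n_malignant <= 0 or n_benign <= 0:
        raise ValueError("group counts must be positive")
    return (sensitivity * n_malignant + specificity * n_benign) / (n_malignant + n_benign)


@dataclass
class ROCResult:
    """Diagnostic evaluation of one scalar marker: direction, AUC with
    DeLong CI, Youden cut-off and its operating point."""

    direction: str
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_benign: int
    n_malignant: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "Dir": self.direction,
                "AUC": self.auc,
                "CI1": self.ci_low,
                "CI2": self.ci_high,
                "Cut-off": self.cutoff,
                "Sen": self.sensitivity,
                "Spec": self.specificity,
                "Acc": self.accuracy,
            }
        )


class LesionROC:
    """ROC model for one marker over a benign/malignant lesion cohort.

    ``fit()`` chooses the orientation (unless given), computes the
    empirical AUC, its DeLong variance and CI, the Youden cut-off with
    sensitivity/specificity, and the prevalence-weighted accuracy.
    """

    def __init__(self, benign, malignant, direction: str | None = None, level: float = 0.95):
        self.benign = np.asarray(benign, float)
        self.malignant = np.asarray(malignant, float)
        self.direction = direction
        self.level = level

    def fit(self) -> ROCResult:
        direction = self.direction or choose_direction(self.benign, self.malignant)
        auc = empirical_auc(self.benign, self.malignant, direction)
        var = delong_variance(self.benign, self.malignant, direction)
        lo, hi = auc_confidence_interval(auc, var, self.level)
        cut, sens, spec = youden_cutoff(self.benign, self.malignant, direction)
        acc = accuracy(sens, spec, len(self.malignant), len(self.benign))
        return ROCResult(
            direction=direction,
            auc=auc,
            variance=var,
            ci_low=lo,
            ci_high=hi,
            cutoff=cut,
            sensitivity=sens,
            specificity=spec,
            accuracy=acc,
            n_benign=len(self.benign),
            n_malignant=len(self.malignant),
        )


def evaluate_roc(benign, malignant, direction: str | None = None, level: float = 0.95) -> ROCResult:
    """Functional shorthand for ``LesionROC(...).fit()``."""
    return LesionROC(benign, malignant, direction, level).fit()


@dataclass
class PairedAUCComparison:
    """DeLong comparison of two AUCs measured on the same lesions."""

    auc_a: float
    auc_b: float
    z: float
    p: float


def delong_test(benign_a, malignant_a, benign_b, malignant_b,
                direction_a: str | None = None, direction_b: str | None = None) -> PairedAUCComparison:
    """Two-sided DeLong z test for paired (dependent) ROC curves.

    Markers A and B must be measured on the same lesions in the same
    order.  ``z = (AUC_a − AUC_b)/√(var_a + var_b − 2·cov)`` with a
    standard-normal reference.  A zero-variance difference gives p = 1
    when the AUCs are equal and a degenerate-case warning otherwise.
    """
    if direction_a is None:
        direction_a = choose_direction(benign_a, malignant_a)
    if direction_b is None:
        direction_b = choose_direction(benign_b, malignant_b)
    auc_a = empirical_auc(benign_a, malignant_a, direction_a)
    auc_b = empirical_auc(benign_b, malignant_b, direction_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var_a = delong_variance(benign_a, malignant_a, direction_a)
        var_b = delong_variance(benign_b, malignant_b, direction_b)
    cov = delong_covariance(benign_a, malignant_a, benign_b, malignant_b,
                            direction_a, direction_b)
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-15:
        if np.isclose(auc_a, auc_b):
            return PairedAUCComparison(auc_a, auc_b, 0.0, 1.0)
        warnings.warn("degenerate DeLong test: zero variance but unequal AUCs")
        z = np.inf if auc_a > auc_b else -np.inf
        return PairedAUCComparison(auc_a, auc_b, float(z), 0.0)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedAUCComparison(auc_a, auc_b, float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# cohort-level tables


def _marker(summaries: pd.DataFrame, parameter: str, extent: str, tissue: str,
            metric: str) -> pd.DataFrame:
    sel = summaries[
        (summaries["parameter"] == parameter)
        & (summaries["extent"] == extent)
        & (summaries["tissue"] == tissue)
    ]
    out = sel[["lesion", "class", metric]].rename(columns={metric: "value"})
    return out.dropna(subset=["value"])


def _split(df: pd.DataFrame):
    return (
        df.loc[df["class"] == "benign", "value"].to_numpy(),
        df.loc[df["class"] == "malignant", "value"].to_numpy(),
    )


def roc_table(summaries: pd.DataFrame, metrics=("mean",), level: float = 0.95) -> pd.DataFrame:
    """Table-style ROC evaluation: one row per (parameter, variant, metric).

    ``summaries`` is the long per-lesion table from
    :func:`ivimroi.roi.summarize_all` (values already in report units).
    Lesions whose summary for a marker is unavailable are dropped from
    that marker's evaluation; group means/SDs/Ns are reported alongside.
    """
    rows = []
    for parameter in summaries["parameter"].unique():
        for extent in EXTENTS:
            for tissue in TISSUES:
                for metric in metrics:
                    df = _marker(summaries, parameter, extent, tissue, metric)
                    if df.empty:
                        continue
                    ben, mal = _split(df)
                    if len(ben) < 2 or len(mal) < 2:
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = evaluate_roc(ben, mal, level=level)
                    rows.append(
                        {
                            "parameter": parameter,
                            "extent": extent,
                            "tissue": tissue,
                            "metric": metric,
                            "mv_malignant": mal.mean(),
                            "sd_malignant": mal.std(ddof=1),
                            "n_malignant": len(mal),
                            "mv_benign": ben.mean(),
                            "sd_benign": ben.std(ddof=1),
                            "n_benign": len(ben),
                            "dir": res.direction,
                            "auc": res.auc,
                            "ci1": res.ci_low,
                            "ci2": res.ci_high,
                            "cutoff": res.cutoff,
                            "sen": res.sensitivity,
                            "spec": res.specificity,
                            "acc": res.accuracy,
                        }
                    )
    return pd.DataFrame(rows)


def _paired_test(summaries: pd.DataFrame, arm_a: tuple, arm_b: tuple):
    """DeLong-compare two (parameter, extent, tissue, metric) arms with
    pairwise deletion of lesions missing either value.  Returns the
    comparison plus the lesion counts used, or None if a group is too small."""
    a = _marker(summaries, *arm_a)
    b = _marker(summaries, *arm_b)
    merged = a.merge(b, on=["lesion", "class"], suffixes=("_a", "_b"))
    ben = merged[merged["class"] == "benign"]
    mal = merged[merged["class"] == "malignant"]
    if len(ben) < 2 or len(mal) < 2:
        return None
    cmp = delong_test(
        ben["value_a"].to_numpy(), mal["value_a"].to_numpy(),
        ben["value_b"].to_numpy(), mal["value_b"].to_numpy(),
    )
    n_dropped = (len(a) - len(merged)) + (len(b) - len(merged))
    return cmp, len(ben), len(mal), n_dropped


def compare_modes(summaries: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """The three comparison families of the ROI-strategy analysis.

    * ``extent``: 2D vs 3DG vs 3DA per parameter and tissue mode (mean).
    * ``tissue``: inclCDA vs exclCDA per parameter and extent (mean).
    * ``metric``: each 2D histogram metric vs the 2D mean, in three tissue
      pairings — incl/incl, excl/excl, and the cross pairing
      metric-inclCDA vs mean-exclCDA (can low percentiles replace manual
      CDA exclusion?).

    Missing arms are skipped with a warning.  Returns one DataFrame per
    family with AUCs, z, p and a significance flag at ``alpha``.
    """
    parameters = list(summaries["parameter"].unique())
    fam_extent = []
    for tissue in TISSUES:
        for parameter in parameters:
            for ext_a, ext_b in combinations(EXTENTS, 2):
                r = _paired_test(
                    summaries,
                    (parameter, ext_a, tissue, "mean"),
                    (parameter, ext_b, tissue, "mean"),
                )
                if r is None:
                    warnings.warn(f"extent comparison skipped for {parameter}/{tissue}")
                    continue
                cmp, nb, nm, drop = r
                fam_extent.append(
                    {
                        "parameter": parameter,
                        "tissue": tissue,
                        "extent_a": ext_a,
                        "extent_b": ext_b,
                        "auc_a": cmp.auc_a,
                        "auc_b": cmp.auc_b,
                        "z": cmp.z,
                        "p": cmp.p,
                        "significant": cmp.p < alpha,
                        "n_benign": nb,
                        "n_malignant": nm,
                        "n_dropped": drop,
                    }
                )

    fam_tissue = []
    for parameter in parameters:
        for extent in EXTENTS:
            r = _paired_test(
                summaries,
                (parameter, extent, "inclCDA", "mean"),
                (parameter, extent, "exclCDA", "mean"),
            )
            if r is None:
                warnings.warn(f"tissue comparison skipped for {parameter}/{extent}")
                continue
            cmp, nb, nm, drop = r
            fam_tissue.append(
                {
                    "parameter": parameter,
                    "extent": extent,
                    "auc_incl": cmp.auc_a,
                    "auc_excl": cmp.auc_b,
                    "z": cmp.z,
                    "p": cmp.p,
                    "significant": cmp.p < alpha,
                    "n_benign": nb,
                    "n_malignant": nm,
                    "n_dropped": drop,
                }
            )

    pairings = (
        ("incl-incl", "inclCDA", "inclCDA"),
        ("excl-excl", "exclCDA", "exclCDA"),
        ("metricIncl-meanExcl", "inclCDA", "exclCDA"),
    )
    fam_metric = []
    for parameter in parameters:
        for metric in METRICS[1:]:
            for label, tissue_metric, tissue_mean in pairings:
                r = _paired_test(
                    summaries,
                    (parameter, "2D", tissue_metric, metric),
                    (parameter, "2D", tissue_mean, "mean"),
                )
                if r is None:
                    warnings.warn(
                        f"metric comparison skipped for {parameter}/{metric}/{label}"
                    )
                    continue
                cmp, nb, nm, drop = r
                fam_metric.append(
                    {
                        "parameter": parameter,
                        "metric": metric,
                        "pairing": label,
                        "auc_metric": cmp.auc_a,
                        "auc_mean": cmp.auc_b,
                        "z": cmp.z,
                        "p": cmp.p,
                        "significant": cmp.p < alpha,
                        "n_benign": nb,
                        "n_malignant": nm,
                        "n_dropped": drop,
                    }
                )

    return {
        "extent": pd.DataFrame(fam_extent),
        "tissue": pd.DataFrame(fam_tissue),
        "metric": pd.DataFrame(fam_metric),
    }
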