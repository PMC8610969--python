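"""Replication experiments: the study's qualitative findings on synthetic cohorts.

The published analysis rests on three reproducible effects rather than on
exact AUC values (those depend on the patient material): (1) excluding
centrally deviating areas (CDA) raises the AUC of the diffusion-sensitive
parameters; (2) low percentiles (p10) of CDA-including ROIs recover the
diagnostic performance of CDA-excluding mean analysis; (3) 2D and
whole-lesion 3D ROIs perform equivalently.  :func:`cohort_findings`
measures all three on one seeded synthetic cohort; repeated over seeds it
gives the majority-vote replication used by the validation suite.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import pandas as pd

from .maps import DIFFUSION_PARAMETERS, REPORT_SCALE, SimplifiedIVIM
from .phantom import CohortSpec, generate_cohort
from .roc import delong_test, empirical_auc, choose_direction
from .roi import ROIVariant, assemble_roi, summarize_roi


def _lesion_markers(lesions) -> pd.DataFrame:
    """Per-lesion mean / p10 markers of the diffusion parameters for the
    three variants the replication needs (2D incl, 2D excl, 3DA excl/incl)."""
    variants = {
        "2D_incl": ROIVariant("2D", "inclCDA"),
        "2D_excl": ROIVariant("2D", "exclCDA"),
        "3DA_incl": ROIVariant("3DA", "inclCDA"),
        "3DA_excl": ROIVariant("3DA", "exclCDA"),
    }
    rows = []
    for study, roiset, _ in lesions:
        maps = SimplifiedIVIM(study).fit()
        row: dict = {"lesion": roiset.lesion_id, "class": roiset.class_label}
        for vname, variant in variants.items():
            idx = tuple(assemble_roi(roiset, variant).T)
            for p in DIFFUSION_PARAMETERS:
                summ = summarize_roi(
                    maps.values(p)[idx] * REPORT_SCALE[p], maps.defined_mask(p)[idx]
                )
                row[f"{p}_{vname}_mean"] = summ.mean
                row[f"{p}_{vname}_p10"] = summ.p10
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_findings(seed: int, spec: CohortSpec | None = None) -> dict:
    """Measure the three qualitative findings on one synthetic cohort.

    Returns a flat dict with, per diffusion parameter: the 2D mean AUC
    including/excluding CDA, the 2D p10 AUC including CDA, and the DeLong
    p of 2D vs 3DA (CDA excluded, mean).  ``spec`` defaults to the
    calibrated noisy study-sized cohort.
    """
    spec = replace(spec or CohortSpec(), seed=seed)
    lesions, _ = generate_cohort(spec)
    markers = _lesion_markers(lesions)
    ben = markers[markers["class"] == "benign"]
    mal = markers[markers["class"] == "malignant"]

    out: dict = {"seed": seed}
    for p in DIFFUSION_PARAMETERS:
        aucs = {}
        for marker in (f"{p}_2D_incl_mean", f"{p}_2D_excl_mean", f"{p}_2D_incl_p10"):
            b, m = ben[marker].to_numpy(), mal[marker].to_numpy()
            aucs[marker] = empirical_auc(b, m, choose_direction(b, m))
        out[f"auc_{p}_2d_incl_mean"] = aucs[f"{p}_2D_incl_mean"]
        out[f"auc_{p}_2d_excl_mean"] = aucs[f"{p}_2D_excl_mean"]
        out[f"auc_{p}_2d_incl_p10"] = aucs[f"{p}_2D_incl_p10"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp = delong_test(
                ben[f"{p}_2D_excl_mean"].to_numpy(),
                mal[f"{p}_2D_excl_mean"].to_numpy(),
                ben[f"{p}_3DA_excl_mean"].to_numpy(),
                mal[f"{p}_3DA_excl_mean"].to_numpy(),
            )
        out[f"p_{p}_2d_vs_3da"] = cmp.p
    return out


def replicate_findings(n_seeds: int = 20, base_seed: int = 0,
                       spec: CohortSpec | None = None) -> pd.DataFrame:
    """Run :func:`cohort_findings` over ``n_seeds`` seeded cohorts."""
    rows = [cohort_findings(base_seed + k, spec) for k in range(n_seeds)]
    return pd.DataFrame(rows)


def findings_summary(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Majority-vote summary of a :func:`replicate_findings` table.

    Per diffusion parameter: the fraction of seeds with
    AUC(exclCDA) ≥ AUC(inclCDA), the median |AUC(p10, inclCDA) −
    AUC(mean, exclCDA)|, and the fraction of seeds where 2D vs 3DA is
    non-significant at ``alpha``.
    """
    out = {}
    for p in DIFFUSION_PARAMETERS:
        out[f"frac_excl_ge_incl_{p}"] = float(
            (table[f"auc_{p}_2d_excl_mean"] >= table[f"auc_{p}_2d_incl_mean"]).mean()
        )
        out[f"median_absdiff_p10incl_meanexcl_{p}"] = float(
            (table[f"auc_{p}_2d_incl_p10"] - table[f"auc_{p}_2d_excl_mean"]).abs().median()
        )
        out[f"frac_2d_vs_3da_nonsig_{p}"] = float((table[f"p_{p}_2d_vs_3da"] > alpha).mean())
    return out
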