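"""Baseline biomarker screening: responder/non-responder comparison and
ROC analysis.

Six candidate baseline (post-burn-in, pre-dose) biomarkers are screened:
PD-L1 expression per cancer cell, CD4+ helper and CD8+ effector T-cell
densities in the tumour, Treg density, and the CD4/Treg and CD8/Treg ratios.
Groups are compared with the Wilcoxon rank-sum test; discrimination is
quantified by the ROC AUC, which (with the tie convention used here) equals
the Mann–Whitney U statistic divided by n₁·n₂.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import SIDX, tumour_volume_mm3

BIOMARKER_NAMES = (
    "pdl1_expr",
    "cd4_density",
    "cd8_density",
    "treg_density",
    "cd4_treg_ratio",
    "cd8_treg_ratio",
)


def extract_biomarkers(patient, baseline_state) -> dict:
    """Baseline biomarker row for one patient.

    Densities are tumour compartment cell counts divided by the baseline
    tumour volume (cells/mm³); PD-L1 expression is read from the patient's
    sampled parameter.
    """
    y = np.asarray(baseline_state, dtype=float)
    vol = tumour_volume_mm3(y[SIDX["C"]], patient.params.DEN_T_cell)
    if vol <= 0:
        raise ValueError("zero tumour volume at baseline")
    cd8 = y[SIDX["T8_t"]] / vol
    # CD4+ staining counts helper and regulatory T cells alike
    cd4 = (y[SIDX["Th_t"]] + y[SIDX["Treg_t"]]) / vol
    treg = y[SIDX["Treg_t"]] / vol
    return {
        "patient_id": patient.id,
        "pdl1_expr": patient.params.pdl1_expr,
        "cd4_density": cd4,
        "cd8_density": cd8,
        "treg_density": treg,
        "cd4_treg_ratio": cd4 / treg if treg > 0 else np.nan,
        "cd8_treg_ratio": cd8 / treg if treg > 0 else np.nan,
    }


def rank_sum_test(values_a, values_b) -> tuple:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Mid-ranks for ties; exact enumeration when n₁+n₂ ≤ 12 and no ties,
    otherwise the tie-corrected normal approximation.  Returns
    ``(U statistic of the first sample, two-sided p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size + b.size) <= 12 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ROCResult:
    """ROC curve (threshold sweep) and its trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC analysis of ``scores`` against boolean ``labels`` (True = positive).

    Thresholds sweep the unique scores; a case is called positive when its
    score is ≥ threshold.  Ties between the groups contribute ½ to the AUC,
    so ``auc == U/(n₁·n₂)`` exactly.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        called = s >= thr
        sens[i] = np.sum(called & lab) / n_pos
        spec[i] = np.sum(~called & ~lab) / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc)


def biomarker_table(patients, trajectories, records) -> pd.DataFrame:
    """Assemble the per-patient biomarker table with responder labels."""
    by_id = {p.id: p for p in patients}
    resp = {r.patient_id: r.responder for r in records}
    rows = []
    for tr in trajectories:
        row = extract_biomarkers(by_id[tr.patient_id], tr.baseline_state)
        row["responder"] = bool(resp[tr.patient_id])
        rows.append(row)
    return pd.DataFrame(rows)


def biomarker_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-biomarker rank-sum p, ROC AUC, and group medians, ranked by AUC.

    ``table`` is the output of :func:`biomarker_table`.  Aborts when either
    responders or non-responders are absent.
    """
    lab = table["responder"].to_numpy(dtype=bool)
    if lab.all() or not lab.any():
        raise ValueError(
            "need both responders and non-responders for biomarker analysis")
    rows = []
    for name in BIOMARKER_NAMES:
        x = table[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        u, p = rank_sum_test(x[ok & lab], x[ok & ~lab])
        roc = roc_auc(x[ok], lab[ok])
        rows.append({
            "biomarker": name,
            "auc": roc.auc,
            "p_value": p,
            "median_R": float(np.median(x[ok & lab])),
            "median_NR": float(np.median(x[ok & ~lab])),
            "n_R": int((ok & lab).sum()),
            "n_NR": int((ok & ~lab).sum()),
        })
    out = pd.DataFrame(rows).sort_values("auc", ascending=False)
    return out.reset_index(drop=True)


def roc_plot(table: pd.DataFrame, path) -> None:
    """Overlay ROC curves for all six biomarkers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lab = table["responder"].to_numpy(dtype=bool)
    fig, ax = plt.subplots(figsize=(5, 5))
    for name in BIOMARKER_NAMES:
        x = table[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        roc = roc_auc(x[ok], lab[ok])
        ax.plot(1.0 - roc.specificity, roc.sensitivity,
                label=f"{name} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
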