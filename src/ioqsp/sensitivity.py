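"""Global sensitivity analysis: Latin hypercube sampling + partial rank
correlation coefficients (PRCC) against percent tumour-volume change.

The PRCC of parameter j is the Pearson correlation between the residuals of
rank(Xj) and rank(y) after linearly regressing each on the remaining
rank-transformed parameters — a monotone, distribution-free measure of each
parameter's influence controlling for all others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import PopulationSpec, build_population
from .engine import simulate_cohort
from .pharmacokinetics import Regimen


class SingularDesignError(ValueError):
    """Raised when the rank-transformed design matrix is collinear."""


def prcc(X, y) -> np.ndarray:
    """Partial rank correlation coefficient of each column of X with y.

    ``X`` is n×k (array or DataFrame), ``y`` length n.  Requires
    n > k + 2 and no constant columns.  Ties receive average ranks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ValueError("X and y sizes disagree")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    const = [j for j in range(k) if np.ptp(X[:, j]) == 0.0]
    if const:
        raise SingularDesignError(f"constant columns: {const}")

    rx = np.column_stack([stats.rankdata(X[:, j]) for j in range(k)])
    ry = stats.rankdata(y)

    out = np.empty(k)
    ones = np.ones(n)
    for j in range(k):
        others = np.column_stack([ones, np.delete(rx, j, axis=1)])
        # residualise rank(Xj) and rank(y) on the other ranked columns
        beta_x, _, rank_x, _ = np.linalg.lstsq(others, rx[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        if rank_x < others.shape[1]:
            raise SingularDesignError(
                f"collinear design when partialling out column {j}")
        ex = rx[:, j] - others @ beta_x
        ey = ry - others @ beta_y
        denom = np.sqrt(np.sum(ex ** 2) * np.sum(ey ** 2))
        if denom == 0.0:
            raise SingularDesignError(
                f"zero residual variance for column {j}")
        out[j] = float(np.sum(ex * ey) / denom)
    return out


@dataclass
class PSAResult:
    """Ranked PRCC table for one regimen."""

    table: pd.DataFrame          # parameter, prcc, rank (1 = largest |PRCC|)
    output: str
    n: int
    arm: str

    def top(self, m: int = 5) -> list:
        return list(self.table.sort_values("rank").head(m)["parameter"])


def run_psa(spec: PopulationSpec, regimen: Regimen, n: int, seed,
            duration: float = 400.0) -> PSAResult:
    """LHS sample → simulate → PRCC of each parameter against the percent
    change in tumour volume at end of treatment.

    Aborts if more than 10% of patients fail integration.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for a stable PRCC")
    patients, _ = build_population(n, spec, seed)
    cohort = simulate_cohort(patients, regimen, duration=duration)
    if cohort.n_excluded > 0.1 * n:
        raise RuntimeError(
            f"{cohort.n_excluded}/{n} integrations failed: "
            + "; ".join(m for _, m in cohort.failures[:5]))

    ok_ids = [tr.patient_id for tr in cohort.trajectories]
    by_id = {p.id: p for p in patients}
    names = spec.names
    X = np.array([[getattr(by_id[i].params, nm) for nm in names]
                  for i in ok_ids])
    y = np.array([
        100.0 * (tr.volume_mm3[-1] - tr.volume_mm3[0]) / tr.volume_mm3[0]
        for tr in cohort.trajectories
    ])
    coeffs = prcc(X, y)
    ranks = stats.rankdata(-np.abs(coeffs), method="average")
    table = pd.DataFrame({
        "parameter": names,
        "prcc": coeffs,
        "rank": ranks,
    }).sort_values("rank", kind="stable").reset_index(drop=True)
    return PSAResult(table=table, n=len(ok_ids), arm=regimen.name,
                     output=f"% change in tumour volume at day {duration:g}")


def tornado_plot(result: PSAResult, path, top: int = 15) -> None:
    """Horizontal-bar PRCC plot (largest |PRCC| on top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table.sort_values("rank").head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(tab) + 1.5))
    colors = ["#b2182b" if v > 0 else "#2166ac" for v in tab["prcc"]]
    ax.barh(tab["parameter"], tab["prcc"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"PRCC vs {result.output}")
    ax.set_title(result.arm)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
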