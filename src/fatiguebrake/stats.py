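"""Pearson correlation between spectral features and subjective fatigue.

Thin, validated wrappers around the exact small-sample Pearson test
(two-tailed p from ``t = r sqrt(n-2)/sqrt(1-r^2)`` on ``n-2`` degrees of
freedom, as implemented by :func:`scipy.stats.pearsonr`), plus the pairwise
matrix over the study variables (CF/PSE of two channels and the fatigue
score) presented with correlation coefficients in the lower triangle and
p-values in the upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CorrelationResult", "pearson", "correlation_matrix", "CorrelationMatrix"]

STUDY_VARIABLES = ["cf_ch7", "pse_ch7", "cf_ch10", "pse_ch10", "fss"]


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson r, its two-tailed p-value and the pair count."""

    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with exact t-distribution p-value.

    Raises on length mismatch, fewer than 3 pairs, or a constant input
    (for which the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


@dataclass
class CorrelationMatrix:
    """All pairwise correlations among a set of named variables."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def combined(self) -> pd.DataFrame:
        """Lower triangle: r; upper triangle: p; diagonal: 1 (heatmap layout)."""
        out = self.r.copy()
        cols = list(out.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                out.iloc[i, j] = self.p.iloc[i, j]
        return out

    def plot(self, path=None):
        """Render the combined matrix as an annotated heatmap (optional)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = self.combined()
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(mat)), mat.index)
        for i in range(len(mat)):
            for j in range(len(mat)):
                ax.text(j, i, f"{mat.iloc[i, j]:.2g}", ha="center", va="center",
                        fontsize=8)
        fig.colorbar(im, ax=ax, label="r")
        ax.set_title("lower: r, upper: p")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def correlation_matrix(
    frame: pd.DataFrame, variables: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson r and p over the given columns of ``frame``.

    Defaults to the study variables (channel-7/10 centroid frequency and
    spectral entropy plus the fatigue score). Missing values are not
    tolerated: rows must be complete.
    """
    variables = variables or STUDY_VARIABLES
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise KeyError(f"frame lacks columns {missing}")
    if frame[variables].isna().any().any():
        bad = frame.index[frame[variables].isna().any(axis=1)].tolist()
        raise ValueError(f"unmatched/missing values in rows {bad}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = pearson(frame[variables[i]], frame[variables[j]])
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.p
    idx = pd.Index(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=len(frame),
    )
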