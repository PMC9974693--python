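"""Statistics for rate-all-that-apply (RATA) sensory panels.

Panelists rate a fixed list of attributes on a 1–4 intensity scale for
each solution, separately for odour and taste.  Analysis follows the
common treatment of such panels: per-cell mean intensities, a one-way
ANOVA per attribute across solutions (scores treated as numeric — an
ordinal-regression treatment would be more principled for 4-level data,
but the numeric ANOVA is the field's convention and is what is
implemented here), and a centered PCA of the panelist-level score
matrix with explained-variance percentages.

No correction for multiple testing across attributes is applied by
default; :func:`anova_by_attribute` exposes Bonferroni and Holm flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ANOVAResult",
    "RATA_ATTRIBUTES",
    "SensoryPCA",
    "anova_by_attribute",
    "load_panel",
    "mean_scores",
    "one_way_anova",
    "panel_score_matrix",
    "pca_scores",
]

#: The seven-attribute vocabulary used for the grape model solutions.
RATA_ATTRIBUTES: tuple[str, ...] = (
    "citrus", "apple", "banana", "grass", "floral", "alcoholic", "pungent",
)
MODALITIES: tuple[str, ...] = ("odour", "taste")

_KEY = ["panelist", "solution", "modality", "attribute"]


def load_panel(path, attributes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read and validate a panel table
    (panelist, solution, modality, attribute, score)."""
    df = pd.read_csv(path)
    return validate_panel(df, attributes)


def validate_panel(
    df: pd.DataFrame, attributes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    missing = set(_KEY + ["score"]) - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns {sorted(missing)}")
    scores = df["score"]
    if not np.array_equal(scores, scores.astype(int)) or (
        (scores < 1) | (scores > 4)
    ).any():
        raise ValueError("scores must be integers in [1, 4]")
    if attributes is not None:
        unknown = set(df["attribute"]) - set(attributes)
        if unknown:
            raise ValueError(f"unknown attribute(s): {sorted(unknown)}")
    if df.duplicated(subset=_KEY).any():
        raise ValueError(
            "at most one record per (panelist, solution, modality, attribute)"
        )
    return df


def mean_scores(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per solution × attribute × modality.

    Cells with no record are absent from the output (not zero)."""
    if panel.empty:
        raise ValueError("panel table is empty")
    out = (
        panel.groupby(["solution", "modality", "attribute"], sort=True)["score"]
        .mean()
        .rename("mean_score")
        .reset_index()
    )
    return out


@dataclass
class ANOVAResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    zero_within_variance: bool = False
    attribute: str | None = None


def one_way_anova(groups) -> ANOVAResult:
    """One-way fixed-effects ANOVA from sums of squares.

    ``groups`` is a sequence of per-group score arrays.  With zero
    within-group variance and non-zero between-group variance, the
    F statistic is infinite and p is reported as the 0 sentinel with
    ``zero_within_variance`` set.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(a.size for a in arrays)
    df_between, df_within = k - 1, n - k
    if df_within < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if ss_within == 0:
        if ss_between == 0:
            return ANOVAResult(0.0, df_between, df_within, 1.0)
        return ANOVAResult(
            float("inf"), df_between, df_within, 0.0, zero_within_variance=True
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return ANOVAResult(float(f), df_between, df_within, p)


def anova_by_attribute(
    panel: pd.DataFrame,
    modality: str = "odour",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-attribute one-way ANOVA across solutions for one modality.

    ``correction`` may be ``'bonferroni'`` or ``'holm'``; the default is
    no correction (each attribute tested at its nominal level).
    """
    sub = panel[panel["modality"] == modality]
    if sub.empty:
        raise ValueError(f"no records for modality {modality!r}")
    rows = []
    for attr, block in sub.groupby("attribute", sort=True):
        groups = [g["score"].to_numpy() for _, g in block.groupby("solution")]
        res = one_way_anova(groups)
        rows.append(
            {
                "attribute": attr,
                "f_statistic": res.f_statistic,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p_value": res.p_value,
                "zero_within_variance": res.zero_within_variance,
            }
        )
    out = pd.DataFrame(rows)
    if correction is None:
        out["p_adjusted"] = out["p_value"]
    elif correction == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p_value"] * len(out), 1.0)
    elif correction == "holm":
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[i])
            adj[i] = min(running, 1.0)
        out["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def panel_score_matrix(panel: pd.DataFrame, modality: str = "odour") -> pd.DataFrame:
    """Panelist-level observation × attribute matrix (rows indexed by
    (panelist, solution))."""
    sub = panel[panel["modality"] == modality]
    if sub.empty:
        raise ValueError(f"no records for modality {modality!r}")
    return sub.pivot_table(
        index=["panelist", "solution"], columns="attribute", values="score"
    )


@dataclass
class SensoryPCA:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray


def pca_scores(matrix: pd.DataFrame, scale: bool = False) -> SensoryPCA:
    """Centered (optionally autoscaled) PCA of an observation × attribute
    score matrix; explained-variance percentages sum to 100."""
    if matrix.isna().any().any():
        raise ValueError("score matrix has missing cells")
    n, p = matrix.shape
    if n < 2 or p < 2:
        raise ValueError(f"need >= 2 observations and >= 2 attributes, got {n}x{p}")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant attribute column under autoscaling")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2
    total = eig.sum()
    pct = 100 * eig / total if total > 0 else np.zeros_like(eig)
    cols = [f"PC{i + 1}" for i in range(s.size)]
    return SensoryPCA(
        scores=pd.DataFrame(u * s, index=matrix.index, columns=cols),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=cols),
        explained_pct=pct,
    )
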