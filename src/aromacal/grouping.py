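"""Grouping of aroma compounds into sensory attributes.

Selected compounds are related to four attributes of the wine aroma
wheel (fruity, green/vegetative, floral, microbiological).  The grouping
is operationalized as a nearest-centroid rule in the space of the first
two principal-component loadings of the autoscaled concentration matrix,
with centroids derived from seed compounds of known attribute and
descriptor-based overrides (e.g. 1-hexanol -> green/vegetative, the
"leaf alcohol") taking precedence.  The per-sample calibration reference
for each attribute is the sum of aroma values over its compounds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import AromaValueTable

__all__ = [
    "SensoryAttribute",
    "PCAResult",
    "assign_attributes",
    "attribute_scores",
    "default_assignments",
    "pca_loadings",
    "reference_compound_stats",
    "reference_loadings",
]


class SensoryAttribute(enum.Enum):
    """The four wine-aroma-wheel attributes; enumeration order is the
    deterministic tie-break order for centroid assignment."""

    FRUITY = "fruity"
    GREEN_VEGETATIVE = "green_vegetative"
    FLORAL = "floral"
    MICROBIOLOGICAL = "microbiological"

    @classmethod
    def coerce(cls, value: "SensoryAttribute | str") -> "SensoryAttribute":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValueError(
                f"unknown sensory attribute {value!r}; expected one of "
                f"{[a.value for a in cls]}"
            ) from None


ATTRIBUTE_ORDER: tuple[SensoryAttribute, ...] = tuple(SensoryAttribute)


@dataclass
class PCAResult:
    """Loadings (variables × components) and explained-variance fractions
    of a centered (optionally autoscaled) PCA."""

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    scaled: bool


def pca_loadings(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of a sample × compound concentration (or aroma-value) matrix.

    With ``scale=True`` (default) columns are autoscaled (z-scored with
    the n−1 standard deviation), i.e. the PCA of the correlation matrix —
    the natural choice when concentrations span µg to mg ranges.  Note
    that autoscaled PCA is identical for concentrations and aroma values,
    which differ only by per-column scale factors.

    Eigenvector signs follow the convention that the largest-magnitude
    coefficient of each component is positive.
    """
    if matrix.isna().any().any():
        raise ValueError("concentration matrix has missing cells")
    n, p = matrix.shape
    if n < 2 or p < 2:
        raise ValueError(f"need >= 2 samples and >= 2 compounds, got {n}x{p}")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [matrix.columns[i] for i in zero]
            raise ValueError(
                f"constant-valued compound column(s) under autoscaling: {names}"
            )
        x = x / sd
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    # sign convention: largest |coefficient| positive per component
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    total = eigenvalues.sum()
    ratio = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    cols = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=cols),
        explained_variance_ratio=ratio,
        eigenvalues=eigenvalues,
        scaled=scale,
    )


def assign_attributes(
    loadings: pd.DataFrame,
    seeds: Mapping[str, "SensoryAttribute | str"],
    overrides: Mapping[str, "SensoryAttribute | str"] | None = None,
) -> pd.DataFrame:
    """Assign each compound in ``loadings`` to a sensory attribute.

    Precedence: explicit ``overrides`` win; compounds named in ``seeds``
    keep their seed attribute (the seeds define the centroids, so they
    are assignments, not suggestions); remaining compounds go to the
    nearest attribute centroid in PC1/PC2, ties broken by attribute
    enumeration order.  Compounds without PC coordinates and without an
    override are flagged unassigned.

    Returns a frame indexed by compound with columns ``attribute``
    (attribute value or ``None``), ``basis`` (override/seed/pca/
    unassigned), ``pc1``, ``pc2``.
    """
    overrides = {k: SensoryAttribute.coerce(v) for k, v in (overrides or {}).items()}
    seed_map = {k: SensoryAttribute.coerce(v) for k, v in seeds.items()}
    if not {"PC1", "PC2"} <= set(loadings.columns):
        raise ValueError("loadings must contain PC1 and PC2 columns")

    coords = loadings[["PC1", "PC2"]].astype(float)
    centroids: dict[SensoryAttribute, np.ndarray] = {}
    for attr in ATTRIBUTE_ORDER:
        members = [c for c, a in seed_map.items() if a is attr and c in coords.index]
        if members:
            centroids[attr] = coords.loc[members].to_numpy().mean(axis=0)
    if not centroids and not overrides and not seed_map:
        raise ValueError("no seeds or overrides given; cannot assign attributes")

    names = list(coords.index) + [c for c in overrides if c not in coords.index]
    records = []
    for name in names:
        pc = coords.loc[name].to_numpy() if name in coords.index else (np.nan, np.nan)
        if name in overrides:
            attr, basis = overrides[name], "override"
        elif name in seed_map:
            attr, basis = seed_map[name], "seed"
        elif name in coords.index and centroids:
            dists = {
                a: float(np.hypot(*(coords.loc[name].to_numpy() - c)))
                for a, c in centroids.items()
            }
            best = min(dists.values())
            # tie-break: first attribute in enumeration order at the minimum
            attr = next(a for a in ATTRIBUTE_ORDER if a in dists and dists[a] == best)
            basis = "pca"
        else:
            attr, basis = None, "unassigned"
        records.append(
            {
                "compound": name,
                "attribute": attr.value if attr else None,
                "basis": basis,
                "pc1": float(pc[0]),
                "pc2": float(pc[1]),
            }
        )
    return pd.DataFrame(records).set_index("compound")


def attribute_scores(
    aroma_values: AromaValueTable | pd.DataFrame,
    assignment: pd.DataFrame | Mapping[str, "SensoryAttribute | str"],
) -> pd.DataFrame:
    """Per-sample summed aroma values for each sensory attribute.

    ``assignment`` is either the frame returned by
    :func:`assign_attributes` or a plain compound -> attribute mapping.
    Every attribute column is always present; attributes with no assigned
    compound in the table score 0.  Missing aroma-value cells contribute
    nothing to the sum.
    """
    values = (
        aroma_values.values
        if isinstance(aroma_values, AromaValueTable)
        else aroma_values
    )
    if isinstance(assignment, pd.DataFrame):
        mapping = {
            c: SensoryAttribute.coerce(a)
            for c, a in assignment["attribute"].items()
            if a is not None and not (isinstance(a, float) and np.isnan(a))
        }
    else:
        mapping = {c: SensoryAttribute.coerce(a) for c, a in assignment.items()}

    out = pd.DataFrame(
        0.0, index=values.index, columns=[a.value for a in ATTRIBUTE_ORDER]
    )
    for attr in ATTRIBUTE_ORDER:
        cols = [c for c, a in mapping.items() if a is attr and c in values.columns]
        if cols:
            out[attr.value] = values[cols].sum(axis=1, skipna=True)
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Bundled grouping fixture


def reference_compound_stats() -> pd.DataFrame:
    """Published statistics of the 15 selected compounds: concentration
    average and SD (µg/L), first two PC loadings of the grouping PCA, the
    assigned attribute, and whether the compound was kept in the reduced
    (model-solution) calibration set."""
    with resources.as_file(
        resources.files("aromacal.data").joinpath("compound_stats.csv")
    ) as p:
        df = pd.read_csv(p)
    return df.set_index("compound")


def reference_loadings() -> pd.DataFrame:
    """PC1/PC2 loadings of the 15 selected compounds (published values)."""
    stats = reference_compound_stats()
    return stats[["pc1", "pc2"]].rename(columns={"pc1": "PC1", "pc2": "PC2"})


def default_assignments() -> dict[str, SensoryAttribute]:
    """The published compound -> attribute assignment (the default seed
    set for nearest-centroid grouping)."""
    stats = reference_compound_stats()
    return {
        c: SensoryAttribute.coerce(a) for c, a in stats["attribute"].items()
    }
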