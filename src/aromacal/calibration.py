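"""PLS calibration of attribute scores on NIR spectra.

The calibration method mirrors vendor "XLS regression": partial least
squares on the first derivative of the (optionally scatter-corrected)
spectra, at most 15 latent variables, validated by segmented
cross-validation with contiguous blocks (S = 5 by default).  For each of
the three pretreatment variants (none, SNV, MSC) and every latent-
variable count, the standard error of cross-validation (SECV) is
computed and the global minimizer selects the model.

Reported metrics: R²C and R²CV (squared Pearson correlations of
reference with fitted / cross-validated predictions), SEC with
denominator n − 1 − LV, SECV with denominator n, and RPD = SD(y)/SECV.

The PLS algorithm is NIPALS for a univariate response with deflation of
X only; predictions are ŷ = ȳ + (x − x̄)·β with β = W(PᵀW)⁻¹q.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import (
    DEFAULT_DERIV_POLYORDER,
    DEFAULT_DERIV_WINDOW,
    SpectraSet,
    derivative_transform,
    msc_transform,
    snv_transform,
)

__all__ = [
    "DEFAULT_LV_MAX",
    "DEFAULT_SEGMENTS",
    "PRETREATMENTS",
    "FittedPretreatment",
    "ModelSelectionResult",
    "PerformanceMetrics",
    "PLSModel",
    "PretreatmentConfig",
    "compute_metrics",
    "fit_pls",
    "fit_pretreatment",
    "model_selection",
    "segmented_cv",
    "segments_of",
    "select_best_cell",
]

DEFAULT_LV_MAX = 15
DEFAULT_SEGMENTS = 5
#: Selection order doubles as the tie-break order after latent-variable count.
PRETREATMENTS: tuple[str, ...] = ("none", "snv", "msc")

_RANK_TOL = 1e-12


# ---------------------------------------------------------------------------
# Pretreatment pipeline


@dataclass(frozen=True)
class PretreatmentConfig:
    """Spectral pretreatment: scatter correction followed by the first
    derivative (always applied under XLS regression unless disabled).

    ``log_inverse_reflectance`` optionally converts reflectance to
    log(1/R) first; off by default — values are treated as given.
    """

    scatter: str = "none"
    apply_derivative: bool = True
    deriv_window: int = DEFAULT_DERIV_WINDOW
    deriv_polyorder: int = DEFAULT_DERIV_POLYORDER
    log_inverse_reflectance: bool = False

    def __post_init__(self) -> None:
        if self.scatter not in PRETREATMENTS:
            raise ValueError(
                f"unknown scatter correction {self.scatter!r}; "
                f"expected one of {PRETREATMENTS}"
            )


@dataclass
class FittedPretreatment:
    """A pretreatment with its training-set statistics frozen.

    The MSC reference is the mean of the *training* spectra only, so
    cross-validation never leaks test-sample information through the
    pretreatment.
    """

    config: PretreatmentConfig
    step: float
    msc_reference: np.ndarray | None = None

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if self.config.log_inverse_reflectance:
            values = np.log10(1.0 / values)
        if self.config.scatter == "snv":
            values = snv_transform(values)
        elif self.config.scatter == "msc":
            values = msc_transform(values, self.msc_reference)
        if self.config.apply_derivative:
            values = derivative_transform(
                values, self.step, self.config.deriv_window,
                self.config.deriv_polyorder,
            )
        return values


def fit_pretreatment(
    train_values: np.ndarray, config: PretreatmentConfig, step: float
) -> FittedPretreatment:
    """Freeze pretreatment statistics on training spectra."""
    train_values = np.atleast_2d(np.asarray(train_values, dtype=float))
    reference = None
    if config.scatter == "msc":
        base = train_values
        if config.log_inverse_reflectance:
            base = np.log10(1.0 / base)
        reference = base.mean(axis=0)
    return FittedPretreatment(config=config, step=step, msc_reference=reference)


# ---------------------------------------------------------------------------
# NIPALS PLS (univariate response)


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    x_scores: np.ndarray | None = None  # T, (n, A)
    _coef_cache: dict = field(default_factory=dict, repr=False)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector β for the first ``n_components`` LVs."""
        a = self.n_components if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        if a not in self._coef_cache:
            w, p, q = self.x_weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
            self._coef_cache[a] = w @ np.linalg.solve(p.T @ w, q)
        return self._coef_cache[a]

    def predict(self, x: np.ndarray, n_components: int | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        beta = self.coefficients(n_components)
        return self.y_mean + (x - self.x_mean) @ beta

    def predict_components(self, x: np.ndarray) -> np.ndarray:
        """Predictions for every truncation 1..A; shape (n, A)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.column_stack(
            [self.predict(x, a) for a in range(1, self.n_components + 1)]
        )


def fit_pls(x: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit univariate-response PLS by NIPALS with mean centering.

    X is deflated component by component; y is not (equivalent for a
    univariate response).  If the requested number of components exceeds
    the effective rank of centered X, the model is truncated with a
    warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n != y.size:
        raise ValueError("X and y have different numbers of samples")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response; PLS undefined")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    bound = min(n - 1, p)
    if n_components > bound:
        warnings.warn(
            f"n_components={n_components} exceeds bound {bound}; truncating",
            stacklevel=2,
        )
        n_components = bound

    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xc = x - x_mean
    yc = y - y_mean
    scale0 = float(np.abs(xc).max()) or 1.0

    ws, ps, qs, ts = [], [], [], []
    for _ in range(n_components):
        w = xc.T @ yc
        norm = np.linalg.norm(w)
        if norm <= _RANK_TOL * scale0:
            warnings.warn(
                "response variance exhausted; truncating latent variables",
                stacklevel=2,
            )
            break
        w = w / norm
        t = xc @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * scale0) ** 2:
            warnings.warn("X rank exhausted; truncating latent variables", stacklevel=2)
            break
        pvec = xc.T @ t / tt
        qval = float(yc @ t / tt)
        xc = xc - np.outer(t, pvec)
        ws.append(w)
        ps.append(pvec)
        qs.append(qval)
        ts.append(t)
    if not ws:
        raise ValueError("no latent variable could be extracted")
    return PLSModel(
        n_components=len(ws),
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=np.column_stack(ws),
        x_loadings=np.column_stack(ps),
        y_loadings=np.array(qs),
        x_scores=np.column_stack(ts),
    )


# ---------------------------------------------------------------------------
# Segmented cross-validation


def segments_of(n: int, segments: int) -> list[np.ndarray]:
    """Contiguous blocks in input order with sizes differing by <= 1
    (e.g. n=36, S=5 -> 8,7,7,7,7)."""
    if segments < 2:
        raise ValueError("need at least 2 segments")
    if n < segments:
        raise ValueError(f"cannot split {n} samples into {segments} segments")
    return np.array_split(np.arange(n), segments)


def _cv_predictions(
    values: np.ndarray,
    y: np.ndarray,
    config: PretreatmentConfig,
    n_components: int,
    segments: int,
    step: float,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """CV predictions for every LV truncation 1..n_components; (n, A).

    For each fold the pretreatment statistics and the PLS model are
    refit on the training folds only.
    """
    n = values.shape[0]
    idx = np.arange(n) if order is None else np.asarray(order)
    blocks = segments_of(n, segments)
    preds = np.full((n, n_components), np.nan)
    for block in blocks:
        test = idx[block]
        train = np.setdiff1d(idx, test)
        if train.size < 2:
            raise ValueError("a segment leaves fewer than 2 training samples")
        pre = fit_pretreatment(values[train], config, step)
        xt = pre.transform(values[train])
        model = fit_pls(xt, y[train], n_components)
        block_pred = model.predict_components(pre.transform(values[test]))
        if model.n_components < n_components:
            # rank-truncated: extend with the last available component
            pad = np.repeat(block_pred[:, -1:], n_components - model.n_components, 1)
            block_pred = np.hstack([block_pred, pad])
        preds[test] = block_pred
    return preds


def segmented_cv(
    spectra: "SpectraSet | np.ndarray",
    y: np.ndarray,
    config: PretreatmentConfig,
    n_components: int,
    segments: int = DEFAULT_SEGMENTS,
    *,
    step: float | None = None,
    shuffle: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cross-validated predictions, one per sample.

    Samples are partitioned into ``segments`` contiguous blocks in input
    order (vendor-style segmented CV).  ``shuffle=True`` randomizes the
    fold membership (seedable via ``rng``) for robustness checks.
    """
    values, step = _unpack(spectra, step)
    y = np.asarray(y, dtype=float).ravel()
    order = None
    if shuffle:
        rng = rng or np.random.default_rng()
        order = rng.permutation(values.shape[0])
    preds = _cv_predictions(values, y, config, n_components, segments, step, order)
    return preds[:, n_components - 1]


def _unpack(spectra, step):
    if isinstance(spectra, SpectraSet):
        return spectra.values, spectra.step
    values = np.atleast_2d(np.asarray(spectra, dtype=float))
    if step is None:
        raise ValueError("step (nm per channel) required for array input")
    return values, float(step)


# ---------------------------------------------------------------------------
# Metrics and model selection


@dataclass
class PerformanceMetrics:
    r2_c: float
    r2_cv: float
    sec: float
    secv: float
    rpd: float
    n_components: int
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "r2_c": self.r2_c,
            "r2_cv": self.r2_cv,
            "sec": self.sec,
            "secv": self.secv,
            "rpd": self.rpd,
            "n_lv": self.n_components,
            "n": self.n_samples,
        }


def _r2(y: np.ndarray, pred: np.ndarray, definition: str) -> float:
    if definition == "pearson":
        sy, sp = np.std(y), np.std(pred)
        if sy == 0 or sp == 0:
            return float("nan")
        return float(np.corrcoef(y, pred)[0, 1] ** 2)
    if definition == "explained":
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            return float("nan")
        return 1.0 - float(np.sum((y - pred) ** 2)) / sst
    raise ValueError(f"unknown R² definition {definition!r}")


def compute_metrics(
    y: np.ndarray,
    y_fit: np.ndarray,
    y_cv: np.ndarray,
    n_components: int,
    r2_definition: str = "pearson",
) -> PerformanceMetrics:
    """Calibration and cross-validation metrics.

    R² values are squared Pearson correlations by default
    (``r2_definition='explained'`` switches to 1 − SSE/SST);
    SEC = √(Σe²_fit/(n − 1 − LV)), SECV = √(Σe²_cv/n),
    RPD = SD(y, n−1)/SECV (infinite when SECV is 0).
    """
    y = np.asarray(y, dtype=float).ravel()
    y_fit = np.asarray(y_fit, dtype=float).ravel()
    y_cv = np.asarray(y_cv, dtype=float).ravel()
    n = y.size
    if y_fit.size != n or y_cv.size != n:
        raise ValueError("prediction vectors must match the response length")
    if n <= n_components + 1:
        raise ValueError("need n > n_lv + 1 for the SEC denominator")
    sec = float(np.sqrt(np.sum((y - y_fit) ** 2) / (n - 1 - n_components)))
    secv = float(np.sqrt(np.sum((y - y_cv) ** 2) / n))
    sd = float(np.std(y, ddof=1))
    rpd = float("inf") if secv == 0 else sd / secv
    return PerformanceMetrics(
        r2_c=_r2(y, y_fit, r2_definition),
        r2_cv=_r2(y, y_cv, r2_definition),
        sec=sec,
        secv=secv,
        rpd=rpd,
        n_components=n_components,
        n_samples=n,
    )


def select_best_cell(rows: Sequence[dict]) -> dict:
    """The SECV-minimizing grid cell; exact ties go to the smaller
    latent-variable count, then to pretreatment order none < snv < msc."""
    rank = {s: i for i, s in enumerate(PRETREATMENTS)}
    return min(
        rows, key=lambda r: (r["secv"], r["n_lv"], rank.get(r["pretreatment"], 99))
    )


@dataclass
class ModelSelectionResult:
    pretreatment: str
    n_components: int
    metrics: PerformanceMetrics
    grid: pd.DataFrame  # columns: pretreatment, n_lv, secv
    model: PLSModel
    fitted_pretreatment: FittedPretreatment
    y_fit: np.ndarray
    y_cv: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "pretreatment": self.pretreatment,
            "n_lv": self.n_components,
            "r2_c": self.metrics.r2_c,
            "r2_cv": self.metrics.r2_cv,
            "sec": self.metrics.sec,
            "secv": self.metrics.secv,
            "rpd": self.metrics.rpd,
            "model": {
                "x_mean": self.model.x_mean.tolist(),
                "y_mean": self.model.y_mean,
                "coefficients": self.model.coefficients(self.n_components).tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def model_selection(
    spectra: "SpectraSet | np.ndarray",
    y: np.ndarray,
    lv_max: int = DEFAULT_LV_MAX,
    segments: int = DEFAULT_SEGMENTS,
    pretreatments: Sequence[str] = PRETREATMENTS,
    *,
    step: float | None = None,
    base_config: PretreatmentConfig | None = None,
    r2_definition: str = "pearson",
) -> ModelSelectionResult:
    """Evaluate the pretreatment × latent-variable grid and pick the
    SECV minimizer.

    The first derivative is applied in every grid cell; the grid varies
    only the scatter correction (none, SNV, MSC) and the LV count.  Ties
    are broken by the smaller LV count, then by pretreatment order
    none < snv < msc.
    """
    values, step = _unpack(spectra, step)
    y = np.asarray(y, dtype=float).ravel()
    n = values.shape[0]
    min_train = n - max(len(b) for b in segments_of(n, segments))
    a_max = min(lv_max, min_train - 1, values.shape[1])
    if a_max < 1:
        raise ValueError("too few samples for even one latent variable")

    base = base_config or PretreatmentConfig()
    rows = []
    cv_store: dict[str, np.ndarray] = {}
    for scatter in pretreatments:
        config = PretreatmentConfig(
            scatter=scatter,
            apply_derivative=base.apply_derivative,
            deriv_window=base.deriv_window,
            deriv_polyorder=base.deriv_polyorder,
            log_inverse_reflectance=base.log_inverse_reflectance,
        )
        preds = _cv_predictions(values, y, config, a_max, segments, step)
        cv_store[scatter] = preds
        for a in range(1, a_max + 1):
            secv = float(np.sqrt(np.mean((y - preds[:, a - 1]) ** 2)))
            rows.append({"pretreatment": scatter, "n_lv": a, "secv": secv})
    grid = pd.DataFrame(rows)

    best = select_best_cell(rows)
    scatter, a_best = best["pretreatment"], int(best["n_lv"])

    config = PretreatmentConfig(
        scatter=scatter,
        apply_derivative=base.apply_derivative,
        deriv_window=base.deriv_window,
        deriv_polyorder=base.deriv_polyorder,
        log_inverse_reflectance=base.log_inverse_reflectance,
    )
    fitted_pre = fit_pretreatment(values, config, step)
    model = fit_pls(fitted_pre.transform(values), y, a_best)
    y_fit = model.predict(fitted_pre.transform(values), a_best)
    y_cv = cv_store[scatter][:, a_best - 1]
    metrics = compute_metrics(y, y_fit, y_cv, a_best, r2_definition)
    return ModelSelectionResult(
        pretreatment=scatter,
        n_components=a_best,
        metrics=metrics,
        grid=grid,
        model=model,
        fitted_pretreatment=fitted_pre,
        y_fit=y_fit,
        y_cv=y_cv,
    )
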