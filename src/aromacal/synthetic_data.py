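"""Synthetic grape-mash datasets with known ground truth.

No public dataset accompanies the on-line NIR measurements this package
analyzes, so every pipeline stage is exercised on simulated data whose
statistical structure matches what the analysis assumes:

* per-compound concentrations are log-normal with the published
  per-compound arithmetic mean and SD, and compounds sharing a sensory
  attribute share a latent factor inducing a within-attribute
  correlation ρ;
* spectra are Beer–Lambert-style linear mixtures of fictional but fixed
  Gaussian constituent bands plus a constant background, distorted by a
  per-sample affine scatter (additive offset, log-normal gain) and
  per-channel noise;
* panel scores arise from a latent intensity (standardized attribute
  score + panelist random effect + noise) cut into the ordinal 1–4
  scale at fixed cut-points.

Everything is driven by one integer seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from . import compounds as _compounds
from . import grouping as _grouping
from .spectra import SpectraSet, default_grid

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "default_band_library",
    "default_compound_stats",
    "simulate_concentrations",
    "simulate_dataset",
    "simulate_sensory_panel",
    "simulate_spectra",
]


def default_compound_stats() -> pd.DataFrame:
    """Per-compound mean/SD (µg/L) and attribute for the 15 selected
    compounds, from the published summary statistics."""
    stats = _grouping.reference_compound_stats()
    return stats[["average_ug_L", "sd_ug_L", "attribute"]].rename(
        columns={"average_ug_L": "mean_ug_L"}
    )


def default_band_library() -> pd.DataFrame:
    """The fictional, fixed constituent band library (center, width,
    amplitude per compound).  Amplitudes scale inversely with the
    compound's mean concentration so each constituent's band varies on
    an O(1) scale; realism of the shapes is not a goal — linear
    encodability of the target plus scatter distortion is."""
    with resources.as_file(
        resources.files("aromacal.data").joinpath("synthetic_band_library.csv")
    ) as p:
        return pd.read_csv(p).set_index("compound")


# Fixed background: broad water/sugar-like absorption bands plus a gentle
# baseline; constant across samples (per-sample variation enters through
# the scatter model).
_BACKGROUND_BANDS = ((970.0, 45.0, 0.3), (1190.0, 60.0, 0.4), (1450.0, 70.0, 0.8))
_BACKGROUND_OFFSET = 0.2
_BACKGROUND_SLOPE = 2e-4  # per nm above 400


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the published study: 36 mash samples, the published
    compound means/SDs, a 30-member panel rating on the 1–4 scale.
    """

    n_samples: int = 36
    compound_stats: pd.DataFrame | None = None  # mean_ug_L, sd_ug_L, attribute
    within_attribute_correlation: float = 0.6
    band_library: pd.DataFrame | None = None  # center_nm, width_nm, amplitude
    background_scale: float = 1.0
    scatter_offset_sd: float = 0.01
    scatter_gain_log_sd: float = 0.005
    noise_sd: float = 0.002
    n_panelists: int = 30
    panelist_sd: float = 0.3
    panel_noise_sd: float = 0.5
    panel_effect_scale: float = 1.0
    panel_cutpoints: tuple[float, float, float] = (-0.5, 0.5, 1.5)
    panel_modality: str = "odour"
    seed: int = 0

    def __post_init__(self) -> None:
        rho = self.within_attribute_correlation
        if not 0 <= rho < 1:
            raise ValueError(f"correlation must be in [0, 1), got {rho}")
        for name in (
            "scatter_offset_sd", "scatter_gain_log_sd", "noise_sd",
            "panelist_sd", "panel_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_panelists < 1:
            raise ValueError("n_panelists must be >= 1")
        if list(self.panel_cutpoints) != sorted(self.panel_cutpoints):
            raise ValueError("panel cut-points must be non-decreasing")

    def stats(self) -> pd.DataFrame:
        return (
            default_compound_stats()
            if self.compound_stats is None
            else self.compound_stats
        )

    def bands(self) -> pd.DataFrame:
        return (
            default_band_library() if self.band_library is None else self.band_library
        )

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneratorConfig":
        payload = dict(payload)
        if "compound_stats" in payload and payload["compound_stats"] is not None:
            payload["compound_stats"] = pd.DataFrame(
                payload["compound_stats"]
            ).set_index("compound")
        if "band_library" in payload and payload["band_library"] is not None:
            payload["band_library"] = pd.DataFrame(
                payload["band_library"]
            ).set_index("compound")
        if "panel_cutpoints" in payload:
            payload["panel_cutpoints"] = tuple(payload["panel_cutpoints"])
        return cls(**payload)


def _rngs(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(3)
    return {
        "concentrations": np.random.default_rng(children[0]),
        "spectra": np.random.default_rng(children[1]),
        "panel": np.random.default_rng(children[2]),
    }


def simulate_concentrations(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a long-format concentration table (sample_id, compound,
    value, unit) with log-normal marginals matching the configured
    arithmetic mean and SD per compound, and within-attribute
    correlation ρ via a shared latent factor."""
    rng = rng if rng is not None else _rngs(config)["concentrations"]
    stats = config.stats()
    rho = config.within_attribute_correlation
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    attrs = stats["attribute"].astype(str)
    latent = {a: rng.standard_normal(n) for a in attrs.unique()}
    rows = []
    for name, row in stats.iterrows():
        mean, sd = float(row["mean_ug_L"]), float(row["sd_ug_L"])
        if sd < 0:
            raise ValueError(f"{name}: SD must be >= 0")
        if sd > 0 and mean <= 0:
            raise ValueError(f"{name}: mean must be > 0 when SD > 0")
        if sd == 0:
            values = np.full(n, mean)
        else:
            u = np.sqrt(rho) * latent[attrs[name]] + np.sqrt(1 - rho) * (
                rng.standard_normal(n)
            )
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2
            values = np.exp(mu + np.sqrt(sigma2) * u)
        for sid, v in zip(sample_ids, values):
            rows.append((sid, name, float(v), "ug/L"))
    return pd.DataFrame(rows, columns=["sample_id", "compound", "value", "unit"])


def _gauss(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def background_spectrum(grid: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """The fixed background profile shared by all samples."""
    bg = _BACKGROUND_OFFSET + _BACKGROUND_SLOPE * (grid - grid[0])
    for center, width, amp in _BACKGROUND_BANDS:
        bg = bg + amp * _gauss(grid, center, width)
    return scale * bg


def simulate_spectra(
    concentrations: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> SpectraSet:
    """Linear constituent mixing with affine scatter and additive noise.

    clean_i = background + Σ_c conc_ic · amplitude_c · gauss(center_c, width_c)
    observed_i = a_i + b_i · clean_i + ε_i,  a~N(0,σ_a), log b~N(0,σ_b),
    ε per channel N(0, σ_ε).
    """
    rng = rng if rng is not None else _rngs(config)["spectra"]
    bands = config.bands()
    grid = default_grid()
    conc = concentrations.pivot_table(
        index="sample_id", columns="compound", values="value", aggfunc="mean",
        sort=False,
    )
    missing = [c for c in conc.columns if c not in bands.index]
    if missing:
        raise ValueError(f"no band definition for compound(s): {missing}")
    profiles = []
    for name in conc.columns:
        b = bands.loc[name]
        center, width, amp = float(b.center_nm), float(b.width_nm), float(b.amplitude)
        if not grid[0] <= center <= grid[-1]:
            raise ValueError(
                f"band center {center} nm for {name!r} outside the "
                f"{grid[0]:.0f}-{grid[-1]:.0f} nm grid"
            )
        profiles.append(amp * _gauss(grid, center, width))
    clean = conc.to_numpy(dtype=float) @ np.vstack(profiles)
    clean = clean + background_spectrum(grid, config.background_scale)

    n = clean.shape[0]
    a = rng.normal(0.0, config.scatter_offset_sd, size=(n, 1))
    b = np.exp(rng.normal(0.0, config.scatter_gain_log_sd, size=(n, 1)))
    eps = rng.normal(0.0, config.noise_sd, size=clean.shape)
    observed = a + b * clean + eps
    return SpectraSet(grid, observed, [str(s) for s in conc.index])


def simulate_sensory_panel(
    attribute_scores: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ordinal panel ratings from latent intensities.

    Latent intensity for panelist p on sample s and attribute k is the
    standardized attribute score (times ``panel_effect_scale``) plus a
    panelist random effect and residual noise; fixed cut-points map it
    onto the 1–4 scale.
    """
    rng = rng if rng is not None else _rngs(config)["panel"]
    scores = attribute_scores.to_numpy(dtype=float)
    sd = scores.std(axis=0, ddof=0)
    mean = scores.mean(axis=0)
    with np.errstate(invalid="ignore"):
        standardized = np.where(sd > 0, (scores - mean) / np.where(sd > 0, sd, 1), 0.0)
    standardized = standardized * config.panel_effect_scale

    cut = np.asarray(config.panel_cutpoints, dtype=float)
    n_samples, n_attrs = scores.shape
    rows = []
    panelist_effect = rng.normal(0.0, config.panelist_sd, size=config.n_panelists)
    noise = rng.normal(
        0.0, config.panel_noise_sd, size=(config.n_panelists, n_samples, n_attrs)
    )
    latent = standardized[None, :, :] + panelist_effect[:, None, None] + noise
    rating = np.searchsorted(cut, latent, side="left") + 1
    for pi in range(config.n_panelists):
        for si, sid in enumerate(attribute_scores.index):
            for ai, attr in enumerate(attribute_scores.columns):
                rows.append(
                    (f"P{pi + 1:02d}", str(sid), config.panel_modality, str(attr),
                     int(rating[pi, si, ai]))
                )
    return pd.DataFrame(
        rows, columns=["panelist", "solution", "modality", "attribute", "score"]
    )


@dataclass
class SyntheticDataset:
    """A complete simulated study: concentrations, spectra, ground-truth
    attribute scores, panel ratings, and the config that produced them."""

    concentrations: pd.DataFrame
    spectra: SpectraSet
    truth_scores: pd.DataFrame
    panel: pd.DataFrame
    config: GeneratorConfig

    def recompute_scores(self) -> pd.DataFrame:
        """Recompute attribute scores from the concentration table via
        the scoring and grouping modules (round-trip check)."""
        table = _compounds.compute_aroma_values(
            self.concentrations, _compounds.reference_compounds()
        )
        return _grouping.attribute_scores(table, _grouping.default_assignments())


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full dataset; the stored truth scores are computed from
    the simulated concentrations with the published thresholds and the
    published attribute assignment."""
    rngs = _rngs(config)
    conc = simulate_concentrations(config, rngs["concentrations"])
    spectra = simulate_spectra(conc, config, rngs["spectra"])
    table = _compounds.compute_aroma_values(conc, _compounds.reference_compounds())
    truth = _grouping.attribute_scores(table, _grouping.default_assignments())
    truth = truth.loc[[sid for sid in spectra.sample_ids]]
    panel = simulate_sensory_panel(truth, config, rngs["panel"])
    return SyntheticDataset(
        concentrations=conc,
        spectra=spectra,
        truth_scores=truth,
        panel=panel,
        config=config,
    )
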