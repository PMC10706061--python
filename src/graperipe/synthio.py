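"""Synthetic chemistry and Vis-NIR reflectance generator.

No raw grape data accompany the study this package reproduces, so the whole
pipeline is exercised on synthetic material with the statistical structure
the downstream analysis assumes:

* per-stage chemistry (SSC, TA, TP, TN) drawn from truncated normals with
  the published stage means/SDs and stage counts 32/34/55/49/30;
* reflectance on the 1507-channel 400-1029 nm grid, built from a smooth
  baseline minus Gaussian absorption bands near 535, 680, 820 and 970 nm
  whose depths are affine in the linked chemistry value (the chlorophyll
  band decays with stage index instead, mimicking veraison colour loss);
* per-replicate multiplicative-affine scatter (a*s + b) plus additive
  noise, with 10 replicate sub-spectra per sample.

The scatter layer is deliberately the model that multiplicative scatter
correction inverts exactly, so preprocessing has a well-defined optimum.
Channels within +/-2 sigma of a band centre are exposed through
:func:`informative_channel_mask` so wavelength-selection recovery can be
scored against the generator's own truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .containers import (
    CHEMISTRY_COLUMNS,
    ReplicateSet,
    stage_name,
)

__all__ = [
    "StageChemistryModel",
    "SpectralBand",
    "SynthConfig",
    "default_chemistry_models",
    "default_bands",
    "generate_chemistry",
    "generate_spectra",
    "informative_channel_mask",
    "write_chemistry_csv",
    "read_chemistry_csv",
    "write_spectra_csv",
    "read_spectra_csv",
]


class ConfigurationError(ValueError):
    """Raised when a synthesis configuration is internally inconsistent."""


@dataclass(frozen=True)
class StageChemistryModel:
    """Mean/SD model of the four maturity indicators for one stage.

    Units: SSC in degrees Brix, TA in g/L, TP in mg gallic-acid
    equivalents per g skin powder, TN in mg epicatechin equivalents per g.
    """

    stage: str
    mean_ssc: float
    sd_ssc: float
    mean_ta: float
    sd_ta: float
    mean_tp: float
    sd_tp: float
    mean_tn: float
    sd_tn: float
    n_samples: int

    def __post_init__(self) -> None:
        for name in ("mean_ssc", "mean_ta", "mean_tp", "mean_tn"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("sd_ssc", "sd_ta", "sd_tp", "sd_tn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")


def default_chemistry_models() -> list[StageChemistryModel]:
    """The published per-stage indicator means/SDs with counts 32/34/55/49/30."""
    rows = [
        # stage, ssc, sd, ta, sd, tp, sd, tn, sd, n
        ("I", 11.93, 3.07, 12.91, 4.49, 62.12, 8.57, 48.60, 11.17, 32),
        ("II", 14.84, 1.24, 5.92, 1.55, 45.79, 5.136, 30.64, 5.14, 34),
        ("III", 15.71, 1.27, 3.76, 0.79, 34.13, 3.08, 14.96, 3.53, 55),
        ("IV", 17.78, 0.65, 3.39, 0.35, 40.86, 2.93, 19.12, 3.21, 49),
        ("V", 18.71, 0.71, 3.42, 0.38, 49.44, 3.65, 25.49, 3.16, 30),
    ]
    return [StageChemistryModel(*r) for r in rows]


@dataclass(frozen=True)
class SpectralBand:
    """One Gaussian absorption band of the forward model.

    ``amplitude_link`` names the chemistry value the band depth follows:
    one of ``ssc``, ``ta``, ``tp`` or ``chlorophyll_stage`` (depth decays
    linearly with stage index, emulating chlorophyll breakdown).
    """

    center: float
    width: float
    amplitude_link: str
    link_sign: int = 1
    base_amplitude: float = 0.1

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 1029.0:
            raise ConfigurationError("band centre must lie within 400-1029 nm")
        if self.width <= 0:
            raise ConfigurationError("band width (sigma) must be positive")
        if self.amplitude_link not in ("ssc", "ta", "tp", "chlorophyll_stage"):
            raise ConfigurationError(f"unknown amplitude link {self.amplitude_link!r}")
        if self.link_sign not in (-1, 1):
            raise ConfigurationError("link_sign must be +1 or -1")


def default_bands() -> list[SpectralBand]:
    """Default four-band forward model.

    535 nm tracks anthocyanin/phenolics (TP), 680 nm tracks chlorophyll
    loss with ripening, and the two weak near-infrared bands at 820 and
    970 nm track sugar (SSC) and acid (TA) O-H/C-H overtones.
    """
    return [
        SpectralBand(535.0, 22.0, "tp", 1, 0.18),
        SpectralBand(680.0, 18.0, "chlorophyll_stage", 1, 0.22),
        SpectralBand(820.0, 25.0, "ssc", 1, 0.06),
        SpectralBand(970.0, 30.0, "ta", 1, 0.05),
    ]


@dataclass
class SynthConfig:
    """Everything that determines a synthetic dataset (incl. the seed)."""

    chemistry_models: list[StageChemistryModel] = field(
        default_factory=default_chemistry_models
    )
    bands: list[SpectralBand] = field(default_factory=default_bands)
    grid_start: float = 400.0
    grid_end: float = 1029.0
    n_channels: int = 1507
    scatter_slope_sd: float = 0.08
    scatter_offset_sd: float = 0.015
    noise_sd: float = 0.004
    replicates_per_sample: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if not self.grid_start < self.grid_end:
            raise ConfigurationError("grid_start must be < grid_end")
        if self.replicates_per_sample < 1:
            raise ConfigurationError("replicates_per_sample must be >= 1")
        if self.noise_sd < 0 or self.scatter_slope_sd < 0 or self.scatter_offset_sd < 0:
            raise ConfigurationError("noise/scatter SDs must be >= 0")
        if not self.chemistry_models:
            raise ConfigurationError("at least one stage chemistry model required")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.grid_end, self.n_channels)

    @property
    def n_total_samples(self) -> int:
        return sum(m.n_samples for m in self.chemistry_models)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["chemistry_models"] = [
            StageChemistryModel(**m) for m in d.get("chemistry_models", [])
        ] or default_chemistry_models()
        d["bands"] = [SpectralBand(**b) for b in d.get("bands", [])] or default_bands()
        return cls(**d)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0; degenerate at the mean for sd=0."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd  # lower bound in standard units
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.rvs(size=size, random_state=rng)


def generate_chemistry(config: SynthConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the per-sample chemistry table and its true stage labels.

    Returns a DataFrame with :data:`~graperipe.containers.CHEMISTRY_COLUMNS`
    (SSC/TA ratio included) and an int array of 0-based stage indices.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    labels = []
    counter = 0
    for stage_idx, model in enumerate(config.chemistry_models):
        n = model.n_samples
        ssc = _truncated_normal(rng, model.mean_ssc, model.sd_ssc, n)
        ta = _truncated_normal(rng, model.mean_ta, model.sd_ta, n)
        tp = _truncated_normal(rng, model.mean_tp, model.sd_tp, n)
        tn = _truncated_normal(rng, model.mean_tn, model.sd_tn, n)
        for i in range(n):
            records.append(
                {
                    "sample_id": f"S{counter:03d}",
                    "stage": stage_name(stage_idx) if len(config.chemistry_models) <= 5
                    else str(stage_idx),
                    "ssc_brix": ssc[i],
                    "ta_g_l": ta[i],
                    "tp_mg_g": tp[i],
                    "tn_mg_g": tn[i],
                    "ssc_ta_ratio": ssc[i] / ta[i],
                }
            )
            labels.append(stage_idx)
            counter += 1
    chem = pd.DataFrame.from_records(records, columns=list(CHEMISTRY_COLUMNS))
    return chem, np.asarray(labels, dtype=int)


def _band_amplitudes(
    chem: pd.DataFrame, labels: np.ndarray, config: SynthConfig
) -> np.ndarray:
    """Per-sample depth of each band: affine in the linked chemistry value.

    Indicator-linked depths scale the base amplitude by the sample value over
    the count-weighted grand mean of the configured stage models, so a
    'typical' sample has depth ``base_amplitude``.  The chlorophyll link
    decays linearly from full depth at the first stage to 20% at the last.
    """
    link_col = {"ssc": "ssc_brix", "ta": "ta_g_l", "tp": "tp_mg_g"}
    n_stages = max(len(config.chemistry_models) - 1, 1)
    weights = np.array([m.n_samples for m in config.chemistry_models], dtype=float)
    amps = np.empty((len(chem), len(config.bands)))
    for j, band in enumerate(config.bands):
        if band.amplitude_link == "chlorophyll_stage":
            frac = (n_stages - labels) / n_stages  # 1 at stage I, 0 at last stage
            rel = 0.2 + 0.8 * frac
        else:
            col = link_col[band.amplitude_link]
            attr = f"mean_{band.amplitude_link}"
            grand = np.average(
                [getattr(m, attr) for m in config.chemistry_models], weights=weights
            )
            rel = chem[col].to_numpy() / grand
        amps[:, j] = band.link_sign * band.base_amplitude * rel
    return amps


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth sigmoidal reflectance baseline rising through the red edge."""
    return 0.30 + 0.45 / (1.0 + np.exp(-(wl - 560.0) / 90.0))


def generate_spectra(
    chem: pd.DataFrame, labels: np.ndarray, config: SynthConfig
) -> ReplicateSet:
    """Forward-model reflectance replicates for every chemistry record.

    Each clean spectrum is the smooth baseline minus the Gaussian band
    stack; each replicate is then distorted as ``a*s + b + eps`` with
    ``a ~ N(1, scatter_slope_sd)``, ``b ~ N(0, scatter_offset_sd)`` and
    i.i.d. channel noise ``eps ~ N(0, noise_sd)``, clipped to [0, 1.5].
    """
    if len(chem) != len(labels):
        raise ConfigurationError("chemistry table and labels are not aligned")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1])
    )  # independent of the chemistry stream
    wl = config.wavelengths
    base = _baseline(wl)
    amps = _band_amplitudes(chem, labels, config)
    profiles = np.stack(
        [np.exp(-0.5 * ((wl - b.center) / b.width) ** 2) for b in config.bands]
    )  # (n_bands, p)
    clean = base[None, :] - amps @ profiles  # (n, p)

    n, p = clean.shape
    r = config.replicates_per_sample
    a = rng.normal(1.0, config.scatter_slope_sd, size=(n, r, 1))
    b = rng.normal(0.0, config.scatter_offset_sd, size=(n, r, 1))
    eps = rng.normal(0.0, config.noise_sd, size=(n, r, p))
    reps = a * clean[:, None, :] + b + eps
    np.clip(reps, 0.0, 1.5, out=reps)
    return ReplicateSet(reps, wl, [str(s) for s in chem["sample_id"]])


def informative_channel_mask(config: SynthConfig) -> np.ndarray:
    """Boolean mask over the grid: channels within +/-2 sigma of a band centre.

    This is the generator's record of which channels carry chemistry signal;
    wavelength-selection recovery is scored against it.
    """
    wl = config.wavelengths
    mask = np.zeros(wl.size, dtype=bool)
    for band in config.bands:
        mask |= np.abs(wl - band.center) <= 2.0 * band.width
    return mask


# ---------------------------------------------------------------------------
# CSV round-trips


def write_chemistry_csv(chem: pd.DataFrame, path: str | Path) -> None:
    chem.to_csv(path, index=False)


def read_chemistry_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sample_id": str})


def write_spectra_csv(reps: ReplicateSet, path: str | Path) -> None:
    reps.to_dataframe().to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> ReplicateSet:
    return ReplicateSet.from_dataframe(pd.read_csv(path, dtype={"sample_id": str}))
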