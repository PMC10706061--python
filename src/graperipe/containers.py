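"""Shared in-memory containers for the maturity-staging pipeline.

Spectra travel through the pipeline as a :class:`SpectraMatrix` (one row per
sample, columns bound to an ascending wavelength grid in nm) or, before
replicate-representative selection, as a :class:`ReplicateSet` (sample x
replicate x channel).  Chemistry tables are plain :class:`pandas.DataFrame`
objects with the fixed column set in :data:`CHEMISTRY_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Roman numerals for the five maturity stages, index 0..4 -> I..V.
STAGE_NAMES = ("I", "II", "III", "IV", "V")

#: Column order of the chemistry table written/read by this package.
CHEMISTRY_COLUMNS = (
    "sample_id",
    "stage",
    "ssc_brix",
    "ta_g_l",
    "tp_mg_g",
    "tn_mg_g",
    "ssc_ta_ratio",
)

#: The four measured maturity indicators (the SSC/TA ratio is derived).
INDICATOR_COLUMNS = ("ssc_brix", "ta_g_l", "tp_mg_g", "tn_mg_g")


def stage_name(index: int) -> str:
    """Roman label for a 0-based stage index."""
    return STAGE_NAMES[int(index)]


def stage_index(name: str) -> int:
    """0-based stage index for a roman label such as ``"III"``."""
    return STAGE_NAMES.index(name)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 1:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly ascending")
    return wl


@dataclass
class SpectraMatrix:
    """n x p reflectance values bound to a wavelength grid and sample ids."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x channels)")
        self.wavelengths = _check_grid(self.wavelengths)
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"channel mismatch: {self.values.shape[1]} columns vs "
                f"{self.wavelengths.size} wavelengths"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select_channels(self, mask: np.ndarray) -> "SpectraMatrix":
        """Restrict to a boolean channel mask (or integer index array)."""
        mask = np.asarray(mask)
        return SpectraMatrix(
            self.values[:, mask], self.wavelengths[mask], list(self.sample_ids)
        )

    def select_samples(self, idx) -> "SpectraMatrix":
        idx = np.asarray(idx)
        return SpectraMatrix(
            self.values[idx],
            self.wavelengths,
            [self.sample_ids[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{wl:.4f}" for wl in self.wavelengths]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraMatrix":
        wl_cols = [c for c in df.columns if c not in ("sample_id", "replicate_id")]
        return cls(
            df[wl_cols].to_numpy(dtype=float),
            np.array([float(c) for c in wl_cols]),
            [str(s) for s in df["sample_id"]],
        )


@dataclass
class ReplicateSet:
    """Per-sample replicate sub-spectra: values shaped (samples, reps, channels)."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (samples x replicates x channels)")
        self.wavelengths = _check_grid(self.wavelengths)
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("channel count does not match wavelength grid")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match number of samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long/wide CSV layout: sample_id, replicate_id, then one column per nm."""
        n, r, p = self.values.shape
        cols = [f"{wl:.4f}" for wl in self.wavelengths]
        df = pd.DataFrame(self.values.reshape(n * r, p), columns=cols)
        df.insert(0, "replicate_id", np.tile(np.arange(r), n))
        df.insert(0, "sample_id", np.repeat(self.sample_ids, r))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ReplicateSet":
        wl_cols = [c for c in df.columns if c not in ("sample_id", "replicate_id")]
        wl = np.array([float(c) for c in wl_cols])
        ids = list(dict.fromkeys(str(s) for s in df["sample_id"]))
        reps = df.groupby("sample_id", sort=False).size().unique()
        if reps.size != 1:
            raise ValueError("unequal replicate counts across samples")
        vals = df[wl_cols].to_numpy(dtype=float).reshape(len(ids), int(reps[0]), wl.size)
        return cls(vals, wl, ids)
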