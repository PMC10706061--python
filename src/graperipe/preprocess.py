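"""Spectral preprocessing: band trimming, replicate selection, SNV/MSC/S-G.

The pretreatments mirror standard chemometric practice: standard normal
variate (per-spectrum centre/scale), multiplicative scatter correction
(per-spectrum affine regression on a reference spectrum, then inversion)
and Savitzky-Golay smoothing with window 23 / polynomial order 5.  All of
them are row-local or reference-local; the MSC reference is learned on the
calibration set and frozen before it ever touches prediction spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .containers import ReplicateSet, SpectraMatrix

__all__ = [
    "PreprocessConfig",
    "MscFit",
    "trim_bands",
    "representative_spectrum",
    "snv",
    "msc_fit_apply",
    "savgol",
    "apply_method",
]


class DegenerateSampleError(ValueError):
    """A spectrum is constant (SNV) or scatter-colinear (MSC slope ~ 0)."""


@dataclass
class PreprocessConfig:
    """Pretreatment choice and parameters.

    ``method`` is one of ``none``, ``snv``, ``msc``, ``savgol``; the S-G
    window/order defaults (23, 5) and the 400-1029 nm retention window are
    the ones used throughout the pipeline.
    """

    method: str = "msc"
    sg_window: int = 23
    sg_polyorder: int = 5
    trim_low: float = 400.0
    trim_high: float = 1029.0

    def __post_init__(self) -> None:
        if self.method not in ("none", "snv", "msc", "savgol"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if not self.trim_low < self.trim_high:
            raise ValueError("trim_low must be < trim_high")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def trim_bands(spectra: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    """Keep only channels with trim_low <= lambda <= trim_high (inclusive)."""
    wl = spectra.wavelengths
    mask = (wl >= config.trim_low) & (wl <= config.trim_high)
    if not mask.any():
        raise ValueError(
            f"no channels remain in [{config.trim_low}, {config.trim_high}] nm"
        )
    return spectra.select_channels(mask)


def representative_spectrum(
    replicates: ReplicateSet,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Pick, per sample, the replicate closest to its siblings.

    The chosen replicate minimises the sum of Euclidean distances to the
    sample's other replicates; ties go to the lowest replicate index.
    Returns the one-row-per-sample matrix and the chosen indices.
    """
    vals = replicates.values  # (n, r, p)
    n, r, _ = vals.shape
    chosen = np.empty(n, dtype=int)
    rows = np.empty((n, vals.shape[2]))
    for i in range(n):
        # pairwise distances among this sample's replicates
        diff = vals[i, :, None, :] - vals[i, None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        totals = dist.sum(axis=1)
        chosen[i] = int(np.argmin(totals))  # argmin takes the first minimum
        rows[i] = vals[i, chosen[i]]
    return SpectraMatrix(rows, replicates.wavelengths, list(replicates.sample_ids)), chosen


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: per row, (x - mean) / SD with ddof=1."""
    x = spectra.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise DegenerateSampleError(
            f"constant spectrum for sample {spectra.sample_ids[bad[0]]}"
        )
    return SpectraMatrix((x - mu) / sd, spectra.wavelengths, list(spectra.sample_ids))


@dataclass
class MscFit:
    """Frozen MSC state: the reference spectrum and the last fit's (a_i, b_i)."""

    reference: np.ndarray
    slope_per_sample: np.ndarray
    offset_per_sample: np.ndarray

    def apply(self, spectra: SpectraMatrix) -> SpectraMatrix:
        """Correct new spectra against the frozen reference (no refit of it)."""
        corrected, fit = msc_fit_apply(spectra, reference=self.reference)
        self.slope_per_sample = fit.slope_per_sample
        self.offset_per_sample = fit.offset_per_sample
        return corrected


def msc_fit_apply(
    spectra: SpectraMatrix, reference: np.ndarray | None = None
) -> tuple[SpectraMatrix, MscFit]:
    """Multiplicative scatter correction.

    Each row is regressed on the reference spectrum (OLS, x_i = a_i*ref +
    b_i) and inverted to (x_i - b_i)/a_i.  The reference defaults to the
    column-wise mean of the input; passing the calibration-set reference
    corrects prediction spectra without leakage.
    """
    x = spectra.values
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != x.shape[1]:
        raise ValueError("reference length does not match spectral grid")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateSampleError("constant MSC reference spectrum")
    a = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(a) < 1e-8)
    if bad.size:
        raise DegenerateSampleError(
            f"MSC slope ~ 0 for sample {spectra.sample_ids[bad[0]]}"
        )
    b = x.mean(axis=1) - a * ref.mean()
    corrected = (x - b[:, None]) / a[:, None]
    fit = MscFit(ref.copy(), a, b)
    return (
        SpectraMatrix(corrected, spectra.wavelengths, list(spectra.sample_ids)),
        fit,
    )


def savgol(spectra: SpectraMatrix, config: PreprocessConfig) -> SpectraMatrix:
    """Savitzky-Golay smoothing (0th derivative), mirror-padded edges."""
    if spectra.n_channels < config.sg_window:
        raise ValueError(
            f"S-G window {config.sg_window} exceeds channel count {spectra.n_channels}"
        )
    sm = savgol_filter(
        spectra.values,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        axis=1,
        mode="mirror",
    )
    return SpectraMatrix(sm, spectra.wavelengths, list(spectra.sample_ids))


def apply_method(
    spectra: SpectraMatrix,
    config: PreprocessConfig,
    msc_fit: MscFit | None = None,
) -> tuple[SpectraMatrix, MscFit | None]:
    """Dispatch on config.method; threads the frozen MSC fit when given.

    Returns the treated spectra and the MSC fit (None for other methods).
    """
    if config.method == "none":
        return spectra, None
    if config.method == "snv":
        return snv(spectra), None
    if config.method == "savgol":
        return savgol(spectra, config), None
    # msc
    if msc_fit is not None:
        return msc_fit.apply(spectra), msc_fit
    corrected, fit = msc_fit_apply(spectra)
    return corrected, fit
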