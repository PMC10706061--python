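"""Calibration/prediction partitioning with SPXY.

SPXY (sample-set partitioning based on joint x-y distances) extends
Kennard-Stone accretion to a distance that weighs the predictor space and
the response space equally: d(i,j) = dx(i,j)/max dx + dy(i,j)/max dy, both
Euclidean.  The two mutually farthest samples seed the calibration set;
thereafter the sample whose minimum distance to the current calibration
set is largest is added until the requested size is reached.  The
algorithm is fully deterministic; ties break to the lowest sample index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = ["SplitAssignment", "spxy_split", "random_split"]


class DegenerateInputError(ValueError):
    pass


@dataclass
class SplitAssignment:
    """Disjoint, jointly exhaustive calibration/prediction index lists."""

    calibration_ids: list[int] = field(default_factory=list)
    prediction_ids: list[int] = field(default_factory=list)
    fraction: float = 0.75

    @property
    def n_total(self) -> int:
        return len(self.calibration_ids) + len(self.prediction_ids)

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        ids = sample_ids or [str(i) for i in range(self.n_total)]
        rows = [(ids[i], "calibration") for i in self.calibration_ids] + [
            (ids[i], "prediction") for i in self.prediction_ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "set"])


def _pairwise(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _round_half_up(value: float) -> int:
    return int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def spxy_split(
    x: np.ndarray, y: np.ndarray, fraction: float = 0.75
) -> SplitAssignment:
    """Joint x-y Kennard-Stone split at |calibration| = round(fraction * n).

    ``x``: predictor matrix (e.g. preprocessed spectra); ``y``: response
    matrix (here the standardized chemistry indicators), row-aligned.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be row-aligned")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")

    dx = _pairwise(x)
    dy = _pairwise(y)
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise DegenerateInputError("all samples identical; SPXY distance is zero")
    d = (dx / mx if mx > 0 else 0.0) + (dy / my if my > 0 else 0.0)

    n_cal = _round_half_up(fraction * n)
    n_cal = min(max(n_cal, 2), n)

    # seed pair: arg-max combined distance, lowest indices on ties
    flat = np.argmax(d)  # row-major argmax -> lowest (i, j) among ties
    i0, j0 = divmod(int(flat), n)
    selected = [min(i0, j0), max(i0, j0)]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[selected] = True
    # min distance from each remaining sample to the calibration set
    min_d = np.minimum(d[:, selected[0]], d[:, selected[1]])
    while len(selected) < n_cal:
        min_d_masked = np.where(in_cal, -np.inf, min_d)
        nxt = int(np.argmax(min_d_masked))  # argmax takes lowest index on ties
        selected.append(nxt)
        in_cal[nxt] = True
        min_d = np.minimum(min_d, d[:, nxt])
    prediction = [i for i in range(n) if not in_cal[i]]
    return SplitAssignment(sorted(selected), prediction, fraction)


def random_split(
    n: int, fraction: float = 0.75, seed: int = 0
) -> SplitAssignment:
    """Plain seeded-shuffle split, provided for ablation against SPXY."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = _round_half_up(fraction * n)
    return SplitAssignment(
        sorted(int(i) for i in perm[:n_cal]),
        sorted(int(i) for i in perm[n_cal:]),
        fraction,
    )
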