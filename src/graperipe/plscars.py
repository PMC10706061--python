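"""PLS1 regression core and CARS wavelength selection.

CARS (competitive adaptive reweighted sampling) runs N Monte-Carlo rounds.
Each round fits a PLS model on a random 80% of the calibration samples
restricted to the currently retained channels, ranks channels by |b|
(the PLS regression coefficient), enforces the exponentially decreasing
retention cap r_i = a*exp(-k*i) (calibrated so r_1 = 1 and r_N = 2/p),
then resamples channels with replacement with probability proportional to
|b| (adaptive reweighted sampling) and keeps the unique set.  Every
round's retained set is scored by 10-fold RMSECV; the subset with the
minimum RMSECV wins.

The PLS core is NIPALS PLS1 on column-centred data; for a univariate
response each component is a deterministic deflation step, so no inner
iteration is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PlsModel",
    "pls_fit",
    "pls_predict",
    "rmsecv",
    "CarsSchedule",
    "cars_schedule",
    "CarsRunRecord",
    "CarsResult",
    "cars_select",
]


@dataclass
class PlsModel:
    """Fitted PLS1 model with coefficients mapped back to channel space."""

    n_components: int
    x_means: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A)
    loadings: np.ndarray  # (p, A)
    scores: np.ndarray  # (n, A)
    coef: np.ndarray  # (p,) regression coefficients on centred data

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.x_means) @ self.coef + self.y_mean


def pls_fit(x: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """NIPALS PLS1 on column-centred X and centred y.

    ``n_components`` is clipped to min(n-1, p); components whose weight
    vector vanishes (X fully deflated) terminate the loop early.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if y.size != n:
        raise ValueError("x and y must be row-aligned")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    a_max = min(n_components, n - 1, p)
    x_means = x.mean(axis=0)
    y_mean = float(y.mean())
    e = x - x_means
    f = y - y_mean

    ws, ps, ts, qs = [], [], [], []
    for _ in range(a_max):
        w = e.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = e @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p_load = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, p_load)
        f = f - q * t
        ws.append(w)
        ps.append(p_load)
        ts.append(t)
        qs.append(q)
    if not ws:
        # y carries no covariance with X: the PLS solution is the null model
        return PlsModel(
            0,
            x_means,
            y_mean,
            np.zeros((p, 0)),
            np.zeros((p, 0)),
            np.zeros((n, 0)),
            np.zeros(p),
        )
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    t_mat = np.column_stack(ts)
    q_vec = np.array(qs)
    # b = W (P'W)^-1 q maps weights back to the original channel space
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return PlsModel(len(ws), x_means, y_mean, w_mat, p_mat, t_mat, coef)


def pls_predict(model: PlsModel, x: np.ndarray) -> np.ndarray:
    return model.predict(x)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def rmsecv(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Root mean squared error over a seeded shuffled k-fold partition."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if folds > n:
        raise ValueError("more folds than samples")
    if n < 2 * folds:
        raise ValueError("each fold needs at least 2 samples")
    rng = np.random.default_rng(seed)
    sq = np.empty(n)
    for test_idx in _fold_indices(n, folds, rng):
        train = np.setdiff1d(np.arange(n), test_idx)
        if train.size < 2:
            raise ValueError("a fold leaves fewer than 2 training samples")
        model = pls_fit(x[train], y[train], n_components)
        sq[test_idx] = (model.predict(x[test_idx]) - y[test_idx]) ** 2
    return float(np.sqrt(sq.mean()))


@dataclass
class CarsSchedule:
    """Exponentially decreasing retention ratios r_1 = 1 .. r_N = 2/p."""

    n_runs: int
    a: float
    k: float
    ratios: np.ndarray

    def cap(self, run: int, p: int) -> int:
        """Hard channel cap ceil(r_i * p) for 1-based run index."""
        return math.ceil(self.ratios[run - 1] * p)


def cars_schedule(p: int, n_runs: int) -> CarsSchedule:
    """EDF schedule: r_i = a*exp(-k*i), a = (p/2)^(1/(N-1)), k = ln(p/2)/(N-1)."""
    if p < 3:
        raise ValueError("need at least 3 channels")
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return CarsSchedule(n_runs, a, k, a * np.exp(-k * i))


@dataclass
class CarsRunRecord:
    run_index: int
    retained_channels: np.ndarray
    rmsecv: float


@dataclass
class CarsResult:
    """Per-run retention records plus the arg-min RMSECV selection."""

    records: list[CarsRunRecord] = field(default_factory=list)
    best_run: int = 0
    selected_channels: np.ndarray = field(default_factory=lambda: np.array([], int))
    selected_wavelengths: np.ndarray = field(default_factory=lambda: np.array([]))
    schedule: CarsSchedule | None = None

    @property
    def rmsecv_trajectory(self) -> np.ndarray:
        return np.array([r.rmsecv for r in self.records])

    @property
    def retained_counts(self) -> np.ndarray:
        return np.array([r.retained_channels.size for r in self.records])

    def reduction_fraction(self, p_total: int) -> float:
        """Fraction of channels discarded by the winning subset."""
        return 1.0 - self.selected_channels.size / p_total

    def to_json(self, path: str | Path) -> None:
        d = {
            "best_run": self.best_run,
            "selected_channels": self.selected_channels.tolist(),
            "selected_wavelengths": np.round(self.selected_wavelengths, 4).tolist(),
            "rmsecv_trajectory": self.rmsecv_trajectory.tolist(),
            "retained_counts": self.retained_counts.tolist(),
        }
        if self.schedule is not None:
            d["schedule"] = {
                "n_runs": self.schedule.n_runs,
                "a": self.schedule.a,
                "k": self.schedule.k,
            }
        Path(path).write_text(json.dumps(d, indent=2))


def cars_select(
    x: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray | None = None,
    n_runs: int = 100,
    folds: int = 10,
    n_components: int = 10,
    mc_fraction: float = 0.8,
    seed: int = 0,
) -> CarsResult:
    """Competitive adaptive reweighted sampling over the channels of ``x``.

    ``y`` is the numeric response the RMSECV criterion scores (here the
    stage index 0-4 treated as one continuous response).  Returns the
    per-run records and the arg-min RMSECV subset, mapped to nm when a
    wavelength grid is supplied.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    sched = cars_schedule(p, n_runs)
    rng = np.random.default_rng(seed)
    n_mc = math.ceil(mc_fraction * n)

    retained = np.arange(p)
    records: list[CarsRunRecord] = []
    for run in range(1, n_runs + 1):
        sub = rng.choice(n, size=n_mc, replace=False)
        a_comp = min(n_components, n_mc - 1, retained.size)
        model = pls_fit(x[np.ix_(sub, retained)], y[sub], a_comp)
        absb = np.abs(model.coef)
        cap = min(sched.cap(run, p), retained.size)
        # EDF: keep the top-|b| channels up to the cap (ties -> lower index)
        order = np.lexsort((np.arange(retained.size), -absb))
        kept_local = np.sort(order[:cap])
        retained = retained[kept_local]
        absb = absb[kept_local]
        # ARS: draw cap channels with replacement, prob ~ |b|; unique set
        if absb.sum() <= 0:
            probs = np.full(absb.size, 1.0 / absb.size)
        else:
            probs = absb / absb.sum()
        draw = rng.choice(retained.size, size=cap, replace=True, p=probs)
        retained = retained[np.unique(draw)]
        if retained.size == 0:
            raise RuntimeError(f"CARS retained no channels at run {run}")
        a_cv = min(n_components, retained.size)
        cv = rmsecv(
            x[:, retained], y, a_cv, folds=folds, seed=int(rng.integers(2**31 - 1))
        )
        records.append(CarsRunRecord(run, retained.copy(), cv))

    best = int(np.argmin([r.rmsecv for r in records]))  # earliest on ties
    sel = records[best].retained_channels
    return CarsResult(
        records=records,
        best_run=records[best].run_index,
        selected_channels=sel,
        selected_wavelengths=np.asarray(wavelengths, dtype=float)[sel],
        schedule=sched,
    )
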