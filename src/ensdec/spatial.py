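"""Moran's I spatial autocorrelation of selectivity over the electrode grid.

Selectivity categories are numeric-encoded as per-category indicator maps on
the 10x10 array (Moran's I needs numeric values; an electrode's category is
the majority category of its units, ties broken by the most significant
unit).  The statistic is computed with binary neighborhood weights
w_ij = 1 for 0 < d_ij <= max_distance (Euclidean, electrode-pitch units) over
a range of spatial scales, and compared with a central 95% null band from
shuffling electrode labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRID_SIZE = 10


@dataclass
class ArrayFeatureMap:
    """Numeric feature values on the electrode grid with a wired/active mask."""

    values: np.ndarray  # (rows, cols) float
    mask: np.ndarray    # (rows, cols) bool, True = electrode in play

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if max(self.values.shape) > GRID_SIZE:
            raise ValueError(f"grid larger than {GRID_SIZE}x{GRID_SIZE}")

    @property
    def active_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def active_coords(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class MoranResult:
    """Moran's I over spatial scales with a shuffle null band."""

    scales: list
    I_per_scale: list
    null_low_per_scale: list
    null_high_per_scale: list
    significant_per_scale: list
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "scales": [float(s) for s in self.scales],
            "I_per_scale": self.I_per_scale,
            "null_low_per_scale": self.null_low_per_scale,
            "null_high_per_scale": self.null_high_per_scale,
            "significant_per_scale": self.significant_per_scale,
            "n_perm": self.n_perm, "seed": self.seed,
        }


def _weights(coords: np.ndarray, max_distance: float) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    w = ((dist > 0) & (dist <= max_distance)).astype(float)
    return w


def _morans_i_from(values: np.ndarray, w: np.ndarray) -> float:
    n = len(values)
    x = values - values.mean()
    denom = (x ** 2).sum()
    w_sum = w.sum()
    if denom == 0 or w_sum == 0:
        return float("nan")
    num = (w * np.outer(x, x)).sum()
    return float((n / w_sum) * (num / denom))


def morans_i(fmap: ArrayFeatureMap, max_distance: float) -> float:
    """Moran's I of the active electrodes at one neighborhood scale.

    I = (N / sum w_ij) * (sum_ij w_ij (x_i - xbar)(x_j - xbar)) / sum_i (x_i - xbar)^2
    with w_ij = 1 when 0 < d_ij <= ``max_distance``.  NaN when the values have
    zero variance or no pair of electrodes is within the scale.
    """
    vals = fmap.active_values
    if len(vals) < 2:
        raise ValueError("need at least 2 active electrodes")
    w = _weights(fmap.active_coords.astype(float), max_distance)
    return _morans_i_from(vals, w)


def clustering_profile(fmap: ArrayFeatureMap, scales, n_perm: int = 1000,
                       seed: int = 0) -> MoranResult:
    """Moran's I at each scale plus a label-shuffle null band.

    The null band is the central 95% (2.5th-97.5th percentile) of I over
    ``n_perm`` shuffles of the feature values across active electrodes;
    the observed value is flagged significant when it falls outside the band.
    """
    vals = fmap.active_values
    if len(vals) < 2:
        raise ValueError("need at least 2 active electrodes")
    coords = fmap.active_coords.astype(float)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(vals) for _ in range(n_perm)]

    scales = list(scales)
    I_obs, lo_b, hi_b, sig = [], [], [], []
    for s in scales:
        w = _weights(coords, float(s))
        obs = _morans_i_from(vals, w)
        null = np.array([_morans_i_from(p, w) for p in perms])
        if np.isnan(obs) or np.isnan(null).all():
            I_obs.append(float("nan"))
            lo_b.append(float("nan"))
            hi_b.append(float("nan"))
            sig.append(False)
            continue
        lo, hi = np.nanpercentile(null, [2.5, 97.5])
        I_obs.append(float(obs))
        lo_b.append(float(lo))
        hi_b.append(float(hi))
        sig.append(bool(obs < lo or obs > hi))
    return MoranResult(scales, I_obs, lo_b, hi_b, sig, n_perm, seed)


def selectivity_feature_map(units: pd.DataFrame, categories: pd.DataFrame,
                            category: str,
                            grid_shape: tuple = (GRID_SIZE, GRID_SIZE)) -> ArrayFeatureMap:
    """Indicator map for one selectivity category over the array.

    ``units`` is the session's array map (unit_id, electrode_row,
    electrode_col, wired); ``categories`` carries per-unit ``category`` and,
    if available, p-values used to break majority ties (smallest
    p_location/p_direction wins).  Electrodes without units are masked out, as
    are unwired electrodes.
    """
    merged = units.merge(categories, on="unit_id", how="inner")
    values = np.zeros(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    p_cols = [c for c in ("p_location", "p_direction") if c in merged.columns]
    for (r, c), grp in merged.groupby(["electrode_row", "electrode_col"]):
        if "wired" in grp.columns and not grp["wired"].any():
            continue
        counts = grp["category"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) == 1:
            winner = top[0]
        elif p_cols:
            cand = grp[grp["category"].isin(top)].copy()
            cand["best_p"] = cand[p_cols].min(axis=1)
            winner = cand.sort_values("best_p").iloc[0]["category"]
        else:
            winner = sorted(top)[0]
        mask[r, c] = True
        values[r, c] = 1.0 if winner == category else 0.0
    return ArrayFeatureMap(values, mask)
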