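"""Spike-density functions and the consecutive-bin latency statistic.

Population response profiles are built by convolving each unit's spike trains
with a Gaussian kernel (sigma 25 ms by default), averaging over trials, and
normalizing each unit by the maximum of its preferred-condition trace.  The
onset of selectivity is then estimated by comparing preferred vs nonpreferred
normalized responses across units in 20-ms bins with a paired t test: the
latency is the start of the first run of at least five consecutive
significant bins, and the magnitude is the mean t across all bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .io import Session, EpochWindow, DEFAULT_OUTCOMES

logger = logging.getLogger(__name__)

GRID_STEP_S = 0.001  # 1-ms evaluation grid
KERNEL_TRUNCATE_SD = 4.0


@dataclass
class SDFResult:
    """Normalized population spike-density traces for one factor.

    ``unit_pref`` / ``unit_nonpref`` are (n_units, n_time) arrays of
    trial-averaged, unit-normalized, kernel-smoothed rates for the preferred
    and nonpreferred level of the factor.  ``unit_pref_raw`` /
    ``unit_nonpref_raw`` hold the same quantities without kernel smoothing
    (1-ms histogram rates, same normalization constants); the latency
    statistic uses these so that the non-causal kernel cannot leak a
    divergence backwards in time.
    """

    time_s: np.ndarray
    unit_ids: np.ndarray
    unit_pref: np.ndarray
    unit_nonpref: np.ndarray
    norm_constants: np.ndarray
    kernel_width_s: float
    unit_pref_raw: np.ndarray | None = None
    unit_nonpref_raw: np.ndarray | None = None

    @property
    def mean_pref(self) -> np.ndarray:
        return self.unit_pref.mean(axis=0)

    @property
    def mean_nonpref(self) -> np.ndarray:
        return self.unit_nonpref.mean(axis=0)

    def sem(self, which: str = "pref") -> np.ndarray:
        arr = self.unit_pref if which == "pref" else self.unit_nonpref
        return arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])


@dataclass
class LatencyResult:
    """Consecutive-bin latency and mean-t magnitude of a selectivity contrast."""

    latency_s: float | None
    magnitude_t: float
    bin_starts_s: np.ndarray
    t_per_bin: np.ndarray
    p_per_bin: np.ndarray
    run: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "latency_s": None if self.latency_s is None else float(self.latency_s),
            "magnitude_t": float(self.magnitude_t),
            "bin_starts_s": [float(b) for b in self.bin_starts_s],
            "t_per_bin": [float(t) for t in self.t_per_bin],
            "p_per_bin": [float(p) for p in self.p_per_bin],
            "run": self.run, "alpha": self.alpha,
        }


def _aligned_spikes(session: Session, window: EpochWindow,
                    include_outcomes) -> tuple[np.ndarray, dict]:
    """Kept trials and per-trial alignment times for a window."""
    trials = session.trials
    keep = trials["outcome"].isin(set(include_outcomes)).to_numpy()
    event = trials[window.alignment_event + "_s"].to_numpy(dtype=float)
    keep &= np.isfinite(event)
    kept = trials.loc[keep]
    align = dict(zip(kept["trial_id"].to_numpy(), event[keep]))
    return kept, align


def single_unit_sdf(spike_times: np.ndarray, n_trials: int, window: EpochWindow,
                    kernel_width_s: float = 0.025,
                    return_raw: bool = False):
    """Trial-averaged Gaussian-smoothed rate (Hz) on a 1-ms grid.

    ``spike_times`` are already aligned to the window's event.  The kernel is
    truncated at +-4 sigma with no edge correction, so traces within ~4 sigma
    of the window edges are biased low.  With ``return_raw`` the unsmoothed
    histogram rate is returned as well.
    """
    grid = np.arange(window.start_s, window.end_s, GRID_STEP_S)
    hist, _ = np.histogram(spike_times, bins=len(grid),
                           range=(window.start_s, window.start_s + len(grid) * GRID_STEP_S))
    rate = hist / (max(n_trials, 1) * GRID_STEP_S)
    smoothed = gaussian_filter1d(rate, sigma=kernel_width_s / GRID_STEP_S,
                                 mode="constant", truncate=KERNEL_TRUNCATE_SD)
    if return_raw:
        return grid, smoothed, rate
    return grid, smoothed


def spike_density(session: Session, units: np.ndarray, window: EpochWindow,
                  factor: str, preferred: dict,
                  kernel_width_s: float = 0.025,
                  include_outcomes=DEFAULT_OUTCOMES) -> SDFResult:
    """Per-unit normalized SDF traces for preferred vs nonpreferred trials.

    Parameters
    ----------
    units
        Unit ids to include (e.g. the units selective for ``factor``).
    factor
        ``target_location`` or ``motion_direction``.
    preferred
        Mapping unit_id -> preferred level of the factor; trials at the other
        level are the nonpreferred set.

    Each unit's traces are divided by the maximum of its preferred-condition
    trace; units with an all-zero preferred trace are excluded with a warning.
    """
    kept, align = _aligned_spikes(session, window, include_outcomes)
    if not len(kept):
        raise ValueError("no trials left after outcome/alignment filtering")
    levels = kept[factor].unique()

    sp = session.spikes
    sp = sp[sp["unit_id"].isin(set(np.asarray(units).tolist()))]
    sp = sp[sp["trial_id"].isin(set(kept["trial_id"]))]
    trial_level = dict(zip(kept["trial_id"], kept[factor]))
    n_per_level = kept[factor].value_counts().to_dict()

    grid = np.arange(window.start_s, window.end_s, GRID_STEP_S)
    pref_traces, nonpref_traces, norms, kept_units = [], [], [], []
    pref_raw, nonpref_raw = [], []
    grouped = dict(tuple(sp.groupby("unit_id")))
    for u in units:
        g = grouped.get(u)
        pref_level = preferred[u]
        traces, raws = {}, {}
        for level in levels:
            if g is not None and len(g):
                lv = g["trial_id"].map(trial_level)
                t_sel = g.loc[lv == level]
                aligned = t_sel["spike_time_s"].to_numpy() \
                    - t_sel["trial_id"].map(align).to_numpy()
            else:
                aligned = np.array([])
            _, trace, raw = single_unit_sdf(aligned, n_per_level.get(level, 0),
                                            window, kernel_width_s,
                                            return_raw=True)
            traces[level] = trace
            raws[level] = raw
        norm = traces[pref_level].max()
        if norm <= 0:
            logger.warning("spike_density: unit %s has empty preferred trace; excluded", u)
            continue
        nonpref_level = [l for l in levels if l != pref_level][0]
        pref_traces.append(traces[pref_level] / norm)
        nonpref_traces.append(traces[nonpref_level] / norm)
        pref_raw.append(raws[pref_level] / norm)
        nonpref_raw.append(raws[nonpref_level] / norm)
        norms.append(norm)
        kept_units.append(u)

    if not kept_units:
        raise ValueError("no unit with a non-empty preferred-condition trace")
    return SDFResult(grid, np.asarray(kept_units), np.vstack(pref_traces),
                     np.vstack(nonpref_traces), np.asarray(norms),
                     kernel_width_s, np.vstack(pref_raw),
                     np.vstack(nonpref_raw))


def selectivity_latency(sdf: SDFResult, bin_s: float = 0.020,
                        alpha: float = 0.05, run: int = 5,
                        smoothed: bool = False) -> LatencyResult:
    """Latency and magnitude of the preferred/nonpreferred divergence.

    Bins tile the trace starting at its left edge; per bin, the mean
    normalized response per unit is compared preferred vs nonpreferred with a
    paired t test across units.  The latency is the start of the first run of
    ``run`` consecutive bins with p < ``alpha`` (absent if none); the
    magnitude is the mean t over all bins.

    By default the per-bin means come from the unsmoothed normalized
    responses (the 20-ms bins provide the temporal averaging); with
    ``smoothed=True`` the kernel-smoothed traces are used instead, which
    biases the latency early by up to the kernel width.
    """
    if sdf.unit_pref.shape[0] < 2:
        raise ValueError("need at least 2 units for the paired t test")
    use_raw = not smoothed and sdf.unit_pref_raw is not None
    pref_arr = sdf.unit_pref_raw if use_raw else sdf.unit_pref
    nonpref_arr = sdf.unit_nonpref_raw if use_raw else sdf.unit_nonpref
    n_bins = int(np.floor((sdf.time_s[-1] + GRID_STEP_S - sdf.time_s[0]) / bin_s))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    per_bin = int(round(bin_s / GRID_STEP_S))
    starts = sdf.time_s[0] + bin_s * np.arange(n_bins)

    t_vals = np.empty(n_bins)
    p_vals = np.empty(n_bins)
    for b in range(n_bins):
        sl = slice(b * per_bin, (b + 1) * per_bin)
        pref = pref_arr[:, sl].mean(axis=1)
        nonpref = nonpref_arr[:, sl].mean(axis=1)
        diff = pref - nonpref
        if np.allclose(diff, diff[0]):
            # zero-variance differences: no evidence either way
            t_vals[b], p_vals[b] = 0.0, 1.0
        else:
            res = stats.ttest_rel(pref, nonpref)
            t_vals[b], p_vals[b] = res.statistic, res.pvalue

    sig = p_vals < alpha
    latency = None
    count = 0
    for b in range(n_bins):
        count = count + 1 if sig[b] else 0
        if count >= run:
            latency = float(starts[b - run + 1])
            break
    return LatencyResult(latency, float(np.nanmean(t_vals)), starts,
                         t_vals, p_vals, run, alpha)
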