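"""Seeded generator of synthetic sessions with known ground truth.

The generator emulates a two-location x two-direction covert attention task:
on each trial two moving random-dot patterns appear left and right of
fixation, a color cue designates one as the target, and the animal holds
attention on the target through a postcue period.  Units are Poisson spikers
with log-normal baseline rates; a configurable fraction is tuned to the
attended location, the stimulus motion direction, or both, via multiplicative
rate gains.  A per-trial shared log-normal gain induces within-condition
(noise) correlations whose sign structure is set by unit loadings.  Trial
outcomes are drawn independently of the spikes except that on error trials
the simulated attention state may sit on the distractor (``coupling_kappa``),
which is what couples decoding accuracy to behavior.

Timeline per trial (seconds from fixation acquisition): 353-ms fixation, then
stimulus onset; a 294/471/647-ms pre-cue interval; a 706-ms color cue; then a
postcue period.  Condition-dependent gains switch on ``divergence_onset_s``
after the relevant event — stimulus onset for direction tuning, color (cue)
onset for attended-location tuning — and stay on for the rest of the trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .io import (LOCATIONS, DIRECTIONS, OUTCOMES, Session, EpochWindow,
                 extract_counts, POSTCUE_WINDOW)

FIXATION_DUR_S = 0.353
PRECUE_DURS_S = (0.294, 0.471, 0.647)
CUE_DUR_S = 0.706
POSTCUE_RECORDED_S = 0.750  # spikes simulated this long past cue offset

CATEGORIES = ("location", "direction", "both", "none")


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Defaults describe a plausible single session of the task: ~100 units of
    which 36%/17%/8% are location-/direction-/both-tuned, log-normal baseline
    rates with median 5 Hz, moderate tuning gains, weak shared-gain noise
    correlations, and outcome frequencies dominated by hits with false alarms
    as the main error type.
    """

    n_units: int = 100
    n_trials: int = 600
    p_location_tuned: float = 0.36
    p_direction_tuned: float = 0.17
    p_both_tuned: float = 0.08
    baseline_log_mean: float = float(np.log(5.0))
    baseline_log_sd: float = 0.8
    gain_location: float = 1.5
    gain_direction: float = 1.5
    shared_noise_sd: float = 0.2
    loading_mode: str = "random"  # aligned | anti_aligned | random
    divergence_onset_s: float = 0.25
    outcome_probs: tuple = (0.75, 0.05, 0.15, 0.05)  # hit, miss, fa, fix break
    coupling_kappa: float = 0.5
    cluster_strength: float = 0.0
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        p_sum = self.p_location_tuned + self.p_direction_tuned + self.p_both_tuned
        for name, p in (("p_location_tuned", self.p_location_tuned),
                        ("p_direction_tuned", self.p_direction_tuned),
                        ("p_both_tuned", self.p_both_tuned),
                        ("coupling_kappa", self.coupling_kappa),
                        ("cluster_strength", self.cluster_strength)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if p_sum > 1.0 + 1e-12:
            raise ConfigError(f"tuned proportions sum to {p_sum} > 1")
        if self.gain_location < 1.0 or self.gain_direction < 1.0:
            raise ConfigError("gains must be >= 1")
        if self.shared_noise_sd < 0:
            raise ConfigError("shared_noise_sd must be >= 0")
        if self.loading_mode not in ("aligned", "anti_aligned", "random"):
            raise ConfigError(f"unknown loading_mode {self.loading_mode!r}")
        if len(self.outcome_probs) != 4 or abs(sum(self.outcome_probs) - 1.0) > 1e-9 \
                or min(self.outcome_probs) < 0:
            raise ConfigError("outcome_probs must be 4 non-negative values summing to 1")
        if self.n_units < 1 or self.n_trials < 0:
            raise ConfigError("n_units >= 1 and n_trials >= 0 required")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcome_probs"] = list(self.outcome_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "outcome_probs" in d:
            d["outcome_probs"] = tuple(d["outcome_probs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generator-side truth: per-unit tuning and per-trial latent state."""

    units: pd.DataFrame   # unit_id, category, preferred_location,
                          # preferred_direction, baseline_rate_hz, loading
    trials: pd.DataFrame  # trial_id, target_location, motion_direction,
                          # outcome, attention_state, shared_z
    config: GeneratorConfig

    def category_counts(self) -> dict:
        c = self.units["category"].value_counts()
        return {k: int(c.get(k, 0)) for k in CATEGORIES}

    def write(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "units": self.units.to_dict(orient="list"),
            "trials": self.trials.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["units"]), pd.DataFrame(payload["trials"]),
                   GeneratorConfig.from_dict(payload["config"]))


def _assign_categories(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_units
    n_loc = round(cfg.p_location_tuned * n)
    n_dir = round(cfg.p_direction_tuned * n)
    n_both = round(cfg.p_both_tuned * n)
    if n_loc + n_dir + n_both > n:
        raise ConfigError("rounded tuned counts exceed n_units")
    cats = np.array(["location"] * n_loc + ["direction"] * n_dir
                    + ["both"] * n_both + ["none"] * (n - n_loc - n_dir - n_both))
    rng.shuffle(cats)
    return cats


def _assign_electrodes(cats: np.ndarray, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place units on the 10x10 grid, optionally clustering tuning by region.

    With ``cluster_strength`` s, a tuned unit lands with probability s inside a
    category-specific block (location-tuned left half, direction-tuned right
    half, both-tuned the middle band) and uniformly otherwise.  s = 0 gives
    the spatially unstructured regime; s = 1 gives block clustering that
    spatial autocorrelation must detect.
    """
    n = len(cats)
    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    blocks = {
        "location": (slice(0, 10), slice(0, 5)),
        "direction": (slice(0, 10), slice(5, 10)),
        "both": (slice(3, 7), slice(3, 7)),
    }
    for i, cat in enumerate(cats):
        clustered = cat in blocks and rng.random() < cfg.cluster_strength
        if clustered:
            rs, cs = blocks[cat]
            rows[i] = rng.integers(rs.start, rs.stop)
            cols[i] = rng.integers(cs.start, cs.stop)
        else:
            rows[i] = rng.integers(0, 10)
            cols[i] = rng.integers(0, 10)
    return rows, cols


def _loadings(cats: np.ndarray, pref_loc: np.ndarray, cfg: GeneratorConfig,
              rng: np.random.Generator) -> np.ndarray:
    n = len(cats)
    if cfg.loading_mode == "aligned":
        # one common gain axis: cancellable by a contrast readout, so these
        # correlations *help* a linear decoder of mixed-preference ensembles
        return np.ones(n)
    if cfg.loading_mode == "anti_aligned":
        # loading sign tied to the preferred location: shared noise lies along
        # the signal axis and limits the decoder
        sign = np.where(pref_loc == LOCATIONS[0], 1.0, -1.0)
        return sign
    return rng.choice([-1.0, 1.0], size=n)


def generate_session(config: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Simulate one session; returns the Session and its GroundTruth."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- units ------------------------------------------------------------
    cats = _assign_categories(cfg, rng)
    pref_loc = np.array([rng.choice(LOCATIONS) for _ in range(cfg.n_units)])
    pref_dir = np.array([rng.choice(DIRECTIONS) for _ in range(cfg.n_units)])
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             size=cfg.n_units)
    loading = _loadings(cats, pref_loc, cfg, rng)
    erow, ecol = _assign_electrodes(cats, cfg, rng)

    loc_tuned = np.isin(cats, ("location", "both"))
    dir_tuned = np.isin(cats, ("direction", "both"))
    gain_loc_u = np.where(loc_tuned, cfg.gain_location, 1.0)
    gain_dir_u = np.where(dir_tuned, cfg.gain_direction, 1.0)

    # ---- trials -----------------------------------------------------------
    n = cfg.n_trials
    conditions = [(l, d) for l in LOCATIONS for d in DIRECTIONS]
    cond_idx = np.tile(np.arange(4), n // 4 + 1)[:n]
    rng.shuffle(cond_idx)
    t_loc = np.array([conditions[i][0] for i in cond_idx])
    t_dir = np.array([conditions[i][1] for i in cond_idx])

    stim_on = np.full(n, FIXATION_DUR_S)
    precue = rng.choice(PRECUE_DURS_S, size=n)
    color_on = stim_on + precue
    color_off = color_on + CUE_DUR_S
    change = color_off + rng.uniform(0.753, 1.600, size=n)

    outcome = rng.choice(OUTCOMES, size=n, p=np.asarray(cfg.outcome_probs))
    responded = np.isin(outcome, ("hit", "false_alarm"))
    response = np.where(responded, change + rng.uniform(0.100, 0.650, size=n),
                        np.nan)

    other = {LOCATIONS[0]: LOCATIONS[1], LOCATIONS[1]: LOCATIONS[0]}
    attn = t_loc.copy()
    err = outcome != "hit"
    flip = err & (rng.random(n) < cfg.coupling_kappa)
    attn[flip] = np.array([other[l] for l in t_loc[flip]])

    z = rng.standard_normal(n)
    shared = np.exp(cfg.shared_noise_sd * np.outer(z, loading)
                    - 0.5 * (cfg.shared_noise_sd * loading) ** 2)  # (n_trials, n_units)

    # ---- spikes -----------------------------------------------------------
    attended_pref = attn[:, None] == pref_loc[None, :]
    dir_pref = t_dir[:, None] == pref_dir[None, :]
    g_loc = np.where(attended_pref, gain_loc_u[None, :], 1.0)
    g_dir = np.where(dir_pref, gain_dir_u[None, :], 1.0)
    base = baseline[None, :] * shared

    unit_ids_all, trial_ids_all, times_all = [], [], []
    trial_ids = np.arange(n, dtype=np.int64)
    for t in range(n):
        t_end = color_off[t] + POSTCUE_RECORDED_S
        dir_on = stim_on[t] + cfg.divergence_onset_s
        loc_on = color_on[t] + cfg.divergence_onset_s
        edges = np.unique(np.clip([0.0, stim_on[t], dir_on, loc_on, t_end],
                                  0.0, t_end))
        for a, b in zip(edges[:-1], edges[1:]):
            if b <= a:
                continue
            rate = base[t].copy()
            if a >= dir_on - 1e-12:
                rate = rate * g_dir[t]
            if a >= loc_on - 1e-12:
                rate = rate * g_loc[t]
            # direction information needs the stimulus on screen
            if a < stim_on[t] - 1e-12:
                rate = base[t]
            k = rng.poisson(rate * (b - a))
            total = int(k.sum())
            if total == 0:
                continue
            u = np.repeat(np.arange(cfg.n_units), k)
            times = rng.uniform(a, b, size=total)
            unit_ids_all.append(u)
            trial_ids_all.append(np.full(total, t, dtype=np.int64))
            times_all.append(times)

    if unit_ids_all:
        sp_units = np.concatenate(unit_ids_all)
        sp_trials = np.concatenate(trial_ids_all)
        sp_times = np.concatenate(times_all)
        order = np.lexsort((sp_times, sp_trials, sp_units))
        spikes = pd.DataFrame({"unit_id": sp_units[order],
                               "trial_id": sp_trials[order],
                               "spike_time_s": sp_times[order]})
    else:
        spikes = pd.DataFrame({"unit_id": np.array([], dtype=np.int64),
                               "trial_id": np.array([], dtype=np.int64),
                               "spike_time_s": np.array([], dtype=float)})

    trials = pd.DataFrame({
        "trial_id": trial_ids, "target_location": t_loc,
        "motion_direction": t_dir, "outcome": outcome,
        "stimulus_onset_s": stim_on, "color_onset_s": color_on,
        "color_offset_s": color_off, "change_time_s": change,
        "response_time_s": response,
    })
    units = pd.DataFrame({
        "unit_id": np.arange(cfg.n_units, dtype=np.int64),
        "electrode_row": erow, "electrode_col": ecol,
        "wired": np.ones(cfg.n_units, dtype=bool),
    })
    session = Session(f"synthetic-seed{cfg.seed}", trials, spikes, units).validate()

    gt_units = pd.DataFrame({
        "unit_id": units["unit_id"], "category": cats,
        "preferred_location": pref_loc, "preferred_direction": pref_dir,
        "baseline_rate_hz": baseline, "loading": loading,
        "electrode_row": erow, "electrode_col": ecol,
    })
    gt_trials = pd.DataFrame({
        "trial_id": trial_ids, "target_location": t_loc,
        "motion_direction": t_dir, "outcome": outcome,
        "attention_state": attn, "shared_z": z,
    })
    return session, GroundTruth(gt_units, gt_trials, cfg)


def validate_statistics(session: Session, truth: GroundTruth,
                        config: GeneratorConfig | None = None,
                        window: EpochWindow = POSTCUE_WINDOW) -> dict:
    """Compare empirical session statistics to the configured generative model.

    Returns a report dict; violations are flagged, never raised.  On an empty
    session the report is empty apart from ``n_trials``.
    """
    cfg = (config or truth.config).validate()
    report: dict = {"n_trials": session.n_trials, "checks": []}
    if session.n_trials == 0:
        return report

    cm = extract_counts(session, window, include_outcomes={"hit"})
    rates = cm.rates()

    # grand mean rate vs log-normal expectation (tuning inflates it slightly)
    expected = float(np.exp(cfg.baseline_log_mean + cfg.baseline_log_sd ** 2 / 2))
    observed = float(rates.mean())
    report["mean_rate_hz"] = {"observed": observed, "baseline_expected": expected}
    report["checks"].append({
        "name": "grand_mean_rate",
        "ok": bool(0.5 * expected <= observed <=
                   2.5 * expected * max(cfg.gain_location, cfg.gain_direction)),
    })

    # within-condition pairwise noise correlations, split by loading sign
    cond = cm.condition_labels()
    resid = np.empty_like(rates, dtype=float)
    for c in np.unique(cond):
        m = cond == c
        resid[m] = rates[m] - rates[m].mean(axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(resid.T)
    iu = np.triu_indices(cm.n_units, k=1)
    load = truth.units["loading"].to_numpy()
    same_sign = np.sign(load[iu[0]]) == np.sign(load[iu[1]])
    pair_corr = corr[iu]
    finite = np.isfinite(pair_corr)
    mean_same = float(np.nanmean(pair_corr[finite & same_sign])) \
        if (finite & same_sign).any() else float("nan")
    mean_all = float(np.nanmean(pair_corr[finite])) if finite.any() else float("nan")
    report["noise_correlation"] = {"mean_all_pairs": mean_all,
                                   "mean_same_sign_pairs": mean_same}
    if cfg.shared_noise_sd == 0:
        ok = abs(mean_all) < 3.0 / np.sqrt(max(cm.n_trials, 2))
    else:
        ok = mean_same > 0
    report["checks"].append({"name": "noise_correlation_sign", "ok": bool(ok)})

    # condition effect: attended-preferred vs not, for location-tuned units
    loc_tuned = np.isin(truth.units["category"].to_numpy(), ("location", "both"))
    if loc_tuned.any() and cfg.gain_location > 1:
        pref = truth.units["preferred_location"].to_numpy()[loc_tuned]
        sub = rates[:, loc_tuned]
        loc = cm.labels["target_location"].to_numpy()
        on = loc[:, None] == pref[None, :]
        ratio = float(sub[on].mean() / max(sub[~on].mean(), 1e-12))
        report["location_gain"] = {"observed_ratio": ratio,
                                   "configured": cfg.gain_location}
        report["checks"].append({
            "name": "location_gain",
            "ok": bool(1.0 + 0.5 * (cfg.gain_location - 1.0) <= ratio
                       <= 1.0 + 2.0 * (cfg.gain_location - 1.0)),
        })

    report["ok"] = all(c["ok"] for c in report["checks"])
    return report
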