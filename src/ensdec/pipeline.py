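"""One-command orchestration of the full analysis on a session bundle.

Stages run in order — synth (optional) -> selectivity -> dynamics ->
spatial -> ensembles (both labels) -> behavior — each writing its own JSON
file so stages are independently re-runnable, plus an aggregate report.json
with seeds and versions.  All stage seeds derive deterministically from one
master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import (read_session, write_session, extract_counts,
                 POSTCUE_WINDOW, CUE_WINDOW, BASELINE_WINDOW)
from .synth import GeneratorConfig, generate_session
from .selectivity import (task_relatedness, classify_selectivity,
                          proportion_permutation_test)
from .dynamics import spike_density, selectivity_latency
from .spatial import selectivity_feature_map, clustering_profile
from .decoder import DecoderConfig
from .ensembles import curve_with_controls, summarize_curve
from .behavior import outcome_conditioned_decoding

logger = logging.getLogger(__name__)

STAGES = ("selectivity", "dynamics", "spatial", "ensembles", "behavior")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``bundle`` (path to an existing session bundle) or
    ``generator`` must be given.  ``stages`` toggles individual stages;
    ``master_seed`` deterministically derives every stage seed.
    """

    out_dir: str = "ensdec_run"
    bundle: str | None = None
    generator: GeneratorConfig | None = None
    master_seed: int = 0
    alpha: float = 0.05
    n_perm: int = 1000
    moran_scales: tuple = (1.0, 2.0, 3.0, 4.0)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    max_ensemble_size: int | None = 12
    n_decorr: int = 20
    n_chance: int = 5
    n_behavior_shuffles: int = 100
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if d.get("decoder") is not None and not isinstance(d["decoder"], DecoderConfig):
            d["decoder"] = DecoderConfig(**d["decoder"])
        stages = {s: True for s in STAGES}
        stages.update(d.get("stages") or {})
        d["stages"] = stages
        if "moran_scales" in d:
            d["moran_scales"] = tuple(d["moran_scales"])
        return cls(**d)


def _stage_seeds(master_seed: int) -> dict:
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES) + 1)
    seeds = {s: int(state[i] % (2**31 - 1)) for i, s in enumerate(STAGES)}
    seeds["synth"] = int(state[-1] % (2**31 - 1))
    return seeds


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    report: dict = {"schema_version": "1.0", "ensdec_version": __version__,
                    "master_seed": config.master_seed, "stage_seeds": seeds,
                    "stages_run": []}

    # ---- data -------------------------------------------------------------
    if (config.bundle is None) == (config.generator is None):
        raise StageError("config must set exactly one of bundle / generator")
    if config.generator is not None:
        gen_cfg = config.generator
        session, truth = generate_session(gen_cfg)
        bundle_dir = out / "bundle"
        write_session(session, bundle_dir)
        truth.write(bundle_dir / "ground_truth.json")
        report["bundle"] = str(bundle_dir)
    else:
        session = read_session(config.bundle)
        report["bundle"] = str(config.bundle)
    report["session_id"] = session.session_id
    report["n_units"] = session.n_units
    report["n_trials"] = session.n_trials

    def _run(stage, fn):
        if not config.stages.get(stage, True):
            return
        try:
            fn()
            report["stages_run"].append(stage)
        except Exception as exc:
            _write_json(out / "report.json", report)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    postcue = extract_counts(session, POSTCUE_WINDOW)
    cue = extract_counts(session, CUE_WINDOW)
    baseline = extract_counts(session, BASELINE_WINDOW)

    state: dict = {}

    # ---- selectivity ------------------------------------------------------
    def _selectivity():
        screen = task_relatedness(postcue, cue, baseline, config.alpha)
        cls = classify_selectivity(postcue, config.alpha)
        merged = screen.merge(cls, on="unit_id")
        tr_ids = screen.loc[screen["task_related"], "unit_id"].to_numpy()
        summary = None
        if len(tr_ids):
            summary = proportion_permutation_test(
                postcue.restrict_units(tr_ids), config.alpha,
                n_perm=config.n_perm, seed=seeds["selectivity"])
        state["selectivity"] = merged
        state["task_related_ids"] = tr_ids
        payload = {"units": json.loads(merged.to_json(orient="records")),
                   "proportions": summary.to_dict() if summary else None}
        _write_json(out / "selectivity.json", payload)
        report["selectivity"] = {
            "n_task_related": int(screen["task_related"].sum()),
            "proportions": payload["proportions"]}

    _run("selectivity", _selectivity)

    # ---- dynamics ---------------------------------------------------------
    def _dynamics():
        sel = state["selectivity"]
        result = {}
        for factor, cats, event in (
                ("target_location", ("location", "both"), "color_onset"),
                ("motion_direction", ("direction", "both"), "stimulus_onset")):
            rows = sel[sel["category"].isin(cats) & sel["task_related"]]
            if len(rows) < 2:
                result[factor] = None
                continue
            pref_col = ("preferred_location" if factor == "target_location"
                        else "preferred_direction")
            preferred = dict(zip(rows["unit_id"], rows[pref_col]))
            from .io import EpochWindow
            win = EpochWindow(event, -0.1, 0.66)
            sdf = spike_density(session, rows["unit_id"].to_numpy(), win,
                                factor, preferred)
            lat = selectivity_latency(sdf)
            result[factor] = {"n_units": int(sdf.unit_pref.shape[0]),
                              "alignment_event": event, **lat.to_dict()}
        _write_json(out / "dynamics.json", result)
        report["dynamics"] = {
            k: (None if v is None else
                {"latency_s": v["latency_s"], "magnitude_t": v["magnitude_t"]})
            for k, v in result.items()}

    _run("dynamics", _dynamics)

    # ---- spatial ----------------------------------------------------------
    def _spatial():
        sel = state["selectivity"]
        result = {}
        for category in ("location", "direction"):
            fmap = selectivity_feature_map(session.units, sel, category)
            if int(fmap.mask.sum()) < 2 or fmap.active_values.std() == 0:
                result[category] = None
                continue
            prof = clustering_profile(fmap, config.moran_scales,
                                      n_perm=config.n_perm,
                                      seed=seeds["spatial"])
            result[category] = prof.to_dict()
        _write_json(out / "moran.json", result)
        report["spatial"] = result

    _run("spatial", _spatial)

    # ---- ensembles --------------------------------------------------------
    def _ensembles():
        tr_ids = state.get("task_related_ids")
        cm = postcue if tr_ids is None or not len(tr_ids) \
            else postcue.restrict_units(tr_ids)
        cond = cm.condition_labels()
        result = {}
        state["best_be"] = {}
        for label in ("target_location", "motion_direction"):
            cfg = DecoderConfig(**{**config.decoder.__dict__,
                                   "label": label, "seed": seeds["ensembles"]})
            res = curve_with_controls(
                cm.counts, cm.binary_labels(label), cfg, cond,
                n_decorr=config.n_decorr, n_chance=config.n_chance,
                unit_ids=cm.unit_ids, max_size=config.max_ensemble_size)
            curves = {f"{m}_{v}": c.to_dict()
                      for (m, v), c in res["curves"].items()}
            summaries = {f"{m}_{v}": summarize_curve(c).to_dict()
                         for (m, v), c in res["curves"].items()
                         if v in ("raw",)}
            tests = {f"{m}_{t}": vals for (m, t), vals in res["tests"].items()}
            result[label] = {"curves": curves, "summaries": summaries,
                             "tests": tests}
            be_raw = res["curves"][("BE", "raw")]
            best_k = summarize_curve(be_raw).size_at_max
            state["best_be"][label] = [int(u) for u in
                                       be_raw.membership_order[:best_k]]
        _write_json(out / "curves.json", result)
        report["ensembles"] = {
            label: {"summaries": result[label]["summaries"],
                    "best_be_membership": state["best_be"][label]}
            for label in result}

    _run("ensembles", _ensembles)

    # ---- behavior ---------------------------------------------------------
    def _behavior():
        result = {}
        for label in ("target_location", "motion_direction"):
            membership = state.get("best_be", {}).get(label)
            if not membership:
                result[label] = None
                continue
            cfg = DecoderConfig(**{**config.decoder.__dict__, "label": label,
                                   "seed": seeds["behavior"]})
            res = outcome_conditioned_decoding(
                session, membership, label, cfg,
                n_shuffles=config.n_behavior_shuffles, seed=seeds["behavior"])
            result[label] = [r.to_dict() for r in res]
        _write_json(out / "behavior.json", result)
        report["behavior"] = {
            label: (None if rows is None else
                    {r["subset"]: {"accuracy": r["accuracy"], "p": r["p"]}
                     for r in rows})
            for label, rows in result.items()}

    _run("behavior", _behavior)

    _write_json(out / "report.json", report)
    return report
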