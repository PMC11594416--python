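"""End-to-end orchestration: stimuli -> networks -> behavior -> evidence
-> SDT -> paradigm, with YAML-configurable runs, per-stage CSV/JSON
artifacts, and a config hash carried through every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stimuli, behavior, evidence as evidence_mod, sdt
from .network import ConvNetClassifier, train_ensemble, save_ensemble, load_ensemble
from .paradigm import ParadigmConfig, run_paradigm, metad_slopes

__all__ = ["RunConfig", "run_pipeline", "generate_fixtures"]

_STAGES = ("stimuli", "train", "behavior", "evidence", "sdt", "paradigm")


@dataclass
class RunConfig:
    experiment: str = "single_gabor"
    n_instances: int = 3
    base_seed: int = 1000
    data_seed: int = 11
    n_train: int = 10000
    n_val: int = 1000
    n_test_per_condition: int = 1000
    epochs: int = 25
    conv_filters: tuple = (4, 8)
    stages: tuple = _STAGES
    out_dir: str = "runs/pipeline"
    scaled_down: bool = False

    def __post_init__(self):
        if self.scaled_down:
            self.n_instances = min(self.n_instances, 3)
            self.n_train = min(self.n_train, 4000)
            self.epochs = min(self.epochs, 6)
            self.n_test_per_condition = min(self.n_test_per_condition, 500)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {unknown}")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "conv_filters" in data:
            data["conv_filters"] = tuple(data["conv_filters"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return a report dict.

    Stage outputs land in ``config.out_dir`` as CSV/JSON stamped with the
    config hash; a stage failure halts downstream stages but preserves
    whatever was already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config": asdict(config), "config_hash": config.config_hash,
              "stages": {}}
    state: dict = {}
    try:
        for stage in _STAGES:
            if stage not in config.stages:
                continue
            t0 = time.time()
            _run_stage(stage, config, state, out)
            report["stages"][stage] = {"status": "ok",
                                       "seconds": round(time.time() - t0, 2)}
    except Exception as exc:  # pragma: no cover - error path
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_json(out / "report.json", report)
        raise
    _write_json(out / "report.json", report)
    return report


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> None:
    exp = config.experiment
    if stage == "stimuli":
        train = stimuli.make_training_set(exp, config.n_train, seed=config.data_seed)
        val = stimuli.make_training_set(exp, config.n_val, seed=config.data_seed + 1)
        state["train"] = (stimuli.stack_pixels(train), stimuli.labels_of(train))
        state["val"] = (stimuli.stack_pixels(val), stimuli.labels_of(val))
    elif stage == "train":
        (X, y), (Xv, yv) = state["train"], state["val"]
        nets = train_ensemble(X, y, Xv, yv, n_instances=config.n_instances,
                              base_seed=config.base_seed,
                              conv_filters=config.conv_filters,
                              epochs=config.epochs)
        state["ensemble"] = nets
        save_ensemble(nets, out / "ensemble")
    elif stage == "behavior":
        nets = state.get("ensemble") or load_ensemble(out / "ensemble")
        state["ensemble"] = nets
        trials, summaries = behavior.run_energy_experiment(
            nets, exp, n_per_condition=config.n_test_per_condition,
            seed=config.data_seed + 100)
        state["trials"], state["summaries"] = trials, summaries
        trials.to_csv(out / "trials.csv", index=False)
        summaries.to_csv(out / "summaries.csv", index=False)
        stats = {"config_hash": config.config_hash}
        if config.n_instances >= 2:
            stats["anova_confidence"] = behavior.rm_anova(summaries, "mean_confidence")
            stats["anova_accuracy"] = behavior.rm_anova(summaries, "accuracy")
            stats["ttest_confidence_low_high"] = behavior.paired_ttest(
                summaries, ("low", "high"), dv="mean_confidence")
        _write_json(out / "behavior_stats.json", stats)
    elif stage == "evidence":
        st = evidence_mod.evidence_stats(state["trials"])
        state["evidence"] = st
        st.to_csv(out / "evidence.csv", index=False)
    elif stage == "sdt":
        rows = []
        for (inst, cond), g in state["trials"].groupby(["instance_id", "condition"]):
            ratings, _ = sdt.bin_confidence(g["confidence"].to_numpy(), 4)
            counts = sdt.counts_from_trials(g["true_label"].to_numpy(),
                                            g["response"].to_numpy(), ratings, 4)
            m = sdt.fit_meta_d(counts, response_specific=True)
            rows.append({"instance_id": inst, "condition": cond,
                         "d_prime": m.d_prime, "criterion_c": m.criterion_c,
                         "meta_d": m.meta_d, "meta_d_s1": m.meta_d_s1,
                         "meta_d_s2": m.meta_d_s2})
        pd.DataFrame(rows).to_csv(out / "sdt_measures.csv", index=False)
    elif stage == "paradigm":
        if exp not in ("single_gabor", "gabor_array", "superimposed"):
            return
        pc = ParadigmConfig(experiment=exp,
                            n_per_level=config.n_test_per_condition,
                            seed=config.data_seed + 200)
        res = run_paradigm(state["ensemble"], pc)
        res.to_csv(out / "paradigm.csv", index=False)
        metad_slopes(res).to_csv(out / "paradigm_slopes.csv", index=False)


def generate_fixtures(seed: int = 0, outdir=None, n: int = 64) -> dict:
    """Miniature deterministic datasets (one per stimulus family) plus a
    quickly trained toy network on easy single-Gabor stimuli, for fast
    tests and demos."""
    rng_seed = int(seed)
    sets = {exp: stimuli.make_training_set(exp, n=n, seed=rng_seed + i)
            for i, exp in enumerate(stimuli.EXPERIMENTS)}
    # easy, high-contrast, low-noise discrimination for the toy net
    easy = [stimuli.make_single_gabor(1.0, 0.05, int(i % 2), seed=rng_seed + 7 * i + 1)
            for i in range(128)]
    X, y = stimuli.stack_pixels(easy), stimuli.labels_of(easy)
    toy = ConvNetClassifier(conv_filters=(2, 4), dense_units=8, epochs=4,
                            random_state=rng_seed)
    toy.fit(X[:96], y[:96], validation_data=(X[96:], y[96:]))
    out = {"sets": sets, "toy_net": toy,
           "toy_accuracy": float(toy.score(X[96:], y[96:]))}
    if outdir is not None:
        outdir = Path(outdir)
        for exp, samples in sets.items():
            stimuli.save_set(samples, outdir / exp)
        toy.save(outdir / "toy_net")
    return out
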