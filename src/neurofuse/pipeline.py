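"""End-to-end orchestration: simulate/load → preprocess → extract → select → report.

Configuration is a sectioned plain-text YAML file (diffable); one master
seed deterministically derives every stage seed through a SeedSequence
tree, so a rerun with the same config produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import compare_methods, run_experiment
from .features import extract_features, fuse_features
from .preprocessing import preprocess_eeg, preprocess_fnirs
from .simulate import GroundTruth, generate_trialset, load_bundle, save_bundle

__all__ = ["PipelineConfig", "read_config", "write_config", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, grouped by stage.

    Defaults mirror the study protocol: 30 trials per class, 10 s trials,
    30 EEG + 36 fNIRS channels, 10 whales, 50 iterations, 80/20 split,
    10 runs.
    """

    simulate: dict = field(
        default_factory=lambda: {
            "n_trials_per_class": 30,
            "n_eeg_channels": 30,
            "n_fnirs_channels": 36,
            "trial_duration": 10.0,
            "fs_eeg": 200.0,
            "fs_fnirs": 10.0,
            "eeg_effect": 0.5,
            "fnirs_effect": 0.8,
            "informative_eeg_channels": [8, 23],
            "informative_fnirs_channels": [2, 19],
        }
    )
    optimizer: dict = field(
        default_factory=lambda: {
            "n_whales": 10,
            "max_iter": 50,
            "pool_size": 20,
            "migration_rate": 0.2,
            "neighborhood_radius": 0.1,
            "transfer": "sigmoid",
            "threshold": 0.5,
        }
    )
    wrapper: dict = field(
        default_factory=lambda: {"alpha": 0.99, "cv_folds": 5, "svm_c": 1.0}
    )
    protocol: dict = field(
        default_factory=lambda: {
            "train_fraction": 0.8,
            "n_runs": 10,
            "resplit": True,
            "leaky_normalization": False,
            "methods": ["none", "ewoa"],
        }
    )
    seed: int = 7
    bundle: str | None = None  # load an existing bundle instead of simulating

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise KeyError(
                f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        cfg = cls()
        for section in ("simulate", "optimizer", "wrapper", "protocol"):
            if section in d:
                defaults = getattr(cfg, section)
                bad = set(d[section]) - set(defaults)
                if bad:
                    raise KeyError(
                        f"unknown key(s) {sorted(bad)} in section '{section}'; "
                        f"valid: {sorted(defaults)}"
                    )
                defaults.update(d[section])
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "bundle" in d:
            cfg.bundle = d["bundle"]
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def ground_truth(self, seed: int) -> GroundTruth:
        s = self.simulate
        return GroundTruth(
            informative_eeg_channels=tuple(s["informative_eeg_channels"]),
            informative_fnirs_channels=tuple(s["informative_fnirs_channels"]),
            eeg_effect=float(s["eeg_effect"]),
            fnirs_effect=float(s["fnirs_effect"]),
            seed=seed,
        )


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _stage_seeds(master: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(master).spawn(n)
    ]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full workflow and persist every stage's output.

    Writes under ``out_dir``: the trial bundle, the fused feature matrix
    (TSV), one per-run report per method, a comparison table, the resolved
    config, and a log with seeds, config hash and per-stage timing.
    Returns a dict with the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[name] = time.perf_counter() - self_inner.t0

        return _Timer()

    sim_seed, protocol_seed = _stage_seeds(config.seed, 2)
    log_lines.append(f"config_hash\t{config.content_hash()}")
    log_lines.append(f"master_seed\t{config.seed}")
    log_lines.append(f"sim_seed\t{sim_seed}")
    log_lines.append(f"protocol_seed\t{protocol_seed}")

    with stage("simulate_or_load"):
        if config.bundle:
            trialset, gt = load_bundle(config.bundle)
        else:
            s = config.simulate
            trialset, gt = generate_trialset(
                n_trials_per_class=int(s["n_trials_per_class"]),
                ground_truth=config.ground_truth(sim_seed),
                n_eeg_channels=int(s["n_eeg_channels"]),
                n_fnirs_channels=int(s["n_fnirs_channels"]),
                trial_duration=float(s["trial_duration"]),
                fs_eeg=float(s["fs_eeg"]),
                fs_fnirs=float(s["fs_fnirs"]),
                seed=sim_seed,
            )
        save_bundle(out / "bundle", trialset, gt)

    with stage("preprocess"):
        pre = preprocess_fnirs(preprocess_eeg(trialset))

    with stage("extract"):
        fnirs_fm, eeg_fm = extract_features(pre)
        fused = fuse_features(fnirs_fm, eeg_fm)
        fused.to_tsv(out / "features.tsv")

    methods = list(config.protocol["methods"])
    if int(config.optimizer["max_iter"]) == 0:
        logger.info("max_iter=0: baseline-only report")
        methods = ["none"]

    summaries = {}
    with stage("select_evaluate"):
        for method in methods:
            summary = run_experiment(
                pre,
                method,
                n_runs=int(config.protocol["n_runs"]),
                seed=protocol_seed,
                train_fraction=float(config.protocol["train_fraction"]),
                optimizer=config.optimizer,
                wrapper=config.wrapper,
                preprocess=False,
                resplit=bool(config.protocol["resplit"]),
                leaky_normalization=bool(config.protocol["leaky_normalization"]),
            )
            summaries[method] = summary
            summary.to_frame().to_csv(out / f"report_{method}.tsv", sep="\t", index=False)

    with stage("report"):
        if len(summaries) >= 2:
            rows = []
            names = list(summaries)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    t, p = compare_methods(summaries[names[i]], summaries[names[j]])
                    rows.append(f"{names[i]}\t{names[j]}\t{t:.6g}\t{p:.6g}")
            (out / "comparison.tsv").write_text(
                "method_a\tmethod_b\tt\tp\n" + "\n".join(rows) + "\n"
            )
        write_config(config, out / "config.yaml")

    for name, dt in timings.items():
        log_lines.append(f"timing_{name}_s\t{dt:.3f}")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")

    return {"trialset": trialset, "ground_truth": gt, "fused": fused, "summaries": summaries}
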