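"""End-to-end experiment orchestration.

``run_experiment`` reproduces the full protocol on synthetic motion data:
generate the corpus, build sliding windows, split 70/15/15, fit the
min-max scaler on the training split, tokenize, optionally rebalance the
training split with conditional-GAN rows, train the transformer
classifier, and evaluate on the held-out real test windows. Every run
directory carries a manifest (config hash, per-stage seeds, row counts,
test-split hash) so a balanced-vs-unbalanced comparison
(``compare_arms``) can verify both arms scored the same test set.
Synthetic GAN rows enter the training split only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from skelseq.classifier import (
    ModelConfig,
    TrainConfig,
    TransformerSequenceClassifier,
    split_dataset,
)
from skelseq.evaluation import confusion, per_class_metrics, compare_runs, plot_confusion
from skelseq.gan import ConditionalTabularGAN, GANConfig, build_plan, diagnostics
from skelseq.synthdata import MotionConfig, generate_sequence, imbalance_profile
from skelseq.tokenization import MinMaxTokenizer
from skelseq.windowing import WindowSpec, build_windows, windows_to_frame


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment arm needs; one global seed fans out to
    fixed per-stage seeds so stages can be rerun in isolation."""

    workdir: str = "runs"
    # synthetic corpus
    budget_windows: int = 3000
    imbalance_style: str = "upfall_like"
    seconds_per_sequence: float = 4.0
    noise_sd: float = 3.0
    fps: float = 18.0
    # windowing
    window: WindowSpec = WindowSpec()
    # tokenization
    vocab_numeric: int = 30_000
    fit_scope: str = "train"
    # model + training
    model: ModelConfig = field(default_factory=ModelConfig.tiny)
    train: TrainConfig = TrainConfig()
    # augmentation
    gan: GANConfig = GANConfig()
    # a 5% per-class target reproduces the published augmentation intensity
    # (about 40% dataset growth; minority shares 2.8-6.4% after balancing)
    plan_strategy: str = "target_share"
    target_share: float = 0.05
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df.reset_index(drop=True), index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def build_corpus_windows(config: RunConfig) -> pd.DataFrame:
    """Generate the synthetic corpus and window it to the requested budget.

    Per-class window targets come from the imbalance profile; each class
    generates just enough fixed-length sequences and the surplus windows
    are trimmed, so per-class counts match the profile exactly.
    """
    targets = imbalance_profile(config.imbalance_style, config.budget_windows)
    n_frames = int(round(config.seconds_per_sequence * config.fps))
    wps = (n_frames - config.window.window_frames) // config.window.stride_frames + 1
    if wps < 1:
        raise ValueError("sequences too short for the window size")
    motion = MotionConfig(
        class_counts={c: math.ceil(n / wps) for c, n in targets.items()},
        fps=config.fps,
        seconds=config.seconds_per_sequence,
        noise_sd=config.noise_sd,
        seed=config.stage_seed("synth"),
    )
    rng = np.random.default_rng(motion.seed)
    frames = []
    for class_id in sorted(targets):
        collected = 0
        for rep in range(motion.class_counts[class_id]):
            sid = f"synth-c{class_id:02d}-{rep:04d}"
            seq = generate_sequence(class_id, motion, rng, source_id=sid)
            wins = build_windows(seq, config.window)
            need = targets[class_id] - collected
            wins = wins[:need]
            collected += len(wins)
            frames.append(windows_to_frame(wins))
            if collected >= targets[class_id]:
                break
    return pd.concat(frames, ignore_index=True)


def run_experiment(config: RunConfig, augment: bool = False) -> Path:
    """Execute one experiment arm; returns the run directory.

    The corpus, split, scaler, and test set depend only on ``config`` and
    its seed — not on ``augment`` — so a plain arm and an augmented arm of
    the same config share a bit-identical test set.
    """
    run_dir = Path(config.workdir) / f"{'gan' if augment else 'plain'}-{config.config_hash()}-s{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "augment": augment,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in ("synth", "split", "gan", "train")},
        "stages": [],
    }

    def _stage(name: str, **counts):
        manifest["stages"].append({"stage": name, **counts})
        _write_manifest(run_dir, manifest)

    try:
        windows = build_corpus_windows(config)
        windows.to_csv(run_dir / "windows.csv", index=False)
        _stage("windows", rows=len(windows))

        tcfg = dataclasses.replace(config.train, seed=config.stage_seed("split"))
        train_df, val_df, test_df = split_dataset(windows, tcfg)
        manifest["test_split_hash"] = _hash_frame(test_df)
        _stage("split", train=len(train_df), val=len(val_df), test=len(test_df))

        feat_cols = [c for c in windows.columns if c.startswith("f") and c[1:].isdigit()]
        fit_rows = windows if config.fit_scope == "all" else train_df
        tokenizer = MinMaxTokenizer(
            vocab_numeric=config.vocab_numeric, fit_scope=config.fit_scope
        ).fit(fit_rows[feat_cols])
        tokenizer.params_.to_json(run_dir / "scaler.json")
        _stage("scaler", f_min=tokenizer.f_min_, f_max=tokenizer.f_max_)

        train_feats = train_df[feat_cols].to_numpy()
        train_labels = train_df["label"].to_numpy()
        provenance = np.array(["real"] * len(train_df), dtype=object)

        if augment:
            gan_cfg = dataclasses.replace(config.gan, seed=config.stage_seed("gan"))
            gan = ConditionalTabularGAN(gan_cfg).fit(train_feats, train_labels)
            class_counts = dict(zip(*np.unique(train_labels, return_counts=True)))
            plan = build_plan(
                {int(c): int(n) for c, n in class_counts.items()},
                strategy=config.plan_strategy,
                target_share=config.target_share,
            )
            fake_parts, fake_labels = [], []
            for class_id, n_fake in sorted(plan.counts.items()):
                if n_fake == 0:
                    continue
                fake_parts.append(gan.sample(class_id, n_fake))
                fake_labels.extend([class_id] * n_fake)
            if fake_parts:
                fake_feats = np.vstack(fake_parts)
                fake_df = pd.DataFrame(fake_feats, columns=feat_cols)
                fake_df.insert(0, "label", fake_labels)
                fake_df.to_csv(run_dir / "fake.csv", index=False)
                diag = diagnostics(
                    pd.DataFrame(train_feats, columns=feat_cols),
                    fake_df[feat_cols],
                    plot_path=str(run_dir / "gan_diagnostics.png"),
                )
                diag.to_csv(run_dir / "gan_diagnostics.csv", index=False)
                train_feats = np.vstack([train_feats, fake_feats])
                train_labels = np.concatenate([train_labels, fake_labels])
                provenance = np.concatenate([provenance, ["gan"] * len(fake_labels)])
            _stage("augment", fake=plan.total, train_total=len(train_labels))

        X_train = tokenizer.transform(train_feats)
        X_val = tokenizer.transform(val_df[feat_cols])
        X_test = tokenizer.transform(test_df[feat_cols])
        vocab_size = tokenizer.params_.vocab_size
        model_cfg = dataclasses.replace(config.model, vocab_size=vocab_size)
        clf = TransformerSequenceClassifier(
            model_config=model_cfg,
            train_config=dataclasses.replace(config.train, seed=config.stage_seed("train")),
        )
        clf.fit(X_train, train_labels, X_val=X_val, y_val=val_df["label"].to_numpy())
        clf.history_.to_csv(run_dir / "history.csv", index=False)
        clf.save(run_dir / "model")
        _stage("train", epochs=len(clf.history_), train_rows=len(train_labels))

        y_test = test_df["label"].to_numpy()
        y_pred = clf.predict(X_test)
        cm = confusion(y_test, y_pred, n_classes=model_cfg.n_classes)
        report = per_class_metrics(cm)
        report.to_csv(run_dir / "metrics.csv")
        pd.DataFrame(cm).to_csv(run_dir / "confusion.csv", index=False)
        plot_confusion(cm, run_dir / "confusion.png")
        manifest["macro"] = {
            m: float(report.macro[m]) for m in ("accuracy", "precision", "recall", "specificity", "f1")
        }
        manifest["provenance_counts"] = {
            k: int(v) for k, v in zip(*np.unique(provenance, return_counts=True))
        }
        _stage("evaluate", test_rows=int(len(y_test)))
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1]["stage"] if manifest["stages"] else "init"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(run_dir, manifest)
        raise
    manifest["complete"] = True
    _write_manifest(run_dir, manifest)
    return run_dir


def _write_manifest(run_dir: Path, manifest: dict) -> None:
    (run_dir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")


def load_metrics(run_dir: str | Path):
    """Rehydrate a run's MetricsReport from its artifacts."""
    run_dir = Path(run_dir)
    table = pd.read_csv(run_dir / "metrics.csv", index_col=0)
    cm = pd.read_csv(run_dir / "confusion.csv").to_numpy()
    from skelseq.evaluation import MetricsReport

    return MetricsReport(table=table, cm=cm)


def compare_arms(run_a: str | Path, run_b: str | Path) -> dict:
    """Compare two completed arms evaluated on the same test split.

    Returns a dict with the side-by-side macro table, per-class recall
    deltas (b - a), and the configuration fields that differ. Raises if
    the test-split hashes disagree (the comparison would be meaningless).
    """
    run_a, run_b = Path(run_a), Path(run_b)
    man_a = json.loads((run_a / "manifest.json").read_text())
    man_b = json.loads((run_b / "manifest.json").read_text())
    for man, d in ((man_a, run_a), (man_b, run_b)):
        if not man.get("complete"):
            raise ValueError(f"run {d} is incomplete")
    if man_a["test_split_hash"] != man_b["test_split_hash"]:
        raise ValueError("test split hashes differ; arms are not comparable")

    rep_a, rep_b = load_metrics(run_a), load_metrics(run_b)
    delta = compare_runs(rep_a, rep_b)
    macro_table = pd.DataFrame(
        {"run_a": rep_a.macro.drop("support"), "run_b": rep_b.macro.drop("support")}
    )
    macro_table["delta"] = macro_table["run_b"] - macro_table["run_a"]
    config_delta = []
    if man_a["augment"] != man_b["augment"]:
        config_delta.append("augment")
    if man_a["config_hash"] != man_b["config_hash"]:
        config_delta.append("config_hash")
    return {
        "macro": macro_table,
        "recall_deltas": delta.loc[[i for i in delta.index if i.startswith("recall_")]],
        "config_delta": config_delta,
        "test_split_hash": man_a["test_split_hash"],
    }


def run_bert_vs_gan(config: RunConfig) -> dict:
    """Run both arms of the balanced-vs-unbalanced protocol and compare."""
    plain = run_experiment(config, augment=False)
    augmented = run_experiment(config, augment=True)
    comparison = compare_arms(plain, augmented)
    out = Path(config.workdir) / f"compare-{config.config_hash()}-s{config.seed}.csv"
    comparison["macro"].to_csv(out)
    comparison["run_dirs"] = (str(plain), str(augmented))
    return comparison
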