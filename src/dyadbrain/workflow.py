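"""End-to-end experiment drivers: configuration, the full synthetic pipeline,
and the two reproduction sweeps (positive-context length and epoch length).

The full-scale recording regime (61 channels at 500 Hz) is what the
architecture defaults target, but the learning experiments here run at a
reduced desk scale — 8 channels at 100 Hz with a smaller embedder — so a
complete pretext + downstream + baseline study executes on one CPU core in
minutes.  The statistical structure (slow spectral drift, alpha asymmetry,
inter-member coupling) is the same at both scales.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .biomarkers import dyad_features, fit_baseline, participant_features
from .embedder import EmbedderConfig
from .multibrain import ClassifierConfig, build_multibrain, evaluate, train_downstream
from .preprocess import epoch, reject_epochs
from .pretext import (
    OptimizerConfig,
    SamplerConfig,
    evaluate_triplets,
    sample_triplets,
    train_pretext,
)
from .synthdata import SynthConfig, make_dyad_recordings, make_pretext_recordings
from .types import DyadEpochPair, EEGRecording, EpochArray

__all__ = [
    "RunConfig",
    "desk_scale_synth",
    "desk_scale_embedder",
    "dyad_pairs_from_recordings",
    "inject_spikes",
    "random_search",
    "run_pipeline",
    "sweep_context",
    "sweep_epoch_length",
]


def desk_scale_synth(seed: int = 0, duration: float = 120.0) -> SynthConfig:
    """The reduced-scale synthetic regime used by the learning experiments."""
    return SynthConfig(n_channels=8, sfreq=100.0, duration=duration, seed=seed)


def desk_scale_embedder(d: int = 50) -> EmbedderConfig:
    """An embedder sized for the desk-scale regime (8 ch, 101 samples)."""
    return EmbedderConfig(
        n_channels=8,
        n_times=101,
        n_temporal_filters=16,
        k_time=25,
        pool_len=25,
        pool_stride=5,
        D=d,
        dropout=0.4,
    )


@dataclass
class RunConfig:
    """One full synthetic study: every stage's config plus global seed/outdir."""

    seed: int = 0
    outdir: str = "run_out"
    n_pretext_recordings: int = 12
    n_dyads_per_class: int = 8
    alpha_power_ratio: float = 2.0
    coupling_control: float = 0.3
    coupling_mixed: float = 0.1
    synth: SynthConfig = field(default_factory=desk_scale_synth)
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(n_triplets=80))
    embedder: EmbedderConfig = field(default_factory=desk_scale_embedder)
    pretext_opt: OptimizerConfig = field(default_factory=OptimizerConfig)
    classifier: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(
            batch_size=16, n_iterations=150, split="dyad"
        )
    )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("synth", SynthConfig),
            ("sampler", SamplerConfig),
            ("embedder", EmbedderConfig),
            ("pretext_opt", OptimizerConfig),
            ("classifier", ClassifierConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


def dyad_pairs_from_recordings(
    dyads: list[tuple[EEGRecording, EEGRecording, int]],
    epoch_len: float = 1.0,
) -> list[DyadEpochPair]:
    """Epoch both members of each dyad and pair epochs by time index."""
    out: list[DyadEpochPair] = []
    for k, (r1, r2, label) in enumerate(dyads):
        e1, e2 = epoch(r1, epoch_len), epoch(r2, epoch_len)
        n = min(e1.n_epochs, e2.n_epochs)
        for i in range(n):
            out.append(DyadEpochPair(e1.data[i], e2.data[i], dyad_id=f"dyad{k:03d}", label=label))
    return out


def inject_spikes(
    rec: EEGRecording,
    n_events: int,
    amplitude: float,
    seed: int = 0,
    width: int = 5,
) -> EEGRecording:
    """Add brief high-amplitude transients at random positions (all channels).

    Used to emulate movement/electrode artifacts for the epoch-length sweep
    and the rejection tests.
    """
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n = rec.n_samples
    starts = rng.choice(max(1, n - width), size=n_events, replace=False)
    for s in starts:
        data[:, s : s + width] += amplitude
    return rec.copy(data=data)


def _epoch_sets_for_pretext(cfg: RunConfig) -> list[EpochArray]:
    recs = make_pretext_recordings(cfg.n_pretext_recordings, cfg.synth, seed=cfg.seed)
    return [epoch(r) for r in recs]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic study and write artifacts under ``cfg.outdir``.

    Stages: pretext pretraining on drifting single-brain data; downstream
    fine-tuning of the SSL model and the supervised-from-scratch baseline on
    labeled dyads; the spectral-biomarker logistic baseline.  Writes the
    pretext checkpoint, a metrics JSON, the dyad feature CSV, and a manifest
    (package version, seed, config hash).  Returns the metrics dict.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    try:
        epoch_sets = _epoch_sets_for_pretext(cfg)
        model, head, hist = train_pretext(epoch_sets, cfg.embedder, cfg.sampler, cfg.pretext_opt)
    except Exception as exc:
        raise RuntimeError(f"pretext stage failed: {exc}") from exc
    model.save(os.path.join(cfg.outdir, "pretext_embedder.npz"))

    try:
        dyads = make_dyad_recordings(
            cfg.n_dyads_per_class,
            cfg.synth,
            seed=cfg.seed + 1,
            alpha_power_ratio=cfg.alpha_power_ratio,
            coupling_control=cfg.coupling_control,
            coupling_mixed=cfg.coupling_mixed,
        )
        pairs = dyad_pairs_from_recordings(dyads)
        ssl_model = build_multibrain(model, cfg.classifier)
        ssl_model, ssl_hist = train_downstream(pairs, ssl_model, cfg.classifier)
        test_pairs = [pairs[i] for i in ssl_hist["test_idx"]]
        eval_pairs = test_pairs if len({p.label for p in test_pairs}) == 2 else pairs
        ssl_report = evaluate(ssl_model, eval_pairs, cfg.classifier)

        sup_model = build_multibrain(None, cfg.classifier, embedder_cfg=cfg.embedder)
        sup_model, sup_hist = train_downstream(pairs, sup_model, cfg.classifier)
        sup_report = evaluate(sup_model, eval_pairs, cfg.classifier)
    except Exception as exc:
        raise RuntimeError(f"downstream stage failed: {exc}") from exc

    try:
        feats = []
        for r1, r2, label in dyads:
            f1 = participant_features(epoch(r1))
            f2 = participant_features(epoch(r2))
            feats.append(dyad_features(f1, f2, label))
        _, base_report, base_info = fit_baseline(feats, seed=cfg.seed)
        _write_features_csv(os.path.join(cfg.outdir, "dyad_features.csv"), feats, dyads)
    except Exception as exc:
        raise RuntimeError(f"biomarker stage failed: {exc}") from exc

    metrics = {
        "pretext": {
            "val_acc": hist.get("final_val_acc"),
            "test_acc": hist.get("test_acc"),
            "n_triplets": hist.get("n_triplets"),
            "class_balance": list(hist.get("class_balance", ())),
        },
        "ssl_downstream": ssl_report.to_dict(),
        "supervised_downstream": sup_report.to_dict(),
        "biomarker_baseline": {**base_report.to_dict(), "cv_accuracy": base_info["cv_accuracy"]},
    }
    with open(os.path.join(cfg.outdir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2)
    cfg_yaml = cfg.to_yaml()
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "metrics_sha256": hashlib.sha256(
            json.dumps(metrics, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(os.path.join(cfg.outdir, "config.yaml"), "w") as fh:
        fh.write(cfg_yaml)
    return metrics


def _write_features_csv(path: str, feats, dyads) -> None:
    import pandas as pd

    f1 = participant_features(epoch(dyads[0][0]))
    cols = [f"p1_{n}" for n in f1.names] + [f"p2_{n}" for n in f1.names]
    df = pd.DataFrame([f.values for f in feats], columns=cols)
    df.insert(0, "label", [f.label for f in feats])
    df.to_csv(path, index=False)


def sweep_context(
    cfg: RunConfig,
    tau_pos_values: tuple[int, ...] = (1, 4, 10),
) -> list[dict]:
    """Train the pretext model once per positive-context length.

    Shares the synthetic data and the seed across runs.  Besides each run's
    own validation accuracy, every trained model is scored on one *shared
    reference* triplet set sampled at the largest requested context — task
    difficulty varies with the context length, so only the reference column
    is comparable across rows.  Returns one row per value (sorted) with both
    accuracies and the ordered/shuffled count ratio.
    """
    epoch_sets = _epoch_sets_for_pretext(cfg)
    tau_ref = max(tau_pos_values)
    ref_triplets = []
    for rid, ep_set in enumerate(epoch_sets):
        ref_sampler = dataclasses.replace(
            cfg.sampler, tau_pos=tau_ref, seed=cfg.seed + 777 + 13 * rid
        )
        ref_triplets.extend(sample_triplets(ep_set, ref_sampler, rec_id=rid))
    rows = []
    for tau in sorted(tau_pos_values):
        sampler = dataclasses.replace(cfg.sampler, tau_pos=tau)
        try:
            model, head, hist = train_pretext(
                epoch_sets, cfg.embedder, sampler, cfg.pretext_opt
            )
        except Exception as exc:
            raise RuntimeError(
                f"pretext run for tau_pos={tau} failed (partial results discarded): {exc}"
            ) from exc
        _, ref_acc = evaluate_triplets(model, head, epoch_sets, ref_triplets)
        n_pos, n_neg = hist["class_balance"]
        rows.append(
            {
                "tau_pos": tau,
                "val_acc": hist["final_val_acc"],
                "test_acc": hist.get("test_acc"),
                "reference_acc": ref_acc,
                "pos_neg_ratio": n_pos / max(1, n_neg),
            }
        )
    return rows


def random_search(
    pairs: list[DyadEpochPair],
    pretrained,
    space: dict[str, tuple],
    n_trials: int = 10,
    base_cfg: ClassifierConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Seeded random search over downstream hyperparameters.

    ``space`` maps ClassifierConfig field names to (low, high) ranges
    (sampled log-uniformly for ``lr``, uniformly otherwise) or to explicit
    choice tuples of length != 2.  Each trial trains the dyadic classifier
    and records its best validation accuracy; rows come back sorted best
    first.  A deliberately lightweight stand-in for full Bayesian
    hyperparameter optimization.
    """
    import dataclasses as _dc

    base_cfg = base_cfg or ClassifierConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        draw = {}
        for name, spec_range in space.items():
            if len(spec_range) == 2 and all(
                isinstance(v, (int, float)) and not isinstance(v, bool)
                for v in spec_range
            ):
                lo, hi = spec_range
                if name == "lr":
                    draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                elif isinstance(lo, int) and isinstance(hi, int):
                    draw[name] = int(rng.integers(lo, hi + 1))
                else:
                    draw[name] = float(rng.uniform(lo, hi))
            else:
                draw[name] = spec_range[rng.integers(0, len(spec_range))]
        cfg = _dc.replace(base_cfg, seed=base_cfg.seed + trial, **draw)
        model = build_multibrain(pretrained, cfg)
        _, hist = train_downstream(pairs, model, cfg)
        val_acc = max(hist["val_acc"]) if hist["val_acc"] else float("nan")
        rows.append({"trial": trial, "val_acc": val_acc, **draw})
    return sorted(rows, key=lambda r: -(r["val_acc"] if r["val_acc"] == r["val_acc"] else -1))


def sweep_epoch_length(
    rec: EEGRecording,
    lengths: tuple[float, ...] = (1.0, 2.0, 3.0, 10.0),
    threshold: float | str = "auto",
) -> list[dict]:
    """Epoch the same recording at several lengths and count rejections.

    With point artifacts injected into the recording, the rejected *fraction*
    is non-decreasing in epoch length (longer windows are more likely to
    contain at least one artifact).  A numeric threshold applies the same
    peak-to-peak policy at every length.
    """
    rows = []
    for length in lengths:
        ep = epoch(rec, epoch_len=length)
        if isinstance(threshold, str):
            kept = reject_epochs(ep, threshold)
        else:
            try:
                kept = reject_epochs(ep, threshold)
            except Exception:
                kept = EpochArray(
                    data=np.empty((0, ep.n_channels, ep.n_times)),
                    sfreq=ep.sfreq,
                    epoch_len=length,
                    kept_indices=np.empty(0, dtype=int),
                )
        rows.append(
            {
                "epoch_len": length,
                "n_epochs": ep.n_epochs,
                "n_kept": kept.n_epochs,
                "n_rejected": ep.n_epochs - kept.n_epochs,
                "rejected_fraction": (ep.n_epochs - kept.n_epochs) / ep.n_epochs,
                "covered_seconds": ep.n_epochs * length,
            }
        )
    return rows
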