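"""Dyadic ("multi-brain") classification of hyperscanning EEG.

Two embedders — usually copies of one pretrained shallow-ConvNet — map the
two simultaneous epochs of a dyad to D-dimensional vectors; a fully connected
head on the fused embeddings outputs P(mixed dyad), i.e. the probability that
the interaction involves at least one autistic participant (label 1).
Training minimizes binary logistic loss with Adam.  Evaluation reports the
standard confusion-matrix metrics, ROC AUC over raw probabilities, and the
mean accuracy over consecutive groups of ``eval_group`` test pairs (the
"batch-of-5" convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._nn import Adam, Dropout, Linear, Network, ReLU
from .embedder import EmbedderConfig, EmbedderModel, build_embedder
from .types import DyadEpochPair, InvalidConfigError

__all__ = [
    "ClassifierConfig",
    "MetricsReport",
    "MultiBrainModel",
    "build_multibrain",
    "predict_dyad",
    "train_downstream",
    "evaluate",
    "metrics_from_confusion",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Downstream training/evaluation settings.

    Defaults follow the study protocol: batch 8, learning rate 9.3e-4,
    dropout 0.38 in the head, decision threshold 0.5, accuracy additionally
    averaged over groups of 5 test pairs.
    """

    hidden_sizes: tuple[int, ...] = (100, 50)
    dropout: float = 0.38
    lr: float = 9.3e-4
    batch_size: int = 8
    n_iterations: int = 200
    fusion: str = "concat"  # concat | absdiff | sum
    split: str = "epoch"  # epoch-level (study protocol) | dyad-level (leakage-safe)
    tie_embedders: bool = False
    freeze_embedders: bool = False
    threshold: float = 0.5
    eval_group: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise InvalidConfigError("threshold must be in (0, 1)")
        if self.eval_group < 1:
            raise InvalidConfigError("eval_group must be >= 1")
        if self.fusion not in ("concat", "absdiff", "sum"):
            raise InvalidConfigError(f"unknown fusion {self.fusion!r}")
        if self.split not in ("epoch", "dyad"):
            raise InvalidConfigError(f"unknown split mode {self.split!r}")
        if not 0 <= self.dropout < 1:
            raise InvalidConfigError("dropout must be in [0, 1)")


@dataclass
class MetricsReport:
    """Confusion-derived metrics with explicit NaN for undefined ratios."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float
    confusion: tuple[int, int, int, int]  # (tp, fp, tn, fn)
    per_group_accuracies: list[float] = field(default_factory=list)
    undefined: tuple[str, ...] = ()

    @property
    def group_accuracy(self) -> float:
        if not self.per_group_accuracies:
            return float("nan")
        return float(np.mean(self.per_group_accuracies))

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "confusion": {"tp": self.confusion[0], "fp": self.confusion[1],
                          "tn": self.confusion[2], "fn": self.confusion[3]},
            "group_accuracy": self.group_accuracy,
            "per_group_accuracies": list(self.per_group_accuracies),
            "undefined": list(self.undefined),
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Standard binary metrics from confusion counts (positive class = 1).

    Ratios with zero denominators are reported as NaN and named in
    ``undefined`` rather than silently coerced to 0.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    undefined = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    accuracy = (tp + tn) / total
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        roc_auc=float("nan"),
        confusion=counts,
        undefined=tuple(undefined),
    )


class MultiBrainModel:
    """Two embedders plus a fully connected sigmoid head."""

    def __init__(
        self,
        embedder1: EmbedderModel,
        embedder2: EmbedderModel,
        head: Network,
        cfg: ClassifierConfig,
        head_dropouts: list[Dropout],
    ) -> None:
        self.embedder1 = embedder1
        self.embedder2 = embedder2
        self.head = head
        self.cfg = cfg
        self._head_dropouts = head_dropouts

    @property
    def d_embed(self) -> int:
        return self.embedder1.config.D

    def fuse(self, z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
        if self.cfg.fusion == "concat":
            return np.concatenate([z1, z2], axis=-1)
        if self.cfg.fusion == "absdiff":
            return np.abs(z1 - z2)
        return z1 + z2

    def forward(self, x1: np.ndarray, x2: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of dyadic epochs."""
        z1 = self.embedder1.forward(x1, train=train)
        z2 = self.embedder2.forward(x2, train=train)
        self._z1, self._z2 = z1, z2
        logits = self.head.forward(self.fuse(z1, z2), train=train)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits[:, None])
        d = self.d_embed
        if self.cfg.fusion == "concat":
            dz1, dz2 = dfused[:, :d], dfused[:, d:]
        elif self.cfg.fusion == "absdiff":
            s = np.sign(self._z1 - self._z2)
            dz1, dz2 = dfused * s, -dfused * s
        else:
            dz1 = dz2 = dfused
        if not self.cfg.freeze_embedders:
            self.embedder1.backward(dz1)
            self.embedder2.backward(dz2)
            if self.cfg.tie_embedders:
                # shared weights: accumulate both streams' gradients
                for m1, m2 in zip(self.embedder1.net.modules, self.embedder2.net.modules):
                    for name, g in m2.grads.items():
                        m1.grads[name] = m1.grads.get(name, 0.0) + g

    def trainable_networks(self) -> list[Network]:
        nets = [self.head]
        if not self.cfg.freeze_embedders:
            nets.append(self.embedder1.net)
            if not self.cfg.tie_embedders:
                nets.append(self.embedder2.net)
        return nets


def build_multibrain(
    pretrained: EmbedderModel | None,
    cfg: ClassifierConfig,
    embedder_cfg: EmbedderConfig | None = None,
) -> MultiBrainModel:
    """Assemble the dyadic classifier.

    With ``pretrained`` given, both embedders start from its weights (the
    supervised-from-scratch baseline passes ``None`` and random embedders are
    built from ``embedder_cfg``).  ``tie_embedders`` makes the two embedders
    literally share parameter arrays, so updates coincide.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if pretrained is not None:
        emb1 = pretrained.copy(seed=cfg.seed)
        emb2 = pretrained.copy(seed=cfg.seed + 1)
    else:
        if embedder_cfg is None:
            raise InvalidConfigError("embedder_cfg required when pretrained is None")
        emb1 = build_embedder(embedder_cfg, seed=cfg.seed)
        emb2 = build_embedder(embedder_cfg, seed=cfg.seed + 1)
    emb1.set_rng(np.random.default_rng(cfg.seed + 10))
    emb2.set_rng(np.random.default_rng(cfg.seed + 11))
    if cfg.tie_embedders:
        for m1, m2 in zip(emb1.net.modules, emb2.net.modules):
            m2.params = m1.params  # same dict objects -> identical parameters
    d = emb1.config.D
    n_in = 2 * d if cfg.fusion == "concat" else d
    sizes = [n_in, *cfg.hidden_sizes, 1]
    layers = []
    dropouts = []
    for i in range(len(sizes) - 1):
        layers.append(Linear(sizes[i], sizes[i + 1], rng))
        if i < len(sizes) - 2:
            layers.append(ReLU())
            drop = Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 20 + i))
            dropouts.append(drop)
            layers.append(drop)
    head = Network(layers)
    return MultiBrainModel(emb1, emb2, head, cfg, dropouts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def predict_dyad(model: MultiBrainModel, pair: DyadEpochPair) -> float:
    """P(label = 1) for one dyadic epoch pair (evaluation mode)."""
    logit = model.forward(pair.x1[None], pair.x2[None], train=False)[0]
    return float(_sigmoid(logit))


def _stack(pairs: list[DyadEpochPair], idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x1 = np.stack([pairs[i].x1 for i in idx])
    x2 = np.stack([pairs[i].x2 for i in idx])
    y = np.array([pairs[i].label for i in idx], dtype=float)
    return x1, x2, y


def _predict_proba(model: MultiBrainModel, pairs: list[DyadEpochPair], idx: np.ndarray,
                   chunk: int = 256) -> np.ndarray:
    out = []
    for s in range(0, idx.size, chunk):
        x1, x2, _ = _stack(pairs, idx[s : s + chunk])
        out.append(_sigmoid(model.forward(x1, x2, train=False)))
    return np.concatenate(out)


def train_downstream(
    pairs: list[DyadEpochPair],
    model: MultiBrainModel,
    cfg: ClassifierConfig | None = None,
) -> tuple[MultiBrainModel, dict]:
    """Fine-tune (or train from scratch) the dyadic classifier.

    Pairs are split 90/10 into train/eval and the eval part 90/10 into
    validation/test.  The default ``split="epoch"`` partitions at the
    epoch-pair level (the study's protocol, which maximizes sample count but
    lets epochs of one dyad appear on both sides); ``split="dyad"`` holds out
    whole dyads, which is the leakage-safe mode.  Minibatch Adam minimizes
    binary cross-entropy on the sigmoid output; the best-validation-loss
    weights are restored at the end.  History records per-iteration training
    loss/accuracy and the validation trace; ``history['test_idx']`` exposes
    the held-out indices so callers can evaluate on untouched pairs.
    """
    cfg = cfg or model.cfg
    cfg.validate()
    labels = {p.label for p in pairs}
    if len(labels) < 2:
        raise ValueError("training pairs must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    if cfg.split == "dyad":
        dyad_ids = sorted({p.dyad_id for p in pairs})
        order = rng.permutation(len(dyad_ids))
        n_tr = max(2, int(round(0.8 * len(dyad_ids))))
        n_va = max(1, int(round(0.5 * (len(dyad_ids) - n_tr))))
        tr_ids = {dyad_ids[i] for i in order[:n_tr]}
        va_ids = {dyad_ids[i] for i in order[n_tr : n_tr + n_va]}
        train_idx = np.array(
            [i for i, p in enumerate(pairs) if p.dyad_id in tr_ids], dtype=int
        )
        val_idx = np.array(
            [i for i, p in enumerate(pairs) if p.dyad_id in va_ids], dtype=int
        )
        test_idx = np.array(
            [i for i, p in enumerate(pairs)
             if p.dyad_id not in tr_ids and p.dyad_id not in va_ids],
            dtype=int,
        )
    else:
        perm = rng.permutation(len(pairs))
        n_train = int(round(0.9 * len(pairs)))
        train_idx, rest = perm[:n_train], perm[n_train:]
        n_val = int(round(0.9 * rest.size))
        val_idx, test_idx = rest[:n_val], rest[n_val:]

    if len({pairs[i].label for i in train_idx}) < 2:
        raise ValueError("training split ended up single-class; use more dyads")
    nets = model.trainable_networks()
    optim = Adam(nets, lr=cfg.lr)
    history: dict = {"train_loss": [], "train_acc": [], "val_iter": [], "val_loss": [], "val_acc": []}
    best_val = np.inf
    best = [net.get_flat() for net in nets]
    for it in range(cfg.n_iterations):
        batch = rng.choice(train_idx, size=min(cfg.batch_size, train_idx.size), replace=False)
        x1, x2, y = _stack(pairs, batch)
        optim.zero_grad()
        logits = model.forward(x1, x2, train=True)
        p = _sigmoid(logits)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        if not np.isfinite(loss):
            raise RuntimeError(f"downstream training diverged at iteration {it}")
        model.backward((p - y) / y.size)
        optim.step()
        history["train_loss"].append(loss)
        history["train_acc"].append(float(np.mean((p >= cfg.threshold) == (y == 1))))
        if (it + 1) % 10 == 0 and val_idx.size:
            pv = _predict_proba(model, pairs, val_idx)
            yv = np.array([pairs[i].label for i in val_idx], dtype=float)
            vloss = float(-np.mean(yv * np.log(pv + eps) + (1 - yv) * np.log(1 - pv + eps)))
            vacc = float(np.mean((pv >= cfg.threshold) == (yv == 1)))
            history["val_iter"].append(it + 1)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
            if vloss < best_val:
                best_val = vloss
                best = [net.get_flat() for net in nets]
    for net, flat in zip(nets, best):
        net.set_flat(flat)
    history["train_idx"] = train_idx
    history["val_idx"] = val_idx
    history["test_idx"] = test_idx
    return model, history


def evaluate(
    model: MultiBrainModel,
    pairs: list[DyadEpochPair],
    cfg: ClassifierConfig | None = None,
) -> MetricsReport:
    """Full metrics on a set of dyadic pairs.

    Probabilities are binarized at ``cfg.threshold``; the confusion matrix
    treats the mixed (label 1) dyad as the positive class.  Accuracy is also
    reported as the mean over consecutive, non-overlapping groups of
    ``eval_group`` pairs in a once-shuffled (seeded) order.  ROC AUC uses the
    raw probabilities (NaN for single-class inputs).
    """
    cfg = cfg or model.cfg
    cfg.validate()
    if not pairs:
        raise ValueError("no pairs to evaluate")
    order = np.random.default_rng(cfg.seed).permutation(len(pairs))
    probs = _predict_proba(model, pairs, order)
    y = np.array([pairs[i].label for i in order])
    pred = (probs >= cfg.threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    report = metrics_from_confusion(tp, fp, tn, fn)
    if len(set(y.tolist())) == 2:
        report.roc_auc = float(roc_auc_score(y, probs))
    else:
        report.undefined = report.undefined + ("roc_auc",)
    correct = (pred == y).astype(float)
    groups = [
        float(correct[s : s + cfg.eval_group].mean())
        for s in range(0, len(correct) - cfg.eval_group + 1, cfg.eval_group)
    ]
    if not groups:  # fewer pairs than one group
        groups = [float(correct.mean())]
    report.per_group_accuracies = groups
    return report
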