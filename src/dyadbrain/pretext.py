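"""Temporal-shuffling (TS) pretext task.

From unlabeled epoched EEG, triplets ``(x_e, x_e', x_e'')`` are sampled with
two *anchor* epochs ``e < e''`` at most ``tau_pos`` epochs apart and a probe
epoch ``e'``.  The label is ``y = +1`` if the probe falls strictly between
the anchors (*ordered*) and ``y = -1`` if it falls outside them, in the
negative context governed by ``tau_neg`` (*shuffled*).  A contrastive feature
``g_TS = (|z_e - z_e'| , |z_e' - z_e''|)`` over embeddings ``z = h_theta(x)``
feeds a linear head ``(w, w0)``; embedder and head are trained jointly with
the mean logistic loss

    L = (1/|N|) * sum log(1 + exp(-y * (w^T g_TS + w0))).

With all-zero head the loss is exactly ``ln 2`` regardless of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Network
from .embedder import EmbedderConfig, EmbedderModel, build_embedder
from .types import EpochArray, InvalidConfigError

__all__ = [
    "SamplerConfig",
    "TripletSample",
    "PretextHead",
    "OptimizerConfig",
    "sample_triplets",
    "contrast_ts",
    "ts_loss",
    "train_pretext",
    "evaluate_triplets",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Too few epochs to form the requested triplets."""


@dataclass(frozen=True)
class SamplerConfig:
    """Triplet-sampling parameters (contexts are in epochs; 1 epoch = 1 s).

    ``tau_pos`` bounds the anchor separation (positive context); ``tau_neg``
    bounds how far beyond an anchor a shuffled probe may lie (negative
    context).  ``balance`` forces ordered/shuffled counts equal within one.
    """

    tau_pos: int = 10
    tau_neg: int = 3
    n_triplets: int = 100
    balance: bool = True
    negative_mode: str = "far"  # "far": beyond tau_neg; "near": within tau_neg
    seed: int = 0

    def validate(self) -> None:
        if self.tau_pos < 1:
            raise InvalidConfigError("tau_pos must be >= 1")
        if self.tau_neg < 1:
            raise InvalidConfigError("tau_neg must be >= 1")
        if self.n_triplets < 0:
            raise InvalidConfigError("n_triplets must be >= 0")
        if self.negative_mode not in ("far", "near"):
            raise InvalidConfigError(f"unknown negative_mode {self.negative_mode!r}")

    @property
    def min_separation(self) -> int:
        """Smallest anchor separation: 2 when an ordered (interior) probe
        must exist, 1 when ``tau_pos`` itself forbids any interior epoch."""
        return 2 if self.tau_pos >= 2 else 1

    @property
    def max_separation(self) -> int:
        return self.tau_pos

    @property
    def ordered_constructible(self) -> bool:
        """With ``tau_pos < 2`` no epoch fits strictly between the anchors,
        so the ordered class cannot be sampled at all — the sampler then
        emits only shuffled triplets and the class imbalance is reported
        rather than hidden."""
        return self.tau_pos >= 2


@dataclass(frozen=True)
class TripletSample:
    """One labeled TS sample: anchors ``e < e_dprime``, probe ``e_prime``."""

    rec_id: int
    e: int
    e_prime: int
    e_dprime: int
    y: int

    def __post_init__(self) -> None:
        if not self.e < self.e_dprime:
            raise ValueError("anchors must satisfy e < e_dprime")
        if self.y not in (-1, 1):
            raise ValueError("y must be -1 or +1")


@dataclass
class PretextHead:
    """Linear context-discriminative model on g_TS features: score = w.g + w0."""

    w: np.ndarray
    w0: float = 0.0

    @classmethod
    def zeros(cls, d_embed: int) -> "PretextHead":
        return cls(w=np.zeros(2 * d_embed), w0=0.0)

    def scores(self, g: np.ndarray) -> np.ndarray:
        return g @ self.w + self.w0


def sample_triplets(ep: EpochArray, cfg: SamplerConfig, rec_id: int = 0) -> list[TripletSample]:
    """Sample labeled triplets from one recording's epochs.

    Anchors: ``e`` uniform over valid starts, separation uniform in
    ``[2, tau_pos]``.  A one-epoch positive context leaves no room for an
    interior epoch, so with ``tau_pos=1`` only shuffled triplets can exist:
    the sampler then emits a single-class (all shuffled) set and the caller
    sees the imbalance in the label counts.  Ordered probes are uniform
    strictly between the anchors.  Shuffled probes come from the
    negative context: with the default ``negative_mode="far"`` they are
    uniform over epochs *more than* ``tau_neg`` away from the nearest anchor
    (the temporal-contrast region of the source formulation of this task);
    ``"near"`` instead draws them within ``tau_neg`` of the nearest anchor
    boundary.  With ``balance`` on, labels alternate (in seeded-shuffled
    order) so counts differ by at most one.
    """
    cfg.validate()
    e_total = ep.n_epochs
    # anchors plus at least one reachable negative-context slot
    if cfg.negative_mode == "far":
        need = cfg.max_separation + cfg.tau_neg + 2
    else:
        need = cfg.max_separation + 2
    if cfg.n_triplets == 0:
        return []
    if e_total < need:
        raise InsufficientDataError(
            f"{e_total} epochs < {need} required for tau_pos={cfg.tau_pos}"
        )
    rng = np.random.default_rng(cfg.seed)
    if not cfg.ordered_constructible:
        labels = np.full(cfg.n_triplets, -1)
    elif cfg.balance:
        labels = np.where(np.arange(cfg.n_triplets) % 2 == 0, 1, -1)
        rng.shuffle(labels)
    else:
        labels = np.where(rng.random(cfg.n_triplets) < 0.5, 1, -1)
    out: list[TripletSample] = []
    for y in labels:
        for _ in range(100):
            sep = int(rng.integers(cfg.min_separation, cfg.max_separation + 1))
            e = int(rng.integers(0, e_total - sep))
            edp = e + sep
            if y == 1:
                e_prime = int(rng.integers(e + 1, edp))
                out.append(TripletSample(rec_id, e, e_prime, edp, 1))
                break
            if cfg.negative_mode == "far":
                support = list(range(0, max(0, e - cfg.tau_neg))) + list(
                    range(min(e_total, edp + cfg.tau_neg + 1), e_total)
                )
            else:
                support = list(range(max(0, e - cfg.tau_neg), e)) + list(
                    range(edp + 1, min(e_total, edp + cfg.tau_neg + 1))
                )
            if support:
                e_prime = int(support[rng.integers(0, len(support))])
                out.append(TripletSample(rec_id, e, e_prime, edp, -1))
                break
        else:
            raise InsufficientDataError(
                "could not place a shuffled probe after 100 attempts"
            )
    return out


def contrast_ts(z_e: np.ndarray, z_ep: np.ndarray, z_edp: np.ndarray) -> np.ndarray:
    """g_TS: concatenated elementwise absolute differences, length 2D.

    Accepts single D-vectors or (B, D) batches.
    """
    z_e, z_ep, z_edp = (np.asarray(a, dtype=float) for a in (z_e, z_ep, z_edp))
    if not z_e.shape == z_ep.shape == z_edp.shape:
        raise ValueError("embedding shapes must match")
    return np.concatenate([np.abs(z_e - z_ep), np.abs(z_ep - z_edp)], axis=-1)


def ts_loss(
    y: np.ndarray, g: np.ndarray, head: PretextHead
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Mean logistic loss over samples plus its gradients.

    Returns ``(loss, dL/dw, dL/dw0, dL/dg)``.  ``y`` is (B,) in {-1, +1};
    ``g`` is (B, 2D).  Raises on an empty sample set (the mean is undefined).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.size == 0:
        raise ValueError("loss undefined for an empty sample set")
    if g.shape != (y.size, head.w.size):
        raise ValueError(f"g shape {g.shape} does not match ({y.size}, {head.w.size})")
    s = head.scores(g)
    margins = y * s
    loss = float(np.mean(np.logaddexp(0.0, -margins)))
    # d/ds log(1+exp(-y s)) = -y sigmoid(-y s); expit avoids exp overflow
    from scipy.special import expit

    ds = -y * expit(-margins) / y.size
    dw = g.T @ ds
    dw0 = float(ds.sum())
    dg = ds[:, None] * head.w[None, :]
    return loss, dw, dw0, dg


def evaluate_triplets(
    model: EmbedderModel,
    head: PretextHead,
    epoch_sets: list[EpochArray],
    triplets: list[TripletSample],
) -> tuple[float, float]:
    """Evaluation-mode loss and accuracy of a trained pretext model on a
    fixed triplet set (used, e.g., to compare sweep runs on one yardstick)."""
    if not triplets:
        raise ValueError("no triplets to evaluate")
    idx = np.arange(len(triplets))
    xs, ys = _gather_epochs(epoch_sets, triplets, idx)
    loss, acc, _ = _forward_batch(model, head, xs, ys, train=False)
    return loss, acc


@dataclass(frozen=True)
class OptimizerConfig:
    """Pretext training-loop settings.

    Defaults follow the study protocol where applicable: 200 Adam iterations,
    batch 128, early stopping on validation loss.  ``lr`` drives the embedder;
    the linear head starts at zero weights and learns with its own, larger
    rate (``head_lr``) because Adam's per-step displacement is bounded by the
    learning rate and the optimal head weights sit far from the origin.
    """

    n_iterations: int = 200
    lr: float = 1e-4
    head_lr: float = 5e-2
    batch_size: int = 128
    eval_every: int = 5
    patience: int = 10
    seed: int = 0


def _split_indices(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """90% train / 10% eval; eval split 90% val / 10% test."""
    perm = rng.permutation(n)
    n_train = int(round(0.9 * n))
    train, rest = perm[:n_train], perm[n_train:]
    n_val = int(round(0.9 * rest.size))
    return train, rest[:n_val], rest[n_val:]


def _gather_epochs(
    epoch_sets: list[EpochArray], triplets: list[TripletSample], idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack(
        [
            np.stack(
                [
                    epoch_sets[t.rec_id].data[t.e],
                    epoch_sets[t.rec_id].data[t.e_prime],
                    epoch_sets[t.rec_id].data[t.e_dprime],
                ]
            )
            for t in (triplets[i] for i in idx)
        ]
    )  # (B, 3, C, T)
    ys = np.array([triplets[i].y for i in idx], dtype=float)
    return xs, ys


def _forward_batch(
    model: EmbedderModel, head: PretextHead, xs: np.ndarray, ys: np.ndarray, train: bool
) -> tuple[float, float, np.ndarray | None]:
    b = xs.shape[0]
    flat = xs.reshape(b * 3, *xs.shape[2:])
    z = model.forward(flat, train=train).reshape(b, 3, -1)
    g = contrast_ts(z[:, 0], z[:, 1], z[:, 2])
    loss, dw, dw0, dg = ts_loss(ys, g, head)
    preds = np.where(head.scores(g) >= 0, 1.0, -1.0)
    acc = float(np.mean(preds == ys))
    if not train:
        return loss, acc, None
    # backprop dg -> dz for the three roles, using sign of the differences
    z_e, z_ep, z_edp = z[:, 0], z[:, 1], z[:, 2]
    d = head.w.size // 2
    s1 = np.sign(z_e - z_ep)
    s2 = np.sign(z_ep - z_edp)
    dz = np.empty_like(z)
    dz[:, 0] = dg[:, :d] * s1
    dz[:, 1] = -dg[:, :d] * s1 + dg[:, d:] * s2
    dz[:, 2] = -dg[:, d:] * s2
    model.backward(dz.reshape(b * 3, -1))
    return loss, acc, np.concatenate([dw, [dw0]])


def train_pretext(
    epoch_sets: list[EpochArray],
    embedder_cfg: EmbedderConfig | None = None,
    sampler_cfg: SamplerConfig | None = None,
    optimizer_cfg: OptimizerConfig | None = None,
) -> tuple[EmbedderModel, PretextHead, dict]:
    """Jointly train embedder and head on TS triplets from the given epochs.

    Triplets are pooled over recordings, split 90/10 into train/eval and the
    eval part 90/10 into validation/test.  Minibatch Adam minimizes the TS
    loss; validation is evaluated every ``eval_every`` iterations and training
    stops early when validation loss has not improved for ``patience``
    evaluations.  The best-validation weights are restored before the test
    accuracy is computed.

    Returns ``(model, head, history)`` where history holds per-iteration train
    loss/accuracy, the validation trace, and final test metrics.
    """
    if not epoch_sets:
        raise InsufficientDataError("no epoch sets given")
    embedder_cfg = embedder_cfg or EmbedderConfig()
    sampler_cfg = sampler_cfg or SamplerConfig()
    optimizer_cfg = optimizer_cfg or OptimizerConfig()

    triplets: list[TripletSample] = []
    for rid, ep in enumerate(epoch_sets):
        scfg = SamplerConfig(
            tau_pos=sampler_cfg.tau_pos,
            tau_neg=sampler_cfg.tau_neg,
            n_triplets=sampler_cfg.n_triplets,
            balance=sampler_cfg.balance,
            seed=sampler_cfg.seed + 1000003 * rid,
        )
        triplets.extend(sample_triplets(ep, scfg, rec_id=rid))
    if not triplets:
        raise InsufficientDataError("sampler produced no triplets")

    rng = np.random.default_rng(optimizer_cfg.seed)
    train_idx, val_idx, test_idx = _split_indices(len(triplets), rng)
    if train_idx.size == 0 or val_idx.size == 0:
        raise InsufficientDataError("not enough triplets to split")

    model = build_embedder(embedder_cfg, seed=optimizer_cfg.seed)
    model.set_rng(np.random.default_rng(optimizer_cfg.seed + 1))
    head = PretextHead.zeros(embedder_cfg.D)
    head_net = _HeadAdapter(head)
    optim = Adam([model.net], lr=optimizer_cfg.lr)
    optim_head = Adam([head_net.net], lr=optimizer_cfg.head_lr)

    history: dict = {"train_loss": [], "train_acc": [], "val_iter": [], "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_flat = model.net.get_flat()
    best_head = (head.w.copy(), head.w0)
    bad_evals = 0
    stopped_at = None

    for it in range(optimizer_cfg.n_iterations):
        batch = rng.choice(train_idx, size=min(optimizer_cfg.batch_size, train_idx.size), replace=False)
        xs, ys = _gather_epochs(epoch_sets, triplets, batch)
        optim.zero_grad()
        optim_head.zero_grad()
        loss, acc, dhead = _forward_batch(model, head, xs, ys, train=True)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={loss!r}"
            )
        head_net.set_grad(dhead)
        optim.step()
        optim_head.step()
        head_net.sync_out()
        history["train_loss"].append(loss)
        history["train_acc"].append(acc)

        if (it + 1) % optimizer_cfg.eval_every == 0:
            xs, ys = _gather_epochs(epoch_sets, triplets, val_idx)
            vloss, vacc, _ = _forward_batch(model, head, xs, ys, train=False)
            history["val_iter"].append(it + 1)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_flat = model.net.get_flat()
                best_head = (head.w.copy(), head.w0)
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= optimizer_cfg.patience:
                    stopped_at = it + 1
                    break

    model.net.set_flat(best_flat)
    head.w, head.w0 = best_head[0].copy(), best_head[1]
    history["stopped_at"] = stopped_at
    history["n_triplets"] = len(triplets)
    n_pos = sum(1 for t in triplets if t.y == 1)
    history["class_balance"] = (n_pos, len(triplets) - n_pos)
    if test_idx.size:
        xs, ys = _gather_epochs(epoch_sets, triplets, test_idx)
        tloss, tacc, _ = _forward_batch(model, head, xs, ys, train=False)
        history["test_loss"], history["test_acc"] = tloss, tacc
    xs, ys = _gather_epochs(epoch_sets, triplets, val_idx)
    vloss, vacc, _ = _forward_batch(model, head, xs, ys, train=False)
    history["final_val_loss"], history["final_val_acc"] = vloss, vacc
    return model, head, history


class _HeadAdapter:
    """Expose a PretextHead as a one-module Network so Adam can update it."""

    def __init__(self, head: PretextHead) -> None:
        from ._nn import Module

        self.head = head
        mod = Module()
        mod.params["wv"] = np.concatenate([head.w, [head.w0]])
        self._mod = mod
        self.net = Network([mod])

    def set_grad(self, dflat: np.ndarray) -> None:
        self._mod.grads["wv"] = dflat

    def sync_out(self) -> None:
        v = self._mod.params["wv"]
        self.head.w = v[:-1].copy()
        self.head.w0 = float(v[-1])
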