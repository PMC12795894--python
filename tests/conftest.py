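"""Shared fixtures.

The expensive artifacts — synthetic recordings, the trained pretext model,
the downstream runs — are session-scoped so the learning-behaviour tests and
the acceptance suite share one training run each.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from dyadbrain.multibrain import ClassifierConfig, build_multibrain, train_downstream
from dyadbrain.preprocess import epoch
from dyadbrain.pretext import OptimizerConfig, SamplerConfig, sample_triplets, train_pretext
from dyadbrain.synthdata import make_dyad_recordings, make_pretext_recordings
from dyadbrain.workflow import desk_scale_embedder, desk_scale_synth, dyad_pairs_from_recordings

SEED = 1


@pytest.fixture(scope="session")
def pretext_epoch_sets():
    recs = make_pretext_recordings(12, desk_scale_synth(), seed=SEED)
    return [epoch(r) for r in recs]


@pytest.fixture(scope="session")
def holdout_epoch_sets():
    recs = make_pretext_recordings(4, desk_scale_synth(), seed=901)
    return [epoch(r) for r in recs]


@pytest.fixture(scope="session")
def holdout_triplets(holdout_epoch_sets):
    out = []
    for rid, ep_set in enumerate(holdout_epoch_sets):
        out.extend(
            sample_triplets(
                ep_set, SamplerConfig(tau_pos=10, n_triplets=150, seed=555 + rid), rid
            )
        )
    return out


@pytest.fixture(scope="session")
def trained_pretext(pretext_epoch_sets):
    """Pretext model trained at the default positive context (10 epochs)."""
    model, head, hist = train_pretext(
        pretext_epoch_sets,
        desk_scale_embedder(),
        SamplerConfig(tau_pos=10, n_triplets=150, seed=SEED),
        OptimizerConfig(seed=SEED),
    )
    return model, head, hist


@pytest.fixture(scope="session")
def trained_pretext_tau1(pretext_epoch_sets):
    """Pretext model trained with a one-epoch positive context (degenerate)."""
    model, head, hist = train_pretext(
        pretext_epoch_sets,
        desk_scale_embedder(),
        SamplerConfig(tau_pos=1, n_triplets=150, seed=SEED),
        OptimizerConfig(seed=SEED),
    )
    return model, head, hist


@pytest.fixture(scope="session")
def effect_dyad_pairs():
    """Labeled dyads with a strong group effect (alpha power ratio 2)."""
    dyads = make_dyad_recordings(10, desk_scale_synth(), seed=2, alpha_power_ratio=2.0)
    return dyad_pairs_from_recordings(dyads)


@pytest.fixture(scope="session")
def downstream_cfg():
    return ClassifierConfig(batch_size=16, n_iterations=150, split="dyad", seed=3)


def _heldout(pairs, hist):
    test = [pairs[i] for i in hist["test_idx"]]
    if len({p.label for p in test}) < 2:
        idx = np.concatenate([hist["val_idx"], hist["test_idx"]])
        test = [pairs[i] for i in idx]
    return test


@pytest.fixture(scope="session")
def ssl_downstream(trained_pretext, effect_dyad_pairs, downstream_cfg):
    model, _, _ = trained_pretext
    mb = build_multibrain(model, downstream_cfg)
    mb, hist = train_downstream(effect_dyad_pairs, mb, downstream_cfg)
    return mb, hist, _heldout(effect_dyad_pairs, hist)


@pytest.fixture(scope="session")
def supervised_downstream(effect_dyad_pairs, downstream_cfg):
    mb = build_multibrain(None, downstream_cfg, embedder_cfg=desk_scale_embedder())
    mb, hist = train_downstream(effect_dyad_pairs, mb, downstream_cfg)
    return mb, hist, _heldout(effect_dyad_pairs, hist)


@pytest.fixture(scope="session")
def null_downstream(trained_pretext, downstream_cfg):
    """Model trained on no-effect dyads plus an independent fresh test set."""
    base = dataclasses.replace(desk_scale_synth(), duration=40.0)
    kwargs = dict(alpha_power_ratio=1.0, coupling_control=0.2, coupling_mixed=0.2)
    train_dyads = make_dyad_recordings(8, base, seed=4, **kwargs)
    test_dyads = make_dyad_recordings(8, base, seed=99, **kwargs)
    train_pairs = dyad_pairs_from_recordings(train_dyads)
    test_pairs = dyad_pairs_from_recordings(test_dyads)
    model, _, _ = trained_pretext
    mb = build_multibrain(model, downstream_cfg)
    mb, hist = train_downstream(train_pairs, mb, downstream_cfg)
    return mb, test_pairs
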