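"""Dyadic spectral-biomarker baseline.

Per participant: Welch power spectral density per epoch and channel; five
canonical bands (delta 2-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-48
Hz) in absolute and normalized form give 10 markers; each marker's (epoch x
channel) table is collapsed by a two-stage aggregation into four descriptors
(mean of channel means, mean of channel stds, std of channel means, std of
channel stds, inner statistic over epochs) for a 40-dimensional feature
vector.  A dyad concatenates its two participants' vectors (80 dimensions)
and an L2 logistic regression classifies control (TD-TD, 0) vs mixed
(ASC-TD, 1) dyads.

The *absolute* marker is the band-average PSD; the *normalized* marker is the
band's share of total broadband power over 2-48 Hz, so the five normalized
markers of any (epoch, channel) with nonzero broadband power sum to exactly 1
(the bands partition the broadband interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .multibrain import MetricsReport, metrics_from_confusion
from .types import EpochArray, InvalidConfigError

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "SpectralFeatures",
    "DyadFeatures",
    "compute_psd",
    "band_powers",
    "summarize",
    "participant_features",
    "dyad_features",
    "fit_baseline",
    "DESCRIPTOR_NAMES",
]

DESCRIPTOR_NAMES = ("meanmean", "meanstd", "stdmean", "stdstd")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidConfigError(f"band {self.name}: low must be < high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 48.0),
)


@dataclass(frozen=True)
class SpectralFeatures:
    """One participant's 40-entry biomarker vector with aligned names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")


@dataclass(frozen=True)
class DyadFeatures:
    """Participant-1 block followed by participant-2 block, plus the label."""

    values: np.ndarray
    label: int


def compute_psd(
    ep: EpochArray, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per epoch and channel: returns ``(psd (E,C,F), freqs (F,))``.

    Default is a single Hann-windowed segment spanning the whole epoch
    (about 1 Hz resolution for 1-s epochs); values are one-sided densities in
    signal-units^2/Hz.
    """
    t = ep.n_times
    nperseg = t if nperseg is None else int(nperseg)
    if nperseg > t or nperseg < 2:
        raise InvalidConfigError(f"nperseg {nperseg} invalid for epochs of {t} samples")
    freqs, psd = welch(ep.data, fs=ep.sfreq, window="hann", nperseg=nperseg, axis=-1)
    return psd, freqs


def band_powers(
    psd: np.ndarray,
    freqs: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> tuple[np.ndarray, list[str]]:
    """Absolute and normalized band powers: (E, C, F) -> (E, C, 2*n_bands).

    Bands are half-open ``[low, high)`` except the last, which closes at its
    upper edge so the set partitions the broadband interval.  Absolute marker:
    mean PSD over the band's bins.  Normalized marker: band-integrated power
    divided by broadband-integrated power (sums to 1 across bands).
    """
    masks = []
    for i, b in enumerate(bands):
        if i == len(bands) - 1:
            mask = (freqs >= b.low) & (freqs <= b.high)
        else:
            mask = (freqs >= b.low) & (freqs < b.high)
        if not mask.any():
            raise InvalidConfigError(
                f"band {b.name} [{b.low}, {b.high}) contains no frequency bins"
            )
        masks.append(mask)
    broadband = np.zeros(len(freqs), dtype=bool)
    for m in masks:
        broadband |= m
    total = psd[..., broadband].sum(axis=-1)
    safe_total = np.where(total > 0, total, 1.0)
    markers = []
    names = []
    for b, m in zip(bands, masks):
        markers.append(psd[..., m].mean(axis=-1))
        names.append(f"{b.name}_abs")
    for b, m in zip(bands, masks):
        markers.append(psd[..., m].sum(axis=-1) / safe_total)
        names.append(f"{b.name}_norm")
    return np.stack(markers, axis=-1), names


def summarize(
    markers: np.ndarray,
    marker_names: list[str],
    inner: str = "epochs",
) -> SpectralFeatures:
    """Two-stage aggregation of (E, C, M) markers into 4 descriptors each.

    Default order (``inner="epochs"``): per channel, mean and std over
    epochs; then mean and std of those across channels — giving mean-of-
    means, mean-of-stds, std-of-means, std-of-stds per marker (population
    std throughout).  ``inner="channels"`` swaps the two axes for the
    alternate reading of the aggregation order.
    """
    markers = np.asarray(markers, dtype=float)
    if markers.ndim != 3:
        raise ValueError("markers must be (E, C, M)")
    e, c, _ = markers.shape
    if e < 2 or c < 2:
        raise ValueError(f"need at least 2 epochs and 2 channels, got E={e}, C={c}")
    axis = 0 if inner == "epochs" else 1
    inner_mean = markers.mean(axis=axis)  # (C, M) or (E, M)
    inner_std = markers.std(axis=axis)
    values = []
    names = []
    for mi, mname in enumerate(marker_names):
        values += [
            inner_mean[:, mi].mean(),
            inner_std[:, mi].mean(),
            inner_mean[:, mi].std(),
            inner_std[:, mi].std(),
        ]
        names += [f"{mname}_{d}" for d in DESCRIPTOR_NAMES]
    return SpectralFeatures(values=np.array(values), names=tuple(names))


def participant_features(
    ep: EpochArray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    inner: str = "epochs",
) -> SpectralFeatures:
    """Convenience chain: PSD -> band powers -> 40-entry summary."""
    psd, freqs = compute_psd(ep)
    markers, names = band_powers(psd, freqs, bands)
    return summarize(markers, names, inner=inner)


def dyad_features(f1: SpectralFeatures, f2: SpectralFeatures, label: int) -> DyadFeatures:
    """Concatenate the two participants' vectors (participant order kept)."""
    if len(f1.values) != len(f2.values):
        raise ValueError("participant feature lengths differ")
    return DyadFeatures(values=np.concatenate([f1.values, f2.values]), label=int(label))


def fit_baseline(
    features: list[DyadFeatures],
    seed: int = 0,
    test_size: float = 0.25,
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
) -> tuple[Pipeline, MetricsReport, dict]:
    """Standardized L2 logistic regression over dyadic feature vectors.

    The regularization strength is chosen by seeded stratified
    cross-validated grid search on the training split; metrics are reported
    on the held-out split.  Returns ``(fitted pipeline, held-out metrics,
    info)`` where info carries the cross-validated accuracy and chosen C.
    """
    x = np.stack([f.values for f in features])
    y = np.array([f.label for f in features])
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes required to fit the baseline")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, random_state=seed, stratify=y
    )
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("logreg", LogisticRegression(max_iter=5000)),  # default L2 penalty
        ]
    )
    n_splits = int(min(5, np.bincount(y_tr).min()))
    cv = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, {"logreg__C": list(c_grid)}, cv=cv, scoring="accuracy")
    search.fit(x_tr, y_tr)
    best = search.best_estimator_
    pred = best.predict(x_te)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    tn = int(np.sum((pred == 0) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    report = metrics_from_confusion(tp, fp, tn, fn)
    if len(set(y_te.tolist())) == 2:
        from sklearn.metrics import roc_auc_score

        report.roc_auc = float(roc_auc_score(y_te, best.predict_proba(x_te)[:, 1]))
    info = {
        "cv_accuracy": float(search.best_score_),
        "C": float(search.best_params_["logreg__C"]),
        "coef": best.named_steps["logreg"].coef_[0],
    }
    return best, report, info
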