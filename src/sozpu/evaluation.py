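"""Experiment protocols: splits, partial labeling, summaries, channel reports.

Two evaluation schemes are supported: shuffled 10-fold cross-validation for
pooled segment collections, and a temporal split (first 105 of 120 minutes
for training, 87.5%) for continuous per-channel recordings. The partial
annotation setting labels a random subset of SOZ training segments
(default fraction 0.1587 of the training rows) and hides every other label.

Channel-level aggregation turns segment predictions into a ranked report of
the fraction of segments called SOZ per channel — decision support, not a
hard SOZ call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .classifiers import FCNNClassifier, SVMSegmentClassifier, CNNClassifier
from .core_io import ConfigError, DatasetSplit, NONSOZ, SOZ, Segment
from .pu import PUClassifier, prior_from_composition


@dataclass
class ProtocolConfig:
    """Configuration of one experiment run."""

    scheme: str = "kfold10"  # {"kfold10", "temporal_105_15"}
    labeled_fraction: float = 0.1587
    small_baseline: bool = True
    seeds: list[int] = field(default_factory=lambda: [0])
    epochs: int = 60
    train_minutes: float = 105.0
    total_minutes: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.labeled_fraction < 1:
            raise ConfigError("labeled_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# splits


def kfold_split(n: int, k: int = 10, seed: int = 0) -> list[DatasetSplit]:
    """Shuffled k-fold splits over ``n`` items; fold sizes n/k (+-1)."""
    if n < k:
        raise ConfigError(f"cannot make {k} folds from {n} items")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        DatasetSplit(train_idx=tr, test_idx=te, scheme="kfold", fold=i)
        for i, (tr, te) in enumerate(kf.split(np.arange(n)))
    ]


def temporal_split(
    segments: list[Segment],
    train_minutes: float = 105.0,
    total_minutes: float = 120.0,
) -> DatasetSplit:
    """Train on all segments starting before ``train_minutes``, test on the rest."""
    t0s = np.array([s.t0 for s in segments])
    cut = train_minutes * 60.0
    train = np.flatnonzero(t0s < cut)
    test = np.flatnonzero(t0s >= cut)
    if len(test) == 0:
        raise ConfigError("temporal split leaves no test segments")
    if len(train) == 0:
        raise ConfigError("temporal split leaves no training segments")
    return DatasetSplit(train_idx=train, test_idx=test, scheme="temporal")


def select_labeled_positives(
    y_train: np.ndarray, fraction: float = 0.1587, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Reveal a random subset of SOZ labels; everything else becomes unlabeled.

    The labeled count is round(fraction x train size), capped by the number
    of available positives (13,500 training rows at the default fraction
    give 2,142 labeled SOZ segments).
    """
    y_train = np.asarray(y_train)
    if fraction <= 0:
        raise ConfigError("fraction must be positive")
    pos = np.flatnonzero(y_train == SOZ)
    if len(pos) == 0:
        raise ConfigError("training fold contains no positives")
    n_labeled = int(round(fraction * len(y_train)))
    if n_labeled > len(pos):
        raise ConfigError(
            f"requested {n_labeled} labeled positives but only {len(pos)} exist"
        )
    rng = np.random.default_rng(seed)
    labeled = np.sort(rng.choice(pos, size=n_labeled, replace=False))
    unlabeled = np.setdiff1d(np.arange(len(y_train)), labeled)
    return labeled, unlabeled


def last_epochs_summary(trace: np.ndarray, n: int = 10) -> tuple[float, float]:
    """Mean and sample SD (%) of the final ``n`` entries of an epoch trace."""
    trace = np.asarray(trace, dtype=float)
    if len(trace) < n:
        raise ConfigError(f"trace of length {len(trace)} has no last {n} epochs")
    tail = trace[-n:]
    return float(np.mean(tail)), float(np.std(tail, ddof=1)) if n > 1 else 0.0


# ---------------------------------------------------------------------------
# channel aggregation


@dataclass
class ChannelReport:
    """Ranked per-channel fractions of segments predicted SOZ."""

    table: pd.DataFrame  # columns: channel_id, n_segments, frac_predicted_soz, rank


def aggregate_channels(predictions: list[tuple[str, str]]) -> ChannelReport:
    """Rank channels by the fraction of their segments predicted SOZ.

    Channels where most segments are called SOZ are the most probable SOZ
    channels; ties are broken lexicographically by channel id so reports are
    deterministic.
    """
    if not predictions:
        warnings.warn("no predictions to aggregate; empty report")
        return ChannelReport(
            table=pd.DataFrame(
                columns=["channel_id", "n_segments", "frac_predicted_soz", "rank"]
            )
        )
    df = pd.DataFrame(predictions, columns=["channel_id", "label"])
    grouped = (
        df.assign(is_soz=lambda d: (d["label"] == SOZ).astype(float))
        .groupby("channel_id", as_index=False)
        .agg(n_segments=("label", "size"), frac_predicted_soz=("is_soz", "mean"))
    )
    grouped = grouped.sort_values(
        ["frac_predicted_soz", "channel_id"], ascending=[False, True]
    ).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return ChannelReport(table=grouped)


# ---------------------------------------------------------------------------
# full experiment


def _accuracy(model, X, y) -> float:
    return 100.0 * float(np.mean(model.predict(X) == np.asarray(y)))


def run_experiment(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ProtocolConfig | None = None,
    images: np.ndarray | None = None,
    segments: list[Segment] | None = None,
) -> pd.DataFrame:
    """Compare the supervised, PU and small-supervised arms on one dataset.

    For each seed the data is split (shuffled fold 0 of a 10-fold split, or
    the temporal split when ``segments`` are supplied), then six arms are
    evaluated: SVM / FCNN on entropy features, CNN on the entropy-matrix
    image (when ``images`` is given), PU-trained FCNN at ``labeled_fraction``
    and a small-supervised FCNN trained on the same number of rows. Returns a
    tidy table (model, features, seed, accuracy_pct, accuracy_sd).
    """
    cfg = cfg or ProtocolConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rows = []
    for seed in cfg.seeds:
        if cfg.scheme == "temporal_105_15":
            if segments is None:
                raise ConfigError("temporal scheme needs the segment list for t0")
            split = temporal_split(segments, cfg.train_minutes, cfg.total_minutes)
        elif cfg.scheme == "kfold10":
            split = kfold_split(len(X), k=10, seed=seed)[0]
        else:
            raise ConfigError(f"unknown scheme {cfg.scheme!r}")
        tr, te = split.train_idx, split.test_idx
        Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]

        arms: list[tuple[str, str, object, tuple]] = [
            ("svm", "entropy", SVMSegmentClassifier(epochs=cfg.epochs, seed=seed),
             (Xtr, ytr)),
            ("fcnn", "entropy", FCNNClassifier(epochs=cfg.epochs, seed=seed),
             (Xtr, ytr)),
        ]
        if images is not None:
            arms.append(
                ("cnn", "entropy_image",
                 CNNClassifier(epochs=cfg.epochs, seed=seed),
                 (images[tr], ytr))
            )

        for model_name, feat_name, model, (Xa, ya) in arms:
            eval_X = images[te] if feat_name == "entropy_image" else Xte
            model.fit(Xa, ya, eval_set=(eval_X, yte))
            mean, sd = last_epochs_summary(
                model.epoch_trace_, n=min(10, len(model.epoch_trace_))
            )
            rows.append((model_name, feat_name, seed, mean, sd))

        # PU arm: reveal labeled_fraction of the training rows as positives
        labeled, unlabeled = select_labeled_positives(
            ytr, fraction=cfg.labeled_fraction, seed=seed
        )
        pi_p = prior_from_composition(
            int(np.sum(ytr == SOZ)), len(labeled), len(unlabeled)
        )
        s = np.zeros(len(ytr), dtype=int)
        s[labeled] = 1
        pu = PUClassifier(pi_p=pi_p, epochs=cfg.epochs, seed=seed)
        pu.fit(Xtr, s, eval_set=(Xte, yte))
        mean, sd = last_epochs_summary(pu.epoch_trace_, n=min(10, len(pu.epoch_trace_)))
        rows.append(("pu_fcnn", "entropy", seed, mean, sd))

        if cfg.small_baseline:
            # same labeled budget, split half/half across classes, supervised only
            n_small = len(labeled)
            rng = np.random.default_rng(seed + 1)
            pos = np.flatnonzero(ytr == SOZ)
            neg = np.flatnonzero(ytr == NONSOZ)
            n_half = max(1, n_small // 2)
            pick = np.concatenate(
                [rng.choice(pos, size=min(n_half, len(pos)), replace=False),
                 rng.choice(neg, size=min(n_small - n_half, len(neg)), replace=False)]
            )
            small = FCNNClassifier(epochs=cfg.epochs, seed=seed)
            small.fit(Xtr[pick], ytr[pick], eval_set=(Xte, yte))
            mean, sd = last_epochs_summary(
                small.epoch_trace_, n=min(10, len(small.epoch_trace_))
            )
            rows.append(("small_fcnn", "entropy", seed, mean, sd))

    return pd.DataFrame(
        rows, columns=["model", "features", "seed", "accuracy_pct", "accuracy_sd"]
    )
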