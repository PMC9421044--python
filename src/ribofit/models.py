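"""Sequence-to-activity regressors: Random Forest, LSTM-hybrid, and baselines.

Two primary approaches are provided. The first fits a Random Forest
regressor directly to the flattened L x 4 one-hot encoding of each sequence.
The second trains an LSTM against fraction cleaved and uses the final hidden
state h_n of each sequence as the feature vector for a Random Forest
regressor (the "hybrid"). Ordinary least squares and a small multilayer
perceptron on the same one-hot features serve as baselines.

All models share one contract: a RegressorBundle knows its encoding, its
training seed, and a fingerprint of the training keys; predictions are
order-preserving, reported raw (regression output is not clipped to [0, 1]
unless asked), and reproducible from a persisted bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

from .genotypes import (
    Genotype,
    ReferenceSequence,
    encoding_feature_labels,
    one_hot_encode,
    sequence_to_indices,
)
from .lstm import LSTMConfig, LSTMRegressor
from .reads import ActivityTable

MODEL_KINDS = ("random_forest", "lstm_hybrid", "linear", "mlp")


@dataclass
class EncodedDataset:
    """Aligned (features, targets, genotype keys) ready for model fitting.

    ``features`` is the n x 4L flattened one-hot matrix (position-major);
    ``seq_indices`` the n x L integer-symbol view used by the recurrent path.
    Rows with missing targets are never admitted.
    """

    features: np.ndarray
    seq_indices: np.ndarray
    targets: np.ndarray
    keys: list[str]
    reference: ReferenceSequence

    def __post_init__(self) -> None:
        n = len(self.targets)
        if not (len(self.features) == len(self.seq_indices) == len(self.keys) == n):
            raise ValueError("features, seq_indices, targets, keys must align")
        if np.isnan(self.targets).any():
            raise ValueError("missing targets are not admitted")

    def __len__(self) -> int:
        return len(self.targets)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.keys):
            h.update(k.encode())
        return h.hexdigest()[:16]

    def subset(self, idx: Sequence[int]) -> "EncodedDataset":
        idx = np.asarray(idx, dtype=int)
        return EncodedDataset(
            self.features[idx],
            self.seq_indices[idx],
            self.targets[idx],
            [self.keys[i] for i in idx],
            self.reference,
        )


def encode_dataset(
    table: ActivityTable, genotype_labels: Sequence[str] | None = None
) -> EncodedDataset:
    """Encode (a subset of) an activity table; rows with NaN activity are dropped."""
    df = table.data
    if genotype_labels is not None:
        wanted = set(genotype_labels)
        df = df.loc[df["genotype"].isin(wanted)]
    df = df.dropna(subset=["fraction_cleaved"])
    ref = table.reference
    feats, seqs, keys = [], [], []
    for label in df["genotype"]:
        g = Genotype.from_string(label)
        feats.append(one_hot_encode(g, ref).reshape(-1))
        seqs.append(sequence_to_indices(g.sequence(ref)))
        keys.append(label)
    return EncodedDataset(
        features=np.array(feats) if feats else np.empty((0, 4 * len(ref))),
        seq_indices=np.array(seqs, dtype=np.int64) if seqs else np.empty((0, len(ref)), dtype=np.int64),
        targets=df["fraction_cleaved"].to_numpy(float),
        keys=keys,
        reference=ref,
    )


@dataclass
class RegressorBundle:
    """A fitted predictor plus everything needed to reproduce its predictions."""

    kind: str
    reference: ReferenceSequence
    seed: int
    train_fingerprint: str
    sk_model: object | None = None
    lstm: LSTMRegressor | None = None
    clip_predictions: bool = False
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Training


def train_random_forest(data: EncodedDataset, seed: int = 0) -> RegressorBundle:
    """Random Forest on flattened one-hot features, library-default hyperparameters."""
    if len(data) < 2:
        raise ValueError("need at least two training rows")
    rf = RandomForestRegressor(random_state=seed)
    rf.fit(data.features, data.targets)
    return RegressorBundle(
        kind="random_forest",
        reference=data.reference,
        seed=seed,
        train_fingerprint=data.fingerprint(),
        sk_model=rf,
        hyperparameters=rf.get_params(),
    )


def train_lstm_extractor(data: EncodedDataset, cfg: LSTMConfig) -> LSTMRegressor:
    """Train the recurrent feature extractor against fraction cleaved (MSE)."""
    if len(data) < 2:
        raise ValueError("need at least two training rows")
    lengths = {s.shape[0] for s in (data.seq_indices,)}
    if data.seq_indices.ndim != 2:
        raise ValueError("sequences must have uniform length")
    net = LSTMRegressor(cfg)
    net.fit(data.seq_indices, data.targets)
    return net


def train_hybrid(
    data: EncodedDataset, cfg: LSTMConfig | None = None, seed: int = 0
) -> RegressorBundle:
    """LSTM feature extraction followed by a Random Forest on h_n."""
    cfg = cfg if cfg is not None else LSTMConfig(seed=seed)
    net = train_lstm_extractor(data, cfg)
    hidden = net.hidden_features(data.seq_indices)
    rf = RandomForestRegressor(random_state=seed)
    rf.fit(hidden, data.targets)
    return RegressorBundle(
        kind="lstm_hybrid",
        reference=data.reference,
        seed=seed,
        train_fingerprint=data.fingerprint(),
        sk_model=rf,
        lstm=net,
        hyperparameters={"lstm": cfg.__dict__, "rf": rf.get_params()},
    )


def train_baseline(data: EncodedDataset, kind: str, seed: int = 0) -> RegressorBundle:
    """Linear (least-squares) or MLP baseline on one-hot features.

    The linear fit uses the minimum-norm least-squares solution, which
    handles the singular designs one-hot encodings produce (the four
    indicator columns of a position sum to 1).
    """
    if kind == "linear":
        model = LinearRegression()
    elif kind == "mlp":
        model = MLPRegressor(random_state=seed, max_iter=500)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    model.fit(data.features, data.targets)
    return RegressorBundle(
        kind=kind,
        reference=data.reference,
        seed=seed,
        train_fingerprint=data.fingerprint(),
        sk_model=model,
        hyperparameters=model.get_params(),
    )


def train_model(
    data: EncodedDataset,
    kind: str,
    seed: int = 0,
    lstm_cfg: LSTMConfig | None = None,
) -> RegressorBundle:
    """Dispatch on model kind; the one entry point the harness uses."""
    if kind == "random_forest":
        return train_random_forest(data, seed)
    if kind == "lstm_hybrid":
        return train_hybrid(data, lstm_cfg, seed)
    return train_baseline(data, kind, seed)


# ---------------------------------------------------------------------------
# Prediction


def predict(
    bundle: RegressorBundle, genotypes: Sequence[Genotype | str]
) -> np.ndarray:
    """Predicted fraction cleaved, one value per genotype, order-preserving."""
    gs = [
        Genotype.from_string(g) if isinstance(g, str) else g for g in genotypes
    ]
    if not gs:
        return np.empty(0)
    ref = bundle.reference
    if bundle.kind == "lstm_hybrid":
        X = np.array([sequence_to_indices(g.sequence(ref)) for g in gs])
        feats = bundle.lstm.hidden_features(X)
    else:
        feats = np.array([one_hot_encode(g, ref).reshape(-1) for g in gs])
    out = np.asarray(bundle.sk_model.predict(feats), dtype=float)
    if bundle.clip_predictions:
        out = np.clip(out, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Feature importance


def feature_importance(bundle: RegressorBundle):
    """Impurity-based importances mapped back to (position, base) labels.

    Only meaningful for the Random Forest on one-hot features: hybrid models
    operate on latent LSTM features with no positional mapping, and the
    baselines have no impurity-based importances. Returns
    (per-feature DataFrame sorted descending, per-position aggregate Series).
    """
    import pandas as pd

    if bundle.kind != "random_forest":
        raise ValueError(
            f"feature importance is only supported for random_forest bundles, got {bundle.kind!r}"
        )
    imps = np.asarray(bundle.sk_model.feature_importances_, dtype=float)
    labels = encoding_feature_labels(len(bundle.reference))
    df = pd.DataFrame(
        {
            "position": [p for p, _ in labels],
            "base": [b for _, b in labels],
            "importance": imps,
        }
    )
    total = df["importance"].sum()
    if total > 0:
        df["importance"] = df["importance"] / total
    df = df.sort_values("importance", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    per_position = df.groupby("position")["importance"].sum().sort_values(
        ascending=False, kind="mergesort"
    )
    return df, per_position


# ---------------------------------------------------------------------------
# Persistence


def save_bundle(bundle: RegressorBundle, directory: str | Path) -> None:
    """Versioned directory: JSON metadata + opaque fitted-state blobs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "kind": bundle.kind,
        "reference": bundle.reference.bases,
        "seed": bundle.seed,
        "train_fingerprint": bundle.train_fingerprint,
        "clip_predictions": bundle.clip_predictions,
        "hyperparameters": json.loads(json.dumps(bundle.hyperparameters, default=str)),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    if bundle.sk_model is not None:
        joblib.dump(bundle.sk_model, directory / "model.joblib")
    if bundle.lstm is not None:
        bundle.lstm.save(directory / "lstm.npz")


def load_bundle(directory: str | Path) -> RegressorBundle:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    lstm = None
    if (directory / "lstm.npz").exists():
        lstm = LSTMRegressor.load(directory / "lstm.npz")
    return RegressorBundle(
        kind=meta["kind"],
        reference=ReferenceSequence(meta["reference"]),
        seed=meta["seed"],
        train_fingerprint=meta["train_fingerprint"],
        sk_model=joblib.load(directory / "model.joblib"),
        lstm=lstm,
        clip_predictions=meta.get("clip_predictions", False),
        hyperparameters=meta.get("hyperparameters", {}),
    )
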