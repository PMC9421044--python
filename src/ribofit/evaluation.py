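"""Experiment harness: mutational-distance splits, cumulative training, subsampling, metrics.

The central design mirrors deep-mutational-scanning extrapolation studies:
genotypes are binned by mutational distance (order) from the wild-type; 20%
of each bin is held out for testing, except orders 1 and 2 which go entirely
to training; training sets are cumulative (all bins up to a maximum order);
and optionally subsampled to measure how little data suffices. The same
persisted split is reused for every model so all models see byte-identical
test sets.

All randomness flows from one base seed through a documented derivation
(SHA-256 of the base seed plus a purpose tag), so a single integer
reproduces an entire run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lstm import LSTMConfig
from .models import (
    EncodedDataset,
    RegressorBundle,
    encode_dataset,
    predict,
    train_model,
)
from .reads import ActivityTable


def derive_seed(base_seed: int, *tags) -> int:
    """Deterministic child seed: SHA-256 of the base seed and purpose tags."""
    h = hashlib.sha256()
    h.update(str(int(base_seed)).encode())
    for t in tags:
        h.update(b"|")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class BinnedSplit:
    """Per-order train/test genotype label sets from one seeded draw."""

    train: dict[int, list[str]]
    test: dict[int, list[str]]
    test_fraction: float
    seed: int
    forced_train_orders: tuple[int, ...] = (0, 1, 2)

    def training_labels(self, max_order: int | None = None) -> list[str]:
        orders = sorted(self.train)
        if max_order is not None:
            orders = [o for o in orders if o <= max_order]
        return [lab for o in orders for lab in self.train[o]]

    def test_labels(self, order: int) -> list[str]:
        return list(self.test.get(order, []))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "test_fraction": self.test_fraction,
                    "seed": self.seed,
                    "forced_train_orders": list(self.forced_train_orders),
                    "train": {str(k): v for k, v in self.train.items()},
                    "test": {str(k): v for k, v in self.test.items()},
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BinnedSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            train={int(k): v for k, v in d["train"].items()},
            test={int(k): v for k, v in d["test"].items()},
            test_fraction=d["test_fraction"],
            seed=d["seed"],
            forced_train_orders=tuple(d["forced_train_orders"]),
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_by_order(
    table: ActivityTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    forced_train_orders: tuple[int, ...] = (0, 1, 2),
) -> BinnedSplit:
    """Per-bin random holdout; orders in ``forced_train_orders`` train in full.

    Per-bin test size is round-half-up(test_fraction * bin size). Bins too
    small to split (fewer than 2 rows) go entirely to training with a warning.
    Rows with missing activity are ignored.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    df = table.data.dropna(subset=["fraction_cleaved"])
    rng = np.random.default_rng(seed)
    train: dict[int, list[str]] = {}
    test: dict[int, list[str]] = {}
    for order, group in df.groupby("order"):
        labels = sorted(group["genotype"])
        if order in forced_train_orders or test_fraction == 0.0:
            train[int(order)] = labels
            test[int(order)] = []
            continue
        if len(labels) < 2:
            warnings.warn(
                f"order-{order} bin has {len(labels)} row(s); assigning all to training"
            )
            train[int(order)] = labels
            test[int(order)] = []
            continue
        n_test = _round_half_up(test_fraction * len(labels))
        n_test = min(n_test, len(labels) - 1)
        chosen = rng.choice(len(labels), size=n_test, replace=False)
        mask = np.zeros(len(labels), dtype=bool)
        mask[chosen] = True
        test[int(order)] = [lab for lab, m in zip(labels, mask) if m]
        train[int(order)] = [lab for lab, m in zip(labels, mask) if not m]
    return BinnedSplit(train, test, test_fraction, seed, forced_train_orders)


def table1_counts(split: BinnedSplit) -> pd.DataFrame:
    """Per-order train/test counts in the standard accounting layout.

    Orders fully forced into training display an em dash in the Testing
    column; the wild-type row (order 0) is omitted from the display just as
    it is from the usual accounting.
    """
    rows = []
    orders = sorted(set(split.train) | set(split.test))
    for o in orders:
        if o == 0:
            continue
        n_test = len(split.test.get(o, []))
        rows.append(
            {
                "No. of mutations": o,
                "Training": len(split.train.get(o, [])),
                "Testing": "—" if (o in split.forced_train_orders and n_test == 0) else n_test,
            }
        )
    return pd.DataFrame(rows, columns=["No. of mutations", "Training", "Testing"])


# ---------------------------------------------------------------------------
# Training-set construction


def build_cumulative_training(
    split: BinnedSplit,
    table: ActivityTable,
    max_order: int,
    include_wildtype: bool = True,
) -> EncodedDataset:
    """Union of the training portions of orders 1..max_order (plus wild-type)."""
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    available = max(o for o in split.train if split.train[o]) if split.train else 0
    if max_order > available:
        warnings.warn(
            f"max_order {max_order} exceeds available orders; clamping to {available}"
        )
        max_order = available
    labels = []
    if include_wildtype and 0 in split.train:
        labels.extend(split.train[0])
    for o in sorted(split.train):
        if 1 <= o <= max_order:
            labels.extend(split.train[o])
    return encode_dataset(table, labels)


def subsample_training(
    data: EncodedDataset, fraction: float, seed: int = 0
) -> EncodedDataset:
    """Uniform sample without replacement of round-half-up(fraction * n) rows."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(data)
    if fraction == 1.0:
        return data
    k = _round_half_up(fraction * n)
    if k < 2:
        raise ValueError(f"subsample of {k} row(s) is too small to train on")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return data.subset(idx)


@dataclass(frozen=True)
class SubsampleSpec:
    """Training-set reduction design: fractions and per-fraction replicates."""

    fractions: tuple[float, ...] = (0.6, 0.4, 0.2, 0.1, 0.01)
    smallest_fraction_replicates: int = 5
    default_replicates: int = 1

    def __post_init__(self) -> None:
        if any(not 0.0 < f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must be in (0, 1]")
        if min(self.smallest_fraction_replicates, self.default_replicates) < 1:
            raise ValueError("replicates must be >= 1")

    def replicates_for(self, fraction: float) -> int:
        if self.fractions and fraction == min(self.fractions):
            return self.smallest_fraction_replicates
        return self.default_replicates


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(predicted: Sequence[float], observed: Sequence[float]) -> dict:
    """Pearson r, R^2 (both conventions), and MSE of predictions vs observations.

    ``r_squared`` is the square of Pearson r; ``r_squared_cod`` is the
    coefficient of determination 1 - SS_res/SS_tot. r is NaN (flagged) when
    either vector has zero variance.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D vectors")
    if len(p) < 2:
        raise ValueError("need at least two pairs")
    mse = float(np.mean((p - o) ** 2))
    degenerate = bool(np.ptp(p) == 0 or np.ptp(o) == 0)
    if degenerate:
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, o).statistic)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    cod = float("nan") if ss_tot == 0 else 1.0 - float(np.sum((p - o) ** 2)) / ss_tot
    return {
        "pearson_r": r,
        "r_squared": r**2 if not np.isnan(r) else float("nan"),
        "r_squared_cod": cod,
        "mse": mse,
        "n_test": int(len(p)),
        "degenerate_variance": degenerate,
    }


# ---------------------------------------------------------------------------
# The full factorial experiment


def run_prediction_experiment(
    table: ActivityTable,
    model_kinds: Sequence[str] = ("random_forest",),
    max_orders: Sequence[int] = (2,),
    test_orders: Sequence[int] | None = None,
    subsample_spec: SubsampleSpec | None = None,
    base_seed: int = 0,
    test_fraction: float = 0.2,
    lstm_cfg: LSTMConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Factorial run over (model kind x max training order x test bin x subsample).

    One split (derived from the base seed) is persisted and reused for every
    cell, so test sets are identical across models and training conditions.
    Returns the metrics table; with ``out_dir`` also writes the split, the
    Table-1-style accounting, per-cell prediction TSVs, and the metrics TSV.
    """
    split = split_by_order(table, test_fraction, derive_seed(base_seed, "split"))
    if test_orders is None:
        test_orders = sorted(o for o in split.test if split.test[o])
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        split.to_json(out_path / "split.json")
        table1_counts(split).to_csv(out_path / "table1_counts.tsv", sep="\t", index=False)

    records = []
    fractions: list[float | None]
    for kind in model_kinds:
        for max_order in max_orders:
            full_train = build_cumulative_training(split, table, max_order)
            if subsample_spec is None:
                cells: list[tuple[float, int, EncodedDataset]] = [(1.0, 0, full_train)]
            else:
                cells = []
                for frac in subsample_spec.fractions:
                    for rep in range(subsample_spec.replicates_for(frac)):
                        sub = subsample_training(
                            full_train,
                            frac,
                            derive_seed(base_seed, "subsample", max_order, frac, rep),
                        )
                        cells.append((frac, rep, sub))
            for frac, rep, train_data in cells:
                seed = derive_seed(base_seed, "model", kind, max_order, frac, rep)
                try:
                    bundle = train_model(train_data, kind, seed, lstm_cfg)
                except Exception as exc:  # record, continue the factorial
                    records.append(
                        {
                            "model": kind,
                            "max_train_order": max_order,
                            "subsample_fraction": frac,
                            "replicate": rep,
                            "test_order": None,
                            "error": str(exc),
                        }
                    )
                    continue
                for test_order in test_orders:
                    labels = split.test_labels(test_order)
                    if len(labels) < 2:
                        continue
                    test_data = encode_dataset(table, labels)
                    preds = predict(bundle, test_data.keys)
                    m = compute_metrics(preds, test_data.targets)
                    rec = {
                        "model": kind,
                        "max_train_order": max_order,
                        "subsample_fraction": frac,
                        "replicate": rep,
                        "n_train": len(train_data),
                        "test_order": test_order,
                        "train_fingerprint": bundle.train_fingerprint,
                        "seed": seed,
                        "error": "",
                        **{k: v for k, v in m.items() if k != "degenerate_variance"},
                    }
                    records.append(rec)
                    if out_path is not None:
                        cell = (
                            f"pred_{kind}_max{max_order}_f{frac}_rep{rep}_test{test_order}.tsv"
                        )
                        pd.DataFrame(
                            {
                                "genotype": test_data.keys,
                                "predicted": preds,
                                "observed": test_data.targets,
                            }
                        ).to_csv(out_path / cell, sep="\t", index=False)
    metrics = pd.DataFrame(records)
    if out_path is not None:
        metrics.to_csv(out_path / "metrics.tsv", sep="\t", index=False)
    return metrics
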