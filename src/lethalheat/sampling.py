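"""Leakage-safe chronological splitting and class-imbalance correction.

The split keeps geography balanced while avoiding temporal leakage: within
every region the most recent events form the test set, and a seeded
unstratified sample of the remainder forms the validation set, giving an
80/10/10 train/validation/test split overall. Resampling (random majority
downsampling or SMOTE) is applied to the training partition only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SplitAssignment",
    "ResampleSpec",
    "temporal_split",
    "downsample_majority",
    "smote",
    "apply_resampling",
]


@dataclass
class SplitAssignment:
    """Partition of events into train/validation/test.

    ``assignment`` maps event_id → partition name; ``split_dates`` records,
    per region, the last training-era date and the first test date.
    """

    assignment: pd.Series
    region_key: str
    split_dates: pd.DataFrame

    def partition_ids(self, name: str) -> pd.Index:
        if name not in {"train", "validation", "test"}:
            raise ValueError(f"unknown partition {name!r}")
        return self.assignment.index[self.assignment == name]

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.rename("partition").rename_axis("event_id").reset_index()


@dataclass
class ResampleSpec:
    """Training-set rebalancing strategy: 'none', 'downsample' or 'smote'."""

    strategy: str = "smote"
    downsample_keep_fraction: float = 0.25
    smote_k: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in {"none", "downsample", "smote"}:
            raise ValueError(f"unknown resampling strategy {self.strategy!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.strategy == "downsample" and not 0.0 < self.downsample_keep_fraction <= 1.0:
            raise ValueError("downsample_keep_fraction must lie in (0, 1]")


def temporal_split(
    events: pd.DataFrame,
    test_frac: float = 0.10,
    val_frac: float = 0.10,
    region_key: str = "city_id",
    seed: int = 0,
) -> SplitAssignment:
    """Chronological split per region.

    Within each region, events are sorted by start date and the latest
    ⌈test_frac·count⌉ become the test set; a seeded unstratified sample of
    val_frac/(1 − test_frac) of the remainder becomes the validation set.
    Regions with fewer than 3 events go entirely to training (with a
    warning): too few events to reserve a held-out tail.
    """
    required = {region_key, "start_date", "event_id"}
    if not required.issubset(events.columns):
        raise ValueError(f"events frame must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    val_share = val_frac / (1.0 - test_frac)

    parts: dict[str, str] = {}
    date_rows = []
    for region, grp in events.groupby(region_key, sort=True):
        grp = grp.sort_values(["start_date", "event_id"])
        ids = grp["event_id"].to_numpy()
        n = len(ids)
        if n < 3:
            warnings.warn(
                f"region {region!r} has only {n} event(s); assigning all to train",
                stacklevel=2,
            )
            for eid in ids:
                parts[eid] = "train"
            continue
        n_test = math.ceil(test_frac * n)
        test_ids = ids[n - n_test :]
        rest = ids[: n - n_test]
        n_val = int(round(val_share * len(rest)))
        val_ids = rng.choice(rest, size=n_val, replace=False) if n_val else np.array([])
        val_set = set(val_ids.tolist())
        for eid in rest:
            parts[eid] = "validation" if eid in val_set else "train"
        for eid in test_ids:
            parts[eid] = "test"
        dates = pd.to_datetime(grp["start_date"])
        date_rows.append(
            {
                "region": region,
                "last_train_date": dates.iloc[n - n_test - 1],
                "first_test_date": dates.iloc[n - n_test],
            }
        )

    assignment = pd.Series(parts, name="partition").reindex(events["event_id"])
    assignment.index.name = "event_id"
    return SplitAssignment(
        assignment=assignment,
        region_key=region_key,
        split_dates=pd.DataFrame(date_rows),
    )


def downsample_majority(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    keep_fraction: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Retain all minority (label 1) rows and a seeded uniform sample of
    ``keep_fraction`` of the majority rows."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    labels = pd.Series(np.asarray(labels), index=features.index)
    maj_idx = features.index[labels == 0]
    min_idx = features.index[labels == 1]
    n_keep = int(round(keep_fraction * len(maj_idx)))
    rng = np.random.default_rng(seed)
    kept = rng.choice(len(maj_idx), size=n_keep, replace=False)
    keep_index = min_idx.append(maj_idx[np.sort(kept)])
    keep_index = features.index[features.index.isin(set(keep_index))]  # original order
    return features.loc[keep_index], labels.loc[keep_index]


def smote(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic Minority Over-sampling Technique.

    New minority points are x_i + u·(x_nn − x_i) with u ~ Uniform(0, 1)
    and x_nn one of the k Euclidean nearest minority neighbours of x_i.
    Because the features mix °C, % and kg/m², the neighbour search runs in
    per-feature standardized space (statistics from the supplied training
    data); the convex interpolation itself commutes with that affine map,
    so synthetic points live in the original feature space. Originals are
    returned untouched, synthetic rows appended with ids ``smote<No.>``.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    X_min = features.loc[labels == 1]
    n_min, n_maj = len(X_min), int((labels == 0).sum())
    if n_min <= k:
        raise ValueError(
            f"SMOTE needs more minority samples ({n_min}) than neighbours k={k}; "
            "use a smaller k"
        )
    n_target = int(round(target_ratio * n_maj))
    n_new = n_target - n_min
    if n_new <= 0:
        return features.copy(), labels.copy()

    mu = features.mean(axis=0).to_numpy()
    sd = features.std(axis=0, ddof=0).to_numpy()
    sd[sd == 0.0] = 1.0
    Z_min = (X_min.to_numpy(dtype=float) - mu) / sd

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z_min)
    neigh = nn.kneighbors(Z_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = neigh[base, rng.integers(0, k, size=n_new)]
    u = rng.random((n_new, 1))
    X_min_arr = X_min.to_numpy(dtype=float)
    synth = X_min_arr[base] + u * (X_min_arr[pick] - X_min_arr[base])

    synth_df = pd.DataFrame(
        synth,
        columns=features.columns,
        index=pd.Index([f"smote{i:06d}" for i in range(n_new)], name=features.index.name),
    )
    X_out = pd.concat([features, synth_df])
    y_out = pd.concat(
        [labels, pd.Series(1, index=synth_df.index, dtype=labels.dtype)]
    )
    return X_out, y_out


def apply_resampling(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    spec: ResampleSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Dispatch on the configured strategy (training partition only)."""
    labels = pd.Series(np.asarray(labels), index=features.index)
    if spec.strategy == "none":
        return features.copy(), labels.copy()
    if spec.strategy == "downsample":
        return downsample_majority(
            features, labels, spec.downsample_keep_fraction, seed=spec.seed
        )
    return smote(
        features, labels, k=spec.smote_k, target_ratio=spec.target_ratio, seed=spec.seed
    )
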