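"""Minority oversampling (SMOTE) combined with Tomek-link cleaning.

SMOTE synthesizes minority-class rows by convex interpolation between a
minority row and one of its k nearest minority neighbours; categorical
columns are copied from the anchor row rather than interpolated.  After
oversampling to parity, Tomek links (mutual nearest-neighbour pairs with
opposite labels) are identified and the majority member of each link is
removed; removal is iterated until no links remain, so the cleaned set is
link-free by construction.

Distances are computed on a standardized design: continuous columns are
z-scored and categorical columns one-hot coded with weight 1/sqrt(2), so a
category mismatch contributes unit squared distance.  Balancing is meant to
be applied to training rows only — never to validation or external rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


def _encode_for_distance(table: pd.DataFrame, feature_cols: list[str],
                         categorical_cols: list[str]) -> np.ndarray:
    blocks = []
    for col in feature_cols:
        vals = table[col].to_numpy(dtype=float)
        if col in categorical_cols:
            levels = np.unique(vals)
            onehot = (vals[:, None] == levels[None, :]).astype(float)
            blocks.append(onehot / np.sqrt(2.0))
        else:
            sd = vals.std()
            blocks.append(((vals - vals.mean()) / sd if sd > 1e-12
                           else np.zeros_like(vals))[:, None])
    return np.hstack(blocks)


def _smote(table: pd.DataFrame, y: np.ndarray, feature_cols: list[str],
           categorical_cols: list[str], k_neighbors: int,
           rng: np.random.Generator) -> pd.DataFrame:
    counts = pd.Series(y).value_counts()
    minority, majority = counts.idxmin(), counts.idxmax()
    n_new = int(counts[majority] - counts[minority])
    if n_new == 0:
        return table.iloc[0:0].copy()
    min_rows = table[y == minority].reset_index(drop=True)
    if len(min_rows) <= k_neighbors:
        raise ValueError(
            f"minority count {len(min_rows)} must exceed k_neighbors={k_neighbors}")
    X_min = _encode_for_distance(min_rows, feature_cols, categorical_cols)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, nbr = nn.kneighbors(X_min)
    nbr = nbr[:, 1:]  # drop self

    anchors = rng.integers(len(min_rows), size=n_new)
    picks = nbr[anchors, rng.integers(k_neighbors, size=n_new)]
    gammas = rng.random(n_new)

    synth = min_rows.iloc[anchors].reset_index(drop=True).copy()
    for col in feature_cols:
        if col not in categorical_cols:
            a = min_rows[col].to_numpy(dtype=float)[anchors]
            b = min_rows[col].to_numpy(dtype=float)[picks]
            synth[col] = a + gammas * (b - a)
    # categorical (and all non-feature) columns stay copied from the anchor
    if "patient_id" in synth.columns:
        synth["patient_id"] = [f"SYN{i:05d}" for i in range(n_new)]
    return synth


def find_tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Indices (i, j) of mutual-1NN pairs with opposite labels, i < j."""
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, nbr = nn.kneighbors(X)
    first = nbr[:, 1]
    links = []
    for i, j in enumerate(first):
        if i < j and first[j] == i and y[i] != y[j]:
            links.append((i, int(j)))
    return links


def smote_tomek(table: pd.DataFrame, outcome_col: str = "vpi",
                feature_cols: list[str] | None = None,
                categorical_cols: list[str] | None = None,
                k_neighbors: int = 5, seed: int = 0) -> pd.DataFrame:
    """Balance a training table by SMOTE oversampling then Tomek cleaning."""
    from .cohorts import ALL_FEATURES, CATEGORICAL_FEATURES

    if feature_cols is None:
        feature_cols = [c for c in ALL_FEATURES if c in table.columns]
    if categorical_cols is None:
        categorical_cols = [c for c in CATEGORICAL_FEATURES if c in feature_cols]
    y = table[outcome_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for balancing")
    rng = np.random.default_rng(seed)

    synth = _smote(table, y, feature_cols, categorical_cols, k_neighbors, rng)
    combined = pd.concat([table, synth], ignore_index=True)

    majority = pd.Series(y).value_counts().idxmax()
    while True:
        yc = combined[outcome_col].to_numpy()
        Xc = _encode_for_distance(combined, feature_cols, categorical_cols)
        links = find_tomek_links(Xc, yc)
        drop = {i if yc[i] == majority else j for i, j in links
                if majority in (yc[i], yc[j])}
        if not drop:
            break
        combined = combined.drop(index=list(drop)).reset_index(drop=True)
    return combined
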