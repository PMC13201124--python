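"""K-means partitioning of in-mask voxels into radiomic subregions.

The cluster count is fixed a priori (default nc = 6) rather than tuned per
dataset; for tiny or homogeneous lesions with fewer distinct feature rows
than nc, k is reduced so k-means remains well posed, and the obtained
cluster count is reported as ``nc_effective``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .features import LocalFeatureMap


@dataclass
class SubregionLabelMap:
    """Integer label volume: 0 = background, 1..nc_effective inside the mask."""

    labels: np.ndarray
    nc_requested: int
    nc_effective: int
    dimensionality: str = "3d"
    provenance: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def labels_from_array(arr: np.ndarray, nc_requested: int | None = None,
                      **provenance) -> SubregionLabelMap:
    """Wrap a plain integer array (0 = background) as a SubregionLabelMap."""
    arr = np.asarray(arr)
    present = np.unique(arr[arr > 0])
    return SubregionLabelMap(
        labels=arr.astype(np.int32),
        nc_requested=nc_requested if nc_requested is not None else len(present),
        nc_effective=len(present),
        dimensionality="2d" if arr.ndim == 2 else "3d",
        provenance=provenance,
    )


def cluster_voxels(fmap: LocalFeatureMap, nc: int = 6, seed: int = 42,
                   n_init: int = 10, max_iter: int = 300,
                   tol: float = 1e-4) -> SubregionLabelMap:
    """Cluster the normalized feature rows and materialise the label map.

    k = min(nc, number of distinct feature rows); k-means++ initialisation
    with ``n_init`` restarts and a fixed seed makes the labels reproducible.
    Empty clusters are removed and labels compacted to 1..nc_effective.
    """
    if nc < 1:
        raise ValueError("nc must be >= 1")
    X = fmap.values
    if X.shape[0] < 1:
        raise ValueError("feature map has no rows")
    n_distinct = len(np.unique(X, axis=0))
    k = min(nc, n_distinct)
    if k == 1:
        assign = np.zeros(X.shape[0], dtype=int)
        inertia, n_iter = 0.0, 0
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    max_iter=max_iter, tol=tol, random_state=seed)
        assign = km.fit_predict(X)
        inertia, n_iter = float(km.inertia_), int(km.n_iter_)
    # compact to 1..nc_effective preserving cluster-index order
    present = np.unique(assign)
    remap = {old: new for new, old in enumerate(present, start=1)}
    compact = np.array([remap[a] for a in assign], dtype=np.int32)
    vol = np.zeros(fmap.grid_shape, dtype=np.int32)
    vol[tuple(fmap.coords.T)] = compact
    return SubregionLabelMap(
        labels=vol,
        nc_requested=nc,
        nc_effective=len(present),
        dimensionality=fmap.dimensionality,
        provenance={"seed": seed, "n_init": n_init, "inertia": inertia,
                    "n_iter": n_iter, "n_distinct_rows": int(n_distinct)},
    )
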