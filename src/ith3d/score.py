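"""Connected-component analysis of subregion label maps and the ITH scores.

The ITH (intratumoral heterogeneity) score measures how fragmented the
clustered subregions of a lesion are.  For a label map with clusters
l = 1..nc, total in-mask size ``N`` (pixels in 2D, voxels in 3D), largest
connected component size ``max_l`` and component count ``n_l`` per cluster,

    score = 1 - (1/N) * sum_l (max_l / n_l)

The score lies in [0, 1) and is exactly 0 iff every cluster forms a single
connected component.  2D components use 8-connectivity (the planar analogue
of the 3D rule), 3D components use 26-connectivity (face, edge and corner
neighbours); both are configurable.  Sizes are raw pixel/voxel counts, so
the score is invariant under uniform voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CTLesion, crop_to_mask, largest_axial_slice
from .features import extract_local_features, normalize_features
from .clustering import SubregionLabelMap, cluster_voxels

#: connectivity name -> (ndim, neighbourhood rank passed to scipy)
_CONNECTIVITY = {
    "4_2d": (2, 1),
    "8_2d": (2, 2),
    "6_3d": (3, 1),
    "18_3d": (3, 2),
    "26_3d": (3, 3),
}


def _structure(labels: np.ndarray, connectivity: str | None) -> np.ndarray:
    ndim = labels.ndim
    if connectivity is None:
        connectivity = "8_2d" if ndim == 2 else "26_3d"
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"unknown connectivity {connectivity!r}; "
                         f"one of {sorted(_CONNECTIVITY)}")
    cdim, rank = _CONNECTIVITY[connectivity]
    if cdim != ndim:
        raise ValueError(f"connectivity {connectivity!r} does not match a {ndim}D map")
    return ndimage.generate_binary_structure(ndim, rank)


@dataclass
class ClusterComponents:
    """Per-cluster connectivity statistics (n_l / m_l, S_l,max / V_l,max)."""

    label: int
    total_size: int
    n_components: int
    largest_size: int


@dataclass
class ITHResult:
    """Scalar 2D/3D ITH scores with a full per-cluster audit trail."""

    score_2d: float
    score_3d: float
    components_2d: list[ClusterComponents]
    components_3d: list[ClusterComponents]
    total_2d: int
    total_3d: int
    nc_effective_2d: int
    nc_effective_3d: int
    slice_index: int
    connectivity_2d: str = "8_2d"
    connectivity_3d: str = "26_3d"
    seed: int = 42
    provenance: dict = field(default_factory=dict)


def connected_components(labels, connectivity: str | None = None) -> list[ClusterComponents]:
    """Component count and largest-component size for every cluster label.

    ``labels`` may be a :class:`SubregionLabelMap` or a plain integer array
    with 0 = background.  Components are computed independently per label.
    """
    arr = labels.labels if isinstance(labels, SubregionLabelMap) else np.asarray(labels)
    if arr.size == 0 or not (arr > 0).any():
        raise ValueError("label map is empty")
    structure = _structure(arr, connectivity)
    out = []
    for lab in np.unique(arr[arr > 0]):
        binary = arr == lab
        comp, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(comp.ravel())[1:]
        out.append(ClusterComponents(
            label=int(lab),
            total_size=int(binary.sum()),
            n_components=int(n),
            largest_size=int(sizes.max()),
        ))
    return out


def ith_score_from_labels(labels, connectivity: str | None = None) -> float:
    """Evaluate the ITH dispersion score on a subregion label map."""
    import math

    comps = connected_components(labels, connectivity)
    total = sum(c.total_size for c in comps)
    # fsum: correctly rounded, so the score is exactly invariant under any
    # relabeling (summation-order independent)
    return 1.0 - math.fsum(c.largest_size / c.n_components for c in comps) / total


@dataclass
class ITHConfig:
    """Knobs of the end-to-end scoring chain."""

    nc: int = 6                     # predefined cluster number
    seed: int = 42
    bin_width: float = 25.0         # HU, discretisation of window intensities
    connectivity_2d: str = "8_2d"
    connectivity_3d: str = "26_3d"
    margin: int = 1                 # crop margin in voxels


def _score_path(image, mask, window, nc, seed, bin_width, connectivity):
    import math

    from .clustering import labels_from_array

    fmap = extract_local_features(image, mask, window=window, bin_width=bin_width)
    try:
        fmap = normalize_features(fmap)
    except ValueError:
        # perfectly homogeneous lesion: every local descriptor is constant,
        # so there is exactly one subregion and the dispersion is zero
        labmap = labels_from_array(mask.astype(np.int32), nc_requested=nc,
                                   degenerate="homogeneous")
    else:
        labmap = cluster_voxels(fmap, nc=nc, seed=seed)
    comps = connected_components(labmap, connectivity)
    total = sum(c.total_size for c in comps)
    score = 1.0 - math.fsum(c.largest_size / c.n_components for c in comps) / total
    return score, comps, total, labmap


def compute_ith(lesion: CTLesion, config: ITHConfig | None = None) -> ITHResult:
    """Run the full scoring chain on one lesion and return both scores.

    The chain runs twice: the largest-axial-slice path (2x2 window,
    8-connectivity) yields ``score_2d``; the whole-volume path (2x2x2
    window, 26-connectivity) yields ``score_3d``.  Deterministic for a
    fixed seed.
    """
    cfg = config or ITHConfig()
    cropped = crop_to_mask(lesion, margin=cfg.margin)

    sl_img, sl_mask, idx = largest_axial_slice(cropped)
    s2d, comps2d, tot2d, lab2d = _score_path(
        sl_img, sl_mask, (2, 2), cfg.nc, cfg.seed, cfg.bin_width, cfg.connectivity_2d)
    s3d, comps3d, tot3d, lab3d = _score_path(
        cropped.image, cropped.mask, (2, 2, 2), cfg.nc, cfg.seed, cfg.bin_width,
        cfg.connectivity_3d)

    return ITHResult(
        score_2d=float(s2d),
        score_3d=float(s3d),
        components_2d=comps2d,
        components_3d=comps3d,
        total_2d=tot2d,
        total_3d=tot3d,
        nc_effective_2d=lab2d.nc_effective,
        nc_effective_3d=lab3d.nc_effective,
        slice_index=idx,
        connectivity_2d=cfg.connectivity_2d,
        connectivity_3d=cfg.connectivity_3d,
        seed=cfg.seed,
        provenance={"lesion_id": lesion.lesion_id, "nc": cfg.nc,
                    "bin_width": cfg.bin_width},
    )
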