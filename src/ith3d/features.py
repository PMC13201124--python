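"""Per-voxel local radiomic descriptors from small sliding windows.

Every in-mask voxel is described by the intensity pattern of the 2x2 (2D)
or 2x2x2 (3D) window anchored with that voxel at its minimum corner
(even-sized windows have no centre voxel; anchoring at the corner gives a
deterministic, mask-complete assignment).  Windows that would protrude past
the crop are served by edge-replication padding.

Feature classes: first-order statistics plus the gray-level texture-matrix
families (co-occurrence GLCM, run length GLRLM, size zone GLSZM, dependence
GLDM, neighbouring gray tone difference NGTDM).  Window intensities are
discretised with a fixed bin width (default 25 HU) relative to the window
minimum, so adding a constant to all intensities leaves texture features
unchanged.  Shape descriptors are computed once per lesion and kept out of
the per-voxel matrix — the shape of a 2-wide window is constant and carries
no information.

A 2-voxel-wide window has the useful property that *all* of its voxels are
mutually adjacent under 8-/26-connectivity (Chebyshev distance 1), which
lets every texture matrix be evaluated in closed form over the window's
voxel pairs.  All features are therefore computed fully vectorised over
windows; no per-window Python loop is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

_EPS = 1e-12
_COARSENESS_CAP = 1e6  # conventional cap for flat neighbourhoods

ALL_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


class FeatureConfigError(ValueError):
    """Unknown feature class or invalid extraction configuration."""


@dataclass
class LocalFeatureMap:
    """Matrix of local descriptors for the in-mask voxels of one lesion.

    Rows follow ``coords`` (C-order scan of the mask); columns follow
    ``feature_names``.  After :func:`normalize_features` each retained
    column has zero mean and unit variance over rows, constant columns are
    dropped, and ``normalization`` records the per-feature location/scale.
    """

    coords: np.ndarray
    values: np.ndarray
    feature_names: list[str]
    grid_shape: tuple[int, ...]
    dimensionality: str  # "2d" | "3d"
    normalization: dict | None = None
    shape_features: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# window geometry
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _geometry(shape: tuple[int, ...]):
    """Pairwise structure of a small window where all voxels are adjacent."""
    positions = np.array(list(np.ndindex(shape)))
    n = len(positions)
    i_idx, j_idx = np.triu_indices(n, k=1)
    disps = positions[j_idx] - positions[i_idx]
    n_directions = len({tuple(d) for d in disps})
    n_pairs = len(i_idx)
    total_singles = n_directions * n - 2 * n_pairs
    assert total_singles % n == 0
    return {
        "n": n,
        "i_idx": i_idx,
        "j_idx": j_idx,
        "n_directions": n_directions,
        "n_pairs": n_pairs,
        "singles_per_voxel": total_singles // n,
    }


# ---------------------------------------------------------------------------
# grouped (per-row histogram) reductions
# ---------------------------------------------------------------------------

def _row_groups(codes: np.ndarray, weights: np.ndarray | None = None):
    """Group equal integer codes within each row of ``codes``.

    Returns flat arrays ``(row, value, gsum)``: for every distinct code in
    every row, the row index, the code value and the summed weight.
    """
    N, K = codes.shape
    order = np.argsort(codes, axis=1, kind="stable")
    c = np.take_along_axis(codes, order, axis=1)
    if weights is None:
        w = np.ones(c.shape, dtype=np.float64)
    else:
        w = np.take_along_axis(weights, order, axis=1)
    base = np.int64(c.max()) + 1
    flat = c.ravel().astype(np.int64) + np.repeat(
        np.arange(N, dtype=np.int64) * base, K)
    starts = np.flatnonzero(np.concatenate(([True], flat[1:] != flat[:-1])))
    gsum = np.add.reduceat(w.ravel(), starts)
    row = starts // K
    value = c.ravel()[starts]
    return row, value.astype(np.float64), gsum


def _rowsum(row, x, n_rows):
    out = np.zeros(n_rows)
    np.add.at(out, row, x)
    return out


def _group_entropy(row, gsum, totals, n_rows):
    p = gsum / totals[row]
    good = p > 0
    return _rowsum(row[good], -p[good] * np.log2(p[good]), n_rows)


def _group_max(row, gsum, n_rows):
    out = np.zeros(n_rows)
    np.maximum.at(out, row, gsum)
    return out


# ---------------------------------------------------------------------------
# feature classes (each returns dict name -> (N,) array)
# ---------------------------------------------------------------------------

def _firstorder(W, G, geom):
    n = geom["n"]
    mu = W.mean(axis=1)
    var = W.var(axis=1)
    sd = np.sqrt(var)
    centred = W - mu[:, None]
    safe = np.maximum(sd, _EPS)
    skew = np.where(sd > _EPS, (centred ** 3).mean(axis=1) / safe ** 3, 0.0)
    kurt = np.where(sd > _EPS, (centred ** 4).mean(axis=1) / safe ** 4, 0.0)
    p10, p25, p50, p75, p90 = np.percentile(W, [10, 25, 50, 75, 90], axis=1)
    row, _, gsum = _row_groups(G)
    totals = np.full(W.shape[0], float(n))
    N = W.shape[0]
    return {
        "firstorder_mean": mu,
        "firstorder_median": p50,
        "firstorder_minimum": W.min(axis=1),
        "firstorder_maximum": W.max(axis=1),
        "firstorder_range": W.max(axis=1) - W.min(axis=1),
        "firstorder_variance": var,
        "firstorder_skewness": skew,
        "firstorder_kurtosis": kurt,
        "firstorder_energy": (W ** 2).sum(axis=1),
        "firstorder_rms": np.sqrt((W ** 2).mean(axis=1)),
        "firstorder_mad": np.abs(centred).mean(axis=1),
        "firstorder_iqr": p75 - p25,
        "firstorder_p10": p10,
        "firstorder_p90": p90,
        "firstorder_entropy": _group_entropy(row, gsum, totals, N),
        "firstorder_uniformity": _rowsum(row, (gsum / n) ** 2, N),
    }


def _glcm(W, G, geom):
    i_idx, j_idx = geom["i_idx"], geom["j_idx"]
    A = G[:, i_idx].astype(np.float64)
    B = G[:, j_idx].astype(np.float64)
    Pa = np.concatenate([A, B], axis=1)  # symmetric, ordered pairs
    Pb = np.concatenate([B, A], axis=1)
    diff = Pa - Pb
    absdiff = np.abs(diff)
    mu = Pa.mean(axis=1)
    var = ((Pa - mu[:, None]) ** 2).mean(axis=1)
    autocorr = (Pa * Pb).mean(axis=1)
    corr = np.where(var > _EPS, (autocorr - mu ** 2) / np.maximum(var, _EPS), 0.0)
    spread = Pa + Pb - 2 * mu[:, None]
    M = np.int64(G.max()) + 1
    codes = (G[:, i_idx].astype(np.int64) * M + G[:, j_idx])
    codes = np.concatenate([codes, G[:, j_idx].astype(np.int64) * M + G[:, i_idx]], axis=1)
    row, _, gsum = _row_groups(codes)
    N, K = Pa.shape
    p = gsum / K
    return {
        "glcm_contrast": (diff ** 2).mean(axis=1),
        "glcm_dissimilarity": absdiff.mean(axis=1),
        "glcm_inverse_difference": (1.0 / (1.0 + absdiff)).mean(axis=1),
        "glcm_idm": (1.0 / (1.0 + diff ** 2)).mean(axis=1),
        "glcm_correlation": corr,
        "glcm_joint_average": mu,
        "glcm_autocorrelation": autocorr,
        "glcm_cluster_shade": (spread ** 3).mean(axis=1),
        "glcm_cluster_prominence": (spread ** 4).mean(axis=1),
        "glcm_joint_energy": _rowsum(row, p ** 2, N),
        "glcm_joint_entropy": _group_entropy(row, gsum, np.full(N, float(K)), N),
        "glcm_max_probability": _group_max(row, p, N),
    }


def _glrlm(W, G, geom):
    i_idx, j_idx = geom["i_idx"], geom["j_idx"]
    n, P, D = geom["n"], geom["n_pairs"], geom["n_directions"]
    spp = geom["singles_per_voxel"]
    A, B = G[:, i_idx], G[:, j_idx]
    eq = A == B
    n2 = eq.sum(axis=1).astype(np.float64)           # runs of length 2
    n1 = 2.0 * (P - n2) + spp * n                    # runs of length 1
    Nr = n1 + n2
    # run-instance representation: gray codes with multiplicity weights
    codes = np.concatenate([A, B, G], axis=1).astype(np.int64)
    w = np.concatenate(
        [np.ones_like(A, dtype=np.float64),
         (~eq).astype(np.float64),
         np.full(G.shape, float(spp))], axis=1)
    g = codes.astype(np.float64)
    Eg = (w * g).sum(axis=1) / Nr
    Eg2 = (w * g ** 2).sum(axis=1) / Nr
    N = G.shape[0]
    row, _, gsum = _row_groups(codes, w)
    gln = _rowsum(row, gsum ** 2, N) / Nr
    # joint (gray, length) codes for run entropy; length-2 runs live on A
    codes_len = np.concatenate([A * 2 + eq, B * 2, G * 2], axis=1).astype(np.int64)
    row2, _, gsum2 = _row_groups(codes_len, w)
    return {
        "glrlm_sre": (n1 + n2 / 4.0) / Nr,
        "glrlm_lre": (n1 + 4.0 * n2) / Nr,
        "glrlm_gln": gln,
        "glrlm_glnn": gln / Nr,
        "glrlm_rln": (n1 ** 2 + n2 ** 2) / Nr,
        "glrlm_rlnn": (n1 ** 2 + n2 ** 2) / Nr ** 2,
        "glrlm_rp": Nr / float(n * D),
        "glrlm_glv": Eg2 - Eg ** 2,
        "glrlm_run_entropy": _group_entropy(row2, gsum2, Nr, N),
        "glrlm_lglre": (w / g ** 2).sum(axis=1) / Nr,
        "glrlm_hglre": Eg2,
    }


def _glszm(W, G, geom):
    # inside a 2-wide window all voxels are mutually adjacent, so each gray
    # level present forms exactly one zone whose size is its voxel count
    n = geom["n"]
    N = G.shape[0]
    row, val, s = _row_groups(G)
    Nz = _rowsum(row, np.ones_like(s), N)
    Es = _rowsum(row, s, N) / Nz
    Es2 = _rowsum(row, s ** 2, N) / Nz
    return {
        "glszm_sae": _rowsum(row, 1.0 / s ** 2, N) / Nz,
        "glszm_lae": Es2,
        "glszm_zone_percentage": Nz / n,
        "glszm_zone_entropy": np.log2(Nz),
        "glszm_zone_variance": Es2 - Es ** 2,
        "glszm_lglze": _rowsum(row, 1.0 / val ** 2, N) / Nz,
        "glszm_hglze": _rowsum(row, val ** 2, N) / Nz,
    }


def _gldm(W, G, geom):
    n = geom["n"]
    N = G.shape[0]
    eqmat = G[:, :, None] == G[:, None, :]
    cnt = eqmat.sum(axis=2).astype(np.float64)   # same-level count incl. self
    d = cnt                                      # dependence of each voxel
    row_d, _, gsum_d = _row_groups(d.astype(np.int64))
    dn = _rowsum(row_d, gsum_d ** 2, N) / n
    codes = G.astype(np.int64) * (n + 1) + d.astype(np.int64)
    row_j, _, gsum_j = _row_groups(codes)
    gf = G.astype(np.float64)
    row_g, _, s_g = _row_groups(G)
    return {
        "gldm_sde": (1.0 / d ** 2).mean(axis=1),
        "gldm_lde": (d ** 2).mean(axis=1),
        "gldm_dn": dn,
        "gldm_dnn": dn / n ** 2,
        "gldm_de": _group_entropy(row_j, gsum_j, np.full(N, float(n)), N),
        "gldm_gln": _rowsum(row_g, s_g ** 2, N) / n,
        "gldm_dv": d.var(axis=1),
        "gldm_lgle": (1.0 / gf ** 2).mean(axis=1),
        "gldm_hgle": (gf ** 2).mean(axis=1),
    }


def _ngtdm(W, G, geom):
    n = geom["n"]
    N = G.shape[0]
    g = G.astype(np.float64)
    neigh_mean = (g.sum(axis=1, keepdims=True) - g) / (n - 1)
    diffv = np.abs(g - neigh_mean)               # per-voxel gray-tone difference
    eqmat = G[:, :, None] == G[:, None, :]
    cnt = eqmat.sum(axis=2).astype(np.float64)   # n_i broadcast to voxels
    p = cnt / n
    S = (eqmat * diffv[:, None, :]).sum(axis=2)  # s_i broadcast to voxels
    sum_ps = (p * diffv).sum(axis=1)             # sum_i p_i s_i
    sum_s = diffv.sum(axis=1)                    # sum_i s_i
    row_g, _, s_g = _row_groups(G)
    Ng = _rowsum(row_g, np.ones_like(s_g), N)

    gd2 = (g[:, :, None] - g[:, None, :]) ** 2
    pairsum = gd2.sum(axis=(1, 2)) / n ** 2      # sum_ij p_i p_j (i-j)^2
    denom_c = np.maximum(Ng * (Ng - 1), 1.0)
    contrast = np.where(Ng > 1, pairsum / denom_c * (sum_s / n), 0.0)

    # pairwise tensors over voxels; dividing by n_a * n_b converts voxel-pair
    # sums into present-level-pair sums
    mult = cnt[:, :, None] * cnt[:, None, :]
    diff_level = ~eqmat
    ip = g * p
    t_busy = np.abs(ip[:, :, None] - ip[:, None, :]) / mult
    denom_b = np.where(diff_level, t_busy, 0.0).sum(axis=(1, 2))
    busyness = np.where(denom_b > _EPS, sum_ps / np.maximum(denom_b, _EPS), 0.0)

    ps = p * S
    num_cx = (np.abs(g[:, :, None] - g[:, None, :])
              * (ps[:, :, None] + ps[:, None, :])
              / (p[:, :, None] + p[:, None, :]) / mult)
    complexity = np.where(diff_level, num_cx, 0.0).sum(axis=(1, 2)) / n

    num_st = (p[:, :, None] + p[:, None, :]) * gd2 / mult
    strength_num = np.where(diff_level, num_st, 0.0).sum(axis=(1, 2))
    strength = np.where(sum_s > _EPS, strength_num / np.maximum(sum_s, _EPS), 0.0)

    coarseness = np.minimum(1.0 / np.maximum(sum_ps, 1.0 / _COARSENESS_CAP),
                            _COARSENESS_CAP)
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


_CLASS_FUNCS = {
    "firstorder": _firstorder,
    "glcm": _glcm,
    "glrlm": _glrlm,
    "glszm": _glszm,
    "gldm": _gldm,
    "ngtdm": _ngtdm,
}


def window_features(W: np.ndarray, bin_width: float = 25.0,
                    window_shape: tuple[int, ...] = (2, 2, 2),
                    classes=ALL_CLASSES):
    """Compute the descriptor matrix for pre-gathered windows ``W`` (N, n).

    Intensities are discretised per window as
    ``level = floor((x - window_min) / bin_width) + 1``.
    Returns ``(values, names)``.
    """
    geom = _geometry(tuple(window_shape))
    if W.shape[1] != geom["n"]:
        raise ValueError("window value count does not match window shape")
    for c in classes:
        if c not in _CLASS_FUNCS:
            raise FeatureConfigError(f"unknown feature class {c!r}")
    W = W.astype(np.float64)
    G = np.floor((W - W.min(axis=1, keepdims=True)) / bin_width).astype(np.int64) + 1
    feats = {}
    for c in classes:
        feats.update(_CLASS_FUNCS[c](W, G, geom))
    names = list(feats)
    values = np.column_stack([feats[k] for k in names])
    return values, names


def _lesion_shape_features(mask: np.ndarray, spacing) -> dict:
    """Whole-lesion shape descriptors (computed once, not per window)."""
    from skimage import measure

    out = {"shape_voxel_count": float(mask.sum())}
    if mask.ndim == 3:
        vol = float(mask.sum()) * float(np.prod(spacing))
        out["shape_volume_mm3"] = vol
        padded = np.pad(mask.astype(float), 1)
        if mask.sum() >= 8 and min(mask.shape) >= 2:
            try:
                verts, faces, _, _ = measure.marching_cubes(
                    padded, level=0.5, spacing=tuple(spacing))
                area = measure.mesh_surface_area(verts, faces)
                out["shape_surface_area_mm2"] = float(area)
                out["shape_sphericity"] = float(
                    (np.pi ** (1 / 3)) * (6 * vol) ** (2 / 3) / area)
            except (ValueError, RuntimeError):
                pass
    else:
        out["shape_area_px"] = float(mask.sum())
        out["shape_perimeter_px"] = float(measure.perimeter(mask))
    return out


def extract_local_features(image_or_lesion, mask: np.ndarray | None = None, *,
                           window: tuple[int, ...] | None = None,
                           bin_width: float = 25.0,
                           classes=ALL_CLASSES,
                           masked_fill: bool = False,
                           spacing=None) -> LocalFeatureMap:
    """Extract the per-voxel local descriptor matrix for one lesion.

    Parameters
    ----------
    image_or_lesion : CTLesion, or intensity array (2D slice or 3D volume).
    mask : binary array matching the image (ignored for a CTLesion input).
    window : window shape; defaults to 2 voxels per image axis.
    bin_width : discretisation bin width in HU, relative to the window minimum.
    classes : feature classes to compute.
    """
    from .io import CTLesion  # local import to avoid a cycle

    if isinstance(image_or_lesion, CTLesion):
        image = image_or_lesion.image
        mask = image_or_lesion.mask
        spacing = image_or_lesion.spacing
    else:
        image = np.asarray(image_or_lesion)
        if mask is None:
            raise ValueError("mask required when passing a raw image array")
        mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    if window is None:
        window = (2,) * image.ndim
    if len(window) != image.ndim:
        raise ValueError("window dimensionality does not match the image")

    image = image.astype(np.float64)
    if masked_fill and not mask.all():
        # optional mask-respecting fill: out-of-mask voxels take the nearest
        # in-mask intensity, so windows describe lesion tissue only.  Off by
        # default: windows include surrounding voxels as acquired, matching
        # patch-based extraction on real images.
        from scipy import ndimage
        nearest = ndimage.distance_transform_edt(
            ~mask, return_distances=False, return_indices=True)
        image = image[tuple(nearest)]

    pad = [(0, w - 1) for w in window]
    padded = np.pad(image, pad, mode="edge")
    views = np.lib.stride_tricks.sliding_window_view(padded, window)
    coords = np.argwhere(mask)
    W = views[tuple(coords.T)].reshape(len(coords), -1)
    values, names = window_features(W, bin_width=bin_width,
                                    window_shape=tuple(window), classes=classes)
    shape_feats = _lesion_shape_features(
        mask, spacing if spacing is not None else (1.0,) * image.ndim)
    return LocalFeatureMap(
        coords=coords,
        values=values,
        feature_names=names,
        grid_shape=image.shape,
        dimensionality="2d" if image.ndim == 2 else "3d",
        shape_features=shape_feats,
    )


def normalize_features(fmap: LocalFeatureMap, mode: str = "per_lesion") -> LocalFeatureMap:
    """Z-score each feature over the lesion's voxels (population SD).

    Constant features carry no clustering information and are dropped; the
    per-feature location/scale and the dropped names are stored in
    ``normalization`` for reproducibility.
    """
    if mode != "per_lesion":
        raise ValueError("only per-lesion normalization is supported")
    if fmap.n_voxels < 2:
        raise ValueError("need at least 2 voxels to normalize")
    X = fmap.values
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    keep = stds > 1e-12
    if not keep.any():
        raise ValueError("all features are constant; degenerate lesion")
    Xn = (X[:, keep] - means[keep]) / stds[keep]
    kept_names = [n for n, k in zip(fmap.feature_names, keep) if k]
    dropped = [n for n, k in zip(fmap.feature_names, keep) if not k]
    return replace(
        fmap,
        values=Xn,
        feature_names=kept_names,
        normalization={
            "mode": mode,
            "mean": dict(zip(kept_names, means[keep].tolist())),
            "scale": dict(zip(kept_names, stds[keep].tolist())),
            "dropped_constant": dropped,
        },
    )
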