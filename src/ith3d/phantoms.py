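"""Nodule phantoms with analytically known subregion structure.

A phantom is a ball-shaped "nodule" mask on a small voxel grid whose
interior is partitioned into G planted subregions.  Two geometries are
available:

``laminar`` (default)
    Subregions are stacked axial slabs (equal-mass by default, optionally
    fractioned), each slab carrying a deterministic *texture pattern*: a
    fixed level multiset assigned over the eight parity sublattices of the
    voxel grid, so that every 2x2x2 window inside a slab sees exactly the
    same discretised intensity multiset.  A one-voxel layer at every slab
    interface is excluded from the mask (the image continues the lower
    slab's pattern there), so every in-mask window samples a single
    subregion — the geometry is *separable by construction* and pipeline
    recovery is limited only by clustering, not by partial-volume mixing.
    Fragmented subregions are realised as multiple non-adjacent slabs.

``blobs``
    Subregions grown from well-separated seeds by 6-connected region
    growing until target volume fractions are met; fragments of one
    subregion are kept 26-disconnected.  Interfaces here are irregular and
    windows straddle them — a harder, more organic configuration used to
    exercise robustness rather than exact recovery.

The planted label map is returned alongside the image, so the ITH score of
the ground truth is available analytically for any pipeline check, and
generation is bit-reproducible for a fixed seed.  The default grid
(32x32x32 voxels, 1 mm isotropic) keeps a full pipeline run in the seconds
range while leaving room for 2x2x2 windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CTLesion
from .clustering import SubregionLabelMap, labels_from_array
from .score import ith_score_from_labels

_MIN_FRAGMENT_VOXELS = 8  # a fragment smaller than a window is not meaningful

#: texture patterns: per-subregion level multisets over the 8 parity
#: sublattices (z%2, y%2, x%2).  Chosen to spread all pairwise distances in
#: descriptor space (flat, two-level, multi-level and skewed patterns).
DEFAULT_PATTERNS = (
    (1, 2, 3, 4, 1, 2, 3, 4),
    (1, 1, 1, 7, 1, 1, 1, 7),
    (1, 1, 1, 1, 1, 1, 1, 1),
    (1, 1, 1, 5, 5, 8, 8, 8),
    (1, 2, 3, 4, 5, 6, 7, 8),
    (1, 1, 1, 2, 1, 1, 1, 2),
)

#: fixed per-subregion texture orientations for the "blobs" sinusoid texture
_TEXTURE_DIRS = np.array([
    [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
    [1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 1.0],
    [1.0, 1.0, 1.0], [1.0, -1.0, 0.0],
])


class PhantomSizingError(ValueError):
    """Grid too small to host the requested subregions at their fractions."""


@dataclass
class PhantomSpec:
    """Recipe for one phantom; all randomness flows from ``seed``.

    ``pattern_step`` is the texture-contrast parameter: the HU step between
    consecutive pattern levels (laminar geometry) or the sinusoid amplitude
    (blobs geometry).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fractions: tuple[float, ...] = (1.0,)       # per-subregion volume fractions
    fragments: tuple[int, ...] = (1,)           # connected fragments per subregion
    means: tuple[float, ...] = (0.0,)           # HU
    noise_sd: float = 0.5
    pattern_step: float = 28.0                  # HU per texture level; kept
                                                # off multiples of the 25 HU bin
                                                # width so noise cannot flip levels
    patterns: tuple[tuple[int, ...], ...] | None = None
    geometry: str = "laminar"                   # "laminar" | "blobs"
    interface_margin: int = 1                   # laminar: voxel layers masked out
    background_hu: float = -900.0               # blobs geometry only
    seed: int = 0

    @property
    def n_subregions(self) -> int:
        return len(self.fractions)

    def validate(self) -> None:
        G = self.n_subregions
        if G < 1:
            raise ValueError("need at least one subregion")
        if len(self.fragments) != G or len(self.means) != G:
            raise ValueError("fractions, fragments and means must have equal length")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("volume fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ValueError("volume fractions must sum to 1")
        if any(f < 1 for f in self.fragments):
            raise ValueError("fragmentation counts must be >= 1")
        if self.geometry not in ("laminar", "blobs"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.patterns is not None and len(self.patterns) < G:
            raise ValueError("need one texture pattern per subregion")


def separable_phantom_spec(n_subregions: int = 6,
                           fragments: tuple[int, ...] | None = None,
                           seed: int = 0,
                           grid_shape: tuple[int, int, int] = (32, 32, 32),
                           noise_sd: float = 0.5) -> PhantomSpec:
    """Laminar preset whose subregions are separable by construction.

    Each subregion combines a distinct mean intensity (40 HU apart, two
    orders of magnitude above the noise SD) with a distinct deterministic
    texture pattern, and interfaces are excluded from the mask, so local
    descriptors separate the planted subregions cleanly.
    """
    G = n_subregions
    if fragments is None:
        fragments = (1,) * G
    means = tuple(-250.0 + 40.0 * i for i in range(G))
    fractions = tuple(1.0 / G for _ in range(G))
    patterns = tuple(DEFAULT_PATTERNS[i % len(DEFAULT_PATTERNS)] for i in range(G))
    return PhantomSpec(grid_shape=grid_shape, fractions=fractions,
                       fragments=fragments, means=means, noise_sd=noise_sd,
                       patterns=patterns, geometry="laminar", seed=seed)


def _ball_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0
    radius = min(shape) / 2.0 - 2.0
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    dist2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    return dist2 <= radius ** 2


def _pattern_offsets(spec: PhantomSpec, g: int) -> np.ndarray:
    if spec.patterns is not None:
        pat = np.asarray(spec.patterns[g], dtype=float)
    else:
        pat = np.asarray(DEFAULT_PATTERNS[g % len(DEFAULT_PATTERNS)], dtype=float)
    return spec.pattern_step * (pat - pat.mean())


# ---------------------------------------------------------------------------
# laminar geometry
# ---------------------------------------------------------------------------

def _laminar_phantom(spec: PhantomSpec, rng: np.random.Generator):
    shape = spec.grid_shape
    G = spec.n_subregions
    ball = _ball_mask(shape)

    # slab sequence: one slab per fragment; a random interleaving keeps the
    # stack order seed-dependent while interface gaps keep fragments apart
    seq = []
    for g in range(G):
        seq.extend([g] * spec.fragments[g])
    seq = list(rng.permutation(np.array(seq, dtype=int)))
    nfrag = len(seq)

    # slab extents: contiguous z-layer runs with masses as close to the
    # requested fraction/fragment weights as the layer granularity allows;
    # every slab keeps at least one layer beyond its interface margin
    layer_mass = ball.sum(axis=(1, 2)).astype(float)
    occupied = np.flatnonzero(layer_mass > 0)
    z0, z1 = occupied[0], occupied[-1] + 1
    weights = np.array([spec.fractions[g] / spec.fragments[g] for g in seq])
    targets = weights / weights.sum() * layer_mass.sum()
    min_layers = [1] + [spec.interface_margin + 1] * (nfrag - 1)
    if sum(min_layers) > z1 - z0:
        raise PhantomSizingError(
            f"{z1 - z0} occupied z-layers cannot host {nfrag} slab fragments "
            f"with a {spec.interface_margin}-layer interface margin")
    # interface removal consumes each non-first slab's leading layers, so
    # budget that dead mass into the slab's raw target
    mean_layer = layer_mass[z0:z1].mean()
    adj = targets + np.concatenate(
        [[0.0], np.full(nfrag - 1, spec.interface_margin * mean_layer)])
    adj *= layer_mass.sum() / adj.sum()
    frag_of_z = np.zeros(shape[0], dtype=int)
    frag_of_z[:z0] = 0
    frag_of_z[z1:] = nfrag - 1
    z = z0
    for f in range(nfrag):
        reserve = sum(min_layers[f + 1:])
        taken = 0
        acc = 0.0
        while z < z1 - reserve:
            # stop before a layer that would overshoot the target by more
            # than it helps (nearest-mass rounding)
            if (taken >= min_layers[f] and f < nfrag - 1
                    and acc + layer_mass[z] / 2.0 >= adj[f]):
                break
            frag_of_z[z] = f
            acc += layer_mass[z]
            taken += 1
            z += 1
    lab_of_z = np.array([seq[f] for f in frag_of_z])

    # interface layers: first `interface_margin` z-layers of every slab but
    # the lowest are removed from the mask; the image continues the slab
    # below, so no in-mask window straddles two subregions
    interface = np.zeros(shape[0], dtype=bool)
    change = np.flatnonzero(np.diff(frag_of_z)) + 1
    img_lab_of_z = lab_of_z.copy()
    for zb in change:
        hi = min(zb + spec.interface_margin, shape[0])
        interface[zb:hi] = True
        img_lab_of_z[zb:hi] = lab_of_z[zb - 1]

    mask = ball & ~interface[:, None, None]
    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = lab_of_z[:, None, None].repeat(shape[1], 1).repeat(shape[2], 2)[mask] + 1

    sizes = np.bincount(labels.ravel(), minlength=G + 1)[1:]
    if sizes.min() / max(spec.fragments) < _MIN_FRAGMENT_VOXELS:
        raise PhantomSizingError(
            f"grid holds {int(mask.sum())} mask voxels; requested fractions "
            f"leave a fragment below {_MIN_FRAGMENT_VOXELS} voxels")

    zg, yg, xg = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    sub = 4 * (zg % 2) + 2 * (yg % 2) + (xg % 2)
    img = np.zeros(shape)
    field = img_lab_of_z[:, None, None].repeat(shape[1], 1).repeat(shape[2], 2)
    for g in range(G):
        offsets = _pattern_offsets(spec, g)
        reg = field == g
        img[reg] = spec.means[g] + offsets[sub[reg]]
    img += rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else 0.0
    return img, mask, labels


# ---------------------------------------------------------------------------
# blobs geometry (seeded region growing)
# ---------------------------------------------------------------------------

def _pick_seeds(mask: np.ndarray, n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point sampling among interior voxels -> well separated seeds."""
    interior = ndimage.distance_transform_edt(mask) >= 2.0
    cand = np.argwhere(interior if interior.sum() >= n_seeds else mask)
    first = rng.integers(len(cand))
    chosen = [cand[first]]
    d2 = np.sum((cand - chosen[0]) ** 2, axis=1).astype(float)
    for _ in range(1, n_seeds):
        idx = int(np.argmax(d2))
        chosen.append(cand[idx])
        d2 = np.minimum(d2, np.sum((cand - chosen[-1]) ** 2, axis=1))
    return np.array(chosen)


def _grow_regions(mask: np.ndarray, seeds: np.ndarray, frag_targets: np.ndarray,
                  frag_sub: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Seeded region growing (6-connected) until target sizes are met.

    One voxel is grown at a time from the fragment with the largest relative
    deficit; FIFO frontiers keep growth fronts compact.  A fragment may not
    claim a voxel 26-adjacent to a *different* fragment of the same
    subregion, so planted fragments stay disconnected; unreachable leftovers
    join a 6-adjacent fragment as a last resort.
    """
    from collections import deque

    shape = mask.shape
    strides = (shape[1] * shape[2], shape[2], 1)
    frag_of = np.full(mask.size, -1, dtype=np.int32)
    flat_mask = mask.ravel()
    F = len(seeds)
    sizes = np.zeros(F, dtype=np.int64)
    frontiers: list[deque] = [deque() for _ in range(F)]

    def coords(flat: int):
        z, rem = divmod(flat, strides[0])
        y, x = divmod(rem, strides[1])
        return z, y, x

    def neighbours6(flat: int):
        z, y, x = coords(flat)
        if z > 0:
            yield flat - strides[0]
        if z < shape[0] - 1:
            yield flat + strides[0]
        if y > 0:
            yield flat - strides[1]
        if y < shape[1] - 1:
            yield flat + strides[1]
        if x > 0:
            yield flat - 1
        if x < shape[2] - 1:
            yield flat + 1

    def blocked(flat: int, f: int) -> bool:
        z, y, x = coords(flat)
        for dz in (-1, 0, 1):
            nz = z + dz
            if not 0 <= nz < shape[0]:
                continue
            for dy in (-1, 0, 1):
                ny = y + dy
                if not 0 <= ny < shape[1]:
                    continue
                for dx in (-1, 0, 1):
                    nx = x + dx
                    if not 0 <= nx < shape[2] or (dz == dy == dx == 0):
                        continue
                    g = frag_of[nz * strides[0] + ny * strides[1] + nx]
                    if g >= 0 and g != f and frag_sub[g] == frag_sub[f]:
                        return True
        return False

    for f, s in enumerate(seeds):
        flat = int(s[0] * strides[0] + s[1] * strides[1] + s[2])
        frag_of[flat] = f
        sizes[f] += 1
        for nb in neighbours6(flat):
            if flat_mask[nb] and frag_of[nb] < 0:
                frontiers[f].append(nb)

    remaining = int(flat_mask.sum()) - F
    while remaining > 0:
        best, best_score = -1, -np.inf
        for f in range(F):
            if frontiers[f]:
                score = (frag_targets[f] - sizes[f]) / frag_targets[f]
                if score > best_score:
                    best, best_score = f, score
        if best < 0:
            break
        frontier = frontiers[best]
        voxel = -1
        while frontier:
            cand = frontier.popleft()
            if frag_of[cand] < 0 and not blocked(cand, best):
                voxel = cand
                break
        if voxel < 0:
            continue  # frontier exhausted (blocked voxels stay discarded)
        frag_of[voxel] = best
        sizes[best] += 1
        remaining -= 1
        for nb in neighbours6(voxel):
            if flat_mask[nb] and frag_of[nb] < 0:
                frontier.append(nb)

    if remaining > 0:
        leftover = [i for i in np.flatnonzero(flat_mask) if frag_of[i] < 0]
        changed = True
        while leftover and changed:
            changed = False
            still = []
            for flat in leftover:
                nb_frags = [frag_of[nb] for nb in neighbours6(flat)
                            if frag_of[nb] >= 0]
                if nb_frags:
                    frag_of[flat] = nb_frags[0]
                    changed = True
                else:
                    still.append(flat)
            leftover = still
    return frag_of.reshape(shape)


def _blobs_phantom(spec: PhantomSpec, rng: np.random.Generator):
    shape = spec.grid_shape
    G = spec.n_subregions
    mask = _ball_mask(shape)
    V = int(mask.sum())

    frag_sub = []
    max_frag = max(spec.fragments)
    for r in range(max_frag):
        for g in range(G):
            if r < spec.fragments[g]:
                frag_sub.append(g)
    frag_sub = np.array(frag_sub)
    frag_targets = np.array([
        spec.fractions[g] / spec.fragments[g] * V for g in frag_sub])
    if frag_targets.min() < _MIN_FRAGMENT_VOXELS:
        raise PhantomSizingError(
            f"grid holds {V} mask voxels; smallest requested fragment would be "
            f"{frag_targets.min():.1f} voxels (< {_MIN_FRAGMENT_VOXELS})")

    seeds = _pick_seeds(mask, len(frag_sub), rng)
    frag_map = _grow_regions(mask, seeds, frag_targets, frag_sub, rng)
    labels = np.zeros(shape, dtype=np.int32)
    inside = frag_map >= 0
    labels[inside] = frag_sub[frag_map[inside]] + 1

    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                             indexing="ij")
    img = np.full(shape, spec.background_hu)
    for g in range(G):
        direction = _TEXTURE_DIRS[g % len(_TEXTURE_DIRS)]
        direction = direction / np.linalg.norm(direction)
        wavelength = 4.0 + g
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(
            2 * np.pi * (direction[0] * zz + direction[1] * yy + direction[2] * xx)
            / wavelength + phase)
        region = labels == g + 1
        img[region] = spec.means[g] + spec.pattern_step * carrier[region]
    img = img + rng.normal(0.0, max(spec.noise_sd, 1e-12), size=shape)
    return img, mask, labels


def make_phantom(spec: PhantomSpec) -> tuple[CTLesion, SubregionLabelMap]:
    """Generate one phantom and its planted ground-truth label map."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "laminar":
        img, mask, labels = _laminar_phantom(spec, rng)
    else:
        img, mask, labels = _blobs_phantom(spec, rng)
    lesion = CTLesion(image=img, mask=mask, spacing=spec.spacing,
                      lesion_id=f"phantom_{spec.geometry}_seed{spec.seed}")
    label_map = labels_from_array(labels, nc_requested=spec.n_subregions,
                                  kind="planted", seed=spec.seed)
    return lesion, label_map


def analytic_ith_on_labels(labels, connectivity: str | None = None) -> float:
    """ITH score of a ground-truth label map, bypassing feature extraction.

    This is the dispersion formula evaluated directly on planted labels; it
    equals :func:`ith3d.score.ith_score_from_labels` exactly by construction
    and serves as the analytic reference for pipeline-recovery checks.
    """
    arr = labels.labels if isinstance(labels, SubregionLabelMap) else np.asarray(labels)
    if not (np.asarray(arr) > 0).any():
        raise ValueError("label map is empty")
    return ith_score_from_labels(arr, connectivity)
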