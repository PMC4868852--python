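"""Dense gradient-orientation descriptors over a multilayer spatial pyramid.

Volumes are processed slice-wise: every ``slice_step``-th slice along
``slice_axis`` is treated as a 2-D image, and dense SIFT-style descriptors
are computed on a regular grid of patches (no keypoint detection).  Each
descriptor concatenates per-spatial-bin gradient-orientation histograms,
is l2-normalized, clamped at 0.2 and re-normalized — the standard dense-SIFT
scheme.  Descriptors from all slices of a volume are pooled into one
:class:`DescriptorSet`, preserving the bag-of-features abstraction.

The spatial pyramid assigns each descriptor to one cell per layer: layer 1
is always the undivided slice, layer 2 subdivides the in-slice plane into a
disjoint grid (2×2 by default), and the "stacked" mode concatenates both
layers downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import ModalityVolume
from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "DenseGeometry",
    "PyramidLayout",
    "DescriptorSet",
    "extract_dense_descriptors",
    "assign_pyramid_cells",
    "DenseDescriptorExtractor",
]

_CLAMP = 0.2
_EPS = 1e-12


@dataclass(frozen=True)
class DenseGeometry:
    """Dense sampling geometry.

    patch_size × patch_size patches on a grid with the given stride;
    ``spatial_bins`` bins per axis within a patch and ``orientation_bins``
    gradient-orientation bins give descriptors of dimension
    ``spatial_bins**2 * orientation_bins`` (128 with the defaults).
    """

    patch_size: int = 16
    stride: int = 8
    spatial_bins: int = 4
    orientation_bins: int = 8
    slice_axis: int = 0
    slice_step: int = 2

    def __post_init__(self):
        if self.patch_size < self.spatial_bins:
            raise ConfigurationError(
                f"patch_size ({self.patch_size}) must be >= spatial_bins "
                f"({self.spatial_bins})"
            )
        if self.stride < 1:
            raise ConfigurationError(f"stride must be >= 1, got {self.stride}")
        if self.orientation_bins < 4:
            raise ConfigurationError(
                f"orientation_bins must be >= 4, got {self.orientation_bins}"
            )
        if self.slice_axis not in (0, 1, 2):
            raise ConfigurationError(
                f"slice_axis must be 0, 1 or 2, got {self.slice_axis}"
            )
        if self.slice_step < 1:
            raise ConfigurationError(
                f"slice_step must be >= 1, got {self.slice_step}"
            )

    @property
    def descriptor_dim(self) -> int:
        return self.spatial_bins**2 * self.orientation_bins


@dataclass(frozen=True)
class PyramidLayout:
    """Pyramid layer layout.

    ``mode`` selects which layers feed the encoded representation:
    'layer1' (whole slice), 'layer2' (disjoint grid only) or 'stacked'
    (both).  Layer 1 is always the undivided slice; layer 2 is the
    ``layer2_grid`` in-slice subdivision with half-open cell intervals.
    """

    mode: str = "stacked"
    layer2_grid: tuple[int, int] = (2, 2)

    def __post_init__(self):
        if self.mode not in ("layer1", "layer2", "stacked"):
            raise ConfigurationError(
                f"mode must be layer1, layer2 or stacked, got {self.mode!r}"
            )
        if any(g < 1 for g in self.layer2_grid):
            raise ConfigurationError(
                f"layer2_grid factors must be >= 1, got {self.layer2_grid}"
            )

    @property
    def grids(self) -> tuple[tuple[int, int], ...]:
        """Subdivision grids of the active layers, layer 1 first."""
        if self.mode == "layer1":
            return ((1, 1),)
        if self.mode == "layer2":
            return (self.layer2_grid,)
        return ((1, 1), self.layer2_grid)

    @property
    def total_cells(self) -> int:
        return sum(gr * gc for gr, gc in self.grids)


@dataclass
class DescriptorSet:
    """Dense descriptors of one volume with locations and pyramid cells.

    Attributes
    ----------
    descriptors : (M, D) float array
    locations : (M, 3) int array
        (slice index, row center, column center) per descriptor.
    slice_shape : (H, W)
        In-slice image shape used for cell assignment.
    cells : dict
        Maps layer index (position in ``layout.grids``) to an (M,) int
        array of cell ids; populated by :func:`assign_pyramid_cells`.
    """

    descriptors: np.ndarray
    locations: np.ndarray
    slice_shape: tuple[int, int]
    geometry: DenseGeometry | None = None
    layout: PyramidLayout | None = None
    cells: dict[int, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.descriptors.shape[0]


def _integral(channel: np.ndarray) -> np.ndarray:
    ii = np.zeros((channel.shape[0] + 1, channel.shape[1] + 1))
    np.cumsum(channel, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    return ii


def _dense_sift_slice(
    img: np.ndarray, geom: DenseGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense descriptors for one 2-D slice.

    Returns (descriptors (G, D), row centers (gr,), col centers (gc,))
    with G = gr * gc grid positions.
    """
    H, W = img.shape
    p, s = geom.patch_size, geom.stride
    sb, ob = geom.spatial_bins, geom.orientation_bins
    gy, gx = np.gradient(img.astype(float))
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    obin = np.minimum((ang / (2.0 * np.pi / ob)).astype(int), ob - 1)

    rs = np.arange(0, H - p + 1, s)
    cs = np.arange(0, W - p + 1, s)
    edges = np.round(np.linspace(0, p, sb + 1)).astype(int)

    desc = np.zeros((rs.size, cs.size, sb, sb, ob))
    for o in range(ob):
        ii = _integral(np.where(obin == o, mag, 0.0))
        for bi in range(sb):
            r0 = rs + edges[bi]
            r1 = rs + edges[bi + 1]
            for bj in range(sb):
                c0 = cs + edges[bj]
                c1 = cs + edges[bj + 1]
                desc[:, :, bi, bj, o] = (
                    ii[np.ix_(r1, c1)]
                    - ii[np.ix_(r0, c1)]
                    - ii[np.ix_(r1, c0)]
                    + ii[np.ix_(r0, c0)]
                )

    flat = desc.reshape(-1, geom.descriptor_dim)
    np.maximum(flat, 0.0, out=flat)  # integral-image roundoff
    norms = np.linalg.norm(flat, axis=1)
    nz = norms > _EPS
    flat[nz] /= norms[nz, None]
    np.minimum(flat, _CLAMP, out=flat)
    norms = np.linalg.norm(flat, axis=1)
    nz = norms > _EPS
    flat[nz] /= norms[nz, None]
    return flat, rs + p // 2, cs + p // 2


def extract_dense_descriptors(
    volume: ModalityVolume | np.ndarray, geom: DenseGeometry = DenseGeometry()
) -> DescriptorSet:
    """Extract dense descriptors from every sampled slice of a volume.

    The descriptor count is ``n_slices × ⌊(H−patch)/stride+1⌋ ×
    ⌊(W−patch)/stride+1⌋``.  Zero-gradient (constant) patches yield the
    zero descriptor.
    """
    vox = volume.voxels if isinstance(volume, ModalityVolume) else np.asarray(volume)
    if vox.ndim != 3:
        raise InputDataError(f"expected a 3-D volume, got shape {vox.shape}")
    if not np.all(np.isfinite(vox)):
        raise InputDataError("volume contains non-finite voxels")

    axes = [a for a in range(3) if a != geom.slice_axis]
    H, W = vox.shape[axes[0]], vox.shape[axes[1]]
    if H < geom.patch_size or W < geom.patch_size:
        raise InputDataError(
            f"in-slice shape ({H}, {W}) is smaller than one "
            f"{geom.patch_size}x{geom.patch_size} patch"
        )

    all_desc, all_loc = [], []
    for idx in range(0, vox.shape[geom.slice_axis], geom.slice_step):
        img = np.take(vox, idx, axis=geom.slice_axis)
        flat, rc, cc = _dense_sift_slice(img, geom)
        all_desc.append(flat)
        rr, ccg = np.meshgrid(rc, cc, indexing="ij")
        loc = np.column_stack(
            [np.full(rr.size, idx), rr.ravel(), ccg.ravel()]
        ).astype(int)
        all_loc.append(loc)
    return DescriptorSet(
        descriptors=np.vstack(all_desc),
        locations=np.vstack(all_loc),
        slice_shape=(H, W),
        geometry=geom,
    )


def assign_pyramid_cells(
    dset: DescriptorSet, layout: PyramidLayout = PyramidLayout()
) -> DescriptorSet:
    """Assign every descriptor to its cell in each pyramid layer.

    Cells are half-open intervals covering the slice, so every descriptor
    center falls in exactly one cell per layer; assignment depends only on
    locations, never on descriptor values, and is idempotent.
    """
    if dset.locations.shape[0] != len(dset):
        raise InputDataError("locations missing or inconsistent")
    H, W = dset.slice_shape
    rows = dset.locations[:, 1]
    cols = dset.locations[:, 2]
    cells = {}
    for li, (gr, gc) in enumerate(layout.grids):
        ri = np.minimum(rows * gr // H, gr - 1)
        ci = np.minimum(cols * gc // W, gc - 1)
        cells[li] = (ri * gc + ci).astype(int)
    dset.cells = cells
    dset.layout = layout
    return dset


def _cache_key(vox: np.ndarray, geom: DenseGeometry) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(vox).tobytes())
    h.update(repr(geom).encode())
    return h.hexdigest()


class DenseDescriptorExtractor:
    """Transformer-style wrapper: volumes in, descriptor sets out.

    Stateless apart from configuration; ``fit`` is a no-op so the class
    composes with sklearn-style pipelines.  If ``cache_dir`` is set,
    per-volume descriptor arrays are cached keyed by the content hash of
    the voxels plus the geometry, so a cache hit can never change results.
    """

    def __init__(
        self,
        geometry: DenseGeometry = DenseGeometry(),
        layout: PyramidLayout = PyramidLayout(),
        cache_dir: str | Path | None = None,
    ):
        self.geometry = geometry
        self.layout = layout
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None

    def fit(self, volumes=None, y=None):
        return self

    def transform_one(self, volume: ModalityVolume | np.ndarray) -> DescriptorSet:
        vox = volume.voxels if isinstance(volume, ModalityVolume) else volume
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            path = self.cache_dir / f"{_cache_key(vox, self.geometry)}.npz"
            if path.exists():
                data = np.load(path)
                dset = DescriptorSet(
                    descriptors=data["descriptors"],
                    locations=data["locations"],
                    slice_shape=tuple(int(v) for v in data["slice_shape"]),
                    geometry=self.geometry,
                )
            else:
                dset = extract_dense_descriptors(vox, self.geometry)
                np.savez(
                    path,
                    descriptors=dset.descriptors,
                    locations=dset.locations,
                    slice_shape=np.array(dset.slice_shape),
                )
        else:
            dset = extract_dense_descriptors(vox, self.geometry)
        return assign_pyramid_cells(dset, self.layout)

    def transform(self, volumes) -> list[DescriptorSet]:
        return [self.transform_one(v) for v in volumes]
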