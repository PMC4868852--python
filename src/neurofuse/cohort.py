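"""Synthetic paired-modality cohorts for multimodal fusion experiments.

The pipeline targets studies that pair two preprocessed 3-D brain maps per
subject — modality A standing in for a gray-matter density map from
structural MRI, modality B for an FDG-PET intensity map — with a diagnostic
label in {AD, MCI-C, MCI-NC, NC}.  Real cohorts of this kind are
access-restricted, so this module synthesises cohorts exhibiting the
structural ingredients the pipeline is sensitive to: a class-informative
latent signal shared by both modalities, modality-specific structure, and
additive noise.

Disease severity is modelled as a single latent axis with ordinal class
positions (NC=0, MCI-NC=1, MCI-C=2, AD=3); ``shared_effect`` is the
displacement of the latent mean per severity step.  The remaining latent
coordinates carry benign inter-subject variation whose dispersion is scaled
by ``modality_noise``, so a noise-free cohort is fully deterministic: one
"noise level" knob controls both biological variability and measurement
noise.

Two generators are provided:

``generate_paired_vectors``
    Low-dimensional paired feature matrices for unit-testing CCA and the
    classifier stack: each view is a (different) linear mixing of the shared
    latent plus independent Gaussian noise.

``generate_paired_volumes``
    Renderable 3-D volumes: smooth anisotropic Gaussian blobs whose
    amplitudes carry the class effect, on a fixed band-limited texture (so
    dense gradient descriptors are non-degenerate), plus per-subject
    band-limited noise.  Voxels are clipped to be nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "LABELS",
    "SEVERITY",
    "CohortSpec",
    "ModalityVolume",
    "SubjectRecord",
    "generate_paired_vectors",
    "generate_paired_volumes",
    "save_cohort",
    "load_cohort",
]

#: Diagnostic labels, in generation order.
LABELS = ("AD", "MCI-C", "MCI-NC", "NC")

#: Ordinal position of each label on the latent severity axis.
SEVERITY = {"NC": 0.0, "MCI-NC": 1.0, "MCI-C": 2.0, "AD": 3.0}

# Fixed blob geometry (fractions of the voxel grid).  Centers are spread so
# blob overlap at each other's center is negligible; sigmas are anisotropic.
_BLOB_CENTER_FRACS = np.array(
    [
        [0.30, 0.35, 0.40],
        [0.68, 0.38, 0.62],
        [0.38, 0.70, 0.55],
        [0.64, 0.66, 0.30],
    ]
)
_BLOB_SIGMA_FRACS = np.array(
    [
        [0.10, 0.14, 0.09],
        [0.12, 0.08, 0.11],
        [0.09, 0.11, 0.13],
        [0.13, 0.10, 0.08],
    ]
)
_BASE_AMPLITUDE = 1.0
_MODALITY_GAIN = {"A": 1.0, "B": 0.9}
_BACKGROUND = 0.30
_TEXTURE_AMPLITUDE = 0.15
_TEXTURE_SMOOTH_SIGMA = 1.5
_NOISE_SMOOTH_SIGMA = 0.8
_POSITION_SCALE_FRAC = 0.015  # voxel shift per unit latent, × min(shape)
_MIN_AXIS = 8


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_per_class : int
        Subjects generated per diagnostic label (>= 2).
    latent_dim : int
        Dimension of the shared latent ``t``.  May be 0 for vector cohorts
        (no shared signal at all); volume cohorts require >= 1.
    shared_effect : float
        Latent-mean displacement per severity step; this is also the
        expected blob-amplitude difference between adjacent classes in
        rendered volumes.
    modality_noise : float
        Standard deviation of the per-modality additive noise, and of the
        benign per-subject latent variation (>= 0).
    volume_shape : tuple of int
        Voxel grid, each axis >= 8 (room for the blob kernels).
    seed : int
        Seed of the cohort's random stream.  Per-subject streams are split
        from it by subject counter, so generation is order-independent.
    """

    n_per_class: int = 20
    latent_dim: int = 4
    shared_effect: float = 1.0
    modality_noise: float = 0.2
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    seed: int = 0

    def validate(self, for_volumes: bool = False) -> "CohortSpec":
        if self.n_per_class < 2:
            raise ConfigurationError(
                f"n_per_class must be >= 2, got {self.n_per_class}"
            )
        min_latent = 1 if for_volumes else 0
        if self.latent_dim < min_latent:
            raise ConfigurationError(
                f"latent_dim must be >= {min_latent}, got {self.latent_dim}"
            )
        if self.shared_effect < 0:
            raise ConfigurationError(
                f"shared_effect must be >= 0, got {self.shared_effect}"
            )
        if self.modality_noise < 0:
            raise ConfigurationError(
                f"modality_noise must be >= 0, got {self.modality_noise}"
            )
        shape = tuple(self.volume_shape)
        if for_volumes and (len(shape) != 3 or any(s < _MIN_AXIS for s in shape)):
            raise ConfigurationError(
                "volume_shape axes must all be >= "
                f"{_MIN_AXIS} (too small for the blob kernel), got {shape}"
            )
        return self


@dataclass(frozen=True)
class ModalityVolume:
    """One modality's scalar voxel grid with its physical spacing in mm."""

    modality: str
    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if not np.all(np.isfinite(self.voxels)):
            raise InputDataError("voxels must be finite")
        if np.any(self.voxels < 0):
            raise InputDataError("voxels must be nonnegative")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: paired modality volumes plus diagnostic label."""

    subject_id: str
    label: str
    volume_A: ModalityVolume
    volume_B: ModalityVolume

    def __post_init__(self):
        if self.volume_A.voxels.shape != self.volume_B.voxels.shape:
            raise InputDataError(
                f"subject {self.subject_id}: modality volumes must share a "
                "voxel grid shape"
            )


def _structural_rng(spec: CohortSpec) -> np.random.Generator:
    """Stream for cohort-level structure (mixings, texture fields)."""
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))


def _subject_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    """Per-subject stream, split from the cohort seed by counter."""
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 1, index]))


def cohort_labels(spec: CohortSpec) -> np.ndarray:
    return np.repeat(np.array(LABELS, dtype=object), spec.n_per_class)


def _latent(spec: CohortSpec, label: str, rng: np.random.Generator) -> np.ndarray:
    """Shared latent t = shared_effect·severity·e1 + modality_noise·z."""
    t = spec.modality_noise * rng.standard_normal(spec.latent_dim)
    if spec.latent_dim:
        t[0] += spec.shared_effect * SEVERITY[label]
    return t


def generate_paired_vectors(
    spec: CohortSpec, d: int, mixing: str = "random"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate paired feature matrices sharing a class-informative latent.

    Each view is ``X_v = t @ A_v.T + modality_noise * eps`` with ``t`` the
    shared latent and ``A_v`` a view-specific mixing with orthonormal
    columns (or the identity when ``mixing='identity'``).

    Parameters
    ----------
    spec : CohortSpec
    d : int
        Feature dimension of each view; must be >= ``spec.latent_dim``.
    mixing : {'random', 'identity'}
        'identity' requires ``d == spec.latent_dim`` and makes both views'
        mixings the identity map (useful for exactness tests).

    Returns
    -------
    X1, X2 : ndarray of shape (n, d)
        One row per subject, classes in generation order.
    labels : ndarray of shape (n,)
        Diagnostic label strings.
    """
    spec.validate()
    if d < spec.latent_dim:
        raise ConfigurationError(
            f"latent_dim ({spec.latent_dim}) must not exceed the feature "
            f"dimension d ({d})"
        )
    rng = _structural_rng(spec)
    if mixing == "identity":
        if d != spec.latent_dim:
            raise ConfigurationError(
                "mixing='identity' requires d == latent_dim, got "
                f"d={d}, latent_dim={spec.latent_dim}"
            )
        mixings = [np.eye(d), np.eye(d)]
    elif mixing == "random":
        mixings = []
        for _ in range(2):
            if spec.latent_dim == 0:
                mixings.append(np.zeros((d, 0)))
            else:
                g = rng.standard_normal((d, spec.latent_dim))
                q, _ = np.linalg.qr(g)
                mixings.append(q)
    else:
        raise ConfigurationError(f"unknown mixing {mixing!r}")

    labels = cohort_labels(spec)
    n = labels.size
    X1 = np.empty((n, d))
    X2 = np.empty((n, d))
    for i, label in enumerate(labels):
        srng = _subject_rng(spec, i)
        t = _latent(spec, label, srng)
        for X, A in zip((X1, X2), mixings):
            X[i] = A @ t + spec.modality_noise * srng.standard_normal(d)
    return X1, X2, labels


def _volume_structure(spec: CohortSpec) -> dict:
    """Cohort-level volume structure: amplitude mixings, position maps,
    fixed texture fields.

    The amplitude mixing of every blob has unit weight on the severity
    coordinate, so the expected blob-amplitude difference between adjacent
    classes equals ``shared_effect`` exactly; modality-specific structure
    enters through a smaller orthogonal component.  Position coupling is
    restricted to the non-severity latent coordinates, so blob centers do
    not move with the class effect.
    """
    rng = _structural_rng(spec)
    L = spec.latent_dim
    n_blobs = _BLOB_CENTER_FRACS.shape[0]
    shape = np.asarray(spec.volume_shape)

    amp_mix = {}
    for mod in ("A", "B"):
        w = np.zeros((n_blobs, L))
        w[:, 0] = 1.0
        if L > 1:
            m = rng.standard_normal((n_blobs, L))
            m[:, 0] = 0.0
            norms = np.linalg.norm(m, axis=1, keepdims=True)
            m = np.divide(m, norms, out=np.zeros_like(m), where=norms > 0)
            w = w + 0.3 * m
        amp_mix[mod] = w

    pos_map = rng.standard_normal((n_blobs, 3, L))
    pos_map[:, :, 0] = 0.0
    pos_map *= _POSITION_SCALE_FRAC * shape.min()

    textures = {}
    for mod in ("A", "B"):
        field = gaussian_filter(
            rng.standard_normal(spec.volume_shape), _TEXTURE_SMOOTH_SIGMA
        )
        field /= field.std()
        textures[mod] = _TEXTURE_AMPLITUDE * field

    return {
        "amp_mix": amp_mix,
        "pos_map": pos_map,
        "textures": textures,
        "base_centers": _BLOB_CENTER_FRACS * (shape - 1),
        "sigmas": _BLOB_SIGMA_FRACS * shape,
    }


def _render_volume(
    spec: CohortSpec,
    structure: dict,
    modality: str,
    t: np.ndarray,
    noise_field: np.ndarray | None,
) -> np.ndarray:
    shape = spec.volume_shape
    gx, gy, gz = np.ogrid[: shape[0], : shape[1], : shape[2]]
    vol = np.full(shape, _BACKGROUND, dtype=float)
    gain = _MODALITY_GAIN[modality]
    for b in range(structure["base_centers"].shape[0]):
        center = structure["base_centers"][b] + structure["pos_map"][b] @ t
        sig = structure["sigmas"][b]
        amp = gain * max(
            0.0, _BASE_AMPLITUDE + float(structure["amp_mix"][modality][b] @ t)
        )
        d2 = (
            ((gx - center[0]) / sig[0]) ** 2
            + ((gy - center[1]) / sig[1]) ** 2
            + ((gz - center[2]) / sig[2]) ** 2
        )
        vol += amp * np.exp(-0.5 * d2)
    vol += structure["textures"][modality]
    if noise_field is not None:
        vol += noise_field
    return np.clip(vol, 0.0, None)


def generate_paired_volumes(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate one :class:`SubjectRecord` per subject with rendered volumes.

    Both modalities of a subject are driven by the same latent ``t``
    (amplitudes and blob positions), plus modality-specific amplitude mixing
    and independent band-limited noise of SD ``modality_noise``.  Identical
    seeds yield bit-identical volumes.
    """
    spec.validate(for_volumes=True)
    structure = _volume_structure(spec)
    labels = cohort_labels(spec)
    records = []
    for i, label in enumerate(labels):
        srng = _subject_rng(spec, i)
        t = _latent(spec, label, srng)
        volumes = {}
        for mod in ("A", "B"):
            if spec.modality_noise > 0:
                field = gaussian_filter(
                    srng.standard_normal(spec.volume_shape), _NOISE_SMOOTH_SIGMA
                )
                field *= spec.modality_noise / field.std()
            else:
                field = None
            volumes[mod] = ModalityVolume(
                modality=mod,
                voxels=_render_volume(spec, structure, mod, t, field),
            )
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i:04d}",
                label=str(label),
                volume_A=volumes["A"],
                volume_B=volumes["B"],
            )
        )
    return records


def save_cohort(records: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write volumes as NIfTI (.nii.gz) plus a manifest CSV.

    The manifest has header ``subject_id,label,path_A,path_B`` with paths
    relative to the manifest's directory.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = {}
        for mod in ("A", "B"):
            vol: ModalityVolume = getattr(rec, f"volume_{mod}")
            affine = np.diag(list(vol.spacing) + [1.0])
            img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine)
            fname = f"{rec.subject_id}_{mod}.nii.gz"
            nib.save(img, outdir / fname)
            paths[mod] = fname
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "path_A": paths["A"],
                "path_B": paths["B"],
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`save_cohort` (or any manifest with
    the same schema and NIfTI volumes)."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    required = {"subject_id", "label", "path_A", "path_B"}
    if not required.issubset(table.columns):
        raise InputDataError(
            f"manifest must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    records = []
    for row in table.itertuples(index=False):
        if row.label not in LABELS:
            raise InputDataError(
                f"unknown label {row.label!r} for subject {row.subject_id}"
            )
        vols = {}
        for mod in ("A", "B"):
            path = manifest.parent / getattr(row, f"path_{mod}")
            img = nib.load(path)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            vols[mod] = ModalityVolume(
                modality=mod,
                voxels=np.asarray(img.dataobj, dtype=np.float64),
                spacing=spacing,
            )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                label=str(row.label),
                volume_A=vols["A"],
                volume_B=vols["B"],
            )
        )
    return records
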