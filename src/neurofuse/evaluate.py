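"""Repeated stratified cross-validation of the full pipeline.

For every training fold the complete stack is refit from scratch — K-means
codebooks, the L2AL2W normalization statistics, the CCA bases, the SVM cost
C and the hybrid fusion weight α (both via an inner split of the training
fold) — and applied to the held-out fold, so no test-fold information leaks
into any fitted component.  Metrics are aggregated as mean ± SD over all
k × repeats folds.

Representations mirror the multimodal comparison grid:

- ``MRI`` / ``PET``  — one modality's encoded features;
- ``MRIPET``         — plain concatenation of both;
- ``MRIPETLF``       — modality-level fusion: concatenation augmented with
  the CCA projections, ``F = [X1; X2; Z1; Z2]``;
- ``MRIPETHF``       — hybrid fusion: the augmented features encoded both
  as BoVW and as VLAD, one linear SVM per encoding, decision scores fused
  with the adaptively selected weight α.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .cca import CCAFusion, augment_features
from .classify import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_C_GRID,
    METRIC_NAMES,
    compute_metrics,
    predict_from_scores,
    select_fusion_weight,
    train_linear_svm,
)
from .cohort import SubjectRecord
from .descriptors import DenseDescriptorExtractor, DenseGeometry, PyramidLayout
from .encoding import encode_bovw, encode_vlad, fit_codebook
from .exceptions import ConfigurationError, InputDataError
from .kernel_maps import KernelMapConfig, apply_kernel_map
from .normalize import L2AL2W, power_normalize

__all__ = ["PipelineConfig", "EvalReport", "run_repeated_cv", "run_vector_cv",
           "TASKS"]

#: The three binary diagnostic tasks; "MCI" merges MCI-C and MCI-NC.
TASKS = (("AD", "NC"), ("MCI", "NC"), ("MCI-C", "MCI-NC"))

_GROUPS = {"MCI": {"MCI-C", "MCI-NC"}}

REPRESENTATIONS = ("MRI", "PET", "MRIPET", "MRIPETLF", "MRIPETHF")


@dataclass(frozen=True)
class PipelineConfig:
    """Experiment-scale configuration of the feature pipeline.

    Codebook sizes default to 64 (BoVW) and 16 (VLAD), sized to the few
    thousand training descriptors per fold that the synthetic desk-scale
    cohorts produce; the encoder classes themselves default to 256/64 for
    larger descriptor pools.
    """

    geometry: DenseGeometry = DenseGeometry()
    layout: PyramidLayout = PyramidLayout()
    bovw_words: int = 64
    vlad_words: int = 16
    kmeans_n_init: int = 2
    rho: float = 0.5
    kernel_map_bovw: KernelMapConfig = KernelMapConfig("hellinger")
    kernel_map_vlad: KernelMapConfig = KernelMapConfig("linear")
    cca_stage: str = "encoded"  # encoded | input | none
    epsilon: float | str = "auto"
    cca_components: int | None = None
    representations: tuple[str, ...] = REPRESENTATIONS
    primary_encoding: str = "bovw"
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    inner_folds: int = 5
    vlad_intra_l2: bool = False
    exact_assign: bool = False
    cache_dir: str | None = None

    def __post_init__(self):
        if self.cca_stage not in ("encoded", "input", "none"):
            raise ConfigurationError(
                f"cca_stage must be encoded, input or none, got {self.cca_stage!r}"
            )
        if self.primary_encoding not in ("bovw", "vlad"):
            raise ConfigurationError(
                f"primary_encoding must be bovw or vlad, got {self.primary_encoding!r}"
            )
        unknown = set(self.representations) - set(REPRESENTATIONS)
        if unknown:
            raise ConfigurationError(
                f"unknown representations {sorted(unknown)}; valid: {REPRESENTATIONS}"
            )
        if any(c <= 0 for c in self.C_grid):
            raise ConfigurationError(f"C grid must be positive, got {self.C_grid}")
        if self.cca_stage in ("none",) and {"MRIPETLF", "MRIPETHF"} & set(
            self.representations
        ):
            raise ConfigurationError(
                "MRIPETLF/MRIPETHF require a CCA stage (cca_stage != 'none')"
            )

    @property
    def needed_encodings(self) -> tuple[str, ...]:
        if "MRIPETHF" in self.representations:
            return ("bovw", "vlad")
        return (self.primary_encoding,)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def task_name(task: tuple[str, str]) -> str:
    return f"{task[0]}_vs_{task[1]}"


def _members(group: str) -> set[str]:
    return _GROUPS.get(group, {group})


def task_subset(labels: np.ndarray, task: tuple[str, str]):
    """Indices and ±1 targets of the subjects in a binary task.

    The first task label is the positive class.
    """
    pos, neg = _members(task[0]), _members(task[1])
    if pos & neg:
        raise ConfigurationError(f"task groups overlap: {task}")
    labels = np.asarray(labels, dtype=object)
    mask = np.isin(labels, sorted(pos | neg))
    idx = np.flatnonzero(mask)
    y = np.where(np.isin(labels[idx], sorted(pos)), 1, -1)
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise InputDataError(f"task {task_name(task)}: a class has no subjects")
    return idx, y


# ---------------------------------------------------------------------------
# Per-fold feature construction.


def _encode_stream(dsets, train_idx, enc, cfg: PipelineConfig, seed: int):
    """Codebook (train only) → encode all → power → L2AL2W (train stats).

    Returns the normalized feature matrix for all subjects plus the fitted
    codebook centroids (for provenance/leakage checks).
    """
    pooled = np.vstack([dsets[i].descriptors for i in train_idx])
    n_words = cfg.bovw_words if enc == "bovw" else cfg.vlad_words
    codebook = fit_codebook(
        pooled, n_words, seed=seed, n_init=cfg.kmeans_n_init,
        train_fold_id=f"seed{seed}",
    )
    if enc == "bovw":
        rows = [
            encode_bovw(codebook, d, cfg.layout, exact=cfg.exact_assign).vector
            for d in dsets
        ]
    else:
        rows = [
            encode_vlad(
                codebook, d, cfg.layout, exact=cfg.exact_assign,
                intra_l2=cfg.vlad_intra_l2,
            ).vector
            for d in dsets
        ]
    X = power_normalize(np.vstack(rows), cfg.rho)
    norm = L2AL2W().fit(X[train_idx])
    return norm.transform(X), codebook


def _kernel_cfg(cfg: PipelineConfig, enc: str) -> KernelMapConfig:
    return cfg.kernel_map_bovw if enc == "bovw" else cfg.kernel_map_vlad


class _VolumeFeaturizer:
    """Encoded-stage pipeline: descriptors are extracted once (they depend
    only on the volume), everything supervised by fold membership is refit
    per fold."""

    supports_hybrid = True

    def __init__(self, records: list[SubjectRecord], cfg: PipelineConfig):
        self.cfg = cfg
        extractor = DenseDescriptorExtractor(cfg.geometry, cfg.layout,
                                             cfg.cache_dir)
        self.dsets = {
            "A": extractor.transform([r.volume_A for r in records]),
            "B": extractor.transform([r.volume_B for r in records]),
        }

    def fold_features(self, train_idx: np.ndarray, fold_seed: int):
        cfg = self.cfg
        feats: dict[tuple[str, str], np.ndarray] = {}
        artifacts: dict = {}
        for ei, enc in enumerate(cfg.needed_encodings):
            X_mod = {}
            for mi, mod in enumerate(("A", "B")):
                seed = (fold_seed * 4 + ei * 2 + mi) % (2**31)
                X_mod[mod], codebook = _encode_stream(
                    self.dsets[mod], train_idx, enc, cfg, seed
                )
                artifacts[f"codebook_{enc}_{mod}"] = codebook.centroids
            kmap = _kernel_cfg(cfg, enc)
            KA = apply_kernel_map(X_mod["A"], kmap)
            KB = apply_kernel_map(X_mod["B"], kmap)
            feats[("MRI", enc)] = KA
            feats[("PET", enc)] = KB
            feats[("MRIPET", enc)] = np.hstack([KA, KB])
            if cfg.cca_stage == "encoded":
                cca = CCAFusion(
                    n_components=cfg.cca_components, epsilon=cfg.epsilon
                ).fit(X_mod["A"][train_idx], X_mod["B"][train_idx])
                ZA, ZB = cca.transform(X_mod["A"], X_mod["B"])
                feats[("MRIPETLF", enc)] = augment_features(KA, KB, ZA, ZB).F
                artifacts[f"cca_{enc}_B1"] = cca.B1_
                artifacts[f"cca_{enc}_B2"] = cca.B2_
                artifacts[f"cca_{enc}_correlations"] = cca.correlations_
        return feats, artifacts


class _InputCCAFeaturizer:
    """Input-stage (filter-bank) pipeline: CCA is fit on flattened training
    volume intensities; each subject gains two pseudo-modalities rendered as
    the rank-c shared-structure reconstruction, which re-enter descriptor
    extraction.  The fused representation concatenates all four encoded
    streams."""

    supports_hybrid = True

    def __init__(self, records: list[SubjectRecord], cfg: PipelineConfig):
        self.cfg = cfg
        self.extractor = DenseDescriptorExtractor(cfg.geometry, cfg.layout,
                                                  cfg.cache_dir)
        self.volumes = {
            "A": np.stack([r.volume_A.voxels for r in records]),
            "B": np.stack([r.volume_B.voxels for r in records]),
        }
        self.shape = records[0].volume_A.voxels.shape
        self.dsets = {
            mod: self.extractor.transform(list(self.volumes[mod]))
            for mod in ("A", "B")
        }

    def fold_features(self, train_idx: np.ndarray, fold_seed: int):
        cfg = self.cfg
        flat = {m: v.reshape(v.shape[0], -1) for m, v in self.volumes.items()}
        cca = CCAFusion(n_components=cfg.cca_components, epsilon=cfg.epsilon).fit(
            flat["A"][train_idx], flat["B"][train_idx]
        )
        ZA, ZB = cca.transform(flat["A"], flat["B"])
        recon = {
            "Ac": np.clip(ZA @ cca.B1_.T + cca.mean1_, 0.0, None),
            "Bc": np.clip(ZB @ cca.B2_.T + cca.mean2_, 0.0, None),
        }
        dsets = dict(self.dsets)
        for key, mat in recon.items():
            vols = [row.reshape(self.shape) for row in mat]
            dsets[key] = self.extractor.transform(vols)

        feats: dict[tuple[str, str], np.ndarray] = {}
        artifacts = {
            "cca_input_B1": cca.B1_,
            "cca_input_B2": cca.B2_,
            "cca_input_correlations": cca.correlations_,
        }
        for ei, enc in enumerate(cfg.needed_encodings):
            streams = {}
            for si, stream in enumerate(("A", "B", "Ac", "Bc")):
                seed = (fold_seed * 8 + ei * 4 + si) % (2**31)
                X, codebook = _encode_stream(
                    dsets[stream], train_idx, enc, cfg, seed
                )
                streams[stream] = apply_kernel_map(X, _kernel_cfg(cfg, enc))
                artifacts[f"codebook_{enc}_{stream}"] = codebook.centroids
            feats[("MRI", enc)] = streams["A"]
            feats[("PET", enc)] = streams["B"]
            feats[("MRIPET", enc)] = np.hstack([streams["A"], streams["B"]])
            feats[("MRIPETLF", enc)] = np.hstack(
                [streams["A"], streams["Ac"], streams["B"], streams["Bc"]]
            )
        return feats, artifacts


class _VectorFeaturizer:
    """Direct feature-matrix pipeline for low-dimensional paired vectors:
    no encoding, CCA augmentation refit per fold."""

    supports_hybrid = False

    def __init__(self, X1: np.ndarray, X2: np.ndarray, cfg: PipelineConfig):
        self.X1 = np.asarray(X1, dtype=float)
        self.X2 = np.asarray(X2, dtype=float)
        self.cfg = cfg

    def fold_features(self, train_idx: np.ndarray, fold_seed: int):
        cfg = self.cfg
        enc = "vec"
        feats = {
            ("MRI", enc): self.X1,
            ("PET", enc): self.X2,
            ("MRIPET", enc): np.hstack([self.X1, self.X2]),
        }
        artifacts: dict = {}
        if cfg.cca_stage != "none":
            cca = CCAFusion(
                n_components=cfg.cca_components, epsilon=cfg.epsilon
            ).fit(self.X1[train_idx], self.X2[train_idx])
            Z1, Z2 = cca.transform(self.X1, self.X2)
            feats[("MRIPETLF", enc)] = augment_features(
                self.X1, self.X2, Z1, Z2
            ).F
            artifacts["cca_vec_B1"] = cca.B1_
            artifacts["cca_vec_correlations"] = cca.correlations_
        return feats, artifacts


# ---------------------------------------------------------------------------
# Inner model selection and the fold loop.


def _inner_splits(y: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount((np.asarray(y) == 1).astype(int), minlength=2)
    nf = min(n_folds, counts.min())
    if nf < 2:
        return None
    skf = StratifiedKFold(n_splits=int(nf), shuffle=True,
                          random_state=seed % (2**31))
    return list(skf.split(np.zeros((y.size, 1)), y))


def _select_C(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig, seed: int):
    """Pick C from the grid by inner-split accuracy; returns (C, oof scores).

    Ties go to the smaller C.  When an inner split is impossible (a class
    with a single member) the middle of the grid is used and the training
    decision values stand in for the out-of-fold scores.
    """
    splits = _inner_splits(y, cfg.inner_folds, seed)
    if splits is None:
        C = cfg.C_grid[len(cfg.C_grid) // 2]
        model = train_linear_svm(X, y, C)
        return C, model.decision_function(X)
    best = None
    for C in cfg.C_grid:
        oof = np.zeros(y.size)
        for tr, va in splits:
            m = train_linear_svm(X[tr], y[tr], C)
            oof[va] = m.decision_function(X[va])
        acc = float(np.mean(predict_from_scores(oof) == y))
        if best is None or acc > best[0]:
            best = (acc, C, oof)
    return best[1], best[2]


@dataclass
class EvalReport:
    """Cross-validation results: per-fold metrics plus aggregation.

    ``fold_metrics`` has one row per (repeat, fold, representation) with the
    seven metrics, the test-fold size and (for the hybrid representation)
    the selected fusion weight.  ``summary()`` aggregates mean ± SD over all
    k × repeats folds (the SD is across folds of all repeats, ignoring
    NaN-valued undefined metrics).
    """

    task: str
    k: int
    repeats: int
    seed: int
    config: dict
    fold_metrics: pd.DataFrame
    fold_assignments: list[dict] = field(default_factory=list)
    models: list[dict] | None = None

    def summary(self) -> pd.DataFrame:
        agg = self.fold_metrics.groupby("representation")[list(METRIC_NAMES)].agg(
            ["mean", "std"]
        )
        return agg

    def mean_metric(self, representation: str, metric: str = "ACC") -> float:
        rows = self.fold_metrics[
            self.fold_metrics["representation"] == representation
        ]
        return float(rows[metric].mean())

    def summary_text(self) -> str:
        """Human-readable table (percent, mean ± SD to 2 decimals)."""
        lines = [f"task: {self.task}  ({self.k}-fold x {self.repeats} repeats)"]
        header = "representation".ljust(12) + "".join(
            m.rjust(17) for m in METRIC_NAMES
        )
        lines.append(header)
        summ = self.summary()
        for rep in summ.index:
            cells = []
            for m in METRIC_NAMES:
                mean = summ.loc[rep, (m, "mean")] * 100.0
                sd = summ.loc[rep, (m, "std")] * 100.0
                cells.append(f"{mean:.2f} ± {sd:.2f}".rjust(17))
            lines.append(rep.ljust(12) + "".join(cells))
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "task": self.task,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "config": self.config,
            "fold_metrics": self.fold_metrics.to_dict(orient="list"),
            "fold_assignments": self.fold_assignments,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        payload = json.loads(Path(path).read_text())
        return cls(
            task=payload["task"],
            k=payload["k"],
            repeats=payload["repeats"],
            seed=payload["seed"],
            config=payload["config"],
            fold_metrics=pd.DataFrame(payload["fold_metrics"]),
            fold_assignments=payload["fold_assignments"],
        )

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: one row per representation × metric."""
        summ = self.summary()
        rows = []
        for rep in summ.index:
            for m in METRIC_NAMES:
                rows.append(
                    {
                        "task": self.task,
                        "representation": rep,
                        "metric": m,
                        "mean": summ.loc[rep, (m, "mean")],
                        "sd": summ.loc[rep, (m, "std")],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def _run_cv(featurizer, y, ids, cfg: PipelineConfig, k, repeats, seed,
            keep_models, name):
    y = np.asarray(y)
    counts = np.bincount((y == 1).astype(int), minlength=2)
    if counts.min() < k:
        raise InputDataError(
            f"stratified {k}-fold is impossible: the smaller class has only "
            f"{int(counts.min())} subjects"
        )
    reps = [
        r for r in cfg.representations
        if featurizer.supports_hybrid or r != "MRIPETHF"
    ]
    if "MRIPETHF" in cfg.representations and not featurizer.supports_hybrid:
        raise ConfigurationError(
            "the hybrid representation needs BoVW/VLAD encodings; it is not "
            "available for pre-featurized vector cohorts"
        )

    rskf = RepeatedStratifiedKFold(
        n_splits=k, n_repeats=repeats, random_state=seed % (2**31)
    )
    rows, assignments, models = [], [], []
    for fidx, (tr, te) in enumerate(rskf.split(np.zeros((y.size, 1)), y)):
        repeat, fold = fidx // k, fidx % k
        fold_seed = int(
            np.random.SeedSequence([seed, repeat, fold]).generate_state(1)[0]
            % (2**31)
        )
        feats, artifacts = featurizer.fold_features(tr, fold_seed)
        fold_models = {"repeat": repeat, "fold": fold, "train": tr.copy(),
                       "test": te.copy(), **artifacts}
        for rep in reps:
            alpha = float("nan")
            if rep == "MRIPETHF":
                Xb = feats[("MRIPETLF", "bovw")]
                Xv = feats[("MRIPETLF", "vlad")]
                Cb, oof_b = _select_C(Xb[tr], y[tr], cfg, fold_seed + 1)
                Cv, oof_v = _select_C(Xv[tr], y[tr], cfg, fold_seed + 2)
                alpha = select_fusion_weight(oof_b, oof_v, y[tr],
                                             cfg.alpha_grid)
                mb = train_linear_svm(Xb[tr], y[tr], Cb)
                mv = train_linear_svm(Xv[tr], y[tr], Cv)
                scores = alpha * mb.decision_function(Xb[te]) + (
                    1.0 - alpha
                ) * mv.decision_function(Xv[te])
                if keep_models:
                    fold_models[f"svm_{rep}_bovw_coef"] = mb.coef_.copy()
                    fold_models[f"svm_{rep}_vlad_coef"] = mv.coef_.copy()
                    fold_models[f"svm_{rep}_alpha"] = alpha
            else:
                enc = (
                    "vec"
                    if not featurizer.supports_hybrid
                    else cfg.primary_encoding
                )
                X = feats[(rep, enc)]
                C, _ = _select_C(X[tr], y[tr], cfg, fold_seed + 3)
                m = train_linear_svm(X[tr], y[tr], C)
                scores = m.decision_function(X[te])
                if keep_models:
                    fold_models[f"svm_{rep}_coef"] = m.coef_.copy()
                    fold_models[f"svm_{rep}_intercept"] = m.intercept_.copy()
            pred = predict_from_scores(scores)
            met = compute_metrics(y[te], pred, scores)
            rows.append(
                {
                    "repeat": repeat,
                    "fold": fold,
                    "representation": rep,
                    "n_test": int(te.size),
                    "alpha": alpha,
                    **met,
                }
            )
        assignments.append(
            {"repeat": repeat, "fold": fold,
             "test": [str(s) for s in np.asarray(ids)[te]]}
        )
        if keep_models:
            models.append(fold_models)

    return EvalReport(
        task=name,
        k=k,
        repeats=repeats,
        seed=seed,
        config=cfg.to_dict(),
        fold_metrics=pd.DataFrame(rows),
        fold_assignments=assignments,
        models=models if keep_models else None,
    )


def run_repeated_cv(
    records: list[SubjectRecord],
    task: tuple[str, str] = ("AD", "NC"),
    cfg: PipelineConfig = PipelineConfig(),
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    keep_models: bool = False,
) -> EvalReport:
    """Evaluate the volume pipeline on one binary task.

    Every fold refits the full stack on the training fold only; the report
    is bit-reproducible given ``seed``.
    """
    labels = np.asarray([r.label for r in records], dtype=object)
    idx, y = task_subset(labels, task)
    subset = [records[i] for i in idx]
    ids = np.asarray([r.subject_id for r in subset])
    if cfg.cca_stage == "input":
        featurizer = _InputCCAFeaturizer(subset, cfg)
    else:
        featurizer = _VolumeFeaturizer(subset, cfg)
    return _run_cv(featurizer, y, ids, cfg, k, repeats, seed, keep_models,
                   task_name(task))


def run_vector_cv(
    X1: np.ndarray,
    X2: np.ndarray,
    labels: np.ndarray,
    task: tuple[str, str] = ("AD", "NC"),
    cfg: PipelineConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    keep_models: bool = False,
) -> EvalReport:
    """Evaluate the CCA-augmentation pipeline on paired feature matrices."""
    if cfg is None:
        cfg = PipelineConfig(
            representations=("MRI", "PET", "MRIPET", "MRIPETLF")
        )
    idx, y = task_subset(np.asarray(labels, dtype=object), task)
    featurizer = _VectorFeaturizer(np.asarray(X1)[idx], np.asarray(X2)[idx],
                                   cfg)
    ids = np.asarray([f"sub-{i:04d}" for i in idx])
    return _run_cv(featurizer, y, ids, cfg, k, repeats, seed, keep_models,
                   task_name(task))
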