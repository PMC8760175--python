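"""Multi-modal feature fusion: PCA-reduced fingerprints + z-scored descriptors.

A fused feature vector concatenates (a) the projection of a centered
2048-bit fingerprint block onto its principal axes and (b) the per-column
z-scored quantitative descriptor block.  The default component count is
``min(n_samples, n_features)`` — full rank — so the projection loses no
variance (the explained-variance ratios sum to 1) and the fused width on n
training molecules is ``n + d`` (356 + 108 = 464 at the reference scale).

By default the fusion statistics (PCA loadings, column means/stds) are
fitted once on the full dataset before cross-validation; ``fold_safe``
callers may instead refit inside each training fold.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.decomposition import PCA

from aievote.dataio import Dataset
from aievote.featurize import (
    FINGERPRINT_MODES,
    QUANTITATIVE_MODE,
    FeatureBlock,
    FeaturizeConfig,
    featurize_dataset,
)

FUSION_SCHEMA_VERSION = 1


def multimodal_mode_name(fingerprint_mode: str) -> str:
    return f"{fingerprint_mode}+quantitative"


@dataclasses.dataclass
class FusionModel:
    """Fitted fusion statistics for one fingerprint mode.

    ``components`` holds the principal-axis loadings with shape (k,
    n_features); ``fingerprint_center`` is the column mean removed before
    projection.  Quantitative columns are standardized with the stored
    means/stds; a constant column (std 0) maps to 0.
    """

    components: np.ndarray
    explained_variance_ratio: np.ndarray
    fingerprint_center: np.ndarray
    column_means: np.ndarray
    column_stds: np.ndarray
    fingerprint_mode: str = "morgan"
    descriptor_hash: str = ""

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio)
        if (evr < -1e-12).any():
            raise ValueError("explained variance ratios must be non-negative")
        if (np.diff(evr) > 1e-12).any():
            raise ValueError("explained variance ratios must be non-increasing")
        if (np.asarray(self.column_stds) < 0).any():
            raise ValueError("column stds must be non-negative")

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def d(self) -> int:
        return self.column_means.shape[0]

    def transform_fingerprints(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape[1] != self.components.shape[1]:
            raise ValueError(
                f"fingerprint width {matrix.shape[1]} != fitted {self.components.shape[1]}"
            )
        return (matrix - self.fingerprint_center) @ self.components.T

    def transform_quantitative(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape[1] != self.d:
            raise ValueError(f"descriptor width {matrix.shape[1]} != fitted {self.d}")
        stds = np.where(self.column_stds > 0, self.column_stds, 1.0)
        z = (matrix - self.column_means) / stds
        z[:, self.column_stds == 0] = 0.0
        return z

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "schema_version": FUSION_SCHEMA_VERSION,
            "fingerprint_mode": self.fingerprint_mode,
            "descriptor_hash": self.descriptor_hash,
        }
        np.savez(
            path,
            components=self.components,
            explained_variance_ratio=self.explained_variance_ratio,
            fingerprint_center=self.fingerprint_center,
            column_means=self.column_means,
            column_stds=self.column_stds,
            meta=np.array(json.dumps(meta)),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FusionModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["schema_version"] != FUSION_SCHEMA_VERSION:
                raise ValueError(f"unsupported fusion schema {meta['schema_version']}")
            return cls(
                components=data["components"],
                explained_variance_ratio=data["explained_variance_ratio"],
                fingerprint_center=data["fingerprint_center"],
                column_means=data["column_means"],
                column_stds=data["column_stds"],
                fingerprint_mode=meta["fingerprint_mode"],
                descriptor_hash=meta["descriptor_hash"],
            )


@dataclasses.dataclass
class FusedBlock:
    """A molecules x (k + d) fused feature matrix with provenance."""

    matrix: np.ndarray
    k: int
    d: int
    provenance: tuple[str, str]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != self.k + self.d:
            raise ValueError(
                f"fused width {self.matrix.shape[1]} != k + d = {self.k + self.d}"
            )


def fit_fusion(
    fingerprint_block: FeatureBlock,
    quantitative_block: FeatureBlock,
    k: int | None = None,
) -> FusionModel:
    """Fit PCA on the fingerprint block and z-score stats on the descriptors.

    Default ``k`` is ``min(n_samples, n_features)``: all variance retained.
    """
    fp = fingerprint_block.matrix
    qt = quantitative_block.matrix
    if fp.shape[0] != qt.shape[0]:
        raise ValueError(
            f"row mismatch: {fp.shape[0]} fingerprint vs {qt.shape[0]} quantitative"
        )
    if fingerprint_block.row_ids != quantitative_block.row_ids:
        raise ValueError("fingerprint and quantitative blocks are not row-aligned")
    n, p = fp.shape
    if n < 2:
        raise ValueError("need at least 2 samples to fit fusion")
    k_max = min(n, p)
    if k is None:
        k = k_max
    if not 1 <= k <= k_max:
        raise ValueError(f"k must be in [1, {k_max}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(fp)
    import hashlib

    names = quantitative_block.feature_names or []
    dhash = hashlib.sha256("\n".join(names).encode()).hexdigest()[:12]
    return FusionModel(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        fingerprint_center=pca.mean_,
        column_means=qt.mean(axis=0),
        column_stds=qt.std(axis=0, ddof=0),
        fingerprint_mode=fingerprint_block.mode,
        descriptor_hash=dhash,
    )


def apply_fusion(
    model: FusionModel,
    fingerprint_block: FeatureBlock,
    quantitative_block: FeatureBlock,
) -> FusedBlock:
    """Project fingerprints onto the fitted axes and append z-scored descriptors."""
    if fingerprint_block.matrix.shape[0] != quantitative_block.matrix.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    projected = model.transform_fingerprints(fingerprint_block.matrix)
    scaled = model.transform_quantitative(quantitative_block.matrix)
    return FusedBlock(
        matrix=np.hstack([projected, scaled]),
        k=model.k,
        d=model.d,
        provenance=(model.fingerprint_mode, model.descriptor_hash),
    )


@dataclasses.dataclass
class ModeMatrices:
    """Feature matrices per mode plus any fitted fusion models."""

    matrices: dict[str, np.ndarray]
    fusion: dict[str, FusionModel]
    modality: str

    @property
    def modes(self) -> list[str]:
        return list(self.matrices)


def assemble_modes(
    dataset: Dataset,
    config: FeaturizeConfig | None = None,
    multimodal: bool = False,
    fingerprint_modes: tuple[str, ...] = FINGERPRINT_MODES,
    cache_dir: str | Path | None = None,
    blocks: Mapping[str, FeatureBlock] | None = None,
    k: int | None = None,
) -> ModeMatrices:
    """Build the per-mode training matrices.

    Single-modal: one raw matrix per fingerprint mode plus the raw
    quantitative matrix (five modes by default).  Multi-modal: one fused
    matrix per fingerprint mode (four by default), each fitted on the
    given dataset.  Precomputed ``blocks`` may be passed to skip
    featurization.
    """
    for mode in fingerprint_modes:
        if mode not in FINGERPRINT_MODES:
            raise ValueError(f"unknown fingerprint mode {mode!r}")
    if not fingerprint_modes:
        raise ValueError("no fingerprint modes enabled")
    config = config or FeaturizeConfig()
    if blocks is None:
        blocks = {
            m: featurize_dataset(dataset, m, config, cache_dir)
            for m in (*fingerprint_modes, QUANTITATIVE_MODE)
        }
    quant = blocks[QUANTITATIVE_MODE]
    if not multimodal:
        matrices = {m: blocks[m].matrix for m in fingerprint_modes}
        matrices[QUANTITATIVE_MODE] = quant.matrix
        return ModeMatrices(matrices, {}, "single")
    matrices = {}
    fusion = {}
    for m in fingerprint_modes:
        model = fit_fusion(blocks[m], quant, k=k)
        fused = apply_fusion(model, blocks[m], quant)
        matrices[multimodal_mode_name(m)] = fused.matrix
        fusion[m] = model
    return ModeMatrices(matrices, fusion, "multi")
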