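"""The five single-modal molecular representations.

Four hashed binary fingerprints, each folded to a uniform 2048 bits so the
modes are directly comparable:

* ``morgan`` — circular (ECFP-style) environments up to a radius, default 2;
* ``daylight_path`` — hashed linear bond paths of length 1-7, the classic
  topological/path fingerprint family;
* ``atom_pair`` — (atom type, atom type, shortest-path distance) triples;
* ``torsion`` — topological torsions over bonded paths of four heavy atoms;

plus ``quantitative`` — a 108-dimensional real vector of 1D/2D RDKit
descriptors (see :mod:`aievote.descriptors`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from aievote.dataio import Dataset, InvalidSMILESError
from aievote.descriptors import (
    DEFAULT_DESCRIPTOR_NAMES,
    ONE_D_DESCRIPTORS,
    descriptor_function,
)

FINGERPRINT_MODES = ("morgan", "daylight_path", "atom_pair", "torsion")
QUANTITATIVE_MODE = "quantitative"
MODES = FINGERPRINT_MODES + (QUANTITATIVE_MODE,)


class FeaturizationError(ValueError):
    """A molecule could not be featurized; the message names the record."""


@dataclasses.dataclass(frozen=True)
class FingerprintSpec:
    """Parameters of one hashed binary fingerprint.

    ``radius`` applies to the morgan kind; ``min_path``/``max_path`` to the
    path kind; ``torsion_size`` is the number of heavy atoms in a torsion.
    """

    kind: str = "morgan"
    n_bits: int = 2048
    radius: int = 2
    min_path: int = 1
    max_path: int = 7
    torsion_size: int = 4

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_MODES:
            raise ValueError(f"kind must be one of {FINGERPRINT_MODES}, got {self.kind!r}")
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.min_path > self.max_path:
            raise ValueError("min_path must be <= max_path")

    def make_generator(self):
        if self.kind == "morgan":
            return rdFingerprintGenerator.GetMorganGenerator(
                radius=self.radius, fpSize=self.n_bits
            )
        if self.kind == "daylight_path":
            return rdFingerprintGenerator.GetRDKitFPGenerator(
                minPath=self.min_path, maxPath=self.max_path, fpSize=self.n_bits
            )
        if self.kind == "atom_pair":
            return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=self.n_bits)
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(
            torsionAtomCount=self.torsion_size, fpSize=self.n_bits
        )


@dataclasses.dataclass(frozen=True)
class DescriptorSpec:
    """An ordered list of RDKit descriptor names with its 1D/2D split."""

    names: tuple[str, ...] = DEFAULT_DESCRIPTOR_NAMES
    n_1d: int = len(ONE_D_DESCRIPTORS)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        if not 0 <= self.n_1d <= len(self.names):
            raise ValueError("n_1d out of range")
        for name in self.names:
            descriptor_function(name)  # raises on unknown names

    @property
    def n_2d(self) -> int:
        return len(self.names) - self.n_1d


@dataclasses.dataclass(frozen=True)
class FeaturizeConfig:
    """Fingerprint and descriptor parameters for all five modes."""

    n_bits: int = 2048
    morgan_radius: int = 2
    min_path: int = 1
    max_path: int = 7
    descriptor_names: tuple[str, ...] = DEFAULT_DESCRIPTOR_NAMES

    def fingerprint_spec(self, kind: str) -> FingerprintSpec:
        return FingerprintSpec(
            kind=kind,
            n_bits=self.n_bits,
            radius=self.morgan_radius,
            min_path=self.min_path,
            max_path=self.max_path,
        )

    def descriptor_spec(self) -> DescriptorSpec:
        n_1d = sum(1 for n in self.descriptor_names if n in ONE_D_DESCRIPTORS)
        return DescriptorSpec(tuple(self.descriptor_names), n_1d)

    def spec_dict(self, mode: str) -> dict:
        if mode == QUANTITATIVE_MODE:
            return {"mode": mode, "names": list(self.descriptor_names)}
        spec = self.fingerprint_spec(mode)
        return {"mode": mode, **dataclasses.asdict(spec)}


@dataclasses.dataclass
class FeatureBlock:
    """A (molecules x features) matrix for one feature mode."""

    mode: str
    matrix: np.ndarray
    row_ids: list[str]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.row_ids):
            raise ValueError("row count must equal number of row ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"non-finite values in {self.mode} feature block")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _mol_from_smiles(smiles: str, record: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" (record {record})" if record else ""
        raise InvalidSMILESError(f"unparseable SMILES{who}: {smiles!r}")
    return mol


def compute_fingerprint(smiles: str, spec: FingerprintSpec) -> np.ndarray:
    """Hashed binary fingerprint of one molecule as a 0/1 vector of n_bits."""
    mol = _mol_from_smiles(smiles)
    fp = spec.make_generator().GetFingerprint(mol)
    arr = np.zeros(spec.n_bits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def compute_descriptor_vector(
    smiles: str, spec: DescriptorSpec | None = None, record: str | None = None
) -> np.ndarray:
    """Quantitative descriptor vector in spec order; all entries finite."""
    spec = spec or DescriptorSpec()
    mol = _mol_from_smiles(smiles, record)
    values = np.empty(len(spec.names), dtype=np.float64)
    for i, name in enumerate(spec.names):
        try:
            values[i] = float(descriptor_function(name)(mol))
        except Exception as exc:  # a descriptor can raise on exotic inputs
            raise FeaturizationError(
                f"descriptor {name!r} failed on record {record or smiles!r}: {exc}"
            ) from exc
        if not math.isfinite(values[i]):
            raise FeaturizationError(
                f"descriptor {name!r} is non-finite on record {record or smiles!r}"
            )
    return values


def dataset_hash(dataset: Dataset) -> str:
    """Stable hex digest of the ordered (id, smiles) pairs of a dataset."""
    h = hashlib.sha256()
    for rec in dataset:
        h.update(rec.id.encode())
        h.update(b"\x00")
        h.update(rec.smiles.encode())
        h.update(b"\x01")
    return h.hexdigest()[:16]


def _cache_paths(cache_dir: Path, dataset: Dataset, mode: str, spec: dict) -> tuple[Path, Path]:
    key_src = json.dumps({"dataset": dataset_hash(dataset), "spec": spec}, sort_keys=True)
    key = hashlib.sha256(key_src.encode()).hexdigest()[:16]
    return cache_dir / f"{mode}-{key}.npy", cache_dir / f"{mode}-{key}.json"


def featurize_dataset(
    dataset: Dataset,
    mode: str,
    config: FeaturizeConfig | None = None,
    cache_dir: str | Path | None = None,
) -> FeatureBlock:
    """Featurize every record of a dataset under one mode.

    Rows are aligned with dataset order.  Per-record failures are collected
    and raised together as one :class:`FeaturizationError`.  When
    ``cache_dir`` is given, the matrix is cached on disk keyed by the
    dataset hash and the mode spec, with a JSON sidecar recording both.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    config = config or FeaturizeConfig()
    spec_dict = config.spec_dict(mode)

    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        npy_path, meta_path = _cache_paths(cache_dir, dataset, mode, spec_dict)
        if npy_path.exists() and meta_path.exists():
            matrix = np.load(npy_path)
            names = json.loads(meta_path.read_text()).get("feature_names")
            return FeatureBlock(mode, matrix, dataset.ids, names)

    failures: list[str] = []
    rows: list[np.ndarray] = []
    feature_names: list[str] | None = None
    if mode == QUANTITATIVE_MODE:
        dspec = config.descriptor_spec()
        feature_names = list(dspec.names)
        for rec in dataset:
            try:
                rows.append(compute_descriptor_vector(rec.smiles, dspec, rec.id))
            except (FeaturizationError, InvalidSMILESError) as exc:
                failures.append(str(exc))
    else:
        fspec = config.fingerprint_spec(mode)
        for rec in dataset:
            try:
                rows.append(compute_fingerprint(rec.smiles, fspec))
            except InvalidSMILESError as exc:
                failures.append(str(exc))
    if failures:
        raise FeaturizationError(
            f"{len(failures)} record(s) failed in mode {mode}:\n" + "\n".join(failures)
        )
    block = FeatureBlock(mode, np.vstack(rows), dataset.ids, feature_names)

    if cache_dir is not None:
        np.save(npy_path, block.matrix)
        import rdkit

        meta = {
            "spec": spec_dict,
            "dataset_hash": dataset_hash(dataset),
            "rdkit_version": rdkit.__version__,
            "feature_names": feature_names,
            "shape": list(block.matrix.shape),
        }
        meta_path.write_text(json.dumps(meta, indent=1))
    return block


def featurize_all(
    dataset: Dataset,
    config: FeaturizeConfig | None = None,
    cache_dir: str | Path | None = None,
    modes: Sequence[str] = MODES,
) -> dict[str, FeatureBlock]:
    """Convenience: featurize a dataset under every requested mode."""
    return {m: featurize_dataset(dataset, m, config, cache_dir) for m in modes}
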