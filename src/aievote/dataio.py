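"""Reading, validation and writing of labeled SMILES tables.

The unit of data is one molecule: an identifier, a canonical SMILES string
and an optional binary AIE/ACQ label.  Structures are canonicalized with
RDKit; multi-fragment inputs (salts, solvates) are reduced to their largest
organic fragment before anything downstream sees them.  Rows whose SMILES
does not parse are never silently dropped — they are collected into a
rejection report the caller can persist.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Positive class: emission turns ON upon aggregation (the minority class).
AIE = "AIE"
#: Negative class: emission is quenched upon aggregation.
ACQ = "ACQ"

LABELS = (AIE, ACQ)

#: Accepted spellings for each class (case-insensitive), including 1/0 aliases.
DEFAULT_LABEL_ALIASES: Mapping[str, str] = {
    "aie": AIE,
    "acq": ACQ,
    "1": AIE,
    "0": ACQ,
    "true": AIE,
    "false": ACQ,
}


class DataError(ValueError):
    """Fatal problem with an input table (missing file/column, no valid rows...)."""


class InvalidSMILESError(ValueError):
    """A SMILES string that RDKit cannot parse into a molecule."""


@dataclasses.dataclass(frozen=True)
class MoleculeRecord:
    """One canonicalized molecule with an optional AIE/ACQ label."""

    id: str
    smiles: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclasses.dataclass(frozen=True)
class RejectedRow:
    """A row that failed validation, with the reason it was rejected."""

    id: str
    smiles: str
    reason: str


@dataclasses.dataclass
class Dataset:
    """An ordered collection of molecule records with unique ids."""

    records: list[MoleculeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DataError(f"duplicate record id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(r.label for r in self.records if r.label is not None)
        return {c: counts.get(c, 0) for c in LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "smiles": self.smiles, "label": self.labels}
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def canonicalize_smiles(smiles: str, keep_largest_fragment: bool = True) -> str:
    """Return the RDKit canonical SMILES, reduced to the largest fragment.

    Canonicalization is idempotent: applying it to its own output returns
    the same string.  Raises :class:`InvalidSMILESError` on parse failure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"unparseable SMILES: {smiles!r}")
    if keep_largest_fragment and "." in Chem.MolToSmiles(mol):
        mol = _FRAGMENT_CHOOSER.choose(mol)
    return Chem.MolToSmiles(mol)


def parse_label(
    raw: object, aliases: Mapping[str, str] = DEFAULT_LABEL_ALIASES
) -> str:
    """Map a raw label cell onto the canonical AIE/ACQ vocabulary."""
    key = str(raw).strip().lower()
    # "1.0"/"0.0" appear when pandas reads an integer label column as float
    if key.endswith(".0"):
        key = key[:-2]
    if key not in aliases:
        raise DataError(f"unrecognized label {raw!r}; accepted: {sorted(set(aliases))}")
    return aliases[key]


def _build_dataset(
    rows: Iterable[tuple[str, str, object | None]],
    label_aliases: Mapping[str, str],
) -> tuple[Dataset, list[RejectedRow]]:
    records: list[MoleculeRecord] = []
    rejected: list[RejectedRow] = []
    seen_ids: set[str] = set()
    for rec_id, smiles, raw_label in rows:
        if rec_id in seen_ids:
            raise DataError(f"duplicate record id: {rec_id!r}")
        seen_ids.add(rec_id)
        try:
            canonical = canonicalize_smiles(smiles)
            label = None if raw_label is None else parse_label(raw_label, label_aliases)
        except (InvalidSMILESError, DataError) as exc:
            rejected.append(RejectedRow(rec_id, str(smiles), str(exc)))
            continue
        records.append(MoleculeRecord(rec_id, canonical, label))
    if not records:
        raise DataError("no valid rows in input")
    return Dataset(records), rejected


def read_dataset(
    path: str | Path,
    smiles_column: str = "smiles",
    label_column: str | None = "label",
    id_column: str | None = "id",
    label_aliases: Mapping[str, str] = DEFAULT_LABEL_ALIASES,
) -> tuple[Dataset, list[RejectedRow]]:
    """Read a labeled molecule table from CSV.

    Returns the dataset of valid, canonicalized molecules together with the
    rejection report for rows that failed SMILES parsing or label parsing.
    Pass ``label_column=None`` to read an unlabeled prediction set.  When
    ``id_column`` is absent from the file, row numbers are used as ids.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str)
    for col in filter(None, [smiles_column, label_column]):
        if col not in frame.columns:
            raise DataError(f"column {col!r} not found in {path} (has {list(frame.columns)})")
    if id_column is not None and id_column in frame.columns:
        ids = frame[id_column].astype(str).tolist()
    else:
        ids = [f"row{i}" for i in range(len(frame))]
    labels: Sequence[object | None]
    if label_column is None:
        labels = [None] * len(frame)
    else:
        labels = frame[label_column].tolist()
    rows = zip(ids, frame[smiles_column].astype(str).tolist(), labels)
    return _build_dataset(rows, label_aliases)


def read_smi_file(
    path: str | Path,
    label_aliases: Mapping[str, str] = DEFAULT_LABEL_ALIASES,
) -> tuple[Dataset, list[RejectedRow]]:
    """Read a ``.smi`` file: whitespace-separated ``SMILES id [label]`` lines."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    rows: list[tuple[str, str, object | None]] = []
    for i, line in enumerate(path.read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        smiles = parts[0]
        rec_id = parts[1] if len(parts) > 1 else f"line{i}"
        label = parts[2] if len(parts) > 2 else None
        rows.append((rec_id, smiles, label))
    if not rows:
        raise DataError(f"no molecule lines in {path}")
    return _build_dataset(rows, label_aliases)


def write_predictions(
    dataset: Dataset,
    tallies: Sequence[Mapping[str, int]],
    final: Sequence[str],
    path: str | Path,
) -> Path:
    """Write per-record vote tallies and final labels to CSV.

    Columns: ``id, smiles, votes_AIE, votes_ACQ, predicted_label,
    vote_fraction`` where ``vote_fraction`` is the fraction of voters that
    chose AIE.  The file round-trips losslessly through ``pd.read_csv``.
    """
    if len(tallies) == 0:
        raise DataError("empty vote set")
    if not (len(dataset) == len(tallies) == len(final)):
        raise DataError(
            f"length mismatch: {len(dataset)} records, "
            f"{len(tallies)} tallies, {len(final)} final labels"
        )
    votes_aie = [int(t.get(AIE, 0)) for t in tallies]
    votes_acq = [int(t.get(ACQ, 0)) for t in tallies]
    total = [a + q for a, q in zip(votes_aie, votes_acq)]
    if min(total) == 0:
        raise DataError("a record has zero votes")
    frame = pd.DataFrame(
        {
            "id": dataset.ids,
            "smiles": dataset.smiles,
            "votes_AIE": votes_aie,
            "votes_ACQ": votes_acq,
            "predicted_label": list(final),
            "vote_fraction": [a / t for a, t in zip(votes_aie, total)],
        }
    )
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def write_rejections(rejected: Sequence[RejectedRow], path: str | Path) -> Path:
    """Persist a rejection report as CSV with columns id, smiles, reason."""
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(r) for r in rejected],
                 columns=["id", "smiles", "reason"]).to_csv(path, index=False)
    return path
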