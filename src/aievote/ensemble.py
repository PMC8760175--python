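"""Majority-vote ensembling over (classifier family, feature mode) voters.

Every voter casts a hard AIE/ACQ label for each molecule and the category
with more votes wins: 25 voters in the single-modal setting (5 families x
5 modes), 20 in the multi-modal one (5 families x 4 fused modes).  The
vote fraction (share of voters choosing AIE) doubles as the ensemble's
soft score for ROC/AUC purposes.  An even panel can tie; the default tie
policy predicts the training-majority class (ACQ) and flags the record.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from aievote.dataio import ACQ, AIE
from aievote.models import TunedClassifier, predict_labels

TIE_POLICIES = ("majority-class", "aie", "acq")


@dataclasses.dataclass
class VoteRecord:
    """Vote tally and final category for one molecule."""

    id: str
    tally: dict[str, int]
    final: str
    vote_fraction: float
    tied: bool = False

    def __post_init__(self) -> None:
        if self.final not in (AIE, ACQ):
            raise ValueError(f"final must be AIE or ACQ, got {self.final!r}")


@dataclasses.dataclass
class VotePanel:
    """An ordered list of fitted voters with its modality."""

    voters: list[TunedClassifier]
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in ("single", "multi"):
            raise ValueError("modality must be 'single' or 'multi'")
        if not self.voters:
            raise ValueError("empty voter panel")

    def __len__(self) -> int:
        return len(self.voters)

    def manifest(self) -> list[dict]:
        return [
            {
                "family": v.family,
                "mode": v.mode,
                "chosen_params": v.chosen_params,
                "inner_cv_score": v.inner_cv_score,
                "seed": v.seed,
            }
            for v in self.voters
        ]


def enumerate_voters(
    families: Sequence[str], modes: Sequence[str], modality: str
) -> list[tuple[str, str]]:
    """(family, mode) pairs in deterministic family-major order."""
    if not families or not modes:
        raise ValueError("families and modes must be non-empty")
    if modality not in ("single", "multi"):
        raise ValueError("modality must be 'single' or 'multi'")
    return [(f, m) for f in families for m in modes]


def majority_vote(
    votes: Sequence[str],
    tie_break: str = "majority-class",
    majority_class: str = ACQ,
) -> VoteRecord:
    """Tally a list of AIE/ACQ votes; the category with more votes wins."""
    if len(votes) == 0:
        raise ValueError("empty vote list")
    if tie_break not in TIE_POLICIES:
        raise ValueError(f"unknown tie policy {tie_break!r}")
    n_aie = sum(1 for v in votes if v == AIE)
    n_acq = len(votes) - n_aie
    tied = n_aie == n_acq
    if n_aie > n_acq:
        final = AIE
    elif n_acq > n_aie:
        final = ACQ
    else:
        final = {"majority-class": majority_class, "aie": AIE, "acq": ACQ}[tie_break]
    return VoteRecord(
        id="",
        tally={AIE: n_aie, ACQ: n_acq},
        final=final,
        vote_fraction=n_aie / len(votes),
        tied=tied,
    )


def ensemble_predict(
    panel: VotePanel,
    matrices: Mapping[str, np.ndarray],
    ids: Sequence[str] | None = None,
    tie_break: str = "majority-class",
    majority_class: str = ACQ,
) -> list[VoteRecord]:
    """Majority-vote prediction for every row of the per-mode matrices."""
    missing = {v.mode for v in panel.voters} - set(matrices)
    if missing:
        raise ValueError(f"no feature matrix for mode(s): {sorted(missing)}")
    n_rows = {m.shape[0] for m in matrices.values()}
    if len(n_rows) != 1:
        raise ValueError("per-mode matrices disagree on row count")
    n = n_rows.pop()
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length must match matrix rows")
    # votes: (n_voters, n_records)
    all_votes = np.stack(
        [predict_labels(v, matrices[v.mode]) for v in panel.voters]
    )
    records = []
    for j in range(n):
        rec = majority_vote(list(all_votes[:, j]), tie_break, majority_class)
        rec.id = ids[j]
        records.append(rec)
    return records


def train_panel(
    families: Sequence[str],
    matrices: Mapping[str, np.ndarray],
    y: Sequence[str],
    modality: str,
    inner_folds: int = 5,
    seed: int = 0,
    grid_preset: str = "full",
    scoring: str = "accuracy",
) -> VotePanel:
    """Tune and fit one voter per (family, mode) on the given training data."""
    from aievote.models import build_grid, tune_classifier

    pairs = enumerate_voters(families, list(matrices), modality)
    voters = [
        tune_classifier(
            build_grid(family, grid_preset),
            matrices[mode],
            y,
            inner_folds=inner_folds,
            seed=seed,
            mode=mode,
            scoring=scoring,
        )
        for family, mode in pairs
    ]
    return VotePanel(voters, modality)
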