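"""Core containers: protein records, feature views, multi-view datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids in alphabetical one-letter order.  All
#: composition vectors are indexed in this order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinRecord:
    """One protein: accession, sanitized sequence, and its location set.

    ``labels`` may be empty at prediction time; a training record must
    carry at least one location.
    """

    accession: str
    sequence: str
    labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in STANDARD_AA:
                raise ValueError(
                    f"{self.accession}: non-standard residue {ch!r} at "
                    f"position {pos + 1} (sanitize or drop the record)"
                )


def sanitize_sequence(raw: str, *, accession: str = "?") -> str:
    """Uppercase, map selenocysteine U->C, and reject anything else
    outside the 20 standard residues.

    Silent coercion of ambiguity codes (B/Z/J/X) or gaps would corrupt
    composition features, so they raise instead.
    """
    seq = raw.strip().upper().replace("U", "C")
    for pos, ch in enumerate(seq):
        if ch not in STANDARD_AA:
            raise ValueError(
                f"{accession}: invalid residue {ch!r} at position {pos + 1}"
            )
    if not seq:
        raise ValueError(f"{accession}: empty sequence")
    return seq


@dataclass
class FeatureView:
    """A named n x d feature matrix, row-aligned with the dataset."""

    name: str
    matrix: np.ndarray
    column_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"view {self.name!r}: matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"view {self.name!r}: non-finite entries")
        if self.column_names is not None and len(self.column_names) != self.matrix.shape[1]:
            raise ValueError(f"view {self.name!r}: column_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MultiViewDataset:
    """n samples described in m feature views with a {-1,+1} label matrix.

    ``Y[i, k] == +1`` iff sample i carries label k.  ``ground_truth``
    is populated by the synthetic generator only.
    """

    accessions: list[str]
    views: list[FeatureView]
    Y: np.ndarray | None = None
    label_names: list[str] | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.accessions)
        if len(set(self.accessions)) != n:
            raise ValueError("duplicate accessions in dataset")
        if not self.views:
            raise ValueError("dataset needs at least one feature view")
        for v in self.views:
            if v.n_samples != n:
                raise ValueError(
                    f"view {v.name!r} has {v.n_samples} rows, expected {n}"
                )
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=int)
            if self.Y.shape[0] != n:
                raise ValueError("label matrix row count mismatch")
            if not np.isin(self.Y, (-1, 1)).all():
                raise ValueError("label matrix entries must be -1 or +1")
            if self.label_names is not None and len(self.label_names) != self.Y.shape[1]:
                raise ValueError("label_names length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.accessions)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_labels(self) -> int:
        if self.Y is None:
            raise ValueError("dataset has no labels")
        return self.Y.shape[1]

    def subset(self, idx: np.ndarray) -> "MultiViewDataset":
        """Row subset (order-preserving fancy indexing)."""
        idx = np.asarray(idx)
        return MultiViewDataset(
            accessions=[self.accessions[i] for i in idx],
            views=[
                FeatureView(v.name, v.matrix[idx], v.column_names) for v in self.views
            ],
            Y=None if self.Y is None else self.Y[idx],
            label_names=self.label_names,
            ground_truth=self.ground_truth,
        )
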