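"""Sequence- and annotation-based feature views.

Five views are used for the localization problem: three binary GO-term
indicator views (biological process, molecular function, cellular
component), amino-acid composition (AAC), and pseudo amino-acid
composition (PseAAC), which augments AAC with ``lam`` sequence-order
correlation factors computed from physicochemical residue properties.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np

from .data import STANDARD_AA, FeatureView

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

# Classic physicochemical triple used for PseAAC correlation factors:
# hydrophobicity, hydrophilicity (Hopp-Woods), and side-chain mass.
# Values are standardized (zero mean / unit variance over the 20
# residues) before use, so only relative differences matter.
PROPERTY_TABLE: dict[str, dict[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
        "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
        "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
        "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
    },
    "side_chain_mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
        "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
        "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
        "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
    },
}


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    for pos, ch in enumerate(sequence):
        if ch not in _AA_INDEX:
            raise ValueError(
                f"unknown residue {ch!r} at position {pos + 1}; "
                "sanitize the sequence first"
            )
    return sequence


def amino_acid_composition(sequence: str) -> np.ndarray:
    """Fraction of each of the 20 standard residues, alphabetical order.

    The output is nonnegative and sums to 1 exactly (it is a count
    vector divided by the sequence length).
    """
    _check_sequence(sequence)
    counts = np.zeros(20)
    for ch in sequence:
        counts[_AA_INDEX[ch]] += 1
    return counts / len(sequence)


def _standardized_properties(
    property_table: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """Stack properties as a (n_props, 20) array, each standardized to
    zero mean / unit variance over the 20 residues."""
    rows = []
    for name, values in property_table.items():
        missing = set(STANDARD_AA) - set(values)
        if missing:
            raise ValueError(f"property {name!r} missing residues {sorted(missing)}")
        row = np.array([values[aa] for aa in STANDARD_AA], dtype=float)
        sd = row.std()
        if sd == 0:
            raise ValueError(f"property {name!r} is constant across residues")
        rows.append((row - row.mean()) / sd)
    if not rows:
        raise ValueError("property table is empty")
    return np.vstack(rows)


def pseudo_aac(
    sequence: str,
    lam: int = 15,
    weight: float = 0.05,
    property_table: Mapping[str, Mapping[str, float]] | None = None,
) -> np.ndarray:
    """Pseudo amino-acid composition: 20 composition components plus
    ``lam`` sequence-order correlation factors.

    The tier-t correlation factor is the mean squared property
    difference between residues t apart::

        tau_t = (1 / (L - t)) * sum_i Theta(R_i, R_{i+t})
        Theta(a, b) = mean_p (P_p(b) - P_p(a))**2

    over standardized properties ``P_p``.  The full vector is
    ``(f_1..f_20, w*tau_1..w*tau_lam)`` normalized to sum to 1, so with
    ``lam=0`` it reduces exactly to :func:`amino_acid_composition`.

    Parameters
    ----------
    lam
        Number of correlation tiers; requires ``len(sequence) > lam``.
    weight
        Weight factor balancing the correlation factors against the
        composition components.
    property_table
        Mapping ``property name -> {residue: value}``; defaults to the
        hydrophobicity / hydrophilicity / side-chain-mass triple.
    """
    _check_sequence(sequence)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if weight <= 0:
        raise ValueError("weight must be positive")
    L = len(sequence)
    if L <= lam:
        raise ValueError(
            f"sequence length {L} must exceed lam={lam}; lower lam"
        )
    comp = amino_acid_composition(sequence)
    if lam == 0:
        return comp

    props = _standardized_properties(property_table or PROPERTY_TABLE)
    seq_idx = np.array([_AA_INDEX[ch] for ch in sequence])
    prof = props[:, seq_idx]  # (n_props, L)
    taus = np.empty(lam)
    for t in range(1, lam + 1):
        diff = prof[:, t:] - prof[:, :-t]
        taus[t - 1] = np.mean(diff**2, axis=0).mean()

    denom = comp.sum() + weight * taus.sum()  # comp sums to 1
    out = np.concatenate([comp, weight * taus]) / denom
    return out


def go_binary_view(
    annotations: Mapping[str, Iterable[str]],
    vocabulary: list[str],
    accessions: list[str],
    name: str = "go",
) -> FeatureView:
    """Binary indicator view of GO terms over a fixed vocabulary.

    Rows follow ``accessions``; an accession absent from the annotation
    map yields an all-zero row and a logged warning (unannotated
    proteins are legal inputs, they just carry no GO signal).
    """
    if not vocabulary:
        raise ValueError("empty GO vocabulary")
    if len(set(vocabulary)) != len(vocabulary):
        dupes = sorted({t for t in vocabulary if vocabulary.count(t) > 1})
        raise ValueError(f"duplicated vocabulary terms: {dupes}")
    term_idx = {t: j for j, t in enumerate(vocabulary)}
    matrix = np.zeros((len(accessions), len(vocabulary)))
    n_missing = 0
    for i, acc in enumerate(accessions):
        terms = annotations.get(acc)
        if terms is None:
            n_missing += 1
            continue
        for t in terms:
            j = term_idx.get(t)
            if j is not None:
                matrix[i, j] = 1.0
    if n_missing:
        logger.warning(
            "%d/%d accessions missing from GO annotation map (%s); "
            "their rows are all-zero",
            n_missing, len(accessions), name,
        )
    return FeatureView(name=name, matrix=matrix, column_names=list(vocabulary))


def build_go_vocabulary(
    annotations: Mapping[str, Iterable[str]], accessions: list[str]
) -> list[str]:
    """Sorted union of the GO terms seen in the training accessions.

    Frozen into the model archive so prediction-time vectors align.
    """
    terms: set[str] = set()
    for acc in accessions:
        terms.update(annotations.get(acc, ()))
    return sorted(terms)
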