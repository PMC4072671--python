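"""Fixed-length sequence descriptors for transporter classification.

Five encoders are provided, each mapping a protein sequence (and, for the
profile encoder, its PSSM) to a fixed-length numeric vector:

========  ====  ===========================================================
encoder   dim   definition
========  ====  ===========================================================
AAC        20   percentage of each amino acid: 100 * count / L
DPC       400   percentage of each consecutive dipeptide: 100 * count/(L-1)
PHC        11   percentage of residues in each physico-chemical class
AAI        49   mean of each 0-1 normalised biochemical property over L
PSSM      400   per-residue-pair sums of profile scores, length-normalised
                and min-max scaled to [0, 1]
========  ====  ===========================================================

Hybrids concatenate encoders; the biochemical+profile hybrid (AAI+PSSM,
449 components) is the best-performing combination for substrate-class
prediction. Component ordering everywhere follows the single alphabetical
residue order declared in :mod:`transpred.constants`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from transpred.constants import AA_INDEX, AMINO_ACIDS
from transpred.io import ProteinSequence, PssmProfile

logger = logging.getLogger(__name__)

ENCODER_DIMS = {"AAC": 20, "DPC": 400, "PHC": 11, "AAI": 49, "PSSM": 400}


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length descriptor with named components and encoder tag."""

    values: np.ndarray
    names: tuple
    encoder: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.names):
            raise ValueError(
                f"{self.encoder}: {len(values)} values for "
                f"{len(self.names)} component names"
            )
        if self.encoder in ENCODER_DIMS and len(values) != ENCODER_DIMS[self.encoder]:
            raise ValueError(
                f"{self.encoder}: expected {ENCODER_DIMS[self.encoder]} "
                f"components, got {len(values)}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return len(self.values)


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("transpred").joinpath("data", filename)))


_warned_identical_classes = False


def load_residue_classes(path: str | Path | None = None) -> dict:
    """Load the 11 physico-chemical residue classes from YAML.

    Returns an ordered mapping class name -> frozenset of residues.
    Warns once if two classes have identical member sets (the shipped
    default table prints polar and neutral with the same residues).
    """
    global _warned_identical_classes
    if path is None:
        path = _data_path("residue_classes.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if len(raw) != 11:
        raise ValueError(f"expected 11 residue classes, got {len(raw)}")
    table: dict = {}
    for name, members in raw.items():
        members = frozenset(members)
        bad = members - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"class {name!r}: unknown residues {sorted(bad)}")
        table[name] = members
    if not _warned_identical_classes:
        sets = list(table.items())
        for i, (n1, s1) in enumerate(sets):
            for n2, s2 in sets[i + 1:]:
                if s1 == s2:
                    logger.warning(
                        "residue classes %r and %r have identical member "
                        "sets; override the class table to change this",
                        n1,
                        n2,
                    )
                    _warned_identical_classes = True
    return table


def load_property_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the 49 x 20 biochemical property table (values in [0, 1]).

    The shipped default (``aaindex49_synthetic.tsv``) is a synthetic
    stand-in with the contract of the published 0-1 normalised
    49-property residue scale set: 49 named rows, 20 residue columns,
    all entries finite in [0, 1]. Substitute a real table with the same
    layout via ``path``.
    """
    if path is None:
        path = _data_path("aaindex49_synthetic.tsv")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape != (49, 20):
        raise ValueError(f"property table must be 49x20, got {table.shape}")
    if list(table.columns) != list(AMINO_ACIDS):
        raise ValueError(
            "property table columns must be the 20 residues in "
            f"alphabetical order {AMINO_ACIDS}"
        )
    values = table.to_numpy()
    if not np.isfinite(values).all() or values.min() < 0 or values.max() > 1:
        raise ValueError("property table entries must be finite and in [0, 1]")
    return table


def encode_aac(seq: ProteinSequence) -> FeatureVector:
    """Amino acid composition: percentage of each residue (sums to 100)."""
    if not seq.residues:
        raise ValueError(f"sequence {seq.id!r} is empty")
    counts = np.zeros(20)
    for aa in seq.residues:
        counts[AA_INDEX[aa]] += 1
    values = 100.0 * counts / len(seq.residues)
    return FeatureVector(values, tuple(AMINO_ACIDS), "AAC")


_DIPEPTIDES = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)


def encode_dpc(seq: ProteinSequence) -> FeatureVector:
    """Dipeptide composition over the (L-1) consecutive pairs (sums to 100)."""
    if len(seq.residues) < 2:
        raise ValueError(f"sequence {seq.id!r}: dipeptide encoding needs length >= 2")
    counts = np.zeros(400)
    for a, b in zip(seq.residues, seq.residues[1:]):
        counts[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
    values = 100.0 * counts / (len(seq.residues) - 1)
    return FeatureVector(values, _DIPEPTIDES, "DPC")


def encode_phc(
    seq: ProteinSequence, table: Mapping[str, frozenset] | None = None
) -> FeatureVector:
    """Physico-chemical class composition (11 overlapping classes).

    Components are percentages of residues belonging to each class; the
    classes overlap, so the vector does not sum to a constant.
    """
    if not seq.residues:
        raise ValueError(f"sequence {seq.id!r} is empty")
    if table is None:
        table = load_residue_classes()
    names = tuple(table)
    values = np.array(
        [
            100.0 * sum(aa in table[name] for aa in seq.residues) / len(seq.residues)
            for name in names
        ]
    )
    return FeatureVector(values, names, "PHC")


def encode_aai(
    seq: ProteinSequence, table: pd.DataFrame | None = None
) -> FeatureVector:
    """Biochemical composition: mean of each of 49 properties over the sequence."""
    if not seq.residues:
        raise ValueError(f"sequence {seq.id!r} is empty")
    if table is None:
        table = load_property_table()
    missing = set(seq.residues) - set(table.columns)
    if missing:
        raise ValueError(
            f"sequence {seq.id!r}: residues {sorted(missing)} missing from "
            "the property table"
        )
    counts = np.zeros(20)
    for aa in seq.residues:
        counts[AA_INDEX[aa]] += 1
    values = table.to_numpy() @ (counts / len(seq.residues))
    return FeatureVector(values, tuple(table.index), "AAI")


def encode_pssm(profile: PssmProfile, scale: str = "per_vector") -> FeatureVector:
    """Summed PSSM profile descriptor (400 components in [0, 1]).

    Component (a, b) sums ``scores[pos, b]`` over every position whose
    query residue is ``a``, then divides by the sequence length. With
    ``scale="per_vector"`` (default) the 400-vector is min-max scaled to
    [0, 1]; an all-equal vector maps to 0.5 everywhere. ``scale="none"``
    returns the unscaled length-normalised sums (useful when a caller
    wants dataset-global scaling instead).
    """
    length = len(profile)
    sums = np.zeros((20, 20))
    for pos, aa in enumerate(profile.query_residues):
        sums[AA_INDEX[aa]] += profile.scores[pos]
    values = sums.ravel() / length
    if scale == "per_vector":
        lo, hi = values.min(), values.max()
        if hi == lo:
            values = np.full(400, 0.5)
        else:
            values = (values - lo) / (hi - lo)
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    return FeatureVector(values, _DIPEPTIDES, "PSSM")


def encode_hybrid(parts: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate feature vectors; names are prefixed with their encoder tag."""
    if not parts:
        raise ValueError("hybrid encoding needs at least one part")
    values = np.concatenate([p.values for p in parts])
    names = tuple(
        f"{p.encoder}:{name}" for p in parts for name in p.names
    )
    tag = "hybrid(" + "+".join(p.encoder for p in parts) + ")"
    return FeatureVector(values, names, tag)


def composition_summary(
    dataset: Iterable[tuple],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-class mean amino acid composition and its across-class variance.

    Mirrors the compositional-bias analysis used to motivate the
    classifiers: for each residue, the mean AAC within each class and the
    (population) variance of those class means across classes highlight
    which residues carry between-class signal.

    Parameters
    ----------
    dataset : iterable of (ProteinSequence, class_label)

    Returns
    -------
    means : DataFrame (classes x 20 residues) of mean percentages
    variance : Series (20 residues) of across-class variance of the means
    """
    by_class: dict = {}
    for seq, label in dataset:
        by_class.setdefault(label, []).append(encode_aac(seq).values)
    if len(by_class) < 2:
        raise ValueError("composition summary needs at least 2 classes")
    for label, rows in by_class.items():
        if not rows:
            raise ValueError(f"class {label!r} has no members")
    means = pd.DataFrame(
        {label: np.mean(rows, axis=0) for label, rows in by_class.items()},
        index=list(AMINO_ACIDS),
    ).T
    variance = means.var(axis=0, ddof=0)
    return means, variance


def encode_dataset(
    sequences: Sequence[ProteinSequence],
    encoder: str,
    pssms: Mapping[str, PssmProfile] | None = None,
    property_table: pd.DataFrame | None = None,
    class_table: Mapping[str, frozenset] | None = None,
) -> pd.DataFrame:
    """Encode a list of sequences into a feature matrix (rows = sequences).

    ``encoder`` is one of AAC, DPC, PHC, AAI, PSSM or a ``+``-joined
    hybrid such as ``AAI+PSSM``. PSSM-using encoders require ``pssms``
    to resolve every sequence id.
    """
    parts = encoder.split("+")
    unknown = [p for p in parts if p not in ENCODER_DIMS]
    if unknown:
        raise ValueError(
            f"unknown encoder(s) {unknown}; valid: {sorted(ENCODER_DIMS)}"
        )
    if "PSSM" in parts:
        if pssms is None:
            raise ValueError(f"encoder {encoder!r} requires PSSM profiles")
        missing = [s.id for s in sequences if s.id not in pssms]
        if missing:
            raise ValueError(f"missing PSSM profiles for: {', '.join(missing)}")
    if "AAI" in parts and property_table is None:
        property_table = load_property_table()
    if "PHC" in parts and class_table is None:
        class_table = load_residue_classes()

    def encode_one(seq: ProteinSequence) -> FeatureVector:
        vecs = []
        for part in parts:
            if part == "AAC":
                vecs.append(encode_aac(seq))
            elif part == "DPC":
                vecs.append(encode_dpc(seq))
            elif part == "PHC":
                vecs.append(encode_phc(seq, class_table))
            elif part == "AAI":
                vecs.append(encode_aai(seq, property_table))
            elif part == "PSSM":
                vecs.append(encode_pssm(pssms[seq.id]))
        return vecs[0] if len(vecs) == 1 else encode_hybrid(vecs)

    vectors = [encode_one(seq) for seq in sequences]
    return pd.DataFrame(
        [v.values for v in vectors],
        index=[s.id for s in sequences],
        columns=list(vectors[0].names),
    )
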