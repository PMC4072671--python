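"""Sequence, PSSM-profile and dataset-manifest input/output.

Three plain-text formats are supported:

* multi-record FASTA (via Biopython), wrapped or unwrapped;
* PSI-BLAST ASCII PSSM files as written by ``psiblast -out_ascii_pssm``
  (header lines, then one row per position holding the position index, the
  query residue, 20 log-odds columns, 20 percentage columns and trailing
  per-row statistics);
* a two-column TSV manifest mapping sequence ids to class labels.

Only the log-odds block of a PSSM is retained; columns are re-mapped from
PSI-BLAST's native residue order to the package-wide alphabetical order at
parse time so every downstream matrix shares one column convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from transpred.constants import (
    AA_INDEX,
    AMINO_ACIDS,
    CLASS_LABELS,
    PSIBLAST_COLUMN_ORDER,
)

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset(AMINO_ACIDS)


class ParseError(ValueError):
    """A file could not be parsed in its declared format."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: unique id plus residues over the 20-letter alphabet."""

    id: str
    residues: str

    def validate(self) -> "ProteinSequence":
        """Check alphabet membership and the minimum length of 2.

        Dipeptide encoding needs at least one consecutive residue pair,
        so shorter sequences are rejected up front.
        """
        if len(self.residues) < 2:
            raise ValueError(
                f"sequence {self.id!r}: length {len(self.residues)} < 2"
            )
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in _VALID_RESIDUES:
                raise ValueError(
                    f"sequence {self.id!r}: non-standard residue "
                    f"{aa!r} at position {pos}"
                )
        return self

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PssmProfile:
    """An L x 20 matrix of per-position log-odds substitution scores.

    ``scores`` columns follow :data:`transpred.constants.AMINO_ACIDS`
    (alphabetical) regardless of the on-disk column order.
    """

    sequence_id: str
    query_residues: str
    scores: np.ndarray  # shape (L, 20), integer log-odds

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.sequence_id!r}: scores must be Lx20, "
                f"got shape {scores.shape}"
            )
        if scores.shape[0] != len(self.query_residues):
            raise ValueError(
                f"PSSM {self.sequence_id!r}: {scores.shape[0]} rows for "
                f"{len(self.query_residues)} query residues"
            )
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.query_residues)


@dataclass
class DatasetManifest:
    """Ordered mapping of sequence ids to one of the eight class labels."""

    entries: list = field(default_factory=list)  # list[(sequence_id, label)]

    def __post_init__(self) -> None:
        seen = set()
        for seq_id, label in self.entries:
            if seq_id in seen:
                raise ValueError(f"duplicate sequence id {seq_id!r} in manifest")
            seen.add(seq_id)
            if label not in CLASS_LABELS:
                raise ValueError(
                    f"unknown class label {label!r} for {seq_id!r}; "
                    f"valid labels: {', '.join(CLASS_LABELS)}"
                )

    @property
    def labels(self) -> dict:
        return dict(self.entries)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASS_LABELS}
        for _, label in self.entries:
            counts[label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


def read_fasta(path: str | Path, strict: bool = True) -> list:
    """Read a multi-record FASTA file into validated :class:`ProteinSequence`.

    In strict mode (default) any residue outside the 20-letter alphabet is
    an error naming the residue and its position. In lenient mode such
    letters are dropped from the sequence and a warning with per-sequence
    counts is logged.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found (empty or malformed file)")
    sequences: list = []
    for rec in records:
        residues = str(rec.seq).upper()
        if strict:
            seq = ProteinSequence(rec.id, residues)
            seq.validate()
        else:
            kept = "".join(aa for aa in residues if aa in _VALID_RESIDUES)
            dropped = len(residues) - len(kept)
            if dropped:
                logger.warning(
                    "sequence %r: dropped %d non-standard residue(s)",
                    rec.id,
                    dropped,
                )
            seq = ProteinSequence(rec.id, kept).validate()
        sequences.append(seq)
    return sequences


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def _is_pssm_header(tokens: Sequence[str]) -> bool:
    # The column-header line lists 40 single residue letters.
    return len(tokens) >= 40 and all(
        t in PSIBLAST_COLUMN_ORDER for t in tokens[:40]
    )


# Permutation from PSI-BLAST column order to alphabetical order.
_PSIBLAST_TO_ALPHA = np.array(
    [PSIBLAST_COLUMN_ORDER.index(aa) for aa in AMINO_ACIDS]
)


def read_pssm_ascii(path: str | Path, sequence_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PssmProfile`.

    Only the first 20 numeric columns per row (the log-odds block) are
    kept; the percentage block and the trailing information/weight
    statistics are ignored. Columns are re-ordered alphabetically.
    """
    path = Path(path)
    if sequence_id is None:
        sequence_id = path.stem
    residues: list = []
    rows: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if _is_pssm_header(tokens):
                continue
            if not tokens[0].isdigit():
                continue  # header prose / trailing K,lambda statistics
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: malformed PSSM row")
            idx, residue = tokens[0], tokens[1]
            if residue not in _VALID_RESIDUES:
                raise ParseError(
                    f"{path}:{lineno}: row {idx} has non-amino-acid "
                    f"residue {residue!r}"
                )
            numeric = tokens[2:]
            # Rows carry 40 integer columns plus optionally two trailing
            # floating statistics (information content, gapless weight).
            if len(numeric) not in (40, 42):
                raise ParseError(
                    f"{path}:{lineno}: row {idx} has {len(numeric)} numeric "
                    f"columns, expected 40 (+2 optional statistics)"
                )
            try:
                log_odds = [int(tok) for tok in numeric[:20]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: row {idx}: non-integer log-odds value"
                ) from exc
            residues.append(residue)
            rows.append(log_odds)
    if not rows:
        raise ParseError(f"{path}: no PSSM data rows found")
    scores = np.array(rows, dtype=np.int64)[:, _PSIBLAST_TO_ALPHA]
    return PssmProfile(sequence_id, "".join(residues), scores)


def write_pssm_ascii(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (fixture writer).

    Emits the full 40-column layout: the 20 log-odds columns in
    PSI-BLAST's native residue order, a percentage block derived from the
    softmax-normalised scores, and two trailing per-row statistics, so
    the parser is exercised against the real format.
    """
    alpha_to_psiblast = np.array(
        [AA_INDEX[aa] for aa in PSIBLAST_COLUMN_ORDER]
    )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "pseudocounts applied\n"
        )
        header = "           " + "  ".join(PSIBLAST_COLUMN_ORDER) * 2 + "\n"
        fh.write(header)
        for pos, residue in enumerate(profile.query_residues):
            row = profile.scores[pos][alpha_to_psiblast]
            exp = np.exp(row - row.max())
            pct = np.round(100 * exp / exp.sum()).astype(int)
            cells = " ".join(f"{v:3d}" for v in row)
            pcts = " ".join(f"{v:3d}" for v in pct)
            fh.write(
                f"{pos + 1:5d} {residue} {cells}  {pcts}  "
                f"{row.std():.2f} {1.00:.2f}\n"
            )
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3176\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a two-column TSV of (sequence_id, class_label)."""
    path = Path(path)
    entries: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            entries.append((parts[0], parts[1]))
    if not entries:
        raise ParseError(f"{path}: empty manifest")
    return DatasetManifest(entries)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, label in manifest.entries:
            fh.write(f"{seq_id}\t{label}\n")
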