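"""Reading, validation, deduplication and splitting of labeled peptide data.

Peptides are upper-case strings over the 20 standard amino-acid letters,
minimum length 5 (the shortest length for which every downstream encoder —
including order-3 n-grams and rank-1 sequence-order correlation terms — is
well defined). Sequences containing non-standard residues (B, J, O, U, X, Z)
are rejected rather than imputed because every encoder assumes the
20-letter alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)
MIN_LENGTH = 5


class PeptideValidationError(ValueError):
    """Raised when a sequence fails alphabet or length validation."""


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide record."""

    id: str
    sequence: str


@dataclass
class PeptideDataset:
    """An ordered collection of peptides with parallel binary labels.

    Label 1 marks the positive class (TTCA), 0 the negative class. Labels
    may be None for prediction-mode (unlabeled) data.
    """

    peptides: list[Peptide] = field(default_factory=list)
    labels: list[int] | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.peptides):
            raise ValueError(
                f"{len(self.peptides)} peptides but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError(f"dataset {self.name!r} is unlabeled")
        return np.asarray(self.labels, dtype=int)

    def subset(self, indices, name: str | None = None) -> "PeptideDataset":
        idx = list(indices)
        labels = None if self.labels is None else [self.labels[i] for i in idx]
        return PeptideDataset(
            peptides=[self.peptides[i] for i in idx],
            labels=labels,
            name=name or self.name,
        )


def validate_peptide(raw: str) -> str:
    """Canonicalize a raw sequence: strip, upper-case, check alphabet/length.

    Raises
    ------
    PeptideValidationError
        If the sequence is shorter than 5 residues or contains a character
        outside the 20 standard amino-acid letters.
    """
    seq = raw.strip().upper()
    if len(seq) < MIN_LENGTH:
        raise PeptideValidationError(
            f"sequence {seq!r} shorter than minimum length {MIN_LENGTH}"
        )
    bad = set(seq) - _ALPHABET_SET
    if bad:
        raise PeptideValidationError(
            f"sequence {seq!r} contains non-standard residue(s) {sorted(bad)}"
        )
    return seq


def read_fasta(path, label: int | None = None, name: str | None = None) -> PeptideDataset:
    """Read a FASTA file into a PeptideDataset, validating every record.

    Parameters
    ----------
    path : str or Path
        FASTA file; multi-line records are allowed.
    label : int, optional
        Class label (0 or 1) assigned to every record, or None for
        unlabeled prediction input.
    """
    peptides: list[Peptide] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueError subclasses
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        # distinguish empty file from a file with no '>' header
        with open(path) as fh:
            if any(line.strip() for line in fh):
                raise FastaParseError(f"{path}: no FASTA records found (missing '>' header?)")
    for rec in records:
        try:
            seq = validate_peptide(str(rec.seq))
        except PeptideValidationError as exc:
            raise PeptideValidationError(f"record {rec.id!r}: {exc}") from exc
        peptides.append(Peptide(id=rec.id, sequence=seq))
    labels = None if label is None else [int(label)] * len(peptides)
    return PeptideDataset(peptides=peptides, labels=labels, name=name or str(path))


def read_table(path, name: str | None = None) -> PeptideDataset:
    """Read a two-column TSV (sequence<TAB>label) into a PeptideDataset."""
    peptides: list[Peptide] = []
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FastaParseError(
                    f"{path}:{lineno}: expected 'sequence<TAB>label', got {line!r}"
                )
            seq_raw, lab = parts
            if lab not in ("0", "1"):
                raise FastaParseError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            try:
                seq = validate_peptide(seq_raw)
            except PeptideValidationError as exc:
                raise PeptideValidationError(f"{path}:{lineno}: {exc}") from exc
            peptides.append(Peptide(id=f"seq{lineno}", sequence=seq))
            labels.append(int(lab))
    return PeptideDataset(peptides=peptides, labels=labels, name=name or str(path))


def deduplicate(ds: PeptideDataset) -> PeptideDataset:
    """Remove duplicate sequences, keeping first occurrences.

    A sequence appearing with both labels is dropped from both classes
    entirely (a label conflict means the annotation is unreliable); a
    warning is logged for every conflicting sequence.
    """
    if ds.labels is None:
        seen: set[str] = set()
        keep = []
        for i, p in enumerate(ds.peptides):
            if p.sequence not in seen:
                seen.add(p.sequence)
                keep.append(i)
        return ds.subset(keep)

    label_sets: dict[str, set[int]] = {}
    for p, lab in zip(ds.peptides, ds.labels):
        label_sets.setdefault(p.sequence, set()).add(lab)
    conflicted = {s for s, labs in label_sets.items() if len(labs) > 1}
    for s in conflicted:
        logger.warning("sequence %r appears with both labels; dropped from both classes", s)
    seen = set()
    keep = []
    for i, p in enumerate(ds.peptides):
        if p.sequence in conflicted or p.sequence in seen:
            continue
        seen.add(p.sequence)
        keep.append(i)
    return ds.subset(keep)


def split_dataset(
    ds: PeptideDataset, n_train_pos: int, n_train_neg: int, seed: int
) -> tuple[PeptideDataset, PeptideDataset]:
    """Random stratified train/test split by absolute per-class counts.

    Samples exactly ``n_train_pos`` positives and ``n_train_neg`` negatives
    without replacement into the training set; the complement becomes the
    test set. Reproducible for a fixed seed.
    """
    y = ds.y
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if n_train_pos > len(pos_idx):
        raise ValueError(f"requested {n_train_pos} positives but only {len(pos_idx)} available")
    if n_train_neg > len(neg_idx):
        raise ValueError(f"requested {n_train_neg} negatives but only {len(neg_idx)} available")
    rng = np.random.default_rng(seed)
    train_pos = rng.choice(pos_idx, size=n_train_pos, replace=False)
    train_neg = rng.choice(neg_idx, size=n_train_neg, replace=False)
    train_set = set(train_pos.tolist()) | set(train_neg.tolist())
    train_idx = [i for i in range(len(ds)) if i in train_set]
    test_idx = [i for i in range(len(ds)) if i not in train_set]
    return (
        ds.subset(train_idx, name=f"{ds.name}:train"),
        ds.subset(test_idx, name=f"{ds.name}:test"),
    )


def write_fasta(ds: PeptideDataset, path) -> None:
    with open(path, "w") as fh:
        for p in ds.peptides:
            fh.write(f">{p.id}\n{p.sequence}\n")


def write_table(ds: PeptideDataset, path) -> None:
    with open(path, "w") as fh:
        for p, lab in zip(ds.peptides, ds.y):
            fh.write(f"{p.sequence}\t{lab}\n")
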