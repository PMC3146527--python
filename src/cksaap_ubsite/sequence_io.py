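"""Sequence and site-table I/O, fragment extraction and redundancy filtering.

A prediction instance is a lysine-centered sequence fragment: the central K
plus up to ``n`` residues on each side (window ``2n + 1``, 27 by default).
Fragments near a protein terminus are stored truncated; padding is applied
only at encoding time, never here.

Coordinates in site tables are 1-based (biological convention); all indices
inside ``Fragment`` objects are 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: the 20 standard amino acids, alphabetical by one-letter code
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD = frozenset(AMINO_ACIDS)

SITE_TABLE_COLUMNS = ("protein_id", "position", "label", "fragment")

LABELS = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class Protein:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class Fragment:
    """A lysine-centered window cut from a protein.

    Parameters
    ----------
    protein_id : source accession.
    center_pos : 1-based position of the central K in the protein.
    residues : the fragment string; length ``2n + 1`` unless the site lies
        within ``n`` residues of a terminus, in which case that side is
        shorter (no padding characters are stored).
    center_index : 0-based index of the central K within ``residues``.
    label : one of ``positive``, ``negative``, ``unknown``.
    """

    protein_id: str
    center_pos: int
    residues: str
    center_index: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if not (0 <= self.center_index < len(self.residues)):
            raise ValueError("center_index outside fragment")
        if self.residues[self.center_index] != "K":
            raise ValueError(
                f"fragment for {self.protein_id!r} at {self.center_pos}: "
                f"center residue is {self.residues[self.center_index]!r}, not 'K'"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def is_truncated(self, window: int) -> bool:
        """True if the fragment is shorter than ``window``."""
        return len(self.residues) < window


@dataclass
class SiteDataset:
    """Labeled lysine-centered fragments plus class bookkeeping."""

    fragments: list[Fragment]
    window: int = 27

    def __post_init__(self) -> None:
        _check_window(self.window)

    @property
    def positives(self) -> list[int]:
        return [i for i, f in enumerate(self.fragments) if f.label == "positive"]

    @property
    def negatives(self) -> list[int]:
        return [i for i, f in enumerate(self.fragments) if f.label == "negative"]

    def subset(self, indices: Sequence[int]) -> "SiteDataset":
        return SiteDataset([self.fragments[i] for i in indices], self.window)

    def labels(self) -> list[str]:
        return [f.label for f in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)


def _check_window(window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")


def read_fasta(path: str | Path, policy: str = "strict") -> list[Protein]:
    """Read a multi-record FASTA file into :class:`Protein` objects.

    Record ids are taken from the header up to the first whitespace and
    sequences are uppercased.  ``policy`` controls non-standard residue
    letters (B, Z, X, U, ...): ``"strict"`` rejects them with an error naming
    the offending position, ``"mask"`` replaces them with ``X`` (pairs
    involving ``X`` are later skipped by the encoder).
    """
    if policy not in ("strict", "mask"):
        raise ValueError(f"unknown residue policy {policy!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    proteins: list[Protein] = []
    seen: set[str] = set()
    for rec in records:
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate record id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        bad = [(i, c) for i, c in enumerate(seq) if c not in _STANDARD]
        if bad:
            if policy == "strict":
                i, c = bad[0]
                raise ValueError(
                    f"record {pid!r}: non-standard residue {c!r} at position {i + 1}"
                )
            for i, _ in bad:
                seq = seq[:i] + "X" + seq[i + 1 :]
        proteins.append(Protein(pid, seq))
    return proteins


def extract_fragments(protein: Protein, window: int = 27) -> list[Fragment]:
    """Cut one fragment per lysine in ``protein``, truncated at the termini.

    The number of fragments always equals the K count of the sequence.
    """
    _check_window(window)
    n = (window - 1) // 2
    seq = protein.sequence
    out: list[Fragment] = []
    for i, res in enumerate(seq):
        if res != "K":
            continue
        start = max(0, i - n)
        end = min(len(seq), i + n + 1)
        out.append(
            Fragment(
                protein_id=protein.id,
                center_pos=i + 1,
                residues=seq[start:end],
                center_index=i - start,
            )
        )
    return out


def fragment_identity(a: Fragment, b: Fragment) -> float:
    """Sequence identity of two fragments under a center-anchored, ungapped
    alignment: matching positions divided by the length of the shorter
    fragment."""
    lo = max(-a.center_index, -b.center_index)
    hi = min(len(a) - a.center_index, len(b) - b.center_index)  # exclusive
    matches = sum(
        1
        for r in range(lo, hi)
        if a.residues[a.center_index + r] == b.residues[b.center_index + r]
    )
    return matches / min(len(a), len(b))


def filter_redundant(
    fragments: Iterable[Fragment], max_identity: float = 0.4
) -> list[Fragment]:
    """Greedy first-come-kept redundancy filter.

    Fragments are visited in input order; a fragment is kept iff its identity
    to every already-kept fragment is strictly below ``max_identity``.  To
    preferentially retain positives, list them before the negatives in the
    input.  The operation is idempotent.
    """
    if not (0 < max_identity <= 1):
        raise ValueError(f"max_identity must be in (0, 1], got {max_identity}")
    kept: list[Fragment] = []
    for frag in fragments:
        if all(fragment_identity(frag, k) < max_identity for k in kept):
            kept.append(frag)
    return kept


def _center_index_for(position: int, window: int) -> int:
    # left truncation eats min(n, position - 1) residues
    return min(position - 1, (window - 1) // 2)


def read_site_table(
    path: str | Path, window: int = 27, require_labels: bool = True
) -> SiteDataset:
    """Read a TSV site table (``protein_id  position  label  fragment``).

    ``position`` is the 1-based index of the central K in the source protein;
    it determines how a short fragment is anchored.  Rows whose fragment
    center is not K raise an error naming the row.
    """
    _check_window(window)
    fragments: list[Fragment] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty site table")
        if tuple(header) != SITE_TABLE_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(SITE_TABLE_COLUMNS)}, got {header}"
            )
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}: row {rowno}: expected 4 columns")
            pid, pos_s, label, frag = row
            position = int(pos_s)
            if label not in LABELS or (require_labels and label == "unknown"):
                raise ValueError(f"{path}: row {rowno}: invalid label {label!r}")
            ci = _center_index_for(position, window)
            if ci >= len(frag) or frag[ci] != "K":
                raise ValueError(
                    f"{path}: row {rowno}: fragment center is not 'K' "
                    f"(protein {pid!r}, position {position})"
                )
            fragments.append(Fragment(pid, position, frag.upper(), ci, label))
    return SiteDataset(fragments, window)


def write_site_table(dataset: SiteDataset, path: str | Path) -> None:
    """Write a dataset as the TSV site-table dialect (round-trips with
    :func:`read_site_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TABLE_COLUMNS)
        for f in dataset.fragments:
            writer.writerow([f.protein_id, f.center_pos, f.label, f.residues])


def relabel(fragment: Fragment, label: str) -> Fragment:
    return replace(fragment, label=label)
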