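"""Feature encodings for lysine-centered fragments.

Two schemes are provided:

* **CKSAAP** — the composition of k-spaced amino-acid pairs.  For a spacing
  ``k``, an ordered residue pair occupies positions ``(i, i + k + 1)`` of the
  fragment; there are 400 such pairs per spacing.  Each pair's feature value
  is its count divided by ``N_total``, the number of k-spaced pairs the
  fragment contains (``L - k - 1`` for a fragment of length ``L``, which is
  26 at k=0 for the full 27-residue window and shrinks automatically for
  terminally truncated fragments).  Spacings k = 0..5 concatenated give the
  default 2400-dimensional vector.

* **binary** — a position-specific one-hot baseline over the 21-letter
  alphabet ``ACDEFGHIKLMNPQRSTVWYO``, where ``O`` pads positions beyond a
  sequence terminus.  The central K carries no information and is excluded,
  giving 21 x 26 = 546 dimensions at window 27.

Feature order in CKSAAP vectors is k-major, then first residue, then second
residue, each in ``ACDEFGHIKLMNPQRSTVWY`` order; this order is fixed so that
serialized models remain portable.  Pairs spanning the central K are counted
like any other pair; pairs touching a masked ``X`` residue are skipped, and
``N_total`` then counts only the scorable pairs so each per-k block still
sums to one.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .sequence_io import AMINO_ACIDS, Fragment, SiteDataset

BINARY_ALPHABET = AMINO_ACIDS + "O"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_BIN_INDEX = {aa: i for i, aa in enumerate(BINARY_ALPHABET)}

_NAME_RE = re.compile(r"^([A-Z])(x*)([A-Z])$")

N_PAIRS = len(AMINO_ACIDS) ** 2  # 400 ordered pairs per spacing


class PairFeature(NamedTuple):
    """An ordered residue pair at spacing ``k`` (positions ``i`` and
    ``i + k + 1``)."""

    first: str
    second: str
    k: int


def feature_name(feature: PairFeature) -> str:
    """Render a pair feature in the conventional notation: first residue,
    ``k`` literal ``x`` characters, second residue (``(E, E, 1)`` -> ``ExE``)."""
    return feature.first + "x" * feature.k + feature.second


def parse_feature_name(name: str) -> PairFeature:
    """Inverse of :func:`feature_name`; raises on malformed names."""
    m = _NAME_RE.match(name)
    if not m or m.group(1) not in _AA_INDEX or m.group(3) not in _AA_INDEX:
        raise ValueError(f"malformed pair-feature name {name!r}")
    return PairFeature(m.group(1), m.group(3), len(m.group(2)))


def _residues(fragment: Fragment | str) -> str:
    return fragment.residues if isinstance(fragment, Fragment) else fragment


def count_k_spaced_pairs(
    fragment: Fragment | str, k: int
) -> tuple[dict[tuple[str, str], int], int]:
    """Count ordered k-spaced residue pairs in a fragment.

    Returns ``(counts, n_total)`` where ``counts`` maps ``(first, second)``
    to the number of index pairs ``(i, i + k + 1)`` carrying that pair and
    ``n_total`` is the number of scorable pairs (``L - k - 1`` when every
    residue is standard; fewer if masked ``X`` residues are present).  A
    fragment shorter than ``k + 2`` yields empty counts and ``n_total = 0``.
    """
    if k < 0:
        raise ValueError(f"spacing k must be >= 0, got {k}")
    seq = _residues(fragment)
    counts: dict[tuple[str, str], int] = {}
    n_total = 0
    for i in range(len(seq) - k - 1):
        a, b = seq[i], seq[i + k + 1]
        if a in _AA_INDEX and b in _AA_INDEX:
            counts[a, b] = counts.get((a, b), 0) + 1
            n_total += 1
    return counts, n_total


def cksaap_feature_names(k_max: int = 5) -> list[str]:
    """All CKSAAP feature names in vector order (k-major, then first, then
    second residue)."""
    return [
        feature_name(PairFeature(a, b, k))
        for k in range(k_max + 1)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
    ]


def cksaap_encode(fragment: Fragment | str, k_max: int = 5) -> np.ndarray:
    """Encode a fragment as the concatenated k-spaced pair compositions for
    k = 0..``k_max`` (dimension ``400 * (k_max + 1)``; 2400 at the default).

    Each 400-feature block sums to 1 whenever the fragment contains at least
    one pair at that spacing, and is all-zero otherwise.
    """
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    vec = np.zeros(N_PAIRS * (k_max + 1))
    for k in range(k_max + 1):
        counts, n_total = count_k_spaced_pairs(fragment, k)
        if n_total == 0:
            continue
        base = k * N_PAIRS
        for (a, b), m in counts.items():
            vec[base + 20 * _AA_INDEX[a] + _AA_INDEX[b]] = m / n_total
    return vec


def padded_window(fragment: Fragment, window: int = 27) -> str:
    """The fragment re-expanded to the full window, with ``O`` filling
    positions beyond the protein termini."""
    n = (window - 1) // 2
    left = n - fragment.center_index
    right = n - (len(fragment.residues) - 1 - fragment.center_index)
    if left < 0 or right < 0:
        raise ValueError("fragment longer than window")
    return "O" * left + fragment.residues + "O" * right


def binary_encode(fragment: Fragment, window: int = 27) -> np.ndarray:
    """Position-specific one-hot encoding over ``ACDEFGHIKLMNPQRSTVWYO``.

    The central K is excluded (it is constant), so the dimension is
    ``21 * (window - 1)`` — 546 at window 27.  Exactly one bit is set per
    encoded position.
    """
    padded = padded_window(fragment, window)
    n = (window - 1) // 2
    positions = padded[:n] + padded[n + 1 :]
    vec = np.zeros(len(BINARY_ALPHABET) * (window - 1))
    for j, res in enumerate(positions):
        vec[j * len(BINARY_ALPHABET) + _BIN_INDEX.get(res, _BIN_INDEX["O"])] = 1.0
    return vec


def encode_dataset(
    fragments: SiteDataset | Sequence[Fragment] | Iterable[Fragment],
    k_max: int = 5,
    scheme: str = "cksaap",
    window: int | None = None,
) -> np.ndarray:
    """Encode a collection of fragments into a feature matrix (rows in input
    order)."""
    if isinstance(fragments, SiteDataset):
        window = window or fragments.window
        fragments = fragments.fragments
    window = window or 27
    frags = list(fragments)
    if scheme == "cksaap":
        rows = [cksaap_encode(f, k_max) for f in frags]
    elif scheme == "binary":
        rows = [binary_encode(f, window) for f in frags]
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    return np.asarray(rows)


def labels_to_array(dataset: SiteDataset) -> np.ndarray:
    """Class labels as a 0/1 integer array (1 = ubiquitination site)."""
    y = np.empty(len(dataset), dtype=int)
    for i, f in enumerate(dataset.fragments):
        if f.label == "positive":
            y[i] = 1
        elif f.label == "negative":
            y[i] = 0
        else:
            raise ValueError(f"fragment {i} has label 'unknown'; cannot train on it")
    return y
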