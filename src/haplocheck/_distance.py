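"""Sequence-distance primitives shared by the processing stages.

Levenshtein distances are computed with edlib (banded, so a small distance
cap ``k`` makes calls cheap).  For large centroid collections the stages use
an exact-position piece index as a candidate prefilter: by pigeonhole, two
equal-length sequences within Hamming distance ``d`` share at least one of
``d+1`` contiguous pieces at the same offsets.  The filter is exact for
substitution-type differences (the regime of fixed-length amplicons);
alignment-shifted matches below the cap could in principle be missed, which
is why the stages fall back to exhaustive scans on small inputs.
"""

from __future__ import annotations

import numpy as np
import edlib

_BASE_TO_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance; returns -1 if it exceeds ``k`` (when k >= 0)."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(raw), dtype=np.uint8)
    for byte, code in _BASE_TO_CODE.items():
        out[raw == byte] = code
    return out


def decode_rows(mat: np.ndarray) -> list[str]:
    """(n, L) uint8 code matrix -> list of ACGT strings."""
    chars = CODE_TO_BASE[mat]
    n, L = chars.shape
    flat = np.ascontiguousarray(chars).view(f"S{L}").ravel()
    return [s.decode() for s in flat.tolist()]


def piece_bounds(length: int, n_pieces: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, length, n_pieces + 1).astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(n_pieces)]


class PieceIndex:
    """Candidate index over equal-length sequences.

    Sequences are split into ``n_pieces`` contiguous pieces at fixed
    offsets; a query retrieves every indexed sequence sharing at least one
    identical piece.  With ``n_pieces = d + 1`` this finds all sequences
    within Hamming distance ``d`` of the query.
    """

    def __init__(self, length: int, n_pieces: int):
        self.length = length
        self.bounds = piece_bounds(length, n_pieces)
        # piece -> [id list, cached int array or None]
        self._tables: list[dict[str, list]] = [{} for _ in self.bounds]

    def add(self, seq: str, idx: int) -> None:
        for table, (lo, hi) in zip(self._tables, self.bounds):
            bucket = table.get(seq[lo:hi])
            if bucket is None:
                table[seq[lo:hi]] = [[idx], None]
            else:
                bucket[0].append(idx)
                bucket[1] = None

    @property
    def n_pieces(self) -> int:
        return len(self.bounds)

    def candidates(self, seq: str) -> list[int]:
        """Indexed ids sharing a piece with ``seq``, ascending, unique."""
        hits: set[int] = set()
        for table, (lo, hi) in zip(self._tables, self.bounds):
            got = table.get(seq[lo:hi])
            if got:
                hits.update(got[0])
        return sorted(hits)

    def shared_piece_counts(self, seq: str, n_indexed: int) -> np.ndarray:
        """Per-id count of pieces shared with ``seq`` (length ``n_indexed``).

        An id within Hamming distance d of ``seq`` shares at least
        ``n_pieces - d`` pieces, so ``counts`` supports distance-based
        pruning of the candidate list.
        """
        counts = np.zeros(n_indexed, dtype=np.int32)
        for table, (lo, hi) in zip(self._tables, self.bounds):
            got = table.get(seq[lo:hi])
            if got:
                if got[1] is None:
                    got[1] = np.array(got[0], dtype=np.intp)
                counts[got[1]] += 1
        return counts
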