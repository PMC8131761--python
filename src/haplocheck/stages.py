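"""Interchangeable read-processing stages.

Three archetypal algorithms stand in for the ecosystem of published
amplicon tools, so their false-positive / false-negative trade-offs can be
compared inside one harness:

``denoise``
    Abundance-ratio denoiser: a unique sequence merges into an accepted
    centroid when it is close enough *and* rare enough relative to it
    (``abundance(u)/abundance(c) <= 2**-(alpha*d + 1)``).
``cluster_greedy``
    Greedy abundance-sorted clustering at a global identity threshold.
``cluster_linkage``
    Single-linkage clustering at a small local edit distance (connected
    components of the d-neighbour graph).

plus ``remove_chimeras``, a de-novo two-parent crossover detector.

All stages are deterministic and permutation-invariant: sequences are
processed in descending total abundance, ties broken lexicographically.
Counts are conserved by every stage (chimera removal accounts removed
reads in its log).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._distance import PieceIndex, edit_distance
from .types import DataError, Feature, FeatureSet, ReplicateCountTable

logger = logging.getLogger(__name__)

# exhaustive centroid scans below this size; piece-index prefilter above
_INDEX_THRESHOLD = 64


def _merge_counts(dst: dict[str, int], src: dict[str, int]) -> None:
    for k, v in src.items():
        dst[k] = dst.get(k, 0) + v


def _representative(members: dict[str, int]) -> str:
    """Most abundant member sequence, ties broken lexicographically."""
    return min(members, key=lambda s: (-members[s], s))


def _build_featureset(
    clusters: list[dict[str, object]], design, provenance: str
) -> FeatureSet:
    ordered = sorted(
        clusters, key=lambda c: (-sum(c["counts"].values()), _representative(c["members"]))
    )
    feats = []
    for i, c in enumerate(ordered):
        feats.append(
            Feature(
                feature_id=f"F{i + 1:06d}",
                sequence=_representative(c["members"]),
                counts=dict(c["counts"]),
                members=sorted(c["members"]),
                provenance=provenance,
            )
        )
    return FeatureSet(feats, design)


def _sorted_uniques(features: FeatureSet) -> list[Feature]:
    seqs = [f.sequence for f in features]
    if len(set(seqs)) != len(seqs):
        raise DataError("input contains duplicate sequences; dereplicate first")
    return sorted(features, key=lambda f: (-f.total, f.sequence))


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def dereplicate(table: ReplicateCountTable) -> FeatureSet:
    """One feature per unique sequence; counts conserved exactly."""
    if not table.entries:
        raise DataError("empty count table")
    clusters = [
        {"counts": dict(row), "members": {seq: sum(row.values())}}
        for seq, row in table.entries.items()
    ]
    return _build_featureset(clusters, table.design, "dereplicate")


# ---------------------------------------------------------------------------
# Abundance-ratio denoiser
# ---------------------------------------------------------------------------

def denoise(features: FeatureSet, alpha: float = 2.0, d_max: int = 10) -> FeatureSet:
    """Merge likely error sequences into more abundant centroids.

    Unique sequences are visited in descending abundance.  A centroid ``c``
    can absorb ``u`` when ``d = editdist(u, c) <= d_max`` and
    ``abundance(u) / abundance(c) <= beta(d) = 2**-(alpha*d + 1)``; among
    qualifying centroids ``u`` merges into the *closest* (ties: the more
    abundant, then the lexicographically smaller) so that error reads are
    attributed to the haplotype they most plausibly derive from.  With no
    qualifying centroid ``u`` is accepted as a new centroid.  Abundances
    are the static dereplicated totals, so the outcome is independent of
    merge order.
    """
    order = _sorted_uniques(features)
    lengths = {len(f.sequence) for f in order}
    use_index = len(lengths) == 1
    index = PieceIndex(lengths.pop(), d_max + 1) if use_index else None

    cent_seq: list[str] = []
    cent_abund: list[int] = []
    clusters: list[dict[str, object]] = []

    n_pieces = d_max + 1
    factor = 2.0 ** (alpha + 1.0)
    abund_arr = np.empty(0, dtype=np.int64)

    def _feasible_k(a_c: float, a_u: float) -> int:
        return min(d_max, int(math.floor((math.log2(a_c / a_u) - 1.0) / alpha)))

    for u in order:
        a_u = u.total
        target = -1
        best_d = d_max + 1
        if use_index and len(cent_seq) > _INDEX_THRESHOLD:
            if len(abund_arr) < len(cent_abund):
                abund_arr = np.array(cent_abund, dtype=np.int64)
            shared = index.shared_piece_counts(u.sequence, len(cent_seq))
            cand = np.flatnonzero(
                (shared > 0) & (abund_arr[: len(shared)] >= a_u * factor)
            )
            if len(cand) == 0:
                survivors = []
            else:
                # probe the best-supported candidate to pin a small best_d
                probe = int(cand[np.argmax(shared[cand])])
                k = _feasible_k(cent_abund[probe], a_u)
                if k >= 1:
                    d = edit_distance(u.sequence, cent_seq[probe], k=k)
                    if d >= 1:
                        best_d, target = d, probe
                # prune: nothing sharing fewer pieces can lie at < best_d
                # (superset: tie wins for more abundant candidates)
                survivors = cand[shared[cand] >= n_pieces - best_d].tolist()
        else:
            survivors = range(len(cent_seq))
        for ci in survivors:
            ci = int(ci)
            if ci == target:
                continue
            a_c = cent_abund[ci]
            if a_c < a_u * factor:
                if isinstance(survivors, range):
                    break  # centroids sorted by abundance: none later can work
                continue
            # ties go to the more abundant centroid (smaller index)
            allowed = best_d if ci < target or target < 0 else best_d - 1
            k = min(_feasible_k(a_c, a_u), allowed)
            if k < 1:
                continue
            d = edit_distance(u.sequence, cent_seq[ci], k=k)
            if d < 1:
                continue
            best_d, target = d, ci
            if d == 1:
                break  # ascending scan: no later candidate can beat or tie-win
        if target >= 0:
            _merge_counts(clusters[target]["counts"], u.counts)
            clusters[target]["members"][u.sequence] = a_u
        else:
            if use_index:
                index.add(u.sequence, len(cent_seq))
            cent_seq.append(u.sequence)
            cent_abund.append(a_u)
            clusters.append({"counts": dict(u.counts), "members": {u.sequence: a_u}})

    return _build_featureset(
        clusters, features.design, f"denoise(alpha={alpha},d_max={d_max})"
    )


# ---------------------------------------------------------------------------
# Greedy identity clustering
# ---------------------------------------------------------------------------

def cluster_greedy(features: FeatureSet, identity_threshold: float = 0.99) -> FeatureSet:
    """Greedy abundance-sorted clustering at a global identity threshold.

    ``u`` joins the highest-identity existing centroid with
    ``identity = 1 - editdist/max(len)`` at or above the threshold; ties go
    to the more abundant centroid, then the lexicographically smaller one.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise DataError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    order = _sorted_uniques(features)
    lengths = {len(f.sequence) for f in order}
    equal_len = len(lengths) == 1
    L = max(len(f.sequence) for f in order)
    d_allow_global = int(math.floor((1.0 - identity_threshold) * L))
    index = (
        PieceIndex(L, d_allow_global + 1) if equal_len and d_allow_global >= 0 else None
    )

    cent_seq: list[str] = []
    cent_abund: list[int] = []
    clusters: list[dict[str, object]] = []

    n_pieces = d_allow_global + 1
    for u in order:
        best_ci = -1
        if equal_len:
            # identity ranking == distance ranking at one length; ties go to
            # the more abundant centroid, which is scanned first
            use_prune = index is not None and len(cent_seq) > _INDEX_THRESHOLD
            if use_prune:
                shared = index.shared_piece_counts(u.sequence, len(cent_seq))
                cand = np.flatnonzero(shared)
            else:
                cand = range(len(cent_seq))
            best_d = d_allow_global + 1
            for ci in cand:
                if use_prune and shared[ci] < n_pieces - (best_d - 1):
                    continue  # cannot lie strictly closer than current best
                k = min(d_allow_global, best_d - 1)
                if k < 0:
                    break
                d = edit_distance(u.sequence, cent_seq[int(ci)], k=k)
                if d == -1:
                    continue
                best_d, best_ci = d, int(ci)
                if d == 0:
                    break
        else:
            best_key = None
            for ci in range(len(cent_seq)):
                c = cent_seq[ci]
                maxlen = max(len(u.sequence), len(c))
                d_allow = int(math.floor((1.0 - identity_threshold) * maxlen))
                d = edit_distance(u.sequence, c, k=d_allow)
                if d == -1:
                    continue
                key = (-(1.0 - d / maxlen), -cent_abund[ci], c)
                if best_key is None or key < best_key:
                    best_key, best_ci = key, ci
        if best_ci >= 0:
            _merge_counts(clusters[best_ci]["counts"], u.counts)
            clusters[best_ci]["members"][u.sequence] = u.total
        else:
            if index is not None:
                index.add(u.sequence, len(cent_seq))
            cent_seq.append(u.sequence)
            cent_abund.append(u.total)
            clusters.append({"counts": dict(u.counts), "members": {u.sequence: u.total}})

    return _build_featureset(
        clusters, features.design, f"greedy(t={identity_threshold})"
    )


# ---------------------------------------------------------------------------
# Local-linkage clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[max(ra, rb)] = min(ra, rb)
        return True


_BRUTE_FORCE_LIMIT = 4000


def cluster_linkage(features: FeatureSet, d: int = 1) -> FeatureSet:
    """Single-linkage clusters: connected components at edit distance <= d.

    For equal-length inputs at d=1 (the default, swarm-style) neighbours
    are found exactly by column-masked hashing: edit distance 1 between
    equal-length sequences is a single substitution.  Other settings use a
    quadratic exact scan, guarded by an input-size limit.
    """
    if d < 1:
        raise DataError(f"linkage distance must be >= 1, got {d}")
    order = _sorted_uniques(features)
    n = len(order)
    uf = _UnionFind(n)
    lengths = {len(f.sequence) for f in order}

    if d == 1 and len(lengths) == 1:
        _link_hamming1(order, uf)
    else:
        if n > _BRUTE_FORCE_LIMIT:
            raise DataError(
                f"linkage clustering with d={d} on {n} unique sequences exceeds "
                f"the exact-scan limit ({_BRUTE_FORCE_LIMIT})"
            )
        for i in range(n):
            for j in range(i + 1, n):
                dij = edit_distance(order[i].sequence, order[j].sequence, k=d)
                if dij != -1:
                    uf.union(i, j)

    groups: dict[int, dict[str, object]] = {}
    for i, f in enumerate(order):
        root = uf.find(i)
        g = groups.setdefault(root, {"counts": {}, "members": {}})
        _merge_counts(g["counts"], f.counts)
        g["members"][f.sequence] = f.total
    return _build_featureset(list(groups.values()), features.design, f"linkage(d={d})")


def _link_hamming1(order, uf: _UnionFind) -> None:
    """Union all equal-length pairs at Hamming distance exactly 1."""
    seqs = [f.sequence for f in order]
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    L = mat.shape[1]
    rng = np.random.default_rng(12345)  # fixed: hashing only, verified exactly
    col_hash = rng.integers(0, 2**63, size=(L, 256), dtype=np.int64)
    total = np.zeros(len(seqs), dtype=np.int64)
    for i in range(L):
        total += col_hash[i, mat[:, i]]
    for i in range(L):
        masked = total - col_hash[i, mat[:, i]]
        orderv = np.argsort(masked, kind="stable")
        sortedv = masked[orderv]
        starts = np.flatnonzero(np.r_[True, sortedv[1:] != sortedv[:-1]])
        ends = np.r_[starts[1:], len(sortedv)]
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            grp = orderv[s:e]
            anchor = grp[0]
            for other in grp[1:]:
                # equal masked rows hash equally, so true neighbours always
                # land here; the check only guards against hash collisions
                if np.count_nonzero(mat[anchor] != mat[other]) == 1:
                    uf.union(int(anchor), int(other))


# ---------------------------------------------------------------------------
# Chimera removal
# ---------------------------------------------------------------------------

@dataclass
class ChimeraHit:
    feature_id: str
    breakpoint: int
    parent_a: str
    parent_b: str
    reads_removed: int


def remove_chimeras(
    features: FeatureSet,
    skew: float = 2.0,
    max_mismatch: int = 0,
    min_seg: int = 10,
) -> tuple[FeatureSet, list[ChimeraHit]]:
    """Flag and drop de-novo two-parent crossover features.

    A feature ``x`` is chimeric when two distinct other features A and B,
    each at least ``skew`` times as abundant as ``x``, explain ``x`` as
    ``A[:k] + B[k:]`` (up to ``max_mismatch`` total mismatches) for some
    breakpoint ``k`` at least ``min_seg`` away from both ends.  The
    reported breakpoint is the smallest valid ``k``.
    """
    feats = sorted(features, key=lambda f: (-f.total, f.sequence))
    hits: list[ChimeraHit] = []
    kept: list[Feature] = []
    for x in feats:
        hit = _find_chimera(x, feats, skew, max_mismatch, min_seg)
        if hit is not None:
            hits.append(hit)
        else:
            kept.append(x)
    out = FeatureSet(
        [
            Feature(f.feature_id, f.sequence, dict(f.counts), list(f.members),
                    False, f.provenance + "+chimera_removed")
            for f in kept
        ],
        features.design,
    )
    for h in hits:
        logger.info(
            "chimera %s: breakpoint %d, parents %s/%s, %d reads removed",
            h.feature_id, h.breakpoint, h.parent_a, h.parent_b, h.reads_removed,
        )
    return out, hits


def _find_chimera(x, feats, skew, max_mismatch, min_seg) -> ChimeraHit | None:
    L = len(x.sequence)
    if L < 2 * min_seg:
        return None
    parents = [
        f for f in feats
        if f.total >= skew * x.total and f.sequence != x.sequence
        and len(f.sequence) == L
    ]
    if len(parents) < 2:
        return None
    xa = np.frombuffer(x.sequence.encode(), dtype=np.uint8)
    pm = np.frombuffer("".join(f.sequence for f in parents).encode(),
                       dtype=np.uint8).reshape(len(parents), L)
    mism = (pm != xa[None, :]).astype(np.int32)
    pre = np.concatenate(
        [np.zeros((len(parents), 1), dtype=np.int32), np.cumsum(mism, axis=1)], axis=1
    )  # pre[j, k] = mismatches of parent j vs x over [0, k)
    suf = pre[:, -1:] - pre  # suf[j, k] = mismatches over [k, L)

    ks = np.arange(min_seg, L - min_seg + 1)
    pre_k = pre[:, ks]
    suf_k = suf[:, ks]
    a1 = np.argmin(pre_k, axis=0)
    b1 = np.argmin(suf_k, axis=0)
    best_pre = pre_k[a1, np.arange(len(ks))]
    best_suf = suf_k[b1, np.arange(len(ks))]

    for pos, k in enumerate(ks):
        if best_pre[pos] + best_suf[pos] > max_mismatch:
            continue
        ai, bi = int(a1[pos]), int(b1[pos])
        if ai != bi:
            return ChimeraHit(x.feature_id, int(k),
                              parents[ai].feature_id, parents[bi].feature_id,
                              x.total)
        # same parent minimises both ends: try second-best on either side
        col_pre = pre_k[:, pos].copy()
        col_suf = suf_k[:, pos].copy()
        col_pre[ai] = np.iinfo(np.int32).max
        col_suf[bi] = np.iinfo(np.int32).max
        alt_a = int(np.argmin(col_pre))
        alt_b = int(np.argmin(col_suf))
        opts = []
        if col_pre[alt_a] + best_suf[pos] <= max_mismatch:
            opts.append((alt_a, bi))
        if best_pre[pos] + col_suf[alt_b] <= max_mismatch:
            opts.append((ai, alt_b))
        if opts:
            pa, pb = opts[0]
            return ChimeraHit(x.feature_id, int(k),
                              parents[pa].feature_id, parents[pb].feature_id,
                              x.total)
    return None
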