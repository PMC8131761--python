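"""Comparison layer: scoring pipeline output against ground truth.

Covers haplotype accounting (recovered / missing / unexpected), read-vs-
colony proportion correlations, Friedman and paired Wilcoxon tests with
multiplicity adjustment, the Mantel test between distance matrices,
Fisher's exact species-proportion test, UPGMA population clustering and
minimum-spanning haplotype networks.

Permutation tests expose exact enumeration modes on small instances; the
unit tests hold the large-sample paths to those enumerations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .assignment import AssignmentRecord
from .types import ColonyTable, DataError, FeatureSet, ReferenceSet

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Haplotype accounting
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAccounting:
    recovered: list[str]
    missing: list[str]
    unexpected: list[str]          # feature ids
    pct_reads_unexpected: float

    @property
    def n_expected(self) -> int:
        return len(self.recovered) + len(self.missing)


def haplotype_accounting(
    features: FeatureSet,
    truth: ColonyTable,
    refs: ReferenceSet,
) -> HaplotypeAccounting:
    """Score features against the haplotypes actually carried by colonies.

    Expected haplotypes are those carried by at least one colony; a
    haplotype is recovered when some feature matches its reference
    sequence exactly.  Features matching no expected haplotype are
    unexpected, and their read share is reported as a percentage of all
    retained reads.
    """
    hap_seq = refs.sequences_by_haplotype()
    expected = sorted(
        {h for counts in truth.counts_by_location().values() for h in counts}
    )
    feature_seqs = {f.sequence for f in features}
    recovered = [h for h in expected if hap_seq[h] in feature_seqs]
    missing = [h for h in expected if hap_seq[h] not in feature_seqs]
    expected_seqs = {hap_seq[h] for h in expected}
    unexpected = [f.feature_id for f in features if f.sequence not in expected_seqs]
    total = features.total_reads()
    bad = sum(f.total for f in features if f.sequence not in expected_seqs)
    pct = 100.0 * bad / total if total else 0.0
    return HaplotypeAccounting(recovered, missing, unexpected, pct)


# ---------------------------------------------------------------------------
# Proportion correlation
# ---------------------------------------------------------------------------

def proportion_correlation(
    reads_by_jar: dict[tuple[str, str], dict[str, float]],
    colonies_by_jar: dict[tuple[str, str], dict[str, float]],
) -> tuple[list[tuple[float, float]], float]:
    """Pooled (read share, colony share) points over haplotypes x jars.

    For every jar present in both inputs, every haplotype seen by either
    method contributes one point; returns the point list and Pearson r.
    """
    points: list[tuple[float, float]] = []
    for jar in sorted(set(reads_by_jar) & set(colonies_by_jar)):
        r_counts = reads_by_jar[jar]
        c_counts = colonies_by_jar[jar]
        r_total = sum(r_counts.values())
        c_total = sum(c_counts.values())
        if r_total == 0 or c_total == 0:
            continue
        for h in sorted(set(r_counts) | set(c_counts)):
            points.append(
                (r_counts.get(h, 0.0) / r_total, c_counts.get(h, 0.0) / c_total)
            )
    if len(points) < 3:
        raise DataError(f"need >= 3 (haplotype, jar) points, got {len(points)}")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return points, r


def reads_by_jar_from_features(
    features: FeatureSet, assignments: list[AssignmentRecord]
) -> dict[tuple[str, str], dict[str, float]]:
    """Haplotype-assigned read totals per (location, jar)."""
    design = features.design
    rec = {r.feature_id: r for r in assignments}
    out: dict[tuple[str, str], dict[str, float]] = {}
    for f in features:
        a = rec.get(f.feature_id)
        if a is None or a.haplotype_id is None:
            continue
        for rid, c in f.counts.items():
            sid = design.sample_of(rid)
            if sid is None:
                continue
            s = design.sample(sid)
            jar = out.setdefault((s.location, s.jar), {})
            jar[a.haplotype_id] = jar.get(a.haplotype_id, 0.0) + c
    return out


def colonies_by_jar_from_table(truth: ColonyTable) -> dict[tuple[str, str], dict[str, float]]:
    return {
        jar: {h: float(c) for h, c in counts.items()}
        for jar, counts in truth.counts_by_jar().items()
    }


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def friedman_test(matrix, method: str = "chi2") -> tuple[float, int, float]:
    """Friedman rank test over a blocks x treatments matrix.

    Within-block average ranks (mean ranks for ties), the standard
    tie-corrected statistic, and a chi-square p-value with df = k - 1.
    ``method="exact"`` enumerates all within-block orderings (feasible for
    small instances only).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DataError("Friedman test needs >= 2 blocks and >= 2 treatments")
    n, k = m.shape
    q = _friedman_statistic(m)
    if math.isnan(q):
        raise DataError("Friedman statistic undefined: all values tied in every block")
    df = k - 1
    if method == "chi2":
        p = float(stats.chi2.sf(q, df))
    elif method == "exact":
        if math.factorial(k) ** n > 2_000_000:
            raise DataError("exact Friedman enumeration infeasible for this size")
        count = 0
        total = 0
        perms = list(itertools.permutations(range(k)))
        for assign_perm in itertools.product(perms, repeat=n):
            shuffled = np.array([m[i, list(pi)] for i, pi in enumerate(assign_perm)])
            qs = _friedman_statistic(shuffled)
            total += 1
            if qs >= q - _EPS:
                count += 1
        p = count / total
    else:
        raise DataError(f"unknown method {method!r}")
    return float(q), df, p


def _friedman_statistic(m: np.ndarray) -> float:
    n, k = m.shape
    ranks = np.array([stats.rankdata(row) for row in m])
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * (k**3 - k))
    if c == 0.0:
        return float("nan")
    return (12.0 * ssbn / (n * k * (k + 1))) / c


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y, mode: str = "auto") -> float:
    """Two-sided paired Wilcoxon p-value.

    Zero differences are dropped.  The exact null is enumerated (a
    subset-sum count over the — possibly tied, mean-assigned — ranks) for
    n <= 25; larger samples use the tie-corrected normal approximation.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.info("all paired differences zero: p = 1 by convention")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= 25 else "normal"
    if mode == "exact":
        return _wilcoxon_exact_p(ranks, w_plus)
    if mode != "normal":
        raise DataError(f"unknown mode {mode!r}")
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by counting sign assignments (integer DP on 2*rank)."""
    ir = np.rint(2 * ranks).astype(int)  # mean ties make ranks half-integers
    total = int(ir.sum())
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in ir:
        shifted = np.zeros_like(dp)
        shifted[r:] = dp[: total + 1 - r]
        dp = dp + shifted
    dp /= dp.sum()
    w2 = int(round(2 * w_plus))
    p_low = float(dp[: w2 + 1].sum())
    p_high = float(dp[w2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_pairwise(matrix, adjust: str = "holm") -> np.ndarray:
    """Adjusted p-value matrix for all treatment pairs of a blocks x k matrix."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if n < 2:
        raise DataError("need >= 2 paired observations per comparison")
    pairs = list(itertools.combinations(range(k), 2))
    raw = [wilcoxon_signed_rank(m[:, i], m[:, j]) for i, j in pairs]
    method = {"holm": "holm", "bh": "fdr_bh"}.get(adjust)
    if method is None:
        raise DataError(f"unknown adjustment {adjust!r}")
    adj = multipletests(raw, method=method)[1] if raw else []
    out = np.full((k, k), np.nan)
    for (i, j), p in zip(pairs, adj):
        out[i, j] = out[j, i] = p
    return out


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    d1, d2, n_perm: int = 999, seed: int = 0, method: str = "auto"
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation of the lower triangles; the p-value
    permutes rows and columns of the second matrix jointly,
    ``p = (1 + #{r_perm >= r}) / (1 + n_perm)``.  For n <= 7 labels the
    full permutation set is enumerated instead.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DataError("matrices must be square and of equal shape")
    n = a.shape[0]
    if n < 3:
        raise DataError("Mantel test needs >= 3 labels")
    if np.max(np.abs(a - a.T)) > 1e-9 or np.max(np.abs(b - b.T)) > 1e-9:
        raise DataError("matrices must be symmetric")
    il = np.tril_indices(n, k=-1)
    va, vb = a[il], b[il]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DataError("constant distance triangle: Mantel r undefined")
    r_obs = float(stats.pearsonr(va, vb).statistic)

    if method == "auto":
        method = "exact" if n <= 7 else "permutation"
    if method == "exact":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            bp = b[np.ix_(perm, perm)]
            r = float(stats.pearsonr(va, bp[il]).statistic)
            total += 1
            if r >= r_obs - _EPS:
                count += 1
        return r_obs, count / total
    if method != "permutation":
        raise DataError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        r = float(stats.pearsonr(va, bp[il]).statistic)
        if r >= r_obs - _EPS:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Species-proportion test
# ---------------------------------------------------------------------------

def species_proportion_test(
    reads_by_location: dict[str, dict[str, float]],
    colonies_by_location: dict[str, dict[str, int]],
    species: tuple[str, str],
) -> dict[str, float]:
    """Two-sided Fisher's exact test per location on 2x2 method x species counts.

    Raw read counts would make any difference significant, so reads are
    downscaled to a colony-equivalent sample: the location's colony total,
    split by the observed read proportions (rounded).
    """
    s1, s2 = species
    out: dict[str, float] = {}
    for loc in sorted(colonies_by_location):
        c1 = int(colonies_by_location[loc].get(s1, 0))
        c2 = int(colonies_by_location[loc].get(s2, 0))
        reads = reads_by_location.get(loc, {})
        r1 = float(reads.get(s1, 0.0))
        r2 = float(reads.get(s2, 0.0))
        n_col = c1 + c2
        if n_col == 0 or (r1 + r2) == 0:
            out[loc] = 1.0
            continue
        e1 = int(round(r1 / (r1 + r2) * n_col))
        table = np.array([[c1, c2], [e1, n_col - e1]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            out[loc] = 1.0
            continue
        out[loc] = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return out


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(matrix, labels: list[str]) -> str:
    """Average-linkage (UPGMA) newick tree from a distance matrix.

    Negative entries are floored at zero (logged); NaN entries are an
    error.  Branch lengths follow the ultrametric convention: a cluster
    formed at distance d sits at height d/2.
    """
    m = np.asarray(matrix, dtype=float).copy()
    if np.isnan(m).any():
        raise DataError("distance matrix contains NaN")
    if (m < 0).any():
        logger.info("flooring %d negative distances at 0", int((m < 0).sum()))
        m[m < 0] = 0.0
    np.fill_diagonal(m, 0.0)
    z = linkage(squareform(m, checks=False), method="average")
    return _linkage_to_newick(z, labels)


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for idx, (a, b, dist, _) in enumerate(z):
        a, b = int(a), int(b)
        h = dist / 2.0
        la = h - heights[a]
        lb = h - heights[b]
        new = n + idx
        nodes[new] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[new] = h
    return nodes[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# Haplotype network
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    nodes: list[str]
    sizes: dict[str, float]                    # fourth root of abundance
    mst_edges: list[tuple[str, str, int]]
    alternative_edges: list[tuple[str, str, int]] = field(default_factory=list)

    def edge_rows(self):
        rows = [(a, b, w, "mst") for a, b, w in self.mst_edges]
        rows += [(a, b, w, "alternative") for a, b, w in self.alternative_edges]
        return rows


def haplotype_network(
    sequences: dict[str, str], abundances: dict[str, float]
) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network with alternative links.

    Nodes are sequences (equal length required; distances are Hamming,
    i.e. mutation counts).  Kruskal's algorithm with deterministic
    tie-breaking by node-label order builds the tree; a non-tree edge is
    an alternative link when its weight equals the largest weight on the
    tree path between its endpoints (so swapping it in would cost
    nothing).  Node display size is the fourth root of abundance.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise DataError("network needs >= 2 sequences")
    lengths = {len(sequences[i]) for i in ids}
    if len(lengths) != 1:
        raise DataError("unequal sequence lengths: no indel handling in networks")
    edges = []
    for a, b in itertools.combinations(ids, 2):
        w = sum(1 for x, y in zip(sequences[a], sequences[b]) if x != y)
        edges.append((w, a, b))
    edges.sort()

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst: list[tuple[str, str, int]] = []
    rejected: list[tuple[int, str, str]] = []
    adj: dict[str, list[tuple[str, int]]] = {i: [] for i in ids}
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
            mst.append((a, b, w))
            adj[a].append((b, w))
            adj[b].append((a, w))
        else:
            rejected.append((w, a, b))

    alternatives = []
    for w, a, b in rejected:
        if w == _path_bottleneck(adj, a, b):
            alternatives.append((a, b, w))

    sizes = {i: float(abundances.get(i, 0.0)) ** 0.25 for i in ids}
    return HaplotypeNetwork(ids, sizes, mst, alternatives)


def _path_bottleneck(adj, start: str, goal: str) -> int:
    """Maximum edge weight on the unique tree path start -> goal (DFS)."""
    stack = [(start, None, 0)]
    while stack:
        node, prev, best = stack.pop()
        if node == goal:
            return best
        for nxt, w in adj[node]:
            if nxt != prev:
                stack.append((nxt, node, max(best, w)))
    raise DataError("nodes not connected in tree")
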