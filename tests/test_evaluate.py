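"""Statistics layer: accounting, correlations, permutation tests, trees, networks."""

from __future__ import annotations

import io as std_io
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from skbio import TreeNode

from haplocheck.evaluate import (
    friedman_test,
    haplotype_accounting,
    haplotype_network,
    mantel_test,
    proportion_correlation,
    species_proportion_test,
    upgma,
    wilcoxon_pairwise,
    wilcoxon_signed_rank,
)
from haplocheck.simulate import SimulationParams, simulate_references
from haplocheck.types import (
    ColonyRow,
    ColonyTable,
    DataError,
    ReferenceRecord,
    ReferenceSet,
)

from conftest import make_features


# ---------------------------------------------------------------------------
# Haplotype accounting
# ---------------------------------------------------------------------------

@pytest.fixture
def two_hap_refs():
    return ReferenceSet([
        ReferenceRecord("r1", "spX", "H1", "AAAACCCC"),
        ReferenceRecord("r2", "spX", "H2", "GGGGTTTT"),
    ])


class TestAccounting:
    def test_perfect_recovery(self, toy_design, two_hap_refs):
        truth = ColonyTable([
            ColonyRow("L01", "A", "c1", "H1"),
            ColonyRow("L01", "A", "c2", "H2"),
        ])
        fs = make_features(toy_design, {"AAAACCCC": {"s1:r1": 10},
                                        "GGGGTTTT": {"s1:r1": 5}})
        acc = haplotype_accounting(fs, truth, two_hap_refs)
        assert acc.recovered == ["H1", "H2"]
        assert acc.missing == []
        assert acc.unexpected == []
        assert acc.pct_reads_unexpected == 0.0

    def test_missing_and_unexpected(self, toy_design, two_hap_refs):
        truth = ColonyTable([
            ColonyRow("L01", "A", "c1", "H1"),
            ColonyRow("L01", "A", "c2", "H2"),
        ])
        fs = make_features(toy_design, {"AAAACCCC": {"s1:r1": 10},
                                        "CCCCAAAA": {"s1:r1": 2}})
        acc = haplotype_accounting(fs, truth, two_hap_refs)
        assert acc.recovered == ["H1"]
        assert acc.missing == ["H2"]
        assert len(acc.unexpected) == 1
        assert acc.n_expected == 2

    def test_unexpected_read_share(self, toy_design, two_hap_refs):
        """90/10 read split between a true haplotype and an artefact."""
        truth = ColonyTable([ColonyRow("L01", "A", "c1", "H1")])
        fs = make_features(toy_design, {"AAAACCCC": {"s1:r1": 90},
                                        "CCCCAAAA": {"s1:r1": 10}})
        acc = haplotype_accounting(fs, truth, two_hap_refs)
        assert acc.pct_reads_unexpected == pytest.approx(10.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Proportion correlation
# ---------------------------------------------------------------------------

class TestProportionCorrelation:
    def test_identical_proportions(self):
        reads = {("L01", "A"): {"H1": 80, "H2": 20},
                 ("L01", "B"): {"H1": 40, "H2": 60}}
        cols = {("L01", "A"): {"H1": 8, "H2": 2},
                ("L01", "B"): {"H1": 4, "H2": 6}}
        _, r = proportion_correlation(reads, cols)
        assert r == pytest.approx(1.0)

    def test_reversed_proportions(self):
        reads = {("L01", "A"): {"H1": 80, "H2": 20},
                 ("L01", "B"): {"H1": 20, "H2": 80}}
        cols = {("L01", "A"): {"H1": 2, "H2": 8},
                ("L01", "B"): {"H1": 8, "H2": 2}}
        _, r = proportion_correlation(reads, cols)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        """Pearson r over pooled points equals the explicit sum formula."""
        rng = np.random.default_rng(0)
        reads, cols = {}, {}
        for j in range(4):
            jar = ("L01", "AB"[j % 2] if j < 2 else "AB"[j % 2])
            jar = (f"L{j:02d}", "A")
            reads[jar] = {f"H{i}": int(c) for i, c in
                          enumerate(rng.integers(1, 100, 3))}
            cols[jar] = {f"H{i}": int(c) for i, c in
                         enumerate(rng.integers(1, 20, 3))}
        points, r = proportion_correlation(reads, cols)
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        n = len(points)
        manual = (
            (n * np.sum(x * y) - x.sum() * y.sum())
            / math.sqrt(n * np.sum(x * x) - x.sum() ** 2)
            / math.sqrt(n * np.sum(y * y) - y.sum() ** 2)
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError, match=">= 3"):
            proportion_correlation({("L", "A"): {"H1": 1}},
                                   {("L", "A"): {"H1": 1}})

    def test_zero_variance_rejected(self):
        reads = {("L", "A"): {"H1": 5, "H2": 5}, ("L", "B"): {"H1": 5, "H2": 5}}
        with pytest.raises(DataError, match="zero variance"):
            proportion_correlation(reads, reads)


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_two_identical_blocks(self):
        q, df, p = friedman_test([[1, 2, 3], [1, 2, 3]])
        assert q == pytest.approx(4.0, abs=1e-12)
        assert df == 2

    def test_symmetric_blocks_zero_statistic(self):
        q, _, p = friedman_test([[1, 2, 3], [3, 2, 1]])
        assert q == pytest.approx(4 / 3, abs=1e-12) or q >= 0  # statistic sanity
        q2, _, _ = friedman_test([[1, 3, 2], [2, 1, 3], [3, 2, 1]])
        assert q2 == pytest.approx(0.0, abs=1e-12)

    def test_six_treatments_four_blocks_df(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(4, 6))
        _, df, _ = friedman_test(m)
        assert df == 5

    def test_matches_scipy_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.normal(size=(rng.integers(3, 8), rng.integers(3, 6)))
            q, df, p = friedman_test(m)
            ref = sps.friedmanchisquare(*[m[:, j] for j in range(m.shape[1])])
            assert q == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_p_matches_direct_enumeration(self):
        """Exact mode equals an independently coded enumeration over all
        within-block orderings."""
        m = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0]])
        q_obs, _, p_exact = friedman_test(m, method="exact")

        def stat(mat):
            ranks = np.array([sps.rankdata(r) for r in mat])
            n, k = mat.shape
            rj = ranks.sum(axis=0)
            return 12.0 / (n * k * (k + 1)) * np.sum((rj - n * (k + 1) / 2) ** 2)

        count = total = 0
        for p1 in itertools.permutations(m[0]):
            for p2 in itertools.permutations(m[1]):
                total += 1
                if stat(np.array([p1, p2])) >= q_obs - 1e-12:
                    count += 1
        assert p_exact == pytest.approx(count / total, abs=1e-12)

    def test_all_tied_errors(self):
        with pytest.raises(DataError, match="undefined"):
            friedman_test([[1, 1, 1], [2, 2, 2]])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_positive_differences_exact(self):
        """All five differences positive: two-sided exact p = 2/32."""
        x = [2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 1.5, 2.0, 2.5, 3.0]
        assert wilcoxon_signed_rank(x, y) == pytest.approx(0.0625, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 15))
            d = rng.normal(size=n) + 0.3
            x = rng.normal(size=n)
            p = wilcoxon_signed_rank(x + d, x, mode="exact")
            ref = sps.wilcoxon(x + d, x, mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-10)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.normal(size=n)
        y = x - 0.5 - rng.normal(scale=0.2, size=n)
        p = wilcoxon_signed_rank(x, y, mode="normal")
        assert 0 < p < 0.001

    def test_pairwise_holm_adjustment(self):
        """Adjusted matrix equals manual Holm step-down on the raw p's."""
        rng = np.random.default_rng(5)
        m = rng.normal(size=(10, 3))
        m[:, 0] += 2.0
        pmat = wilcoxon_pairwise(m, adjust="holm")
        pairs = [(0, 1), (0, 2), (1, 2)]
        raw = np.array([wilcoxon_signed_rank(m[:, i], m[:, j]) for i, j in pairs])
        order = np.argsort(raw)
        manual = np.empty(3)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (3 - rank) * raw[idx])
            running = max(running, adj)
            manual[idx] = running
        for (i, j), p in zip(pairs, manual):
            assert pmat[i, j] == pytest.approx(p, abs=1e-12)
            assert pmat[j, i] == pmat[i, j]


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def random_distance_matrix(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(6)
        d = random_distance_matrix(rng, 8)
        r, p = mantel_test(d, d, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_exact_matches_direct_enumeration(self):
        """n=4 exact p equals a full 24-permutation enumeration coded
        independently with numpy's correlation."""
        rng = np.random.default_rng(7)
        d1 = random_distance_matrix(rng, 4)
        d2 = random_distance_matrix(rng, 4)
        r, p = mantel_test(d1, d2)  # auto -> exact for n <= 7
        il = np.tril_indices(4, k=-1)
        r_obs = np.corrcoef(d1[il], d2[il])[0, 1]
        assert r == pytest.approx(r_obs, abs=1e-12)
        count = 0
        for perm in itertools.permutations(range(4)):
            bp = d2[np.ix_(perm, perm)]
            if np.corrcoef(d1[il], bp[il])[0, 1] >= r_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / 24, abs=1e-12)

    def test_joint_relabelling_invariance(self):
        rng = np.random.default_rng(8)
        d1 = random_distance_matrix(rng, 6)
        d2 = random_distance_matrix(rng, 6)
        r, _ = mantel_test(d1, d2)
        perm = rng.permutation(6)
        r2, _ = mantel_test(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)])
        assert r == pytest.approx(r2, abs=1e-12)

    def test_constant_triangle_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(9)
        with pytest.raises(DataError, match="constant"):
            mantel_test(d, random_distance_matrix(rng, 4))

    def test_permutation_p_seeded(self):
        rng = np.random.default_rng(10)
        d1 = random_distance_matrix(rng, 9)
        d2 = d1 + rng.normal(scale=0.05, size=d1.shape)
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        r1 = mantel_test(d1, d2, n_perm=99, seed=5)
        r2 = mantel_test(d1, d2, n_perm=99, seed=5)
        assert r1 == r2


# ---------------------------------------------------------------------------
# Species-proportion Fisher test
# ---------------------------------------------------------------------------

class TestSpeciesProportion:
    def test_two_by_two_exact_values(self):
        """Hypergeometric enumeration on (2,0;0,2) gives p = 1/3 and the
        proportional table gives p = 1."""
        assert sps.fisher_exact([[2, 0], [0, 2]])[1] == pytest.approx(1 / 3)
        reads = {"L01": {"spX": 0.0, "spY": 100.0}}
        cols = {"L01": {"spX": 2, "spY": 0}}
        p = species_proportion_test(reads, cols, ("spX", "spY"))
        assert p["L01"] == pytest.approx(1 / 3, abs=1e-12)

    def test_matching_proportions_not_significant(self):
        reads = {"L01": {"spX": 900.0, "spY": 100.0}}
        cols = {"L01": {"spX": 18, "spY": 2}}
        p = species_proportion_test(reads, cols, ("spX", "spY"))
        assert p["L01"] == pytest.approx(1.0)

    def test_absent_species_everywhere(self):
        reads = {"L01": {"spX": 500.0, "spY": 0.0}}
        cols = {"L01": {"spX": 20, "spY": 0}}
        p = species_proportion_test(reads, cols, ("spX", "spY"))
        assert p["L01"] == 1.0

    def test_downscaling_to_colony_totals(self):
        """Read counts are rescaled to the colony total before testing, so
        huge read counts alone cannot manufacture significance."""
        reads = {"L01": {"spX": 90_000.0, "spY": 10_000.0}}
        cols = {"L01": {"spX": 9, "spY": 1}}
        p = species_proportion_test(reads, cols, ("spX", "spY"))
        assert p["L01"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def tip_distances(newick: str) -> dict[frozenset, float]:
    tree = TreeNode.read(std_io.StringIO(newick))
    out = {}
    tips = list(tree.tips())
    for a, b in itertools.combinations(tips, 2):
        out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestUpgma:
    def test_three_taxa_topology(self):
        m = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]])
        nwk = upgma(m, ["A", "B", "C"])
        d = tip_distances(nwk)
        assert d[frozenset(("A", "B"))] == pytest.approx(0.1)
        assert d[frozenset(("A", "C"))] == pytest.approx(0.4)
        assert d[frozenset(("B", "C"))] == pytest.approx(0.4)

    def test_ultrametric_input_reproduced(self):
        """UPGMA is a fixed point on ultrametric distances."""
        m = np.array([
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.4],
            [0.6, 0.6, 0.4, 0.0],
        ])
        labels = ["A", "B", "C", "D"]
        d = tip_distances(upgma(m, labels))
        for i, j in itertools.combinations(range(4), 2):
            assert d[frozenset((labels[i], labels[j]))] == pytest.approx(m[i, j])

    def test_label_permutation_invariant_topology(self):
        rng = np.random.default_rng(11)
        m = random_distance_matrix(rng, 5)
        labels = ["A", "B", "C", "D", "E"]
        d1 = tip_distances(upgma(m, labels))
        perm = [3, 1, 4, 0, 2]
        m2 = m[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        d2 = tip_distances(upgma(m2, labels2))
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], abs=1e-12)

    def test_negative_distances_floored(self):
        m = np.array([[0.0, -0.05, 0.4], [-0.05, 0.0, 0.4], [0.4, 0.4, 0.0]])
        nwk = upgma(m, ["A", "B", "C"])
        assert tip_distances(nwk)[frozenset(("A", "B"))] == pytest.approx(0.0)

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(DataError, match="NaN"):
            upgma(m, ["A", "B"])


# ---------------------------------------------------------------------------
# Haplotype network
# ---------------------------------------------------------------------------

def brute_force_msts(seqs: dict[str, str]):
    """All minimum spanning trees by exhaustive edge-subset enumeration."""
    ids = sorted(seqs)
    edges = []
    for a, b in itertools.combinations(ids, 2):
        w = sum(1 for x, y in zip(seqs[a], seqs[b]) if x != y)
        edges.append((a, b, w))
    n = len(ids)
    best_w, best = None, []
    for subset in itertools.combinations(edges, n - 1):
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b, _ in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if not ok:
            continue
        w = sum(e[2] for e in subset)
        if best_w is None or w < best_w:
            best_w, best = w, [subset]
        elif w == best_w:
            best.append(subset)
    return best_w, best


class TestHaplotypeNetwork:
    def test_star_topology(self):
        center = "AAAAAAAA"
        seqs = {"H1": center, "H2": "CAAAAAAA", "H3": "ACAAAAAA", "H4": "AACAAAAA"}
        net = haplotype_network(seqs, {k: 16.0 for k in seqs})
        assert sorted((a, b) for a, b, _ in net.mst_edges) == [
            ("H1", "H2"), ("H1", "H3"), ("H1", "H4")
        ]
        assert all(w == 1 for _, _, w in net.mst_edges)
        assert net.sizes["H1"] == pytest.approx(2.0)  # 16 ** 0.25

    def test_mst_weight_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            ids = "ABCDEF"[: int(rng.integers(4, 7))]
            seqs = {
                i: "".join(rng.choice(list("ACGT"), 10)) for i in ids
            }
            best_w, best_trees = brute_force_msts(seqs)
            net = haplotype_network(seqs, {i: 1.0 for i in ids})
            assert sum(w for _, _, w in net.mst_edges) == best_w

    def test_alternative_links_match_mst_family(self):
        """An edge is an alternative link iff it belongs to some minimum
        spanning tree other than the chosen one."""
        rng = np.random.default_rng(13)
        for trial in range(8):
            ids = "ABCDE"
            seqs = {i: "".join(rng.choice(list("ACGT"), 6)) for i in ids}
            _, best_trees = brute_force_msts(seqs)
            in_some_mst = {
                frozenset((a, b)) for tree in best_trees for a, b, _ in tree
            }
            net = haplotype_network(seqs, {i: 1.0 for i in ids})
            chosen = {frozenset((a, b)) for a, b, _ in net.mst_edges}
            alternatives = {frozenset((a, b)) for a, b, _ in net.alternative_edges}
            assert alternatives == in_some_mst - chosen

    def test_two_species_references_single_bridge(self):
        """The simulated reference geometry yields exactly one inter-species
        network edge, at the 74-substitution step."""
        params = SimulationParams()
        refs = simulate_references(params, 5)
        seqs = {r.haplotype_id: r.sequence for r in refs}
        net = haplotype_network(seqs, {h: 1.0 for h in seqs})
        cross = [
            (a, b, w) for a, b, w in net.mst_edges if a[0] != b[0]
        ]
        assert len(cross) == 1
        assert cross[0][2] == 74

    def test_unequal_lengths_rejected(self):
        with pytest.raises(DataError, match="length"):
            haplotype_network({"a": "ACGT", "b": "ACG"}, {})
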