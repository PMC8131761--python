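"""Ground-truthed mock-community read simulator.

The simulator emulates a two-species colonial-ascidian study design: ten
locations, each sampled into two preservation jars, 32-36 colonies per
location, a fixed-length COI insert, two species separated by a large
substitution step (74 by default) with star-like within-species haplotype
topologies, and per-sample libraries of nine technical replicates (three
extraction x three tagged-PCR) sequenced to a fixed depth alongside twelve
unused control index combinations.

Error processes, applied per technical replicate:

1. *Amplification bias* — every colony in the jar receives a lognormal
   weight; the expected read share of a haplotype is the normalised sum of
   its colonies' weights.
2. *Template sampling* — the replicate's depth is drawn multinomially from
   those expected shares.
3. *Chimeras* — each read is, with probability ``chimera_rate``, replaced
   by a two-parent crossover: parents drawn abundance-weighted, breakpoint
   uniform away from the ends.
4. *Substitution errors* — every base flips independently with probability
   ``error_rate`` to a uniformly chosen other base (optional hotspot
   positions use an elevated rate, shared across replicates).
5. *Index jumps* — each finished read is, with probability
   ``index_jump_rate``, reassigned to a uniformly chosen other replicate or
   control combination.

Total reads are conserved: the sum over all replicates and controls equals
the summed per-replicate depths.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from ._distance import CODE_TO_BASE, encode
from .types import (
    MISSING,
    ColonyRow,
    ColonyTable,
    DataError,
    ReferenceRecord,
    ReferenceSet,
    ReplicateCountTable,
    SampleDesign,
)

logger = logging.getLogger(__name__)

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Tunable knobs of the mock-community generator.

    Defaults reproduce the emulated study design: 10 locations x 2 jars,
    32-36 colonies per location, a 412-nt insert, a 74-substitution
    interspecies step, within-species satellites 1-8 mutations from the
    central haplotype, depth 20,000 reads per technical replicate,
    lognormal amplification bias (sigma 0.5), substitution rate 2e-3 per
    base, chimera rate 0.01 per read, and index-jump rate 1e-3 per read.
    """

    n_locations: int = 10
    jars_per_location: int = 2
    colonies_min: int = 32
    colonies_max: int = 36
    amplicon_length: int = 412
    interspecies_distance: int = 74
    # Hamming steps of each satellite haplotype from its species' central
    # haplotype; one tuple per species.
    within_species_steps: tuple[tuple[int, ...], ...] = ((1, 2, 2, 3, 5, 8), (1,))
    # location -> haplotype -> frequency; None = built-in default spec
    haplotype_frequency_spec: dict[str, dict[str, float]] | None = None
    depth_per_replicate: int = 20_000
    bias_sd: float = 0.5
    error_rate: float = 2e-3
    hotspot_error_rate: float = 0.0
    hotspot_positions: tuple[int, ...] = ()
    chimera_rate: float = 0.01
    chimera_min_seg: int = 10
    index_jump_rate: float = 1e-3
    # degradation applied to ebDNA12 samples
    ebdna12_depth_factor: float = 0.5
    ebdna12_dropout: float = 0.25
    # probability that a colony fails individual barcoding (haplotype MISSING
    # in the observed colony table; the colony still sheds reads)
    colony_fail_prob: float = 0.003
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "hotspot_error_rate", "chimera_rate",
                     "index_jump_rate", "ebdna12_dropout", "colony_fail_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.amplicon_length < self.interspecies_distance:
            raise DataError("amplicon_length must be >= interspecies_distance")
        if self.colonies_min > self.colonies_max:
            raise DataError("colonies_min must be <= colonies_max")
        if self.haplotype_frequency_spec is not None:
            for loc, freqs in self.haplotype_frequency_spec.items():
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise DataError(
                        f"frequencies for location {loc!r} sum to {total}, not 1"
                    )

    @property
    def locations(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_locations)]


@dataclass
class GroundTruth:
    """Everything the evaluation layer needs to score a simulated run."""

    refs: ReferenceSet
    colonies: ColonyTable                      # true haplotypes, no MISSING
    # sample_id -> haplotype -> expected read proportion (colony shares)
    expected_proportions: dict[str, dict[str, float]]
    # replicate_id -> {"error_reads", "error_bases", "chimera_reads", "jumped_reads"}
    event_log: dict[str, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Haplotype naming / default frequency structure
# ---------------------------------------------------------------------------

def _haplotype_ids(params: SimulationParams) -> tuple[list[str], list[str]]:
    n_a = 1 + len(params.within_species_steps[0])
    n_b = 1 + len(params.within_species_steps[1])
    return (
        [f"A-H{i + 1}" for i in range(n_a)],
        [f"B-H{i + 1}" for i in range(n_b)],
    )


def default_frequency_spec(params: SimulationParams) -> dict[str, dict[str, float]]:
    """Deterministic per-location haplotype frequencies.

    The layout mirrors a realistic marina survey of two clonal species: one
    species dominates everywhere, its central haplotype is the commonest,
    two common satellites trade places along a geographic gradient (giving
    genuine between-location differentiation), a few satellites are rare
    and patchy, and the second species occurs in three locations only at a
    modest share.
    """
    haps_a, haps_b = _haplotype_ids(params)
    n = params.n_locations
    spec: dict[str, dict[str, float]] = {}
    b_locations = {i for i in range(n) if i % 4 == 2}  # e.g. L03, L07 of 10
    for i, loc in enumerate(params.locations):
        grad = i / max(n - 1, 1)
        w: dict[str, float] = {h: 0.0 for h in haps_a}
        w[haps_a[0]] = 6.0                      # central, dominant everywhere
        if len(haps_a) > 1:
            w[haps_a[1]] = 1.0 + 3.0 * grad     # common satellite, rising
        if len(haps_a) > 2:
            w[haps_a[2]] = 4.0 - 3.0 * grad     # common satellite, falling
        if len(haps_a) > 3:
            w[haps_a[3]] = 1.2 if i % 2 == 0 else 0.0
        if len(haps_a) > 4:
            w[haps_a[4]] = 0.9 if i % 3 == 1 else 0.0
        if len(haps_a) > 5:
            w[haps_a[5]] = 0.8 if i >= n - 3 else 0.0
        for j in range(6, len(haps_a)):
            w[haps_a[j]] = 0.7 if (i + j) % 4 == 0 else 0.0
        total_a = sum(w.values())
        b_total = 0.15 if i in b_locations else 0.0
        freqs = {h: (1.0 - b_total) * v / total_a for h, v in w.items()}
        if len(haps_b) == 1:
            freqs[haps_b[0]] = b_total
        else:
            freqs[haps_b[0]] = b_total * 0.7
            freqs[haps_b[1]] = b_total * 0.3
            for h in haps_b[2:]:
                freqs[h] = 0.0
        spec[loc] = freqs
    return spec


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

def simulate_references(params: SimulationParams, seed: int | None = None) -> ReferenceSet:
    """Two-species reference haplotypes with controlled Hamming geometry.

    The two central haplotypes differ at exactly
    ``interspecies_distance`` positions.  Satellite haplotypes mutate
    position sets disjoint from the interspecies sites and from each other,
    so every within-species distance is the sum of the two satellites'
    steps and every between-species distance is at least the interspecies
    step.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng([seed, _tag("refs")])
    L = params.amplicon_length
    steps_all = [s for sp in params.within_species_steps for s in sp]
    needed = params.interspecies_distance + sum(steps_all)
    if needed > L:
        raise DataError(
            f"infeasible distance constraints: need {needed} distinct sites "
            f"but amplicon_length is {L}"
        )

    central_a = rng.integers(0, 4, size=L).astype(np.uint8)
    positions = rng.permutation(L)
    inter = positions[: params.interspecies_distance]
    central_b = central_a.copy()
    central_b[inter] = (central_b[inter] + 1 + rng.integers(0, 3, size=len(inter))) % 4

    pool = positions[params.interspecies_distance:]
    cursor = 0
    records: list[ReferenceRecord] = []
    ref_no = 0
    for sp_idx, (species, central) in enumerate(
        [(SPECIES_A, central_a), (SPECIES_B, central_b)]
    ):
        haps = _haplotype_ids(params)[sp_idx]
        seqs = [central]
        for step in params.within_species_steps[sp_idx]:
            sites = pool[cursor: cursor + step]
            cursor += step
            var = central.copy()
            var[sites] = (var[sites] + 1 + rng.integers(0, 3, size=len(sites))) % 4
            seqs.append(var)
        for hap, seq in zip(haps, seqs):
            ref_no += 1
            records.append(
                ReferenceRecord(
                    f"ref{ref_no:02d}", species, hap,
                    bytes(CODE_TO_BASE[seq]).decode(),
                )
            )
    return ReferenceSet(records)


# ---------------------------------------------------------------------------
# Assemblages
# ---------------------------------------------------------------------------

def simulate_assemblages(
    params: SimulationParams, refs: ReferenceSet, seed: int | None = None
) -> ColonyTable:
    """Draw colonies per location and split them between jars A and B.

    Returns the *true* colony table (every haplotype known).  Use
    :func:`mask_failed_colonies` to emulate individual-barcoding failures
    on the observed copy.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng([seed, _tag("colonies")])
    spec = params.haplotype_frequency_spec or default_frequency_spec(params)
    missing = set(params.locations) - set(spec)
    if missing:
        raise DataError(f"frequency spec missing locations: {sorted(missing)}")

    rows: list[ColonyRow] = []
    for loc in params.locations:
        freqs = spec[loc]
        haps = sorted(freqs)
        p = np.array([freqs[h] for h in haps], dtype=float)
        p = p / p.sum()
        n = int(rng.integers(params.colonies_min, params.colonies_max + 1))
        draws = rng.choice(len(haps), size=n, p=p)
        for idx, h_idx in enumerate(draws):
            jar = "A" if idx < (n + 1) // 2 else "B"
            rows.append(
                ColonyRow(loc, jar, f"{loc}-c{idx + 1:03d}", haps[h_idx])
            )
    return ColonyTable(rows, refs=refs)


def mask_failed_colonies(
    colonies: ColonyTable, fail_prob: float, seed: int
) -> ColonyTable:
    """Observed colony table: each colony fails barcoding with ``fail_prob``."""
    rng = np.random.default_rng([seed, _tag("fail")])
    rows = [
        ColonyRow(r.location, r.jar, r.colony_id,
                  MISSING if rng.random() < fail_prob else r.haplotype_id)
        for r in colonies
    ]
    return ColonyTable(rows)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _tag(text: str) -> int:
    """Stable 32-bit stream tag for seeding independent RNG streams."""
    return zlib.crc32(text.encode())


def simulate_reads(
    params: SimulationParams,
    refs: ReferenceSet,
    colonies: ColonyTable,
    design: SampleDesign,
    seed: int | None = None,
) -> tuple[ReplicateCountTable, GroundTruth]:
    """Per-replicate read-count tables plus the ground truth used to score them.

    Each technical replicate draws from its own RNG stream (seeded from the
    run seed and the replicate id), so replicates are independent and
    individually reproducible; index-jump destinations are drawn within the
    source replicate's stream.
    """
    if seed is None:
        seed = params.seed
    hap_seq = refs.sequences_by_haplotype()
    hap_code = {h: encode(s) for h, s in hap_seq.items()}
    L = params.amplicon_length
    for h, s in hap_seq.items():
        if len(s) != L:
            raise DataError(f"haplotype {h} length {len(s)} != amplicon_length {L}")

    by_jar: dict[tuple[str, str], list[str]] = {}
    for row in colonies:
        if row.haplotype_id == MISSING:
            raise DataError(
                "simulate_reads needs the true colony table (no MISSING); "
                "mask failures only on the observed copy"
            )
        by_jar.setdefault((row.location, row.jar), []).append(row.haplotype_id)

    table = ReplicateCountTable(design)
    truth_events: dict[str, dict[str, int]] = {}
    expected: dict[str, dict[str, float]] = {}
    all_reps = design.all_replicate_ids(include_controls=True)

    for sample in design.samples:
        jar_haps = by_jar.get((sample.location, sample.jar), [])
        counts: dict[str, int] = {}
        for h in jar_haps:
            counts[h] = counts.get(h, 0) + 1
        total = sum(counts.values())
        expected[sample.sample_id] = (
            {h: c / total for h, c in sorted(counts.items())} if total else {}
        )
        degraded = sample.sample_type == "ebDNA12"
        depth = params.depth_per_replicate
        if degraded:
            depth = int(round(depth * params.ebdna12_depth_factor))

        for rid in design.replicate_ids(sample.sample_id):
            rng = np.random.default_rng([seed, _tag(rid)])
            events = {"error_reads": 0, "error_bases": 0,
                      "chimera_reads": 0, "jumped_reads": 0}
            truth_events[rid] = events

            haps = list(jar_haps)
            if degraded and params.ebdna12_dropout > 0:
                keep = rng.random(len(haps)) >= params.ebdna12_dropout
                haps = [h for h, k in zip(haps, keep) if k]
            if not haps or depth == 0:
                logger.warning("replicate %s: no colonies after dropout, zero reads", rid)
                continue

            # 1) lognormal amplification weight per colony -> haplotype shares
            weights = rng.lognormal(mean=0.0, sigma=params.bias_sd, size=len(haps))
            hap_ids = sorted(set(haps))
            share = np.zeros(len(hap_ids))
            for w, h in zip(weights, haps):
                share[hap_ids.index(h)] += w
            share /= share.sum()

            # 2) multinomial template sampling
            hap_counts = rng.multinomial(depth, share)

            # 3) chimeras: replace a binomial number of reads by crossovers
            n_chim = rng.binomial(depth, params.chimera_rate)
            chim_counts: dict[str, int] = {}
            if n_chim > 0:
                events["chimera_reads"] = int(n_chim)
                removed = _hypergeometric_removal(rng, hap_counts, n_chim)
                hap_counts = hap_counts - removed
                p_parent = (hap_counts + removed) / depth
                for _ in range(n_chim):
                    i = rng.choice(len(hap_ids), p=p_parent)
                    if len(hap_ids) == 1:
                        j = i
                    else:
                        q = p_parent.copy()
                        q[i] = 0.0
                        q /= q.sum()
                        j = rng.choice(len(hap_ids), p=q)
                    k = int(rng.integers(params.chimera_min_seg,
                                         L - params.chimera_min_seg + 1))
                    seq = hap_seq[hap_ids[i]][:k] + hap_seq[hap_ids[j]][k:]
                    chim_counts[seq] = chim_counts.get(seq, 0) + 1

            templates: list[tuple[np.ndarray, int]] = [
                (hap_code[h], int(c))
                for h, c in zip(hap_ids, hap_counts) if c > 0
            ]
            templates += [(encode(s), c) for s, c in sorted(chim_counts.items())]

            # 4) per-base substitution errors, then count unique sequences
            rep_counts = _apply_errors(rng, templates, params, events)

            # 5) index jumps: reassign a binomial number of finished reads
            _apply_jumps(rng, rep_counts, rid, all_reps, params.index_jump_rate,
                         events, table)

    truth = GroundTruth(
        refs=refs,
        colonies=colonies,
        expected_proportions=expected,
        event_log=truth_events,
    )
    return table, truth


def _hypergeometric_removal(rng, counts: np.ndarray, n: int) -> np.ndarray:
    """Remove ``n`` reads uniformly at random across categories."""
    total = int(counts.sum())
    picks = rng.choice(total, size=n, replace=False)
    edges = np.cumsum(counts)
    cat = np.searchsorted(edges, picks, side="right")
    removed = np.bincount(cat, minlength=len(counts))
    return removed


def _apply_errors(rng, templates, params: SimulationParams, events) -> dict[str, int]:
    """Flip bases independently per read; return unique sequence counts.

    The independent per-base Bernoulli(rate) field over the n x L grid is
    sampled exactly as a binomial total plus a uniform set of distinct
    cells, so only reads that actually carry an error are materialised.
    """
    L = params.amplicon_length
    hot = sorted(set(params.hotspot_positions)) if params.hotspot_error_rate > 0 else []
    cold = np.setdiff1d(np.arange(L), hot) if hot else np.arange(L)
    out: dict[str, int] = {}
    for code, n in templates:
        if n == 0:
            continue
        cells = []
        if params.error_rate > 0 and len(cold):
            cells.append(_flip_cells(rng, n, cold, params.error_rate))
        if hot:
            cells.append(_flip_cells(rng, n, np.asarray(hot), params.hotspot_error_rate))
        rows = np.concatenate([c[0] for c in cells]) if cells else np.empty(0, int)
        cols = np.concatenate([c[1] for c in cells]) if cells else np.empty(0, int)
        if len(rows) == 0:
            seq = bytes(CODE_TO_BASE[code]).decode()
            out[seq] = out.get(seq, 0) + n
            continue
        flip_rows, inverse = np.unique(rows, return_inverse=True)
        n_err = len(flip_rows)
        events["error_reads"] += n_err
        events["error_bases"] += len(rows)
        reads = np.broadcast_to(code, (n_err, L)).copy()
        shift = rng.integers(1, 4, size=len(rows)).astype(np.uint8)
        reads[inverse, cols] = (reads[inverse, cols] + shift) % 4
        n_clean = n - n_err
        if n_clean:
            seq = bytes(CODE_TO_BASE[code]).decode()
            out[seq] = out.get(seq, 0) + n_clean
        for seq, c in _count_rows(reads).items():
            out[seq] = out.get(seq, 0) + c
    return out


def _flip_cells(rng, n_reads: int, columns: np.ndarray, rate: float):
    """Uniform distinct cells of an (n_reads x len(columns)) Bernoulli field."""
    n_cells = n_reads * len(columns)
    m = rng.binomial(n_cells, rate)
    if m == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    flat = rng.choice(n_cells, size=m, replace=False)
    return flat // len(columns), columns[flat % len(columns)]


def _count_rows(mat: np.ndarray) -> dict[str, int]:
    from collections import Counter

    chars = CODE_TO_BASE[mat]
    n, L = chars.shape
    flat = np.ascontiguousarray(chars).view(f"S{L}").ravel().tolist()
    return {k.decode(): v for k, v in Counter(flat).items()}


def _apply_jumps(rng, rep_counts: dict[str, int], rid: str, all_reps: list[str],
                 jump_rate: float, events, table: ReplicateCountTable) -> None:
    total = sum(rep_counts.values())
    n_jump = rng.binomial(total, jump_rate) if (jump_rate > 0 and total) else 0
    if n_jump == 0:
        for seq, c in rep_counts.items():
            table.add(seq, rid, c)
        return
    events["jumped_reads"] = int(n_jump)
    seqs = sorted(rep_counts)
    counts = np.array([rep_counts[s] for s in seqs])
    removed = _hypergeometric_removal(rng, counts, n_jump)
    targets = [r for r in all_reps if r != rid]
    dest_idx = rng.integers(0, len(targets), size=n_jump)
    jumped_seq_idx = np.repeat(np.arange(len(seqs)), removed)
    for s_idx, d_idx in zip(jumped_seq_idx, dest_idx):
        table.add(seqs[s_idx], targets[d_idx], 1)
    kept = counts - removed
    for seq, c in zip(seqs, kept):
        if c > 0:
            table.add(seq, rid, int(c))
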