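"""Haplotype-frequency population genetics.

Two standard indices, computed identically from colony counts (the
individual-barcoding surrogate) and from read counts:

* Nei gene diversity with small-sample correction,
  ``H = n/(n-1) * (1 - sum_a p_a^2)`` — the probability that two gene
  copies drawn without replacement differ.
* Weir & Cockerham's variance-component estimator of pairwise F_ST in its
  haploid (haplotype-frequency) form: for populations i in {1, 2} with
  sizes ``n_i`` and frequencies ``p_i(a)``,

      nbar  = (n_1 + n_2) / 2
      n_c   = 2*nbar - (n_1^2 + n_2^2) / (2*nbar)
      pbar  = sum_i n_i p_i(a) / (2*nbar)
      MSP(a) = sum_i n_i (p_i(a) - pbar(a))^2
      MSG(a) = sum_i n_i p_i(a)(1 - p_i(a)) / sum_i (n_i - 1)
      theta  = sum_a [MSP - MSG] / sum_a [MSP + (n_c - 1) MSG]

Negative estimates are reported as computed (they are a property of the
estimator around theta = 0); optional truncation to zero is available for
display purposes.
"""

from __future__ import annotations

import logging

import numpy as np

from .assignment import AssignmentRecord
from .types import (
    ColonyTable,
    DataError,
    FeatureSet,
    PopulationFrequencies,
    PopulationFrequencyTable,
    ReferenceSet,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

def frequencies_from_reads(
    features: FeatureSet,
    assignments: list[AssignmentRecord],
    species: str,
    group_by: str = "location",
    allele_level: str = "feature",
) -> PopulationFrequencyTable:
    """Read-based allele frequencies for one species, jars pooled.

    With ``allele_level="feature"`` (default) every feature assigned to the
    requested species is one allele, mirroring how read frequencies feed
    population-genetic software in practice; ``"haplotype"`` restricts to
    exact (100%-identity) haplotype calls and pools features by haplotype.
    The sample size of a population is its total of contributing reads.
    """
    if group_by not in ("location", "sample"):
        raise DataError(f"unsupported group_by {group_by!r}")
    if allele_level not in ("feature", "haplotype"):
        raise DataError(f"unsupported allele_level {allele_level!r}")
    design = features.design
    rec_by_id = {r.feature_id: r for r in assignments}
    totals: dict[str, dict[str, int]] = {}
    for f in features:
        rec = rec_by_id.get(f.feature_id)
        if rec is None or rec.best_species != species:
            continue
        if allele_level == "haplotype":
            if rec.haplotype_id is None:
                continue
            allele = rec.haplotype_id
        else:
            allele = rec.haplotype_id or f.feature_id
        for rid, c in f.counts.items():
            sid = design.sample_of(rid)
            if sid is None:
                continue
            s = design.sample(sid)
            pop = s.location if group_by == "location" else sid
            d = totals.setdefault(pop, {})
            d[allele] = d.get(allele, 0) + c
    pops = []
    for pop in sorted(totals):
        reads = totals[pop]
        n = sum(reads.values())
        if n < 2:
            logger.warning("population %s: %d assigned reads, excluded", pop, n)
            continue
        pops.append(
            PopulationFrequencies(pop, "reads", float(n),
                                  {h: c / n for h, c in sorted(reads.items())})
        )
    return PopulationFrequencyTable(pops)


def frequencies_from_colonies(
    colonies: ColonyTable,
    refs: ReferenceSet,
    species: str,
) -> PopulationFrequencyTable:
    """Colony-based haplotype frequencies for one species, jars pooled."""
    wanted = {r.haplotype_id for r in refs if r.species == species}
    pops = []
    for loc, counts in sorted(colonies.counts_by_location().items()):
        sub = {h: c for h, c in counts.items() if h in wanted}
        n = sum(sub.values())
        if n < 2:
            logger.warning("population %s: %d colonies of %s, excluded", loc, n, species)
            continue
        pops.append(
            PopulationFrequencies(loc, "colonies", float(n),
                                  {h: c / n for h, c in sorted(sub.items())})
        )
    return PopulationFrequencyTable(pops)


# ---------------------------------------------------------------------------
# Gene diversity
# ---------------------------------------------------------------------------

def gene_diversity(p, n: float) -> float:
    """Nei gene diversity with the n/(n-1) small-sample correction."""
    if n < 2:
        raise DataError(f"gene diversity needs sample size >= 2, got {n}")
    p = np.asarray(list(p), dtype=float)
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def gene_diversity_table(table: PopulationFrequencyTable) -> dict[str, float]:
    return {
        pop.pop_id: gene_diversity(pop.freqs.values(), pop.n)
        for pop in table
    }


# ---------------------------------------------------------------------------
# Pairwise F_ST
# ---------------------------------------------------------------------------

class PairwiseFstMatrix:
    """Symmetric matrix of pairwise theta estimates with labels."""

    def __init__(self, values: np.ndarray, labels: list[str]):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise DataError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(values - values.T)) > 1e-12:
                raise DataError("matrix is not symmetric")
        self.values = values
        self.labels = list(labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def theta_pair(n1: float, p1: np.ndarray, n2: float, p2: np.ndarray) -> float:
    """Weir-Cockerham haploid theta for one population pair."""
    nbar = (n1 + n2) / 2.0
    nc = 2.0 * nbar - (n1 * n1 + n2 * n2) / (2.0 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (n1 + n2 - 2.0)
    num = float(np.sum(msp - msg))
    den = float(np.sum(msp + (nc - 1.0) * msg))
    if den == 0.0:
        return float("nan")
    return num / den


def pairwise_fst(
    table: PopulationFrequencyTable,
    truncate_negative: bool = False,
) -> PairwiseFstMatrix:
    """All pairwise theta estimates over the table's shared haplotype list.

    Haplotypes absent from a population enter with frequency 0.  A pair of
    populations both fixed for the same haplotype has an undefined theta
    (reported as NaN with a warning).
    """
    if len(table) < 2:
        raise DataError("pairwise F_ST needs at least two populations")
    haps = table.haplotypes
    vecs = {
        pop.pop_id: np.array([pop.freqs.get(h, 0.0) for h in haps])
        for pop in table
    }
    sizes = {pop.pop_id: pop.n for pop in table}
    labels = table.pop_ids
    k = len(labels)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            th = theta_pair(sizes[a], vecs[a], sizes[b], vecs[b])
            if np.isnan(th):
                logger.warning("theta undefined for (%s, %s): shared monomorphism", a, b)
            elif truncate_negative:
                th = max(th, 0.0)
            out[i, j] = out[j, i] = th
    return PairwiseFstMatrix(out, labels)
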