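"""Species- and haplotype-level assignment against the reference database.

Rules:

* alignments must cover at least ``min_subject_coverage`` percent of the
  reference (subject) sequence;
* among qualifying alignments the highest identity wins the species call;
* a tie at best identity between references of *different* species voids
  the species call (``UNASSIGNED``);
* a haplotype is called only for an exact full-length sequence match to a
  single reference; any distinct-reference tie voids the haplotype call.

Alignment is global and end-gap-free (match +1, mismatch -1, gap -2, end
gaps free), appropriate for near-full-length amplicons against a curated
reference set; identity is computed over the aligned columns between the
first and last aligned positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from Bio import Align

from .types import DataError, FeatureSet, ReferenceSet

UNASSIGNED = "UNASSIGNED"


@dataclass
class AssignmentRecord:
    feature_id: str
    best_species: str            # species name or UNASSIGNED
    best_identity: float         # percent; 0.0 when nothing qualifies
    haplotype_id: str | None     # exact-match haplotype, or None
    haplotype_tie: bool = False  # several references matched exactly
    qualifying: list = field(default_factory=list)  # (ref_id, identity, coverage)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def align_identity(query: str, subject: str) -> tuple[float, float]:
    """Percent identity and percent subject coverage of the best alignment.

    Identity is ``100 * matches / alignment columns`` over the region
    between the first and last aligned pair (internal gaps count as
    columns, terminal overhangs do not).  Subject coverage is the percent
    of the subject spanned by that region.
    """
    identity, coverage, _, _ = _align_stats(query, subject)
    return identity, coverage


def _align_stats(query: str, subject: str) -> tuple[float, float, int, int]:
    """(identity%, coverage%, matches, columns); exact fast path for equality."""
    if not query or not subject:
        raise DataError("empty sequence in alignment")
    if query == subject:
        n = len(subject)
        return 100.0, 100.0, n, n
    aln = _ALIGNER.align(subject, query)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_cols += te - ts
        matches += sum(
            1 for a, b in zip(subject[ts:te], query[qs:qe]) if a == b
        )
    columns = aligned_cols
    for k in range(1, len(t_blocks)):
        dt = t_blocks[k][0] - t_blocks[k - 1][1]
        dq = q_blocks[k][0] - q_blocks[k - 1][1]
        columns += dt + dq
    span = int(t_blocks[-1][1] - t_blocks[0][0])
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * span / len(subject)
    return identity, coverage, matches, columns


def assign(
    features: FeatureSet,
    refs: ReferenceSet,
    min_subject_coverage: float = 99.0,
) -> list[AssignmentRecord]:
    """Assign every feature at the species and haplotype levels."""
    if refs is None or len(refs) == 0:
        raise DataError("empty reference set")
    records: list[AssignmentRecord] = []
    for f in features:
        hits = []  # (ref, identity_frac: Fraction, identity%, coverage%)
        for r in refs.records:
            identity, coverage, matches, columns = _align_stats(f.sequence, r.sequence)
            if coverage < min_subject_coverage:
                continue
            frac = Fraction(matches, columns) if columns else Fraction(0)
            hits.append((r, frac, identity, coverage))
        if not hits:
            records.append(AssignmentRecord(f.feature_id, UNASSIGNED, 0.0, None))
            continue
        best_frac = max(h[1] for h in hits)
        best = [h for h in hits if h[1] == best_frac]
        best_species_set = {h[0].species for h in best}
        species = best[0][0].species if len(best_species_set) == 1 else UNASSIGNED
        identity_pct = float(best[0][2])

        exact = [h for h in hits if f.sequence == h[0].sequence]
        haplotype = None
        tie = False
        if exact:
            if len(exact) == 1:
                haplotype = exact[0][0].haplotype_id
            else:
                tie = True  # several identical references: haplotype voided
        records.append(
            AssignmentRecord(
                feature_id=f.feature_id,
                best_species=species,
                best_identity=identity_pct,
                haplotype_id=haplotype,
                haplotype_tie=tie,
                qualifying=sorted(
                    ((h[0].ref_id, float(h[2]), float(h[3])) for h in hits),
                    key=lambda t: (-t[1], t[0]),
                ),
            )
        )
    return records
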