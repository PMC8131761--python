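"""Post-treatment corrections applied after denoising/clustering.

Two rule-based filters:

``index_jump_filter``
    Reads can be misassigned between multiplexed libraries ("index
    jumps").  Unused control index combinations catch such strays; any
    feature that does not account for more than twice the maximum read
    count observed in a control combination is discarded (per sample by
    default).

``replicate_filter``
    Technical-replicate consensus: a feature is kept in a sample only if
    present in at least ``min_replicates`` of that sample's technical
    replicates (presence = at least one read by default).

Both filters are idempotent and account every removed read in their
report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .types import DataError, Feature, FeatureSet

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    filter_name: str
    thresholds: dict = field(default_factory=dict)
    removed_features: list = field(default_factory=list)  # (feature_id, reason)
    reads_removed: int = 0
    reads_kept: int = 0


def _rebuild(features: list[Feature], design) -> FeatureSet:
    kept = [f for f in features if f.total > 0]
    return FeatureSet(kept, design)


# ---------------------------------------------------------------------------
# Index-jump filter
# ---------------------------------------------------------------------------

def index_jump_filter(
    features: FeatureSet,
    mode: str = "per_sample",
    control_max_mode: str = "combo_total",
) -> tuple[FeatureSet, FilterReport]:
    """Discard features not exceeding twice the worst control-combo count.

    ``M`` is the maximum over control combinations of the total read count
    landing in that combination (``control_max_mode="per_feature"`` uses
    the per-feature-per-combo maximum instead); the threshold is
    ``T = 2 * M``.  In ``per_sample`` mode a feature's counts in a sample
    are zeroed when its summed count there is <= T; in ``global`` mode the
    feature is removed when its dataset-wide total is <= T.  Control-column
    reads are dropped from the output (controls are not samples) and
    accounted in the report.
    """
    design = features.design
    controls = design.control_combos
    if not controls:
        raise DataError("index-jump filter needs control index combinations")
    if mode not in ("per_sample", "global"):
        raise DataError(f"unknown mode {mode!r}")

    combo_totals = {c: 0 for c in controls}
    per_feature_max = 0
    for f in features:
        for c in controls:
            got = f.counts.get(c, 0)
            combo_totals[c] += got
            per_feature_max = max(per_feature_max, got)
    M = max(combo_totals.values()) if control_max_mode == "combo_total" else per_feature_max
    T = 2 * M

    report = FilterReport(
        "index_jump",
        thresholds={"control_max": M, "threshold": T, "mode": mode,
                    "control_max_mode": control_max_mode},
    )
    out: list[Feature] = []
    for f in features:
        counts = {r: c for r, c in f.counts.items() if not design.is_control(r)}
        control_reads = f.total - sum(counts.values())
        report.reads_removed += control_reads
        if mode == "global":
            if sum(counts.values()) <= T:
                report.reads_removed += sum(counts.values())
                report.removed_features.append((f.feature_id, f"total<= {T}"))
                continue
        else:
            for s in design.sample_ids:
                reps = design.replicate_ids(s)
                in_sample = sum(counts.get(r, 0) for r in reps)
                if 0 < in_sample <= T:
                    report.reads_removed += in_sample
                    for r in reps:
                        counts.pop(r, None)
            if not counts:
                report.removed_features.append((f.feature_id, f"all samples <= {T}"))
                continue
        out.append(Feature(f.feature_id, f.sequence, counts, list(f.members),
                           f.chimera_flag, f.provenance))
    fs = _rebuild(out, design)
    report.reads_kept = fs.total_reads()
    logger.info("index-jump filter: M=%d T=%d, removed %d reads, kept %d features",
                M, T, report.reads_removed, len(fs))
    return fs, report


# ---------------------------------------------------------------------------
# Replicate-consensus filter
# ---------------------------------------------------------------------------

def replicate_filter(
    features: FeatureSet,
    min_replicates: int = 5,
    presence_min_reads: int = 1,
) -> tuple[FeatureSet, FilterReport]:
    """Keep a feature in a sample only if seen in enough technical replicates."""
    design = features.design
    if min_replicates > design.replicates_per_sample:
        raise DataError(
            f"min_replicates={min_replicates} exceeds replicates_per_sample="
            f"{design.replicates_per_sample}"
        )
    report = FilterReport(
        "replicate",
        thresholds={"min_replicates": min_replicates,
                    "presence_min_reads": presence_min_reads},
    )
    out: list[Feature] = []
    for f in features:
        counts = dict(f.counts)
        for s in design.sample_ids:
            reps = design.replicate_ids(s)
            present = sum(1 for r in reps if counts.get(r, 0) >= presence_min_reads)
            if present < min_replicates:
                dropped = sum(counts.pop(r, 0) for r in reps)
                report.reads_removed += dropped
        if not any(counts.values()):
            report.removed_features.append(
                (f.feature_id, f"present in < {min_replicates} replicates everywhere")
            )
            continue
        out.append(Feature(f.feature_id, f.sequence, counts, list(f.members),
                           f.chimera_flag, f.provenance))
    fs = _rebuild(out, design)
    report.reads_kept = fs.total_reads()
    logger.info("replicate filter: removed %d reads, kept %d features",
                report.reads_removed, len(fs))
    return fs, report
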