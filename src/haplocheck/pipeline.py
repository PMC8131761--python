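"""End-to-end orchestration: simulate -> process -> assign -> popgen -> evaluate.

``run_arm`` executes one processing arm (denoiser / greedy / linkage, with
or without chimera removal) on a simulated dataset and scores it against
the ground truth; ``compare_arms`` runs the six-arm comparison harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluate as eval_mod
from . import popgen
from .assignment import assign as assign_features
from .stages import (
    cluster_greedy,
    cluster_linkage,
    denoise as denoise_reads,
    dereplicate,
    remove_chimeras,
)
from .filters import FilterReport, index_jump_filter, replicate_filter
from .simulate import (
    SPECIES_A,
    GroundTruth,
    SimulationParams,
    mask_failed_colonies,
    simulate_assemblages,
    simulate_reads,
    simulate_references,
)
from .types import (
    ColonyTable,
    FeatureSet,
    ReferenceSet,
    ReplicateCountTable,
    RunConfig,
    SampleDesign,
    build_design,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulatedDataset:
    params: SimulationParams
    refs: ReferenceSet
    colonies_true: ColonyTable
    colonies_observed: ColonyTable
    design: SampleDesign
    table: ReplicateCountTable
    truth: GroundTruth


def simulate_dataset(
    params: SimulationParams,
    seed: int | None = None,
    sample_type: str = "ebDNA3",
) -> SimulatedDataset:
    """Simulate references, assemblages and reads for one sample type."""
    if seed is None:
        seed = params.seed
    refs = simulate_references(params, seed)
    colonies = simulate_assemblages(params, refs, seed)
    observed = mask_failed_colonies(colonies, params.colony_fail_prob, seed)
    design = build_design(params.locations, sample_type=sample_type)
    table, truth = simulate_reads(params, refs, colonies, design, seed)
    return SimulatedDataset(params, refs, colonies, observed, design, table, truth)


@dataclass
class ProcessResult:
    features: FeatureSet
    raw_feature_count: int
    stage_feature_count: int
    chimera_hits: list = field(default_factory=list)
    filter_reports: list[FilterReport] = field(default_factory=list)
    counts_trail: dict[str, int] = field(default_factory=dict)


def process_reads(table: ReplicateCountTable, config: RunConfig) -> ProcessResult:
    """Dereplicate, run the configured stage, then the post filters."""
    raw = dereplicate(table)
    logger.info("dereplicated: %d unique sequences", len(raw))
    if config.stage == "denoiser":
        feats = denoise_reads(raw, config.denoise_alpha, config.denoise_d_max)
    elif config.stage == "greedy":
        feats = cluster_greedy(raw, config.identity_threshold)
    elif config.stage == "linkage":
        feats = cluster_linkage(raw, config.linkage_d)
    else:
        raise ValueError(f"unknown stage {config.stage!r}")
    logger.info("stage %s: %d features", config.stage, len(feats))
    stage_count = len(feats)

    hits: list = []
    if config.chimera_removal:
        feats, hits = remove_chimeras(
            feats, config.chimera_skew, config.chimera_max_mismatch,
            config.chimera_min_seg,
        )
        logger.info("chimera removal: %d flagged", len(hits))

    trail = {
        "dereplicated": len(raw),
        "stage": stage_count,
        "after_chimera": len(feats),
    }
    reports: list[FilterReport] = []
    for name in config.filter_order:
        if name == "index_jump":
            feats, rep = index_jump_filter(
                feats, config.index_jump_mode, config.control_max_mode
            )
        elif name == "replicate":
            feats, rep = replicate_filter(
                feats, config.min_replicates, config.presence_min_reads
            )
        else:
            raise ValueError(f"unknown filter {name!r}")
        reports.append(rep)
        trail[f"after_{name}"] = len(feats)
    return ProcessResult(feats, len(raw), stage_count, hits, reports, trail)


@dataclass
class ArmResult:
    config: RunConfig
    features: FeatureSet
    process: ProcessResult
    assignments: list
    accounting: eval_mod.HaplotypeAccounting
    proportion_r: float
    hs_reads: dict[str, float]
    hs_colonies: dict[str, float]
    hs_correlation: float
    fst_reads: popgen.PairwiseFstMatrix | None
    fst_colonies: popgen.PairwiseFstMatrix | None
    mantel_r: float
    mantel_p: float


def run_arm(ds: SimulatedDataset, config: RunConfig) -> ArmResult:
    """One processing arm, scored against the dataset's ground truth.

    Population-genetic indices are computed for the focal (first) species
    only; read-based and colony-based tables are restricted to locations
    present in both so the correlation and Mantel comparisons are paired.
    """
    proc = process_reads(ds.table, config)
    feats = proc.features
    assignments = assign_features(feats, ds.refs, config.min_subject_coverage)
    accounting = eval_mod.haplotype_accounting(feats, ds.colonies_observed, ds.refs)

    reads_jar = eval_mod.reads_by_jar_from_features(feats, assignments)
    col_jar = eval_mod.colonies_by_jar_from_table(ds.colonies_observed)
    _, prop_r = eval_mod.proportion_correlation(reads_jar, col_jar)

    freq_reads = popgen.frequencies_from_reads(
        feats, assignments, SPECIES_A, allele_level=config.popgen_allele_level
    )
    freq_col = popgen.frequencies_from_colonies(
        ds.colonies_observed, ds.refs, SPECIES_A
    )
    hs_reads = popgen.gene_diversity_table(freq_reads)
    hs_col = popgen.gene_diversity_table(freq_col)
    shared = sorted(set(hs_reads) & set(hs_col))
    if len(shared) >= 3 and np.ptp([hs_col[p] for p in shared]) > 0:
        from scipy import stats as _st

        hs_r = float(
            _st.pearsonr(
                [hs_reads[p] for p in shared], [hs_col[p] for p in shared]
            ).statistic
        )
    else:
        hs_r = float("nan")

    fst_r = fst_c = None
    mantel_r = mantel_p = float("nan")
    if len(shared) >= 3:
        sub_reads = popgen.PopulationFrequencyTable(
            [p for p in freq_reads if p.pop_id in shared]
        )
        sub_col = popgen.PopulationFrequencyTable(
            [p for p in freq_col if p.pop_id in shared]
        )
        fst_r = popgen.pairwise_fst(sub_reads, config.truncate_negative_fst)
        fst_c = popgen.pairwise_fst(sub_col, config.truncate_negative_fst)
        if not (np.isnan(fst_r.values).any() or np.isnan(fst_c.values).any()):
            try:
                mantel_r, mantel_p = eval_mod.mantel_test(
                    fst_r.values, fst_c.values,
                    n_perm=config.mantel_permutations, seed=config.seed,
                    method="permutation",
                )
            except Exception as exc:  # constant triangles on tiny runs
                logger.warning("Mantel test skipped: %s", exc)

    return ArmResult(
        config=config,
        features=feats,
        process=proc,
        assignments=assignments,
        accounting=accounting,
        proportion_r=prop_r,
        hs_reads=hs_reads,
        hs_colonies=hs_col,
        hs_correlation=hs_r,
        fst_reads=fst_r,
        fst_colonies=fst_c,
        mantel_r=mantel_r,
        mantel_p=mantel_p,
    )


ARM_NAMES = [
    ("denoiser", True), ("denoiser", False),
    ("greedy", True), ("greedy", False),
    ("linkage", True), ("linkage", False),
]


def compare_arms(
    ds: SimulatedDataset, base_config: RunConfig | None = None
) -> dict[str, ArmResult]:
    """Run all six stage x chimera-removal arms on one dataset."""
    base = base_config or RunConfig()
    out: dict[str, ArmResult] = {}
    for stage, chim in ARM_NAMES:
        cfg = RunConfig(**{**base.__dict__, "stage": stage, "chimera_removal": chim})
        name = f"{stage}{'+chim' if chim else ''}"
        logger.info("running arm %s", name)
        out[name] = run_arm(ds, cfg)
    return out
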