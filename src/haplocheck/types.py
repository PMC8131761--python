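"""Core domain types for the haplotype-metabarcoding pipeline.

The pipeline moves data through a small set of containers:

``ReferenceSet``
    Labelled haplotype sequences (species + haplotype id) used both as the
    assignment database and as simulation templates.
``ColonyTable``
    Ground-truth individuals (the individual-barcoding surrogate): one row
    per colony with its location, jar and haplotype.
``SampleDesign``
    The library layout — samples, their technical replicates (extraction x
    tagged-PCR), and the unused control index combinations that catch
    index jumps.
``ReplicateCountTable``
    Unique-sequence x technical-replicate read counts, including control
    columns.
``FeatureSet``
    Post-processing ASVs/OTUs ("features") with per-replicate counts and
    provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

VALID_BASES = frozenset("ACGT")
MISSING = "NA"

JAR_NAMES = ("A", "B")
SAMPLE_TYPES = ("ebDNA3", "ebDNA6", "ebDNA12", "bulkDNA")


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    species: str
    haplotype_id: str
    sequence: str


class ReferenceSet:
    """Validated collection of labelled reference haplotype sequences."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        records = list(records)
        if not records:
            raise DataError("reference set contains no records")
        seen: set[str] = set()
        for rec in records:
            if rec.ref_id in seen:
                raise DataError(f"duplicate reference id: {rec.ref_id!r}")
            seen.add(rec.ref_id)
            if not rec.sequence:
                raise DataError(f"empty sequence for reference {rec.ref_id!r}")
            bad = set(rec.sequence) - VALID_BASES
            if bad:
                raise DataError(
                    f"reference {rec.ref_id!r} contains non-ACGT characters: "
                    f"{sorted(bad)}"
                )
        self.records = records
        self._by_id = {r.ref_id: r for r in records}
        self._by_hap = {r.haplotype_id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceSet) and self.records == other.records

    def get(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    def by_haplotype(self, haplotype_id: str) -> ReferenceRecord:
        return self._by_hap[haplotype_id]

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return out

    @property
    def haplotype_ids(self) -> list[str]:
        return [r.haplotype_id for r in self.records]

    def sequences_by_haplotype(self) -> dict[str, str]:
        return {r.haplotype_id: r.sequence for r in self.records}


# ---------------------------------------------------------------------------
# Ground-truth colonies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColonyRow:
    location: str
    jar: str
    colony_id: str
    haplotype_id: str  # MISSING for a failed individual


class ColonyTable:
    """Ground-truth table of individually barcoded colonies."""

    def __init__(self, rows: Iterable[ColonyRow], refs: ReferenceSet | None = None):
        rows = list(rows)
        seen: set[tuple[str, str, str]] = set()
        for row in rows:
            if row.jar not in JAR_NAMES:
                raise DataError(f"jar must be one of {JAR_NAMES}, got {row.jar!r}")
            key = (row.location, row.jar, row.colony_id)
            if key in seen:
                raise DataError(f"duplicate colony key: {key}")
            seen.add(key)
            if refs is not None and row.haplotype_id != MISSING:
                if row.haplotype_id not in refs.haplotype_ids:
                    raise DataError(
                        f"colony {key} carries unknown haplotype "
                        f"{row.haplotype_id!r}"
                    )
        self.rows = rows

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, ColonyTable) and self.rows == other.rows

    @property
    def locations(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row.location not in out:
                out.append(row.location)
        return out

    def counts_by_jar(self) -> dict[tuple[str, str], dict[str, int]]:
        """Haplotype colony counts per (location, jar); failed colonies skipped."""
        out: dict[tuple[str, str], dict[str, int]] = {}
        for row in self.rows:
            if row.haplotype_id == MISSING:
                continue
            jar = out.setdefault((row.location, row.jar), {})
            jar[row.haplotype_id] = jar.get(row.haplotype_id, 0) + 1
        return out

    def counts_by_location(self) -> dict[str, dict[str, int]]:
        """Haplotype colony counts per location (jars pooled)."""
        out: dict[str, dict[str, int]] = {}
        for row in self.rows:
            if row.haplotype_id == MISSING:
                continue
            loc = out.setdefault(row.location, {})
            loc[row.haplotype_id] = loc.get(row.haplotype_id, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Sample / replicate layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    location: str
    jar: str
    sample_type: str = "ebDNA3"


class SampleDesign:
    """Sample sheet: samples, technical replicates and control combinations.

    Each sample carries ``replicates_per_sample`` technical replicates
    (by default 9 = 3 extraction replicates x 3 tagged-PCR replicates).
    ``control_combos`` are index combinations never used in a PCR; reads
    can only arrive there by index jumping.
    """

    def __init__(
        self,
        samples: Iterable[Sample],
        replicates_per_sample: int = 9,
        control_combos: Iterable[str] | None = None,
    ):
        self.samples = list(samples)
        if replicates_per_sample < 1:
            raise DataError("replicates_per_sample must be >= 1")
        self.replicates_per_sample = replicates_per_sample
        if control_combos is None:
            control_combos = [f"ctrl{i:02d}" for i in range(1, 13)]
        self.control_combos = list(control_combos)

        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample ids in design")
        if set(ids) & set(self.control_combos):
            raise DataError("control ids must be disjoint from sample ids")
        for s in self.samples:
            if s.sample_type not in SAMPLE_TYPES:
                raise DataError(
                    f"unknown sample_type {s.sample_type!r}; "
                    f"expected one of {SAMPLE_TYPES}"
                )

        self._rep_to_sample: dict[str, str] = {}
        self._sample_reps: dict[str, list[str]] = {}
        for s in self.samples:
            reps = [
                f"{s.sample_id}:r{k}" for k in range(1, replicates_per_sample + 1)
            ]
            self._sample_reps[s.sample_id] = reps
            for rid in reps:
                self._rep_to_sample[rid] = s.sample_id

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SampleDesign)
            and self.samples == other.samples
            and self.replicates_per_sample == other.replicates_per_sample
            and self.control_combos == other.control_combos
        )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def replicate_ids(self, sample_id: str) -> list[str]:
        return list(self._sample_reps[sample_id])

    def all_replicate_ids(self, include_controls: bool = True) -> list[str]:
        out = [r for s in self.samples for r in self._sample_reps[s.sample_id]]
        if include_controls:
            out += self.control_combos
        return out

    def sample_of(self, replicate_id: str) -> str | None:
        """Sample owning a replicate; None for control combinations."""
        if replicate_id in self.control_combos:
            return None
        return self._rep_to_sample[replicate_id]

    def is_control(self, replicate_id: str) -> bool:
        return replicate_id in self.control_combos


def build_design(
    locations: Iterable[str],
    sample_type: str = "ebDNA3",
    jars: Iterable[str] = JAR_NAMES,
    replicates_per_sample: int = 9,
    n_controls: int = 12,
) -> SampleDesign:
    """One sample per (location, jar) of the given type, plus controls."""
    samples = [
        Sample(f"{loc}-{jar}-{sample_type}", loc, jar, sample_type)
        for loc in locations
        for jar in jars
    ]
    controls = [f"ctrl{i:02d}" for i in range(1, n_controls + 1)]
    return SampleDesign(samples, replicates_per_sample, controls)


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

class ReplicateCountTable:
    """Unique-sequence x replicate read counts, including control columns.

    Stored sparsely as ``{sequence: {replicate_id: count}}``; replicate ids
    must be declared in the design (sample replicates or control combos).
    """

    def __init__(
        self,
        design: SampleDesign,
        entries: Mapping[str, Mapping[str, int]] | None = None,
    ):
        self.design = design
        self._valid_reps = set(design.all_replicate_ids(include_controls=True))
        self.entries: dict[str, dict[str, int]] = {}
        if entries:
            for seq, percol in entries.items():
                for rid, count in percol.items():
                    self.add(seq, rid, count)

    def add(self, sequence: str, replicate_id: str, count: int) -> None:
        if replicate_id not in self._valid_reps:
            raise DataError(f"unknown replicate id: {replicate_id!r}")
        if count < 0:
            raise DataError(
                f"negative count for ({sequence[:20]!r}..., {replicate_id!r})"
            )
        if count == 0:
            return
        row = self.entries.setdefault(sequence, {})
        row[replicate_id] = row.get(replicate_id, 0) + count

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReplicateCountTable)
            and self.design == other.design
            and self.entries == other.entries
        )

    @property
    def sequences(self) -> list[str]:
        return list(self.entries)

    def count(self, sequence: str, replicate_id: str) -> int:
        return self.entries.get(sequence, {}).get(replicate_id, 0)

    def total_reads(self) -> int:
        return sum(c for row in self.entries.values() for c in row.values())

    def replicate_totals(self) -> dict[str, int]:
        out = {rid: 0 for rid in self.design.all_replicate_ids()}
        for row in self.entries.values():
            for rid, c in row.items():
                out[rid] += c
        return out


# ---------------------------------------------------------------------------
# Features (ASVs / OTUs)
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    feature_id: str
    sequence: str          # representative: most abundant member, ties lexicographic
    counts: dict[str, int]  # replicate_id -> reads
    members: list[str] = field(default_factory=list)
    chimera_flag: bool = False
    provenance: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count_in_sample(self, design: SampleDesign, sample_id: str) -> int:
        return sum(self.counts.get(r, 0) for r in design.replicate_ids(sample_id))


class FeatureSet:
    """Processed features with per-replicate counts and provenance."""

    def __init__(self, features: Iterable[Feature], design: SampleDesign):
        self.features = list(features)
        self.design = design
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate feature ids")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureSet)
            and self.design == other.design
            and self.features == other.features
        )

    def total_reads(self) -> int:
        return sum(f.total for f in self.features)

    def by_sequence(self) -> dict[str, Feature]:
        return {f.sequence: f for f in self.features}


# ---------------------------------------------------------------------------
# Population frequencies
# ---------------------------------------------------------------------------

@dataclass
class PopulationFrequencies:
    pop_id: str
    source: str            # "reads" | "colonies"
    n: float               # sample size (reads or colonies)
    freqs: dict[str, float]  # haplotype_id -> frequency

    def __post_init__(self):
        if self.source not in ("reads", "colonies"):
            raise DataError(f"source must be 'reads' or 'colonies', got {self.source!r}")
        if self.n < 2:
            raise DataError(f"population {self.pop_id!r}: sample size must be >= 2")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(
                f"population {self.pop_id!r}: frequencies sum to {total}, not 1"
            )


class PopulationFrequencyTable:
    """Per-population haplotype frequencies over a shared haplotype list."""

    def __init__(self, populations: Iterable[PopulationFrequencies]):
        self.populations = list(populations)
        ids = [p.pop_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate population ids")

    def __len__(self) -> int:
        return len(self.populations)

    def __iter__(self):
        return iter(self.populations)

    @property
    def pop_ids(self) -> list[str]:
        return [p.pop_id for p in self.populations]

    @property
    def haplotypes(self) -> list[str]:
        """Shared haplotype list (union, in first-seen order)."""
        out: list[str] = []
        for p in self.populations:
            for h in p.freqs:
                if h not in out:
                    out.append(h)
        return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable of the pipeline, serialisable to/from JSON."""

    # stage choices
    stage: str = "denoiser"          # denoiser | greedy | linkage
    chimera_removal: bool = True
    # denoiser
    denoise_alpha: float = 2.0
    denoise_d_max: int = 10
    # greedy clustering
    identity_threshold: float = 0.99
    # linkage clustering
    linkage_d: int = 1
    # chimera removal
    chimera_skew: float = 2.0
    chimera_max_mismatch: int = 0
    chimera_min_seg: int = 10
    # post filters
    index_jump_mode: str = "per_sample"   # per_sample | global
    control_max_mode: str = "combo_total"  # combo_total | per_feature
    min_replicates: int = 5
    presence_min_reads: int = 1
    filter_order: tuple[str, str] = ("index_jump", "replicate")
    # assignment
    min_subject_coverage: float = 99.0
    # popgen
    truncate_negative_fst: bool = False
    popgen_allele_level: str = "feature"   # feature | haplotype
    # evaluation
    mantel_permutations: int = 999
    p_adjust: str = "holm"                # holm | bh
    # bookkeeping
    seed: int = 0
    output_dir: str = "out"

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["filter_order"] = list(self.filter_order)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "filter_order" in d:
            d["filter_order"] = tuple(d["filter_order"])
        return cls(**d)
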