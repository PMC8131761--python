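"""Readers and writers for the package's on-disk formats.

Conventions:

* Reference FASTA headers follow ``>refID|species|haplotypeID``.
* TSV files are tab-separated with a header row, UTF-8.
* All writers emit deterministic output for a fixed input (stable sort
  orders: features by id, sequences/rows lexicographic where not otherwise
  meaningful).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .types import (
    MISSING,
    ColonyRow,
    ColonyTable,
    DataError,
    Feature,
    FeatureSet,
    ReferenceRecord,
    ReferenceSet,
    ReplicateCountTable,
    Sample,
    SampleDesign,
)


# ---------------------------------------------------------------------------
# Reference FASTA
# ---------------------------------------------------------------------------

def load_reference_fasta(path: str | Path) -> ReferenceSet:
    """Load ``>refID|species|haplotypeID`` FASTA into a validated ReferenceSet.

    Sequences are uppercased; ambiguity codes are rejected with an error
    naming the offending record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise DataError(
                f"malformed header {rec.id!r}: expected 'refID|species|haplotypeID'"
            )
        seq = str(rec.seq).upper()
        records.append(ReferenceRecord(parts[0], parts[1], parts[2], seq))
    if not records:
        raise DataError(f"no records found in {path}")
    return ReferenceSet(records)


def write_reference_fasta(refs: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.ref_id}|{r.species}|{r.haplotype_id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Colony table
# ---------------------------------------------------------------------------

def load_colony_table(path: str | Path, refs: ReferenceSet | None = None) -> ColonyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["location", "jar", "colony_id", "haplotype_id"]
    if list(df.columns) != required:
        raise DataError(f"colony table columns must be {required}, got {list(df.columns)}")
    rows = [
        ColonyRow(r.location, r.jar, r.colony_id, r.haplotype_id)
        for r in df.itertuples()
    ]
    return ColonyTable(rows, refs=refs)


def write_colony_table(table: ColonyTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.location, r.jar, r.colony_id, r.haplotype_id) for r in table],
        columns=["location", "jar", "colony_id", "haplotype_id"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

def load_design(path: str | Path) -> SampleDesign:
    with open(path) as fh:
        d = json.load(fh)
    samples = [Sample(**s) for s in d["samples"]]
    return SampleDesign(samples, d["replicates_per_sample"], d["control_combos"])


def write_design(design: SampleDesign, path: str | Path) -> None:
    d = {
        "samples": [
            {
                "sample_id": s.sample_id,
                "location": s.location,
                "jar": s.jar,
                "sample_type": s.sample_type,
            }
            for s in design.samples
        ],
        "replicates_per_sample": design.replicates_per_sample,
        "control_combos": design.control_combos,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, design: SampleDesign) -> ReplicateCountTable:
    """Load a ReplicateCountTable from a TSV file or a directory of FASTQ.

    TSV: columns ``sequence, replicate, count``, validated against the design.
    FASTQ directory: one ``<replicate_id>.fastq`` per replicate; reads are
    dereplicated exactly (byte-identical sequences pooled); quality strings
    are ignored.
    """
    path = Path(path)
    table = ReplicateCountTable(design)
    if path.is_dir():
        for fq in sorted(path.glob("*.fastq")):
            rid = fq.stem
            for rec in SeqIO.parse(str(fq), "fastq"):
                table.add(str(rec.seq).upper(), rid, 1)
        return table
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "replicate": str, "count": int})
    required = ["sequence", "replicate", "count"]
    if list(df.columns) != required:
        raise DataError(f"counts TSV columns must be {required}, got {list(df.columns)}")
    for r in df.itertuples():
        table.add(r.sequence, r.replicate, r.count)
    return table


def write_counts(table: ReplicateCountTable, path: str | Path) -> None:
    rows = [
        (seq, rid, c)
        for seq in sorted(table.entries)
        for rid, c in sorted(table.entries[seq].items())
    ]
    pd.DataFrame(rows, columns=["sequence", "replicate", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def write_features(fs: FeatureSet, fasta_path: str | Path, counts_path: str | Path) -> None:
    """FeatureSet as representative FASTA plus a long-format counts TSV."""
    with open(fasta_path, "w") as fh:
        for f in fs:
            flag = " chimera" if f.chimera_flag else ""
            fh.write(f">{f.feature_id} total={f.total}{flag}\n{f.sequence}\n")
    rows = [
        (f.feature_id, f.sequence, rid, c, int(f.chimera_flag), f.provenance,
         ";".join(f.members))
        for f in fs.features
        for rid, c in sorted(f.counts.items())
    ]
    pd.DataFrame(
        rows,
        columns=["feature_id", "sequence", "replicate", "count",
                 "chimera_flag", "provenance", "members"],
    ).to_csv(counts_path, sep="\t", index=False)


def load_features(counts_path: str | Path, design: SampleDesign) -> FeatureSet:
    df = pd.read_csv(counts_path, sep="\t", dtype=str, keep_default_na=False)
    feats: dict[str, Feature] = {}
    for r in df.itertuples():
        f = feats.get(r.feature_id)
        if f is None:
            members = r.members.split(";") if r.members else []
            f = Feature(
                r.feature_id, r.sequence, {}, members,
                bool(int(r.chimera_flag)), r.provenance,
            )
            feats[r.feature_id] = f
        f.counts[r.replicate] = f.counts.get(r.replicate, 0) + int(r.count)
    return FeatureSet(list(feats.values()), design)


# ---------------------------------------------------------------------------
# Matrices, trees, networks
# ---------------------------------------------------------------------------

def write_matrix(matrix, labels: list[str], path: str | Path) -> None:
    """Square matrix as a labelled TSV."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="id"
    )


def read_matrix(path: str | Path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.columns)


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")


def write_edge_list(edges, path: str | Path) -> None:
    """Network edges as TSV: node1, node2, weight, kind (mst|alternative)."""
    pd.DataFrame(edges, columns=["node1", "node2", "weight", "kind"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def write_outputs(obj, path: str | Path) -> list[Path]:
    """Type-dispatched writer; returns the files written.

    FeatureSets become a FASTA plus counts TSV next to each other;
    ReferenceSets a FASTA; ColonyTables and ReplicateCountTables a TSV;
    designs JSON.  ``path`` is the primary output file; companions share
    its stem.
    """
    path = Path(path)
    if isinstance(obj, FeatureSet):
        counts = path.with_suffix(".counts.tsv")
        write_features(obj, path, counts)
        return [path, counts]
    if isinstance(obj, ReferenceSet):
        write_reference_fasta(obj, path)
    elif isinstance(obj, ColonyTable):
        write_colony_table(obj, path)
    elif isinstance(obj, ReplicateCountTable):
        write_counts(obj, path)
    elif isinstance(obj, SampleDesign):
        write_design(obj, path)
    else:
        raise DataError(f"no writer for {type(obj).__name__}")
    return [path]
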