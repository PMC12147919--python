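"""File formats: FASTA/FASTQ records and the pipeline's tabular outputs.

All tables are plain TSV/CSV through pandas; sequence records go through
Biopython (FASTA) and pysam (FASTQ, including gzip).  Coordinates are
1-based in every file written and converted back internally.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .copy_number import PartitionCount
from .growth_kinetics import GrowthCurve
from .population import ClonePopulation, PhenotypeMap
from .reference import MutantGenotype, OriReference
from .simulate.reads import ReadBatch
from .variant_counts import BASE_COLUMNS, PositionCounts


# -- sequences --------------------------------------------------------------

def write_fasta(ori: OriReference, path) -> None:
    record = SeqRecord(
        Seq(ori.amplicon),
        id=ori.name,
        description=(
            f"orf_start={ori.orf_start} orf_end={ori.orf_end} "
            f"wt_copy_number={ori.wt_copy_number}"
        ),
    )
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path, wt_copy_number: float | None = None) -> OriReference:
    """Load a single-record FASTA as an :class:`OriReference`.

    ORF coordinates and copy number are recovered from the description when
    present (as written by :func:`write_fasta`); otherwise the whole record
    is treated as the ORF if its length is divisible by 3, and the copy
    number defaults to 1.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly 1 FASTA record, found {len(records)}")
    record = records[0]
    seq = str(record.seq).upper()
    fields = dict(
        part.split("=", 1)
        for part in record.description.split()
        if "=" in part
    )
    orf_start = int(fields.get("orf_start", 0))
    orf_end = int(fields.get("orf_end", len(seq)))
    if wt_copy_number is None:
        wt_copy_number = float(fields.get("wt_copy_number", 1.0))
    return OriReference(
        name=record.id,
        amplicon=seq,
        orf_start=orf_start,
        orf_end=orf_end,
        wt_copy_number=wt_copy_number,
    )


def read_fastq(path) -> ReadBatch:
    """Load a (possibly gzipped) FASTQ into a :class:`ReadBatch`.

    Sequence/quality length mismatches are rejected with the record index.
    """
    import pysam

    seqs, quals, names = [], [], []
    with pysam.FastxFile(str(path)) as handle:
        iterator = iter(handle)
        i = 0
        while True:
            try:
                entry = next(iterator)
            except StopIteration:
                break
            except ValueError as err:  # pysam flags malformed records itself
                raise ValueError(f"record {i}: {err}") from err
            if entry.quality is None:
                raise ValueError(f"record {i} ({entry.name}): missing qualities")
            if len(entry.sequence) != len(entry.quality):
                raise ValueError(
                    f"record {i} ({entry.name}): sequence length "
                    f"{len(entry.sequence)} != quality length {len(entry.quality)}"
                )
            seqs.append(entry.sequence.upper())
            quals.append(entry.quality)
            names.append(entry.name)
            i += 1
    return ReadBatch.from_strings(seqs, quals, names)


# -- pipeline tables --------------------------------------------------------

def write_counts_tsv(counts: PositionCounts, ori: OriReference, path) -> None:
    frame = counts.to_frame(ori)
    with open(path, "w") as handle:
        handle.write(f"# sample_id={counts.sample_id}\n")
        handle.write(f"# ori={counts.ori_name}\n")
        handle.write(
            f"# reads_mapped={counts.n_reads_mapped} "
            f"reads_unmapped={counts.n_reads_unmapped}\n"
        )
        frame.to_csv(handle, sep="\t", index=False)


def read_counts_tsv(path) -> PositionCounts:
    meta = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            for part in line[1:].split():
                if "=" in part:
                    key, value = part.split("=", 1)
                    meta[key] = value
    frame = pd.read_csv(path, sep="\t", comment="#")
    counts = frame[list(BASE_COLUMNS)].to_numpy(dtype=np.int64)
    return PositionCounts(
        sample_id=meta.get("sample_id", Path(path).stem),
        ori_name=meta.get("ori", "unknown"),
        counts=counts,
        n_reads_mapped=int(meta.get("reads_mapped", 0)),
        n_reads_unmapped=int(meta.get("reads_unmapped", 0)),
    )


def write_enrichment_tsv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out.insert(0, "pos_1based", out.pop("position") + 1)
    out.to_csv(path, sep="\t", index=False)


def write_truth_tsv(
    population: ClonePopulation, phenotypes: PhenotypeMap, path
) -> None:
    """Genotype truth table: clone id, substitutions, copy number, count."""
    rows = []
    for i, (genotype, count) in enumerate(population.clones.items()):
        rows.append(
            {
                "clone_id": f"clone_{i}",
                "substitutions": str(genotype),
                "copy_number": phenotypes.copy_number[genotype],
                "count": count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path, ori: OriReference):
    frame = pd.read_csv(path, sep="\t")
    clones = {}
    copies = {}
    for _, row in frame.iterrows():
        genotype = MutantGenotype.parse(row["substitutions"])
        clones[genotype] = int(row["count"])
        copies[genotype] = float(row["copy_number"])
    population = ClonePopulation(ori=ori, clones=clones)
    phenotypes = PhenotypeMap(ori=ori, copy_number=copies)
    return population, phenotypes


def write_checkerboard_tsv(grid, od_wt, od_mut, path) -> None:
    rows = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            condition = grid.condition(r, c)
            rows.append(
                {
                    "well": condition.well,
                    "gentamicin_mg_per_l": condition.gentamicin,
                    "salicylic_acid_molar": condition.salicylic_acid,
                    "od_wt": od_wt[r, c],
                    "od_mut": od_mut[r, c],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dpcr_csv(counts, path) -> None:
    pd.DataFrame(
        [
            {
                "sample": pc.sample_id,
                "channel": pc.channel,
                "n_partitions": pc.n_total,
                "n_positive": pc.n_positive,
            }
            for pc in counts
        ]
    ).to_csv(path, index=False)


def read_dpcr_csv(path) -> list:
    frame = pd.read_csv(path)
    return [
        PartitionCount(
            sample_id=str(row["sample"]),
            channel=str(row["channel"]),
            n_total=int(row["n_partitions"]),
            n_positive=int(row["n_positive"]),
        )
        for _, row in frame.iterrows()
    ]


def write_growth_tsv(curves, path) -> None:
    frames = []
    for curve in curves:
        frames.append(
            pd.DataFrame(
                {"sample": curve.sample_id, "time_h": curve.times, "od": curve.od}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_growth_tsv(path) -> list:
    frame = pd.read_csv(path, sep="\t")
    curves = []
    for sample, group in frame.groupby("sample", sort=False):
        group = group.sort_values("time_h")
        curves.append(
            GrowthCurve(
                sample_id=str(sample),
                times=group["time_h"].to_numpy(),
                od=group["od"].to_numpy(),
            )
        )
    return curves
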