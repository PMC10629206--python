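"""Readers and writers for the plain-text formats the pipeline exchanges.

Variants travel as a minimal VCF (CHROM, POS, REF, ALT plus a per-sample
AD field) or as TSV; coverage as BED-like TSV; log-ratio tracks as
BEDGRAPH; segments and TADs and genes as BED; junctions as BEDPE with
extra support/depth columns; expression and timelines as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cna import CoverageTrack, LogRatioTrack
from .genome import ReferenceGenome
from .sv import SVJunction
from .tad import GeneAnnotation, TADMap
from .variants import CohortVariantTable


# ---------------------------------------------------------------- variants

def write_vcf(table: CohortVariantTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Ref and alt read depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for (chrom, pos, ref, alt), row in table.frame.iterrows():
            cells = [
                f"{int(row[f'{s}.ref'])},{int(row[f'{s}.alt'])}" for s in table.samples
            ]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tAD\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> CohortVariantTable:
    samples, records = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, ref, alt = fields[0], int(fields[1]), fields[3], fields[4]
            fmt = fields[8].split(":")
            ad_idx = fmt.index("AD")
            counts = {}
            for s, cell in zip(samples, fields[9:]):
                ad = cell.split(":")[ad_idx]
                r, a = (int(x) for x in ad.split(",")[:2])
                counts[s] = (a, r)
            records.append((chrom, pos, ref, alt, counts))
    return CohortVariantTable.from_records(records, samples)


def write_variant_tsv(table: CohortVariantTable, path, provenance=None) -> None:
    frame = table.frame.reset_index()
    if provenance is not None:
        frame["provenance"] = provenance.to_numpy()
    frame.to_csv(path, sep="\t", index=False)


def read_germline_db(path) -> set:
    frame = pd.read_csv(path, sep="\t")
    return {
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
        for _, r in frame.iterrows()
    }


def write_germline_db(db: set, path) -> None:
    frame = pd.DataFrame(sorted(db), columns=["chrom", "pos", "ref", "alt"])
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- coverage

def write_coverage_bed(track: CoverageTrack, genome: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        for chrom, counts in track.counts.items():
            length = genome.lengths[chrom]
            for i, c in enumerate(counts):
                start = i * track.window_size
                end = min(start + track.window_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{c:g}\n")


def read_coverage_bed(path, window_size: int | None = None) -> CoverageTrack:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"]
    )
    if window_size is None:
        window_size = int((frame["end"] - frame["start"]).max())
    counts = {
        str(chrom): sub.sort_values("start")["count"].to_numpy(float)
        for chrom, sub in frame.groupby("chrom")
    }
    return CoverageTrack(window_size=window_size, counts=counts)


def write_bedgraph(track: LogRatioTrack, path, name: str = "log2_ratio") -> None:
    step = track.window_size * track.decimation_factor
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, values in track.values.items():
            for i, v in enumerate(values):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{i * step}\t{(i + 1) * step}\t{v:.4f}\n")


def write_segments_bed(segments, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, state in segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{state}\n")


# ---------------------------------------------------------------- SVs

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name",
    "junction_reads", "strand1", "strand2", "span_reads_a", "span_reads_b",
    "total_depth_junction", "total_depth_a", "total_depth_b", "sample",
]


def write_bedpe(junctions: list[SVJunction], path) -> None:
    rows = [
        (
            j.chrom_a, j.pos_a, j.pos_a + 1, j.chrom_b, j.pos_b, j.pos_b + 1,
            j.name or ".", j.junction_reads, j.orient_a, j.orient_b,
            j.span_reads_a, j.span_reads_b, j.total_depth_junction,
            j.total_depth_a, j.total_depth_b, j.sample,
        )
        for j in junctions
    ]
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedpe(path) -> list[SVJunction]:
    frame = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS)
    return [
        SVJunction(
            sample=str(r["sample"]),
            chrom_a=str(r["chrom1"]),
            pos_a=int(r["start1"]),
            orient_a=str(r["strand1"]),
            chrom_b=str(r["chrom2"]),
            pos_b=int(r["start2"]),
            orient_b=str(r["strand2"]),
            junction_reads=int(r["junction_reads"]),
            span_reads_a=int(r["span_reads_a"]),
            span_reads_b=int(r["span_reads_b"]),
            total_depth_junction=int(r["total_depth_junction"]),
            total_depth_a=int(r["total_depth_a"]),
            total_depth_b=int(r["total_depth_b"]),
            name=str(r["name"]),
        )
        for _, r in frame.iterrows()
    ]


# ---------------------------------------------------------------- TADs / genes

def write_tads_bed(tads: TADMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in tads.intervals:
            for start, end, tad_id in tads.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{tad_id}\n")


def read_tads_bed(path) -> TADMap:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    intervals: dict[str, list] = {}
    for _, r in frame.iterrows():
        intervals.setdefault(str(r["chrom"]), []).append(
            (int(r["start"]), int(r["end"]), str(r["name"]))
        )
    return TADMap(intervals)


def write_genes_bed(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\t{g.tss}\t{g.strand}\n"
            )


def read_genes_bed(path) -> list[GeneAnnotation]:
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene", "tss", "strand"],
    )
    return [
        GeneAnnotation(
            gene=str(r["gene"]), chrom=str(r["chrom"]), start=int(r["start"]),
            end=int(r["end"]), tss=int(r["tss"]), strand=str(r["strand"]),
        )
        for _, r in frame.iterrows()
    ]


# ---------------------------------------------------------------- matrices

def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
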