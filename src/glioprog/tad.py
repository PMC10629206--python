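"""TAD-constrained integration of rearrangements with expression change.

A gene is reported as recurrently rearranged when, in at least
``min_patients`` patients, a rearrangement unique to the grade 4 tumor has
a breakend inside the gene's topologically associating domain (TAD) and
the gene's expression changes in the same direction by more than the fold
change threshold between the matched grade 2-3 and grade 4 tumors.
Because regulatory elements rarely act across TAD boundaries, a breakend
inside the TAD can rewire the gene's regulation even without touching the
gene body.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sv import SVJunction, breakpoints_match


@dataclass
class TADMap:
    """Sorted, non-overlapping 0-based half-open intervals per chromosome."""

    intervals: dict[str, list[tuple[int, int, str]]]  # (start, end, tad_id)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping TADs on {chrom}")
            for s, e, _ in ivs:
                if s >= e:
                    raise ValueError(f"empty TAD interval on {chrom}")

    def locate(self, chrom: str, pos: int) -> str | None:
        """TAD id containing ``pos``, or None in a boundary gap."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return None
        i = bisect.bisect_right([s for s, _, _ in ivs], pos) - 1
        if i >= 0 and ivs[i][0] <= pos < ivs[i][1]:
            return ivs[i][2]
        return None


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    chrom: str
    start: int
    end: int
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start <= self.tss < self.end:
            raise ValueError(f"TSS outside gene body for {self.gene}")


@dataclass
class TADGeneReport:
    gene: str
    direction: str  # up | down
    supporting_patients: list[str]
    expression_only_patients: list[str] = field(default_factory=list)


def assign_tad(gene: GeneAnnotation, tads: TADMap) -> str | None:
    """TAD containing the gene's transcription start site (promoter rule)."""
    return tads.locate(gene.chrom, gene.tss)


def expressed_filter(
    raw_counts: pd.DataFrame,
    grade_groups: dict[str, str],
    min_count: int = 15,
    min_samples: int = 2,
) -> list[str]:
    """Genes with more than ``min_count`` raw counts in at least
    ``min_samples`` samples of either grade group (strict '>' on counts).

    ``grade_groups`` maps sample -> {"grade_2_3", "grade_4"}.
    """
    missing = set(raw_counts.columns) - set(grade_groups)
    if missing:
        raise ValueError(f"samples without grade labels: {sorted(missing)}")
    keep = pd.Series(False, index=raw_counts.index)
    for group in ("grade_2_3", "grade_4"):
        cols = [s for s in raw_counts.columns if grade_groups[s] == group]
        if cols:
            keep |= (raw_counts[cols] > min_count).sum(axis=1) >= min_samples
    return sorted(raw_counts.index[keep])


def progression_fold_change(
    raw_counts: pd.DataFrame,
    pairs: dict[str, tuple[str, str]],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-patient log2 fold change, grade 4 over grade 2-3.

    ``pairs`` maps patient -> (pre_sample, post_sample).  Counts are
    library-size normalized to counts-per-million before the ratio, with a
    pseudocount so the result stays finite; positive values mean higher
    expression in the grade 4 tumor.
    """
    totals = raw_counts.sum(axis=0)
    cpm = raw_counts * 1e6 / totals
    out = {}
    for patient, (pre, post) in pairs.items():
        out[patient] = np.log2(cpm[post] + pseudocount) - np.log2(
            cpm[pre] + pseudocount
        )
    return pd.DataFrame(out)


def grade4_unique_junctions(
    post_junctions: list[SVJunction],
    pre_junctions: list[SVJunction],
    match_radius: int = 200,
) -> list[SVJunction]:
    """Junctions of the grade 4 sample with no matched-breakpoint partner
    (200 bp / orientation rule) in the earlier tumor."""
    return [
        j
        for j in post_junctions
        if not any(
            breakpoints_match(j, p, radius=match_radius) for p in pre_junctions
        )
    ]


def recurrent_tad_genes(
    patient_junctions: dict[str, list[SVJunction]],
    tads: TADMap,
    genes: list[GeneAnnotation],
    fold_changes: pd.DataFrame,
    expressed_genes: list[str] | None = None,
    fc_threshold: float = 1.0,
    min_patients: int = 2,
    both_ends: bool = False,
) -> list[TADGeneReport]:
    """Report genes recurrently hit by grade-4-unique rearrangements.

    ``patient_junctions`` holds each patient's grade-4-unique junctions;
    ``fold_changes`` is genes x patients (log2, grade 4 over grade 2-3).
    A junction counts toward a TAD when either breakend falls inside it
    (both with ``both_ends``).  A gene is reported when >= ``min_patients``
    patients combine an in-TAD junction with |log2FC| > ``fc_threshold``
    in the same direction; patients with the expression change but no
    rearrangement are listed separately.  Output sorted by gene id.
    """
    expressed = (
        set(expressed_genes) if expressed_genes is not None else set(fold_changes.index)
    )
    # patient -> set of TADs containing at least one breakend
    hit_tads: dict[str, set[str]] = {}
    for patient, junctions in patient_junctions.items():
        tad_ids = set()
        for j in junctions:
            t_a = tads.locate(j.chrom_a, j.pos_a)
            t_b = tads.locate(j.chrom_b, j.pos_b)
            if both_ends:
                if t_a is not None and t_a == t_b:
                    tad_ids.add(t_a)
            else:
                tad_ids.update(t for t in (t_a, t_b) if t is not None)
        hit_tads[patient] = tad_ids

    reports = []
    for gene in sorted(genes, key=lambda g: g.gene):
        if gene.gene not in expressed or gene.gene not in fold_changes.index:
            continue
        tad_id = assign_tad(gene, tads)
        if tad_id is None:
            continue
        fc = fold_changes.loc[gene.gene]
        for direction, sign in (("up", 1), ("down", -1)):
            changed = {
                p for p in fold_changes.columns if sign * fc[p] > fc_threshold
            }
            supporting = sorted(
                p for p in changed if tad_id in hit_tads.get(p, set())
            )
            if len(supporting) >= min_patients:
                reports.append(
                    TADGeneReport(
                        gene=gene.gene,
                        direction=direction,
                        supporting_patients=supporting,
                        expression_only_patients=sorted(changed - set(supporting)),
                    )
                )
    return reports
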