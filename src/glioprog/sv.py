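"""Post-detection structural-variant analysis.

Junction records (paired breakends with read support) are filtered by
support and cohort recurrence, classified as clonal/subclonal by allele
fraction or matched-sample breakpoint sharing, binned by geometry
(focal / large intrachromosomal / interchromosomal), and scanned for
breakpoint microhomology, whose length points at the repair pathway that
formed the junction (NHEJ for none/short, MMEJ for ~5-18 bp).

Breakend orientation convention: each breakend stores which genomic side
survives in the derivative chromosome. ``+`` keeps the left (5') side, so
the retained segment ends at ``pos`` (inclusive); ``-`` keeps the right
(3') side, which starts at ``pos``.  Reading the derivative 5'->3', the A
breakend contributes the sequence ending at the junction and the B
breakend the sequence leaving it; a ``-`` A side or ``+`` B side therefore
appears reverse-complemented.  All four orientation pairs (deletion-like
+/-, duplication-like -/+, and the two inversion types +/+ and -/-) are
supported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .genome import ReferenceGenome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

FOCAL_LIMIT = 2_000_000  # intrachromosomal span below this is "focal"

#: microhomology-length bins by the repair pathway able to produce them
REPAIR_BINS = ("none_or_short", "mmej_only", "long")


@dataclass(frozen=True)
class SVJunction:
    sample: str
    chrom_a: str
    pos_a: int
    orient_a: str  # '+': left side retained; '-': right side retained
    chrom_b: str
    pos_b: int
    orient_b: str
    junction_reads: int = 0
    span_reads_a: int = 0
    span_reads_b: int = 0
    total_depth_junction: int = 0
    total_depth_a: int = 0
    total_depth_b: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        for o in (self.orient_a, self.orient_b):
            if o not in "+-":
                raise ValueError(f"bad orientation {o!r}")
        if self.junction_reads > self.total_depth_junction and self.total_depth_junction:
            raise ValueError("junction support exceeds junction depth")

    def breakends(self):
        return (
            (self.chrom_a, self.pos_a, self.orient_a),
            (self.chrom_b, self.pos_b, self.orient_b),
        )

    def canonical(self) -> "SVJunction":
        """Breakends ordered by (chrom, pos, orient) for symmetric matching."""
        a, b = self.breakends()
        if a <= b:
            return self
        return replace(
            self,
            chrom_a=self.chrom_b,
            pos_a=self.pos_b,
            orient_a=self.orient_b,
            chrom_b=self.chrom_a,
            pos_b=self.pos_a,
            orient_b=self.orient_a,
            span_reads_a=self.span_reads_b,
            span_reads_b=self.span_reads_a,
            total_depth_a=self.total_depth_b,
            total_depth_b=self.total_depth_a,
        )


@dataclass(frozen=True)
class ClonalityCall:
    label: str  # clonal | subclonal
    basis: str  # junction_af | span_af | matched_breakpoint | none
    sharing: str  # shared | private


@dataclass(frozen=True)
class MicrohomologyResult:
    length: int  # 0 or in [min_len, max_len]
    sequence: str  # the matched bases, 5'->3' in fused orientation
    censored_at_max: bool = False
    truncated_flank: bool = False


def breakpoints_match(
    j1: SVJunction,
    j2: SVJunction,
    radius: int = 200,
    both_ends: bool = True,
) -> bool:
    """Whether two junctions describe the same breakpoint pair.

    With ``both_ends`` (default) both breakends must lie within ``radius``
    on the same chromosome with the same orientation, after canonical
    breakend ordering; the laxer single-end reading accepts one matching
    breakend.
    """
    a1, b1 = j1.canonical().breakends()
    a2, b2 = j2.canonical().breakends()

    def end_match(e1, e2):
        return e1[0] == e2[0] and e1[2] == e2[2] and abs(e1[1] - e2[1]) <= radius

    if both_ends:
        return end_match(a1, a2) and end_match(b1, b2)
    return any(end_match(x, y) for x in (a1, b1) for y in (a2, b2))


def filter_junctions(
    junctions: list[SVJunction],
    n_cohort_samples: int,
    min_support: int = 5,
    recurrence_cap: float = 0.30,
    match_radius: int = 200,
) -> list[SVJunction]:
    """Support and cohort-recurrence filtering.

    Junctions with fewer than ``min_support`` junction-spanning reads are
    dropped; junctions whose breakpoint pair recurs in strictly more than
    ``recurrence_cap`` of the cohort's samples are dropped as technical
    artifacts (real somatic SVs do not recur at identical base pairs
    across patients).
    """
    if n_cohort_samples <= 0:
        raise ValueError("cohort sample count must be positive")
    supported = [j for j in junctions if j.junction_reads >= min_support]
    kept = []
    for j in supported:
        samples_with = {
            other.sample
            for other in supported
            if breakpoints_match(j, other, radius=match_radius)
        }
        if len(samples_with) / n_cohort_samples > recurrence_cap:
            continue
        kept.append(j)
    return kept


def clonality(
    junction: SVJunction,
    matched_junctions: list[SVJunction],
    af_threshold: float = 0.2,
    match_radius: int = 200,
    both_ends: bool = True,
) -> ClonalityCall:
    """Clonal/subclonal call plus shared/private status vs the matched tumor.

    Clonal iff the junction-read allele fraction reaches ``af_threshold``,
    or the spanning-pair allele fraction reaches it on *both* sides, or
    the matched sample carries the same breakpoint pair within
    ``match_radius`` (clonal in both tumors by definition of a shared
    truncal event).
    """
    shared = any(
        breakpoints_match(junction, m, radius=match_radius, both_ends=both_ends)
        for m in matched_junctions
    )
    usable_depths = [
        d
        for d in (
            junction.total_depth_junction,
            junction.total_depth_a,
            junction.total_depth_b,
        )
        if d > 0
    ]
    if not usable_depths and not shared:
        raise ValueError("clonality undefined: all depths zero and no match")
    if junction.total_depth_junction > 0:
        if junction.junction_reads / junction.total_depth_junction >= af_threshold:
            return ClonalityCall("clonal", "junction_af", "shared" if shared else "private")
    if junction.total_depth_a > 0 and junction.total_depth_b > 0:
        af_a = junction.span_reads_a / junction.total_depth_a
        af_b = junction.span_reads_b / junction.total_depth_b
        if af_a >= af_threshold and af_b >= af_threshold:
            return ClonalityCall("clonal", "span_af", "shared" if shared else "private")
    if shared:
        return ClonalityCall("clonal", "matched_breakpoint", "shared")
    return ClonalityCall("subclonal", "none", "private")


def geometry(junction: SVJunction) -> str:
    if junction.chrom_a != junction.chrom_b:
        return "interchromosomal"
    if abs(junction.pos_b - junction.pos_a) < FOCAL_LIMIT:
        return "focal"
    return "intrachromosomal_large"


def _a_side_base(genome: ReferenceGenome, j: SVJunction, i: int) -> str | None:
    """Base ``i`` positions 5' of the junction on the retained A side (i=0
    adjacent), in fused orientation; None past the contig edge."""
    seq = genome.chromosomes[j.chrom_a]
    if j.orient_a == "+":
        p = j.pos_a - i
        return chr(seq[p]) if 0 <= p < len(seq) else None
    p = j.pos_a + i
    return _COMP[chr(seq[p])] if 0 <= p < len(seq) else None


def _b_flank_base(genome: ReferenceGenome, j: SVJunction, i: int) -> str | None:
    """Reference base ``i`` positions 5'-ward of breakend B's retained start
    (i=0 adjacent) in fused orientation — the displaced-side bases whose
    identity with the A tail makes the junction position ambiguous."""
    seq = genome.chromosomes[j.chrom_b]
    if j.orient_b == "-":
        p = j.pos_b - 1 - i
        return chr(seq[p]) if 0 <= p < len(seq) else None
    p = j.pos_b + 1 + i
    return _COMP[chr(seq[p])] if 0 <= p < len(seq) else None


def microhomology(
    junction: SVJunction,
    genome: ReferenceGenome,
    max_len: int = 20,
    min_len: int = 2,
) -> MicrohomologyResult:
    """Microhomology at the fused seam, against the reference genome.

    Walks outward from the junction comparing the retained A-side tail
    with the reference continuation 5'-ward of B's breakpoint (the bases
    that could belong to either partner), up to ``max_len`` bases.  Runs
    shorter than ``min_len`` report length 0; a run reaching ``max_len``
    is censored (longer homology is not searched for).
    """
    run = []
    truncated = False
    for i in range(max_len):
        a = _a_side_base(genome, junction, i)
        b = _b_flank_base(genome, junction, i)
        if a is None or b is None:
            truncated = True
            break
        if a != b:
            break
        run.append(a)
    length = len(run)
    censored = length == max_len
    if length < min_len:
        return MicrohomologyResult(0, "", False, truncated)
    # run was collected walking 5'-ward; report the seam sequence 5'->3'
    return MicrohomologyResult(length, "".join(reversed(run)), censored, truncated)


def repair_bin(length: int) -> str:
    """Repair-pathway bin for a microhomology length.

    0-4 bp is compatible with NHEJ (or MMEJ); 5-18 bp can only be produced
    by MMEJ; >18 bp would point toward homology-directed repair.
    """
    if length == 1 or length < 0 or length > 20:
        raise ValueError(f"invalid microhomology length {length}")
    if length <= 4:
        return "none_or_short"
    if length <= 18:
        return "mmej_only"
    return "long"


def sv_summary(
    junctions: list[SVJunction],
    calls: list[ClonalityCall],
    homologies: list[MicrohomologyResult] | None = None,
) -> dict:
    """Per-sample counts for a classified junction set.

    Returns total/clonal/shared/private counts, focal and interchromosomal
    fractions, and the microhomology-length histogram (which sums to the
    junction count when homologies are supplied).
    """
    if len(junctions) != len(calls):
        raise ValueError("junctions and clonality calls must align")
    n = len(junctions)
    geometries = Counter(geometry(j) for j in junctions)
    summary = {
        "n_total": n,
        "n_clonal": sum(c.label == "clonal" for c in calls),
        "n_shared": sum(c.sharing == "shared" for c in calls),
        "n_private": sum(c.sharing == "private" for c in calls),
        "focal_fraction": geometries["focal"] / n if n else 0.0,
        "interchromosomal_fraction": geometries["interchromosomal"] / n if n else 0.0,
        "microhomology_histogram": {},
    }
    if homologies is not None:
        if len(homologies) != n:
            raise ValueError("homologies must align with junctions")
        summary["microhomology_histogram"] = dict(
            sorted(Counter(h.length for h in homologies).items())
        )
    return summary
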