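"""Synthetic matched-pair tumor cohorts with known ground truth.

Generates, at desk scale, everything the downstream stages consume: a toy
reference genome (a few chromosomes of a few hundred kb instead of hg38),
matched pre/post-progression tumor pairs with planted point mutations,
copy-number events and rearrangement junctions (including their breakpoint
microhomologies, written into the reference sequence), per-window fragment
coverage, gene-expression count matrices with progression-shifted
programs, and patient treatment/surgery timelines.

Noise models are deliberately simple and mean-calibrated: binomial
sampling for allele and junction read counts (alt fraction = clone
fraction x purity / 2 for heterozygous point mutations, clone fraction for
junction support), Poisson-Gamma (negative binomial) counts for coverage
windows and expression.  Setting ``noise=0`` replaces sampling with
rounded expectations so label-recovery tests can run at zero noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna import CoverageTrack
from .genome import ConfigurationError, ReferenceGenome, reverse_complement
from .sv import SVJunction
from .survival import PatientTimeline, Reoperation, TherapyEpisode
from .tad import GeneAnnotation, TADMap
from .variants import CohortVariantTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Raised when event placement fails after bounded retries."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``depth`` is the mean fragment depth in x (mean fragments per coverage
    window and mean reads per variant site); the cohort emulates 30x WGS
    of matched grade 2-3 / grade 4 pairs.
    """

    seed: int = 0
    n_patients: int = 5
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    window_size: int = 1000
    depth: float = 30.0
    purity: float = 1.0
    noise: float = 1.0  # 0 disables sampling (rounded expectations)
    # small variants
    n_clonal_snvs: int = 40
    n_private_snvs: int = 15
    shared_fraction: float = 0.7
    germline_rate: float = 0.05  # variants per kb, VAF 0.5 in every sample
    hypermutator: bool = False
    hypermutator_multiplier: float = 4.0
    hypermutator_cpg_weight: float = 10.0  # CpG C>T excess among extra SNVs
    # copy number (planted in the post sample)
    homozygous_deletion_length: int = 100_000
    hemizygous_loss_length: int = 100_000
    amplification_length: int = 20_000
    amplification_extra_copies: int = 12
    include_amplification: bool = True
    coverage_dispersion: float = 0.02  # NB overdispersion; 0 = Poisson
    mapping_noise: float = 0.0  # residual mean coverage inside homozygous deletions
    # structural variants
    n_clonal_svs: int = 10
    n_subclonal_svs: int = 4
    subclonal_fraction: float = 0.1
    sv_depth: float = 50.0
    microhomology_lengths: tuple = (0, 2, 4, 10, 16)
    interchromosomal_fraction: float = 0.3
    # expression
    n_genes: int = 300
    genes_per_set: int = 12
    program_shift: dict = field(
        default_factory=lambda: {"proliferation": 1.5, "hypoxia": 1.0}
    )
    expression_dispersion: float = 0.05
    expression_mean: float = 100.0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.sv_depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.n_chromosomes < 2 or self.chrom_length < 100_000:
            raise ConfigurationError(
                "need >=2 chromosomes of >=100 kb for inter- and intrachromosomal events"
            )
        if not 0 <= self.purity <= 1 or not 0 <= self.shared_fraction <= 1:
            raise ConfigurationError("fractions must be in [0, 1]")
        for L in self.microhomology_lengths:
            if not (L == 0 or 2 <= L <= 20):
                raise ConfigurationError(f"microhomology length {L} outside {{0}} u [2,20]")


@dataclass
class TruthEvent:
    """Planted ground-truth event; observations trace back to ``uid``."""

    uid: str
    kind: str  # snv | homozygous_deletion | hemizygous_loss | amplification | sv_junction
    chrom: str
    start: int
    end: int
    clone_fraction: float = 1.0
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise ConfigurationError("clone_fraction outside [0, 1]")


@dataclass
class ObservedSample:
    sample: str
    variants: pd.DataFrame  # chrom,pos,ref,alt,alt_count,ref_count,event_uid
    coverage: CoverageTrack
    junctions: list[SVJunction]
    expression: pd.Series  # counts per gene


def simulate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Uniform-random ACGT toy genome; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    chroms = {}
    for i in range(config.n_chromosomes):
        seq = _BASES[rng.integers(0, 4, size=config.chrom_length)]
        chroms[f"chr{i + 1}"] = bytearray(seq.tobytes())
    return ReferenceGenome(chroms)


class _Placer:
    """Collision-free interval placement with bounded retries."""

    def __init__(self, genome: ReferenceGenome, rng, margin: int = 30):
        self.lengths = genome.lengths
        self.names = list(self.lengths)
        self.rng = rng
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.names}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        s, e = start - self.margin, end + self.margin
        return all(e <= os or oe <= s for os, oe in self.occupied[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place(self, length: int, chrom: str | None = None, retries: int = 200):
        for _ in range(retries):
            c = chrom or self.names[self.rng.integers(len(self.names))]
            limit = self.lengths[c] - length - self.margin
            if limit <= self.margin:
                continue
            start = int(self.rng.integers(self.margin, limit))
            if self._free(c, start, start + length):
                self.reserve(c, start, start + length)
                return c, start
        raise GenerationError("event placement collision after bounded retries")


def _random_snv(placer: _Placer, genome: ReferenceGenome, rng, uid, cf, cpg=False):
    for _ in range(200):
        chrom, pos = placer.place(1)
        ref = genome.base(chrom, pos)
        if cpg:
            # need a C followed by G (or its reverse complement): rewrite context
            if pos + 1 >= genome.lengths[chrom]:
                continue
            genome.replace(chrom, pos, "CG")
            ref, alt = "C", "T"
        else:
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
        return TruthEvent(
            uid=uid,
            kind="snv",
            chrom=chrom,
            start=pos,
            end=pos + 1,
            clone_fraction=cf,
            payload={"ref": ref, "alt": alt, "cpg_ct": cpg},
        )
    raise GenerationError("could not place SNV")


def _plant_junction(
    genome: ReferenceGenome, placer: _Placer, rng, uid, cf, mh_len, interchrom, config
):
    """Place one junction and write its microhomology into the reference.

    The bases immediately 5'-ward of breakend B's retained start (in fused
    orientation) are overwritten to copy the retained A tail for exactly
    ``mh_len`` bases, with a forced mismatch at the next base, so the
    planted length is exact.
    """
    from .sv import _a_side_base, _b_flank_base

    orient_a, orient_b = rng.choice(["+", "-"]), rng.choice(["+", "-"])
    chrom_a, start_a = placer.place(1 + 2 * 25)
    pos_a = start_a + 25
    if interchrom:
        others = [c for c in placer.names if c != chrom_a]
        chrom_b = others[rng.integers(len(others))]
        chrom_b, start_b = placer.place(1 + 2 * 25, chrom=chrom_b)
    else:
        chrom_b, start_b = placer.place(1 + 2 * 25, chrom=chrom_a)
    pos_b = start_b + 25
    junction = SVJunction(
        sample="",
        chrom_a=chrom_a,
        pos_a=pos_a,
        orient_a=orient_a,
        chrom_b=chrom_b,
        pos_b=pos_b,
        orient_b=orient_b,
        name=uid,
    )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(mh_len + 1):
        a_base = _a_side_base(genome, junction, i)
        if a_base is None:
            raise GenerationError("junction too close to contig edge")
        want = a_base if i < mh_len else comp[a_base]  # mismatch terminates the run
        if junction.orient_b == "-":
            genome.replace(chrom_b, pos_b - 1 - i, want)
        else:
            genome.replace(chrom_b, pos_b + 1 + i, comp[want])
    assert _b_flank_base(genome, junction, mh_len) != _a_side_base(
        genome, junction, mh_len
    )
    return TruthEvent(
        uid=uid,
        kind="sv_junction",
        chrom=chrom_a,
        start=pos_a,
        end=pos_a + 1,
        clone_fraction=cf,
        payload={
            "chrom_a": chrom_a,
            "pos_a": pos_a,
            "orient_a": orient_a,
            "chrom_b": chrom_b,
            "pos_b": pos_b,
            "orient_b": orient_b,
            "microhomology": mh_len,
        },
    )


def simulate_patient_pair(
    genome: ReferenceGenome,
    config: SimulationConfig,
    patient: str = "P1",
    rng=None,
    placer: _Placer | None = None,
):
    """Truth events for one matched pre/post pair.

    The post tumor inherits ``shared_fraction`` of the pre tumor's somatic
    events and gains private ones, including exactly one homozygous
    deletion, one hemizygous loss, and (optionally) one amplification.
    Junction microhomologies are planted into the shared reference.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    placer = placer or _Placer(genome, rng)

    n_pre_snvs = config.n_clonal_snvs
    n_new_snvs = config.n_private_snvs
    cpg_flags_pre = [False] * n_pre_snvs
    cpg_flags_new = [False] * n_new_snvs
    if config.hypermutator:
        extra = int(round(n_new_snvs * (config.hypermutator_multiplier - 1)))
        w = config.hypermutator_cpg_weight
        cpg_flags_new += [bool(rng.random() < w / (w + 1.0)) for _ in range(extra)]
        n_new_snvs += extra

    pre: list[TruthEvent] = []
    for i in range(n_pre_snvs):
        pre.append(
            _random_snv(placer, genome, rng, f"{patient}.snv{i}", 1.0, cpg_flags_pre[i])
        )
    mh_cycle = list(config.microhomology_lengths) or [0]
    for i in range(config.n_clonal_svs + config.n_subclonal_svs):
        cf = 1.0 if i < config.n_clonal_svs else config.subclonal_fraction
        pre.append(
            _plant_junction(
                genome,
                placer,
                rng,
                f"{patient}.sv{i}",
                cf,
                mh_cycle[i % len(mh_cycle)],
                rng.random() < config.interchromosomal_fraction,
                config,
            )
        )

    # post: inherit a fraction of pre events, then add private ones
    inherit = rng.random(len(pre)) < config.shared_fraction
    post: list[TruthEvent] = [ev for ev, keep in zip(pre, inherit) if keep]
    if config.shared_fraction >= 1.0:
        post = list(pre)
    for i in range(n_new_snvs):
        post.append(
            _random_snv(
                placer, genome, rng, f"{patient}.post.snv{i}", 1.0, cpg_flags_new[i]
            )
        )
    for i in range(config.n_clonal_svs + config.n_subclonal_svs):
        cf = 1.0 if i < config.n_clonal_svs else config.subclonal_fraction
        post.append(
            _plant_junction(
                genome,
                placer,
                rng,
                f"{patient}.post.sv{i}",
                cf,
                mh_cycle[i % len(mh_cycle)],
                rng.random() < config.interchromosomal_fraction,
                config,
            )
        )
    # CNA segments are private to this patient's coverage track, so they
    # only need to avoid each other, not other patients' events
    cna_placer = _Placer(genome, rng, margin=2 * config.window_size)
    chrom, start = cna_placer.place(config.homozygous_deletion_length)
    post.append(
        TruthEvent(
            uid=f"{patient}.homdel",
            kind="homozygous_deletion",
            chrom=chrom,
            start=start,
            end=start + config.homozygous_deletion_length,
            payload={"copy_number": 0},
        )
    )
    chrom, start = cna_placer.place(config.hemizygous_loss_length)
    post.append(
        TruthEvent(
            uid=f"{patient}.hemiloss",
            kind="hemizygous_loss",
            chrom=chrom,
            start=start,
            end=start + config.hemizygous_loss_length,
            payload={"copy_number": 1},
        )
    )
    if config.include_amplification:
        chrom, start = cna_placer.place(config.amplification_length)
        post.append(
            TruthEvent(
                uid=f"{patient}.amp",
                kind="amplification",
                chrom=chrom,
                start=start,
                end=start + config.amplification_length,
                payload={"copy_number": 2 + config.amplification_extra_copies},
            )
        )
    return pre, post


def simulate_germline(genome: ReferenceGenome, config: SimulationConfig, rng, placer):
    """Cohort-wide germline heterozygous variants (VAF 0.5 in every sample).

    Returns ``(events, db)`` where ``db`` is the exact-allele germline
    database handed to the somatic filter.
    """
    total_kb = sum(genome.lengths.values()) / 1000
    n = int(round(config.germline_rate * total_kb))
    events, db = [], set()
    for i in range(n):
        ev = _random_snv(placer, genome, rng, f"germline{i}", 1.0)
        ev.payload["germline"] = True
        events.append(ev)
        db.add((ev.chrom, ev.start + 1, ev.payload["ref"], ev.payload["alt"]))
    return events, db


def _nb_counts(rng, mean, dispersion, noise):
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if noise == 0:
        return np.round(mean)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def _binomial(rng, n, p, noise):
    if noise == 0:
        return np.round(np.asarray(n) * p)
    return rng.binomial(np.asarray(n).astype(int), p)


def emit_observed_sample(
    truth: list[TruthEvent],
    genome: ReferenceGenome,
    config: SimulationConfig,
    sample: str,
    rng=None,
    gene_table: pd.DataFrame | None = None,
    is_post: bool = False,
) -> ObservedSample:
    """Noisy observations for one sample given its truth events.

    Expected values: alt fraction of a clonal heterozygous SNV is
    clone_fraction x purity / 2; window coverage mean is depth x effective
    copy number / 2; junction support is binomial at the clone fraction;
    expression is negative binomial around the gene table's base mean,
    shifted by the configured program log2 shift in post samples.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    rows = []
    for ev in truth:
        if ev.kind != "snv":
            continue
        depth = _nb_counts(rng, [config.depth], 0.0, config.noise)[0]
        depth = max(int(depth), 1)
        af = 0.5 if ev.payload.get("germline") else ev.clone_fraction * config.purity / 2
        alt = int(_binomial(rng, depth, af, config.noise))
        rows.append(
            {
                "chrom": ev.chrom,
                "pos": ev.start + 1,
                "ref": ev.payload["ref"],
                "alt": ev.payload["alt"],
                "alt_count": alt,
                "ref_count": depth - alt,
                "event_uid": ev.uid,
            }
        )
    variants = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "alt_count", "ref_count", "event_uid"],
    )

    # coverage: per-window effective copy number from CNA truth
    cn = {c: np.full(-(-length // config.window_size), 2.0) for c, length in genome.lengths.items()}
    for ev in truth:
        if ev.kind not in ("homozygous_deletion", "hemizygous_loss", "amplification"):
            continue
        w0 = ev.start // config.window_size
        w1 = -(-ev.end // config.window_size)
        copy = ev.payload["copy_number"]
        eff = 2.0 + ev.clone_fraction * config.purity * (copy - 2.0)
        cn[ev.chrom][w0:w1] = eff
    counts = {}
    for chrom, eff in cn.items():
        mean = config.depth * eff / 2.0 + config.mapping_noise
        counts[chrom] = _nb_counts(rng, mean, config.coverage_dispersion, config.noise)
    coverage = CoverageTrack(window_size=config.window_size, counts=counts)

    junctions = []
    for ev in truth:
        if ev.kind != "sv_junction":
            continue
        p = ev.payload
        depth_j = max(int(_nb_counts(rng, [config.sv_depth], 0.0, config.noise)[0]), 1)
        depth_a = max(int(_nb_counts(rng, [config.sv_depth], 0.0, config.noise)[0]), 1)
        depth_b = max(int(_nb_counts(rng, [config.sv_depth], 0.0, config.noise)[0]), 1)
        cf = ev.clone_fraction * config.purity
        junctions.append(
            SVJunction(
                sample=sample,
                chrom_a=p["chrom_a"],
                pos_a=p["pos_a"],
                orient_a=p["orient_a"],
                chrom_b=p["chrom_b"],
                pos_b=p["pos_b"],
                orient_b=p["orient_b"],
                junction_reads=int(_binomial(rng, depth_j, cf, config.noise)),
                span_reads_a=int(_binomial(rng, depth_a, cf, config.noise)),
                span_reads_b=int(_binomial(rng, depth_b, cf, config.noise)),
                total_depth_junction=depth_j,
                total_depth_a=depth_a,
                total_depth_b=depth_b,
                name=ev.uid,
            )
        )

    if gene_table is None:
        gene_table = simulate_gene_table(genome, config)
    mean = gene_table["base_mean"].to_numpy(float).copy()
    if is_post:
        for program, shift in config.program_shift.items():
            member = (gene_table["program"] == program).to_numpy()
            mean[member] *= 2.0**shift
    expr = _nb_counts(rng, mean, config.expression_dispersion, config.noise)
    expression = pd.Series(expr, index=gene_table.index, name=sample)

    return ObservedSample(
        sample=sample, variants=variants, coverage=coverage, junctions=junctions,
        expression=expression,
    )


def simulate_gene_table(genome: ReferenceGenome, config: SimulationConfig) -> pd.DataFrame:
    """Toy gene model: genes tiled uniformly, some assigned to programs.

    Deterministic given the seed (uses its own generator so sample
    emission order cannot perturb it).  Columns: chrom, start, end, tss,
    strand, program, base_mean.
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = list(genome.lengths)
    per_chrom = -(-config.n_genes // len(chroms))
    rows = []
    gene_no = 0
    for chrom in chroms:
        length = genome.lengths[chrom]
        spacing = length // (per_chrom + 1)
        for k in range(per_chrom):
            if gene_no >= config.n_genes:
                break
            start = spacing * (k + 1)
            rows.append(
                {
                    "gene": f"G{gene_no:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + 2000, length),
                    "tss": start,
                    "strand": "+",
                }
            )
            gene_no += 1
    table = pd.DataFrame(rows).set_index("gene")
    programs = np.array([""] * len(table), dtype=object)
    cursor = 0
    for program in sorted(config.program_shift):
        programs[cursor : cursor + config.genes_per_set] = program
        cursor += config.genes_per_set
    table["program"] = programs
    table["base_mean"] = rng.lognormal(
        mean=np.log(config.expression_mean), sigma=0.5, size=len(table)
    )
    return table


def build_cohort_table(
    samples: list[ObservedSample], config: SimulationConfig, rng=None
) -> CohortVariantTable:
    """Union the per-sample variant observations into a cohort table.

    Samples lacking a variant contribute reference-only read counts at
    sampled depth, which is what a caller sees in a tumor where the
    variant is absent.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    keys: dict[tuple, dict] = {}
    for obs in samples:
        for _, row in obs.variants.iterrows():
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            keys.setdefault(key, {})[obs.sample] = (
                int(row["alt_count"]),
                int(row["ref_count"]),
            )
    names = [obs.sample for obs in samples]
    records = []
    for key in sorted(keys):
        counts = keys[key]
        for name in names:
            if name not in counts:
                depth = max(int(_nb_counts(rng, [config.depth], 0.0, config.noise)[0]), 1)
                counts[name] = (0, depth)
        records.append((*key, counts))
    return CohortVariantTable.from_records(records, names)


def simulate_tads(genome: ReferenceGenome, tad_size: int = 50_000, gap: int = 5_000) -> TADMap:
    """Tile each chromosome into fixed TADs separated by boundary gaps."""
    intervals = {}
    for chrom, length in genome.lengths.items():
        ivs, start, k = [], 0, 0
        while start + tad_size <= length:
            ivs.append((start, start + tad_size, f"{chrom}.tad{k}"))
            start += tad_size + gap
            k += 1
        intervals[chrom] = ivs
    return TADMap(intervals)


def gene_annotations(gene_table: pd.DataFrame) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(
            gene=name,
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            tss=int(row["tss"]),
            strand=row["strand"],
        )
        for name, row in gene_table.iterrows()
    ]


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genome: ReferenceGenome
    gene_table: pd.DataFrame
    tads: TADMap
    germline_db: set
    truth: dict[str, list[TruthEvent]]  # sample -> events
    samples: dict[str, ObservedSample]
    pairs: dict[str, tuple[str, str]]  # patient -> (pre, post) sample names
    variant_table: CohortVariantTable
    reference_coverage: CoverageTrack


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """End-to-end cohort generation; deterministic given ``config.seed``."""
    genome = simulate_genome(config)
    rng = np.random.default_rng(config.seed + 10)
    placer = _Placer(genome, rng)
    germline_events, germline_db = simulate_germline(genome, config, rng, placer)
    gene_table = simulate_gene_table(genome, config)
    tads = simulate_tads(genome)

    truth: dict[str, list[TruthEvent]] = {}
    samples: dict[str, ObservedSample] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for i in range(config.n_patients):
        patient = f"P{i + 1:02d}"
        cfg = config
        if config.hypermutator and i != 0:
            cfg = dataclasses.replace(config, hypermutator=False)
        pre, post = simulate_patient_pair(genome, cfg, patient, rng, placer)
        pre_name, post_name = f"{patient}a", f"{patient}b"
        truth[pre_name] = pre + germline_events
        truth[post_name] = post + germline_events
        pairs[patient] = (pre_name, post_name)

    for name, events in truth.items():
        samples[name] = emit_observed_sample(
            events,
            genome,
            config,
            name,
            rng,
            gene_table=gene_table,
            is_post=name.endswith("b"),
        )

    variant_table = build_cohort_table(list(samples.values()), config, rng)
    ref_counts = {
        c: _nb_counts(
            rng,
            np.full(-(-length // config.window_size), config.depth),
            config.coverage_dispersion,
            config.noise,
        )
        for c, length in genome.lengths.items()
    }
    reference_coverage = CoverageTrack(window_size=config.window_size, counts=ref_counts)
    return SyntheticCohort(
        config=config,
        genome=genome,
        gene_table=gene_table,
        tads=tads,
        germline_db=germline_db,
        truth=truth,
        samples=samples,
        pairs=pairs,
        variant_table=variant_table,
        reference_coverage=reference_coverage,
    )


def expression_matrix(cohort: SyntheticCohort) -> pd.DataFrame:
    return pd.DataFrame(
        {name: obs.expression for name, obs in cohort.samples.items()}
    )


def simulate_tad_fixture(
    seed: int = 0,
    n_patients: int = 4,
    n_recurrent: int = 3,
    n_singleton: int = 4,
    n_background: int = 20,
    fc_magnitude: float = 3.0,
):
    """TAD-integration fixture with known recurrent/singleton gene truth.

    Lays one gene per 50 kb TAD on a toy chromosome and plants, for
    ``n_recurrent`` genes, an in-TAD grade-4-unique junction plus a
    same-direction expression change (|log2FC| = ``fc_magnitude``) in two
    patients; ``n_singleton`` genes get the same signal in one patient
    only; background genes get neither.  Returns ``(patient_junctions,
    tads, genes, fold_changes, recurrent_genes, singleton_genes)``.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_recurrent + n_singleton + n_background
    tad_size, gap = 50_000, 5_000
    chrom = "chr1"
    intervals = []
    genes = []
    for k in range(n_genes):
        start = k * (tad_size + gap)
        intervals.append((start, start + tad_size, f"tad{k}"))
        genes.append(
            GeneAnnotation(
                gene=f"G{k:03d}",
                chrom=chrom,
                start=start + 10_000,
                end=start + 12_000,
                tss=start + 10_000,
            )
        )
    tads = TADMap({chrom: intervals})
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    fold_changes = pd.DataFrame(
        rng.normal(0.0, 0.2, size=(n_genes, n_patients)),
        index=[g.gene for g in genes],
        columns=patients,
    )
    junctions: dict[str, list[SVJunction]] = {p: [] for p in patients}

    def plant(gene_idx: int, patient: str, direction: float) -> None:
        start, _, _ = intervals[gene_idx]
        pos = start + int(rng.integers(1_000, tad_size - 1_000))
        junctions[patient].append(
            SVJunction(
                sample=patient,
                chrom_a=chrom,
                pos_a=pos,
                orient_a="+",
                chrom_b=chrom,
                pos_b=pos + 5_000_000,  # partner breakend outside every TAD
                orient_b="-",
                junction_reads=20,
                total_depth_junction=40,
            )
        )
        fold_changes.loc[genes[gene_idx].gene, patient] = direction * fc_magnitude

    recurrent, singleton = [], []
    for k in range(n_recurrent):
        direction = 1.0 if k % 2 == 0 else -1.0
        p1, p2 = patients[k % n_patients], patients[(k + 1) % n_patients]
        plant(k, p1, direction)
        plant(k, p2, direction)
        recurrent.append(genes[k].gene)
    for k in range(n_recurrent, n_recurrent + n_singleton):
        plant(k, patients[k % n_patients], -1.0)
        singleton.append(genes[k].gene)
    return junctions, tads, genes, fold_changes, recurrent, singleton


def simulate_null_variant_table(
    n_variants: int, vaf: float, depth: int, n_samples: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Null variants with one shared true VAF: binomial alt counts at fixed
    depth across samples.  Returns (alt, ref) arrays of shape
    (n_variants, n_samples); used to calibrate the heterogeneity test."""
    alt = rng.binomial(depth, vaf, size=(n_variants, n_samples))
    return alt, depth - alt


@dataclass
class SurvivalConfig:
    """Event-time and treatment-assignment model for timeline simulation.

    Exponential hazards per day; rates of zero disable the event.  The
    treatment hazard ratio multiplies every event hazard for patients in
    the combination group (values < 1 mean protective combination
    therapy).
    """

    seed: int = 0
    n_patients: int = 75
    reoperation_rate: float = 1 / 1500.0
    grade4_given_reoperation: float = 0.45
    death_rate: float = 1 / 3000.0
    follow_up_days: float = 5000.0
    p_radiation: float = 0.8
    p_chemo: float = 0.5
    therapy_start_scale: float = 120.0
    combination_hazard_ratio: float = 1.0


def simulate_survival_cohort(config: SurvivalConfig) -> list[PatientTimeline]:
    """Patient timelines: primary surgery at day 0, optional therapies,
    possible reoperation (grade 4 with a configured probability), death,
    and a follow-up horizon.  All dates are nondecreasing by construction."""
    rng = np.random.default_rng(config.seed)
    timelines = []
    for i in range(config.n_patients):
        patient = f"S{i + 1:03d}"
        therapies = []
        has_rad = rng.random() < config.p_radiation
        has_chemo = rng.random() < config.p_chemo
        if has_rad:
            start = float(rng.exponential(config.therapy_start_scale))
            therapies.append(TherapyEpisode("radiation", start, start + 40.0))
        if has_chemo:
            start = float(rng.exponential(config.therapy_start_scale) + 30.0)
            therapies.append(TherapyEpisode("chemo", start, start + 120.0))
        hr = config.combination_hazard_ratio if (has_rad and has_chemo) else 1.0

        def draw(rate):
            if rate * hr <= 0:
                return None
            return float(rng.exponential(1.0 / (rate * hr)))

        reop_time = draw(config.reoperation_rate)
        death_time = draw(config.death_rate)
        fup = config.follow_up_days
        reoperations = []
        if reop_time is not None and reop_time < fup and (
            death_time is None or reop_time < death_time
        ):
            grade = 4 if rng.random() < config.grade4_given_reoperation else 3
            reoperations.append(Reoperation(time=reop_time, grade=grade))
        death = None
        if death_time is not None and death_time < fup:
            death = death_time
        timelines.append(
            PatientTimeline(
                patient=patient,
                therapies=therapies,
                reoperations=reoperations,
                death=death,
                follow_up_end=fup,
            )
        )
    return timelines
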