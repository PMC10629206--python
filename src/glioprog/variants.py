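"""Tumor-only somatic small-variant filtering and mutation spectra.

Without a matched normal, somatic status is approximated by three gates
applied per candidate variant across the whole cohort:

(a) support — at least ``min_support`` alt reads and a variant allele
    fraction of at least ``min_vaf`` in at least one sample;
(b) heterogeneity — a chi-square goodness-of-fit test must reject the
    null that every sample shares one underlying VAF (constant-VAF sites
    are germline or systematic artifacts);
(c) germline — exact-allele matches to a germline variant database are
    removed.

The trinucleotide spectrum classifies SNVs into the 96 pyrimidine-centered
substitution classes used in mutational-signature analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import ReferenceGenome, reverse_complement

VariantKey = tuple[str, int, str, str]  # (chrom, pos 1-based, ref, alt)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
#: The 96 trinucleotide classes in canonical order, e.g. "A[C>A]A".
SPECTRUM_CLASSES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five, three in itertools.product("ACGT", repeat=2)
)


@dataclass
class SomaticFilterConfig:
    min_support: int = 3  # 30 in deep targeted-panel mode
    min_vaf: float = 0.10
    heterogeneity_alpha: float = 0.01
    germline_db: set[VariantKey] = field(default_factory=set)
    per_pair: bool = False  # heterogeneity within patient pairs vs whole cohort

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf < 1:
            raise ValueError("min_vaf must be in (0, 1)")
        if not 0 < self.heterogeneity_alpha < 1:
            raise ValueError("heterogeneity_alpha must be in (0, 1)")


class CohortVariantTable:
    """Candidate variants with per-sample alt/ref read counts.

    Backed by a DataFrame with index (chrom, pos, ref, alt) and columns
    ``{sample}.alt`` / ``{sample}.ref`` plus an optional ``effect`` label.
    """

    def __init__(self, frame: pd.DataFrame, samples: list[str]):
        for s in samples:
            for part in ("alt", "ref"):
                col = f"{s}.{part}"
                if col not in frame.columns:
                    raise ValueError(f"missing column {col}")
                if (frame[col] < 0).any():
                    raise ValueError(f"negative counts in {col}")
        if frame.index.duplicated().any():
            raise ValueError("duplicate variant rows")
        self.frame = frame
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.frame)

    def alt_matrix(self) -> np.ndarray:
        return self.frame[[f"{s}.alt" for s in self.samples]].to_numpy(float)

    def ref_matrix(self) -> np.ndarray:
        return self.frame[[f"{s}.ref" for s in self.samples]].to_numpy(float)

    @classmethod
    def from_records(cls, records, samples):
        """records: iterable of (chrom, pos, ref, alt, {sample: (alt, ref)})."""
        rows, index = [], []
        for chrom, pos, ref, alt, counts in records:
            index.append((chrom, int(pos), ref, alt))
            row = {}
            for s in samples:
                a, r = counts.get(s, (0, 0))
                row[f"{s}.alt"] = int(a)
                row[f"{s}.ref"] = int(r)
            rows.append(row)
        columns = [f"{s}.{part}" for s in samples for part in ("alt", "ref")]
        frame = pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(
                index, names=["chrom", "pos", "ref", "alt"]
            )
            if index
            else pd.MultiIndex.from_arrays(
                [[], [], [], []], names=["chrom", "pos", "ref", "alt"]
            ),
            columns=columns,
        )
        return cls(frame.fillna(0).astype(int), list(samples))


def vaf(alt_count: int, ref_count: int) -> float:
    """Variant allele fraction alt / (alt + ref)."""
    depth = alt_count + ref_count
    if depth <= 0:
        raise ZeroDivisionError("VAF undefined at zero depth")
    return alt_count / depth


def chi_square_vaf_heterogeneity(alt_counts, ref_counts):
    """Chi-square goodness-of-fit test for identical VAF across samples.

    Under the null every sample shares the pooled VAF p = sum(alt)/sum(depth);
    the statistic sums (observed - expected)^2 / expected over the alt and
    ref cells of every sample with nonzero depth, with df = (#usable
    samples) - 1.  Returns ``(statistic, df, p_value)``.
    """
    alt = np.asarray(alt_counts, dtype=float)
    ref = np.asarray(ref_counts, dtype=float)
    depth = alt + ref
    usable = depth > 0
    if usable.sum() < 2:
        raise ValueError("heterogeneity test needs >=2 samples with depth")
    alt, depth = alt[usable], depth[usable]
    pooled = alt.sum() / depth.sum()
    df = int(usable.sum()) - 1
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, df, 1.0  # no heterogeneity detectable at the boundary
    exp_alt = pooled * depth
    exp_ref = (1.0 - pooled) * depth
    stat = float(
        (((alt - exp_alt) ** 2) / exp_alt).sum()
        + ((((depth - alt) - exp_ref) ** 2) / exp_ref).sum()
    )
    return stat, df, float(sps.chi2.sf(stat, df))


def filter_somatic(
    table: CohortVariantTable,
    config: SomaticFilterConfig,
    pairs: dict[str, list[str]] | None = None,
):
    """Apply the three somatic gates; returns ``(retained, provenance)``.

    ``provenance`` is a Series over the input index holding "retained" or
    the first failing gate ("support" / "heterogeneity" / "germline").
    With ``config.per_pair`` the heterogeneity test passes if any patient
    pair (``pairs``: patient -> sample names) rejects the constant-VAF null.
    """
    alt = table.alt_matrix()
    ref = table.ref_matrix()
    depth = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        vafs = np.where(depth > 0, alt / np.where(depth > 0, depth, 1), 0.0)

    provenance = pd.Series("retained", index=table.frame.index, dtype=object)

    support_ok = ((alt >= config.min_support) & (vafs >= config.min_vaf)).any(axis=1)
    provenance[~support_ok] = "support"

    if config.per_pair:
        if not pairs:
            raise ValueError("per_pair mode requires a patient -> samples mapping")
        groups = [
            [table.samples.index(s) for s in members] for members in pairs.values()
        ]
    else:
        groups = [list(range(len(table.samples)))]

    for i in np.flatnonzero(support_ok):
        het = False
        for idx in groups:
            a, r = alt[i, idx], ref[i, idx]
            if (a + r > 0).sum() < 2:
                continue
            _, _, p = chi_square_vaf_heterogeneity(a, r)
            if p < config.heterogeneity_alpha:
                het = True
                break
        if not het:
            provenance.iloc[i] = "heterogeneity"

    keep = provenance == "retained"
    if config.germline_db:
        in_db = pd.Index(
            [key in config.germline_db for key in table.frame.index], dtype=bool
        )
        provenance[keep & in_db.to_numpy()] = "germline"
        keep = provenance == "retained"

    retained = CohortVariantTable(table.frame[keep.to_numpy()].copy(), table.samples)
    return retained, provenance


def trinucleotide_class(
    chrom: str, pos: int, ref: str, alt: str, genome: ReferenceGenome
) -> str | None:
    """96-class label for an SNV at 1-based ``pos``; None when unclassifiable.

    The substitution is strand-normalized so the reference base is a
    pyrimidine (C or T); purine-reference calls are reverse-complemented
    together with their flanks.  Variants at a chromosome edge (missing
    flank) or whose stated ref disagrees with the genome return None.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    length = len(genome.chromosomes[chrom])
    i = pos - 1
    if i < 1 or i >= length - 1:
        return None
    context = genome.sequence(chrom, i - 1, i + 2)
    if context[1] != ref:
        return None
    if ref in "GA":
        context = reverse_complement(context)
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def trinucleotide_spectrum(table: CohortVariantTable, genome: ReferenceGenome):
    """96-class spectrum; returns ``(counts, n_excluded)``.

    ``counts`` is a Series over :data:`SPECTRUM_CLASSES`; indels,
    edge-of-chromosome SNVs and ref-mismatched rows are excluded and
    counted in ``n_excluded``.
    """
    counts = pd.Series(0, index=list(SPECTRUM_CLASSES), dtype=int)
    excluded = 0
    for chrom, pos, ref, alt in table.frame.index:
        label = trinucleotide_class(chrom, int(pos), ref, alt, genome)
        if label is None:
            excluded += 1
        else:
            counts[label] += 1
    return counts, excluded
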