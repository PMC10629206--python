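"""Correlation-filtered gene sets and per-sample activity z-scores.

Curated gene sets (hypoxia, S/G2M proliferation, HRR, NHEJ, MMEJ, FA) are
first reduced to a core whose members are mutually correlated across the
cohort (every pair must reach both Pearson and Spearman correlation of at
least 0.4 on the log-normalized layer), then summarized per sample as a
combined z-score; a 0-1 rescaling is provided for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GeneSet:
    name: str
    members: list[str]
    provenance: str = ""
    missing: list[str] = field(default_factory=list)

    def intersect(self, matrix_genes) -> "GeneSet":
        present = [g for g in self.members if g in set(matrix_genes)]
        absent = [g for g in self.members if g not in set(matrix_genes)]
        return GeneSet(self.name, present, self.provenance, absent)


def log_normalize(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million, log2(x + 1): the package's normalized layer."""
    totals = raw_counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    return np.log2(raw_counts * 1e6 / totals + 1.0)


def correlation_filter(
    normalized: pd.DataFrame, candidates: GeneSet, threshold: float = 0.4
) -> GeneSet:
    """Largest-effort mutually correlated core of a candidate gene set.

    Repeatedly removes the gene involved in the most pairwise violations
    (a pair violates when either Pearson or Spearman correlation across
    samples falls below ``threshold``), breaking ties by gene id, until
    every remaining pair satisfies both.  Greedy worst-offender removal is
    an approximation to the (NP-hard) maximum mutually correlated subset,
    chosen for determinism.
    """
    if normalized.shape[1] < 3:
        raise ValueError("correlation filter needs at least 3 samples")
    genes = sorted(g for g in candidates.members if g in normalized.index)
    if len(genes) <= 1:
        return GeneSet(candidates.name, genes, candidates.provenance)
    data = normalized.loc[genes]
    pearson = np.corrcoef(data.to_numpy())
    spearman = sps.spearmanr(data.to_numpy(), axis=1)[0]
    spearman = np.atleast_2d(spearman)
    ok = (pearson >= threshold) & (spearman >= threshold)
    np.fill_diagonal(ok, True)
    active = list(range(len(genes)))
    while True:
        violations = [(~ok[i, active]).sum() for i in active]
        worst = max(violations)
        if worst == 0:
            break
        # ties -> lexicographically smallest gene id (genes are sorted)
        drop = active[int(np.argmax(violations))]
        active.remove(drop)
    kept = [genes[i] for i in active]
    return GeneSet(candidates.name, kept, candidates.provenance)


def activity_zscore(
    normalized: pd.DataFrame, gene_set: GeneSet, combined: bool = True
) -> pd.Series:
    """Per-sample activity score for a gene set.

    Each member gene is standardized across samples (mean 0, sd 1 on the
    normalized layer; zero-variance genes are dropped with a warning); the
    sample score is the mean member z-score times sqrt(k) (Stouffer-style
    combined z; ``combined=False`` drops the sqrt(k) factor).  Scores sum
    to zero across the cohort by construction.
    """
    members = [g for g in gene_set.members if g in normalized.index]
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} is empty after intersection")
    data = normalized.loc[members]
    sd = data.std(axis=1, ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(
            f"dropping zero-variance genes from {gene_set.name!r}: {degenerate}",
            stacklevel=2,
        )
        data = data.drop(index=degenerate)
        if data.empty:
            raise ValueError(f"gene set {gene_set.name!r} has no variable genes")
        sd = sd.drop(index=degenerate)
    z = data.sub(data.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0)
    if combined:
        score = score * np.sqrt(len(data))
    score.name = gene_set.name
    return score


def scale_unit(scores: pd.Series) -> pd.Series:
    """Min-max rescaling to [0, 1] for display; order-preserving."""
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        warnings.warn("constant scores: scaled values set to 0.5", stacklevel=2)
        return pd.Series(0.5, index=scores.index, name=scores.name)
    return (scores - lo) / (hi - lo)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(parts[0], parts[2:], provenance=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.provenance or "."] + list(s.members)) + "\n")
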