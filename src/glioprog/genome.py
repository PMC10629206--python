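"""Reference genome container for desk-scale analyses.

Sequences live in memory as plain ``bytes`` over the ACGT alphabet; all
coordinates in this package are 0-based half-open unless a file format
dictates otherwise (VCF positions are written 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")
_ALPHABET = frozenset(b"ACGT")


def reverse_complement(seq: str | bytes) -> str:
    """Reverse complement of an ACGT sequence (case preserved per base)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return seq.translate(_COMPLEMENT)[::-1].decode()


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


@dataclass
class ReferenceGenome:
    """A set of named chromosomes restricted to the ACGT alphabet.

    ``chromosomes`` maps name -> mutable ``bytearray`` so the simulator can
    plant sequence features (e.g. junction microhomologies) in place.
    """

    chromosomes: dict[str, bytearray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coerced = {}
        for name, seq in self.chromosomes.items():
            if isinstance(seq, str):
                seq = bytearray(seq.encode())
            else:
                seq = bytearray(seq)
            if len(seq) == 0:
                raise ConfigurationError(f"chromosome {name!r} is empty")
            if not _ALPHABET.issuperset(seq.upper()):
                raise ConfigurationError(
                    f"chromosome {name!r} contains non-ACGT characters"
                )
            coerced[name] = bytearray(seq.upper())
        self.chromosomes = coerced

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def sequence(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        """Sequence of ``chrom[start:end]`` (0-based half-open)."""
        seq = self.chromosomes[chrom]
        if end is None:
            end = len(seq)
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"{chrom}:{start}-{end} out of bounds (len {len(seq)})")
        return seq[start:end].decode()

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence(chrom, pos, pos + 1)

    def replace(self, chrom: str, start: int, replacement: str) -> None:
        """Overwrite bases in place (used to plant simulated features)."""
        end = start + len(replacement)
        seq = self.chromosomes[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(f"{chrom}:{start}-{end} out of bounds")
        seq[start:end] = replacement.upper().encode()

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                text = seq.decode()
                for i in range(0, len(text), width):
                    fh.write(text[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()
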