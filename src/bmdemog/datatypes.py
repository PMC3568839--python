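"""Core containers for diploid microsatellite genotypes and mtDNA alignments.

The study system is the Bering-Chukchi-Beaufort Seas (BCB) stock of bowhead
whales: 324 individuals typed at 22 autosomal microsatellite loci and a
subset of 168 individuals sequenced for a 2494-bp concatenation of three
mitochondrial regions (HVRI, Cytb, ND1).  These containers carry the minimal
structure the downstream statistics need: unordered diploid allele pairs
with an explicit per-cell missing mask, and equal-length sequences with a
per-gene partition map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "SequenceAlignment",
    "LocusSummary",
    "MISSING",
]

#: Sentinel allele value marking a missing call (GENEPOP "000"/"00" code).
MISSING = 0


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls for ``individuals x loci``.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` with integer allele
    sizes (repeat-unit scaled or raw fragment sizes; the statistics only care
    about identity, and about step distances under stepwise mutation models).
    A call is missing iff either allele equals :data:`MISSING`; both alleles
    of a missing call are stored as :data:`MISSING`.
    """

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n_ind, n_loc = len(self.individuals), len(self.loci)
        if n_ind < 1 or n_loc < 1:
            raise ValueError("GenotypeMatrix needs at least one individual and one locus")
        if self.alleles.shape != (n_ind, n_loc, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"({n_ind}, {n_loc}, 2)"
            )
        if len(set(self.loci)) != n_loc:
            raise ValueError("duplicate locus names")
        # normalize: half-missing calls become fully missing, pairs unordered
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING
        self.alleles = np.sort(self.alleles, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)``; True where the call is missing."""
        return (self.alleles == MISSING).all(axis=2)

    def locus_calls(self, locus: int | str) -> np.ndarray:
        """Non-missing allele pairs at one locus, shape ``(m, 2)``."""
        j = self.loci.index(locus) if isinstance(locus, str) else locus
        calls = self.alleles[:, j, :]
        return calls[~self.missing_mask[:, j]]

    def allele_counts(self, locus: int | str) -> dict[int, int]:
        """Allele -> count of gene copies among non-missing calls."""
        calls = self.locus_calls(locus)
        vals, counts = np.unique(calls.ravel(), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class SequenceAlignment:
    """Haplotype alignment over ``{A, C, G, T, -, N}`` with gene partitions.

    ``partitions`` maps gene name to a 0-based half-open column interval;
    intervals must be disjoint and jointly cover the alignment.  The study
    layout is HVRI/Cytb/ND1 of lengths 397/1140/957 (2494 columns total).
    """

    ids: list[str]
    sequences: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    ALPHABET = frozenset("ACGT-N")

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if not self.sequences:
            raise ValueError("empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        for sid, s in zip(self.ids, self.sequences):
            if len(s) != L:
                raise ValueError(f"ragged alignment: record {sid!r} has length {len(s)} != {L}")
            bad = set(s) - self.ALPHABET
            if bad:
                raise ValueError(f"record {sid!r} contains invalid symbols {sorted(bad)}")
        if not self.partitions:
            self.partitions = {"all": (0, L)}
        ivals = sorted(self.partitions.values())
        if ivals[0][0] != 0 or ivals[-1][1] != L:
            raise ValueError("partitions do not cover the alignment")
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if a1 != b0:
                raise ValueError("partitions are not disjoint and contiguous")
        for a0, a1 in ivals:
            if not 0 <= a0 < a1:
                raise ValueError("empty or inverted partition interval")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def as_array(self) -> np.ndarray:
        """Alignment as a byte matrix, shape ``(n, length)``."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(
            self.n, self.length
        )


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus summary: allele count, heterozygosities, sample size.

    ``He`` is the unbiased (sample-size corrected) gene diversity
    ``n/(n-1) * (1 - sum p_i^2)`` over ``n_genes`` gene copies.
    """

    name: str
    k: int
    Ho: float
    He: float
    n_genes: int
    allele_freqs: tuple[float, ...] | None = None
    hwe_p: float | None = None
    p_homozygote_excess: float | None = None
    null_freq: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("allele count must be >= 1")
        if not (0.0 <= self.Ho <= 1.0 and 0.0 <= self.He <= 1.0):
            raise ValueError("heterozygosities must lie in [0, 1]")
        if self.k == 1 and self.He != 0.0:
            raise ValueError("monomorphic locus must have He = 0")
        if self.allele_freqs is not None and len(self.allele_freqs) != self.k:
            raise ValueError("allele_freqs length must equal k")
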