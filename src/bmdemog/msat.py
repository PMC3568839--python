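"""Per-locus and dataset-level microsatellite summary statistics.

Gene diversity uses Nei's unbiased estimator throughout (the sample-size
corrected form standard in GENEPOP and in heterozygosity-excess bottleneck
software), Hardy-Weinberg equilibrium is tested with a Monte-Carlo exact
test on random re-pairings of the observed gene copies, and null-allele
frequencies follow Chakraborty's heterozygote-deficit estimator
``(He - Ho) / (He + Ho)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np

from .datatypes import GenotypeMatrix, LocusSummary

__all__ = [
    "gene_diversity",
    "observed_heterozygosity",
    "null_allele_freq",
    "hwe_exact_test",
    "summarize_dataset",
    "DatasetSummary",
]


def gene_diversity(allele_counts) -> float:
    """Unbiased expected heterozygosity ``n/(n-1) * (1 - sum p_i^2)``.

    Parameters
    ----------
    allele_counts
        Integer spectrum of gene-copy counts per allele (mapping values or a
        sequence); total gene copies must be at least 2.
    """
    counts = np.asarray(
        list(allele_counts.values()) if isinstance(allele_counts, dict) else allele_counts,
        dtype=float,
    )
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity requires at least 2 gene copies")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Fraction of non-missing diploid calls with two distinct alleles.

    ``calls`` is an ``(m, 2)`` array of allele pairs (no missing rows), e.g.
    from :meth:`GenotypeMatrix.locus_calls`.
    """
    calls = np.asarray(calls)
    if calls.ndim != 2 or calls.shape[0] == 0:
        raise ValueError("need at least one non-missing genotype")
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def null_allele_freq(Ho: float, He: float) -> float:
    """Chakraborty's null-allele frequency estimate ``(He - Ho)/(He + Ho)``.

    Negative values (heterozygote excess) are legitimate output and are
    reported as-is.
    """
    if He + Ho <= 0:
        raise ValueError("null-allele estimate undefined when He + Ho = 0")
    return (He - Ho) / (He + Ho)


def _table_log_prob(pair_codes: np.ndarray, k: int, log_const: float) -> float:
    """Log Levene probability of the genotype table given the allele counts."""
    codes, counts = np.unique(pair_codes, return_counts=True)
    het = int(np.sum((codes // k != codes % k) * counts))
    log_prod_factorials = float(np.sum([lgamma(c + 1) for c in counts]))
    return log_const + het * np.log(2.0) - log_prod_factorials


def hwe_exact_test(
    calls: np.ndarray,
    n_montecarlo: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo exact test for Hardy-Weinberg equilibrium at one locus.

    The observed gene copies are randomly re-paired ``n_montecarlo`` times;
    the p-value is the fraction of pairings whose conditional (Levene)
    probability is less than or equal to that of the observed table.  A
    monomorphic locus returns 1.0 by convention.

    ``calls`` is an ``(m, 2)`` array of non-missing allele pairs.
    """
    calls = np.asarray(calls)
    genes = calls.ravel()
    alleles, allele_counts = np.unique(genes, return_counts=True)
    k = len(alleles)
    if k < 2:
        return 1.0
    if n_montecarlo < 1000:
        raise ValueError("use at least 1000 Monte-Carlo pairings")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recode = np.searchsorted(alleles, genes)
    n = calls.shape[0]
    # constant part of the Levene log-probability (depends only on counts)
    log_const = (
        lgamma(n + 1)
        + float(np.sum([lgamma(c + 1) for c in allele_counts]))
        - lgamma(2 * n + 1)
    )

    def codes_of(g: np.ndarray) -> np.ndarray:
        pairs = np.sort(g.reshape(n, 2), axis=1)
        return pairs[:, 0] * k + pairs[:, 1]

    obs_logp = _table_log_prob(codes_of(recode), k, log_const)
    hits = 0
    g = recode.copy()
    for _ in range(n_montecarlo):
        rng.shuffle(g)
        if _table_log_prob(codes_of(g), k, log_const) <= obs_logp + 1e-12:
            hits += 1
    return hits / n_montecarlo


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset-level roll-up of per-locus summaries."""

    loci: tuple[LocusSummary, ...]
    mean_k: float
    mean_Ho: float
    mean_He: float


def summarize_dataset(
    matrix: GenotypeMatrix,
    n_montecarlo: int = 10000,
    seed: int | None = None,
) -> DatasetSummary:
    """Compute the full per-locus summary table from raw genotypes."""
    rng = np.random.default_rng(seed)
    out: list[LocusSummary] = []
    for j, locus in enumerate(matrix.loci):
        calls = matrix.locus_calls(j)
        if calls.shape[0] == 0:
            raise ValueError(f"locus {locus!r} has no non-missing genotypes")
        counts = matrix.allele_counts(j)
        he = gene_diversity(counts) if sum(counts.values()) >= 2 else 0.0
        ho = observed_heterozygosity(calls)
        total = sum(counts.values())
        freqs = tuple(c / total for c in counts.values())
        out.append(
            LocusSummary(
                name=locus,
                k=len(counts),
                Ho=ho,
                He=he,
                n_genes=total,
                allele_freqs=freqs,
                hwe_p=hwe_exact_test(calls, n_montecarlo, rng),
                null_freq=null_allele_freq(ho, he) if he + ho > 0 else None,
            )
        )
    return DatasetSummary(
        loci=tuple(out),
        mean_k=float(np.mean([s.k for s in out])),
        mean_Ho=float(np.mean([s.Ho for s in out])),
        mean_He=float(np.mean([s.He for s in out])),
    )
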