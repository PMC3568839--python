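"""Synthetic data generators.

Two modes:

* target-driven genotype tables — per-locus (allele count, expected
  heterozygosity) targets such as the published 22-locus panel, realized by
  solving a geometric-decay frequency profile for each locus and sampling
  diploid genotypes under Hardy-Weinberg proportions (with an optional
  null-allele injection mode for exercising the null-frequency estimator);
* scenario-driven sequence alignments — coalescent samples under a sudden
  expansion with known (theta0, theta1, tau), for validating the mismatch
  machinery on data with known truth.
"""

from __future__ import annotations

import numpy as np

from .coalescent import DemographicScenario, simulate_genealogy
from .datatypes import MISSING, GenotypeMatrix, SequenceAlignment
from .fixture import load_table2_fixture

__all__ = [
    "feasible_he",
    "solve_locus_frequencies",
    "generate_genotypes_matching",
    "generate_table2_like",
    "generate_expansion_alignment",
]


def feasible_he(k: int, n_genes: int) -> float:
    """Upper bound of unbiased He for k alleles in n gene copies:
    ``(k-1)/k * n/(n-1)`` (equifrequent alleles)."""
    return (k - 1) / k * n_genes / (n_genes - 1)


def solve_locus_frequencies(k: int, target_he: float, n_genes: int,
                            floor: float | None = None) -> np.ndarray:
    """Allele frequencies with exactly ``k`` alleles whose population gene
    diversity matches ``target_he`` (unbiased scale).

    Uses a geometric-decay profile ``p_i ~ r**i`` on top of a small floor
    frequency (so rare alleles survive sampling); the decay rate r is solved
    by bisection — diversity is monotone in r.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        if target_he != 0:
            raise ValueError("monomorphic locus forces He = 0")
        return np.ones(1)
    cap = feasible_he(k, n_genes)
    # lowest diversity with k segregating alleles: one near-fixed allele
    low = n_genes / (n_genes - 1) * (
        1.0 - ((n_genes - k + 1) ** 2 + (k - 1)) / n_genes**2
    )
    if not low - 1e-12 <= target_he <= cap + 1e-12:
        raise ValueError(
            f"target He={target_he} infeasible for k={k}, n={n_genes} "
            f"(feasible range [{low:.4f}, {cap:.4f}])"
        )
    target_plain = target_he * (n_genes - 1) / n_genes
    floor = 6.0 / n_genes if floor is None else floor
    floor = min(floor, 1.0 / k)

    def diversity(r: float) -> float:
        g = r ** np.arange(k)
        p = floor + (1 - k * floor) * g / g.sum()
        return 1.0 - np.sum(p * p)

    lo, hi = 1e-9, 1.0
    if diversity(hi) < target_plain:  # equifrequent still below target: cap
        r = 1.0
    elif diversity(lo) > target_plain:
        r = lo
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if diversity(mid) < target_plain:
                lo = mid
            else:
                hi = mid
        r = 0.5 * (lo + hi)
    g = r ** np.arange(k)
    return floor + (1 - k * floor) * g / g.sum()


def generate_genotypes_matching(
    targets: list[tuple[int, float]],
    n_individuals: int,
    seed: int | np.random.Generator | None = None,
    he_tol: float = 0.02,
    null_freqs: list[float] | None = None,
    max_tries: int = 200,
) -> GenotypeMatrix:
    """Diploid genotype table matching per-locus (k, He) targets.

    Genotypes are drawn under Hardy-Weinberg proportions; a draw is retried
    until the realized allele count is exactly k and the realized unbiased
    gene diversity is within ``he_tol`` of the target.  ``null_freqs``
    optionally adds a non-amplifying allele per locus: null homozygotes
    become missing calls and null heterozygotes appear as visible
    homozygotes (the signal the Chakraborty estimator detects).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_genes = 2 * n_individuals
    calls = np.empty((n_individuals, len(targets), 2), dtype=np.int64)
    for j, (k, he) in enumerate(targets):
        freqs = solve_locus_frequencies(k, he, n_genes)
        q_null = null_freqs[j] if null_freqs else 0.0
        p = np.append(freqs * (1 - q_null), q_null) if q_null > 0 else freqs
        for attempt in range(max_tries):
            genes = rng.choice(len(p), size=(n_individuals, 2), p=p)
            vis_genes = genes[genes < k] if q_null > 0 else genes.ravel()
            counts = np.bincount(vis_genes, minlength=k)
            if (counts == 0).any():
                continue
            tot = counts.sum()
            he_real = tot / (tot - 1) * (1 - np.sum((counts / tot) ** 2))
            if abs(he_real - he) <= he_tol:
                break
        else:
            raise RuntimeError(
                f"could not realize (k={k}, He={he}) within tolerance "
                f"{he_tol} after {max_tries} draws"
            )
        out = genes + 1  # allele codes are 1-based; 0 is the missing code
        if q_null > 0:
            null_mask = genes == k
            both_null = null_mask.all(axis=1)
            one_null = null_mask.any(axis=1) & ~both_null
            vis = np.where(null_mask[one_null][:, 0], genes[one_null][:, 1], genes[one_null][:, 0])
            out[one_null] = (vis + 1)[:, None]
            out[both_null] = MISSING
        calls[:, j, :] = out
    return GenotypeMatrix(
        individuals=[f"synth{i + 1}" for i in range(n_individuals)],
        loci=[f"locus{j + 1}" for j in range(len(targets))],
        alleles=calls,
    )


def generate_table2_like(
    seed: int | np.random.Generator | None = None,
    n_individuals: int | None = None,
) -> GenotypeMatrix:
    """Genotype table with the published panel's per-locus (k, He) profile."""
    fx = load_table2_fixture()
    return generate_genotypes_matching(
        [(s.k, s.He) for s in fx.loci],
        n_individuals or fx.n_individuals,
        seed,
    )


_BASES = "ACGT"
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}


def generate_expansion_alignment(
    theta0: float,
    theta1: float,
    tau: float,
    n: int,
    L: int,
    seed: int | np.random.Generator | None = None,
    kappa: float = 20.0,
) -> SequenceAlignment:
    """Coalescent sample under a sudden expansion with known parameters.

    The genealogy is simulated directly in mutational units (pair
    coalescence hazard 1/theta, mutation intensity 1/2 per branch unit);
    each mutation hits a uniformly chosen site and applies one HKY-style
    substitution (transition probability kappa/(kappa+2)).  With L well
    above the expected mutation count this reproduces the
    infinite-sites mismatch model the expansion fit assumes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = 1e-9
    if tau > 0:
        scenario = DemographicScenario(
            epochs=((0.0, max(theta1, eps) / 2), (tau, max(theta0, eps) / 2))
        )
    else:
        scenario = DemographicScenario.constant(max(theta0, eps) / 2)
    tree = simulate_genealogy(n, scenario, 1.0, rng)
    m = rng.poisson(0.5 * tree.branch_lengths())
    states = np.empty((2 * n - 1, L), dtype=np.int8)
    states[2 * n - 2] = rng.integers(0, 4, L)
    p_ts = kappa / (kappa + 2.0)
    for i in range(2 * n - 3, -1, -1):
        states[i] = states[tree.parent[i]]
        for _ in range(m[i]):
            site = rng.integers(L)
            b = states[i, site]
            if rng.random() < p_ts:
                states[i, site] = _TS_PARTNER[int(b)]
            else:
                tv = [x for x in range(4) if x != b and x != _TS_PARTNER[int(b)]]
                states[i, site] = tv[rng.integers(2)]
    seqs = ["".join(_BASES[b] for b in row) for row in states[:n]]
    return SequenceAlignment(
        ids=[f"hap{i + 1}" for i in range(n)], sequences=seqs
    )
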