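"""Post-hoc heterozygosity-loss simulations.

Answers the question the classical bottleneck battery leaves open: how much
gene diversity *should* the commercial-whaling bottleneck have erased?  An
ancestral population at mutation-drift equilibrium (SMM, theta =
4*Ne_ancestral*mu) is reduced to Ne_contemporary for a given number of
generations; the bottleneck phase is simulated forward in time by explicit
Wright-Fisher resampling of gene copies with mutation, the deep (ancestral)
history by the coalescent.  The study's grid crosses contemporary sizes
{50, 500, 1000} with durations {5, 50, 500} generations under ancestral
Ne = 10,000 and mu = 1e-4; the whaling episode corresponds to roughly
Ne 1000 for 1.3-5 generations.

The expected drift-only decay is ``H_t = H_0 * (1 - 1/(2*Ne))**t``; mutation
adds a small replenishment floor that matters only when ``mu * t`` is no
longer negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import MsatMutationModel, equilibrium_msat_stats
from . import _kernels

__all__ = [
    "HetLossScenario",
    "simulate_het_trajectory",
    "expected_het_retention",
    "fig5_grid",
    "het_loss_boxstats",
]


@dataclass(frozen=True)
class HetLossScenario:
    """One ancestral -> contemporary size-change experiment."""

    ne_contemporary: int
    generations: int
    ne_ancestral: int = 10000
    mu: float = 1e-4
    n_loci: int = 22
    n_sampled: int = 324

    def __post_init__(self) -> None:
        if min(self.ne_contemporary, self.ne_ancestral, self.n_loci, self.n_sampled) < 1:
            raise ValueError("sizes and counts must be positive")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")


def expected_het_retention(ne: float, t: float) -> float:
    """Drift-only expected fraction of heterozygosity retained:
    ``(1 - 1/(2*Ne))**t``."""
    if ne < 1 or t < 0:
        raise ValueError("need Ne >= 1 and t >= 0")
    return float((1.0 - 1.0 / (2.0 * ne)) ** t)


def _sample_gene_diversity(states: np.ndarray) -> np.ndarray:
    """Unbiased gene diversity per row of an (R, m) allele-state matrix."""
    s = np.sort(states, axis=1)
    m = s.shape[1]
    run_start = np.ones(s.shape, dtype=bool)
    run_start[:, 1:] = s[:, 1:] != s[:, :-1]
    starts = np.flatnonzero(run_start.ravel())
    lengths = np.diff(starts, append=s.size).astype(float)
    # every row's first column starts a run, so runs never span rows
    rows = starts // m
    sumsq = np.bincount(rows, weights=lengths**2, minlength=s.shape[0])
    return m / (m - 1.0) * (1.0 - sumsq / (float(m) * m))


def simulate_het_trajectory(
    scenario: HetLossScenario,
    n_reps: int = 1000,
    seed: int | None = None,
    block: int = 6000,
) -> np.ndarray:
    """Sampled-dataset expected heterozygosity after the bottleneck, one
    value per replicate (mean unbiased gene diversity over the loci).

    The contemporary population's ``2*Ne_contemporary`` gene copies start
    from an equilibrium coalescent sample (SMM at theta =
    4*Ne_ancestral*mu), drift forward ``generations`` rounds of multinomial
    resampling with SMM mutation at ``mu``, and are then sampled down to
    ``2 * min(n_sampled, Ne_contemporary)`` copies.
    """
    rng = np.random.default_rng(seed)
    theta = 4.0 * scenario.ne_ancestral * scenario.mu
    pop = 2 * scenario.ne_contemporary
    n_sample = 2 * min(scenario.n_sampled, scenario.ne_contemporary)
    smm = MsatMutationModel.smm()
    total_rows = n_reps * scenario.n_loci
    he_rows = np.empty(total_rows)
    for lo in range(0, total_rows, block):
        hi = min(lo + block, total_rows)
        R = hi - lo
        starts = np.zeros((R, 1))
        sizes = np.full((R, 1), 0.5)
        mu_arr = np.full(R, theta / 2.0)
        state = _kernels.sim_msat_tips(
            pop, starts, sizes, 1.0, mu_arr, smm.code,
            np.zeros(R), np.full(R, 0.5), int(rng.integers(2**31)),
        ).astype(np.int32)
        for _ in range(scenario.generations):
            idx = rng.integers(0, pop, size=(R, pop))
            state = np.take_along_axis(state, idx, axis=1)
            n_mut = rng.poisson(scenario.mu * R * pop)
            if n_mut:
                rr = rng.integers(0, R, n_mut)
                cc = rng.integers(0, pop, n_mut)
                state[rr, cc] += rng.choice((-1, 1), n_mut).astype(np.int32)
        he_rows[lo:hi] = _sample_gene_diversity(state[:, :n_sample])
    return he_rows.reshape(n_reps, scenario.n_loci).mean(axis=1)


def fig5_grid() -> list[HetLossScenario]:
    """The study's nine (ancestral 10,000 -> contemporary, duration)
    combinations; combination 7 (1000, 5) is the one closest to the
    bowhead whaling episode."""
    return [
        HetLossScenario(ne_contemporary=ne, generations=t)
        for ne in (50, 500, 1000)
        for t in (5, 50, 500)
    ]


def het_loss_boxstats(
    grid: list[HetLossScenario] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Box-plot statistics (min, quartiles, max) of sampled heterozygosity
    for each grid combination, plus the drift-only retention prediction."""
    rng = np.random.default_rng(seed)
    grid = grid if grid is not None else fig5_grid()
    rows = []
    for sc in grid:
        he = simulate_het_trajectory(sc, n_reps, int(rng.integers(2**31)))
        q = np.percentile(he, [0, 25, 50, 75, 100])
        rows.append(
            {
                "ne_contemporary": sc.ne_contemporary,
                "generations": sc.generations,
                "he_min": q[0], "he_q25": q[1], "he_median": q[2],
                "he_q75": q[3], "he_max": q[4], "he_mean": he.mean(),
                "expected_retention": expected_het_retention(
                    sc.ne_contemporary, sc.generations
                ),
            }
        )
    return pd.DataFrame(rows)
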