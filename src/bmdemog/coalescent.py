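"""Coalescent simulation under piecewise-constant demography.

Two layers:

* a readable single-genealogy simulator (:func:`simulate_genealogy`,
  :func:`mutate_msat`, :func:`mutate_sequence`, :func:`simulate_dataset`)
  used for sequence data, synthetic datasets, and as a cross-check;
* batched numba kernels (:func:`batch_msat_stats`,
  :func:`equilibrium_msat_stats`) that drive the bottleneck battery and the
  ABC reference tables, where millions of 648-gene genealogies are needed.

Time is measured backward in generations (0 = sampling).  Within an epoch of
diploid size ``N``, ``c`` lineages coalesce at rate ``c(c-1)/2`` per
``2*N*s`` generations, where ``s`` is the marker's effective-copy scaling:
1 for autosomes, 1/4 for mtDNA under the study's 1:1 sex ratio (haploid and
maternally inherited).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .datatypes import GenotypeMatrix, SequenceAlignment

__all__ = [
    "DemographicScenario",
    "MsatMutationModel",
    "SeqMutationModel",
    "Genealogy",
    "simulate_genealogy",
    "mutate_msat",
    "mutate_sequence",
    "simulate_dataset",
    "batch_msat_stats",
    "equilibrium_msat_stats",
    "AUTOSOMAL_SCALING",
    "MTDNA_SCALING",
]

AUTOSOMAL_SCALING = 1.0
#: mtDNA effective copy number is 1/4 of autosomal under a 1:1 sex ratio.
MTDNA_SCALING = 0.25

GENERATION_YEARS = 52.0  # bowhead whale generation time in years

_FAMILY_CODE = {"SMM": _kernels.SMM, "IAM": _kernels.IAM, "TPM": _kernels.GEN, "GSM": _kernels.GEN}


@dataclass(frozen=True)
class DemographicScenario:
    """Piecewise-constant diploid effective sizes, backward in time.

    ``epochs`` is an ordered list of ``(start_generation, Ne)`` with start
    times strictly increasing from 0; the last epoch extends to infinity.
    """

    epochs: tuple[tuple[float, float], ...]
    generation_years: float = GENERATION_YEARS

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("scenario needs at least one epoch")
        starts = [e[0] for e in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        # fractional sizes are allowed so statistics modules can express
        # scenarios directly in coalescent/mutational units
        if any(e[1] <= 0 for e in self.epochs):
            raise ValueError("all effective sizes must be positive")

    @classmethod
    def constant(cls, ne: float, generation_years: float = GENERATION_YEARS) -> "DemographicScenario":
        return cls(epochs=((0.0, float(ne)),), generation_years=generation_years)

    @classmethod
    def from_toml(cls, path) -> "DemographicScenario":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        epochs = tuple((float(e["start"]), float(e["ne"])) for e in cfg["epochs"])
        if any(ne < 1 for _, ne in epochs):
            raise ValueError(f"{path}: demographic effective sizes must be >= 1")
        return cls(epochs=epochs, generation_years=float(cfg.get("generation_years", GENERATION_YEARS)))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        starts = np.array([e[0] for e in self.epochs], dtype=np.float64)
        sizes = np.array([e[1] for e in self.epochs], dtype=np.float64)
        return starts, sizes

    def size_at(self, generation: float) -> float:
        starts, sizes = self.arrays()
        return float(sizes[np.searchsorted(starts, generation, side="right") - 1])


@dataclass(frozen=True)
class MsatMutationModel:
    """Microsatellite mutation model: IAM, SMM, TPM or GSM.

    ``p_multistep`` is the fraction of mutations that are multi-step
    (geometric step sizes with parameter ``geom_p``).  The two-phase model
    used for bottleneck testing is parameterized by its multi-step fraction
    and multi-step variance; the generalized stepwise model draws every step
    from the geometric (DIYABC-era default shape 0.22).
    """

    family: str
    rate: float
    p_multistep: float = 0.0
    geom_p: float = 0.22

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_CODE:
            raise ValueError(f"unknown mutation model family {self.family!r}")
        if self.rate < 0:
            raise ValueError("mutation rate must be non-negative")
        if not 0.0 <= self.p_multistep <= 1.0:
            raise ValueError("p_multistep must lie in [0, 1]")
        if not 0.0 < self.geom_p <= 1.0:
            raise ValueError("geom_p must lie in (0, 1]")

    @property
    def code(self) -> int:
        return _FAMILY_CODE[self.family]

    @classmethod
    def iam(cls, rate: float = 1e-4) -> "MsatMutationModel":
        return cls("IAM", rate)

    @classmethod
    def smm(cls, rate: float = 1e-4) -> "MsatMutationModel":
        return cls("SMM", rate)

    @classmethod
    def tpm(cls, pct_multistep: float, variance: float = 30.0, rate: float = 1e-4) -> "MsatMutationModel":
        """Two-phase model with ``pct_multistep`` % multi-step mutations.

        The geometric parameter is solved from the requested multi-step
        variance: a symmetric +/- geometric step of parameter p has variance
        ``(2 - p) / p**2``.
        """
        p = (-1.0 + np.sqrt(1.0 + 8.0 * variance)) / (2.0 * variance)
        return cls("TPM", rate, p_multistep=pct_multistep / 100.0, geom_p=float(p))

    @classmethod
    def gsm(cls, rate: float = 1e-4, continuation_p: float = 0.22) -> "MsatMutationModel":
        """Generalized stepwise model: every step size is geometric.

        ``continuation_p`` is the geometric parameter in the convention of
        the ABC microsatellite literature (probability of lengthening the
        jump by one more repeat), so the mean step is
        ``1/(1 - continuation_p)`` — 1.28 repeats at the 0.22 default.
        """
        return cls("GSM", rate, p_multistep=1.0, geom_p=1.0 - continuation_p)


@dataclass(frozen=True)
class SeqMutationModel:
    """HKY substitution model with invariant sites and gamma rate variation.

    ``rate`` is the expected number of substitutions per (variable-class)
    site per generation before the invariant/gamma modifiers; the model used
    for the study's mtDNA is HKY + I(0.5) + G(0.05).
    """

    rate: float
    kappa: float = 20.0
    p_invariant: float = 0.5
    gamma_shape: float = 0.05
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must lie in [0, 1)")


@dataclass
class Genealogy:
    """A coalescent tree: ``parent[i]`` and ``time[i]`` (generations) for
    nodes ``0..2n-2``; tips are ``0..n-1``, the root is ``2n-2`` and node
    ids increase with coalescence time."""

    n: int
    parent: np.ndarray
    time: np.ndarray

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length (generations) of the branch above each non-root node."""
        return self.time[self.parent[: 2 * self.n - 2]] - self.time[: 2 * self.n - 2]


def simulate_genealogy(
    n_lineages: int,
    scenario: DemographicScenario,
    marker_scaling: float = AUTOSOMAL_SCALING,
    seed: int | np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one Kingman genealogy under the scenario.

    Waiting times are exact exponentials with epoch-boundary carry-over: the
    residual standard-exponential deviate left at a boundary is re-scaled by
    the next epoch's coalescence rate.
    """
    n = int(n_lineages)
    if n < 2:
        raise ValueError("need at least 2 lineages")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts, sizes = scenario.arrays()
    n_epochs = len(starts)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1, dtype=np.float64)
    active = list(range(n))
    t = 0.0
    ep = 0
    for step in range(n - 1):
        j = n - step
        pairs = 0.5 * j * (j - 1)
        e = rng.exponential()
        while ep < n_epochs - 1 and t >= starts[ep + 1]:
            ep += 1
        while True:
            rate = pairs / (2.0 * sizes[ep] * marker_scaling)
            if ep < n_epochs - 1:
                cap = (starts[ep + 1] - t) * rate
                if e > cap:
                    e -= cap
                    t = starts[ep + 1]
                    ep += 1
                    continue
            t += e / rate
            break
        node = n + step
        time[node] = t
        a, b = rng.choice(j, size=2, replace=False)
        parent[active[a]] = node
        parent[active[b]] = node
        for idx in sorted((a, b), reverse=True):
            del active[idx]
        active.append(node)
    return Genealogy(n=n, parent=parent, time=time)


def mutate_msat(
    tree: Genealogy,
    model: MsatMutationModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Drop microsatellite mutations on a genealogy; returns tip allele states.

    The root allele is 0 (size-zero reference for stepwise families, label 0
    for the IAM); each branch receives a Poisson number of mutations with
    mean ``rate * branch_length``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n
    values = np.zeros(2 * n - 1, dtype=np.int64)
    m = rng.poisson(model.rate * tree.branch_lengths())
    for i in range(2 * n - 3, -1, -1):
        pv = values[tree.parent[i]]
        if m[i] == 0:
            values[i] = pv
        elif model.family == "IAM":
            values[i] = i + 1
        elif model.family == "SMM":
            values[i] = pv + 2 * rng.binomial(m[i], 0.5) - m[i]
        else:
            multi = rng.random(m[i]) < model.p_multistep
            steps = np.where(multi, rng.geometric(model.geom_p, m[i]), 1)
            signs = rng.choice((-1, 1), size=m[i])
            values[i] = pv + int(np.sum(steps * signs))
    return values[:n]


def _hky_jump_tables(model: SeqMutationModel) -> np.ndarray:
    """Cumulative target probabilities for one substitution event, per base.

    Bases are coded A=0, C=1, G=2, T=3; transitions are A<->G and C<->T.
    From base i the embedded jump chain moves to j != i with probability
    proportional to ``kappa * pi_j`` (transition) or ``pi_j`` (transversion).
    """
    pi = np.asarray(model.base_freqs)
    transition_partner = {0: 2, 1: 3, 2: 0, 3: 1}
    cum = np.zeros((4, 4))
    for i in range(4):
        w = np.array([
            0.0 if j == i else (model.kappa if j == transition_partner[i] else 1.0) * pi[j]
            for j in range(4)
        ])
        cum[i] = np.cumsum(w / w.sum())
    return cum


def mutate_sequence(
    tree: Genealogy,
    model: SeqMutationModel,
    n_sites: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate sequences at the tips; returns an ``(n, n_sites)`` int8 array
    with bases coded A=0, C=1, G=2, T=3.

    Each site is invariant with probability ``p_invariant``; otherwise its
    rate is multiplied by a Gamma(shape, mean 1) deviate.  Substitution
    events per branch-site are Poisson with the HKY embedded jump chain
    applied per event.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n
    pi = np.asarray(model.base_freqs)
    mult = np.where(
        rng.random(n_sites) < model.p_invariant,
        0.0,
        rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=n_sites),
    )
    cum = _hky_jump_tables(model)
    states = np.empty((2 * n - 1, n_sites), dtype=np.int8)
    root = 2 * n - 2
    states[root] = rng.choice(4, size=n_sites, p=pi)
    blen = tree.branch_lengths()
    events = rng.poisson(np.outer(blen, model.rate * mult))
    for i in range(root - 1, -1, -1):
        states[i] = states[tree.parent[i]]
        hit = np.nonzero(events[i])[0]
        for s in hit:
            b = states[i, s]
            for _ in range(events[i, s]):
                b = int(np.searchsorted(cum[b], rng.random(), side="right"))
            states[i, s] = b
    return states[:n]


_BASES = np.array([b"A", b"C", b"G", b"T"])


def sequence_array_to_alignment(states: np.ndarray, ids: list[str] | None = None,
                                partitions: dict[str, tuple[int, int]] | None = None) -> SequenceAlignment:
    """Wrap an integer-coded base matrix as a :class:`SequenceAlignment`."""
    n = states.shape[0]
    ids = ids or [f"hap{i + 1}" for i in range(n)]
    seqs = ["".join(_BASES[row].astype("U1")) for row in states]
    return SequenceAlignment(ids=ids, sequences=seqs, partitions=partitions or {})


def simulate_dataset(
    scenario: DemographicScenario,
    n_individuals: int,
    msat_models: list[MsatMutationModel],
    seq_model: SeqMutationModel | None = None,
    n_sites: int = 2494,
    n_sequences: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SequenceAlignment | None]:
    """Simulate a full dataset: one independent genealogy per microsatellite
    locus (2n gene copies, randomly paired into diploids) and optionally an
    mtDNA alignment (one sequence per individual, 1/4 copy-number scaling)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_genes = 2 * n_individuals
    starts, sizes = scenario.arrays()
    calls = np.empty((n_individuals, len(msat_models), 2), dtype=np.int64)
    for j, model in enumerate(msat_models):
        tips = _kernels.sim_msat_tips(
            n_genes,
            np.tile(starts, (1, 1)),
            np.tile(sizes, (1, 1)),
            AUTOSOMAL_SCALING,
            np.array([model.rate]),
            model.code,
            np.array([model.p_multistep]),
            np.array([model.geom_p]),
            int(rng.integers(2**31)),
        )[0]
        rng.shuffle(tips)
        # offset so GENEPOP-style positive codes survive stepwise excursions
        calls[:, j, :] = (tips - tips.min() + 1).reshape(n_individuals, 2)
    matrix = GenotypeMatrix(
        individuals=[f"ind{i + 1}" for i in range(n_individuals)],
        loci=[f"L{j + 1}" for j in range(len(msat_models))],
        alleles=calls,
    )
    alignment = None
    if seq_model is not None:
        n_seq = n_sequences or n_individuals
        tree = simulate_genealogy(n_seq, scenario, MTDNA_SCALING, rng)
        states = mutate_sequence(tree, seq_model, n_sites, rng)
        alignment = sequence_array_to_alignment(states)
    return matrix, alignment


def batch_msat_stats(
    n_genes: int,
    epoch_starts: np.ndarray,
    epoch_sizes: np.ndarray,
    mu: np.ndarray,
    model: MsatMutationModel,
    seed: int,
    scale: float = AUTOSOMAL_SCALING,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched (allele count, unbiased He) for R independent loci.

    ``epoch_starts``/``epoch_sizes`` are (R, E) per-replicate scenarios and
    ``mu`` the (R,) per-locus per-generation rates; the mutation family and
    shape come from ``model`` (its ``rate`` field is ignored here).
    """
    R = len(mu)
    return _kernels.sim_msat_stats(
        int(n_genes),
        np.ascontiguousarray(epoch_starts, dtype=np.float64),
        np.ascontiguousarray(epoch_sizes, dtype=np.float64),
        float(scale),
        np.ascontiguousarray(mu, dtype=np.float64),
        model.code,
        np.full(R, model.p_multistep),
        np.full(R, model.geom_p),
        int(seed) % 2**31,
    )


def equilibrium_msat_stats(
    n_genes: int,
    theta: float,
    model: MsatMutationModel,
    n_reps: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched (K, He) under mutation-drift equilibrium at ``theta = 4*N*mu``.

    Implemented as a single-epoch scenario in coalescent units: with
    ``2N = 1`` time unit the per-branch mutation intensity is ``theta / 2``.
    """
    starts = np.zeros((n_reps, 1))
    sizes = np.full((n_reps, 1), 0.5)
    mu = np.full(n_reps, theta / 2.0)
    return _kernels.sim_msat_stats(
        int(n_genes), starts, sizes, 1.0, mu, model.code,
        np.full(n_reps, model.p_multistep), np.full(n_reps, model.geom_p),
        int(seed) % 2**31,
    )
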