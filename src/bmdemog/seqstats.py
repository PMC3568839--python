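"""Mitochondrial sequence demographic statistics.

Diversity descriptors, Tajima's D and Fu's Fs neutrality tests (with
coalescent-simulation p-values), the sudden-expansion mismatch-distribution
fit with SSD/raggedness bootstrap, and the conversion of the expansion
parameter tau = 2*mu*t into calendar time.

Conventions pinned here:

* pairwise differences are uncorrected; a site with a gap or N in either
  member of a pair is skipped for that pair;
* theta-hat for both neutrality tests is the mean number of pairwise
  differences;
* haplotype distinctness uses the full sequence including indel columns
  (an indel is a variable position), while the transition/transversion
  tally covers nucleotide-only columns;
* raggedness uses the trailing-zero convention: r = sum_{i=1..d+1}
  (x_i - x_{i-1})^2 with x_{d+1} = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .coalescent import DemographicScenario, simulate_genealogy
from .datatypes import SequenceAlignment

__all__ = [
    "SeqStats",
    "MismatchFit",
    "seq_summary",
    "pairwise_differences",
    "tajimas_d",
    "tajimas_d_pvalue",
    "fus_fs",
    "expected_mismatch",
    "raggedness",
    "mismatch_expansion_fit",
    "tau_to_time",
]

_CODE = {b"A": 0, b"C": 1, b"G": 2, b"T": 3, b"-": 4, b"N": 5}
_GAP, _N = 4, 5
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}


def _encode(alignment: SequenceAlignment) -> np.ndarray:
    arr = alignment.as_array()
    out = np.empty(arr.shape, dtype=np.int8)
    for sym, code in _CODE.items():
        out[arr == sym] = code
    return out


@dataclass(frozen=True)
class SeqStats:
    """Scalar descriptors of a haplotype alignment."""

    n: int
    length: int
    S: int
    n_haplotypes: int
    mean_pairwise_differences: float
    nucleotide_diversity: float
    transitions: int
    transversions: int
    indels: int


@dataclass(frozen=True)
class MismatchFit:
    """Sudden-expansion fit to a mismatch distribution.

    ``tau = 2*mu*t`` is the expansion time in mutational units; theta0 and
    theta1 are the pre- and post-expansion scaled population sizes.
    """

    spectrum: np.ndarray  # observed relative frequencies, classes 0..d
    theta0: float
    theta1: float
    tau: float
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_raggedness: float | None = None
    degenerate: bool = False


def pairwise_differences(alignment: SequenceAlignment) -> tuple[np.ndarray, float]:
    """Mismatch spectrum (counts over difference classes 0..max) and the mean
    number of uncorrected pairwise differences.

    Sites with a gap or N in either member of a pair are skipped for that
    pair.
    """
    if alignment.n < 2:
        raise ValueError("need at least 2 sequences")
    enc = _encode(alignment)
    n = alignment.n
    valid = enc < _GAP
    diffs = []
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        d = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        diffs.append(d)
    d = np.concatenate(diffs)
    spectrum = np.bincount(d)
    return spectrum, float(d.mean())


def _alignment_S(enc: np.ndarray) -> int:
    """Number of variable columns (N treated as missing; '-' is a state)."""
    S = 0
    for col in enc.T:
        states = np.unique(col[col != _N])
        if len(states) > 1:
            S += 1
    return S


def seq_summary(alignment: SequenceAlignment) -> SeqStats:
    """Descriptive statistics: S, haplotypes, pi, mpd, ts/tv/indel tallies."""
    enc = _encode(alignment)
    spectrum, mpd = pairwise_differences(alignment)
    ts = tv = indels = 0
    for col in enc.T:
        states = np.unique(col[col != _N])
        if len(states) < 2:
            continue
        if _GAP in states:
            indels += 1
            states = states[states != _GAP]
        bases = [s for s in states if s < _GAP]
        for i, a in enumerate(bases):
            for b in bases[i + 1 :]:
                if (int(a), int(b)) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    n_hap = len(set(alignment.sequences))
    return SeqStats(
        n=alignment.n,
        length=alignment.length,
        S=_alignment_S(enc),
        n_haplotypes=n_hap,
        mean_pairwise_differences=mpd,
        nucleotide_diversity=mpd / alignment.length,
        transitions=ts,
        transversions=tv,
        indels=indels,
    )


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, denominator coefficients e1, e2) of Tajima's 1989 test."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float(a1), float(e1), float(e2)


def tajimas_d_from_counts(n: int, S: int, mpd: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (the estimator-comparison form)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        raise ValueError("Tajima's D is undefined when S = 0")
    a1, e1, e2 = _tajima_constants(n)
    return float((mpd - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)))


def tajimas_d(alignment: SequenceAlignment) -> float:
    """Tajima's D of an alignment (uncorrected differences, nucleotide S)."""
    enc = _encode(alignment)
    _, mpd = pairwise_differences(alignment)
    # S restricted to nucleotide variation, matching the mpd convention
    S = 0
    for col in enc.T:
        states = np.unique(col[col < _GAP])
        if len(states) > 1:
            S += 1
    return tajimas_d_from_counts(alignment.n, S, mpd)


def _simulate_neutral_d(n: int, theta: float, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """D under the standard neutral coalescent with theta = mpd (infinite
    sites); used for the randomization p-value."""
    out = np.full(n_sims, np.nan)
    scenario = DemographicScenario.constant(0.5)  # 2N = 1 coalescent unit
    n_pairs = n * (n - 1) / 2.0
    for r in range(n_sims):
        tree = simulate_genealogy(n, scenario, 1.0, rng)
        # subtended tip counts per branch
        sub = np.zeros(2 * n - 1, dtype=np.int64)
        sub[:n] = 1
        for i in range(2 * n - 2):
            sub[tree.parent[i]] += sub[i]
        m = rng.poisson(0.5 * theta * tree.branch_lengths())
        S = int(m.sum())
        if S == 0:
            continue
        c = sub[: 2 * n - 2]
        mpd = float(np.sum(m * c * (n - c)) / n_pairs)
        out[r] = tajimas_d_from_counts(n, S, mpd)
    return out


def tajimas_d_pvalue(
    alignment: SequenceAlignment,
    n_sims: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """(D, p) where p is the proportion of neutral constant-size coalescent
    simulations (theta = observed mpd) with D <= observed."""
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_obs = tajimas_d(alignment)
    _, mpd = pairwise_differences(alignment)
    sims = _simulate_neutral_d(alignment.n, mpd, n_sims, rng)
    sims = sims[~np.isnan(sims)]
    if len(sims) == 0:
        raise RuntimeError("no polymorphic neutral replicates; increase n_sims")
    return d_obs, float(np.mean(sims <= d_obs))


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind),
    via the recurrence |s(n,k)| = |s(n-1,k-1)| + (n-1)|s(n-1,k)| in log
    space (overflow-safe at the study's n = 168)."""
    row = np.full(n + 1, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(2, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = np.logaddexp(
            row[0:m], math.log(m - 1) + row[1 : m + 1]
        )
        row = new
    return row


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_row(n)
    k = np.arange(n + 1)
    log_norm = np.sum(np.log(theta + np.arange(n)))
    logp = logs + k * math.log(theta) - log_norm
    p = np.exp(logp)
    return p / p.sum()


def fus_fs(alignment: SequenceAlignment) -> float:
    """Fu's Fs: ln(S'/(1-S')) with S' = P(K >= k_obs | theta = mpd, n) from
    the Ewens sampling formula.  Returns +inf when k_obs = 1 (S' = 1)."""
    _, mpd = pairwise_differences(alignment)
    if mpd <= 0:
        raise ValueError("Fu's Fs is undefined when mean pairwise differences = 0")
    n = alignment.n
    k_obs = len(set(alignment.sequences))
    return fus_fs_from_counts(n, k_obs, mpd)


def fus_fs_from_counts(n: int, k_obs: int, theta: float) -> float:
    if k_obs <= 1:
        return math.inf
    pk = ewens_k_distribution(n, theta)
    s_prime = float(pk[k_obs:].sum())
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


def expected_mismatch(j: np.ndarray, tau: float, theta0: float, theta1: float) -> np.ndarray:
    """Probability of j pairwise differences under the sudden-expansion
    model: constant theta1 since the expansion (tau mutational units ago),
    theta0 before.

    Closed form via the pair-coalescence density: for x < tau the hazard is
    1/theta1, beyond it 1/theta0; the difference count given coalescence at
    x is Poisson(x).
    """
    j = np.atleast_1d(np.asarray(j, dtype=int))
    jmax = int(j.max())
    theta0 = max(float(theta0), 1e-12)
    theta1 = max(float(theta1), 1e-12)
    tau = max(float(tau), 0.0)
    i = np.arange(jmax + 1)
    # recent-epoch term: theta1^j/(1+theta1)^(j+1) * P(j+1, tau*(1+theta1)/theta1)
    geom1 = np.exp(i * math.log(theta1) - (i + 1) * math.log1p(theta1))
    term1 = geom1 * special.gammainc(i + 1, tau * (theta1 + 1.0) / theta1)
    # ancestral term: exp(-tau/theta1) * conv(geom0, Poisson(tau))_j
    geom0 = np.exp(i * math.log(theta0) - (i + 1) * math.log1p(theta0))
    if tau == 0:
        pois = np.zeros(jmax + 1)
        pois[0] = 1.0
    else:
        pois = np.exp(i * math.log(tau) - special.gammaln(i + 1) - tau)
    anc = math.exp(-tau / theta1) * np.convolve(geom0, pois)[: jmax + 1]
    return (term1 + anc)[j]


def raggedness(spectrum: np.ndarray) -> float:
    """Harpending's raggedness index with the trailing-zero convention."""
    x = np.asarray(spectrum, dtype=float)
    x = x / x.sum()
    padded = np.append(x, 0.0)
    return float(np.sum(np.diff(padded) ** 2))


def _fit_sudden_expansion(rel: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares (tau, theta0, theta1, SSD) for an observed relative
    mismatch spectrum; multi-start Nelder-Mead on log-scale parameters."""
    j = np.arange(len(rel))
    mean_d = float(np.sum(j * rel))

    def ssd(params: np.ndarray) -> float:
        # clip log-parameters so the simplex cannot wander into overflow
        tau, theta0, delta = np.exp(np.clip(params, -14.0, 9.0))
        exp = expected_mismatch(j, tau, theta0, theta0 + delta)
        return float(np.sum((rel - exp) ** 2))

    guess_tau = max(mean_d, 0.1)
    starts = []
    for tau0 in (guess_tau, guess_tau / 2, 2 * guess_tau):
        for th0 in (0.1, max(mean_d / 2, 0.5)):
            starts.append(np.log([tau0, th0, max(10 * mean_d, 10.0)]))
    # equilibrium start: tiny tau, theta0 near the observed mean
    starts.append(np.log([1e-3, max(mean_d, 0.1), 1.0]))
    best = None
    for x0 in starts:
        res = optimize.minimize(ssd, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    tau, theta0, delta = np.exp(np.clip(best.x, -14.0, 9.0))
    # Parsimony tie-break: when theta0 = theta1 the model is tau-invariant,
    # so an (near-)equilibrium spectrum admits any tau at the same SSD.
    # Prefer the stationary fit (tau = 0) whenever it is not measurably worse.
    def ssd_eq(logtheta: np.ndarray) -> float:
        exp = expected_mismatch(j, 0.0, math.exp(logtheta[0]), 1.0)
        return float(np.sum((rel - exp) ** 2))

    res_eq = optimize.minimize(ssd_eq, [math.log(max(mean_d, 0.1))], method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-14})
    if res_eq.fun <= best.fun + 1e-9:
        theta_eq = math.exp(res_eq.x[0])
        return 0.0, float(theta_eq), float(theta_eq), float(res_eq.fun)
    return float(tau), float(theta0), float(theta0 + delta), float(best.fun)


def _simulate_mismatch(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> np.ndarray:
    """Parametric-bootstrap mismatch spectrum under the fitted demography.

    Simulated directly in mutational units: with epoch 'sizes' theta/2 the
    pair-coalescence hazard is 1/theta per unit and the per-branch mutation
    intensity is 1/2 (infinite sites).
    """
    eps = 1e-9
    if tau > eps:
        scenario = DemographicScenario(epochs=((0.0, max(theta1, eps) / 2), (tau, max(theta0, eps) / 2)))
    else:
        scenario = DemographicScenario.constant(max(theta0, eps) / 2)
    tree = simulate_genealogy(n, scenario, 1.0, rng)
    m = rng.poisson(0.5 * tree.branch_lengths())
    total = int(m.sum())
    if total == 0:
        return np.array([n * (n - 1) // 2], dtype=float)
    # genotype matrix of mutations -> pairwise hamming distances
    geno = np.zeros((n, total), dtype=np.int8)
    sub_members = [[i] for i in range(n)] + [[] for _ in range(n - 1)]
    for i in range(2 * n - 2):
        sub_members[tree.parent[i]].extend(sub_members[i])
    col = 0
    for i in range(2 * n - 2):
        if m[i]:
            geno[sub_members[i], col : col + m[i]] = 1
            col += m[i]
    d = []
    for i in range(n - 1):
        d.append(np.sum(geno[i] != geno[i + 1 :], axis=1))
    return np.bincount(np.concatenate(d)).astype(float)


def mismatch_expansion_fit(
    spectrum: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    n_samples: int | None = None,
) -> MismatchFit:
    """Fit the sudden-expansion model to a mismatch spectrum.

    ``spectrum`` holds counts (or relative frequencies) of pairwise
    difference classes 0..d.  The SSD and raggedness p-values come from a
    parametric bootstrap that re-simulates pairwise-difference spectra under
    the fitted demography and refits each replicate (set ``n_boot=0`` to
    skip).  ``n_samples`` is the sample size used for bootstrap genealogies;
    it is required when ``n_boot > 0``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(spectrum, dtype=float)
    if x.sum() <= 0:
        raise ValueError("empty mismatch spectrum")
    rel = x / x.sum()
    r_obs = raggedness(rel)
    if len(rel) == 1 or np.isclose(rel[0], 1.0):
        return MismatchFit(spectrum=rel, theta0=0.0, theta1=0.0, tau=0.0,
                           ssd=0.0, raggedness=r_obs, degenerate=True)
    tau, theta0, theta1, ssd = _fit_sudden_expansion(rel)
    p_ssd = p_rag = None
    if n_boot > 0:
        if n_samples is None:
            raise ValueError("n_samples is required for the parametric bootstrap")
        ssd_boot = np.empty(n_boot)
        rag_boot = np.empty(n_boot)
        for b in range(n_boot):
            sim = _simulate_mismatch(n_samples, tau, theta0, theta1, rng)
            sim_rel = sim / sim.sum()
            if len(sim_rel) == 1:
                ssd_boot[b] = np.inf  # degenerate replicate: maximally unlike the fit
                rag_boot[b] = 1.0
                continue
            _, _, _, ssd_b = _fit_sudden_expansion(sim_rel)
            ssd_boot[b] = ssd_b
            rag_boot[b] = raggedness(sim_rel)
        p_ssd = float(np.mean(ssd_boot >= ssd))
        p_rag = float(np.mean(rag_boot >= r_obs))
    return MismatchFit(spectrum=rel, theta0=theta0, theta1=theta1, tau=tau,
                       ssd=ssd, raggedness=r_obs, p_ssd=p_ssd, p_raggedness=p_rag)


def tau_to_time(
    tau: float,
    mu_per_site_per_gen: float,
    n_sites: int,
    gen_years: float,
) -> float:
    """Years before present of an expansion dated at ``tau = 2*mu*L*t``.

    The per-sequence mutation rate is ``mu_per_site_per_gen * n_sites``;
    ``t`` in generations is ``tau / (2 mu L)`` and is scaled by the
    generation time in years.
    """
    if mu_per_site_per_gen <= 0 or n_sites <= 0 or gen_years <= 0:
        raise ValueError("mutation rate, sequence length and generation time must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    t_generations = tau / (2.0 * mu_per_site_per_gen * n_sites)
    return t_generations * gen_years
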