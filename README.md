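# bmdemog

Coalescent-based demographic inference for bowhead whale (*Balaena
mysticetus*) genetic data — and, more generally, for any diploid
microsatellite panel plus mtDNA alignment where the question is *"did this
population go through a recent bottleneck, and what older size changes
shaped it?"*

The Bering-Chukchi-Beaufort Seas (BCB) bowhead stock lost an estimated 93%
of its census size to commercial whaling (1848-1914), yet — because a
bowhead generation is 52 years — that episode spans only ~1.3 generations.
This package implements the full analysis chain used to test whether such
an event leaves a detectable genetic signature:

* **Classical sequence statistics** (`bmdemog.seqstats`): nucleotide
  diversity, Tajima's *D* with coalescent-simulation p-values, Fu's *F*_S
  via the Ewens sampling formula (log-space Stirling numbers), the
  sudden-expansion mismatch-distribution fit (exact Rogers-Harpending
  expectation, SSD + raggedness parametric bootstrap), and the
  τ = 2*μt* → years conversion.
* **Heterozygosity-excess bottleneck battery** (`bmdemog.bottleneck`):
  per-locus equilibrium heterozygosity *H*_eq conditioned on the observed
  allele count under IAM / TPM / SMM mutation models, aggregated with
  sign, standardized-differences and Wilcoxon tests, plus the
  allele-frequency mode-shift check.
* **ABC model choice** (`bmdemog.abc`): coalescent simulation of
  bottleneck vs. no-bottleneck four-epoch scenarios (324 diploids × 22
  generalized-stepwise loci per dataset), rejection on (mean *k*, mean
  *H*_E), local-linear-regression model posteriors and parameter
  adjustment, pseudo-observed-dataset error rates, prior-sensitivity
  sweeps.
* **Heterozygosity-loss grid** (`bmdemog.hetloss`): forward Wright-Fisher
  simulation of an ancestral-equilibrium population contracted to a given
  size for a given duration, against the drift law (1 − 1/(2*N*_e))^t.
* **Synthetic data** (`bmdemog.synth`) and **I/O** (`bmdemog.io`):
  GENEPOP and FASTA readers/writers, generators that realize per-locus
  (k, *H*_E) targets or known-truth expansion alignments.

The published per-locus summary table (22 loci × {k, *H*_O, *H*_E, ...},
324 whales) ships as `bmdemog.fixture.load_table2_fixture()` and is the
observed data for every fixture-mode analysis; the raw genotypes were
never deposited.

## Worked example

```python
import numpy as np
from bmdemog import load_table2_fixture, MsatMutationModel, run_battery
from bmdemog.abc import ScenarioPriors, build_reference_table, model_posterior

fx = load_table2_fixture()
print(f"panel means: k={fx.mean_k:.1f} Ho={fx.mean_Ho:.3f} He={fx.mean_He:.3f}")

# Heterozygosity-excess test under two mutation models (Heq conditioned on k)
for model in (MsatMutationModel.iam(), MsatMutationModel.smm()):
    res = run_battery(fx.loci, model, n_sims=10000, seed=1)
    print(f"{model.family}: {res.n_excess} excess / {res.n_deficiency} deficiency "
          f"(Wilcoxon two-tailed p = {res.wilcoxon_p_two_tailed:.2g})")

# ABC: does a model enforcing a recent bottleneck fit better?
priors = {"no_bottleneck": ScenarioPriors(ne_max=20000),
          "bottleneck": ScenarioPriors(ne_max=20000, ne_bottleneck_max=2000)}
table = build_reference_table(priors, n_sims=25000, seed=42)
probs = model_posterior(table, np.array([fx.mean_k, fx.mean_He]))
print({m: round(p, 2) for m, p in probs.items()})
```

prints (seeds as shown; the battery takes a few minutes):

```
panel means: k=15.7 Ho=0.808 He=0.821
IAM: 22 excess / 0 deficiency (Wilcoxon two-tailed p = 4.8e-07)
SMM: 6 excess / 16 deficiency (Wilcoxon two-tailed p = 0.0032)
{'bottleneck': 0.1, 'no_bottleneck': 0.9}
```

Read: under the unrealistic infinite-alleles model every locus looks like
a bottleneck signature, under the stepwise model the panel instead shows a
heterozygosity *deficiency* (an expansion-like signal), and the ABC — whose
two models differ only in whether the post-whaling effective size is
forced below 2000 — puts ~0.9 posterior probability on the model *without*
a bottleneck. A drastic but short census crash in a long-generation species
is genetically invisible, which the heterozygosity-loss grid
(`bmdemog hetloss`) makes explicit: 10,000 → 1,000 diploids for 5
generations retains > 99% of heterozygosity.

A command-line interface mirrors the library:

```bash
bmdemog stats data.gen                      # per-locus summary table
bmdemog seqstats mtdna.fasta --boot 1000    # D, Fs, mismatch fit, dating
bmdemog bottleneck --fixture table2 --model SMM --sims 10000 --seed 1
bmdemog abc --sims 50000 --pods 250 --seed 1 --out abc_out/
bmdemog hetloss --reps 1000 --seed 1
bmdemog synth --like table2 --seed 1 --out synth_data
```

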