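# karyorate

Do lineages with holocentric chromosomes change chromosome number faster
than lineages with monocentric chromosomes? `karyorate` is a Python
package for asking that question with comparative data: it fits a
continuous-time Markov model of haploid chromosome number *i* coupled to
centromere type *c* ∈ {monocentric, holocentric} on time-calibrated
phylogenies, by Bayesian MCMC over a posterior set of trees, and
summarizes the answer as the rate-difference statistic

    ΔR_x = x_holo − x_mono        x ∈ {γ (fission), δ (fusion), ρ (polyploidy)}

with its 95% highest-posterior-density interval: an interval entirely
above zero supports faster chromosome-number evolution in holocentric
clades, entirely below zero supports monocentric clades, and an interval
spanning zero supports no difference.

The model allows four transitions from a state (i, c): fission
(i → i + 1 at γ_c), fusion (i → i − 1 at δ_c), whole-genome duplication
(i → 2i at ρ_c), and a switch of centromere regime (q_MH, q_HM). The full
model has eight rates; a constrained variant sets ρ = 0. Likelihoods come
from the pruning algorithm on trees rescaled to unit height, with rates
back-transformed to events per million years; each rate carries an
Exp(0.5) prior and chains are sampled by univariate slice sampling. See
`docs/methods.md` for the full model description, priors, numerics and
design decisions.

It is aimed at researchers in phylogenetic comparative methods and
cytogenetics who have (1) a chromosome-count table with clade-level
centromere assignments and (2) one or more ultrametric trees, and who want
regime-specific rates with honest uncertainty. A synthetic-data module
simulates trees, trait histories, multi-record tables and posterior tree
sets, so the entire pipeline is testable without any external data.

## Worked example

Simulate a dataset in which holocentric lineages truly fission three times
faster (γ_H = 0.03/Myr vs γ_M = 0.01/Myr), then fit the constrained model
over the emulated posterior tree set:

```bash
karyorate simulate --seed 7 --out-dir sim --n-tips 80 --n-trees 10 --height 100
cat > config.json <<'EOF'
{
  "trees_path": "sim/trees.nwk",
  "data_path": "sim/records.tsv",
  "output_dir": "fit",
  "seed": 0,
  "model": "no_polyploidy",
  "n_generations": 100,
  "burnin": 50
}
EOF
karyorate fit --config config.json --seed 11
```

which prints (abridged):

```json
{
  "mechanisms": {
    "fission": {
      "classification": "no_difference",
      "fraction_positive": 0.844,
      "hpd_low": -0.0328, "hpd_high": 0.0932,
      "mean": 0.0322, "n_samples": 500
    },
    "fusion": {
      "classification": "no_difference",
      "fraction_positive": 0.592,
      "hpd_low": -0.0662, "hpd_high": 0.0595,
      "mean": 0.0031, "n_samples": 500
    }
  }
}
```

Read this as: across the pooled posterior (10 trees × 50 retained
generations), the fission-rate difference ΔR_γ averages +0.032 events/Myr
and 84% of its posterior mass is above zero — holocentric-biased, as
simulated — but the 95% HPD still spans zero at this small problem size
(80 tips, noisy duplicate records), so the sign test stays conservative:
`no_difference`. The fusion difference is centred near zero, as simulated
(δ_H = δ_M). Larger trees and exact records tighten the intervals until
the fission contrast is detected; the acceptance suite demonstrates
exactly that at 200 tips.

Other subcommands: `karyorate deltar` (re-summarize saved chains),
`karyorate bootstrap` (tree/record-uncertainty bootstrap), `karyorate
compare` (contrast two runs, e.g. alternative backbone tree sets), plus
library entry points `run_order_level` for single-regime fits of
individual clades.

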