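# indelabc

Insertions and deletions (indels) shape genes and genomes, but their
evolutionary dynamics are much harder to infer than substitutions: the
likelihood of an indel history along a phylogeny is effectively
incomputable for more than a pair of sequences, and simply counting
alignment gaps confounds multiple overlapping events and inherits every
bias of the alignment program. `indelabc` is a likelihood-free toolkit
for people who want indel rates and length distributions from a
multiple sequence alignment and its rooted tree: it simulates indel
evolution forward along the tree, compresses alignments into gap-pattern
summary statistics, and estimates parameters by rejection approximate
Bayesian computation (ABC).

Two nested models are supported:

* **SIM** — simple indel model: one indel-to-substitution rate ratio
  `R_ID` (the sum of equal insertion and deletion rates) and one
  truncated-Zipf length exponent `A_ID`, plus the root sequence length
  `RL`.
* **RIM** — rich indel model: separate insertion and deletion rates
  `R_I`, `R_D` and length exponents `A_I`, `A_D`, plus `RL`. RIM is the
  model that can ask whether deletions outpace insertions.

Indel lengths follow `P(k) ∝ k^(−a)` truncated at 50 residues. The ABC
scheme: simulate `N_s` parameter draws from uniform priors, summarize
each true alignment with 27 gap statistics (block counts by length and
sharing class, column gap counts, sequence-length extremes, …), rank
simulations by the weighted Euclidean distance
`d = sqrt(Σ_j w_j (s_obs,j − s_sim,j)²)` with inverse-variance weights
calibrated on prior simulations, keep the closest fraction `p`, and
average the accepted draws. Model choice between SIM and RIM pools half
the simulation budget per model and reads each model's posterior
probability off its retained frequency. Because real alignments are
*inferred* while reference simulations are *true* alignments, a
per-data-set lasso regression can be trained that maps true-alignment
statistics to their expected post-aligner values, removing aligner
biases such as gap attraction from the comparison.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

Simulate a data set with known truth on an 8-taxon tree (total branch
length 3.0 substitutions/site), then infer the parameters back and run
model selection, all at the reduced "desk" profile (10,000 simulations,
1% acceptance):

```python
import numpy as np
from indelabc import (
    AbcConfig, IndelParams, ModelSelection, PhyloTree, PriorConfig,
    RejectionABC, simulate_alignment,
)

bl = 3.0 / 14
nw = (f"(((t1:{bl},t2:{bl}):{bl},(t3:{bl},t4:{bl}):{bl}):{bl},"
      f"((t5:{bl},t6:{bl}):{bl},(t7:{bl},t8:{bl}):{bl}):{bl});")
tree = PhyloTree.from_newick(nw)

truth = IndelParams(model="RIM", root_length=100,
                    r_i=0.01, r_d=0.04, a_i=1.3, a_d=1.6)
msa, history = simulate_alignment(tree, truth, np.random.default_rng(42))

prior = PriorConfig(rl_range=(80, 110))
fit = RejectionABC(msa, tree, model="RIM", prior=prior,
                   config=AbcConfig.desk_profile()).fit(seed=0)
print(fit.summary())
```

```
Rejection-ABC results (RIM)
  simulations: 10000   accepted: 100   max accepted distance: 3.995

  parameter     post. mean    post. sd
  r_i             0.010707    0.008025
  r_d             0.034435     0.01079
  a_i               1.5313      0.2981
  a_d               1.6221      0.2702
  root_length        93.69       8.998

  summary statistics used: 27/27
```

The deletion rate (truth 0.04) is recovered as 0.034 and the insertion
rate (truth 0.01) as 0.011 — the deletion excess is clearly detected;
the length exponents are recovered with much wider posteriors, which is
the expected behaviour (gap-pattern statistics carry far less
information about length distributions than about rates). Model
selection on the same data:

```python
post = ModelSelection(msa, tree, prior=prior,
                      config=AbcConfig.desk_profile()).fit(seed=0)
print(post.summary())
```

```
ABC model selection (SIM vs RIM)
  pooled simulations: 10000   accepted: 100
  SIM: retained    24   P(SIM|data) = 0.240
  RIM: retained    76   P(RIM|data) = 0.760
  selected model: RIM
```

The rich model is (correctly) preferred with posterior probability
0.76. Fitted exponents convert to mean indel lengths with
`truncated_zipf_mean`: here the posterior-mean `a_d = 1.62` corresponds
to a mean deletion length of 4.58 residues.

The same workflow is available from the shell:

```sh
indelabc simulate --tree tree.nwk --model RIM \
    --params r_i=0.01,r_d=0.04,a_i=1.3,a_d=1.6,rl=100 \
    --seed 42 --out-msa sim.fasta --out-events events.tsv
indelabc stats --msa sim.fasta
indelabc infer --msa sim.fasta --tree tree.nwk --model RIM \
    --nsim 10000 --accept-frac 0.01 --n-weight-sims 2000 --seed 0
indelabc run --msa msa.fasta --tree tree.nwk --profile desk \
    --correction "mafft --auto {input}" --out report.json
```

`indelabc run` executes the full pipeline — optional aligner-bias
correction, weight calibration, SIM/RIM model selection and per-model
inference — and writes a JSON report that records every constant, seed
and mask needed to reproduce it; `indelabc batch` does the same over a
list of data sets and aggregates the per-data-set results into one
table.

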