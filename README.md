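# causalnpa

Signed causal-network compilation and **Network Perturbation Amplitude
(NPA)** scoring for transcriptomic data.

Toxic exposures rarely act through a single protein; they perturb networks
of molecular events. `causalnpa` implements the reverse-causal-reasoning
workflow used in systems toxicology to quantify such perturbations: causal
statements curated from literature (in a BEL 1.0 subset) are compiled into
a signed directed network (the *functional layer*); gene signatures
attached to a subset of nodes (the *transcript layer*) let node activities
be inferred from a differential-expression profile; and a network-wide
score condenses the result into a single amplitude with uncertainty and
significance. It was built with developmental neurotoxicity networks for
larval zebrafish in mind, but nothing in it is organism-specific.

## The model and statistic

For each inferable node (iNode) *x* with signed signature *T(x)*, the
activity is the signed mean of measured log2 fold-changes:

    a(x) = mean_{g ∈ T(x)} s_xg · β_g

Node coefficients *c* reconcile the activities with the signed backbone by
minimising the quadratic consistency functional

    J(c) = Σ_{(x→y), σ≠0} w_xy (c(y) − σ_xy c(x))²  +  λ Σ_{x anchored} (c(x) − a(x))²

(one sparse SPD linear solve), and the amplitude is the node-mean of
squared coefficients:

    NPA = (1/|V|) Σ_x c(x)²

Activities that the topology accommodates propagate and produce a large
NPA; contradictions shrink the fit. The NPA is reported with a parametric
Monte-Carlo confidence interval and two permutation p-values: **o**
(transcript-layer gene assignments permuted — is the signature assignment
specific?) and **k** (backbone edge targets rewired — does the wiring
matter?). Leading nodes — the smallest set of nodes carrying ≥ 80% of the
NPA — localise the perturbation, each with an activation direction.
Hub (degree) and bottleneck (betweenness) tables describe the network
itself. See `docs/methods.md` for the full account.

## Worked example

The package ships a fixture generator, so the whole workflow runs without
any external data:

```sh
causalnpa fixtures --out fx
causalnpa compile fx/worked_example.bel --out compiled
# -> compiled 4 nodes, 3 edges (3 causal, 0 association)
```

The worked example is the three-statement microcephaly fragment — ethanol
increases microcephaly, agrin and shha activity decrease it — which
compiles to 4 nodes and 3 edges with signs (+1, −1, −1). Scoring the
10-node toy model against its consistency-generated profile:

```sh
causalnpa score --network fx/toy_network.bel --layer fx/toy_layer.tsv \
    --deg fx/toy_profile_consistent.tsv \
    --permutations 200 --ci-draws 500 --seed 1 --out score_out
# -> NPA 0.743609  CI [0.677726, 0.81031]  o 0.004975  k 0.0199
```

The NPA of 0.74 with a tight CI says the profile perturbs the model
strongly and stably; o = 0.005 and k = 0.02 say fewer than 5% of
transcript-layer and backbone permutations reach the observed amplitude,
so the perturbation is specific to both layers. Decomposing it:

```sh
causalnpa leading-nodes --score-report score_out --network fx/toy_network.bel --out ln_out
# -> 8 leading nodes at threshold 0.8
head -4 ln_out/leading_nodes.tsv
# node_id         contribution         cumulative           direction
# p(SYN:n002)     0.1067500602591825   0.1067500602591825   inactivated
# p(SYN:n003)     0.1054199668994099   0.2121700271585924   activated
# p(SYN:n000)     0.1021768659100224   0.3143468930686148   inactivated
```

Eight nodes carry 80% of the amplitude; the direction column gives each
node's inferred activation sign. The same operations are available as a
library (`compile_network`, `attach_transcript_layer`, `score`,
`leading_nodes`, ...), and `causalnpa topology --both-conventions` writes
the hub/bottleneck tables.

## Input formats

- **Network**: BEL script (`.bel`, one statement per line, OpenBEL-style
  SET/DEFINE preamble tolerated; typographic arrows `→`/`−|` accepted), or
  the package's JSON/GraphML exports.
- **Transcript layer**: TSV with columns `inode_id`, `gene_id`, `sign`.
- **Expression profile**: TSV with columns `gene_id`, `log2fc` and
  optional `se`.

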