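# Methods

## Model

`menc` scores each somatically mutated gene by the influence it exerts, within
a two-hop neighbourhood of a protein–protein interaction (PPI) network, on
other mutated genes and on genes whose expression changes in tumors. The
working assumption is the standard one for network-based driver detection:
driver mutations perturb the expression of their network neighbours, so a
true driver should sit centrally among the expression changes it can explain,
even when its own mutation frequency is low.

### Mutation scores

From the binary gene × patient matrix `M`, with `K_i` the patients mutated in
gene *i* and `N_k` the number of mutated genes in patient *k*:

```
M(i) = Σ_{k ∈ K_i} 1/N_k          if K_i ≠ ∅
M(i) = 1/N_max                    otherwise (background score, BMS)
```

Dividing by the patient burden discounts mutations in hypermutated samples.
Patients with zero mutated genes contribute to no score. The BMS is a lower
bound: every mutated gene satisfies `M(i) ≥ 1/N_max`. Note the bound is the
only monotone guarantee that survives edge cases — adding a first mutation to
a previously unmutated gene switches it from the background branch to the sum
branch and can *lower* its score; adding a mutation to an already-mutated
gene always raises it.

### Mutation-impact function

```
MIF(i, j) = M(i)·M(j) / d(i, j)²
```

where `d` is the Euclidean distance between the two genes' binary patient
rows (so `d²` is their Hamming distance), computed over the full patient
axis. The form is gravitational: two high-scoring genes with similar
incidence profiles interact strongly. Two readings of the distance term are
circulated, and they invert the similarity relationship; the default
`mif_mode="gravity"` divides by `d²` (high similarity ⇒ high MIF, consistent
with the gravity analogy), while `mif_mode="literal"` treats the denominator
as the *reciprocal* of the distance, i.e. multiplies by `d²`. The literal
mode exists for auditability only.

Identical profiles give `d = 0`; the gravity mode floors `d` at 1 — the
smallest distance two *distinct* binary rows can achieve — so the MIF stays
finite and maximal. MIF values are computed lazily per visited edge and
memoized; no all-pairs table is materialized.

### DEG calling

Per patient *j* and gene *i*, with paired tumor/normal expression on a linear
nonnegative scale:

```
lfc = log2( (tumor[i,j] + pseudocount) / (normal[i,j] + pseudocount) )
```

Gene *i* is a DEG of patient *j* iff `|lfc| > threshold`, strictly; the
default threshold is 1 (a twofold change is *not* sufficient — the inequality
is strict) and the default pseudocount 1 keeps zero-expression cells defined.
The cohort DEG set is the union over patients. The log is taken of the ratio,
not as a difference of logs, so exact power-of-two fold changes land exactly
on the threshold. No variance model or multiple-testing correction is
applied; the criterion is intentionally a pure fold-change cutoff, and
statistical DE testing is out of scope.

### Semi-local network and objective

The merged graph is the PPI induced on (mutated genes ∪ cohort DEGs); genes
absent from the PPI are dropped (counts logged). Each node carries a role:
MUTATED, DEG, or BOTH. For each mutated source *v* the semi-local network is
the subgraph induced on the nodes within ≤ 2 hops of *v* in the merged graph.
With `Γ(x)` the neighbourhood and `N(x)` the scalar neighbourhood size of `x`
*inside the semi-local network*:

```
score(v) = N(v) + Σ_{u∈Γ(v), u mut} c(u)·MIF(v,u) + Σ_{u∈Γ(v), u DEG} b(u)
c(u)     = Σ_{w∈Γ(u), w mut} N(u)·MIF(u,w)        + Σ_{w∈Γ(u), w DEG} N(w)
b(u)     = Σ_{w∈Γ(u), w mut} c(w)                 + Σ_{w∈Γ(u), w DEG} N(w)
```

Sources are ranked by descending score; ties break by higher `M(i)`, then
lexicographic gene symbol, so rankings are deterministic and byte-identical
across runs.

Design choices where the objective admits more than one reading (each
exposed as a configuration option, defaults first):

- **`neighbor_count = "degree" | "two_hop"`** — the scalar `N(x)` is the
  degree of `x` in the semi-local network; degree is the only scalarization
  consistent with `N(·)` also denoting the neighbour *set*. The two-hop
  neighbour count is a plausible alternative from the local-centrality
  literature and is available.
- **`c_variant = "literal" | "nw"`** — the factor `N(u)·MIF(u,w)` in `c(u)`
  is constant in `w`; it is implemented literally as printed. The `nw`
  variant uses `N(w)`, symmetric with the DEG branch, for sensitivity
  analysis; no intent is guessed.
- **BOTH-role genes** contribute to the mutation branch *and* the DEG branch
  of every sum — the only reading under which carrying both labels can only
  increase a gene's score.
- Degrees and neighbourhoods are evaluated inside the semi-local network,
  not the merged graph (the objective is defined locally); neighbour walks
  may revisit the source — no back-edge exclusion is applied.

Consequences used as test invariants: `score(v) ≥ deg(v) ≥ 0`; adding a DEG
neighbour to the source never decreases its score; gravity-mode MIF strictly
decreases as profiles drift apart.

### Evaluation

For a ranking and a benchmark catalog, at every cutoff k:
`precision = hits/k`, `recall = hits/D`, F1 the harmonic mean with `0/0 = 0`.
The recall denominator `D` defaults to `|benchmark ∩ mutated genes|`
(`"in_dataset"`): a cohort-restricted ranker can never return a catalog gene
that is not mutated in the cohort, so counting those genes says nothing about
the ranker. `"full_set"` uses the whole catalog for the literal formula. The
choice does not affect precision.

Rare drivers are top-n genes with mutation frequency strictly below 2% of
patients. Catalog membership is reported as an annotation, not used as a
filter — curated catalogs do contain low-frequency drivers, and filtering on
membership would contradict the table this report format mirrors.
Frequencies are exported at six decimal places.

## Synthetic cohorts

The generator emulates the four inputs end to end:

- **PPI**: Barabási–Albert preferential attachment (`attach_m = 2` default),
  giving a connected graph with a heavy-tailed degree distribution.
- **Mutations**: `n_drivers` planted on the highest-degree nodes, each with a
  carrier frequency drawn uniformly from `driver_freq_range` (default
  1–20% — the lower bound sits below the 2% rare-driver line on purpose);
  passenger mutations i.i.d. at `passenger_freq` (default 1%) per gene per
  patient. Every planted driver is forced to have ≥ 1 carrier, since a driver
  nobody carries would simply be absent from the mutation data.
- **Expression**: per-gene baseline `log2` level ~ Normal(6, 1); in patients
  carrying a driver, that driver's direct PPI neighbours are shifted by
  ± `fc_effect` log2 units (sign drawn once per driver–neighbour pair;
  default 2.5), plus Normal(0, `noise_sd`) measurement noise (default 0.3)
  on both matrices. The baseline mean of 6 (≈ 64 on the linear scale) keeps
  the +1 pseudocount from attenuating planted fold changes.

Default sizes are 300 genes × 60 patients with 5 drivers. All randomness
flows through a single `numpy.random.default_rng(seed)`; integer artifacts
are bit-reproducible across platforms.

What the simulation does *not* model: mutational signatures, CNV segment
structure, count-based expression noise (negative binomial), unpaired or
batch-confounded samples, and incompleteness/bias of the interaction network.
Passing recovery tests therefore demonstrate that the implementation detects
the causal structure it assumes, not that the method is robust to real-data
violations of those assumptions.

Because drivers are planted on hubs and the score is degree-anchored,
recovery experiments compare planted drivers against **degree-matched**
mutated passengers (greedy nearest-degree matching without replacement,
deterministic tie-breaks); beating the passenger pool at large would be
trivial.

## Numerical and degenerate-input choices

- All-zero mutation matrix → error (the background score is undefined).
- Zero expression with `pseudocount = 0` → error naming the gene and patient.
- Empty merged node set (nothing maps onto the PPI) → error.
- Gene symbols are matched by exact case-sensitive equality after trimming
  whitespace; one `uppercase` flag normalizes case and applies to all inputs
  of a run at once, since mixed-case symbol mismatch between sources is the
  dominant silent failure mode.
- MAF input collapses any ≥ 1 record per (gene, sample) to a binary 1; SNV
  and CNV evidence merge by binary OR.
- Scores are accumulated in double precision; the scorer's equivalence with
  a naive reference implementation is asserted to a relative tolerance of
  1e-12 in the tests.

## Problem sizes

The test and acceptance workloads use the default synthetic conditions
(300 genes × 60 patients, 10 seeds for recovery experiments) and random
graphs of ≤ 15 nodes for oracle-equivalence checks — sizes at which every
stage, including the brute-force reference scorer, runs in seconds while
still exercising heavy-tailed degree structure and 100+ mutated genes per
cohort.

## Known limitations

- Ranking quality on real cohorts depends on PPI completeness; the method
  cannot rank a mutated gene that does not map onto the network.
- The objective is degree-anchored, so it inherits the hub bias of the
  underlying interactome; the literature's ascertainment bias toward
  well-studied genes is not corrected.
- Per-patient (individualized) driver calls are out of scope; the ranking is
  cohort-level.
- The DEG rule is a hard fold-change threshold; subtle but consistent
  expression shifts are invisible to it.
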