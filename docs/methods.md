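# Methods

## Model and test

Each K ID (KEGG Orthology group) k carries a fold-change trajectory
f_k ∈ ℝ^T, the per-time log2 ratio of treatment to control expression
after flooring both conditions at 0.1 RPKM. A gene set G with m members
present in the data is summarised by the column mean m̄ of its members'
rows. The null model is *exchangeability of rows*: if G is no different
from an arbitrary group of m genes, m̄ is distributed like the column
mean of m rows drawn uniformly without replacement from the full
matrix. The background matrix B stacks R such resampled means
(R = 6000 by default), and the test statistic is the dominance count

    p_upper = (1 + #{ j : B_j ≥ m̄ componentwise }) / (R + 1).

The multivariate ECDF F(x) = (1/R) Σ_j Π_t 1[B_jt ≤ x_t] is reported
alongside as `ecdf_value`. The add-one guard keeps p strictly positive
with resolution 1/(R+1); with R = 6000 the smallest reportable p is
1/6001 ≈ 1.7·10⁻⁴.

**Tail convention.** A multivariate ECDF admits several one-number
summaries. We default to the upper tail (componentwise dominance of the
observed mean by background means), which flags coordinated
*up*-regulation; `lower` flags down-regulation and `two_sided` doubles
the smaller tail (capped at 1). The raw F(m̄) is always emitted so any
other convention can be recovered from the output.

**Calibration caveat.** The dominance p-value is exactly uniform under
exchangeability when the T coordinates of each row are strongly
dependent — the empirically relevant case: in replicate-free data a
gene's apparent fold change is dominated by a gene-level effect that
persists across the time course, so its trajectory moves as a block.
If instead rows had independent coordinates across time, the dominance
probability would factorise into a product of ~T uniforms and the test
would be anti-conservative (for T = 4, P(p < 0.05) ≈ 0.6 under full
independence). This is a property of componentwise-dominance counting
itself, not of the implementation. The synthetic generator therefore
models background fold change as a per-gene constant (see below), and
users applying the test to data whose trajectories are close to
white noise should prefer the two-sided tail and treat p-values as
exploratory.

**Other choices.**

- Resampling draws from the *whole* fold-change matrix; the tested
  set's own rows may be redrawn. Excluding them is available
  (`exclude_set_members=True`) but off by default.
- The resampling pool is canonicalised by sorting rows by K ID, so
  p-values are invariant to the ordering of the input table.
- One master seed; each set's substream is derived from
  (seed, CRC32(set_id)), so adding or reordering sets never perturbs
  another set's p-value.
- Raw p-values are reported by default (sets are few — tens of
  pathways); Benjamini–Hochberg q-values are an opt-in column. The
  `significant` flag compares the raw p to alpha (default 0.05).
- Sets with no member in the data are skipped with a warning and
  listed separately, not treated as errors.
- Ties: results sort by (p-value, set_id) for deterministic output.

## Preparation

Order of operations: drop sequences with all-zero RPKM in both
conditions → drop unannotated sequences (counted in the log) → average
RPKM vectors per K ID, elementwise per condition → floor at 0.1 RPKM →
log2 ratio. The floor is applied to each condition *before* the log,
which keeps every entry finite (0/0 → log2(0.1/0.1) = 0) and damps
ratios driven by a handful of reads. The log base (default 2) and floor
(default 0.1 RPKM, a conventional noise threshold for RPKM-scale data)
are both configurable. Negative or non-finite RPKM, missing condition
columns, and non-increasing time labels are hard validation errors
naming the offending sequence or column.

## Compound graphs

KGML files are parsed with the standard library XML parser: compound
entries become nodes; each `reaction` element expands to one directed
edge per (substrate, product) pair keyed by its reaction ID and
labelled with the K IDs of the ortholog entries bound to that reaction;
`type="reversible"` adds the reverse arcs. Multi-substrate reactions
(e.g. sugar + ATP) therefore produce all cross pairs, which is faithful
to the encoding but means cofactor hubs can create chemically
uninteresting shortcuts — pathway selection and, if needed, manual
compound exclusion are the user's control points, as they are with any
compound-graph analysis.

Merging unions nodes by compound ID (pathway-membership sets unioned)
and collapses identical (reaction, substrate, product) edges while
merging their ortholog sets. Pruning removes degree-0 compounds only.
The graph is directed by default — the biologically conservative
reading, since KGML states reversibility explicitly — with an
`--undirected` switch for the permissive reading.

Shortest paths are *all* minimum-hop simple paths (networkx breadth-
first search under the hood), returned lexicographically sorted; path
length is reported as a compound count including both endpoints, with
hop count = compounds − 1. Source = target yields the single
zero-length path; unreachable targets yield an empty list, not an
error.

Edge direction overlays: an edge's sign at time t is the sign of the
mean fold change over its orthologs present in the data — strictly
positive → `up`, strictly negative → `down`, exactly zero (after
floating-point evaluation) or no data → `unknown`. No third "flat"
state is invented for zero. GraphML export flattens set-valued
attributes to sorted space-joined strings and round-trips losslessly
through `read_compound_graph`.

## Synthetic data

`simulate_rpkm` emulates the shape of a replicate-free diatom-style
time course: control RPKM is log-normal (median 50 RPKM, log-sd 1.5 —
heavy-tailed, with a realistic share of small values near the 0.1
floor); treatment equals control · 2^lfc; 5% of sequences are all-zero;
10% of K IDs are carried by two sequences so the averaging step does
real work. Defaults: 1,000 genes, time points 0/24/48/60 h, background
fold-change sd 0.5 log2 units.

Background lfc is one **per-gene constant** L_g ~ N(0, sd) applied at
every time point. This is deliberate: without replicates the dominant
fold-change "noise" is a stable gene-level effect, and the dominance
test's calibration rests on exactly that cross-time dependence (see the
caveat above). An optional `time_jitter_sd` (default 0) adds
independent per-time noise for sensitivity analyses. Planted sets add a
mean trajectory δ(t) on top of the gene effect; offered shapes are
constant, linear in time, and late-onset (zero before 48 h), the last
exercising the time-lag situation in which whole-course tests lose
power. What the generator does **not** emulate: count-level sampling
noise, transcript-length effects, correlated co-regulation between
background genes, and batch structure — so green tests demonstrate
correctness of the machinery under the stated model, not performance on
any particular real data set.

`make_toy_kgml` writes schema-valid KGML for small designed pathways
(default: a three-pathway miniature of glycolysis, glycerolipid
metabolism and pyruvate/TCA entry, sharing pyruvate, ADP/ATP,
glycerone-phosphate and acetyl-CoA across pathways, with one
deliberately isolated compound and exactly two equal-length glucose →
triacylglycerol routes). Its manifest records entity counts and all
shortest paths computed at generation time by exhaustive simple-path
enumeration — an oracle independent of the production graph code.

## Problem sizes and numerics

Default test and demonstration sizes were chosen to mirror the target
study's scale where that matters (a few thousand K-ID vectors, four
time points, tens of gene sets, R = 6000) and to be generous for
Monte-Carlo stability elsewhere (200 null sets for calibration checks,
20 replicates for power checks at R = 1000). Resampling is vectorised
(per-iteration subsets via random-key argpartition) with scratch memory
capped at ~64 MB; identical seeds give byte-identical outputs across
runs, which the pipeline's run manifest records together with a config
hash.

## Known limitations

- The dominance p-value's calibration degrades as cross-time dependence
  weakens (quantified above); it is exact only under row
  exchangeability.
- Overlapping gene sets are tested marginally; no joint or conditional
  analysis of shared K IDs.
- Fold changes from unreplicated samples conflate biological and
  technical variation; the test ranks sets against background, it does
  not separate those sources.
- Compound-graph shortest paths ignore stoichiometry, compartments and
  cofactor semantics; routes through currency metabolites can appear
  unless the pathway selection excludes them.
- KEGG pathway content is release-dependent; graph statistics are only
  comparable across runs using the same KGML snapshot.
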