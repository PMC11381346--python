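# Methods

## Problem and model

Best-match genome search asks: given a query assembly (or proteome), find
the K database genomes with the highest average nucleotide identity (ANI)
or average amino-acid identity (AAI). `genosketch` answers this without
alignment, in three stages:

1. **k-mer multisets.** Each genome is reduced to the multiset of its
   canonical k-mers (lexicographic minimum of each window and its reverse
   complement; amino-acid k-mers are used as-is). Windows never span
   contig boundaries, and any window containing an ambiguity code (N, R,
   Y, ... for nucleotides; X for amino acids) is skipped. No low-count
   filtering is applied. Tokens are bit-packed (2 bits/base up to k = 32;
   5 bits/residue up to k = 12).
2. **Sketches.** The multiset is compressed to m registers by one of four
   sketch families (below). Two genomes' sketches are comparable only if
   algorithm, m, k, alphabet and seed all match; comparison across
   parameter sets is a hard error.
3. **Index.** Sketches are nodes of a hierarchical navigable small world
   (HNSW) graph under the estimated sketch distance; greedy layered
   search returns approximate nearest neighbors in O(log N) distance
   evaluations per query.

Distances convert to identity proxies through the Mash equation

    ANI (or AAI) = 1 + (1/k) · ln( 2J / (1+J) ),

with J the (probability) Jaccard similarity at the level's own k. The
inverse is J = c/(2−c) with c = exp(k·(ANI−1)); at k = 16 an ANI of 78%
corresponds to a sketch distance 1−J of 0.9850, which is the pipeline's
nucleotide/proteome switching threshold and is re-derived (and asserted)
at pipeline startup.

## Sketch algorithms

All randomness derives from a splitmix64-style counter-based hash of the
packed k-mer token XOR a seed, so the same token produces the same stream
in every genome — the property that makes register collisions estimate
similarity.

**Weighted MinHash (`probminhash3a`, the default).** Register i holds the
token x minimizing an Exp(w(x)) draw, with w(x) the count-normalized
k-mer frequency. The probability that two genomes agree on a register is
exactly the probability Jaccard index

    J_p = Σ_{x shared} 1 / Σ_y max(w_A(y)/w_A(x), w_B(y)/w_B(x)),

which accounts for k-mer multiplicity and genome size. The
implementation generates, per token, its m register values in ascending
order (exponential spacings of order statistics, assigned through a
truncated Fisher–Yates permutation with a tag-array trick) and stops as
soon as a value exceeds the current register maximum, which is tracked
with amortized O(1) refreshes. Expected cost is O(n + m log m)-like
rather than O(n·m). Exact ties are broken toward the smaller token so
sketches are bit-reproducible. The estimator is the register match
fraction; its MSE is J_p(1−J_p)/m (validated empirically in the
acceptance suite; the order-statistics scheme's negative coupling can
push variance slightly *below* this law for supports smaller than m).

**SuperMinHash (`superminhash`).** Unweighted. Per element, register
p(j) receives value j + U_j through a random permutation p; registers
keep the minimum and equality across genomes has probability J with
lower variance than m independent hash functions. Same early-stop and
permutation machinery as above.

**Densified one-permutation hashing (`oph_optimal`, `oph_faster`).** One
64-bit hash per element, binned into m slots keeping the bin minimum.
Empty bins are filled by optimal densification (seeded re-hash probing
until an occupied bin is found) or faster densification (fixed-direction
rotation to the next occupied bin, then a bijective per-bin remix that
decorrelates copies without breaking cross-sketch equality). The fastest
option by a wide margin because hashing is single-pass.

**SetSketch (`setsketch`).** Geometric base-b registers
K_i = clamp(max over elements of 1 + ⌊log_b(a/E)⌋, 0, q+1) with
E standard-exponential per (element, register); P(K_i ≤ k) =
exp(−n·a·b^(−k)). Defaults b = 1.001 (near the MinHash end of the
MinHash↔HyperLogLog continuum), a = 20 (probability of an unsaturated
zero register is e^(−20n), negligible), q = 2^16 − 2 (registers fit 16
bits). Sketches merge by element-wise max. The inner loop avoids
logarithms by comparing the uniform against exp(−a·b^(−K_current)) and
only computing the floor when the register improves. Cardinality is
estimated by maximum likelihood on the register histogram. Jaccard
estimators:

* *LSH*: register-equality fraction minus the accidental-collision
  probability of two different dominating elements landing in the same
  geometric bin, computed numerically from the two marginal register
  distributions at the estimated cardinalities.
* *JMLE* (default): joint maximum likelihood over register pairs using
  P(K_A ≤ x, K_B ≤ y) = exp(−a(n_S g(min(x,y)) + n_x g(x) + n_y g(y))),
  fit by L-BFGS-B over the shared/exclusive support sizes with analytic
  gradients and multi-start (finite-difference gradients are numerically
  unreliable at this likelihood's scale and the n_S ≥ 0 boundary needs
  guarding). Identical register vectors short-circuit to J = 1, the MLE
  limit.

In this implementation both estimators are unbiased at J ~ 0.005 within
measurement error; JMLE remains the default.

## HNSW index

Standard multilayer construction: node levels follow
level = ⌊−ln(U)·mL⌋ with mL = 1/ln(M) by default; per-node neighbor caps
are M above layer 0 and 2M at layer 0; insertion runs an
ef_construct-wide beam search per layer, selects neighbors with the
diversity heuristic (keep a candidate only if it is closer to the new
node than to any already-selected neighbor, then fill nearest-first),
and reverse-updates each selected neighbor with cap-respecting
re-pruning. Queries descend greedily through the upper layers keeping
the single closest node and run an ef_search-wide beam at layer 0 only;
they never mutate the graph. All ordering ties break on
(distance, genome_id), and the level RNG is seeded from
(graph seed, node ordinal), so a database built in one session is
bit-identical to one built, dumped, reloaded and extended — the add
path is equivalence-tested against single-session builds.

Persistence is a directory of `manifest.json` (all parameters, counts,
format version), `ids.tsv`, `sketches.npy` (register matrix) and
`graph.npz` (per-level CSR adjacency + levels); round trips are
bit-exact and loading validates version, counts and sketch width.

**Navigability caveat.** HNSW requires graded distances to navigate. A
database in which unrelated entries all sit at exactly distance 1.0
(e.g. isolated clusters with no background relatedness) develops a
lexicographic sink under deterministic tie-breaking and fragments into
unreachable components. Real genome collections have a relatedness
continuum, and the synthetic generators reproduce one (see below). For
databases of mutually unrelated genomes, exhaustive per-piece search
(ef_search ≥ piece size) remains exact regardless of navigability.

## Search pipeline

Per query: nucleotide search first; if the best hit's distance exceeds
0.9850 (78% ANI at k = 16), escalate to the whole-proteome database
(k = 7); beyond 0.9720 there, escalate to the universal-gene database
(k = 5). Viral mode skips the nucleotide step (k-mer search at the
nucleotide level is ineffective for viruses); the 0.9800 viral cutoff
applies only to recall filtering when nucleotide search is forced. Hits
beyond a level's cutoff are kept but flagged "beyond reliable range".
Suggestions: same species if the top hit's ANI proxy ≥ 0.95; same genus
(new species) if ≥ 5 of the top 10 AAI proxies ≥ 0.65 — with optional
genus labels the vote additionally requires a strict majority sharing
one genus, and without labels the result is flagged unlabeled; same
family (new genus) if the top 5 hits all have AAI proxy ≥ 0.52;
otherwise unclassified at family rank. When a nucleotide-level report
fails the species rule, the AAI votes draw on an auxiliary proteome
search if that database and query input exist. Suggestions are evidence,
not taxonomy assignments.

Database splitting partitions genomes uniformly at random (seeded) into
pieces, builds each independently, and at query time pools every piece's
top-k (k ≥ K) and re-sorts by (distance, id); this is exactly equivalent
to the unsplit search when per-piece search is exhaustive, and is
asserted as exact hit-list equality in the acceptance suite.

## Synthetic data: what it does and does not emulate

* Random genomes: i.i.d. bases at configurable length and GC.
* Mutants: independent per-site substitutions (no indels), so expected
  ANI is exactly 1 − rate and the parent–mutant k-mer Jaccard follows
  the Mash equation analytically — sacrificing indel realism for a
  closed-form truth.
* Incompleteness: removal of random contiguous blocks (5 by default) to
  a target completeness fraction, mimicking MAG fragmentation rather
  than uniform site loss.
* Group databases: ancestors of each group all descend from one root at
  0.08 substitutions/site, giving small but graded between-group
  similarity like the between-family continuum of real collections —
  required for index navigability (see caveat above).
* Proteomes: i.i.d. amino-acid sequences; related pairs share a copied
  prefix fraction per sequence, controlling amino-acid Jaccard directly
  (gene prediction is upstream and out of scope).
* Planted sketch clouds for index benchmarks: registers are randomly
  shifted quantization bins of random projections of a latent Gaussian
  mixture, so register-match distance decays smoothly with latent
  distance.

Passing tests on these generators demonstrates the estimators' and the
index's statistical contracts; they do not certify recall on real MAG
collections, where repeat content, contamination and indel divergence
also matter.

## Problem sizes and numerical choices

The test and acceptance workloads use deliberately moderate sizes chosen
to exercise the asymptotic claims while staying desk-scale: sketches of
m = 96–4096 on sets of 10^2–10^5 tokens, databases of 200–4000 entries
(index fidelity at 1000, sub-linear growth over 250–4000, split
equivalence at 500 genomes), 200-seed replication for the MSE law, and
500 random triples for metricity. Production defaults remain m = 12000,
k = 16 (bacterial nucleotide), m = 48000/k = 21 (fungal), k = 7
(proteome), k = 5 (universal genes), M = 16 and ef_construct in the
hundreds-to-thousands. Quadrature for the register entropy uses adaptive
Gauss–Kronrod with absolute tolerance 1e−6 and the integrand extended
continuously at both endpoints (the z → 1 log singularity is
integrable). Uniform variates are built from the top 53 hash bits offset
by 2^−54 so logarithms never see 0. Empty k-mer multisets are skippable
at build time (recorded in the manifest) and hard errors at sketch time.

## Known limitations

* No indels in the mutation model; expected-ANI calibration is
  substitution-only.
* The JMLE fit is two orders of magnitude slower than register matching;
  SetSketch databases therefore pay a large constant per distance
  evaluation inside the index.
* Graph quality (and hence recall at fixed ef_search) degrades on
  databases without a relatedness continuum; exhaustive or split-
  exhaustive search is the fallback.
* No deletion support in the index; no memory-mapped loading — databases
  must fit in memory.
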