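# genosketch

Alignment-free best-match genome search for microbiome-scale databases.

Genome collections now grow faster than alignment-based ANI/AAI tools can
search them: brute-force comparison of every query against every database
genome is quadratic in collection size. `genosketch` combines two ideas so
that the best match is found in O(log N) distance evaluations per query:

1. **MinHash-family sketching.** Each genome's canonical k-mer multiset is
   compressed to m registers. The default algorithm is a weighted MinHash
   whose register-collision probability equals the *probability Jaccard
   index* J_p (it weights k-mers by abundance and normalizes by genome
   size); SuperMinHash, densified one-permutation hashing and SetSketch
   (a space-efficient register sketch interpolating between MinHash and
   HyperLogLog, with LSH and joint-maximum-likelihood estimators) cover
   the unweighted Jaccard J.
2. **A hierarchical navigable small world (HNSW) graph** over the sketch
   distance 1 − J_p (or 1 − J), built with reverse neighbor updates and
   searched greedily layer by layer.

Distances map to identity through the Mash equation,
`ANI = 1 + ln(2J/(1+J))/k`, and a three-step pipeline escalates novel
queries from whole-genome nucleotide search (k = 16) to whole-proteome
(k = 7) to universal-gene (k = 5) amino-acid search, emitting a
classification *suggestion* (same species / same genus / same family /
unclassified) from standard ANI/AAI thresholds (95% / 65% / 52%).
Databases can be split into independently built pieces whose pooled
per-piece results are exactly equivalent to the unsplit search.

## Worked example

Build a small synthetic database of 4 groups × 5 mutants (per-site
substitution rates cycling through 0, 1% and 3%) and search one genome
against it:

```sh
genosketch synth --out genomes --n-groups 4 --group-size 5 \
    --length 20000 --rates 0.0,0.01,0.03 --seed 11
genosketch tohnsw --in genomes --out db --sketch 1024 \
    --max-nb-conn 8 --ef 100 --seed 11
mkdir -p queries && cp genomes/grp002_m03.fna queries/
genosketch request --db-nt db --query queries --nbest 5 --out-json report.json
```

prints

```
query	level	rank	hit	distance	identity_proxy
grp002_m03	nucleotide	1	grp002_m00	0.000000	1.0000
grp002_m03	nucleotide	2	grp002_m03	0.000000	1.0000
grp002_m03	nucleotide	3	grp002_m01	0.215820	0.9919
grp002_m03	nucleotide	4	grp002_m04	0.233398	0.9911
grp002_m03	nucleotide	5	grp002_m02	0.589844	0.9661
```

The query was resolved at the nucleotide level. `distance` is the
estimated 1 − J_p from 1024 sketch registers; `identity_proxy` is the
Mash-transformed ANI estimate. Both `grp002_m00` and the query itself
were generated at rate 0 from the same ancestor, hence two exact hits at
distance 0 (ties rank by id); its 1%-mutants score ≈ 99.2% ANI and the
3%-mutant ≈ 96.6% ANI, matching the expected ANI ≈ 1 − rate. The JSON
report records the suggestion for the query: `same_species` (top-1 ANI
proxy ≥ 0.95).

The library API mirrors the CLI: `extract_kmers` → `sketch` →
`HnswGraph.insert`/`knn_query`, with `tohnsw`/`add`/`request`/
`split_build`/`split_request` as pipeline entry points and exact oracles
(`j_exact`, `jp_exact`, `brute_force_knn`) plus synthetic generators in
`genosketch.synthetic` for validation.

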