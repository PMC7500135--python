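# netsketch

Two small, reusable analysis pipelines with fully synthetic, seeded test
data:

1. **Seeded PPI signal-propagation profiling** — read STRING-style
   interaction tables, filter by combined confidence score (default ≥ 0.4),
   build a simple undirected network, rank hub degrees, decompose each
   seed's neighbourhood into breadth-first shells S(r) (default r ≤ 8), and
   compute the propagation profile |D(r)| = |S(r)| / Σ|S(r′)| together with
   its exponential rise rate and saturation radius r_s (first peak of
   |D(r)|).  Degree-moment statistics (⟨k⟩, ⟨k²⟩, expansion ratio
   ⟨k²⟩/⟨k⟩, mean excess degree) and the matching exponential growth model
   are provided alongside.

2. **Alignment-free phylogenomics** — canonical k-mer bottom-s MinHash
   sketches (seeded 64-bit hash; defaults k = 16, s = 5000), merged-sketch
   Jaccard estimates, conversion to nucleotide divergence (p-distance
   inversion by default, classical Poisson log formula available), optional
   Jukes–Cantor-style correction (off by default), neighbor joining with a
   balanced-minimum-evolution NNI refinement (Pauplin weights), and
   per-branch confidence as the rate of elementary quartets (REQ) in
   [0, 1].

The `netsketch.synthetic_data` module generates every input needed to
exercise both pipelines: seeded Erdős–Rényi / Barabási–Albert /
configuration-model / b-ary-tree networks, a packaged degree-constrained
78-node / 216-edge hub fixture, and genome sets evolved along a known guide
tree by exact-proportion point substitution.

> **Note on the fixture:** the advertised hub degree table
> (55, 53, 39, 30, 29, 23, 22, 21; sum 272) is not realizable by any simple
> graph with 216 edges — eight designated nodes can jointly reach degree sum
> at most C(8,2) + 216 = 244 (`synthetic_data.hub_degree_sum_bound`).  The
> packaged fixture keeps 78 nodes, 216 edges, the hub rank order and the
> maximum degree 55 exactly, and uses the closest feasible table
> (55, 45, 33, 26, 25, 20, 19, 17) for the lower seven hubs.  One acceptance
> test asserting the unrealizable table is intentionally left failing.

## CLI

```sh
# generate the fixture network (edge-list TSV + manifest)
printf 'kind=network\nmodel=bat_fixture\nseed=42\n' > fixture.cfg
netsketch simulate --spec fixture.cfg --out-dir out/fixture

# hub degree ranking
netsketch hubs --links out/fixture/network.tsv \
    --seeds BatD,Hypo,BatE,BatB,BatA,BatC,MoxR,PA3071

# per-seed propagation profiles + summary
netsketch propagate --links out/fixture/network.tsv \
    --seeds BatD,Hypo,BatE,BatB,BatA,BatC,MoxR,PA3071 --out-dir out/prop

# simulate genomes along a guide tree (branch lengths = substitution
# proportions), sketch them, and build the supported tree
printf 'kind=genomes\ntree=((A:0.03,B:0.03):0.03,(C:0.03,D:0.03):0.03);\nlength=50000\nseed=8\n' > genomes.cfg
netsketch simulate --spec genomes.cfg --out-dir out/sim
netsketch phylo-sketch --fasta-dir out/sim/genomes --out out/dist.phylip
netsketch phylo-tree --matrix out/dist.phylip --out out/tree.nwk
```

`hubs` and `propagate` accept either a scored STRING-style links table
(3+ columns; `--threshold 0.4` on the normalised scale, 0–1000 files
auto-detected) or a bare 2-column edge list like the one `simulate` writes.
Every command accepts `--config file` with
flat `key=value` lines; precedence is flags > config > defaults, and each
run writes a JSON manifest (resolved configuration, inputs, seeds, warning
count).

## Layout

```
src/netsketch/
  net_io.py          interaction tables, confidence filter, seed networks
  propagation.py     shells, |D(r)|, r_s, degree moments, growth model
  sketch_phylo/      MinHash sketches, distances, NJ + BME + REQ trees
  synthetic_data.py  seeded network & genome generators, packaged fixture
  cli.py             click CLI: simulate, hubs, propagate, phylo-sketch, phylo-tree
  data/bat_fixture.tsv   frozen copy of gen_bat_fixture(42)
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
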