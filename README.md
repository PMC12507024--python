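# syncom-select

Function-based design of synthetic microbial communities (SynComs): select a
fixed-size consortium of genomes whose combined protein-family (Pfam)
repertoire best represents a group of metagenomes, with function weighting,
taxonomy-aware combinatorial ranking, and rule-based ecological viability
screening.

## How it works

Genomes and metagenomes are reduced to binary Pfam presence/absence vectors
(parsed from HMMER `tblout`/`domtblout` annotation output). Selection then
runs in four steps:

1. **Sample-specific greedy selection** — for each metagenome, genomes are
   scored by the number of matching Pfams (one point each, plus an additive
   per-Pfam weight for matches); the top genome is picked, its Pfams are
   masked, and the loop repeats up to a depth of 20 strains.
2. **Prevalence shortlist** — strains picked in at least 33.3% of samples are
   kept and all size-k combinations (default k = 10) are enumerated.
3. **Group scoring** — combinations containing two members of the same
   species (GTDB-Tk taxonomy) are dropped; the rest are scored as a single
   combined vector against every sample, and ranked by the mean ("group")
   score.
4. **Viability screen** — pairwise interactions are classified from growth
   data (a >10% relative growth change in co-culture vs alone is
   positive/negative); a community is viable when >50% of pairs are
   non-negative, every strain receives at least one positive effect, and
   every strain grows in the full-community run. Candidates are screened in
   rank order until one is viable.

Weighting promotes functions that are *core* to the target metagenomes
(>50% prevalence, +0.0005 by default) or *discriminatory* between two sample
groups (two-sided Fisher exact p < .05 on prevalence, +0.0012 by default).
A weight-estimation scan (`syncom weights`) re-runs selection over a grid of
weights to pick values for a new dataset.

External growth simulators plug in through a three-file CSV contract
(`alone.csv`, `pairs.csv`, `community.csv`); a deterministic toy simulator is
built in. The `syncom_select.synthetic` module generates complete seeded
fixtures (genomes, metagenomes, taxonomy, HMMER files, growth tables) so the
whole pipeline runs with no external data.

## CLI

```sh
syncom run --seed 1 --out outdir/        # end-to-end on the default synthetic fixture
syncom fixtures --seed 1 --out fx/       # write a full synthetic input set
syncom vectorize --input-dir tblout/ --dialect tblout --out matrix.tsv
syncom weights --samples A.tsv --samples2 B.tsv --genomes G.tsv \
    --strategy disc --grid-stop 0.01 --grid-step 0.0001 --out scan.csv
syncom select --samples A.tsv --genomes G.tsv --taxonomy gtdbtk.summary.tsv \
    --syn-size 10 --depth 20 --prevalence 0.333 --out outdir/
syncom viability --growth-dir growth/ --threshold 0.10 --out report.json
syncom screen --candidates ranked.csv --genomes G.tsv --samples A.tsv \
    --sim-config toy.yaml --seed 1 --out winner.json
```

`syncom run` exits 0 on a viable winner, 2 on input errors, 3 when too few
strains are shortlisted, and 4 when no screened candidate is viable. Profile
matrices are plain TSV (first column `entity_id`, then 0/1 Pfam columns);
all outputs are CSV/TSV/JSON.

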