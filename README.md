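# mcekit

A comparative-genomics toolkit for MCE-domain proteins. Starting from
per-domain HMMER hits, protein metadata, GFF3 gene annotation and
all-vs-all BLAST tabular alignments, it:

1. **assigns domain architectures** — gathering-threshold filtering,
   resolution of overlapping same-clan predictions (the most significant
   hit wins; MCE hits are never removed), ordering by start position —
   and classifies each protein as type **I** (one MCE domain), **II**
   (MCE + DUF3407), **III** (3 tandem MCE), **IV** (7 tandem MCE),
   `other_mce` or `non_mce`;
2. **aggregates prevalence** — one randomly chosen genome per species
   (seeded), then the percentage of species per phylum carrying each type;
3. **builds a sequence-similarity network** — greedy longest-first
   (CD-HIT-style) representative clustering at 50% identity, edges kept at
   e-value ≤ 1e-15, GraphML/SIF export for Cytoscape, connected-component
   summaries;
4. **clusters gene neighbourhoods** — up to 10 genes within 10 kb on each
   side of a focal MCE gene, orientation-normalized, compared with a
   centre-weighted similarity (w(i) = r^(|i|−1), r = 0.5) and agglomerated
   by single linkage until similarity drops below τ = 0.5, with per-type
   consensus patterns and percentages.

Because the original database snapshots are not reproducible offline, the
package ships a first-class synthetic-data generator (`mcekit.simulate`)
that emits all four input formats with planted ground truth (architectures,
species-level type presence, protein families separated across the e-value
threshold, and operon-style gene contexts), plus a hand-written miniature
*E. coli*-like fixture with the mla / pqi / yeb operon layouts.

## CLI

```sh
mcekit simulate --seed 1 --out out/data            # synthetic bundle + ground truth
mcekit architectures --hits out/data/hits.domtbl \
    --proteins out/data/proteins.tsv --out out/arch
mcekit prevalence --architectures out/arch/architectures.tsv \
    --proteins out/data/proteins.tsv --seed 1 --out out/prev
mcekit network --alignments out/data/alignments.tsv \
    --architectures out/arch/architectures.tsv \
    --proteins out/data/proteins.tsv --out out/net
mcekit neighbourhoods --gff out/data/genes.gff3 \
    --architectures out/arch/architectures.tsv --out out/nbhd
mcekit all --seed 1 --out out                      # the whole pipeline
```

Stage parameters (thresholds, synonym map, window size, decay ratio r,
stop threshold τ, linkage) live in a YAML config passed with `--config`;
defaults are the published parameters where they exist. Every output
directory gets a `manifest.json` with the seed, config echo, input SHA-256
digests and row counts; reruns with the same seed are byte-identical.

## Layout

```
src/mcekit/
  io.py             readers/writers: domtblout dialect, GFF3, BLAST outfmt 6, TSV
  architecture.py   threshold filtering, clan-overlap resolution, type classification
  prevalence.py     representative genomes, phylum × type matrix, eukaryote flagging
  network.py        greedy identity clustering, similarity graph, components, exports
  neighbourhood.py  slot extraction, weighted similarity, agglomeration, summaries
  simulate.py       synthetic bundles with planted ground truth; E. coli fixture
  cli.py            click subcommands, config, manifests
tests/              unit + property tests; test_acceptance.py (one test per criterion)
scripts/acceptance.py
```
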