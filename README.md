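# metboxscan

Comparative-genomics reconstruction of a repressor regulon built around an
8-bp palindromic operator box ("metbox"). The package:

- builds a **palindromic information weight matrix** from binding-site 8-mers
  (each box is symmetrized into two 4-bp half-sites; weights are
  `mu + log2(count / N)` bits with zero counts pseudocounted),
- **scans** strand-aware 400-bp upstream windows of annotated genes for
  tandem arrays of boxes under two consensus-derived thresholds (a single
  box needs >= 1/4 of the consensus score; a run of >= 2 abutting boxes
  needs the full consensus score),
- refines the matrix by a **two-stage bootstrap** (seed matrix ->
  preliminary scan of candidate-gene operators in one representative species
  per genus -> final matrix -> genome-wide scan -> per-order regulon
  summary),
- classifies **cross-species conservation** of site regions (+8-bp flanks)
  into strong (>= 70% identity), weak (>= 60%) and divergent tiers,
- computes **reporter-assay** Miller units and repression ratios, and
- generates **synthetic cohorts** with planted tandem sites and exact truth
  records so every stage is testable without downloads.

The published final counts table (832 half-sites) ships with the package and
is available as `metboxscan.published_matrix()`.

## CLI

All subcommands log to stderr, write artifacts plus a reproducible
`manifest.json`, and exit 1 on stage failures / 2 on usage errors.

```sh
# synthetic cohort with planted sites (FASTA + gene tables + truth)
metboxscan simulate --out-dir cohort/ --seed 1 --n-species 5 --genes-per-species 50

# matrix from a counts TSV or a plain-text list of 8-mers
metboxscan build-matrix --counts counts.tsv --out matrix.tsv
metboxscan build-matrix --boxes boxes.txt

# scan one genome for tandem sites (BED6 + detailed TSV)
metboxscan scan --genome cohort/sp00.fasta --genes cohort/sp00.genes.tsv --out-dir scanout/

# full two-stage bootstrap over a cohort directory
metboxscan discover --data-dir cohort/ --seed-boxes seeds.txt --out-dir disc/

# conservation tiers against a reference species
metboxscan conserve --contexts contexts.tsv --reference sp00 --out tiers.tsv

# regulon summary from existing site TSVs; reporter-assay ratios
metboxscan summarize --data-dir cohort/ --sites-dir disc/ --out-dir summary/
metboxscan assay --measurements assay.tsv --out ratios.tsv
```

Threshold, window, pseudocount and spacing knobs are exposed as flags
(`--tau-box`, `--tau-site`, `--window`, `--mu`, `--pseudocount`,
`--spacing-tolerance`).

## Python API

```python
import metboxscan as mb

iwm = mb.published_matrix()            # counts + bit weights, mu=2, pseudocount 1
iwm.score_window("AGACGTCT")           # 12.58 bits (the consensus)
th = mb.ScanThresholds.from_matrix(iwm)

genome = mb.read_genome("genome.fasta")
genes = mb.read_annotations("genes.gff3")
sites = mb.scan_genome(genome, genes, iwm, th, window=400)
```

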