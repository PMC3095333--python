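# apctools

A tested reimplementation of a comparative-genomics analysis of plant
anaphase-promoting complex (APC/C) subunits and activators:

- **Pairwise protein alignment** (Needleman–Wunsch and Smith–Waterman with
  affine gaps, BLOSUM62, gap open 10 / extend 0.5, free end gaps in global
  mode) reporting percent identity and similarity over the full alignment
  length — the statistics behind the published paralog identity figures.
- **TPR repeat detection**: a calibrated 34-column position-weight profile
  scans a protein, non-overlapping windows are kept greedily by score, and
  all-vs-all local-alignment score matrices between repeat units expose
  internal duplication patterns; diagonal runs of high-scoring cells are
  called as duplication blocks. A motif scanner flags the activator docking
  elements (C-box `DR[FY]IPxR`, C-terminal IR tail) and APC degrons (KEN,
  RxxL).
- **Distance phylogenetics**: Poisson-corrected distances
  (`d = -ln(1 - p)`, complete- or pairwise-deletion site handling),
  neighbor joining, column-resampling bootstrap with integer percent
  supports, and condensation of edges below a support threshold.
- **Ka/Ks**: Nei–Gojobori counting with equal-weight pathway averaging and
  Jukes–Cantor correction for orthologous CDS pairs.
- **Promoter motif over-representation**: overlapping IUPAC word counts, an
  empirical surrogate null from a background promoter set,
  `Z = (Ctrue - mean) / sd`, one-tailed normal p, 5% significance, and
  shared-element comparison between duplicated genes' promoters.
- **Synthetic data generators** for every stage (repeat proteins with
  planted duplications, sequences evolved along a known tree, CDS pairs
  with a planted dN/dS, promoter sets with planted motif enrichment), each
  emitting a JSON truth record.

## CLI

One executable, `apctools`, with per-stage subcommands:

```bash
apctools align proteins.fasta --ids OsCDC23_1 OsCDC23_2   # identity/similarity
apctools tpr detect proteins.fasta --id AtCDC27a          # repeat units
apctools tpr matrix proteins.fasta --id-a AtCDC27a --out m.tsv [--image m.png]
apctools tpr blocks m.tsv                                 # duplication blocks
apctools tpr motifs activators.fasta                      # C-box / IR / KEN / D
apctools phylo tree --aln aln.afa --bootstrap 2000 --seed 1 \
    --condense 50 --out tree.nwk
apctools kaks --pair a.fna b.fna
apctools motif enrich --promoters p.fa --background bg.fa \
    --motifs place.tsv [--both-strands] [--empirical]
apctools simulate {repeat-protein|tree-seqs|cds-pair|promoters} ...
apctools run config.yaml                                  # full pipeline
```

`apctools run` executes the stages named in a YAML config (see the
docstring of `apctools/pipeline.py` for the layout), writes per-stage TSVs,
Newick trees and a summary table, and records provenance (config hash,
seeds, version). Reruns of an unchanged config are byte-identical. Exit
codes: 0 success, 2 config error, 3 stage failure.

## Reference data

The published identity percentages, repeat counts and the 61-sequence
census refer to a supplementary FASTA of APC subunit and activator
proteins (Arabidopsis/rice/poplar and other species; TAIR, TIGR and JGI
gene identifiers) that is **not redistributable** with this repository and
cannot be fetched in an offline environment. To run those analyses, drop
the file at `data/apc_proteins.fasta` or set `APCTOOLS_PROTEINS=/path/to/it`.
Records are located by configurable regex alternatives (gene symbol or
locus id — see `apctools/reference.py`), so header naming schemes are not
hard-coded. Without the file, the acceptance tests covering those figures
fail with an explanatory message and `scripts/acceptance.py` omits the
corresponding targets.

The packaged TPR profile (`src/apctools/data/tpr_profile.tsv`, version 1)
is a BLOSUM62 profile on the idealized 34-residue TPR consensus with a
threshold calibrated to separate repeat units at up to ~40% point mutation
from random sequence. The packaged motif table
(`src/apctools/data/place_motifs.tsv`) is a small demonstration subset of
named plant cis-element words; supply a full table for real analyses.

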