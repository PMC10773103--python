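# taxdecon

Foreign contamination in RNA-Seq samples — reads from bacteria, fungi, or
the humans who handled the tube — degrades de novo transcriptome assembly:
it produces contaminated and chimeric transcripts that survive into the
final assembly, which matters most for organisms with no reference genome
to check against. `taxdecon` implements a taxonomy-structured screening
workflow that removes such reads *before* assembly, plus the post-assembly
filters used to clean the transcript set afterwards.

## What it does

**Taxonomy-partitioned databases.** All taxa under the four superkingdoms
are partitioned into 19 mutually exclusive, hierarchical groups
(Bacteria, Archaea, Liliopsida, Eudicotyledons, Viridiplantae, Fungi,
Arthropoda, Neoteleostei, Actinopterygii, Glires, Primates, Carnivora,
Artiodactyla, Amphibia, Sauropsida, Sarcopterygii, Chordata, Eukaryota,
Viruses). A taxid belongs to the group whose anchor clade is the *deepest*
anchor in its lineage, so a monocot is Liliopsida rather than
Viridiplantae, and a mollusc falls through Metazoa to Eukaryota. From
assembly metadata the package selects one assembly per taxon (reference
genome if available, else the latest), discards unplaced scaffolds and
the `NW_`/`NZ_` accession prefixes (keeping `NZ_CM`/`NZ_CP` complete
chromosomes), and writes per-group databases as three files: FASTA,
accession↔taxid map, and a byte-offset index for direct record extraction.

**Two-step read screening.** Step 1 aligns every read against the target
organism's group; a read with a passing hit is *correct*. Step 2 aligns
only the remainder against the other 18 groups; a read is a *contaminant*
of the group holding its best hit (max bitscore), otherwise
*unidentified*. A hit counts as a match when

> identity > 75 %, query coverage > 75 %, e-value < 10⁻⁵

(all strict), with blastn-style scoring (+2/−3, gap 5/2) and
Karlin–Altschul statistics `E = K·m·n·e^(−λS)`. Reads kept for assembly
are correct + unidentified by default, or correct only for well-annotated
organisms. Hits can come from external BLAST outfmt-6 files or from the
built-in seed-and-verify Smith–Waterman aligner.

**Simulation with ground truth.** A fixture world generator builds a
taxonomy spanning all 19 groups and one genome per group with *no shared
31-mer between groups*, tiles or samples reads from a target
transcriptome, and spikes contaminants at fixed proportions (default
4 % Bacteria, 1 % Archaea, 10 % Fungi, 1 % each
Arthropoda/Chordata/Metazoa/Eukaryota/Viruses = 20 % of the sample), with
truth labels encoded in the read ids.

**Post-assembly filters.** TPM ≥ 2.5 expression cutoff, a vector screen,
a foreign-transcript screen (best-hit group vs. target group), and
exon-coverage quantification: transcript-vs-genome HSPs intersected with
annotated exon intervals, reported per transcript and binned
(>80 %, 60–80, 40–60, 20–40, ≤20, no match).

## Worked example

```bash
python examples/classify_spiked_sample.py
```

builds a fixture world, spikes a 2,000-read sample and screens it:

```
sample: 2000 reads (1600 clean + 400 spiked)

screen report (target group = Eudicotyledons):
  Bacteria           4.00%  (80 reads)
  Eudicotyledons    80.00%  (1600 reads)
  Fungi             10.00%  (200 reads)
  Arthropoda         1.00%  (20 reads)
  ...
reads for assembly: 1600 (80.00%) -- correct + unidentified

per-source recovery (fraction of reads assigned to the expected group):
  Bacteria     100.00%
  Fungi        100.00%
  target       100.00%
  ...
```

The 1,600 clean reads are classified correct, the 400 spiked reads land
in their source groups (20 % contaminant exactly), and nothing is
unidentified — the expected outcome when the source genomes share no
k-mer across groups. `examples/` holds similar walk-throughs for database
building, the aligner/criteria, and the post-assembly filters. The same
workflow is scriptable from a shell via `taxdecon simulate|build|classify|post`.

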