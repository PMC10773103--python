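# Methods

## The partition model

The package organises sequence databases by clade rather than by a flat
taxid list. Each of the 19 groups is defined by an *anchor clade* given by
scientific name (Bacteria, Archaea, Liliopsida, eudicotyledons,
Viridiplantae, Fungi, Arthropoda, Neoteleostei, Actinopterygii, Glires,
Primates, Carnivora, Artiodactyla, Amphibia, Sauropsida, Sarcopterygii,
Chordata, Eukaryota, Viruses). A taxid is assigned to the group whose
anchor sits deepest in its lineage. Because anchors are nested clades,
this most-specific-wins rule makes the partition total (over taxa under
the four superkingdoms), single-valued, and independent of the order in
which groups are listed. Ranks are ignored — the groups mix kingdoms,
classes and unranked clades, so ancestry alone decides.

Choices made where the design was open:

* Anchors are resolved by scientific name against the loaded tree at run
  time, not hard-coded as taxids, so the same table works on the public
  taxonomy and on fixture trees. A duplicated scientific name makes the
  anchor ambiguous and is an error, never an arbitrary pick.
* Taxa outside every anchor (e.g. "unclassified sequences" directly under
  the root) raise an error rather than being silently binned.
* Two distinct anchors at the same depth of one lineage cannot occur in a
  tree; the code still guards the case and fails loudly on corrupt input.
* `merged.dmp` remaps are applied on lookup; unmapped taxids error.

## Database construction

Per taxon, the reference genome wins; otherwise the latest release date,
with ties broken by accession string descending so builds are
deterministic. Unplaced scaffolds are dropped (they are the usual home of
submission contamination), as are accessions with `NW_`/`NZ_` prefixes
except `NZ_CM`/`NZ_CP` (complete chromosomes). The exclusion list is
configurable; only these two prefixes are excluded by default. Each group
is written as FASTA (fixed 80-column wrap), an accession↔taxid map, and an
accession/taxid/byte-offset index; offsets address the `>` byte of each
record so extraction is a single seek. Record order is (taxid, assembly
accession, input order), which together with the fixed wrapping makes
rebuilds byte-identical.

## Alignment and match criteria

A read–subject hit is a *match* iff identity > 75 %, query coverage
> 75 % and e-value < 10⁻⁵, all strict bounds. Coverage is per-HSP
(aligned query span / read length); for ≥100 bp reads summing HSPs makes
little difference, and a summed-interval variant remains available
through the hit contract. Identity is counted over alignment columns
including gaps, the blastn convention.

The built-in aligner exists so the whole workflow runs without an
external aligner. It is a Gotoh affine-gap local aligner (match +2,
mismatch −3, gap open 5, gap extend 2 — the classic blastn scheme for a
−3 mismatch penalty; a gap of length L costs open + L·extend) preceded by
exact k-mer seeding (k = 31): a read's k-mers on both strands nominate
candidate diagonals, exact full-length placements short-circuit the DP,
and everything else is verified by DP on a window around the seed.
Consequences to be aware of:

* A read sharing no 31-mer with a subject produces **no** hit. This is a
  deliberate sensitivity floor, far above the match criteria's own
  requirements for ≥100 bp reads, and it is what makes recovery on the
  synthetic data exact. It is not a general-purpose BLAST replacement.
* E-values use Karlin–Altschul `E = K·m·n·e^(−λS)` with n the total
  database length. λ is the ungapped value solved from
  Σ pᵢpⱼ·e^(λ·sᵢⱼ) = 1 at uniform base composition (0.6337 for +2/−3)
  and K = 0.41; e-values are therefore backend-dependent, and parsed
  external hits simply carry their own.
* One best alignment per strand per subject is reported.

External hits are consumed from outfmt-6 tabular files with the column
set `qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore staxids qlen` (configurable).

## Two-step screening

Step 1 screens all reads against the target group only; matched reads are
final ("correct") and are never aligned against other groups — this
reproduces the intended behaviour for horizontally transferred genes
present in the target group's sequences. Step 2 screens the remainder
against the other groups and assigns each read to the group of its best
passing hit; the tie order is bitscore, then lower e-value, then group
order in the table (ties are logged). Reads are processed in chunks
(default 50,000, matching the FASTQ→FASTA splitting used at production
scale); chunking is I/O only and classification is invariant to it
(tested at chunk sizes 7, 1,000 and 50,000).

Paired-end policy (the workflow is defined per read; a policy is needed
when filtering pairs): a pair is contaminant if either mate is
contaminant; else correct if either mate is correct; else unidentified.
Both mates are kept or dropped together. The policy is configurable.

Reports carry exact counts alongside 2-decimal percentages; rounded
columns may sum to 99.99 or 100.01.

## Synthetic data

The generator emulates the study conditions, not real sequencing:

* ~60-node taxonomy covering every group anchor plus the instructive
  edge cases (plants split three ways; mammals nested under
  Sarcopterygii; a tunicate staying at Chordata; a mollusc whose group is
  Eukaryota; unclassified entries that must error).
* One random genome per source species, 6–12 kb (sizes chosen to keep the
  19-database screen comfortable on one CPU), regenerated in the
  astronomically unlikely event two sources share a canonical 31-mer. The
  target transcriptome is 20 substrings (300–1,500 bp) of the target
  genome.
* Reads are error-free extracts: tiled 100-mers every 50 bp (transcripts
  shorter than one read yield none, with a warning), or length-weighted
  random paired-end fragments (normal fragment length 300 ± 30, mates on
  opposite strands). Qualities are constant `I`.
* Spiking: the default profile (Bacteria 4 %, Archaea 1 %, Fungi 10 %,
  Arthropoda/Chordata/Metazoa/Eukaryota/Viruses 1 % each) is expressed as
  fractions of the *final* sample, so the default sums to the intended
  20 % contamination. Integer counts use round-then-largest-remainder so
  they sum exactly. The "Metazoa" source keeps its truth label but its
  expected assignment is Eukaryota, which the evaluation harness encodes
  via an explicit truth-label → expected-group map.

What passing on this data does **not** show: robustness to sequencing
error, quality variation, cross-group homology (real clades share
sequence), database incompleteness, or rRNA/cognate contamination. The
synthetic setting isolates the bookkeeping — partition correctness,
screening order, threshold boundaries, conservation — which is exactly
what it is used to verify.

## Post-assembly filters

* TPM filter: keep ≥ 2.5 (inclusive); duplicate transcript ids are an
  error; the filter is idempotent.
* Vector screen: a transcript is flagged on any hit clearing the strict
  identity and e-value bounds. The query-coverage bound is *off* by
  default because a vector insert is normally a small fraction of its
  transcript; `require_query_coverage=True` restores the full criteria.
* Foreign-transcript screen: best passing hit (bitscore, then e-value)
  decides; a transcript is contaminant iff that hit's taxid partitions
  into a non-target group. Best-hit rather than any-hit avoids flagging
  transcripts with strong target homology plus a weak foreign hit.
* Exon coverage: HSP genome intervals (minus-strand coordinates
  normalised; strand otherwise ignored) are merged and intersected with
  each candidate isoform's merged exon intervals; coverage is the
  percentage of exon bases touched. Best isoform is the argmax, ties to
  the larger exon total then the smaller id. Bins are (80,100], (60,80],
  (40,60], (20,40], [0,20] plus no-match; the top edge is strict (>80 %)
  and the edges are configurable since only the top class is fixed by
  convention. External coordinates stay 1-based inclusive (BLAST, GFF3);
  interval arithmetic is 0-based half-open internally with conversion at
  the boundary.

The intron-retention class of false positives (a transcript assembled
from intronic coverage that matches no annotated isoform) is documented
but has no detection rule here; with no reference genome it is not
reliably detectable, and no heuristic is attempted.

## Problem sizes and determinism

The test suite and the acceptance script run the full workflow at desk
scale: 2,000-read samples for end-to-end classification, 100,000 reads
for the spike arithmetic, 500 random pairs for the aligner-vs-DP
cross-check (independent oracle: Biopython's `PairwiseAligner` in local
mode) and 1,000 random interval fixtures for the coverage-vs-bitmask
cross-check. All randomness funnels through seeded numpy generators;
equal seeds give byte-identical databases, worlds and samples.

## Known limitations

* The built-in aligner's seed requirement bounds its sensitivity; for
  production screening, bring BLAST tabular output (the
  `PrecomputedAligner` path) and use the package for the partitioning,
  bookkeeping and reporting.
* Group databases are held as plain FASTA with a Python k-mer index;
  memory scales with database size, which is fine at fixture scale and
  intentionally not engineered beyond it.
* The NCBI Datasets metadata converter maps report fields only; sequence
  payloads must be attached separately.
* Virus-host composite samples (e.g. a virus sequenced from host tissue)
  are reported like any other: host reads count as contaminants of the
  host's group. No special-casing is applied.
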