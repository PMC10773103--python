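"""Post-assembly transcript filtering and exon-coverage binning.

Applies the TPM >= 2.5 expression cutoff, the vector screen, and the
foreign-transcript screen to a toy assembled transcript set, then
quantifies how well transcripts cover annotated isoform exons.
"""

from taxdecon.align import AlignmentHit
from taxdecon.postassembly import (
    GenomeHSP,
    IsoformModel,
    QuantRecord,
    bin_coverage_report,
    exon_coverage,
    filter_tpm,
    foreign_transcript_screen,
    vector_screen,
)
from taxdecon.simulate import make_fixture_world

# --- expression filter ------------------------------------------------------
quants = [
    QuantRecord("tr1", 120.0),
    QuantRecord("tr2", 2.5),    # exactly at the cutoff: kept
    QuantRecord("tr3", 2.49),   # just below: dropped
    QuantRecord("tr4", 0.1),
]
kept = filter_tpm(quants, cutoff=2.5)
print(f"TPM filter keeps {kept} of {[q.transcript_id for q in quants]}")

# --- vector screen ----------------------------------------------------------
vector_hit = AlignmentHit(
    "tr1", "uv:pUC19", 99.0, 60, 0, 0, 301, 360, 1, 60, 1e-25, 110.0, query_length=900
)
print(f"vector screen flags: {sorted(vector_screen([vector_hit]))} "
      "(a 60-bp insert in a 900-bp transcript still counts)")

# --- foreign-transcript screen ---------------------------------------------
world = make_fixture_world(seed=7)
group_of = world.taxid_partition().assignment
hits = [
    # tr2's best nucleotide hit is bacterial -> contaminant
    AlignmentHit("tr2", "NC_900001.1", 98.0, 95, 1, 0, 1, 95, 1, 95, 1e-40, 180.0,
                 subject_taxid=294, query_length=100),
    # tr1 hits the target dicot more strongly than anything foreign
    AlignmentHit("tr1", "NC_900004.1", 99.0, 98, 0, 0, 1, 98, 1, 98, 1e-45, 195.0,
                 subject_taxid=4081, query_length=100),
]
foreign = foreign_transcript_screen(hits, target_group="Eudicotyledons", group_of=group_of)
print(f"foreign transcripts: {foreign}")

# --- exon coverage ----------------------------------------------------------
isoform = IsoformModel("iso1", "chr1", "+", exons=[(101, 200), (301, 400)])
calls = [
    exon_coverage([GenomeHSP("trA", "chr1", 1, 200, 101, 400, 99.0, 300.0)], [isoform]),
    exon_coverage([GenomeHSP("trB", "chr1", 1, 100, 101, 200, 99.0, 150.0)], [isoform]),
    exon_coverage([], [isoform]),
]
for call in calls:
    print(f"  {call.transcript_id or '(no HSPs)':<10} coverage={call.coverage:6.2f}%  bin={call.bin}")
print(f"bin histogram: {bin_coverage_report(calls)}")
print("\ntrA spans both exons (100%, bin gt80); trB covers one of two equal "
      "exons (50%, bin b40_60); a transcript with no HSP is 'no_match'.")
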