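"""Structurally annotate one provirus: LTRs, TSD, ORFs, deletions, MER11.

Implants a recombinant provirus carrying the shared pro-pol deletion
(consensus coordinates 3384-5639), then recovers its structure: terminal
LTRs and the target-site duplication, per-gene ORF status under the
90%-completeness rule, the deletion matched against the shared catalog,
and the HML-8-LTR-derived MER11 region.
"""

from paleoerv.annotate import annotate_locus
from paleoerv.mining import LocusRecord
from paleoerv.simulate import ImplantSpec, implant, make_element_library, simulate_host_genome

library = make_element_library(1)
genome = simulate_host_genome(1, 60_000, 0.41, seed=3)
spec = ImplantSpec(
    "chr1", 30_000, age_myr=4.0, deletions=("pro_pol",),
    recombinant=True, ltr_variant="Δ1+Δ2", tsd_len=6,
)
genome, truth = implant(genome, spec, library, seed=5)

record = LocusRecord(
    name=truth.locus_id,
    seq=genome["chr1"][truth.start - 1000 : truth.end + 1000],
    flank=1000, strand="+", chrom="chr1", start=truth.start, end=truth.end,
)
ann = annotate_locus(record, library)

print(f"locus {ann.name}: LTR variant {ann.ltr_variant}, "
      f"TSD match {ann.tsd_match} ({ann.tsd_up})")
print(f"recombinant: {ann.recombinant} "
      f"(MER11 identity {ann.mer11_identity:.2f})")
print("shared deletions:", ann.deletions)
for gene, call in ann.orf_status.items():
    extra = f" at codon {call.disruption_codon}" if call.disruption_codon else ""
    print(f"  {gene}: {call.status}{extra}")
# pro is disrupted and pol mostly removed by the 2256-bp pro-pol deletion;
# gag and env remain intact.
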