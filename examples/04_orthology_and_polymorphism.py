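"""Cross-species presence calls, OCA assignment, and allele frequencies.

Derives four Old-World-monkey genomes from a focal assembly (insertions
shared according to a species tree, flanks diverged), then determines
presence/absence of each insertion by flanking-junction intactness and
places it on the tree as its oldest common ancestor. Finally computes
insertion allele frequencies from a 3-primer PCR genotype table.
"""

from paleoerv.orthology import (
    allele_frequency, assign_oca, classify_polymorphism, presence_matrix,
)
from paleoerv.simulate import simulate_genotype_table, simulate_study, speciate

TREE = "(((Mmul:1,Mfas:1)mac:1,Panu:2)cerc:2,Rrox:4)owm;"

study = simulate_study(
    seed=2, n_chrom=1, chrom_len=800_000,
    n_full=4, n_pro_pol=1, n_pol_env=1, n_both=0,
    n_nonrecomb=0, n_solo=1, n_decoy=1,
)
patterns = [
    {"Mmul": True, "Mfas": False, "Panu": False, "Rrox": False},  # rhesus-specific
    {"Mmul": True, "Mfas": True, "Panu": True, "Rrox": True},     # all-OWM
]
presence = {r.locus_id: dict(patterns[i % 2]) for i, r in enumerate(study.truth)}
genomes, truth = speciate(
    study.assembly, study.truth, TREE, "Mmul", presence,
    flank_divergence=0.005, seed=4,
)

loci = [r for r in truth if not r.decoy]
matrix = presence_matrix(loci, study.assembly, genomes, "Mmul")
print(matrix)
for locus_id in matrix.index[:4]:
    oca = assign_oca(matrix.loc[locus_id].to_dict(), TREE, "Mmul")
    print(f"{locus_id}: oldest common ancestor = {oca}")
# rhesus-specific insertions map to the Mmul terminal branch; shared ones
# to the OWM root, mirroring junction-based presence calls.

table = simulate_genotype_table(
    ["locusA", "locusB"], 14, {"locusA": 3 / 28, "locusB": 1.0}, seed=6
)
for locus in ("locusA", "locusB"):
    res = allele_frequency(table, locus)
    cls = classify_polymorphism(table, locus)
    print(f"{locus}: frequency {100 * res.frequency:.1f}% "
          f"({res.insertion_alleles}/{res.total_alleles} alleles), {cls}")
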