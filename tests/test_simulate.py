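"""Generator contracts: determinism, structural layout, clock calibration."""

import numpy as np
import pytest

from paleoerv.simulate import (
    ImplantSpec,
    emit_repeatmasker_track,
    implant,
    implant_many,
    make_element_library,
    mutate_ltr_pair,
    simulate_flow_events,
    simulate_genotype_table,
    simulate_host_genome,
    simulate_spliced_reads,
    speciate,
)


class TestElementLibrary:
    def test_consensus_terminal_ltrs_identical(self, library):
        c = library.consensus_provirus
        assert c[:588] == c[-588:] == library.short_ltr

    def test_deterministic_for_seed(self):
        a, b = make_element_library(3), make_element_library(3)
        assert a.consensus_provirus == b.consensus_provirus
        assert a.mer11_ref == b.mer11_ref
        assert a.decoy_families == b.decoy_families

    def test_mer11_region_length(self, library):
        # the recombinant clade is defined by a 726-bp HML-8-LTR-derived
        # region between env and the 3' LTR
        assert len(library.mer11_ref) == 726

    def test_orfs_translate_without_internal_stops(self, library):
        from Bio.Seq import Seq

        for gene, seq in library.genes.items():
            aa = str(Seq(seq).translate())
            assert aa.startswith("M")
            assert "*" not in aa[:-1], gene
            assert aa.endswith("*")

    def test_recombinant_tail_composition(self, library):
        tail = library.recombinant_tail
        assert tail == library.hml8_env_tail + library.mer11_ref + library.ppt_remnant
        assert len(library.ppt_remnant) == 42
        assert set(library.ppt_remnant) <= {"A", "G"}

    def test_splice_model_geometry(self, library):
        m = library.splice_model
        assert m.donor < m.acceptor
        assert m.exon1_nt == 261 and m.exon2_nt == 189
        assert m.exon1_nt % 3 == 0 and m.exon2_nt % 3 == 0


class TestHostGenome:
    def test_length_contract(self):
        g = simulate_host_genome(1, 100_000, 0.41, 7)
        assert set(g) == {"chr1"} and len(g["chr1"]) == 100_000

    def test_gc_content(self):
        g = simulate_host_genome(1, 1_000_000, 0.41, 7)["chr1"]
        gc = (g.count("G") + g.count("C")) / len(g)
        assert abs(gc - 0.41) < 0.01

    def test_deterministic(self):
        assert simulate_host_genome(2, 5000, 0.5, 3) == simulate_host_genome(2, 5000, 0.5, 3)

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            simulate_host_genome(1, 0, 0.4, 1)
        with pytest.raises(ValueError):
            simulate_host_genome(1, 1000, 1.5, 1)


class TestMutateLtrPair:
    def test_zero_age_identical(self, library):
        l5, l3 = mutate_ltr_pair(library.short_ltr, 0.0, seed=1)
        assert l5 == l3 == library.short_ltr

    def test_clock_calibration(self, library):
        # mean pairwise differences over replicates at age 10 Myr should be
        # ~ L * rate * age = 588 * 0.0034 * 10 = 20
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(500):
            l5, l3 = mutate_ltr_pair(library.short_ltr, 10.0, seed=rng)
            diffs.append(sum(a != b for a, b in zip(l5, l3)))
        expected = 588 * 0.0034 * 10
        se = np.sqrt(2 * expected / 2 / 500) * np.sqrt(2)
        assert abs(np.mean(diffs) - expected) < max(3 * se, 1.0)

    def test_single_difference_half_myr(self, library):
        # 0.5 Myr is the expected waiting time for one difference between
        # two 588-bp LTRs at the default rate
        rng = np.random.default_rng(7)
        diffs = [
            sum(a != b for a, b in zip(*mutate_ltr_pair(library.short_ltr, 0.5, seed=rng)))
            for _ in range(500)
        ]
        assert abs(np.mean(diffs) - 1.0) < 0.2

    def test_negative_age_rejected(self, library):
        with pytest.raises(ValueError):
            mutate_ltr_pair(library.short_ltr, -1.0)


class TestImplant:
    def test_solo_ltr_inserted_length(self, library):
        genome = simulate_host_genome(1, 50_000, 0.5, 2)
        spec = ImplantSpec("chr1", 20_000, solo_ltr=True, recombinant=False,
                           ltr_variant="Δ1+Δ2", tsd_len=6)
        new, row = implant(genome, spec, library, seed=0)
        assert len(new["chr1"]) - len(genome["chr1"]) == 588 + 6
        assert row.end - row.start == 588

    def test_pro_pol_deletion_shortens_element(self, library):
        genome = simulate_host_genome(1, 80_000, 0.5, 2)
        full = ImplantSpec("chr1", 30_000, recombinant=False, ltr_variant="Δ1+Δ2")
        deleted = ImplantSpec("chr1", 30_000, recombinant=False,
                              ltr_variant="Δ1+Δ2", deletions=("pro_pol",))
        _, row_full = implant(genome, full, library, seed=0)
        _, row_del = implant(genome, deleted, library, seed=0)
        # printed coordinates 3384-5639 (1-based inclusive) span 2256 bases
        assert (row_full.end - row_full.start) - (row_del.end - row_del.start) == 2256

    def test_zero_age_ltrs_identical_and_truth_sequence_exact(self, library):
        genome = simulate_host_genome(1, 80_000, 0.5, 2)
        spec = ImplantSpec("chr1", 30_000, age_myr=0.0, ltr_variant="Δ1+Δ2")
        new, row = implant(genome, spec, library, seed=0)
        elem = new["chr1"][row.start : row.end]
        assert elem == row.element_seq
        assert elem[:588] == elem[-588:]
        assert row.tsd_up == row.tsd_down

    def test_minus_strand_reverse_complement(self, library):
        from Bio.Seq import Seq

        genome = simulate_host_genome(1, 80_000, 0.5, 2)
        plus = ImplantSpec("chr1", 30_000, strand="+", age_myr=0.0)
        minus = ImplantSpec("chr1", 30_000, strand="-", age_myr=0.0)
        new_p, row_p = implant(genome, plus, library, seed=5)
        new_m, row_m = implant(genome, minus, library, seed=5)
        assert row_m.element_seq == str(Seq(row_p.element_seq).reverse_complement())

    def test_unknown_deletion_name_rejected(self, library):
        genome = simulate_host_genome(1, 80_000, 0.5, 2)
        with pytest.raises(ValueError, match="unknown deletion"):
            implant(genome, ImplantSpec("chr1", 30_000, deletions=("nope",)),
                    library, seed=0)

    def test_solo_with_deletions_rejected(self):
        with pytest.raises(ValueError):
            ImplantSpec("chr1", 10, solo_ltr=True, deletions=("pro_pol",))


class TestTrack:
    def test_full_provirus_record_count(self, library):
        genome = simulate_host_genome(1, 80_000, 0.5, 2)
        _, row = implant(genome, ImplantSpec("chr1", 30_000, recombinant=False),
                         library, seed=0)
        genome2, row2 = implant(genome, ImplantSpec("chr1", 30_000, recombinant=True),
                                library, seed=0)
        from paleoerv.simulate import TruthTable

        recs = emit_repeatmasker_track(genome, TruthTable([row]), "none", 0)
        assert len(recs) == 3  # LTR, internal, LTR
        recs2 = emit_repeatmasker_track(genome2, TruthTable([row2]), "none", 0)
        assert len(recs2) == 4
        assert sum(r.family == "MER11A" for r in recs2) == 1

    def test_decoy_family_labeled(self, small_study):
        recs = emit_repeatmasker_track(small_study.assembly, small_study.truth, "none", 0)
        decoy_names = set(small_study.library.decoy_families)
        assert {r.family for r in recs if r.family in decoy_names}

    def test_deterministic(self, small_study):
        a = emit_repeatmasker_track(small_study.assembly, small_study.truth, "split", 3)
        b = emit_repeatmasker_track(small_study.assembly, small_study.truth, "split", 3)
        assert a == b


class TestSpeciate:
    TREE = "(((Mmul:1,Mfas:1)mac:1,Panu:2)cerc:2,Rrox:4)owm;"

    def _presence(self, truth, pattern):
        return {r.locus_id: dict(pattern) for r in truth}

    def test_absent_species_has_clean_empty_site(self, small_study):
        pattern = {"Mmul": True, "Mfas": False, "Panu": False, "Rrox": False}
        genomes, truth = speciate(
            small_study.assembly, small_study.truth, self.TREE, "Mmul",
            self._presence(small_study.truth, pattern),
            flank_divergence=0.0, seed=1,
        )
        # with zero divergence the absent-species genome is exactly the
        # pre-integration background
        total_inserted = sum(
            (r.end - r.start) + r.tsd_len for r in small_study.truth
        )
        assert len(genomes["Mfas"]["chr1"]) == len(small_study.assembly["chr1"]) - total_inserted

    def test_ancestral_element_present_everywhere(self, small_study):
        pattern = {"Mmul": True, "Mfas": True, "Panu": True, "Rrox": True}
        genomes, truth = speciate(
            small_study.assembly, small_study.truth, self.TREE, "Mmul",
            self._presence(small_study.truth, pattern),
            flank_divergence=0.0, seed=1,
        )
        for sp in ("Mfas", "Panu", "Rrox"):
            assert genomes[sp]["chr1"] == small_study.assembly["chr1"]
            assert all(r.presence[sp] for r in truth)

    def test_unknown_species_rejected(self, small_study):
        with pytest.raises(ValueError, match="not on tree"):
            speciate(
                small_study.assembly, small_study.truth, self.TREE, "Mmul",
                {small_study.truth.rows[0].locus_id: {"Hsap": True}}, seed=1,
            )


class TestSplicedReads:
    def test_zero_fraction_no_gaps(self, library):
        reads = simulate_spliced_reads(
            library.recombinant_provirus, library.splice_model,
            200, 100, 0.0, seed=1,
        )
        assert all("N" not in r["cigar"] for r in reads)

    def test_junction_gap_spans_intron(self, library):
        m = library.splice_model
        reads = simulate_spliced_reads(
            library.recombinant_provirus, m, 500, 100, 0.5, seed=1
        )
        gapped = [r for r in reads if "N" in r["cigar"]]
        assert gapped
        import re

        for r in gapped:
            n_len = int(re.search(r"(\d+)N", r["cigar"]).group(1))
            assert n_len == m.acceptor - m.donor

    def test_junction_count_binomial(self, library):
        reads = simulate_spliced_reads(
            library.recombinant_provirus, library.splice_model,
            1000, 100, 0.2, seed=9,
        )
        n_gap = sum("N" in r["cigar"] for r in reads)
        assert abs(n_gap - 200) < 3 * np.sqrt(160)

    def test_read_len_bound(self, library):
        with pytest.raises(ValueError):
            simulate_spliced_reads("ACGT" * 10, library.splice_model, 10, 100, 0.1)


class TestEventAndGenotypeTables:
    def test_flow_deterministic(self):
        a = simulate_flow_events(1000, seed=5)
        b = simulate_flow_events(1000, seed=5)
        assert a.equals(b)

    def test_flow_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            simulate_flow_events(0)

    def test_genotypes_fixed_and_absent(self):
        t = simulate_genotype_table(["a", "b"], 10, {"a": 1.0, "b": 0.0}, seed=1)
        assert (t["a"] == "+/+").all()
        assert (t["b"] == "-/-").all()

    def test_genotype_frequency_bounds(self):
        with pytest.raises(ValueError):
            simulate_genotype_table(["a"], 5, {"a": 1.2}, seed=1)


class TestImplantMany:
    def test_truth_intervals_exact_and_nonoverlapping(self, small_study):
        truth = sorted(small_study.truth, key=lambda r: (r.chrom, r.start))
        for a, b in zip(truth, truth[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start
        for r in truth:
            assert small_study.assembly[r.chrom][r.start : r.end] == r.element_seq

    def test_deterministic(self):
        from paleoerv.simulate import simulate_study

        a = simulate_study(5, n_chrom=1, chrom_len=300_000, n_full=2, n_pro_pol=1,
                           n_pol_env=1, n_both=0, n_nonrecomb=1, n_solo=1, n_decoy=1)
        b = simulate_study(5, n_chrom=1, chrom_len=300_000, n_full=2, n_pro_pol=1,
                           n_pol_env=1, n_both=0, n_nonrecomb=1, n_solo=1, n_decoy=1)
        assert a.assembly == b.assembly
        assert [r.locus_id for r in a.truth] == [r.locus_id for r in b.truth]
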