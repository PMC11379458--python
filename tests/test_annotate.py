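"""Structural annotation: alignment substrate, LTR/TSD, ORFs, deletions,
recombinant region, breakpoints, LTR typing, consensus."""

import numpy as np
import pytest

from paleoerv.annotate import (
    OrfPolicy,
    annotate_locus,
    call_orfs,
    detect_deletions,
    detect_mer11_region,
    find_terminal_ltrs_and_tsd,
    majority_consensus,
    match_shared_deletions,
    pairwise_align_affine,
    scan_breakpoints,
    type_ltr_deletions,
)
from paleoerv.simulate import ImplantSpec, implant, simulate_host_genome

from conftest import diverge, random_seq


class TestPairwiseAlignment:
    def test_identical_sequences(self, rng):
        s = random_seq(rng, 500)
        aln = pairwise_align_affine(s, s)
        assert aln.identity == 1.0
        assert aln.n_gap_columns == 0
        assert aln.score == 2 * len(s)

    def test_single_block_deletion(self, rng):
        ref = random_seq(rng, 6000)
        query = ref[:2000] + ref[2000 + 2256 :]
        aln = pairwise_align_affine(query, ref)
        runs = [r for r in aln.ref_gap_runs() if r[1] - r[0] >= 50]
        assert len(runs) == 1
        s, e = runs[0]
        assert e - s == 2256

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align_affine("", "ACGT")


class TestLtrTsd:
    def _locus_record(self, library, spec, seed=0):
        genome = simulate_host_genome(1, 60_000, 0.5, 3)
        new, row = implant(genome, spec, library, seed=seed)
        seq = new["chr1"][row.start - 1000 : row.end + 1000]
        return seq, row

    def test_matching_tsd_detected(self, library):
        seq, row = self._locus_record(
            library, ImplantSpec("chr1", 30_000, age_myr=2.0, tsd_len=6)
        )
        res = find_terminal_ltrs_and_tsd(seq, 1000, [library.full_ltr, library.short_ltr])
        assert res.status == "ok"
        assert res.tsd_match
        # the detected duplication may extend the true TSD by chance-matching
        # adjacent bases; it must contain it
        assert row.tsd_up in res.tsd_up

    def test_mismatched_tsd_flags_translocation(self, library):
        seq, _ = self._locus_record(
            library, ImplantSpec("chr1", 30_000, mismatched_tsd=True)
        )
        res = find_terminal_ltrs_and_tsd(seq, 1000, [library.full_ltr, library.short_ltr])
        assert res.status == "ok"
        assert not res.tsd_match

    def test_solo_ltr_single_interval(self, library):
        seq, _ = self._locus_record(
            library,
            ImplantSpec("chr1", 30_000, solo_ltr=True, recombinant=False,
                        ltr_variant="full"),
        )
        res = find_terminal_ltrs_and_tsd(seq, 1000, [library.full_ltr, library.short_ltr])
        assert res.status == "solo"
        assert res.ltr3 is None
        assert res.tsd_match  # the solo LTR keeps its flanking duplication

    def test_no_ltr_reports_not_found(self, library, rng):
        seq = random_seq(rng, 4000)
        res = find_terminal_ltrs_and_tsd(seq, 1000, [library.full_ltr, library.short_ltr])
        assert res.status == "ltr_not_found"


def _with_stop(gene_seq: str, codon_index: int) -> str:
    out = list(gene_seq)
    out[3 * codon_index : 3 * codon_index + 3] = "TAA"
    return "".join(out)


class TestOrfCalling:
    def _internal_with(self, library, gene, mutator):
        parts = [library.utr5]
        for g in ("gag", "pro", "pol", "env"):
            seq = library.genes[g]
            parts.append(mutator(seq) if g == gene else seq)
        parts.append(library.utr3)
        return "".join(parts)

    def test_stop_at_95_percent_is_intact(self, library):
        # "nearly full length": first 90% clean
        n = len(library.genes["gag"]) // 3
        internal = self._internal_with(library, "gag",
                                       lambda s: _with_stop(s, int(0.95 * n)))
        calls = call_orfs(internal, library)
        assert calls["gag"].status == "intact"
        assert calls["pro"].status == "intact"

    def test_stop_at_50_percent_disrupts_with_position(self, library):
        n = len(library.genes["pol"]) // 3
        internal = self._internal_with(library, "pol",
                                       lambda s: _with_stop(s, n // 2))
        calls = call_orfs(internal, library)
        assert calls["pol"].status == "disrupted"
        assert calls["pol"].disruption_kind == "nonsense"
        assert abs(calls["pol"].disruption_codon - n // 2) <= 1

    def test_pro_stop_after_slip_site_tolerated(self, library):
        # pro truncated by a few codons, stop after the pro-pol frameshift:
        # still counts as intact
        n = len(library.genes["pro"]) // 3
        internal = self._internal_with(library, "pro",
                                       lambda s: _with_stop(s, n - 4))
        calls = call_orfs(internal, library)
        assert calls["pro"].status == "intact"

    def test_frameshift_before_90_disrupts(self, library):
        internal = self._internal_with(
            library, "env", lambda s: s[:300] + s[301:]  # 1-base deletion
        )
        calls = call_orfs(internal, library)
        assert calls["env"].status == "disrupted"
        assert calls["env"].disruption_kind == "frameshift"

    def test_inframe_deletion_tolerated_but_flagged(self, library):
        internal = self._internal_with(
            library, "gag", lambda s: s[:300] + s[330:]  # 30-base in-frame
        )
        calls = call_orfs(internal, library)
        assert calls["gag"].status == "intact"
        assert calls["gag"].inframe_indels

    def test_mostly_deleted_gene_absent(self, library):
        internal = self._internal_with(
            library, "pol", lambda s: s[: len(s) // 4]
        )
        calls = call_orfs(internal, library)
        assert calls["pol"].status == "absent"


class TestDeletions:
    def test_no_gaps_empty(self, rng):
        s = random_seq(rng, 2000)
        assert detect_deletions(pairwise_align_affine(s, s)) == []

    def test_printed_coordinates_recovered(self, library):
        # pol-env deletion: consensus coordinates 6233..8152 (1-based)
        internal = library.internal_seq
        query = internal[: 6232 - 588] + internal[8152 - 588 :]
        aln = pairwise_align_affine(query, internal)
        dels = detect_deletions(aln)
        assert len(dels) == 1
        s, e = dels[0]
        assert abs(s - (6232 - 588)) <= 3 and abs(e - (8152 - 588)) <= 3

    def test_two_deletions_sorted(self, rng):
        ref = random_seq(rng, 5000)
        query = ref[:1000] + ref[1100:3000] + ref[3200:]
        dels = detect_deletions(pairwise_align_affine(query, ref))
        assert len(dels) == 2
        assert dels[0][0] < dels[1][0]

    def test_catalog_matching(self):
        catalog = {"pro_pol": (3383, 5639), "pol_env": (6232, 8152)}
        names, novel = match_shared_deletions([(3383, 5639)], catalog)
        assert names == ["pro_pol"] and not novel
        names, novel = match_shared_deletions([(3383 + 25, 5639 - 25)], catalog)
        assert not names and novel == [(3408, 5614)]
        names, _ = match_shared_deletions(
            [(3383, 5639), (6232, 8152)], catalog
        )
        assert set(names) == {"pro_pol", "pol_env"}


class TestMer11:
    def test_exact_copy_identity_one(self, library, rng):
        region = random_seq(rng, 300) + library.mer11_ref + random_seq(rng, 300)
        call = detect_mer11_region(region, library.mer11_ref)
        assert call.recombinant and call.identity == 1.0

    def test_diverged_copy_near_85_percent(self, library, rng):
        # the recombinant region is recognized at the ~85% identity typical
        # of MER11A matches
        region = random_seq(rng, 200) + diverge(library.mer11_ref, 0.15, rng) \
            + random_seq(rng, 200)
        call = detect_mer11_region(region, library.mer11_ref)
        assert call.recombinant
        assert 0.78 <= call.identity <= 0.92

    def test_background_not_recombinant(self, library, rng):
        call = detect_mer11_region(random_seq(rng, 1200), library.mer11_ref)
        assert not call.recombinant


class TestBreakpoints:
    def test_single_crossover_localized(self, rng):
        errs = []
        for k in (600, 1000, 1400):
            a = random_seq(rng, 2000)
            b = diverge(a, 0.15, rng)
            scan = scan_breakpoints(a[:k] + b[k:], a, b)
            assert scan.status == "ok"
            assert len(scan.crossovers) == 1
            errs.append(abs(scan.crossovers[0] - k))
        assert max(errs) <= 25

    def test_pure_parent_no_crossovers(self, rng):
        a = random_seq(rng, 1500)
        b = diverge(a, 0.2, rng)
        assert scan_breakpoints(a, a, b).crossovers == []

    def test_aba_mosaic_two_ordered_crossovers(self, rng):
        a = random_seq(rng, 3000)
        b = diverge(a, 0.15, rng)
        q = a[:800] + b[800:2000] + a[2000:]
        scan = scan_breakpoints(q, a, b)
        assert len(scan.crossovers) == 2
        assert scan.crossovers[0] < scan.crossovers[1]
        assert abs(scan.crossovers[0] - 800) <= 25
        assert abs(scan.crossovers[1] - 2000) <= 25

    def test_unalignable_query(self, rng):
        q = random_seq(rng, 1000)
        a = random_seq(rng, 1000)
        b = random_seq(rng, 1000)
        assert scan_breakpoints(q, a, b).status == "unalignable"


class TestLtrTyping:
    def test_full_length(self, library):
        label, novel = type_ltr_deletions(
            library.full_ltr, library.full_ltr, library.ltr_deletions
        )
        assert label == "full" and not novel

    @pytest.mark.parametrize("variant", ["Δ1", "Δ2", "Δ1+Δ2", "Δ3", "Δ4", "Δ5+Δ6", "Δ4+Δ7"])
    def test_variants_recovered(self, library, variant):
        seq = library.ltr_variant_seq(variant)
        label, _ = type_ltr_deletions(seq, library.full_ltr, library.ltr_deletions)
        assert label == variant

    def test_novel_deletion(self, library):
        seq = library.full_ltr[:700] + library.full_ltr[790:]
        label, novel = type_ltr_deletions(seq, library.full_ltr, library.ltr_deletions)
        assert label == "novel" and len(novel) == 1


class TestConsensus:
    def test_identical_sequences(self, rng):
        s = random_seq(rng, 200)
        assert majority_consensus([s, s, s]) == s

    def test_majority_base(self):
        assert majority_consensus(["A", "A", "C"]) == "A"

    def test_gap_majority_column_dropped(self):
        assert majority_consensus(["AT", "A-", "A-"]) == "A"

    def test_tie_breaks_alphabetically(self):
        assert majority_consensus(["A", "C", "G", "T"]) == "A"

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            majority_consensus(["ACGT"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus(["ACGT", "ACG"])


class TestGff3Export:
    def test_features_and_attributes(self, library):
        from paleoerv.annotate import annotation_to_gff3
        from paleoerv.mining import LocusRecord

        genome = simulate_host_genome(1, 60_000, 0.5, 8)
        new, row = implant(
            genome, ImplantSpec("chr1", 30_000, deletions=("pro_pol",)),
            library, seed=4,
        )
        rec = LocusRecord(
            row.locus_id, new["chr1"][row.start - 1000 : row.end + 1000],
            1000, "+", "chr1", row.start, row.end,
        )
        gff = annotation_to_gff3([annotate_locus(rec, library)])
        assert gff.startswith("##gff-version 3")
        assert "proviral_locus" in gff
        assert gff.count("long_terminal_repeat") == 2
        assert "MER11_region" in gff
        assert "shared_deletions=pro_pol" in gff
        # all positioned features carry valid 1-based coordinates
        for line in gff.strip().splitlines()[1:]:
            fields = line.split("\t")
            assert int(fields[3]) >= 1 and int(fields[4]) >= int(fields[3])


class TestReverseComplementInvariance:
    def test_annotation_identical_after_strand_normalization(self, library):
        from Bio.Seq import Seq
        from paleoerv.mining import LocusRecord

        genome = simulate_host_genome(1, 60_000, 0.5, 8)
        new, row = implant(
            genome,
            ImplantSpec("chr1", 30_000, age_myr=3.0, deletions=("pro_pol",)),
            library, seed=4,
        )
        seq = new["chr1"][row.start - 1000 : row.end + 1000]
        fwd = LocusRecord("x", seq, 1000, "+", "chr1", row.start, row.end)
        # a minus-strand copy of the same locus, strand-normalized by mining
        rc = LocusRecord(
            "x", str(Seq(str(Seq(seq).reverse_complement())).reverse_complement()),
            1000, "-", "chr1", row.start, row.end,
        )
        a1 = annotate_locus(fwd, library)
        a2 = annotate_locus(rc, library)
        assert a1.deletions == a2.deletions
        assert a1.ltr_variant == a2.ltr_variant
        assert {g: c.status for g, c in a1.orf_status.items()} == {
            g: c.status for g, c in a2.orf_status.items()
        }
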