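"""Splice-junction detection from spliced alignments and the sRec transcript.

The rec-like subgenomic mRNA of SERV-K/MER11 is doubly spliced; in RNA-seq
alignments against the provirus its intron shows up as an N operation in
the CIGAR. Junctions are extracted from every N operation, aggregated by
(donor, acceptor) and support-filtered, then compared to the predicted
splice model. Splicing the predicted transcript in silico and translating
it yields the chimeric sRec protein: a 261-nt first coding exon (ancestral
Rec-derived) plus a 189-nt second exon (HML-8-derived) produce a
149-residue protein split 87 + 62 at the junction codon.

Coordinate convention: junction donor/acceptor are reported 1-based on the
provirus — donor is the last exonic base before the gap, acceptor the first
exonic base after it, so the N-operation length equals
``acceptor − donor − 1``. The internal splice model uses 0-based half-open
exon bounds (``model.donor`` = first intron base); both directions of the
conversion are exercised in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pysam
from Bio.Seq import Seq

__all__ = [
    "SpliceJunction",
    "junctions_from_sam",
    "match_predicted_junction",
    "splice_and_translate",
]


@dataclass(frozen=True)
class SpliceJunction:
    donor: int  # 1-based last exonic base before the gap
    acceptor: int  # 1-based first exonic base after the gap
    read_support: int

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError("donor must precede acceptor")
        if self.read_support < 1:
            raise ValueError("support must be >= 1")


def junctions_from_sam(
    path: str | Path,
    reference: str | None = None,
    min_support: int = 2,
) -> tuple[list[SpliceJunction], int]:
    """Extract splice junctions from N operations in a SAM file.

    Every N operation contributes one junction; junctions are aggregated by
    (donor, acceptor) and those with support below ``min_support`` dropped.
    Returns (junctions sorted by support then position, n_skipped) where
    skipped reads are those aligned to a reference other than ``reference``
    (when given) or unmapped.
    """
    counts: dict[tuple[int, int], int] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.cigartuples is None:
                skipped += 1
                continue
            if reference is not None and read.reference_name != reference:
                skipped += 1
                continue
            ref_pos = read.reference_start  # 0-based
            for op, length in read.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                    ref_pos += length
                elif op == 3:  # N
                    donor = ref_pos  # 1-based last exonic base
                    acceptor = ref_pos + length + 1
                    counts[(donor, acceptor)] = counts.get((donor, acceptor), 0) + 1
                    ref_pos += length
    junctions = [
        SpliceJunction(d, a, n)
        for (d, a), n in counts.items()
        if n >= min_support
    ]
    junctions.sort(key=lambda j: (-j.read_support, j.donor, j.acceptor))
    return junctions, skipped


@dataclass
class JunctionMatch:
    junction: SpliceJunction
    matched: bool
    exact: bool
    donor_offset: int
    acceptor_offset: int


def match_predicted_junction(
    junctions: Sequence[SpliceJunction],
    splice_model,
    tolerance: int = 0,
) -> list[JunctionMatch]:
    """Compare observed junctions to a splice model.

    The model's 0-based first intron base / first exon2 base convert to the
    1-based observed convention as donor = model.donor and acceptor =
    model.acceptor + 1. Default tolerance 0 requires both sites exact;
    non-zero tolerance matches within that many bases but flags inexact.
    """
    pred_donor = splice_model.donor
    pred_acceptor = splice_model.acceptor + 1
    out = []
    for j in junctions:
        d_off = j.donor - pred_donor
        a_off = j.acceptor - pred_acceptor
        matched = abs(d_off) <= tolerance and abs(a_off) <= tolerance
        out.append(
            JunctionMatch(j, matched, matched and d_off == 0 and a_off == 0,
                          d_off, a_off)
        )
    return out


def splice_and_translate(
    provirus: str, splice_model
) -> tuple[str, str, tuple[int, int]]:
    """Remove the intron and translate the spliced ORF.

    Returns (spliced transcript, protein, (exon1_aa, exon2_aa)): the
    protein runs from the annotated start codon through the first stop
    (stop excluded from the count), and the exon split is taken at the
    junction codon.
    """
    donor, acceptor = splice_model.donor, splice_model.acceptor
    if not 0 <= donor < acceptor <= len(provirus):
        raise ValueError("splice sites outside the sequence")
    transcript = provirus[:donor] + provirus[acceptor:]
    start = splice_model.start
    if transcript[start : start + 3] != "ATG":
        raise ValueError("no start codon at the annotated sRec start")
    cds_region = transcript[start:]
    cds_region = cds_region[: len(cds_region) - len(cds_region) % 3]
    aa = str(Seq(cds_region).translate())
    stop = aa.find("*")
    if stop == -1:
        raise ValueError("no in-frame stop codon in the spliced transcript")
    protein = aa[:stop]
    exon1_aa = (donor - start) // 3
    exon2_aa = len(protein) - exon1_aa
    return transcript, protein, (exon1_aa, exon2_aa)
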