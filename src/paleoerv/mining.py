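"""Reconstruction of candidate proviral loci from repeat-annotation tracks.

Genome-wide repeat annotators (RepeatMasker and kin) report an endogenous
retrovirus as several abutting records — an LTR at each terminus, one or more
internal-sequence fragments, and, for the recombinant SERV-K/MER11 clade, a
MER11A record between *env* and the 3' LTR. This module rebuilds proviral
loci from such tracks: records belonging to the target families are merged
when they lie within a configurable gap of each other (default 1 kb), merged
intervals are classified (provirus / solo LTR / short fragment / off-target),
named by their genomic position, and extracted as strand-normalized
sequences with flanking DNA for downstream structural annotation.

Coordinates are 0-based half-open internally; RepeatMasker ``.out`` files
(1-based inclusive, strand ``C`` for minus) are converted on read/write, and
locus names use 1-based leftmost coordinates following UCSC convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "RepeatAnnotation",
    "MiningConfig",
    "LocusCandidate",
    "LocusRecord",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_bed6",
    "write_bed6",
    "merge_annotations",
    "build_candidates",
    "classify_candidate",
    "name_locus",
    "extract_locus_sequences",
    "mine_loci",
]

# Families whose records are assembled into candidate loci. LTR5_RM / LTR5B
# are LTR annotations, HERVK-int is internal coding sequence, MER11A is the
# HML-8-LTR-derived recombinant region.
DEFAULT_WHITELIST = frozenset({"LTR5_RM", "LTR5B", "HERVK-int", "MER11A"})
LTR_FAMILIES = frozenset({"LTR5_RM", "LTR5B"})


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat-track record, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if not self.family:
            raise ValueError("family label must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MiningConfig:
    max_gap: int = 1000
    min_locus_len: int = 2000
    family_whitelist: frozenset[str] = DEFAULT_WHITELIST
    ltr_families: frozenset[str] = LTR_FAMILIES
    min_gap_run: int = 50  # N-run length that flags a locus as gapped

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_locus_len <= 0:
            raise ValueError("min_locus_len must be > 0")


@dataclass
class LocusCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    members: list[RepeatAnnotation]
    locus_class: str = "unclassified"
    locus_name: str = ""
    gapped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusRecord:
    """Strand-normalized locus sequence plus flanks, ready for annotation."""

    name: str
    seq: str
    flank: int
    strand: str
    chrom: str
    start: int
    end: int
    clipped: bool = False

    @property
    def locus_seq(self) -> str:
        """Sequence of the locus proper, flanks stripped."""
        return self.seq[self.flank : len(self.seq) - self.flank]


# ---------------------------------------------------------------------------
# RepeatMasker .out and BED I/O

_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query              matching"
    "            repeat         position in repeat\n"
    "score   div. del. ins.  sequence  begin end          (left)   repeat"
    "            class/family   begin  end    (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a standard RepeatMasker ``.out`` file.

    The dialect has 3 header lines and whitespace-separated columns; the
    strand column uses ``C`` for minus. 1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: "
                    f"expected >=11 columns, got {len(fields)}"
                )
            try:
                score = float(fields[0])
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else fields[8]
                family = fields[9]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: {exc}"
                ) from exc
            annotations.append(
                RepeatAnnotation(chrom, start, end, strand, family, score)
            )
    return annotations


def write_repeatmasker_out(
    path: str | Path, annotations: Iterable[RepeatAnnotation]
) -> None:
    """Write a 15-column RepeatMasker ``.out`` file with the standard header."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, ann in enumerate(
            sorted(annotations, key=lambda a: (a.chrom, a.start)), start=1
        ):
            strand = "C" if ann.strand == "-" else "+"
            score = int(ann.score) if ann.score is not None else 1000
            fh.write(
                f"{score:>5d}    1.0  0.0  0.0  {ann.chrom:<10s}"
                f"{ann.start + 1:>9d}{ann.end:>9d} (0) {strand} "
                f"{ann.family:<15s} LTR/ERVK {1:>6d}{ann.length:>7d} (0) "
                f"{i:>5d}\n"
            )


def read_bed6(path: str | Path) -> list[RepeatAnnotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: BED6 line {lineno} has <6 columns")
            annotations.append(
                RepeatAnnotation(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[5], fields[3],
                    float(fields[4]) if fields[4] != "." else None,
                )
            )
    return annotations


def write_bed6(path: str | Path, annotations: Iterable[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        for ann in sorted(annotations, key=lambda a: (a.chrom, a.start)):
            score = int(ann.score) if ann.score is not None else 0
            fh.write(
                f"{ann.chrom}\t{ann.start}\t{ann.end}\t{ann.family}\t"
                f"{score}\t{ann.strand}\n"
            )


# ---------------------------------------------------------------------------
# Merging, classification, naming

def merge_annotations(
    annotations: Sequence[RepeatAnnotation], config: MiningConfig | None = None
) -> list[LocusCandidate]:
    """Merge whitelisted records within ``max_gap`` of each other.

    The merge is the transitive closure of the pairwise rule
    ``gap = next.start - prev.end <= max_gap`` (matching
    ``bedtools merge -d``), applied per chromosome after sorting, so the
    result is independent of input order and idempotent.
    """
    config = config or MiningConfig()
    by_chrom: dict[str, list[RepeatAnnotation]] = {}
    for ann in annotations:
        by_chrom.setdefault(ann.chrom, []).append(ann)

    candidates: list[LocusCandidate] = []
    for chrom in sorted(by_chrom):
        anns = sorted(by_chrom[chrom], key=lambda a: (a.start, a.end))
        cluster: list[RepeatAnnotation] = []
        for ann in anns:
            if cluster and ann.start - max(a.end for a in cluster) > config.max_gap:
                candidates.append(_finish_cluster(chrom, cluster))
                cluster = []
            cluster.append(ann)
        if cluster:
            candidates.append(_finish_cluster(chrom, cluster))
    return candidates


def _finish_cluster(chrom: str, members: list[RepeatAnnotation]) -> LocusCandidate:
    start = min(a.start for a in members)
    end = max(a.end for a in members)
    # Strand of the longest member: fragments of one element share strand.
    longest = max(members, key=lambda a: a.length)
    return LocusCandidate(chrom, start, end, longest.strand, list(members))


def classify_candidate(
    candidate: LocusCandidate, config: MiningConfig | None = None
) -> str:
    """Assign a class to a merged candidate.

    Order of precedence: off_target (no whitelisted member), solo_ltr
    (LTR-family members only — checked before the length filter so a single
    detached LTR is reported as what it is, not as a short fragment),
    short_fragment (< min_locus_len), else provirus.
    """
    config = config or MiningConfig()
    families = {m.family for m in candidate.members}
    if not families & config.family_whitelist:
        return "off_target"
    whitelisted = families & config.family_whitelist
    if whitelisted <= config.ltr_families:
        return "solo_ltr"
    if candidate.length < config.min_locus_len:
        return "short_fragment"
    return "provirus"


def name_locus(candidate: LocusCandidate, assembly_tag: str) -> str:
    """``<chrom-number>-<1-based leftmost coordinate>_<assembly_tag>``.

    e.g. a provirus at chr16:60,303,645 first found in rheMac10 is named
    ``16-60303645_RM10``.
    """
    chrom = candidate.chrom
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return f"{chrom}-{candidate.start + 1}_{assembly_tag}"


def build_candidates(
    annotations: Sequence[RepeatAnnotation],
    config: MiningConfig | None = None,
    assembly_tag: str = "SIM",
    assembly: Mapping[str, str] | None = None,
) -> list[LocusCandidate]:
    """Whitelist-filter, merge, classify, and name in one pass.

    Off-target families are merged separately (so decoy implants surface as
    reportable off_target candidates rather than being silently dropped).
    If ``assembly`` is given, candidates whose merged interval contains an
    N-run of ``min_gap_run`` or more are flagged gapped.
    """
    config = config or MiningConfig()
    inside = [a for a in annotations if a.family in config.family_whitelist]
    outside = [a for a in annotations if a.family not in config.family_whitelist]
    candidates = merge_annotations(inside, config) + merge_annotations(outside, config)
    for cand in candidates:
        cand.locus_class = classify_candidate(cand, config)
        cand.locus_name = name_locus(cand, assembly_tag)
        if assembly is not None:
            segment = assembly[cand.chrom][cand.start : cand.end]
            cand.gapped = "N" * config.min_gap_run in segment
    candidates.sort(key=lambda c: (c.chrom, c.start))
    return candidates


def extract_locus_sequences(
    assembly: Mapping[str, str],
    candidates: Iterable[LocusCandidate],
    flank: int = 1000,
) -> list[LocusRecord]:
    """Extract each candidate plus ``flank`` bases of genomic context.

    Minus-strand loci are reverse-complemented so the proviral annotation
    always runs 5'→3'; intervals exceeding chromosome bounds are clipped and
    flagged.
    """
    records = []
    for cand in candidates:
        chrom_seq = assembly[cand.chrom]
        lo = cand.start - flank
        hi = cand.end + flank
        clipped = lo < 0 or hi > len(chrom_seq)
        lo = max(lo, 0)
        hi = min(hi, len(chrom_seq))
        seq = chrom_seq[lo:hi]
        if cand.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        records.append(
            LocusRecord(
                name=cand.locus_name or name_locus(cand, "SIM"),
                seq=seq,
                flank=flank if not clipped else min(cand.start, flank),
                strand=cand.strand,
                chrom=cand.chrom,
                start=cand.start,
                end=cand.end,
                clipped=clipped,
            )
        )
    return records


def mine_loci(
    assembly: Mapping[str, str],
    annotations: Sequence[RepeatAnnotation],
    config: MiningConfig | None = None,
    assembly_tag: str = "SIM",
    flank: int = 1000,
) -> tuple[list[LocusCandidate], list[LocusRecord]]:
    """Full mining pass: merge/classify/name, then extract provirus and
    solo-LTR sequences (gapped loci are excluded from extraction)."""
    candidates = build_candidates(annotations, config, assembly_tag, assembly)
    keep = [
        c for c in candidates
        if c.locus_class in ("provirus", "solo_ltr") and not c.gapped
    ]
    records = extract_locus_sequences(assembly, keep, flank)
    return candidates, records
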