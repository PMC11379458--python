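"""Structural annotation of proviral loci against reference elements.

Each mined locus is compared to a reference element set: terminal LTRs and
the target-site duplication are located, per-gene ORF intactness is called
under the 90%-completeness rule (a gene counts as full length or nearly
full length if the first 90% of its reference codons are free of nonsense
or frameshift mutations), internal deletions are detected as alignment gap
runs and matched against the shared-deletion catalog, the HML-8/MER11
recombinant region is detected by local alignment, two-parent recombination
breakpoints are localized with a sliding-window identity scan, and LTRs are
typed by their U3 deletion combination (Δ1–Δ7).

All comparisons run on a global affine-gap pairwise alignment substrate
(defaults match +2 / mismatch −3 / gap open −8 / gap extend −1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "OrfPolicy",
    "ProvirusAnnotation",
    "pairwise_align_affine",
    "infix_align",
    "local_align",
    "find_terminal_ltrs_and_tsd",
    "call_orfs",
    "detect_deletions",
    "match_shared_deletions",
    "detect_mer11_region",
    "scan_breakpoints",
    "BreakpointScan",
    "type_ltr_deletions",
    "majority_consensus",
    "annotate_locus",
]

LTR_OFFSET = 588  # consensus internal coordinates start after the 5' LTR


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


def _aligner(params: AlignParams, mode: str = "global") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local" if mode == "local" else "global"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    if mode == "infix":
        # query may sit inside a longer target: free query end gaps
        al.open_left_deletion_score = 0
        al.extend_left_deletion_score = 0
        al.open_right_deletion_score = 0
        al.extend_right_deletion_score = 0
    elif mode == "semiglobal":
        # query may extend past the target: free target end gaps
        al.open_left_insertion_score = 0
        al.extend_left_insertion_score = 0
        al.open_right_insertion_score = 0
        al.extend_right_insertion_score = 0
    return al


class PairwiseAlignment:
    """Wrapper over one Biopython alignment of (reference, query).

    Exposes the coordinate maps the structure callers need: per-reference
    aligned query position (−1 in deletions), insertion lengths, gap runs,
    and identity over aligned columns.
    """

    def __init__(self, ref: str, query: str, aln) -> None:
        self.ref = ref
        self.query = query
        self.score = aln.score
        t_blocks, q_blocks = aln.aligned
        self.blocks = list(zip(map(tuple, t_blocks), map(tuple, q_blocks)))
        qpos = np.full(len(ref), -1, dtype=np.int64)
        ins_after = np.zeros(len(ref) + 1, dtype=np.int64)
        prev_t = prev_q = 0
        first = True
        for (t0, t1), (q0, q1) in self.blocks:
            if q0 > prev_q:
                anchor = t0 if first else prev_t
                ins_after[anchor] += q0 - prev_q
            qpos[t0:t1] = np.arange(q0, q1)
            prev_t, prev_q = t1, q1
            first = False
        if len(query) > prev_q:
            ins_after[len(ref)] += len(query) - prev_q
        self.qpos = qpos
        self.ins_after = ins_after

    @property
    def n_aligned_columns(self) -> int:
        return int((self.qpos >= 0).sum())

    @property
    def matches(self) -> int:
        r = np.frombuffer(self.ref.encode(), dtype="S1")
        q = np.frombuffer(self.query.encode(), dtype="S1")
        mask = self.qpos >= 0
        return int((r[mask] == q[self.qpos[mask]]).sum())

    @property
    def identity(self) -> float:
        n = self.n_aligned_columns
        return self.matches / n if n else 0.0

    @property
    def n_gap_columns(self) -> int:
        del_cols = int((self.qpos < 0).sum())
        ins_cols = int(self.ins_after.sum())
        return del_cols + ins_cols

    def ref_gap_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of reference positions with no query base
        (deletions in the query), as 0-based half-open ref intervals."""
        runs = []
        in_run = False
        start = 0
        for r in range(len(self.ref)):
            if self.qpos[r] < 0:
                if not in_run:
                    start, in_run = r, True
            elif in_run:
                runs.append((start, r))
                in_run = False
        if in_run:
            runs.append((start, len(self.ref)))
        return runs

    def query_match_mask(self) -> np.ndarray:
        """Boolean per query position: aligned to an identical ref base."""
        mask = np.zeros(len(self.query), dtype=bool)
        r = np.frombuffer(self.ref.encode(), dtype="S1")
        q = np.frombuffer(self.query.encode(), dtype="S1")
        sel = self.qpos >= 0
        qp = self.qpos[sel]
        mask[qp] = r[sel] == q[qp]
        return mask


def pairwise_align_affine(
    query: str, reference: str, params: AlignParams | None = None,
    mode: str = "global",
) -> PairwiseAlignment:
    """Global (or infix/semiglobal/local) affine-gap alignment.

    Returned object maps reference coordinates to query coordinates;
    tie-breaking is deterministic (first optimal alignment).
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    params = params or AlignParams()
    al = _aligner(params, mode)
    aln = al.align(reference, query)[0]
    return PairwiseAlignment(reference, query, aln)


def infix_align(window: str, ref: str, params: AlignParams | None = None):
    """Locate ``ref`` within ``window`` with free end gaps on the window.

    Returns (start, end, PairwiseAlignment) where [start, end) is the
    window interval covered by the reference (terminal mismatches are kept
    inside the interval, unlike a local alignment).
    """
    params = params or AlignParams()
    al = _aligner(params, "infix")
    aln = al.align(window, ref)[0]
    t_blocks, _ = aln.aligned
    start = int(t_blocks[0][0])
    end = int(t_blocks[-1][1])
    pa = PairwiseAlignment(ref, window[start:end], _Realigned(aln, start))
    return start, end, pa


class _Realigned:
    """Adapter presenting an infix alignment with ref as target."""

    def __init__(self, aln, offset: int) -> None:
        t_blocks, q_blocks = aln.aligned
        self.aligned = (
            [(int(q0), int(q1)) for q0, q1 in q_blocks],
            [(int(t0) - offset, int(t1) - offset) for t0, t1 in t_blocks],
        )
        self.score = aln.score


def local_align(target: str, query: str, params: AlignParams | None = None):
    """Best local alignment; returns (t_interval, q_interval, identity, cols)."""
    params = params or AlignParams()
    al = _aligner(params, "local")
    aln = al.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    cols = matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        cols += te - ts
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    identity = matches / cols if cols else 0.0
    return (t0, t1), (q0, q1), identity, cols


# ---------------------------------------------------------------------------
# LTR / TSD detection

@dataclass
class LtrTsdResult:
    status: str  # ok | solo | ltr_not_found
    ltr5: tuple[int, int] | None  # locus coordinates
    ltr3: tuple[int, int] | None
    tsd_up: str | None
    tsd_down: str | None
    tsd_match: bool | None
    tsd_len: int | None


def find_terminal_ltrs_and_tsd(
    seq: str,
    flank: int,
    ltr_refs: Sequence[str],
    min_identity: float = 0.75,
    tsd_range: tuple[int, int] = (4, 8),
) -> LtrTsdResult:
    """Locate LTR copies at both ends of a locus and the flanking TSD.

    ``seq`` carries ``flank`` bases of genomic context on each side of the
    locus. The TSD is the longest exact duplication (4–8 bp) immediately
    flanking the element; a solo LTR yields a single LTR interval whose
    flanking duplication is still reported.
    """
    locus = seq[flank : len(seq) - flank] if flank else seq
    max_ref = max(len(r) for r in ltr_refs)
    pad = 60

    def best_end(window: str, offset: int):
        best = None
        for ref in ltr_refs:
            s, e, pa = infix_align(window, ref)
            if best is None or pa.score > best[2]:
                best = (s + offset, e + offset, pa.score, pa.identity)
        return best

    w5 = locus[: min(len(locus), max_ref + pad)]
    hit5 = best_end(w5, 0)
    start3 = max(0, len(locus) - max_ref - pad)
    hit3 = best_end(locus[start3:], start3)

    ok5 = hit5 is not None and hit5[3] >= min_identity
    ok3 = hit3 is not None and hit3[3] >= min_identity
    if not ok5 and not ok3:
        return LtrTsdResult("ltr_not_found", None, None, None, None, None, None)

    solo = False
    if ok5 and ok3 and hit3[0] < hit5[1]:
        solo = True  # the two windows found the same (only) LTR
    elif ok5 and not ok3:
        solo = True
    elif ok3 and not ok5:
        hit5, solo = hit3, True

    ltr5 = (hit5[0], hit5[1])
    ltr3 = None if solo else (hit3[0], hit3[1])
    el_start = ltr5[0]
    el_end = ltr5[1] if solo else ltr3[1]

    tsd_up = tsd_down = None
    tsd_len = None
    tsd_match = False
    lo, hi = tsd_range
    found = False
    # exact element boundaries first; small offsets only as a fallback for
    # boundary jitter from mutated LTR termini
    offsets = [(0, 0)] + [
        (da, db)
        for da in (0, -1, 1, -2, 2, -3, 3)
        for db in (0, -1, 1, -2, 2, -3, 3)
        if (da, db) != (0, 0)
    ]
    for da, db in offsets:
        for length in range(hi, lo - 1, -1):
            a = flank + el_start + da
            b = flank + el_end + db
            if a - length < 0 or b + length > len(seq):
                continue
            up = seq[a - length : a]
            down = seq[b : b + length]
            if up == down:
                tsd_up, tsd_down, tsd_len, tsd_match = up, down, length, True
                found = True
                break
        if found:
            break
    if not found:
        # mismatched duplications (e.g. translocation): report the flanks
        tsd_len = 6
        a = flank + el_start
        b = flank + el_end
        tsd_up = seq[max(0, a - tsd_len) : a]
        tsd_down = seq[b : b + tsd_len]
        tsd_match = False

    return LtrTsdResult(
        "solo" if solo else "ok", ltr5, ltr3, tsd_up, tsd_down, tsd_match, tsd_len
    )


# ---------------------------------------------------------------------------
# ORF calling

@dataclass
class OrfPolicy:
    completeness_fraction: float = 0.90
    genes: tuple[str, ...] = ("gag", "pro", "pol", "env")
    # reference codon index of the pro-pol programmed frameshift slip site:
    # nonsense codons at/after this index do not disrupt that gene
    frameshift_sites: Mapping[str, int] = field(
        default_factory=lambda: {"pro": 290}
    )
    absent_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not 0 < self.completeness_fraction <= 1:
            raise ValueError("completeness_fraction must be in (0, 1]")


@dataclass
class OrfCall:
    status: str  # intact | disrupted | absent
    disruption_codon: int | None = None
    disruption_kind: str | None = None  # nonsense | frameshift
    inframe_indels: bool = False


STOPS = {"TAA", "TAG", "TGA"}


def _call_gene(
    aln: PairwiseAlignment, gs: int, ge: int, policy: OrfPolicy, gene: str
) -> OrfCall:
    n_codons = (ge - gs) // 3
    aligned = int((aln.qpos[gs:ge] >= 0).sum())
    if aligned < (1 - policy.absent_fraction) * (ge - gs):
        return OrfCall("absent")

    threshold = int(np.ceil(policy.completeness_fraction * n_codons))
    slip = policy.frameshift_sites.get(gene)
    events: list[tuple[int, str]] = []
    cum_del = 0
    cum_ins = 0  # insertions ahead of the gene don't shift its frame
    inframe = False
    for i in range(n_codons):
        c0 = gs + 3 * i
        qp = aln.qpos[c0 : c0 + 3]
        cum_del += int((qp < 0).sum())
        cum_ins += int(aln.ins_after[c0 + 1 : c0 + 4].sum())
        offset = (cum_ins - cum_del) % 3
        if offset != 0:
            events.append((i, "frameshift"))
            break
        if (cum_ins - cum_del) != 0 and not inframe:
            inframe = True
        if (qp >= 0).all() and qp[2] - qp[0] == 2:
            codon = aln.query[qp[0] : qp[0] + 3]
            if codon in STOPS and i < n_codons - 1:
                if slip is not None and i >= slip:
                    continue
                events.append((i, "nonsense"))
                break
    if cum_ins != cum_del and not events:
        inframe = True
    if not events:
        return OrfCall("intact", inframe_indels=inframe)
    codon, kind = events[0]
    if codon >= threshold:
        return OrfCall("intact", inframe_indels=inframe)
    return OrfCall("disrupted", disruption_codon=codon, disruption_kind=kind)


def call_orfs(
    locus_internal: str,
    refs,
    policy: OrfPolicy | None = None,
    alignment: PairwiseAlignment | None = None,
) -> dict[str, OrfCall]:
    """Per-gene ORF status for a locus internal region.

    ``refs`` provides ``internal_seq`` (coding reference between the LTRs)
    and ``gene_intervals`` in consensus coordinates. A precomputed
    reference-vs-locus alignment may be passed to avoid re-aligning.
    """
    policy = policy or OrfPolicy()
    ref_internal = refs.internal_seq
    if alignment is None:
        alignment = pairwise_align_affine(locus_internal, ref_internal,
                                          mode="semiglobal")
    calls = {}
    for gene in policy.genes:
        gs, ge = refs.gene_intervals[gene]
        calls[gene] = _call_gene(
            alignment, gs - LTR_OFFSET, ge - LTR_OFFSET, policy, gene
        )
    return calls


# ---------------------------------------------------------------------------
# Deletions

def detect_deletions(
    alignment: PairwiseAlignment, min_len: int = 50, merge_island: int = 8
) -> list[tuple[int, int]]:
    """Maximal query-gap runs >= min_len, as reference-coordinate intervals
    (0-based half-open), sorted.

    Gap runs separated by fewer than ``merge_island`` aligned reference
    positions are merged first: inside a real deletion the aligner
    occasionally anchors a handful of coincidentally matching bases, which
    would otherwise split one deletion into two.
    """
    runs = sorted(alignment.ref_gap_runs())
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_island:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_len]


def match_shared_deletions(
    detected: Iterable[tuple[int, int]],
    catalog: Mapping[str, tuple[int, int]],
    match_tolerance: int = 20,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Match detected intervals to the catalog: both endpoints within
    tolerance. Unmatched intervals are returned as novel."""
    names: list[str] = []
    novel: list[tuple[int, int]] = []
    for ds, de in detected:
        hit = None
        for name, (cs, ce) in catalog.items():
            if abs(ds - cs) <= match_tolerance and abs(de - ce) <= match_tolerance:
                hit = name
                break
        if hit is None:
            novel.append((ds, de))
        elif hit not in names:
            names.append(hit)
    return names, novel


# ---------------------------------------------------------------------------
# Recombinant region and breakpoints

@dataclass
class Mer11Call:
    recombinant: bool
    interval: tuple[int, int] | None  # coordinates within the searched region
    identity: float


def detect_mer11_region(
    region: str,
    mer11_ref: str,
    min_identity: float = 0.70,
    min_len: int = 200,
) -> Mer11Call:
    """Local alignment of the MER11 reference to the env→3'LTR region."""
    if not region:
        return Mer11Call(False, None, 0.0)
    (t0, t1), _q, identity, cols = local_align(region, mer11_ref)
    if cols >= min_len and identity >= min_identity:
        return Mer11Call(True, (t0, t1), identity)
    return Mer11Call(False, (t0, t1) if cols else None, identity)


@dataclass
class BreakpointScan:
    status: str  # ok | unalignable
    crossovers: list[int]
    positions: np.ndarray | None = None
    identity_a: np.ndarray | None = None
    identity_b: np.ndarray | None = None

    @property
    def uncertainty(self) -> int:
        return 50  # +- window/2 for the default window


def scan_breakpoints(
    query: str,
    parent_a: str,
    parent_b: str,
    window: int = 100,
    step: int = 10,
    persistence: int = 3,
) -> BreakpointScan:
    """Two-parent crossover scan.

    Per-window identity of the query to each parent (from global pairwise
    alignments projected onto query coordinates); a crossover is called
    where the identity-majority parent switches and the new majority
    persists for at least ``persistence`` consecutive windows. Reported
    positions are window centers in query coordinates (±window/2).
    """
    aln_a = pairwise_align_affine(parent_a, query)
    aln_b = pairwise_align_affine(parent_b, query)
    id_a_total = aln_a.matches / len(query)
    id_b_total = aln_b.matches / len(query)
    if id_a_total < 0.6 and id_b_total < 0.6:
        return BreakpointScan("unalignable", [])

    match_a = aln_a.query_match_mask().astype(float)
    match_b = aln_b.query_match_mask().astype(float)
    starts = np.arange(0, max(1, len(query) - window + 1), step)
    ida = np.array([match_a[s : s + window].mean() for s in starts])
    idb = np.array([match_b[s : s + window].mean() for s in starts])

    majority = np.zeros(len(starts), dtype=int)  # +1 = A, -1 = B, 0 = tie
    majority[ida > idb] = 1
    majority[idb > ida] = -1
    for i in range(1, len(majority)):  # ties inherit the previous majority
        if majority[i] == 0:
            majority[i] = majority[i - 1]

    # cumulative match counts for boundary refinement
    cum_a = np.concatenate([[0], np.cumsum(match_a)])
    cum_b = np.concatenate([[0], np.cumsum(match_b)])

    def refine(coarse: int, old: int) -> int:
        """Best split point near the coarse estimate: maximize matches to
        the outgoing parent on the left plus the incoming on the right."""
        lo = max(0, coarse - window)
        hi = min(len(query), coarse + window)
        cum_old = cum_a if old == 1 else cum_b
        cum_new = cum_b if old == 1 else cum_a
        ps = np.arange(lo, hi + 1)
        score = (cum_old[ps] - cum_old[lo]) + (cum_new[hi] - cum_new[ps])
        return int(ps[np.argmax(score)])

    crossovers = []
    current = next((m for m in majority if m != 0), 0)
    i = 0
    while i < len(majority):
        m = majority[i]
        if m != 0 and m != current:
            run = 1
            while i + run < len(majority) and majority[i + run] == m:
                run += 1
            if run >= persistence:
                coarse = int(starts[i]) + window // 2 - step // 2
                crossovers.append(refine(coarse, current))
                current = m
                i += run
                continue
            i += run
            continue
        i += 1
    return BreakpointScan("ok", crossovers, starts, ida, idb)


# ---------------------------------------------------------------------------
# LTR typing and consensus

def type_ltr_deletions(
    ltr_seq: str,
    full_ltr: str,
    catalog: Mapping[str, tuple[int, int]],
    match_tolerance: int = 20,
    min_len: int = 50,
) -> tuple[str, list[tuple[int, int]]]:
    """Label an LTR by its U3 deletion combination.

    Returns (label, novel_intervals) with label "full" when no catalog
    deletion is detected, the sorted '+'-joined names otherwise, and
    "novel" when only unmatched deletions are present.
    """
    aln = pairwise_align_affine(ltr_seq, full_ltr)
    detected = detect_deletions(aln, min_len=min_len)
    names, novel = match_shared_deletions(detected, catalog, match_tolerance)
    if not names and not novel:
        return "full", []
    if not names:
        return "novel", novel
    label = "+".join(sorted(names))
    return label, novel


def majority_consensus(aligned: Sequence[str]) -> str:
    """Per-column majority over pre-aligned sequences.

    Columns with gap fraction >= 0.5 are omitted; ties among bases break by
    fixed symbol order A < C < G < T.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s.upper()) for s in aligned])
    out = []
    for col in arr.T:
        gaps = (col == "-").sum()
        if gaps / len(col) >= 0.5:
            continue
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        order = sorted(zip(bases, counts), key=lambda bc: (-bc[1], bc[0]))
        out.append(order[0][0])
    return "".join(out)


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class ProvirusAnnotation:
    name: str
    status: str  # ok | solo | ltr_not_found
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    tsd_up: str | None = None
    tsd_down: str | None = None
    tsd_match: bool | None = None
    orf_status: dict[str, OrfCall] = field(default_factory=dict)
    deletions: list[str] = field(default_factory=list)
    novel_deletions: list[tuple[int, int]] = field(default_factory=list)
    recombinant: bool = False
    mer11_interval: tuple[int, int] | None = None
    mer11_identity: float = 0.0
    ltr_variant: str = ""
    ltr5_seq: str = ""
    ltr3_seq: str = ""


def annotation_to_gff3(annotations: Sequence["ProvirusAnnotation"]) -> str:
    """Serialize locus annotations as GFF3 (coordinates 1-based on each
    locus sequence; features: LTRs, ORFs, deletions, MER11 region)."""
    lines = ["##gff-version 3"]
    for ann in annotations:
        if ann.status == "ltr_not_found" or ann.ltr5 is None:
            continue
        seqid = ann.name
        end = (ann.ltr3 or ann.ltr5)[1]

        def row(ftype, start, stop, attrs):
            lines.append(
                f"{seqid}\tpaleoerv\t{ftype}\t{start + 1}\t{stop}\t.\t+\t.\t{attrs}"
            )

        attrs = [f"ID={seqid}", f"status={ann.status}"]
        if ann.orf_status:
            attrs.append("orf_status=" + ",".join(
                f"{g}:{c.status}" for g, c in ann.orf_status.items()
            ))
        if ann.deletions:
            attrs.append("shared_deletions=" + ",".join(ann.deletions))
        if ann.tsd_up is not None:
            attrs.append(
                f"tsd_up={ann.tsd_up};tsd_down={ann.tsd_down};"
                f"tsd_match={str(ann.tsd_match).lower()}"
            )
        ftype = "solo_LTR" if ann.status == "solo" else "proviral_locus"
        row(ftype, ann.ltr5[0], end, ";".join(attrs))
        row("long_terminal_repeat", *ann.ltr5,
            f"ID={seqid}.LTR5;Parent={seqid};variant={ann.ltr_variant}")
        if ann.ltr3:
            row("long_terminal_repeat", *ann.ltr3,
                f"ID={seqid}.LTR3;Parent={seqid}")
        if ann.mer11_interval and ann.recombinant:
            row("MER11_region", *ann.mer11_interval,
                f"ID={seqid}.MER11;Parent={seqid};"
                f"identity={ann.mer11_identity:.3f}")
    return "\n".join(lines) + "\n"


def annotate_locus(
    record,
    refs,
    policy: OrfPolicy | None = None,
    match_tolerance: int = 20,
) -> ProvirusAnnotation:
    """Full structural annotation of one locus record.

    ``record`` needs ``name``, ``seq`` and ``flank`` attributes (as produced
    by mining); ``refs`` is an element reference set (consensus internal
    region, gene intervals, LTR references, MER11 reference, deletion
    catalogs) such as a simulated ElementLibrary.
    """
    policy = policy or OrfPolicy()
    ltr_result = find_terminal_ltrs_and_tsd(
        record.seq, record.flank, [refs.full_ltr, refs.short_ltr]
    )
    ann = ProvirusAnnotation(name=record.name, status=ltr_result.status)
    if ltr_result.status == "ltr_not_found":
        return ann
    ann.ltr5 = ltr_result.ltr5
    ann.ltr3 = ltr_result.ltr3
    ann.tsd_up = ltr_result.tsd_up
    ann.tsd_down = ltr_result.tsd_down
    ann.tsd_match = ltr_result.tsd_match

    locus = record.seq[record.flank : len(record.seq) - record.flank] \
        if record.flank else record.seq
    ann.ltr5_seq = locus[ltr_result.ltr5[0] : ltr_result.ltr5[1]]
    ann.ltr_variant, _ = type_ltr_deletions(
        ann.ltr5_seq, refs.full_ltr, refs.ltr_deletions, match_tolerance
    )
    if ltr_result.status == "solo":
        return ann
    ann.ltr3_seq = locus[ltr_result.ltr3[0] : ltr_result.ltr3[1]]

    internal = locus[ltr_result.ltr5[1] : ltr_result.ltr3[0]]

    # recombinant region: search the tail of the internal region
    tail_window = internal[-1500:] if len(internal) > 1500 else internal
    mer = detect_mer11_region(tail_window, refs.mer11_ref)
    ann.recombinant = mer.recombinant
    ann.mer11_identity = mer.identity
    if mer.interval is not None:
        off = ltr_result.ltr5[1] + max(0, len(internal) - 1500)
        ann.mer11_interval = (mer.interval[0] + off, mer.interval[1] + off)

    # reference internal region matching the detected architecture
    coding = refs.internal_seq[: refs.gene_intervals["env"][1] - LTR_OFFSET]
    ref_internal = coding + (refs.recombinant_tail if mer.recombinant else refs.utr3)
    aln = pairwise_align_affine(internal, ref_internal)

    env_end = refs.gene_intervals["env"][1] - LTR_OFFSET
    detected = [
        (s, e) for s, e in detect_deletions(aln) if s < env_end
    ]
    consensus_coords = [(s + LTR_OFFSET, e + LTR_OFFSET) for s, e in detected]
    ann.deletions, ann.novel_deletions = match_shared_deletions(
        consensus_coords, refs.internal_deletions, match_tolerance
    )
    ann.orf_status = call_orfs(internal, refs, policy, alignment=aln)
    return ann
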