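"""Cross-species presence/absence of insertions and insertional polymorphism.

An insertion is scored present in a species when at least one
provirus–flank junction is intact in that species' assembly: a query built
from the focal genome (flanking sequence plus the adjoining element end) is
searched by exact k-mer seeding and diagonal extension, and the junction
counts as intact when the best placement covers a minimum window on BOTH
sides of the junction point at high identity, with a unique best hit.
Proviral sequence at a locus without intact junctions is NOT counted
present (such hits are often assembly artifacts). When the primary 1000-bp
flank is insufficient the search escalates to 5000 bp; species with neither
junction are tested for the empty pre-integration site (flank–flank query
across a single TSD copy). Presence calls across species are then placed on
a species tree as the oldest common ancestor (OCA) of the focal species and
every species carrying the insertion.

Genotype tables from 3-primer allele-specific PCR screens ('+/+', '+/-',
'-/-', 'failed') yield insertion allele frequencies — failed reactions are
excluded from the denominator (two alleles per non-failed individual) — and
an insertional-polymorphism classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OrthologyConfig",
    "OrthologCall",
    "KmerIndex",
    "JunctionHit",
    "search_junction",
    "call_presence",
    "presence_matrix",
    "assign_oca",
    "allele_frequency",
    "classify_polymorphism",
]


@dataclass
class OrthologyConfig:
    flank_len_primary: int = 1000
    flank_len_escalated: int = 5000
    junction_half_window: int = 50
    min_junction_identity: float = 0.90
    seed_k: int = 12
    uniqueness_ratio: float = 0.90  # second best must be below this × best

    def __post_init__(self) -> None:
        if self.flank_len_escalated <= self.flank_len_primary:
            raise ValueError("escalated flank must exceed primary")
        if not 0 < self.min_junction_identity <= 1:
            raise ValueError("identity must be in (0, 1]")


_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i


class KmerIndex:
    """Exact k-mer index over an assembly, numpy-backed.

    Rolling 2-bit codes per chromosome, sorted for binary-search lookup;
    positions overlapping non-ACGT characters are excluded.
    """

    def __init__(self, assembly: Mapping[str, str], k: int = 12) -> None:
        if k > 31:
            raise ValueError("k too large")
        self.k = k
        self.chroms: list[str] = sorted(assembly)
        self.seqs: dict[str, str] = dict(assembly)
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for chrom in self.chroms:
            codes = self._encode(assembly[chrom])
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes[order]
            self._order[chrom] = order

    def _encode(self, seq: str) -> np.ndarray:
        arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        bad = arr == 255
        vals = arr.astype(np.int64)
        vals[bad] = 0
        k = self.k
        n = len(vals) - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        codes = np.zeros(n, dtype=np.int64)
        for i in range(k):
            codes = (codes << 2) | vals[i : i + n]
        invalid = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64))[
            k - 1 : k - 1 + n
        ] > 0
        codes[invalid] = -1
        return codes

    def lookup(self, code: int, chrom: str) -> np.ndarray:
        codes = self._codes[chrom]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return self._order[chrom][lo:hi]

    def seed_hits(self, query: str, stride: int = 4) -> dict[tuple[str, int], int]:
        """Diagonal seed counts: (chrom, diagonal) -> #seeds, where
        diagonal = target_pos - query_pos, binned to ±8."""
        qcodes = self._encode(query)
        hits: dict[tuple[str, int], int] = {}
        for qpos in range(0, len(qcodes), stride):
            code = qcodes[qpos]
            if code < 0:
                continue
            for chrom in self.chroms:
                for tpos in self.lookup(int(code), chrom):
                    diag = (int(tpos) - qpos) // 16
                    key = (chrom, diag)
                    hits[key] = hits.get(key, 0) + 1
        return hits


@dataclass
class JunctionHit:
    chrom: str
    diagonal: int
    score: int  # matched bases over the query span
    identity_left: float
    identity_right: float

    @property
    def intact(self) -> bool:
        return self._intact

    _intact: bool = field(default=False, repr=False)


def _diagonal_identity(
    query: str, target: str, diag: int, lo: int, hi: int
) -> tuple[float, int]:
    """Identity of query[lo:hi] against the target at the given diagonal."""
    t0 = lo + diag
    t1 = hi + diag
    if t0 < 0 or t1 > len(target):
        span_lo = max(lo, -diag)
        span_hi = min(hi, len(target) - diag)
        if span_hi <= span_lo:
            return 0.0, 0
        lo, hi = span_lo, span_hi
        t0, t1 = lo + diag, hi + diag
    q = np.frombuffer(query[lo:hi].encode(), dtype="S1")
    t = np.frombuffer(target[t0:t1].encode(), dtype="S1")
    m = int((q == t).sum())
    return m / (hi - lo), m


def search_junction(
    query: str,
    breakpoint: int,
    index: KmerIndex,
    config: OrthologyConfig | None = None,
) -> tuple[str, JunctionHit | None]:
    """Search one junction query against an indexed genome.

    ``breakpoint`` is the query offset of the junction point. Returns
    (state, best_hit) with state in {"intact", "absent", "unresolved"}:
    intact requires coverage of ``junction_half_window`` bases on BOTH
    sides of the breakpoint at ``min_junction_identity``, plus a unique
    best hit (second-best score < uniqueness_ratio × best).
    """
    config = config or OrthologyConfig()
    w = config.junction_half_window
    if breakpoint < w or len(query) - breakpoint < w:
        raise ValueError("query must span the junction window on both sides")

    seed_hits = search_candidates(query, index, config)
    if not seed_hits:
        return "absent", None

    scored: list[JunctionHit] = []
    for chrom, diag_bin in seed_hits:
        target = index.seqs[chrom]
        best = None
        for diag in range(diag_bin * 16 - 8, diag_bin * 16 + 24):
            id_all, score = _diagonal_identity(query, target, diag, 0, len(query))
            if best is None or score > best[1]:
                best = (diag, score, id_all)
        diag, score, _ = best
        # identity measured over up to 4 half-windows per side: coverage of
        # one half-window is required, but the longer span damps the
        # per-window binomial noise of diverged flanks
        wl = min(4 * w, breakpoint)
        wr = min(4 * w, len(query) - breakpoint)
        idl, _ = _diagonal_identity(query, target, diag, breakpoint - wl, breakpoint)
        idr, _ = _diagonal_identity(query, target, diag, breakpoint, breakpoint + wr)
        hit = JunctionHit(chrom, diag, score, idl, idr)
        hit._intact = (
            idl >= config.min_junction_identity
            and idr >= config.min_junction_identity
        )
        scored.append(hit)

    scored.sort(key=lambda h: -h.score)
    best = scored[0]
    if len(scored) > 1 and scored[1].score >= config.uniqueness_ratio * best.score:
        # two near-equal placements (e.g. segmental duplication)
        if scored[1].chrom != best.chrom or abs(scored[1].diagonal - best.diagonal) > 100:
            return "unresolved", best
    if best.intact:
        return "intact", best
    return "absent", best


def search_candidates(
    query: str, index: KmerIndex, config: OrthologyConfig, max_candidates: int = 8
) -> list[tuple[str, int]]:
    hits = index.seed_hits(query)
    if not hits:
        return []
    min_seeds = max(3, len(query) // 400)
    ranked = sorted(hits.items(), key=lambda kv: -kv[1])
    return [key for key, n in ranked[:max_candidates] if n >= min_seeds]


@dataclass
class OrthologCall:
    species: str
    state: str  # present | empty_site | unresolved
    evidence: dict[str, str] = field(default_factory=dict)


def call_presence(
    locus_start: int,
    locus_end: int,
    chrom: str,
    focal_assembly: Mapping[str, str],
    target_index: KmerIndex,
    species: str,
    config: OrthologyConfig | None = None,
    tsd_len: int = 6,
) -> OrthologCall:
    """Presence state of one insertion in one target species.

    Junction queries are built from the focal assembly: genomic flank on one
    side of each junction, element sequence on the other. If neither
    junction resolves at the primary flank length the search escalates; if
    no junction is intact, a flank–flank empty-site query (skipping the
    downstream TSD copy) distinguishes a clean pre-integration site from an
    unresolvable locus.
    """
    config = config or OrthologyConfig()
    seq = focal_assembly[chrom]
    evidence: dict[str, str] = {}

    # the element-side span is capped: the junction neighborhood carries the
    # information, while long element stretches match paralogous proviruses
    # and defeat the unique-best-hit test
    elem_span = min(locus_end - locus_start, 500)
    for flank in (config.flank_len_primary, config.flank_len_escalated):
        states = {}
        for junction in ("left", "right"):
            if junction == "left":
                lo = max(0, locus_start - flank)
                hi = min(len(seq), locus_start + elem_span)
                query = seq[lo:hi]
                bp = locus_start - lo
            else:
                lo = max(0, locus_end - elem_span)
                hi = min(len(seq), locus_end + flank)
                query = seq[lo:hi]
                bp = locus_end - lo
            state, hit = search_junction(query, bp, target_index, config)
            states[junction] = state
            evidence[f"{junction}@{flank}"] = state
        if "intact" in states.values():
            return OrthologCall(species, "present", evidence)
        if set(states.values()) == {"absent"}:
            break  # junctions cleanly absent; no need to escalate

    flank = config.flank_len_primary
    lo = max(0, locus_start - flank)
    up = seq[lo:locus_start]
    down = seq[locus_end + tsd_len : locus_end + tsd_len + flank]
    if len(up) >= config.junction_half_window and len(down) >= config.junction_half_window:
        state, _ = search_junction(up + down, len(up), target_index, config)
        evidence["empty_site"] = state
        if state == "intact":
            return OrthologCall(species, "empty_site", evidence)
    return OrthologCall(species, "unresolved", evidence)


def presence_matrix(
    truth_or_loci: Sequence,
    focal_assembly: Mapping[str, str],
    species_genomes: Mapping[str, Mapping[str, str]],
    focal_species: str,
    config: OrthologyConfig | None = None,
) -> pd.DataFrame:
    """Presence calls for every locus × species; loci are objects with
    chrom/start/end/locus_id (or name) attributes plus optional tsd_len."""
    config = config or OrthologyConfig()
    indexes = {
        sp: KmerIndex(genome, config.seed_k)
        for sp, genome in species_genomes.items()
        if sp != focal_species
    }
    records = {}
    for locus in truth_or_loci:
        lid = getattr(locus, "locus_id", None) or getattr(locus, "name")
        tsd = getattr(locus, "tsd_len", 6)
        row = {focal_species: "present"}
        for sp, idx in indexes.items():
            call = call_presence(
                locus.start, locus.end, locus.chrom, focal_assembly,
                idx, sp, config, tsd,
            )
            row[sp] = call.state
        records[lid] = row
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "locus"
    return df


def assign_oca(
    calls: Mapping[str, str],
    species_tree: str | dendropy.Tree,
    focal_species: str,
) -> str:
    """Oldest common ancestor: the MRCA of the focal species and every
    species called present. Unresolved species are ignored; an empty_site
    species inside the OCA clade triggers a tree-coherence warning."""
    import warnings

    tree = (
        species_tree
        if isinstance(species_tree, dendropy.Tree)
        else dendropy.Tree.get(data=species_tree, schema="newick")
    )
    tree.is_rooted = True  # OCA is defined on the rooted species tree
    labels = {t.label for t in tree.taxon_namespace}
    if focal_species not in labels:
        raise ValueError(f"focal species {focal_species!r} not on tree")
    present = sorted({sp for sp, st in calls.items() if st == "present"} | {focal_species})
    for sp in present:
        if sp not in labels:
            raise ValueError(f"called species {sp!r} not on tree")
    mrca = tree.mrca(taxon_labels=present)
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    for sp, st in calls.items():
        if st == "empty_site" and sp in clade and sp not in present:
            warnings.warn(
                f"{sp} lacks the insertion but descends from the OCA "
                "(loss or incomplete lineage sorting)", stacklevel=2,
            )
    if mrca.is_leaf():
        return mrca.taxon.label
    if mrca.label:
        return mrca.label
    return "+".join(sorted(clade))


# ---------------------------------------------------------------------------
# Genotype statistics

_GENOTYPE_ALLELES = {"+/+": 2, "+/-": 1, "-/-": 0}


@dataclass
class FrequencyResult:
    frequency: float
    insertion_alleles: int
    total_alleles: int
    n_failed: int


def allele_frequency(
    table: pd.DataFrame, locus: str, species: str | None = None
) -> FrequencyResult:
    """Insertion allele frequency from a 3-primer PCR genotype table.

    frequency = (2·n(+/+) + n(+/−)) / (2·n(non-failed)); failed reactions
    are excluded from the denominator.
    """
    col = _genotype_column(table, locus, species)
    non_failed = col[col != "failed"]
    if non_failed.empty:
        raise ValueError(f"all genotypes failed for locus {locus}")
    bad = set(non_failed) - set(_GENOTYPE_ALLELES)
    if bad:
        raise ValueError(f"unknown genotype value(s): {sorted(bad)}")
    ins = int(sum(_GENOTYPE_ALLELES[g] for g in non_failed))
    total = 2 * len(non_failed)
    return FrequencyResult(ins / total, ins, total, int((col == "failed").sum()))


def classify_polymorphism(
    table: pd.DataFrame, locus: str, species: str | None = None
) -> str:
    """fixed_present / polymorphic / absent: polymorphic requires at least
    one insertion allele AND one empty-site allele among non-failed calls."""
    res = allele_frequency(table, locus, species)
    if res.insertion_alleles == 0:
        return "absent"
    if res.insertion_alleles == res.total_alleles:
        return "fixed_present"
    return "polymorphic"


def _genotype_column(
    table: pd.DataFrame, locus: str, species: str | None
) -> pd.Series:
    df = table
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
    if locus not in df.columns:
        raise KeyError(f"locus {locus!r} not in genotype table")
    return df[locus]
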