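"""Synthetic genomes with implanted proviruses and known ground truth.

Everything downstream of this module (mining, structural annotation, LTR
dating, orthology, transcript and assay quantification) is exercised on data
produced here. The generator emulates the features of real data those
analyses depend on:

* a consensus SERV-K/MER11-style provirus — 588-bp LTRs at both termini,
  gag/pro/pol/env ORFs that translate cleanly, a recombinant variant
  carrying an HML-8-env tail (283 nt), a 726-nt MER11 region, and a 42-nt
  PPT remnant between *env* and the 3' LTR;
* a catalog of shared internal deletions at the coordinates the clade is
  known for (pro-pol 3384–5639, pol-env 6233–8152, 1-based on the
  consensus) and seven U3 LTR deletions (Δ1–Δ7) combined into the observed
  LTR variants;
* implantation with target-site duplication, strand, and an LTR pair
  mutated to a target age under a Poisson substitution model calibrated so
  the expected pairwise LTR divergence is ``rate × age`` (default rate
  0.34%/site/Myr, i.e. one expected difference between two 588-bp LTRs per
  0.5 Myr);
* fragmented RepeatMasker-style annotation tracks, per-species derived
  genomes with shared/absent insertions, spliced reads over a rec-like
  junction, Hardy–Weinberg genotype tables, and two-channel flow-cytometry
  event tables.

All generators are deterministic given their seed. A TruthTable row records
the exact final interval and structure of every implant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .mining import RepeatAnnotation

__all__ = [
    "ElementLibrary",
    "ImplantSpec",
    "TruthRow",
    "TruthTable",
    "SpliceModel",
    "make_element_library",
    "simulate_host_genome",
    "implant",
    "implant_many",
    "mutate_ltr_pair",
    "emit_repeatmasker_track",
    "speciate",
    "simulate_spliced_reads",
    "write_sam",
    "simulate_flow_events",
    "simulate_genotype_table",
    "write_fasta",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

# --- consensus layout (0-based half-open, short-LTR consensus) -------------
LTR_FULL_LEN = 968
LTR_SHORT_LEN = 588
R_LEN = 30
U5_LEN = 94
U3_FULL_LEN = LTR_FULL_LEN - R_LEN - U5_LEN  # 844
U3R_SHORT_LEN = 494  # U3+R of the short (Δ1+Δ2) LTR

UTR5 = (588, 900)
GENES = {
    "gag": (900, 2910),
    "pro": (2910, 3810),
    "pol": (3810, 6510),
    "env": (6510, 8610),
}
UTR3 = (8610, 8900)
CONSENSUS_LEN = 9488  # 588 + internal + 588

# Shared internal deletions, 0-based half-open on consensus coordinates
# (1-based inclusive 3384–5639 and 6233–8152).
INTERNAL_DELETIONS = {
    "pro_pol": (3383, 5639),
    "pol_env": (6232, 8152),
}

# U3 deletions on the full-length LTR, 0-based half-open. Lengths follow the
# reported approximate sizes (~100/260/250/200/370/100/180; Δ1 sized so that
# Δ1+Δ2 yields exactly the 588-bp short LTR).
LTR_DELETIONS = {
    "Δ1": (100, 220),
    "Δ2": (300, 560),
    "Δ3": (250, 500),
    "Δ4": (350, 550),
    "Δ5": (150, 520),
    "Δ6": (600, 700),
    "Δ7": (560, 740),
}
LTR_VARIANTS = {
    "full": (),
    "Δ1": ("Δ1",),
    "Δ2": ("Δ2",),
    "Δ1+Δ2": ("Δ1", "Δ2"),
    "Δ3": ("Δ3",),
    "Δ4": ("Δ4",),
    "Δ5+Δ6": ("Δ5", "Δ6"),
    "Δ4+Δ7": ("Δ4", "Δ7"),
}

HML8_ENV_TAIL_LEN = 283
MER11_LEN = 726
PPT_REMNANT_LEN = 42
SREC_EXON1_NT = 261
SREC_EXON2_NT = 189

DEFAULT_RATE = 0.0034  # pairwise LTR divergence per site per Myr


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) sense codons + TAA."""
    body = rng.choice(np.array(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def apply_deletions(seq: str, intervals: Iterable[tuple[int, int]]) -> str:
    """Delete 0-based half-open intervals (given in ``seq`` coordinates)."""
    out, prev = [], 0
    for start, end in sorted(intervals):
        if start < prev:
            raise ValueError("overlapping deletion intervals")
        out.append(seq[prev:start])
        prev = end
    out.append(seq[prev:])
    return "".join(out)


@dataclass(frozen=True)
class SpliceModel:
    """Doubly-spliced rec-like transcript model, 0-based coordinates on the
    recombinant provirus: exon1 = [start, donor), intron = [donor, acceptor),
    exon2 coding continues from ``acceptor``."""

    start: int
    donor: int
    acceptor: int
    exon1_nt: int = SREC_EXON1_NT
    exon2_nt: int = SREC_EXON2_NT

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError("splice donor must precede acceptor")
        if self.exon1_nt % 3 or self.exon2_nt % 3:
            raise ValueError("coding exon lengths must be divisible by 3")


@dataclass
class ElementLibrary:
    """Reference element set for one synthetic study."""

    seed: int
    consensus_provirus: str
    full_ltr: str
    short_ltr: str
    mer11_ref: str
    hml8_env_tail: str
    ppt_remnant: str
    utr5: str
    utr3: str
    genes: dict[str, str]
    splice_model: SpliceModel
    decoy_families: dict[str, str]
    internal_deletions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(INTERNAL_DELETIONS)
    )
    ltr_deletions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(LTR_DELETIONS)
    )
    gene_intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(GENES)
    )

    @property
    def internal_seq(self) -> str:
        """Non-recombinant internal region (between the LTRs)."""
        return (
            self.utr5
            + "".join(self.genes[g] for g in ("gag", "pro", "pol", "env"))
            + self.utr3
        )

    @property
    def recombinant_tail(self) -> str:
        """HML-8-derived region replacing the 3' UTR in recombinants."""
        return self.hml8_env_tail + self.mer11_ref + self.ppt_remnant

    @property
    def recombinant_provirus(self) -> str:
        env_end = self.gene_intervals["env"][1]
        return (
            self.consensus_provirus[:env_end]
            + self.recombinant_tail
            + self.short_ltr
        )

    @property
    def u3r_short(self) -> str:
        """U3+R of the short LTR (the reporter-construct U3R segment)."""
        return self.short_ltr[:U3R_SHORT_LEN]

    def ltr_variant_seq(self, variant: str) -> str:
        try:
            names = LTR_VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown LTR variant {variant!r}") from None
        return apply_deletions(self.full_ltr, [self.ltr_deletions[n] for n in names])

    def build_element(
        self, spec: "ImplantSpec"
    ) -> tuple[str, str, dict[str, tuple[int, int]]]:
        """Assemble the unmutated element for ``spec``.

        Returns ``(ltr_seq, internal_seq, features)`` where features are
        intervals in element coordinates assuming both LTRs have the
        (unmutated) variant length; internal deletions and ORF disruptions
        are already applied. For solo LTRs internal_seq is empty.
        """
        ltr = self.ltr_variant_seq(spec.ltr_variant)
        if spec.solo_ltr:
            return ltr, "", {"ltr5": (0, len(ltr))}

        internal = self.internal_seq
        if spec.recombinant:
            env_end = self.gene_intervals["env"][1]
            internal = internal[: env_end - LTR_SHORT_LEN] + self.recombinant_tail

        # premature stops, positions in internal coordinates
        internal = list(internal)
        for gene, frac in (spec.orf_disruptions or {}).items():
            gs, ge = self.gene_intervals[gene]
            n_codons = (ge - gs) // 3
            codon = int(frac * n_codons)
            pos = gs - LTR_SHORT_LEN + 3 * codon
            internal[pos : pos + 3] = "TAA"
        internal = "".join(internal)

        dels = []
        for name in spec.deletions:
            try:
                ds, de = self.internal_deletions[name]
            except KeyError:
                raise ValueError(f"unknown deletion name {name!r}") from None
            dels.append((ds - LTR_SHORT_LEN, de - LTR_SHORT_LEN))
        internal = apply_deletions(internal, dels)

        nl = len(ltr)
        features = {
            "ltr5": (0, nl),
            "internal": (nl, nl + len(internal)),
            "ltr3": (nl + len(internal), 2 * nl + len(internal)),
        }
        if spec.recombinant:
            # MER11 region position after upstream deletions
            mer_start = self.gene_intervals["env"][1] - LTR_SHORT_LEN + HML8_ENV_TAIL_LEN
            removed = sum(
                de - ds
                for name in spec.deletions
                for ds, de in [self.internal_deletions[name]]
            )
            mer_start -= removed
            features["mer11"] = (nl + mer_start, nl + mer_start + MER11_LEN)
        return ltr, internal, features


def make_element_library(seed: int) -> ElementLibrary:
    """Deterministically build the synthetic reference element set."""
    rng = np.random.default_rng(seed)
    full_ltr = _random_seq(rng, LTR_FULL_LEN)
    short_ltr = apply_deletions(
        full_ltr, [LTR_DELETIONS["Δ1"], LTR_DELETIONS["Δ2"]]
    )
    assert len(short_ltr) == LTR_SHORT_LEN

    utr5 = _random_seq(rng, UTR5[1] - UTR5[0])
    genes = {g: _random_orf(rng, (e - s) // 3) for g, (s, e) in GENES.items()}
    utr3 = _random_seq(rng, UTR3[1] - UTR3[0])

    # HML-8 env tail carries the sRec second coding exon in frame:
    # 40 nt lead-in + 62 sense codons + TAA + 54 nt tail = 283 nt.
    exon2 = "".join(rng.choice(np.array(SENSE_CODONS), size=62)) + "TAA"
    hml8_env_tail = _random_seq(rng, 40) + exon2 + _random_seq(rng, 54)
    assert len(hml8_env_tail) == HML8_ENV_TAIL_LEN
    mer11_ref = _random_seq(rng, MER11_LEN)
    ppt_remnant = rng.choice(np.frombuffer(b"AG", dtype="S1"),
                             size=PPT_REMNANT_LEN).tobytes().decode()

    env_start, env_end = GENES["env"]
    splice_model = SpliceModel(
        start=env_start,
        donor=env_start + SREC_EXON1_NT,
        acceptor=env_end + 40,
    )

    decoys = {
        "AluSyn": _random_seq(rng, 300),
        "L1Syn": _random_seq(rng, 1800),
    }

    consensus = short_ltr + utr5 + "".join(
        genes[g] for g in ("gag", "pro", "pol", "env")
    ) + utr3 + short_ltr
    assert len(consensus) == CONSENSUS_LEN

    return ElementLibrary(
        seed=seed,
        consensus_provirus=consensus,
        full_ltr=full_ltr,
        short_ltr=short_ltr,
        mer11_ref=mer11_ref,
        hml8_env_tail=hml8_env_tail,
        ppt_remnant=ppt_remnant,
        utr5=utr5,
        utr3=utr3,
        genes=genes,
        splice_model=splice_model,
        decoy_families=decoys,
    )


@dataclass
class ImplantSpec:
    chrom: str
    position: int
    strand: str = "+"
    age_myr: float = 0.0
    deletions: tuple[str, ...] = ()
    ltr_variant: str = "Δ1+Δ2"
    recombinant: bool = True
    tsd_len: int = 6
    solo_ltr: bool = False
    decoy: str | None = None
    orf_disruptions: dict[str, float] | None = None
    mismatched_tsd: bool = False

    def __post_init__(self) -> None:
        if self.solo_ltr and self.deletions:
            raise ValueError("solo_ltr implies no internal deletions")
        if not np.isfinite(self.age_myr) or self.age_myr < 0:
            raise ValueError("age_myr must be finite and non-negative")
        if not 4 <= self.tsd_len <= 8:
            raise ValueError("tsd_len must be in [4, 8]")


@dataclass
class TruthRow:
    locus_id: str
    chrom: str
    start: int  # element interval, 0-based half-open, excl. TSD copies
    end: int
    strand: str
    age_myr: float
    solo_ltr: bool
    recombinant: bool
    deletions: tuple[str, ...]
    ltr_variant: str
    decoy: str | None
    tsd_len: int
    tsd_up: str
    tsd_down: str
    element_seq: str
    features: dict[str, tuple[int, int]]  # genomic intervals per label
    orf_truth: dict[str, str] = field(default_factory=dict)
    presence: dict[str, bool] = field(default_factory=dict)
    allele_freq: float | None = None


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def by_id(self, locus_id: str) -> TruthRow:
        for row in self.rows:
            if row.locus_id == locus_id:
                return row
        raise KeyError(locus_id)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = dataclasses.asdict(r)
            d["deletions"] = ",".join(r.deletions)
            d["features"] = ";".join(
                f"{k}:{s}-{e}" for k, (s, e) in r.features.items()
            )
            d["presence"] = ";".join(
                f"{sp}:{int(v)}" for sp, v in sorted(r.presence.items())
            )
            d.pop("element_seq")
            recs.append(d)
        return pd.DataFrame(recs)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def simulate_host_genome(
    n_chrom: int, chrom_len: int, gc: float = 0.41, seed: int = 0
) -> dict[str, str]:
    """I.i.d. background assembly: ``n_chrom`` chromosomes of ``chrom_len``."""
    if chrom_len <= 0 or n_chrom <= 0:
        raise ValueError("n_chrom and chrom_len must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return {
        f"chr{i + 1}": _random_seq(rng, chrom_len, gc)
        for i in range(n_chrom)
    }


def mutate_ltr_pair(
    ltr: str, age_myr: float, rate: float = DEFAULT_RATE,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """Diverge an LTR pair to a target age.

    Each copy receives ``Poisson(L * rate/2 * age)`` substitutions at
    distinct uniform positions (no indels), so the expected pairwise
    divergence between the copies is ``rate * age``.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if age_myr < 0:
        raise ValueError("age must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    lam = len(ltr) * rate / 2 * age_myr
    for _ in range(2):
        n = min(int(rng.poisson(lam)), len(ltr))
        copy = np.frombuffer(ltr.encode(), dtype="S1").copy()
        pos = rng.choice(len(ltr), size=n, replace=False)
        for p in pos:
            choices = BASES[BASES != copy[p]]
            copy[p] = rng.choice(choices)
        out.append(copy.tobytes().decode())
    return out[0], out[1]


def _chrom_number(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def implant(
    assembly: Mapping[str, str],
    spec: ImplantSpec,
    library: ElementLibrary,
    seed: int | np.random.Generator = 0,
    assembly_tag: str = "SIM",
) -> tuple[dict[str, str], TruthRow]:
    """Insert one element with a duplicated target site.

    The target-site bases at the insertion point are duplicated on both
    sides of the element; minus-strand implants are reverse-complemented;
    the LTR pair is mutated to the target age before assembly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assembly = dict(assembly)
    chrom_seq = assembly[spec.chrom]

    if spec.decoy is not None:
        elem = library.decoy_families[spec.decoy]
        features = {spec.decoy: (0, len(elem))}
        orf_truth = {}
    else:
        ltr, internal, features = library.build_element(spec)
        if spec.solo_ltr:
            ltr5, _ = mutate_ltr_pair(ltr, spec.age_myr, seed=rng)
            elem = ltr5
        else:
            ltr5, ltr3 = mutate_ltr_pair(ltr, spec.age_myr, seed=rng)
            elem = ltr5 + internal + ltr3
        orf_truth = _orf_truth(spec, library)

    p = spec.position
    if p + len(elem) > len(chrom_seq) or p < spec.tsd_len:
        raise ValueError("implant does not fit within chromosome")
    tsd = chrom_seq[p : p + spec.tsd_len]
    tsd_down = tsd
    if spec.mismatched_tsd:
        tsd_down = _random_seq(rng, spec.tsd_len)

    if spec.strand == "-":
        elem_ins = str(Seq(elem).reverse_complement())
        n = len(elem)
        features = {
            k: (n - e, n - s) for k, (s, e) in features.items()
        }
        # 5'/3' swap under reverse complement: keep labels tied to the
        # element's own orientation but genomic intervals are flipped.
    else:
        elem_ins = elem

    new_seq = chrom_seq[: p + spec.tsd_len] + elem_ins + tsd_down + chrom_seq[p + spec.tsd_len :]
    assembly[spec.chrom] = new_seq
    start = p + spec.tsd_len
    end = start + len(elem_ins)
    genomic_features = {k: (start + s, start + e) for k, (s, e) in features.items()}

    row = TruthRow(
        locus_id=f"{_chrom_number(spec.chrom)}-{start + 1}_{assembly_tag}",
        chrom=spec.chrom,
        start=start,
        end=end,
        strand=spec.strand,
        age_myr=spec.age_myr,
        solo_ltr=spec.solo_ltr,
        recombinant=spec.recombinant and spec.decoy is None and not spec.solo_ltr,
        deletions=tuple(spec.deletions),
        ltr_variant=spec.ltr_variant,
        decoy=spec.decoy,
        tsd_len=spec.tsd_len,
        tsd_up=tsd,
        tsd_down=tsd_down,
        element_seq=elem_ins,
        features=genomic_features,
        orf_truth=orf_truth,
    )
    return assembly, row


def _orf_truth(spec: ImplantSpec, library: ElementLibrary) -> dict[str, str]:
    """Expected per-gene ORF status, derived analytically from the spec.

    Mirrors the 90%-completeness rule: a premature stop or net-frameshifting
    deletion before 90% of the reference codons disrupts; loss of >=50% of
    the gene span means absent.
    """
    if spec.solo_ltr or spec.decoy:
        return {}
    status = {}
    for gene, (gs, ge) in library.gene_intervals.items():
        n_codons = (ge - gs) // 3
        events = []
        if spec.orf_disruptions and gene in spec.orf_disruptions:
            events.append(int(spec.orf_disruptions[gene] * n_codons))
        removed = 0
        for name in spec.deletions:
            ds, de = library.internal_deletions[name]
            ov = max(0, min(de, ge) - max(ds, gs))
            removed += ov
            # the within-gene overlap length decides the reading frame
            if ov and ov % 3 != 0:
                events.append((max(ds, gs) - gs) // 3)
        if removed >= 0.5 * (ge - gs):
            status[gene] = "absent"
        elif events and min(events) < spec_completeness(n_codons):
            status[gene] = "disrupted"
        else:
            status[gene] = "intact"
    return status


def spec_completeness(n_codons: int, fraction: float = 0.9) -> int:
    return int(np.ceil(fraction * n_codons))


def implant_many(
    assembly: Mapping[str, str],
    specs: Sequence[ImplantSpec],
    library: ElementLibrary,
    seed: int = 0,
    assembly_tag: str = "SIM",
) -> tuple[dict[str, str], TruthTable]:
    """Implant several elements; positions are interpreted on the original
    assembly and must be pairwise non-overlapping after insertion."""
    rng = np.random.default_rng(seed)
    # Insert right-to-left per chromosome so earlier positions stay valid.
    order = sorted(range(len(specs)), key=lambda i: (specs[i].chrom, -specs[i].position))
    assembly = dict(assembly)
    rows: list[TruthRow] = [None] * len(specs)  # type: ignore[list-item]
    for i in order:
        assembly, rows[i] = implant(assembly, specs[i], library, rng, assembly_tag)
    # Recompute genomic coordinates: insertions upstream shift later ones.
    for chrom in {s.chrom for s in specs}:
        idx = [i for i in range(len(specs)) if specs[i].chrom == chrom]
        idx.sort(key=lambda i: specs[i].position)
        offset = 0
        for i in idx:
            row = rows[i]
            shift = offset
            rows[i] = dataclasses.replace(
                row,
                start=row.start + shift,
                end=row.end + shift,
                features={k: (s + shift, e + shift) for k, (s, e) in row.features.items()},
                locus_id=f"{_chrom_number(row.chrom)}-{row.start + shift + 1}_{assembly_tag}",
            )
            offset += (row.end - row.start) + specs[i].tsd_len
    truth = TruthTable(sorted(rows, key=lambda r: (r.chrom, r.start)))
    # sanity: implanted sequence must equal the element string
    for row in truth:
        got = assembly[row.chrom][row.start : row.end]
        if got != row.element_seq:
            raise AssertionError(f"truth interval mismatch for {row.locus_id}")
    return assembly, truth


# ---------------------------------------------------------------------------
# Annotation track emission

def emit_repeatmasker_track(
    assembly: Mapping[str, str],
    truth: TruthTable,
    fragmentation: str = "none",
    seed: int = 0,
) -> list[RepeatAnnotation]:
    """Annotation records for every implant, RepeatMasker-style.

    LTR termini are reported as LTR5_RM, internal sequence as HERVK-int,
    the recombinant region as MER11A, decoys under their own family name.
    With ``fragmentation="split"`` internal records are broken into pieces
    separated by sub-kilobase gaps (drawn uniform on [50, 900]) and outer
    record edges are jittered by up to 3 bases, mimicking real-track
    fragmentation without violating the 1-kb merge rule.
    """
    if fragmentation not in ("none", "split"):
        raise ValueError("fragmentation must be 'none' or 'split'")
    rng = np.random.default_rng(seed)
    records: list[RepeatAnnotation] = []
    for row in truth:
        jit = (lambda: int(rng.integers(0, 4))) if fragmentation == "split" else (lambda: 0)
        for label, (s, e) in sorted(row.features.items(), key=lambda kv: kv[1]):
            if row.decoy is not None:
                family = row.decoy
            elif label.startswith("ltr"):
                family = "LTR5_RM"
            elif label == "mer11":
                family = "MER11A"
            else:
                family = "HERVK-int"
            if label == "internal" and fragmentation == "split" and e - s > 2500:
                records.extend(
                    RepeatAnnotation(row.chrom, ps, pe, row.strand, family)
                    for ps, pe in _split_interval(s, e, rng)
                )
            else:
                s2 = max(0, s - jit()) if label in ("ltr5", "ltr3") or row.decoy else s
                e2 = e + jit() if label in ("ltr5", "ltr3") or row.decoy else e
                records.append(RepeatAnnotation(row.chrom, s2, e2, row.strand, family))
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def _split_interval(
    s: int, e: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n_pieces = int(rng.integers(2, 4))
    cuts = sorted(rng.choice(np.arange(s + 600, e - 600), size=n_pieces - 1, replace=False))
    pieces = []
    prev = s
    for c in cuts:
        gap = int(rng.integers(50, 901))
        pieces.append((prev, max(prev + 50, int(c) - gap // 2)))
        prev = int(c) + gap // 2
    pieces.append((prev, e))
    return [(a, b) for a, b in pieces if b - a >= 30]


# ---------------------------------------------------------------------------
# Speciation

def speciate(
    assembly: Mapping[str, str],
    truth: TruthTable,
    species_tree: str,
    focal_species: str,
    presence_map: Mapping[str, Mapping[str, bool]],
    flank_divergence: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], TruthTable]:
    """Derive one genome per species on ``species_tree`` (newick).

    Elements absent in a species are replaced by the empty pre-integration
    site (a single TSD copy). Background and flanks accumulate substitutions
    at ``flank_divergence`` per unit patristic distance from the focal
    species; retained elements are left unmutated so presence truth is
    exact. ``presence_map``: locus_id -> {species: bool}.
    """
    tree = dendropy.Tree.get(data=species_tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if focal_species not in taxa:
        raise ValueError(f"focal species {focal_species!r} not on tree")
    for pm in presence_map.values():
        for sp in pm:
            if sp not in taxa:
                raise ValueError(f"species {sp!r} not on tree")

    rng = np.random.default_rng(seed)
    genomes: dict[str, dict[str, str]] = {}
    new_rows = [dataclasses.replace(r, presence={}) for r in truth]

    for sp in sorted(taxa):
        dist = (
            0.0 if sp == focal_species
            else pdm.patristic_distance(taxa[focal_species], taxa[sp])
        )
        genome: dict[str, str] = {}
        kept_intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom in sorted(assembly):
            rows = [r for r in truth if r.chrom == chrom]
            seq = assembly[chrom]
            # remove absent elements right-to-left; track retained offsets
            removals = []
            for r in rows:
                present = presence_map.get(r.locus_id, {}).get(sp, sp == focal_species)
                if not present:
                    removals.append((r.start, r.end + r.tsd_len))
            shift_at = sorted(removals)
            parts, prev = [], 0
            for s, e in shift_at:
                parts.append(seq[prev:s])
                prev = e
            parts.append(seq[prev:])
            new_seq = "".join(parts)

            kept = []
            for i, r in enumerate(rows):
                present = presence_map.get(r.locus_id, {}).get(sp, sp == focal_species)
                for row_out in new_rows:
                    if row_out.locus_id == r.locus_id:
                        row_out.presence[sp] = bool(present)
                if present:
                    shift = sum(e - s for s, e in shift_at if e <= r.start)
                    kept.append((r.start - shift, r.end - shift))
            genome[chrom] = new_seq
            kept_intervals[chrom] = kept

        if dist > 0:
            p_sub = flank_divergence * dist
            for chrom, seq in genome.items():
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                mask = rng.random(len(arr)) < p_sub
                for s, e in kept_intervals[chrom]:
                    mask[s:e] = False
                idx = np.nonzero(mask)[0]
                for i in idx:
                    arr[i] = rng.choice(BASES[BASES != arr[i]])
                genome[chrom] = arr.tobytes().decode()
        genomes[sp] = genome

    return genomes, TruthTable(new_rows)


# ---------------------------------------------------------------------------
# Spliced reads, flow events, genotype tables

def simulate_spliced_reads(
    provirus: str,
    splice_model: SpliceModel,
    n_reads: int = 1000,
    read_len: int = 100,
    junction_fraction: float = 0.2,
    seed: int = 0,
) -> list[dict]:
    """Reads over a rec-like junction, as plain alignment dicts.

    Junction reads carry a CIGAR with an N gap spanning exactly
    [donor, acceptor); the rest are contiguous M reads. Use ``write_sam``
    to serialize with an @SQ header.
    """
    if read_len >= len(provirus):
        raise ValueError("read_len must be shorter than the provirus")
    rng = np.random.default_rng(seed)
    intron = splice_model.acceptor - splice_model.donor
    reads = []
    for i in range(n_reads):
        if rng.random() < junction_fraction:
            k = int(rng.integers(10, read_len - 9))  # bases before the gap
            pos = splice_model.donor - k
            seq = provirus[pos : splice_model.donor] + provirus[
                splice_model.acceptor : splice_model.acceptor + read_len - k
            ]
            cigar = f"{k}M{intron}N{read_len - k}M"
        else:
            pos = int(rng.integers(0, len(provirus) - read_len + 1))
            seq = provirus[pos : pos + read_len]
            cigar = f"{read_len}M"
        reads.append({"name": f"read{i}", "pos": pos, "cigar": cigar, "seq": seq})
    return reads


def write_sam(
    path: str | Path, reads: Sequence[dict], ref_name: str, ref_len: int
) -> None:
    """Serialize reads from ``simulate_spliced_reads`` as SAM with @SQ."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r["name"]
            a.query_sequence = r["seq"]
            a.reference_id = 0
            a.reference_start = r["pos"]
            a.cigarstring = r["cigar"]
            a.mapping_quality = 60
            a.flag = 0
            fh.write(a)


def simulate_flow_events(
    n: int,
    mfi_gfp: float = 3500.0,
    mfi_mcherry: float = 1000.0,
    untransfected_fraction: float = 0.3,
    seed: int = 0,
    cv: float = 0.5,
    autofluorescence: float = 30.0,
    debris_fraction: float = 0.05,
) -> pd.DataFrame:
    """Two-channel reporter event table (columns FSC, SSC, GFP, mCherry).

    Transfected events draw log-normal intensities with the requested
    channel means; untransfected events sit near autofluorescence in both
    channels; a small debris fraction falls outside the scatter gate.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    def lognorm(mean: float, size: int) -> np.ndarray:
        mu = np.log(mean) - sigma**2 / 2
        return rng.lognormal(mu, sigma, size)

    untr = rng.random(n) < untransfected_fraction
    gfp = np.where(untr, lognorm(autofluorescence, n), lognorm(mfi_gfp, n))
    mch = np.where(untr, lognorm(autofluorescence, n), lognorm(mfi_mcherry, n))
    fsc = rng.normal(50_000, 8_000, n)
    ssc = rng.normal(30_000, 6_000, n)
    debris = rng.random(n) < debris_fraction
    fsc[debris] = rng.normal(5_000, 2_000, debris.sum())
    ssc[debris] = rng.normal(90_000, 10_000, debris.sum())
    return pd.DataFrame({"FSC": fsc, "SSC": ssc, "GFP": gfp, "mCherry": mch})


def simulate_genotype_table(
    loci: Sequence[str],
    n_individuals: int,
    allele_freqs: Mapping[str, float],
    seed: int = 0,
    fail_rate: float = 0.0,
    species: str = "macaca_mulatta",
) -> pd.DataFrame:
    """Hardy–Weinberg diploid genotypes per individual and locus.

    Cells are '+/+', '+/-', '-/-' (the three outcomes the 3-primer
    allele-specific PCR design distinguishes) or 'failed'.
    """
    rng = np.random.default_rng(seed)
    data = {}
    for locus in loci:
        p = allele_freqs[locus]
        if not 0 <= p <= 1:
            raise ValueError(f"allele frequency for {locus} outside [0, 1]")
        probs = [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]
        draws = rng.choice(["+/+", "+/-", "-/-"], size=n_individuals, p=probs)
        fails = rng.random(n_individuals) < fail_rate
        draws[fails] = "failed"
        data[locus] = draws
    df = pd.DataFrame(data, index=[f"{species}_{i + 1}" for i in range(n_individuals)])
    df.index.name = "individual"
    df.insert(0, "species", species)
    return df


def simulate_ltr_pair_set(
    library: ElementLibrary,
    n: int = 30,
    age_range: tuple[float, float] = (0.5, 6.0),
    lineage_range: tuple[float, float] = (8.0, 15.0),
    rate: float = DEFAULT_RATE,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, tuple[str, str]], dict[str, float]]:
    """Cognate LTR pairs with realistic between-provirus structure.

    Each provirus descends from its own viral-lineage branch: the ancestral
    LTR first accrues private substitutions equivalent to ``lineage_range``
    Myr of single-lineage evolution, then is duplicated at integration and
    the two copies diverge for the integration age. Inter-provirus LTR
    distances therefore dwarf intra-pair divergence, as in a real LTR
    phylogeny where cognate pairs form cherries.

    Returns (sequences keyed ``<locus>__5p``/``<locus>__3p``, pairing map,
    true ages in Myr).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    pairing: dict[str, tuple[str, str]] = {}
    ages: dict[str, float] = {}
    base = library.short_ltr
    for i in range(n):
        lineage = rng.uniform(*lineage_range)
        ancestral, _ = mutate_ltr_pair(base, 2 * lineage, rate, rng)
        age = float(rng.uniform(*age_range))
        l5, l3 = mutate_ltr_pair(ancestral, age, rate, rng)
        pid = f"prov{i:03d}"
        seqs[f"{pid}__5p"] = l5
        seqs[f"{pid}__3p"] = l3
        pairing[pid] = (f"{pid}__5p", f"{pid}__3p")
        ages[pid] = age
    return seqs, pairing, ages


# ---------------------------------------------------------------------------
# Standard study scenario

@dataclass
class StudyData:
    library: ElementLibrary
    assembly: dict[str, str]
    truth: TruthTable
    specs: list[ImplantSpec]


def simulate_study(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 2_500_000,
    gc: float = 0.41,
    n_full: int = 12,
    n_pro_pol: int = 8,
    n_pol_env: int = 10,
    n_both: int = 6,
    n_nonrecomb: int = 6,
    n_solo: int = 10,
    n_decoy: int = 8,
    max_age: float = 12.0,
) -> StudyData:
    """The default synthetic study: 60 implants in a 5-Mb background.

    The mixture mirrors the structural classes the clade is known for —
    full-length recombinant proviruses, shared pro-pol / pol-env deletion
    carriers, non-recombinant relatives, solo LTRs, and decoy repeat
    families that the mining whitelist must reject. Ages are uniform on
    [0, max_age] Myr with a third of the full-length class pinned at age 0
    (identical LTRs). Some proviruses carry implanted premature stops so
    ORF-status recovery is informative.
    """
    rng = np.random.default_rng(seed)
    # the library shares the study seed so reference elements can be
    # reconstructed downstream from the seed alone
    library = make_element_library(seed)
    assembly = simulate_host_genome(n_chrom, chrom_len, gc, int(rng.integers(2**31)))

    total = n_full + n_pro_pol + n_pol_env + n_both + n_nonrecomb + n_solo + n_decoy
    chroms = sorted(assembly)
    per_chrom = int(np.ceil(total / len(chroms)))
    positions = []
    for chrom in chroms:
        spacing = (chrom_len - 100_000) // per_chrom
        for i in range(per_chrom):
            base = 50_000 + i * spacing
            positions.append((chrom, base + int(rng.integers(0, max(1, spacing - 15_000)))))
    rng.shuffle(positions)

    ltr_variants = list(LTR_VARIANTS)
    specs: list[ImplantSpec] = []

    def next_pos():
        return positions[len(specs)]

    def age():
        return float(np.round(rng.uniform(0.0, max_age), 3))

    for i in range(n_full):
        chrom, pos = next_pos()
        disrupt = {}
        if i % 3 == 1:
            disrupt = {"pol": float(rng.uniform(0.1, 0.8))}
        specs.append(ImplantSpec(
            chrom, pos, strand="+" if i % 2 == 0 else "-",
            age_myr=0.0 if i % 3 == 0 else age(),
            ltr_variant=ltr_variants[i % len(ltr_variants)],
            recombinant=True, orf_disruptions=disrupt or None,
            tsd_len=int(rng.integers(4, 9)),
        ))
    for i in range(n_pro_pol):
        chrom, pos = next_pos()
        specs.append(ImplantSpec(
            chrom, pos, strand="+" if i % 2 == 0 else "-", age_myr=age(),
            deletions=("pro_pol",), recombinant=True,
            ltr_variant="Δ1+Δ2", tsd_len=int(rng.integers(4, 9)),
        ))
    for i in range(n_pol_env):
        chrom, pos = next_pos()
        specs.append(ImplantSpec(
            chrom, pos, strand="-" if i % 2 == 0 else "+", age_myr=age(),
            deletions=("pol_env",), recombinant=True,
            ltr_variant="Δ2", tsd_len=int(rng.integers(4, 9)),
        ))
    for i in range(n_both):
        chrom, pos = next_pos()
        specs.append(ImplantSpec(
            chrom, pos, age_myr=age(), deletions=("pro_pol", "pol_env"),
            recombinant=True, ltr_variant="Δ1+Δ2",
            tsd_len=int(rng.integers(4, 9)),
        ))
    for i in range(n_nonrecomb):
        chrom, pos = next_pos()
        specs.append(ImplantSpec(
            chrom, pos, strand="+" if i % 2 == 0 else "-", age_myr=age(),
            recombinant=False, ltr_variant="full",
            orf_disruptions={"gag": 0.5} if i % 2 == 0 else None,
            tsd_len=int(rng.integers(4, 9)),
        ))
    for i in range(n_solo):
        chrom, pos = next_pos()
        specs.append(ImplantSpec(
            chrom, pos, strand="+" if i % 2 == 0 else "-", age_myr=age(),
            solo_ltr=True, recombinant=False,
            ltr_variant=ltr_variants[i % len(ltr_variants)],
            tsd_len=int(rng.integers(4, 9)),
        ))
    decoy_names = list(library.decoy_families)
    for i in range(n_decoy):
        chrom, pos = next_pos()
        specs.append(ImplantSpec(
            chrom, pos, strand="+", decoy=decoy_names[i % len(decoy_names)],
            recombinant=False, tsd_len=6,
        ))

    assembly, truth = implant_many(
        assembly, specs, library, seed=int(rng.integers(2**31))
    )
    return StudyData(library, assembly, truth, specs)


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
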