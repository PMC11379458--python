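"""Integration-age estimation from 5'–3' LTR divergence, and LTR trees.

At integration a provirus's two LTRs are identical; they subsequently
accumulate substitutions independently, so their pairwise divergence clocks
the insertion. Ages are obtained by dividing the gap-excluded p-distance by
a pairwise divergence rate (default 0.34% per site per Myr, calibrated from
orthologous human/chimpanzee HML-2 proviruses). Identical LTR pairs only
bound the age from above by the expected single-difference waiting time
(~500,000 yr for 588-bp LTRs); such proviruses are reported with the
interval [0, T_res] and its midpoint as the point estimate, matching the
convention of plotting zero-divergence proviruses at 250,000 yr.

Distance trees of LTRs (neighbor joining on the p-distance matrix) stand in
for maximum-likelihood phylogenies, which are exported to external tools.
Proviruses whose 5' and 3' LTRs cluster discordantly on that tree — a
signature of inter-provirus recombination or gene conversion — are flagged
and excluded from dating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .annotate import AlignParams, pairwise_align_affine

__all__ = [
    "DatingModel",
    "DivergenceResult",
    "AgeEstimate",
    "ltr_p_distance",
    "estimate_age",
    "date_ltr_pair",
    "pairwise_distance_matrix",
    "nj_tree",
    "detect_discordance",
]

DEFAULT_RATE = 0.0034


@dataclass(frozen=True)
class DatingModel:
    """LTR molecular clock. ``rate`` is the pairwise divergence accumulated
    between cognate LTRs per site per Myr (each LTR accrues half)."""

    rate: float = DEFAULT_RATE
    basis: str = "pairwise 5'-3' LTR divergence per site per Myr"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class DivergenceResult:
    compared_sites: int  # ungapped aligned columns
    substitutions: int
    p_distance: float


@dataclass(frozen=True)
class AgeEstimate:
    point_age: float  # Myr
    low: float
    high: float
    identical_ltrs: bool
    excluded_discordant: bool = False


def ltr_p_distance(ltr5: str, ltr3: str,
                   params: AlignParams | None = None) -> DivergenceResult:
    """Gap-excluded p-distance between cognate LTRs.

    Columns containing a gap in the global alignment are excluded from the
    compared sites; substitutions are counted on the remainder.
    """
    if not ltr5 or not ltr3:
        raise ValueError("LTR sequences must be non-empty")
    aln = pairwise_align_affine(ltr3, ltr5, params)
    compared = aln.n_aligned_columns
    subs = compared - aln.matches
    return DivergenceResult(compared, subs, subs / compared if compared else 0.0)


def estimate_age(
    divergence: DivergenceResult,
    model: DatingModel | None = None,
    ci: float = 0.95,
) -> AgeEstimate:
    """Convert LTR divergence to an integration age.

    With zero substitutions, only an upper bound exists: the expected time
    for one difference to arise, ``T_res = (1 / compared_sites) / rate``;
    the interval is [0, T_res] and the point estimate its midpoint. With
    substitutions, the point age is ``p_distance / rate`` and the interval
    is the exact Poisson CI on the substitution count, rescaled.
    """
    model = model or DatingModel()
    n = divergence.compared_sites
    if n == 0:
        raise ValueError("no compared sites")
    if divergence.substitutions == 0:
        t_res = (1.0 / n) / model.rate
        return AgeEstimate(t_res / 2, 0.0, t_res, identical_ltrs=True)
    point = divergence.p_distance / model.rate
    alpha = 1 - ci
    k = divergence.substitutions
    lo_k = stats.chi2.ppf(alpha / 2, 2 * k) / 2
    hi_k = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    scale = 1.0 / (n * model.rate)
    return AgeEstimate(point, lo_k * scale, hi_k * scale, identical_ltrs=False)


def date_ltr_pair(ltr5: str, ltr3: str,
                  model: DatingModel | None = None) -> AgeEstimate:
    return estimate_age(ltr_p_distance(ltr5, ltr3), model)


def pairwise_distance_matrix(
    sequences: Mapping[str, str], params: AlignParams | None = None
) -> DistanceMatrix:
    """Symmetric p-distance matrix under the gap-column-exclusion rule."""
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ltr_p_distance(sequences[labels[i]], sequences[labels[j]], params)
            mat[i, j] = mat[j, i] = d.p_distance
    return DistanceMatrix(mat, labels)


def nj_tree(matrix: DistanceMatrix | np.ndarray,
            labels: Sequence[str] | None = None) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    Labels are canonically sorted before joining so tie-breaking does not
    depend on input order.
    """
    if not isinstance(matrix, DistanceMatrix):
        arr = np.asarray(matrix, dtype=float)
        if labels is None or arr.shape[0] != len(labels):
            raise ValueError("labels must match matrix dimension")
        if not np.allclose(arr, arr.T):
            raise ValueError("matrix must be symmetric")
        matrix = DistanceMatrix(arr, list(labels))
    order = sorted(matrix.ids)
    matrix = matrix.filter(order)
    tree = nj(matrix, neg_as_zero=True)
    return tree


def detect_discordance(
    tree: TreeNode, pairing: Mapping[str, tuple[str, str]]
) -> dict[str, bool]:
    """Flag proviruses whose two LTRs have discordant tree positions.

    ``pairing`` maps a provirus id to its (5' leaf, 3' leaf) labels. A
    provirus is discordant iff its LTRs are not a cherry AND at least one of
    them has a nearer leaf (patristic distance) from a *different* provirus,
    strictly closer than its own partner. Identical pairs (zero intra-pair
    distance) are never flagged.
    """
    tips = {t.name: t for t in tree.tips()}
    for pid, (a, b) in pairing.items():
        if a not in tips or b not in tips:
            raise KeyError(f"unpaired LTR label for {pid}: {a}, {b}")
    dm = tree.tip_tip_distances()
    owner = {}
    for pid, (a, b) in pairing.items():
        owner[a] = pid
        owner[b] = pid

    flags = {}
    for pid, (a, b) in pairing.items():
        intra = dm[a, b]
        ta, tb = tips[a], tips[b]
        cherry = ta.parent is tb.parent
        foreign_closer = False
        for leaf in (a, b):
            for other in dm.ids:
                if other == a or other == b:
                    continue
                if owner.get(other) == pid:
                    continue
                if dm[leaf, other] < intra:
                    foreign_closer = True
                    break
            if foreign_closer:
                break
        flags[pid] = (not cherry) and foreign_closer
    return flags
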