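"""Rank-based signature overlap statistics (running Fisher test).

The running Fisher test asks whether two ranked gene signatures share more
genes than chance, scanning ranked prefixes of both lists: for each cutoff
pair it computes the one-sided hypergeometric enrichment tail of the prefix
overlap against the common gene universe of size N, takes the best (minimum)
tail over the scan, and corrects it for the number of cutoffs scanned
(Bonferroni-style, capped at 1).

Two cutoff schemes are provided:

``"deciles"`` (default)
    Matched fractional prefixes at the deciles of the shorter signature —
    ten cutoff pairs ``(ceil(f*n_query), ceil(f*n_reference))`` for
    f = 0.1 .. 1.0; every rank when the shorter signature has fewer than
    ten entries.
``"per-rank"``
    One fraction per rank of the shorter signature (an exhaustive scan).

Direction information is handled by decomposing the overlap into the four
direction pairs (up,up), (down,down), (up,down), (down,up); each sub-test
restricts both signatures to one direction and runs against the full
universe N. A Bonferroni threshold of alpha/4 (0.0125 at alpha = 0.05)
guards the four sub-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .orthologs import UniverseSpec
from .signatures import GeneSignature

__all__ = [
    "OverlapResult",
    "DirectionalOverlap",
    "CutoffPair",
    "hypergeometric_tail",
    "cutoff_pairs",
    "running_fisher",
    "directional_decomposition",
    "bonferroni_threshold",
    "classify_correlation",
    "DIRECTION_PAIRS",
]

DIRECTION_PAIRS: tuple[tuple[str, str], ...] = (
    ("up", "up"),
    ("down", "down"),
    ("up", "down"),
    ("down", "up"),
)

_P_FLOOR = 5e-324


def hypergeometric_tail(k: int, n1: int, n2: int, N: int) -> float:
    """Upper tail P(X >= k) of the hypergeometric(N, n1, n2) distribution.

    X counts the overlap of a random n2-subset with a fixed n1-subset of a
    universe of N genes. Returns a probability in (0, 1].
    """
    for name, v in (("k", k), ("n1", n1), ("n2", n2), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, n1, n2, N = int(k), int(n1), int(n2), int(N)
    if n1 > N or n2 > N:
        raise ValueError(f"set sizes ({n1}, {n2}) exceed universe size {N}")
    if k > min(n1, n2):
        raise ValueError(f"overlap {k} exceeds min set size {min(n1, n2)}")
    if k <= max(0, n1 + n2 - N):
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    return max(min(p, 1.0), _P_FLOOR)


@dataclass(frozen=True)
class CutoffPair:
    """One scanned prefix pair with its overlap and tail probability."""

    n_query: int
    n_reference: int
    n_overlap: int
    p: float


@dataclass(frozen=True)
class OverlapResult:
    """Overall overlap between two signatures under a universe of size N."""

    n_query: int
    n_reference: int
    n_overlap: int
    universe_size: int
    p_raw_best: float
    n_cutoffs_scanned: int
    p_final: float
    overlap_gene_ids: tuple[str, ...]
    cutoffs: tuple[CutoffPair, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_query": self.n_query,
            "n_reference": self.n_reference,
            "n_overlap": self.n_overlap,
            "universe_size": self.universe_size,
            "p_raw_best": self.p_raw_best,
            "n_cutoffs_scanned": self.n_cutoffs_scanned,
            "p_final": self.p_final,
            "overlap_gene_ids": list(self.overlap_gene_ids),
        }


@dataclass(frozen=True)
class DirectionalOverlap:
    """The four direction-pair sub-tests of an overall overlap."""

    overall: OverlapResult
    sub_results: dict[tuple[str, str], OverlapResult]
    alpha: float
    threshold: float  # alpha / 4

    def count(self, pair: tuple[str, str]) -> int:
        return self.sub_results[pair].n_overlap

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        return {pair: r.n_overlap for pair, r in self.sub_results.items()}

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.to_dict(),
            "directional": {
                f"{q}_{r}": res.to_dict() for (q, r), res in self.sub_results.items()
            },
            "alpha": self.alpha,
            "directional_threshold": self.threshold,
        }


def cutoff_pairs(n_query: int, n_reference: int, scheme: str = "deciles") -> list[tuple[int, int]]:
    """Matched fractional prefix cutoffs for the running scan.

    Duplicate pairs produced by the ceiling on short lists are removed so
    the correction factor counts distinct tests.
    """
    n_min = min(n_query, n_reference)
    if n_min == 0:
        return []
    if scheme == "deciles":
        steps = min(10, n_min)
    elif scheme == "per-rank":
        steps = n_min
    else:
        raise ValueError(f"unknown cutoff scheme {scheme!r}")
    pairs: list[tuple[int, int]] = []
    for j in range(1, steps + 1):
        f = j / steps
        pair = (math.ceil(f * n_query), math.ceil(f * n_reference))
        if not pairs or pair != pairs[-1]:
            pairs.append(pair)
    return pairs


def running_fisher(
    query: GeneSignature,
    reference: GeneSignature,
    universe: UniverseSpec,
    cutoff_scheme: str = "deciles",
) -> OverlapResult:
    """Rank-scanned hypergeometric overlap of two signatures.

    Both signatures must lie inside the universe; genes outside it are a
    caller error (restrict signatures with ``GeneSignature.restrict_to``
    first). Empty signatures give the degenerate p_final = 1 result.
    """
    for sig, role in ((query, "query"), (reference, "reference")):
        outside = sig.gene_set - universe.members
        if outside:
            ex = sorted(outside)[:5]
            raise ValueError(
                f"{role} signature {sig.name!r} has {len(outside)} genes outside "
                f"the universe (e.g. {ex}); restrict it to the universe first"
            )
    q_genes = query.gene_ids
    r_genes = reference.gene_ids
    shared = sorted(set(q_genes) & set(r_genes))
    pairs = cutoff_pairs(len(q_genes), len(r_genes), cutoff_scheme)
    if not pairs:
        return OverlapResult(
            n_query=len(q_genes),
            n_reference=len(r_genes),
            n_overlap=0,
            universe_size=universe.size,
            p_raw_best=1.0,
            n_cutoffs_scanned=0,
            p_final=1.0,
            overlap_gene_ids=(),
        )
    r_set_cache: set[str] = set()
    r_prefix_len = 0
    scanned: list[CutoffPair] = []
    for cq, cr in pairs:
        while r_prefix_len < cr:
            r_set_cache.add(r_genes[r_prefix_len])
            r_prefix_len += 1
        k = sum(1 for g in q_genes[:cq] if g in r_set_cache)
        p = hypergeometric_tail(k, cq, cr, universe.size)
        scanned.append(CutoffPair(cq, cr, k, p))
    p_raw_best = min(c.p for c in scanned)
    p_final = min(1.0, p_raw_best * len(scanned))
    return OverlapResult(
        n_query=len(q_genes),
        n_reference=len(r_genes),
        n_overlap=len(shared),
        universe_size=universe.size,
        p_raw_best=p_raw_best,
        n_cutoffs_scanned=len(scanned),
        p_final=p_final,
        overlap_gene_ids=tuple(shared),
        cutoffs=tuple(scanned),
    )


def directional_decomposition(
    query: GeneSignature,
    reference: GeneSignature,
    universe: UniverseSpec,
    cutoff_scheme: str = "deciles",
    alpha: float = 0.05,
) -> DirectionalOverlap:
    """Split an overlap into the four direction pairs and test each.

    Each sub-test restricts the query and reference to one direction and
    runs the same rank scan against the full universe size N. Because every
    shared gene has exactly one direction in each signature, the four
    sub-overlaps partition the overall overlap.
    """
    overall = running_fisher(query, reference, universe, cutoff_scheme)
    sub: dict[tuple[str, str], OverlapResult] = {}
    for dq, dr in DIRECTION_PAIRS:
        sub[(dq, dr)] = running_fisher(
            query.subset_direction(dq), reference.subset_direction(dr), universe, cutoff_scheme
        )
    return DirectionalOverlap(
        overall=overall,
        sub_results=sub,
        alpha=alpha,
        threshold=bonferroni_threshold(alpha, len(DIRECTION_PAIRS)),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha/m for m comparisons."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def classify_correlation(directional: DirectionalOverlap) -> str:
    """Label the dominant direction relationship of an overlap.

    ``"positive"`` when concordant genes — (up,up) plus (down,down) —
    outnumber discordant ones, ``"negative"`` when the reverse holds,
    ``"mixed"`` on a tie (including the empty overlap).
    """
    pos = directional.count(("up", "up")) + directional.count(("down", "down"))
    neg = directional.count(("up", "down")) + directional.count(("down", "up"))
    if pos > neg:
        return "positive"
    if neg > pos:
        return "negative"
    return "mixed"
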