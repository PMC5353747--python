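"""Cross-species ortholog mapping of gene signatures.

Comparing a human disease signature to a mouse developmental signature
requires translating one id space into the other and defining the common
background ("universe") of genes measured on both platforms: the universe
size N is the population parameter of every hypergeometric overlap test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .signatures import GeneSignature, SignatureEntry, normalize_gene_id, rank_entries
from .signatures import DifferentialResult

__all__ = ["OrthologTable", "UniverseSpec", "map_signature", "build_universe"]


@dataclass(frozen=True)
class OrthologTable:
    """A possibly many-to-many relation between two species' gene ids."""

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        normed = []
        seen = set()
        for a, b in pairs:
            pair = (normalize_gene_id(a), normalize_gene_id(b))
            if pair not in seen:
                seen.add(pair)
                normed.append(pair)
        object.__setattr__(self, "pairs", tuple(normed))

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, gene_ids: Iterable[str]) -> "OrthologTable":
        """Table mapping every gene to itself (same-species comparisons)."""
        return cls((g, g) for g in gene_ids)

    def forward(self) -> dict[str, set[str]]:
        """species-A gene -> set of species-B orthologs."""
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def reverse(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out

    def reversed(self) -> "OrthologTable":
        return OrthologTable((b, a) for a, b in self.pairs)


@dataclass(frozen=True)
class UniverseSpec:
    """Background gene set for the overlap tests."""

    members: frozenset[str]

    def __init__(self, members: Iterable[str]) -> None:
        object.__setattr__(self, "members", frozenset(normalize_gene_id(g) for g in members))
        if not self.members:
            raise ValueError("empty universe: overlap tests are undefined")

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


def map_signature(
    signature: GeneSignature, table: OrthologTable, direction: str = "a_to_b"
) -> GeneSignature:
    """Translate a signature into the orthologous species' id space.

    A source gene with several orthologs contributes every target (each
    inheriting the source's fold change and p); a target hit by several
    source genes keeps the entry with the smallest p (ties: largest |FC|,
    then lexicographic source id). Source genes without an ortholog are
    dropped, and the result is re-ranked by the standard ranking rule.
    """
    if direction not in ("a_to_b", "b_to_a"):
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    if len(table) == 0:
        raise ValueError("empty ortholog table")
    mapping = table.forward() if direction == "a_to_b" else table.reverse()
    best: dict[str, tuple[tuple, SignatureEntry]] = {}
    for entry in signature.entries:
        for target in mapping.get(entry.gene_id, ()):
            key = (entry.p_value, -abs(entry.signed_fold_change), entry.gene_id)
            cur = best.get(target)
            if cur is None or key < cur[0]:
                best[target] = (key, entry)
    results = [
        DifferentialResult(
            feature_id=target,
            mean_log2_numerator=float("nan"),
            mean_log2_denominator=float("nan"),
            signed_fold_change=entry.signed_fold_change,
            p_value=entry.p_value,
        )
        for target, (_, entry) in best.items()
    ]
    entries = tuple(rank_entries(results))
    return GeneSignature(
        signature.name, signature.species, entries, signature.fc_threshold, signature.p_threshold
    )


def build_universe(
    platform_a_genes: Iterable[str],
    platform_b_genes: Iterable[str],
    table: OrthologTable | None = None,
) -> UniverseSpec:
    """Common background: platform-A genes with an ortholog measured on B.

    Membership is expressed in species A's id space. With ``table=None`` the
    identity relation is assumed (same-species platforms) and the universe
    is the plain intersection of the two measured gene sets.
    """
    a = {normalize_gene_id(g) for g in platform_a_genes}
    b = {normalize_gene_id(g) for g in platform_b_genes}
    if table is None:
        members = a & b
    else:
        fwd = table.forward()
        members = {g for g in a if fwd.get(g, set()) & b}
    return UniverseSpec(members)
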