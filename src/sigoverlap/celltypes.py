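"""Concordant biosets and cell-type contribution partitioning.

Genes altered in the *same* direction in both a disease comparison and a
developmental comparison form a concordant bioset — the gene set whose
resemblance to immature tissue the analysis quantifies. This module derives
such biosets from a directional overlap, partitions them across three
cell-type developmental gene sets into the eight exclusive Venn regions
(FS neurons, astrocytes, oligodendrocytes in the original study), and
reports region counts, per-set marginals, contribution percentages and
direction-concordance counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .overlap import DirectionalOverlap
from .signatures import GeneSignature, normalize_gene_id

__all__ = [
    "BiosetMember",
    "ConcordantBioset",
    "VennPartition",
    "derive_concordant_bioset",
    "venn_partition",
    "contribution_percentage",
    "direction_concordance",
]


@dataclass(frozen=True)
class BiosetMember:
    """One concordant gene: its shared direction and per-source statistics."""

    gene_id: str
    direction: str  # the direction shared by both source comparisons
    query_fold_change: float | None = None
    query_p: float | None = None
    reference_fold_change: float | None = None
    reference_p: float | None = None


@dataclass(frozen=True)
class ConcordantBioset:
    """Genes changed in the same direction in two comparisons."""

    name: str
    members: tuple[BiosetMember, ...]
    sources: tuple[str, str]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(m.gene_id for m in self.members)

    def directions(self) -> dict[str, str]:
        return {m.gene_id: m.direction for m in self.members}


@dataclass(frozen=True)
class VennPartition:
    """Exhaustive 8-region partition of a bioset across three gene sets.

    Regions are keyed by a membership triple of booleans in label order,
    e.g. ``(True, False, False)`` is the first set's exclusive region and
    ``(False, False, False)`` collects bioset genes in none of the sets.
    """

    labels: tuple[str, str, str]
    bioset_size: int
    region_counts: dict[tuple[bool, bool, bool], int]
    region_genes: dict[tuple[bool, bool, bool], tuple[str, ...]]

    def marginal(self, label: str) -> int:
        """Total overlap of the bioset with one set (sum of its 4 regions)."""
        i = self.labels.index(label)
        return sum(c for key, c in self.region_counts.items() if key[i])

    @property
    def marginals(self) -> dict[str, int]:
        return {lab: self.marginal(lab) for lab in self.labels}

    def exclusive(self, label: str) -> int:
        """Genes specific to one set (in it and in neither other set)."""
        i = self.labels.index(label)
        key = tuple(j == i for j in range(3))
        return self.region_counts[key]

    def percentage(self, key: tuple[bool, bool, bool]) -> float:
        return contribution_percentage(self.region_counts[key], self.bioset_size)

    @property
    def region_percentages(self) -> dict[tuple[bool, bool, bool], float]:
        return {key: self.percentage(key) for key in self.region_counts}

    def to_dict(self) -> dict:
        def key_name(key: tuple[bool, bool, bool]) -> str:
            inside = [lab for lab, m in zip(self.labels, key) if m]
            return "&".join(inside) if inside else "none"

        return {
            "labels": list(self.labels),
            "bioset_size": self.bioset_size,
            "regions": {
                key_name(k): {
                    "count": self.region_counts[k],
                    "percentage": self.percentage(k) if self.bioset_size else None,
                    "genes": list(self.region_genes[k]),
                }
                for k in sorted(self.region_counts, reverse=True)
            },
            "marginals": self.marginals,
        }


def derive_concordant_bioset(
    directional: DirectionalOverlap,
    sources: tuple[str, str],
    name: str = "concordant",
    query_signature: GeneSignature | None = None,
    reference_signature: GeneSignature | None = None,
) -> ConcordantBioset:
    """Union of the (up,up) and (down,down) overlap gene sets.

    Each member records the direction shared by both comparisons; when the
    source signatures are supplied, per-source fold changes and p-values are
    attached. An empty bioset is legal.
    """
    q_stats = {e.gene_id: e for e in query_signature.entries} if query_signature else {}
    r_stats = {e.gene_id: e for e in reference_signature.entries} if reference_signature else {}
    members: list[BiosetMember] = []
    for direction in ("up", "down"):
        for gene in directional.sub_results[(direction, direction)].overlap_gene_ids:
            q = q_stats.get(gene)
            r = r_stats.get(gene)
            members.append(
                BiosetMember(
                    gene_id=gene,
                    direction=direction,
                    query_fold_change=q.signed_fold_change if q else None,
                    query_p=q.p_value if q else None,
                    reference_fold_change=r.signed_fold_change if r else None,
                    reference_p=r.p_value if r else None,
                )
            )
    members.sort(key=lambda m: m.gene_id)
    return ConcordantBioset(name=name, members=tuple(members), sources=tuple(sources))


def _directed_genes(obj) -> dict[str, str | None]:
    """Accept a GeneSignature, a gene->direction mapping, or a bare set."""
    if isinstance(obj, GeneSignature):
        return dict(obj.directions())
    if isinstance(obj, Mapping):
        return {normalize_gene_id(g): d for g, d in obj.items()}
    return {normalize_gene_id(g): None for g in obj}


def venn_partition(
    bioset: ConcordantBioset,
    set_a,
    set_b,
    set_c,
    labels: tuple[str, str, str] = ("FS", "AS", "OL"),
) -> VennPartition:
    """Assign every bioset gene to exactly one of the 8 membership regions.

    The three sets may be signatures, direction mappings, or plain gene-id
    sets; only membership matters here. Gene ids must already share the
    bioset's id space (apply ortholog mapping beforehand).
    """
    sets = [frozenset(_directed_genes(s)) for s in (set_a, set_b, set_c)]
    genes_by_region: dict[tuple[bool, bool, bool], list[str]] = {
        (a, b, c): [] for a in (False, True) for b in (False, True) for c in (False, True)
    }
    for member in bioset.members:
        key = tuple(member.gene_id in s for s in sets)
        genes_by_region[key].append(member.gene_id)
    return VennPartition(
        labels=tuple(labels),
        bioset_size=len(bioset),
        region_counts={k: len(v) for k, v in genes_by_region.items()},
        region_genes={k: tuple(sorted(v)) for k, v in genes_by_region.items()},
    )


def contribution_percentage(count: int, bioset_size: int) -> float:
    """100 * count / bioset_size, rounded half-up to one decimal place."""
    if bioset_size <= 0:
        raise ValueError("bioset_size must be positive")
    if not (0 <= count <= bioset_size):
        raise ValueError(f"count {count} outside [0, {bioset_size}]")
    pct = Decimal(100 * count) / Decimal(bioset_size)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def direction_concordance(bioset: ConcordantBioset, celltype_signature) -> tuple[int, int]:
    """(shared gene count, same-direction count) against a cell-type set.

    A gene counts as same-direction when its shared bioset direction equals
    its direction in the cell-type developmental signature; cell-type sets
    without direction annotation contribute no same-direction counts.
    """
    directed = _directed_genes(celltype_signature)
    n_shared = 0
    n_same = 0
    for member in bioset.members:
        if member.gene_id in directed:
            n_shared += 1
            if directed[member.gene_id] == member.direction:
                n_same += 1
    return n_shared, n_same
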