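"""Differential-expression gene signatures from two-group expression data.

A *signature* (a "bioset" in correlation-engine terminology) is the ordered
list of genes that pass a fold-change and a t-test p-value filter in a
two-group comparison, each gene carrying its direction of change.  The
ordering matters: the rank-based overlap statistics downstream scan ranked
prefixes of two signatures.

Fold changes use the signed linear convention common in microarray work:
the linear ratio r = 2**(mean_log2_numerator - mean_log2_denominator) is
reported as +r when r >= 1 and as -1/r when r < 1, so |FC| >= 1 always and
the sign encodes direction (up in the numerator group when positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "DifferentialResult",
    "SignatureEntry",
    "GeneSignature",
    "normalize_gene_id",
    "signed_fold_change",
    "two_group_t_test",
    "differential_expression",
    "build_signature",
    "signature_from_results",
    "collapse_probes",
    "rank_entries",
]

#: smallest positive double; used as the p-value floor for the degenerate
#: zero-variance-but-different-means case so p stays in (0, 1]
_P_FLOOR = 5e-324


def normalize_gene_id(gene_id: str) -> str:
    """Strip surrounding whitespace and uppercase a gene/probe identifier."""
    norm = str(gene_id).strip().upper()
    if not norm:
        raise ValueError("empty gene identifier")
    return norm


@dataclass(frozen=True)
class ExpressionDataset:
    """A log2 expression matrix with a two-group sample design.

    Parameters
    ----------
    name:
        Dataset label, used in reports.
    feature_ids:
        Probe or gene identifiers, one per matrix row; unique and non-empty.
    values:
        Matrix of log base-2 intensities, features x samples; all finite.
    sample_ids:
        Column labels, one per matrix column.
    sample_groups:
        Mapping of every sample id to one of exactly two group labels.
    group_roles:
        ``(numerator, denominator)`` group labels: the ratio reported by the
        differential test is numerator-group over denominator-group
        (infant/adult, patient/control).
    """

    name: str
    feature_ids: tuple[str, ...]
    values: np.ndarray
    sample_ids: tuple[str, ...]
    sample_groups: Mapping[str, str]
    group_roles: tuple[str, str]

    def __init__(
        self,
        name: str,
        feature_ids: Sequence[str],
        values,
        sample_ids: Sequence[str],
        sample_groups: Mapping[str, str],
        group_roles: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        feature_ids = tuple(str(f) for f in feature_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape[0] != len(feature_ids):
            raise ValueError(
                f"matrix has {values.shape[0]} rows but {len(feature_ids)} feature ids"
            )
        if values.shape[1] != len(sample_ids):
            raise ValueError(
                f"matrix has {values.shape[1]} columns but {len(sample_ids)} sample ids"
            )
        if len(set(feature_ids)) != len(feature_ids):
            seen: set[str] = set()
            dup = next(f for f in feature_ids if f in seen or seen.add(f))
            raise ValueError(f"duplicate feature id: {dup!r}")
        if any(not f.strip() for f in feature_ids):
            raise ValueError("feature ids must be non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        missing = [s for s in sample_ids if s not in sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        groups = {sample_groups[s] for s in sample_ids}
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups, got {sorted(groups)}")
        numerator, denominator = group_roles
        if {numerator, denominator} != groups:
            raise ValueError(
                f"group_roles {group_roles!r} do not match group labels {sorted(groups)}"
            )
        for label in (numerator, denominator):
            n = sum(1 for s in sample_ids if sample_groups[s] == label)
            if n < 2:
                raise ValueError(f"group {label!r} has {n} samples; need >= 2")
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "sample_groups", dict(sample_groups))
        object.__setattr__(self, "group_roles", (numerator, denominator))

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to ``label``."""
        idx = [i for i, s in enumerate(self.sample_ids) if self.sample_groups[s] == label]
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature two-group differential statistics."""

    feature_id: str
    mean_log2_numerator: float
    mean_log2_denominator: float
    signed_fold_change: float
    p_value: float


@dataclass(frozen=True)
class SignatureEntry:
    """One gene of a signature: direction, effect size and rank."""

    gene_id: str
    direction: str  # "up" | "down"
    signed_fold_change: float
    p_value: float
    rank: int

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        expected = "up" if self.signed_fold_change > 0 else "down"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with "
                f"signed fold change {self.signed_fold_change}"
            )


@dataclass(frozen=True)
class GeneSignature:
    """An ordered, direction-annotated differentially-expressed gene set."""

    name: str
    species: str
    entries: tuple[SignatureEntry, ...]
    fc_threshold: float
    p_threshold: float

    def __post_init__(self) -> None:
        genes = [e.gene_id for e in self.entries]
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            dup = next(g for g in genes if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene in signature: {dup!r}")
        for i, e in enumerate(self.entries, start=1):
            if e.rank != i:
                raise ValueError(f"ranks must be 1..n without gaps; entry {i} has rank {e.rank}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        """Genes in rank order."""
        return tuple(e.gene_id for e in self.entries)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries)

    def direction_of(self, gene_id: str) -> str:
        return self._by_gene[gene_id].direction

    @property
    def _by_gene(self) -> dict[str, SignatureEntry]:
        return {e.gene_id: e for e in self.entries}

    def directions(self) -> dict[str, str]:
        """Mapping gene -> 'up'/'down'."""
        return {e.gene_id: e.direction for e in self.entries}

    def subset_direction(self, direction: str) -> "GeneSignature":
        """Entries of one direction, relative order kept, ranks renumbered."""
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        kept = [e for e in self.entries if e.direction == direction]
        return self._renumbered(kept, f"{self.name}_{direction.upper()}")

    def restrict_to(self, membership: Iterable[str]) -> "GeneSignature":
        """Drop genes outside ``membership``; relative order kept."""
        member = set(membership)
        kept = [e for e in self.entries if e.gene_id in member]
        return self._renumbered(kept, self.name)

    def _renumbered(self, kept: Sequence[SignatureEntry], name: str) -> "GeneSignature":
        entries = tuple(
            SignatureEntry(e.gene_id, e.direction, e.signed_fold_change, e.p_value, i)
            for i, e in enumerate(kept, start=1)
        )
        return GeneSignature(name, self.species, entries, self.fc_threshold, self.p_threshold)


def signed_fold_change(mean_log2_numerator: float, mean_log2_denominator: float) -> float:
    """Signed linear fold change of a log2-mean difference.

    Returns ``r = 2**(num - den)`` when ``r >= 1`` and ``-1/r`` otherwise, so
    the magnitude is always >= 1 and a ratio of exactly 1 maps to ``+1.0``.
    """
    if not (math.isfinite(mean_log2_numerator) and math.isfinite(mean_log2_denominator)):
        raise ValueError("log2 means must be finite")
    diff = mean_log2_numerator - mean_log2_denominator
    if diff == 0.0:
        return 1.0
    # computed on |diff| so the sign always tracks the mean difference and
    # the swap antisymmetry survives even when 2**diff rounds to 1.0
    r = 2.0 ** abs(diff)  # the linear ratio, or its reciprocal when diff < 0
    return r if diff > 0 else -r


def two_group_t_test(values_group1: Sequence[float], values_group2: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Identical constant groups give p = 1.0 by convention; constant groups
    with different values give the smallest positive double, keeping the
    result inside (0, 1].
    """
    a = np.asarray(values_group1, dtype=float)
    b = np.asarray(values_group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if a[0] == b[0] else _P_FLOOR
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return max(min(p, 1.0), _P_FLOOR)


def differential_expression(dataset: ExpressionDataset) -> list[DifferentialResult]:
    """Per-feature signed fold change and Welch p for a two-group dataset."""
    numerator, denominator = dataset.group_roles
    num = dataset.values[:, dataset.group_columns(numerator)]
    den = dataset.values[:, dataset.group_columns(denominator)]
    mean_num = num.mean(axis=1)
    mean_den = den.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(num, den, axis=1, equal_var=False).pvalue
    # scipy yields nan when both groups have zero variance
    var0 = (num.var(axis=1) == 0.0) & (den.var(axis=1) == 0.0)
    p = np.where(var0 & (mean_num == mean_den), 1.0, p)
    p = np.where(var0 & (mean_num != mean_den), _P_FLOOR, p)
    p = np.clip(p, _P_FLOOR, 1.0)
    return [
        DifferentialResult(
            feature_id=f,
            mean_log2_numerator=float(mn),
            mean_log2_denominator=float(md),
            signed_fold_change=signed_fold_change(float(mn), float(md)),
            p_value=float(pv),
        )
        for f, mn, md, pv in zip(dataset.feature_ids, mean_num, mean_den, p)
    ]


def _entry_sort_key(r: DifferentialResult) -> tuple:
    # ascending p, ties by descending |FC|, then lexicographic id
    return (r.p_value, -abs(r.signed_fold_change), normalize_gene_id(r.feature_id))


def rank_entries(results: Sequence[DifferentialResult]) -> list[SignatureEntry]:
    """Order differential results by the standard ranking rule and number them.

    The rule — ascending p-value, ties broken by descending absolute fold
    change, then lexicographic gene id — makes every signature ordering
    deterministic, which the rank-scanning overlap test requires.
    """
    ordered = sorted(results, key=_entry_sort_key)
    return [
        SignatureEntry(
            gene_id=normalize_gene_id(r.feature_id),
            direction="up" if r.signed_fold_change > 0 else "down",
            signed_fold_change=r.signed_fold_change,
            p_value=r.p_value,
            rank=i,
        )
        for i, r in enumerate(ordered, start=1)
    ]


def signature_from_results(
    results: Sequence[DifferentialResult],
    fc_threshold: float,
    p_threshold: float,
    name: str,
    species: str = "",
) -> GeneSignature:
    """Filter differential results by strict thresholds and rank the survivors.

    A feature is kept iff ``|FC| > fc_threshold`` and ``p < p_threshold``
    (both strict). Features whose fold change is exactly +1 (no change) are
    never included. An empty signature is legal.
    """
    if fc_threshold < 1:
        raise ValueError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    kept = [
        r
        for r in results
        if abs(r.signed_fold_change) > fc_threshold and r.p_value < p_threshold
    ]
    entries = tuple(rank_entries(kept))
    return GeneSignature(name, species, entries, fc_threshold, p_threshold)


def build_signature(
    dataset: ExpressionDataset,
    fc_threshold: float,
    p_threshold: float,
    name: str | None = None,
    species: str = "",
    probe_to_gene: Mapping[str, str] | None = None,
) -> GeneSignature:
    """Differential signature of a two-group dataset.

    When ``probe_to_gene`` is given, probe-level results are first collapsed
    to gene level (see :func:`collapse_probes`); unmapped probes are dropped.
    """
    results = differential_expression(dataset)
    if probe_to_gene is not None:
        results = collapse_probes(results, probe_to_gene)
    return signature_from_results(
        results, fc_threshold, p_threshold, name or dataset.name, species
    )


def collapse_probes(
    results: Sequence[DifferentialResult], probe_to_gene: Mapping[str, str]
) -> list[DifferentialResult]:
    """Collapse probe-level results to one result per gene.

    For each gene, the representative probe is the one with the smallest
    p-value; ties are broken by the largest absolute fold change, then by
    lexicographic probe id. Probes absent from the mapping are dropped.
    """
    norm_map = {str(k): normalize_gene_id(v) for k, v in probe_to_gene.items()}
    best: dict[str, DifferentialResult] = {}
    for r in results:
        gene = norm_map.get(r.feature_id)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None or _probe_key(r) < _probe_key(cur):
            best[gene] = r
    return [
        DifferentialResult(
            feature_id=gene,
            mean_log2_numerator=r.mean_log2_numerator,
            mean_log2_denominator=r.mean_log2_denominator,
            signed_fold_change=r.signed_fold_change,
            p_value=r.p_value,
        )
        for gene, r in sorted(best.items())
    ]


def _probe_key(r: DifferentialResult) -> tuple:
    return (r.p_value, -abs(r.signed_fold_change), r.feature_id)
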