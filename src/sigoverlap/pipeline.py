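"""End-to-end orchestration: signatures -> mapping -> overlap -> contribution.

The pipeline compares a *query* study (disease vs control) against a
*reference* study (infant vs adult development), optionally across species,
and then partitions the concordant gene set across cell-type developmental
signatures. All reports echo the thresholds, universe size and correction
factors used, and identical inputs produce byte-identical report files.

Id-space convention: the comparison is carried out in the query study's
gene-id space. When an ortholog table is supplied (columns ``gene_a`` =
query space, ``gene_b`` = reference space), the reference signature is
translated into the query space and the universe is the set of query-space
genes with at least one ortholog measured on the reference platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import io as sio
from .celltypes import (
    ConcordantBioset,
    derive_concordant_bioset,
    direction_concordance,
    venn_partition,
)
from .orthologs import OrthologTable, UniverseSpec, build_universe, map_signature
from .overlap import (
    DirectionalOverlap,
    bonferroni_threshold,
    classify_correlation,
    directional_decomposition,
)
from .signatures import (
    DifferentialResult,
    ExpressionDataset,
    GeneSignature,
    build_signature,
    normalize_gene_id,
    rank_entries,
)

__all__ = [
    "StudyConfig",
    "RunConfig",
    "run_overlap_analysis",
    "run_contribution_analysis",
    "overlap_report",
    "contribution_report",
    "bioset_signature",
]


@dataclass(frozen=True)
class StudyConfig:
    """One two-group study: where its data live and how to threshold it."""

    expr: str
    groups: str
    numerator: str
    denominator: str
    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    name: str = ""
    species: str = ""

    def load(self) -> ExpressionDataset:
        return sio.load_expression_dataset(
            self.expr, self.groups, self.numerator, self.denominator, self.name or None
        )


@dataclass(frozen=True)
class RunConfig:
    """Full-run configuration (YAML-loadable)."""

    query: StudyConfig
    reference: StudyConfig
    out_dir: str
    orthologs: str | None = None
    cutoff_scheme: str = "deciles"
    alpha: float = 0.05
    n_pairs: int = 1  # dataset pairs in the family, for pair-level Bonferroni
    celltype_gmt: str | None = None
    celltype_orthologs: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        return cls(
            query=StudyConfig(**raw["query"]),
            reference=StudyConfig(**raw["reference"]),
            out_dir=raw["out_dir"],
            orthologs=raw.get("orthologs"),
            cutoff_scheme=raw.get("cutoff_scheme", "deciles"),
            alpha=raw.get("alpha", 0.05),
            n_pairs=raw.get("n_pairs", 1),
            celltype_gmt=raw.get("celltype_gmt"),
            celltype_orthologs=raw.get("celltype_orthologs"),
            seed=raw.get("seed", 0),
        )


def prepare_pair(
    query_sig: GeneSignature,
    reference_sig: GeneSignature,
    query_platform: Sequence[str],
    reference_platform: Sequence[str],
    table: OrthologTable | None,
) -> tuple[GeneSignature, GeneSignature, UniverseSpec]:
    """Map the reference into query space and restrict both to the universe."""
    universe = build_universe(query_platform, reference_platform, table)
    if table is not None:
        reference_sig = map_signature(reference_sig, table, direction="b_to_a")
    q = query_sig.restrict_to(universe.members)
    r = reference_sig.restrict_to(universe.members)
    if len(q) == 0 and len(query_sig) > 0:
        raise ValueError(
            f"no gene of query signature {query_sig.name!r} lies in the universe; "
            "the id spaces or the ortholog table are mismatched"
        )
    if len(r) == 0 and len(reference_sig) > 0:
        raise ValueError(
            f"no gene of reference signature {reference_sig.name!r} lies in the "
            "universe; the id spaces or the ortholog table are mismatched"
        )
    return q, r, universe


def overlap_report(
    query_sig: GeneSignature,
    reference_sig: GeneSignature,
    directional: DirectionalOverlap,
    alpha: float,
    n_pairs: int,
) -> dict:
    pair_threshold = bonferroni_threshold(alpha, n_pairs)
    overall = directional.overall
    return {
        "query_signature": {"name": query_sig.name, "size": len(query_sig)},
        "reference_signature": {"name": reference_sig.name, "size": len(reference_sig)},
        "overlap": directional.to_dict(),
        "alpha": alpha,
        "n_dataset_pairs": n_pairs,
        "pair_threshold": pair_threshold,
        "significant_at_pair_threshold": overall.p_final < pair_threshold,
        "correlation": classify_correlation(directional),
    }


def run_overlap_analysis(config: RunConfig) -> dict:
    """Execute signatures -> mapping -> overlap and write the reports.

    Returns the report dict; writes ``overlap_report.json``, a flat TSV,
    per-study signature GMT/TSV files and the concordant bioset under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds_q = config.query.load()
    ds_r = config.reference.load()
    sig_q = build_signature(
        ds_q, config.query.fc_threshold, config.query.p_threshold,
        name=config.query.name or ds_q.name, species=config.query.species,
    )
    sig_r = build_signature(
        ds_r, config.reference.fc_threshold, config.reference.p_threshold,
        name=config.reference.name or ds_r.name, species=config.reference.species,
    )
    table = sio.load_ortholog_tsv(config.orthologs) if config.orthologs else None
    q_platform = [normalize_gene_id(f) for f in ds_q.feature_ids]
    r_platform = [normalize_gene_id(f) for f in ds_r.feature_ids]
    q, r, universe = prepare_pair(sig_q, sig_r, q_platform, r_platform, table)
    directional = directional_decomposition(
        q, r, universe, config.cutoff_scheme, config.alpha
    )
    report = overlap_report(q, r, directional, config.alpha, config.n_pairs)
    report["cutoff_scheme"] = config.cutoff_scheme
    bioset = derive_concordant_bioset(
        directional, sources=(q.name, r.name), name=f"{q.name}_x_{r.name}_concordant",
        query_signature=q, reference_signature=r,
    )
    report["concordant_bioset"] = {"name": bioset.name, "size": len(bioset)}

    sio.write_report(out / "overlap_report.json", report)
    _write_overlap_tsv(out / "overlap_report.tsv", report)
    sio.write_gmt(out / "signatures.gmt", [q, r])
    sio.write_signature_tsv(out / f"{q.name}.signature.tsv", q)
    sio.write_signature_tsv(out / f"{r.name}.signature.tsv", r)
    sio.write_signature_tsv(out / "bioset.signature.tsv", bioset_signature(bioset))
    _write_bioset_tsv(out / "bioset.tsv", bioset)
    return report


def _write_overlap_tsv(path, report: Mapping) -> None:
    rows = []
    overall = report["overlap"]["overall"]
    rows.append({"test": "overall", **{k: overall[k] for k in
                 ("n_query", "n_reference", "n_overlap", "universe_size",
                  "n_cutoffs_scanned", "p_raw_best", "p_final")}})
    for key, sub in report["overlap"]["directional"].items():
        rows.append({"test": key, **{k: sub[k] for k in
                     ("n_query", "n_reference", "n_overlap", "universe_size",
                      "n_cutoffs_scanned", "p_raw_best", "p_final")}})
    sio.write_report_tsv(
        path, rows,
        ["test", "n_query", "n_reference", "n_overlap", "universe_size",
         "n_cutoffs_scanned", "p_raw_best", "p_final"],
    )


def _write_bioset_tsv(path, bioset: ConcordantBioset) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "direction": m.direction,
            "query_fold_change": m.query_fold_change,
            "query_p": m.query_p,
            "reference_fold_change": m.reference_fold_change,
            "reference_p": m.reference_p,
        }
        for m in bioset.members
    ]
    sio.write_report_tsv(
        path, rows,
        ["gene_id", "direction", "query_fold_change", "query_p",
         "reference_fold_change", "reference_p"],
    )


def bioset_signature(bioset: ConcordantBioset) -> GeneSignature:
    """View a concordant bioset as a ranked signature for overlap testing.

    Members are ranked by their query-side p-value (the standard rule);
    members without stats fall back to a neutral p of 1, ranking last.
    """
    results = [
        DifferentialResult(
            feature_id=m.gene_id,
            mean_log2_numerator=float("nan"),
            mean_log2_denominator=float("nan"),
            signed_fold_change=(
                m.query_fold_change
                if m.query_fold_change is not None
                else (1.0 if m.direction == "up" else -1.0)
            ),
            p_value=m.query_p if m.query_p is not None else 1.0,
        )
        for m in bioset.members
    ]
    return GeneSignature(
        name=bioset.name,
        species="",
        entries=tuple(rank_entries(results)),
        fc_threshold=1.0,
        p_threshold=1.0,
    )


def contribution_report(
    bioset: ConcordantBioset,
    celltype_sigs: Mapping[str, GeneSignature],
    universe: UniverseSpec,
    cutoff_scheme: str = "deciles",
    alpha: float = 0.05,
    n_pairs: int = 1,
) -> dict:
    """Marginal overlaps, direction concordance and the Venn partition.

    Cell-type signatures must already be in the bioset's id space. An empty
    bioset yields an explicit ``empty`` marker instead of statistics.
    """
    if len(bioset) == 0:
        return {"bioset": {"name": bioset.name, "size": 0}, "empty": True}
    labels = sorted(celltype_sigs)
    if len(labels) != 3:
        raise ValueError(f"need exactly 3 cell-type signatures, got {len(labels)}")
    bio_sig = bioset_signature(bioset).restrict_to(universe.members)
    per_celltype: dict[str, dict] = {}
    for label in labels:
        sig = celltype_sigs[label].restrict_to(universe.members)
        directional = directional_decomposition(
            bio_sig, sig, universe, cutoff_scheme, alpha
        )
        n_shared, n_same = direction_concordance(bioset, celltype_sigs[label])
        per_celltype[label] = {
            "signature_size": len(sig),
            "overlap": directional.overall.to_dict(),
            "n_shared": n_shared,
            "n_same_direction": n_same,
            "correlation": classify_correlation(directional),
        }
    partition = venn_partition(
        bioset,
        celltype_sigs[labels[0]],
        celltype_sigs[labels[1]],
        celltype_sigs[labels[2]],
        labels=tuple(labels),
    )
    return {
        "bioset": {"name": bioset.name, "size": len(bioset)},
        "empty": False,
        "alpha": alpha,
        "n_dataset_pairs": n_pairs,
        "pair_threshold": bonferroni_threshold(alpha, n_pairs),
        "cutoff_scheme": cutoff_scheme,
        "universe_size": universe.size,
        "celltypes": per_celltype,
        "venn": partition.to_dict(),
    }


def run_contribution_analysis(
    config: RunConfig,
    bioset: ConcordantBioset,
    celltype_sigs: Mapping[str, GeneSignature] | None = None,
    universe: UniverseSpec | None = None,
) -> dict:
    """Contribution analysis against the configured cell-type sets.

    Cell-type sets come either in-memory or from ``config.celltype_gmt``
    (translated into the bioset's id space through
    ``config.celltype_orthologs`` when given). The universe defaults to the
    same platform background the overlap analysis used: query-platform
    genes with an ortholog measured on the reference platform.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if celltype_sigs is None:
        if config.celltype_gmt is None:
            raise ValueError("no cell-type signatures supplied or configured")
        directed = sio.load_directed_sets(config.celltype_gmt)
        celltype_sigs = {
            name: _signature_from_directed(name, genes)
            for name, genes in directed.items()
        }
    if config.celltype_orthologs:
        table = sio.load_ortholog_tsv(config.celltype_orthologs)
        celltype_sigs = {
            name: map_signature(sig, table, direction="b_to_a")
            for name, sig in celltype_sigs.items()
        }
    if universe is None:
        ds_q = config.query.load()
        ds_r = config.reference.load()
        table = sio.load_ortholog_tsv(config.orthologs) if config.orthologs else None
        universe = build_universe(
            [normalize_gene_id(f) for f in ds_q.feature_ids],
            [normalize_gene_id(f) for f in ds_r.feature_ids],
            table,
        )
    report = contribution_report(
        bioset, celltype_sigs, universe, config.cutoff_scheme, config.alpha, config.n_pairs
    )
    sio.write_report(out / "contribution_report.json", report)
    if not report.get("empty"):
        rows = [
            {"celltype": label, **{k: info[k] for k in ("signature_size", "n_shared",
             "n_same_direction", "correlation")},
             "p_final": info["overlap"]["p_final"]}
            for label, info in report["celltypes"].items()
        ]
        sio.write_report_tsv(
            out / "contribution_report.tsv", rows,
            ["celltype", "signature_size", "n_shared", "n_same_direction",
             "correlation", "p_final"],
        )
    return report


def _signature_from_directed(name: str, genes: Mapping[str, str | None]) -> GeneSignature:
    results = [
        DifferentialResult(
            feature_id=g,
            mean_log2_numerator=float("nan"),
            mean_log2_denominator=float("nan"),
            signed_fold_change=-1.5 if d == "down" else 1.5,
            p_value=0.01,
        )
        for g, d in genes.items()
    ]
    return GeneSignature(
        name=name, species="", entries=tuple(rank_entries(results)),
        fc_threshold=1.0, p_threshold=1.0,
    )
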