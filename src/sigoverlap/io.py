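"""Readers and writers for the community formats the pipeline consumes.

Expression matrices travel as GCT 1.2 or plain TSV, sample groupings as a
two-column TSV, gene sets as extended GMT (one ``<name>_UP`` and one
``<name>_DOWN`` line per signature) with a companion per-gene statistics
TSV, and ortholog relations as a two-column TSV. Reports are JSON with a
schema version plus a flat TSV. All writers round-trip exactly through
their readers, and parse errors name the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthologs import OrthologTable
from .signatures import (
    ExpressionDataset,
    GeneSignature,
    SignatureEntry,
    normalize_gene_id,
)

__all__ = [
    "SCHEMA_VERSION",
    "load_gct",
    "write_gct",
    "load_tsv_matrix",
    "load_groups",
    "write_groups",
    "load_gmt",
    "write_gmt",
    "load_signature_tsv",
    "write_signature_tsv",
    "load_ortholog_tsv",
    "write_ortholog_tsv",
    "write_report",
    "load_report",
]

SCHEMA_VERSION = "1.0"


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _fail(path, lineno: int | None, msg: str) -> None:
    where = f"{path}" + (f", line {lineno}" if lineno is not None else "")
    raise ParseError(f"{where}: {msg}")


# ---------------------------------------------------------------- matrices


def _matrix_from_frame(df: pd.DataFrame, path) -> tuple[list[str], np.ndarray, list[str]]:
    feature_ids = [str(x) for x in df.index]
    seen: set[str] = set()
    for i, f in enumerate(feature_ids):
        if f in seen:
            _fail(path, None, f"duplicate feature id {f!r}")
        seen.add(f)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        _fail(path, None, f"non-numeric expression cell ({exc})")
    return feature_ids, values, [str(c) for c in df.columns]


def load_gct(path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a GCT 1.2 file -> (feature_ids, values, sample_ids)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            _fail(path, 1, f"expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2 or not all(d.isdigit() for d in dims):
            _fail(path, 2, "expected '<n_rows>\\t<n_cols>'")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" not in df.columns:
        _fail(path, 3, "missing 'Description' column")
    df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        _fail(
            path,
            2,
            f"header declares {n_rows} x {n_cols} but body is {df.shape[0]} x {df.shape[1]}",
        )
    return _matrix_from_frame(df, path)


def write_gct(
    path, feature_ids: Sequence[str], values: np.ndarray, sample_ids: Sequence[str],
    descriptions: Sequence[str] | None = None,
) -> None:
    path = Path(path)
    values = np.asarray(values, dtype=float)
    desc = list(descriptions) if descriptions is not None else ["na"] * len(feature_ids)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(feature_ids)}\t{len(sample_ids)}\n")
        fh.write("NAME\tDescription\t" + "\t".join(sample_ids) + "\n")
        for f, d, row in zip(feature_ids, desc, values):
            fh.write(f + "\t" + d + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_tsv_matrix(path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a plain TSV matrix (first column feature ids, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        _fail(path, None, f"cannot parse TSV matrix ({exc})")
    return _matrix_from_frame(df, path)


def load_groups(path) -> dict[str, str]:
    """Read a two-column sample->group TSV (header ``sample_id\\tgroup``)."""
    path = Path(path)
    groups: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            _fail(path, 1, f"expected 2 columns, got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                _fail(path, lineno, f"expected 2 columns, got {len(parts)}")
            sample, group = parts
            if sample in groups:
                _fail(path, lineno, f"duplicate sample id {sample!r}")
            groups[sample] = group
    return groups


def write_groups(path, sample_groups: Mapping[str, str]) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in sample_groups.items():
            fh.write(f"{sample}\t{group}\n")


def load_expression_dataset(
    expr_path, groups_path, numerator: str, denominator: str, name: str | None = None
) -> ExpressionDataset:
    """Load a GCT or TSV matrix plus its group file into a dataset."""
    expr_path = Path(expr_path)
    with expr_path.open() as fh:
        is_gct = fh.readline().startswith("#1.2")
    loader = load_gct if is_gct else load_tsv_matrix
    feature_ids, values, sample_ids = loader(expr_path)
    groups = load_groups(groups_path)
    return ExpressionDataset(
        name=name or expr_path.stem,
        feature_ids=feature_ids,
        values=values,
        sample_ids=sample_ids,
        sample_groups=groups,
        group_roles=(numerator, denominator),
    )


# ------------------------------------------------------------- gene sets


def write_gmt(path, signatures: Sequence[GeneSignature]) -> None:
    """Write signatures as extended GMT: one line per direction set."""
    with Path(path).open("w") as fh:
        for sig in signatures:
            for direction in ("up", "down"):
                genes = [e.gene_id for e in sig.entries if e.direction == direction]
                fh.write(
                    f"{sig.name}_{direction.upper()}\t"
                    f"{direction}-regulated genes of {sig.name}\t"
                    + "\t".join(genes)
                    + "\n"
                )


def load_gmt(path) -> dict[str, list[str]]:
    """Read GMT -> mapping set name -> gene list."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                _fail(path, lineno, f"GMT line needs >= 3 fields, got {len(parts)}")
            name = parts[0]
            if name in sets:
                _fail(path, lineno, f"duplicate gene-set name {name!r}")
            sets[name] = [normalize_gene_id(g) for g in parts[2:] if g.strip()]
    return sets


def load_directed_sets(path) -> dict[str, dict[str, str]]:
    """Read an extended GMT into gene->direction mappings per base name."""
    sets = load_gmt(path)
    directed: dict[str, dict[str, str]] = {}
    for name, genes in sets.items():
        for suffix, direction in (("_UP", "up"), ("_DOWN", "down")):
            if name.endswith(suffix):
                base = name[: -len(suffix)]
                directed.setdefault(base, {}).update({g: direction for g in genes})
                break
        else:
            directed.setdefault(name, {}).update({g: None for g in genes})
    return directed


_SIG_COLUMNS = ["gene_id", "direction", "signed_fold_change", "p_value", "rank"]


def write_signature_tsv(path, signature: GeneSignature) -> None:
    """Companion per-gene table: gene, direction, FC, p, rank (rank order)."""
    with Path(path).open("w") as fh:
        fh.write("# name=" + signature.name + "\n")
        fh.write("# species=" + signature.species + "\n")
        fh.write(f"# fc_threshold={signature.fc_threshold!r}\n")
        fh.write(f"# p_threshold={signature.p_threshold!r}\n")
        fh.write("\t".join(_SIG_COLUMNS) + "\n")
        for e in signature.entries:
            fh.write(
                f"{e.gene_id}\t{e.direction}\t{e.signed_fold_change!r}\t{e.p_value!r}\t{e.rank}\n"
            )


def load_signature_tsv(path) -> GeneSignature:
    path = Path(path)
    meta = {"name": path.stem, "species": "", "fc_threshold": "1.0", "p_threshold": "1.0"}
    entries: list[SignatureEntry] = []
    with path.open() as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts != _SIG_COLUMNS:
                    _fail(path, lineno, f"expected header {_SIG_COLUMNS}, got {parts}")
                header_seen = True
                continue
            if len(parts) != 5:
                _fail(path, lineno, f"expected 5 columns, got {len(parts)}")
            gene, direction, fc, p, rank = parts
            if any(e.gene_id == gene for e in entries):
                _fail(path, lineno, f"duplicate gene id {gene!r}")
            try:
                entries.append(
                    SignatureEntry(gene, direction, float(fc), float(p), int(rank))
                )
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return GeneSignature(
        name=meta["name"],
        species=meta["species"],
        entries=tuple(entries),
        fc_threshold=float(meta["fc_threshold"]),
        p_threshold=float(meta["p_threshold"]),
    )


# ------------------------------------------------------------- orthologs


def load_ortholog_tsv(path) -> OrthologTable:
    """Two-column TSV with header ``gene_a\\tgene_b``."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_a", "gene_b"]:
            _fail(path, 1, f"expected header 'gene_a\\tgene_b', got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                _fail(path, lineno, f"expected 2 columns, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    return OrthologTable(pairs)


def write_ortholog_tsv(path, table: OrthologTable) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in table.pairs:
            fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------- reports


def write_report(path, report: Mapping) -> None:
    """Deterministic JSON report (sorted keys, schema-versioned)."""
    payload = {"schema_version": SCHEMA_VERSION, **report}
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def write_report_tsv(path, rows: Iterable[Mapping], columns: Sequence[str]) -> None:
    """Flat tabular companion to a JSON report."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
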