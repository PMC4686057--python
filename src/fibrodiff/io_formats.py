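"""Readers and writers for the tabular and network formats the pipeline touches.

Supported formats: plain tab-delimited expression matrices; the GEO
series-matrix dialect (the table between the ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` sentinels, with optionally quoted identifiers);
two-column probe→symbol annotation TSV; GMT gene-set collections; SIF and
GraphML network exports that Cytoscape ingests.

All outputs are UTF-8 with Unix newlines and tab delimiters. Expression
matrices round-trip at full float precision; derived tables (gene lists, edge
tables) print floats with 4 decimals, matching the style of published result
tables. Missing expression values may be encoded as an empty cell or ``NA``
and are propagated as NaN; parsing never silently drops a row.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffnet import DiffNetwork
from .errors import ParseError
from .rankprod import DETable
from .study import ExpressionStudy

_NA_STRINGS = {"", "NA", "NaN", "nan", "null"}


def _parse_cell(text: str, line_no: int) -> float:
    if text.strip() in _NA_STRINGS:
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"non-numeric cell {text!r}", line=line_no) from None


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in "\"'":
        s = s[1:-1]
    return s


def _matrix_lines(path: Path, dialect: str):
    """Yield (line_number, fields) for the data table of the given dialect."""
    with open(path, encoding="utf-8") as fh:
        if dialect == "tsv":
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n").rstrip("\r")
                if line:
                    yield i, line.split("\t")
        elif dialect == "geo-series-matrix":
            inside = False
            seen_table = False
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n").rstrip("\r")
                if line.startswith("!series_matrix_table_begin"):
                    inside, seen_table = True, True
                    continue
                if line.startswith("!series_matrix_table_end"):
                    inside = False
                    continue
                if inside and line:
                    yield i, [_unquote(f) for f in line.split("\t")]
            if not seen_table:
                raise ParseError("no !series_matrix_table_begin sentinel found")
        else:
            raise ParseError(f"unknown dialect {dialect!r}")


def read_group_map(path) -> pd.Series:
    """Two-column TSV (sample, group) → Series mapping sample → group."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", line=i)
            sample, group = fields[0].strip(), fields[1].strip()
            if sample in mapping:
                raise ParseError(f"duplicate sample id {sample!r}", line=i)
            if not group:
                raise ParseError(f"empty group for sample {sample!r}", line=i)
            mapping[sample] = group
    return pd.Series(mapping, name="group")


def read_expression_matrix(
    path,
    group_map,
    dialect: str = "tsv",
    linear: bool = False,
) -> ExpressionStudy:
    """Read a gene-by-sample expression matrix into an :class:`ExpressionStudy`.

    ``group_map`` is a sample→group mapping (dict/Series) or the path of a
    two-column TSV; group membership is never inferred from sample names.
    Values are assumed log2 already; pass ``linear=True`` to log2-transform
    on load. Ragged rows, non-numeric cells and duplicate identifiers raise
    :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    lines = _matrix_lines(path, dialect)
    try:
        header_no, header = next(lines)
    except StopIteration:
        raise ParseError("empty matrix file") from None
    sample_ids = [s.strip() for s in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"duplicate sample ids {dupes}", line=header_no)
    genes: list[str] = []
    data: list[list[float]] = []
    seen = set()
    for i, fields in lines:
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"ragged row: expected {len(sample_ids) + 1} fields, got {len(fields)}",
                line=i,
            )
        gene = fields[0].strip()
        if gene in seen:
            raise ParseError(f"duplicate gene/probe id {gene!r}", line=i)
        seen.add(gene)
        genes.append(gene)
        data.append([_parse_cell(c, i) for c in fields[1:]])
    values = pd.DataFrame(data, index=genes, columns=sample_ids, dtype=float)
    if linear:
        values = np.log2(values)
    if not isinstance(group_map, (pd.Series, dict)):
        group_map = read_group_map(group_map)
    groups = pd.Series(group_map, name="group")
    return ExpressionStudy(values, groups.loc[values.columns])


def write_expression_matrix(study: ExpressionStudy, path, fmt: str = "%.17g") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(study.samples) + "\n")
        for gene, row in zip(study.genes, study.values.to_numpy()):
            cells = ["NA" if not np.isfinite(v) else fmt % v for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def write_group_map(groups: pd.Series, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_probe_annotation(path) -> dict[str, str]:
    """Two-column TSV (probe, gene symbol) → dict; conflicting duplicates error."""
    mapping: dict[str, str] = {}
    conflicts = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", line=i)
            probe, symbol = fields[0].strip(), fields[1].strip()
            if not symbol:
                raise ParseError(f"empty gene symbol for probe {probe!r}", line=i)
            if probe in mapping and mapping[probe] != symbol:
                conflicts.append((probe, mapping[probe], symbol))
            mapping[probe] = symbol
    if conflicts:
        raise ParseError(
            "conflicting annotations for probes: "
            + "; ".join(f"{p}: {a!r} vs {b!r}" for p, a, b in conflicts)
        )
    return mapping


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file → {name: member set}; each line needs >= 1 member."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise ParseError("GMT line requires name, description and >= 1 member", line=i)
            name = fields[0].strip()
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", line=i)
            sets[name] = {f.strip() for f in fields[2:] if f.strip()}
    return sets


def read_gene_list(path) -> list[str]:
    """One gene symbol per line (first tab-separated field); '#' comments skipped."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def write_gene_list(genes: pd.DataFrame, path) -> None:
    """Write a gene list in result-table layout: Gene symbol, Gene name, FC, FDR.

    ``genes`` needs columns gene, fc_signed, pfp; an optional ``name`` column
    fills the Gene name field.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Gene symbol\tGene name\tFC\tFDR\n")
        for _, row in genes.iterrows():
            name = row.get("name", "")
            fdr = min(float(row["pfp"]), 1.0)
            fh.write(f"{row['gene']}\t{name}\t{row['fc_signed']:.4f}\t{fdr:.4f}\n")


def write_de_table(table: DETable, path) -> None:
    """Per-probe DE statistics TSV; pfp clipped at 1 for reporting."""
    out = table.stats.copy()
    for col in ("pfp_up", "pfp_down"):
        out[col] = out[col].clip(upper=1.0)
    out.to_csv(path, sep="\t", index=False, float_format="%.4f", lineterminator="\n")


def network_to_graph(net: DiffNetwork, de_direction: dict[str, str] | None = None) -> nx.Graph:
    """DiffNetwork → networkx Graph with per-edge and per-node attributes."""
    g = nx.Graph()
    g.add_nodes_from(net.panel)
    if de_direction:
        for node, direction in de_direction.items():
            if node in g:
                g.nodes[node]["de_direction"] = direction
    for e in net.edges:
        g.add_edge(
            e.gene_a,
            e.gene_b,
            R_patient=float(e.r_patient),
            R_control=float(e.r_control),
            p_patient=float(e.p_patient),
            p_control=float(e.p_control),
            **{"class": e.edge_class},
        )
    return g


def write_network(
    net: DiffNetwork,
    path,
    format: str = "sif",
    de_direction: dict[str, str] | None = None,
) -> None:
    """Export a classified network as SIF (class = interaction type) or GraphML."""
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for e in net.edges:
                fh.write(f"{e.gene_a} {e.edge_class} {e.gene_b}\n")
    elif format == "graphml":
        nx.write_graphml(network_to_graph(net, de_direction), path)
    else:
        raise ParseError(f"unknown network format {format!r}")
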