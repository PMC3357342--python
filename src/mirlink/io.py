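"""Readers and writers for the plain-text formats the pipeline touches.

Formats: expression TSV (header of sample IDs, first column feature IDs),
GMT gene-set collections, two-column miRNA->target TSV, interaction TSV/SIF,
probe->gene collapse-map TSV, and the tabular result exports.  Loading never
silently reorders features or samples, and every writer emits the dialect
its reader consumes, so write -> read is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .containers import (
    CollapseMap,
    DERecord,
    ExpressionMatrix,
    FeatureKind,
    GeneSet,
    GeneSetCollection,
    GroupDesign,
    InteractionTable,
    TargetMap,
)

__all__ = [
    "ParseError",
    "DEFAULT_NA_TOKENS",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_target_map",
    "read_interactions",
    "write_interactions",
    "read_collapse_map",
    "write_collapse_map",
    "read_design",
    "write_design",
    "write_de_table",
    "read_de_table",
    "write_enrichment_table",
    "write_modules_json",
    "read_modules_json",
    "write_links_tsv",
    "read_links_tsv",
]

DEFAULT_NA_TOKENS = frozenset({"NA", ""})


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def _lines(path) -> List[str]:
    text = Path(path).read_text()
    # keep empty interior lines out; GMT/TSV files may end with a newline
    return [ln for ln in text.split("\n") if ln.strip() != ""]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path,
    feature_kind: FeatureKind | str,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> ExpressionMatrix:
    """Load a features-x-samples log2 intensity TSV.

    The header row holds sample IDs (first cell is a corner label, ignored);
    each following row is ``feature_id<TAB>value...``.  Cells matching an NA
    token load as NaN and are flagged undetected; if no NA cell occurs the
    matrix carries no detection flags.
    """
    na = set(na_tokens)
    lines = _lines(path)
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise ParseError(f"{path}: line 1: no sample columns in header")
    n_cols = len(samples)
    feat_ids: List[str] = []
    rows: List[List[float]] = []
    det_rows: List[List[bool]] = []
    seen: Set[str] = set()
    any_na = False
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols + 1} fields, got {len(parts)}"
            )
        fid = parts[0]
        if fid in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate feature ID {fid!r}")
        seen.add(fid)
        vals: List[float] = []
        det: List[bool] = []
        for j, cell in enumerate(parts[1:]):
            if cell.strip() in na:
                vals.append(np.nan)
                det.append(False)
                any_na = True
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r} "
                        f"in column {samples[j]!r}"
                    ) from None
                det.append(True)
        feat_ids.append(fid)
        rows.append(vals)
        det_rows.append(det)
    values = pd.DataFrame(rows, index=feat_ids, columns=samples)
    detected = (
        pd.DataFrame(det_rows, index=feat_ids, columns=samples) if any_na else None
    )
    return ExpressionMatrix(values, feature_kind, detected)


def write_expression_tsv(m: ExpressionMatrix, path, na_token: str = "NA") -> None:
    """Write an expression matrix; undetected/NaN cells emit the NA token."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        vals = m.values.to_numpy()
        det = m.detected.to_numpy() if m.detected is not None else None
        for i, fid in enumerate(m.feature_ids):
            cells = []
            for j in range(m.n_samples):
                hidden = (det is not None and not det[i, j]) or np.isnan(vals[i, j])
                cells.append(na_token if hidden else repr(float(vals[i, j])))
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Load a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Members are de-duplicated per set; lines with fewer than three fields or
    repeated set names are rejected.
    """
    sets: List[GeneSet] = []
    names: Set[str] = set()
    for lineno, ln in enumerate(_lines(path), start=1):
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}: line {lineno}: GMT line needs >=3 tab-fields, got {len(parts)}"
            )
        name, desc = parts[0], parts[1]
        if name in names:
            raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
        names.add(name)
        members = [g for g in parts[2:] if g != ""]
        if not members:
            raise ParseError(f"{path}: line {lineno}: set {name!r} has no members")
        sets.append(GeneSet(name, desc, frozenset(members)))
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write(s.name + "\t" + s.description + "\t")
            fh.write("\t".join(sorted(s.members)) + "\n")


# ---------------------------------------------------------------------------
# miRNA target maps
# ---------------------------------------------------------------------------

def read_target_map(path) -> TargetMap:
    """Load a two-column ``mirna<TAB>gene`` TSV; duplicates collapse."""
    lines = _lines(path)
    if not lines:
        raise ParseError(f"{path}: empty target map")
    targets: Dict[str, Set[str]] = {}
    for lineno, ln in enumerate(lines, start=1):
        parts = ln.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(
                f"{path}: line {lineno}: expected 'mirna<TAB>gene', got {ln!r}"
            )
        targets.setdefault(parts[0], set()).add(parts[1])
    return TargetMap(targets)


def write_target_map(tmap: TargetMap, path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(tmap.mirna_ids):
            for gene in sorted(tmap[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# interaction tables (TSV or SIF)
# ---------------------------------------------------------------------------

def _is_sif(parts: List[str]) -> bool:
    # SIF: "a<TAB>relation<TAB>b" — three fields with a non-numeric middle
    if len(parts) != 3:
        return False
    mid = parts[1]
    try:
        float(mid)
        return False
    except ValueError:
        return True


def read_interactions(path, sif: Optional[bool] = None) -> InteractionTable:
    """Load an undirected edge list.

    Accepts two-column ``geneA<TAB>geneB``, three-column
    ``geneA<TAB>geneB<TAB>source`` and SIF ``geneA<TAB>relation<TAB>geneB``
    dialects.  A ``gene_a<TAB>gene_b<TAB>source`` header line (as emitted by
    :func:`write_interactions`) pins the three-column reading for the whole
    file; otherwise the SIF reading of a three-field line is auto-detected
    from a non-numeric middle field unless ``sif`` forces the choice.
    """
    lines = _lines(path)
    if not lines:
        raise ParseError(f"{path}: empty interaction table")
    start = 0
    if lines[0].split("\t") == ["gene_a", "gene_b", "source"]:
        start = 1
        sif = False
    if len(lines) == start:
        raise ParseError(f"{path}: interaction table has no edges")
    edges: List[Tuple[str, str, str]] = []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split("\t")
        if len(parts) == 2:
            a, b, src = parts[0], parts[1], ""
        elif len(parts) == 3:
            use_sif = sif if sif is not None else _is_sif(parts)
            if use_sif:
                a, src, b = parts
            else:
                a, b, src = parts
        else:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 or 3 fields, got {len(parts)}"
            )
        if not a or not b:
            raise ParseError(f"{path}: line {lineno}: empty node ID")
        edges.append((a, b, src))
    return InteractionTable(edges)


def write_interactions(table: InteractionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b, src in sorted(table.edges):
            fh.write(f"{a}\t{b}\t{src}\n")


# ---------------------------------------------------------------------------
# collapse maps
# ---------------------------------------------------------------------------

def read_collapse_map(path) -> CollapseMap:
    """Load a ``probe<TAB>gene`` TSV (a probe may appear once only)."""
    lines = _lines(path)
    if not lines:
        raise ParseError(f"{path}: empty collapse map")
    mapping: Dict[str, str] = {}
    for lineno, ln in enumerate(lines, start=1):
        parts = ln.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(
                f"{path}: line {lineno}: expected 'probe<TAB>gene', got {ln!r}"
            )
        if parts[0] in mapping:
            raise ParseError(f"{path}: line {lineno}: duplicate probe {parts[0]!r}")
        mapping[parts[0]] = parts[1]
    return CollapseMap(mapping)


def write_collapse_map(cmap: CollapseMap, path) -> None:
    with open(path, "w") as fh:
        for probe in sorted(cmap.mapping):
            fh.write(f"{probe}\t{cmap.mapping[probe]}\n")


# ---------------------------------------------------------------------------
# sample -> group designs
# ---------------------------------------------------------------------------

def read_design(path) -> GroupDesign:
    """Load a ``sample<TAB>group`` TSV (groups: exposure/control; header optional)."""
    lines = _lines(path)
    if not lines:
        raise ParseError(f"{path}: empty design file")
    start = 0
    first = lines[0].split("\t")
    if len(first) == 2 and first[1] not in ("exposure", "control"):
        start = 1  # header row
    assignment: Dict[str, str] = {}
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 'sample<TAB>group'")
        sample, group = parts
        if group not in ("exposure", "control"):
            raise ParseError(
                f"{path}: line {lineno}: group must be exposure/control, got {group!r}"
            )
        if sample in assignment:
            raise ParseError(f"{path}: line {lineno}: duplicate sample {sample!r}")
        assignment[sample] = group
    return GroupDesign(assignment)


def write_design(design, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in sorted(design.assignment):
            fh.write(f"{s}\t{design.assignment[s]}\n")


# ---------------------------------------------------------------------------
# differential expression tables
# ---------------------------------------------------------------------------

_DE_COLUMNS = ["feature", "fold", "t", "p", "q", "direction"]


def write_de_table(records: Sequence[DERecord], path) -> None:
    """Write DE results with the fixed downstream column contract."""
    with open(path, "w") as fh:
        fh.write("\t".join(_DE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.fold!r}\t{r.t_stat!r}\t{r.p_value!r}\t"
                f"{r.q_value!r}\t{r.direction}\n"
            )


def read_de_table(path) -> List[DERecord]:
    lines = _lines(path)
    if not lines or lines[0].split("\t") != _DE_COLUMNS:
        raise ParseError(f"{path}: missing or malformed DE table header")
    out: List[DERecord] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(_DE_COLUMNS):
            raise ParseError(f"{path}: line {lineno}: expected {len(_DE_COLUMNS)} fields")
        try:
            out.append(
                DERecord(
                    feature_id=parts[0],
                    fold=float(parts[1]),
                    t_stat=float(parts[2]),
                    p_value=float(parts[3]),
                    q_value=float(parts[4]),
                    direction=parts[5],
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}: line {lineno}: {e}") from None
    return out


# ---------------------------------------------------------------------------
# enrichment / module / link result exports
# ---------------------------------------------------------------------------

def write_enrichment_table(results, path) -> None:
    """Write per-set enrichment results (leading-edge genes semicolon-joined)."""
    with open(path, "w") as fh:
        fh.write("set\tES\tNES\tp\tQ\tsize\tleading_edge\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.es!r}\t{r.nes!r}\t{r.p_value!r}\t"
                f"{r.q_value!r}\t{r.size}\t" + ";".join(r.leading_edge) + "\n"
            )


def write_modules_json(modules, path) -> None:
    payload = [
        {
            "name": m.module_name,
            "member_sets": list(m.member_sets),
            "direction": m.direction,
            "leading_edge": [
                {"gene": g, "direction": m.gene_directions[g]}
                for g in m.leading_edge
            ],
        }
        for m in modules
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_modules_json(path):
    from .gsea import ModuleResult

    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for m in payload:
        genes = [e["gene"] for e in m["leading_edge"]]
        out.append(
            ModuleResult(
                module_name=m["name"],
                member_sets=tuple(m["member_sets"]),
                leading_edge=tuple(genes),
                gene_directions={e["gene"]: e["direction"] for e in m["leading_edge"]},
                direction=m["direction"],
            )
        )
    return out


def write_links_tsv(links, path) -> None:
    """Write miRNA->module links; linking genes as ``gene:direction`` pairs."""
    with open(path, "w") as fh:
        fh.write("mirna\tdirection\tmodule\tlinking_genes\n")
        for l in links:
            joined = ";".join(f"{g}:{d}" for g, d in l.linking_genes)
            fh.write(f"{l.mirna_id}\t{l.mirna_direction}\t{l.module_name}\t{joined}\n")


def read_links_tsv(path):
    from .integrate import MiRNAModuleLink

    lines = _lines(path)
    if not lines or not lines[0].startswith("mirna\t"):
        raise ParseError(f"{path}: missing links header")
    out = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields")
        genes = []
        for tok in parts[3].split(";"):
            if ":" not in tok:
                raise ParseError(f"{path}: line {lineno}: bad linking gene {tok!r}")
            g, d = tok.rsplit(":", 1)
            genes.append((g, d))
        out.append(
            MiRNAModuleLink(
                mirna_id=parts[0],
                mirna_direction=parts[1],
                module_name=parts[2],
                linking_genes=tuple(genes),
            )
        )
    return out
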