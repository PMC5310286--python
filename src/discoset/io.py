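"""File formats: z-score / expression TSV, GMT gene sets, result tables.

TSV (tab-separated, decimal point) is the canonical tabular dialect
throughout; fitted parameters and run provenance travel as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import DiscordanceResult, GeneSetCollection
from .mixture import DiscosetError, MixtureParams
from .zscores import PairedExpressionDataset, ZScoreMatrix


class ParseError(DiscosetError):
    pass


def read_zscore_tsv(path) -> ZScoreMatrix:
    """Read a gene-by-dataset z-score TSV (first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene IDs in {path}: {dups[:10]}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad) or df.isna().any().any():
        rows = df.index[df.isna().any(axis=1) |
                        df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)]
        raise ParseError(f"non-numeric or missing entries in {path}; "
                         f"offending rows: {rows.tolist()[:10]}, "
                         f"columns: {bad.tolist()}")
    return ZScoreMatrix(gene_ids=[str(g) for g in df.index],
                        dataset_ids=[str(c) for c in df.columns],
                        z=df.to_numpy(dtype=float))


def write_zscore_tsv(zm: ZScoreMatrix, path) -> None:
    df = pd.DataFrame(zm.z, index=zm.gene_ids, columns=zm.dataset_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_tsv(path) -> PairedExpressionDataset:
    """Read a paired expression TSV whose header encodes pair and condition
    as ``<pair>_case`` / ``<pair>_control``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cases, controls = {}, {}
    for col in df.columns:
        name, _, cond = str(col).rpartition("_")
        if cond == "case":
            cases[name] = col
        elif cond == "control":
            controls[name] = col
        else:
            raise ParseError(f"column {col!r} lacks a _case/_control suffix")
    if set(cases) != set(controls):
        odd = set(cases) ^ set(controls)
        raise ParseError(f"pairs missing a case or control column: {sorted(odd)}")
    pair_ids = sorted(cases)
    return PairedExpressionDataset(
        gene_ids=[str(g) for g in df.index],
        case=df[[cases[p] for p in pair_ids]].to_numpy(dtype=float),
        control=df[[controls[p] for p in pair_ids]].to_numpy(dtype=float),
        pair_ids=pair_ids)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then gene IDs.

    Duplicate genes within a line are dropped with a warning inside the
    collection; duplicate set names are an error.  CRLF and LF line
    endings are treated identically.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: GMT line has fewer than 3 fields")
        name, desc, genes = fields[0].strip(), fields[1], fields[2:]
        if name in sets:
            raise ParseError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = [g for g in genes if g.strip()]
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             source=str(path))


def write_params_json(params: MixtureParams, path, meta: dict | None = None) -> None:
    d = params.to_dict()
    d["tool_version"] = __version__
    if meta:
        d["fit"] = meta
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_params_json(path) -> MixtureParams:
    return MixtureParams.from_dict(json.loads(Path(path).read_text()))


def write_results(result: DiscordanceResult, prefix,
                  meta: dict | None = None) -> tuple[Path, Path]:
    """Write the DES table (TSV, decreasing DES) and a JSON sidecar with
    theta and provenance.  Returns (tsv_path, json_path)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")

    rows = [{"set_name": r.name, "m_S": r.m_S, "DES": r.des,
             "FDR_at_rank": result.fdr_at_rank[i], "method": r.method,
             "B": r.B if r.B is not None else ""}
            for i, r in enumerate(result.records)]
    pd.DataFrame(rows, columns=["set_name", "m_S", "DES", "FDR_at_rank",
                                "method", "B"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.10g")

    sidecar = {
        "theta": result.theta,
        "n_sets_scored": len(result.records),
        "skipped_sets": result.skipped_sets,
        "tool_version": __version__,
    }
    if meta:
        sidecar.update(meta)
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return tsv_path, json_path
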