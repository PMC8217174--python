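"""Readers and writers for the plain-text formats the pipeline exchanges.

Series travel as delimited tables (tab or comma, auto-detected) with a header
row of region labels and one sample per line, accompanied by a JSON sidecar
carrying the sampling interval, block boundaries, condition and provenance.
Graphs are written both as diff-friendly TSV edge lists (stable-sorted) and as
JSON documents; classification results as JSON plus long-format TSV.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import Block, MultichannelSeries, RegionSet, DEFAULT_REPETITION_TIME
from .pcmci import CausalGraph, CITestResult, LinkResult

__all__ = [
    "read_series_table",
    "write_series",
    "write_table",
    "read_study",
    "write_graph",
    "read_graph",
    "write_classification",
    "sidecar_path",
]

_PRECISION = 6  # significant digits of every numeric text output


def _format(v: float, precision: int = _PRECISION) -> str:
    return f"{v:.{precision}g}"


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_table(values: np.ndarray, labels, path, precision: int = _PRECISION) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    lines = ["\t".join(labels)]
    for row in values:
        lines.append("\t".join(_format(v, precision) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_series_table(
    path,
    repetition_time: float | None = None,
    condition: str | None = None,
) -> MultichannelSeries:
    """Read a delimited samples x regions table with a header of region labels.

    The delimiter is auto-detected (tab or comma). Ragged rows and non-numeric
    cells are rejected with their line numbers. Sampling interval, block
    boundaries and condition come from the JSON sidecar when present; explicit
    arguments override it; the sampling interval defaults to 1.6 s.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty table")
    delim = "\t" if "\t" in lines[0] else ","
    labels = [c.strip() for c in lines[0].split(delim)]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate region labels in header: {labels}")
    rows, errors = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delim)
        if len(cells) != len(labels):
            errors.append(f"line {lineno}: expected {len(labels)} cells, got {len(cells)}")
            continue
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            errors.append(f"line {lineno}: non-numeric cell")
    if errors:
        shown = "; ".join(errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        raise ValueError(f"{path}: malformed table: {shown}{more}")

    meta = {}
    sc = sidecar_path(path)
    if sc.exists() and sc != path:
        meta = json.loads(sc.read_text())
    tr = repetition_time or meta.get("repetition_time") or DEFAULT_REPETITION_TIME
    boundaries = tuple(meta.get("block_boundaries", (0,)))
    return MultichannelSeries(
        values=np.asarray(rows, dtype=float),
        regions=RegionSet(tuple(labels)),
        repetition_time=float(tr),
        block_boundaries=boundaries,
        condition=condition or meta.get("condition"),
        subjects=tuple(meta.get("subjects", ())),
    )


def write_series(series: MultichannelSeries, path, provenance: dict | None = None) -> Path:
    """Write a series TSV plus its JSON sidecar (boundaries + provenance)."""
    path = Path(path)
    write_table(series.values, series.regions.labels, path)
    meta = {
        "repetition_time": series.repetition_time,
        "block_boundaries": list(series.block_boundaries),
        "condition": series.condition,
        "subjects": list(series.subjects),
        "n_samples": series.n_samples,
        "regions": list(series.regions.labels),
    }
    if provenance:
        meta["provenance"] = provenance
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_study(manifest_path) -> tuple[list[Block], dict]:
    """Load all blocks referenced by a study manifest; returns (blocks, manifest)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    regions = RegionSet(tuple(manifest["regions"]))
    blocks = []
    for entry in manifest["blocks"]:
        series = read_series_table(manifest_path.parent / entry["file"])
        if series.regions.labels != regions.labels:
            raise ValueError(f"{entry['file']}: region labels differ from manifest")
        blocks.append(
            Block(values=series.values, regions=regions, subject=entry["subject"],
                  condition=entry["condition"], index=entry["block"])
        )
    return blocks, manifest


# ---------------------------------------------------------------------------
# Graphs and classification
# ---------------------------------------------------------------------------

def write_graph(graph: CausalGraph, basepath, all_results: bool = False) -> tuple[Path, Path]:
    """Write a graph as TSV edge list + JSON document. Returns both paths."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    tsv = basepath.with_suffix(".tsv")
    df = graph.to_dataframe(all_results=all_results)
    df_fmt = df.copy()
    df_fmt["statistic"] = df_fmt["statistic"].map(_format)
    df_fmt["p"] = df_fmt["p"].map(_format)
    df_fmt.to_csv(tsv, sep="\t", index=False)
    doc = {
        "condition": graph.condition,
        "method": graph.method,
        "alpha": graph.alpha,
        "tau_max": graph.tau_max,
        "links": [
            {"source": l.source, "target": l.target, "lag": l.lag,
             "statistic": l.statistic, "p": l.p_value,
             "n_effective": l.result.n_effective}
            for l in graph.links
        ],
    }
    jsonp = basepath.with_suffix(".json")
    jsonp.write_text(json.dumps(doc, indent=2))
    return tsv, jsonp


def read_graph(path) -> CausalGraph:
    """Reload a graph written by :func:`write_graph` (significant links only)."""
    doc = json.loads(Path(path).read_text())
    links = [
        LinkResult(
            source=l["source"], target=l["target"], lag=l["lag"],
            result=CITestResult(
                method=doc["method"], statistic=l["statistic"], p_value=l["p"],
                n_effective=l.get("n_effective", 0),
            ),
        )
        for l in doc["links"]
    ]
    return CausalGraph(
        condition=doc["condition"], method=doc["method"], alpha=doc["alpha"],
        tau_max=doc["tau_max"], links=links,
    )


def write_graphml(graph: CausalGraph, path) -> Path:
    import networkx as nx

    g = graph.to_networkx()
    nx.write_graphml(g, path)
    return Path(path)


def write_classification(classified, outdir, stem: str = "classification") -> dict:
    """Write the classification JSON + long TSV + counts TSV; returns paths."""
    from .linkclass import long_table, normalize_statistics, tabulate_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = [
        {"source": cl.source, "target": cl.target, "lag": cl.lag,
         "timing": cl.timing, "nature": cl.nature, "persistence": cl.persistence,
         "methods": list(cl.methods),
         "evidence": {f"{c}|{m}": [s, p] for (c, m), (s, p) in sorted(cl.evidence.items())}}
        for cl in classified
    ]
    jsonp = outdir / f"{stem}.json"
    jsonp.write_text(json.dumps(doc, indent=2))
    table = long_table(classified)
    if not table.empty:
        table = normalize_statistics(table)
    longp = outdir / f"{stem}_long.tsv"
    table.to_csv(longp, sep="\t", index=False, float_format=f"%.{_PRECISION}g")
    counts = tabulate_counts(classified)
    countsp = outdir / f"{stem}_counts.tsv"
    counts.to_csv(countsp, sep="\t", index=False)
    return {"json": jsonp, "long": longp, "counts": countsp}
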