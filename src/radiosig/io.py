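"""Plain-text readers and writers for the pipeline's input bundle.

Formats
-------
expression TSV : first column ``gene_id``, remaining columns named
    ``<cellline>__t<hours>`` (e.g. ``CL01__t24``).
SF2 TSV : columns ``cell_line``, ``sf2``.
heat TSV : columns ``gene_id``, ``heat``.
edge list TSV : columns ``gene_a``, ``gene_b``, ``weight``.
gene sets : standard GMT (name, description, members, tab-separated).
truth / manifest : JSON.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .radioscreen import validate_sf2
from .timecourse import TimeCourseExperiment

_SAMPLE_RE = re.compile(r"^(?P<line>.+)__t(?P<hour>\d+(?:\.\d+)?)$")


def _wrap_io(path, exc: Exception) -> Exception:
    return IOError(f"{path}: {exc}")


def _parse_sample(name: str) -> tuple[str, float]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"sample column {name!r} is not '<cellline>__t<hours>'")
    hour = float(m.group("hour"))
    return m.group("line"), int(hour) if hour.is_integer() else hour


def _format_sample(line: str, hour) -> str:
    h = int(hour) if float(hour).is_integer() else hour
    return f"{line}__t{h}"


def read_expression(path) -> TimeCourseExperiment:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    pairs = [_parse_sample(c) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(pairs, names=["cell_line", "hour"])
    return TimeCourseExperiment(values=df)


def write_expression(expr: TimeCourseExperiment, path) -> None:
    out = expr.values.copy()
    out.columns = [_format_sample(l, h) for l, h in out.columns]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sf2(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    sf2 = pd.Series(df["sf2"].to_numpy(), index=df["cell_line"], name="sf2")
    return validate_sf2(sf2)


def write_sf2(sf2: pd.Series, path) -> None:
    validate_sf2(sf2).rename_axis("cell_line").rename("sf2").to_csv(path, sep="\t")


def read_heat(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["heat"].to_numpy(), index=df["gene_id"], name="heat")


def write_heat(heat: pd.Series, path) -> None:
    heat.rename_axis("gene_id").rename("heat").to_csv(path, sep="\t")


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["gene_a", "gene_b", "weight"]].to_csv(path, sep="\t", index=False)


def edges_to_graph(edges: pd.DataFrame, min_weight: float | None = None) -> nx.Graph:
    """Build an undirected graph, optionally filtering on edge confidence."""
    G = nx.Graph()
    for a, b, w in edges[["gene_a", "gene_b", "weight"]].itertuples(index=False):
        if min_weight is not None and w < min_weight:
            continue
        G.add_edge(a, b, weight=float(w))
    return G


def read_gmt(path) -> dict[str, list]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict, path, description: str = "radiosig") -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Bundle:
    """All pipeline inputs, as loaded from a fixture directory."""

    expression: TimeCourseExperiment
    sf2: pd.Series
    heats: dict = field(default_factory=dict)  # kind -> Series
    edges: pd.DataFrame | None = None
    gene_sets: dict = field(default_factory=dict)
    truth: dict | None = None


BUNDLE_FILES = {
    "expression": "expression.tsv",
    "sf2": "sf2.tsv",
    "mutation": "mutation_heat.tsv",
    "cna": "cna_heat.tsv",
    "edges": "ppi_edges.tsv",
    "gene_sets": "gene_sets.gmt",
    "truth": "truth.json",
}


def read_bundle(directory) -> Bundle:
    d = Path(directory)
    try:
        expression = read_expression(d / BUNDLE_FILES["expression"])
        sf2 = read_sf2(d / BUNDLE_FILES["sf2"])
        heats = {
            kind: read_heat(d / BUNDLE_FILES[kind]) for kind in ("mutation", "cna")
        }
        edges = read_edges(d / BUNDLE_FILES["edges"])
        gene_sets = read_gmt(d / BUNDLE_FILES["gene_sets"])
    except OSError as exc:
        raise _wrap_io(directory, exc) from exc
    truth_path = d / BUNDLE_FILES["truth"]
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return Bundle(
        expression=expression,
        sf2=sf2,
        heats=heats,
        edges=edges,
        gene_sets=gene_sets,
        truth=truth,
    )
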