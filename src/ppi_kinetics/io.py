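"""Readers, writers and shipped reference fixtures.

Edge lists are plain two-column text (one interaction per line, the
dialect BIND/DIP/COSIN exports reduce to); PSI-MI-TAB-like multi-column
files are handled by pointing ``id_columns`` at the interactor columns.
Normalization drops self-interactions and collapses duplicate unordered
pairs, reporting the bookkeeping counts.

The shipped fixtures are the three summary tables of the reference
analysis (ten species interactome sizes, the seven fitted yeast
observables with percent standard errors, and the estimated kinetic
rates), so the whole pipeline runs without any database downloads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import KineticParameters
from .fitting import DegreeHistogram, InteractomeSummary
from .param_estimation import ChiSquareReference

__all__ = [
    "EdgeList",
    "read_edge_list",
    "write_edge_list",
    "read_degree_histogram",
    "write_degree_histogram",
    "read_interactome_summaries",
    "load_interactome_summaries",
    "load_reference_observables",
    "load_fitted_kinetics",
    "YEAST_N_INF",
]

YEAST_N_INF = 4135  # interacting proteins in the reference yeast interactome


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Normalized undirected interaction list with parsing bookkeeping."""

    edges: list[tuple[str, str]]
    source: str = ""
    n_raw: int = 0
    n_self_dropped: int = 0
    n_duplicates: int = 0
    n_malformed: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> set[str]:
        return {p for e in self.edges for p in e}

    @property
    def N(self) -> int:
        return len(self.proteins)

    @property
    def L(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        counts: dict[str, int] = {}
        for a, b in self.edges:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return np.array(sorted(counts.values()), dtype=int)


def read_edge_list(path, id_columns: tuple[int, int] = (0, 1),
                   delimiter: str | None = None, comment: str = "#",
                   max_malformed_fraction: float = 0.05) -> EdgeList:
    """Parse and normalize a protein-protein edge-list file.

    Identifiers are opaque case-sensitive strings. Self-pairs are dropped,
    duplicate unordered pairs collapsed. Malformed lines produce warnings;
    more than ``max_malformed_fraction`` of them is an error.
    """
    path = Path(path)
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    n_raw = n_self = n_dup = n_bad = 0
    messages: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or (comment and line.startswith(comment)):
                continue
            fields = line.split(delimiter)
            n_raw += 1
            try:
                a, b = fields[id_columns[0]], fields[id_columns[1]]
            except IndexError:
                n_bad += 1
                messages.append(f"line {lineno}: fewer columns than expected")
                continue
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(key)
    if n_raw == 0:
        raise ValueError(f"{path}: no interaction records found")
    if n_bad / n_raw > max_malformed_fraction:
        raise ValueError(f"{path}: {n_bad}/{n_raw} malformed lines")
    for msg in messages:
        warnings.warn(f"{path}: {msg}")
    return EdgeList(edges=edges, source=str(path), n_raw=n_raw,
                    n_self_dropped=n_self, n_duplicates=n_dup,
                    n_malformed=n_bad, warnings=messages)


def write_edge_list(edges: EdgeList | Sequence[tuple], path) -> None:
    """Write one tab-separated interaction per line."""
    pairs = edges.edges if isinstance(edges, EdgeList) else edges
    with Path(path).open("w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# histograms and summaries as headered TSV
# ---------------------------------------------------------------------------

def write_degree_histogram(hist: DegreeHistogram, path) -> None:
    hist.to_frame().to_csv(path, sep="\t", index=False)


def read_degree_histogram(path) -> DegreeHistogram:
    df = pd.read_csv(path, sep="\t")
    edges = []
    if {"bin_lo", "bin_hi"}.issubset(df.columns):
        edges = list(zip(df["bin_lo"].astype(int), df["bin_hi"].astype(int)))
    n = int(round((df["count_per_degree"]
                   * (np.array([hi - lo + 1 for lo, hi in edges])
                      if edges else 1.0)).sum()))
    return DegreeHistogram(df["degree"].to_numpy(),
                           df["count_per_degree"].to_numpy(),
                           bin_edges=edges, n_proteins=n)


def read_interactome_summaries(path) -> list[InteractomeSummary]:
    df = pd.read_csv(path, sep="\t")
    return [InteractomeSummary(str(r["species"]), int(r["N_inf"]), int(r["L"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# shipped fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("ppi_kinetics").joinpath("data", name)


def load_interactome_summaries() -> list[InteractomeSummary]:
    """(N_inf, L) for the ten reference species interactomes."""
    with resources.as_file(_data_path("interactomes.tsv")) as p:
        return read_interactome_summaries(p)


def load_reference_observables() -> ChiSquareReference:
    """The seven fitted yeast observables with percent standard errors."""
    with resources.as_file(_data_path("yeast_observables.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    est = dict(zip(df["quantity"], df["estimate"]))
    pct = dict(zip(df["quantity"], df["se_percent"]))
    return ChiSquareReference.from_percent(est, pct)


def load_fitted_kinetics(which: str = "best") -> KineticParameters:
    """Reference kinetic rates: ``which`` is 'best' or 'mean_top10'."""
    if which not in ("best", "mean_top10"):
        raise ValueError("which must be 'best' or 'mean_top10'")
    with resources.as_file(_data_path("kinetic_parameters.tsv")) as p:
        df = pd.read_csv(p, sep="\t").set_index("parameter")
    col = "best" if which == "best" else "mean_top10"
    values = df[col].to_dict()
    return KineticParameters(
        f0=values["f0"], ki=values["ki"], k2=values["k2"],
        kXY=values["kXY"], kYX=values["kYX"], xi0=values["xi0"],
        mu=values["mu"], delta_eps=values["delta_eps"], r=values["r"])
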