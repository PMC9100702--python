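"""Attributed structural brain networks and their on-disk formats.

A subject is represented by an undirected weighted graph over ``m`` cortical
regions (Destrieux atlas: 74 per hemisphere, 148 total) whose edge weights are
tractography fiber counts, together with an ``m x d`` node-attribute matrix
whose first column is the regional amyloid SUVR, and an optional diagnostic
label in {NC, MCI, AD}.

Node ordering convention: regions ``0 .. m/2-1`` are the left hemisphere,
``m/2 .. m-1`` the right, with homologous regions at offset ``m/2``.

On disk a network is either a pair of CSV tables (headerless square adjacency
matrix; attribute table with a header whose first column is ``suvr``) or a
single GraphML file. Cohorts are described by a YAML/JSON manifest listing one
entry per subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LABELS",
    "LABEL_TO_INT",
    "INT_TO_LABEL",
    "BrainNetwork",
    "CohortManifest",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "read_graphml",
    "load_cohort",
    "write_cohort",
]

#: Diagnostic labels in severity order; the integer encoding follows this order.
LABELS = ("NC", "MCI", "AD")
LABEL_TO_INT = {lab: i for i, lab in enumerate(LABELS)}
INT_TO_LABEL = {i: lab for i, lab in enumerate(LABELS)}

SYMMETRY_TOL = 1e-6


class NetworkFormatError(ValueError):
    """A file does not parse into the expected tabular shape."""


class NetworkValidationError(ValueError):
    """Parsed data violate a brain-network invariant."""


@dataclass
class BrainNetwork:
    """One subject's attributed structural brain network.

    Parameters
    ----------
    adjacency
        Symmetric nonnegative ``(m, m)`` matrix of fiber counts, zero diagonal.
    attributes
        ``(m, d)`` node-attribute matrix; column 0 is regional amyloid SUVR.
    label
        Diagnosis in {"NC", "MCI", "AD"}, or None if unlabeled.
    subject_id
        Optional identifier carried through cohort I/O.
    """

    adjacency: np.ndarray
    attributes: np.ndarray
    label: str | None = None
    subject_id: str | None = None
    attribute_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.attributes = np.asarray(self.attributes, dtype=float)
        if self.attributes.ndim == 1:
            self.attributes = self.attributes[:, None]
        if not self.attribute_names:
            self.attribute_names = tuple(
                ["suvr"] + [f"attr{j}" for j in range(1, self.attributes.shape[1])]
            )
        _validate(self.adjacency, self.attributes)
        if self.label is not None and self.label not in LABELS:
            raise NetworkValidationError(
                f"label {self.label!r} not one of {LABELS}"
            )

    @property
    def m(self) -> int:
        """Number of regions (nodes)."""
        return self.adjacency.shape[0]

    @property
    def d(self) -> int:
        """Number of node attributes."""
        return self.attributes.shape[1]

    @property
    def label_int(self) -> int | None:
        """Severity-ordered integer encoding NC=0, MCI=1, AD=2."""
        return None if self.label is None else LABEL_TO_INT[self.label]

    @property
    def suvr(self) -> np.ndarray:
        """Regional amyloid SUVR (first attribute column)."""
        return self.attributes[:, 0]


def _validate(adjacency: np.ndarray, attributes: np.ndarray) -> None:
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise NetworkFormatError(
            f"adjacency must be square, got shape {adjacency.shape}"
        )
    m = adjacency.shape[0]
    if attributes.shape[0] != m:
        raise NetworkFormatError(
            f"attribute rows ({attributes.shape[0]}) do not match "
            f"adjacency size ({adjacency.shape})"
        )
    neg = np.argwhere(adjacency < 0)
    if neg.size:
        i, j = neg[0]
        raise NetworkValidationError(
            f"negative adjacency entry {adjacency[i, j]} at cell ({i}, {j})"
        )
    asym = np.abs(adjacency - adjacency.T).max() if m else 0.0
    if asym > SYMMETRY_TOL:
        raise NetworkValidationError(
            f"adjacency asymmetry {asym:.3e} exceeds tolerance {SYMMETRY_TOL}"
        )
    if np.any(np.diag(adjacency) != 0):
        raise NetworkValidationError("adjacency diagonal must be zero")


def _clean_adjacency(A: np.ndarray, source: str) -> np.ndarray:
    """Symmetrize within tolerance and zero the diagonal, warning on repairs."""
    asym = np.abs(A - A.T).max() if A.size else 0.0
    if asym > SYMMETRY_TOL:
        raise NetworkValidationError(
            f"{source}: adjacency asymmetry {asym:.3e} exceeds {SYMMETRY_TOL}"
        )
    A = (A + A.T) / 2.0
    if np.any(np.diag(A) != 0):
        warnings.warn(
            f"{source}: nonzero diagonal entries set to zero "
            "(self-connections are not meaningful in tractography)",
            stacklevel=3,
        )
        np.fill_diagonal(A, 0.0)
    return A


def read_network(
    adjacency_path: str | Path,
    attributes_path: str | Path,
    label: str | None = None,
    subject_id: str | None = None,
    permutation: Sequence[int] | None = None,
) -> BrainNetwork:
    """Read a network from a CSV adjacency matrix and a CSV attribute table.

    The adjacency CSV is headerless and square; the attribute CSV has a header
    row naming its columns (first column ``suvr``). The matrix is symmetrized
    as ``(A + A.T) / 2`` after checking asymmetry is below 1e-8.

    ``permutation`` optionally reorders nodes into the left-block-first
    convention: entry ``k`` gives the on-disk row index of internal node ``k``.
    """
    adjacency_path, attributes_path = Path(adjacency_path), Path(attributes_path)
    A = pd.read_csv(adjacency_path, header=None).to_numpy(dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise NetworkFormatError(
            f"{adjacency_path}: adjacency table is {A.shape}, expected square"
        )
    attr_df = pd.read_csv(attributes_path)
    F = attr_df.to_numpy(dtype=float)
    if F.shape[0] != A.shape[0]:
        raise NetworkFormatError(
            f"{attributes_path}: {F.shape[0]} attribute rows vs "
            f"{A.shape[0]}x{A.shape[1]} adjacency"
        )
    if permutation is not None:
        p = np.asarray(permutation, dtype=int)
        A = A[np.ix_(p, p)]
        F = F[p]
    A = _clean_adjacency(A, str(adjacency_path))
    return BrainNetwork(
        A, F, label=label, subject_id=subject_id,
        attribute_names=tuple(str(c) for c in attr_df.columns),
    )


def write_network(
    net: BrainNetwork, out_dir: str | Path, format: str = "csv",
    stem: str | None = None,
) -> dict[str, Path]:
    """Write a network to ``out_dir`` as CSV tables or a GraphML file.

    Returns a dict of the files written. Round-trips through :func:`read_network`
    (or :func:`read_graphml`) reproduce adjacency and attributes to 1e-12.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or net.subject_id or "network"
    if format == "csv":
        adj_path = out_dir / f"{stem}_adjacency.csv"
        attr_path = out_dir / f"{stem}_attributes.csv"
        pd.DataFrame(net.adjacency).to_csv(
            adj_path, header=False, index=False, float_format="%.17g"
        )
        pd.DataFrame(net.attributes, columns=list(net.attribute_names)).to_csv(
            attr_path, index=False, float_format="%.17g"
        )
        return {"adjacency": adj_path, "attributes": attr_path}
    if format == "graphml":
        G = nx.Graph()
        if net.label is not None:
            G.graph["label"] = net.label
        for i in range(net.m):
            attrs = {
                name: float(net.attributes[i, j])
                for j, name in enumerate(net.attribute_names)
            }
            G.add_node(i, **attrs)
        rows, cols = np.nonzero(np.triu(net.adjacency))
        for i, j in zip(rows.tolist(), cols.tolist()):
            G.add_edge(i, j, weight=float(net.adjacency[i, j]))
        path = out_dir / f"{stem}.graphml"
        nx.write_graphml(G, path)
        return {"graphml": path}
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'graphml'")


def read_graphml(path: str | Path, subject_id: str | None = None) -> BrainNetwork:
    """Read a single network from a GraphML file written by :func:`write_network`."""
    G = nx.read_graphml(path, node_type=int)
    m = G.number_of_nodes()
    nodes = sorted(G.nodes)
    sample = G.nodes[nodes[0]]
    names = [k for k in sample.keys()]
    A = np.zeros((m, m))
    for i, j, data in G.edges(data=True):
        A[i, j] = A[j, i] = float(data.get("weight", 1.0))
    F = np.array([[float(G.nodes[i][k]) for k in names] for i in nodes])
    return BrainNetwork(
        A, F, label=G.graph.get("label"), subject_id=subject_id,
        attribute_names=tuple(names),
    )


@dataclass
class CohortManifest:
    """Ordered list of subjects with file locations and diagnoses."""

    subjects: list[str]
    labels: list[str]
    adjacency_paths: list[Path]
    attribute_paths: list[Path]
    permutation: list[int] | None = None

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if not (len(self.labels) == len(self.adjacency_paths) == len(self.attribute_paths) == n):
            raise NetworkFormatError("manifest lists have inconsistent lengths")
        bad = sorted({lab for lab in self.labels} - set(LABELS))
        if bad:
            raise NetworkValidationError(f"labels {bad} not in {LABELS}")


def _parse_manifest(path: Path) -> CohortManifest:
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base = path.parent
    subs = data["subjects"]
    return CohortManifest(
        subjects=[str(s["subject_id"]) for s in subs],
        labels=[str(s["label"]) for s in subs],
        adjacency_paths=[base / s["adjacency"] for s in subs],
        attribute_paths=[base / s["attributes"] for s in subs],
        permutation=data.get("permutation"),
    )


def load_cohort(manifest_path: str | Path) -> list[BrainNetwork]:
    """Load every subject listed in a YAML/JSON cohort manifest, in order.

    Raises if any file is missing or any subject's node count differs from the
    first subject's.
    """
    manifest = _parse_manifest(Path(manifest_path))
    nets: list[BrainNetwork] = []
    m0: int | None = None
    for sid, lab, adj, attr in zip(
        manifest.subjects, manifest.labels,
        manifest.adjacency_paths, manifest.attribute_paths,
    ):
        if not adj.exists():
            raise NetworkFormatError(f"subject {sid}: missing file {adj}")
        if not attr.exists():
            raise NetworkFormatError(f"subject {sid}: missing file {attr}")
        net = read_network(
            adj, attr, label=lab, subject_id=sid, permutation=manifest.permutation
        )
        if m0 is None:
            m0 = net.m
        elif net.m != m0:
            raise NetworkValidationError(
                f"subject {sid} has m={net.m}, cohort has m={m0}"
            )
        nets.append(net)
    return nets


def write_cohort(
    networks: Sequence[BrainNetwork], out_dir: str | Path,
    manifest_name: str = "manifest.yaml",
) -> Path:
    """Write a cohort as per-subject CSV pairs plus a YAML manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, net in enumerate(networks):
        sid = net.subject_id or f"sub{k:04d}"
        paths = write_network(net, out_dir, format="csv", stem=sid)
        entries.append(
            {
                "subject_id": sid,
                "label": net.label,
                "adjacency": paths["adjacency"].name,
                "attributes": paths["attributes"].name,
            }
        )
    manifest_path = out_dir / manifest_name
    manifest_path.write_text(yaml.safe_dump({"subjects": entries}, sort_keys=False))
    return manifest_path
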