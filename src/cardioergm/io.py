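"""Readers, writers, configuration and provenance shared by all stages.

Networks travel as GraphML (attribute-rich, directed, broadly readable)
with a plain delimited edge list alongside; configurations as YAML or
JSON with unknown keys rejected and defaults injected; excitation
histories as compressed NPZ with a JSON sidecar (plus a small CSV of
per-step excited counts).  All writers order keys deterministically so
outputs are diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from cardioergm.abstraction import CausalNetwork
from cardioergm.simulator import LatticeConfig, StateSeries

__all__ = [
    "write_network",
    "read_network",
    "write_edge_list",
    "read_edge_list",
    "load_config",
    "dump_config",
    "config_from_mapping",
    "write_series",
    "read_series",
    "RunProvenance",
]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


# ---------------------------------------------------------------------------
# networks


def write_network(path, net: CausalNetwork) -> None:
    """Write a causal network as GraphML with node (row, col) and edge
    (score, weight, lag) attributes."""
    import networkx as nx

    nx.write_graphml(net.to_networkx(), str(path))


def read_network(path) -> CausalNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    import networkx as nx
    from xml.etree.ElementTree import ParseError

    try:
        G = nx.read_graphml(str(path), node_type=int)
    except ParseError as exc:
        raise ValueError(
            f"malformed GraphML in {path}: {exc} "
            f"(line, column) = {getattr(exc, 'position', '?')}"
        ) from exc
    nodes = sorted(G.nodes())
    coords = np.array(
        [(int(G.nodes[v]["row"]), int(G.nodes[v]["col"])) for v in nodes],
        dtype=np.int64,
    ).reshape(len(nodes), 2)
    index = {v: k for k, v in enumerate(nodes)}
    rows = [
        {
            "src": index[u],
            "dst": index[v],
            "score": float(d["score"]),
            "weight": float(d["weight"]),
            "lag": int(d["lag"]),
        }
        for u, v, d in G.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=list(CausalNetwork.EDGE_COLUMNS))
    edges = edges.sort_values(["src", "dst"], ignore_index=True)
    grid = None
    if "grid_rows" in G.graph:
        grid = (int(G.graph["grid_rows"]), int(G.graph["grid_cols"]))
    return CausalNetwork(
        node_coords=coords,
        edges=edges,
        threshold=float(G.graph.get("threshold", 0.0)),
        grid_shape=grid,
    )


def write_edge_list(path, net: CausalNetwork, sep: str = "\t") -> None:
    """Delimited (src, dst, score, weight, lag) edge list for inspection."""
    edges = net.edges.sort_values(["src", "dst"], ignore_index=True)
    edges.to_csv(path, sep=sep, index=False)


def read_edge_list(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# configuration


def config_from_mapping(data: dict, cls=LatticeConfig):
    """Build a config dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s): {sorted(unknown)} "
            f"(allowed: {sorted(names)})"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path, cls=LatticeConfig):
    """Load a YAML or JSON configuration file into a typed config.

    Defaults are injected for omitted fields; unknown keys and invariant
    violations raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return config_from_mapping(data, cls)


def dump_config(config, path=None) -> str:
    """Serialize a config dataclass to YAML (stable key order)."""
    import yaml

    data = dataclasses.asdict(config)
    data = {k: data[k] for k in sorted(data)}
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# excitation histories


def write_series(path, series: StateSeries, csv_counts: bool = True) -> None:
    """Store an excitation history as compressed NPZ + JSON sidecar.

    ``path`` is the NPZ file; a ``<path>.json`` sidecar records the
    configuration, and ``<path stem>_counts.csv`` the per-step excited
    count for spreadsheet inspection.
    """
    path = Path(path)
    arrays = {
        "excitation": np.packbits(series.excitation, axis=-1),
        "excited_count": series.excited_count,
        "shape": np.array(series.excitation.shape),
    }
    np.savez_compressed(path, **arrays)
    sidecar = {
        "config": dataclasses.asdict(series.config),
        "dtype": "packed bits along last axis",
        "shape": list(series.excitation.shape),
    }
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    if csv_counts:
        pd.DataFrame(
            {"t": np.arange(series.horizon), "excited_count": series.excited_count}
        ).to_csv(path.with_name(path.stem + "_counts.csv"), index=False)


def read_series(path) -> StateSeries:
    """Load an excitation history written by :func:`write_series`.

    The quenched lattice is not stored; it is rebuilt from the config
    seed on demand (construction is deterministic)."""
    path = Path(path)
    with np.load(path) as data:
        shape = tuple(int(v) for v in data["shape"])
        packed = data["excitation"]
        excitation = np.unpackbits(packed, axis=-1)[..., : shape[-1]].reshape(shape)
        counts = data["excited_count"]
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = config_from_mapping(sidecar["config"], LatticeConfig)
    return StateSeries(
        excitation=excitation.astype(np.uint8),
        excited_count=counts,
        config=config,
        lattice=None,
    )


# ---------------------------------------------------------------------------
# provenance


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunProvenance:
    """Reproducibility record of one pipeline run."""

    config: dict
    seeds: dict
    artifact_version: str
    created: str = ""
    files: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def add_file(self, path) -> None:
        self.files[str(Path(path).name)] = _digest(path)

    def verify(self, directory) -> bool:
        directory = Path(directory)
        return all(
            _digest(directory / name) == digest
            for name, digest in self.files.items()
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunProvenance":
        return cls(**json.loads(text))

    @classmethod
    def read(cls, path) -> "RunProvenance":
        return cls.from_json(Path(path).read_text())
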