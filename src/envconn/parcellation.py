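"""Connectome parcellation and frequency-band definitions.

The analysis operates on a fixed, ordered set of cortical nodes grouped into
six canonical resting-state networks (default-mode DMN, dorsal attention DAN,
ventral attention VAN, language LAN, sensorimotor SMN, visual VIN) and five
oscillatory frequency bands (delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, low
beta 12-21 Hz, high beta 21-30 Hz).  Node order is significant: it defines
row/column indexing of every connectivity matrix downstream.

The shipped 32-node atlas is a reconstruction: node labels, network
memberships and hemispheres were assembled from the published figure labels
of the study design this package reimplements, completed from the upstream
42-node resting-state atlas it was adapted from.  MNI coordinates are not
part of the reconstruction and are left empty; they are only ever needed for
plotting, never for computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

NETWORKS = ("DMN", "DAN", "VAN", "LAN", "SMN", "VIN")
HEMISPHERES = ("L", "R", "M")

#: Canonical five-band decomposition (name, low edge Hz, high edge Hz).
DEFAULT_BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta_low", 12.0, 21.0),
    ("beta_high", 21.0, 30.0),
)


class ConnectomeError(ValueError):
    """Invalid connectome or band definition."""


@dataclass(frozen=True)
class NodeDef:
    """One connectome node.

    ``alias_network`` carries an alternative network attribution where the
    literature supports two labelings (e.g. the left inferior temporal gyrus
    node sits in the DMN but acts as a language-network node); it never
    affects indexing, only interpretation of results.
    """

    label: str
    network: str
    hemisphere: str
    alias_network: str | None = None
    coordinate: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise ConnectomeError(
                f"unknown network {self.network!r} for node {self.label!r}; "
                f"expected one of {NETWORKS}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ConnectomeError(
                f"unknown hemisphere {self.hemisphere!r} for node {self.label!r}"
            )
        if self.alias_network is not None and self.alias_network not in NETWORKS:
            raise ConnectomeError(
                f"unknown alias network {self.alias_network!r} for {self.label!r}"
            )


@dataclass(frozen=True)
class BandDef:
    """A frequency band [low_hz, high_hz) in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ConnectomeError(
                f"band {self.name!r}: low edge {self.low_hz} must be below "
                f"high edge {self.high_hz}"
            )


def default_bands() -> tuple[BandDef, ...]:
    return tuple(BandDef(n, lo, hi) for n, lo, hi in DEFAULT_BANDS)


@dataclass(frozen=True)
class ConnectomeDef:
    """Ordered node and band sets; the indexing contract of the pipeline.

    Flat (node, band) indexing is node-major, band-minor:
    ``flat = node_index * n_bands + band_index``.
    """

    nodes: tuple[NodeDef, ...]
    bands: tuple[BandDef, ...] = field(default_factory=default_bands)

    def __post_init__(self) -> None:
        labels = [n.label for n in self.nodes]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ConnectomeError(f"duplicate node labels: {sorted(dupes)}")
        band_names = [b.name for b in self.bands]
        if len(set(band_names)) != len(band_names):
            raise ConnectomeError("duplicate band names")

    # -- sizes ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_entries(self) -> int:
        """Number of (node, band) layers in the multi-layer matrix."""
        return self.n_nodes * self.n_bands

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = {n.network for n in self.nodes}
        return tuple(nw for nw in NETWORKS if nw in present)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.nodes)

    # -- indexing ------------------------------------------------------
    def flat_index(self, node: int, band: int) -> int:
        if not (0 <= node < self.n_nodes and 0 <= band < self.n_bands):
            raise IndexError(f"(node={node}, band={band}) out of range")
        return node * self.n_bands + band

    def unflatten(self, flat: int) -> tuple[int, int]:
        if not 0 <= flat < self.n_entries:
            raise IndexError(f"flat index {flat} out of range")
        return divmod(flat, self.n_bands)

    def node_index(self, label: str) -> int:
        return self.labels.index(label)

    def network_nodes(self, network: str) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.network == network]


def load_connectome(
    path: str | Path,
    bands: Sequence[BandDef] | None = None,
    strict: bool = True,
) -> ConnectomeDef:
    """Read an atlas table (TSV with columns label/network/hemisphere,
    optional alias_network and mni_{x,y,z}) into a validated connectome.

    Row order defines node order.  With ``strict`` the atlas must have
    exactly 32 nodes spanning 6 networks; relax it for toy parcellations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"label", "network", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeError(f"atlas file missing columns: {sorted(missing)}")

    nodes = []
    for row in df.itertuples(index=False):
        alias = getattr(row, "alias_network", None)
        alias = None if alias is None or pd.isna(alias) else str(alias)
        coord = None
        if {"mni_x", "mni_y", "mni_z"} <= set(df.columns):
            xyz = (row.mni_x, row.mni_y, row.mni_z)
            if not any(pd.isna(v) for v in xyz):
                coord = tuple(float(v) for v in xyz)
        nodes.append(
            NodeDef(str(row.label), str(row.network), str(row.hemisphere),
                    alias_network=alias, coordinate=coord)
        )
    conn = ConnectomeDef(tuple(nodes), tuple(bands) if bands else default_bands())
    if strict:
        if conn.n_nodes != 32:
            raise ConnectomeError(
                f"strict atlas must have 32 nodes, got {conn.n_nodes}"
            )
        if len(conn.networks) != 6:
            raise ConnectomeError(
                f"strict atlas must span 6 networks, got {len(conn.networks)}"
            )
    return conn


def save_connectome(conn: ConnectomeDef, path: str | Path) -> None:
    """Persist the atlas table; inverse of :func:`load_connectome`."""
    rows = []
    for n in conn.nodes:
        x, y, z = n.coordinate if n.coordinate else (None, None, None)
        rows.append(
            dict(label=n.label, network=n.network, hemisphere=n.hemisphere,
                 alias_network=n.alias_network, mni_x=x, mni_y=y, mni_z=z)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_connectome(bands: Sequence[BandDef] | None = None) -> ConnectomeDef:
    """The shipped 32-node / 6-network atlas with the five canonical bands."""
    with resources.as_file(
        resources.files("envconn").joinpath("data/atlas32.tsv")
    ) as p:
        return load_connectome(p, bands=bands, strict=True)


def load_bands(path: str | Path) -> tuple[BandDef, ...]:
    """Read a band table (TSV: name, low_hz, high_hz)."""
    df = pd.read_csv(path, sep="\t")
    return tuple(
        BandDef(str(r.name), float(r.low_hz), float(r.high_hz))
        for r in df.itertuples(index=False)
    )


# ---------------------------------------------------------------------------
# Pair enumeration

@dataclass(frozen=True)
class PairSets:
    """Index sets over which connectivity statistics are formed.

    node_pairs: unordered distinct node pairs (i < j) — n(n-1)/2 of them.
    cross_network_pairs: unordered distinct network pairs.
    within_networks: one entry per network (the within-network "pair").
    band_pairs: unordered band pairs *including* same-band pairs — the
        layers of the multi-layer matrix.
    cross_band_pairs: the strictly cross-frequency subset.
    """

    node_pairs: tuple[tuple[int, int], ...]
    cross_network_pairs: tuple[tuple[str, str], ...]
    within_networks: tuple[str, ...]
    band_pairs: tuple[tuple[int, int], ...]
    cross_band_pairs: tuple[tuple[int, int], ...]


def enumerate_pairs(conn: ConnectomeDef) -> PairSets:
    """Enumerate the node-, network- and band-pair families of a connectome.

    For the full design (32 nodes, 6 networks, 5 bands) this yields the
    published design counts: 496 node pairs, 15 cross-network pairs,
    6 within-network entries, 10 cross-band pairs and 15 band pairs in all.
    """
    n = conn.n_nodes
    node_pairs = tuple((i, j) for i in range(n) for j in range(i + 1, n))
    nets = conn.networks
    cross_net = tuple(
        (a, b) for k, a in enumerate(nets) for b in nets[k + 1:]
    )
    nb = conn.n_bands
    band_pairs = tuple((a, b) for a in range(nb) for b in range(a, nb))
    cross_band = tuple(p for p in band_pairs if p[0] != p[1])
    return PairSets(node_pairs, cross_net, nets, band_pairs, cross_band)
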