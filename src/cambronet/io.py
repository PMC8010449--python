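"""Tabular and network I/O plus stratigraphic binning and windowing.

The central container is :class:`AbundanceMatrix`: a levels-by-taxa matrix of
specimen counts where each row is a stratigraphic level of fixed thickness,
ordered oldest (lowest) first.  Trait tables attach preservation-relevant
categories (body type, size class, habitat, motility) to taxa.  Correlation
networks produced downstream are plain :class:`networkx.Graph` objects whose
edges carry a signed correlation ``weight`` and an FDR-adjusted ``q_value``;
they are serialized as edge-list CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "TaxonTraits",
    "StratWindow",
    "FormatError",
    "BODY_TYPES",
    "SIZE_CLASSES",
    "HABITATS",
    "read_abundance_table",
    "write_abundance_table",
    "read_trait_table",
    "write_trait_table",
    "bin_levels",
    "make_windows",
    "read_network",
    "write_network",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


BODY_TYPES = frozenset({"soft", "intermediate", "hard"})
SIZE_CLASSES = frozenset({"small", "medium", "large"})
HABITATS = frozenset({"endo/epibenthic", "nektobenthic", "nektonic/pelagic"})

# tolerated spellings seen in trait compilations, mapped to canonical labels
_HABITAT_ALIASES = {
    "endobenthic/epibenthic": "endo/epibenthic",
    "endobenthic": "endo/epibenthic",
    "epibenthic": "endo/epibenthic",
    "nektonic": "nektonic/pelagic",
    "pelagic": "nektonic/pelagic",
}


@dataclass(frozen=True)
class AbundanceMatrix:
    """Specimen counts per stratigraphic level (rows) and taxon (columns).

    Levels are ordered stratigraphically, oldest (lowest in the section)
    first.  ``level_thickness_cm`` is the uniform thickness of one level
    (10 cm in raw quarry data).
    """

    level_ids: tuple
    counts: np.ndarray
    taxon_names: tuple
    level_thickness_cm: float = 10.0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.level_ids), len(self.taxon_names)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.level_ids)} levels x {len(self.taxon_names)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValueError("duplicate taxon names")
        if self.level_thickness_cm <= 0:
            raise ValueError("level_thickness_cm must be positive")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "level_ids", tuple(self.level_ids))
        object.__setattr__(self, "taxon_names", tuple(self.taxon_names))

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def total_specimens(self) -> int:
        return int(self.counts.sum())

    @property
    def depths_cm(self) -> np.ndarray:
        """Depth of the base of each level above the section bottom."""
        return np.arange(self.n_levels) * self.level_thickness_cm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.level_ids), columns=list(self.taxon_names)
        )

    def select_levels(self, idx) -> "AbundanceMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            level_ids=tuple(self.level_ids[i] for i in idx),
            counts=self.counts[idx],
        )


@dataclass(frozen=True)
class TaxonTraits:
    """Per-taxon categorical traits relevant to preservation potential."""

    table: pd.DataFrame  # index = taxon, columns = body_type, size_class, habitat, motility

    REQUIRED = ("body_type", "size_class", "habitat", "motility")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"trait table lacks column(s): {', '.join(missing)}")
        bad = set(t["body_type"]) - BODY_TYPES
        if bad:
            raise FormatError(
                f"unrecognized body_type value(s) {sorted(bad)}; "
                f"allowed: {sorted(BODY_TYPES)}"
            )
        bad = set(t["size_class"]) - SIZE_CLASSES
        if bad:
            raise FormatError(
                f"unrecognized size_class value(s) {sorted(bad)}; "
                f"allowed: {sorted(SIZE_CLASSES)}"
            )
        bad = set(t["habitat"]) - HABITATS
        if bad:
            raise FormatError(
                f"unrecognized habitat value(s) {sorted(bad)}; "
                f"allowed: {sorted(HABITATS)}"
            )
        if t["motility"].isna().any() or (t["motility"].astype(str) == "").any():
            raise FormatError("motility must be a non-empty category for every taxon")
        if t.index.duplicated().any():
            raise FormatError("duplicate taxon rows in trait table")

    def labels(self, factor: str, taxa) -> dict:
        """Map each requested taxon to its category for ``factor``.

        ``factor`` is one of body_type, size_class, habitat, motility.
        """
        if factor not in self.REQUIRED:
            raise ValueError(f"unknown trait factor {factor!r}")
        out = {}
        for t in taxa:
            if t not in self.table.index:
                raise KeyError(f"taxon {t!r} missing from trait table")
            out[t] = self.table.at[t, factor]
        return out

    def validate_cover(self, m: AbundanceMatrix) -> None:
        missing = [t for t in m.taxon_names if t not in self.table.index]
        if missing:
            raise KeyError(f"taxa without trait rows: {missing}")


@dataclass(frozen=True)
class StratWindow:
    """A contiguous run of levels used in the running time-frame analysis."""

    window_id: int
    level_indices: tuple
    depth_span_cm: tuple  # (start_cm, stop_cm)

    def __post_init__(self):
        idx = tuple(self.level_indices)
        if len(idx) == 0:
            raise ValueError("window must contain at least one level")
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("window levels must be contiguous")
        object.__setattr__(self, "level_indices", idx)


def read_abundance_table(path) -> AbundanceMatrix:
    """Read a level-by-taxon count CSV (first column = level id / depth)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate taxon column(s): {dupes}")
    df = pd.read_csv(path, index_col=0)
    arr = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i, v in enumerate(vals):
            if pd.isna(v) or v != int(v) or v < 0:
                raise FormatError(
                    f"non-integer or negative count at level {df.index[i]!r}, "
                    f"taxon {col!r}: {df[col].iloc[i]!r}"
                )
            arr[i, j] = int(v)
    return AbundanceMatrix(
        level_ids=tuple(str(i) for i in df.index),
        counts=arr,
        taxon_names=tuple(df.columns),
    )


def write_abundance_table(m: AbundanceMatrix, path) -> None:
    m.to_frame().to_csv(path, index_label="level")


def read_trait_table(path) -> TaxonTraits:
    """Read a taxon trait CSV with body_type, size_class, habitat, motility."""
    df = pd.read_csv(path)
    taxon_col = df.columns[0]
    df = df.set_index(taxon_col)
    df.index = df.index.astype(str)
    df.index.name = None
    if "habitat" in df.columns:
        df["habitat"] = df["habitat"].replace(_HABITAT_ALIASES)
    return TaxonTraits(table=df)


def write_trait_table(traits: TaxonTraits, path) -> None:
    traits.table.to_csv(path, index_label="taxon")


def bin_levels(m: AbundanceMatrix, bin_cm: float) -> AbundanceMatrix:
    """Sum consecutive levels into coarser bins of ``bin_cm`` thickness.

    Trailing levels that do not fill a complete bin are dropped, so a 9.3 m
    section of 10 cm levels yields 46 complete 20 cm bins.
    """
    ratio = bin_cm / m.level_thickness_cm
    if bin_cm <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"bin_cm={bin_cm} is not a positive integer multiple of the "
            f"level thickness {m.level_thickness_cm}"
        )
    k = int(round(ratio))
    n_bins = m.n_levels // k
    trimmed = m.counts[: n_bins * k]
    binned = trimmed.reshape(n_bins, k, m.n_taxa).sum(axis=1)
    ids = tuple(
        f"{m.level_ids[i * k]}-{m.level_ids[i * k + k - 1]}" if k > 1 else m.level_ids[i]
        for i in range(n_bins)
    )
    return AbundanceMatrix(
        level_ids=ids,
        counts=binned,
        taxon_names=m.taxon_names,
        level_thickness_cm=bin_cm,
    )


def make_windows(m: AbundanceMatrix, width: int, step: int = 1) -> list:
    """Sliding contiguous windows of ``width`` levels advancing by ``step``."""
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if width > m.n_levels:
        raise ValueError(f"width {width} exceeds number of levels {m.n_levels}")
    windows = []
    for w, start in enumerate(range(0, m.n_levels - width + 1, step)):
        idx = tuple(range(start, start + width))
        windows.append(
            StratWindow(
                window_id=w,
                level_indices=idx,
                depth_span_cm=(
                    start * m.level_thickness_cm,
                    (start + width) * m.level_thickness_cm,
                ),
            )
        )
    return windows


def write_network(g: nx.Graph, path) -> None:
    """Write a correlation network as a signed weighted edge-list CSV."""
    rows = [
        {
            "taxon_a": a,
            "taxon_b": b,
            "weight": d.get("weight", np.nan),
            "q_value": d.get("q_value", np.nan),
        }
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight", "q_value"]).to_csv(
        path, index=False
    )


def read_network(path, nodes=None) -> nx.Graph:
    """Read an edge-list CSV written by :func:`write_network`.

    ``nodes`` optionally supplies the full node set (isolated nodes are not
    recoverable from the edge list alone).
    """
    df = pd.read_csv(path)
    expected = ["taxon_a", "taxon_b", "weight", "q_value"]
    if list(df.columns) != expected:
        raise FormatError(f"edge list columns must be exactly {expected}")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        if row.taxon_a == row.taxon_b:
            raise FormatError(f"self-loop on taxon {row.taxon_a!r}")
        g.add_edge(row.taxon_a, row.taxon_b, weight=row.weight, q_value=row.q_value)
    return g
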