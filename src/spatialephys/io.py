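"""Readers and writers for every on-disk representation the pipeline touches.

Expression data travel as a MatrixMarket triplet (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``) with a positions table, or as a single
delimited gene x spot table.  LFP events travel as delimited text or an HDF5
container.  Graphs are exported as GEXF for Gephi.  Every reader/writer pair
round-trips its own output exactly (integers) or to <=1e-9 relative (floats).

Coordinate conventions: positions written by this package are already in
micrometres (columns ``x_um``/``y_um``).  Visium-style ``tissue_positions``
tables carry full-resolution pixel coordinates; they are converted on read
using the physical spot diameter (55 µm) against the spot diameter in
pixels, and the pixel row axis (downward) is flipped so y increases upward.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .datatypes import (
    EVENT_COLUMNS,
    ElectrodeArraySpec,
    ExpressionMatrix,
    LFPEventTable,
    ValidationError,
)

VISIUM_SPOT_DIAMETER_UM = 55.0

_POSITION_COLUMNS = ["barcode", "x_um", "y_um", "region"]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | os.PathLike,
    dialect: str = "auto",
    spot_diameter_px: float | None = None,
    max_barcode_mismatch: float = 0.05,
) -> ExpressionMatrix:
    """Read a gene x spot matrix plus spot positions from ``path``.

    ``path`` is a directory holding either a MatrixMarket triplet
    (``matrix.mtx``, ``features.tsv``, ``barcodes.tsv``) or a delimited
    table ``expression.tsv`` (genes in rows, spot barcodes in columns),
    together with a positions table: ``positions.csv`` in this package's
    µm dialect, or a Visium-style ``tissue_positions.csv``.

    Parameters
    ----------
    dialect
        ``"mtx"``, ``"table"`` or ``"auto"`` (detect from files present).
    spot_diameter_px
        Spot diameter in full-resolution pixels, required to convert a
        Visium pixel position table to micrometres.
    max_barcode_mismatch
        Maximum tolerated fraction of matrix barcodes missing from the
        positions table before a :class:`ValidationError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "mtx" if (path / "matrix.mtx").exists() else "table"

    if dialect == "mtx":
        mtx_file = path / "matrix.mtx"
        if not mtx_file.exists():
            raise FileNotFoundError(mtx_file)
        if mtx_file.stat().st_size == 0:
            raise ValidationError(f"empty matrix file: {mtx_file}")
        counts = np.asarray(scipy.io.mmread(mtx_file).todense(), dtype=float)
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0]
        genes = genes.astype(str).tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        barcodes = barcodes.astype(str).tolist()
    elif dialect == "table":
        table_file = path / "expression.tsv"
        if not table_file.exists():
            raise FileNotFoundError(table_file)
        if table_file.stat().st_size == 0:
            raise ValidationError(f"empty matrix file: {table_file}")
        df = pd.read_csv(table_file, sep="\t", index_col=0)
        counts = df.to_numpy(dtype=float)
        genes = df.index.astype(str).tolist()
        barcodes = df.columns.astype(str).tolist()
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if counts.size == 0:
        raise ValidationError("expression matrix has no entries")
    if counts.min() < 0:
        raise ValidationError("negative count in expression matrix")

    positions = _read_positions(path, spot_diameter_px)
    missing = [b for b in barcodes if b not in positions.index]
    if len(missing) > max_barcode_mismatch * max(len(barcodes), 1):
        raise ValidationError(
            f"{len(missing)}/{len(barcodes)} barcodes lack positions "
            f"(first: {missing[:3]})"
        )
    keep = [i for i, b in enumerate(barcodes) if b not in set(missing)]
    barcodes = [barcodes[i] for i in keep]
    counts = counts[:, keep]
    pos = positions.loc[barcodes]
    return ExpressionMatrix(
        genes=genes,
        spots=barcodes,
        counts=counts,
        spot_xy=pos[["x_um", "y_um"]].to_numpy(dtype=float),
        region=pos["region"].astype(str).tolist(),
        normalized=False,
    )


def _read_positions(path: Path, spot_diameter_px: float | None) -> pd.DataFrame:
    own = path / "positions.csv"
    visium = path / "tissue_positions.csv"
    if own.exists():
        pos = pd.read_csv(own, dtype={"barcode": str})
        missing = set(_POSITION_COLUMNS[:3]) - set(pos.columns)
        if missing:
            raise ValidationError(f"positions.csv lacks columns {missing}")
        if "region" not in pos.columns:
            pos["region"] = "none"
        return pos.set_index("barcode")
    if visium.exists():
        pos = pd.read_csv(visium, dtype={"barcode": str})
        required = {"barcode", "pxl_row_in_fullres", "pxl_col_in_fullres"}
        if not required <= set(pos.columns):
            raise ValidationError(
                f"tissue_positions.csv lacks columns {required - set(pos.columns)}"
            )
        if spot_diameter_px is None:
            raise ValidationError(
                "spot_diameter_px required to convert pixel positions to µm"
            )
        um_per_px = VISIUM_SPOT_DIAMETER_UM / float(spot_diameter_px)
        if "in_tissue" in pos.columns:
            pos = pos[pos["in_tissue"].astype(int) == 1]
        # pixel rows grow downward; flip so y grows upward from the slide's
        # lower-left corner
        row = pos["pxl_row_in_fullres"].to_numpy(dtype=float)
        col = pos["pxl_col_in_fullres"].to_numpy(dtype=float)
        pos = pos.assign(
            x_um=col * um_per_px, y_um=(row.max() - row) * um_per_px
        )
        if "region" not in pos.columns:
            pos["region"] = "none"
        return pos.set_index("barcode")[["x_um", "y_um", "region"]]
    raise FileNotFoundError(f"no positions table found under {path}")


def write_expression_matrix(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write ``expr`` as a MatrixMarket triplet plus µm positions table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(expr.counts)
    scipy.io.mmwrite(path / "matrix.mtx", sparse)
    pd.Series(expr.genes).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(expr.spots).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {
            "barcode": expr.spots,
            "x_um": expr.spot_xy[:, 0],
            "y_um": expr.spot_xy[:, 1],
            "region": expr.region,
        }
    ).to_csv(path / "positions.csv", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# LFP event tables
# ---------------------------------------------------------------------------

def read_lfp_events(
    path: str | os.PathLike,
    duration: float | None = None,
    array_spec: ElectrodeArraySpec | None = None,
) -> LFPEventTable:
    """Read an LFP event table from delimited text or an HDF5 container.

    The delimited dialect needs at least ``electrode_id`` and ``time``
    columns (minimal dialect); the full dialect adds amplitude, peak counts
    and energy.  ``duration`` and the array geometry are read from the HDF5
    attributes when present, otherwise they must be supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            ev = pd.DataFrame(
                {
                    col: (
                        f["events"][col][...].astype(str)
                        if col == "electrode_id"
                        else f["events"][col][...]
                    )
                    for col in f["events"]
                }
            )
            duration = float(f.attrs["duration"])
            array_spec = ElectrodeArraySpec(
                rows=int(f.attrs["rows"]),
                cols=int(f.attrs["cols"]),
                pitch=float(f.attrs["pitch"]),
                electrode_size=float(f.attrs["electrode_size"]),
            )
    else:
        ev = pd.read_csv(path, dtype={"electrode_id": str})
        if duration is None:
            raise ValueError("duration required for delimited event tables")
    required = {"electrode_id", "time"}
    if not required <= set(ev.columns):
        raise ValidationError(f"event table lacks columns {required - set(ev.columns)}")
    return LFPEventTable(
        events=ev,
        duration=float(duration),
        array_spec=array_spec or ElectrodeArraySpec(),
    )


def write_lfp_events(table: LFPEventTable, path: str | os.PathLike) -> None:
    """Write an event table as CSV (``.csv``) or HDF5 (``.h5``/``.hdf5``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("events")
            for col in EVENT_COLUMNS:
                data = table.events[col].to_numpy()
                if col == "electrode_id":
                    grp.create_dataset(
                        col, data=np.asarray(data, dtype="S")
                    )
                else:
                    grp.create_dataset(col, data=np.asarray(data, dtype=float))
            f.attrs["duration"] = table.duration
            for k in ("rows", "cols", "pitch", "electrode_size"):
                f.attrs[k] = getattr(table.array_spec, k)
    else:
        table.events.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def write_gexf(graph, path: str | os.PathLike) -> None:
    """Export a :class:`~spatialephys.topology.GraphModel` (or bare
    ``networkx.Graph``) as GEXF 1.2 for Gephi.

    Node size carries the degree, ``module`` carries the region/module
    label; coordinates are written as plain ``x``/``y`` attributes (µm).
    """
    g = getattr(graph, "graph", graph)
    if not isinstance(g, nx.Graph):
        raise TypeError("write_gexf expects a GraphModel or networkx graph")
    out = nx.Graph()
    for node, attrs in g.nodes(data=True):
        if node is None or str(node) == "":
            raise ValidationError("unnamed node cannot be exported")
        xy = attrs.get("xy", (np.nan, np.nan))
        out.add_node(
            str(node),
            label=str(node),
            x=float(xy[0]),
            y=float(xy[1]),
            size=float(g.degree(node)),
            module=str(attrs.get("module", "none")),
        )
    for u, v, attrs in g.edges(data=True):
        out.add_edge(str(u), str(v), weight=float(attrs.get("weight", 1.0)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_gexf(out, path, version="1.2draft")


def read_gexf(path: str | os.PathLike) -> nx.Graph:
    return nx.read_gexf(path)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | os.PathLike) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def save_config(cfg: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
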