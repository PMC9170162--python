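"""Readers and writers for traces, geometry, and result tables.

Formats: trace matrices as delimited text (rows = cells, header row of times
in seconds, index column of cell ids); tissue geometry as a GeoJSON
FeatureCollection (one polygon feature per cell with ``cell_id`` and
``is_boundary`` properties) or a 16-bit label TIFF (0 = background, label =
cell_id + 1); event logs and edge lists as CSV; null and metrics summaries
as JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from .network import FunctionalNetwork, NullDistribution
from .tissue import TissueMap, flag_boundary_cells, neighbors_from_rois
from .traces import CalciumRecording


# -------------------------------------------------------------- traces


def write_traces(rec: CalciumRecording, path) -> None:
    df = pd.DataFrame(rec.values, index=pd.Index(rec.cell_ids, name="cell_id"),
                      columns=rec.times)
    header = {"fs": rec.fs, "onset": rec.onset}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        df.to_csv(fh, float_format="%.17g")


def read_traces(path) -> CalciumRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing metadata header line")
        meta = json.loads(first[2:])
        df = pd.read_csv(fh, index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty trace file")
    return CalciumRecording(values=df.to_numpy(dtype=float),
                            fs=float(meta["fs"]), onset=float(meta["onset"]),
                            cell_ids=df.index.to_numpy(dtype=int))


# ------------------------------------------------------------- geometry


def tissue_to_geojson(tissue: TissueMap) -> dict:
    feats = []
    for i, poly in enumerate(tissue.polygons):
        feats.append({
            "type": "Feature",
            "geometry": poly.__geo_interface__,
            "properties": {
                "cell_id": int(i),
                "is_boundary": bool(tissue.is_boundary[i]),
            },
        })
    return {"type": "FeatureCollection", "features": feats}


def write_geometry(tissue: TissueMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(tissue_to_geojson(tissue), fh)


def read_geometry(path, contact_tol: float = 1e-9,
                  recompute_boundary: bool = False,
                  hull_ratio: float = 0.2) -> TissueMap:
    """Rebuild a TissueMap from GeoJSON; adjacency is recomputed from the
    polygons by the zero-separation rule."""
    with open(path) as fh:
        data = json.load(fh)
    feats = data.get("features", [])
    if not feats:
        raise ValueError(f"{path}: no features in GeoJSON")
    order = sorted(feats, key=lambda f: f["properties"]["cell_id"])
    polygons, flags = [], []
    for k, f in enumerate(order):
        if f["properties"]["cell_id"] != k:
            raise ValueError(f"{path}: cell ids are not dense from 0")
        polygons.append(shape(f["geometry"]))
        flags.append(bool(f["properties"].get("is_boundary", False)))
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polygons])
    nbrs = neighbors_from_rois(polygons, contact_tol)
    if recompute_boundary:
        flags = flag_boundary_cells(polygons, centroids, ratio=hull_ratio)
    return TissueMap(polygons=polygons, centroids=centroids, neighbors=nbrs,
                     is_boundary=np.asarray(flags, dtype=bool))


def write_label_image(tissue: TissueMap, path, px_per_um: float = 1.0) -> None:
    """Rasterize cell polygons to a 16-bit label TIFF (label = cell_id + 1)."""
    import tifffile
    from skimage.draw import polygon as draw_polygon

    allx = np.concatenate([np.asarray(p.exterior.coords)[:, 0]
                           for p in tissue.polygons])
    ally = np.concatenate([np.asarray(p.exterior.coords)[:, 1]
                           for p in tissue.polygons])
    x0, y0 = allx.min(), ally.min()
    w = int(np.ceil((allx.max() - x0) * px_per_um)) + 2
    h = int(np.ceil((ally.max() - y0) * px_per_um)) + 2
    img = np.zeros((h, w), dtype=np.uint16)
    for i, p in enumerate(tissue.polygons):
        xy = np.asarray(p.exterior.coords)
        rr, cc = draw_polygon((xy[:, 1] - y0) * px_per_um,
                              (xy[:, 0] - x0) * px_per_um, shape=img.shape)
        img[rr, cc] = i + 1
    tifffile.imwrite(path, img)


def read_label_image(path, px_per_um: float = 1.0):
    """Label TIFF → (polygons in µm, label image).

    Polygons are the outer contours of each label; use a contact tolerance
    of about one pixel when deriving adjacency from them, or use
    :func:`label_adjacency` on the image directly.
    """
    import tifffile
    from skimage import measure

    img = tifffile.imread(path)
    labels = np.unique(img)
    labels = labels[labels > 0]
    polygons = []
    for lab in labels:
        contours = measure.find_contours(img == lab, 0.5)
        longest = max(contours, key=len)
        # contours are (row, col); convert to (x, y) in µm
        xy = np.column_stack([longest[:, 1], longest[:, 0]]) / px_per_um
        polygons.append(Polygon(xy).buffer(0))
    return polygons, img


def label_adjacency(img: np.ndarray) -> tuple:
    """Structural adjacency straight from a label image: two labels are
    neighbours when any of their pixels are 4-adjacent."""
    n = int(img.max())
    nbrs = [set() for _ in range(n)]
    for a, b in ((img[:, :-1], img[:, 1:]), (img[:-1, :], img[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        for i, j in set(zip(a[diff].ravel().tolist(),
                            b[diff].ravel().tolist())):
            nbrs[i - 1].add(j - 1)
            nbrs[j - 1].add(i - 1)
    return tuple(frozenset(s) for s in nbrs)


# --------------------------------------------------------------- results


def write_event_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)


def write_edge_list(net: FunctionalNetwork, path) -> None:
    rows = [
        {"cell_a": a, "cell_b": b,
         "coefficient": d.get("weight", np.nan),
         "best_lag_s": d.get("lag_s", np.nan)}
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["cell_a", "cell_b", "coefficient",
                                "best_lag_s"]).to_csv(path, index=False)


def write_null_summary(null: NullDistribution, path) -> None:
    with open(path, "w") as fh:
        json.dump({"n_iter": null.n_iter, "cutoff": null.cutoff,
                   "aggregation": null.aggregation,
                   "n_pairs": null.n_pairs}, fh, indent=2)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
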