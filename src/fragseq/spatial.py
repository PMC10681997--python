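"""Post-segmentation operators for imaging-based validation data.

Given nuclear label images from an external segmenter, this module expands
segment labels outward, assigns detected transcripts to the expanded
segments, removes outlier-sized segments (median + k·MAD rule, MAD
unscaled), annotates cells with manually drawn area polygons, and runs the
cell-type colocalization permutation test on radius neighbor graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.segmentation import expand_labels as _sk_expand_labels

from .io import ValidationError


@dataclass
class LabelImage:
    """Integer label matrix; 0 = background, k > 0 = segment k."""

    labels: np.ndarray
    pixel_size: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label image must be 2-D")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be non-negative integers")
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be positive")

    def segment_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @classmethod
    def from_text(cls, path, pixel_size: float = 1.0) -> "LabelImage":
        return cls(np.loadtxt(path, dtype=int), pixel_size)

    def to_text(self, path) -> None:
        np.savetxt(path, self.labels, fmt="%d")


def expand_labels(img: LabelImage, distance: float) -> LabelImage:
    """Grow each segment into the background by ``distance`` µm.

    Background pixels within the distance of one or more segments adopt the
    nearest segment's label; existing labels never change and segments
    never merge (equidistant pixels pick one of the nearest segments).
    """
    if distance < 0:
        raise ValidationError("expansion distance must be >= 0")
    px = distance / img.pixel_size
    out = _sk_expand_labels(img.labels, distance=px)
    return LabelImage(out, img.pixel_size)


def assign_transcripts(
    img: LabelImage, transcripts: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Assign transcripts (µm coordinates, ``x``/``y``/``gene``) to segments.

    A transcript takes the label of its containing pixel (row = y / pixel
    size, column = x / pixel size); label 0 and out-of-bounds positions are
    unassigned.  Returns (segments x genes count table, n_unassigned);
    assigned + unassigned equals the input row count.
    """
    xy = transcripts[["x", "y"]].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise ValidationError("transcript coordinates must be finite")
    cols = np.floor(xy[:, 0] / img.pixel_size).astype(int)
    rows = np.floor(xy[:, 1] / img.pixel_size).astype(int)
    h, w = img.labels.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    label = np.zeros(len(transcripts), dtype=int)
    label[inside] = img.labels[rows[inside], cols[inside]]
    assigned = label > 0
    n_unassigned = int((~assigned).sum())
    table = (
        pd.crosstab(label[assigned], transcripts["gene"].to_numpy()[assigned])
        if assigned.any()
        else pd.DataFrame()
    )
    table.index = [f"segment{int(i)}" for i in table.index]
    table.index.name = "segment"
    return table, n_unassigned


def segment_areas(img: LabelImage) -> pd.Series:
    """Pixel area per segment id."""
    counts = np.bincount(img.labels.ravel())
    ids = np.flatnonzero(counts)
    ids = ids[ids > 0]
    return pd.Series(counts[ids], index=ids, name="area_px")


def filter_segments_by_area(
    img: LabelImage, k_mad: float = 4.0
) -> tuple[LabelImage, list[int]]:
    """Remove segments larger than median + k·MAD of the segment areas.

    MAD is the raw median absolute deviation, without the 1.4826 normality
    rescaling.  Returns the filtered image and the removed segment ids.
    """
    areas = segment_areas(img)
    if areas.empty:
        raise ValidationError("label image contains no segments")
    med = float(np.median(areas))
    mad = float(np.median(np.abs(areas - med)))
    cutoff = med + k_mad * mad
    removed = [int(i) for i in areas.index[areas > cutoff]]
    out = img.labels.copy()
    if removed:
        out[np.isin(out, removed)] = 0
    if len(removed) == len(areas):
        warnings.warn("area filter removed every segment")
    return LabelImage(out, img.pixel_size), removed


# ---------------------------------------------------------------------------
# Area polygons


def read_polygons(path) -> pd.DataFrame:
    """Read area polygons from CSV (area, group, x, y, ordered vertices)."""
    df = pd.read_csv(path)
    for col in ("area", "group", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"{path}: polygons CSV needs column {col!r}")
    return df


def annotate_areas(cells: pd.DataFrame, polygons: pd.DataFrame) -> pd.DataFrame:
    """Annotate cells with the area polygon containing their centroid.

    Boundary is closed (a cell exactly on an edge is inside).  When
    polygons overlap, the first-listed wins with a warning.  Cells outside
    every polygon keep empty roi/group.
    """
    out = cells.copy()
    out["roi"] = ""
    out["group"] = ""
    pts = shapely.points(out["x"].to_numpy(float), out["y"].to_numpy(float))
    taken = np.zeros(len(out), dtype=bool)
    overlap_warned = False
    for area, sub in polygons.groupby("area", sort=False):
        if len(sub) < 3:
            raise ValidationError(f"polygon {area!r} has fewer than 3 vertices")
        poly = Polygon(sub[["x", "y"]].to_numpy(float))
        if not poly.is_valid:
            raise ValidationError(f"polygon {area!r} is degenerate or self-intersecting")
        inside = shapely.covers(poly, pts)
        clash = inside & taken
        if clash.any() and not overlap_warned:
            warnings.warn("overlapping polygons: first-listed area wins")
            overlap_warned = True
        take = inside & ~taken
        out.loc[take, "roi"] = str(area)
        out.loc[take, "group"] = str(sub["group"].iloc[0])
        taken |= inside
    return out


# ---------------------------------------------------------------------------
# Neighbor graph and colocalization


def build_neighbor_graph(
    cells: pd.DataFrame, radius: float = 10.0, k_cap: int = 41
) -> np.ndarray:
    """Undirected edges between cells strictly closer than ``radius`` µm.

    kd-tree radius search; each vertex keeps at most ``k_cap`` − 1 nearest
    neighbors (a saturated cap drops edges, so it warns).  Returns an
    (n_edges, 2) array of positional vertex indices, each edge once.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    xy = cells[["x", "y"]].to_numpy(float)
    if len(xy) < 2:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]  # strictly smaller than the radius
    degree = np.bincount(pairs.ravel(), minlength=len(xy)) if pairs.size else np.zeros(len(xy))
    if np.any(degree >= k_cap):
        warnings.warn(
            f"{int((degree >= k_cap).sum())} vertices reach the k_cap of {k_cap}; "
            "increase k_cap to avoid dropping edges"
        )
        keep = np.ones(len(pairs), dtype=bool)
        order = np.argsort(np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1))
        deg = np.zeros(len(xy), dtype=int)
        for idx in order:
            u, v = pairs[idx]
            if deg[u] >= k_cap - 1 or deg[v] >= k_cap - 1:
                keep[idx] = False
            else:
                deg[u] += 1
                deg[v] += 1
        pairs = pairs[keep]
    return pairs


def _pair_edge_scores(
    edges: np.ndarray,
    type_codes: np.ndarray,
    roi_codes: np.ndarray,
    n_types: int,
    n_rois: int,
) -> np.ndarray:
    """Normalized edge counts per ROI and unordered type pair.

    Within each ROI, E(t1, t2) / (n_t1 + n_t2); same-type pairs use
    2·n_t as denominator.  Pairs with both types absent give NaN.
    Returns array (n_rois, n_types, n_types), symmetric in the type axes.
    """
    counts = np.zeros((n_rois, n_types, n_types))
    if edges.size:
        same_roi = roi_codes[edges[:, 0]] == roi_codes[edges[:, 1]]
        e = edges[same_roi]
        r = roi_codes[e[:, 0]]
        t1 = type_codes[e[:, 0]]
        t2 = type_codes[e[:, 1]]
        lo = np.minimum(t1, t2)
        hi = np.maximum(t1, t2)
        np.add.at(counts, (r, lo, hi), 1.0)
    n_per = np.zeros((n_rois, n_types))
    np.add.at(n_per, (roi_codes, type_codes), 1.0)
    denom = n_per[:, :, None] + n_per[:, None, :]  # same-type diagonal = 2 n_t
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, counts / denom, np.nan)
    scores = np.triu(scores) + np.triu(scores, 1).transpose(0, 2, 1)
    return scores


def colocalization_test(
    cells: pd.DataFrame,
    radius: float = 10.0,
    contrast: tuple[str, str] = ("distal", "proximal"),
    m: int = 1000,
    seed: int = 0,
    k_cap: int = 41,
    alpha: float = 0.05,
    tail: str = "absolute",
) -> pd.DataFrame:
    """Permutation test for type-type colocalization differences between
    two ROI groups, per slide, plus the signed cross-slide score.

    Per slide: the radius graph is built once; per ROI the normalized edge
    count of each unordered type pair is computed; the observed statistic
    is (mean over group-2 ROIs) − (mean over group-1 ROIs).  The null
    permutes the cell-type labels over the slide's vertices (graph and ROI
    membership fixed) ``m`` times.  ``b`` counts null draws at least as
    extreme as observed — on the |difference| tail by default, or on the
    one-sided tail of the observed sign with ``tail="signed"`` — and
    p = (b + 1)/(m + 1).  The cross-slide score is the fraction of slides
    with p < ``alpha``, signed by the direction of the observed difference
    (positive = colocalization gain in group 2).
    """
    if tail not in ("absolute", "signed"):
        raise ValidationError("tail must be 'absolute' or 'signed'")
    results = []
    types = sorted(cells["cell_type"].unique())
    t_index = {t: i for i, t in enumerate(types)}
    T = len(types)
    for slide, sub in cells.groupby("slide", sort=True):
        g1 = sub["roi"][sub["group"] == contrast[0]].unique()
        g2 = sub["roi"][sub["group"] == contrast[1]].unique()
        if len(g1) == 0 or len(g2) == 0:
            raise ValidationError(f"slide {slide}: both groups need >= 1 ROI")
        rois = list(g1) + list(g2)
        sub = sub[sub["roi"].isin(rois)]
        r_index = {r: i for i, r in enumerate(rois)}
        roi_codes = sub["roi"].map(r_index).to_numpy()
        type_codes = sub["cell_type"].map(t_index).to_numpy()
        in_g2 = np.array([r in set(g2) for r in rois])

        edges = build_neighbor_graph(sub, radius=radius, k_cap=k_cap)

        def group_diff(tc: np.ndarray) -> np.ndarray:
            scores = _pair_edge_scores(edges, tc, roi_codes, T, len(rois))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                m2 = np.nanmean(scores[in_g2], axis=0)
                m1 = np.nanmean(scores[~in_g2], axis=0)
            return m2 - m1

        observed = group_diff(type_codes)
        rng = np.random.default_rng(seed)
        null = np.empty((m, T, T))
        for b in range(m):
            null[b] = group_diff(rng.permutation(type_codes))

        for i in range(T):
            for j in range(i, T):
                obs = observed[i, j]
                if np.isnan(obs):
                    continue
                nd = null[:, i, j]
                valid = ~np.isnan(nd)
                nv = nd[valid]
                if tail == "absolute":
                    b_count = int(np.count_nonzero(np.abs(nv) >= abs(obs)))
                else:
                    b_count = int(
                        np.count_nonzero(nv >= obs) if obs >= 0 else np.count_nonzero(nv <= obs)
                    )
                m_eff = int(valid.sum())
                p = (b_count + 1) / (m_eff + 1)
                results.append(
                    {
                        "slide": slide,
                        "type1": types[i],
                        "type2": types[j],
                        "observed_diff": float(obs),
                        "b": b_count,
                        "m": m_eff,
                        "p": float(p),
                    }
                )
    df = pd.DataFrame(results)
    if df.empty:
        return df
    sig = df.assign(
        signed_sig=np.sign(df["observed_diff"]) * (df["p"] < alpha).astype(float)
    )
    score = (
        sig.groupby(["type1", "type2"])["signed_sig"].mean().rename("score").reset_index()
    )
    df = df.merge(score, on=["type1", "type2"], how="left")
    return df
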