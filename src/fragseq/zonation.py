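"""Niche reconstruction: lobule-layer zonation coordinates and
metastasis-proximity labels.

Each liver fragment is placed on the central-portal lobule axis by a
zonation coordinate (ZC) computed from landmark genes in its liver
endothelial cells (LECs):

    ZC_raw = pLM / (pLM + cLM)

where pLM and cLM are the per-fragment sums of max-normalized portal and
central landmark-gene expression, followed by a min-max rescale so the most
central retained fragment sits at 0 and the most portal at 1.  Rescaled
ZCs are binned into lobule layers L1..L10 (deciles) and optionally grouped
into pericentral (L1-L5) and periportal (L6-L10) zones.

Alternatively a fragment's niche is defined by a landmark *cell type*:
fragments containing at least one metastatic cell are "proximal" to a
metastatic site, fragments without are "distal".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .io import SENTINELS, FragmentExperiment, ValidationError

MERGED_LEVELS = ["L1-L3", "L4", "L5", "L6", "L7", "L8-L10"]


class DegenerateRescaleError(ValueError):
    """All retained fragments share one raw ZC; the rescale is undefined."""


# ---------------------------------------------------------------------------
# Landmark panel


def read_landmark_panel(path) -> pd.DataFrame:
    """Read a landmark panel TSV: columns ``gene``, ``zone`` and per-layer
    ``L{k}_mean`` / ``L{k}_sem`` (9 or 10 layers accepted)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "zone" not in df.columns:
        raise ValidationError(f"{path}: landmark panel needs gene and zone columns")
    bad = set(df["zone"]) - {"central", "portal"}
    if bad:
        raise ValidationError(f"{path}: unknown zone tags {sorted(bad)}")
    return df


def write_landmark_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _layer_columns(panel: pd.DataFrame) -> list[int]:
    layers = sorted(
        int(c[1:].split("_")[0]) for c in panel.columns if c.endswith("_mean")
    )
    if not layers:
        raise ValidationError("landmark panel has no L{k}_mean columns")
    return layers


def filter_landmarks(
    panel: pd.DataFrame,
    min_expression: float = 1e-5,
    min_fold_change: float = 1.1,
    max_cv: float = 0.2,
) -> pd.DataFrame:
    """Keep reference genes that are (i) expressed, (ii) zonated, (iii) stable.

    (i)  max per-layer mean > ``min_expression`` (a gene silenced at one
         pole — often the most zonated kind — still passes);
    (ii) fold change between the first and last available layer
         >= ``min_fold_change``; a zero at exactly one pole counts as an
         infinite fold change and passes, flagged in ``fold_change``;
    (iii) mean over layers of SEM/mean < ``max_cv`` (drops noisy profiles).
    """
    layers = _layer_columns(panel)
    first, last = layers[0], layers[-1]
    means = panel[[f"L{k}_mean" for k in layers]].to_numpy(float)
    sems = panel[[f"L{k}_sem" for k in layers]].to_numpy(float)

    expressed = means.max(axis=1) > min_expression

    a, b = means[:, 0], means[:, -1]
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    zonated = fc >= min_fold_change

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(means > 0, sems / means, np.nan)
    cv = np.nanmean(ratio, axis=1)
    stable = np.nan_to_num(cv, nan=np.inf) < max_cv

    out = panel.copy()
    out["fold_change"] = fc
    out["mean_cv"] = cv
    keep = expressed & zonated & stable
    n_inf = int(np.isinf(fc[keep]).sum())
    if n_inf:
        warnings.warn(f"{n_inf} landmark genes silenced at one pole kept (infinite fold change)")
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pseudobulk


def fragment_pseudobulk(
    exp: FragmentExperiment,
    cell_type: str | None,
    min_cells: int = 5,
    mode: str = "sum",
) -> pd.DataFrame:
    """Per-fragment expression over cells of one type (fragments x genes).

    Only fragments carrying >= ``min_cells`` cells of ``cell_type`` (or of
    any type when ``cell_type`` is None) are emitted.  ``sum`` mode adds raw
    counts; ``mean`` mode averages log1p counts-per-10k normalized
    expression across the cells.
    """
    if mode not in ("sum", "mean"):
        raise ValidationError(f"unknown pseudobulk mode {mode!r}")
    cells = exp.cells[~exp.cells["fragment"].isin(SENTINELS)]
    if cell_type is not None:
        if cell_type not in set(exp.cells["cell_type"]):
            raise ValidationError(f"cell type {cell_type!r} not present")
        cells = cells[cells["cell_type"] == cell_type]
    sizes = cells.groupby("fragment").size()
    keep_frags = sizes[sizes >= min_cells].index
    cells = cells[cells["fragment"].isin(keep_frags)]
    if cells.empty:
        warnings.warn("no fragment passes the min_cells cutoff")
        return pd.DataFrame(columns=exp.counts.genes)

    cidx = exp.counts.cell_index()
    cols = np.array([cidx[c] for c in cells.index])
    sub = exp.counts.counts[:, cols]  # genes x selected cells
    frags = pd.Categorical(cells["fragment"], categories=sorted(keep_frags))
    # indicator matrix cells x fragments
    import scipy.sparse as sp

    ind = sp.csr_matrix(
        (np.ones(len(cells)), (np.arange(len(cells)), frags.codes)),
        shape=(len(cells), len(frags.categories)),
    )
    if mode == "sum":
        agg = sub @ ind  # genes x fragments
        data = np.asarray(agg.todense()).T
    else:
        dense = np.asarray(sub.todense(), dtype=float)
        libsize = dense.sum(axis=0)
        libsize[libsize == 0] = 1.0
        norm = np.log1p(dense / libsize * 1e4)
        counts_per_frag = np.asarray(ind.sum(axis=0)).ravel()
        data = (norm @ np.asarray(ind.todense())).T / counts_per_frag[:, None]
    return pd.DataFrame(data, index=list(frags.categories), columns=exp.counts.genes)


# ---------------------------------------------------------------------------
# Zonation coordinate


def compute_zc(pseudobulk: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Zonation coordinates for each fragment from a filtered landmark panel.

    Per-gene max-normalization over fragments equalizes gene contributions;
    ``zc_raw = plm_sum / (plm_sum + clm_sum)``; fragments with zero landmark
    expression (no LEC signal) are dropped with a warning; the min-max
    rescale spans the retained fragments.
    """
    if len(pseudobulk) < 2:
        raise ValidationError("need >= 2 fragments to compute zonation coordinates")
    genes = set(pseudobulk.columns)
    central = [g for g, z in zip(panel["gene"], panel["zone"]) if z == "central" and g in genes]
    portal = [g for g, z in zip(panel["gene"], panel["zone"]) if z == "portal" and g in genes]
    if not central or not portal:
        raise ValidationError("need measured landmark genes in both zones")

    block = pseudobulk[central + portal].to_numpy(float)
    colmax = block.max(axis=0)
    nonzero = colmax > 0
    colmax[~nonzero] = 1.0
    norm = block / colmax
    clm = norm[:, : len(central)].sum(axis=1)
    plm = norm[:, len(central) :].sum(axis=1)

    total = plm + clm
    retained = total > 0
    if (~retained).any():
        dropped = list(pseudobulk.index[~retained])
        warnings.warn(f"dropping {len(dropped)} fragments without landmark expression: {dropped[:5]}…")
    idx = pseudobulk.index[retained]
    zc_raw = plm[retained] / total[retained]
    lo, hi = zc_raw.min(), zc_raw.max()
    if hi == lo:
        raise DegenerateRescaleError("all fragments share one raw ZC; cannot rescale")
    zc_rescaled = (zc_raw - lo) / (hi - lo)
    return pd.DataFrame(
        {
            "plm_sum": plm[retained],
            "clm_sum": clm[retained],
            "zc_raw": zc_raw,
            "zc_rescaled": zc_rescaled,
        },
        index=idx,
    )


def bin_layers(result: pd.DataFrame, merge_extremes: bool = True) -> pd.DataFrame:
    """Assign lobule layers from rescaled ZCs.

    Decile bins: L_k covers [0.1(k-1), 0.1k) for k = 1..9 and L10 covers
    [0.9, 1.0] — the upper end is closed so the binning is total on [0, 1].
    With ``merge_extremes`` the sparse poles are grouped into L1-L3 and
    L8-L10 in an extra ``layer_merged`` column.
    """
    zc = result["zc_rescaled"].to_numpy(float)
    if np.any((zc < 0) | (zc > 1)):
        raise ValidationError("rescaled ZC outside [0, 1]")
    k = np.minimum(np.floor(zc * 10).astype(int) + 1, 10)
    out = result.copy()
    out["layer"] = [f"L{i}" for i in k]
    if merge_extremes:
        merged = np.where(k <= 3, "L1-L3", np.where(k >= 8, "L8-L10", ""))
        merged = np.where(merged == "", [f"L{i}" for i in k], merged)
        out["layer_merged"] = pd.Categorical(merged, categories=MERGED_LEVELS, ordered=True)
    return out


def group_zone(result: pd.DataFrame) -> pd.DataFrame:
    """Group layers into pericentral (L1-L5) and periportal (L6-L10) zones."""
    if "layer" not in result.columns:
        raise ValidationError("bin_layers must run before group_zone")
    k = result["layer"].str.lstrip("L").astype(int)
    out = result.copy()
    out["zone"] = np.where(k <= 5, "central", "portal")
    return out


# ---------------------------------------------------------------------------
# Proximity and landmark clustering


def assign_proximity(
    exp: FragmentExperiment,
    landmark_type: str = "metastatic",
    min_cells_per_fragment: int = 5,
    min_landmark_cells_per_sample: int = 20,
) -> pd.DataFrame:
    """Label fragments proximal/distal by presence of a landmark cell type.

    Samples with fewer than ``min_landmark_cells_per_sample`` landmark cells
    overall are excluded (low tumor burden); fragments below the cell-count
    cutoff are excluded; a retained fragment is "proximal" iff it contains
    at least one landmark cell.
    """
    cells = exp.cells[~exp.cells["fragment"].isin(SENTINELS)]
    lm_per_sample = (
        (cells["cell_type"] == landmark_type).groupby(cells["sample"]).sum()
    )
    good_samples = lm_per_sample[lm_per_sample >= min_landmark_cells_per_sample].index
    cells = cells[cells["sample"].isin(good_samples)]
    sizes = cells.groupby("fragment").size()
    keep = sizes[sizes >= min_cells_per_fragment].index
    cells = cells[cells["fragment"].isin(keep)]
    has_lm = (cells["cell_type"] == landmark_type).groupby(cells["fragment"]).any()
    out = pd.DataFrame(index=pd.Index(sorted(keep), name="fragment"))
    out["proximity"] = np.where(has_lm.reindex(out.index).fillna(False), "proximal", "distal")
    out["n_cells"] = sizes.reindex(out.index)
    return out


def landmark_cluster_fragments(
    exp: FragmentExperiment,
    landmark_genes: list[str],
    n_pcs: int = 10,
    k_range: tuple[int, int] = (2, 6),
    min_cells: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster fragment pseudobulks on a small landmark-gene panel.

    Mean-mode pseudobulks over all cells are restricted to the landmark
    genes, scaled to unit variance, projected to ``min(n_pcs, rank)``
    principal components, and partitioned with k-means; k is chosen from
    ``k_range`` by silhouette score.  Deterministic under ``seed``.
    """
    pb = fragment_pseudobulk(exp, cell_type=None, min_cells=min_cells, mode="mean")
    missing = [g for g in landmark_genes if g not in pb.columns]
    if missing:
        raise ValidationError(f"landmark genes not measured: {missing[:5]}")
    X = pb[landmark_genes].to_numpy(float)
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 fragments to cluster")
    X = StandardScaler().fit_transform(X)
    rank = min(X.shape[0] - 1, X.shape[1])
    ncomp = min(n_pcs, rank)
    if ncomp < n_pcs:
        warnings.warn(f"components truncated to {ncomp} (matrix rank)")
    Z = PCA(n_components=ncomp, random_state=seed).fit_transform(X)
    if np.allclose(Z.std(axis=0), 0):
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        best_k, best_s, best_labels = 1, -np.inf, np.zeros(X.shape[0], dtype=int)
        for k in range(k_range[0], min(k_range[1], X.shape[0] - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
            if len(set(km.labels_)) < 2:
                continue
            s = silhouette_score(Z, km.labels_)
            if s > best_s:
                best_k, best_s, best_labels = k, s, km.labels_
        labels = best_labels
    out = pd.DataFrame(index=pb.index)
    out["cluster"] = [f"cluster{i + 1}" for i in labels]
    return out


# ---------------------------------------------------------------------------
# Spot allocation (deconvolved slice-based data)


def allocate_spot_celltype(weights: pd.DataFrame, threshold: float = 0.75) -> pd.Series:
    """Label deconvolved spots: the argmax cell type if its fraction reaches
    ``threshold`` (default 75%), else ``mixed``.  Ties break to the
    first-listed type with a warning."""
    W = weights.to_numpy(float)
    sums = W.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 0.01):
        raise ValidationError("deconvolution fractions must sum to 1 (±1%) per spot")
    arg = W.argmax(axis=1)
    ties = (W == W.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} spots with tied top fractions; first type wins")
    top = W.max(axis=1)
    labels = np.where(top >= threshold, weights.columns.to_numpy()[arg], "mixed")
    return pd.Series(labels, index=weights.index, name="cell_type")
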