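"""Synthetic fragment-based single-cell and spatial data with known truth.

The generators emulate the statistical structure of fragment-based
dissociation experiments on the metastatic mouse liver:

* per-fragment zonation coordinates (ZC) on the central(0)-portal(1) lobule
  axis, with landmark genes expressed in liver endothelial cells (LECs) as
  two opposed monotone gradients;
* niche-dependent cell-type composition — fragments proximal to a
  metastatic site carry metastatic cells and more macrophages/monocytes,
  and fewer Kupffer cells (KCs) and LECs, than distal fragments;
* per-cell hashing-barcode counts with doublet and negative contamination;
* biosorter readouts where time-of-flight (TOF) is linear in fragment size
  plus noise;
* 2-D segmented-cell point patterns with planted type-type attraction for
  the colocalization test.

Expression counts are negative binomial (variance mu + alpha*mu^2);
hashing counts are Poisson.  Every generator is deterministic under its
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    NEGATIVE,
    CountMatrix,
    FragmentExperiment,
    ValidationError,
    make_cell_annotation,
    make_fragment_table,
)

#: Composition (cell-type fractions) of metastasis-distal fragments.
DISTAL_COMPOSITION = {
    "LEC": 0.40,
    "KC": 0.37,
    "mac_mono": 0.04,
    "T": 0.12,
    "B": 0.07,
    "metastatic": 0.00,
}
#: Composition of metastasis-proximal fragments: metastatic cells appear,
#: macrophages/monocytes are enriched, KCs and LECs are depleted.
PROXIMAL_COMPOSITION = {
    "LEC": 0.30,
    "KC": 0.27,
    "mac_mono": 0.20,
    "T": 0.09,
    "B": 0.05,
    "metastatic": 0.09,
}


@dataclass
class ZonatedGeneSpec:
    """A gene whose log-mean in ``cell_type`` is linear in the true ZC."""

    gene: str
    cell_type: str
    slope: float  # log-mean change per unit ZC; >0 = portal, <0 = central
    base_mean: float = 5.0  # mean counts/cell at ZC = 0.5


@dataclass
class LobuleSimConfig:
    n_fragments: int = 200
    n_samples: int = 3
    cells_per_fragment_mean: float = 30.0
    cells_per_fragment_dispersion: float = 5.0  # NB size parameter
    proximal_fraction: float = 0.3
    composition_distal: dict = field(default_factory=lambda: dict(DISTAL_COMPOSITION))
    composition_proximal: dict = field(default_factory=lambda: dict(PROXIMAL_COMPOSITION))
    n_landmarks_per_zone: int = 20
    landmark_base_mean: float = 5.0
    landmark_slope: float = 2.0  # magnitude of the log-linear ZC gradient
    zonated_genes: list = field(default_factory=list)  # list[ZonatedGeneSpec]
    n_background_genes: int = 30
    background_mean: float = 2.0
    nb_dispersion: float = 0.3  # alpha in var = mu + alpha mu^2
    # hashing
    hash_signal_mean: float = 500.0
    hash_background_mean: float = 5.0
    doublet_rate: float = 0.05
    negative_rate: float = 0.02
    # biosorter
    size_lo: float = 200.0
    size_hi: float = 450.0
    tof_slope: float = 2.0
    tof_intercept: float = 10.0
    tof_noise_sd: float = 5.0
    # ZC prior: "uniform" or "truncnorm" (sparse extreme layers)
    zc_prior: str = "uniform"
    seed: int = 0

    def validate(self) -> None:
        if self.n_fragments < 1:
            raise ValidationError("n_fragments must be >= 1")
        for rate in (self.proximal_fraction, self.doublet_rate, self.negative_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        for mean in (
            self.cells_per_fragment_mean,
            self.landmark_base_mean,
            self.hash_signal_mean,
        ):
            if mean <= 0:
                raise ValidationError("means must be positive")
        if not (0 < self.size_lo < self.size_hi < 1000):
            raise ValidationError("size range must satisfy 0 < lo < hi < 1000 um")
        if self.n_landmarks_per_zone + self.n_background_genes + len(self.zonated_genes) == 0:
            raise ValidationError("empty gene panel")


@dataclass
class GroundTruth:
    zc: pd.Series  # per-fragment true ZC in [0, 1]
    proximity: pd.Series  # per-fragment "proximal" / "distal"
    cell_fragment: pd.Series  # per-cell true fragment id
    cell_type: pd.Series  # per-cell true type
    zonated_genes: list  # list[ZonatedGeneSpec], landmark genes included
    hashing_call: pd.Series | None = None  # per-cell truth after contamination


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mu + alpha mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=mean * alpha)
    return rng.poisson(lam)


def landmark_gene_names(cfg: LobuleSimConfig) -> tuple[list[str], list[str]]:
    central = [f"cLM{i:02d}" for i in range(1, cfg.n_landmarks_per_zone + 1)]
    portal = [f"pLM{i:02d}" for i in range(1, cfg.n_landmarks_per_zone + 1)]
    return central, portal


def _gene_panel(cfg: LobuleSimConfig) -> list[ZonatedGeneSpec]:
    """Full panel as zonated-gene specs (background genes have slope 0)."""
    central, portal = landmark_gene_names(cfg)
    panel = [
        ZonatedGeneSpec(g, "LEC", -cfg.landmark_slope, cfg.landmark_base_mean)
        for g in central
    ]
    panel += [
        ZonatedGeneSpec(g, "LEC", +cfg.landmark_slope, cfg.landmark_base_mean)
        for g in portal
    ]
    panel += list(cfg.zonated_genes)
    names = {g.gene for g in panel}
    for i in range(1, cfg.n_background_genes + 1):
        name = f"BG{i:03d}"
        if name not in names:
            panel.append(ZonatedGeneSpec(name, "*", 0.0, cfg.background_mean))
    return panel


def simulate_lobule_experiment(
    cfg: LobuleSimConfig,
) -> tuple[FragmentExperiment, GroundTruth]:
    """Simulate a full fragment experiment with known zonation truth.

    Counts for a planted gene in its cell type are NB with
    ``log mean = log(base_mean) + slope * (ZC - 0.5)``; in other cell types
    the gene is expressed at 10% of its base mean with no gradient.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fragments

    frag_ids = [f"F{i:04d}" for i in range(1, n + 1)]
    samples = [f"S{1 + i % cfg.n_samples}" for i in range(n)]
    if cfg.zc_prior == "truncnorm":
        zc = np.clip(rng.normal(0.5, 0.18, size=n), 0.0, 1.0)
    else:
        zc = rng.uniform(0.0, 1.0, size=n)
    proximal = rng.uniform(size=n) < cfg.proximal_fraction
    proximity = np.where(proximal, "proximal", "distal")

    # fragment sizes and sorter readouts
    sizes = rng.uniform(cfg.size_lo, cfg.size_hi, size=n)
    tof = cfg.tof_slope * sizes + cfg.tof_intercept + rng.normal(0, cfg.tof_noise_sd, n)
    extinction = 0.5 * tof + rng.normal(0, cfg.tof_noise_sd, n)

    # cells per fragment (NB, at least 1)
    ncells = 1 + _nb_draws(
        rng,
        np.full(n, cfg.cells_per_fragment_mean - 1),
        1.0 / cfg.cells_per_fragment_dispersion,
    )

    types = sorted(set(cfg.composition_distal) | set(cfg.composition_proximal))
    comp_d = np.array([cfg.composition_distal.get(t, 0.0) for t in types], float)
    comp_p = np.array([cfg.composition_proximal.get(t, 0.0) for t in types], float)
    comp_d /= comp_d.sum()
    comp_p /= comp_p.sum()

    cell_frag: list[str] = []
    cell_type: list[str] = []
    cell_zc: list[float] = []
    for i in range(n):
        comp = comp_p if proximal[i] else comp_d
        drawn = rng.choice(len(types), size=ncells[i], p=comp)
        cell_frag.extend([frag_ids[i]] * ncells[i])
        cell_type.extend(types[j] for j in drawn)
        cell_zc.extend([zc[i]] * ncells[i])
    n_cells_total = len(cell_frag)
    cell_ids = [f"C{i:06d}" for i in range(1, n_cells_total + 1)]
    cell_type_arr = np.array(cell_type)
    cell_zc_arr = np.array(cell_zc)

    panel = _gene_panel(cfg)
    genes = [g.gene for g in panel]
    rows = []
    for spec in panel:
        mu = np.full(n_cells_total, 0.1 * spec.base_mean)
        if spec.cell_type == "*":
            mu[:] = spec.base_mean
        else:
            in_type = cell_type_arr == spec.cell_type
            mu[in_type] = spec.base_mean * np.exp(spec.slope * (cell_zc_arr[in_type] - 0.5))
        rows.append(sp.csr_matrix(_nb_draws(rng, mu, cfg.nb_dispersion)))
    counts = sp.vstack(rows, format="csr")

    cm = CountMatrix(genes, cell_ids, counts)
    frag_sample = dict(zip(frag_ids, samples))
    cells = make_cell_annotation(
        cell_ids,
        sample=[frag_sample[f] for f in cell_frag],
        fragment=cell_frag,
        cell_type=cell_type,
    )
    fragments = make_fragment_table(
        frag_ids,
        well=[f"W{i:03d}" for i in range(1, n + 1)],
        sample=samples,
        tof=tof,
        extinction=extinction,
    )
    exp = FragmentExperiment(cm, cells, fragments).recount_fragments()

    truth = GroundTruth(
        zc=pd.Series(zc, index=frag_ids, name="zc"),
        proximity=pd.Series(proximity, index=frag_ids, name="proximity"),
        cell_fragment=pd.Series(cell_frag, index=cell_ids, name="fragment"),
        cell_type=pd.Series(cell_type, index=cell_ids, name="cell_type"),
        zonated_genes=panel[: 2 * cfg.n_landmarks_per_zone] + list(cfg.zonated_genes),
    )
    return exp, truth


def simulate_landmark_panel(cfg: LobuleSimConfig, n_layers: int = 10) -> pd.DataFrame:
    """Reference per-layer landmark profiles matching the generative model.

    Layer k's mean is the model's expected expression at the ZC midpoint of
    layer k, scaled to expression fractions; SEMs are a small fixed fraction
    of the mean.  Returns the TSV-schema frame consumed by
    :func:`fragseq.zonation.read_landmark_panel` users: columns ``gene``,
    ``zone``, ``L1..L{n} mean``, ``L1..L{n} sem``.
    """
    central, portal = landmark_gene_names(cfg)
    mids = (np.arange(n_layers) + 0.5) / n_layers
    rows = []
    for zone, names, sign in (("central", central, -1), ("portal", portal, +1)):
        for g in names:
            prof = np.exp(sign * cfg.landmark_slope * (mids - 0.5))
            prof = prof / prof.sum() * 1e-3  # expression-fraction scale
            row = {"gene": g, "zone": zone}
            for k in range(n_layers):
                row[f"L{k + 1}_mean"] = prof[k]
                row[f"L{k + 1}_sem"] = 0.05 * prof[k]
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_hashing_counts(
    truth: GroundTruth, cfg: LobuleSimConfig, barcode_per_fragment: dict | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Hashing-barcode x cell counts with doublet/negative contamination.

    The assigned barcode is Poisson(signal); all others Poisson(background).
    A ``doublet_rate`` fraction of cells receives a second signal barcode; a
    ``negative_rate`` fraction receives background only.  Returns the count
    matrix plus a copy of the truth with per-cell hashing calls filled in
    ("F…" for clean singlets, "DOUBLET", "NEGATIVE").
    """
    rng = np.random.default_rng(cfg.seed + 1)
    frag_ids = list(truth.zc.index)
    n_frags = len(frag_ids)
    if barcode_per_fragment is None:
        # default: barcode rows named by their fragment, so classification
        # calls are directly comparable with the truth
        barcode_per_fragment = {f: f for f in frag_ids}
    if len(set(barcode_per_fragment.values())) < n_frags:
        raise ValidationError("more fragments than barcodes")
    barcodes = [barcode_per_fragment[f] for f in frag_ids]
    bc_index = {b: i for i, b in enumerate(barcodes)}

    cell_ids = list(truth.cell_fragment.index)
    n_cells = len(cell_ids)
    frag_of_cell = truth.cell_fragment.to_numpy()
    own = np.array([bc_index[barcode_per_fragment[f]] for f in frag_of_cell])

    counts = rng.poisson(cfg.hash_background_mean, size=(n_frags, n_cells))
    u = rng.uniform(size=n_cells)
    negative = u < cfg.negative_rate
    doublet = (~negative) & (u < cfg.negative_rate + cfg.doublet_rate)
    signal = rng.poisson(cfg.hash_signal_mean, size=n_cells)
    keep = ~negative
    counts[own[keep], np.arange(n_cells)[keep]] += signal[keep]
    second = rng.integers(0, n_frags, size=n_cells)
    second = np.where(second == own, (second + 1) % max(n_frags, 1), second)
    extra = rng.poisson(cfg.hash_signal_mean, size=n_cells)
    idx = np.arange(n_cells)[doublet]
    counts[second[doublet], idx] += extra[doublet]

    call = np.array(frag_of_cell, dtype=object)
    call[negative] = NEGATIVE
    call[doublet] = "DOUBLET"
    truth_out = replace(
        truth, hashing_call=pd.Series(call, index=cell_ids, name="hashing_call")
    )
    cm = CountMatrix(barcodes, cell_ids, sp.csr_matrix(counts))
    return cm, truth_out


def simulate_species_mixing(
    n_fragments: int = 100,
    cells_per_fragment: int = 20,
    mismatch_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species-mixing wells: half mouse, half human; each cell's species
    flips with ``mismatch_rate``.  Returns (cell annotation with species
    truth, fragment table with per-well expected species column
    ``well_species``)."""
    if not 0.0 <= mismatch_rate < 1.0 + 1e-12:
        raise ValidationError("mismatch_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frag_ids = [f"F{i:04d}" for i in range(1, n_fragments + 1)]
    well_species = np.array(
        ["mouse" if i < n_fragments / 2 else "human" for i in range(n_fragments)]
    )
    cell_ids, cell_frag, cell_species = [], [], []
    k = 0
    for i, f in enumerate(frag_ids):
        for _ in range(cells_per_fragment):
            k += 1
            cell_ids.append(f"C{k:06d}")
            cell_frag.append(f)
            sp_true = well_species[i]
            if rng.uniform() < mismatch_rate:
                sp_true = "human" if sp_true == "mouse" else "mouse"
            cell_species.append(sp_true)
    cells = make_cell_annotation(
        cell_ids, sample="S1", fragment=cell_frag, species=cell_species
    )
    fragments = make_fragment_table(frag_ids, sample="S1")
    fragments["well_species"] = well_species
    fragments["n_cells"] = cells.groupby("fragment").size().reindex(frag_ids).fillna(0).astype(int)
    return cells, fragments


def simulate_point_pattern(
    n_cells_per_type: dict,
    roi_size: float = 300.0,
    attraction_pairs: list | None = None,
    n_rois: int = 2,
    group_labels: tuple[str, str] = ("distal", "proximal"),
    attract_in_group: str | None = None,
    n_slides: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Segmented-cell map over square ROIs with optional planted attraction.

    ``attraction_pairs`` is a list of ``(type_a, type_b, fraction_paired,
    pair_distance_um)``: in ROIs of group ``attract_in_group`` (default: the
    second group label) the stated fraction of B cells is placed uniformly
    within ``pair_distance`` of a random A cell instead of uniformly in the
    ROI.  Returns a cell table with columns x, y, cell_type, roi, group,
    slide.
    """
    rng = np.random.default_rng(seed)
    attraction_pairs = attraction_pairs or []
    for _, _, frac, dist in attraction_pairs:
        if dist >= roi_size:
            raise ValidationError("pair_distance must be smaller than the ROI extent")
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("fraction_paired must lie in [0, 1]")
    if attract_in_group is None:
        attract_in_group = group_labels[1]

    rows = []
    roi_counter = 0
    for s in range(1, n_slides + 1):
        for group in group_labels:
            for _ in range(n_rois):
                roi_counter += 1
                roi = f"ROI{roi_counter:03d}"
                # ROIs are laid out on disjoint translated squares
                x0 = roi_counter * (roi_size * 2.0)
                placed: dict[str, np.ndarray] = {}
                for ctype, n_c in n_cells_per_type.items():
                    xy = rng.uniform(0, roi_size, size=(n_c, 2))
                    placed[ctype] = xy
                if group == attract_in_group:
                    for ta, tb, frac, dist in attraction_pairs:
                        if ta not in placed or tb not in placed:
                            continue
                        nb = placed[tb].shape[0]
                        n_pair = int(round(frac * nb))
                        if n_pair == 0 or placed[ta].shape[0] == 0:
                            continue
                        anchors = placed[ta][rng.integers(0, placed[ta].shape[0], n_pair)]
                        r = dist * np.sqrt(rng.uniform(size=n_pair))
                        theta = rng.uniform(0, 2 * math.pi, size=n_pair)
                        off = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
                        placed[tb][:n_pair] = np.clip(anchors + off, 0, roi_size)
                for ctype, xy in placed.items():
                    for px, py in xy:
                        rows.append(
                            {
                                "x": px + x0,
                                "y": py,
                                "cell_type": ctype,
                                "roi": roi,
                                "group": group,
                                "slide": f"slide{s}",
                            }
                        )
    df = pd.DataFrame(rows)
    df.index = [f"cell{i:06d}" for i in range(1, len(df) + 1)]
    df.index.name = "cell"
    return df


def simulate_null_pseudobulk(
    n_units: int,
    n_genes: int,
    mean: float = 50.0,
    dispersion: float = 0.2,
    n_samples: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Null fragments x genes pseudobulk for test calibration.

    All genes share one NB law with no covariate effect; library sizes vary
    two-fold across units.  Returns (counts frame, ordered layer labels,
    sample ids)."""
    rng = np.random.default_rng(seed)
    units = [f"F{i:04d}" for i in range(1, n_units + 1)]
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    libfac = rng.uniform(0.7, 1.4, size=n_units)
    mu = mean * libfac[:, None] * np.ones((1, n_genes))
    counts = _nb_draws(rng, mu, dispersion)
    df = pd.DataFrame(counts, index=units, columns=genes)
    levels = ["L1-L3", "L4", "L5", "L6", "L7", "L8-L10"]
    layers = pd.Series([levels[i % 6] for i in range(n_units)], index=units)
    samples = pd.Series([f"S{1 + i % n_samples}" for i in range(n_units)], index=units)
    return df, layers, samples
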