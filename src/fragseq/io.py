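"""Domain types and readers/writers for the formats the pipeline touches.

The central in-memory objects are:

* :class:`CountMatrix` — a sparse genes x cells (or barcodes x cells,
  segments x genes …) UMI count matrix with identifier sidecars.
* cell annotation — a :class:`pandas.DataFrame` indexed by cell id with
  columns ``sample``, ``fragment``, ``cell_type`` and optionally
  ``species``.  Fragment ids are opaque strings; the reserved sentinels
  :data:`NEGATIVE`, :data:`DOUBLET` and :data:`UNASSIGNED` mark cells that
  could not be placed in a fragment and are excluded from all per-fragment
  statistics.
* fragment table — a :class:`pandas.DataFrame` indexed by fragment id with
  sorter metadata (``well``, ``sample``, ``tof``, ``extinction``,
  ``fluorescence``), the derived ``size`` (µm diameter), ``n_cells`` and
  optional niche labels (``layer``, ``zone``, ``proximity``, ``cluster``).
* :class:`FragmentExperiment` — the bundle of all three.

On disk, count matrices are MatrixMarket coordinate files (1-based, per the
standard) with one-column TSV sidecars for gene and cell identifiers; all
in-memory indices are 0-based.  Tables are UTF-8 CSV/TSV with header rows
and LF line endings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

NEGATIVE = "NEGATIVE"
DOUBLET = "DOUBLET"
UNASSIGNED = "UNASSIGNED"
#: Reserved fragment-id strings; never valid fragment identifiers.
SENTINELS = frozenset({NEGATIVE, DOUBLET, UNASSIGNED})

#: Optional niche-label columns of a fragment table.
NICHE_COLUMNS = ("layer", "zone", "proximity", "cluster")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# CountMatrix


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, genes x cells."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell identifiers")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cells)}

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index()
        cols = [idx[c] for c in cells]
        return CountMatrix(list(self.genes), list(cells), self.counts[:, cols])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


def read_count_matrix(mtx_path, genes_path, cells_path) -> CountMatrix:
    """Read an MTX triplet file with gene/cell TSV sidecars."""
    for p in (mtx_path, genes_path, cells_path):
        if not Path(p).exists():
            raise FormatError(f"missing file: {p}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}")
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"dimension mismatch: {mtx_path} declares {mat.shape} but "
            f"sidecars have {len(genes)} genes / {len(cells)} cells"
        )
    if mat.data.size and (np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))):
        raise ValidationError(f"negative or non-integer entry in {mtx_path}")
    return CountMatrix(genes, cells, sp.csr_matrix(mat, dtype=np.int64))


def write_count_matrix(cm: CountMatrix, mtx_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts), field="integer")
    _write_id_column(genes_path, cm.genes)
    _write_id_column(cells_path, cm.cells)


def _read_id_column(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _write_id_column(path, ids: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# Cell annotation / fragment table


def make_cell_annotation(
    cell_ids: Sequence[str],
    sample: Sequence[str] | str,
    fragment: Sequence[str] | str = UNASSIGNED,
    cell_type: Sequence[str] | str = "unknown",
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a cell-annotation table indexed by unique cell id."""
    df = pd.DataFrame(index=pd.Index([str(c) for c in cell_ids], name="cell"))
    if df.index.has_duplicates:
        raise ValidationError("duplicate cell ids in annotation")
    df["sample"] = sample
    df["fragment"] = fragment
    df["cell_type"] = cell_type
    if species is not None:
        df["species"] = species
    return df


def make_fragment_table(
    fragment_ids: Sequence[str],
    well: Sequence[str] | None = None,
    sample: Sequence[str] | str = "S1",
    tof: Sequence[float] | None = None,
    extinction: Sequence[float] | None = None,
    fluorescence: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Build a fragment table indexed by unique fragment id."""
    ids = [str(f) for f in fragment_ids]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate fragment ids")
    bad = SENTINELS.intersection(ids)
    if bad:
        raise ValidationError(f"reserved sentinel used as fragment id: {sorted(bad)}")
    df = pd.DataFrame(index=pd.Index(ids, name="fragment"))
    df["well"] = well if well is not None else ids
    df["sample"] = sample
    df["tof"] = np.asarray(tof, dtype=float) if tof is not None else np.nan
    df["extinction"] = np.asarray(extinction, dtype=float) if extinction is not None else np.nan
    df["fluorescence"] = np.asarray(fluorescence, dtype=float) if fluorescence is not None else np.nan
    df["size"] = np.nan
    df["n_cells"] = 0
    for col in NICHE_COLUMNS:
        df[col] = pd.NA
    return df


def read_biosorter_export(
    path,
    well_col: str = "well",
    tof_col: str = "TOF",
    extinction_col: str = "extinction",
    fluorescence_col: str | None = "fluorescence",
    sample: str = "S1",
) -> pd.DataFrame:
    """Read a biosorter well export CSV into a fragment table.

    One row per sorted well; ``size`` and niche fields are left unset.
    Column names follow the quantities the sorter reports (TOF, extinction,
    fluorescence) and are configurable.
    """
    df = pd.read_csv(path)
    for col in (well_col, tof_col, extinction_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    wells = df[well_col].astype(str)
    if wells.duplicated().any():
        raise ValidationError(f"{path}: duplicate well id")
    fluo = None
    if fluorescence_col is not None and fluorescence_col in df.columns:
        fluo = df[fluorescence_col].to_numpy(dtype=float)
    return make_fragment_table(
        fragment_ids=wells.tolist(),
        well=wells.tolist(),
        sample=sample,
        tof=df[tof_col].to_numpy(dtype=float),
        extinction=df[extinction_col].to_numpy(dtype=float),
        fluorescence=fluo,
    )


def write_fragment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True, lineterminator="\n")


def read_fragment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="fragment")
    df.index = df.index.astype(str)
    for col in NICHE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df


def write_cell_annotation(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=True, lineterminator="\n")


def read_cell_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="cell")
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# Ligand-receptor database


@dataclass
class LRInteraction:
    id: str
    ligand: list[str]
    receptor: list[str]


@dataclass
class LRDatabase:
    """Known ligand-receptor pairs; components of multi-subunit complexes
    are semicolon-joined on disk and kept as ordered lists in memory."""

    interactions: list[LRInteraction] = field(default_factory=list)

    def __iter__(self):
        return iter(self.interactions)

    def __len__(self) -> int:
        return len(self.interactions)

    def ids(self) -> list[str]:
        return [i.id for i in self.interactions]


def read_lr_database(path) -> LRDatabase:
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        lig = _split_components(row["ligand"], path, row["id"])
        rec = _split_components(row["receptor"], path, row["id"])
        out.append(LRInteraction(str(row["id"]), lig, rec))
    return LRDatabase(out)


def write_lr_database(db: LRDatabase, path) -> None:
    rows = [
        {"id": i.id, "ligand": ";".join(i.ligand), "receptor": ";".join(i.receptor)}
        for i in db
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def _split_components(raw, path, iid) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        raise ValidationError(f"{path}: interaction {iid}: empty component field")
    parts = [p.strip() for p in str(raw).split(";")]
    if not parts or any(p == "" for p in parts):
        raise ValidationError(f"{path}: interaction {iid}: empty gene name in component list")
    return parts


# ---------------------------------------------------------------------------
# FragmentExperiment


@dataclass
class FragmentExperiment:
    """Gene x cell counts plus cell->fragment assignments and fragment metadata."""

    counts: CountMatrix
    cells: pd.DataFrame
    fragments: pd.DataFrame

    def assigned_cells(self) -> pd.DataFrame:
        """Cells carrying a real (non-sentinel) fragment id."""
        return self.cells[~self.cells["fragment"].isin(SENTINELS)]

    def recount_fragments(self) -> "FragmentExperiment":
        """Recompute ``n_cells`` from the annotation (in place; returns self)."""
        counts = self.assigned_cells().groupby("fragment").size()
        self.fragments["n_cells"] = (
            counts.reindex(self.fragments.index).fillna(0).astype(int)
        )
        return self


def validate_experiment(exp: FragmentExperiment) -> list[str]:
    """Return a list of cross-type invariant violations (empty iff consistent)."""
    violations: list[str] = []
    matrix_cells = set(exp.counts.cells)
    for cell in exp.cells.index:
        if cell not in matrix_cells:
            violations.append(f"annotated cell {cell!r} is not a matrix column")
    assigned = exp.cells.loc[~exp.cells["fragment"].isin(SENTINELS), "fragment"]
    known = set(exp.fragments.index)
    for frag in assigned.unique():
        if frag not in known:
            violations.append(f"cell references unknown fragment {frag!r}")
    recount = assigned.groupby(assigned).size()
    for frag in exp.fragments.index:
        expected = int(recount.get(frag, 0))
        actual = int(exp.fragments.at[frag, "n_cells"])
        if expected != actual:
            violations.append(
                f"fragment {frag!r}: n_cells={actual} but {expected} cells assigned"
            )
    sizes = exp.fragments["size"].dropna()
    for frag, size in sizes.items():
        if size <= 0:
            violations.append(f"fragment {frag!r}: non-positive size {size}")
    return violations
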