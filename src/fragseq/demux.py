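"""Hashing-barcode design and cell-to-fragment classification.

Fragments are labeled with fragment-specific lipid-anchored DNA barcodes
before pooling; each cell's fragment of origin is recovered from its
barcode UMI counts.  This module designs barcode sets under a minimum
pairwise Hamming-distance constraint, classifies cells as
POSITIVE/NEGATIVE/DOUBLET, attaches calls to an experiment, and scores
species-mixing control experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    DOUBLET,
    NEGATIVE,
    SENTINELS,
    UNASSIGNED,
    CountMatrix,
    FragmentExperiment,
    ValidationError,
)

_ALPHABET = np.array(list("ACGT"))


class CapacityError(RuntimeError):
    """The requested barcode set could not be constructed within budget."""


@dataclass
class BarcodeSet:
    sequences: list[str]
    length: int
    min_distance: int

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValidationError("duplicate barcode sequences")
        if any(len(s) != self.length for s in self.sequences):
            raise ValidationError("barcodes differ in length")
        d = min_pairwise_distance(self.sequences)
        if d is not None and d < self.min_distance:
            raise ValidationError(
                f"pairwise Hamming distance {d} below required {self.min_distance}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for i, s in enumerate(self.sequences, 1):
                fh.write(f">BC{i:03d}\n{s}\n")

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("barcode\tsequence\n")
            for i, s in enumerate(self.sequences, 1):
                fh.write(f"BC{i:03d}\t{s}\n")


def min_pairwise_distance(sequences: list[str]) -> int | None:
    """Minimum pairwise Hamming distance by the O(n^2 * L) direct check."""
    if len(sequences) < 2:
        return None
    arr = np.array([list(s) for s in sequences])
    best = arr.shape[1]
    for i in range(len(sequences) - 1):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
        best = min(best, int(d))
        if best == 0:
            break
    return best


def design_barcodes(
    n: int,
    length: int = 8,
    min_distance: int = 3,
    seed: int = 0,
    max_attempts: int | None = None,
) -> BarcodeSet:
    """Design ``n`` DNA barcodes of ``length`` nt with all pairwise Hamming
    distances >= ``min_distance``.

    Seeded random candidate generation with greedy rejection: a candidate is
    accepted iff it is at distance >= min_distance from every accepted code.
    Fails with :class:`CapacityError` once the attempt budget (default
    ``5000 * n``) is exhausted, and immediately for requests that exceed the
    Singleton bound ``4**(length - min_distance + 1)``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 1 <= min_distance <= length:
        raise ValidationError("need 1 <= min_distance <= length")
    if n > 4 ** (length - min_distance + 1):
        raise CapacityError(
            f"{n} codes of length {length} at distance {min_distance} exceed "
            f"the Singleton bound {4 ** (length - min_distance + 1)}"
        )
    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else 5000 * n
    accepted = np.empty((0, length), dtype=np.int8)
    attempts = 0
    while accepted.shape[0] < n:
        if attempts >= budget:
            raise CapacityError(
                f"search budget of {budget} candidates exhausted with "
                f"{accepted.shape[0]}/{n} codes accepted"
            )
        attempts += 1
        cand = rng.integers(0, 4, size=length, dtype=np.int8)
        if accepted.shape[0]:
            dists = (accepted != cand).sum(axis=1)
            if dists.min() < min_distance:
                continue
        accepted = np.vstack([accepted, cand])
    seqs = ["".join(_ALPHABET[row]) for row in accepted]
    return BarcodeSet(seqs, length, min_distance)


# ---------------------------------------------------------------------------
# Classification


@dataclass
class ClassificationResult:
    calls: pd.Series  # per-cell: fragment/barcode id, NEGATIVE, or DOUBLET
    thresholds: pd.Series  # per-barcode threshold on log1p counts
    quantile: float  # sweep quantile selected

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"call": self.calls})
        df["status"] = np.where(
            df["call"].isin([NEGATIVE, DOUBLET]), df["call"], "POSITIVE"
        )
        return df

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "cell"
        df["quantile"] = self.quantile
        df.to_csv(path, lineterminator="\n")


def _two_means(x: np.ndarray, iters: int = 25) -> tuple[float, float]:
    """1-D 2-means (Lloyd) returning (low, high) centers."""
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo, hi
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        low_mask = x <= mid
        if low_mask.all() or not low_mask.any():
            break
        nlo, nhi = float(x[low_mask].mean()), float(x[~low_mask].mean())
        if nlo == lo and nhi == hi:
            break
        lo, hi = nlo, nhi
    return lo, hi


def classify_cells(
    barcode_counts: CountMatrix,
    quantiles: np.ndarray | None = None,
) -> ClassificationResult:
    """Classify cells from a barcode x cell count matrix.

    Per barcode, the log1p counts are split into a background and a signal
    component (1-D 2-means); candidate thresholds are quantiles
    q in {0.10, 0.15, …, 0.90} of the interval between the two component
    centers.  The single q maximizing the singlet (exactly one barcode
    above threshold) fraction is kept.  Calls: 0 barcodes above threshold →
    NEGATIVE, 1 → POSITIVE for that barcode, >=2 → DOUBLET.
    """
    if quantiles is None:
        quantiles = np.arange(0.10, 0.901, 0.05)
    X = np.log1p(np.asarray(barcode_counts.counts.todense(), dtype=float))
    n_bc, n_cells = X.shape
    if n_bc < 1 or n_cells < 1:
        raise ValidationError("need at least one barcode and one cell")
    if not np.any(X > 0):
        warnings.warn("all-zero barcode matrix: every cell called NEGATIVE")
        calls = pd.Series(NEGATIVE, index=barcode_counts.cells, name="call")
        thr = pd.Series(np.inf, index=barcode_counts.genes, name="threshold")
        return ClassificationResult(calls, thr, float(quantiles[0]))

    centers = np.array([_two_means(X[b]) for b in range(n_bc)])  # (n_bc, 2)
    lo, hi = centers[:, 0], centers[:, 1]
    best_q, best_frac, best_above = None, -1.0, None
    for q in quantiles:
        thr = lo + q * (hi - lo)
        above = X > thr[:, None]
        n_above = above.sum(axis=0)
        frac_singlet = float((n_above == 1).mean())
        if frac_singlet > best_frac:
            best_q, best_frac, best_above = float(q), frac_singlet, above
    thr = lo + best_q * (hi - lo)
    n_above = best_above.sum(axis=0)
    call = np.empty(n_cells, dtype=object)
    call[n_above == 0] = NEGATIVE
    call[n_above >= 2] = DOUBLET
    singlet_idx = np.flatnonzero(n_above == 1)
    which = best_above[:, singlet_idx].argmax(axis=0)
    barcodes = np.array(barcode_counts.genes, dtype=object)
    call[singlet_idx] = barcodes[which]
    calls = pd.Series(call, index=barcode_counts.cells, name="call")
    thresholds = pd.Series(thr, index=barcode_counts.genes, name="threshold")
    return ClassificationResult(calls, thresholds, best_q)


def attach_fragments(
    result: ClassificationResult,
    exp: FragmentExperiment,
    barcode_to_fragment: dict | None = None,
) -> FragmentExperiment:
    """Set cell->fragment assignments from classification calls.

    Cells absent from the hashing matrix become UNASSIGNED; NEGATIVE and
    DOUBLET calls are kept as sentinels.  ``n_cells`` is recomputed.
    """
    mapping = barcode_to_fragment or {}
    calls = result.calls

    def translate(call: str) -> str:
        if call in SENTINELS:
            return call
        return mapping.get(call, call)

    new_frag = pd.Series(UNASSIGNED, index=exp.cells.index, dtype=object)
    shared = exp.cells.index.intersection(calls.index)
    new_frag.loc[shared] = calls.loc[shared].map(translate)
    known = set(exp.fragments.index) | SENTINELS
    unknown = ~new_frag.isin(known)
    if unknown.any():
        new_frag[unknown] = UNASSIGNED
    exp.cells["fragment"] = new_frag
    return exp.recount_fragments()


# ---------------------------------------------------------------------------
# Species mixing


def score_species_mixing(
    cells: pd.DataFrame,
    fragments: pd.DataFrame,
    flip_threshold: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-fragment mismatch fraction and overall assignment accuracy.

    A cell is mismatched when its species differs from its well's expected
    species.  The flip rule is applied first: a fragment whose cells are
    100% mismatched (``flip_threshold`` of 1.0; configurable) has its well
    species flipped — such wells are attributed to a sorting error.
    Fragments with zero cells are excluded.
    """
    if "species" not in cells.columns:
        raise ValidationError("cell annotation lacks a species column")
    if "well_species" not in fragments.columns:
        raise ValidationError("fragment table lacks a well_species column")
    assigned = cells[~cells["fragment"].isin(SENTINELS)].copy()
    well = fragments["well_species"]
    assigned["well_species"] = assigned["fragment"].map(well)
    assigned = assigned.dropna(subset=["well_species"])

    frac = (
        (assigned["species"] != assigned["well_species"])
        .groupby(assigned["fragment"])
        .mean()
    )
    flipped = frac[frac >= flip_threshold].index
    flip_map = {"mouse": "human", "human": "mouse"}
    assigned.loc[assigned["fragment"].isin(flipped), "well_species"] = assigned.loc[
        assigned["fragment"].isin(flipped), "well_species"
    ].map(flip_map)

    mism = assigned["species"] != assigned["well_species"]
    per_frag = mism.groupby(assigned["fragment"]).mean().rename("mismatch_fraction")
    out = per_frag.to_frame()
    out["n_cells"] = assigned.groupby("fragment").size()
    out["flipped"] = out.index.isin(flipped)
    accuracy = float(1.0 - mism.mean()) if len(assigned) else float("nan")
    return out, accuracy


def normalize_fluorescence(
    table: pd.DataFrame, channel: str = "fluorescence"
) -> pd.DataFrame:
    """Add ``{channel}_norm`` = raw signal / fragment size (per µm).

    Larger fragments autofluoresce more; dividing by the size diameter puts
    wells on a comparable scale.
    """
    if channel not in table.columns:
        raise ValidationError(f"no channel {channel!r} in fragment table")
    size = table["size"]
    if size.isna().any() or (size <= 0).any():
        raise ValidationError("fragment size must be set and positive for all fragments")
    out = table.copy()
    out[f"{channel}_norm"] = out[channel] / size
    return out
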