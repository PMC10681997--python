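"""Ligand-receptor interaction scoring by cluster-label permutation.

For a sender and a receiver cell cluster within one niche group, an
interaction is *tested* only if every ligand component is expressed in more
than ``min_frac_expressing`` of sender cells and every receptor component
likewise in receiver cells.  Component expression is the mean normalized
expression (log1p of library-size-scaled counts) over the cluster's cells;
multi-subunit complexes are summarized by the minimum over components (the
limiting subunit).  The interaction score is

    score = (ligand_expression + receptor_expression) / 2

and its one-sided (enrichment) p-value comes from ``n_perm`` random
permutations of the cluster labels over the pooled sender+receiver cells:
p = (#{null >= observed} + 1) / (n_perm + 1), so p is never 0 and never
below 1/(n_perm+1).  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FragmentExperiment, LRDatabase, ValidationError


@dataclass
class InteractionScore:
    interaction_id: str
    sender: str
    receiver: str
    group: str
    tested: bool
    score: float | None = None
    p: float | None = None
    reason: str | None = None  # why an interaction was not tested


def normalize_expression(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log1p of library-size-scaled counts, per cell (columns)."""
    lib = counts.sum(axis=0, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * scale)


def score_interactions(
    exp: FragmentExperiment,
    db: LRDatabase,
    sender: str,
    receiver: str,
    group: str = "",
    min_frac_expressing: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    within_sample: bool = False,
) -> list[InteractionScore]:
    """Score every database interaction between two clusters of one group.

    ``exp`` should already be subset to the niche group of interest.  By
    default labels are permuted over the pooled cells; ``within_sample``
    restricts shuffles to each sample's cells.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    cells = exp.cells
    send_ids = cells.index[cells["cell_type"] == sender]
    recv_ids = cells.index[cells["cell_type"] == receiver]
    if len(send_ids) == 0 or len(recv_ids) == 0:
        raise ValidationError("both clusters must contain at least one cell")

    pool = list(send_ids) + list(recv_ids)
    n_s = len(send_ids)
    cidx = exp.counts.cell_index()
    cols = np.array([cidx[c] for c in pool])

    genes_needed = sorted(
        {g for i in db for g in i.ligand} | {g for i in db for g in i.receptor}
    )
    gidx = exp.counts.gene_index()
    present = [g for g in genes_needed if g in gidx]
    rows = np.array([gidx[g] for g in present]) if present else np.array([], int)
    # normalize on the full transcriptome, then restrict to needed genes
    sub_all = np.asarray(exp.counts.counts[:, cols].todense(), dtype=float)
    norm_all = normalize_expression(sub_all)
    norm = norm_all[rows] if rows.size else np.empty((0, len(pool)))
    expressed = sub_all[rows] > 0 if rows.size else np.empty((0, len(pool)), bool)
    gpos = {g: i for i, g in enumerate(present)}

    is_sender = np.zeros(len(pool), dtype=bool)
    is_sender[:n_s] = True

    def complex_expr(components: list[str], mask: np.ndarray) -> tuple[float, float]:
        """(min-over-components mean expression, min fraction expressing)."""
        means, fracs = [], []
        for g in components:
            r = gpos[g]
            means.append(norm[r, mask].mean())
            fracs.append(expressed[r, mask].mean())
        return min(means), min(fracs)

    rng = np.random.default_rng(seed)
    samples = cells.loc[pool, "sample"].to_numpy() if within_sample else None
    perm_masks = np.empty((n_perm, len(pool)), dtype=bool)
    for b in range(n_perm):
        if within_sample:
            perm = np.empty(len(pool), dtype=int)
            for s in np.unique(samples):
                idx = np.flatnonzero(samples == s)
                perm[idx] = idx[rng.permutation(len(idx))]
        else:
            perm = rng.permutation(len(pool))
        perm_masks[b] = is_sender[perm]

    out: list[InteractionScore] = []
    for inter in db:
        missing = [g for g in inter.ligand + inter.receptor if g not in gpos]
        if missing:
            out.append(
                InteractionScore(
                    inter.id, sender, receiver, group, tested=False,
                    reason=f"missing genes: {missing}",
                )
            )
            continue
        lig_expr, lig_frac = complex_expr(inter.ligand, is_sender)
        rec_expr, rec_frac = complex_expr(inter.receptor, ~is_sender)
        if lig_frac <= min_frac_expressing or rec_frac <= min_frac_expressing:
            out.append(
                InteractionScore(
                    inter.id, sender, receiver, group, tested=False,
                    reason="below min_frac_expressing",
                )
            )
            continue
        observed = 0.5 * (lig_expr + rec_expr)

        lrows = np.array([gpos[g] for g in inter.ligand])
        rrows = np.array([gpos[g] for g in inter.receptor])
        null = np.empty(n_perm)
        for b in range(n_perm):
            m = perm_masks[b]
            lig_null = norm[np.ix_(lrows, np.flatnonzero(m))].mean(axis=1).min()
            rec_null = norm[np.ix_(rrows, np.flatnonzero(~m))].mean(axis=1).min()
            null[b] = 0.5 * (lig_null + rec_null)
        p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
        out.append(
            InteractionScore(
                inter.id, sender, receiver, group, tested=True,
                score=float(observed), p=float(p),
            )
        )
    return out


def scores_to_frame(scores: list[InteractionScore]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "interaction": [s.interaction_id for s in scores],
            "sender": [s.sender for s in scores],
            "receiver": [s.receiver for s in scores],
            "group": [s.group for s in scores],
            "tested": [s.tested for s in scores],
            "score": [s.score if s.tested else np.nan for s in scores],
            "p": [s.p if s.tested else np.nan for s in scores],
            "reason": [s.reason for s in scores],
        }
    )
    return df.set_index("interaction")


def compare_groups(
    scores_a: list[InteractionScore], scores_b: list[InteractionScore]
) -> pd.DataFrame:
    """Paired comparison of two groups, ordered by decreasing score
    difference (B − A).  An interaction untested in one group enters with
    score 0 there, flagged by the ``tested_*`` columns."""
    fa, fb = scores_to_frame(scores_a), scores_to_frame(scores_b)
    if set(fa.index) != set(fb.index):
        raise ValidationError("score lists cover different interaction universes")
    fb = fb.reindex(fa.index)
    out = pd.DataFrame(index=fa.index)
    out["group_a"] = fa["group"]
    out["group_b"] = fb["group"]
    out["score_a"] = fa["score"].fillna(0.0)
    out["score_b"] = fb["score"].fillna(0.0)
    out["tested_a"] = fa["tested"]
    out["tested_b"] = fb["tested"]
    out["p_a"] = fa["p"]
    out["p_b"] = fb["p"]
    out["difference"] = out["score_b"] - out["score_a"]
    return out.sort_values("difference", ascending=False)


def recover_planted_interaction(
    comparison: pd.DataFrame, planted_id: str, top_k: int = 1
) -> dict:
    """Report whether a planted interaction ranks in the top k by group
    difference (simulation harness)."""
    if planted_id not in comparison.index:
        raise ValidationError(f"{planted_id!r} not in the comparison table")
    ranks = comparison["difference"].rank(ascending=False, method="min")
    rank = int(ranks.loc[planted_id])
    return {
        "interaction": planted_id,
        "rank": rank,
        "universe": len(comparison),
        "in_top_k": rank <= top_k,
        "difference": float(comparison.loc[planted_id, "difference"]),
    }
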