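"""Gene-set enrichment of CNA prevalence with a gene-label permutation null.

Genes are ranked by their CNA prevalence (fraction of patients with the
event at the gene's representative probe) and a weighted
Kolmogorov-Smirnov running-sum enrichment score (ES) is computed per gene
set, exactly as in expression GSEA.  Because a single group is profiled
(there is no phenotype to permute), the null distribution is built by
permuting gene labels: a null ES for a set of size m is the ES of a
uniformly random m-subset of the gene universe against the fixed ranking.
Significant sets must replicate across a random discovery/validation
split of the cohort (and optionally further strata) to be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .data_model import CohortDesign, GeneSetCollection

_NULL_CHUNK = 1024


@dataclass
class RankedGeneList:
    """Genes ordered by non-increasing score (CNA prevalence).

    Ties are broken by gene id so the ranking is deterministic.
    """

    gene_ids: np.ndarray
    scores: np.ndarray
    event: str = "gain"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.gene_ids.shape != self.scores.shape:
            raise ValueError("gene_ids and scores must have equal length")
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranking")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def positions_of(self, members) -> np.ndarray:
        index = pd.Index(self.gene_ids)
        pos = index.get_indexer(list(members))
        return np.sort(pos[pos >= 0])


def rank_genes(gene_results: pd.DataFrame, event: str = "gain") -> RankedGeneList:
    """Build a ranking from gene-level results (``collapse_to_genes``)."""
    df = gene_results.sort_values(
        ["prevalence", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return RankedGeneList(
        df["gene_id"].to_numpy(dtype=object),
        df["prevalence"].to_numpy(dtype=float),
        event=event,
    )


def _hit_weights(scores_at_hits: np.ndarray, weight_exponent: float) -> np.ndarray:
    w = np.abs(scores_at_hits) ** weight_exponent
    total = w.sum(axis=-1, keepdims=True)
    # all-zero scores among the hits: fall back to unweighted increments
    flat = total == 0
    if np.any(flat):
        w = np.where(flat, 1.0, w)
        total = np.where(flat, w.shape[-1], total)
    return w / total


def running_enrichment(
    ranked: RankedGeneList, members, weight_exponent: float = 1.0
) -> np.ndarray:
    """Full running-sum curve over the ranked list (for plots)."""
    n = len(ranked)
    pos = ranked.positions_of(members)
    if pos.size == 0:
        raise ValueError("gene set has no member in the ranked universe")
    if pos.size == n:
        raise ValueError("gene set equals the whole gene universe")
    increments = np.full(n, -1.0 / (n - pos.size))
    increments[pos] = _hit_weights(ranked.scores[pos], weight_exponent)
    return np.cumsum(increments)

def enrichment_score(
    ranked: RankedGeneList, members, weight_exponent: float = 1.0
) -> float:
    """Signed maximal deviation of the running sum from zero."""
    curve = running_enrichment(ranked, members, weight_exponent)
    return float(curve[int(np.argmax(np.abs(curve)))])


def _es_from_positions(
    pos: np.ndarray, scores: np.ndarray, n: int, weight_exponent: float
) -> np.ndarray:
    """ES for many same-size subsets given by their sorted hit positions.

    The running sum attains its extrema immediately before or after a hit,
    so only 2m break points per subset need evaluating.  ``pos`` is
    (B, m), sorted ascending along axis 1.
    """
    m = pos.shape[1]
    w = _hit_weights(scores[pos], weight_exponent)
    cum = np.cumsum(w, axis=1)
    miss_before = (pos - np.arange(m)) / (n - m)
    after = cum - miss_before
    before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cum[:, :-1]], axis=1
    ) - miss_before
    candidates = np.concatenate([after, before], axis=1)
    best = np.argmax(np.abs(candidates), axis=1)
    return candidates[np.arange(pos.shape[0]), best]


@dataclass
class EnrichmentResult:
    set_name: str
    n_members_in_universe: int
    ES: float
    p_value: float
    B: int


def gene_label_permutation_test(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    B: int = 20000,
    min_set_size: int = 15,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """One-sided positive-enrichment p-values by gene-label permutation.

    Null ES draws are shared across sets of equal effective size (the null
    depends on a set only through its size, so this is an exact
    optimization, not an approximation).  p = (1 + #{ES_null >= ES_obs})
    / (1 + B).
    """
    n = len(ranked)
    index = pd.Index(ranked.gene_ids)
    filtered: list[tuple[str, np.ndarray]] = []
    for name, members in collection.items():
        pos = index.get_indexer(members)
        pos = np.sort(pos[pos >= 0])
        if len(pos) >= min_set_size and len(pos) < n:
            filtered.append((name, pos))
    if not filtered:
        raise ValueError(
            f"no gene set has at least {min_set_size} members in the universe"
        )
    rng = np.random.default_rng(seed)
    sizes = sorted({len(pos) for _, pos in filtered})
    null_by_size: dict[int, np.ndarray] = {}
    for m in sizes:
        draws = np.empty(B)
        done = 0
        while done < B:
            chunk = min(_NULL_CHUNK, B - done)
            # m distinct uniform positions per row == permuted gene labels
            pos = np.argpartition(rng.random((chunk, n)), m, axis=1)[:, :m]
            pos.sort(axis=1)
            draws[done:done + chunk] = _es_from_positions(
                pos, ranked.scores, n, weight_exponent
            )
            done += chunk
        null_by_size[m] = draws
    records = []
    for name, pos in filtered:
        es = float(
            _es_from_positions(pos[None, :], ranked.scores, n, weight_exponent)[0]
        )
        null = null_by_size[len(pos)]
        p = (1.0 + np.sum(null >= es)) / (1.0 + B)
        records.append(
            {
                "set_name": name,
                "n_members_in_universe": len(pos),
                "ES": es,
                "p_value": p,
                "B": B,
            }
        )
    return pd.DataFrame.from_records(records)


def discovery_validation_split(
    design: CohortDesign, seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Random split of the tumor samples into discovery (ceil(n/2)) and
    validation (floor(n/2)) halves; disjoint and exhaustive."""
    tumors = design.tumors
    if len(tumors) < 2:
        raise ValueError("need at least 2 tumors to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tumors))
    n_disc = ceil(len(tumors) / 2)
    discovery = [tumors[i] for i in order[:n_disc]]
    validation = [tumors[i] for i in order[n_disc:]]
    return discovery, validation


def two_stage_report(*stages: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Gene sets with p < alpha (strict) in every supplied stage
    (discovery, validation, and optionally further strata)."""
    if not stages:
        raise ValueError("at least one stage of results is required")
    surviving: set[str] | None = None
    for stage in stages:
        hits = set(stage.loc[stage["p_value"] < alpha, "set_name"])
        surviving = hits if surviving is None else surviving & hits
    return sorted(surviving)
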