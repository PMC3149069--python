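"""Per-locus CNA prevalence statistics.

At each probe the number of patients carrying the event (gain or loss) is
modelled as Binomial(n, pi0), where the null probability pi0 is estimated
empirically as the genome-wide event rate: total event probe-cells divided
by (number of probes x number of samples).  Exact upper-tail p-values are
computed per locus and converted to Benjamini-Hochberg q-values across the
genome.  Gene-level results take, per gene, the probe with the highest
prevalence (equivalently the smallest p-value) as the representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    DEFAULT_FLANK,
    CallMatrix,
    GeneTable,
    ProbeMap,
    probes_by_gene,
)


@dataclass(frozen=True)
class EmpiricalNull:
    """Genome-wide event rate used as the binomial null probability."""

    pi0: float
    event: str
    total_event_probes: int
    n_probes: int
    n_samples: int


def estimate_empirical_null(
    calls: CallMatrix, sample_subset: list[str], event: str
) -> EmpiricalNull:
    """pi0 = (event probe-cells over the subset) / (probes x subset size)."""
    if not sample_subset:
        raise ValueError("empty sample subset")
    rows = calls.sample_indexer(sample_subset)
    events = calls.event_matrix(event)[rows]
    total = int(events.sum())
    n_probes = len(calls.probe_map)
    n_samples = len(sample_subset)
    return EmpiricalNull(
        pi0=total / (n_probes * n_samples),
        event=event,
        total_event_probes=total,
        n_probes=n_probes,
        n_samples=n_samples,
    )


def binomial_tail_p(k, n, pi0):
    """Exact upper tail P(X >= k) for X ~ Binomial(n, pi0).

    Evaluated through the regularized incomplete beta function, which is
    numerically stable for tail probabilities down to ~1e-300.  Accepts
    scalars or arrays (broadcast).
    """
    k = np.asarray(k)
    if (k < 0).any() or (k > np.asarray(n)).any():
        raise ValueError("require 0 <= k <= n")
    p = stats.binom.sf(k - 1, n, pi0)
    if np.ndim(p) == 0:
        return float(p)
    return p


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonized)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def storey_qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda (optional alternative to BH)."""
    p = np.asarray(pvalues, dtype=float)
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
    q = bh_qvalues(p) * pi0
    return np.minimum(q, 1.0)


def locus_prevalence_tests(
    calls: CallMatrix,
    subset: list[str],
    event: str,
    null: EmpiricalNull,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-probe prevalence, exact binomial p and FDR q over the genome.

    Returns a DataFrame with columns probe_id, k, n, prevalence, p_value,
    q_value, in probe-map order.
    """
    if null.event != event:
        raise ValueError("null was estimated for a different event type")
    rows = calls.sample_indexer(subset)
    events = calls.event_matrix(event)[rows]
    k = events.sum(axis=0).astype(int)
    n = len(subset)
    p = binomial_tail_p(k, n, null.pi0)
    if fdr_method == "bh":
        q = bh_qvalues(p)
    elif fdr_method == "storey":
        q = storey_qvalues(p)
    else:
        raise ValueError(f"unknown fdr method {fdr_method!r}")
    return pd.DataFrame(
        {
            "probe_id": calls.probe_map.probe_ids,
            "k": k,
            "n": n,
            "prevalence": k / n,
            "p_value": p,
            "q_value": q,
        }
    )


def collapse_to_genes(
    locus_results: pd.DataFrame,
    probe_map: ProbeMap,
    genes: GeneTable,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Collapse per-probe results to per-gene results.

    A probe belongs to a gene iff its position lies within the gene
    interval extended by ``flank`` bp (inclusive); probes overlapping
    several extended genes count for each of them.  Per gene the
    representative probe attains the maximum prevalence, ties broken by
    smaller genomic position; genes covered by no probe are omitted.
    """
    if len(locus_results) != len(probe_map):
        raise ValueError("locus results are not aligned to the probe map")
    prevalence = locus_results["prevalence"].to_numpy()
    assignment = probes_by_gene(probe_map, genes, flank)
    records = []
    for gid in genes.gene_ids:
        idx = assignment.get(gid)
        if idx is None:
            continue
        best = idx[int(np.argmax(prevalence[idx]))]  # argmax -> smallest position
        row = locus_results.iloc[best]
        records.append(
            {
                "gene_id": gid,
                "representative_probe": row["probe_id"],
                "n_probes": len(idx),
                "prevalence": row["prevalence"],
                "p_value": row["p_value"],
                "q_value": row["q_value"],
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id", "representative_probe", "n_probes",
            "prevalence", "p_value", "q_value",
        ],
    )
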