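"""Positional selection of CNAs relative to gene locations.

For each sample, TP counts the probes carrying the event (gain or loss)
and GP the subset of those lying within genes (extended by the promoter
flank).  Under the null hypothesis that CNAs fall at random with respect
to gene location, the expected G/T ratio equals the array's in-gene probe
fraction (40.64% for the 250K array: 104,256 of 256,554 autosomal
probes).  A mean G/T ratio below that fraction indicates purifying
selection pushing CNAs away from genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DEFAULT_FLANK,
    CallMatrix,
    GeneTable,
    ProbeMap,
    in_gene_mask,
)


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, str]
    statistic: float
    p_value: float
    test: str

    def summary(self) -> str:
        return (
            f"{self.test}: {self.groups[0]} vs {self.groups[1]}; "
            f"statistic = {self.statistic:.4g}, p = {self.p_value:.4g}"
        )


def compute_gt_metrics(
    calls: CallMatrix,
    probe_map: ProbeMap,
    genes: GeneTable,
    event: str,
    flank: int = DEFAULT_FLANK,
    sample_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample TP (event probes), GP (event probes inside extended
    genes) and their G/T ratio (NaN where TP = 0)."""
    mask = in_gene_mask(probe_map, genes, flank)
    ids = sample_subset if sample_subset is not None else list(calls.sample_ids)
    rows = calls.sample_indexer(ids)
    events = calls.event_matrix(event)[rows]
    tp = events.sum(axis=1).astype(int)
    gp = events[:, mask].sum(axis=1).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tp > 0, gp / np.maximum(tp, 1), np.nan)
    return pd.DataFrame(
        {"sample_id": ids, "TP": tp, "GP": gp, "gt_ratio": ratio}
    )


def null_gt_ratio(
    probe_map: ProbeMap, genes: GeneTable, flank: int = DEFAULT_FLANK
) -> float:
    """Fraction of probes inside extended genes: the no-selection G/T
    expectation."""
    return float(in_gene_mask(probe_map, genes, flank).mean())


def test_gt_vs_null(
    metrics: pd.DataFrame, r0: float, method: str = "t"
) -> GroupComparison:
    """Test whether per-sample G/T ratios deviate from the null fraction r0.

    ``method="t"`` (default): two-sided one-sample t test on the
    per-sample ratios (samples with TP = 0 excluded).  ``method="pooled"``:
    exact binomial test of the pooled GP count against Binomial(TP, r0).
    """
    if method == "t":
        ratios = metrics["gt_ratio"].dropna().to_numpy()
        if len(ratios) < 2:
            raise ValueError("need at least 2 samples with defined G/T ratio")
        if np.ptp(ratios) == 0 and ratios[0] == r0:
            return GroupComparison(("samples", "null"), 0.0, 1.0, "one_sample_vs_null")
        t, p = stats.ttest_1samp(ratios, r0)
        return GroupComparison(("samples", "null"), float(t), float(p), "one_sample_vs_null")
    if method == "pooled":
        tp = int(metrics["TP"].sum())
        gp = int(metrics["GP"].sum())
        if tp == 0:
            raise ValueError("no event probes in any sample")
        res = stats.binomtest(gp, tp, r0, alternative="two-sided")
        return GroupComparison(
            ("samples", "null"), gp / tp - r0, float(res.pvalue), "pooled_binomial_vs_null"
        )
    raise ValueError(f"unknown method {method!r}")


def compare_groups(
    metric_a, metric_b, labels: tuple[str, str] = ("A", "B")
) -> GroupComparison:
    """Welch two-sample two-sided t test on a per-sample metric
    (TP, GP or G/T ratio) between two groups."""
    a = np.asarray(pd.Series(metric_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(metric_b).dropna(), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # degenerate: both groups constant and equal
        return GroupComparison(labels, 0.0, 1.0, "welch_two_sample")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(labels, float(t), float(p), "welch_two_sample")
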