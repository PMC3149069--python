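"""Permutation-based global test for genome-wide CNA pattern differences.

For two groups of samples, each locus i contributes the standardized
difference of stabilized event proportions

    d_i = (p_1i - p_2i) / sqrt(p_1i (1 - p_1i) / n_1 + p_2i (1 - p_2i) / n_2)

with p_ji = (x_ji + 0.5) / n_j (0.5 added to the numerator to stabilize
empty loci; when x_ji = n_j the denominator becomes n_j + 1 so the
proportion stays inside (0, 1)).  The global statistic is
D = sum_i d_i^2; its null distribution comes from permuting group
membership among the pooled samples (group sizes preserved), which
automatically accounts for multiple comparisons and for the spatial
correlation of copy numbers between loci.  A matched-pairs variant swaps
the two members within each pair instead of relabelling freely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data_model import CallMatrix, CohortDesign

_PERM_CHUNK = 256


@dataclass
class GlobalTestResult:
    D_observed: float
    null_draws: np.ndarray
    B: int
    p_value: float
    event: str
    group_labels: tuple[str, str]
    n1: int
    n2: int
    method: str = "permutation"

    def summary(self) -> str:
        return (
            f"global CNA test ({self.event}): {self.group_labels[0]} "
            f"(n={self.n1}) vs {self.group_labels[1]} (n={self.n2}); "
            f"D = {self.D_observed:.4g}, p = {self.p_value:.4g} "
            f"({self.method}, B = {self.B})"
        )


@dataclass
class MatchedPairs:
    """Late/early sample pairs; each sample may appear at most once."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("a sample appears in more than one pair")


def stabilized_proportion(x, n):
    """(x + 0.5) / n, falling back to (x + 0.5) / (n + 1) where x = n so
    the result stays strictly inside (0, 1)."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    denom = np.where(x >= n, n + 1.0, n)
    return (x + 0.5) / denom


def standardized_difference(x1, n1, x2, n2, pooled: bool = False):
    """Per-locus standardized difference of two stabilized proportions.

    ``pooled=True`` uses the pooled-proportion variance estimate; the
    default is the unpooled two-sample form.  Accepts scalars or arrays.
    """
    if np.any(np.asarray(n1) < 1) or np.any(np.asarray(n2) < 1):
        raise ValueError("group sizes must be >= 1")
    p1 = stabilized_proportion(x1, n1)
    p2 = stabilized_proportion(x2, n2)
    if pooled:
        pbar = (np.asarray(x1) + np.asarray(x2) + 0.5) / (
            np.asarray(n1) + np.asarray(n2)
        )
        pbar = np.clip(pbar, 1e-12, 1 - 1e-12)
        var = pbar * (1 - pbar) * (1.0 / np.asarray(n1) + 1.0 / np.asarray(n2))
    else:
        var = p1 * (1 - p1) / np.asarray(n1) + p2 * (1 - p2) / np.asarray(n2)
    d = (p1 - p2) / np.sqrt(var)
    if np.ndim(d) == 0:
        return float(d)
    return d


def _d_statistic(x1, n1, x2, n2, pooled=False):
    d = standardized_difference(x1, n1, x2, n2, pooled=pooled)
    return np.sum(np.square(d), axis=-1)


def global_cna_test(
    calls: CallMatrix,
    group_a: list[str],
    group_b: list[str],
    event: str,
    B: int = 10000,
    seed: int | None = None,
    pooled: bool = False,
    method: str = "permutation",
    group_labels: tuple[str, str] = ("A", "B"),
) -> GlobalTestResult:
    """Two-group global test of genome-wide CNA pattern difference.

    ``method="permutation"`` draws B random relabellings (p-value with the
    add-one rule so it is never 0); ``method="exact"`` enumerates all
    distinct assignments of pooled samples to the two groups, feasible for
    small cohorts, and reports the exact permutation p-value.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    ev = calls.event_matrix(event)
    rows_a = calls.sample_indexer(group_a)
    rows_b = calls.sample_indexer(group_b)
    pooled_events = ev[np.concatenate([rows_a, rows_b])].astype(np.float64)
    n1, n2 = len(group_a), len(group_b)
    total = pooled_events.sum(axis=0)
    x1_obs = pooled_events[:n1].sum(axis=0)
    D_obs = float(_d_statistic(x1_obs, n1, total - x1_obs, n2, pooled=pooled))

    if method == "exact":
        combos = list(itertools.combinations(range(n1 + n2), n1))
        null = np.empty(len(combos))
        for j, combo in enumerate(combos):
            x1 = pooled_events[list(combo)].sum(axis=0)
            null[j] = _d_statistic(x1, n1, total - x1, n2, pooled=pooled)
        # the identity assignment is among the enumerated ones, so the
        # exact p-value is a plain tail fraction and is never 0
        p = float(np.mean(null >= D_obs - 1e-12))
        B_eff = len(combos)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(B)
        done = 0
        npool = n1 + n2
        while done < B:
            chunk = min(_PERM_CHUNK, B - done)
            sel = np.zeros((chunk, npool))
            for r in range(chunk):
                sel[r, rng.permutation(npool)[:n1]] = 1.0
            x1 = sel @ pooled_events
            null[done:done + chunk] = _d_statistic(
                x1, n1, total[None, :] - x1, n2, pooled=pooled
            )
            done += chunk
        p = (1.0 + np.sum(null >= D_obs)) / (1.0 + B)
        B_eff = B
    else:
        raise ValueError(f"unknown method {method!r}")

    return GlobalTestResult(
        D_observed=D_obs, null_draws=null, B=B_eff, p_value=p, event=event,
        group_labels=group_labels, n1=n1, n2=n2, method=method,
    )


def match_by_pack_years(design: CohortDesign, seed: int | None = None) -> MatchedPairs:
    """Pair each late-stage tumor with the unused early-stage tumor of
    closest smoking pack-years.

    Greedy matching in descending order of late-stage pack-years; exact
    ties among candidates are broken by a seeded draw.  Samples with
    missing pack-years are excluded.  The greedy total |difference| is not
    guaranteed optimal, but is deterministic and mirrors one-at-a-time
    clinical matching.
    """
    df = design.table
    tumors = df[(df["tissue"] == "tumor") & df["pack_years"].notna()]
    late = tumors[tumors["stage"] == "late"].sort_values(
        "pack_years", ascending=False, kind="mergesort"
    )
    early = tumors[tumors["stage"] == "early"]
    if len(late) == 0:
        raise ValueError("no late-stage tumors with pack-years available")
    if len(early) < len(late):
        raise ValueError("early-stage pool smaller than the late-stage group")
    rng = np.random.default_rng(seed)
    available = early[["sample_id", "pack_years"]].reset_index(drop=True)
    used = np.zeros(len(available), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for _, row in late.iterrows():
        delta = np.abs(
            available["pack_years"].to_numpy(dtype=float) - row["pack_years"]
        )
        delta[used] = np.inf
        best = np.flatnonzero(delta == delta.min())
        choice = int(best[0]) if len(best) == 1 else int(rng.choice(best))
        used[choice] = True
        pairs.append((row["sample_id"], available.loc[choice, "sample_id"]))
    return MatchedPairs(pairs)


def paired_global_test(
    calls: CallMatrix,
    pairs: MatchedPairs,
    event: str,
    B: int = 10000,
    seed: int | None = None,
    pooled: bool = False,
    method: str = "permutation",
    group_labels: tuple[str, str] = ("first", "second"),
) -> GlobalTestResult:
    """Matched-pairs global test.

    The D statistic is the same as in the unpaired test, computed between
    the two pair members' groups; the null swaps the two members within
    each pair independently with probability 1/2 (sign-flip permutation),
    preserving the pairing structure.  ``method="exact"`` enumerates all
    2^m swap patterns.
    """
    if not pairs.pairs:
        raise ValueError("no pairs")
    first_ids = [p[0] for p in pairs.pairs]
    second_ids = [p[1] for p in pairs.pairs]
    ev = calls.event_matrix(event)
    first = ev[calls.sample_indexer(first_ids)].astype(np.float64)
    second = ev[calls.sample_indexer(second_ids)].astype(np.float64)
    m = len(pairs.pairs)
    x1_obs = first.sum(axis=0)
    x2_obs = second.sum(axis=0)
    D_obs = float(_d_statistic(x1_obs, m, x2_obs, m, pooled=pooled))
    total = x1_obs + x2_obs

    if method == "exact":
        patterns = np.array(list(itertools.product([0.0, 1.0], repeat=m)))
        x1 = (1 - patterns) @ first + patterns @ second
        null = _d_statistic(x1, m, total[None, :] - x1, m, pooled=pooled)
        p = float(np.mean(null >= D_obs - 1e-12))
        B_eff = len(patterns)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(B)
        done = 0
        while done < B:
            chunk = min(_PERM_CHUNK, B - done)
            flips = rng.integers(0, 2, size=(chunk, m)).astype(np.float64)
            x1 = (1 - flips) @ first + flips @ second
            null[done:done + chunk] = _d_statistic(
                x1, m, total[None, :] - x1, m, pooled=pooled
            )
            done += chunk
        p = (1.0 + np.sum(null >= D_obs)) / (1.0 + B)
        B_eff = B
    else:
        raise ValueError(f"unknown method {method!r}")

    return GlobalTestResult(
        D_observed=D_obs, null_draws=null, B=B_eff, p_value=p, event=event,
        group_labels=group_labels, n1=m, n2=m, method=f"paired-{method}",
    )
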