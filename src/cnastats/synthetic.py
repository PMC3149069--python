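"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a germline -> early tumor -> late tumor design:
segmental (positionally contiguous) gains and losses whose per-genome
rates increase with disease progression, an array whose in-gene probe
fraction is configurable (40.64% by default, the 250K array value), an
optional odds penalty against placing segments over gene probes
(purifying positional selection), optional regional hotspots, and planted
CNA-enriched gene sets for benchmarking enrichment detection.

Observed copy numbers mix the tumor value with a diploid normal fraction
(contamination c), add i.i.d. Gaussian noise and floor at zero, so the
2.7/1.3 calling thresholds can be exercised under their design conditions
(true CN >= 3 / <= 1 with up to 30% contamination).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_FLANK,
    GAIN,
    CallMatrix,
    CohortDesign,
    CopyNumberMatrix,
    GeneSetCollection,
    GeneTable,
    ProbeMap,
    in_gene_mask,
    probes_by_gene,
)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort stratum: label, tissue/stage, size and event rates
    (expected CNA segments per genome)."""

    label: str
    tissue: str
    stage: str
    n_samples: int
    gain_rate: float
    loss_rate: float

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("event rates must be non-negative")


@dataclass(frozen=True)
class PlantedSet:
    set_name: str
    n_member_genes: int
    prevalence_boost: float


def default_group_specs() -> tuple[GroupSpec, ...]:
    """Cohort structure mirroring the study: 63 blood + 50 non-involved
    lung references, 246 early-stage and 25 late-stage tumors.

    Segment rates are chosen so that, with the default 20,000-probe axis
    and 50-probe mean segment length, the expected fraction of probes
    altered per genome matches the study's mean event-probe fractions
    (gains: ~0.28% germline, ~5.5% early, ~17.8% late; losses: ~0.37%,
    ~0.94%, ~1.7%).
    """
    return (
        GroupSpec("blood", "blood", "none", 63, 1.1, 1.5),
        GroupSpec("non_involved", "non_involved", "none", 50, 1.1, 1.5),
        GroupSpec("early_tumor", "tumor", "early", 246, 22.0, 3.8),
        GroupSpec("late_tumor", "tumor", "late", 25, 71.0, 6.9),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_probes: int = 20000
    n_chromosomes: int = 22
    gene_fraction: float = 0.4064
    group_specs: tuple[GroupSpec, ...] = field(default_factory=default_group_specs)
    segment_length_mean: int = 50
    selection_strength: float = 1.5
    hotspot_loci: tuple[tuple[str, int, float], ...] = ()
    planted_sets: tuple[PlantedSet, ...] = ()
    noise_sd: float = 0.2
    contamination: float = 0.0
    probe_spacing: int = 5000
    flank: int = DEFAULT_FLANK
    gene_block_period: int = 25

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_chromosomes <= 0:
            raise ValueError("counts must be positive")
        if self.n_chromosomes > 22:
            raise ValueError("at most 22 autosomes")
        if not 0 < self.gene_fraction <= 1:
            raise ValueError("gene_fraction must be in (0, 1]")
        if self.segment_length_mean < 1:
            raise ValueError("segment_length_mean must be >= 1")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must be in [0, 1)")


def simulate_probe_map_and_genes(
    config: SimulationConfig,
) -> tuple[ProbeMap, GeneTable]:
    """Evenly spaced probes on ``n_chromosomes`` autosomes, with genes
    tiling the axis so the realized fraction of probes inside extended
    gene bounds matches ``gene_fraction`` (cumulative rounding keeps the
    error below one probe per gene block)."""
    if config.flank >= config.probe_spacing:
        raise ValueError(
            "gene_fraction unreachable with given probe spacing: the flank "
            "extension spans neighbouring probes"
        )
    pad = (config.probe_spacing - config.flank) // 2
    per_chrom = np.full(config.n_chromosomes, config.n_probes // config.n_chromosomes)
    per_chrom[: config.n_probes % config.n_chromosomes] += 1
    if per_chrom.min() < 1:
        raise ValueError("more chromosomes than probes")
    probe_rows = []
    gene_rows = []
    f = config.gene_fraction
    period = config.gene_block_period
    cum = 0  # probes processed so far, across chromosomes
    gene_no = 0
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        k = int(per_chrom[c])
        positions = config.probe_spacing * np.arange(1, k + 1)
        for j in range(k):
            probe_rows.append((f"p{cum + j:06d}", chrom, int(positions[j])))
        start = 0
        while start < k:
            block = min(period, k - start)
            g = round(f * (cum + start + block)) - round(f * (cum + start))
            g = min(g, block)
            if g > 0:
                first, last = start, start + g - 1
                gene_rows.append(
                    (
                        f"g{gene_no:05d}",
                        chrom,
                        int(positions[first]) - pad,
                        int(positions[last]) + pad,
                    )
                )
                gene_no += 1
            start += block
        cum += k
    probe_map = ProbeMap(
        pd.DataFrame(probe_rows, columns=["probe_id", "chromosome", "position"])
    )
    genes = GeneTable(
        pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "start", "end"])
    )
    realized = in_gene_mask(probe_map, genes, config.flank).mean()
    if abs(realized - f) > 0.01:
        raise ValueError(
            f"gene_fraction unreachable: realized {realized:.4f}, target {f:.4f}"
        )
    return probe_map, genes


def _sample_design(config: SimulationConfig, rng: np.random.Generator) -> CohortDesign:
    rows = []
    tumor_patients: list[str] = []
    patient_no = 0
    for spec in config.group_specs:
        if spec.tissue == "tumor":
            for i in range(spec.n_samples):
                pid = f"pt{patient_no:04d}"
                patient_no += 1
                tumor_patients.append(pid)
    cursor = 0
    patient_iter = iter(tumor_patients)
    for spec in config.group_specs:
        for i in range(spec.n_samples):
            sid = f"{spec.label}_s{i:03d}"
            if spec.tissue == "tumor":
                pid = next(patient_iter)
                histology = "ACA" if rng.random() < 0.7 else "SCC"
                stage = spec.stage
            else:
                # pair references to tumor patients where available
                if cursor < len(tumor_patients):
                    pid = tumor_patients[cursor]
                    cursor += 1
                else:
                    pid = f"ref{spec.label}_{i:03d}"
                histology = "none"
                stage = "none"
            pack_years = round(float(rng.gamma(4.0, 10.0)), 1)
            rows.append((sid, spec.tissue, stage, histology, pack_years, pid))
    return CohortDesign(
        pd.DataFrame(rows, columns=list(CohortDesign.COLUMNS))
    )


def _start_weights(
    config: SimulationConfig, probe_map: ProbeMap
) -> np.ndarray:
    w = np.ones(len(probe_map))
    slices = probe_map.chromosome_slices()
    width = config.segment_length_mean
    for chrom, center, rel_rate in config.hotspot_loci:
        sl = slices[str(chrom)]
        lo = max(sl.start, sl.start + int(center) - width)
        hi = min(sl.stop, sl.start + int(center) + width + 1)
        w[lo:hi] *= rel_rate
    return w / w.sum()


def simulate_cohort(
    config: SimulationConfig,
    probe_map: ProbeMap,
    genes: GeneTable,
    return_truth: bool = False,
):
    """Draw a cohort of noisy copy-number profiles plus its design table.

    Per sample, segment counts are Poisson(group rate), segment lengths
    geometric with the configured mean, and segment starts are drawn
    proportionally to the hotspot weights; when the candidate start probe
    lies inside an extended gene it is accepted with probability
    1/selection_strength (selection acts on segment placement).  Gains
    set the true CN to 3 (4 with probability 0.1), losses to 1 (0 with
    probability 0.05); segments never cross chromosome boundaries.
    Observed CN = (1-c)*true + 2c + Gaussian noise, floored at 0.

    With ``return_truth=True`` also returns the noise-free ternary truth
    calls for benchmarking.
    """
    rng = np.random.default_rng(config.seed)
    design = _sample_design(config, rng)
    gene_mask = in_gene_mask(probe_map, genes, config.flank)
    cum_weights = np.cumsum(_start_weights(config, probe_map))
    cum_weights[-1] = 1.0
    n_probes = len(probe_map)
    chrom_end = np.empty(n_probes, dtype=np.int64)
    for _, sl in probe_map.chromosome_slices().items():
        chrom_end[sl] = sl.stop
    s = config.selection_strength
    accept_gene = 1.0 / s if s > 1 else 1.0

    order = design.table["sample_id"].tolist()
    truth = np.full((len(order), n_probes), 2.0)
    row = 0
    for spec in config.group_specs:
        for _ in range(spec.n_samples):
            for event, rate in (("gain", spec.gain_rate), ("loss", spec.loss_rate)):
                n_seg = rng.poisson(rate)
                for _ in range(n_seg):
                    for _try in range(1000):
                        start = int(np.searchsorted(cum_weights, rng.random()))
                        if not gene_mask[start] or rng.random() < accept_gene:
                            break
                    length = rng.geometric(1.0 / config.segment_length_mean)
                    stop = min(start + length, chrom_end[start])
                    if event == "gain":
                        value = 4.0 if rng.random() < 0.1 else 3.0
                    else:
                        value = 0.0 if rng.random() < 0.05 else 1.0
                    truth[row, start:stop] = value
            row += 1
    c = config.contamination
    # written as truth + c*(2 - truth) so that at the design point c = 0.3
    # the mixed values land exactly on the 2.7 / 1.3 calling thresholds
    observed = truth + c * (2.0 - truth)
    if config.noise_sd > 0:
        observed = observed + rng.normal(0.0, config.noise_sd, size=observed.shape)
    observed = np.maximum(observed, 0.0)
    cn = CopyNumberMatrix(order, observed, probe_map)
    if not return_truth:
        return cn, design
    truth_calls = np.zeros(truth.shape, dtype=np.int8)
    truth_calls[truth >= 3.0] = 1
    truth_calls[truth <= 1.0] = -1
    truth_cm = CallMatrix(order, truth_calls, probe_map)
    return cn, design, truth_cm


def plant_gene_set_enrichment(
    calls: CallMatrix,
    genes: GeneTable,
    planted: tuple[PlantedSet, ...],
    seed: int,
    sample_subset: list[str] | None = None,
    n_decoys_per_set: int = 1,
    flank: int = DEFAULT_FLANK,
) -> tuple[CallMatrix, GeneSetCollection]:
    """Inject gain prevalence into chosen gene sets and build a matching
    collection with size-matched decoy sets.

    For each planted set, member genes are drawn from genes covered by at
    least one probe; each member gene's probes are set to gain in an
    additional ``prevalence_boost`` fraction of the target samples,
    sampled per gene among samples currently gain-free over the gene.
    Decoy sets of matched size are drawn uniformly from non-planted genes.
    """
    rng = np.random.default_rng(seed)
    assignment = probes_by_gene(calls.probe_map, genes, flank)
    covered = np.array(sorted(assignment), dtype=object)
    ids = sample_subset if sample_subset is not None else list(calls.sample_ids)
    rows = calls.sample_indexer(ids)
    new_calls = calls.calls.copy()
    taken: set[str] = set()
    sets: dict[str, list[str]] = {}
    for ps in planted:
        pool = np.array([g for g in covered if g not in taken], dtype=object)
        if len(pool) < ps.n_member_genes:
            raise ValueError("not enough probe-covered genes to plant the set")
        members = list(rng.choice(pool, size=ps.n_member_genes, replace=False))
        taken.update(members)
        n_target = len(rows)
        n_boost = int(round(ps.prevalence_boost * n_target))
        for gene in members:
            idx = assignment[gene]
            has_gain = (new_calls[np.ix_(rows, idx)] == GAIN).any(axis=1)
            free = rows[~has_gain]
            if n_boost > len(free):
                raise ValueError(
                    f"boost {ps.prevalence_boost} would push prevalence of "
                    f"gene {gene} past 1"
                )
            chosen = rng.choice(free, size=n_boost, replace=False)
            new_calls[np.ix_(chosen, idx)] = GAIN
        sets[ps.set_name] = members
    for ps in planted:
        for d in range(n_decoys_per_set):
            pool = np.array([g for g in covered if g not in taken], dtype=object)
            if len(pool) < ps.n_member_genes:
                raise ValueError("not enough genes left for decoy sets")
            members = list(
                rng.choice(pool, size=ps.n_member_genes, replace=False)
            )
            taken.update(members)
            sets[f"decoy_{ps.set_name}_{d}"] = members
    collection = GeneSetCollection(
        sets, {name: "planted" if not name.startswith("decoy_") else "decoy"
               for name in sets},
    )
    return (
        CallMatrix(
            list(calls.sample_ids), new_calls, calls.probe_map,
            theta_gain=calls.theta_gain, theta_loss=calls.theta_loss,
        ),
        collection,
    )
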