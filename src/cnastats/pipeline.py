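"""End-to-end workflow: calling -> locus tests -> gene collapse ->
global tests -> G/T selection metrics -> gene-set enrichment.

The pipeline is driven by a plain-YAML config (paths, thresholds,
permutation counts, seed) and writes every result as TSV/JSON into an
output directory, together with a manifest listing each file's SHA-256
hash so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, global_test, gsea, locus_stats, selection
from .data_model import (
    DEFAULT_FLANK,
    read_cn_matrix,
    read_design,
    read_gene_table,
    read_gmt,
    read_probe_map,
    write_call_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    probe_map: str
    cn_matrix: str
    design: str
    genes: str
    output_dir: str
    seed: int
    gene_sets: str | None = None
    theta_gain: float = 2.7
    theta_loss: float = 1.3
    window: int = 11
    smooth: bool = True
    flank: int = DEFAULT_FLANK
    global_permutations: int = 10000
    gsea_permutations: int = 20000
    min_set_size: int = 15
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_prevalence(
    gain_results: pd.DataFrame,
    loss_results: pd.DataFrame,
    probe_map,
    out: str | Path,
    q_scale: bool = False,
) -> Path:
    """Genome-axis prevalence plot: gains above the axis, losses below,
    chromosome boundaries marked.  A TSV with the plotted values is
    written alongside the image (same stem, '.tsv' suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    x = np.arange(len(probe_map))
    if q_scale:
        up = -np.log10(np.maximum(gain_results["q_value"].to_numpy(), 1e-300))
        down = -np.log10(np.maximum(loss_results["q_value"].to_numpy(), 1e-300))
        ylabel = "-log10(q)  (losses negated)"
    else:
        up = 100.0 * gain_results["prevalence"].to_numpy()
        down = 100.0 * loss_results["prevalence"].to_numpy()
        ylabel = "prevalence (%)  (losses negated)"
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.vlines(x, 0, up, color="crimson", lw=0.5, label="gains")
    ax.vlines(x, 0, -down, color="steelblue", lw=0.5, label="losses")
    for chrom, sl in probe_map.chromosome_slices().items():
        ax.axvline(sl.start, color="0.8", lw=0.5)
        ax.text(
            (sl.start + sl.stop) / 2, ax.get_ylim()[1], chrom,
            ha="center", va="bottom", fontsize=6,
        )
    ax.set_xlabel("genomic locus (probe order)")
    ax.set_ylabel(ylabel)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _write_tsv(
        pd.DataFrame(
            {
                "probe_id": probe_map.probe_ids,
                "gain": up,
                "loss": down,
            }
        ),
        out.with_suffix(".tsv"),
    )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        _write_tsv(df, path)
        outputs.append(path)

    stage = "load-inputs"
    try:
        probe_map = read_probe_map(config.probe_map)
        cn = read_cn_matrix(config.cn_matrix, probe_map)
        design = read_design(config.design)
        genes = read_gene_table(config.genes)
        collection = read_gmt(config.gene_sets) if config.gene_sets else None

        stage = "call"
        if config.smooth:
            cn = calling.median_smooth(cn, calling.SmoothingSpec(config.window))
        calls = calling.call_cnas(cn, config.theta_gain, config.theta_loss)
        call_path = out_dir / "calls.tsv"
        write_call_matrix(calls, call_path)
        outputs.append(call_path)

        tumors = design.tumors
        non_tumor = [s for s in design.table["sample_id"] if s not in set(tumors)]
        early = design.select(tissue="tumor", stage="early")
        late = design.select(tissue="tumor", stage="late")

        stage = "locus-test"
        locus_results: dict[str, pd.DataFrame] = {}
        gene_results: dict[str, pd.DataFrame] = {}
        for event in ("gain", "loss"):
            null = locus_stats.estimate_empirical_null(calls, tumors, event)
            res = locus_stats.locus_prevalence_tests(calls, tumors, event, null)
            locus_results[event] = res
            emit(res, f"locus_{event}.tsv")
            stage = "collapse"
            gene_res = locus_stats.collapse_to_genes(
                res, probe_map, genes, config.flank
            )
            gene_results[event] = gene_res
            emit(gene_res, f"genes_{event}.tsv")
            stage = "locus-test"

        stage = "plot"
        outputs.append(
            plot_prevalence(
                locus_results["gain"], locus_results["loss"], probe_map,
                out_dir / "prevalence.png",
            )
        )
        outputs.append((out_dir / "prevalence.tsv"))

        stage = "global-test"
        global_reports = []
        comparisons = [("non_tumor_vs_tumor", non_tumor, tumors)]
        if early and late:
            comparisons.append(("early_vs_late", early, late))
        for name, ga, gb in comparisons:
            if len(ga) < 2 or len(gb) < 2:
                continue
            for event in ("gain", "loss"):
                res = global_test.global_cna_test(
                    calls, ga, gb, event,
                    B=config.global_permutations, seed=config.seed,
                    group_labels=tuple(name.split("_vs_")),
                )
                global_reports.append(
                    {
                        "comparison": name, "event": event,
                        "D_observed": res.D_observed, "p_value": res.p_value,
                        "B": res.B, "n1": res.n1, "n2": res.n2,
                    }
                )
        emit(pd.DataFrame(global_reports), "global_tests.tsv")

        stage = "gt-ratio"
        r0 = selection.null_gt_ratio(probe_map, genes, config.flank)
        gt_rows = []
        subsets = {"non_tumor": non_tumor, "tumor": tumors,
                   "early_tumor": early, "late_tumor": late}
        for event in ("gain", "loss"):
            for name, ids in subsets.items():
                if len(ids) < 2:
                    continue
                metrics = selection.compute_gt_metrics(
                    calls, probe_map, genes, event, config.flank, ids
                )
                defined = metrics["gt_ratio"].dropna()
                row = {
                    "subset": name, "event": event, "n": len(ids),
                    "mean_TP": metrics["TP"].mean(),
                    "mean_GP": metrics["GP"].mean(),
                    "mean_gt_ratio": defined.mean() if len(defined) else np.nan,
                    "null_ratio": r0,
                }
                if len(defined) >= 2:
                    cmp_null = selection.test_gt_vs_null(metrics, r0)
                    row["p_vs_null"] = cmp_null.p_value
                else:
                    row["p_vs_null"] = np.nan
                gt_rows.append(row)
        emit(pd.DataFrame(gt_rows), "gt_ratio.tsv")

        if collection is not None:
            stage = "gsea"
            discovery, validation = gsea.discovery_validation_split(
                design, config.seed
            )
            for event in ("gain", "loss"):
                stage_results = []
                for half_name, ids in (("discovery", discovery),
                                       ("validation", validation)):
                    null = locus_stats.estimate_empirical_null(calls, ids, event)
                    res = locus_stats.locus_prevalence_tests(calls, ids, event, null)
                    gene_res = locus_stats.collapse_to_genes(
                        res, probe_map, genes, config.flank
                    )
                    ranked = gsea.rank_genes(gene_res, event)
                    enr = gsea.gene_label_permutation_test(
                        ranked, collection, B=config.gsea_permutations,
                        min_set_size=config.min_set_size, seed=config.seed,
                    )
                    enr.insert(0, "half", half_name)
                    stage_results.append(enr)
                    emit(enr, f"gsea_{event}_{half_name}.tsv")
                reported = gsea.two_stage_report(*stage_results, alpha=config.alpha)
                emit(
                    pd.DataFrame({"set_name": reported}),
                    f"gsea_{event}_reported.tsv",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    config_echo = out_dir / "config.yaml"
    config_echo.write_text(yaml.safe_dump(asdict(config)))
    manifest = {
        "config": asdict(config),
        "outputs": {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(set(outputs))
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
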