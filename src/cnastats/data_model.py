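"""Shared domain containers and plain-text readers/writers.

Everything downstream works on a small set of aligned containers:

* :class:`ProbeMap` — the ordered autosomal probe loci that define the
  genome axis of every matrix.
* :class:`CopyNumberMatrix` — samples × probes inferred copy numbers.
* :class:`CallMatrix` — samples × probes ternary gain/neutral/loss calls.
* :class:`GeneTable` — gene intervals used for probe→gene assignment
  (with a promoter/flanking extension, 2 kb by default).
* :class:`CohortDesign` — per-sample metadata (tissue, stage, histology,
  smoking pack-years, patient pairing) that drives group comparisons.
* :class:`GeneSetCollection` — named gene sets in GMT form.

All on-disk formats are plain TSV/GMT/BED; coordinates are 1-based
inclusive internally, BED input is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAIN = 1
NEUTRAL = 0
LOSS = -1

#: Default gene extension in bp, covering promoter and flanking regions.
DEFAULT_FLANK = 2000

_AUTOSOMES = {str(i) for i in range(1, 23)}

TISSUES = ("blood", "non_involved", "tumor")
STAGES = ("early", "late", "none")
HISTOLOGIES = ("ACA", "SCC", "none")


def normalize_chromosome(label: object) -> str:
    """Canonicalize an autosome label ('chr7', '07', 7 -> '7').

    Sex chromosomes and anything non-autosomal are rejected: the analysis
    is defined on somatic (autosomal) chromosomes only.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        s = str(int(s))
    if s not in _AUTOSOMES:
        raise ValueError(
            f"chromosome {label!r} is not an autosome (1-22); sex chromosomes "
            "are excluded from the analysis"
        )
    return s


def _chrom_sort_key(chrom: str) -> int:
    return int(chrom)


class ProbeMap:
    """Ordered autosomal probe loci; the single source of locus order."""

    def __init__(self, table: pd.DataFrame):
        required = {"probe_id", "chromosome", "position"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("no probes")
        df = table.loc[:, ["probe_id", "chromosome", "position"]].copy()
        df["probe_id"] = df["probe_id"].astype(str)
        df["chromosome"] = df["chromosome"].map(normalize_chromosome)
        pos = pd.to_numeric(df["position"], errors="coerce")
        if pos.isna().any():
            bad = df.index[pos.isna()][0]
            raise ValueError(f"non-numeric position at input row {bad}")
        df["position"] = pos.astype(np.int64)
        if (df["position"] <= 0).any():
            raise ValueError("probe positions must be positive (1-based)")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id {dup!r}")
        df["_ck"] = df["chromosome"].map(_chrom_sort_key)
        df = df.sort_values(["_ck", "position"], kind="mergesort").drop(columns="_ck")
        df = df.reset_index(drop=True)
        self.table = df
        self._index = pd.Index(df["probe_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeMap) and self.table.equals(other.table)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous slice of the locus axis occupied by each chromosome."""
        out: dict[str, slice] = {}
        chroms = self.chromosomes
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(chroms)]])
        for s, e in zip(starts, ends):
            out[chroms[s]] = slice(int(s), int(e))
        return out

    def indexer(self, probe_ids: Sequence[str]) -> np.ndarray:
        idx = self._index.get_indexer(probe_ids)
        if (idx < 0).any():
            missing = np.asarray(probe_ids)[idx < 0][0]
            raise ValueError(f"probe {missing!r} absent from probe map")
        return idx


@dataclass
class CopyNumberMatrix:
    """Samples × probes inferred copy numbers aligned to a :class:`ProbeMap`."""

    sample_ids: list[str]
    values: np.ndarray
    probe_map: ProbeMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("copy-number values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.probe_map)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_map)} probes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValueError("missing copy-number values are not allowed")
        if (self.values < 0).any():
            raise ValueError("negative copy-number values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indexer(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = pd.Index(self.sample_ids)
        idx = index.get_indexer(sample_ids)
        if (idx < 0).any():
            missing = np.asarray(sample_ids)[idx < 0][0]
            raise ValueError(f"unknown sample {missing!r}")
        return idx


@dataclass
class CallMatrix:
    """Ternary CNA calls (gain=+1 / neutral=0 / loss=-1) with the thresholds
    that produced them."""

    sample_ids: list[str]
    calls: np.ndarray
    probe_map: ProbeMap
    theta_gain: float = 2.7
    theta_loss: float = 1.3

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.theta_gain <= self.theta_loss:
            raise ValueError("theta_gain must exceed theta_loss")
        if self.calls.shape != (len(self.sample_ids), len(self.probe_map)):
            raise ValueError("call matrix shape mismatch")
        if not np.isin(self.calls, (GAIN, NEUTRAL, LOSS)).all():
            raise ValueError("calls must be in {gain, neutral, loss}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indexer(self, sample_ids: Sequence[str]) -> np.ndarray:
        return CopyNumberMatrix.sample_indexer(self, sample_ids)  # type: ignore[arg-type]

    def event_matrix(self, event: str) -> np.ndarray:
        """Boolean samples × probes indicator of the requested event."""
        return self.calls == event_code(event)


def event_code(event: str) -> int:
    if event == "gain":
        return GAIN
    if event == "loss":
        return LOSS
    raise ValueError(f"event must be 'gain' or 'loss', got {event!r}")


class GeneTable:
    """Gene intervals (1-based inclusive) on the autosomes."""

    def __init__(self, table: pd.DataFrame):
        required = {"gene_id", "chromosome", "start", "end"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        df = table.loc[:, ["gene_id", "chromosome", "start", "end"]].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        df["chromosome"] = df["chromosome"].map(normalize_chromosome)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] > df["end"]).any():
            raise ValueError("gene start > end")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneTable) and self.table.equals(other.table)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()


def in_gene_mask(
    probe_map: ProbeMap, genes: GeneTable, flank: int = DEFAULT_FLANK
) -> np.ndarray:
    """Boolean per-probe mask: probe position within any gene extended by
    ``flank`` bp on both sides (bounds inclusive)."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    mask = np.zeros(len(probe_map), dtype=bool)
    slices = probe_map.chromosome_slices()
    for chrom, sub in genes.table.groupby("chromosome", sort=False):
        sl = slices.get(chrom)
        if sl is None:
            continue
        pos = probe_map.positions[sl]
        lo = np.searchsorted(pos, sub["start"].to_numpy() - flank, side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy() + flank, side="right")
        local = np.zeros(len(pos) + 1, dtype=np.int64)
        np.add.at(local, lo, 1)
        np.add.at(local, hi, -1)
        mask[sl] = np.cumsum(local[:-1]) > 0
    return mask


def probes_by_gene(
    probe_map: ProbeMap, genes: GeneTable, flank: int = DEFAULT_FLANK
) -> dict[str, np.ndarray]:
    """Global probe indices covered by each extended gene.

    A probe overlapping several extended genes is assigned to every one of
    them; genes with no probe are omitted.
    """
    out: dict[str, np.ndarray] = {}
    slices = probe_map.chromosome_slices()
    for chrom, sub in genes.table.groupby("chromosome", sort=False):
        sl = slices.get(chrom)
        if sl is None:
            continue
        pos = probe_map.positions[sl]
        lo = np.searchsorted(pos, sub["start"].to_numpy() - flank, side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy() + flank, side="right")
        for gid, a, b in zip(sub["gene_id"], lo, hi):
            if b > a:
                out[gid] = np.arange(sl.start + a, sl.start + b)
    return out


class CohortDesign:
    """Per-sample metadata table driving all group comparisons."""

    COLUMNS = ("sample_id", "tissue", "stage", "histology", "pack_years", "patient_id")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        df = table.loc[:, list(self.COLUMNS)].copy()
        for col in ("sample_id", "tissue", "stage", "histology", "patient_id"):
            df[col] = df[col].astype(str)
        df["pack_years"] = pd.to_numeric(df["pack_years"], errors="coerce")
        if (df["pack_years"].dropna() < 0).any():
            raise ValueError("pack_years must be non-negative")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        for col, allowed in (
            ("tissue", TISSUES),
            ("stage", STAGES),
            ("histology", HISTOLOGIES),
        ):
            bad = ~df[col].isin(allowed)
            if bad.any():
                raise ValueError(f"invalid {col} value {df.loc[bad, col].iloc[0]!r}")
        non_tumor = df["tissue"] != "tumor"
        if ((df.loc[non_tumor, "stage"] != "none").any()
                or (df.loc[non_tumor, "histology"] != "none").any()):
            raise ValueError("stage/histology must be 'none' for non-tumor samples")
        tumor = ~non_tumor
        if (df.loc[tumor, "stage"] == "none").any():
            raise ValueError("tumor samples must carry a stage")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CohortDesign) and self.table.equals(other.table)

    def select(self, **filters: object) -> list[str]:
        """Sample ids matching an equality conjunction, e.g.
        ``select(tissue="tumor", stage="early")``."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in filters.items():
            if col not in self.table.columns:
                raise ValueError(f"unknown metadata column {col!r}")
            mask &= self.table[col] == str(value)
        return self.table.loc[mask, "sample_id"].tolist()

    @property
    def tumors(self) -> list[str]:
        return self.select(tissue="tumor")


class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> ordered unique members."""

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self.sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, members in sets.items():
            uniq = list(dict.fromkeys(str(m) for m in members))
            if len(uniq) < len(list(members)):
                logger.warning("gene set %s: duplicate members removed", name)
            if not uniq:
                raise ValueError(f"gene set {name!r} has no members")
            self.sets[str(name)] = uniq
            self.descriptions[str(name)] = (
                str(descriptions.get(name, "")) if descriptions else ""
            )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_probe_map(path: str | Path, format: str = "tsv") -> ProbeMap:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if len(df) == 0:
            raise ValueError("no probes")
        rename = {"chrom": "chromosome", "pos": "position"}
        df = df.rename(columns=rename)
    elif format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#",
            names=["chromosome", "start", "end", "probe_id"], usecols=range(4),
        )
        if len(df) == 0:
            raise ValueError("no probes")
        # BED is 0-based half-open; a probe is the point start+1 (1-based)
        df["position"] = df["start"].astype(np.int64) + 1
    else:
        raise ValueError(f"unknown probe map format {format!r}")
    return ProbeMap(df)


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    probe_map.table.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path, format: str = "tsv") -> GeneTable:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
    elif format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#",
            names=["chromosome", "start", "end", "gene_id"], usecols=range(4),
        )
        df["start"] = df["start"].astype(np.int64) + 1  # 0-based -> 1-based
    else:
        raise ValueError(f"unknown gene table format {format!r}")
    if len(df) == 0:
        raise ValueError("no genes")
    return GeneTable(df)


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


def read_cn_matrix(path: str | Path, probe_map: ProbeMap) -> CopyNumberMatrix:
    """Read a samples × probes TSV (first column = sample id, header row of
    probe ids) and align columns to the probe map order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("missing copy-number cell (no imputation is performed)")
    idx = probe_map.indexer([str(c) for c in df.columns])
    if len(df.columns) != len(probe_map):
        raise ValueError(
            f"copy-number matrix has {len(df.columns)} probes; probe map has "
            f"{len(probe_map)}"
        )
    values = np.empty((len(df), len(probe_map)), dtype=float)
    values[:, idx] = df.to_numpy(dtype=float)
    return CopyNumberMatrix(list(df.index.astype(str)), values, probe_map)


def write_cn_matrix(cn: CopyNumberMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cn.values, index=cn.sample_ids, columns=cn.probe_map.probe_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


_CALL_TO_STR = {GAIN: "gain", NEUTRAL: "neutral", LOSS: "loss"}
_STR_TO_CALL = {v: k for k, v in _CALL_TO_STR.items()}


def write_call_matrix(calls: CallMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        calls.calls, index=calls.sample_ids, columns=calls.probe_map.probe_ids
    )
    df.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write(f"#theta_gain={calls.theta_gain}\t#theta_loss={calls.theta_loss}\n")
        df.to_csv(fh, sep="\t")


def read_call_matrix(path: str | Path, probe_map: ProbeMap) -> CallMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(f.lstrip("#").split("=") for f in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", index_col=0)
    idx = probe_map.indexer([str(c) for c in df.columns])
    values = np.empty((len(df), len(probe_map)), dtype=np.int8)
    values[:, idx] = df.to_numpy(dtype=np.int8)
    return CallMatrix(
        list(df.index.astype(str)), values, probe_map,
        theta_gain=float(fields["theta_gain"]),
        theta_loss=float(fields["theta_loss"]),
    )


def read_design(path: str | Path) -> CohortDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CohortDesign(df)


def write_design(design: CohortDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected name, description and at "
                    f"least one member, got {len(fields)} fields"
                )
            name, description, *members = fields
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    if not sets:
        raise ValueError("GMT file contains no gene sets")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
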