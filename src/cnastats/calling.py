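"""Copy-number preprocessing and CNA calling.

Raw copy numbers are the probe signal scaled to a diploid reference
(``2 * signal / reference mean``); inferred copy numbers are obtained by
running-median smoothing along each chromosome (window of 11 probes by
default), and ternary calls use fixed thresholds: gain at CN >= 2.7, loss
at CN <= 1.3.  The thresholds detect true CN >= 3 / <= 1 while tolerating
30% contamination by normal diploid cells (0.7*3 + 0.3*2 = 2.7 and
0.7*1 + 0.3*2 = 1.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CallMatrix, CopyNumberMatrix, ProbeMap

logger = logging.getLogger(__name__)

THETA_GAIN = 2.7
THETA_LOSS = 1.3


@dataclass(frozen=True)
class SmoothingSpec:
    """Running-median window, in probes; must be odd so it is centered."""

    window: int = 11

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")


def raw_copy_number(
    signal: np.ndarray,
    reference_mean: np.ndarray,
    probe_map: ProbeMap,
    sample_ids: Sequence[str],
) -> CopyNumberMatrix:
    """Scale probe signals to copy numbers against a diploid reference.

    Entry (s, i) = 2 * signal(s, i) / reference_mean(i), where the
    reference mean is taken over the reference (blood / non-involved)
    samples at probe i.
    """
    signal = np.asarray(signal, dtype=float)
    reference_mean = np.asarray(reference_mean, dtype=float)
    if reference_mean.shape != (signal.shape[1],):
        raise ValueError("reference_mean length must equal the probe count")
    bad = np.flatnonzero(reference_mean <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive reference mean at probe {probe_map.probe_ids[bad[0]]!r}"
        )
    values = 2.0 * signal / reference_mean
    return CopyNumberMatrix(list(sample_ids), values, probe_map)


def median_smooth(
    cn: CopyNumberMatrix, spec: SmoothingSpec = SmoothingSpec()
) -> CopyNumberMatrix:
    """Centered running median along the locus axis, per sample and per
    chromosome.

    Windows never span a chromosome boundary; at chromosome ends the
    window shrinks (truncated window over the available probes), so the
    output has the same shape as the input.
    """
    out = np.empty_like(cn.values)
    for chrom, sl in cn.probe_map.chromosome_slices().items():
        n = sl.stop - sl.start
        if n < spec.window:
            logger.warning(
                "chromosome %s has %d probes, smaller than window %d; "
                "window shrinks", chrom, n, spec.window,
            )
        block = pd.DataFrame(cn.values[:, sl].T)
        smoothed = block.rolling(spec.window, center=True, min_periods=1).median()
        out[:, sl] = smoothed.to_numpy().T
    return CopyNumberMatrix(list(cn.sample_ids), out, cn.probe_map)


def call_cnas(
    cn: CopyNumberMatrix,
    theta_gain: float = THETA_GAIN,
    theta_loss: float = THETA_LOSS,
) -> CallMatrix:
    """Threshold inferred copy numbers into ternary calls.

    Boundaries are inclusive: gain iff CN >= theta_gain, loss iff
    CN <= theta_loss, neutral otherwise.
    """
    if theta_gain <= theta_loss:
        raise ValueError("theta_gain must exceed theta_loss")
    calls = np.zeros(cn.values.shape, dtype=np.int8)
    calls[cn.values >= theta_gain] = 1
    calls[cn.values <= theta_loss] = -1
    return CallMatrix(
        list(cn.sample_ids), calls, cn.probe_map,
        theta_gain=theta_gain, theta_loss=theta_loss,
    )
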