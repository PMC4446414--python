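"""Expression continuity and variance features for candidate junctions.

A candidate is either a real consecutive gene pair (left gene, intergenic
region, right gene) or a constructed TU (two pseudo-coding flanks around a
made-up intergenic region inside one gene). Both expose the same three
intervals, from which six statistics are computed:

* ``gap_count`` / ``gap_fraction`` — zero-RAPSN positions in the intergenic
  region (expression continuity);
* three log2 fold changes between the mean RAPSN of the flanks and the
  intergenic region (pseudocount 1);
* ``norm_variance`` — variance of per-base RAPSN across the whole candidate
  span after scaling by the span's mean (pseudocount-guarded), a
  scale-free measure of expression-level consistency along the candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .annotation_io import GenePair
from .coverage import CoverageTrack

PSEUDOCOUNT = 1.0

FEATURE_NAMES = (
    "gap_count",
    "gap_fraction",
    "log2_fc_left_ir",
    "log2_fc_right_ir",
    "log2_fc_left_right",
    "norm_variance",
)

Interval = tuple[int, int]


@dataclass(frozen=True)
class FeatureVector:
    gap_count: int
    gap_fraction: float
    log2_fc_left_ir: float
    log2_fc_right_ir: float
    log2_fc_left_right: float
    norm_variance: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.gap_count,
                self.gap_fraction,
                self.log2_fc_left_ir,
                self.log2_fc_right_ir,
                self.log2_fc_left_right,
                self.norm_variance,
            ],
            dtype=float,
        )


def _mean(arr: np.ndarray) -> float:
    return float(arr.mean()) if arr.size else 0.0


def continuity_features(track: CoverageTrack, region: Interval, strand: str) -> tuple[int, float]:
    """Count of zero-RAPSN positions in ``region`` and its fraction of the
    region length; a zero-length region yields ``(0, 0.0)``."""
    s, e = region
    if s < 0 or e > track.length:
        raise ValueError("region outside genome")
    if e <= s:
        return 0, 0.0
    window = track.strand_array(strand)[s:e]
    gap_count = int((window == 0).sum())
    return gap_count, gap_count / (e - s)


def variance_features(
    track: CoverageTrack,
    left: Interval,
    ir: Interval,
    right: Interval,
    strand: str,
) -> tuple[float, float, float, float]:
    """Fold-change and variance statistics over a (left, IR, right) triple.

    Fold changes are ``log2((mean_a + 1) / (mean_b + 1))`` of mean RAPSN.
    ``norm_variance`` is the variance of per-base RAPSN over the
    concatenated span after dividing by (span mean + 1); it is 0 for
    perfectly uniform coverage and nearly scale-invariant.
    """
    arr = track.strand_array(strand)
    left_arr = arr[left[0] : left[1]]
    ir_arr = arr[ir[0] : ir[1]]
    right_arr = arr[right[0] : right[1]]
    ml, mi, mr = _mean(left_arr), _mean(ir_arr), _mean(right_arr)
    fc_l_ir = float(np.log2((ml + PSEUDOCOUNT) / (mi + PSEUDOCOUNT)))
    fc_r_ir = float(np.log2((mr + PSEUDOCOUNT) / (mi + PSEUDOCOUNT)))
    fc_l_r = float(np.log2((ml + PSEUDOCOUNT) / (mr + PSEUDOCOUNT)))
    span = np.concatenate([left_arr, ir_arr, right_arr]).astype(float)
    if span.size == 0:
        norm_var = 0.0
    else:
        norm_var = float(np.var(span / (span.mean() + PSEUDOCOUNT)))
    return fc_l_ir, fc_r_ir, fc_l_r, norm_var


def candidate_intervals(candidate) -> tuple[Interval, Interval, Interval, str]:
    """Resolve a GenePair or constructed TU to (left, IR, right, strand)."""
    if isinstance(candidate, GenePair):
        return (
            (candidate.left.start, candidate.left.end),
            (candidate.intergenic.start, candidate.intergenic.end),
            (candidate.right.start, candidate.right.end),
            candidate.strand,
        )
    # constructed TU: duck-typed on its partition attributes
    return (
        tuple(candidate.left_part),
        (candidate.cir_start, candidate.cir_end),
        tuple(candidate.right_part),
        candidate.strand,
    )


def extract_features(candidate, track: CoverageTrack) -> FeatureVector:
    """Full six-component feature vector for one candidate junction."""
    left, ir, right, strand = candidate_intervals(candidate)
    gap_count, gap_fraction = continuity_features(track, ir, strand)
    fc_l_ir, fc_r_ir, fc_l_r, norm_var = variance_features(track, left, ir, right, strand)
    return FeatureVector(
        gap_count=gap_count,
        gap_fraction=gap_fraction,
        log2_fc_left_ir=fc_l_ir,
        log2_fc_right_ir=fc_r_ir,
        log2_fc_left_right=fc_l_r,
        norm_variance=norm_var,
    )


def feature_matrix(candidates: Sequence, track: CoverageTrack) -> np.ndarray:
    """Stack feature vectors for many candidates into an (n, 6) matrix."""
    if not len(candidates):
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([extract_features(c, track).as_array() for c in candidates])
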