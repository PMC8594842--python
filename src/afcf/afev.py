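"""AF evidence (AFEv): an integer summary of the ΔRR Lorenz plot.

Successive RR-difference pairs (ΔRR_i, ΔRR_{i-1}) form a Lorenz (Poincaré
difference) plot.  Atrial fibrillation scatters these points widely and
symmetrically; sinus rhythm concentrates them near the origin; atrial
ectopy (PAC patterns such as bigeminy) produces a structured short-long
alternation that lands points in quadrants II and IV.  Following the
implantable-monitor detector tradition, the plane is divided into 13
segments, point/bin counts per segment are combined into three evidence
terms, and

    AFEv = IrregularityEvidence - OriginCount - 2 * PACEvidence.

Segment mask (all constants in ms; x = ΔRR_i, y = ΔRR_{i-1}):

====  =========================================================
seg   region
====  =========================================================
0     origin box: |x| <= 80 and |y| <= 80
1-4   axis strips (one coordinate inside the origin band, the
      other outside): +x, +y, -x, -y
5-8   near quadrants: both |x|,|y| > 80, max(|x|,|y|) <= 440,
      quadrant order I, II, III, IV
9-12  far quadrants: both |x|,|y| > 80, max(|x|,|y|) > 440
====  =========================================================

* IrregularityEvidence = number of occupied 40 ms x 40 ms histogram bins
  over segments 1-12 (dispersion of the cloud, insensitive to how many
  points pile into one bin);
* OriginCount = number of points in segment 0;
* PACEvidence = excess of points in quadrants II+IV over I+III
  (segments {6,8,10,12} minus {5,7,9,11}, floored at 0) — the signature
  of regular short-long alternation.

Coordinates are clipped to ±1000 ms before binning.
"""

from __future__ import annotations

import numpy as np

from .rr import RRSeries

__all__ = ["af_evidence", "lorenz_points", "segment_ids"]

BIN_MS = 40.0
ORIGIN_MS = 80.0          # half-width of the central (origin) box
NEAR_FAR_MS = 440.0       # near/far quadrant split
CLIP_MS = 1000.0

_PAC_SEGMENTS = (6, 8, 10, 12)      # quadrants II and IV (near + far)
_NON_PAC_SEGMENTS = (5, 7, 9, 11)   # quadrants I and III


def lorenz_points(rr: RRSeries) -> tuple[np.ndarray, np.ndarray]:
    """(ΔRR_i, ΔRR_{i-1}) pairs; needs >= 4 intervals for >= 1 point."""
    x = rr.require("AFEv", 4)
    d = np.diff(x)
    return d[1:], d[:-1]


def segment_ids(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Segment index 0..12 for each Lorenz point (see module docstring)."""
    x = np.clip(x, -CLIP_MS, CLIP_MS)
    y = np.clip(y, -CLIP_MS, CLIP_MS)
    seg = np.zeros(x.size, dtype=int)
    in_x = np.abs(x) <= ORIGIN_MS
    in_y = np.abs(y) <= ORIGIN_MS
    # axis strips
    seg[(~in_x) & in_y & (x > 0)] = 1
    seg[in_x & (~in_y) & (y > 0)] = 2
    seg[(~in_x) & in_y & (x < 0)] = 3
    seg[in_x & (~in_y) & (y < 0)] = 4
    # quadrants
    quad = np.select(
        [(x > 0) & (y > 0), (x < 0) & (y > 0), (x < 0) & (y < 0)],
        [0, 1, 2],
        default=3,
    )
    both_out = (~in_x) & (~in_y)
    near = np.maximum(np.abs(x), np.abs(y)) <= NEAR_FAR_MS
    seg[both_out & near] = 5 + quad[both_out & near]
    seg[both_out & ~near] = 9 + quad[both_out & ~near]
    return seg


def af_evidence(rr: RRSeries) -> int:
    """Integer AF evidence score of the record's ΔRR Lorenz plot."""
    x, y = lorenz_points(rr)
    x = np.clip(x, -CLIP_MS, CLIP_MS)
    y = np.clip(y, -CLIP_MS, CLIP_MS)
    seg = segment_ids(x, y)

    origin_count = int(np.count_nonzero(seg == 0))

    outside = seg > 0
    bx = np.floor(x[outside] / BIN_MS).astype(int)
    by = np.floor(y[outside] / BIN_MS).astype(int)
    irregularity = int(np.unique(np.stack([bx, by], axis=1), axis=0).shape[0]) \
        if bx.size else 0

    pac_pts = int(np.count_nonzero(np.isin(seg, _PAC_SEGMENTS)))
    non_pac_pts = int(np.count_nonzero(np.isin(seg, _NON_PAC_SEGMENTS)))
    pac = max(0, pac_pts - non_pac_pts)

    return irregularity - origin_count - 2 * pac
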