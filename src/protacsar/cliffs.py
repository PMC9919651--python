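"""Degradation-cliff detection.

A degradation cliff is a pair of structurally similar degraders (count
Tanimoto on sphere fingerprints at or above a similarity threshold, 0.9 by
default) whose degradation difference exceeds a delta threshold — and does
so consistently at both tested concentrations, which guards against
single-point assay noise. Candidate pairs below the similarity threshold can
be injected manually and are tagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import DegradationRecord
from .frameworks import SphereFingerprint

DEFAULT_SIMILARITY_MIN = 0.9
DEFAULT_DELTA_MIN = 40.0


@dataclass(frozen=True)
class CliffPair:
    id_i: str
    id_j: str
    similarity: float
    delta_low: float   # |D_i - D_j| at 0.1 uM, percent
    delta_high: float  # |D_i - D_j| at 1 uM, percent
    passes_dual: bool
    provenance: str = "auto"  # auto | manual


def similar_pairs(
    fps: Mapping[str, SphereFingerprint],
    s_min: float = DEFAULT_SIMILARITY_MIN,
) -> list[tuple[str, str, float]]:
    """All unordered pairs with count-Tanimoto similarity >= s_min."""
    ids = sorted(fps)
    if len(ids) < 2:
        raise ValueError("need at least 2 fingerprints")
    matrix = np.stack([fps[cid].counts for cid in ids]).astype(np.int64)
    totals = matrix.sum(axis=1)
    out = []
    for i in range(len(ids)):
        # sum(min) via broadcasting; sum(max) = total_i + total_j - sum(min)
        mins = np.minimum(matrix[i + 1 :], matrix[i]).sum(axis=1)
        maxs = totals[i + 1 :] + totals[i] - mins
        with np.errstate(invalid="ignore"):
            sims = np.where(maxs > 0, mins / maxs, 0.0)
        for offset in np.nonzero(sims >= s_min)[0]:
            j = i + 1 + int(offset)
            out.append((ids[i], ids[j], float(sims[offset])))
    return out


def detect_degradation_cliffs(
    pairs: Sequence[tuple[str, str, float]],
    records: Sequence[DegradationRecord],
    delta_min: float = DEFAULT_DELTA_MIN,
    require_both: bool = True,
    manual_pairs: Sequence[tuple[str, str, float]] = (),
) -> list[CliffPair]:
    """Annotate candidate pairs with degradation deltas and the dual flag.

    Every candidate pair is returned (the unfiltered stage); passes_dual
    marks those whose delta exceeds delta_min at both concentrations (or at
    the low concentration only when require_both is false). Manual pairs are
    appended with provenance "manual".
    """
    by_id = {rec.id: rec for rec in records}
    out = []
    for provenance, plist in (("auto", pairs), ("manual", manual_pairs)):
        for id_i, id_j, similarity in plist:
            id_i, id_j = sorted((id_i, id_j))
            for cid in (id_i, id_j):
                if cid not in by_id:
                    raise KeyError(f"no degradation record for compound {cid!r}")
                rec = by_id[cid]
                if rec.deg_low is None or rec.deg_high is None:
                    raise ValueError(f"missing concentration value for {cid!r}")
            ri, rj = by_id[id_i], by_id[id_j]
            delta_low = abs(ri.deg_low - rj.deg_low)
            delta_high = abs(ri.deg_high - rj.deg_high)
            if require_both:
                passes = delta_low >= delta_min and delta_high >= delta_min
            else:
                passes = delta_low >= delta_min
            out.append(
                CliffPair(
                    id_i=id_i,
                    id_j=id_j,
                    similarity=float(similarity),
                    delta_low=float(delta_low),
                    delta_high=float(delta_high),
                    passes_dual=bool(passes),
                    provenance=provenance,
                )
            )
    return out
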