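"""Slide-level spatial quantifications.

Implements the per-slide statistics of the melanoma proximity analysis:
marker densities (cells per mm^2), marker frequencies (% of nucleated
cells), the radius-based pairing count (distinct target cells with at least
one reference cell within a Euclidean centroid distance), the pairing
statistic normalized to the reference-cell count, and pre/post log2
fold-changes of any of these metrics.

Pairing semantics: "paired cells" counts distinct target cells, not
(target, reference) edges; an all-pairs mode is available behind
``mode="pairs"``. The distance comparison is boundary-inclusive
(d <= r counts) and performed on squared distances so that accelerated
KD-tree search agrees exactly with brute force even for ties at d == r.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ._errors import ValidationError
from .io import PatientPairRecord, SlideCellTable

logger = logging.getLogger(__name__)

#: Sentinel accepted wherever a radius is expected: pair at any distance
#: (every target pairs as soon as one reference cell exists on the slide).
ANY_RADIUS = "any"


def cell_density(slide: SlideCellTable, marker: str) -> float:
    """Cells carrying ``marker`` per mm^2 of slide region."""
    area = slide.area_mm2
    return slide.marker_count(marker) / area


def marker_frequency(slide: SlideCellTable, marker: str) -> float:
    """Percentage of nucleated cells carrying ``marker``."""
    nuc = slide.cells["nucleated"].to_numpy(dtype=bool)
    n_nuc = int(nuc.sum())
    if n_nuc == 0:
        raise ValidationError(
            f"slide {slide.slide_id!r}: marker frequency undefined with zero "
            "nucleated cells"
        )
    pos = int((slide.marker_mask(marker) & nuc).sum())
    return 100.0 * pos / n_nuc


def _check_radius(radius_um) -> None:
    if radius_um == ANY_RADIUS:
        return
    if not (isinstance(radius_um, (int, float)) and radius_um > 0):
        raise ValidationError(f"radius must be > 0 or 'any', got {radius_um!r}")


def count_paired_cells(
    slide: SlideCellTable,
    target_marker: str,
    reference_marker: str,
    radius_um,
    *,
    mode: str = "cells",
    method: str = "kdtree",
) -> int:
    """Count target cells with >= 1 reference neighbor within ``radius_um``.

    ``mode="cells"`` (default) counts distinct target cells;
    ``mode="pairs"`` counts all (target, reference) pairs within the radius.
    ``method`` selects the KD-tree accelerated search or the O(n^2) brute
    force; both compare squared distances and return identical counts.
    """
    if target_marker == reference_marker:
        raise ValidationError("self-pairing is undefined: target == reference")
    if mode not in ("cells", "pairs"):
        raise ValidationError(f"unknown pairing mode {mode!r}")
    _check_radius(radius_um)

    tgt = slide.positions(target_marker)
    ref = slide.positions(reference_marker)
    if len(tgt) == 0 or len(ref) == 0:
        return 0
    if radius_um == ANY_RADIUS:
        return len(tgt) if mode == "cells" else len(tgt) * len(ref)

    r2 = float(radius_um) ** 2
    if method == "brute":
        d2 = cdist(tgt, ref, metric="sqeuclidean")
        hits = d2 <= r2
        return int(hits.any(axis=1).sum()) if mode == "cells" \
            else int(hits.sum())
    if method != "kdtree":
        raise ValidationError(f"unknown search method {method!r}")

    # Query with a slightly inflated radius, then confirm with the exact
    # squared-distance comparison so boundary ties match brute force.
    tree = cKDTree(ref)
    neighbors = tree.query_ball_point(tgt, float(radius_um) * (1 + 1e-9))
    total = 0
    for i, idx in enumerate(neighbors):
        if not idx:
            continue
        d2 = np.sum((ref[idx] - tgt[i]) ** 2, axis=1)
        n_hit = int((d2 <= r2).sum())
        total += (n_hit > 0) if mode == "cells" else n_hit
    return int(total)


def pair_statistic(
    slide: SlideCellTable,
    target_marker: str,
    reference_marker: str,
    radius_um,
    *,
    mode: str = "cells",
) -> float | None:
    """Paired-cell count normalized to the reference-cell count.

    Returns ``None`` (flagged undefined, logged) when the slide has no
    reference cells; callers propagate the flag and exclude such slides
    pairwise from correlations.
    """
    n_ref = slide.marker_count(reference_marker)
    if n_ref == 0:
        logger.warning(
            "slide %s: pair statistic undefined (no %s cells)",
            slide.slide_id, reference_marker,
        )
        return None
    paired = count_paired_cells(
        slide, target_marker, reference_marker, radius_um, mode=mode)
    return paired / n_ref


def log2_fold_change(
    pre_value: float,
    post_value: float,
    pseudocount: float | None = None,
) -> float | None:
    """log2(post / pre); ``None`` when either side is zero.

    No silent pseudocount: pass ``pseudocount`` explicitly (logged) to add
    epsilon to both sides before the ratio.
    """
    if pre_value is None or post_value is None:
        return None
    if pre_value < 0 or post_value < 0:
        raise ValidationError("fold-change inputs must be >= 0")
    if pseudocount is not None:
        logger.info("log2 fold-change using pseudocount %g", pseudocount)
        pre_value, post_value = pre_value + pseudocount, post_value + pseudocount
    if pre_value == 0 or post_value == 0:
        return None
    return math.log2(post_value / pre_value)


# ---------------------------------------------------------------------------
# per-slide metric bundle and per-patient fold changes
# ---------------------------------------------------------------------------

@dataclass
class PairStat:
    radius: object
    paired_count: int
    reference_count: int
    statistic: float | None


@dataclass
class ProximityMetrics:
    """All per-slide quantifications for one (target, reference) pair."""

    slide_id: str
    target_marker: str
    reference_marker: str
    density_per_mm2: dict = field(default_factory=dict)
    frequency_pct: dict = field(default_factory=dict)
    pair_stats: dict = field(default_factory=dict)

    def metric(self, name: str) -> float | None:
        """Look up a metric by its report name.

        Names: ``density:<marker>``, ``frequency:<marker>``,
        ``pairstat:<radius>`` (radius printed as integer when whole, or
        ``any``).
        """
        kind, _, key = name.partition(":")
        if kind == "density":
            return self.density_per_mm2[key]
        if kind == "frequency":
            return self.frequency_pct[key]
        if kind == "pairstat":
            return self.pair_stats[key].statistic
        raise KeyError(name)


def _radius_key(radius) -> str:
    if radius == ANY_RADIUS:
        return ANY_RADIUS
    r = float(radius)
    return str(int(r)) if r.is_integer() else str(r)


def compute_metrics(
    slide: SlideCellTable,
    target_marker: str = "SOX10",
    reference_marker: str = "CD8",
    radii=(45.0, ANY_RADIUS),
    *,
    mode: str = "cells",
) -> ProximityMetrics:
    """Bundle density, frequency and pairing statistics for one slide."""
    m = ProximityMetrics(slide.slide_id, target_marker, reference_marker)
    for marker in (target_marker, reference_marker):
        m.density_per_mm2[marker] = cell_density(slide, marker)
        m.frequency_pct[marker] = marker_frequency(slide, marker)
    n_ref = slide.marker_count(reference_marker)
    for r in radii:
        paired = count_paired_cells(
            slide, target_marker, reference_marker, r, mode=mode)
        stat = (paired / n_ref) if n_ref else None
        m.pair_stats[_radius_key(r)] = PairStat(r, paired, n_ref, stat)
    return m


@dataclass(frozen=True)
class FoldChangeRecord:
    """Pre -> post change of one per-slide metric for one patient."""

    patient_id: str
    metric: str
    pre_value: float | None
    post_value: float | None
    log2_fc: float | None

    @property
    def defined(self) -> bool:
        return self.log2_fc is not None


def metric_names(
    target_marker: str = "SOX10",
    radii=(45.0, ANY_RADIUS),
) -> list[str]:
    """Canonical report metric names for a target marker and radius list."""
    return (
        [f"density:{target_marker}", f"frequency:{target_marker}"]
        + [f"pairstat:{_radius_key(r)}" for r in radii]
    )


def fold_change_records(
    metrics_by_slide: dict[str, ProximityMetrics],
    clinical: list[PatientPairRecord],
    metrics: list[str] | None = None,
    pseudocount: float | None = None,
) -> list[FoldChangeRecord]:
    """Per-patient log2 fold-changes of each per-slide metric."""
    records = []
    n_undefined = 0
    for rec in clinical:
        pre = metrics_by_slide[rec.pre_slide_id]
        post = metrics_by_slide[rec.post_slide_id]
        names = metrics if metrics is not None else metric_names(
            pre.target_marker, [p.radius for p in pre.pair_stats.values()])
        for name in names:
            pre_v, post_v = pre.metric(name), post.metric(name)
            fc = log2_fold_change(pre_v, post_v, pseudocount) \
                if (pre_v is not None and post_v is not None) else None
            if fc is None:
                n_undefined += 1
            records.append(FoldChangeRecord(rec.patient_id, name,
                                            pre_v, post_v, fc))
    if n_undefined:
        logger.info("%d fold-change values undefined and flagged", n_undefined)
    return records
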