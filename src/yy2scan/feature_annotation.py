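"""Nearest-feature annotation, location classes and lncRNA proximity tiers.

Each peak is annotated with the closest catalog feature within 100 kb
(edge-to-edge gap, 0 when overlapping) and assigned exactly one location
class with precedence TSS > O > (DU|DD) > I:

* ``TSS`` — a peak edge lies within 2,500 bp of some feature's TSS
  (or the peak spans the TSS);
* ``O``   — the peak overlaps a transcribed feature;
* ``DU``  — nearest feature within 100 kb, peak 5' of its TSS;
* ``DD``  — nearest feature within 100 kb, peak 3' of its transcribed end;
* ``I``   — no feature within 100 kb.

All distance thresholds are inclusive.  lncRNA tiers use the same gap
measure against lncRNA-biotype features only: gap <= 5 kb, else
<= 100 kb, else other; the 5 kb tier takes precedence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from yy2scan.enrichment_scoring import Peak
from yy2scan.io_genomics import FeatureCatalog, FeatureRecord, GenomicInterval

LocationClass = Literal["TSS", "O", "DU", "DD", "I"]
LncTier = Literal["lnc_within_5kb", "lnc_within_100kb", "other"]

MAX_ANNOTATION_DIST = 100_000
TSS_RADIUS = 2_500
LNC_NEAR = 5_000


@dataclass
class AnnotationResult:
    peak: Peak
    feature: FeatureRecord | None
    distance_to_tss: int | None
    overlaps_feature: bool
    location_class: LocationClass
    lnc_tier: LncTier


def _gap(peak: GenomicInterval, feature: GenomicInterval) -> int:
    if peak.start < feature.end and feature.start < peak.end:
        return 0
    return max(peak.start, feature.start) - min(peak.end, feature.end)


def _tss_edge_distance(peak: GenomicInterval, tss: int) -> int:
    """Unsigned bp from the nearest peak edge (inclusive bases) to the TSS; 0 if spanned."""
    if peak.start <= tss < peak.end:
        return 0
    return min(abs(peak.start - tss), abs(peak.end - 1 - tss))


def signed_tss_distance(peak: GenomicInterval, feature: FeatureRecord) -> int:
    """Signed bp from the nearest peak edge to the feature's TSS.

    Negative means the peak lies upstream of the TSS in the feature's
    orientation; 0 means the peak spans the TSS.
    """
    tss = feature.tss
    if peak.start <= tss < peak.end:
        return 0
    edge = peak.end - 1 if peak.end <= tss else peak.start
    genomic_offset = edge - tss
    return genomic_offset if feature.strand == "+" else -genomic_offset


def nearest_feature(
    peak: Peak | GenomicInterval,
    catalog: FeatureCatalog,
    max_dist: int = MAX_ANNOTATION_DIST,
) -> tuple[FeatureRecord | None, int | None]:
    """Closest feature within ``max_dist`` by edge gap, with its signed TSS distance.

    Ties on gap break by smaller absolute TSS distance, then feature_id.
    Returns ``(None, None)`` when nothing is within range (boundary
    inclusive: a feature exactly ``max_dist`` away still qualifies).
    """
    iv = peak.interval if isinstance(peak, Peak) else peak
    candidates = catalog.on_chrom(iv.chrom)
    if not candidates:
        return None, None
    best: FeatureRecord | None = None
    best_key: tuple | None = None
    for f in candidates:
        gap = _gap(iv, f.interval)
        if gap > max_dist:
            continue
        key = (gap, abs(signed_tss_distance(iv, f)), f.feature_id)
        if best_key is None or key < best_key:
            best, best_key = f, key
    if best is None:
        return None, None
    return best, signed_tss_distance(iv, best)


def classify_location(
    peak: Peak | GenomicInterval,
    catalog: FeatureCatalog,
    tss_radius: int = TSS_RADIUS,
    max_dist: int = MAX_ANNOTATION_DIST,
) -> LocationClass:
    iv = peak.interval if isinstance(peak, Peak) else peak
    features = catalog.on_chrom(iv.chrom)
    if any(_tss_edge_distance(iv, f.tss) <= tss_radius for f in features):
        return "TSS"
    if any(iv.overlaps(f.interval) for f in features):
        return "O"
    feature, _ = nearest_feature(iv, catalog, max_dist)
    if feature is None:
        return "I"
    # peak does not overlap the feature: it sits on the TSS side or the 3' side
    if feature.strand == "+":
        return "DU" if iv.end <= feature.interval.start else "DD"
    return "DU" if iv.start >= feature.interval.end else "DD"


def lncrna_tier(peak: Peak | GenomicInterval, catalog: FeatureCatalog) -> LncTier:
    iv = peak.interval if isinstance(peak, Peak) else peak
    gaps = [_gap(iv, f.interval) for f in catalog.by_biotype("lncRNA", iv.chrom)]
    if gaps and min(gaps) <= LNC_NEAR:
        return "lnc_within_5kb"
    if gaps and min(gaps) <= MAX_ANNOTATION_DIST:
        return "lnc_within_100kb"
    return "other"


def annotate_peak(
    peak: Peak,
    catalog: FeatureCatalog,
    tss_radius: int = TSS_RADIUS,
    max_dist: int = MAX_ANNOTATION_DIST,
) -> AnnotationResult:
    feature, dist = nearest_feature(peak, catalog, max_dist)
    result = AnnotationResult(
        peak=peak,
        feature=feature,
        distance_to_tss=dist,
        overlaps_feature=feature is not None and peak.interval.overlaps(feature.interval),
        location_class=classify_location(peak, catalog, tss_radius, max_dist),
        lnc_tier=lncrna_tier(peak, catalog),
    )
    peak.annotation = result
    return result


def annotate_peaks(
    peaks: Iterable[Peak],
    catalog: FeatureCatalog,
    tss_radius: int = TSS_RADIUS,
    max_dist: int = MAX_ANNOTATION_DIST,
) -> list[AnnotationResult]:
    return [annotate_peak(p, catalog, tss_radius, max_dist) for p in peaks]


def summarize_classes(results: Sequence[AnnotationResult]) -> dict[str, dict[str, int]]:
    """Counts per location class and lncRNA tier; each family sums to len(results)."""
    loc = Counter(r.location_class for r in results)
    tier = Counter(r.lnc_tier for r in results)
    return {
        "location_class": {c: loc.get(c, 0) for c in ("TSS", "O", "DU", "DD", "I")},
        "lnc_tier": {t: tier.get(t, 0) for t in ("lnc_within_5kb", "lnc_within_100kb", "other")},
    }
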