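"""Reporter-screen fragment filtering and enhancer activity calling.

The screen integrates open-chromatin fragments upstream of a reporter and
recovers active fragments from FACS-sorted high- and low-fluorescence
cells. Three filters clean the recovered fragment sets, applied in order:

1. drop any fragment coordinate-identical to a negative-control fragment
   (PCR artefacts from cells without a reporter cassette);
2. keep only fragments coordinate-identical to some plasmid-library
   fragment (the fragment must have existed in the transfected library);
3. keep only fragments overlapping at least one ATAC peak.

A peak is enhancer-positive if at least one retained fragment overlaps
it. Positive peaks get an activity state from the library-size-normalised
ratio of high- to low-sorted fragments (fragments-per-million); exact
ties go to Low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genomic_core import GenomicInterval, find_overlaps
from .io_formats import FragmentRecord

logger = logging.getLogger(__name__)

__all__ = ["EnhancerCall", "FilterLog", "filter_fragments", "call_enhancer_positive",
           "assign_activity_state", "call_activity"]

STATES = ("High", "Low", "NotPositive")


@dataclass(frozen=True)
class EnhancerCall:
    """Per-peak, per-stage enhancer positivity and activity state."""

    peak_id: str
    stage: str
    positive: bool
    n_high: int
    n_low: int
    norm_high: float
    norm_low: float
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if self.positive != (self.n_high + self.n_low >= 1):
            raise ValueError("positive must equal (n_high + n_low) >= 1")
        if self.positive != (self.state in ("High", "Low")):
            raise ValueError("state High/Low iff positive")


@dataclass
class FilterLog:
    """Removal counts for each step of the fragment filtering cascade."""

    n_input: int = 0
    removed_negative: int = 0
    removed_not_in_plasmid: int = 0
    removed_no_peak: int = 0
    n_retained: int = 0


def _match_keys(frag: GenomicInterval, keys: set[tuple[str, int, int]], slop: int) -> bool:
    if slop == 0:
        return frag.key in keys
    for ds in range(-slop, slop + 1):
        for de in range(-slop, slop + 1):
            if (frag.chrom, frag.start + ds, frag.end + de) in keys:
                return True
    return False


def filter_fragments(
    screen: Sequence[FragmentRecord],
    negatives: Sequence[FragmentRecord],
    plasmid: Sequence[FragmentRecord],
    atac_peaks: Sequence[GenomicInterval],
    slop: int = 0,
) -> tuple[list[FragmentRecord], FilterLog]:
    """Apply the three-step filtering cascade to screen fragments.

    "Identical fragment" means exact chrom/start/end equality by default;
    ``slop`` relaxes the match to +/- that many bp on each edge.
    """
    if not plasmid:
        raise ValueError(
            "plasmid library is empty: the plasmid-membership filter would "
            "silently erase every fragment"
        )
    log = FilterLog(n_input=len(screen))
    neg_keys = {f.interval.key for f in negatives}
    step1 = [f for f in screen if not _match_keys(f.interval, neg_keys, slop)]
    log.removed_negative = len(screen) - len(step1)

    plasmid_keys = {f.interval.key for f in plasmid}
    step2 = [f for f in step1 if _match_keys(f.interval, plasmid_keys, slop)]
    log.removed_not_in_plasmid = len(step1) - len(step2)

    hits = find_overlaps([f.interval for f in step2], list(atac_peaks))
    with_peak = {qi for qi, _ in hits}
    retained = [f for i, f in enumerate(step2) if i in with_peak]
    log.removed_no_peak = len(step2) - len(retained)
    log.n_retained = len(retained)
    logger.info(
        "filter_fragments: %d in, -%d negative-control, -%d not-in-plasmid, "
        "-%d no-peak, %d retained",
        log.n_input, log.removed_negative, log.removed_not_in_plasmid,
        log.removed_no_peak, log.n_retained,
    )
    return retained, log


def call_enhancer_positive(
    atac_peaks: Mapping[str, GenomicInterval],
    retained_fragments: Sequence[FragmentRecord],
) -> dict[str, bool]:
    """positive(peak) = at least one retained fragment overlaps the peak."""
    peak_ids = sorted(atac_peaks)
    hits = find_overlaps(
        [atac_peaks[p] for p in peak_ids], [f.interval for f in retained_fragments]
    )
    positive_idx = {qi for qi, _ in hits}
    return {p: (i in positive_idx) for i, p in enumerate(peak_ids)}


def assign_activity_state(
    peak_id: str,
    stage: str,
    n_high: int,
    n_low: int,
    total_high_library: int,
    total_low_library: int,
    activity_ratio: float = 1.0,
) -> EnhancerCall:
    """Assign High/Low from library-normalised fragment counts.

    ``norm = 1e6 * n / library_total`` (fragments per million). State is
    High iff ``norm_high > activity_ratio * norm_low``; ties (and the
    all-zero degenerate case) go to Low, biasing against over-calling
    strong enhancers.
    """
    if total_high_library <= 0 or total_low_library <= 0:
        raise ValueError("library totals must be positive")
    if n_high + n_low < 1:
        raise ValueError(f"peak {peak_id} is not positive; no state to assign")
    norm_high = 1e6 * n_high / total_high_library
    norm_low = 1e6 * n_low / total_low_library
    state = "High" if norm_high > activity_ratio * norm_low else "Low"
    return EnhancerCall(peak_id, stage, True, n_high, n_low, norm_high, norm_low, state)


def call_activity(
    atac_peaks: Mapping[str, GenomicInterval],
    high_fragments: Sequence[FragmentRecord],
    low_fragments: Sequence[FragmentRecord],
    stage: str,
    total_high_library: int | None = None,
    total_low_library: int | None = None,
    activity_ratio: float = 1.0,
) -> dict[str, EnhancerCall]:
    """Full per-peak calling: count overlapping high/low fragments, call
    positivity, and assign states. Library totals default to the sizes of
    the supplied (already filtered) sorted libraries."""
    if total_high_library is None:
        total_high_library = len(high_fragments)
    if total_low_library is None:
        total_low_library = len(low_fragments)
    peak_ids = sorted(atac_peaks)
    peaks = [atac_peaks[p] for p in peak_ids]
    high_counts = [0] * len(peak_ids)
    for qi, _ in find_overlaps(peaks, [f.interval for f in high_fragments]):
        high_counts[qi] += 1
    low_counts = [0] * len(peak_ids)
    for qi, _ in find_overlaps(peaks, [f.interval for f in low_fragments]):
        low_counts[qi] += 1

    calls: dict[str, EnhancerCall] = {}
    for i, pid in enumerate(peak_ids):
        nh, nl = high_counts[i], low_counts[i]
        if nh + nl >= 1:
            calls[pid] = assign_activity_state(
                pid, stage, nh, nl, total_high_library, total_low_library,
                activity_ratio,
            )
        else:
            calls[pid] = EnhancerCall(pid, stage, False, 0, 0, 0.0, 0.0, "NotPositive")
    return calls
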