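"""Training-corpus construction.

Negative (pseudo-hairpin) examples for the precursor stage are mined
from protein-coding sequences: a scan with randomly sized windows keeps
segments that fold into single stem-loops and pass composition,
pairing-density and stability filters calibrated on real intercepted
plant precursors.  Positive/negative segment sets for the
mature-locating stage are cut from annotated precursors by interception
and by sampling pairing-closed off-target segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .hairpin import (
    HairpinRecord,
    MatureAnnotation,
    RnaSequence,
    intercept,
    is_single_stem_loop,
)
from .features import WINDOW, _gc_fraction, mfe_indices

logger = logging.getLogger(__name__)

# Fitted constants of the precursor-stability sigmoid f(x) = a / (b + e^(x*c)),
# x = MFE/length.
STABILITY_A = 1.339e-12
STABILITY_B = 2.7783e-13
STABILITY_C = 45.843


def stability(mfe: float, length: int) -> float:
    """Stability score f(x) = a/(b + e^(x*c)) with x = MFE/length.

    Monotone decreasing in x; ranges over (0, a/b).  More negative
    folding energy per nucleotide gives a larger score.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    x = mfe / length
    return STABILITY_A / (STABILITY_B + math.exp(x * STABILITY_C))


@dataclass
class PseudoHairpinCriteria:
    """Acceptance rules for mined pseudo hairpins.

    The stability rule is kept literal by default (keep when
    f(x) > threshold with threshold = -4.42); since f is strictly
    positive this default is non-binding, and both the threshold and the
    comparison direction are configurable.
    """

    min_base_pairs: int = 19
    gc_range: tuple = (0.242, 0.825)
    mfei_range: tuple = (0.522, 1.39)
    single_loop: bool = True
    max_consecutive_unpaired: int = 3
    max_unpaired_in_mature: int = 7
    stability_threshold: float = -4.42
    stability_keep_above: bool = True

    def __post_init__(self) -> None:
        if self.gc_range[0] >= self.gc_range[1] or self.mfei_range[0] >= self.mfei_range[1]:
            raise ValueError("criteria ranges must be well-ordered")


def _max_run_unpaired_in_arms(record: HairpinRecord) -> int:
    """Longest run of unpaired positions within the stem region (the
    hairpin loop is excluded -- it would trivially violate any bound)."""
    ann = record.annotation
    best = 0
    for arm in (ann.arm5, ann.arm3):
        if arm is None:
            continue
        run = 0
        for p in range(arm[0], arm[1]):
            if p in ann.partner:
                run = 0
            else:
                run += 1
                best = max(best, run)
    return best


def _best_mature_window_mismatches(record: HairpinRecord) -> int:
    """Minimum unpaired count over all 21-nt windows of either arm: the
    best placement a mature miRNA could take on this hairpin."""
    ann = record.annotation
    best = None
    for arm in (ann.arm5, ann.arm3):
        if arm is None:
            continue
        a, b = arm
        if b - a < WINDOW:
            mism = sum(1 for p in range(a, b) if p not in ann.partner) + (WINDOW - (b - a))
            best = mism if best is None else min(best, mism)
            continue
        for start in range(a, b - WINDOW + 1):
            mism = sum(1 for p in range(start, start + WINDOW) if p not in ann.partner)
            best = mism if best is None else min(best, mism)
    return best if best is not None else WINDOW


def check_criteria(record: HairpinRecord, criteria: PseudoHairpinCriteria) -> dict:
    """Evaluate every pseudo-hairpin rule; returns {rule: passed}."""
    ann = record.annotation
    gc = _gc_fraction(record.sequence.residues)
    mfei1 = abs(mfe_indices(record)["MFEI1"])
    stab = stability(record.structure.mfe, len(record))
    if criteria.stability_keep_above:
        stab_ok = stab > criteria.stability_threshold
    else:
        stab_ok = stab <= criteria.stability_threshold
    return {
        "single_loop": (not criteria.single_loop) or is_single_stem_loop(ann),
        "min_base_pairs": ann.tot_base_pairs >= criteria.min_base_pairs,
        "gc": criteria.gc_range[0] < gc < criteria.gc_range[1],
        "mfei": criteria.mfei_range[0] < mfei1 < criteria.mfei_range[1],
        "consecutive_unpaired": _max_run_unpaired_in_arms(record)
        <= criteria.max_consecutive_unpaired,
        "mature_unpaired": _best_mature_window_mismatches(record)
        <= criteria.max_unpaired_in_mature,
        "stability": stab_ok,
    }


def passes_criteria(record: HairpinRecord, criteria: PseudoHairpinCriteria) -> bool:
    return all(check_criteria(record, criteria).values())


@dataclass
class MinedHairpin:
    record: HairpinRecord
    source_id: str
    offset: int
    width: int


def mine_pseudo_hairpins(
    cds: Sequence[RnaSequence],
    criteria: Optional[PseudoHairpinCriteria] = None,
    window_range: tuple = (60, 150),
    n_windows: Optional[int] = None,
    seed: int = 0,
    temperature: float = 37.0,
) -> List[MinedHairpin]:
    """Scan CDS records with randomly sized windows and keep hairpins
    that satisfy every pseudo-hairpin criterion.

    Windows have widths drawn uniformly from `window_range` at
    sequential (non-overlapping) offsets; the draw is seeded so the
    mined set is reproducible byte-for-byte.  CDS shorter than the
    minimum width contribute nothing.
    """
    criteria = criteria or PseudoHairpinCriteria()
    lo, hi = window_range
    rng = np.random.default_rng(seed)
    out: List[MinedHairpin] = []
    for rec in cds:
        L = len(rec)
        if L < lo:
            logger.info("CDS %s shorter than %d nt; skipped", rec.id, lo)
            continue
        offset = 0
        while offset + lo <= L:
            width = int(rng.integers(lo, hi + 1))
            end = min(offset + width, L)
            if end - offset >= lo:
                window = rec.subsequence(offset, end, id=f"{rec.id}|{offset}-{end}")
                hp = HairpinRecord.from_sequence(window, temperature=temperature)
                if passes_criteria(hp, criteria):
                    out.append(
                        MinedHairpin(record=hp, source_id=rec.id, offset=offset, width=end - offset)
                    )
                    if n_windows is not None and len(out) >= n_windows:
                        return out
            offset += width
    return out


# ---------------------------------------------------------------------------
# Mature-stage segment sets
# ---------------------------------------------------------------------------

MIN_SEGMENT_LEN = 56  # segments must be longer than 55 nt


@dataclass
class SegmentSample:
    parent_id: str
    interval: tuple
    label: str  # mat_positive | mat_negative
    record: HairpinRecord


def build_mat_positives(
    precursors: Sequence[HairpinRecord],
    annotations: Sequence[MatureAnnotation],
    temperature: float = 37.0,
) -> List[SegmentSample]:
    """One positive segment per (precursor, annotation) via interception.

    Annotations lacking a star interval are skipped with a log message.
    """
    by_id: dict = {}
    for ann in annotations:
        by_id.setdefault(ann.precursor_id, []).append(ann)
    out: List[SegmentSample] = []
    for rec in precursors:
        for ann in by_id.get(rec.id, []):
            if ann.star_interval is None:
                logger.info("%s: no miRNA* annotation; positive segment skipped", rec.id)
                continue
            seg = intercept(rec, ann, temperature=temperature)
            start = min(ann.mir_interval[0], ann.star_interval[0])
            end = max(ann.mir_interval[1], ann.star_interval[1])
            out.append(
                SegmentSample(parent_id=rec.id, interval=(start, end), label="mat_positive", record=seg)
            )
    return out


def close_under_pairing(record: HairpinRecord, interval: tuple) -> tuple:
    """Smallest contiguous interval containing `interval` that is closed
    under base pairing: if a position is included, so is its partner."""
    a, b = interval
    partner = record.annotation.partner
    lo, hi = a, b
    changed = True
    while changed:
        changed = False
        for p in range(lo, hi):
            q = partner.get(p)
            if q is not None:
                if q < lo:
                    lo = q
                    changed = True
                elif q >= hi:
                    hi = q + 1
                    changed = True
    return (lo, hi)


def build_mat_negatives(
    precursor: HairpinRecord,
    positive: SegmentSample,
    n: int = 5,
    seed: int = 0,
    temperature: float = 37.0,
    max_attempts_per_sample: int = 50,
) -> List[SegmentSample]:
    """Sample off-target segments of the precursor as mature-stage
    negatives: longer than 55 nt, closed under pairing (partners of
    included paired bases are pulled in to preserve the stem-loop), and
    distinct from the positive interval."""
    L = len(precursor)
    rng = np.random.default_rng(seed)
    out: List[SegmentSample] = []
    seen = {tuple(positive.interval)}
    attempts = 0
    while len(out) < n and attempts < n * max_attempts_per_sample:
        attempts += 1
        if L < MIN_SEGMENT_LEN:
            break
        start = int(rng.integers(0, L - MIN_SEGMENT_LEN + 1))
        length = int(rng.integers(MIN_SEGMENT_LEN, L - start + 1))
        interval = close_under_pairing(precursor, (start, start + length))
        if interval[1] - interval[0] < MIN_SEGMENT_LEN or interval in seen:
            continue
        seen.add(interval)
        sub = precursor.sequence.subsequence(
            interval[0], interval[1], id=f"{precursor.id}|neg:{interval[0]}-{interval[1]}"
        )
        rec = HairpinRecord.from_sequence(sub, temperature=temperature)
        out.append(
            SegmentSample(parent_id=precursor.id, interval=interval, label="mat_negative", record=rec)
        )
    if not out:
        logger.info("%s: no valid mature-stage negatives could be sampled", precursor.id)
    return out
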