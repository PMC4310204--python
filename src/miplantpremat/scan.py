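"""Homology-seeded genome scan for candidate miRNAs.

A known mature miRNA query is split into four nearly equal seeds; each
seed is located exactly with Knuth-Morris-Pratt, and each seed hit
anchors a full-length Hamming comparison of the query.  By pigeonhole,
a site with at most 3 mismatches preserves at least one exact seed, so
the seeded search is complete for the default mismatch bound.  Verified
sites are expanded into candidate precursor windows, folded, filtered
with the pseudo-hairpin criteria plus scan-specific rules, and finally
classified with the two-stage model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .hairpin import (
    HairpinRecord,
    RnaSequence,
    is_single_stem_loop,
    reverse_complement,
)
from .datasets import PseudoHairpinCriteria, check_criteria
from .classify import FeatureConfig, TwoStageModel, Verdict

logger = logging.getLogger(__name__)


def kmp_failure(pattern: str) -> list:
    fail = [0] * len(pattern)
    k = 0
    for i in range(1, len(pattern)):
        while k and pattern[i] != pattern[k]:
            k = fail[k - 1]
        if pattern[i] == pattern[k]:
            k += 1
        fail[i] = k
    return fail


def kmp_search(pattern: str, text: str) -> list:
    """All 0-based exact occurrences of `pattern` in `text`, left to
    right (Knuth-Morris-Pratt; overlapping matches included)."""
    if not pattern:
        raise ValueError("empty pattern")
    if len(pattern) > len(text):
        return []
    fail = kmp_failure(pattern)
    out = []
    k = 0
    for i, ch in enumerate(text):
        while k and ch != pattern[k]:
            k = fail[k - 1]
        if ch == pattern[k]:
            k += 1
        if k == len(pattern):
            out.append(i - k + 1)
            k = fail[k - 1]
    return out


@dataclass(frozen=True)
class SeedPlan:
    """Four nearly equal seeds covering the query, with their offsets."""

    query: str
    seeds: tuple  # of (offset, substring)


def split_seeds(query: str, n_seeds: int = 4) -> SeedPlan:
    """Split into `n_seeds` nearly equal parts: the first (k mod n)
    seeds get the ceiling length, the rest the floor; lengths differ by
    at most 1 and the seeds concatenate back to the query."""
    k = len(query)
    if k < n_seeds:
        raise ValueError(f"query of length {k} cannot be split into {n_seeds} seeds")
    base, extra = divmod(k, n_seeds)
    seeds = []
    off = 0
    for i in range(n_seeds):
        ln = base + (1 if i < extra else 0)
        seeds.append((off, query[off:off + ln]))
        off += ln
    return SeedPlan(query=query, seeds=tuple(seeds))


@dataclass(frozen=True)
class SiteMatch:
    contig: str
    position: int  # 0-based on the + reference
    length: int
    strand: str  # + | -
    mismatches: int
    query_id: str


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_sites(
    query: RnaSequence,
    genome: Sequence[RnaSequence],
    max_mismatch: int = 2,
    n_seeds: int = 4,
) -> List[SiteMatch]:
    """All genome sites matching `query` with at most `max_mismatch`
    substitutions, on both strands.

    Complete for max_mismatch < n_seeds (pigeonhole).  Minus-strand
    hits come from scanning the reverse complement of the query; their
    positions are reported on the + reference with strand '-'.
    """
    if max_mismatch >= n_seeds:
        logger.warning(
            "max_mismatch=%d >= n_seeds=%d: seeded search loses completeness",
            max_mismatch, n_seeds,
        )
    out: List[SiteMatch] = []
    k = len(query)
    for contig in genome:
        text = contig.residues
        for strand, q in (("+", query.residues), ("-", reverse_complement(query.residues))):
            plan = split_seeds(q, n_seeds)
            found = set()
            for off, seed in plan.seeds:
                if len(seed) > len(text):
                    continue
                for pos in kmp_search(seed, text):
                    start = pos - off
                    if start < 0 or start + k > len(text) or start in found:
                        continue
                    mm = _hamming(q, text[start:start + k])
                    if mm <= max_mismatch:
                        found.add(start)
                        out.append(
                            SiteMatch(
                                contig=contig.id, position=start, length=k,
                                strand=strand, mismatches=mm, query_id=query.id,
                            )
                        )
    out.sort(key=lambda s: (s.contig, s.position, s.strand))
    return out


@dataclass
class GenomeHit:
    """A located candidate: site, precursor window, folded record,
    per-rule filter flags and the two-stage verdict."""

    site: SiteMatch
    precursor_interval: tuple  # on the + reference of the contig
    record: HairpinRecord
    filter_flags: dict = field(default_factory=dict)
    verdict: Optional[Verdict] = None

    @property
    def passed_filters(self) -> bool:
        return bool(self.filter_flags) and all(self.filter_flags.values())


@dataclass
class ScanCriteria(PseudoHairpinCriteria):
    """Pseudo-hairpin criteria with scan-specific overrides: GC bounded
    to 30-70% and a mature-site complementarity rule (fewer than 6
    non-complementary bases, no gaps on the complementary strand)."""

    gc_range: tuple = (0.30, 0.70)
    max_mature_noncomplementary: int = 5  # strictly fewer than 6


def extract_candidates(
    site: SiteMatch,
    genome: Sequence[RnaSequence],
    widths: tuple = (60, 150),
    step: int = 10,
    temperature: float = 37.0,
) -> List[GenomeHit]:
    """Fold windows of 60-150 nt around a matched site; keep single
    stem-loops in which the site lies within the stem region.

    Window starts/widths are enumerated on a `step`-nt grid over all
    placements containing the full site; windows truncated at contig
    edges are used as-is (logged).
    """
    contig = next(c for c in genome if c.id == site.contig)
    L = len(contig)
    a, b = site.position, site.position + site.length
    hits: List[GenomeHit] = []
    seen = set()
    for width in range(widths[0], widths[1] + 1, step):
        first = max(0, b - width)
        last = min(a, L - width)
        if last < first:
            logger.debug("site %s:%d: width %d truncated at contig edge", site.contig, a, width)
            last = first
        for start in range(first, last + 1, step):
            end = min(start + width, L)
            if end - start < widths[0] or (start, end) in seen:
                continue
            seen.add((start, end))
            seq = contig.subsequence(start, end, id=f"{site.contig}:{start}-{end}")
            rec = HairpinRecord.from_sequence(seq, temperature=temperature)
            if not is_single_stem_loop(rec.annotation):
                continue
            stem = set(rec.annotation.stem_positions())
            if all(p - start in stem for p in range(a, b)):
                hits.append(GenomeHit(site=site, precursor_interval=(start, end), record=rec))
    return hits


def _mature_complementarity_flags(hit: GenomeHit, criteria: ScanCriteria) -> dict:
    """Scan-specific rules on the matched mature window: fewer than 6
    non-complementary (unpaired) bases and no gaps on the complementary
    strand (the pairing partners form a contiguous run)."""
    rec = hit.record
    start = hit.precursor_interval[0]
    window = range(hit.site.position - start, hit.site.position - start + hit.site.length)
    partner = rec.annotation.partner
    unpaired = sum(1 for p in window if p not in partner)
    partners = sorted(partner[p] for p in window if p in partner)
    no_gaps = all(b - a == 1 for a, b in zip(partners, partners[1:])) if partners else False
    return {
        "mature_complementarity": unpaired <= criteria.max_mature_noncomplementary,
        "no_gaps_on_star_strand": no_gaps,
    }


def filter_candidates(
    candidates: Sequence[GenomeHit],
    criteria: Optional[ScanCriteria] = None,
) -> List[GenomeHit]:
    """Apply every filter rule, flagging each candidate with per-rule
    outcomes; returns the candidates passing all rules.  Rejected
    candidates keep their flags so the failing rule is visible."""
    criteria = criteria or ScanCriteria()
    kept = []
    for hit in candidates:
        flags = check_criteria(hit.record, criteria)
        flags.update(_mature_complementarity_flags(hit, criteria))
        hit.filter_flags = flags
        if all(flags.values()):
            kept.append(hit)
    return kept


def scan_genome(
    queries: Sequence[RnaSequence],
    genome: Sequence[RnaSequence],
    model: Optional[TwoStageModel] = None,
    criteria: Optional[ScanCriteria] = None,
    max_mismatch: int = 2,
    widths: tuple = (60, 150),
    step: int = 10,
    temperature: float = 37.0,
    feature_config: Optional[FeatureConfig] = None,
) -> List[GenomeHit]:
    """Full discovery pipeline: seed search -> candidate extraction ->
    filtering -> two-stage classification.

    Overlapping hits from the same query are collapsed to the
    best-scoring one; hits are sorted by (contig, position).  The
    classifier stage is skipped when no model is supplied (hits then
    carry verdict=None).
    """
    if not queries:
        raise ValueError("empty query set")
    criteria = criteria or ScanCriteria()
    all_hits: List[GenomeHit] = []
    for query in queries:
        hits: List[GenomeHit] = []
        for site in find_sites(query, genome, max_mismatch=max_mismatch):
            cands = extract_candidates(
                site, genome, widths=widths, step=step, temperature=temperature
            )
            hits.extend(filter_candidates(cands, criteria))
        if model is not None:
            for hit in hits:
                hit.verdict = model.predict(
                    hit.record, config=feature_config, temperature=temperature
                )
            hits = [h for h in hits if h.verdict.kind != "reject_pre"]
        # collapse overlapping hits of this query to the best-scoring one
        hits.sort(key=lambda h: (h.site.contig, h.precursor_interval))
        collapsed: List[GenomeHit] = []
        for hit in hits:
            if collapsed and _overlaps(collapsed[-1], hit):
                if _score(hit) > _score(collapsed[-1]):
                    collapsed[-1] = hit
            else:
                collapsed.append(hit)
        all_hits.extend(collapsed)
    all_hits.sort(key=lambda h: (h.site.contig, h.site.position))
    return all_hits


def _overlaps(a: GenomeHit, b: GenomeHit) -> bool:
    if a.site.contig != b.site.contig:
        return False
    (a0, a1), (b0, b1) = a.precursor_interval, b.precursor_interval
    return max(a0, b0) < min(a1, b1)


def _score(hit: GenomeHit) -> float:
    if hit.verdict is not None:
        return hit.verdict.stage1_score
    return -hit.site.mismatches


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def hits_to_bed(hits: Sequence[GenomeHit]) -> str:
    """BED6: contig, precursor start/end, query id, mismatches, strand."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                (
                    h.site.contig,
                    str(h.precursor_interval[0]),
                    str(h.precursor_interval[1]),
                    h.site.query_id,
                    str(h.site.mismatches),
                    h.site.strand,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_table(hits: Sequence[GenomeHit]):
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "contig": h.site.contig,
                "site_pos": h.site.position,
                "strand": h.site.strand,
                "query_id": h.site.query_id,
                "mismatches": h.site.mismatches,
                "precursor_start": h.precursor_interval[0],
                "precursor_end": h.precursor_interval[1],
                "verdict": h.verdict.kind if h.verdict else "",
                "stage1_score": h.verdict.stage1_score if h.verdict else float("nan"),
                **{f"filter_{k}": v for k, v in h.filter_flags.items()},
            }
        )
    return pd.DataFrame(rows)
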