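"""Seeded synthetic-data generators.

Three emulations keep every stage testable without downloads:

* hairpins — single stem-loop precursors built as (possibly degraded)
  inverted repeats with a controllable GC content and a planted mature
  miRNA at the 3' terminus; low arm-degradation rates emulate real
  precursors, high rates emulate pseudo hairpins.
* labelled feature matrices — Gaussian noise with k informative columns
  mean-shifted in the positive class, for selection/recovery tests.
* toy genomes — uniform random background with miRNA copies planted at
  exact Hamming distances, optionally inside a hairpin context.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .hairpin import (
    HairpinRecord,
    MatureAnnotation,
    RnaSequence,
    reverse_complement,
)
from .selection import LabeledDataset

MATURE_LEN = 21


@dataclass
class HairpinSpec:
    """Inverted-repeat hairpin: arm of `stem_len` nt at GC fraction
    `gc`, loop of `loop_len` nt, opposite arm mutated at rate
    `degrade`."""

    stem_len: int = 30
    loop_len: int = 6
    gc: float = 0.5
    degrade: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        if not 0 <= self.degrade <= 1:
            raise ValueError("degrade must be in [0, 1]")


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def make_hairpin(
    spec: HairpinSpec,
    plant_mature: bool = True,
    temperature: float = 37.0,
    with_partition: bool = True,
    record_id: Optional[str] = None,
) -> tuple:
    """Build and fold one synthetic hairpin.

    Returns (HairpinRecord, MatureAnnotation or None).  The 3' arm is
    the reverse complement of the 5' arm with substitutions at rate
    `degrade`; the mature miRNA (21 nt) sits at the 3' terminus with its
    star at the 5' terminus, mirroring the canonical intercepted layout.
    """
    if plant_mature and spec.stem_len < MATURE_LEN:
        raise ValueError(f"stem_len must be >= {MATURE_LEN} to plant a mature miRNA")
    rng = np.random.default_rng(spec.seed)
    arm5 = _random_seq(spec.stem_len, spec.gc, rng)
    loop = _random_seq(spec.loop_len, 0.5, rng)
    arm3 = list(reverse_complement(arm5))
    for i in range(len(arm3)):
        if rng.random() < spec.degrade:
            arm3[i] = rng.choice([c for c in "ACGU" if c != arm3[i]])
    residues = arm5 + loop + "".join(arm3)
    rid = record_id or f"synthetic-hairpin-{spec.seed}"
    record = HairpinRecord.from_sequence(
        RnaSequence(id=rid, residues=residues),
        temperature=temperature,
        with_partition=with_partition,
    )
    mature = None
    if plant_mature:
        L = len(residues)
        mature = MatureAnnotation(
            precursor_id=rid,
            mir_interval=(L - MATURE_LEN, L),
            star_interval=(0, MATURE_LEN),
            arm="3p",
        )
    return record, mature


def make_hairpin_set(
    n: int,
    degrade: float,
    seed: int,
    stem_len: int = 40,
    loop_len: int = 8,
    gc_range: tuple = (0.35, 0.65),
    with_partition: bool = True,
) -> List[HairpinRecord]:
    """A set of n hairpins with per-record GC drawn from `gc_range` and
    derived per-record seeds."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        gc = float(rng.uniform(*gc_range))
        sub = int(rng.integers(0, 2**31 - 1))
        rec, _ = make_hairpin(
            HairpinSpec(stem_len=stem_len, loop_len=loop_len, gc=gc, degrade=degrade, seed=sub),
            plant_mature=False,
            with_partition=with_partition,
            record_id=f"synthetic-{'real' if degrade <= 0.05 else 'pseudo'}-{seed}-{i}",
        )
        out.append(rec)
    return out


@dataclass
class PlantedDatasetSpec:
    """n samples x p Gaussian features with k informative columns
    shifted by `effect` standard deviations in class +1."""

    n: int = 400
    p: int = 50
    k: int = 5
    effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.p:
            raise ValueError("k must be <= p")


def make_feature_dataset(spec: PlantedDatasetSpec) -> tuple:
    """Returns (LabeledDataset, planted column index tuple).

    Balanced labels; informative columns are the first k after a seeded
    permutation of column order (so planted indices are not trivially
    0..k-1)."""
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    y = np.ones(spec.n, dtype=int)
    y[spec.n // 2:] = -1
    perm = rng.permutation(spec.p)
    planted = tuple(sorted(int(c) for c in perm[: spec.k]))
    for c in planted:
        X[y == 1, c] += spec.effect
    names = tuple(f"f{j}" for j in range(spec.p))
    return LabeledDataset(X=X, y=y, feature_names=names), planted


@dataclass
class PlantedSite:
    """Truth record for one planted miRNA copy in a toy genome."""

    query_id: str
    position: int
    strand: str
    mismatches: int
    in_hairpin: bool
    hairpin_interval: Optional[tuple] = None


def make_toy_genome(
    length: int,
    planted: Sequence[tuple],
    seed: int = 0,
    contig_id: str = "toy-contig",
) -> tuple:
    """Uniform-random genome with planted miRNA copies.

    `planted` holds (query: RnaSequence, mismatches: int, in_hairpin:
    bool) triples.  Each copy is embedded with exactly the requested
    Hamming distance from the query; with `in_hairpin`, the (mutated)
    copy forms the 3' arm of a perfect inverted repeat so it folds into
    a stem.  Returns ([RnaSequence contig], [PlantedSite truth]).
    Overlapping placements raise.
    """
    rng = np.random.default_rng(seed)
    background = list(_random_seq(length, 0.5, rng))
    truth: List[PlantedSite] = []
    occupied: List[tuple] = []

    def _place(span: int) -> int:
        for _ in range(200):
            pos = int(rng.integers(0, length - span))
            if all(pos + span <= a or pos >= b for a, b in occupied):
                occupied.append((pos, pos + span))
                return pos
        raise ValueError("planted loci overlap: genome too small for the requested insertions")

    for query, mismatches, in_hairpin in planted:
        q = list(query.residues)
        mut_pos = rng.choice(len(q), size=mismatches, replace=False)
        for i in mut_pos:
            q[i] = rng.choice([c for c in "ACGU" if c != q[i]])
        copy = "".join(q)
        if in_hairpin:
            loop = _random_seq(6, 0.5, rng)
            insert = reverse_complement(copy) + loop + copy
            pos = _place(len(insert))
            background[pos:pos + len(insert)] = insert
            site_pos = pos + len(copy) + len(loop)
            truth.append(
                PlantedSite(
                    query_id=query.id, position=site_pos, strand="+",
                    mismatches=mismatches, in_hairpin=True,
                    hairpin_interval=(pos, pos + len(insert)),
                )
            )
        else:
            pos = _place(len(copy))
            background[pos:pos + len(copy)] = copy
            truth.append(
                PlantedSite(
                    query_id=query.id, position=pos, strand="+",
                    mismatches=mismatches, in_hairpin=False,
                )
            )
    contig = RnaSequence(id=contig_id, residues="".join(background))
    return [contig], truth
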