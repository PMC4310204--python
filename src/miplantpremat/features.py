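"""The 152-feature structure-sequence descriptor of a plant pre-miRNA hairpin.

Six groups, mirroring the lineage of earlier pre-miRNA classifiers:

* MFE-related (9): MFEI1-MFEI9, ratios of (length-normalised) minimum
  free energy to composition/structure quantities.
* Sequence-related (20): 16 overlapping dinucleotide frequencies %XY,
  %G+C, the average mismatch count per 21-nt stem window (Avg_mis_num)
  and the mismatch counts in the first/last 21 stem bases.
* Mfold-related (6): structural entropy dS, enthalpy dH and melting
  temperature Tm, each raw and length-normalised, from a two-temperature
  evaluation of the fixed MFE structure.
* Base-pair-related (7): pair-type counts over L, average base pairs per
  stem, and pair-type proportions per stem.
* Triple-related (96): 32 local structure-nucleotide triplet frequencies
  over the whole stem plus 32 each restricted to the first/last 21 stem
  bases ("(" and ")" treated equally).
* RNAfold-related (14): ensemble quantities dP dG dD dQ dF, their
  z-scores against dinucleotide-preserving shuffles, NEFE, Freq,
  Diversity and Diff.

Zero denominators are guarded (value 0, guard event recorded) so a
feature vector never contains NaN/Inf.
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .hairpin import (
    HairpinRecord,
    RnaSequence,
    eval_structure_energy,
    fold,
)

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"
TRIPLET_PATTERNS = ("(((", "((.", "(.(", "(..", ".((", ".(.", "..(", "...")
WINDOW = 21  # nt; the canonical mature-miRNA length


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogEntry:
    name: str
    group: str
    novel: bool = False


def _build_catalog() -> tuple:
    entries: List[CatalogEntry] = []
    # MFE-related (9)
    for k in range(1, 10):
        entries.append(CatalogEntry(f"MFEI{k}", "MFE-related", novel=k >= 7))
    # Sequence-related (20)
    for x in NUCLEOTIDES:
        for y in NUCLEOTIDES:
            entries.append(CatalogEntry(f"%{x}{y}", "Sequence-related"))
    entries.append(CatalogEntry("%G+C", "Sequence-related"))
    entries.append(CatalogEntry("Avg_mis_num", "Sequence-related"))
    entries.append(CatalogEntry("Mis_num_begin", "Sequence-related", novel=True))
    entries.append(CatalogEntry("Mis_num_end", "Sequence-related", novel=True))
    # Mfold-related (6)
    for name in ("dS", "dS/L", "dH", "dH/L", "Tm", "Tm/L"):
        entries.append(CatalogEntry(name, "Mfold-related"))
    # Base-pair-related (7)
    for name in (
        "|A-U|/L",
        "|G-C|/L",
        "|G-U|/L",
        "Avg_BP_Stem",
        "%(A-U)/n_stems",
        "%(G-C)/n_stems",
        "%(G-U)/n_stems",
    ):
        entries.append(CatalogEntry(name, "BasePair-related"))
    # Triple-related (96)
    for suffix, novel in (("_S", False), ("_begin_S", True), ("_end_S", True)):
        for x in NUCLEOTIDES:
            for pat in TRIPLET_PATTERNS:
                entries.append(CatalogEntry(f"{x}{pat}{suffix}", "Triple-related", novel=novel))
    # RNAfold-related (14)
    for name in (
        "dP", "dG", "dD", "dQ", "dF",
        "zP", "zG", "zD", "zQ", "zF",
        "NEFE", "Freq", "Diversity", "Diff",
    ):
        entries.append(CatalogEntry(name, "RNAfold-related"))
    return tuple(entries)


FEATURE_CATALOG: tuple = _build_catalog()
FEATURE_NAMES: tuple = tuple(e.name for e in FEATURE_CATALOG)
N_FEATURES = len(FEATURE_CATALOG)

GROUP_SIZES = {
    "MFE-related": 9,
    "Sequence-related": 20,
    "Mfold-related": 6,
    "BasePair-related": 7,
    "Triple-related": 96,
    "RNAfold-related": 14,
}


@dataclass
class FeatureConfig:
    """Extraction knobs: shuffle count/seed for z-scores, fold temperature."""

    shuffles: int = 100
    seed: int = 0
    temperature: float = 37.0


@dataclass
class FeatureVector:
    source_id: str
    values: np.ndarray
    guards: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values))


class _Guards:
    """Collects zero-denominator guard events for one extraction."""

    def __init__(self) -> None:
        self.events: List[str] = []

    def ratio(self, num: float, den: float, name: str) -> float:
        if den == 0 or not math.isfinite(den):
            self.events.append(name)
            logger.debug("guard: %s has zero denominator", name)
            return 0.0
        return num / den


# ---------------------------------------------------------------------------
# Region helpers
# ---------------------------------------------------------------------------

def _stem_positions(record: HairpinRecord) -> list:
    return record.annotation.stem_positions()


def _region_positions(record: HairpinRecord, region: str) -> list:
    stem = _stem_positions(record)
    if region == "whole_stem":
        return stem
    if region == "begin21":
        return stem[:WINDOW]
    if region == "end21":
        return stem[-WINDOW:] if stem else []
    raise ValueError(f"unknown region {region!r}")


def _gc_fraction(residues: str) -> float:
    if not residues:
        return 0.0
    return sum(1 for c in residues if c in "GC") / len(residues)


# ---------------------------------------------------------------------------
# Group: Triple-related
# ---------------------------------------------------------------------------

def triplet_features(record: HairpinRecord, region: str = "whole_stem") -> np.ndarray:
    """32 structure-nucleotide triplet frequencies for one region.

    For each position i whose 3-window {i-1, i, i+1} lies entirely in
    the stem region and whose center lies in `region`, the category is
    the center nucleotide plus the 3-symbol local structure with ")"
    mapped to "(".  Counts are normalised to frequencies; a region with
    no valid window yields an all-zero block.
    """
    stem_set = set(_stem_positions(record))
    region_set = set(_region_positions(record, region))
    seq = record.sequence.residues
    db = record.structure.dotbracket
    counts = np.zeros(32)
    index = {
        (x, pat): 8 * xi + pi
        for xi, x in enumerate(NUCLEOTIDES)
        for pi, pat in enumerate(TRIPLET_PATTERNS)
    }
    total = 0
    for i in range(1, len(seq) - 1):
        if i not in region_set:
            continue
        if not ({i - 1, i, i + 1} <= stem_set):
            continue
        pat = "".join("(" if db[k] in "()" else "." for k in (i - 1, i, i + 1))
        counts[index[(seq[i], pat)]] += 1
        total += 1
    if total:
        counts /= total
    return counts


# ---------------------------------------------------------------------------
# Group: Sequence-related
# ---------------------------------------------------------------------------

def sequence_features(record: HairpinRecord, guards: Optional[_Guards] = None) -> dict:
    g = guards or _Guards()
    seq = record.sequence.residues
    L = len(seq)
    out = {}
    if L >= 2:
        for x in NUCLEOTIDES:
            for y in NUCLEOTIDES:
                out[f"%{x}{y}"] = sum(
                    1 for k in range(L - 1) if seq[k] == x and seq[k + 1] == y
                ) / (L - 1)
    else:
        for x in NUCLEOTIDES:
            for y in NUCLEOTIDES:
                out[f"%{x}{y}"] = 0.0
        g.events.append("%XY")
    out["%G+C"] = _gc_fraction(seq)

    stem = _stem_positions(record)
    partner = record.annotation.partner
    mismatches = [p for p in stem if p not in partner]
    n_windows = math.ceil(len(stem) / WINDOW) if stem else 0
    out["Avg_mis_num"] = g.ratio(len(mismatches), n_windows, "Avg_mis_num")
    out["Mis_num_begin"] = float(sum(1 for p in stem[:WINDOW] if p not in partner))
    out["Mis_num_end"] = float(sum(1 for p in stem[-WINDOW:] if p not in partner)) if stem else 0.0
    return out


# ---------------------------------------------------------------------------
# Group: MFE-related
# ---------------------------------------------------------------------------

def _plantmirnapred_mfei56(mfe: float, n_loops: int, n_stems: int, g: _Guards) -> tuple:
    # Convention adopted here: the un-normalised counterparts of
    # MFEI3/MFEI2 -- MFE per hairpin loop and MFE per stem.  Isolated so
    # the formulas can be swapped without touching callers.
    return (
        g.ratio(mfe, n_loops, "MFEI5"),
        g.ratio(mfe, n_stems, "MFEI6"),
    )


def mfe_indices(record: HairpinRecord, guards: Optional[_Guards] = None) -> dict:
    g = guards or _Guards()
    mfe = record.structure.mfe
    L = len(record)
    ann = record.annotation
    seq = record.sequence.residues
    gc = _gc_fraction(seq)
    stem = _stem_positions(record)
    gc_begin = _gc_fraction("".join(seq[p] for p in stem[:WINDOW]))
    gc_end = _gc_fraction("".join(seq[p] for p in stem[-WINDOW:])) if stem else 0.0
    partner = ann.partner
    n_windows = math.ceil(len(stem) / WINDOW) if stem else 0
    avg_mis = (
        sum(1 for p in stem if p not in partner) / n_windows if n_windows else 0.0
    )

    dg = mfe / L
    out = {
        "MFEI1": g.ratio(dg, gc, "MFEI1"),
        "MFEI2": g.ratio(dg, ann.n_stems, "MFEI2"),
        "MFEI3": g.ratio(dg, ann.n_loops, "MFEI3"),
        "MFEI4": g.ratio(mfe, ann.tot_base_pairs, "MFEI4"),
    }
    out["MFEI5"], out["MFEI6"] = _plantmirnapred_mfei56(mfe, ann.n_loops, ann.n_stems, g)
    out["MFEI7"] = g.ratio(mfe, gc_begin, "MFEI7")
    out["MFEI8"] = g.ratio(mfe, gc_end, "MFEI8")
    out["MFEI9"] = g.ratio(mfe, avg_mis, "MFEI9")
    return out


# ---------------------------------------------------------------------------
# Group: BasePair-related
# ---------------------------------------------------------------------------

def basepair_features(record: HairpinRecord, guards: Optional[_Guards] = None) -> dict:
    g = guards or _Guards()
    seq = record.sequence.residues
    ann = record.annotation
    L = len(record)
    counts = {"A-U": 0, "G-C": 0, "G-U": 0}
    for i, j in ann.pairs:
        pair = frozenset((seq[i], seq[j]))
        if pair == frozenset("AU"):
            counts["A-U"] += 1
        elif pair == frozenset("GC"):
            counts["G-C"] += 1
        elif pair == frozenset("GU"):
            counts["G-U"] += 1
    tot = ann.tot_base_pairs
    out = {f"|{k}|/L": counts[k] / L for k in ("A-U", "G-C", "G-U")}
    out["Avg_BP_Stem"] = g.ratio(tot, ann.n_stems, "Avg_BP_Stem")
    for k in ("A-U", "G-C", "G-U"):
        frac = counts[k] / tot if tot else 0.0
        out[f"%({k})/n_stems"] = g.ratio(frac, ann.n_stems, f"%({k})/n_stems")
    return out


# ---------------------------------------------------------------------------
# Group: Mfold-related (thermodynamics of the fixed MFE structure)
# ---------------------------------------------------------------------------

def thermo_features(
    record: HairpinRecord,
    guards: Optional[_Guards] = None,
    t1: float = 37.0,
    t2: float = 67.0,
) -> dict:
    """dS, dH and Tm from a finite difference of the MFE structure's free
    energy at two temperatures: dS = -(G(t2)-G(t1))/(t2-t1),
    dH = G(t1) + T1*dS, Tm = dH/dS - 273.15 (degC)."""
    g = guards or _Guards()
    L = len(record)
    db = record.structure.dotbracket
    if not record.annotation.pairs:
        g.events.append("thermo")
        ds = dh = tm = 0.0
    else:
        g1 = eval_structure_energy(record.sequence, db, t1)
        g2 = eval_structure_energy(record.sequence, db, t2)
        ds = -(g2 - g1) / (t2 - t1)
        dh = g1 + (t1 + 273.15) * ds
        tm = (dh / ds - 273.15) if ds != 0 else 0.0
        if ds == 0:
            g.events.append("Tm")
    return {"dS": ds, "dS/L": ds / L, "dH": dh, "dH/L": dh / L, "Tm": tm, "Tm/L": tm / L}


# ---------------------------------------------------------------------------
# Group: RNAfold-related (ensemble features + shuffle z-scores)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(residues: str, rng: random.Random) -> str:
    """Altschul-Erikson dinucleotide-preserving shuffle.

    Shuffles the sequence uniformly among those with identical
    dinucleotide (and hence mononucleotide) composition, via a random
    Eulerian path in the dinucleotide multigraph.
    """
    if len(residues) < 3:
        return residues
    edges: dict = {}
    for a, b in zip(residues, residues[1:]):
        edges.setdefault(a, []).append(b)
    last = residues[-1]
    vertices = list(edges)

    def connects(last_edges: dict) -> bool:
        for v in vertices:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last and u not in seen:
                seen.add(u)
                u = last_edges.get(u)
                if u is None:
                    return False
            if u != last:
                return False
        return True

    while True:
        last_edges = {
            v: rng.choice(edges[v]) for v in vertices if v != last and edges[v]
        }
        if connects(last_edges):
            break

    shuffled: dict = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edges:
            pool.remove(last_edges[v])
        rng.shuffle(pool)
        if v in last_edges:
            pool.append(last_edges[v])
        shuffled[v] = pool

    out = [residues[0]]
    v = residues[0]
    idx = {v: 0 for v in vertices}
    while len(out) < len(residues):
        nxt = shuffled[v][idx[v]]
        idx[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _ensemble_d_values(record: HairpinRecord, g: _Guards) -> dict:
    s = record.structure
    if s.pair_probabilities is None or s.ensemble_free_energy is None:
        raise ValueError(
            f"{record.id}: partition-function results required (fold with with_partition=True)"
        )
    L = len(record)
    ann = record.annotation
    bpp = s.pair_probabilities
    probs = np.array(list(bpp.values())) if bpp else np.array([])
    spans = np.array([j - i for (i, j) in bpp]) if bpp else np.array([])
    # Shannon entropy of the pairing ensemble, per nucleotide
    q = float(-(probs * np.log2(probs)).sum()) if probs.size else 0.0
    ptot = float(probs.sum())
    mean_span = float((probs * spans).sum() / ptot) if ptot > 0 else 0.0
    return {
        "dP": ann.tot_base_pairs / L,
        "dG": s.mfe / L,
        "dD": (s.ensemble_diversity or 0.0) / L,
        "dQ": q / L,
        "dF": mean_span / L,  # compactness: probability-weighted mean pairing span / L
    }


def rnafold_features(
    record: HairpinRecord,
    shuffles: int = 100,
    seed: int = 0,
    temperature: float = 37.0,
    guards: Optional[_Guards] = None,
) -> dict:
    """Ensemble features and z-scores against dinucleotide shuffles.

    z-scores compare each d-value with its distribution over `shuffles`
    dinucleotide-preserving shuffled copies of the sequence, each
    refolded with the partition function.  Zero variance across the
    shuffles guards the z-score to 0.
    """
    if shuffles < 2:
        raise ValueError("z-score features require at least 2 shuffles")
    g = guards or _Guards()
    s = record.structure
    L = len(record)
    out = _ensemble_d_values(record, g)
    efe = s.ensemble_free_energy
    out["NEFE"] = efe / L
    out["Freq"] = s.mfe_frequency or 0.0
    out["Diversity"] = s.ensemble_diversity or 0.0
    out["Diff"] = abs(s.mfe - efe) / L

    rng = random.Random(seed)
    samples = {k: [] for k in ("dP", "dG", "dD", "dQ", "dF")}
    for _ in range(shuffles):
        shuf = dinucleotide_shuffle(record.sequence.residues, rng)
        rec = HairpinRecord.from_sequence(
            RnaSequence(id=f"{record.id}|shuffle", residues=shuf),
            temperature=temperature,
            with_partition=True,
        )
        d = _ensemble_d_values(rec, g)
        for k in samples:
            samples[k].append(d[k])
    for k in ("P", "G", "D", "Q", "F"):
        vals = np.array(samples[f"d{k}"])
        sd = float(vals.std(ddof=1))
        if sd < 1e-12:
            g.events.append(f"z{k}")
            out[f"z{k}"] = 0.0
        else:
            out[f"z{k}"] = float((out[f"d{k}"] - vals.mean()) / sd)
    return out


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_all(record: HairpinRecord, config: Optional[FeatureConfig] = None) -> FeatureVector:
    """Compute the full 152-value descriptor, in catalog order.

    A pure function of (record, config): repeated calls with the same
    seed return identical vectors.  Requires partition-function data on
    the record's structure; records folded without it are refolded.
    """
    config = config or FeatureConfig()
    if record.structure.pair_probabilities is None:
        record = HairpinRecord.from_sequence(
            record.sequence, temperature=config.temperature, with_partition=True
        )
    g = _Guards()
    values = {}
    values.update(mfe_indices(record, g))
    values.update(sequence_features(record, g))
    values.update(thermo_features(record, g, t1=config.temperature))
    values.update(basepair_features(record, g))
    for region, suffix in (("whole_stem", "_S"), ("begin21", "_begin_S"), ("end21", "_end_S")):
        block = triplet_features(record, region)
        if block.sum() == 0:
            g.events.append(f"triplet{suffix}")
        names = [f"{x}{pat}{suffix}" for x in NUCLEOTIDES for pat in TRIPLET_PATTERNS]
        for n, v in zip(names, block):
            values[n] = float(v)
    values.update(
        rnafold_features(
            record,
            shuffles=config.shuffles,
            seed=config.seed,
            temperature=config.temperature,
            guards=g,
        )
    )
    vec = np.array([values[name] for name in FEATURE_NAMES])
    return FeatureVector(source_id=record.id, values=vec, guards=tuple(g.events))


def extract_matrix(
    records: Sequence[HairpinRecord], config: Optional[FeatureConfig] = None
):
    """Feature DataFrame (rows = records, columns = catalog order)."""
    import pandas as pd

    vectors = [extract_all(r, config) for r in records]
    return pd.DataFrame(
        [v.values for v in vectors],
        index=[v.source_id for v in vectors],
        columns=list(FEATURE_NAMES),
    )


# ---------------------------------------------------------------------------
# Min-max scaling to [-1, 1]
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature linear map sending train min -> -1 and max -> +1.

    Constant features map to 0.  Test values may fall outside [-1, 1];
    no clipping is applied.
    """

    names: tuple
    min_: np.ndarray
    max_: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        X = np.asarray(matrix, dtype=float)
        span = self.max_ - self.min_
        out = np.zeros_like(X)
        nz = span != 0
        out[:, nz] = 2.0 * (X[:, nz] - self.min_[nz]) / span[nz] - 1.0
        return out

    def to_json(self, path) -> None:
        payload = {
            name: [float(lo), float(hi)]
            for name, lo, hi in zip(self.names, self.min_, self.max_)
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureScaler":
        with open(path) as fh:
            payload = json.load(fh)
        names = tuple(payload)
        arr = np.array([payload[n] for n in names], dtype=float)
        return cls(names=names, min_=arr[:, 0], max_=arr[:, 1])


def fit_scaler(matrix, names: Optional[Sequence[str]] = None) -> FeatureScaler:
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        names = tuple(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = tuple(names) if names is not None else tuple(f"f{i}" for i in range(X.shape[1]))
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return FeatureScaler(names=names, min_=X.min(axis=0), max_=X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, matrix):
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        out = scaler.transform(matrix.to_numpy(dtype=float))
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return scaler.transform(matrix)


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

def write_feature_table(df, path) -> None:
    df.to_csv(path, sep="\t", index_label="source_id")


def read_feature_table(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col="source_id")
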