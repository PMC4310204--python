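"""RNA hairpin model: sequences, secondary structure, stem/loop annotation.

A candidate plant pre-miRNA is represented as a :class:`HairpinRecord`
bundling the RNA sequence, its predicted minimum-free-energy (MFE)
secondary structure and a structural annotation (base pairs, stems,
hairpin loops, arms).  Folding is delegated to the ViennaRNA package
behind the narrow :func:`fold` interface so that precomputed structures
can be injected and the engine swapped or pinned.

Coordinates are 0-based, half-open throughout; miRBase-style 1-based
inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

VALID_RESIDUES = frozenset("ACGU")
#: Watson-Crick plus wobble pairs recognised in structural annotation.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FoldingEngineError(RuntimeError):
    """Raised when the RNA folding engine (ViennaRNA) is unavailable."""


class InvalidSequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,U}."""


class DotBracketError(ValueError):
    """Raised for malformed dot-bracket strings; carries the offending index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} at index {index}")
        self.index = index


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A,C,G,U}.

    DNA input is transcribed (T -> U) by :meth:`from_string`.  Sequences
    with any other character (including N) are rejected: downstream
    feature extraction and the genome-scan rules demand unambiguous
    bases.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise InvalidSequenceError(
                f"{self.id}: invalid residues {sorted(bad)} (allowed: A,C,G,U)"
            )

    @classmethod
    def from_string(cls, id: str, raw: str) -> "RnaSequence":
        return cls(id=id, residues=raw.upper().replace("T", "U"))

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, id: Optional[str] = None) -> "RnaSequence":
        if not (0 <= start < end <= len(self)):
            raise IndexError(f"window [{start},{end}) out of bounds for length {len(self)}")
        return RnaSequence(id=id or f"{self.id}:{start}-{end}", residues=self.residues[start:end])


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket structure with MFE and optional ensemble quantities."""

    dotbracket: str
    mfe: float
    ensemble_free_energy: Optional[float] = None
    mfe_frequency: Optional[float] = None
    ensemble_diversity: Optional[float] = None
    pair_probabilities: Optional[dict] = None
    engine: str = "unspecified"

    def __post_init__(self) -> None:
        parse_dotbracket(self.dotbracket)  # validates balance

    def __len__(self) -> int:
        return len(self.dotbracket)


def parse_dotbracket(dotbracket: str) -> set:
    """Stack-parse a dot-bracket string into a set of (i, j) pairs, i < j.

    Raises :class:`DotBracketError` pointing at the first unmatched
    bracket.  Nestedness (no pseudoknots) is guaranteed by construction.
    """
    stack: list = []
    pairs = set()
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise DotBracketError("unmatched ')'", idx)
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise DotBracketError(f"invalid character {ch!r}", idx)
    if stack:
        raise DotBracketError("unclosed '('", stack[0])
    return pairs


def render_dotbracket(pairs: Iterable, length: int) -> str:
    """Inverse of :func:`parse_dotbracket` for a nested pair set."""
    out = ["."] * length
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


@dataclass(frozen=True)
class HairpinAnnotation:
    """Structural annotation derived from the pair set.

    A *stem* is a maximal run of stacked pairs ((i,j),(i+1,j-1),...); any
    bulge or interior loop terminates a stem.  A *hairpin loop* is the
    unpaired interval enclosed by a pair whose interior holds no other
    pair.  For a single-stem-loop structure the arms are the regions
    5' and 3' of the (unique) hairpin loop, bounded by the outermost
    pair.
    """

    pairs: frozenset
    stems: tuple
    loop_spans: tuple
    arm5: Optional[tuple]
    arm3: Optional[tuple]
    partner: dict = field(repr=False, default_factory=dict)

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def n_loops(self) -> int:
        return len(self.loop_spans)

    @property
    def tot_base_pairs(self) -> int:
        return len(self.pairs)

    def stem_positions(self) -> list:
        """Positions in the paired (stem) region: between the outermost
        paired positions, excluding hairpin-loop interiors.  Includes
        unpaired bulge/interior-loop positions within the arms."""
        if not self.pairs:
            return []
        lo = min(i for i, _ in self.pairs)
        hi = max(j for _, j in self.pairs)
        in_loop = set()
        for a, b in self.loop_spans:
            in_loop.update(range(a, b))
        return [p for p in range(lo, hi + 1) if p not in in_loop]

    def is_paired(self, pos: int) -> bool:
        return pos in self.partner


def annotate(structure: SecondaryStructure) -> HairpinAnnotation:
    """Annotate stems, hairpin loops and arms from a dot-bracket structure."""
    pairs = sorted(parse_dotbracket(structure.dotbracket))
    partner: dict = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    # maximal stacked runs
    stems: list = []
    current: list = []
    for p in pairs:
        if current and p == (current[-1][0] + 1, current[-1][1] - 1):
            current.append(p)
        else:
            if current:
                stems.append(tuple(current))
            current = [p]
    if current:
        stems.append(tuple(current))

    # hairpin loops: pairs with empty-paired interior
    loop_spans: list = []
    for i, j in pairs:
        if not any(i < k < j for k in partner):
            loop_spans.append((i + 1, j))
    loop_spans.sort()

    arm5 = arm3 = None
    if pairs and loop_spans:
        lo = min(i for i, _ in pairs)
        hi = max(j for _, j in pairs)
        la, lb = loop_spans[0]
        arm5 = (lo, la)      # up to and including the loop-closing 5' base
        arm3 = (lb, hi + 1)  # from the loop-closing 3' base

    return HairpinAnnotation(
        pairs=frozenset(pairs),
        stems=tuple(stems),
        loop_spans=tuple(loop_spans),
        arm5=arm5,
        arm3=arm3,
        partner=partner,
    )


def is_single_stem_loop(annotation: HairpinAnnotation) -> bool:
    """True iff the structure has exactly one hairpin loop (hence no
    multi-branch loop) and at least one pair."""
    return annotation.n_loops == 1 and annotation.tot_base_pairs >= 1


@dataclass(frozen=True)
class MatureAnnotation:
    """Mature miRNA / miRNA* placement on a precursor (0-based half-open)."""

    precursor_id: str
    mir_interval: tuple
    star_interval: Optional[tuple] = None
    arm: str = "3p"

    def __post_init__(self) -> None:
        a, b = self.mir_interval
        if not a < b:
            raise ValueError("empty mir interval")
        if self.star_interval is not None:
            c, d = self.star_interval
            if not c < d:
                raise ValueError("empty star interval")
            if max(a, c) < min(b, d):
                raise ValueError("mir and star intervals overlap")


@dataclass(frozen=True)
class HairpinRecord:
    """Sequence + structure + annotation for one candidate precursor."""

    sequence: RnaSequence
    structure: SecondaryStructure
    annotation: HairpinAnnotation

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.sequence.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def id(self) -> str:
        return self.sequence.id

    @classmethod
    def from_sequence(
        cls,
        sequence: RnaSequence,
        temperature: float = 37.0,
        with_partition: bool = False,
    ) -> "HairpinRecord":
        structure = fold(sequence, temperature=temperature, with_partition=with_partition)
        return cls(sequence=sequence, structure=structure, annotation=annotate(structure))

    @classmethod
    def from_structure(cls, sequence: RnaSequence, structure: SecondaryStructure) -> "HairpinRecord":
        """Build a record from a precomputed structure (no engine needed)."""
        return cls(sequence=sequence, structure=structure, annotation=annotate(structure))


def _require_engine():
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - engine present in CI image
        raise FoldingEngineError(
            "ViennaRNA python bindings are required for folding; install the "
            "'viennarna' package (conda: viennarna) or supply precomputed "
            "structures via HairpinRecord.from_structure"
        ) from exc
    return RNA


def engine_version() -> str:
    RNA = _require_engine()
    return f"ViennaRNA {RNA.__version__}"


def fold(
    sequence: RnaSequence,
    temperature: float = 37.0,
    with_partition: bool = False,
) -> SecondaryStructure:
    """Predict the MFE structure of `sequence` with ViennaRNA.

    With ``with_partition`` the partition function is also computed,
    yielding the ensemble free energy, the Boltzmann frequency of the
    MFE structure, the ensemble diversity (expected base-pair distance)
    and the base-pair probability matrix.  Deterministic for a fixed
    engine version.
    """
    RNA = _require_engine()
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(sequence.residues, md)
    dotbracket, mfe = fc.mfe()
    mfe = float(mfe)
    efe = freq = div = None
    bpp = None
    if with_partition:
        fc.exp_params_rescale(mfe)
        _, efe = fc.pf()
        efe = float(efe)
        freq = float(fc.pr_structure(dotbracket))
        div = float(fc.mean_bp_distance())
        raw = fc.bpp()
        n = len(sequence)
        bpp = {}
        for i in range(1, n + 1):
            row = raw[i]
            for j in range(i + 1, n + 1):
                p = row[j]
                if p > 1e-8:
                    bpp[(i - 1, j - 1)] = float(p)
    return SecondaryStructure(
        dotbracket=dotbracket,
        mfe=mfe,
        ensemble_free_energy=efe,
        mfe_frequency=freq,
        ensemble_diversity=div,
        pair_probabilities=bpp,
        engine=f"ViennaRNA {RNA.__version__} T={temperature:g}",
    )


def eval_structure_energy(sequence: RnaSequence, dotbracket: str, temperature: float) -> float:
    """Free energy (kcal/mol) of a fixed structure at `temperature` degC."""
    RNA = _require_engine()
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(sequence.residues, md)
    return float(fc.eval_structure(dotbracket))


def intercept(
    record: HairpinRecord,
    mature: MatureAnnotation,
    temperature: float = 37.0,
    with_partition: bool = False,
) -> HairpinRecord:
    """Trim a precursor so the miRNA/miRNA* duplex spans the termini.

    Returns the subsequence from the 5'-most start of {mir, star} to the
    3'-most end, refolded.  Idempotent: re-intercepting with the shifted
    annotation returns the same record.  Requires the star annotation;
    mir and star must lie on opposite arms (non-overlapping by type
    invariant, and neither may contain the other's span).
    """
    if mature.star_interval is None:
        raise ValueError(
            f"{mature.precursor_id}: interception undefined without a miRNA* annotation"
        )
    (ma, mb), (sa, sb) = mature.mir_interval, mature.star_interval
    L = len(record)
    if not (0 <= ma < mb <= L and 0 <= sa < sb <= L):
        raise ValueError(f"{mature.precursor_id}: annotation exceeds precursor bounds (L={L})")
    ann = record.annotation
    if ann.arm5 is not None:
        # classify each interval by its midpoint relative to the hairpin loop
        loop_mid = (ann.arm5[1] + ann.arm3[0]) / 2
        mir_5p = (ma + mb) / 2 < loop_mid
        star_5p = (sa + sb) / 2 < loop_mid
        if mir_5p == star_5p:
            raise ValueError(
                f"{mature.precursor_id}: mir and star must lie on opposite arms"
            )
    start = min(ma, sa)
    end = max(mb, sb)
    sub = record.sequence.subsequence(start, end, id=record.sequence.id)
    return HairpinRecord.from_sequence(sub, temperature=temperature, with_partition=with_partition)


def shift_annotation(mature: MatureAnnotation) -> MatureAnnotation:
    """Mature annotation in the coordinates of the intercepted precursor."""
    if mature.star_interval is None:
        raise ValueError("star annotation required")
    start = min(mature.mir_interval[0], mature.star_interval[0])
    return MatureAnnotation(
        precursor_id=mature.precursor_id,
        mir_interval=(mature.mir_interval[0] - start, mature.mir_interval[1] - start),
        star_interval=(mature.star_interval[0] - start, mature.star_interval[1] - start),
        arm=mature.arm,
    )


def window_mismatches(record: HairpinRecord, window: tuple) -> int:
    """Number of unpaired positions within ``window`` = [a, b)."""
    a, b = window
    if not (0 <= a <= b <= len(record)):
        raise IndexError(f"window [{a},{b}) out of bounds for length {len(record)}")
    partner = record.annotation.partner
    return sum(1 for p in range(a, b) if p not in partner)


# ---------------------------------------------------------------------------
# I/O: FASTA, Vienna dot-bracket files, mature-annotation TSV
# ---------------------------------------------------------------------------

def read_fasta(path_or_handle) -> list:
    """Read a (multi-)FASTA file into RnaSequence records, T -> U."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        records.append(RnaSequence.from_string(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Sequence[RnaSequence], path_or_handle, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(out, path_or_handle, "fasta")


def read_dotbracket_file(path) -> list:
    """Read a Vienna-style file: >id / sequence / dotbracket [ (MFE)].

    Returns HairpinRecord objects with structures taken verbatim (no
    folding engine needed)."""
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1}")
        rid = lines[i][1:].split()[0]
        seq = RnaSequence.from_string(rid, lines[i + 1])
        struct_line = lines[i + 2]
        mfe = 0.0
        db = struct_line
        if " " in struct_line:
            db, _, tail = struct_line.partition(" ")
            mfe = float(tail.strip().strip("()"))
        records.append(
            HairpinRecord.from_structure(seq, SecondaryStructure(dotbracket=db, mfe=mfe))
        )
        i += 3
    return records


def write_dotbracket_file(records: Sequence[HairpinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence.residues}\n")
            fh.write(f"{rec.structure.dotbracket} ({rec.structure.mfe:.2f})\n")


def read_mature_tsv(path) -> list:
    """Read mature annotations (1-based inclusive externally) from TSV.

    Columns: precursor_id, mir_start, mir_end, star_start, star_end, arm.
    Empty star columns yield star_interval=None.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"precursor_id": str, "arm": str})
    out = []
    for row in df.itertuples(index=False):
        star = None
        if not (pd.isna(row.star_start) or pd.isna(row.star_end)):
            star = (int(row.star_start) - 1, int(row.star_end))
        out.append(
            MatureAnnotation(
                precursor_id=row.precursor_id,
                mir_interval=(int(row.mir_start) - 1, int(row.mir_end)),
                star_interval=star,
                arm=row.arm,
            )
        )
    return out


def write_mature_tsv(annotations: Sequence[MatureAnnotation], path) -> None:
    import pandas as pd

    rows = []
    for a in annotations:
        star = a.star_interval
        rows.append(
            {
                "precursor_id": a.precursor_id,
                "mir_start": a.mir_interval[0] + 1,
                "mir_end": a.mir_interval[1],
                "star_start": star[0] + 1 if star else None,
                "star_end": star[1] if star else None,
                "arm": a.arm,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
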