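"""Assay-design utilities for bisulfite methylation assays.

Coordinates are ATG-relative: the "A" of the translation start is +1, the
base immediately upstream is -1, and there is no position 0.  Under this
convention the span -531..+231 is 762 bp, the size conventionally quoted for
the MGMT promoter CpG island.

Provided here: span arithmetic under that convention, in-silico bisulfite
conversion of a sequence carrying a known per-CpG methylation pattern,
CpG counting, CpG-island detection with Gardiner-Garden--Frommer-style
criteria, and validation that a primer pair is methylation independent
(no CpG inside the primer, no CpG under its binding site).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import InvalidCoordinateError, PatternMismatchError, UnmappedPrimerError

_ALPHABET = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterSequence:
    """A promoter-region DNA sequence anchored to the ATG.

    ``origin`` is the ATG-relative coordinate of the first base; it can never
    be 0 because position 0 does not exist in this convention.
    """

    bases: str
    origin: int = 1
    strand: str = "sense"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("sequence must be non-empty")
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        if self.origin == 0:
            raise InvalidCoordinateError("ATG-relative coordinates have no position 0")
        if self.strand not in ("sense", "antisense"):
            raise ValueError("strand must be 'sense' or 'antisense'")

    def __len__(self) -> int:
        return len(self.bases)

    def coord_at(self, offset: int) -> int:
        """ATG-relative coordinate of the base at 0-based ``offset``."""
        c = self.origin + offset
        if self.origin < 0 and c >= 0:
            c += 1  # skip the non-existent position 0
        return c


@dataclass(frozen=True)
class CpGIsland:
    """A maximal CpG-dense region, coordinates ATG-relative and inclusive."""

    start: int
    end: int
    length_bp: int
    n_cpg: int
    gc_fraction: float
    obs_exp_cpg: float


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair; sequences written 5'->3'."""

    name: str
    fwd: str
    rev: str
    binding_coords: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.fwd or not self.rev:
            raise ValueError("primer sequences must be non-empty")


@dataclass(frozen=True)
class MethylationPattern:
    """Per-CpG methylation states for an amplicon.

    Either an explicit tuple of booleans (True = methylated), one per CpG in
    5'->3' order, or a uniform state applied to every CpG.
    """

    states: tuple[bool, ...] | None = None
    uniform: bool | None = None

    @classmethod
    def fully_methylated(cls) -> "MethylationPattern":
        return cls(uniform=True)

    @classmethod
    def fully_unmethylated(cls) -> "MethylationPattern":
        return cls(uniform=False)

    def state_for(self, i: int, n_cpg: int) -> bool:
        if self.states is not None:
            if len(self.states) != n_cpg:
                raise PatternMismatchError(
                    f"pattern has {len(self.states)} states but amplicon has {n_cpg} CpGs"
                )
            return self.states[i]
        if self.uniform is None:
            raise PatternMismatchError("pattern carries neither states nor a uniform value")
        return self.uniform


@dataclass(frozen=True)
class PrimerDiagnostics:
    """Why a primer pair is or is not methylation independent."""

    methylation_independent: bool
    fwd_contains_cg: bool
    rev_contains_cg: bool
    fwd_site: tuple[int, int]
    rev_site: tuple[int, int]
    fwd_cpg_overlap: int
    rev_cpg_overlap: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def region_length(start: int, end: int) -> int:
    """Inclusive span size between two ATG-relative coordinates.

    With no position 0, a span crossing the ATG loses the phantom base:
    region_length(-531, +231) == 762.
    """
    if start == 0 or end == 0:
        raise InvalidCoordinateError("ATG-relative coordinates have no position 0")
    if start >= end:
        raise ValueError(f"start ({start}) must be < end ({end})")
    if (start > 0) == (end > 0):
        return end - start + 1
    return end - start


def count_cpgs(seq: str | PromoterSequence) -> int:
    """Number of CG dinucleotides on the given strand."""
    bases = seq.bases if isinstance(seq, PromoterSequence) else seq
    return bases.count("CG")


def bisulfite_convert(
    seq: str | PromoterSequence,
    pattern: MethylationPattern | bool = False,
) -> str:
    """In-silico bisulfite conversion assuming 100 % conversion efficiency.

    Every cytosine outside a CpG context becomes T (uracil, read as thymine
    after PCR).  A CpG cytosine becomes T if that CpG is unmethylated and
    stays C if it is methylated (5-methylcytosine resists conversion).

    ``pattern`` may be a :class:`MethylationPattern` or a bare boolean for a
    uniform state (True = every CpG methylated).
    """
    bases = seq.bases if isinstance(seq, PromoterSequence) else seq
    if isinstance(pattern, bool):
        pattern = MethylationPattern(uniform=pattern)
    n_cpg = count_cpgs(bases)
    # validate explicit patterns even if the sequence has no CpG
    if pattern.states is not None and len(pattern.states) != n_cpg:
        raise PatternMismatchError(
            f"pattern has {len(pattern.states)} states but sequence has {n_cpg} CpGs"
        )
    out = list(bases)
    cpg_i = 0
    for i, b in enumerate(bases):
        if b != "C":
            continue
        if i + 1 < len(bases) and bases[i + 1] == "G":
            if not pattern.state_for(cpg_i, n_cpg):
                out[i] = "T"
            cpg_i += 1
        else:
            out[i] = "T"
    return "".join(out)


def _island_stats(window: str) -> tuple[int, float, float]:
    n = len(window)
    n_c = window.count("C")
    n_g = window.count("G")
    n_cpg = window.count("CG")
    gc = (n_c + n_g) / n
    oe = (n_cpg * n) / (n_c * n_g) if n_c and n_g else 0.0
    return n_cpg, gc, oe


def find_cpg_islands(
    seq: str | PromoterSequence,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Detect CpG islands by a fixed-window scan with merging.

    Every window of exactly ``min_len`` bp is tested against the three
    Gardiner-Garden--Frommer-style criteria (length, GC fraction, and
    observed/expected CpG ratio ``n_CpG * N / (n_C * n_G)``).  Clusters of
    overlapping qualifying windows are unioned into maximal regions; each
    union is re-checked against the criteria and kept only if it still
    qualifies.  Defaults are the classical 200 bp / GC >= 0.5 / O/E >= 0.6.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ps = seq if isinstance(seq, PromoterSequence) else PromoterSequence(seq)
    bases = ps.bases
    n = len(bases)
    if n < min_len:
        return []

    qualifying: list[int] = []
    for i in range(n - min_len + 1):
        n_cpg, gc, oe = _island_stats(bases[i : i + min_len])
        if gc >= min_gc and oe >= min_oe:
            qualifying.append(i)

    islands: list[CpGIsland] = []
    k = 0
    while k < len(qualifying):
        start = qualifying[k]
        end_excl = start + min_len
        k += 1
        while k < len(qualifying) and qualifying[k] < end_excl:
            end_excl = qualifying[k] + min_len
            k += 1
        region = bases[start:end_excl]
        n_cpg, gc, oe = _island_stats(region)
        if gc >= min_gc and oe >= min_oe:
            islands.append(
                CpGIsland(
                    start=ps.coord_at(start),
                    end=ps.coord_at(end_excl - 1),
                    length_bp=end_excl - start,
                    n_cpg=n_cpg,
                    gc_fraction=gc,
                    obs_exp_cpg=oe,
                )
            )
    return islands


def _map_primer(primer: str, template: PromoterSequence, is_reverse: bool) -> tuple[int, int]:
    """Locate a primer's binding interval (0-based, inclusive) on the template.

    Primers designed on bisulfite-converted DNA are allowed to match either
    the genomic strand or its converted form (fully methylated or fully
    unmethylated, so CpG-overlapping primers still map).
    """
    query = str(Seq(primer).reverse_complement()) if is_reverse else primer
    candidates = (
        template.bases,
        bisulfite_convert(template, False),
        bisulfite_convert(template, True),
    )
    for cand in candidates:
        pos = cand.find(query)
        if pos != -1:
            return pos, pos + len(query) - 1
    raise UnmappedPrimerError(
        f"primer {primer!r} does not map to the template (genomic or bisulfite-converted)"
    )


def validate_primer_methylation_independent(
    pair: PrimerPair, template: PromoterSequence
) -> PrimerDiagnostics:
    """Check that neither primer contains a CpG nor binds across one.

    Methylation-independent amplification requires the primer binding sites
    to be free of CpG sites on the genomic template (otherwise the converted
    template sequence depends on methylation state, biasing amplification)
    and the primer sequences themselves to contain no CG dinucleotide.
    """
    fwd_site = _map_primer(pair.fwd, template, is_reverse=False)
    rev_site = _map_primer(pair.rev, template, is_reverse=True)

    cpg_positions = [i for i in range(len(template.bases) - 1)
                     if template.bases[i : i + 2] == "CG"]

    def overlap(site: tuple[int, int]) -> int:
        lo, hi = site
        return sum(1 for p in cpg_positions if p <= hi and p + 1 >= lo)

    fwd_cg = "CG" in pair.fwd
    rev_cg = "CG" in pair.rev
    fwd_ov = overlap(fwd_site)
    rev_ov = overlap(rev_site)
    ok = not (fwd_cg or rev_cg or fwd_ov or rev_ov)
    to_coords = lambda s: (template.coord_at(s[0]), template.coord_at(s[1]))
    return PrimerDiagnostics(
        methylation_independent=ok,
        fwd_contains_cg=fwd_cg,
        rev_contains_cg=rev_cg,
        fwd_site=to_coords(fwd_site),
        rev_site=to_coords(rev_site),
        fwd_cpg_overlap=fwd_ov,
        rev_cpg_overlap=rev_ov,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, origin: int = 1) -> list[PromoterSequence]:
    """Read sequences from FASTA; all records share the given ATG origin."""
    return [
        PromoterSequence(str(rec.seq).upper(), origin=origin)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_island_report(islands: Iterable[CpGIsland], path: str | Path) -> None:
    """Write islands as a BED-like TSV with ATG-relative coordinates."""
    with open(path, "w") as fh:
        fh.write("start\tend\tlength_bp\tn_cpg\tgc_fraction\tobs_exp_cpg\n")
        for isl in islands:
            fh.write(
                f"{isl.start}\t{isl.end}\t{isl.length_bp}\t{isl.n_cpg}"
                f"\t{isl.gc_fraction:.4f}\t{isl.obs_exp_cpg:.4f}\n"
            )


def read_primer_tsv(path: str | Path) -> list[PrimerPair]:
    """Read primer pairs from a TSV with columns name, fwd, rev."""
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["name", "fwd", "rev"]:
            raise ValueError(f"expected header 'name\\tfwd\\trev', got {header}")
        for line in fh:
            if not line.strip():
                continue
            name, fwd, rev = line.strip().split("\t")[:3]
            pairs.append(PrimerPair(name=name, fwd=fwd.upper(), rev=rev.upper()))
    return pairs
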