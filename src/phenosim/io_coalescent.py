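"""Parsing and writing of coalescent-simulator haplotype output.

Coalescent simulators of the ms family (ms, msHOT, msms) print replicates of
binary haplotypes — one 0/1 string per sampled chromosome, ``0`` ancestral and
``1`` derived — at segregating sites whose positions are fractions of the
simulated locus.  GENOME-style output carries integer base-pair positions
instead.  This module turns either dialect into :class:`HaplotypeMatrix`
objects, writes ms-format text back out (round-trip testing), and provides a
seeded fixture generator so the rest of the package is testable without any
external simulator.
"""
from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence, TextIO

import numpy as np

from ._rng import FIXTURE, substream
from .errors import ParseError, UnitConversionError, ValidationError

__all__ = [
    "HaplotypeMatrix",
    "ReplicateSet",
    "parse_ms",
    "parse_genome",
    "generate_fixture",
    "to_ms_text",
]


def _positions_to_bp(
    positions: np.ndarray, unit: str, locus_length_bp: int | None
) -> np.ndarray:
    """Convert site positions to distinct, non-decreasing integer base pairs.

    Fractional positions map to ``round(fraction * locus_length_bp)`` with
    ties rounding half up.  Collisions (two sites landing on the same bp) are
    resolved by bumping the later site forward 1 bp, with a warning — PLINK
    map files need distinct integers.
    """
    if unit == "bp":
        bp = np.asarray(positions, dtype=np.int64).copy()
    else:
        if locus_length_bp is None:
            raise UnitConversionError(
                "fractional positions need locus_length_bp to convert to base pairs"
            )
        bp = np.floor(np.asarray(positions, dtype=float) * locus_length_bp + 0.5).astype(
            np.int64
        )
    bumped = 0
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
            bumped += 1
    if bumped:
        warnings.warn(
            f"{bumped} base-pair position collision(s) resolved by +1 bp increments",
            stacklevel=3,
        )
    return bp


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes: rows are chromosomes, columns are segregating sites.

    ``alleles[i, j]`` is 0 if chromosome *i* carries the ancestral allele at
    site *j* and 1 if it carries the derived allele.  ``positions`` holds one
    coordinate per site, either as a fraction of the locus in [0, 1]
    (``position_unit="fraction"``, the ms convention) or in base pairs
    (``position_unit="bp"``, the GENOME convention).
    """

    alleles: np.ndarray
    positions: np.ndarray
    position_unit: str = "fraction"
    locus_length_bp: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValidationError("alleles must be a 2-D matrix")
        self.positions = np.asarray(
            self.positions, dtype=np.int64 if self.position_unit == "bp" else float
        )
        if self.position_unit not in ("fraction", "bp"):
            raise ValidationError(f"unknown position unit {self.position_unit!r}")
        if self.positions.ndim != 1 or len(self.positions) != self.alleles.shape[1]:
            raise ValidationError("positions length must equal the number of sites")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValidationError("alleles must be 0 (ancestral) or 1 (derived)")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) < 0):
            raise ValidationError("positions must be non-decreasing")
        if self.n_sites >= 1 and self.n_chromosomes < 1:
            raise ValidationError("a matrix with sites must have at least one chromosome")
        if self.locus_length_bp is not None and self.locus_length_bp <= 0:
            raise ValidationError("locus_length_bp must be positive")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def positions_bp(self, locus_length_bp: int | None = None) -> np.ndarray:
        """Site positions as distinct integer base pairs."""
        length = locus_length_bp if locus_length_bp is not None else self.locus_length_bp
        return _positions_to_bp(self.positions, self.position_unit, length)

    def take_sites(self, site_indices: Sequence[int]) -> "HaplotypeMatrix":
        """New matrix restricted to ``site_indices`` (kept in the given order)."""
        idx = np.asarray(site_indices, dtype=np.intp)
        return HaplotypeMatrix(
            self.alleles[:, idx],
            self.positions[idx],
            position_unit=self.position_unit,
            locus_length_bp=self.locus_length_bp,
        )

    def take_individuals(self, row_indices: Sequence[int]) -> "HaplotypeMatrix":
        """New matrix restricted to the given chromosomes (haploid individuals)."""
        idx = np.asarray(row_indices, dtype=np.intp)
        return HaplotypeMatrix(
            self.alleles[idx, :],
            self.positions,
            position_unit=self.position_unit,
            locus_length_bp=self.locus_length_bp,
        )


@dataclass
class ReplicateSet:
    """Ordered replicates from one simulator run, plus the command that made them."""

    replicates: list[HaplotypeMatrix] = field(default_factory=list)
    source_command: str = ""

    def __post_init__(self) -> None:
        units = {m.position_unit for m in self.replicates}
        if len(units) > 1:
            raise ValidationError("all replicates must share one position unit")

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self) -> Iterator[HaplotypeMatrix]:
        return iter(self.replicates)

    def __getitem__(self, i: int) -> HaplotypeMatrix:
        return self.replicates[i]


def _as_lines(stream: str | TextIO) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


_HAPLOTYPE_RE = re.compile(r"^[01]+$")


def _command_sample_size(command: str) -> int | None:
    """Sample-size token of an ms-style command line (``ms nsam nreps ...``)."""
    tokens = command.split()
    if len(tokens) >= 2:
        try:
            return int(tokens[1])
        except ValueError:
            return None
    return None


def parse_ms(stream: str | TextIO) -> ReplicateSet:
    """Parse ms / msHOT / msms text output.

    Replicates are delimited by ``//`` lines; each carries ``segsites: <k>``,
    a ``positions:`` line of k fractions, and one 0/1 haplotype string per
    chromosome.  Header chatter (command line, seed lines, blanks) is skipped
    permissively since the ms variants differ in it.  ``segsites: 0`` yields
    an empty matrix whose row count is taken from the command line's sample
    size when available.
    """
    lines = _as_lines(stream)
    command = lines[0].strip() if lines else ""
    nsam = _command_sample_size(command)

    # indices of replicate delimiters
    starts = [i for i, ln in enumerate(lines) if ln.strip().startswith("//")]
    if not starts:
        raise ParseError("no replicate delimiter ('//') found")

    replicates: list[HaplotypeMatrix] = []
    bounds = starts + [len(lines)]
    for block_no, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        segsites: int | None = None
        positions: np.ndarray | None = None
        rows: list[np.ndarray] = []
        for i in range(lo + 1, hi):
            raw = lines[i]
            text = raw.strip()
            if not text:
                continue
            if text.startswith("segsites:"):
                try:
                    segsites = int(text.split(":", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"unreadable segsites count {text!r}", i + 1) from exc
                continue
            if text.startswith("positions:"):
                try:
                    positions = np.array(
                        [float(t) for t in text.split(":", 1)[1].split()], dtype=float
                    )
                except ValueError as exc:
                    raise ParseError(f"unreadable positions line {text!r}", i + 1) from exc
                continue
            if segsites is None:
                # pre-segsites chatter (e.g. msms prob lines); skip
                continue
            if not _HAPLOTYPE_RE.match(text):
                raise ParseError(
                    f"haplotype row contains characters outside {{0,1}}: {text!r}", i + 1
                )
            if len(text) != segsites:
                raise ParseError(
                    f"haplotype row has {len(text)} characters, expected {segsites}", i + 1
                )
            rows.append(np.frombuffer(text.encode("ascii"), dtype=np.uint8) - ord("0"))

        if segsites is None:
            raise ParseError(f"replicate {block_no}: missing 'segsites:' line")
        if segsites == 0:
            n_rows = nsam if nsam is not None else 0
            matrix = HaplotypeMatrix(
                np.zeros((n_rows, 0), dtype=np.int8), np.empty(0, dtype=float)
            )
        else:
            if positions is None:
                raise ParseError(f"replicate {block_no}: missing 'positions:' line")
            if len(positions) != segsites:
                raise ParseError(
                    f"replicate {block_no}: {len(positions)} positions for "
                    f"{segsites} segregating sites"
                )
            if not rows:
                raise ParseError(f"replicate {block_no}: no haplotype rows")
            matrix = HaplotypeMatrix(np.vstack(rows), positions)
        if nsam is not None and matrix.n_sites and matrix.n_chromosomes != nsam:
            warnings.warn(
                f"replicate {block_no}: {matrix.n_chromosomes} haplotypes but the "
                f"command line requested {nsam}",
                stacklevel=2,
            )
        replicates.append(matrix)
    return ReplicateSet(replicates, source_command=command)


_POSITIONS_LINE_RE = re.compile(r"(?i)^.*\bpositions?\s*:\s*(.*)$")


def parse_genome(stream: str | TextIO) -> ReplicateSet:
    """Parse GENOME-style output: bp position header lines plus 0/1 haplotype rows.

    The dialect accepted here: each replicate starts with a line containing
    ``positions: <bp1> <bp2> ...`` (integer base pairs; any prefix such as
    ``SNP positions`` is tolerated), followed by one haplotype row per
    chromosome.  Rows may carry a ``label:`` prefix and internal whitespace,
    both of which are stripped.  Non-monotone position headers are re-sorted
    (columns follow) with a warning rather than rejected.
    """
    lines = _as_lines(stream)
    header_starts = [
        i for i, ln in enumerate(lines) if _POSITIONS_LINE_RE.match(ln) and ":" in ln
    ]
    if not header_starts:
        raise ParseError("no position header line found (expected 'positions: <bp> ...')")
    command = ""
    if header_starts[0] > 0:
        command = lines[0].strip()

    replicates: list[HaplotypeMatrix] = []
    bounds = header_starts + [len(lines)]
    for block_no, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        match = _POSITIONS_LINE_RE.match(lines[lo])
        assert match is not None
        try:
            positions = np.array([int(t) for t in match.group(1).split()], dtype=np.int64)
        except ValueError as exc:
            raise ParseError(
                f"unreadable base-pair positions {match.group(1)!r}", lo + 1
            ) from exc
        rows: list[np.ndarray] = []
        for i in range(lo + 1, hi):
            text = lines[i].strip()
            if not text:
                continue
            if ":" in text:  # optional row label, e.g. "POP1-3: 0101"
                text = text.rsplit(":", 1)[1]
            text = "".join(text.split())
            if not _HAPLOTYPE_RE.match(text):
                raise ParseError(
                    f"haplotype row contains characters outside {{0,1}}: {text!r}", i + 1
                )
            if len(text) != len(positions):
                raise ParseError(
                    f"haplotype row has {len(text)} characters, expected {len(positions)}",
                    i + 1,
                )
            rows.append(np.frombuffer(text.encode("ascii"), dtype=np.uint8) - ord("0"))
        if not rows:
            raise ParseError(f"replicate {block_no}: no haplotype rows after header")
        alleles = np.vstack(rows)
        if len(positions) > 1 and np.any(np.diff(positions) < 0):
            warnings.warn(
                f"replicate {block_no}: non-monotone positions re-sorted", stacklevel=2
            )
            order = np.argsort(positions, kind="stable")
            positions = positions[order]
            alleles = alleles[:, order]
        replicates.append(HaplotypeMatrix(alleles, positions, position_unit="bp"))
    return ReplicateSet(replicates, source_command=command)


def generate_fixture(
    n_chromosomes: int,
    n_sites: int,
    freq_spectrum: float | Sequence[float],
    seed: int | np.random.Generator = 0,
) -> HaplotypeMatrix:
    """Draw a synthetic haplotype matrix with independent sites.

    Column *j* carries the derived allele on each chromosome independently
    with probability ``freq_spectrum[j]`` (a scalar is broadcast to all
    sites); positions are sorted uniforms on [0, 1].  This replaces external
    coalescent simulators in tests: it reproduces allele-frequency structure
    but, having no genealogy, no linkage disequilibrium between sites.
    """
    if n_chromosomes < 1:
        raise ValidationError("n_chromosomes must be positive")
    if n_sites < 0:
        raise ValidationError("n_sites must be non-negative")
    rng = substream(seed, FIXTURE)
    p = np.broadcast_to(np.asarray(freq_spectrum, dtype=float), (n_sites,))
    if n_sites and not ((p > 0) & (p < 1)).all():
        raise ValidationError("all target derived-allele probabilities must lie in (0, 1)")
    alleles = (rng.random((n_chromosomes, n_sites)) < p).astype(np.int8)
    positions = np.sort(rng.random(n_sites))
    return HaplotypeMatrix(alleles, positions)


def to_ms_text(rep: ReplicateSet | HaplotypeMatrix) -> str:
    """Serialize replicates as ms-format text; ``parse_ms`` inverts it exactly.

    Positions are printed at full float precision so the round trip is exact.
    Base-pair matrices are converted back to fractions via their
    ``locus_length_bp``; without one the conversion is refused.
    """
    if isinstance(rep, HaplotypeMatrix):
        rep = ReplicateSet([rep])
    out = io.StringIO()
    nsam = rep.replicates[0].n_chromosomes if rep.replicates else 0
    command = rep.source_command or f"ms {nsam} {len(rep.replicates)}"
    out.write(command + "\n")
    for m in rep.replicates:
        if m.position_unit == "bp":
            if m.locus_length_bp is None:
                raise UnitConversionError(
                    "cannot write bp-unit positions as ms fractions without locus_length_bp"
                )
            fractions = m.positions / float(m.locus_length_bp)
        else:
            fractions = m.positions
        out.write("\n//\n")
        out.write(f"segsites: {m.n_sites}\n")
        if m.n_sites:
            out.write("positions: " + " ".join(f"{p:.17g}" for p in fractions) + "\n")
            for row in m.alleles:
                out.write("".join("1" if a else "0" for a in row) + "\n")
    return out.getvalue()
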