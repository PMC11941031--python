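"""Reference, target-CpG and SNP-site input handling.

All coordinates are 0-based half-open internally.  Conversions happen only
at file boundaries: BED comes in native 0-based, VCF positions are shifted
down by one, and the Bismark coverage output (``meth_call``) shifts back up.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

_VALID = set("ACGTN")
_NORMALIZE = {c: (c if c in _VALID else "N") for c in
              "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input is syntactically fine but inconsistent with the reference."""


@dataclass
class Genome:
    """Uppercase ACGTN sequences keyed by contig name."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def slice(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]


@dataclass(frozen=True)
class TargetSpec:
    """A single target CpG, normalized to the plus-strand cytosine.

    ``strand`` is metadata only; a CpG site is its own reverse complement,
    so minus-strand inputs are stored at the same plus-strand position.
    """

    target_id: str
    contig: str
    cpg_pos: int
    strand: str = "+"


@dataclass(frozen=True)
class RegionWithFlanks:
    target: TargetSpec
    window_start: int
    window_end: int
    sequence: str

    @property
    def cpg_offset(self) -> int:
        """Offset of the CpG cytosine within ``sequence``."""
        return self.target.cpg_pos - self.window_start


@dataclass
class SnpIndex:
    """Set of (contig, 0-based position) of common variants."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    def count_in(self, contig: str, start: int, end: int) -> int:
        return sum(1 for p in range(start, end) if (contig, p) in self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def normalize_sequence(seq: str) -> str:
    """Uppercase and mask non-ACGTN characters to N."""
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    return "".join(_NORMALIZE.get(c, "N") for c in up)


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a (multi-)FASTA into a :class:`Genome`.

    Lowercase is normalized to uppercase and anything outside ACGTN is
    masked to N.  Duplicate contig names and empty files are format errors.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig name {record.id!r} in {path}")
        seq = normalize_sequence(str(record.seq))
        if not seq:
            raise FormatError(f"empty sequence for contig {record.id!r} in {path}")
        contigs[record.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return Genome(contigs)


def read_targets_bed(path: str | os.PathLike, genome: Genome) -> list[TargetSpec]:
    """Read target CpGs from a BED file (>= 3 columns, intervals of width
    1 or 2 marking the CpG) and validate each against the genome.

    A width-1 interval may point at either base of the CpG dinucleotide;
    positions on the G are normalized to the plus-strand C.
    """
    targets: list[TargetSpec] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            contig = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if contig not in genome:
                raise ValidationError(f"{path}:{lineno}: unknown contig {contig!r}")
            if end - start not in (1, 2) or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: interval must have width 1 or 2, got {end - start}")
            seq = genome[contig]
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
            cpg_pos = _resolve_cpg_position(seq, start, end)
            if cpg_pos is None:
                context = seq[max(0, start - 1):start + 2]
                raise ValidationError(
                    f"{path}:{lineno}: no C.G dinucleotide at {contig}:{start} "
                    f"(context {context!r})")
            name = cols[3] if len(cols) >= 4 and cols[3] not in (".", "") else f"{contig}_{cpg_pos}"
            targets.append(TargetSpec(name, contig, cpg_pos, strand))
    return targets


def _resolve_cpg_position(seq: str, start: int, end: int) -> int | None:
    if seq[start:start + 2] == "CG":
        return start
    if end - start == 1 and start >= 1 and seq[start - 1:start + 1] == "CG":
        return start - 1  # interval marked the G (minus-strand convention)
    return None


def extract_region_with_flanks(genome: Genome, target: TargetSpec,
                               flank_bp: int) -> RegionWithFlanks:
    """Extract ``[cpg_pos - flank, cpg_pos + 2 + flank)`` around a target.

    Raises :class:`ValidationError` when the window exceeds the contig:
    clipping would silently bias arm enumeration near contig ends.
    """
    seq = genome[target.contig]
    start = target.cpg_pos - flank_bp
    end = target.cpg_pos + 2 + flank_bp
    if start < 0 or end > len(seq):
        raise ValidationError(
            f"target {target.target_id}: window [{start},{end}) exceeds "
            f"contig {target.contig} bounds [0,{len(seq)})")
    return RegionWithFlanks(target, start, end, seq[start:end])


def read_snp_sites(path: str | os.PathLike | None, genome: Genome) -> SnpIndex:
    """Read common-variant positions from a VCF or BED file.

    Only CHROM/POS are consumed; alleles are ignored.  A missing/None path
    returns an empty index.  Positions outside contig bounds are errors.
    """
    index = SnpIndex()
    if path is None:
        return index
    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"SNP file not found: {path}")
    if os.path.getsize(path) == 0:
        return index
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        _read_vcf_positions(path, genome, index)
    else:
        _read_bed_positions(path, genome, index)
    return index


def _check_bounds(index: SnpIndex, genome: Genome, contig: str, pos: int,
                  where: str) -> None:
    if contig not in genome or not 0 <= pos < len(genome[contig]):
        raise ValidationError(f"{where}: SNP position {contig}:{pos} out of bounds")
    index.positions.add((contig, pos))


def _read_vcf_positions(path: str, genome: Genome, index: SnpIndex) -> None:
    import pysam

    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            _check_bounds(index, genome, rec.chrom, rec.pos - 1, path)


def _read_bed_positions(path: str, genome: Genome, index: SnpIndex) -> None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            for pos in range(start, end):
                _check_bounds(index, genome, cols[0], pos, f"{path}:{lineno}")


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_targets_bed(targets: Iterable[TargetSpec], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.contig}\t{t.cpg_pos}\t{t.cpg_pos + 2}\t{t.target_id}\t0\t{t.strand}\n")
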