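"""In-silico bisulfite conversion and probe-arm derivation.

Bisulfite chemistry deaminates unmethylated cytosine to uracil (read as T)
while 5-methylcytosine -- essentially confined to CpG context in human
somatic DNA -- resists conversion.  A converted reference therefore has two
kinds of positions: plain bases with a known converted identity, and CpG
cytosines whose read-out depends on the (unknown) methylation state.  The
latter are encoded with IUPAC degenerate codes:

* **OT** (original top strand): CpG ``C`` becomes ``Y`` (= C or T), every
  other ``C`` becomes ``T``;
* **OB** (original bottom strand, represented in plus-strand orientation):
  CpG ``G`` becomes ``R`` (= A or G), every other ``G`` becomes ``A``.

Probe arms anneal to the converted template, so an arm is the reverse
complement of a template slice with the degenerate mapping Y <-> R.
"""

from __future__ import annotations

from dataclasses import dataclass

OT = "OT"
OB = "OB"

_COMPLEMENT = str.maketrans("ACGTYRN", "TGCARYN")

# Degenerate resolution used for feature computation (Tm/GC): the
# unmethylated expansion, the majority state genome-wide.
_RESOLVE_UNMETH = str.maketrans({"Y": "T", "R": "A"})


def reverse_complement(seq: str) -> str:
    """Reverse complement over ACGT plus Y/R/N (Y <-> R under complement)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConvertedSequence:
    """A bisulfite-converted strand in plus-strand orientation.

    ``ambiguous_positions`` are the 0-based positions that were CpG
    cytosines (OT, now Y) or CpG guanines (OB, now R).
    """

    strand: str
    sequence: str
    ambiguous_positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        return self.sequence[start:end]


def convert_strand(seq: str, strand: str,
                   next_base_context: str | None = None,
                   prev_base_context: str | None = None) -> ConvertedSequence:
    """Convert a plus-strand reference sequence for one bisulfite strand.

    ``next_base_context``/``prev_base_context`` supply the genome base just
    past the right/left end, so CpGs straddling the slice boundary are
    recognized.  Without context, a terminal C (OT) or leading G (OB) is
    treated as non-CpG.
    """
    if strand not in (OT, OB):
        raise ValueError(f"strand must be {OT!r} or {OB!r}, got {strand!r}")
    bases = list(seq)
    ambiguous: list[int] = []
    n = len(bases)
    if strand == OT:
        for i, b in enumerate(bases):
            if b != "C":
                continue
            nxt = bases[i + 1] if i + 1 < n else (next_base_context or "")
            if nxt == "G":
                bases[i] = "Y"
                ambiguous.append(i)
            else:
                bases[i] = "T"
    else:
        for i, b in enumerate(bases):
            if b != "G":
                continue
            prv = bases[i - 1] if i > 0 else (prev_base_context or "")
            # on the original sequence the preceding base of a CpG G is C;
            # after the OT-position edits above never ran here, bases[i-1]
            # may already be converted, so test the original character
            if prv in ("C", "Y"):
                bases[i] = "R"
                ambiguous.append(i)
            else:
                bases[i] = "A"
    return ConvertedSequence(strand, "".join(bases), tuple(ambiguous))


def arm_sequence_for_template(template_subseq: str) -> str:
    """Probe arm (5'->3') annealing to a converted-template slice.

    The arm is the reverse complement with Y <-> R: a template Y (CpG C/T)
    pairs with a probe R (synthesized as an A/G mix), and vice versa.
    """
    allowed = set("ACGTYRN")
    bad = set(template_subseq) - allowed
    if bad:
        raise ValueError(f"unexpected characters in template slice: {sorted(bad)}")
    return reverse_complement(template_subseq)


def resolve_unmethylated(seq: str) -> str:
    """Resolve degenerate codes to the unmethylated expansion.

    Template Y -> T and probe R -> A; used before Tm/GC computation.
    """
    return seq.translate(_RESOLVE_UNMETH)
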