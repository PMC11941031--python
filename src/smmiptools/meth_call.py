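"""Per-CpG methylation calling from classified insert reads.

Inserts are aligned gaplessly to the *expected amplicon* of their probe --
the in-silico converted insert reference -- anchored at offset 0 by the arm
coordinates, with a bisulfite-aware matching rule: a read T matches a
reference Y (CpG of unknown state) or T; a read C matches a reference Y, a
reference C, or a reference T that derives from a genomic C (incomplete
conversion).  The CpG state is read off directly (C = methylated,
T = unmethylated).

Reads sharing a (probe, UMI) pair derive from one capture event; collapsing
them to a per-event majority consensus removes PCR amplification bias from
the beta values.  The per-CpG report follows the Bismark coverage format
(tab-delimited, 1-based inclusive coordinates).
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bisulfite_model import OT, convert_strand, reverse_complement
from .genome_io import Genome
from .read_classify import CATEGORY_WITH_INSERT, PanelIndex, ReadCall

METH = "meth"
UNMETH = "unmeth"
MISSING = "missing"


@dataclass(frozen=True)
class AmpliconRef:
    """Converted insert reference for one probe."""

    probe_id: str
    sequence: str                 # OT-converted insert, Y at CpG positions
    cpg_offsets: tuple[int, ...]  # target CpG offsets within the insert
    c_derived_offsets: frozenset[int]  # reference Ts that were genomic Cs
    contig: str
    insert_start: int

    def padded(self) -> str:
        return "NNNN" + self.sequence + "NNNN"


@dataclass
class CaptureEvent:
    probe_id: str
    umi: str
    calls: dict[int, str]  # cpg offset -> METH/UNMETH/MISSING
    n_duplicate_reads: int


@dataclass(frozen=True)
class MethylationCall:
    cpg_id: str
    contig: str
    pos_1based: int
    n_meth: int
    n_unmeth: int
    umi_collapsed: bool

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def beta(self) -> float:
        return self.n_meth / self.coverage


@dataclass(frozen=True)
class ReportConfig:
    min_coverage: int = 20
    umi_collapse: bool = True
    non_directional: bool = False

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def build_amplicon_refs(panel_index: PanelIndex, genome: Genome,
                        pad_n: bool = False) -> dict[str, AmpliconRef]:
    """One converted insert reference per probe, with target-CpG offsets
    and the mask of C-derived reference Ts.  ``pad_n`` requests 'NNNN'
    padding on FASTA export (for interoperability with external bisulfite
    mappers); internal alignment always ignores padding."""
    refs: dict[str, AmpliconRef] = {}
    for probe_id in sorted(panel_index.expected_insert_len):
        contig = panel_index.probe_contig[probe_id]
        start = panel_index.probe_insert_start[probe_id]
        length = panel_index.expected_insert_len[probe_id]
        contig_seq = genome[contig]
        if start < 0 or start + length > len(contig_seq):
            raise ValueError(f"insert of {probe_id} outside genome bounds")
        raw = contig_seq[start:start + length]
        nxt = contig_seq[start + length] if start + length < len(contig_seq) else None
        prv = contig_seq[start - 1] if start > 0 else None
        conv = convert_strand(raw, OT, next_base_context=nxt,
                              prev_base_context=prv)
        c_derived = frozenset(i for i, (a, b) in enumerate(zip(raw, conv.sequence))
                              if a == "C" and b == "T")
        cpg_off = panel_index.probe_cpg_pos[probe_id] - start
        refs[probe_id] = AmpliconRef(
            probe_id=probe_id, sequence=conv.sequence,
            cpg_offsets=(cpg_off,), c_derived_offsets=c_derived,
            contig=contig, insert_start=start)
    return refs


def write_amplicon_fasta(refs: Mapping[str, AmpliconRef],
                         path: str | os.PathLike, pad_n: bool = True) -> None:
    with open(path, "w") as fh:
        for probe_id in sorted(refs):
            ref = refs[probe_id]
            seq = ref.padded() if pad_n else ref.sequence
            fh.write(f">{probe_id}\n{seq}\n")


def _mismatches_ot(read: str, ref: AmpliconRef) -> int:
    mm = 0
    for i in range(min(len(read), len(ref.sequence))):
        r, t = read[i], ref.sequence[i]
        if r == t:
            continue
        if t == "Y" and r in "CT":
            continue
        if r == "C" and (t == "C" or (t == "T" and i in ref.c_derived_offsets)):
            continue
        mm += 1
    return mm


def align_read_to_amplicon(insert_seq: str, amplicon: AmpliconRef,
                           max_mismatch_frac: float = 0.1,
                           non_directional: bool = False) -> int | None:
    """Gapless, arm-anchored alignment (expected offset 0).

    Returns 0 when accepted, None otherwise.  In non-directional mode the
    reverse-complement orientation is also tried; it never improves on a
    read that already matches the designed orientation.
    """
    if not insert_seq:
        return None
    n = min(len(insert_seq), len(amplicon.sequence))
    cap = int(max_mismatch_frac * n)
    if _mismatches_ot(insert_seq, amplicon) <= cap:
        return 0
    if non_directional:
        flipped = reverse_complement(insert_seq)
        if _mismatches_ot(flipped, amplicon) <= cap:
            return 0
    return None


def extract_cpg_states(insert_seq: str, amplicon: AmpliconRef) -> dict[int, str]:
    """Per-target-CpG state from an accepted offset-0 alignment."""
    states: dict[int, str] = {}
    for off in amplicon.cpg_offsets:
        if off >= len(insert_seq):
            states[off] = MISSING
        elif insert_seq[off] == "C":
            states[off] = METH
        elif insert_seq[off] == "T":
            states[off] = UNMETH
        else:
            states[off] = MISSING
    return states


def collapse_umis(read_states: Iterable[tuple[str, str, dict[int, str]]],
                  ) -> list[CaptureEvent]:
    """Group per-read CpG states by (probe, UMI) into capture events.

    ``read_states`` yields (probe_id, umi, {cpg_offset: state}).  Consensus
    per CpG is by majority over the duplicate reads; exact ties and
    all-missing groups yield MISSING.
    """
    groups: dict[tuple[str, str], list[dict[int, str]]] = defaultdict(list)
    for probe_id, umi, states in read_states:
        groups[(probe_id, umi)].append(states)
    events: list[CaptureEvent] = []
    for (probe_id, umi) in sorted(groups):
        members = groups[(probe_id, umi)]
        offsets = {off for st in members for off in st}
        consensus: dict[int, str] = {}
        for off in sorted(offsets):
            n_m = sum(1 for st in members if st.get(off) == METH)
            n_u = sum(1 for st in members if st.get(off) == UNMETH)
            if n_m > n_u:
                consensus[off] = METH
            elif n_u > n_m:
                consensus[off] = UNMETH
            else:
                consensus[off] = MISSING
        events.append(CaptureEvent(probe_id, umi, consensus, len(members)))
    return events


def summarize_methylation(units: Sequence[CaptureEvent] | Sequence[tuple[str, str, dict[int, str]]],
                          panel_index: PanelIndex,
                          refs: Mapping[str, AmpliconRef],
                          report_config: ReportConfig | None = None,
                          ) -> tuple[list[MethylationCall], list[MethylationCall]]:
    """Per-CpG methylated/unmethylated counts and beta.

    Counts are over capture events when ``units`` holds
    :class:`CaptureEvent` s (UMI-collapsed), otherwise over raw reads.
    Returns ``(full, filtered)`` where the filtered table keeps rows with
    coverage >= ``min_coverage``; zero-coverage CpGs are omitted entirely.
    """
    report_config = report_config or ReportConfig()
    collapsed = bool(units) and isinstance(units[0], CaptureEvent)
    counts: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    for unit in units:
        probe_id, calls = ((unit.probe_id, unit.calls) if collapsed
                           else (unit[0], unit[2]))
        ref = refs[probe_id]
        for off, state in calls.items():
            if off not in ref.cpg_offsets:
                continue
            key = (probe_id, off)
            if state == METH:
                counts[key][0] += 1
            elif state == UNMETH:
                counts[key][1] += 1
    full: list[MethylationCall] = []
    for (probe_id, off) in sorted(counts):
        n_m, n_u = counts[(probe_id, off)]
        if n_m + n_u == 0:
            continue
        ref = refs[probe_id]
        pos0 = ref.insert_start + off
        full.append(MethylationCall(
            cpg_id=panel_index.probe_target[probe_id], contig=ref.contig,
            pos_1based=pos0 + 1, n_meth=n_m, n_unmeth=n_u,
            umi_collapsed=collapsed))
    filtered = [c for c in full if c.coverage >= report_config.min_coverage]
    return full, filtered


def write_bismark_coverage(calls: Sequence[MethylationCall],
                           path: str | os.PathLike) -> None:
    """Bismark coverage report: contig, 1-based start, end(=start),
    methylation percentage, methylated count, unmethylated count; sorted by
    contig then position; no header."""
    rows = sorted(calls, key=lambda c: (c.contig, c.pos_1based))
    with open(path, "w") as fh:
        for c in rows:
            pct = 100.0 * c.beta
            fh.write(f"{c.contig}\t{c.pos_1based}\t{c.pos_1based}\t"
                     f"{pct:g}\t{c.n_meth}\t{c.n_unmeth}\n")


def read_bismark_coverage(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "meth_pct",
                            "n_meth", "n_unmeth"])
    if len(df) and ((df.start != df.end).any() or (df.start < 1).any()):
        raise ValueError("not a valid Bismark coverage file")
    return df


# ---------------------------------------------------------------------------
# pipeline glue

@dataclass
class MethylationResult:
    full_raw: list[MethylationCall] = field(default_factory=list)
    filtered_raw: list[MethylationCall] = field(default_factory=list)
    full_umi: list[MethylationCall] = field(default_factory=list)
    filtered_umi: list[MethylationCall] = field(default_factory=list)
    events: list[CaptureEvent] = field(default_factory=list)
    n_aligned: int = 0
    n_unaligned: int = 0


def call_methylation(read_calls: Iterable[ReadCall], panel_index: PanelIndex,
                     genome: Genome, report_config: ReportConfig | None = None,
                     max_mismatch_frac: float = 0.1) -> MethylationResult:
    """Full calling pipeline over classified reads: align with-insert reads
    to their expected amplicon, extract CpG states, and summarize both raw
    and UMI-collapsed."""
    report_config = report_config or ReportConfig()
    refs = build_amplicon_refs(panel_index, genome)
    res = MethylationResult()
    read_states: list[tuple[str, str, dict[int, str]]] = []
    for rc in read_calls:
        if rc.category != CATEGORY_WITH_INSERT or not rc.probe_hyb:
            continue
        ref = refs[rc.probe_hyb]
        if align_read_to_amplicon(rc.insert_seq, ref, max_mismatch_frac,
                                  report_config.non_directional) is None:
            res.n_unaligned += 1
            continue
        res.n_aligned += 1
        read_states.append((rc.probe_hyb, rc.umi,
                            extract_cpg_states(rc.insert_seq, ref)))
    res.full_raw, res.filtered_raw = summarize_methylation(
        read_states, panel_index, refs, report_config)
    res.events = collapse_umis(read_states)
    res.full_umi, res.filtered_umi = summarize_methylation(
        res.events, panel_index, refs, report_config)
    return res


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cpg_id": c.cpg_id, "contig": c.contig, "pos_1based": c.pos_1based,
          "n_meth": c.n_meth, "n_unmeth": c.n_unmeth,
          "coverage": c.coverage, "beta": round(c.beta, 6),
          "umi_collapsed": c.umi_collapsed} for c in calls],
        columns=["cpg_id", "contig", "pos_1based", "n_meth", "n_unmeth",
                 "coverage", "beta", "umi_collapsed"])
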