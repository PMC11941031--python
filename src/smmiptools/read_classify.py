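"""Read trimming, UMI extraction, probe-arm location and read grouping.

Every read pair falls into one of three groups: reads with a captured
insert (both arms of one probe located, gap >= ``min_insert_bp``), reads
without an insert (self-circularized probes: arms located but the gap is
below 5 bp) and not-probe-related reads (no arm located).  Chimeric
products -- the hybridization arm of one probe joined to the elongation
arm of another -- are attributed to both probes and counted as off-target,
not as a fourth top-level category.

Arm location is a seeded k-mer search with IUPAC-aware Hamming
verification: degenerate Y positions of an arm binding site (CpGs of
unknown methylation state) match C or T, and mismatches are capped at a
configurable fraction of the arm length (default 10 %, rounded down).
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .bisulfite_model import reverse_complement
from .capture_sim import ADAPTER_FILL
from .panel_select import Panel, binding_site

CATEGORY_WITH_INSERT = "with_insert"
CATEGORY_NO_INSERT = "no_insert"
CATEGORY_NOT_PROBE_RELATED = "not_probe_related"

COVERAGE_STRATA = ("0", "1-20", "21-50", ">50")


@dataclass(frozen=True)
class ClassifierConfig:
    min_insert_bp: int = 5
    max_arm_mismatch_frac: float = 0.1
    adapter_seqs: tuple[str, str] = (ADAPTER_FILL, ADAPTER_FILL)
    umi_length: int = 9
    min_adapter_overlap: int = 6

    def __post_init__(self) -> None:
        if self.min_insert_bp < 0:
            raise ValueError("min_insert_bp must be >= 0")
        if not 0 <= self.max_arm_mismatch_frac <= 0.2:
            raise ValueError("max_arm_mismatch_frac must lie in [0, 0.2]")


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    category: str
    probe_hyb: str | None
    probe_elong: str | None
    chimera: bool
    umi: str
    insert_seq: str = ""

    @property
    def insert_len(self) -> int:
        return len(self.insert_seq)


@dataclass(frozen=True)
class ArmHit:
    probe_id: str
    arm_kind: str  # "hyb" | "elong"
    position: int
    mismatches: int


# IUPAC compatibility for read-vs-site comparison (site may hold Y/R/N)
_COMPAT = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "Y": {"C", "T"}, "R": {"A", "G"}, "N": {"A", "C", "G", "T"},
}


def _matches(site_char: str, read_char: str) -> bool:
    return read_char in _COMPAT.get(site_char, set())


def hamming_site(site: str, read: str, start: int) -> int:
    """Mismatches of ``site`` against ``read[start:start+len(site)]``;
    degenerate site positions match any expansion."""
    return sum(1 for k, c in enumerate(site)
               if not _matches(c, read[start + k]))


@dataclass(slots=True)
class _IndexedArm:
    probe_id: str
    arm_kind: str
    site: str          # template-space binding sequence (R1 orientation)
    site_rc: str       # reverse complement (R2 orientation)
    max_mismatches: int


class PanelIndex:
    """Panel arms indexed by k-mer seeds for fast location in reads.

    Seed length adapts to the mismatch cap so that any occurrence within
    the cap contains at least one exact seed (pigeonhole), keeping the
    seeded search equivalent to a full sliding Hamming scan.
    """

    def __init__(self, panel: "Panel | pd.DataFrame",
                 config: ClassifierConfig | None = None) -> None:
        self.config = config or ClassifierConfig()
        self.arms: list[_IndexedArm] = []
        self.expected_insert_len: dict[str, int] = {}
        self.probe_contig: dict[str, str] = {}
        self.probe_target: dict[str, str] = {}
        self.probe_cpg_pos: dict[str, int] = {}
        self.probe_insert_start: dict[str, int] = {}
        if isinstance(panel, Panel):
            rows = []
            for tid in sorted(panel.entries):
                p = panel.entries[tid]
                ap = p.arm_pair
                rows.append((p.probe_id, tid, ap.contig, ap.hyb_seq,
                             ap.elong_seq, ap.insert_interval[0],
                             ap.insert_interval[1], ap.cpg_pos))
        else:
            rows = [(r.probe_id, r.target_id, r.contig, r.hyb_arm_seq,
                     r.elong_arm_seq, int(r.insert_start), int(r.insert_end),
                     int(r.cpg_pos)) for r in panel.itertuples()]
        frac = self.config.max_arm_mismatch_frac
        for probe_id, tid, contig, hyb, elong, ins_s, ins_e, cpg in rows:
            self.expected_insert_len[probe_id] = ins_e - ins_s
            self.probe_contig[probe_id] = contig
            self.probe_target[probe_id] = tid
            self.probe_cpg_pos[probe_id] = cpg
            self.probe_insert_start[probe_id] = ins_s
            for kind, arm in (("hyb", hyb), ("elong", elong)):
                site = binding_site(arm)
                self.arms.append(_IndexedArm(
                    probe_id, kind, site, reverse_complement(site),
                    int(frac * len(site))))
        self._seed_index: dict[str, list[tuple[int, int, bool]]] = defaultdict(list)
        self.seed_len = self._build_seed_index()

    def _build_seed_index(self) -> int:
        min_len = min(len(a.site) for a in self.arms)
        max_mm = max(a.max_mismatches for a in self.arms)
        k = max(6, min_len // (max_mm + 1))
        for ai, arm in enumerate(self.arms):
            for oriented, seq in ((True, arm.site), (False, arm.site_rc)):
                step = max(1, len(seq) // (arm.max_mismatches + 1) - k + 1)
                offsets = set(range(0, len(seq) - k + 1, step))
                offsets.add(len(seq) - k)
                # guarantee the pigeonhole property: take every disjoint
                # k-block start as a seed position
                offsets.update(range(0, len(seq) - k + 1, k))
                for off in sorted(offsets):
                    for seed in _expand_degenerate(seq[off:off + k]):
                        self._seed_index[seed].append((ai, off, oriented))
        return k

    def locate(self, read: str, forward: bool = True) -> list[ArmHit]:
        """All arm occurrences in ``read`` within the mismatch cap; the
        best (fewest-mismatch, leftmost) hit per (probe, arm) retained.
        ``forward`` searches template orientation (R1), else reverse
        complement (R2)."""
        k = self.seed_len
        best: dict[tuple[str, str], ArmHit] = {}
        seen: set[tuple[int, int]] = set()
        for pos in range(0, len(read) - k + 1):
            for ai, off, oriented in self._seed_index.get(read[pos:pos + k], ()):
                if oriented != forward:
                    continue
                arm = self.arms[ai]
                site = arm.site if forward else arm.site_rc
                start = pos - off
                if start < 0 or start + len(site) > len(read):
                    continue
                if (ai, start) in seen:
                    continue
                seen.add((ai, start))
                mm = hamming_site(site, read, start)
                if mm > arm.max_mismatches:
                    continue
                key = (arm.probe_id, arm.arm_kind)
                prev = best.get(key)
                if prev is None or (mm, start) < (prev.mismatches, prev.position):
                    best[key] = ArmHit(arm.probe_id, arm.arm_kind, start, mm)
        return sorted(best.values(),
                      key=lambda h: (h.mismatches, h.position, h.probe_id, h.arm_kind))

    def site_len(self, probe_id: str, arm_kind: str) -> int:
        for arm in self.arms:
            if arm.probe_id == probe_id and arm.arm_kind == arm_kind:
                return len(arm.site)
        raise KeyError((probe_id, arm_kind))


def _expand_degenerate(seed: str, cap: int = 16) -> list[str]:
    outs = [""]
    for c in seed:
        options = "CT" if c == "Y" else "AG" if c == "R" else c
        if len(options) > 1 and len(outs) * len(options) > cap:
            return []  # too ambiguous to seed; other offsets cover the arm
        outs = [o + b for o in outs for b in options]
    return outs


def locate_arms(read: str, panel_index: PanelIndex,
                config: ClassifierConfig | None = None,
                forward: bool = True) -> list[ArmHit]:
    """Module-level convenience wrapper around :meth:`PanelIndex.locate`."""
    return panel_index.locate(read, forward=forward)


def extract_umi_and_trim(read1: str, read2: str,
                         config: ClassifierConfig | None = None,
                         ) -> tuple[str, tuple[str, str]]:
    """First 9 bases of read 1 are the UMI; adapter suffixes are removed
    from both mates by exact suffix-overlap matching."""
    config = config or ClassifierConfig()
    u = config.umi_length
    if len(read1) <= u:
        return "", (read1, read2)
    umi = read1[:u]
    return umi, (_trim_adapter(read1[u:], config.adapter_seqs[0], config),
                 _trim_adapter(read2, config.adapter_seqs[1], config))


def _trim_adapter(read: str, adapter: str, config: ClassifierConfig) -> str:
    full = read.find(adapter)
    if full != -1:
        return read[:full]
    for overlap in range(min(len(adapter), len(read)) - 1,
                         config.min_adapter_overlap - 1, -1):
        if read.endswith(adapter[:overlap]):
            return read[:len(read) - overlap]
    return read


def classify_read(read_pair: tuple[str, str], panel_index: PanelIndex,
                  config: ClassifierConfig | None = None,
                  read_id: str = "") -> ReadCall:
    """Classify one read pair into the three groups (chimeras attributed).

    The gap between the end of the hybridization-arm match and the start of
    the elongation-arm match on read 1 decides no-insert (< 5 bp) versus
    with-insert; when the elongation arm only appears on read 2 (the insert
    pushed it off read 1) the pair is with-insert and the insert sequence
    is reconstructed from both mates.
    """
    config = config or ClassifierConfig()
    umi, (t1, t2) = extract_umi_and_trim(read_pair[0], read_pair[1], config)
    hits1 = panel_index.locate(t1, forward=True) if t1 else []
    hits2 = panel_index.locate(t2, forward=False) if t2 else []
    hyb = _best(hits1, "hyb") or _best_r2(hits2, "hyb")
    elong = _best(hits1, "elong") or _best_r2(hits2, "elong")
    if hyb is not None and elong is not None \
            and hyb.hit.probe_id != elong.hit.probe_id:
        # prefer a same-probe arm pairing over a lower-mismatch cross-probe
        # one before declaring a chimera
        same = (_best(hits1, "elong", hyb.hit.probe_id)
                or _best_r2(hits2, "elong", hyb.hit.probe_id))
        if same is not None:
            elong = same
    if hyb is None and elong is None:
        return ReadCall(read_id, CATEGORY_NOT_PROBE_RELATED, None, None,
                        False, umi)
    if hyb is None or elong is None:
        return ReadCall(read_id, CATEGORY_NOT_PROBE_RELATED,
                        hyb.hit.probe_id if hyb else None,
                        elong.hit.probe_id if elong else None, False, umi)
    if hyb.hit.probe_id != elong.hit.probe_id:
        return ReadCall(read_id, CATEGORY_NOT_PROBE_RELATED,
                        hyb.hit.probe_id, elong.hit.probe_id, True, umi)
    probe_id = hyb.hit.probe_id
    hyb_len = panel_index.site_len(probe_id, "hyb")
    if hyb.on_r1 and elong.on_r1:
        gap = elong.hit.position - (hyb.hit.position + hyb_len)
        if gap < config.min_insert_bp:
            return ReadCall(read_id, CATEGORY_NO_INSERT, probe_id, probe_id,
                            False, umi)
        insert = t1[hyb.hit.position + hyb_len:elong.hit.position]
        return ReadCall(read_id, CATEGORY_WITH_INSERT, probe_id, probe_id,
                        False, umi, insert)
    if hyb.on_r1 and not elong.on_r1:
        insert = _reconstruct_insert(t1, t2, hyb.hit, elong.hit,
                                     panel_index, probe_id)
        if len(insert) < config.min_insert_bp:
            return ReadCall(read_id, CATEGORY_NO_INSERT, probe_id, probe_id,
                            False, umi)
        return ReadCall(read_id, CATEGORY_WITH_INSERT, probe_id, probe_id,
                        False, umi, insert)
    # inconsistent orientation (hyb only on R2): treat as off-target
    return ReadCall(read_id, CATEGORY_NOT_PROBE_RELATED, probe_id, probe_id,
                    False, umi)


@dataclass(frozen=True)
class _Located:
    hit: ArmHit
    on_r1: bool


def _best(hits: Sequence[ArmHit], kind: str,
          probe_id: str | None = None) -> _Located | None:
    for h in hits:
        if h.arm_kind == kind and (probe_id is None or h.probe_id == probe_id):
            return _Located(h, True)
    return None


def _best_r2(hits: Sequence[ArmHit], kind: str,
             probe_id: str | None = None) -> _Located | None:
    for h in hits:
        if h.arm_kind == kind and (probe_id is None or h.probe_id == probe_id):
            return _Located(h, False)
    return None


def _reconstruct_insert(t1: str, t2: str, hyb_hit: ArmHit, elong_hit: ArmHit,
                        index: PanelIndex, probe_id: str) -> str:
    """Merge the insert from R1 (after the hyb arm) and R2 (before the
    reverse-complemented elongation arm), using the panel's expected
    insert length; R1 bases win where the mates overlap."""
    expected = index.expected_insert_len[probe_id]
    from_r1 = t1[hyb_hit.position + index.site_len(probe_id, "hyb"):]
    from_r1 = from_r1[:expected]
    if len(from_r1) >= expected:
        return from_r1
    # rc(R2) region immediately left of the elongation site holds the
    # insert tail; elong site starts at elong_hit.position in R2
    # orientation, i.e. ends at position p_end in rc(t2):
    rc2 = reverse_complement(t2)
    site_len = index.site_len(probe_id, "elong")
    # elong site occupies t2[pos:pos+site_len] => rc2[n-pos-site_len : n-pos]
    n = len(t2)
    tail_end = n - elong_hit.position - site_len
    tail = rc2[max(0, tail_end - expected):tail_end]
    missing = expected - len(from_r1)
    if len(tail) >= missing:
        return from_r1 + tail[len(tail) - missing:]
    return from_r1 + tail  # best effort on short evidence


@dataclass
class ReadGroupSummary:
    category_fractions: dict[str, float]
    per_probe_insert_counts: dict[str, int]
    coverage_strata: dict[str, str]
    off_target_counts: dict[str, int]
    off_target_quartile: dict[str, int]


def tally_read_groups(read_calls: Iterable[ReadCall],
                      panel_index: PanelIndex) -> ReadGroupSummary:
    """Global category fractions, per-probe coverage strata
    (0 / 1-20 / 21-50 / >50 with-insert reads) and off-target quartile
    groups (1 = least off-target contribution, ties broken by probe id)."""
    calls = list(read_calls)
    probe_ids = sorted(index_pid for index_pid in
                       {a.probe_id for a in panel_index.arms})
    n = len(calls)
    cat_counts = {CATEGORY_WITH_INSERT: 0, CATEGORY_NO_INSERT: 0,
                  CATEGORY_NOT_PROBE_RELATED: 0}
    insert_counts = dict.fromkeys(probe_ids, 0)
    off_counts = dict.fromkeys(probe_ids, 0)
    for c in calls:
        cat_counts[c.category] += 1
        if c.category == CATEGORY_WITH_INSERT:
            insert_counts[c.probe_hyb] += 1
        else:
            for pid in {p for p in (c.probe_hyb, c.probe_elong) if p}:
                off_counts[pid] += 1
    strata = {pid: _stratum(cnt) for pid, cnt in insert_counts.items()}
    ranked = sorted(probe_ids, key=lambda p: (off_counts[p], p))
    quartile: dict[str, int] = {}
    for i, pid in enumerate(ranked):
        quartile[pid] = 1 + (4 * i) // max(1, len(ranked))
    fractions = {k: (v / n if n else 0.0) for k, v in cat_counts.items()}
    return ReadGroupSummary(fractions, insert_counts, strata, off_counts,
                            quartile)


def _stratum(count: int) -> str:
    if count == 0:
        return COVERAGE_STRATA[0]
    if count <= 20:
        return COVERAGE_STRATA[1]
    if count <= 50:
        return COVERAGE_STRATA[2]
    return COVERAGE_STRATA[3]


# ---------------------------------------------------------------------------
# file I/O

def read_calls_to_frame(calls: Iterable[ReadCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"read_id": c.read_id, "category": c.category,
          "probe_hyb": c.probe_hyb or "", "probe_elong": c.probe_elong or "",
          "chimera": c.chimera, "umi": c.umi, "insert_len": c.insert_len}
         for c in calls],
        columns=["read_id", "category", "probe_hyb", "probe_elong",
                 "chimera", "umi", "insert_len"])


def summary_to_frames(summary: ReadGroupSummary) -> dict[str, pd.DataFrame]:
    groups = pd.DataFrame(
        sorted(summary.category_fractions.items()),
        columns=["category", "fraction"])
    strata = pd.DataFrame(
        [{"probe_id": pid, "with_insert_reads": summary.per_probe_insert_counts[pid],
          "stratum": summary.coverage_strata[pid]}
         for pid in sorted(summary.per_probe_insert_counts)],
        columns=["probe_id", "with_insert_reads", "stratum"])
    quart = pd.DataFrame(
        [{"probe_id": pid, "off_target_reads": summary.off_target_counts[pid],
          "quartile_group": summary.off_target_quartile[pid]}
         for pid in sorted(summary.off_target_counts)],
        columns=["probe_id", "off_target_reads", "quartile_group"])
    return {"group_summary": groups, "coverage_strata": strata,
            "off_target_quartiles": quart}


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Minimal FASTQ reader returning (read_id, sequence) pairs; the read
    id is stripped of the mate suffix."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        rid = rec.id.split("/")[0]
        out.append((rid, str(rec.seq)))
    return out
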