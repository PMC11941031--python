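"""Candidate arm-pair enumeration and penalty scoring.

An smMIP captures the *insert* between its two arms, which both anneal to
the same converted strand: the elongation (extension) arm immediately
upstream of the insert and the hybridization (ligation) arm immediately
downstream.  Hard constraint windows (arm length, insert length, arm GC,
arm dTm cap) define the search space; soft penalties (CpGs and common SNPs
under the arms, arm hairpins, arm dTm) rank candidates within it:

    penalty = w_cpg * n_cpg_arms + w_snp * n_snp_arms + w_dtm * dTm
              + w_hairpin * max(0, hairpin_tm - hairpin_threshold)

CpGs inside the captured insert are *not* penalized -- only CpGs under the
arms disturb annealing -- but insert CpG density is still available from
the insert interval for downstream coverage analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import thermo
from .bisulfite_model import (ConvertedSequence, arm_sequence_for_template,
                              resolve_unmethylated)
from .genome_io import Genome, RegionWithFlanks, SnpIndex
from .thermo import ThermoParams

NEG_INF = float("-inf")


@dataclass(frozen=True)
class DesignProfile:
    """Hard constraint windows plus screening thresholds.

    The stringent defaults are: target length 90-100 bp, arm length
    25-30 bp, arm GC 0-60 %, arm dTm cap 5 degC, panel Tm spread cap
    10 degC, and a 20 degC Tm reporting threshold for dimers/hairpins.
    ``loosening_schedule`` lists progressively widened profiles tried for
    targets that fail the stringent stage.
    """

    target_len_window: tuple[int, int] = (90, 100)
    arm_len_window: tuple[int, int] = (25, 30)
    gc_window: tuple[float, float] = (0.0, 60.0)
    max_arm_dtm_c: float = 5.0
    max_panel_tm_spread_c: float = 10.0
    dimer_tm_threshold_c: float = 20.0
    hairpin_tm_threshold_c: float = 20.0
    max_candidates_per_target: int = 50_000
    loosening_schedule: tuple["DesignProfile", ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in (self.target_len_window, self.arm_len_window, self.gc_window):
            if lo > hi:
                raise ValueError("empty constraint window")
        prev = self
        for stage in self.loosening_schedule:
            if not stage._widens(prev):
                raise ValueError("loosening schedule must widen or keep each window")
            prev = stage

    def _widens(self, prev: "DesignProfile") -> bool:
        return (self.target_len_window[0] <= prev.target_len_window[0]
                and self.target_len_window[1] >= prev.target_len_window[1]
                and self.arm_len_window[0] <= prev.arm_len_window[0]
                and self.arm_len_window[1] >= prev.arm_len_window[1]
                and self.gc_window[0] <= prev.gc_window[0]
                and self.gc_window[1] >= prev.gc_window[1]
                and self.max_arm_dtm_c >= prev.max_arm_dtm_c)

    def stages(self) -> list["DesignProfile"]:
        """The stringent profile followed by its loosened stages."""
        return [self, *self.loosening_schedule]

    @property
    def min_flank_bp(self) -> int:
        """Flank width needed so arm enumeration space is uniform."""
        widest = max(self.stages(),
                     key=lambda p: p.target_len_window[1] + p.arm_len_window[1])
        return widest.target_len_window[1] + widest.arm_len_window[1]

    @classmethod
    def default(cls) -> "DesignProfile":
        """Stringent profile with the default three-stage loosening
        schedule (terminal target window 80-110 bp)."""
        stage3 = cls(target_len_window=(80, 110), arm_len_window=(22, 34),
                     gc_window=(0.0, 80.0), max_arm_dtm_c=10.0)
        stage2 = cls(target_len_window=(85, 105), arm_len_window=(24, 32),
                     gc_window=(0.0, 70.0), max_arm_dtm_c=7.0)
        return cls(loosening_schedule=(stage2, stage3))

    @classmethod
    def stringent_only(cls) -> "DesignProfile":
        return cls()


@dataclass(frozen=True)
class ScoringWeights:
    w_cpg: float = 1.0
    w_snp: float = 1.0
    w_hairpin: float = 1.0
    w_dtm: float = 1.0
    dimer_conflict_increment: float = 5.0

    def __post_init__(self) -> None:
        if min(self.w_cpg, self.w_snp, self.w_hairpin, self.w_dtm) < 0:
            raise ValueError("weights must be non-negative")
        if self.dimer_conflict_increment <= 0:
            raise ValueError("dimer_conflict_increment must be positive")


@dataclass(frozen=True, slots=True)
class ArmPair:
    """One candidate geometry: probe-orientation arm sequences plus the
    genomic intervals (0-based half-open) they anneal to."""

    target_id: str
    contig: str
    strand: str
    hyb_interval: tuple[int, int]
    hyb_seq: str
    elong_interval: tuple[int, int]
    elong_seq: str
    insert_interval: tuple[int, int]
    cpg_pos: int

    @property
    def insert_len(self) -> int:
        return self.insert_interval[1] - self.insert_interval[0]


@dataclass(frozen=True, slots=True)
class ProbeFeatures:
    tm_h: float
    tm_e: float
    dtm: float
    gc_h: float
    gc_e: float
    len_h: int
    len_e: int
    n_cpg_arms: int
    n_snp_arms: int
    hairpin_tm_c: float  # max over both arms; -inf if no stem found
    target_len: int


@dataclass(slots=True)
class ProbeCandidate:
    arm_pair: ArmPair
    features: ProbeFeatures
    penalty: float


# ---------------------------------------------------------------------------
# enumeration

def enumerate_candidates(region: RegionWithFlanks, converted: ConvertedSequence,
                         profile: DesignProfile) -> list[ArmPair]:
    """All arm pairs satisfying the hard windows of ``profile``.

    Emits every (insert placement, arm length pair) whose insert length and
    arm lengths are inside their windows, whose insert contains the target
    CpG, whose arms fit inside the extracted region, and whose arm GC
    (unmethylated expansion) is inside the GC window.  The arm dTm cap is
    applied later, together with feature computation.
    """
    m = region.cpg_offset
    n = len(region.sequence)
    seq = converted.sequence
    lmin, lmax = profile.target_len_window
    amin, amax = profile.arm_len_window
    gmin, gmax = profile.gc_window
    w0 = region.window_start
    out: list[ArmPair] = []
    gc_cache: dict[tuple[int, int], float] = {}

    def arm_gc(start: int, end: int) -> float:
        key = (start, end)
        if key not in gc_cache:
            gc_cache[key] = thermo.gc_percent(
                resolve_unmethylated(seq[start:end]))
        return gc_cache[key]

    for ins_len in range(lmin, lmax + 1):
        for s in range(max(0, m + 2 - ins_len), m + 1):
            e = s + ins_len
            if e > n:
                continue
            for le in range(amin, amax + 1):
                if s - le < 0:
                    continue
                if not gmin <= arm_gc(s - le, s) <= gmax:
                    continue
                for lh in range(amin, amax + 1):
                    if e + lh > n:
                        continue
                    if not gmin <= arm_gc(e, e + lh) <= gmax:
                        continue
                    out.append(ArmPair(
                        target_id=region.target.target_id,
                        contig=region.target.contig,
                        strand=converted.strand,
                        hyb_interval=(w0 + e, w0 + e + lh),
                        hyb_seq=arm_sequence_for_template(seq[e:e + lh]),
                        elong_interval=(w0 + s - le, w0 + s),
                        elong_seq=arm_sequence_for_template(seq[s - le:s]),
                        insert_interval=(w0 + s, w0 + e),
                        cpg_pos=region.target.cpg_pos,
                    ))
    return out


def compute_features(arm_pair: ArmPair, genome: Genome, snp_index: SnpIndex,
                     thermo_params: ThermoParams = thermo.DEFAULT_THERMO) -> ProbeFeatures:
    """Per-candidate features: arm Tm/GC/length, dTm, CpG and SNP counts
    under the arms (on the pre-conversion genomic sequence), and the best
    arm hairpin stem Tm."""
    hs, he = arm_pair.hyb_interval
    es, ee = arm_pair.elong_interval
    hyb = resolve_unmethylated(arm_pair.hyb_seq)
    elong = resolve_unmethylated(arm_pair.elong_seq)
    tm_h = thermo.tm_nearest_neighbor(hyb, thermo_params)
    tm_e = thermo.tm_nearest_neighbor(elong, thermo_params)
    hp = NEG_INF
    for arm in (arm_pair.hyb_seq, arm_pair.elong_seq):
        hit = thermo.hairpin_screen(arm, params=thermo_params)
        if hit is not None:
            hp = max(hp, hit.tm_c)
    contig_seq = genome[arm_pair.contig]
    n_cpg = (_count_cpg_overlaps(contig_seq, hs, he)
             + _count_cpg_overlaps(contig_seq, es, ee))
    n_snp = (snp_index.count_in(arm_pair.contig, hs, he)
             + snp_index.count_in(arm_pair.contig, es, ee))
    return ProbeFeatures(
        tm_h=tm_h, tm_e=tm_e, dtm=abs(tm_h - tm_e),
        gc_h=thermo.gc_percent(hyb), gc_e=thermo.gc_percent(elong),
        len_h=he - hs, len_e=ee - es,
        n_cpg_arms=n_cpg, n_snp_arms=n_snp, hairpin_tm_c=hp,
        target_len=arm_pair.insert_len,
    )


def _count_cpg_overlaps(seq: str, start: int, end: int) -> int:
    """Genomic CpG sites [p, p+2) intersecting [start, end)."""
    lo = max(0, start - 1)
    return sum(1 for p in range(lo, end - 1 + 1)
               if p < end and p + 2 > start and seq[p:p + 2] == "CG")


def penalty_score(features: ProbeFeatures, weights: ScoringWeights,
                  profile: DesignProfile) -> float:
    """Weighted linear penalty over the soft features.  Hard-window
    violations never reach this function (they are filtered upstream)."""
    hairpin_excess = max(0.0, features.hairpin_tm_c - profile.hairpin_tm_threshold_c)
    return (weights.w_cpg * features.n_cpg_arms
            + weights.w_snp * features.n_snp_arms
            + weights.w_dtm * features.dtm
            + weights.w_hairpin * hairpin_excess)


# ---------------------------------------------------------------------------
# fast path used by panel selection: per-arm memoization

@dataclass(slots=True)
class _ArmInfo:
    seq: str
    tm: float
    gc: float
    hairpin_tm: float
    n_cpg: int
    n_snp: int


def design_candidates(region: RegionWithFlanks, converted: ConvertedSequence,
                      genome: Genome, snp_index: SnpIndex,
                      profile: DesignProfile, weights: ScoringWeights,
                      thermo_params: ThermoParams = thermo.DEFAULT_THERMO,
                      ) -> list[ProbeCandidate]:
    """Enumerate, featurize and score all candidates for one target.

    Equivalent to ``enumerate_candidates`` + ``compute_features`` +
    ``penalty_score`` with the arm dTm hard cap applied, but arms shared by
    many candidates are computed once.  If more than
    ``profile.max_candidates_per_target`` survive, the ones with smallest
    dTm are kept.
    """
    m = region.cpg_offset
    n = len(region.sequence)
    seq = converted.sequence
    contig_seq = genome[region.target.contig]
    w0 = region.window_start
    lmin, lmax = profile.target_len_window
    amin, amax = profile.arm_len_window
    gmin, gmax = profile.gc_window

    def arm_info(start: int, end: int, cache: dict) -> _ArmInfo | None:
        key = (start, end)
        info = cache.get(key, False)
        if info is not False:
            return info
        probe_seq = arm_sequence_for_template(seq[start:end])
        resolved = resolve_unmethylated(probe_seq)
        gc = thermo.gc_percent(resolved)
        if not gmin <= gc <= gmax:
            cache[key] = None
            return None
        hit = thermo.hairpin_screen(probe_seq, params=thermo_params)
        info = _ArmInfo(
            seq=probe_seq,
            tm=thermo.tm_nearest_neighbor(resolved, thermo_params),
            gc=gc,
            hairpin_tm=hit.tm_c if hit is not None else NEG_INF,
            n_cpg=_count_cpg_overlaps(contig_seq, w0 + start, w0 + end),
            n_snp=snp_index.count_in(region.target.contig, w0 + start, w0 + end),
        )
        cache[key] = info
        return info

    left_cache: dict = {}
    right_cache: dict = {}
    out: list[ProbeCandidate] = []
    for ins_len in range(lmin, lmax + 1):
        for s in range(max(0, m + 2 - ins_len), m + 1):
            e = s + ins_len
            if e > n:
                continue
            lefts = [(le, info) for le in range(amin, amax + 1)
                     if s - le >= 0 and (info := arm_info(s - le, s, left_cache))]
            rights = [(lh, info) for lh in range(amin, amax + 1)
                      if e + lh <= n and (info := arm_info(e, e + lh, right_cache))]
            for le, ei in lefts:
                for lh, hi in rights:
                    dtm = abs(hi.tm - ei.tm)
                    if dtm > profile.max_arm_dtm_c:
                        continue
                    feats = ProbeFeatures(
                        tm_h=hi.tm, tm_e=ei.tm, dtm=dtm,
                        gc_h=hi.gc, gc_e=ei.gc, len_h=lh, len_e=le,
                        n_cpg_arms=hi.n_cpg + ei.n_cpg,
                        n_snp_arms=hi.n_snp + ei.n_snp,
                        hairpin_tm_c=max(hi.hairpin_tm, ei.hairpin_tm),
                        target_len=ins_len,
                    )
                    pair = ArmPair(
                        target_id=region.target.target_id,
                        contig=region.target.contig,
                        strand=converted.strand,
                        hyb_interval=(w0 + e, w0 + e + lh),
                        hyb_seq=hi.seq,
                        elong_interval=(w0 + s - le, w0 + s),
                        elong_seq=ei.seq,
                        insert_interval=(w0 + s, w0 + e),
                        cpg_pos=region.target.cpg_pos,
                    )
                    out.append(ProbeCandidate(
                        pair, feats, penalty_score(feats, weights, profile)))
    if len(out) > profile.max_candidates_per_target:
        out.sort(key=lambda c: (c.features.dtm, c.arm_pair.insert_interval,
                                c.features.len_h, c.features.len_e))
        out = out[:profile.max_candidates_per_target]
    return out
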