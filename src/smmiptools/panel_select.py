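"""Panel construction: penalty-weighted random selection with dimer
re-penalization, constraint loosening, probe assembly and CSV output.

Selection is round-based.  Each round samples one candidate per unresolved
target with probability proportional to ``1/(1+penalty)`` (or a softmax),
then screens the tentative panel: probe pairs whose best ungapped dimer
stem melts above the reporting threshold, probes whose assembled sequence
hairpins above it, and -- when the panel arm-Tm spread exceeds its cap --
the probe farthest from the panel median Tm.  Conflicted candidates are
penalized and their targets resampled; the loop repeats until the panel is
conflict-free or the round budget is exhausted, after which still-conflicted
targets are re-enumerated under the next, loosened constraint stage.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import thermo
from .bisulfite_model import (OT, ConvertedSequence, convert_strand,
                              reverse_complement)
from .genome_io import Genome, SnpIndex, TargetSpec, extract_region_with_flanks
from .probe_design import (ArmPair, DesignProfile, ProbeCandidate,
                           ProbeFeatures, ScoringWeights, design_candidates)
from .thermo import DEFAULT_THERMO, ThermoParams

# A fixed 30-nt backbone compatible with common sequencing-adapter priming
# (the widely used MIP backbone); a pure configuration value.
DEFAULT_BACKBONE = "CTTCAGCTTCCCGATATCCGACGGTAGTGT"

UMI_LENGTH = 9


@dataclass(frozen=True)
class SelectionConfig:
    seed: int = 0
    max_rounds_per_stage: int = 50
    weight_transform: str = "inverse"  # or "softmax"
    softmax_temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.max_rounds_per_stage < 1:
            raise ValueError("max_rounds_per_stage must be >= 1")
        if self.weight_transform not in ("inverse", "softmax"):
            raise ValueError(f"unknown weight_transform {self.weight_transform!r}")


@dataclass(frozen=True)
class SmMIP:
    """An assembled probe: hyb arm, 9-N UMI, backbone, elongation arm."""

    probe_id: str
    arm_pair: ArmPair
    features: ProbeFeatures | None
    penalty: float
    backbone_seq: str
    full_sequence: str
    degenerate_arm_positions: tuple[int, ...]
    umi_length: int = UMI_LENGTH


@dataclass
class Panel:
    entries: dict[str, SmMIP] = field(default_factory=dict)
    failures: list[tuple[str, str, int]] = field(default_factory=list)
    profile_stage_used: dict[str, int] = field(default_factory=dict)

    @property
    def panel_tm_values(self) -> list[float]:
        vals: list[float] = []
        for probe in self.entries.values():
            if probe.features is not None:
                vals.extend((probe.features.tm_h, probe.features.tm_e))
        return vals


def assemble_smmip(arm_pair: ArmPair, backbone_seq: str = DEFAULT_BACKBONE,
                   probe_id: str | None = None,
                   features: ProbeFeatures | None = None,
                   penalty: float = 0.0) -> SmMIP:
    """Concatenate hyb arm, the 9 degenerate-N UMI, backbone and elongation
    arm into the orderable probe sequence (5'->3').  Arm CpG positions keep
    their degenerate R codes."""
    if not backbone_seq:
        raise ValueError("empty backbone")
    full = arm_pair.hyb_seq + "N" * UMI_LENGTH + backbone_seq + arm_pair.elong_seq
    degenerate = tuple(i for i, b in enumerate(full) if b == "R")
    return SmMIP(
        probe_id=probe_id or f"smmip_{arm_pair.target_id}",
        arm_pair=arm_pair, features=features, penalty=penalty,
        backbone_seq=backbone_seq, full_sequence=full,
        degenerate_arm_positions=degenerate,
    )


CandidateProvider = Callable[[str, int], list[ProbeCandidate]]


def select_panel(candidates_by_target: Mapping[str, list[ProbeCandidate]] | CandidateProvider,
                 profile: DesignProfile, weights: ScoringWeights,
                 sel_config: SelectionConfig,
                 target_ids: Sequence[str] | None = None,
                 backbone_seq: str = DEFAULT_BACKBONE,
                 thermo_params: ThermoParams = DEFAULT_THERMO) -> Panel:
    """Choose one conflict-free probe per target.

    ``candidates_by_target`` is either a mapping (stringent-stage
    candidates only) or a callable ``provider(target_id, stage_index)``
    that re-enumerates under the loosened profile of each stage.  The same
    seed always yields the identical panel.
    """
    if callable(candidates_by_target):
        provider = candidates_by_target
        if target_ids is None:
            raise ValueError("target_ids required with a provider callable")
        ids = sorted(target_ids)
    else:
        mapping = dict(candidates_by_target)
        ids = sorted(mapping) if target_ids is None else sorted(target_ids)

        def provider(tid: str, stage: int) -> list[ProbeCandidate]:
            return mapping.get(tid, []) if stage == 0 else []

    stages = profile.stages()
    rng = np.random.default_rng(sel_config.seed)
    panel = Panel()
    screener = _ConflictScreener(profile, thermo_params, backbone_seq)

    unresolved = list(ids)
    never_had_candidates = set(ids)
    for stage_idx in range(len(stages)):
        if not unresolved:
            break
        cands = {tid: c for tid in unresolved if (c := provider(tid, stage_idx))}
        never_had_candidates -= set(cands)
        unresolved = _run_stage(panel, cands, stage_idx, screener, weights,
                                sel_config, rng,
                                carryover=[t for t in unresolved if t not in cands])
    for tid in sorted(unresolved):
        reason = "no_candidates" if tid in never_had_candidates else "unresolved_conflicts"
        panel.failures.append((tid, reason, len(stages) - 1))
    return panel


class _ConflictScreener:
    """Memoized dimer/hairpin/Tm-spread screening over assembled probes."""

    def __init__(self, profile: DesignProfile, thermo_params: ThermoParams,
                 backbone_seq: str) -> None:
        self.profile = profile
        self.params = thermo_params
        self.backbone = backbone_seq
        self._dimer: dict[tuple[int, int], float] = {}
        self._hairpin: dict[int, float] = {}

    def full_seq(self, cand: ProbeCandidate) -> str:
        ap = cand.arm_pair
        return ap.hyb_seq + "N" * UMI_LENGTH + self.backbone + ap.elong_seq

    def dimer_tm(self, a: ProbeCandidate, b: ProbeCandidate) -> float:
        key = (min(id(a), id(b)), max(id(a), id(b)))
        tm = self._dimer.get(key)
        if tm is None:
            hit = thermo.heterodimer_screen(self.full_seq(a), self.full_seq(b),
                                            params=self.params)
            tm = hit.tm_c if hit is not None else float("-inf")
            self._dimer[key] = tm
        return tm

    def hairpin_tm(self, cand: ProbeCandidate) -> float:
        tm = self._hairpin.get(id(cand))
        if tm is None:
            hit = thermo.hairpin_screen(self.full_seq(cand), params=self.params)
            tm = hit.tm_c if hit is not None else float("-inf")
            self._hairpin[id(cand)] = tm
        return tm

    def conflicted_targets(self, assignment: dict[str, ProbeCandidate],
                           fixed: dict[str, SmMIP]) -> set[str]:
        """Targets of ``assignment`` that must be re-penalized/resampled."""
        thr = self.profile.dimer_tm_threshold_c
        flagged: set[str] = set()
        items = sorted(assignment.items())
        # self-structure of the assembled probe
        for tid, cand in items:
            if self.hairpin_tm(cand) > self.profile.hairpin_tm_threshold_c:
                flagged.add(tid)
        # cross-dimers among the assignment and against fixed probes
        for i, (tid_a, ca) in enumerate(items):
            for tid_b, cb in items[i + 1:]:
                if self.dimer_tm(ca, cb) > thr:
                    flagged.update((tid_a, tid_b))
            for probe in fixed.values():
                hit = thermo.heterodimer_screen(self.full_seq(ca),
                                                probe.full_sequence,
                                                params=self.params)
                if hit is not None and hit.tm_c > thr:
                    flagged.add(tid_a)
        # arm-Tm spread over the whole tentative panel
        tms: list[tuple[float, str | None]] = []
        for tid, cand in items:
            tms.append((cand.features.tm_h, tid))
            tms.append((cand.features.tm_e, tid))
        for probe in fixed.values():
            if probe.features is not None:
                tms.append((probe.features.tm_h, None))
                tms.append((probe.features.tm_e, None))
        if tms:
            values = [t for t, _ in tms]
            if max(values) - min(values) > self.profile.max_panel_tm_spread_c:
                med = median(values)
                worst = max((t for t in tms if t[1] is not None),
                            key=lambda t: (abs(t[0] - med), t[1]),
                            default=None)
                if worst is not None:
                    flagged.add(worst[1])
        return flagged


def _weights_for(penalties: Sequence[float], cfg: SelectionConfig) -> np.ndarray:
    p = np.asarray(penalties, dtype=float)
    if cfg.weight_transform == "inverse":
        w = 1.0 / (1.0 + p)
    else:
        w = np.exp(-(p - p.min()) / cfg.softmax_temperature)
    return w / w.sum()


def _sample(rng: np.random.Generator, penalties: Sequence[float],
            cfg: SelectionConfig) -> int:
    return int(rng.choice(len(penalties), p=_weights_for(penalties, cfg)))


def _run_stage(panel: Panel, cands: dict[str, list[ProbeCandidate]],
               stage_idx: int, screener: _ConflictScreener,
               weights: ScoringWeights, cfg: SelectionConfig,
               rng: np.random.Generator, carryover: list[str]) -> list[str]:
    """Run one selection stage; returns targets left for the next stage."""
    active = sorted(cands)
    penalties = {tid: [c.penalty for c in cands[tid]] for tid in active}
    selected = {tid: _sample(rng, penalties[tid], cfg) for tid in active}

    flagged: set[str] = set(active)
    for _ in range(cfg.max_rounds_per_stage):
        assignment = {tid: cands[tid][selected[tid]] for tid in active}
        flagged = screener.conflicted_targets(assignment, panel.entries)
        if not flagged:
            break
        for tid in sorted(flagged):
            penalties[tid][selected[tid]] += weights.dimer_conflict_increment
            selected[tid] = _sample(rng, penalties[tid], cfg)
    else:
        assignment = {tid: cands[tid][selected[tid]] for tid in active}
        flagged = screener.conflicted_targets(assignment, panel.entries)

    resolved = [tid for tid in active if tid not in flagged]
    # ensure the set being fixed is internally conflict-free (removing the
    # flagged probes can only remove conflicts, but re-check to be safe)
    while True:
        sub = {tid: cands[tid][selected[tid]] for tid in resolved}
        still = screener.conflicted_targets(sub, panel.entries)
        if not still:
            break
        flagged |= still
        resolved = [tid for tid in resolved if tid not in still]
    # keep a maximal conflict-free subset: conflicted targets are re-added
    # greedily where possible, so a mutually dimerizing pair loses only one
    # member to the next stage
    for tid in sorted(flagged):
        trial = {t: cands[t][selected[t]] for t in (*resolved, tid)}
        if not screener.conflicted_targets(trial, panel.entries):
            resolved.append(tid)
            flagged.discard(tid)
    for tid in resolved:
        cand = cands[tid][selected[tid]]
        probe = assemble_smmip(cand.arm_pair, screener.backbone,
                               probe_id=f"smmip_{tid}",
                               features=cand.features,
                               penalty=penalties[tid][selected[tid]])
        panel.entries[tid] = probe
        panel.profile_stage_used[tid] = stage_idx
    return sorted(set(carryover) | flagged)


# ---------------------------------------------------------------------------
# high-level design entry point

def convert_genome(genome: Genome, strand: str = OT) -> dict[str, ConvertedSequence]:
    return {name: convert_strand(seq, strand) for name, seq in genome.contigs.items()}


def design_panel(genome: Genome, targets: Sequence[TargetSpec],
                 snp_index: SnpIndex | None = None,
                 profile: DesignProfile | None = None,
                 weights: ScoringWeights | None = None,
                 sel_config: SelectionConfig | None = None,
                 thermo_params: ThermoParams = DEFAULT_THERMO,
                 backbone_seq: str = DEFAULT_BACKBONE,
                 strand: str = OT,
                 flank_bp: int | None = None) -> Panel:
    """Design one probe per target CpG: extract flanked regions, convert
    in silico, enumerate/score candidates per stage and select the panel."""
    profile = profile or DesignProfile.default()
    weights = weights or ScoringWeights()
    sel_config = sel_config or SelectionConfig()
    snp_index = snp_index or SnpIndex()
    flank = flank_bp if flank_bp is not None else profile.min_flank_bp
    stages = profile.stages()

    regions: dict[str, tuple] = {}
    failures: list[tuple[str, str, int]] = []
    for t in targets:
        try:
            region = extract_region_with_flanks(genome, t, flank)
        except ValueError:
            failures.append((t.target_id, "window_out_of_bounds", 0))
            continue
        contig_seq = genome[t.contig]
        nxt = contig_seq[region.window_end] if region.window_end < len(contig_seq) else None
        prv = contig_seq[region.window_start - 1] if region.window_start > 0 else None
        conv = convert_strand(region.sequence, strand,
                              next_base_context=nxt, prev_base_context=prv)
        regions[t.target_id] = (region, conv)

    cache: dict[tuple[str, int], list[ProbeCandidate]] = {}

    def provider(tid: str, stage_idx: int) -> list[ProbeCandidate]:
        key = (tid, stage_idx)
        if key not in cache:
            region, conv = regions[tid]
            cache[key] = design_candidates(region, conv, genome, snp_index,
                                           stages[stage_idx], weights,
                                           thermo_params)
        return cache[key]

    panel = select_panel(provider, profile, weights, sel_config,
                         target_ids=sorted(regions), backbone_seq=backbone_seq,
                         thermo_params=thermo_params)
    panel.failures.extend(failures)
    panel.failures.sort()
    return panel


# ---------------------------------------------------------------------------
# specificity scan

_SITE_CLASS = {"A": "[AN]", "C": "[CYN]", "G": "[GN]", "T": "[TYN]",
               "Y": "[CTYN]", "R": "[AGRN]", "N": "."}


def binding_site(arm_probe_seq: str) -> str:
    """Template-space binding site (plus orientation) of a probe arm."""
    return reverse_complement(arm_probe_seq)


def specificity_scan(panel: Panel,
                     converted_genome: Mapping[str, ConvertedSequence]) -> list[tuple[str, str, int]]:
    """Count exact occurrences of each arm's binding site in the converted
    genome (degenerate positions match every expansion, so converted-space
    collisions are never missed).  Arms occurring more than once are
    flagged as ``(probe_id, arm_kind, count)``; a warning, not a rejection.
    """
    flags: list[tuple[str, str, int]] = []
    for tid in sorted(panel.entries):
        probe = panel.entries[tid]
        for kind, arm in (("hyb", probe.arm_pair.hyb_seq),
                          ("elong", probe.arm_pair.elong_seq)):
            site = binding_site(arm)
            pattern = re.compile("(?=" + "".join(_SITE_CLASS[c] for c in site) + ")")
            count = sum(len(pattern.findall(conv.sequence))
                        for conv in converted_genome.values())
            if count > 1:
                flags.append((probe.probe_id, kind, count))
    return flags


# ---------------------------------------------------------------------------
# panel CSV

PANEL_COLUMNS = ["probe_id", "target_id", "contig", "insert_start",
                 "insert_end", "strand", "hyb_arm_seq", "elong_arm_seq",
                 "smmip_seq", "tm_h", "tm_e", "dtm", "gc_h", "gc_e",
                 "n_cpg_arms", "n_snp_arms", "penalty", "stage", "cpg_pos"]


def panel_to_frame(panel: Panel) -> pd.DataFrame:
    rows = []
    for tid in sorted(panel.entries):
        p = panel.entries[tid]
        f = p.features
        ap = p.arm_pair
        rows.append({
            "probe_id": p.probe_id, "target_id": tid, "contig": ap.contig,
            "insert_start": ap.insert_interval[0],
            "insert_end": ap.insert_interval[1], "strand": ap.strand,
            "hyb_arm_seq": ap.hyb_seq, "elong_arm_seq": ap.elong_seq,
            "smmip_seq": p.full_sequence,
            "tm_h": round(f.tm_h, 4), "tm_e": round(f.tm_e, 4),
            "dtm": round(f.dtm, 4), "gc_h": round(f.gc_h, 4),
            "gc_e": round(f.gc_e, 4), "n_cpg_arms": f.n_cpg_arms,
            "n_snp_arms": f.n_snp_arms, "penalty": round(p.penalty, 4),
            "stage": panel.profile_stage_used.get(tid, 0),
            "cpg_pos": ap.cpg_pos,
        })
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel_csv(panel: Panel, path: str | os.PathLike,
                    failures_path: str | os.PathLike | None = None) -> None:
    """Write ``chosen_panel.csv`` plus a sibling failures CSV."""
    panel_to_frame(panel).to_csv(path, index=False)
    if failures_path is None:
        failures_path = os.path.join(os.path.dirname(os.path.abspath(str(path))),
                                     "failures.csv")
    pd.DataFrame(sorted(panel.failures),
                 columns=["target_id", "reason", "last_stage"]).to_csv(
        failures_path, index=False)


def read_panel_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"probe_id": str, "target_id": str, "contig": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return df
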