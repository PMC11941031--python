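"""Synthetic references and smMIP capture-sequencing simulation.

The simulator emits paired-end reads with the failure modes that dominate
real smMIP bisulfite libraries: self-circularized probes (arms abut with
essentially no insert), chimeric products joining the hybridization arm of
one probe to the elongation arm of another, unrelated library artifacts,
strongly probe-dependent capture efficiency (log-normal, wide enough that
the 1st-99th percentile efficiency ratio exceeds 1000-fold), PCR
duplication of single capture events (shared 9-nt UMI) and incomplete
bisulfite conversion of non-CpG cytosines.

Read-pair layout (fixed by this artifact and matched by ``read_classify``):

    M  = UMI(9) | hyb-arm binding site | insert | elong-arm binding site | backbone
    R1 = (M + adapter fill)[:read_len]
    R2 = (revcomp(M) + adapter fill)[:read_len]

Arm regions derive from the synthetic probe (degenerate R positions resolve
uniformly at random per capture event, no conversion noise); the insert
derives from the captured template molecule (target CpG ~ Bernoulli(beta),
other cytosines bisulfite-converted with the configured efficiency).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite_model import reverse_complement
from .genome_io import Genome, TargetSpec
from .panel_select import Panel, binding_site

ADAPTER_FILL = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

CATEGORY_WITH_INSERT = "with_insert"
CATEGORY_NO_INSERT = "no_insert"
CATEGORY_UNRELATED = "unrelated"
CATEGORY_CHIMERA = "chimera"


@dataclass(frozen=True)
class SimParams:
    n_read_pairs: int = 1000
    efficiency_sigma: float = 1.6
    frac_self_circ: float = 0.3
    frac_unrelated: float = 0.1
    frac_chimera: float = 0.05
    conversion_efficiency: float = 0.98
    seq_error_rate: float = 0.001
    pcr_dup_mean: float = 3.0
    pcr_meth_bias_factor: float = 1.0  # >1 duplicates methylated events more
    read_len: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_self_circ, self.frac_unrelated, self.frac_chimera)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("category fractions must lie in [0,1] and sum to <= 1")
        if min(self.conversion_efficiency, 1 - self.seq_error_rate) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimTruth:
    beta_by_cpg: dict[str, float] = field(default_factory=dict)
    read_labels: dict[str, tuple] = field(default_factory=dict)
    event_table: list[dict] = field(default_factory=list)
    efficiency_by_probe: dict[str, float] = field(default_factory=dict)


@dataclass
class SimReads:
    r1: list[tuple[str, str]] = field(default_factory=list)  # (read_id, seq)
    r2: list[tuple[str, str]] = field(default_factory=list)


def make_synthetic_reference(n_targets: int, contig_len: int, seed: int,
                             gc: float = 0.5, min_spacing: int = 300,
                             edge_margin: int = 250,
                             betas: Sequence[float] | None = None,
                             contig_name: str = "sim1",
                             ) -> tuple[Genome, list[TargetSpec], dict[str, float]]:
    """Random ACGT contig with ``n_targets`` planted CpG targets.

    Targets are spaced >= ``min_spacing`` apart and kept ``edge_margin``
    away from the contig ends so flank extraction never clips.  Each target
    gets a true methylation fraction, uniform on [0,1] unless supplied.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    usable = contig_len - 2 * edge_margin
    step = usable // n_targets if n_targets else 0
    if n_targets and step < min_spacing:
        raise ValueError(
            f"contig of {contig_len} bp cannot hold {n_targets} targets "
            f"with {min_spacing} bp spacing")
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    seq = rng.choice(np.array(list("ACGT")), size=contig_len,
                     p=[p_at, p_gc, p_gc, p_at])
    targets: list[TargetSpec] = []
    truth: dict[str, float] = {}
    if betas is not None and len(betas) != n_targets:
        raise ValueError("betas must have one entry per target")
    for i in range(n_targets):
        jitter = int(rng.integers(0, max(1, step - min_spacing + 1)))
        pos = edge_margin + i * step + jitter
        seq[pos] = "C"
        seq[pos + 1] = "G"
        tid = f"t{i:03d}"
        targets.append(TargetSpec(tid, contig_name, pos))
        truth[tid] = float(betas[i]) if betas is not None else float(rng.uniform())
    genome = Genome({contig_name: "".join(seq)})
    return genome, targets, truth


@dataclass(slots=True)
class _ProbeInfo:
    probe_id: str
    target_id: str
    contig: str
    insert_start: int
    insert_end: int
    cpg_pos: int
    hyb_site: str    # template space, Y at CpG positions
    elong_site: str
    backbone: str


def _probes_from_panel(panel: "Panel | pd.DataFrame") -> list[_ProbeInfo]:
    probes: list[_ProbeInfo] = []
    if isinstance(panel, Panel):
        for tid in sorted(panel.entries):
            p = panel.entries[tid]
            ap = p.arm_pair
            probes.append(_ProbeInfo(
                p.probe_id, tid, ap.contig, ap.insert_interval[0],
                ap.insert_interval[1], ap.cpg_pos, binding_site(ap.hyb_seq),
                binding_site(ap.elong_seq), p.backbone_seq))
    else:
        for row in panel.itertuples():
            hyb, elong, full = row.hyb_arm_seq, row.elong_arm_seq, row.smmip_seq
            backbone = full[len(hyb) + 9:len(full) - len(elong)]
            probes.append(_ProbeInfo(
                row.probe_id, row.target_id, row.contig, int(row.insert_start),
                int(row.insert_end), int(row.cpg_pos), binding_site(hyb),
                binding_site(elong), backbone))
    if not probes:
        raise ValueError("panel holds no probes")
    return probes


def _resolve_site(site: str, rng: np.random.Generator) -> str:
    """Resolve degenerate Y positions of an arm binding site for one
    synthesized probe molecule (C/T uniformly)."""
    if "Y" not in site:
        return site
    return "".join(rng.choice(("C", "T")) if c == "Y" else c for c in site)


def _convert_insert(insert: str, methylated: bool, cpg_offset: int,
                    conversion_efficiency: float,
                    rng: np.random.Generator) -> str:
    """Bisulfite-convert one captured template molecule (plus strand).

    The target CpG cytosine follows the event's Bernoulli draw; all other
    cytosines (non-target CpGs are emitted unmethylated) convert to T with
    probability ``conversion_efficiency``.
    """
    out = list(insert)
    for i, b in enumerate(out):
        if b != "C":
            continue
        if i == cpg_offset:
            out[i] = "C" if methylated else "T"
        elif rng.random() < conversion_efficiency:
            out[i] = "T"
    return "".join(out)


def simulate_capture(panel: "Panel | pd.DataFrame", genome: Genome,
                     truth_betas: Mapping[str, float], params: SimParams,
                     ) -> tuple[SimReads, SimTruth]:
    """Emit exactly ``params.n_read_pairs`` read pairs plus ground truth."""
    rng = np.random.default_rng(params.seed)
    probes = _probes_from_panel(panel)
    for p in probes:
        if p.target_id not in truth_betas:
            raise ValueError(f"no true beta for target {p.target_id}")
    eff = np.exp(rng.normal(0.0, params.efficiency_sigma, size=len(probes)))
    eff_p = eff / eff.sum()
    truth = SimTruth(beta_by_cpg=dict(truth_betas),
                     efficiency_by_probe={p.probe_id: float(e)
                                          for p, e in zip(probes, eff)})
    reads = SimReads()
    cat_p = [1 - params.frac_self_circ - params.frac_unrelated - params.frac_chimera,
             params.frac_self_circ, params.frac_unrelated, params.frac_chimera]
    categories = [CATEGORY_WITH_INSERT, CATEGORY_NO_INSERT,
                  CATEGORY_UNRELATED, CATEGORY_CHIMERA]
    bases = np.array(list("ACGT"))
    emitted = 0
    event_idx = 0
    while emitted < params.n_read_pairs:
        category = categories[int(rng.choice(4, p=cat_p))]
        umi = "".join(rng.choice(bases, size=9))
        label: tuple
        meth: bool | None = None
        probe_id = ""
        if category == CATEGORY_UNRELATED:
            m = "".join(rng.choice(bases, size=params.read_len))
            label = (CATEGORY_UNRELATED,)
            n_copies = 1
        else:
            pi = int(rng.choice(len(probes), p=eff_p))
            probe = probes[pi]
            probe_id = probe.probe_id
            hyb_read = _resolve_site(probe.hyb_site, rng)
            if category == CATEGORY_WITH_INSERT:
                beta = truth_betas[probe.target_id]
                meth = bool(rng.random() < beta)
                insert = genome.slice(probe.contig, probe.insert_start,
                                      probe.insert_end)
                cpg_off = probe.cpg_pos - probe.insert_start
                insert_read = _convert_insert(insert, meth, cpg_off,
                                              params.conversion_efficiency, rng)
                elong_read = _resolve_site(probe.elong_site, rng)
                m = umi + hyb_read + insert_read + elong_read + probe.backbone
                label = (CATEGORY_WITH_INSERT, probe.probe_id)
            elif category == CATEGORY_NO_INSERT:
                gap = int(rng.integers(0, 5))
                junk = "".join(rng.choice(bases, size=gap))
                elong_read = _resolve_site(probe.elong_site, rng)
                m = umi + hyb_read + junk + elong_read + probe.backbone
                label = (CATEGORY_NO_INSERT, probe.probe_id)
            else:
                others = [q for q in range(len(probes)) if q != pi]
                qi = others[int(rng.integers(0, len(others)))] if others else pi
                other = probes[qi]
                spacer = "".join(rng.choice(bases, size=int(rng.integers(0, 5))))
                elong_read = _resolve_site(other.elong_site, rng)
                m = umi + hyb_read + spacer + elong_read + other.backbone
                label = (CATEGORY_CHIMERA, probe.probe_id, other.probe_id)
            dup_mean = params.pcr_dup_mean
            if category == CATEGORY_WITH_INSERT and meth:
                dup_mean *= params.pcr_meth_bias_factor
            k = int(rng.geometric(1.0 / (1.0 + dup_mean))) - 1 if dup_mean > 0 else 0
            n_copies = 1 + k
        n_copies = min(n_copies, params.n_read_pairs - emitted)
        r1_t, r2_t = _mate_templates(m, params.read_len)
        for _ in range(n_copies):
            rid = f"r{emitted:07d}"
            reads.r1.append((rid, _with_errors(r1_t, params.seq_error_rate, rng)))
            reads.r2.append((rid, _with_errors(r2_t, params.seq_error_rate, rng)))
            truth.read_labels[rid] = label
            emitted += 1
        truth.event_table.append({
            "event_id": event_idx, "category": category, "probe_id": probe_id,
            "umi": umi if category != CATEGORY_UNRELATED else "",
            "methylated": meth, "n_reads": n_copies,
        })
        event_idx += 1
    return reads, truth


def _mate_templates(m: str, read_len: int) -> tuple[str, str]:
    fill = (ADAPTER_FILL * (read_len // len(ADAPTER_FILL) + 2))
    r1 = (m + fill)[:read_len]
    r2 = (reverse_complement(m) + fill)[:read_len]
    return r1, r2


_ERR_SUB = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.nonzero(mask)[0]:
        out[i] = _ERR_SUB[out[i]][int(rng.integers(0, 3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# file output

def write_fastq(records: Sequence[tuple[str, str]], path: str | os.PathLike,
                mate: int) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: SimTruth, betas_path: str | os.PathLike,
                labels_path: str | os.PathLike,
                events_path: str | os.PathLike) -> None:
    pd.DataFrame(sorted(truth.beta_by_cpg.items()),
                 columns=["target_id", "beta"]).to_csv(betas_path, index=False)
    rows = [{"read_id": rid, "category": lab[0],
             "probe_a": lab[1] if len(lab) > 1 else "",
             "probe_b": lab[2] if len(lab) > 2 else ""}
            for rid, lab in truth.read_labels.items()]
    pd.DataFrame(rows, columns=["read_id", "category", "probe_a", "probe_b"]
                 ).to_csv(labels_path, index=False)
    pd.DataFrame(truth.event_table).to_csv(events_path, index=False)
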