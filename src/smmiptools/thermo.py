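"""Nearest-neighbor melting temperature, GC content and secondary-structure
screening.

Tm uses the stacked nearest-neighbor model

    Tm = dH / (dS + R * ln(C_T / x)) - 273.15

with the SantaLucia unified dH/dS parameter set, duplex initiation terms and
a monovalent-salt entropy correction, delegated to Biopython's
``MeltingTemp.Tm_NN``.  Hairpin and heterodimer screening deliberately use a
simple, reproducible model: the best *ungapped* complementary stretch,
scored by the NN Tm of its stem, against a reporting threshold (default
20 degC).  Degenerate Y/R positions pair optimistically (any expansion that
pairs counts) so that ambiguity codes never hide a dimer; N never pairs,
because the only N runs in assembled probes are random UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor parameterization.

    Defaults mirror the documented defaults of the underlying Tm function:
    SantaLucia unified table, 50 mM monovalent salt, 25 nM oligo.
    """

    nn_table_id: str = "santalucia_unified"
    monovalent_salt_mM: float = 50.0
    oligo_conc_nM: float = 25.0

    def __post_init__(self) -> None:
        if self.monovalent_salt_mM <= 0 or self.oligo_conc_nM <= 0:
            raise ValueError("salt and oligo concentration must be positive")


DEFAULT_THERMO = ThermoParams()

_NN_TABLES = {"santalucia_unified": _mt.DNA_NN3}

# concrete Watson-Crick pairing; degenerate codes expand below
_EXPAND = {"A": "A", "C": "C", "G": "G", "T": "T", "Y": "CT", "R": "AG"}
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def pairs(a: str, b: str) -> bool:
    """True when any expansion of ``a`` is Watson-Crick complementary to
    any expansion of ``b``.  N never pairs."""
    ea = _EXPAND.get(a)
    eb = _EXPAND.get(b)
    if ea is None or eb is None:
        return False
    return any((x, y) in _WC for x in ea for y in eb)


@dataclass(frozen=True)
class DuplexHit:
    """An ungapped complementary stretch between two sequences (or within
    one, for hairpins), with the NN Tm of its stem."""

    pos_a: int
    pos_b: int
    length: int
    tm_c: float


def gc_percent(seq: str) -> float:
    """GC content as a percentage; degenerate codes must be resolved first."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def tm_nearest_neighbor(seq: str, params: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbor duplex Tm in degC for a plain-ACGT sequence.

    Degenerate bases must be resolved by the caller (see
    ``bisulfite_model.resolve_unmethylated``); reaching this layer with one
    is an error.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"degenerate/unknown bases reached Tm layer: {sorted(bad)}")
    return float(_mt.Tm_NN(
        seq,
        nn_table=_NN_TABLES[params.nn_table_id],
        Na=params.monovalent_salt_mM,
        dnac1=params.oligo_conc_nM,
        dnac2=params.oligo_conc_nM,
        saltcorr=5,
    ))


def _resolve_optimistic(seq: str) -> str:
    # for stem Tm scoring resolve toward the stronger pairing so hot stems
    # are never under-reported
    return seq.replace("Y", "C").replace("R", "G")


def _stem_tm(stem: str, params: ThermoParams) -> float:
    stem = _resolve_optimistic(stem)
    if len(stem) < 2:
        return float("-inf")
    return tm_nearest_neighbor(stem, params)


def hairpin_screen(seq: str, min_stem: int = 4, min_loop: int = 3,
                   params: ThermoParams = DEFAULT_THERMO) -> DuplexHit | None:
    """Best self-complementary stem with an intervening loop >= ``min_loop``.

    Scans all antiparallel pairings ``seq[p] . seq[q]`` (p < q) along
    anti-diagonals, keeps maximal ungapped complementary runs of length
    >= ``min_stem`` whose loop is long enough, and returns the hit with the
    highest stem Tm (or None).
    """
    n = len(seq)
    best: DuplexHit | None = None
    for c in range(2 * min_stem + min_loop - 1, 2 * n - 2):
        # positions p pair with q = c - p; require p < q, i.e. p <= (c-1)//2
        p_hi_pair = min((c - 1) // 2, n - 1)
        p_lo = max(0, c - (n - 1))
        run_start = None
        for p in range(p_lo, p_hi_pair + 2):
            ok = p <= p_hi_pair and pairs(seq[p], seq[c - p])
            if ok and run_start is None:
                run_start = p
            elif not ok and run_start is not None:
                best = _consider_stem(seq, run_start, p - 1, c, min_stem,
                                      min_loop, params, best)
                run_start = None
    return best


def _consider_stem(seq: str, p0: int, p1: int, c: int, min_stem: int,
                   min_loop: int, params: ThermoParams,
                   best: DuplexHit | None) -> DuplexHit | None:
    # trim the run so the innermost pair leaves a loop of >= min_loop:
    # loop size for innermost p is (c - p) - p - 1
    p1 = min(p1, (c - min_loop - 1) // 2)
    if p1 - p0 + 1 < min_stem:
        return best
    # Tm is not monotone in stem extension, so every sub-stem of the
    # maximal run competes
    for i in range(p0, p1 - min_stem + 2):
        for j in range(i + min_stem - 1, p1 + 1):
            tm = _stem_tm(seq[i:j + 1], params)
            if best is None or tm > best.tm_c:
                best = DuplexHit(pos_a=i, pos_b=c - j, length=j - i + 1, tm_c=tm)
    return best


def heterodimer_screen(seq_a: str, seq_b: str, min_stem: int = 5,
                       params: ThermoParams = DEFAULT_THERMO) -> DuplexHit | None:
    """Best ungapped antiparallel complementary stretch between two oligos.

    Returns the maximal-Tm stem of length >= ``min_stem`` (positions are
    0-based starts of the stem in each sequence's own orientation), or None.
    Symmetric in its arguments up to reported coordinates.
    """
    na, nb = len(seq_a), len(seq_b)
    if na == 0 or nb == 0:
        return None
    best: DuplexHit | None = None
    br = seq_b[::-1]  # antiparallel: a[i+k] pairs b[j-k]; use reversed b
    # diagonal d aligns a[i] with br[i - d]
    for d in range(-(nb - 1), na):
        i_lo = max(0, d)
        i_hi = min(na - 1, d + nb - 1)
        run_start = None
        for i in range(i_lo, i_hi + 2):
            ok = i <= i_hi and pairs(seq_a[i], br[i - d])
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                if i - run_start >= min_stem:
                    best = _best_substem(seq_a, run_start, i - 1, d, nb,
                                         min_stem, params, best)
                run_start = None
    return best


def _best_substem(seq_a: str, i0: int, i1: int, d: int, nb: int,
                  min_stem: int, params: ThermoParams,
                  best: DuplexHit | None) -> DuplexHit | None:
    # all sub-stems of the maximal run compete (Tm is not monotone in
    # stem extension)
    for i in range(i0, i1 - min_stem + 2):
        for j in range(i + min_stem - 1, i1 + 1):
            tm = _stem_tm(seq_a[i:j + 1], params)
            if best is None or tm > best.tm_c:
                pos_b = nb - 1 - (j - d)
                best = DuplexHit(pos_a=i, pos_b=pos_b,
                                 length=j - i + 1, tm_c=tm)
    return best
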