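"""Panel selection, probe assembly, specificity scan and panel CSV."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smmiptools import panel_select, thermo
from smmiptools.bisulfite_model import OT, convert_strand, reverse_complement
from smmiptools.genome_io import Genome
from smmiptools.panel_select import (Panel, SelectionConfig, assemble_smmip,
                                     design_panel, read_panel_csv,
                                     select_panel, specificity_scan,
                                     write_panel_csv, _weights_for)
from smmiptools.probe_design import (ArmPair, DesignProfile, ProbeCandidate,
                                     ProbeFeatures, ScoringWeights)


def _pair(tid, hyb, elong, contig="c1"):
    return ArmPair(target_id=tid, contig=contig, strand=OT,
                   hyb_interval=(200, 200 + len(hyb)), hyb_seq=hyb,
                   elong_interval=(100 - len(elong), 100), elong_seq=elong,
                   insert_interval=(100, 200), cpg_pos=150)


def _features(tm_h=50.0, tm_e=50.0):
    return ProbeFeatures(tm_h=tm_h, tm_e=tm_e, dtm=abs(tm_h - tm_e),
                         gc_h=30, gc_e=30, len_h=25, len_e=25,
                         n_cpg_arms=0, n_snp_arms=0,
                         hairpin_tm_c=float("-inf"), target_len=100)


def _candidate(tid, hyb, elong, penalty=0.0, tm_h=50.0, tm_e=50.0):
    return ProbeCandidate(_pair(tid, hyb, elong), _features(tm_h, tm_e), penalty)


# AT-rich arms never dimerize above 20 degC
A1 = "ACTTATTATCTTCATTTTCAAATCA"
A2 = "TTATAATCTTATAATCATTTAAATA"
A3 = "TATTATTCATATTCTTTCATAATTA"
A4 = "ATTCTTAATTCAATTATACTATTCA"
# a GC-rich stretch and its reverse complement force a hot cross-dimer
HOT = "GCGGCTAGGCGGTCGTAGCTTATTA"
HOT_RC = reverse_complement(HOT)


class TestAssembly:
    def test_concatenation_order(self):
        probe = assemble_smmip(_pair("t", "AAA", "TTT"), backbone_seq="CCC")
        assert probe.full_sequence == "AAA" + "N" * 9 + "CCC" + "TTT"

    def test_exactly_nine_n_outside_degenerate_positions(self):
        probe = assemble_smmip(_pair("t", A1, A2))
        assert probe.full_sequence.count("N") == 9
        assert probe.full_sequence[len(A1):len(A1) + 9] == "N" * 9

    def test_arm_cpg_keeps_degenerate_r(self):
        hyb = A1[:10] + "R" + A1[11:]
        probe = assemble_smmip(_pair("t", hyb, A2))
        assert probe.full_sequence[:len(hyb)].count("R") == 1
        assert probe.degenerate_arm_positions == (10,)

    def test_empty_backbone_rejected(self):
        with pytest.raises(ValueError):
            assemble_smmip(_pair("t", "AAA", "TTT"), backbone_seq="")


class TestWeightedSampling:
    def test_inverse_transform_pick_ratio(self):
        """Penalties 0 and 1 give weights 1 and 0.5; over 10,000 draws the
        empirical 2:1 ratio holds at a chi-square alpha of 0.01."""
        cfg = SelectionConfig(seed=0)
        rng = np.random.default_rng(cfg.seed)
        w = _weights_for([0.0, 1.0], cfg)
        assert w == pytest.approx([2 / 3, 1 / 3])
        draws = [panel_select._sample(rng, [0.0, 1.0], cfg)
                 for _ in range(10_000)]
        observed = np.bincount(draws, minlength=2)
        chi2 = stats.chisquare(observed, f_exp=[10_000 * 2 / 3, 10_000 / 3])
        assert chi2.pvalue > 0.01

    def test_softmax_transform_available(self):
        cfg = SelectionConfig(weight_transform="softmax")
        w = _weights_for([0.0, 1.0], cfg)
        assert w[0] > w[1] and w.sum() == pytest.approx(1.0)


class TestSelectPanel:
    PROFILE = DesignProfile()
    WEIGHTS = ScoringWeights()

    def test_single_candidate_no_conflict(self):
        cands = {"t1": [_candidate("t1", A1, A2)]}
        panel = select_panel(cands, self.PROFILE, self.WEIGHTS,
                             SelectionConfig(seed=0))
        assert set(panel.entries) == {"t1"}
        assert panel.failures == []
        assert panel.profile_stage_used["t1"] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_dimer_conflict_resolved_vs_exhaustive_oracle(self, seed):
        """Two targets, two candidates each, exactly one of the four
        assignments dimerizes: the panel must be one of the other three."""
        cands = {
            "ta": [_candidate("ta", HOT, A1), _candidate("ta", A3, A1)],
            "tb": [_candidate("tb", HOT_RC, A2), _candidate("tb", A4, A2)],
        }
        # exhaustive oracle over the four assignments
        thr = self.PROFILE.dimer_tm_threshold_c
        conflict_free = []
        for ia, ib in itertools.product(range(2), repeat=2):
            fa = panel_select.assemble_smmip(cands["ta"][ia].arm_pair).full_sequence
            fb = panel_select.assemble_smmip(cands["tb"][ib].arm_pair).full_sequence
            hit = thermo.heterodimer_screen(fa, fb)
            if hit is None or hit.tm_c <= thr:
                conflict_free.append((ia, ib))
        assert len(conflict_free) == 3
        panel = select_panel(cands, self.PROFILE, self.WEIGHTS,
                             SelectionConfig(seed=seed))
        assert set(panel.entries) == {"ta", "tb"}
        chosen = (cands["ta"].index(next(
            c for c in cands["ta"]
            if c.arm_pair.hyb_seq == panel.entries["ta"].arm_pair.hyb_seq)),
            cands["tb"].index(next(
                c for c in cands["tb"]
                if c.arm_pair.hyb_seq == panel.entries["tb"].arm_pair.hyb_seq)))
        assert chosen in conflict_free

    def test_unresolvable_conflict_recorded_as_failure(self):
        cands = {
            "ta": [_candidate("ta", HOT, A1)],
            "tb": [_candidate("tb", HOT_RC, A2)],
        }
        panel = select_panel(cands, self.PROFILE, self.WEIGHTS,
                             SelectionConfig(seed=0, max_rounds_per_stage=3))
        assert len(panel.entries) == 1
        assert len(panel.failures) == 1
        assert panel.failures[0][1] == "unresolved_conflicts"

    def test_no_candidates_reported(self):
        panel = select_panel({"t1": []}, self.PROFILE, self.WEIGHTS,
                             SelectionConfig(seed=0), target_ids=["t1"])
        assert panel.entries == {}
        assert panel.failures == [("t1", "no_candidates", 0)]

    def test_tm_spread_enforced(self):
        """A candidate set straddling more than the spread cap cannot all
        be kept; the outlier target resolves to its in-range candidate."""
        cands = {
            "ta": [_candidate("ta", A1, A2, tm_h=45, tm_e=45)],
            "tb": [_candidate("tb", A3, A4, tm_h=60, tm_e=60),
                   _candidate("tb", A4, A3, tm_h=47, tm_e=47)],
        }
        panel = select_panel(cands, self.PROFILE, self.WEIGHTS,
                             SelectionConfig(seed=0))
        assert set(panel.entries) == {"ta", "tb"}
        tms = panel.panel_tm_values
        assert max(tms) - min(tms) <= self.PROFILE.max_panel_tm_spread_c


class TestDesignedPanelInvariants:
    def test_entries_and_failures_partition_targets(self, small_reference,
                                                    small_panel):
        _, targets, _ = small_reference
        covered = set(small_panel.entries) | {f[0] for f in small_panel.failures}
        assert covered == {t.target_id for t in targets}
        assert len(small_panel.entries) + len(small_panel.failures) == len(targets)

    def test_no_dimer_above_threshold_in_final_panel(self, small_panel):
        probes = sorted(small_panel.entries.values(), key=lambda p: p.probe_id)
        for a, b in itertools.combinations(probes, 2):
            hit = thermo.heterodimer_screen(a.full_sequence, b.full_sequence)
            assert hit is None or hit.tm_c <= 20.0

    def test_panel_tm_spread_within_cap(self, small_panel):
        tms = small_panel.panel_tm_values
        assert max(tms) - min(tms) <= 10.0

    def test_insert_contains_target_cpg(self, small_panel):
        for probe in small_panel.entries.values():
            s, e = probe.arm_pair.insert_interval
            assert s <= probe.arm_pair.cpg_pos
            assert probe.arm_pair.cpg_pos + 2 <= e


class TestDeterminism:
    def test_same_seed_byte_identical_csv(self, tmp_path, small_reference):
        genome, targets, _ = small_reference
        outputs = []
        for run in (1, 2):
            panel = design_panel(
                genome, targets[:3],
                profile=DesignProfile.stringent_only(),
                sel_config=SelectionConfig(seed=99))
            p = tmp_path / f"panel{run}.csv"
            write_panel_csv(panel, p, tmp_path / f"fail{run}.csv")
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]

    def test_different_seed_may_differ_but_stays_valid(self, small_reference):
        genome, targets, _ = small_reference
        panel = design_panel(genome, targets[:2],
                             profile=DesignProfile.stringent_only(),
                             sel_config=SelectionConfig(seed=5))
        assert set(panel.entries) | {f[0] for f in panel.failures} == \
            {t.target_id for t in targets[:2]}


class TestPanelCsv:
    def test_roundtrip_reconstructs_sequences(self, tmp_path, small_panel):
        path = tmp_path / "chosen_panel.csv"
        write_panel_csv(small_panel, path, tmp_path / "failures.csv")
        df = read_panel_csv(path)
        assert len(df) == len(small_panel.entries)
        for row in df.itertuples():
            probe = small_panel.entries[row.target_id]
            assert row.smmip_seq == probe.full_sequence
            assert row.hyb_arm_seq == probe.arm_pair.hyb_seq
            assert row.elong_arm_seq == probe.arm_pair.elong_seq

    def test_column_order_fixed(self, tmp_path, small_panel):
        path = tmp_path / "chosen_panel.csv"
        write_panel_csv(small_panel, path, tmp_path / "failures.csv")
        header = path.read_text().splitlines()[0]
        assert header == ",".join(panel_select.PANEL_COLUMNS)

    def test_failures_written_to_sibling(self, tmp_path):
        panel = Panel()
        panel.failures.append(("tx", "no_candidates", 2))
        write_panel_csv(panel, tmp_path / "p.csv", tmp_path / "f.csv")
        fails = pd.read_csv(tmp_path / "f.csv")
        assert list(fails.target_id) == ["tx"]


class TestSpecificityScan:
    def _panel_with(self, hyb, elong):
        panel = Panel()
        probe = assemble_smmip(_pair("t1", hyb, elong), probe_id="p1")
        panel.entries["t1"] = probe
        return panel

    def test_duplicated_site_flagged(self):
        locus = "ATTAGGTCATTAGAATTCATTAGATA"
        filler = "TTAATTCCTTAATCCTTAATTCCAATT"
        genome = Genome({"c1": locus + filler + locus + filler})
        conv = {"c1": convert_strand(genome["c1"], OT)}
        # the arm binds the *converted* template of the duplicated locus
        site = convert_strand(locus, OT).sequence
        arm = panel_select.binding_site(site)
        flags = specificity_scan(self._panel_with(arm, A2), conv)
        assert ("p1", "hyb", 2) in flags

    def test_unique_arm_not_flagged(self, small_reference, small_panel):
        genome, _, _ = small_reference
        conv = panel_select.convert_genome(genome)
        flags = specificity_scan(small_panel, conv)
        flagged_ids = {f[0] for f in flags}
        # on a random 15 kb reference the designed arms are unique
        assert flagged_ids == set()

    def test_converted_space_collision_detected(self):
        """Two loci identical only after C->T conversion collide."""
        locus_a = "ATCAGGTTATCGATTACATTAGGATTA"
        locus_b = locus_a.replace("CAGG", "TAGG")  # differs at a non-CpG C
        assert locus_a != locus_b
        filler = "TTTTAAAATTTTAAAATTTTAAAA"
        genome = Genome({"c1": locus_a + filler + locus_b})
        conv = {"c1": convert_strand(genome["c1"], OT)}
        site = convert_strand(locus_a, OT).sequence
        arm = panel_select.binding_site(site)
        flags = specificity_scan(self._panel_with(arm, A2), conv)
        assert any(f[1] == "hyb" and f[2] == 2 for f in flags)
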