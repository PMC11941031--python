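"""UMI extraction, arm location (vs. brute-force Hamming oracle) and the
three-group read classification."""

import numpy as np
import pytest

from smmiptools.bisulfite_model import reverse_complement
from smmiptools.capture_sim import ADAPTER_FILL, SimParams, simulate_capture
from smmiptools.read_classify import (CATEGORY_NO_INSERT,
                                      CATEGORY_NOT_PROBE_RELATED,
                                      CATEGORY_WITH_INSERT,
                                      PanelIndex, classify_read,
                                      extract_umi_and_trim, hamming_site,
                                      tally_read_groups)


@pytest.fixture(scope="module")
def index(small_panel_module):
    return PanelIndex(small_panel_module)


@pytest.fixture(scope="module")
def small_panel_module(request):
    return request.getfixturevalue("small_panel")


def _site(index, probe_id, kind):
    for arm in index.arms:
        if arm.probe_id == probe_id and arm.arm_kind == kind:
            return arm.site
    raise KeyError


def _resolved(site):
    return site.replace("Y", "T")


class TestUmiAndTrim:
    def test_first_nine_bases_become_umi(self):
        umi, (t1, _) = extract_umi_and_trim("ACGTACGTA" + "T" * 50, "G" * 50)
        assert umi == "ACGTACGTA"
        assert t1 == "T" * 50

    def test_adapter_suffix_removed(self):
        inset = "TGCATGCATGCATGCATGCA"
        read = inset + ADAPTER_FILL[:12]
        umi, (t1, _) = extract_umi_and_trim("A" * 9 + read, "G" * 20)
        assert t1 == inset

    def test_read_without_adapter_unchanged(self):
        read = "TGCATGCATGCATGCATGCA"
        _, (t1, _) = extract_umi_and_trim("A" * 9 + read, "G" * 20)
        assert t1 == read

    def test_read_shorter_than_umi(self):
        umi, _ = extract_umi_and_trim("ACGT", "ACGT")
        assert umi == ""


class TestLocateArms:
    def test_planted_arms_found_with_offsets(self, index):
        probe_id = sorted(index.expected_insert_len)[0]
        hyb = _resolved(_site(index, probe_id, "hyb"))
        elong = _resolved(_site(index, probe_id, "elong"))
        read = hyb + "A" * 20 + elong
        hits = index.locate(read)
        mine = {(h.arm_kind, h.position) for h in hits
                if h.probe_id == probe_id}
        assert ("hyb", 0) in mine
        assert ("elong", len(hyb) + 20) in mine

    def test_one_mismatch_within_cap_still_hits(self, index):
        probe_id = sorted(index.expected_insert_len)[0]
        hyb = list(_resolved(_site(index, probe_id, "hyb")))
        hyb[5] = "A" if hyb[5] != "A" else "G"
        read = "".join(hyb) + "T" * 30
        hits = [h for h in index.locate(read)
                if h.probe_id == probe_id and h.arm_kind == "hyb"]
        assert hits and hits[0].mismatches == 1

    def _brute_force(self, read, index):
        out = set()
        for arm in index.arms:
            for start in range(len(read) - len(arm.site) + 1):
                if hamming_site(arm.site, read, start) <= arm.max_mismatches:
                    out.add((arm.probe_id, arm.arm_kind))
        return out

    def test_agrees_with_sliding_hamming_oracle(self, index):
        """Seeded mixture of random reads and reads with planted
        (mutated) arms: seeded search finds an arm iff the full scan
        does."""
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        probe_ids = sorted(index.expected_insert_len)
        for i in range(200):
            read = "".join(rng.choice(bases, size=80))
            if i % 2:  # plant an arm with up to 2 mutations
                pid = probe_ids[int(rng.integers(0, len(probe_ids)))]
                kind = ("hyb", "elong")[int(rng.integers(0, 2))]
                site = list(_resolved(_site(index, pid, kind)))
                for _ in range(int(rng.integers(0, 3))):
                    j = int(rng.integers(0, len(site)))
                    site[j] = str(rng.choice(bases))
                pos = int(rng.integers(0, 80 - len(site)))
                read = read[:pos] + "".join(site) + read[pos + len(site):]
            got = {(h.probe_id, h.arm_kind) for h in index.locate(read)}
            assert got == self._brute_force(read, index)


class TestClassifyRead:
    def _read_pair(self, index, probe_id, gap_seq, read_len=150):
        hyb = _resolved(_site(index, probe_id, "hyb"))
        elong = _resolved(_site(index, probe_id, "elong"))
        m = "A" * 9 + hyb + gap_seq + elong + "CTTCAGCTTCCC"
        fill = ADAPTER_FILL * 3
        return ((m + fill)[:read_len], (reverse_complement(m) + fill)[:read_len])

    @pytest.mark.parametrize("gap", [0, 1, 4])
    def test_gap_below_five_is_no_insert(self, index, gap):
        probe_id = sorted(index.expected_insert_len)[0]
        call = classify_read(self._read_pair(index, probe_id, "T" * gap),
                             index, read_id="r")
        assert call.category == CATEGORY_NO_INSERT

    def test_gap_of_five_is_with_insert(self, index):
        probe_id = sorted(index.expected_insert_len)[0]
        call = classify_read(self._read_pair(index, probe_id, "T" * 5),
                             index, read_id="r")
        assert call.category == CATEGORY_WITH_INSERT
        assert call.insert_seq == "T" * 5

    def test_planted_insert_is_with_insert(self, index):
        probe_id = sorted(index.expected_insert_len)[0]
        call = classify_read(self._read_pair(index, probe_id, "TGCA" * 8),
                             index)
        assert call.category == CATEGORY_WITH_INSERT
        assert call.probe_hyb == call.probe_elong == probe_id
        assert not call.chimera

    def test_chimera_detected_and_counted_off_target(self, index):
        ids = sorted(index.expected_insert_len)
        hyb = _resolved(_site(index, ids[0], "hyb"))
        elong = _resolved(_site(index, ids[1], "elong"))
        m = "A" * 9 + hyb + "TT" + elong + "GG"
        pair = ((m + ADAPTER_FILL * 3)[:150],
                (reverse_complement(m) + ADAPTER_FILL * 3)[:150])
        call = classify_read(pair, index)
        assert call.chimera
        assert call.category == CATEGORY_NOT_PROBE_RELATED
        assert (call.probe_hyb, call.probe_elong) == (ids[0], ids[1])

    def test_random_read_not_probe_related(self, index):
        rng = np.random.default_rng(5)
        read = "".join(rng.choice(np.array(list("ACGT")), size=150))
        call = classify_read((read, reverse_complement(read)), index)
        assert call.category == CATEGORY_NOT_PROBE_RELATED
        assert not call.chimera

    def test_umi_recorded(self, index):
        probe_id = sorted(index.expected_insert_len)[0]
        r1, r2 = self._read_pair(index, probe_id, "T" * 30)
        r1 = "GATTACAGA" + r1[9:]
        call = classify_read((r1, r2), index)
        assert call.umi == "GATTACAGA"

    def test_split_mate_insert_reconstructed(self, index, small_reference,
                                             small_panel):
        """A 90+ bp insert pushes the elongation arm onto read 2; the pair
        is still with-insert and the reconstructed insert matches the
        converted reference slice outside degenerate CpG positions."""
        from smmiptools.bisulfite_model import OT, convert_strand

        genome, _, betas = small_reference
        params = SimParams(n_read_pairs=60, seed=9, seq_error_rate=0.0,
                           conversion_efficiency=1.0, frac_self_circ=0,
                           frac_unrelated=0, frac_chimera=0, pcr_dup_mean=0.0)
        reads, truth = simulate_capture(small_panel, genome, betas, params)
        probes = {p.probe_id: p for tid in sorted(small_panel.entries)
                  for p in [small_panel.entries[tid]]}
        checked = 0
        for (rid, s1), (_, s2) in zip(reads.r1, reads.r2):
            probe_id = truth.read_labels[rid][1]
            call = classify_read((s1, s2), index, read_id=rid)
            assert call.category == CATEGORY_WITH_INSERT
            probe = probes[probe_id]
            s, e = probe.arm_pair.insert_interval
            conv = convert_strand(genome.slice(probe.arm_pair.contig, s, e),
                                  OT, next_base_context=genome[
                                      probe.arm_pair.contig][e])
            assert len(call.insert_seq) == e - s
            for i, (got, ref) in enumerate(zip(call.insert_seq, conv.sequence)):
                assert got == ref or ref == "Y" and got in "CT"
            # count pairs whose elongation arm cannot fully fit on R1
            if 9 + len(probe.arm_pair.hyb_seq) + (e - s) \
                    + len(probe.arm_pair.elong_seq) > 150:
                checked += 1
        assert checked > 0

    def test_categories_partition_reads(self, index, small_reference,
                                        small_panel):
        genome, _, betas = small_reference
        params = SimParams(n_read_pairs=400, seed=6)
        reads, truth = simulate_capture(small_panel, genome, betas, params)
        cats = {"with_insert": 0, "no_insert": 0, "not_probe_related": 0}
        for (rid, s1), (_, s2) in zip(reads.r1, reads.r2):
            call = classify_read((s1, s2), index, read_id=rid)
            cats[call.category] += 1
        assert sum(cats.values()) == 400


class TestAgainstSimulatorTruth:
    def test_zero_error_classification_matches_truth(self, small_reference,
                                                     small_panel):
        genome, _, betas = small_reference
        params = SimParams(n_read_pairs=500, seed=7, seq_error_rate=0.0)
        reads, truth = simulate_capture(small_panel, genome, betas, params)
        index = PanelIndex(small_panel)
        expected = {"with_insert": CATEGORY_WITH_INSERT,
                    "no_insert": CATEGORY_NO_INSERT,
                    "unrelated": CATEGORY_NOT_PROBE_RELATED,
                    "chimera": CATEGORY_NOT_PROBE_RELATED}
        for (rid, s1), (_, s2) in zip(reads.r1, reads.r2):
            label = truth.read_labels[rid]
            call = classify_read((s1, s2), index, read_id=rid)
            assert call.category == expected[label[0]], (rid, label)
            if label[0] == "chimera":
                assert call.chimera
            if label[0] == "with_insert":
                assert call.probe_hyb == label[1]

    def test_default_error_rate_matches_truth_for_99pct(self, small_reference,
                                                        small_panel):
        genome, _, betas = small_reference
        params = SimParams(n_read_pairs=800, seed=8)
        reads, truth = simulate_capture(small_panel, genome, betas, params)
        index = PanelIndex(small_panel)
        expected = {"with_insert": CATEGORY_WITH_INSERT,
                    "no_insert": CATEGORY_NO_INSERT,
                    "unrelated": CATEGORY_NOT_PROBE_RELATED,
                    "chimera": CATEGORY_NOT_PROBE_RELATED}
        agree = sum(
            1 for (rid, s1), (_, s2) in zip(reads.r1, reads.r2)
            if classify_read((s1, s2), index).category
            == expected[truth.read_labels[rid][0]])
        assert agree / 800 >= 0.99


class TestTally:
    def _call(self, rid, category, hyb=None, elong=None, chimera=False):
        from smmiptools.read_classify import ReadCall

        return ReadCall(rid, category, hyb, elong, chimera, "A" * 9)

    def test_strata_boundaries(self, index):
        """Counts 0, 5, 30, 99 land in the four strata."""
        ids = sorted(index.expected_insert_len)[:4]
        calls = []
        for pid, n in zip(ids, (0, 5, 30, 99)):
            calls += [self._call(f"{pid}_{i}", CATEGORY_WITH_INSERT, pid, pid)
                      for i in range(n)]
        summary = tally_read_groups(calls, index)
        got = [summary.coverage_strata[pid] for pid in ids]
        assert got == ["0", "1-20", "21-50", ">50"]

    def test_off_target_quartiles_equal_groups(self, index):
        ids = sorted(index.expected_insert_len)[:4]
        calls = []
        for rank, pid in enumerate(ids):
            calls += [self._call(f"{pid}_{i}", CATEGORY_NO_INSERT, pid, pid)
                      for i in range(rank)]
        summary = tally_read_groups(calls, index)
        groups = [summary.off_target_quartile[pid] for pid in ids]
        assert sorted(set(groups)) == sorted(set(groups))
        assert groups == sorted(groups)  # more off-target -> higher group

    def test_category_fractions_sum_to_one(self, index):
        calls = [self._call("a", CATEGORY_WITH_INSERT,
                            sorted(index.expected_insert_len)[0],
                            sorted(index.expected_insert_len)[0]),
                 self._call("b", CATEGORY_NO_INSERT),
                 self._call("c", CATEGORY_NOT_PROBE_RELATED)]
        summary = tally_read_groups(calls, index)
        assert sum(summary.category_fractions.values()) == pytest.approx(1.0)
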