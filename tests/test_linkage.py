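"""Proximal/contact target assignment vs brute-force scans and set algebra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from targetlink.intervals import ContactPair, GenomicInterval, Peak, TSSRecord
from targetlink.linkage import (combine_assignments, contact_link,
                                proximal_link)

from _oracles import brute_contact, brute_proximal


def _peak(chrom, start, end, pid):
    return Peak(GenomicInterval(chrom, start, end), pid)


class TestProximalBoundary:
    TSS = [TSSRecord("gene1", "chr1", 10_000)]

    @pytest.mark.parametrize(
        "start,end,linked,distance",
        [
            (9_000, 9_500, True, 501),    # nearest base 9499
            (12_001, 12_500, False, None),  # distance 2001, just outside
            (12_000, 12_500, True, 2000),   # boundary inclusive
            (9_900, 10_100, True, 0),       # TSS inside the peak
        ],
    )
    def test_window_boundary(self, start, end, linked, distance):
        links = proximal_link([_peak("chr1", start, end, "p")], self.TSS, window=2000)
        if linked:
            assert len(links) == 1 and links[0].evidence == distance
        else:
            assert links == []

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            proximal_link([], self.TSS, window=-1)

    def test_other_chromosome_never_linked(self):
        assert proximal_link([_peak("chr2", 9_900, 10_100, "p")], self.TSS, 2000) == []


class TestContactRule:
    CONTACT = ContactPair(GenomicInterval("chr1", 1_000, 5_000),
                          GenomicInterval("chr1", 200_000, 205_000), "loop1")

    def test_peak_anchor1_tss_anchor2_linked(self):
        links = contact_link([_peak("chr1", 1_500, 1_600, "p")],
                             [TSSRecord("g", "chr1", 202_000)], [self.CONTACT])
        assert len(links) == 1 and links[0].evidence == "loop1"

    def test_no_tss_in_other_anchor_gives_nothing(self):
        links = contact_link([_peak("chr1", 1_500, 1_600, "p")],
                             [TSSRecord("g", "chr1", 500_000)], [self.CONTACT])
        assert links == []

    def test_both_in_same_anchor_gives_nothing(self):
        links = contact_link([_peak("chr1", 1_500, 1_600, "p")],
                             [TSSRecord("g", "chr1", 2_000)], [self.CONTACT])
        assert links == []

    def test_anchor_swap_invariance(self):
        peaks = [_peak("chr1", 1_500, 1_600, "p"), _peak("chr1", 203_000, 203_200, "q")]
        tsss = [TSSRecord("g1", "chr1", 202_000), TSSRecord("g2", "chr1", 3_000)]
        assert contact_link(peaks, tsss, [self.CONTACT]) == \
            contact_link(peaks, tsss, [self.CONTACT.swapped()])

    def test_anchor_pad_extends_containment(self):
        tss = [TSSRecord("g", "chr1", 205_500)]  # 500 bp past anchor2
        peaks = [_peak("chr1", 1_500, 1_600, "p")]
        assert contact_link(peaks, tss, [self.CONTACT], anchor_pad=0) == []
        assert len(contact_link(peaks, tss, [self.CONTACT], anchor_pad=600)) == 1

    def test_trans_chromosomal_contact_honored(self):
        trans = ContactPair(GenomicInterval("chr1", 100, 200),
                            GenomicInterval("chr5", 900, 1_900), "trans1")
        links = contact_link([_peak("chr1", 150, 250, "p")],
                             [TSSRecord("g", "chr5", 1_000)], [trans])
        assert len(links) == 1


def _random_inputs(rng, n_peaks=40, n_tss=30, n_contacts=15):
    chroms = ["chr1", "chr2"]
    peaks = []
    for i in range(n_peaks):
        s = int(rng.integers(0, 100_000))
        peaks.append(_peak(str(rng.choice(chroms)), s, s + int(rng.integers(100, 600)), f"p{i}"))
    tsss = [TSSRecord(f"g{i}", str(rng.choice(chroms)), int(rng.integers(0, 100_000)))
            for i in range(n_tss)]
    contacts = []
    for i in range(n_contacts):
        a = int(rng.integers(0, 100_000))
        b = int(rng.integers(0, 100_000))
        contacts.append(ContactPair(
            GenomicInterval(str(rng.choice(chroms)), a, a + 5_000),
            GenomicInterval(str(rng.choice(chroms)), b, b + 5_000), f"c{i}"))
    return peaks, tsss, contacts


@pytest.mark.parametrize("seed", range(5))
def test_proximal_equals_brute_force_all_pairs(seed):
    rng = np.random.default_rng(seed)
    peaks, tsss, _ = _random_inputs(rng)
    got = {(a.gene_id, a.tss_position, a.peak_id, a.evidence)
           for a in proximal_link(peaks, tsss, window=2000)}
    assert got == brute_proximal(peaks, tsss, 2000)


@pytest.mark.parametrize("seed", range(5))
def test_contact_equals_brute_force_triple_scan(seed):
    rng = np.random.default_rng(seed + 100)
    peaks, tsss, contacts = _random_inputs(rng)
    got = {(a.gene_id, a.tss_position, a.peak_id, a.evidence)
           for a in contact_link(peaks, tsss, contacts)}
    assert got == brute_contact(peaks, tsss, contacts)


@pytest.mark.parametrize("seed", range(3))
def test_window_and_pad_monotonicity(seed):
    rng = np.random.default_rng(seed + 500)
    peaks, tsss, contacts = _random_inputs(rng)
    prox_small = set(proximal_link(peaks, tsss, 1_000))
    prox_big = set(proximal_link(peaks, tsss, 3_000))
    assert prox_small <= prox_big
    cont_small = set(contact_link(peaks, tsss, contacts, anchor_pad=0))
    cont_big = set(contact_link(peaks, tsss, contacts, anchor_pad=2_000))
    assert cont_small <= cont_big


class TestCombine:
    def _assign(self, gene, mode, pid="p"):
        from targetlink.linkage import TargetAssignment
        ev = 5 if mode == "proximal" else "c1"
        return TargetAssignment(gene, 100, "chr1", pid, mode, ev)

    def test_union_and_mode_summary(self):
        prox = [self._assign("t1", "proximal"), self._assign("t2", "proximal")]
        cont = [self._assign("t2", "contact"), self._assign("t3", "contact")]
        calls = combine_assignments(prox, cont)
        assert calls.counts["n_total"] == 3
        assert calls.gene_modes == {"t1": "proximal_only", "t2": "both", "t3": "contact_only"}

    def test_empty_inputs_give_empty_call_set(self):
        calls = combine_assignments([], [])
        assert calls.counts["n_total"] == 0 and calls.genes == set()

    def test_additive_bookkeeping_65_725_overlap_14(self):
        """Category sizes 65 and 725 with 14 genes in both union to 776."""
        prox = [self._assign(f"pg{i}", "proximal") for i in range(65)]
        cont = [self._assign(f"pg{i}", "contact") for i in range(14)]
        cont += [self._assign(f"cg{i}", "contact") for i in range(725 - 14)]
        calls = combine_assignments(prox, cont)
        c = calls.counts
        assert c["n_proximal"] == 65 and c["n_contact"] == 725
        assert c["n_both"] == 14
        assert c["n_total"] == 776


@given(
    st.sets(st.integers(0, 50), max_size=30),
    st.sets(st.integers(0, 50), max_size=30),
)
def test_total_targets_subadditive(prox_ids, cont_ids):
    from targetlink.linkage import TargetAssignment

    prox = [TargetAssignment(f"g{i}", 0, "chr1", "p", "proximal", 0) for i in prox_ids]
    cont = [TargetAssignment(f"g{i}", 0, "chr1", "p", "contact", "c") for i in cont_ids]
    calls = combine_assignments(prox, cont)
    n = calls.counts["n_total"]
    assert n == len({f"g{i}" for i in prox_ids} | {f"g{i}" for i in cont_ids})
    assert n <= len(prox_ids) + len(cont_ids)
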