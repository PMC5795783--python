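"""Peak-to-TSS target assignment.

Two binary rules define a candidate direct target:

* **proximal** — the TSS lies within ``window`` bp (default 2 kb, boundary
  inclusive) of the nearest base of a binding-site peak;
* **contact** — a chromatin interaction has one anchor overlapping the peak
  (>= 1 bp) and the other anchor containing the TSS base.

A gene with several annotated TSSs is a target if any of them is linked.
The combined call set deduplicates genes and labels each as proximal-only,
contact-only or both.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Union

from intervaltree import IntervalTree

from .intervals import ContactPair, Peak, TSSRecord


@dataclass(frozen=True)
class TargetAssignment:
    """One peak -> TSS link with its evidence.

    ``evidence`` is the nearest-base distance in bp for proximal links and
    the contact id for contact links.
    """

    gene_id: str
    tss_position: int
    chrom: str
    peak_id: str
    mode: str  # "proximal" | "contact"
    evidence: Union[int, str]

    def __post_init__(self) -> None:
        if self.mode not in ("proximal", "contact"):
            raise ValueError(f"mode must be 'proximal' or 'contact', got {self.mode!r}")


@dataclass(frozen=True)
class TargetCallSet:
    """Deduplicated union of proximal and contact assignments."""

    assignments: frozenset
    gene_modes: Dict[str, str]  # gene -> proximal_only | contact_only | both

    @property
    def genes(self) -> Set[str]:
        return set(self.gene_modes)

    @property
    def counts(self) -> Dict[str, int]:
        n_prox = sum(1 for m in self.gene_modes.values() if m == "proximal_only")
        n_cont = sum(1 for m in self.gene_modes.values() if m == "contact_only")
        n_both = sum(1 for m in self.gene_modes.values() if m == "both")
        return {
            "n_proximal_only": n_prox,
            "n_contact_only": n_cont,
            "n_both": n_both,
            "n_proximal": n_prox + n_both,
            "n_contact": n_cont + n_both,
            "n_total": len(self.gene_modes),
        }


def _peak_tree_by_chrom(peaks: Iterable[Peak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.interval.chrom].addi(p.interval.start, p.interval.end, p)
    return trees


def proximal_link(
    peaks: Iterable[Peak], tsss: Iterable[TSSRecord], window: int = 2000
) -> List[TargetAssignment]:
    """All (peak, TSS) pairs with nearest-base distance <= window (same chrom).

    Equivalent to intersecting the peak with the closed window
    ``[tss - window, tss + window]``; the boundary distance is inclusive.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    trees = _peak_tree_by_chrom(peaks)
    out: List[TargetAssignment] = []
    for t in tsss:
        tree = trees.get(t.chrom)
        if tree is None:
            continue
        # half-open query over the closed window [tss-window, tss+window]
        for hit in tree.overlap(max(0, t.tss_position - window), t.tss_position + window + 1):
            peak: Peak = hit.data
            dist = peak.interval.distance_to_point(t.tss_position)
            if dist <= window:
                out.append(
                    TargetAssignment(t.gene_id, t.tss_position, t.chrom, peak.peak_id, "proximal", dist)
                )
    return sorted(out, key=lambda a: (a.gene_id, a.tss_position, a.peak_id))


def contact_link(
    peaks: Iterable[Peak],
    tsss: Iterable[TSSRecord],
    contacts: Iterable[ContactPair],
    anchor_pad: int = 0,
) -> List[TargetAssignment]:
    """All (peak, TSS) pairs physically linked by a chromatin contact.

    A contact links a peak to a TSS when one anchor overlaps the peak by at
    least one base and the other anchor (optionally padded by ``anchor_pad``
    bp per side) contains the TSS base. Anchor order is irrelevant;
    trans-chromosomal contacts are honored.
    """
    if anchor_pad < 0:
        raise ValueError(f"anchor_pad must be >= 0, got {anchor_pad}")
    peak_trees = _peak_tree_by_chrom(peaks)
    tss_by_chrom: Dict[str, List[TSSRecord]] = defaultdict(list)
    for t in tsss:
        tss_by_chrom[t.chrom].append(t)

    seen: Set = set()
    out: List[TargetAssignment] = []
    for c in contacts:
        for peak_anchor, tss_anchor in ((c.anchor1, c.anchor2), (c.anchor2, c.anchor1)):
            tree = peak_trees.get(peak_anchor.chrom)
            if tree is None:
                continue
            hit_peaks = [h.data for h in tree.overlap(peak_anchor.start, peak_anchor.end)]
            if not hit_peaks:
                continue
            padded = tss_anchor.padded(anchor_pad)
            for t in tss_by_chrom.get(padded.chrom, ()):
                if padded.start <= t.tss_position < padded.end:
                    for peak in hit_peaks:
                        key = (t.gene_id, t.tss_position, peak.peak_id, c.contact_id)
                        if key not in seen:
                            seen.add(key)
                            out.append(
                                TargetAssignment(
                                    t.gene_id, t.tss_position, t.chrom, peak.peak_id,
                                    "contact", c.contact_id,
                                )
                            )
    return sorted(out, key=lambda a: (a.gene_id, a.tss_position, a.peak_id, str(a.evidence)))


def combine_assignments(
    proximal: Sequence[TargetAssignment], contact: Sequence[TargetAssignment]
) -> TargetCallSet:
    """Union the two assignment sets into a deduplicated target call set.

    The unique-gene total is ``|genes(proximal) ∪ genes(contact)|``; genes
    found by both rules are labeled ``both`` and counted once.
    """
    prox_genes = {a.gene_id for a in proximal}
    cont_genes = {a.gene_id for a in contact}
    modes: Dict[str, str] = {}
    for g in prox_genes | cont_genes:
        if g in prox_genes and g in cont_genes:
            modes[g] = "both"
        elif g in prox_genes:
            modes[g] = "proximal_only"
        else:
            modes[g] = "contact_only"
    return TargetCallSet(frozenset(list(proximal) + list(contact)), modes)


def write_assignments(assignments: Iterable[TargetAssignment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\ttss_position\tchrom\tpeak_id\tmode\tevidence\n")
        for a in sorted(assignments, key=lambda a: (a.gene_id, a.tss_position, a.peak_id, a.mode)):
            fh.write(f"{a.gene_id}\t{a.tss_position}\t{a.chrom}\t{a.peak_id}\t{a.mode}\t{a.evidence}\n")
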