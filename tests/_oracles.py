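"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles (per-base walks,
all-pairs scans, exact rational arithmetic) without touching the code paths
it checks.
"""

from fractions import Fraction
from math import comb


def chain_file_base_map(path):
    """Per-base source->target map from a raw chain file.

    Walks every chain's blocks base by base using only the file text.
    Returns {(src_chrom, src_pos): (tgt_chrom, tgt_pos)}; bases covered by
    more than one chain map to the sentinel "MULTI".
    """
    mapping = {}
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    i = 0
    while i < len(lines):
        assert lines[i].startswith("chain")
        (_, _, t_name, _, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, _) = lines[i].split()
        assert t_strand == "+"
        t_pos, q_pos = int(t_start), int(q_start)
        q_size = int(q_size)
        i += 1
        while i < len(lines) and not lines[i].startswith("chain"):
            nums = [int(x) for x in lines[i].split()]
            size = nums[0]
            dt, dq = (nums[1], nums[2]) if len(nums) == 3 else (0, 0)
            for off in range(size):
                src = (t_name, t_pos + off)
                qp = q_pos + off
                tgt = (q_name, q_size - 1 - qp) if q_strand == "-" else (q_name, qp)
                mapping[src] = "MULTI" if src in mapping else tgt
            t_pos += size + dt
            q_pos += size + dq
            i += 1
    return mapping


def lift_fraction_by_walk(base_map, chrom, start, end):
    """Fraction of interval bases with any image, and their images."""
    images = [base_map[(chrom, p)] for p in range(start, end) if (chrom, p) in base_map]
    return len(images) / (end - start), images


def brute_proximal(peaks, tsss, window):
    """All-pairs (gene, peak) proximal links by direct distance scan."""
    out = set()
    for p in peaks:
        for t in tsss:
            if p.interval.chrom != t.chrom:
                continue
            if p.interval.start <= t.tss_position < p.interval.end:
                d = 0
            else:
                d = min(abs(p.interval.start - t.tss_position),
                        abs(p.interval.end - 1 - t.tss_position))
            if d <= window:
                out.add((t.gene_id, t.tss_position, p.peak_id, d))
    return out


def brute_contact(peaks, tsss, contacts, pad=0):
    """All-triples (gene, peak, contact) scan honoring anchor symmetry."""
    def overlaps(iv, anchor):
        return iv.chrom == anchor.chrom and iv.start < anchor.end and anchor.start < iv.end

    def contains(anchor, chrom, pos):
        return anchor.chrom == chrom and anchor.start - pad <= pos < anchor.end + pad

    out = set()
    for c in contacts:
        for pa, ta in ((c.anchor1, c.anchor2), (c.anchor2, c.anchor1)):
            for p in peaks:
                if not overlaps(p.interval, pa):
                    continue
                for t in tsss:
                    if contains(ta, t.chrom, t.tss_position):
                        out.add((t.gene_id, t.tss_position, p.peak_id, c.contact_id))
    return out


def exact_hypergeom_upper(N, n1, n2, k):
    """P(X >= k) by exact rational summation of the pmf."""
    denom = comb(N, n2)
    total = Fraction(0)
    for i in range(k, min(n1, n2) + 1):
        total += Fraction(comb(n1, i) * comb(N - n1, n2 - i), denom)
    return total
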