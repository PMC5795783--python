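"""UCSC chain-file parsing and block-wise interval lifting between assemblies.

A chain describes a gapped alignment between a *source* assembly (the chain
file's target/``t`` side, where the input coordinates live) and a *target*
assembly (the query/``q`` side, where lifted coordinates land), as an
ordered run of aligned blocks separated by gaps on either side. Negative-
strand query chains are normalized so lifted intervals are always reported
in forward coordinates, with ``strand_flip`` recording the inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .intervals import GenomicInterval


class ChainError(ValueError):
    """Malformed or arithmetically inconsistent chain data."""


@dataclass(frozen=True)
class ChainAlignment:
    """One chain: a block-structured alignment between two assemblies.

    ``blocks`` is an ordered list of ``(aligned_size, gap_after_source,
    gap_after_target)`` in bp; the last block has zero gaps. ``source_span``
    and ``target_span`` are forward-strand half-open spans; when the chain
    file records the query on the negative strand, ``strand_flip`` is True
    and target coordinates within blocks run backwards along
    ``target_span``.
    """

    source_assembly: str
    target_assembly: str
    source_span: GenomicInterval
    target_span: GenomicInterval
    source_size: int
    target_size: int
    blocks: Tuple[Tuple[int, int, int], ...]
    chain_id: str
    strand_flip: bool = False
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ChainError(f"chain {self.chain_id}: no alignment blocks")
        for size, dt, dq in self.blocks:
            if size <= 0:
                raise ChainError(f"chain {self.chain_id}: block size {size} <= 0")
            if dt < 0 or dq < 0:
                raise ChainError(f"chain {self.chain_id}: negative gap")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ChainError(f"chain {self.chain_id}: last block must have zero gaps")
        src_len = sum(s + dt for s, dt, _ in self.blocks)
        tgt_len = sum(s + dq for s, _, dq in self.blocks)
        if src_len != len(self.source_span):
            raise ChainError(
                f"chain {self.chain_id}: block sum {src_len} != source span {len(self.source_span)}"
            )
        if tgt_len != len(self.target_span):
            raise ChainError(
                f"chain {self.chain_id}: block sum {tgt_len} != target span {len(self.target_span)}"
            )

    def map_base(self, position: int) -> Optional[int]:
        """Forward-coordinate image of one source base, or None in a gap."""
        if not (self.source_span.start <= position < self.source_span.end):
            return None
        s = self.source_span.start
        # q walks in file coordinates: forward, or reversed-strand when flipped
        q = (self.target_size - self.target_span.end) if self.strand_flip else self.target_span.start
        for size, dt, dq in self.blocks:
            if s <= position < s + size:
                qpos = q + (position - s)
                return (self.target_size - 1 - qpos) if self.strand_flip else qpos
            s += size + dt
            q += size + dq
        return None

    def block_spans(self) -> Iterable[Tuple[int, int, int, int]]:
        """Yield (src_start, src_end, q_start_filecoord, size) per block."""
        s = self.source_span.start
        q = (self.target_size - self.target_span.end) if self.strand_flip else self.target_span.start
        for size, dt, dq in self.blocks:
            yield s, s + size, q, size
            s += size + dt
            q += size + dq


class LiftStatus(str, Enum):
    MAPPED = "mapped"
    PARTIAL = "partial_below_threshold"
    UNMAPPED = "unmapped"
    SPLIT = "split"


@dataclass(frozen=True)
class LiftResult:
    """Outcome of lifting one interval: status, image and coverage."""

    status: LiftStatus
    mapped_interval: Optional[GenomicInterval]
    mapped_fraction: float
    chain_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValueError("mapped_fraction must lie in [0, 1]")
        if self.status is LiftStatus.MAPPED and self.mapped_interval is None:
            raise ValueError("mapped status requires a mapped interval")
        if self.status is LiftStatus.UNMAPPED and self.mapped_fraction != 0.0:
            raise ValueError("unmapped status requires zero mapped_fraction")


def read_chain(path) -> List[ChainAlignment]:
    """Parse a UCSC chain file; block arithmetic is validated per chain."""
    chains: List[ChainAlignment] = []
    header: Optional[List[str]] = None
    blocks: List[Tuple[int, int, int]] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ChainError(f"chain {header[-1]}: header without blocks in {path}")
        chains.append(_build_chain(header, blocks, path))
        header, blocks = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                fields = line.split()
                if len(fields) != 13:
                    raise ChainError(f"{path}:{lineno}: chain header needs 13 fields, got {len(fields)}")
                header = fields
            else:
                if header is None:
                    raise ChainError(f"{path}:{lineno}: block line outside any chain")
                parts = line.split()
                try:
                    nums = [int(p) for p in parts]
                except ValueError:
                    raise ChainError(f"{path}:{lineno}: non-integer block line {line!r}") from None
                if len(nums) == 1:
                    blocks.append((nums[0], 0, 0))
                elif len(nums) == 3:
                    blocks.append((nums[0], nums[1], nums[2]))
                else:
                    raise ChainError(f"{path}:{lineno}: block line must have 1 or 3 numbers")
    flush()
    return chains


def _build_chain(header: Sequence[str], blocks: List[Tuple[int, int, int]], path) -> ChainAlignment:
    (_, score, t_name, t_size, t_strand, t_start, t_end,
     q_name, q_size, q_strand, q_start, q_end, chain_id) = header
    t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
    q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
    if t_strand != "+":
        raise ChainError(f"chain {chain_id}: tStrand must be '+', got {t_strand!r}")
    if q_strand not in ("+", "-"):
        raise ChainError(f"chain {chain_id}: qStrand must be '+' or '-'")
    flip = q_strand == "-"
    # normalize query span to forward coordinates
    if flip:
        fwd_q = GenomicInterval(q_name, q_size - q_end, q_size - q_start)
    else:
        fwd_q = GenomicInterval(q_name, q_start, q_end)
    return ChainAlignment(
        source_assembly=t_name,
        target_assembly=q_name,
        source_span=GenomicInterval(t_name, t_start, t_end),
        target_span=fwd_q,
        source_size=t_size,
        target_size=q_size,
        blocks=tuple(blocks),
        chain_id=str(chain_id),
        strand_flip=flip,
        score=float(score),
    )


def write_chain(chains: Iterable[ChainAlignment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in chains:
            if c.strand_flip:
                q_strand = "-"
                q_start = c.target_size - c.target_span.end
                q_end = c.target_size - c.target_span.start
            else:
                q_strand = "+"
                q_start, q_end = c.target_span.start, c.target_span.end
            fh.write(
                f"chain {format(c.score, 'g')} {c.source_span.chrom} {c.source_size} + "
                f"{c.source_span.start} {c.source_span.end} {c.target_span.chrom} "
                f"{c.target_size} {q_strand} {q_start} {q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap the source and target roles of a chain.

    The inverted chain lifts coordinates back from the target assembly to
    the source assembly; inverting twice returns an equivalent chain.
    """
    if not chain.strand_flip:
        blocks = tuple((size, dq, dt) for size, dt, dq in chain.blocks)
    else:
        # walking the new source (old target, forward) reverses block order
        sizes = [b[0] for b in chain.blocks]
        gaps = [(b[1], b[2]) for b in chain.blocks[:-1]]  # between consecutive blocks
        rev_sizes = sizes[::-1]
        rev_gaps = [(dq, dt) for dt, dq in gaps[::-1]]
        blocks = tuple(
            (rev_sizes[i],) + (rev_gaps[i] if i < len(rev_gaps) else (0, 0))
            for i in range(len(rev_sizes))
        )
    return ChainAlignment(
        source_assembly=chain.target_assembly,
        target_assembly=chain.source_assembly,
        source_span=chain.target_span,
        target_span=chain.source_span,
        source_size=chain.target_size,
        target_size=chain.source_size,
        blocks=blocks,
        chain_id=chain.chain_id,
        strand_flip=chain.strand_flip,
        score=chain.score,
    )


def _index_by_chrom(chains: Iterable[ChainAlignment]) -> Dict[str, List[ChainAlignment]]:
    index: Dict[str, List[ChainAlignment]] = {}
    for c in chains:
        index.setdefault(c.source_span.chrom, []).append(c)
    return index


def lift_interval(
    interval: GenomicInterval,
    chains: Iterable[ChainAlignment],
    min_match: float = 0.95,
) -> LiftResult:
    """Lift one interval through a chain set.

    The image of every source base inside aligned blocks is computed; the
    result is ``mapped`` when all imaged bases come from a single chain and
    their fraction of the interval is at least ``min_match`` (the reported
    interval spans the first to last image base). Bases imaged by more than
    one chain, or by chains to different chromosomes, give ``split``.
    ``mapped_fraction`` is always reported.
    """
    if not 0.0 < min_match <= 1.0:
        raise ValueError(f"min_match must lie in (0, 1], got {min_match}")
    candidates = _index_by_chrom(chains).get(interval.chrom, [])
    per_chain: List[Tuple[ChainAlignment, int, int, int]] = []  # chain, covered, img_min, img_max
    covered_segments: List[Tuple[int, int]] = []
    for chain in candidates:
        if not chain.source_span.overlaps(interval):
            continue
        covered = 0
        img_min, img_max = None, None
        for src_start, src_end, q_off, size in chain.block_spans():
            lo, hi = max(src_start, interval.start), min(src_end, interval.end)
            if lo >= hi:
                continue
            covered += hi - lo
            covered_segments.append((lo, hi))
            if chain.strand_flip:
                a = chain.target_size - 1 - (q_off + (hi - 1 - src_start))
                b = chain.target_size - 1 - (q_off + (lo - src_start))
            else:
                a = q_off + (lo - src_start)
                b = q_off + (hi - 1 - src_start)
            img_min = a if img_min is None else min(img_min, a)
            img_max = b if img_max is None else max(img_max, b)
        if covered > 0:
            per_chain.append((chain, covered, img_min, img_max))

    total = len(interval)
    if not per_chain:
        return LiftResult(LiftStatus.UNMAPPED, None, 0.0)
    if len(per_chain) > 1:
        return LiftResult(LiftStatus.SPLIT, None, _union_fraction(covered_segments, total))

    chain, covered, img_min, img_max = per_chain[0]
    fraction = covered / total
    strand = interval.strand
    if chain.strand_flip and strand in ("+", "-"):
        strand = "-" if strand == "+" else "+"
    image = GenomicInterval(chain.target_span.chrom, img_min, img_max + 1, strand)
    status = LiftStatus.MAPPED if fraction >= min_match else LiftStatus.PARTIAL
    return LiftResult(status, image, fraction, chain.chain_id)


def _union_fraction(segments: List[Tuple[int, int]], total: int) -> float:
    merged = 0
    last_end = None
    for lo, hi in sorted(segments):
        if last_end is None or lo >= last_end:
            merged += hi - lo
            last_end = hi
        elif hi > last_end:
            merged += hi - last_end
            last_end = hi
    return min(1.0, merged / total)
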