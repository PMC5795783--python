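"""Ortholog mapping and the A-only / shared / B-only target-set partition."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple


@dataclass(frozen=True)
class OrthologMap:
    """A symbol-pair table between two species' gene namespaces.

    One-to-many pairs are permitted and preserved; mapping a gene expands
    it to all of its images.
    """

    species_a: str
    species_b: str
    pairs: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("ortholog map contains duplicated pairs")

    @classmethod
    def from_pairs(cls, species_a: str, species_b: str, pairs: Iterable[Tuple[str, str]]) -> "OrthologMap":
        return cls(species_a, species_b, tuple(dict.fromkeys(pairs)))


def map_orthologs(
    genes: Iterable[str], ortho: OrthologMap, direction: str = "A->B"
) -> Tuple[Set[str], Set[str]]:
    """Translate a gene set across species via the symbol-pair table.

    Returns ``(mapped, unmapped)``: ``mapped`` is the union of images of
    every input gene having at least one pair (one-to-many expands to all
    images); ``unmapped`` collects inputs with no pair.
    """
    if direction not in ("A->B", "B->A"):
        raise ValueError(f"direction must be 'A->B' or 'B->A', got {direction!r}")
    lut: Dict[str, Set[str]] = {}
    for a, b in ortho.pairs:
        src, dst = (a, b) if direction == "A->B" else (b, a)
        lut.setdefault(src, set()).add(dst)
    mapped: Set[str] = set()
    unmapped: Set[str] = set()
    for g in genes:
        images = lut.get(g)
        if images:
            mapped |= images
        else:
            unmapped.add(g)
    return mapped, unmapped


@dataclass(frozen=True)
class TargetPartition:
    """Disjoint decomposition of two target gene sets.

    ``a_only = A \\ B``, ``b_only = B \\ A``, ``shared = A ∩ B``; the three
    classes are pairwise disjoint and their union is ``A ∪ B``.
    """

    a_only: frozenset
    shared: frozenset
    b_only: frozenset
    universe_label: str = ""

    def __post_init__(self) -> None:
        if self.a_only & self.shared or self.b_only & self.shared or self.a_only & self.b_only:
            raise ValueError("partition classes must be pairwise disjoint")

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "n_a_only": len(self.a_only),
            "n_shared": len(self.shared),
            "n_b_only": len(self.b_only),
            "n_union": len(self.a_only) + len(self.shared) + len(self.b_only),
        }

    def class_of(self, gene: str) -> str:
        if gene in self.shared:
            return "shared"
        if gene in self.a_only:
            return "a_only"
        if gene in self.b_only:
            return "b_only"
        return "none"


def partition_targets(
    set_a: Iterable[str], set_b: Iterable[str], universe_label: str = "", uppercase: bool = False
) -> TargetPartition:
    """Partition two target sets into factor-specific and shared classes.

    Symbols are compared case-sensitively; ``uppercase=True`` upper-cases
    both sets first (mouse/human symbol conventions differ in case only).
    """
    a, b = set(set_a), set(set_b)
    if uppercase:
        a = {g.upper() for g in a}
        b = {g.upper() for g in b}
    return TargetPartition(
        a_only=frozenset(a - b),
        shared=frozenset(a & b),
        b_only=frozenset(b - a),
        universe_label=universe_label,
    )


def write_partition(partition: TargetPartition, path) -> None:
    """Three-column TSV: gene, class, source evidence label."""
    rows: List[Tuple[str, str]] = []
    for g in partition.a_only:
        rows.append((g, "a_only"))
    for g in partition.shared:
        rows.append((g, "shared"))
    for g in partition.b_only:
        rows.append((g, "b_only"))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tclass\tsource_evidence\n")
        for g, cls in sorted(rows):
            src = {"a_only": "set_a", "b_only": "set_b", "shared": "set_a+set_b"}[cls]
            fh.write(f"{g}\t{cls}\t{src}\n")
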