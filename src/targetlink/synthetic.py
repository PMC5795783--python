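"""Deterministic toy-genome scenario generator with planted ground truth.

A scenario emulates the structure of the pipeline's real inputs — a TSS
catalog, two factors' ChIP-seq peak sets, a chromatin-contact list, an
assembly chain file, an expression table and an ortholog map — with every
target linkage, partition class and signature membership planted by
construction and recorded in a machine-readable answer key.

Geometry guarantees exact recovery: TSSs are spaced at least three windows
apart, planted proximal peaks sit within the window of their own TSS only,
contact-only peaks and all decoys live in a distal zone more than three
windows from every TSS, and contact anchors are fixed-width bins that
contain exactly the elements they were planted for.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .intervals import ContactPair, GenomicInterval, Peak, TSSRecord
from .io import write_bed, write_bedpe, write_tss_bed6
from .liftover import ChainAlignment, write_chain


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Planted class counts refer to genes: ``a_proximal``/``b_proximal`` are
    factor-specific proximal targets, ``*_contact_only`` are reachable only
    through a chromatin contact, ``shared`` genes are proximal targets of
    both factors, and ``both_mode`` genes are factor-A targets linked by
    both rules at once. Remaining genes are non-targets.
    """

    n_genes: int = 200
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    a_proximal: int = 30
    b_proximal: int = 30
    a_contact_only: int = 10
    b_contact_only: int = 10
    shared: int = 20
    both_mode: int = 5
    n_decoy_peaks: int = 50
    n_decoy_contacts: int = 30
    window: int = 2000
    anchor_width: int = 5000
    peak_width: int = 300
    factor_a: str = "MRTF-SRF"
    factor_b: str = "YAP-TEAD"
    focal_condition: str = "myCAF"
    reference_conditions: Tuple[str, str] = ("iCAF", "quiescent")
    fold_change: float = 4.0
    n_signature: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.a_proximal, self.b_proximal, self.a_contact_only,
                  self.b_contact_only, self.shared, self.both_mode)
        if any(c < 0 for c in counts) or self.n_decoy_peaks < 0 or self.n_decoy_contacts < 0:
            raise ValueError("planted counts must be >= 0")
        if sum(counts) > self.n_genes:
            raise ValueError("planted class counts exceed n_genes")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature exceeds n_genes")
        if self.window < 0 or self.anchor_width <= 0 or self.peak_width <= 0:
            raise ValueError("window/anchor_width/peak_width out of range")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.fold_change <= 2.0:
            raise ValueError("planted fold_change must exceed the 2-fold rule threshold")

    @property
    def gene_spacing(self) -> int:
        # >= 3x window keeps proximal decoys impossible; anchor_width keeps
        # TSS-centered contact anchors from reaching neighbors
        return 3 * self.window + self.anchor_width

    @property
    def slot_size(self) -> int:
        return self.anchor_width + 3 * self.window


@dataclass
class ScenarioBundle:
    """File paths of one generated scenario plus its answer key."""

    out_dir: Path
    tss_path: Path
    peaks_a_path: Path
    peaks_b_path: Path
    contacts_path: Path
    chain_path: Path
    expression_path: Path
    ortholog_path: Path
    truth: Dict


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_scenario(config: ScenarioConfig, out_dir) -> ScenarioBundle:
    """Generate all scenario files and the answer key under ``out_dir``.

    The same config (including seed) always produces byte-identical files.
    Raises before any file is written if the configured counts cannot be
    placed on chromosomes of the configured length.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    order = [genes[i] for i in rng.permutation(config.n_genes)]

    classes: Dict[str, str] = {}
    cursor = 0
    plan: List[Tuple[str, int]] = [
        ("a_proximal", config.a_proximal),
        ("a_contact_only", config.a_contact_only),
        ("both_mode", config.both_mode),
        ("b_proximal", config.b_proximal),
        ("b_contact_only", config.b_contact_only),
        ("shared", config.shared),
    ]
    for label, count in plan:
        for g in order[cursor:cursor + count]:
            classes[g] = label
        cursor += count
    for g in order[cursor:]:
        classes[g] = "none"

    # --- placement ------------------------------------------------------
    spacing, aw = config.gene_spacing, config.anchor_width
    margin = aw
    per_chrom_genes: Dict[str, List[str]] = {_chrom_name(c): [] for c in range(config.n_chromosomes)}
    tss_pos: Dict[str, Tuple[str, int]] = {}
    for i, g in enumerate(genes):
        chrom = _chrom_name(i % config.n_chromosomes)
        idx = len(per_chrom_genes[chrom])
        per_chrom_genes[chrom].append(g)
        tss_pos[g] = (chrom, margin + idx * spacing)

    # distal slots per chromosome, after the gene zone plus a buffer
    n_distal_needed: Dict[str, int] = {c: 0 for c in per_chrom_genes}
    for g in genes:
        if classes[g] in ("a_contact_only", "b_contact_only", "both_mode"):
            n_distal_needed[tss_pos[g][0]] += 1
    decoy_peak_chroms = [_chrom_name(i % config.n_chromosomes) for i in range(config.n_decoy_peaks)]
    decoy_contact_chroms = [_chrom_name(i % config.n_chromosomes) for i in range(config.n_decoy_contacts)]
    for c in decoy_peak_chroms:
        n_distal_needed[c] += 1
    for c in decoy_contact_chroms:
        n_distal_needed[c] += 2

    gene_zone_end: Dict[str, int] = {}
    distal_start: Dict[str, int] = {}
    for chrom, gs in per_chrom_genes.items():
        gene_zone_end[chrom] = margin + len(gs) * spacing
        distal_start[chrom] = gene_zone_end[chrom] + config.slot_size
        needed = distal_start[chrom] + n_distal_needed[chrom] * config.slot_size + margin
        if needed > config.chrom_length:
            raise ValueError(
                f"infeasible placement on {chrom}: requires {needed} bp "
                f"but chrom_length is {config.chrom_length}"
            )

    next_slot: Dict[str, int] = dict(distal_start)

    def take_slot(chrom: str) -> int:
        """Center coordinate of a fresh exclusive distal slot."""
        center = next_slot[chrom] + config.slot_size // 2
        next_slot[chrom] += config.slot_size
        return center

    peaks_a: List[Peak] = []
    peaks_b: List[Peak] = []
    contacts: List[ContactPair] = []
    truth_genes: Dict[str, Dict] = {}

    def proximal_peak(g: str, factor: str, bucket: List[Peak]) -> None:
        chrom, tss = tss_pos[g]
        d = int(rng.integers(0, config.window + 1))
        start = tss + d
        bucket.append(Peak(GenomicInterval(chrom, start, start + config.peak_width),
                           f"{factor}_prox_{g}", factor))

    def contact_peak(g: str, factor: str, bucket: List[Peak]) -> None:
        chrom, tss = tss_pos[g]
        center = take_slot(chrom)
        start = center - config.peak_width // 2
        bucket.append(Peak(GenomicInterval(chrom, start, start + config.peak_width),
                           f"{factor}_dist_{g}", factor))
        anchor_peak = GenomicInterval(chrom, center - aw // 2, center - aw // 2 + aw)
        anchor_tss = GenomicInterval(chrom, tss - aw // 2, tss - aw // 2 + aw)
        # anchor order randomized: consumers must be symmetric
        a1, a2 = (anchor_peak, anchor_tss) if rng.integers(2) else (anchor_tss, anchor_peak)
        contacts.append(ContactPair(a1, a2, f"loop_{factor}_{g}"))

    mode_map = {
        "a_proximal": ("proximal", "none", "a_only"),
        "a_contact_only": ("contact", "none", "a_only"),
        "both_mode": ("both", "none", "a_only"),
        "b_proximal": ("none", "proximal", "b_only"),
        "b_contact_only": ("none", "contact", "b_only"),
        "shared": ("proximal", "proximal", "shared"),
        "none": ("none", "none", "none"),
    }
    for g in genes:
        cls = classes[g]
        mode_a, mode_b, part = mode_map[cls]
        if cls in ("a_proximal", "both_mode", "shared"):
            proximal_peak(g, config.factor_a, peaks_a)
        if cls in ("a_contact_only", "both_mode"):
            contact_peak(g, config.factor_a, peaks_a)
        if cls in ("b_proximal", "shared"):
            proximal_peak(g, config.factor_b, peaks_b)
        if cls == "b_contact_only":
            contact_peak(g, config.factor_b, peaks_b)
        truth_genes[g] = {"class": part, "mode_a": mode_a, "mode_b": mode_b}

    for i, chrom in enumerate(decoy_peak_chroms):
        center = take_slot(chrom)
        start = center - config.peak_width // 2
        factor = config.factor_a if i % 2 == 0 else config.factor_b
        bucket = peaks_a if i % 2 == 0 else peaks_b
        bucket.append(Peak(GenomicInterval(chrom, start, start + config.peak_width),
                           f"{factor}_decoy_{i:03d}", factor))
    for i, chrom in enumerate(decoy_contact_chroms):
        c1, c2 = take_slot(chrom), take_slot(chrom)
        contacts.append(
            ContactPair(
                GenomicInterval(chrom, c1 - aw // 2, c1 - aw // 2 + aw),
                GenomicInterval(chrom, c2 - aw // 2, c2 - aw // 2 + aw),
                f"loop_decoy_{i:03d}",
            )
        )

    strands = rng.choice(["+", "-"], size=config.n_genes)
    tsss = [TSSRecord(g, tss_pos[g][0], tss_pos[g][1], strands[i]) for i, g in enumerate(genes)]

    # --- expression table ----------------------------------------------
    signature = sorted(rng.choice(genes, size=config.n_signature, replace=False).tolist())
    sig_set = set(signature)
    ref1, ref2 = config.reference_conditions
    expr_rows: List[Tuple[str, float, float, float]] = []
    for g in genes:
        base = float(rng.uniform(50, 500))
        r1 = base
        r2 = base * float(rng.uniform(0.8, 1.25))
        if g in sig_set:
            focal = config.fold_change * max(r1, r2)  # min ratio == fold_change exactly
        else:
            focal = min(r1, r2) * float(rng.uniform(0.6, 1.8))  # every ratio <= 1.8
        expr_rows.append((g, focal, r1, r2))
        truth_genes[g]["in_signature"] = g in sig_set

    # --- chain file: toy assembly shift with a gap between zones --------
    shift, gap = 1000, 1000
    chain_list: List[ChainAlignment] = []
    for ci in range(config.n_chromosomes):
        chrom = _chrom_name(ci)
        L = config.chrom_length
        l1 = gene_zone_end[chrom]
        chain_list.append(
            ChainAlignment(
                source_assembly=chrom, target_assembly=chrom,
                source_span=GenomicInterval(chrom, 0, L),
                target_span=GenomicInterval(chrom, shift, shift + L - gap),
                source_size=L, target_size=L + shift,
                blocks=((l1, gap, 0), (L - l1 - gap, 0, 0)),
                chain_id=f"chain_{chrom}", score=1000.0,
            )
        )

    # --- write files ----------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = ScenarioBundle(
        out_dir=out_dir,
        tss_path=out_dir / "tss.bed",
        peaks_a_path=out_dir / "peaks_a.bed",
        peaks_b_path=out_dir / "peaks_b.bed",
        contacts_path=out_dir / "contacts.bedpe",
        chain_path=out_dir / "alignment.chain",
        expression_path=out_dir / "expression.tsv",
        ortholog_path=out_dir / "orthologs.tsv",
        truth={},
    )
    write_tss_bed6(tsss, paths.tss_path)
    write_bed(peaks_a, paths.peaks_a_path)
    write_bed(peaks_b, paths.peaks_b_path)
    write_bedpe(contacts, paths.contacts_path)
    write_chain(chain_list, paths.chain_path)
    with open(paths.expression_path, "w", encoding="utf-8") as fh:
        fh.write(f"gene\t{config.focal_condition}\t{ref1}\t{ref2}\n")
        for g, focal, v1, v2 in expr_rows:
            fh.write(f"{g}\t{focal:.4f}\t{v1:.4f}\t{v2:.4f}\n")
    with open(paths.ortholog_path, "w", encoding="utf-8") as fh:
        fh.write("toyA\ttoyB\n")
        for g in genes:
            fh.write(f"{g}\t{g}\n")

    expected = {
        "partition": {
            "a_only": sorted(g for g in genes if truth_genes[g]["class"] == "a_only"),
            "shared": sorted(g for g in genes if truth_genes[g]["class"] == "shared"),
            "b_only": sorted(g for g in genes if truth_genes[g]["class"] == "b_only"),
        },
        "signature": signature,
    }
    for side, key in (("factor_a", "mode_a"), ("factor_b", "mode_b")):
        modes = {g: truth_genes[g][key] for g in genes}
        expected[side] = {
            "proximal_only": sorted(g for g, m in modes.items() if m == "proximal"),
            "contact_only": sorted(g for g, m in modes.items() if m == "contact"),
            "both": sorted(g for g, m in modes.items() if m == "both"),
            "total": sum(1 for m in modes.values() if m != "none"),
        }
    config_record = asdict(config)
    config_record["reference_conditions"] = list(config.reference_conditions)
    paths.truth = {
        "config": config_record,
        "genes": truth_genes,
        "expected": expected,
    }
    write_truth(paths, out_dir / "truth.json")
    return paths


def write_truth(bundle: ScenarioBundle, path) -> None:
    """Serialize the answer key as JSON with per-gene records."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> Dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
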