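"""End-to-end orchestration: simulate/load -> lift -> link -> partition ->
signature -> enrich, with a consolidated, deterministic JSON report.

Every parameter that fills a methodological gap (window, anchor pad,
liftover min_match, fold threshold, upper-tail convention) is logged so
runs are auditable; identical config and seed give an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .enrichment import overlap_test
from .intervals import ContactPair, GenomicInterval, Peak, TSSRecord
from .io import (read_bed, read_bedpe, read_expression, read_ortholog_table,
                 read_tss, write_gene_list)
from .liftover import LiftStatus, lift_interval, read_chain
from .linkage import (TargetCallSet, combine_assignments, contact_link,
                      proximal_link, write_assignments)
from .signatures import FoldChangeRule, fold_change_signature
from .synthetic import ScenarioConfig, generate_scenario
from .target_sets import OrthologMap, map_orthologs, partition_targets, write_partition

logger = logging.getLogger("targetlink")


class ValidationError(ValueError):
    """Configuration or input-file problem detected before any stage runs."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Either ``simulate`` holds a :class:`~targetlink.synthetic.ScenarioConfig`
    (the scenario is generated into ``out_dir/scenario``) or the explicit
    input paths are set. ``lift_layer`` optionally lifts one input layer
    ("peaks", "contacts" or "tss") through ``chain_path`` before linkage.
    """

    out_dir: Path = Path("targetlink_out")
    simulate: Optional[ScenarioConfig] = None
    tss_path: Optional[Path] = None
    peaks_a_path: Optional[Path] = None
    peaks_b_path: Optional[Path] = None
    contacts_path: Optional[Path] = None
    expression_path: Optional[Path] = None
    ortholog_path: Optional[Path] = None
    chain_path: Optional[Path] = None
    lift_layer: str = "none"  # none | peaks | contacts | tss
    min_match: float = 0.95
    window: int = 2000
    anchor_pad: int = 0
    fold_threshold: float = 2.0
    focal_condition: str = "myCAF"
    reference_conditions: Tuple[str, ...] = ("iCAF", "quiescent")
    ortholog_direction: str = "B->A"
    universe_size: Optional[int] = None  # default: size of the TSS catalog's gene set
    family_m: Optional[int] = None
    factor_a: str = "MRTF-SRF"
    factor_b: str = "YAP-TEAD"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if sim is not None:
            sim = dict(sim)
            if "reference_conditions" in sim:
                sim["reference_conditions"] = tuple(sim["reference_conditions"])
            cfg.simulate = ScenarioConfig(**sim)
        cfg.out_dir = Path(cfg.out_dir)
        cfg.reference_conditions = tuple(cfg.reference_conditions)
        for key in ("tss_path", "peaks_a_path", "peaks_b_path", "contacts_path",
                    "expression_path", "ortholog_path", "chain_path"):
            val = getattr(cfg, key)
            if val is not None:
                setattr(cfg, key, Path(val))
        return cfg

    def validate(self) -> None:
        if self.window < 0:
            raise ValidationError(f"window must be >= 0, got {self.window}")
        if self.anchor_pad < 0:
            raise ValidationError(f"anchor_pad must be >= 0, got {self.anchor_pad}")
        if not 0.0 < self.min_match <= 1.0:
            raise ValidationError(f"min_match must lie in (0, 1], got {self.min_match}")
        if self.fold_threshold <= 0:
            raise ValidationError("fold_threshold must be > 0")
        if self.lift_layer not in ("none", "peaks", "contacts", "tss"):
            raise ValidationError(f"unknown lift_layer {self.lift_layer!r}")
        if self.lift_layer != "none" and self.simulate is None and self.chain_path is None:
            raise ValidationError("lift_layer set but no chain file given")
        if self.simulate is None:
            required = ["tss_path", "peaks_a_path", "peaks_b_path", "contacts_path", "expression_path"]
            for key in required:
                if getattr(self, key) is None:
                    raise ValidationError(f"missing required input {key} (and no simulate block)")
            for key in required + ["ortholog_path", "chain_path"]:
                p = getattr(self, key)
                if p is not None and not Path(p).is_file():
                    raise ValidationError(f"input file does not exist: {p} ({key})")

    def config_hash(self) -> str:
        # output location is not part of the analysis identity
        blob = {k: str(v) for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


def _lift_peaks(peaks: Sequence[Peak], chains, min_match: float) -> List[Peak]:
    out = []
    n_dropped = 0
    for p in peaks:
        res = lift_interval(p.interval, chains, min_match)
        if res.status is LiftStatus.MAPPED:
            out.append(Peak(res.mapped_interval, p.peak_id, p.factor, p.score))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("liftover dropped %d/%d peaks", n_dropped, len(peaks))
    return out


def _lift_contacts(contacts: Sequence[ContactPair], chains, min_match: float) -> List[ContactPair]:
    out = []
    for c in contacts:
        r1 = lift_interval(c.anchor1, chains, min_match)
        r2 = lift_interval(c.anchor2, chains, min_match)
        if r1.status is LiftStatus.MAPPED and r2.status is LiftStatus.MAPPED:
            out.append(ContactPair(r1.mapped_interval, r2.mapped_interval, c.contact_id, c.score))
    return out


def _lift_tss(tsss: Sequence[TSSRecord], chains, min_match: float) -> List[TSSRecord]:
    out = []
    for t in tsss:
        res = lift_interval(GenomicInterval(t.chrom, t.tss_position, t.tss_position + 1, t.strand),
                            chains, min_match)
        if res.status is LiftStatus.MAPPED:
            out.append(TSSRecord(t.gene_id, res.mapped_interval.chrom,
                                 res.mapped_interval.start, res.mapped_interval.strand))
    return out


def link_factor(peaks, tsss, contacts, window: int, anchor_pad: int) -> TargetCallSet:
    """Run both linkage rules for one factor and combine the call sets."""
    prox = proximal_link(peaks, tsss, window)
    cont = contact_link(peaks, tsss, contacts, anchor_pad)
    return combine_assignments(prox, cont)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages and return (and persist) the consolidated report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    config_hash = config.config_hash()  # before simulate fills in derived paths
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        bundle = generate_scenario(config.simulate, out_dir / "scenario")
        config.tss_path = bundle.tss_path
        config.peaks_a_path = bundle.peaks_a_path
        config.peaks_b_path = bundle.peaks_b_path
        config.contacts_path = bundle.contacts_path
        config.expression_path = bundle.expression_path
        config.ortholog_path = bundle.ortholog_path
        config.chain_path = bundle.chain_path
        config.window = config.simulate.window
        config.focal_condition = config.simulate.focal_condition
        config.reference_conditions = tuple(config.simulate.reference_conditions)
        config.factor_a = config.simulate.factor_a
        config.factor_b = config.simulate.factor_b

    logger.info(
        "parameters: window=%d bp (boundary inclusive), anchor_pad=%d bp, "
        "min_match=%.3f, fold threshold=%.2f (strict >), hypergeometric tail=upper P(X>=k)",
        config.window, config.anchor_pad, config.min_match, config.fold_threshold,
    )

    tsss = read_tss(config.tss_path, format="bed6")
    peaks_a = read_bed(config.peaks_a_path, factor=config.factor_a)
    peaks_b = read_bed(config.peaks_b_path, factor=config.factor_b)
    contacts = read_bedpe(config.contacts_path)
    expr = read_expression(config.expression_path)

    if config.lift_layer != "none":
        chains = read_chain(config.chain_path)
        if config.lift_layer == "peaks":
            peaks_a = _lift_peaks(peaks_a, chains, config.min_match)
            peaks_b = _lift_peaks(peaks_b, chains, config.min_match)
        elif config.lift_layer == "contacts":
            contacts = _lift_contacts(contacts, chains, config.min_match)
        elif config.lift_layer == "tss":
            tsss = _lift_tss(tsss, chains, config.min_match)

    calls_a = link_factor(peaks_a, tsss, contacts, config.window, config.anchor_pad)
    calls_b = link_factor(peaks_b, tsss, contacts, config.window, config.anchor_pad)
    write_assignments([a for a in calls_a.assignments], out_dir / "assignments_a.tsv")
    write_assignments([a for a in calls_b.assignments], out_dir / "assignments_b.tsv")

    set_a, set_b = calls_a.genes, calls_b.genes
    n_unmapped_b = 0
    if config.ortholog_path is not None:
        sp_a, sp_b, pairs = read_ortholog_table(config.ortholog_path)
        ortho = OrthologMap.from_pairs(sp_a, sp_b, pairs)
        direction = config.ortholog_direction
        mapped, unmapped = map_orthologs(set_b, ortho, direction)
        n_unmapped_b = len(unmapped)
        if unmapped:
            logger.info("%d factor-B target genes had no ortholog pair", len(unmapped))
        set_b = mapped
    partition = partition_targets(set_a, set_b, universe_label="tss_catalog")
    write_partition(partition, out_dir / "partition.tsv")

    rule = FoldChangeRule(config.focal_condition, list(config.reference_conditions),
                          threshold=config.fold_threshold)
    signature = fold_change_signature(expr, rule)
    write_gene_list(signature, out_dir / "signature.txt")

    universe = sorted({t.gene_id for t in tsss})
    if config.universe_size is not None and config.universe_size < len(universe):
        raise ValidationError("universe_size smaller than the TSS catalog gene set")
    comparisons = [("signature_vs_a_only", partition.a_only),
                   ("signature_vs_shared", partition.shared),
                   ("signature_vs_b_only", partition.b_only)]
    m = config.family_m if config.family_m is not None else len(comparisons)
    enrichment_rows = []
    for label, gene_set in comparisons:
        res = overlap_test(universe, signature, gene_set, m_tests=m)
        enrichment_rows.append(
            {"comparison": label, "N": res.universe_size, "n1": res.set1_size,
             "n2": res.set2_size, "k": res.overlap, "p": res.p_value,
             "p_bonferroni": res.p_bonferroni}
        )

    report = {
        "provenance": {"config_hash": config_hash, "seed": config.seed,
                       "version": __version__},
        "parameters": {"window": config.window, "anchor_pad": config.anchor_pad,
                       "min_match": config.min_match, "fold_threshold": config.fold_threshold,
                       "tail": "upper P(X>=k)", "bonferroni_m": m},
        "factor_a": calls_a.counts,
        "factor_b": calls_b.counts,
        "partition": partition.counts,
        "n_unmapped_orthologs_b": n_unmapped_b,
        "signature_size": len(signature),
        "enrichment": enrichment_rows,
    }
    _check_report_identities(report, calls_a, calls_b, partition)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def evaluate_recovery(scenario_dir) -> Dict:
    """Run the full analysis on a generated scenario and diff against truth.

    Returns a dict with the recovered counts and a ``mismatches`` list that
    is empty exactly when every planted per-factor mode label, partition
    class and signature membership was recovered with zero false positives
    or negatives.
    """
    from .synthetic import read_truth

    scenario_dir = Path(scenario_dir)
    truth = read_truth(scenario_dir / "truth.json")
    cfg = truth["config"]
    tsss = read_tss(scenario_dir / "tss.bed", format="bed6")
    peaks_a = read_bed(scenario_dir / "peaks_a.bed", factor=cfg["factor_a"])
    peaks_b = read_bed(scenario_dir / "peaks_b.bed", factor=cfg["factor_b"])
    contacts = read_bedpe(scenario_dir / "contacts.bedpe")
    expr = read_expression(scenario_dir / "expression.tsv")
    sp_a, sp_b, pairs = read_ortholog_table(scenario_dir / "orthologs.tsv")

    calls_a = link_factor(peaks_a, tsss, contacts, cfg["window"], anchor_pad=0)
    calls_b = link_factor(peaks_b, tsss, contacts, cfg["window"], anchor_pad=0)
    set_b, _ = map_orthologs(calls_b.genes, OrthologMap.from_pairs(sp_a, sp_b, pairs), "B->A")
    partition = partition_targets(calls_a.genes, set_b)
    rule = FoldChangeRule(cfg["focal_condition"], list(cfg["reference_conditions"]))
    signature = fold_change_signature(expr, rule)

    expected = truth["expected"]
    mismatches: List[str] = []

    def diff(label: str, got: set, want: set) -> None:
        if got != want:
            mismatches.append(
                f"{label}: {len(got - want)} false positives, {len(want - got)} false negatives"
            )

    for side, calls in (("factor_a", calls_a), ("factor_b", calls_b)):
        for mode_key, truth_key in (("proximal_only", "proximal_only"),
                                    ("contact_only", "contact_only"), ("both", "both")):
            got = {g for g, m in calls.gene_modes.items() if m == mode_key}
            diff(f"{side}.{mode_key}", got, set(expected[side][truth_key]))
    diff("partition.a_only", set(partition.a_only), set(expected["partition"]["a_only"]))
    diff("partition.shared", set(partition.shared), set(expected["partition"]["shared"]))
    diff("partition.b_only", set(partition.b_only), set(expected["partition"]["b_only"]))
    diff("signature", signature, set(expected["signature"]))

    return {
        "mismatches": mismatches,
        "factor_a": calls_a.counts,
        "factor_b": calls_b.counts,
        "partition": partition.counts,
        "signature_size": len(signature),
    }


def _check_report_identities(report, calls_a, calls_b, partition) -> None:
    """Conservation identities, enforced at report-assembly time."""
    for calls, key in ((calls_a, "factor_a"), (calls_b, "factor_b")):
        c = report[key]
        assert c["n_total"] == c["n_proximal_only"] + c["n_contact_only"] + c["n_both"]
        assert c["n_total"] == len(calls.genes)
    p = report["partition"]
    assert p["n_union"] == p["n_a_only"] + p["n_shared"] + p["n_b_only"]
    assert p["n_union"] == len(partition.a_only | partition.shared | partition.b_only)
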