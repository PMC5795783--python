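"""Fold-change expression signatures and ΔCt relative abundance.

The signature rule selects genes overexpressed strictly more than
``threshold``-fold in a focal condition relative to every (or any)
reference condition, on linear-scale values. The ΔCt formula converts qPCR
cycle thresholds to relative transcript abundance against a housekeeping
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FoldChangeRule:
    """Selection rule for an overexpression signature.

    With ``require_all`` (the default) the focal/reference ratio must
    strictly exceed ``threshold`` for every reference condition; otherwise
    any one suffices. A ratio exactly equal to the threshold never
    qualifies. ``pseudocount``, when set, is added to numerator and
    denominator so zero references do not error.
    """

    focal_condition: str
    reference_conditions: Sequence[str]
    threshold: float = 2.0
    require_all: bool = True
    pseudocount: Optional[float] = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if not self.reference_conditions:
            raise ValueError("at least one reference condition is required")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive when set")


def validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        raise ValueError("expression table has duplicate gene rows")
    if (expr.values < 0).any():
        raise ValueError("expression values must be >= 0")


def fold_change_signature(expr: pd.DataFrame, rule: FoldChangeRule, log2_input: bool = False) -> Set[str]:
    """Genes whose focal/reference ratio strictly exceeds the threshold.

    ``expr`` is a gene x condition table of linear-scale values;
    ``log2_input=True`` converts from log2 at entry. Zero reference values
    raise (naming the first offending gene) unless a pseudo-count is
    configured on the rule.
    """
    validate_expression(expr)
    missing = [c for c in [rule.focal_condition, *rule.reference_conditions] if c not in expr.columns]
    if missing:
        raise KeyError(f"conditions not in expression table: {missing}")
    values = expr.astype(float)
    if log2_input:
        values = np.exp2(values)
    focal = values[rule.focal_condition]
    hits = None
    for ref_col in rule.reference_conditions:
        ref = values[ref_col]
        if rule.pseudocount is None:
            zeros = ref.index[ref == 0]
            if len(zeros):
                raise ZeroDivisionError(
                    f"reference condition {ref_col!r} is zero for gene {zeros[0]!r}; "
                    "configure a pseudocount to allow this"
                )
            ratio = focal / ref
        else:
            ratio = (focal + rule.pseudocount) / (ref + rule.pseudocount)
        passed = ratio > rule.threshold
        hits = passed if hits is None else (hits & passed if rule.require_all else hits | passed)
    return set(expr.index[hits])


def relative_abundance_dct(ct_target: float, ct_reference: float) -> float:
    """Relative transcript abundance ``2^-(Ct_target - Ct_reference)``.

    Normalizes a target gene's qPCR cycle threshold to a housekeeping
    reference (e.g. GAPDH); equal Ct values give 1.0.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def relative_abundance_table(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-sample ΔCt abundances of every gene relative to ``reference_gene``.

    ``ct`` has columns sample, gene, ct; returns sample, gene, rel_abundance
    with the reference gene's own rows omitted.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    rows: List[dict] = []
    for _, row in ct[ct["gene"] != reference_gene].iterrows():
        if row["sample"] not in ref.index:
            raise ValueError(f"sample {row['sample']!r} lacks a {reference_gene!r} measurement")
        rows.append(
            {
                "sample": row["sample"],
                "gene": row["gene"],
                "rel_abundance": relative_abundance_dct(row["ct"], ref[row["sample"]]),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "gene", "rel_abundance"])
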