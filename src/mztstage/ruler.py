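"""Compilation of the "ruler" gene set used to anchor stage estimation.

Ruler genes are maternal transcripts that decrease monotonically across the
reference time-course; because their decline is driven by first-order decay
with gene-specific half-lives, their joint profile acts as a molecular clock
for developmental time. A gene enters the ruler iff

1. it is classified maternal (classification is an input, mirroring the use
   of published maternal/zygotic lists -- it is never inferred here);
2. its first-stage expression is at least ``min_first_stage_expr``;
3. it never rises by more than ``monotone_tolerance`` (fractional) between
   consecutive stages; and
4. its first-to-last-stage decline is at least ``min_total_decline``-fold.

Output order is descending first-stage expression. A published ruler list
can be supplied directly in place of :func:`compile_ruler` output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneClass,
    ReferenceTimecourse,
    ValidationError,
    read_gene_list,
    write_gene_list,
)


@dataclass(frozen=True)
class RulerParams:
    """Filter thresholds for ruler compilation.

    Defaults are conservative: a 5% tolerance absorbs small non-monotone
    jitter between adjacent stages, a 2-fold decline requirement excludes
    near-flat maternal genes that carry no timing signal, and a minimal
    first-stage abundance of 1 (abundance units) removes unexpressed genes.
    """

    min_first_stage_expr: float = 1.0
    monotone_tolerance: float = 0.05
    min_total_decline: float = 2.0

    def __post_init__(self) -> None:
        if self.monotone_tolerance < 0:
            raise ValueError("monotone_tolerance must be >= 0")
        if self.min_total_decline < 1:
            raise ValueError("min_total_decline must be >= 1 (fold)")


@dataclass
class RulerSet:
    """Ordered ruler gene ids plus the parameters that produced them."""

    genes: tuple[str, ...]
    params: RulerParams = field(default_factory=RulerParams)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("ruler set must be non-empty")
        self.genes = tuple(str(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def compile_ruler(
    reference: ReferenceTimecourse,
    classes: GeneClass,
    params: RulerParams | None = None,
) -> RulerSet:
    """Compile the monotonically decreasing maternal gene set.

    Raises a :class:`ValidationError` advising parameter relaxation when no
    gene passes all four predicates.
    """
    params = params or RulerParams()
    if reference.n_stages < 3:
        raise ValidationError("reference needs >= 3 stages to compile a ruler")
    expr = reference.matrix.values
    labels = classes.labels.reindex(expr.index).fillna("unclassified")
    maternal = expr.loc[labels == "maternal"]
    if maternal.empty:
        raise ValidationError("no maternal genes present in the reference")
    vals = maternal.to_numpy()
    first, last = vals[:, 0], vals[:, -1]
    expressed = first >= params.min_first_stage_expr
    monotone = np.all(
        vals[:, 1:] <= vals[:, :-1] * (1.0 + params.monotone_tolerance), axis=1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        decline = np.where(last > 0, first / last, np.inf)
        decline = np.where(first == 0, 1.0, decline)  # 0/0: no decline signal
    declined = decline >= params.min_total_decline
    keep = expressed & monotone & declined
    if not keep.any():
        raise ValidationError(
            "no gene passed the ruler filters; relax min_first_stage_expr, "
            "monotone_tolerance or min_total_decline"
        )
    kept = maternal.index[keep]
    order = np.argsort(-maternal.loc[kept].iloc[:, 0].to_numpy(), kind="stable")
    return RulerSet(tuple(kept[order]), params, provenance="compile_ruler")


def ruler_report(ruler: RulerSet, reference: ReferenceTimecourse) -> pd.DataFrame:
    """Per-ruler-gene summary: first/last expression, decline fold and the
    worst consecutive-stage increase (monotonicity margin, fractional)."""
    missing = [g for g in ruler.genes if g not in reference.gene_ids]
    if missing:
        raise ValidationError(f"ruler gene(s) absent from reference: {missing[:5]}")
    vals = reference.matrix.values.loc[list(ruler.genes)].to_numpy()
    first, last = vals[:, 0], vals[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        decline = np.where(last > 0, first / last, np.inf)
        ratio = np.where(vals[:, :-1] > 0, vals[:, 1:] / vals[:, :-1], np.inf)
        ratio = np.where((vals[:, 1:] == 0) & (vals[:, :-1] == 0), 1.0, ratio)
    margin = ratio.max(axis=1) - 1.0
    return pd.DataFrame(
        {
            "first_stage_expr": first,
            "last_stage_expr": last,
            "decline_fold": decline,
            "monotonicity_margin": margin,
        },
        index=pd.Index(ruler.genes, name="gene_id"),
    )


def write_ruler(ruler: RulerSet, path: str | Path) -> None:
    """Write the ruler as a gene list with a machine-parseable '#' header."""
    p = ruler.params
    header = "\n".join(
        [
            f"min_first_stage_expr={p.min_first_stage_expr:g}",
            f"monotone_tolerance={p.monotone_tolerance:g}",
            f"min_total_decline={p.min_total_decline:g}",
            f"provenance={ruler.provenance}",
        ]
    )
    write_gene_list(ruler.genes, path, header=header)


def read_ruler(path: str | Path) -> RulerSet:
    """Read a ruler gene list, recovering parameters from '#' header lines."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("#") and "=" in line:
            key, _, value = line.lstrip("# ").partition("=")
            kv[key.strip()] = value.strip()
    genes = read_gene_list(path)
    params = RulerParams(
        min_first_stage_expr=float(kv.get("min_first_stage_expr", 1.0)),
        monotone_tolerance=float(kv.get("monotone_tolerance", 0.05)),
        min_total_decline=float(kv.get("min_total_decline", 2.0)),
    )
    return RulerSet(tuple(genes), params, provenance=kv.get("provenance", str(path)))
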