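"""Global maternal/zygotic shift statistics and stage-matched residuals.

A sample that is developmentally older than its comparator shows a global
signature: maternal transcripts down, zygotic transcripts up. This module
quantifies that signature (per-class median log2 fold-change, fraction of
genes moving in the class direction, exact two-sided sign tests) and, after
stage mapping, recomputes fold-changes against the stage-matched reference
profile. On a purely timing-driven difference the residual fold-changes
should lose the signature -- separating staging effects from genuine
condition effects, which survive stage matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import DEFAULT_PSEUDOCOUNT, FoldChangeTable
from .io import ExpressionMatrix, GeneClass, ReferenceTimecourse, ValidationError


@dataclass
class ClassShift:
    """Shift summary for one gene class."""

    n: int
    median_log2fc: float
    fraction_directional: float  # fraction strictly moving in class direction
    sign_test_p: float
    n_zero: int  # zero fold-changes, dropped from the sign test
    degenerate: bool = False  # no non-zero fold-changes to test


@dataclass
class ShiftSummary:
    """Global maternal/zygotic shift between two conditions.

    ``maternal.fraction_directional`` is the fraction of maternal genes
    strictly decreased; ``zygotic.fraction_directional`` the fraction of
    zygotic genes strictly increased. Classes absent from the data are
    ``None``.
    """

    maternal: ClassShift | None
    zygotic: ClassShift | None

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, cls in (("maternal", self.maternal), ("zygotic", self.zygotic)):
            if cls is None:
                rows[name] = dict.fromkeys(
                    ["n", "median_log2fc", "fraction_directional",
                     "sign_test_p", "n_zero"], np.nan
                )
            else:
                rows[name] = {
                    "n": cls.n,
                    "median_log2fc": cls.median_log2fc,
                    "fraction_directional": cls.fraction_directional,
                    "sign_test_p": cls.sign_test_p,
                    "n_zero": cls.n_zero,
                }
        return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Gene-class derivation from a reference time-course
# ---------------------------------------------------------------------------


def derive_gene_class(
    reference: ReferenceTimecourse,
    min_expr: float = 1.0,
    min_fold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    source_tag: str = "derived-from-reference",
) -> GeneClass:
    """Classify genes from their reference trajectory.

    Maternal: expressed at the first stage (>= ``min_expr``) and declining
    >= ``min_fold`` across the time-course. Zygotic: below ``min_expr`` at
    the first stage and rising >= ``min_fold``. Everything else (including
    flat housekeeping genes) is unclassified. A stand-in for published
    maternal/zygotic lists when none are supplied.
    """
    if reference.n_stages < 3:
        raise ValidationError("gene-class derivation needs >= 3 stages")
    if min_fold <= 1.0:
        warnings.warn(
            f"min_fold={min_fold:g} classifies every expressed gene; "
            "results will not separate maternal from zygotic dynamics",
            stacklevel=2,
        )
    vals = reference.matrix.values
    first = vals.iloc[:, 0].to_numpy()
    last = vals.iloc[:, -1].to_numpy()
    decline = (first + pseudocount) / (last + pseudocount)
    rise = (last + pseudocount) / (first + pseudocount)
    labels = np.where(
        (first >= min_expr) & (decline >= min_fold),
        "maternal",
        np.where((first < min_expr) & (rise >= min_fold), "zygotic", "unclassified"),
    )
    return GeneClass(pd.Series(labels, index=vals.index, dtype=str), source_tag)


# ---------------------------------------------------------------------------
# Global shift
# ---------------------------------------------------------------------------


def _class_shift(fc_vals: np.ndarray, direction: int) -> ClassShift:
    """Summarize one class; ``direction`` is -1 (expect down) or +1 (up)."""
    n = len(fc_vals)
    directional = int((np.sign(fc_vals) == direction).sum())
    n_zero = int((fc_vals == 0).sum())
    n_test = n - n_zero
    if n_test == 0:
        return ClassShift(
            n=n, median_log2fc=float(np.median(fc_vals)),
            fraction_directional=0.0, sign_test_p=1.0, n_zero=n_zero,
            degenerate=True,
        )
    k = int((fc_vals > 0).sum())
    p = stats.binomtest(k, n_test, 0.5, alternative="two-sided").pvalue
    return ClassShift(
        n=n,
        median_log2fc=float(np.median(fc_vals)),
        fraction_directional=directional / n,
        sign_test_p=float(p),
        n_zero=n_zero,
    )


def global_shift(fc: FoldChangeTable, classes: GeneClass) -> ShiftSummary:
    """Per-class medians, directional fractions and exact sign tests.

    Zero fold-changes are dropped from the sign test (a sign is undefined
    for them) but counted; the directional fractions use the full class
    denominator, so all-zero data give fractions of 0.
    """
    fc_genes = set(fc.gene_ids)
    out: dict[str, ClassShift | None] = {}
    for name, direction in (("maternal", -1), ("zygotic", +1)):
        genes = [g for g in classes.genes_of(name) if g in fc_genes]
        out[name] = (
            _class_shift(fc.log2fc.loc[genes].to_numpy(), direction)
            if genes
            else None
        )
    if out["maternal"] is None and out["zygotic"] is None:
        raise ValidationError("no classified genes carry a fold-change")
    return ShiftSummary(maternal=out["maternal"], zygotic=out["zygotic"])


# ---------------------------------------------------------------------------
# Stage-matched residuals
# ---------------------------------------------------------------------------


def residual_foldchanges(
    query: ExpressionMatrix,
    matched: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ruler=None,
) -> FoldChangeTable:
    """Fold-changes of a query against its stage-matched reference profile.

    ``log2((query mean + pc) / (matched + pc))`` per gene: what remains once
    the staging difference has been absorbed into the comparator. This table
    is the analysis endpoint; downstream enrichment of the residuals is out
    of scope.

    When ``ruler`` (an iterable of ruler gene ids) is given, the query mean
    is first rescaled by the median ruler-gene ratio matched/query, putting
    it on the matched profile's abundance scale. This is the maternal-gene
    normalization re-anchored at the matched stage; without it, a query
    normalized to the reference start carries the whole-time-course decay
    factor into every residual.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    shared = [g for g in query.gene_ids if g in matched.index]
    if not shared:
        raise ValidationError("empty gene intersection between query and profile")
    q = query.values.loc[shared].mean(axis=1)
    m = matched.loc[shared].astype(float)
    if ruler is not None:
        anchor = [g for g in ruler if g in q.index]
        ratio = m.loc[anchor] / q.loc[anchor]
        ratio = ratio[(q.loc[anchor] > 0) & (m.loc[anchor] > 0)]
        if ratio.empty:
            raise ValidationError("no positive ruler genes to rescale on")
        q = q * float(np.median(ratio))
    fc = np.log2(q + pseudocount) - np.log2(m + pseudocount)
    return FoldChangeTable(
        fc, pseudocount, label_a="stage-matched", label_b="query",
        mean_a=m, mean_b=q,
    )
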