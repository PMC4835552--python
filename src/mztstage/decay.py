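"""The decay clock: developmental offset from maternal mRNA decay kinetics.

Between two samples separated by a developmental offset dt, a maternal
transcript decaying first-order with half-life t_half and no new synthesis
satisfies

    log2 FC_g = log2( m_g(t + dt) / m_g(t) ) = -dt / t_half_g

so (a) the "extent of reduction" (-log2 FC) correlates inversely with
half-life across maternal genes, and (b) regressing log2 FC on 1/t_half
gives a through-origin slope of -dt: an estimate of the offset that is
independent of stage mapping. Half-lives are an input (published per-gene
tables); they are never estimated from the data here.

Genes with apparent induction (log2 FC above a small positive threshold)
violate the decay-only assumption -- typically zygotic re-expression -- and
are excluded from the regression and counted. Genes below the abundance
detection floor in either condition are likewise excluded: once a
transcript decays to the order of the pseudocount its measured fold-change
saturates and no longer tracks -dt / t_half, which would otherwise bias the
offset toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneClass, HalfLifeTable, ValidationError

DEFAULT_PSEUDOCOUNT = 0.5
#: log2 fold-change above which a maternal gene is treated as induced and
#: excluded from the decay regression (decay alone can never raise a level).
INDUCTION_THRESHOLD_LOG2 = 0.5
#: abundance below which a gene is considered undetected (RPKM-like units);
#: fold-changes of undetected genes are pseudocount-compressed.
DETECTION_FLOOR = 1.0
MIN_GENES = 3


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold-change of condition B versus condition A.

    ``mean_a``/``mean_b`` optionally carry the replicate-mean abundances the
    ratio was formed from (populated by :func:`log2_foldchanges`, absent on
    tables read back from disk); they enable detection-floor filtering in
    the decay regression.
    """

    log2fc: pd.Series
    pseudocount: float
    label_a: str = "A"
    label_b: str = "B"
    mean_a: pd.Series | None = None
    mean_b: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        vals = self.log2fc.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.log2fc.index[~np.isfinite(vals)].tolist()
            raise ValidationError(f"non-finite fold-change for gene(s) {bad[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.log2fc.index

    def subset_genes(self, genes) -> "FoldChangeTable":
        sub = lambda s: None if s is None else s.loc[list(genes)].copy()
        return FoldChangeTable(
            self.log2fc.loc[list(genes)].copy(), self.pseudocount,
            self.label_a, self.label_b, sub(self.mean_a), sub(self.mean_b),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pseudocount={self.pseudocount:g}\n")
            fh.write(f"# conditions={self.label_b}_vs_{self.label_a}\n")
            fh.write("gene_id\tlog2fc\n")
            for gene, fc in self.log2fc.items():
                fh.write(f"{gene}\t{fc:.10g}\n")


def read_foldchanges(path: str | Path) -> FoldChangeTable:
    """Read a ``gene<TAB>log2fc`` table written by :meth:`FoldChangeTable.write`."""
    pseudocount, label_a, label_b = 0.5, "A", "B"
    rows: dict[str, float] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("# ")
            if body.startswith("pseudocount="):
                pseudocount = float(body.split("=", 1)[1])
            elif body.startswith("conditions=") and "_vs_" in body:
                label_b, label_a = body.split("=", 1)[1].split("_vs_", 1)
            continue
        if not stripped:
            continue
        parts = stripped.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}: line {line_no}: expected gene<TAB>log2fc")
        if parts[0].strip().lower() in ("gene", "gene_id"):
            continue
        rows[parts[0].strip()] = float(parts[1])
    if not rows:
        raise ValidationError(f"{path}: empty fold-change table")
    return FoldChangeTable(pd.Series(rows), pseudocount, label_a, label_b)


@dataclass
class DecayFit:
    """Decay-clock output: offset estimate and half-life correlations."""

    delta_t_hat: float | None
    correlation_spearman: float
    correlation_pearson: float
    n_genes: int
    residual_sd: float | None
    fit_mode: Literal["through-origin", "free-intercept"] | None
    n_excluded_induced: int = 0
    n_excluded_low: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < MIN_GENES:
            raise ValidationError(
                f"decay fit needs >= {MIN_GENES} maternal genes, got {self.n_genes}"
            )
        if self.delta_t_hat is not None and not np.isfinite(self.delta_t_hat):
            raise ValidationError("delta_t_hat must be finite")


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------


def log2_foldchanges(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    label_a: str = "A",
    label_b: str = "B",
) -> FoldChangeTable:
    """Per-gene log2((mean_B + pc) / (mean_A + pc)) over replicate means."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValidationError("empty gene intersection between conditions")
    mean_a = a.values.loc[shared].mean(axis=1)
    mean_b = b.values.loc[shared].mean(axis=1)
    fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    return FoldChangeTable(fc, pseudocount, label_a, label_b, mean_a, mean_b)


def _maternal_decay_frame(
    fc: FoldChangeTable, hl: HalfLifeTable, classes: GeneClass
) -> pd.DataFrame:
    maternal = set(classes.genes_of("maternal"))
    genes = [g for g in fc.gene_ids if g in maternal and g in set(hl.gene_ids)]
    if len(genes) < MIN_GENES:
        raise ValidationError(
            f"only {len(genes)} maternal genes with both a fold-change and a "
            f"half-life (need >= {MIN_GENES})"
        )
    return pd.DataFrame(
        {
            "log2fc": fc.log2fc.loc[genes],
            "halflife": hl.halflives.loc[genes],
        }
    )


# ---------------------------------------------------------------------------
# Correlation (extent of reduction vs half-life)
# ---------------------------------------------------------------------------


def halflife_correlation(
    fc: FoldChangeTable, hl: HalfLifeTable, classes: GeneClass
) -> DecayFit:
    """Correlate the extent of reduction (-log2 FC) with transcript half-life.

    Restricted to maternal genes carrying both values. When condition B is
    developmentally older, short-lived transcripts drop the most, so both
    coefficients are expected negative. Zero-variance inputs (e.g. a zero
    offset, where every extent is 0) are reported as correlation 0 with the
    ``degenerate`` flag set.
    """
    frame = _maternal_decay_frame(fc, hl, classes)
    extent = -frame["log2fc"].to_numpy()
    thalf = frame["halflife"].to_numpy()
    degenerate = np.allclose(extent, extent[0]) or np.allclose(thalf, thalf[0])
    if degenerate:
        rho_s = rho_p = 0.0
    else:
        rho_s = float(stats.spearmanr(extent, thalf).statistic)
        rho_p = float(stats.pearsonr(extent, thalf).statistic)
    return DecayFit(
        delta_t_hat=None,
        correlation_spearman=rho_s,
        correlation_pearson=rho_p,
        n_genes=len(frame),
        residual_sd=None,
        fit_mode=None,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Offset regression
# ---------------------------------------------------------------------------


def estimate_delta_time_decay(
    fc: FoldChangeTable,
    hl: HalfLifeTable,
    classes: GeneClass,
    fit_mode: Literal["through-origin", "free-intercept"] = "through-origin",
    robust: bool = False,
    induction_threshold: float = INDUCTION_THRESHOLD_LOG2,
    detection_floor: float = DETECTION_FLOOR,
) -> DecayFit:
    """Estimate the developmental offset dt from maternal decay kinetics.

    Regresses log2 FC on x = 1/t_half over maternal genes; under pure decay
    the relation is linear with slope -dt, so ``delta_t_hat = -slope``. The
    through-origin default reflects that FC must vanish at dt = 0; the
    free-intercept mode absorbs residual normalization offsets in real data.
    ``robust`` swaps least squares for median-based slopes (median of
    per-gene ratios through the origin, Siegel repeated medians otherwise).
    When the fold-change table carries condition means, genes below
    ``detection_floor`` in either condition are excluded (their ratios are
    pseudocount-saturated); set the floor to 0 to disable.
    """
    frame = _maternal_decay_frame(fc, hl, classes)
    n_low = 0
    if detection_floor > 0 and fc.mean_a is not None and fc.mean_b is not None:
        detected = (fc.mean_a.reindex(frame.index) >= detection_floor) & (
            fc.mean_b.reindex(frame.index) >= detection_floor
        )
        n_low = int((~detected).sum())
        frame = frame.loc[detected]
    induced = frame["log2fc"] > induction_threshold
    n_excluded = int(induced.sum())
    frame = frame.loc[~induced]
    if len(frame) < MIN_GENES:
        raise ValidationError(
            f"only {len(frame)} maternal genes left after excluding "
            f"{n_excluded} induced and {n_low} undetected genes (need >= {MIN_GENES})"
        )
    x = 1.0 / frame["halflife"].to_numpy()
    y = frame["log2fc"].to_numpy()

    if fit_mode == "through-origin":
        if robust:
            slope = float(np.median(y / x))
        else:
            slope = float((x @ y) / (x @ x))
        resid = y - slope * x
    elif fit_mode == "free-intercept":
        if robust:
            slope, intercept = stats.siegelslopes(y, x)
            slope, intercept = float(slope), float(intercept)
        else:
            slope, intercept = np.polyfit(x, y, 1)
            slope, intercept = float(slope), float(intercept)
        resid = y - (slope * x + intercept)
    else:
        raise ValueError(f"unknown fit_mode {fit_mode!r}")

    corr = halflife_correlation(fc, hl, classes)
    return DecayFit(
        delta_t_hat=-slope,
        correlation_spearman=corr.correlation_spearman,
        correlation_pearson=corr.correlation_pearson,
        n_genes=len(frame),
        residual_sd=float(resid.std(ddof=1)) if len(resid) > 1 else 0.0,
        fit_mode=fit_mode,
        n_excluded_induced=n_excluded,
        n_excluded_low=n_low,
        degenerate=corr.degenerate,
    )
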