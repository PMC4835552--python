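"""Mapping query transcriptomes onto a reference developmental time-course.

A query embryo transcriptome is staged by finding the reference stage whose
expression profile it most resembles over the ruler genes (monotonically
decreasing maternal transcripts). The default similarity is the Spearman
rank correlation of log2-transformed abundances, which is invariant to
per-sample scale; a banded-overlap alternative (fraction of ruler genes
whose query/reference ratio falls within a 2-fold band around the per-stage
median ratio) is provided as a closer reading of "highest overlap" mapping.

The discrete best stage is always reported. A continuous developmental time
can additionally be interpolated, either by densifying the reference in time
(geometric interpolation of stage profiles on a fine minute grid -- exact
for first-order maternal decay, whose log-abundance is linear in time) or by
a 3-point parabola through the similarity peak. Stage differences between
two samples convert directly to minutes via the stage->time table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ReferenceTimecourse, ValidationError
from .ruler import RulerSet

MIN_SHARED_RULER = 10
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class StageEstimate:
    """Result of mapping one query (or replicate set) onto the reference."""

    similarities: np.ndarray  # one value per reference stage
    stage_labels: tuple[str, ...]
    stage_times: np.ndarray
    best_index: int
    interp_time: float
    bootstrap_sd: float | None = None
    method_params: dict = field(default_factory=dict)
    replicates: list["StageEstimate"] | None = None

    @property
    def best_stage(self) -> str:
        return self.stage_labels[self.best_index]

    @property
    def best_stage_time(self) -> float:
        return float(self.stage_times[self.best_index])

    def same_reference(self, other: "StageEstimate") -> bool:
        return self.stage_labels == other.stage_labels and np.array_equal(
            self.stage_times, other.stage_times
        )


@dataclass
class DeltaTimeEstimate:
    """Signed developmental offset between two samples, B minus A, minutes."""

    delta_t: float
    method: Literal["stage-mapping", "decay-regression"]
    components: tuple = ()


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_to_reference(
    query: ExpressionMatrix,
    reference: ReferenceTimecourse,
    ruler: RulerSet,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Rescale each query sample onto the reference abundance scale.

    The per-sample factor is the median, over ruler genes, of the ratio of
    first-reference-stage expression to query expression (maternal-gene
    anchoring: ruler transcripts are already deposited at the start of the
    reference, so their reference-start levels provide a scale that does not
    depend on zygotic activation). Zero query rows are excluded from the
    median. Returns the rescaled matrix and the factors applied.
    """
    shared = [g for g in ruler.genes if g in query.gene_ids and g in reference.gene_ids]
    if len(shared) < MIN_SHARED_RULER:
        raise ValidationError(
            f"only {len(shared)} ruler genes shared between query and reference "
            f"(need >= {MIN_SHARED_RULER})"
        )
    ref_first = reference.matrix.values.loc[shared].iloc[:, 0].to_numpy()
    factors = {}
    scaled = query.values.copy()
    for sample in query.sample_ids:
        q = query.values.loc[shared, sample].to_numpy()
        ok = (q > 0) & (ref_first > 0)
        if not ok.any():
            raise ValidationError(
                f"sample {sample!r}: no positive ruler genes to normalize on"
            )
        factor = float(np.median(ref_first[ok] / q[ok]))
        factors[sample] = factor
        scaled[sample] = scaled[sample] * factor
    return (
        ExpressionMatrix(scaled, query.unit_tag),
        pd.Series(factors, name="scale_factor"),
    )


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------


def _log2p(x: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.log2(x + pseudocount)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def _pearson_vec_mat(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``v`` with each column of ``m``."""
    vc = v - v.mean()
    mc = m - m.mean(axis=0, keepdims=True)
    v_ss = float(vc @ vc)
    m_ss = (mc * mc).sum(axis=0)
    if v_ss == 0:
        raise ValidationError("constant profile: zero rank variance in query")
    if (m_ss == 0).any():
        raise ValidationError("constant profile: zero rank variance in reference stage")
    return (vc @ mc) / np.sqrt(v_ss * m_ss)


def _similarity_curve(
    q_log: np.ndarray,
    ref_log: np.ndarray,
    metric: str,
    band_log2: float = 1.0,
) -> np.ndarray:
    """Similarity of one query profile to each column of a log2 reference."""
    if metric == "spearman":
        return _pearson_vec_mat(stats.rankdata(q_log), _rank_columns(ref_log))
    if metric == "overlap":
        diff = q_log[:, None] - ref_log
        centered = diff - np.median(diff, axis=0, keepdims=True)
        return (np.abs(centered) <= band_log2).mean(axis=0)
    raise ValueError(f"unknown similarity metric {metric!r}")


def stage_similarity(
    query_profile: pd.Series,
    reference: ReferenceTimecourse,
    ruler: RulerSet,
    metric: Literal["spearman", "overlap"] = "spearman",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Similarity of one query expression profile to each reference stage.

    Computed over ruler genes on log2(x + pseudocount) values. ``spearman``
    is the scale-free default; ``overlap`` is the fraction of ruler genes
    within a 2-fold band around the per-stage median query/reference ratio.
    """
    shared = [
        g for g in ruler.genes if g in query_profile.index and g in reference.gene_ids
    ]
    if not shared:
        raise ValidationError("no ruler genes shared with query profile")
    q_log = _log2p(query_profile.loc[shared].to_numpy(dtype=float), pseudocount)
    ref_log = _log2p(reference.matrix.values.loc[shared].to_numpy(), pseudocount)
    return _similarity_curve(q_log, ref_log, metric)


# ---------------------------------------------------------------------------
# Stage estimation and interpolation
# ---------------------------------------------------------------------------


def _argmax_earliest(values: np.ndarray, atol: float = 1e-12) -> int:
    """Index of the maximum; ties (within atol) resolve to the earliest
    stage, because maternal rulers lose resolution late in the time-course."""
    best = values.max()
    return int(np.nonzero(values >= best - atol)[0][0])


def _parabola_vertex(t: np.ndarray, s: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three (t, s) points."""
    coeffs = np.polyfit(t, s, 2)
    a, b = coeffs[0], coeffs[1]
    if a >= 0:  # no interior maximum; fall back to the middle point
        return float(t[1])
    return float(np.clip(-b / (2 * a), t[0], t[2]))


def _dense_reference_log(
    reference: ReferenceTimecourse,
    genes: Sequence[str],
    pseudocount: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Log2 reference profiles geometrically interpolated on a fine grid.

    Linear interpolation in log2 space is exact for first-order decay, whose
    log-abundance is linear in time, so the densified reference reproduces
    the expected maternal profile at any time inside the span.
    """
    times = reference.stage_times
    grid = np.arange(times[0], times[-1] + step / 2, step)
    grid[-1] = min(grid[-1], times[-1])
    ref_log = _log2p(reference.matrix.values.loc[list(genes)].to_numpy(), pseudocount)
    # vectorized piecewise-linear interpolation per gene row
    dense = np.empty((ref_log.shape[0], len(grid)))
    idx = np.clip(np.searchsorted(times, grid, side="right") - 1, 0, len(times) - 2)
    t0, t1 = times[idx], times[idx + 1]
    w = (grid - t0) / (t1 - t0)
    dense = ref_log[:, idx] * (1 - w) + ref_log[:, idx + 1] * w
    return grid, dense


def estimate_stage(
    query: ExpressionMatrix | pd.Series,
    reference: ReferenceTimecourse,
    ruler: RulerSet,
    interpolate: bool = False,
    metric: Literal["spearman", "overlap"] = "spearman",
    interp_method: Literal["dense", "parabola"] = "dense",
    interp_step: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> StageEstimate:
    """Map a query onto the reference time-course.

    The best stage is the argmax of per-stage similarity (ties break to the
    earliest stage). With ``interpolate`` a continuous time is also
    estimated: ``dense`` re-runs the similarity on a geometrically
    densified reference (grid spacing ``interp_step`` minutes), ``parabola``
    fits a 3-point quadratic through the similarity peak. A replicate matrix
    is estimated per column and summarized by the median; per-replicate
    estimates are kept on the result.
    """
    params = dict(
        metric=metric,
        interpolate=interpolate,
        interp_method=interp_method,
        interp_step=interp_step,
        pseudocount=pseudocount,
        n_ruler=len(ruler),
    )
    if isinstance(query, ExpressionMatrix) and query.values.shape[1] > 1:
        reps = [
            estimate_stage(
                query.values[c], reference, ruler, interpolate, metric,
                interp_method, interp_step, pseudocount,
            )
            for c in query.sample_ids
        ]
        sims = np.median([r.similarities for r in reps], axis=0)
        best = _argmax_earliest(sims)
        interp_time = float(np.median([r.interp_time for r in reps]))
        return StageEstimate(
            sims, reference.stage_labels, reference.stage_times.copy(),
            best, interp_time, method_params=params, replicates=reps,
        )
    profile = query.mean_profile() if isinstance(query, ExpressionMatrix) else query
    sims = stage_similarity(profile, reference, ruler, metric, pseudocount)
    best = _argmax_earliest(sims)
    times = reference.stage_times
    interp_time = float(times[best])
    if interpolate:
        if interp_method == "parabola":
            if 0 < best < len(times) - 1:
                interp_time = _parabola_vertex(
                    times[best - 1 : best + 2], sims[best - 1 : best + 2]
                )
        elif interp_method == "dense":
            shared = [
                g for g in ruler.genes if g in profile.index and g in reference.gene_ids
            ]
            grid, dense = _dense_reference_log(
                reference, shared, pseudocount, interp_step
            )
            q_log = _log2p(profile.loc[shared].to_numpy(dtype=float), pseudocount)
            curve = _similarity_curve(q_log, dense, metric)
            interp_time = float(grid[_argmax_earliest(curve)])
        else:
            raise ValueError(f"unknown interp_method {interp_method!r}")
        interp_time = float(np.clip(interp_time, times[0], times[-1]))
    return StageEstimate(
        sims, reference.stage_labels, times.copy(), best, interp_time,
        method_params=params,
    )


def delta_time(est_a: StageEstimate, est_b: StageEstimate) -> DeltaTimeEstimate:
    """Developmental offset in minutes, B minus A (antisymmetric)."""
    if not est_a.same_reference(est_b):
        raise ValidationError("stage estimates come from different references")
    return DeltaTimeEstimate(
        delta_t=float(est_b.interp_time - est_a.interp_time),
        method="stage-mapping",
        components=(est_a, est_b),
    )


def stage_matched_profile(
    reference: ReferenceTimecourse, est: StageEstimate
) -> pd.Series:
    """Reference expression profile (all genes) at a query's estimated stage.

    Without interpolation this is the best-stage column verbatim; with
    interpolation, the geometric (log-linear) interpolation between the
    flanking stage columns at ``interp_time``. Times outside the reference
    span are clamped with a warning.
    """
    t = est.interp_time
    times = reference.stage_times
    if t < times[0] or t > times[-1]:
        warnings.warn(
            f"interp_time {t:g} outside reference span "
            f"[{times[0]:g}, {times[-1]:g}]; clamping",
            stacklevel=2,
        )
        t = float(np.clip(t, times[0], times[-1]))
    vals = reference.matrix.values
    exact = np.nonzero(np.isclose(times, t))[0]
    if not est.method_params.get("interpolate", False) or len(exact):
        col = int(exact[0]) if len(exact) else est.best_index
        return vals.iloc[:, col].copy()
    k = int(np.searchsorted(times, t, side="right") - 1)
    k = min(k, len(times) - 2)
    w = (t - times[k]) / (times[k + 1] - times[k])
    a, b = vals.iloc[:, k].to_numpy(), vals.iloc[:, k + 1].to_numpy()
    # geometric interpolation; zeros propagate to zero as a**(1-w) * b**w
    out = np.where((a > 0) & (b > 0), a ** (1 - w) * b**w, 0.0)
    return pd.Series(out, index=vals.index, name=f"matched@{t:g}min")


def bootstrap_stage(
    query: ExpressionMatrix | pd.Series,
    reference: ReferenceTimecourse,
    ruler: RulerSet,
    n_boot: int = 200,
    seed: int = 0,
    **estimate_kwargs,
) -> tuple[float, np.ndarray]:
    """Gene-resampling bootstrap of the interpolated staging time.

    Ruler genes are resampled with replacement ``n_boot`` times and the
    stage re-estimated; returns the standard deviation of ``interp_time``
    and the bootstrap replicate times. Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable sd")
    profile = query.mean_profile() if isinstance(query, ExpressionMatrix) else query
    shared = [g for g in ruler.genes if g in profile.index and g in reference.gene_ids]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    times = np.empty(n_boot)
    estimate_kwargs.setdefault("interpolate", True)
    for b in range(n_boot):
        idx = rng.integers(0, len(shared), size=len(shared))
        boot_genes = tuple(shared[i] for i in idx)
        # duplicate picks get suffixed ids so the containers stay valid
        uniq = [f"{g}__b{j}" for j, g in enumerate(boot_genes)]
        ref_vals = reference.matrix.values.loc[list(boot_genes)].copy()
        ref_vals.index = uniq
        boot_ref = ReferenceTimecourse(
            ExpressionMatrix(ref_vals, reference.matrix.unit_tag),
            reference.stage_labels,
            reference.stage_times.copy(),
        )
        boot_profile = pd.Series(
            profile.loc[list(boot_genes)].to_numpy(), index=uniq
        )
        boot_ruler = RulerSet(tuple(uniq), ruler.params, provenance="bootstrap")
        est = estimate_stage(boot_profile, boot_ref, boot_ruler, **estimate_kwargs)
        times[b] = est.interp_time
    return float(times.std(ddof=1)), times
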