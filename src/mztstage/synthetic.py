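"""Synthetic maternal-to-zygotic-transition (MZT) expression dynamics.

The generator emulates the statistical structure the staging analysis
assumes: a reference time-course over nuclear-cycle-indexed stages, maternal
transcripts decaying first-order with gene-specific half-lives, zygotic
transcripts switching on sigmoidally around an activation onset, a flat
"stable" housekeeping class, and replicate query samples drawn at hidden
true times under multiplicative log-normal noise (optionally Poisson counts
with library-size scaling).

Noise-free expected abundances are closed-form:

* maternal:  m_g(t) = m_g(0) * 2**(-t / t_half_g)
* zygotic:   z_g(t) = z_max_g / (1 + exp(-(t - t_on) / tau))
* stable:    constant

so every downstream estimator can be checked against exact algebra.

All randomness flows from explicit integer seeds; identical (config, seed)
pairs give bit-identical outputs.
"""

from __future__ import annotations

import functools
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix, GeneClass, HalfLifeTable, ReferenceTimecourse

#: Default stage grid: 8 stages spanning nuclear cycles 10 through 14D,
#: minutes after egg deposition. A documented placeholder with realistic
#: spacing (cycles shorten early, cycle 14 sub-stages stretch late); real
#: analyses supply their own stage table.
DEFAULT_STAGE_TIMES = (60.0, 80.0, 95.0, 105.0, 115.0, 130.0, 150.0, 170.0)
DEFAULT_STAGE_LABELS = ("c10", "c11", "c12", "c13", "c14A", "c14B", "c14C", "c14D")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic MZT generator.

    Half-lives and baseline expression are log2-normal across genes:
    ``log2(t_half) ~ Normal(log2(halflife_log2mean), halflife_log2sd)`` and
    analogously for baselines. ``noise_dispersion`` is the standard
    deviation of per-observation log2 multiplicative noise.
    """

    n_maternal: int = 200
    n_zygotic: int = 100
    n_stable: int = 50
    halflife_log2mean: float = 60.0  # minutes (geometric mean across genes)
    halflife_log2sd: float = 0.8
    onset_time: float = 130.0  # minutes AED; zygotic activation midpoint
    activation_scale: float = 15.0  # minutes; logistic time-scale tau
    baseline_expr_log2mean: float = 5.0  # log2 abundance (RPKM-like)
    baseline_expr_log2sd: float = 2.0
    noise_dispersion: float = 0.25  # sd of log2 multiplicative noise
    reference_times: tuple[float, ...] = DEFAULT_STAGE_TIMES
    stage_labels: tuple[str, ...] = DEFAULT_STAGE_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_times", tuple(float(t) for t in self.reference_times))
        object.__setattr__(self, "stage_labels", tuple(str(s) for s in self.stage_labels))
        for name in ("n_maternal", "n_zygotic", "n_stable"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.activation_scale <= 0:
            raise ValueError("activation_scale must be > 0")
        if self.halflife_log2mean <= 0:
            raise ValueError("halflife_log2mean must be > 0 minutes")
        if self.halflife_log2sd < 0 or self.baseline_expr_log2sd < 0:
            raise ValueError("log2 spreads must be >= 0")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        times = np.asarray(self.reference_times)
        if len(times) < 2 or not np.all(np.diff(times) > 0):
            raise ValueError("reference_times must be strictly increasing, length >= 2")
        if len(self.stage_labels) != len(times):
            raise ValueError("stage_labels and reference_times lengths differ")

    # -- flat key:value (YAML-compatible) persistence -----------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    true_times: pd.Series  # sample id -> minutes AED
    gene_class: pd.Series  # gene id -> {maternal, zygotic, stable}
    halflife: pd.Series  # maternal gene id -> minutes
    onset_time: float
    seed: int

    def __post_init__(self) -> None:
        bad = set(self.gene_class) - {"maternal", "zygotic", "stable"}
        if bad:
            raise ValueError(f"unknown gene classes in truth: {sorted(bad)}")
        hl = self.halflife.to_numpy(dtype=float)
        if not (np.isfinite(hl).all() and (hl > 0).all()):
            raise ValueError("every maternal half-life must be finite and positive")

    def to_gene_class(self, source_tag: str = "simulation") -> GeneClass:
        """Project the 3-way truth onto the analysis labelling.

        Stable housekeeping genes have no maternal/zygotic identity and map
        to ``unclassified``.
        """
        labels = self.gene_class.replace({"stable": "unclassified"})
        return GeneClass(labels.copy(), source_tag)

    def to_halflife_table(self) -> HalfLifeTable:
        return HalfLifeTable(self.halflife.copy())

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "gene_class": self.gene_class,
                "halflife_min": self.halflife.reindex(self.gene_class.index),
            }
        )
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene-table realization (deterministic in config.seed)
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=32)
def _realize_genes(config: SimulationConfig) -> pd.DataFrame:
    """Draw the per-gene parameter table implied by a config.

    Columns: ``gene_class``, ``baseline`` (m(0), z_max or constant level) and
    ``halflife`` (minutes, NaN outside the maternal class). Seeded entirely
    by ``config.seed`` so reference and query simulations from the same
    config share one gene universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    classes = (
        ["maternal"] * config.n_maternal
        + ["zygotic"] * config.n_zygotic
        + ["stable"] * config.n_stable
    )
    ids = (
        [f"mat{i:04d}" for i in range(1, config.n_maternal + 1)]
        + [f"zyg{i:04d}" for i in range(1, config.n_zygotic + 1)]
        + [f"stb{i:04d}" for i in range(1, config.n_stable + 1)]
    )
    n = len(ids)
    baseline = 2.0 ** rng.normal(
        config.baseline_expr_log2mean, config.baseline_expr_log2sd, size=n
    )
    halflife = np.full(n, np.nan)
    halflife[: config.n_maternal] = 2.0 ** rng.normal(
        np.log2(config.halflife_log2mean), config.halflife_log2sd, size=config.n_maternal
    )
    df = pd.DataFrame(
        {"gene_class": classes, "baseline": baseline, "halflife": halflife}, index=ids
    )
    df.index.name = "gene_id"
    return df


def gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Public copy of the realized per-gene parameter table."""
    return _realize_genes(config).copy()


def _truth(config: SimulationConfig, true_times: pd.Series, seed: int) -> SimTruth:
    genes = _realize_genes(config)
    return SimTruth(
        true_times=true_times,
        gene_class=genes["gene_class"].copy(),
        halflife=genes.loc[genes["gene_class"] == "maternal", "halflife"].copy(),
        onset_time=config.onset_time,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Expected (noise-free) expression
# ---------------------------------------------------------------------------


def _expected_matrix(config: SimulationConfig, times: np.ndarray) -> np.ndarray:
    """Noise-free expected abundance, genes x len(times)."""
    genes = _realize_genes(config)
    t = np.asarray(times, dtype=float)[None, :]
    base = genes["baseline"].to_numpy()[:, None]
    out = np.empty((len(genes), t.shape[1]))
    is_mat = (genes["gene_class"] == "maternal").to_numpy()
    is_zyg = (genes["gene_class"] == "zygotic").to_numpy()
    is_stb = (genes["gene_class"] == "stable").to_numpy()
    thalf = genes["halflife"].to_numpy()[:, None]
    with np.errstate(invalid="ignore"):
        out[:] = base * 2.0 ** (-t / thalf)
    z = (t - config.onset_time) / config.activation_scale
    out[is_zyg] = base[is_zyg] / (1.0 + np.exp(-z))
    out[is_stb] = np.broadcast_to(base[is_stb], out[is_stb].shape)
    return out


def expected_expression(config: SimulationConfig, gene: str, t: float) -> float:
    """Noise-free mean abundance of ``gene`` at time ``t`` (minutes AED)."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    genes = _realize_genes(config)
    if gene not in genes.index:
        raise KeyError(f"unknown gene id {gene!r}")
    pos = genes.index.get_loc(gene)
    return float(_expected_matrix(config, np.array([t]))[pos, 0])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _apply_noise(
    mean: np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
    count_mode: bool = False,
    library_size: float = 1e6,
) -> np.ndarray:
    if count_mode:
        noisy = mean * 2.0 ** rng.normal(0.0, dispersion, size=mean.shape) if dispersion > 0 else mean
        total = noisy.sum(axis=0, keepdims=True)
        scale = np.where(total > 0, library_size / total, 0.0)
        return rng.poisson(noisy * scale).astype(float)
    if dispersion == 0:
        return mean.copy()
    return mean * 2.0 ** rng.normal(0.0, dispersion, size=mean.shape)


def simulate_reference(
    config: SimulationConfig, noise: bool = False
) -> tuple[ReferenceTimecourse, SimTruth]:
    """Simulate the reference time-course: one column per reference time.

    Noise-free by default (a reference is usually treated as the ground
    truth the queries are mapped onto); pass ``noise=True`` to perturb each
    column with the configured multiplicative noise.
    """
    times = np.asarray(config.reference_times)
    mean = _expected_matrix(config, times)
    if noise:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
        values = _apply_noise(mean, config.noise_dispersion, rng)
    else:
        values = mean
    genes = _realize_genes(config)
    df = pd.DataFrame(values, index=genes.index, columns=list(config.stage_labels))
    matrix = ExpressionMatrix(df, "abundance")
    reference = ReferenceTimecourse(matrix, config.stage_labels, times)
    truth = _truth(
        config,
        pd.Series(times, index=list(config.stage_labels), dtype=float),
        config.seed,
    )
    return reference, truth


def simulate_query(
    config: SimulationConfig,
    true_time: float,
    n_replicates: int = 1,
    seed: int = 0,
    count_mode: bool = False,
    library_size: float = 1e6,
    effect_log2: pd.Series | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate replicate query transcriptomes at a hidden true time.

    Each replicate is the noise-free expectation at ``true_time`` perturbed
    by multiplicative log-normal noise with sd ``config.noise_dispersion``
    (log2 units), or Poisson counts with library-size scaling when
    ``count_mode`` is set. ``effect_log2`` plants a per-gene condition
    effect (log2 units, added to the mean before noise) for recovery tests.
    """
    if true_time < 0:
        raise ValueError(f"true_time must be >= 0, got {true_time}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    genes = _realize_genes(config)
    mean = _expected_matrix(config, np.array([true_time]))[:, 0]
    if effect_log2 is not None:
        shift = effect_log2.reindex(genes.index).fillna(0.0).to_numpy()
        mean = mean * 2.0 ** shift
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    cols = _apply_noise(
        np.repeat(mean[:, None], n_replicates, axis=1),
        config.noise_dispersion,
        rng,
        count_mode=count_mode,
        library_size=library_size,
    )
    sample_ids = [f"q{true_time:g}_r{i}" for i in range(1, n_replicates + 1)]
    df = pd.DataFrame(cols, index=genes.index, columns=sample_ids)
    matrix = ExpressionMatrix(df, "counts" if count_mode else "abundance")
    truth = _truth(
        config, pd.Series(float(true_time), index=sample_ids, dtype=float), seed
    )
    return matrix, truth
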