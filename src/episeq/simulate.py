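"""Synthetic DE tables, phase gene sets and proliferation counts.

The generator emulates the summary level at which the real analyses operate:
per-gene log2 fold changes with adjusted P values, not read counts.  Two
perturbations share a planted regulon — the "downstream" table carries the
full per-gene effects beta_g ~ Normal(0, effect_sd), the "upstream" table a
fraction ``attenuation_f`` of them — so that regressing upstream on
downstream fold changes over the regulon recovers ``attenuation_f`` as the
slope.  Non-regulon genes are pure measurement noise in both tables.

Noise placement (``noise_mode``):

* ``response_only`` (default) — measurement noise on the upstream (response)
  table everywhere, and on the downstream (predictor) table only for
  non-regulon genes; regulon predictor values are the exact effects.  OLS of
  upstream on downstream over the regulon is then unbiased for
  ``attenuation_f``, which is what CI-coverage recovery tests require.
* ``both`` — noise on every value of both tables.  Realistic, but OLS is
  attenuated below ``attenuation_f`` by the predictor's reliability ratio;
  use for null-calibration and power studies, not slope recovery.

Adjusted P values go through the same BH implementation as the analysis path
(one source of truth): raw two-sided normal-tail p from
z = log2fc / (noise_sd / sqrt(n_reps_per_group)).  The default
``n_reps_per_group = 1`` makes the null z exactly standard normal given the
table's own noise; larger values emulate replicate averaging upstream of the
summary and sharpen significance relative to the table's noise.

Seeding: one global seed fans out to fixed, documented substreams via
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with k = 0 regulon
membership and effects, 1 downstream noise, 2 upstream noise, 3 base-mean
expression, 4 phase gene sets, 5 EdU counts.  Adding a new stream takes the
next integer and never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .prolif import EdUCountTable
from .setstats import adjust_bh
from .tables import DETable, GeneSetCollection

_STREAM_EFFECTS = 0
_STREAM_DOWN_NOISE = 1
_STREAM_UP_NOISE = 2
_STREAM_BASE_MEAN = 3
_STREAM_PHASE_SETS = 4
_STREAM_EDU = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SimParams:
    """Parameters of a paired-perturbation simulation."""

    n_genes: int = 2000
    regulon_fraction: float = 0.25
    attenuation_f: float = 0.43
    effect_sd: float = 1.0
    noise_sd: float = 0.2
    n_reps_per_group: int = 1
    seed: int = 0
    noise_mode: str = "response_only"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError(f"n_genes must be positive, got {self.n_genes}")
        if not 0 < self.regulon_fraction < 1:
            raise ParameterError(
                f"regulon_fraction must be in (0, 1), got {self.regulon_fraction}"
            )
        if not 0 < self.attenuation_f <= 1:
            raise ParameterError(
                f"attenuation_f must be in (0, 1], got {self.attenuation_f}"
            )
        if self.effect_sd <= 0:
            raise ParameterError(f"effect_sd must be > 0, got {self.effect_sd}")
        if self.noise_sd <= 0:
            raise ParameterError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_reps_per_group < 1:
            raise ParameterError(
                f"n_reps_per_group must be positive, got {self.n_reps_per_group}"
            )
        if self.seed < 0:
            raise ParameterError(f"seed must be non-negative, got {self.seed}")
        if self.regulon_fraction * self.n_genes < 1:
            raise ParameterError("regulon_fraction * n_genes must be >= 1")
        if self.noise_mode not in ("response_only", "both"):
            raise ParameterError(f"unknown noise_mode {self.noise_mode!r}")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth of one simulation."""

    regulon_genes: frozenset[str]
    per_gene_effect: Mapping[str, float] = field(default_factory=dict)
    attenuation_f: float = 1.0

    def __post_init__(self) -> None:
        if set(self.per_gene_effect) != set(self.regulon_genes):
            raise ParameterError("per_gene_effect must be keyed exactly by regulon_genes")


def gene_ids(n_genes: int) -> list[str]:
    """Stable zero-padded gene ids: g000001 ... (lexicographic = numeric)."""
    width = max(6, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def _de_table(
    genes: list[str],
    log2fc: np.ndarray,
    base_mean: np.ndarray,
    noise_sd: float,
    n_reps: int,
    label: str,
) -> DETable:
    # adjusted P from the z-statistic of the observed log2fc at the known
    # per-dataset noise level, BH-corrected with the analysis-path routine
    se = noise_sd / np.sqrt(n_reps)
    z = log2fc / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    padj = adjust_bh(p_raw)
    df = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "padj": padj, "base_mean": base_mean}
    )
    return DETable(df, label=label)


def generate_paired_perturbation(
    params: SimParams,
) -> tuple[DETable, DETable, SimTruth]:
    """Simulate downstream and upstream DE tables sharing a planted regulon.

    Returns ``(downstream, upstream, truth)`` over the same gene universe.
    Downstream regulon genes carry effects beta_g; upstream regulon genes
    carry ``attenuation_f * beta_g``; non-regulon genes are noise.
    """
    genes = gene_ids(params.n_genes)
    n_reg = int(round(params.regulon_fraction * params.n_genes))

    rng_eff = _rng(params.seed, _STREAM_EFFECTS)
    reg_idx = rng_eff.choice(params.n_genes, size=n_reg, replace=False)
    effects = rng_eff.normal(0.0, params.effect_sd, size=n_reg)

    beta = np.zeros(params.n_genes)
    beta[reg_idx] = effects
    is_reg = np.zeros(params.n_genes, dtype=bool)
    is_reg[reg_idx] = True

    noise_down = _rng(params.seed, _STREAM_DOWN_NOISE).normal(
        0.0, params.noise_sd, size=params.n_genes
    )
    noise_up = _rng(params.seed, _STREAM_UP_NOISE).normal(
        0.0, params.noise_sd, size=params.n_genes
    )
    if params.noise_mode == "response_only":
        noise_down = np.where(is_reg, 0.0, noise_down)

    down_lfc = beta + noise_down
    up_lfc = params.attenuation_f * beta + noise_up

    base_mean = np.exp(_rng(params.seed, _STREAM_BASE_MEAN).normal(4.0, 1.5, params.n_genes))

    down = _de_table(genes, down_lfc, base_mean, params.noise_sd,
                     params.n_reps_per_group, "downstream")
    up = _de_table(genes, up_lfc, base_mean, params.noise_sd,
                   params.n_reps_per_group, "upstream")
    truth = SimTruth(
        regulon_genes=frozenset(genes[i] for i in reg_idx),
        per_gene_effect={genes[i]: float(b) for i, b in zip(reg_idx, effects)},
        attenuation_f=params.attenuation_f,
    )
    return down, up, truth


def generate_independent_pair(
    n_genes: int, noise_sd: float = 0.2, n_reps_per_group: int = 1, seed: int = 0
) -> tuple[DETable, DETable]:
    """Two pure-noise DE tables with no shared signal (null calibration).

    Equivalent to removing the regulon signal entirely: every gene in both
    tables is independent measurement noise.
    """
    if n_genes < 1:
        raise ParameterError(f"n_genes must be positive, got {n_genes}")
    if noise_sd <= 0:
        raise ParameterError(f"noise_sd must be > 0, got {noise_sd}")
    genes = gene_ids(n_genes)
    a = _rng(seed, _STREAM_DOWN_NOISE).normal(0.0, noise_sd, n_genes)
    b = _rng(seed, _STREAM_UP_NOISE).normal(0.0, noise_sd, n_genes)
    base_mean = np.exp(_rng(seed, _STREAM_BASE_MEAN).normal(4.0, 1.5, n_genes))
    return (
        _de_table(genes, a, base_mean, noise_sd, n_reps_per_group, "downstream"),
        _de_table(genes, b, base_mean, noise_sd, n_reps_per_group, "upstream"),
    )


def generate_phase_gene_sets(
    n_phases: int,
    genes_per_phase: int,
    shift,
    universe: list[str],
    seed: int = 0,
    phase_names: list[str] | None = None,
) -> tuple[GeneSetCollection, dict[str, float]]:
    """Disjoint phase-labeled gene sets with planted rank shifts.

    ``shift`` is a scalar (applied to every phase) or a sequence of length
    ``n_phases``.  The shifts are only recorded here; apply them to a DE
    table with :func:`apply_phase_shifts`.
    """
    if n_phases < 1 or genes_per_phase < 1:
        raise ParameterError("n_phases and genes_per_phase must be positive")
    if n_phases * genes_per_phase > len(universe):
        raise ParameterError(
            f"requested {n_phases}x{genes_per_phase} genes exceed universe of "
            f"{len(universe)}"
        )
    shifts = np.broadcast_to(np.asarray(shift, dtype=float), (n_phases,))
    if phase_names is None:
        canonical = ["G1/S", "S", "G2", "M", "M/G1"]
        phase_names = (
            canonical[:n_phases]
            if n_phases <= len(canonical)
            else [f"phase{i + 1}" for i in range(n_phases)]
        )
    rng = _rng(seed, _STREAM_PHASE_SETS)
    chosen = rng.choice(len(universe), size=n_phases * genes_per_phase, replace=False)
    sets: dict[str, set[str]] = {}
    shift_map: dict[str, float] = {}
    for p, name in enumerate(phase_names):
        idx = chosen[p * genes_per_phase : (p + 1) * genes_per_phase]
        sets[name] = {universe[i] for i in idx}
        shift_map[name] = float(shifts[p])
    meta = {name: {"phase": name, "source": "synthetic"} for name in sets}
    return GeneSetCollection(sets, meta), shift_map


def apply_phase_shifts(
    table: DETable, phases: GeneSetCollection, shift_map: Mapping[str, float]
) -> DETable:
    """Return a copy of ``table`` with each phase's shift added to its genes."""
    df = table.data.copy()
    lfc = df["log2fc"].to_numpy(dtype=float).copy()
    pos = {g: i for i, g in enumerate(df["gene"])}
    for name, delta in shift_map.items():
        for g in phases[name]:
            if g in pos:
                lfc[pos[g]] += delta
    df["log2fc"] = lfc
    return DETable(df, label=table.label)


def generate_edu_counts(
    p_by_group: Mapping[str, float], n_by_group: Mapping[str, int], seed: int = 0
) -> EdUCountTable:
    """Binomial EdU+ counts per genotype group; totals are preserved."""
    if set(p_by_group) != set(n_by_group):
        raise ParameterError("p_by_group and n_by_group must share the same groups")
    for g, p in p_by_group.items():
        if not 0 <= p <= 1:
            raise ParameterError(f"proportion for group {g!r} outside [0, 1]: {p}")
        if n_by_group[g] < 1:
            raise ParameterError(f"n for group {g!r} must be >= 1")
    rng = _rng(seed, _STREAM_EDU)
    groups = list(p_by_group)
    pos = [int(rng.binomial(n_by_group[g], p_by_group[g])) for g in groups]
    neg = [n_by_group[g] - k for g, k in zip(groups, pos)]
    return EdUCountTable(tuple(groups), tuple(pos), tuple(neg))
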