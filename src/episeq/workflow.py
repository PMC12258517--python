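"""End-to-end orchestration of a two-perturbation comparison.

``run_pair_analysis`` drives the full stage order — expression filter, merge
by gene, regulated-set classification, phase-rank enrichment, set overlaps,
bootstrap concordance, attenuation fit — and emits one structured report
(JSON plus TSV tables) whose provenance block records the config hash, seed
and the gene counts surviving each stage.  Given the same config and seed
the JSON report is byte-identical.

``run_recovery_suite`` is the simulation harness: for a grid of planted
attenuation values it measures slope bias, CI coverage, phase-enrichment
type-I rate and bootstrap-Z calibration, and writes them as one table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    attenuation_fit,
    bootstrap_null_concordance,
)
from .cyclephase import phase_enrichment
from .errors import EpiseqError, ParameterError
from .setstats import overlap_batch, set_fraction
from .simulate import (
    SimParams,
    generate_independent_pair,
    generate_paired_perturbation,
    generate_phase_gene_sets,
)
from .tables import (
    DETable,
    GeneSetCollection,
    classify_regulated,
    filter_expressed,
    merge_by_gene,
    read_de_table,
    read_tpm_matrix,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pair analysis.

    All thresholds the analyses rely on live here as explicit defaults —
    significance alpha 0.05, GO-style down-regulation fold-change cutoff 0.1,
    expression floor TPM >= 1 in >= 3 samples, 100,000 bootstrap draws —
    never hard-coded inside operations.
    """

    de_a: str
    de_b: str
    label_a: str = "A"
    label_b: str = "B"
    tpm_a: str | None = None
    tpm_b: str | None = None
    phase_sets: str | None = None  # GMT of cell-cycle phase sets
    annotation_sets: str | None = None  # GMT of extra sets (regulators, ...)
    select_by: str = "B"  # predictor dataset defining the dependent genes
    alpha: float = 0.05
    lfc_threshold: float = 0.0
    lfc_threshold_go: float = 0.1
    min_tpm: float = 1.0
    min_samples: int = 3
    n_iter: int = 100_000
    seed: int = 0
    universe_policy: str = "merged"  # universe for overlap tests
    outdir: str = "episeq_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_iter < 100:
            raise ParameterError(f"n_iter must be >= 100, got {self.n_iter}")
        if self.select_by not in (self.label_a, self.label_b):
            raise ParameterError(
                f"select_by={self.select_by!r} is neither label ({self.label_a!r}, "
                f"{self.label_b!r})"
            )
        if self.universe_policy not in ("merged", "union"):
            raise ParameterError(f"unknown universe_policy {self.universe_policy!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _phase_rows(results) -> list[dict]:
    return [
        {
            "phase": r.phase,
            "n_genes_tested": r.n_genes_tested,
            "median_rank": r.median_rank,
            "q1": r.iqr[0],
            "q3": r.iqr[1],
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
        }
        for r in results
    ]


def analyze_pair(
    table_a: DETable,
    table_b: DETable,
    *,
    phases: GeneSetCollection | None = None,
    annotations: GeneSetCollection | None = None,
    select_by: str | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 0.0,
    n_iter: int = 10_000,
    seed: int = 0,
    expressed_a: set[str] | None = None,
    expressed_b: set[str] | None = None,
) -> dict:
    """Full comparison of two DE tables already in memory.

    ``select_by`` names the predictor dataset: its padj < alpha genes are the
    dependent set for both the Spearman/bootstrap concordance and the
    attenuation slope (response ~ predictor).  Defaults to table_b's label.
    """
    label_a, label_b = table_a.label, table_b.label
    select_by = select_by or label_b
    if expressed_a is not None:
        table_a = DETable(
            table_a.data[table_a.data["gene"].isin(expressed_a)].reset_index(drop=True),
            label=label_a,
        )
    if expressed_b is not None:
        table_b = DETable(
            table_b.data[table_b.data["gene"].isin(expressed_b)].reset_index(drop=True),
            label=label_b,
        )

    merged = merge_by_gene(table_a, table_b)
    universe = merged.genes

    sets = {
        f"up_{label_a}": classify_regulated(table_a, "up", alpha, lfc_threshold),
        f"down_{label_a}": classify_regulated(table_a, "down", alpha, lfc_threshold),
        f"up_{label_b}": classify_regulated(table_b, "up", alpha, lfc_threshold),
        f"down_{label_b}": classify_regulated(table_b, "down", alpha, lfc_threshold),
    }

    report: dict = {
        "labels": {"a": label_a, "b": label_b, "select_by": select_by},
        "counts": {
            "n_a": len(table_a),
            "n_b": len(table_b),
            "n_merged": len(merged),
            **{k: len(v) for k, v in sets.items()},
        },
    }

    if phases is not None:
        report["phase_enrichment"] = {
            label_a: _phase_rows(phase_enrichment(table_a, phases)),
            label_b: _phase_rows(phase_enrichment(table_b, phases)),
        }

    pairs = [
        (sets[f"up_{label_a}"], sets[f"up_{label_b}"]),
        (sets[f"down_{label_a}"], sets[f"down_{label_b}"]),
    ]
    pair_names = [f"up_{label_a}~up_{label_b}", f"down_{label_a}~down_{label_b}"]
    if annotations is not None:
        for ann_name in annotations.names():
            ann = annotations[ann_name]
            pairs.append((sets[f"down_{label_a}"], ann))
            pair_names.append(f"down_{label_a}~{ann_name}")
            pairs.append((sets[f"down_{label_b}"], ann))
            pair_names.append(f"down_{label_b}~{ann_name}")
    overlaps = overlap_batch(pairs, universe)
    report["overlaps"] = [
        {
            "comparison": name,
            "n_universe": r.n_universe,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "n_overlap": r.n_overlap,
            "fold_enrichment": r.fold_enrichment,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
        }
        for name, r in zip(pair_names, overlaps)
    ]
    if annotations is not None:
        report["set_fractions"] = {}
        for ann_name in annotations.names():
            ann = annotations[ann_name]
            for sname in (f"up_{label_a}", f"up_{label_b}"):
                if sets[sname]:
                    frac, n_t, n_i = set_fraction(sets[sname], ann)
                    report["set_fractions"][f"{sname}~{ann_name}"] = {
                        "fraction": frac,
                        "n_target": n_t,
                        "n_overlap": n_i,
                    }

    predictor = select_by
    response = label_a if select_by == label_b else label_b
    padj_sel = merged.padj(predictor)
    selected = set(padj_sel.index[padj_sel < alpha])
    report["counts"]["n_selected"] = len(selected)
    if len(selected) >= 3 and len(selected) < len(universe):
        conc = bootstrap_null_concordance(merged, selected, n_iter=n_iter, seed=seed)
        fit = attenuation_fit(merged, selected, response=response, predictor=predictor)
        report["concordance"] = {
            "n_selected": conc.n_selected,
            "rho": conc.rho,
            "null_mean": conc.null_mean,
            "null_sd": conc.null_sd,
            "n_null_draws": conc.n_null_draws,
            "z_score": conc.z_score,
            "log_p_one_sided": conc.log_p_one_sided,
            "seed": conc.seed,
        }
        report["attenuation"] = {
            "response": response,
            "predictor": predictor,
            "beta0": fit.beta0,
            "beta_upstream": fit.beta_upstream,
            "ci95_lo": fit.ci95[0],
            "ci95_hi": fit.ci95[1],
            "n": fit.n,
            "r_squared": fit.r_squared,
        }
    else:
        report["concordance"] = None
        report["attenuation"] = None
        logger.warning(
            "dependent set of %d genes unusable for concordance/fit", len(selected)
        )
    return report


def run_pair_analysis(config: AnalysisConfig) -> dict:
    """File-based pair analysis; writes report.json and TSV tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        table_a = read_de_table(config.de_a, label=config.label_a)
        table_b = read_de_table(config.de_b, label=config.label_b)
        expressed_a = expressed_b = None
        if config.tpm_a:
            expressed_a = filter_expressed(
                read_tpm_matrix(config.tpm_a), config.min_tpm, config.min_samples
            )
        if config.tpm_b:
            expressed_b = filter_expressed(
                read_tpm_matrix(config.tpm_b), config.min_tpm, config.min_samples
            )
        phases = (
            GeneSetCollection.from_gmt(config.phase_sets) if config.phase_sets else None
        )
        annotations = (
            GeneSetCollection.from_gmt(config.annotation_sets)
            if config.annotation_sets
            else None
        )
        report = analyze_pair(
            table_a,
            table_b,
            phases=phases,
            annotations=annotations,
            select_by=config.select_by,
            alpha=config.alpha,
            lfc_threshold=config.lfc_threshold,
            n_iter=config.n_iter,
            seed=config.seed,
            expressed_a=expressed_a,
            expressed_b=expressed_b,
        )
        report["provenance"] = {
            "episeq_version": __version__,
            "config": dataclasses.asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
        }
        report_path = outdir / "report.json"
        report_path.write_text(report_json(report))
        written.append(report_path)
        if "phase_enrichment" in report:
            for label, rows in report["phase_enrichment"].items():
                p = outdir / f"phase_enrichment_{label}.tsv"
                pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
                written.append(p)
        p = outdir / "overlaps.tsv"
        pd.DataFrame(report["overlaps"]).to_csv(p, sep="\t", index=False)
        written.append(p)
        return report
    except EpiseqError:
        for p in written:  # partial outputs removed on stage failure
            p.unlink(missing_ok=True)
        raise


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys; reproducible bytes)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=True) + "\n"


def run_recovery_suite(
    f_grid: Sequence[float] = (0.34, 0.43, 1.0),
    n_reps: int = 200,
    *,
    n_genes: int = 2000,
    regulon_fraction: float = 0.25,
    effect_sd: float = 1.0,
    noise_sd: float = 0.2,
    n_iter_concord: int = 2000,
    null_set_size: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery and calibration grid over planted attenuation values.

    For each f in ``f_grid``, ``n_reps`` independent simulations are run in
    noise-free-predictor mode and the suite reports: mean fitted slope and
    bias against f, 95% CI coverage of f, planted-regulon bootstrap Z
    summary, plus (shared across the grid) the phase-enrichment type-I rate
    on null phase sets and the null-pair bootstrap Z mean/SD.
    """
    if n_reps < 1:
        raise ParameterError(f"n_reps must be >= 1, got {n_reps}")
    rows = []
    for fi, f in enumerate(f_grid):
        slopes = np.empty(n_reps)
        covered = np.zeros(n_reps, dtype=bool)
        z_planted = np.empty(n_reps)
        logp_planted = np.empty(n_reps)
        for rep in range(n_reps):
            rep_seed = seed + 1000 * fi + rep
            params = SimParams(
                n_genes=n_genes,
                regulon_fraction=regulon_fraction,
                attenuation_f=f,
                effect_sd=effect_sd,
                noise_sd=noise_sd,
                seed=rep_seed,
            )
            down, up, truth = generate_paired_perturbation(params)
            merged = merge_by_gene(down, up)
            fit = attenuation_fit(
                merged, truth.regulon_genes, response="upstream", predictor="downstream"
            )
            slopes[rep] = fit.beta_upstream
            covered[rep] = fit.ci95[0] <= f <= fit.ci95[1]
            conc = bootstrap_null_concordance(
                merged, truth.regulon_genes, n_iter=n_iter_concord, seed=rep_seed
            )
            z_planted[rep] = conc.z_score
            logp_planted[rep] = conc.log_p_one_sided
        rows.append(
            {
                "attenuation_f": f,
                "n_reps": n_reps,
                "slope_mean": float(slopes.mean()),
                "slope_bias": float(slopes.mean() - f),
                "ci_coverage": float(covered.mean()),
                "planted_z_min": float(z_planted.min()),
                "planted_z_mean": float(z_planted.mean()),
                "planted_logp_max": float(logp_planted.max()),
            }
        )
    out = pd.DataFrame(rows)

    # grid-independent calibration columns (type-I and null-Z), one pass
    n_cal = max(n_reps, 50)
    rejections = 0
    z_null = np.empty(n_cal)
    for rep in range(n_cal):
        rep_seed = seed + 900_000 + rep
        down, up = generate_independent_pair(n_genes, noise_sd, seed=rep_seed)
        phases, shift_map = generate_phase_gene_sets(
            1, 50, 0.0, [g for g in down.data["gene"]], seed=rep_seed
        )
        res = phase_enrichment(down, phases)[0]
        rejections += int(res.p_raw < 0.05)
        merged = merge_by_gene(down, up)
        sel_rng = np.random.default_rng(rep_seed)
        sel = set(
            sel_rng.choice(sorted(merged.genes), size=null_set_size, replace=False)
        )
        z_null[rep] = bootstrap_null_concordance(
            merged, sel, n_iter=n_iter_concord, seed=rep_seed
        ).z_score
    out["phase_type1_rate"] = rejections / n_cal
    out["null_z_mean"] = float(z_null.mean())
    out["null_z_sd"] = float(z_null.std(ddof=1))
    out["n_calibration_reps"] = n_cal
    return out
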