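"""Scoring called genotypes against simulation truth and scenario grids.

Provides per-replicate call metrics (genotype error over called entries,
proportion of genotypes called, true/called SNV counts) and a runner for the
coverage-heterogeneity experiment: a grid of sequencing depths times
negative-binomial dispersion levels, simulated on an exponentially growing
population with a fixed number of infinite-site mutations and no
ADO/AI/sequencing error, so the only noise is how the reads distribute.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_cli import ReplicateResult, SimulationConfig, replicate_rng, simulate_replicate
from .likelihoods import STATUS_CALLED
from .mutation import DEL

__all__ = [
    "CallMetrics",
    "score_replicate",
    "score_result",
    "count_true_snv_sites",
    "run_coverage_heterogeneity_experiment",
    "figure_experiment_config",
    "plot_metrics",
]


@dataclass
class CallMetrics:
    """Accuracy summary for one replicate.

    ``genotype_error`` is the fraction of *called* genotypes whose unordered
    allele pair differs from the truth (NaN when nothing is called), so it is
    orthogonal to ``proportion_called``.  ``recovery_error`` instead counts a
    missing genotype as not recovered: the fraction of all cell-site entries
    whose true genotype is not correctly called.  The two differ at low
    depth, where heterogeneous coverage leaves many entries uncalled while
    concentrating the called ones at higher depth.
    """

    genotype_error: float
    proportion_called: float
    n_snvs_called: int
    n_snvs_true: int
    n_called: int
    n_entries: int
    recovery_error: float = float("nan")


def count_true_snv_sites(
    maternal: np.ndarray, paternal: np.ndarray, ancestral: np.ndarray
) -> int:
    """Sites where any sampled cell carries a non-ancestral, non-deleted allele."""
    anc = np.asarray(ancestral)[None, :]
    derived = ((maternal != anc) & (maternal != DEL)) | (
        (paternal != anc) & (paternal != DEL)
    )
    return int(derived.any(axis=0).sum())


def score_replicate(
    true_maternal: np.ndarray,
    true_paternal: np.ndarray,
    called_a1: np.ndarray,
    called_a2: np.ndarray,
    call_status: np.ndarray,
    ancestral: np.ndarray,
) -> CallMetrics:
    """Score called genotypes against truth (unordered comparison).

    The outgroup is never part of these matrices: it is a reference device,
    not a sampled cell.  A site counts as a called SNV when at least one
    cell's called genotype carries a non-ancestral allele.
    """
    if true_maternal.shape != called_a1.shape:
        raise ValueError(
            f"shape mismatch: truth {true_maternal.shape} vs calls {called_a1.shape}"
        )
    called = np.asarray(call_status) == STATUS_CALLED
    n_called = int(called.sum())
    n_entries = int(called.size)

    t_lo = np.minimum(true_maternal, true_paternal)
    t_hi = np.maximum(true_maternal, true_paternal)
    c_lo = np.minimum(called_a1, called_a2)
    c_hi = np.maximum(called_a1, called_a2)
    wrong = called & ((t_lo != c_lo) | (t_hi != c_hi))
    genotype_error = float(wrong.sum() / n_called) if n_called else float("nan")
    recovery_error = float((wrong.sum() + (~called).sum()) / n_entries)

    anc = np.asarray(ancestral)[None, :]
    called_variant = called & (
        ((called_a1 != anc) & (called_a1 != DEL))
        | ((called_a2 != anc) & (called_a2 != DEL))
    )
    return CallMetrics(
        genotype_error=genotype_error,
        proportion_called=n_called / n_entries,
        n_snvs_called=int(called_variant.any(axis=0).sum()),
        n_snvs_true=count_true_snv_sites(true_maternal, true_paternal, anc[0]),
        n_called=n_called,
        n_entries=n_entries,
        recovery_error=recovery_error,
    )


def score_result(result: ReplicateResult) -> CallMetrics:
    """Score one pipeline result (read-count mode)."""
    if result.called_a1 is None:
        raise ValueError("replicate has no genotype calls to score")
    return score_replicate(
        result.genotypes.maternal,
        result.genotypes.paternal,
        result.called_a1,
        result.called_a2,
        result.call_status,
        result.genome.maternal,
    )


def figure_experiment_config(
    depth: float,
    dispersion: float,
    n_cells: int = 100,
    n_sites: int = 100,
    seed: int = 1,
) -> SimulationConfig:
    """The coverage-heterogeneity study conditions.

    100 cells x 100 sites sampled from a population of effective size 10,000
    growing at 0.1 per generation, 100 fixed diploid-ISM mutations, root and
    outgroup branch ratios 0, and no ADO, allelic imbalance, amplification or
    sequencing error; coverage is negative binomial with the given mean and
    dispersion (infinite dispersion = Poisson).
    """
    return SimulationConfig(
        n_replicates=1,
        n_cells=n_cells,
        n_sites=n_sites,
        N0=10_000,
        growth_rate=0.1,
        root_ratio=0.0,
        outgroup_ratio=0.0,
        alphabet="DNA",
        mutation_model="ISM",
        fixed_mutations=100,
        coverage_mean=depth,
        coverage_dispersion=dispersion,
        seed=seed,
        vcf_all_sites=True,
    )


def run_coverage_heterogeneity_experiment(
    depths: Sequence[float] = (1.0, 5.0, 10.0),
    dispersions: Sequence[float] = (1.0, 5.0, 10.0, math.inf),
    n_replicates: int = 100,
    base_config: Optional[SimulationConfig] = None,
    seed: int = 1,
    call_models: Sequence[str] = ("gatk", "gatk_ado"),
) -> pd.DataFrame:
    """Run the depth x dispersion scenario grid and aggregate call metrics.

    ``gatk`` calls with the plain likelihood; ``gatk_ado`` adds the ADO
    mixture with delta equal to the simulated mean dropout (the true
    generating value).  Returns one row per (depth, dispersion, model) with
    scenario means of the per-replicate metrics.
    """
    rows = []
    for i_depth, depth in enumerate(depths):
        for i_disp, disp in enumerate(dispersions):
            if base_config is None:
                cfg = figure_experiment_config(depth, disp, seed=seed)
            else:
                cfg = dataclasses.replace(
                    base_config,
                    coverage_mean=depth,
                    coverage_dispersion=disp,
                    seed=seed,
                )
            scenario = i_depth * len(dispersions) + i_disp
            per_model: dict[str, list[CallMetrics]] = {m: [] for m in call_models}
            for rep in range(n_replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, scenario, rep])
                )
                result = simulate_replicate(cfg, rng, index=rep)
                for model in call_models:
                    if model == "gatk":
                        metrics = score_result(result)
                    elif model == "gatk_ado":
                        from .likelihoods import call_genotypes

                        a1, a2, status, _ = call_genotypes(
                            result.pileups.counts,
                            cfg.calling_prob_matrix(),
                            delta=cfg.ado_rate,
                        )
                        metrics = score_replicate(
                            result.genotypes.maternal,
                            result.genotypes.paternal,
                            a1,
                            a2,
                            status,
                            result.genome.maternal,
                        )
                    else:
                        raise ValueError(f"unknown calling model {model!r}")
                    per_model[model].append(metrics)
            for model, ms in per_model.items():
                errs = np.array([m.genotype_error for m in ms])
                rows.append(
                    {
                        "depth": depth,
                        "dispersion": disp,
                        "call_model": model,
                        "mean_genotype_error": float(np.nanmean(errs)),
                        "mean_recovery_error": float(
                            np.mean([m.recovery_error for m in ms])
                        ),
                        "mean_proportion_called": float(
                            np.mean([m.proportion_called for m in ms])
                        ),
                        "mean_n_snvs_called": float(
                            np.mean([m.n_snvs_called for m in ms])
                        ),
                        "mean_n_snvs_true": float(
                            np.mean([m.n_snvs_true for m in ms])
                        ),
                        "n_replicates": len(ms),
                    }
                )
    return pd.DataFrame(rows)


def plot_metrics(table: pd.DataFrame, path=None):  # pragma: no cover - optional
    """Boxplot-style panels of the scenario grid (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [
        ("mean_genotype_error", "genotype error"),
        ("mean_proportion_called", "proportion called"),
        ("mean_n_snvs_called", "SNVs called"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (col, label) in zip(axes, metrics):
        for model, sub in table.groupby("call_model"):
            for depth, subd in sub.groupby("depth"):
                disp = [
                    100.0 if math.isinf(d) else d for d in subd["dispersion"]
                ]
                ax.plot(disp, subd[col], marker="o", label=f"{model} {depth}x")
        ax.set_xlabel("NB dispersion (100 = Poisson)")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
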