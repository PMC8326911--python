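"""Study orchestration: resampling plans, batch fits, group comparisons.

The study design draws metacommunities by combining one sample from each
group (triples over three groups, or pairs), fits the multi-site neutral
(MSN) and niche-neutral hybrid (NNH) models to each combination, and
aggregates parameter estimates and neutrality pass rates over the
re-samples.  Sloan's near-neutral model runs once per source->destination
group pairing.  Group-level contrasts use Fisher exact tests on species
classes and Wilcoxon rank-sum tests on the per-replicate dispersal
numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .msn import GibbsConfig, gibbs_fit, neutrality_test
from .nnh import fit_nnh
from .otu_io import GroupDesign, OtuTable, filter_singletons, split_by_group
from .sloan import SloanFit, fit_sloan

logger = logging.getLogger("metaneutral")

__all__ = [
    "ResamplePlan",
    "ResampleResult",
    "adjust_p_values",
    "build_resample_plan",
    "run_batch",
    "run_sloan_comparisons",
    "compare_M_values",
    "render_report",
]


@dataclass(frozen=True)
class ResamplePlan:
    """Enumeration of metacommunity combinations to fit."""

    mode: Literal["triple", "pair"]
    groups: tuple[str, ...]
    combination_space: int
    n_resamples: int
    with_replacement: bool
    seed: int
    combinations: tuple[tuple[str, ...], ...] = field(repr=False)


@dataclass(frozen=True)
class ResampleResult:
    """Aggregated model fits over the re-sampled metacommunities."""

    model: str
    per_replicate: pd.DataFrame
    aggregate: pd.DataFrame   # rows: mean / std_err
    n_passed: int
    n_failed: int

    @property
    def n_resamples(self) -> int:
        return len(self.per_replicate)

    @property
    def pass_rate(self) -> float:
        return self.n_passed / self.n_resamples


def build_resample_plan(
    design: GroupDesign,
    mode: Literal["triple", "pair"],
    n_resamples: int,
    seed: int,
    pair: tuple[str, str] | None = None,
    with_replacement: bool = False,
) -> ResamplePlan:
    """Draw metacommunity combinations (one sample per group), seeded.

    The combination space is the product of the group sizes; by default
    distinct combinations are drawn without replacement.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if mode == "triple":
        groups = design.groups
        if len(groups) != 3:
            raise ValueError(f"triple mode needs exactly 3 groups, have {groups}")
    elif mode == "pair":
        if pair is None or len(pair) != 2:
            raise ValueError("pair mode requires two group labels")
        missing = [g for g in pair if g not in design.group_sizes]
        if missing:
            raise ValueError(f"unknown group(s): {missing}")
        groups = tuple(pair)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    samples = [design.samples_in(g) for g in groups]
    sizes = [len(s) for s in samples]
    space = int(np.prod(sizes))
    if not with_replacement and n_resamples > space:
        raise ValueError(
            f"cannot draw {n_resamples} distinct combinations from {space}"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(space, size=n_resamples, replace=with_replacement)
    index_tuples = np.column_stack(np.unravel_index(flat, sizes))
    combos = tuple(
        tuple(samples[g][i] for g, i in enumerate(idx)) for idx in index_tuples
    )
    return ResamplePlan(
        mode=mode,
        groups=groups,
        combination_space=space,
        n_resamples=n_resamples,
        with_replacement=with_replacement,
        seed=seed,
        combinations=combos,
    )


def _replicate_seed(plan_seed: int, index: int) -> int:
    """Deterministic per-replicate seed, independent across replicates."""
    return int(np.random.default_rng([plan_seed, index]).integers(2**31 - 1))


def run_batch(
    plan: ResamplePlan,
    table: OtuTable,
    model: Literal["msn", "nnh"],
    iterations: int = 2000,
    burn_in: int = 500,
    thin: int = 5,
    n_sim: int = 200,
    filter_first: bool = True,
) -> ResampleResult:
    """Fit one model to every combination in the plan and aggregate.

    Singleton filtering is applied to the full table before any
    subsetting, so cross-group singletons are removed consistently.
    Replicate-level failures are logged and counted; the batch aborts if
    more than 20% fail.
    """
    if filter_first:
        table = filter_singletons(table)
    records: list[dict] = []
    n_passed = 0
    n_failed = 0
    for r, combo in enumerate(plan.combinations):
        seed = _replicate_seed(plan.seed, r)
        sub = table.select_samples(list(combo)).drop_empty_taxa()
        sites = {s: sub.counts[:, j] for j, s in enumerate(sub.sample_ids)}
        try:
            if model == "msn":
                fit = gibbs_fit(
                    sites,
                    GibbsConfig(
                        iterations=iterations, burn_in=burn_in, thin=thin, seed=seed
                    ),
                )
                rng = np.random.default_rng(seed + 1)
                meta_res = neutrality_test(fit, sites, "metacommunity", n_sim, rng)
                local_res = neutrality_test(fit, sites, "local", n_sim, rng)
                passed = meta_res.passed and local_res.passed
                records.append(
                    {
                        "replicate": r,
                        "L_O": fit.L_O,
                        "theta": fit.theta,
                        "M": fit.M_value,
                        "L_M": meta_res.L_obs,
                        "N_M": meta_res.N_below,
                        "N": meta_res.N_sim,
                        "p_M": meta_res.p,
                        "L_L": local_res.L_obs,
                        "N_L": local_res.N_below,
                        "p_L": local_res.p,
                        "passed": passed,
                    }
                )
            elif model == "nnh":
                fit = fit_nnh(sites, seed=seed)
                passed = fit.hybrid
                records.append(
                    {
                        "replicate": r,
                        "J": fit.J,
                        "S": fit.S,
                        "theta": fit.theta,
                        "m": fit.m,
                        "x": fit.x,
                        "gamma": fit.gamma,
                        "R2": fit.R2,
                        "chi2": fit.chi2,
                        "p": fit.p,
                        "passed": passed,
                    }
                )
            else:
                raise ValueError(f"unknown model {model!r}")
            n_passed += int(passed)
            logger.info("replicate %d (%s): ok, passed=%s", r, model, passed)
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            logger.warning("replicate %d (%s) failed: %s", r, model, exc)
            if n_failed > 0.2 * plan.n_resamples:
                raise RuntimeError(
                    f"{n_failed} of {plan.n_resamples} replicates failed"
                ) from exc
    per_replicate = pd.DataFrame(records)
    numeric = per_replicate.drop(columns=["replicate", "passed"])
    n = len(per_replicate)
    aggregate = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "std_err": numeric.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        }
    ).T
    return ResampleResult(
        model=model,
        per_replicate=per_replicate,
        aggregate=aggregate,
        n_passed=n_passed,
        n_failed=n_failed,
    )


def run_sloan_comparisons(
    table: OtuTable,
    design: GroupDesign,
    pairings: list[tuple[str, str]],
    alpha: float = 0.05,
) -> dict[tuple[str, str], SloanFit]:
    """Fit the near-neutral model for each (source, destination) pairing."""
    table = filter_singletons(table)
    parts = split_by_group(table, design)
    out = {}
    for source, dest in pairings:
        out[(source, dest)] = fit_sloan(parts[source], parts[dest], alpha=alpha)
    return out


def compare_M_values(
    result_a: ResampleResult, result_b: ResampleResult
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-replicate dispersal numbers."""
    for res in (result_a, result_b):
        if res.model != "msn" or "M" not in res.per_replicate:
            raise ValueError("compare_M_values requires MSN batch results")
        if len(res.per_replicate) < 3:
            raise ValueError("need at least 3 replicates per side")
    a = result_a.per_replicate["M"].to_numpy()
    b = result_b.per_replicate["M"].to_numpy()
    # exact null distribution where affordable and well defined
    small = max(len(a), len(b)) <= 25
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if small and no_ties else "asymptotic"
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p)


def adjust_p_values(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing adjustment across group contrasts.

    Raw p-values are reported by default throughout the pipeline; this is
    a convenience for users who want Benjamini-Hochberg (or any other
    statsmodels-supported) correction over a family of contrasts.
    """
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method=method)[1]


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def render_report(
    sloan_fits: dict[tuple[str, str], SloanFit] | None,
    msn_results: dict[str, ResampleResult] | None,
    nnh_results: dict[str, ResampleResult] | None,
    outdir: str | Path,
    plots: bool = True,
) -> list[Path]:
    """Write JSON/TSV summary tables (and optional figures) for all results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if sloan_fits:
        rows = []
        for (source, dest), fit in sloan_fits.items():
            pct = fit.class_percentages
            rows.append(
                {
                    "source": source,
                    "destination": dest,
                    "N": fit.N_T,
                    "m": fit.m_hat,
                    "R2": fit.R2,
                    "total": fit.n_classifiable,
                    "neutral_pct": pct["neutral"],
                    "below_pct": pct["below"],
                    "above_pct": pct["above"],
                }
            )
            per_path = outdir / f"sloan_{source}_to_{dest}_species.tsv"
            fit.per_species.to_csv(per_path, sep="\t", index=False)
            written.append(per_path)
        path = outdir / "sloan_summary.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
        jpath = outdir / "sloan_summary.json"
        jpath.write_text(json.dumps(rows, indent=2))
        written.append(jpath)
        if plots:
            written.append(_plot_sloan_classes(rows, outdir))

    for label, results in (("msn", msn_results), ("nnh", nnh_results)):
        if not results:
            continue
        frames = []
        for group, res in results.items():
            agg = res.aggregate.copy()
            agg.insert(0, "group", group)
            agg.insert(1, "stat", agg.index)
            agg["n_passed"] = res.n_passed
            agg["pass_rate"] = res.pass_rate
            frames.append(agg)
            rep_path = outdir / f"{label}_{group}_replicates.tsv"
            res.per_replicate.to_csv(rep_path, sep="\t", index=False)
            written.append(rep_path)
        path = outdir / f"{label}_summary.tsv"
        pd.concat(frames).to_csv(path, sep="\t", index=False)
        written.append(path)

    if plots and msn_results and len(msn_results) > 1:
        written.append(_plot_m_values(msn_results, outdir))
    return written


def _plot_sloan_classes(rows: list[dict], outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{r['source']}\nto {r['destination']}" for r in rows]
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.25
    xs = np.arange(len(rows))
    for k, key in enumerate(("neutral_pct", "below_pct", "above_pct")):
        ax.bar(xs + (k - 1) * width, [r[key] for r in rows], width,
               label=key.replace("_pct", ""))
    ax.set_xticks(xs, labels)
    ax.set_ylabel("% of classifiable species")
    ax.legend()
    fig.tight_layout()
    path = outdir / "sloan_classes.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_m_values(results: dict[str, "ResampleResult"], outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    data = [res.per_replicate["M"].to_numpy() for res in results.values()]
    ax.boxplot(data, tick_labels=list(results))
    ax.set_ylabel("fundamental dispersal number M")
    fig.tight_layout()
    path = outdir / "msn_M_boxplot.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
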