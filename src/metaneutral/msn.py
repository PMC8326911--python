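"""Multi-site neutral (MSN) model via a hierarchical Dirichlet process.

Under Hubbell's unified neutral theory a metacommunity of biodiversity
number ``theta`` feeds each local community (site) *j* through an
immigration concentration ``I_j`` (the fundamental dispersal number,
``I = m (N_T - 1)/(1 - m)``).  The HDP formulation makes the joint model
tractable for many sites at once:

* metacommunity relative abundances ``p`` ~ stick-breaking(theta);
* site counts ``n_j`` ~ Dirichlet-multinomial(I_j * p) at depth ``N_j``.

A collapsed Gibbs sampler alternates between (1) latent "ancestor"
counts per site/taxon via the Chinese-restaurant construction, (2) the
metacommunity frequencies from the pooled ancestors, (3) ``theta`` by
the Escobar-West auxiliary-variable update, and (4) each ``I_j`` by the
same auxiliary scheme at the site level.

Neutrality is assessed by posterior-predictive pseudo-p tests at two
levels: the metacommunity level (Ewens sampling-formula log-likelihood
of the ancestor configuration) and the local level (summed
Dirichlet-multinomial log-likelihood of the site counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GibbsConfig",
    "MsnFit",
    "NeutralityResult",
    "dirichlet_multinomial_loglik",
    "ewens_loglik",
    "sample_ancestor_count",
    "gibbs_fit",
    "neutrality_test",
]

# vague Gamma(shape, rate) hyperprior shared by theta and every I_j
PRIOR_SHAPE = 1.0
PRIOR_RATE = 0.001


@dataclass(frozen=True)
class GibbsConfig:
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class MsnFit:
    """Point estimates (posterior medians) and retained posterior draws."""

    theta: float
    I: dict[str, float]
    M_value: float
    L_O: float
    L_M: float
    L_L: float
    seed: int
    site_ids: tuple[str, ...]
    p_hat: np.ndarray                # metacommunity frequencies over observed
                                     # taxa; 1 - sum(p_hat) is unseen mass
    ancestors: np.ndarray            # point-estimate ancestor counts (S, J)
    posterior_draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class NeutralityResult:
    """Posterior-predictive neutrality test at one level.

    ``p`` is the fraction of simulated datasets whose component
    log-likelihood falls below the observed one; the data pass the
    neutrality test when ``p >= 0.05`` (a lower-tail rule: the observed
    data must not look less likely than the model's own replicates).
    """

    level: Literal["metacommunity", "local"]
    L_obs: float
    N_sim: int
    N_below: int

    @property
    def p(self) -> float:
        return self.N_below / self.N_sim

    @property
    def passed(self) -> bool:
        return self.p >= 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.N_below <= self.N_sim:
            raise ValueError("N_below must lie in [0, N_sim]")


# ---------------------------------------------------------------------------
# Likelihood building blocks
# ---------------------------------------------------------------------------

def dirichlet_multinomial_loglik(
    counts: np.ndarray, base: np.ndarray, I: float
) -> float:
    """Compound multinomial log-probability with parameters ``I * base``.

    Taxa with zero base frequency are structural zeros: a positive count
    there makes the data impossible (returns ``-inf`` with a warning).
    """
    counts = np.asarray(counts)
    base = np.asarray(base, dtype=float)
    if I <= 0:
        raise ValueError(f"concentration I must be > 0, got {I}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if base.sum() > 1 + 1e-9:
        raise ValueError("base frequencies must sum to at most 1")
    pos = base > 0
    if np.any(counts[~pos] > 0):
        warnings.warn("positive count at zero base frequency; log-likelihood is -inf")
        return -np.inf
    n = counts.sum()
    alpha = I * base[pos]
    c = counts[pos]
    # base may sum to < 1: the remaining mass stands for never-observed
    # species, contributing nothing when their counts are zero
    return float(
        gammaln(n + 1)
        - gammaln(counts + 1).sum()
        + gammaln(I)
        - gammaln(n + I)
        + (gammaln(c + alpha) - gammaln(alpha)).sum()
    )


def ewens_loglik(config: np.ndarray, theta: float) -> float:
    """Ewens sampling formula log-probability of an abundance configuration.

    ``config`` is the multiset of species abundances (positive integers);
    the probability refers to the unordered partition of ``n = sum(config)``
    individuals into species.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    config = np.asarray(config)
    if np.any(config < 1):
        raise ValueError("abundance configuration must be positive integers")
    n = int(config.sum())
    k = len(config)
    _, multiplicities = np.unique(config, return_counts=True)
    return float(
        gammaln(n + 1)
        + k * np.log(theta)
        - (gammaln(theta + n) - gammaln(theta))
        - np.log(config).sum()
        - gammaln(multiplicities + 1).sum()
    )


def sample_ancestor_count(
    n: int, weight: float, rng: np.random.Generator
) -> int:
    """Number of occupied tables when ``n`` customers enter a CRP.

    ``a = sum_{k=0}^{n-1} Bernoulli(weight / (weight + k))``; always in
    ``[1, n]``.  This is the Antoniak distribution realised sequentially.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    k = np.arange(n)
    return int((rng.random(n) < weight / (weight + k)).sum())


def _escobar_west_update(
    concentration: float,
    n_customers: float,
    n_tables: int,
    rng: np.random.Generator,
) -> float:
    """One auxiliary-variable resample of a DP concentration parameter."""
    if n_customers <= 0:
        return float(rng.gamma(PRIOR_SHAPE, 1.0 / PRIOR_RATE))
    eta = rng.beta(concentration + 1.0, n_customers)
    shape = PRIOR_SHAPE + n_tables
    rate = PRIOR_RATE - np.log(eta)
    odds = (shape - 1.0) / (n_customers * rate)
    if rng.random() < odds / (1.0 + odds):
        return float(rng.gamma(shape, 1.0 / rate))
    return float(rng.gamma(shape - 1.0, 1.0 / rate))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _prepare_counts(
    tables: Mapping[str, np.ndarray], min_sites: int = 2
) -> tuple[np.ndarray, tuple[str, ...]]:
    site_ids = tuple(tables)
    if len(site_ids) < min_sites:
        raise ValueError(f"need at least {min_sites} sites")
    mats = [np.asarray(tables[s], dtype=np.int64) for s in site_ids]
    S = len(mats[0])
    if any(len(v) != S for v in mats):
        raise ValueError("all sites must share one taxon universe")
    counts = np.column_stack(mats)  # (S, J)
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("every site must have a positive total")
    return counts, site_ids


def _run_chain(
    counts: np.ndarray,
    iterations: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    fix_I: float | None = None,
) -> dict[str, np.ndarray]:
    """Run the collapsed Gibbs sweeps on a (taxa x sites) count matrix.

    Returns retained draws of theta, I, p (direct-assignment frequencies
    summing to < 1) and per-cell ancestor counts, plus the cell index
    arrays needed to unflatten them.
    """
    S, J = counts.shape
    depths = counts.sum(axis=0).astype(float)

    # flattened Bernoulli ladder for the ancestor-count update: one slot per
    # read, indexed by its (taxon, site) cell, with within-cell rank k
    taxon_idx, site_idx = np.nonzero(counts)
    cell_counts = counts[taxon_idx, site_idx]
    n_cells = len(cell_counts)
    slot_cell = np.repeat(np.arange(n_cells), cell_counts)
    slot_rank = np.concatenate([np.arange(c) for c in cell_counts]).astype(float)

    # initialisation: pooled frequencies, moment-style concentrations
    p = counts.sum(axis=1).astype(float)
    p /= p.sum()
    theta = float(max(S / max(np.log(depths.sum()), 1.0), 1.0))
    I = np.full(J, 20.0 if fix_I is None else fix_I)

    n_draws = (iterations - burn_in + thin - 1) // thin
    draws_theta = np.empty(n_draws)
    draws_I = np.empty((n_draws, J))
    draws_a = np.empty((n_draws, n_cells), dtype=np.int64)
    draws_p = np.empty((n_draws, S))
    d = 0
    for it in range(iterations):
        # (1) ancestor counts per (taxon, site) cell
        w = I[site_idx] * p[taxon_idx]
        u = rng.random(len(slot_cell))
        bern = u < w[slot_cell] / (w[slot_cell] + slot_rank)
        a_cell = np.bincount(slot_cell, weights=bern, minlength=n_cells).astype(
            np.int64
        )
        a_cell = np.maximum(a_cell, 1)  # every occupied cell has >= 1 ancestor

        a_taxon = np.bincount(taxon_idx, weights=a_cell, minlength=S)
        a_site = np.bincount(site_idx, weights=a_cell, minlength=J)
        A = a_cell.sum()

        # (2) metacommunity frequencies by direct assignment: Dirichlet over
        # the observed taxa plus one slack component of weight theta for the
        # never-observed species mass (p then sums to < 1)
        g = rng.gamma(np.concatenate([a_taxon, [theta]]))
        p = g[:-1] / g.sum()

        # (3) theta given the top-level partition (S species among A ancestors)
        theta = _escobar_west_update(theta, float(A), S, rng)

        # (4) each I_j given its depth and ancestor total
        if fix_I is None:
            for j in range(J):
                I[j] = _escobar_west_update(I[j], depths[j], int(a_site[j]), rng)

        if it >= burn_in and (it - burn_in) % thin == 0 and d < n_draws:
            draws_theta[d] = theta
            draws_I[d] = I
            draws_a[d] = a_cell
            draws_p[d] = p
            d += 1

    if d == 0:
        raise RuntimeError("no posterior draws retained; check iterations/burn_in")
    return {
        "theta": draws_theta[:d],
        "I": draws_I[:d],
        "p": draws_p[:d],
        "a_cell": draws_a[:d],
        "taxon_idx": taxon_idx,
        "site_idx": site_idx,
    }


def gibbs_fit(
    tables: Mapping[str, np.ndarray],
    config: GibbsConfig,
    fix_I: float | None = None,
) -> MsnFit:
    """Fit theta and per-site immigration concentrations by Gibbs sampling.

    ``tables`` maps site id -> count vector over a shared taxon universe
    (zero rows are allowed; taxa absent everywhere are ignored).  Point
    estimates are posterior medians over the retained (post burn-in,
    thinned) draws; ``M_value`` is the mean of the per-site medians.

    ``fix_I`` pins every site's immigration concentration to a constant
    instead of sampling it (useful to reduce the model to a plain
    metacommunity fit; a single site is then allowed).
    """
    counts, site_ids = _prepare_counts(tables, min_sites=1 if fix_I else 2)
    present = counts.sum(axis=1) > 0
    counts = counts[present]
    rng = np.random.default_rng(config.seed)
    chain = _run_chain(
        counts, config.iterations, config.burn_in, config.thin, rng, fix_I=fix_I
    )
    S, J = counts.shape
    draws_theta = chain["theta"]
    draws_I = chain["I"]
    draws_p = chain["p"]

    theta_hat = float(np.median(draws_theta))
    I_hat = np.median(draws_I, axis=0)
    a_hat_cell = np.maximum(
        np.round(np.median(chain["a_cell"], axis=0)), 1
    ).astype(np.int64)
    ancestors = np.zeros((S, J), dtype=np.int64)
    ancestors[chain["taxon_idx"], chain["site_idx"]] = a_hat_cell
    a_taxon_hat = ancestors.sum(axis=1)

    # posterior-mean frequencies; the complement of their sum is the
    # fitted mass of species never seen in these sites
    p_hat = draws_p.mean(axis=0)

    L_M = ewens_loglik(a_taxon_hat[a_taxon_hat > 0], theta_hat)
    L_L = sum(
        dirichlet_multinomial_loglik(counts[:, j], p_hat, I_hat[j]) for j in range(J)
    )
    if not np.isfinite(L_L) or not np.isfinite(L_M):
        raise RuntimeError("non-finite likelihood at the fitted point estimates")

    return MsnFit(
        theta=theta_hat,
        I={s: float(v) for s, v in zip(site_ids, I_hat)},
        M_value=float(np.mean(I_hat)),
        L_O=float(L_M + L_L),
        L_M=float(L_M),
        L_L=float(L_L),
        seed=config.seed,
        site_ids=site_ids,
        p_hat=p_hat,
        ancestors=ancestors,
        posterior_draws={"theta": draws_theta, "I": draws_I, "p": draws_p},
    )


# ---------------------------------------------------------------------------
# Posterior-predictive neutrality tests
# ---------------------------------------------------------------------------

def _stick_breaking(theta: float, S_max: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.beta(1.0, theta, size=S_max)
    w = v * np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    return w / w.sum()


def _dm_draw(
    base: np.ndarray, I: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    g = rng.gamma(np.maximum(I * base, 0.0))
    total = g.sum()
    if total == 0:
        g[rng.choice(len(base), p=base)] = 1.0
        total = 1.0
    return rng.multinomial(depth, g / total)


def _expand_slack(
    p_hat: np.ndarray, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Split the unseen-species slack mass into fresh stick-breaking atoms."""
    slack = max(1.0 - p_hat.sum(), 0.0)
    if slack <= 0:
        return p_hat / p_hat.sum()
    n_atoms = max(256, int(4 * theta))
    atoms = _stick_breaking(theta, n_atoms, rng) * slack
    return np.concatenate([p_hat, atoms])


def _component_stat(
    counts: np.ndarray,
    level: str,
    rng: np.random.Generator,
    sweeps: int = 60,
) -> float:
    """Standardized component log-likelihood of one dataset.

    Runs a short Gibbs refit on the dataset and evaluates the component
    statistic at that refit's own point estimates.  Applying the identical
    procedure to the observed data and to every simulated replicate makes
    the pseudo-p test calibrated by construction.
    """
    counts = counts[counts.sum(axis=1) > 0]
    chain = _run_chain(counts, sweeps, sweeps // 2, 1, rng)
    theta_hat = float(np.median(chain["theta"]))
    I_hat = np.median(chain["I"], axis=0)
    if level == "metacommunity":
        a_cell = np.maximum(
            np.round(np.median(chain["a_cell"], axis=0)), 1
        ).astype(np.int64)
        a_taxon = np.bincount(
            chain["taxon_idx"], weights=a_cell, minlength=counts.shape[0]
        )
        return ewens_loglik(a_taxon[a_taxon > 0], theta_hat)
    p_hat = chain["p"].mean(axis=0)
    p_ren = p_hat / p_hat.sum()
    return float(
        sum(
            dirichlet_multinomial_loglik(counts[:, j], p_ren, I_hat[j])
            for j in range(counts.shape[1])
        )
    )


def neutrality_test(
    fit: MsnFit,
    tables: Mapping[str, np.ndarray],
    level: Literal["metacommunity", "local"],
    N_sim: int = 2500,
    rng: np.random.Generator | None = None,
    refit_sweeps: int = 60,
) -> NeutralityResult:
    """Posterior-predictive pseudo-p neutrality test.

    Simulates ``N_sim`` replicate datasets from the fitted model at the
    observed depths and counts how many have a component log-likelihood
    below the observed one: ``p = N_below / N_sim``.  The statistic is
    pivotal: every dataset (observed or replicate) is scored at its own
    short standardized Gibbs refit, so the comparison is symmetric, and
    replicates are generated from retained posterior draws (posterior
    predictive), which propagates parameter uncertainty.  At the
    metacommunity level the statistic is the Ewens log-probability of
    the refit ancestor configuration and replicates draw a fresh
    metacommunity from stick-breaking; at the local level it is the
    summed Dirichlet-multinomial log-likelihood of the site counts given
    the refit metacommunity frequencies, and replicates keep the drawn
    metacommunity (with its unseen-species mass expanded into fresh
    atoms).
    """
    if N_sim < 100:
        warnings.warn(f"N_sim={N_sim} < 100 gives an unstable pseudo-p")
    if level not in ("metacommunity", "local"):
        raise ValueError(f"unknown level {level!r}")
    if rng is None:
        rng = np.random.default_rng(fit.seed + 1)
    counts, site_ids = _prepare_counts(tables)
    if site_ids != fit.site_ids:
        raise ValueError("tables do not match the sites of the fit")
    counts = counts[counts.sum(axis=1) > 0]
    depths = counts.sum(axis=0)
    J = len(site_ids)
    S = len(fit.p_hat)
    S_sim = max(2 * S, S + 64)
    draws_p = fit.posterior_draws["p"]
    draws_I = fit.posterior_draws["I"]
    draws_theta = fit.posterior_draws["theta"]

    L_obs = _component_stat(counts, level, rng, refit_sweeps)

    n_below = 0
    for _ in range(N_sim):
        t = int(rng.integers(len(draws_theta)))
        if level == "local":
            p_gen = _expand_slack(draws_p[t], float(draws_theta[t]), rng)
        else:
            p_gen = _stick_breaking(float(draws_theta[t]), S_sim, rng)
        rep = np.column_stack(
            [_dm_draw(p_gen, draws_I[t][j], int(depths[j]), rng) for j in range(J)]
        )
        L_rep = _component_stat(rep, level, rng, refit_sweeps)
        if L_rep < L_obs:
            n_below += 1

    return NeutralityResult(
        level=level, L_obs=float(L_obs), N_sim=N_sim, N_below=n_below
    )
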