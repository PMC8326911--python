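"""Sloan's near-neutral community model.

A local community of fixed size ``N_T`` evolves by single-individual
death/replacement: the replacement is an immigrant from a source
community with probability ``m`` (drawn by source frequency ``p_i``) or
the offspring of one of the remaining residents with probability
``1 - m``.  At stationarity the relative abundance ``x_i`` of taxon *i*
follows a Beta distribution with parameters ``N_T*m*p_i`` and
``N_T*m*(1 - p_i)``, so the probability of detecting taxon *i* above a
detection limit ``d`` is a one-parameter (``N_T*m``) function of its
source frequency.  Fitting that curve to observed occurrence
frequencies yields the migration estimate; taxa whose observed
occurrence escapes the 95% band around the neutral prediction are
flagged as positively (above) or negatively (below) selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .otu_io import OtuTable, relative_abundance

__all__ = [
    "SloanParams",
    "SloanFit",
    "transition_probabilities",
    "predicted_occurrence",
    "fit_sloan",
    "classify_species",
    "compare_class_proportions",
]

LABELS = ("neutral", "above", "below")


@dataclass(frozen=True)
class SloanParams:
    """Parameters of the local-community birth-death-immigration process.

    N_T : local community size (reads per sample).
    m   : immigration probability per replacement event.
    d   : detection limit in relative-abundance units.
    """

    N_T: int
    m: float
    d: float = 1e-4

    def __post_init__(self) -> None:
        if self.N_T < 2:
            raise ValueError(f"N_T must be >= 2, got {self.N_T}")
        if not 0 < self.m < 1:
            raise ValueError(f"m must be in (0,1), got {self.m}")
        if not 0 < self.d < 1:
            raise ValueError(f"d must be in (0,1), got {self.d}")


@dataclass(frozen=True)
class SloanFit:
    """Result of fitting the occurrence-frequency curve.

    ``per_species`` has one row per taxon with columns
    ``taxon``, ``p_source`` (mean source relative abundance),
    ``observed`` (fraction of destination samples with >= 1 read),
    ``predicted``, ``lower95``, ``upper95`` and ``label``.
    """

    m_hat: float
    NTm: float
    N_T: float
    d: float
    R2: float
    n_dest_samples: int
    alpha: float
    per_species: pd.DataFrame

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.per_species["label"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in LABELS}

    @property
    def n_classifiable(self) -> int:
        return int((self.per_species["label"] != "unclassifiable").sum())

    @property
    def class_percentages(self) -> dict[str, float]:
        n = self.n_classifiable
        return {lab: 100.0 * c / n for lab, c in self.class_counts.items()}

    def summary(self) -> dict:
        return {
            "N_T": self.N_T,
            "m": self.m_hat,
            "NTm": self.NTm,
            "R2": self.R2,
            "total": self.n_classifiable,
            "n_dest_samples": self.n_dest_samples,
            "percent": self.class_percentages,
        }


def transition_probabilities(
    N_i: int, params: SloanParams, p_i: float
) -> tuple[float, float, float]:
    """One-event gain/loss/stay probabilities for the focal taxon.

    Returns ``(P_gain, P_loss, P_stay)``; the three always sum to one.
    """
    N_T, m = params.N_T, params.m
    if not 0 <= N_i <= N_T:
        raise ValueError(f"N_i={N_i} outside [0, N_T={N_T}]")
    if not 0 <= p_i <= 1:
        raise ValueError(f"p_i={p_i} outside [0,1]")
    frac = N_i / N_T
    p_gain = (1 - frac) * (m * p_i + (1 - m) * N_i / (N_T - 1))
    p_loss = frac * (m * (1 - p_i) + (1 - m) * (N_T - N_i) / (N_T - 1))
    p_stay = 1.0 - p_gain - p_loss
    return p_gain, p_loss, p_stay


def transition_stay_direct(N_i: int, params: SloanParams, p_i: float) -> float:
    """No-change probability evaluated from its explicit two-case form.

    The focal taxon's abundance is unchanged when a focal individual dies
    and is replaced by a focal one, or a non-focal dies and is replaced by
    a non-focal.  Used to cross-check the complement in
    :func:`transition_probabilities`.
    """
    N_T, m = params.N_T, params.m
    frac = N_i / N_T
    stay_focal = frac * (m * p_i + (1 - m) * (N_i - 1) / (N_T - 1))
    stay_other = (1 - frac) * (m * (1 - p_i) + (1 - m) * (N_T - N_i - 1) / (N_T - 1))
    return stay_focal + stay_other


def predicted_occurrence(
    p_i: float | np.ndarray, NTm: float, d: float
) -> float | np.ndarray:
    """Neutral probability that a taxon is detected above the limit ``d``.

    Stationary relative abundance is Beta(NTm*p_i, NTm*(1-p_i)); the
    occurrence probability is its upper tail beyond ``d``.
    """
    if NTm <= 0:
        raise ValueError(f"NTm must be > 0, got {NTm}")
    if not 0 < d < 1:
        raise ValueError(f"detection limit must be in (0,1), got {d}")
    p = np.asarray(p_i, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = np.empty_like(p)
    degenerate0 = p <= 0
    degenerate1 = p >= 1
    if degenerate0.any() or degenerate1.any():
        warnings.warn("degenerate source frequency (0 or 1); returning 0/1")
    interior = ~(degenerate0 | degenerate1)
    out[degenerate0] = 0.0
    out[degenerate1] = 1.0
    out[interior] = stats.beta.sf(d, NTm * p[interior], NTm * (1 - p[interior]))
    return float(out[0]) if scalar else out


def classify_species(
    predicted: np.ndarray,
    observed: np.ndarray,
    n_dest_samples: int,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label taxa against the (1-alpha) sampling band of the prediction.

    The band is the Wilson score interval for a proportion equal to the
    predicted occurrence observed over ``n_dest_samples`` samples — the
    spread expected from sampling noise alone if the taxon were neutral.

    Returns ``(labels, lower, upper)``.
    """
    if n_dest_samples < 2:
        raise ValueError("need at least 2 destination samples")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    lower, upper = proportion_confint(
        predicted * n_dest_samples, n_dest_samples, alpha=alpha, method="wilson"
    )
    lower = np.minimum(lower, predicted)
    upper = np.maximum(upper, predicted)
    labels = np.full(predicted.shape, "neutral", dtype=object)
    labels[observed > upper] = "above"
    labels[observed < lower] = "below"
    return labels, lower, upper


def fit_sloan(
    source: OtuTable,
    destination: OtuTable,
    d: float | str = "auto",
    alpha: float = 0.05,
) -> SloanFit:
    """Fit the neutral occurrence-frequency curve from source to destination.

    Source frequencies ``p_i`` are mean relative abundances across source
    samples; observed occurrence is the fraction of destination samples
    in which the taxon has at least one read.  The single composite
    parameter ``N_T*m`` is fitted by bounded least squares, with
    ``N_T`` taken as the mean destination sample depth.  Taxa absent
    from the source are unclassifiable and excluded from the fit.
    """
    if source.taxon_ids != destination.taxon_ids:
        raise ValueError("source and destination must share a taxon universe")
    if destination.n_samples < 3:
        raise ValueError("destination must have at least 3 samples")
    p_source = relative_abundance(source).mean(axis=1)
    observed = (destination.counts >= 1).mean(axis=1)
    N_T = float(destination.sample_depths.mean())
    if d == "auto":
        # detection by >= 1 read out of D has probability 1 - E[(1-x)^D]
        # ~ 1 - E[exp(-D x)]; the sharp threshold matching that kernel's
        # median is x = ln2 / D, a less biased limit than 1/D
        d_val = np.log(2) / N_T
    else:
        d_val = float(d)
    # only taxa seen in the source or the destination enter the analysis;
    # source-absent taxa cannot have a neutral prediction
    in_universe = (p_source > 0) | (observed > 0)
    usable = p_source > 0
    if usable.sum() < 5:
        raise ValueError(
            f"only {int(usable.sum())} taxa present in the source; need >= 5"
        )
    obs_fit = observed[usable]
    p_fit = p_source[usable]

    def sse(log_ntm: float) -> float:
        pred = predicted_occurrence(p_fit, float(np.exp(log_ntm)), d_val)
        return float(np.sum((obs_fit - pred) ** 2))

    bounds = (np.log(1e-3), np.log(10 * N_T))
    res = optimize.minimize_scalar(sse, bounds=bounds, method="bounded")
    if not res.success:
        raise RuntimeError(
            "occurrence-curve optimisation failed; try wider NTm bounds: "
            + str(res.message)
        )
    NTm = float(np.exp(res.x))
    pred_fit = predicted_occurrence(p_fit, NTm, d_val)
    sse_val = float(np.sum((obs_fit - pred_fit) ** 2))
    sst = float(np.sum((obs_fit - obs_fit.mean()) ** 2))
    R2 = 1.0 - sse_val / sst if sst > 0 else np.nan

    labels_fit, lower_fit, upper_fit = classify_species(
        pred_fit, obs_fit, destination.n_samples, alpha=alpha
    )

    n = source.n_taxa
    predicted = np.full(n, np.nan)
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    labels = np.full(n, "unclassifiable", dtype=object)
    predicted[usable] = pred_fit
    lower[usable] = lower_fit
    upper[usable] = upper_fit
    labels[usable] = labels_fit

    per_species = pd.DataFrame(
        {
            "taxon": list(source.taxon_ids),
            "p_source": p_source,
            "observed": observed,
            "predicted": predicted,
            "lower95": lower,
            "upper95": upper,
            "label": labels,
        }
    )[in_universe].reset_index(drop=True)

    return SloanFit(
        m_hat=NTm / N_T,
        NTm=NTm,
        N_T=N_T,
        d=d_val,
        R2=R2,
        n_dest_samples=destination.n_samples,
        alpha=alpha,
        per_species=per_species,
    )


def compare_class_proportions(fit_a: SloanFit, fit_b: SloanFit) -> pd.DataFrame:
    """Fisher exact test of each class's share between two fits.

    For each label a 2x2 table (class vs not-class) x (fit A vs fit B)
    is tested two-sided.  Returns a frame with odds ratios and p-values.
    """
    n_a, n_b = fit_a.n_classifiable, fit_b.n_classifiable
    if n_a == 0 or n_b == 0:
        raise ValueError("both fits must have classifiable species")
    rows = []
    counts_a, counts_b = fit_a.class_counts, fit_b.class_counts
    for lab in LABELS:
        a, b = counts_a[lab], counts_b[lab]
        table = [[a, n_a - a], [b, n_b - b]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"label": lab, "odds_ratio": odds, "p_value": p})
    return pd.DataFrame(rows)
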