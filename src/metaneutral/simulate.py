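"""Synthetic neutral / non-neutral metacommunity data with known truth.

Two equivalent generative routes are provided for a local community of
size ``N_T`` receiving immigrants from a metacommunity at rate ``m``:

* the exact stationary law — relative abundances drawn from a Dirichlet
  with concentration ``I * meta`` (``I = N_T*m*(N_T-1)/(N_T*(1-m))``
  collapses to the convention ``I = N_T*m`` used throughout), followed
  by multinomial read sampling; and
* the forward Moran process — single-individual death/replacement
  events, optionally with per-taxon multiplicative reproduction
  (fitness) weights, the minimal departure from neutrality.

The default study layout mirrors a three-group tissue-microbiome design:
23 + 12 + 33 samples, read depths around 9,000-16,000, log-series-like
metacommunity abundances, migration rates of order 1e-3, and a handful
of planted singleton OTUs so that singleton filtering is exercised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .otu_io import GroupDesign, OtuTable
from .sloan import SloanParams

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "GroupSpec",
    "SimulationSpec",
    "sample_metacommunity",
    "sample_local_stationary",
    "sample_untb_community",
    "simulate_moran_forward",
    "generate_study_dataset",
]


@dataclass(frozen=True)
class GroupSpec:
    """One study group: label, sample count, migration rate, depth model.

    Depths are lognormal around ``depth_mean`` with shape ``depth_sigma``
    so that community-size estimation from mean depth is meaningfully
    exercised.  ``selected`` controls whether the study-level selection
    vector (if any) acts in this group's local communities — e.g. tumor
    groups under selection while the normal group stays neutral.
    """

    label: str
    n_samples: int
    m: float
    depth_mean: float
    depth_sigma: float = 0.3
    selected: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0 < self.m < 1:
            raise ValueError(f"m must be in (0,1), got {self.m}")
        if self.depth_mean < 2:
            raise ValueError("depth_mean must be >= 2")


def default_group_specs() -> tuple[GroupSpec, ...]:
    """Three-group design: 23 normal / 12 benign / 33 malignant samples."""
    return (
        GroupSpec("normal", 23, 0.003, 12000.0),
        GroupSpec("benign", 12, 0.002, 15686.0),
        GroupSpec("malignant", 33, 0.005, 9120.0),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Full ground-truth specification of a synthetic study dataset."""

    theta: float = 300.0
    S_max: int = 2000
    group_specs: tuple[GroupSpec, ...] = field(default_factory=default_group_specs)
    selection: np.ndarray | None = None  # per-taxon fitness, 1 = neutral
    n_planted_singletons: int = 5
    burnin_factor: int = 100  # Moran events per individual before sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.S_max < 2:
            raise ValueError("theta must be > 0 and S_max >= 2")
        if self.selection is not None:
            sel = np.asarray(self.selection, dtype=float)
            if sel.shape != (self.S_max,) or np.any(sel <= 0):
                raise ValueError("selection must be positive with length S_max")
            object.__setattr__(self, "selection", sel)
        labels = [g.label for g in self.group_specs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate group labels: {labels}")


def sample_metacommunity(
    theta: float, S_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Stick-breaking metacommunity relative abundances.

    Breaks sticks with Beta(1, theta) proportions, truncates at ``S_max``
    and renormalises.  Warns if the truncation discards more than 1% of
    the mass.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    v = rng.beta(1.0, theta, size=S_max)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    w = v * remaining
    leftover = remaining[-1] * (1.0 - v[-1])
    if leftover > 0.01:
        warnings.warn(
            f"stick-breaking truncation at S_max={S_max} discards "
            f"{leftover:.1%} of metacommunity mass"
        )
    return w / w.sum()


def sample_local_stationary(
    meta: np.ndarray, I: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw one local community from the stationary law.

    Relative abundances are Dirichlet with concentration ``I * meta``
    (taxa with zero metacommunity frequency stay at zero), then ``depth``
    reads are drawn multinomially.
    """
    if I <= 0:
        raise ValueError(f"immigration concentration must be > 0, got {I}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    meta = np.asarray(meta, dtype=float)
    # gamma draws with shape 0 are exactly 0, giving the degenerate margins
    g = rng.gamma(np.maximum(I * meta, 0.0))
    total = g.sum()
    if total == 0:  # pathologically tiny I; fall back to a single atom
        g[rng.choice(len(meta), p=meta)] = 1.0
        total = 1.0
    return rng.multinomial(depth, g / total)


def sample_untb_community(
    theta: float, m: float, J: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample one dispersal-limited neutral community (abundance vector).

    Sequential urn construction: individual ``k`` is a new immigrant with
    probability ``I/(I + k)`` (``I = m (J-1)/(1-m)``), whose species comes
    from a metacommunity Chinese restaurant process with concentration
    ``theta``; otherwise it is the offspring of an earlier individual.
    The marginal expected abundance spectrum is the dispersal-limited
    neutral SAD.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if not 0 < m < 1:
        raise ValueError(f"m must be in (0,1), got {m}")
    I = m * (J - 1.0) / (1.0 - m) if J > 1 else 1.0
    labels = np.empty(J, dtype=np.int64)
    ancestor_species: list[int] = []
    n_species = 0
    for k in range(J):
        if k == 0 or rng.random() < I / (I + k):
            a = len(ancestor_species)
            if a == 0 or rng.random() < theta / (theta + a):
                species = n_species
                n_species += 1
            else:
                species = ancestor_species[rng.integers(a)]
            ancestor_species.append(species)
            labels[k] = species
        else:
            labels[k] = labels[rng.integers(k)]
    return np.bincount(labels, minlength=n_species)


# ---------------------------------------------------------------------------
# Forward Moran process
# ---------------------------------------------------------------------------

def _moran_kernel_py(
    individuals: np.ndarray,
    cum_meta: np.ndarray,
    m: float,
    selection: np.ndarray,
    n_events: int,
    seed: int,
) -> None:
    """Reference implementation of the event loop (in-place)."""
    rng = np.random.RandomState(seed)
    N_T = individuals.shape[0]
    s_max = selection.max()
    for _ in range(n_events):
        die = rng.randint(N_T)
        if rng.random_sample() < m:
            new = int(np.searchsorted(cum_meta, rng.random_sample(), side="right"))
        else:
            while True:
                idx = rng.randint(N_T - 1)
                if idx >= die:
                    idx += 1
                label = individuals[idx]
                if rng.random_sample() * s_max <= selection[label]:
                    new = label
                    break
        individuals[die] = new


if _HAVE_NUMBA:  # pragma: no cover - numba path exercised in tests

    @numba.njit(cache=True)
    def _moran_kernel_nb(individuals, cum_meta, m, selection, n_events, seed):
        np.random.seed(seed)
        N_T = individuals.shape[0]
        s_max = selection.max()
        for _ in range(n_events):
            die = np.random.randint(N_T)
            if np.random.random() < m:
                new = np.searchsorted(cum_meta, np.random.random(), side="right")
            else:
                while True:
                    idx = np.random.randint(N_T - 1)
                    if idx >= die:
                        idx += 1
                    label = individuals[idx]
                    if np.random.random() * s_max <= selection[label]:
                        new = label
                        break
            individuals[die] = new


def simulate_moran_forward(
    meta: np.ndarray,
    params: SloanParams,
    n_events: int,
    selection: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_runs: int = 1,
) -> np.ndarray:
    """Run the single-individual death/replacement process forward.

    Each event kills one uniformly chosen resident; the replacement is an
    immigrant drawn from ``meta`` with probability ``m`` or the offspring
    of one of the remaining ``N_T - 1`` residents with probability
    ``1 - m``, parents weighted by ``selection`` (all ones = neutral).

    Returns integer abundances summing to ``N_T`` — shape ``(S,)`` for a
    single run, ``(n_runs, S)`` otherwise.  Runs are independent.
    """
    if params.N_T < 2:
        raise ValueError("N_T must be >= 2")
    meta = np.asarray(meta, dtype=float)
    meta = meta / meta.sum()
    S = len(meta)
    if selection is None:
        selection = np.ones(S)
    selection = np.asarray(selection, dtype=float)
    if np.any(selection <= 0):
        raise ValueError("selection weights must be strictly positive")
    if rng is None:
        rng = np.random.default_rng()
    cum_meta = np.cumsum(meta)
    cum_meta[-1] = 1.0
    kernel = _moran_kernel_nb if _HAVE_NUMBA else _moran_kernel_py
    out = np.zeros((n_runs, S), dtype=np.int64)
    for r in range(n_runs):
        individuals = rng.choice(S, size=params.N_T, p=meta).astype(np.int64)
        seed = int(rng.integers(2**31 - 1))
        kernel(individuals, cum_meta, params.m, selection, int(n_events), seed)
        out[r] = np.bincount(individuals, minlength=S)
    return out[0] if n_runs == 1 else out


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------

def generate_study_dataset(
    spec: SimulationSpec,
) -> tuple[OtuTable, GroupDesign, dict]:
    """Generate a full synthetic study: OTU table, design and ground truth.

    One metacommunity is shared by all groups; each group's samples are
    drawn from the stationary law at its own migration rate (``I =
    depth * m``), or through the forward Moran process when a selection
    vector is supplied.  A few singleton OTUs are planted so singleton
    filtering has work to do.  Identical specs (including seed) give
    identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    meta = sample_metacommunity(spec.theta, spec.S_max, rng)
    neutral = spec.selection is None or np.all(spec.selection == 1.0)

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    depths_by_group: dict[str, list[int]] = {}
    for group in spec.group_specs:
        sigma = group.depth_sigma
        z = rng.standard_normal(group.n_samples)
        depths = np.maximum(
            np.round(group.depth_mean * np.exp(sigma * z - sigma**2 / 2)), 100
        ).astype(int)
        depths_by_group[group.label] = [int(x) for x in depths]
        for k, depth in enumerate(depths):
            sid = f"{group.label}_{k + 1:02d}"
            if neutral or not group.selected:
                counts = sample_local_stationary(
                    meta, depth * group.m, int(depth), rng
                )
            else:
                counts = simulate_moran_forward(
                    meta,
                    SloanParams(int(depth), group.m, 1.0 / depth),
                    n_events=spec.burnin_factor * int(depth),
                    selection=spec.selection,
                    rng=rng,
                )
            columns.append(counts)
            sample_ids.append(sid)
            assignment[sid] = group.label

    counts = np.column_stack(columns)
    taxon_ids = [f"OTU_{i + 1:05d}" for i in range(spec.S_max)]
    # plant singleton OTUs: one read each, in a random sample
    if spec.n_planted_singletons > 0:
        extra = np.zeros((spec.n_planted_singletons, counts.shape[1]), dtype=np.int64)
        cols = rng.integers(counts.shape[1], size=spec.n_planted_singletons)
        extra[np.arange(spec.n_planted_singletons), cols] = 1
        counts = np.vstack([counts, extra])
        taxon_ids += [
            f"SINGLETON_{i + 1:03d}" for i in range(spec.n_planted_singletons)
        ]

    keep = counts.sum(axis=1) > 0  # drop taxa never observed anywhere
    table = OtuTable(
        counts[keep],
        tuple(t for t, k in zip(taxon_ids, keep) if k),
        tuple(sample_ids),
    )
    design = GroupDesign(assignment)
    truth = {
        "seed": spec.seed,
        "theta": spec.theta,
        "S_max": spec.S_max,
        "meta": meta.tolist(),
        "groups": {
            g.label: {
                "n_samples": g.n_samples,
                "m": g.m,
                "depth_mean": g.depth_mean,
                "depths": depths_by_group[g.label],
            }
            for g in spec.group_specs
        },
        "selection": (
            None if spec.selection is None else np.asarray(spec.selection).tolist()
        ),
        "planted_singletons": spec.n_planted_singletons,
    }
    return table, design, truth
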