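"""Compact Markov-state-model toolkit.

Workflow: reduce feature-space trajectories with time-lagged independent
component analysis (tICA), cluster the projections into microstates with
K-means, estimate a (reversible) transition matrix from lagged transition
counts, derive stationary populations and per-state free energies, and
synthesise long stochastic trajectories by kinetic Monte Carlo.

Free energies use the NMR detection-limit relation for a sparsely populated
state exchanging with everything else:

    dG = -R T ln(p / (1 - p))        (complement convention)

so a 0.5% population at 300 K sits at ~3.2 kcal/mol, the conventional
detection limit of CEST/CPMG experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = [
    "FeatureTrajectory",
    "MarkovModel",
    "TicaModel",
    "tica_project",
    "cluster_microstates",
    "estimate_msm",
    "stationary_distribution",
    "from_transition_matrix",
    "population_free_energy",
    "population_from_free_energy",
    "kmc_trajectory",
    "GAS_CONSTANT_KCAL",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)


@dataclass
class FeatureTrajectory:
    """Ordered frames x features matrix with a uniform frame spacing."""

    frames: np.ndarray
    dt: float = 1.0
    traj_id: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class TicaModel:
    eigenvalues: np.ndarray
    components: np.ndarray        # n_components x n_features
    mean: np.ndarray
    lag: int

    def transform(self, traj: FeatureTrajectory) -> np.ndarray:
        return (traj.frames - self.mean) @ self.components.T


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix over microstates at a fixed lag."""

    lag: int
    transition_matrix: np.ndarray
    count_matrix: np.ndarray
    stationary: np.ndarray
    centers: np.ndarray | None = None
    active_states: np.ndarray | None = None   # original labels kept
    dropped_states: list[int] = field(default_factory=list)
    reversible: bool = True

    def __post_init__(self) -> None:
        t = self.transition_matrix
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        pi = self.stationary
        if np.any(pi < -1e-15) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("invalid stationary distribution")
        if not np.allclose(pi @ t, pi, atol=1e-8):
            raise ValueError("stationary distribution does not satisfy pi T = pi")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

def tica_project(
    trajs: list[FeatureTrajectory],
    lag: int,
    n_components: int | None = None,
    regularization: float = 1e-10,
) -> tuple[list[np.ndarray], TicaModel]:
    """Symmetrized time-lagged independent component analysis.

    Solves the generalized eigenproblem ``C_tau v = lambda C_0 v`` with the
    symmetrized lagged covariance ``C_tau`` and the instantaneous covariance
    ``C_0`` (plus a small ridge), both estimated over all trajectories with
    the mean removed.  Eigenvalues (lagged autocorrelations of the tICs) are
    sorted descending; each component's sign is fixed by making its
    largest-magnitude loading positive.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    for t in trajs:
        if t.n_frames <= lag:
            raise ValueError("every trajectory must be longer than the lag")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    all_frames = np.vstack([t.frames for t in trajs])
    mean = all_frames.mean(axis=0)
    nf = all_frames.shape[1]
    c0 = np.zeros((nf, nf))
    ct = np.zeros((nf, nf))
    n_pairs = 0
    for t in trajs:
        x = t.frames - mean
        a, b = x[:-lag], x[lag:]
        c0 += a.T @ a + b.T @ b
        ct += a.T @ b
        n_pairs += len(a)
    c0 /= 2.0 * n_pairs
    ct = (ct + ct.T) / (2.0 * n_pairs)
    c0reg = c0 + regularization * np.eye(nf)
    try:
        evals, evecs = eigh(ct, c0reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular instantaneous covariance; increase regularization"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = n_components or nf
    comps = evecs[:, :k].T
    # unit-normalize rows and fix sign on the largest-|loading| entry
    for i in range(comps.shape[0]):
        nrm = np.linalg.norm(comps[i])
        if nrm > 0:
            comps[i] /= nrm
        if comps[i, int(np.argmax(np.abs(comps[i])))] < 0:
            comps[i] = -comps[i]
    model = TicaModel(eigenvalues=evals[:k], components=comps, mean=mean, lag=lag)
    return [model.transform(t) for t in trajs], model


# ---------------------------------------------------------------------------
# microstates and the MSM
# ---------------------------------------------------------------------------

def cluster_microstates(
    projected: list[np.ndarray], k: int, seed: int = 0
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """K-means microstate assignment; returns (assignments, centers, inertia)."""
    if k <= 0:
        raise ValueError("K must be positive")
    data = np.vstack([np.atleast_2d(p.T).T if p.ndim == 1 else p for p in projected])
    if data.ndim == 1:
        data = data[:, None]
    if k > data.shape[0]:
        raise ValueError("K exceeds the number of frames")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(data)
    lengths = [len(p) for p in projected]
    splits = np.cumsum(lengths)[:-1]
    return (list(np.split(km.labels_, splits)), km.cluster_centers_,
            float(km.inertia_))


def estimate_msm(
    assignments: list[np.ndarray] | np.ndarray,
    lag: int,
    reversible: bool = True,
    pseudocount: float = 0.0,
    centers: np.ndarray | None = None,
) -> MarkovModel:
    """Estimate a transition matrix from microstate assignments.

    Counts use a sliding window at the given lag and never cross trajectory
    boundaries.  Reversible mode symmetrizes counts, ``(C + C^T)/2``, which
    makes detailed balance exact.  The model is restricted to the largest
    connected set of states; dropped states are recorded.
    """
    if isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        assignments = [assignments]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n = int(max(a.max() for a in assignments)) + 1
    counts = np.zeros((n, n))
    for a in assignments:
        a = np.asarray(a, dtype=int)
        if len(a) > lag:
            np.add.at(counts, (a[:-lag], a[lag:]), 1.0)
    if counts.sum() == 0:
        raise ValueError("no transitions at this lag")
    counts += pseudocount
    c = (counts + counts.T) / 2.0 if reversible else counts.copy()

    # largest connected set on the symmetrized connectivity
    adj = (c + c.T) > 0
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = labels == int(np.argmax(sizes))
    else:
        keep = np.ones(n, dtype=bool)
    # states never visited at all are dropped too
    keep &= (counts.sum(axis=1) + counts.sum(axis=0)) > 0
    dropped = [int(i) for i in np.flatnonzero(~keep)]
    active = np.flatnonzero(keep)
    c = c[np.ix_(active, active)]

    rowsum = c.sum(axis=1)
    t = c / rowsum[:, None]
    if reversible:
        pi = rowsum / rowsum.sum()   # exact stationary law of symmetrized counts
    else:
        evals, evecs = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(evals - 1.0)))
        v = np.real(evecs[:, i])
        pi = np.abs(v) / np.abs(v).sum()
    pi = pi / pi.sum()
    return MarkovModel(
        lag=lag, transition_matrix=t, count_matrix=counts, stationary=pi,
        centers=None if centers is None else centers[active],
        active_states=active, dropped_states=dropped, reversible=reversible,
    )


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("matrix must be row-stochastic")
    evals, evecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.abs(np.real(evecs[:, i]))
    return pi / pi.sum()


def from_transition_matrix(t: np.ndarray, lag: int = 1) -> MarkovModel:
    """Wrap a known transition matrix as a model (e.g. for kinetic Monte Carlo)."""
    t = np.asarray(t, dtype=float)
    return MarkovModel(
        lag=lag, transition_matrix=t, count_matrix=np.zeros_like(t),
        stationary=stationary_distribution(t), reversible=False,
    )


# ---------------------------------------------------------------------------
# populations <-> free energies
# ---------------------------------------------------------------------------

def population_free_energy(
    populations: float | np.ndarray,
    temperature_K: float = 300.0,
    reference: str = "complement",
    reference_state: int = 0,
) -> np.ndarray | float:
    """Per-state free energy (kcal/mol) from populations.

    ``"complement"``: dG = -RT ln(p / (1-p)) — the exchange free energy of a
    state against everything else (NMR detection-limit convention).
    ``"ground-state"``: dG_i = -RT ln(p_i / p_ref).
    """
    p = np.asarray(populations, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("populations must lie strictly in (0, 1)")
    rt = GAS_CONSTANT_KCAL * temperature_K
    if reference == "complement":
        dg = -rt * np.log(p / (1.0 - p))
    elif reference == "ground-state":
        dg = -rt * np.log(p / p.flat[reference_state])
    else:
        raise ValueError(f"unknown reference convention '{reference}'")
    return float(dg) if np.isscalar(populations) else dg


def population_from_free_energy(
    dg_kcal_mol: float | np.ndarray,
    temperature_K: float = 300.0,
) -> np.ndarray | float:
    """Inverse of the complement-convention free energy: p = 1/(1+e^{dG/RT})."""
    g = np.asarray(dg_kcal_mol, dtype=float)
    rt = GAS_CONSTANT_KCAL * temperature_K
    p = 1.0 / (1.0 + np.exp(g / rt))
    return float(p) if np.isscalar(dg_kcal_mol) else p


# ---------------------------------------------------------------------------
# kinetic Monte Carlo
# ---------------------------------------------------------------------------

def kmc_trajectory(
    model: MarkovModel, n_steps: int, start_state: int = 0, seed: int = 0
) -> np.ndarray:
    """Sample a discrete state sequence from the transition matrix.

    Each step draws the next state from the current row's categorical
    distribution; reproducible given the seed.
    """
    t = model.transition_matrix
    if not 0 <= start_state < model.n_states:
        raise ValueError(f"start state {start_state} not in model")
    if np.any(np.isclose(np.diag(t), 1.0)):
        absorbing = np.flatnonzero(np.isclose(np.diag(t), 1.0))
        warnings.warn(f"absorbing state(s) {absorbing.tolist()}: the chain "
                      "may never leave them", stacklevel=2)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0
    draws = rng.random(n_steps)
    out = np.empty(n_steps + 1, dtype=np.int64)
    out[0] = start_state
    s = start_state
    for i in range(n_steps):
        s = int(np.searchsorted(cum[s], draws[i], side="right"))
        out[i + 1] = s
    return out
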