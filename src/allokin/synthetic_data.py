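"""Seeded generators with planted ground truth for every analysis stage.

Each generator emulates the statistical structure its consumer assumes:

- ``gen_shift_tables``: a ligation series (apo -> nucleotide -> ternary) of
  amide peak tables in which planted residue networks respond linearly to a
  common activation coordinate x in [0, 1] (plus Gaussian noise), while the
  remaining residues only wiggle within their linewidths.  Substrate for
  the covariance (CHESCA) and equilibrium-density (CONCISE) analyses.
- ``gen_itc_experiment``: a pair of single-site isotherms with a planted
  dissociation constant, enthalpy and cooperativity coefficient sigma.
- ``gen_markov_features``: metastable hidden-state dynamics with Gaussian
  emissions in feature space, for the MSM toolkit.
- ``gen_ensemble_shifts``: two-state (ground/excited) conformer shift
  ensembles with stated means and spreads, for the Δω comparison.

All generators are deterministic given their seed and return the planted
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .itc import BindingIsotherm, simulate_isotherm
from .peakio import PeakTable, StateSet, align_states
from .cs_tools import EnsembleShiftTable
from .msmkit import FeatureTrajectory

__all__ = [
    "ClusterSpec",
    "NetworkSpec",
    "PlantedNetwork",
    "gen_shift_tables",
    "gen_itc_experiment",
    "gen_markov_features",
    "gen_ensemble_shifts",
]

#: default activation-coordinate values of the four ligation states:
#: apo (open), ADP-bound, ATPgN-bound (intermediate), ternary (closed)
DEFAULT_STATE_COORDS = {
    "apo": 0.0,
    "ADP": 0.5,
    "ATPgN": 0.8,
    "ATPgN_PKI": 1.0,
}


@dataclass
class ClusterSpec:
    """One planted allosteric network.

    Members respond along a common (H, N) shift direction with per-residue
    magnitudes, driven by a common per-cluster activation coordinate, so
    the members' centered response rows are proportional — the signature a
    covariance analysis looks for.  ``coords`` maps state -> coordinate
    value; None means the cluster follows the series' primary activation
    coordinate.  Per-residue amplitudes are ``magnitude * direction``.
    """

    residues: list[int]
    direction_H_ppm: float = 0.1
    direction_N_ppm: float = 0.65
    magnitudes: np.ndarray | None = None   # per-residue scalars, default U(0.6, 1.4)
    coords: dict[str, float] | None = None


@dataclass
class NetworkSpec:
    """Study conditions of the planted ligation series.

    ``noise_fraction`` scales the per-nucleus Gaussian noise sd relative to
    the residue's across-state RMS response deviation (so 0.05 means the
    scatter around the linear trajectory is 5% of the trajectory's spread).
    ``sign_flips`` lists residues whose whole response runs in the opposite
    direction (an uncoordinated responder).  ``coordinate_jitter`` adds a
    per-residue, per-state perturbation to x for non-linear responses.
    """

    n_residues: int = 150
    state_coords: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_COORDS))
    clusters: list[ClusterSpec] | None = None
    noise_fraction: float = 0.05
    sign_flips: set[int] = field(default_factory=set)
    coordinate_jitter: float = 0.0
    linewidth_H_ppm: float = 0.01
    linewidth_N_ppm: float = 0.05
    background_sd_H_ppm: float = 0.002
    background_sd_N_ppm: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.state_coords) < 2:
            raise ValueError("need at least 2 states")
        xs = list(self.state_coords.values())
        if len(set(xs)) != len(xs):
            raise ValueError("state coordinate values must be distinct")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.clusters is not None:
            seen: set[int] = set()
            for c in self.clusters:
                overlap = seen & set(c.residues)
                if overlap:
                    raise ValueError(f"clusters overlap at residues {sorted(overlap)}")
                seen |= set(c.residues)


@dataclass
class PlantedNetwork:
    """Ground truth shipped with a generated ligation series."""

    cluster_of: dict[int, int]        # residue -> cluster index (0 = background)
    state_coords: dict[str, float]
    amp_H_ppm: dict[int, float]
    amp_N_ppm: dict[int, float]
    sign: dict[int, int]

    @property
    def network_residues(self) -> list[int]:
        return sorted(r for r, c in self.cluster_of.items() if c > 0)

    def labels(self, residues: list[int]) -> np.ndarray:
        return np.array([self.cluster_of[r] for r in residues])


def _orthogonal_coords(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A centered state pattern orthogonal to the primary coordinate.

    Two residue networks responding to *different* underlying equilibria are
    mutually uncorrelated exactly when their centered coordinate patterns
    are orthogonal; this draws such a pattern with the same spread as x.
    """
    xc = x - x.mean()
    for _ in range(100):
        y = rng.normal(0.0, 1.0, len(x))
        yc = y - y.mean()
        yc = yc - (yc @ xc) / (xc @ xc) * xc
        if np.linalg.norm(yc) > 1e-8:
            break
    else:  # pragma: no cover - vanishing probability
        raise RuntimeError("could not construct an orthogonal pattern")
    yc *= x.std() / yc.std()
    return yc + x.mean()


def _default_clusters(spec: NetworkSpec, rng: np.random.Generator,
                      labels: list[str], x: np.ndarray) -> list[ClusterSpec]:
    """Two 15-residue networks in fixed sequence blocks.

    The first follows the primary activation coordinate; the second follows
    an orthogonal state pattern (a distinct allosteric process).
    """
    n = spec.n_residues
    if n < 40:
        raise ValueError("default cluster layout needs >= 40 residues")
    blocks = [list(range(10, 25)), list(range(n - 30, n - 15))]
    y = _orthogonal_coords(x, rng)
    out = []
    for bi, block in enumerate(blocks):
        out.append(ClusterSpec(
            residues=block,
            direction_H_ppm=float(rng.uniform(0.05, 0.15)),
            direction_N_ppm=float(rng.uniform(0.3, 1.0)),
            magnitudes=rng.uniform(0.6, 1.4, len(block)),
            coords=None if bi == 0 else dict(zip(labels, y)),
        ))
    return out


def gen_shift_tables(spec: NetworkSpec) -> tuple[StateSet, PlantedNetwork]:
    """Generate the per-state peak tables and the planted truth record.

    A networked residue's shift in state s is
    ``baseline + sign * magnitude * direction * c_s + noise`` per nucleus,
    with c the cluster's activation coordinate; background residues receive
    independent perturbations well inside their linewidths.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.state_coords)
    x = np.array([spec.state_coords[s] for s in labels])
    x_spread = x.std()
    clusters = spec.clusters or _default_clusters(spec, rng, labels, x)

    cluster_of = {r: 0 for r in range(1, spec.n_residues + 1)}
    amp_h: dict[int, float] = {}
    amp_n: dict[int, float] = {}
    sign: dict[int, int] = {}
    coord_of: dict[int, np.ndarray] = {}
    for ci, c in enumerate(clusters, start=1):
        mags = (np.asarray(c.magnitudes, dtype=float) if c.magnitudes is not None
                else rng.uniform(0.6, 1.4, len(c.residues)))
        if len(mags) != len(c.residues):
            raise ValueError("one magnitude per cluster residue required")
        coords = (x if c.coords is None
                  else np.array([c.coords[s] for s in labels]))
        for r, s_i in zip(c.residues, mags):
            if not 1 <= r <= spec.n_residues:
                raise ValueError(f"cluster residue {r} outside 1..{spec.n_residues}")
            cluster_of[r] = ci
            amp_h[r] = float(s_i * c.direction_H_ppm)
            amp_n[r] = float(s_i * c.direction_N_ppm)
            sign[r] = -1 if r in spec.sign_flips else 1
            coord_of[r] = coords

    base_h = rng.uniform(7.0, 9.5, spec.n_residues)
    base_n = rng.uniform(105.0, 130.0, spec.n_residues)

    tables = []
    for s_idx, lab in enumerate(labels):
        rows = []
        for i, r in enumerate(range(1, spec.n_residues + 1)):
            if cluster_of[r] > 0:
                cr = coord_of[r][s_idx]
                if spec.coordinate_jitter > 0:
                    cr = cr + rng.normal(0.0, spec.coordinate_jitter)
                sh = base_h[i] + sign[r] * amp_h[r] * cr
                sn = base_n[i] + sign[r] * amp_n[r] * cr
                sh += rng.normal(0.0, spec.noise_fraction * amp_h[r] * x_spread)
                sn += rng.normal(0.0, spec.noise_fraction * amp_n[r] * x_spread)
            else:
                sh = base_h[i] + rng.normal(0.0, spec.background_sd_H_ppm)
                sn = base_n[i] + rng.normal(0.0, spec.background_sd_N_ppm)
            rows.append({"residue": r, "atom": "H", "shift_ppm": sh,
                         "linewidth_ppm": spec.linewidth_H_ppm})
            rows.append({"residue": r, "atom": "N", "shift_ppm": sn,
                         "linewidth_ppm": spec.linewidth_N_ppm})
        tables.append(PeakTable(state_label=lab, data=pd.DataFrame(rows)))

    states = align_states(tables)
    truth = PlantedNetwork(
        cluster_of=cluster_of, state_coords=dict(spec.state_coords),
        amp_H_ppm=amp_h, amp_N_ppm=amp_n, sign=sign,
    )
    return states, truth


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def gen_itc_experiment(
    Kd_uM: float = 17.0,
    dH_kcal_mol: float = -11.0,
    n: float = 1.0,
    sigma_planted: float = 3.0,
    noise_fraction: float = 0.02,
    seed: int = 0,
    cell_conc_uM: float = 100.0,
    syringe_conc_uM: float = 1000.0,
    cell_volume_uL: float = 300.0,
    n_injections: int = 25,
    injection_volume_uL: float = 2.0,
    temperature_K: float = 300.0,
) -> tuple[BindingIsotherm, BindingIsotherm, dict]:
    """Paired isotherms (apo-like, nucleotide-saturated-like) with planted sigma.

    The second experiment's dissociation constant is ``Kd / sigma_planted``.
    Noise is multiplicative Gaussian on each injection heat, with a small
    additive floor so near-zero saturated heats are not noise-free.
    """
    if sigma_planted <= 0:
        raise ValueError("sigma_planted must be positive")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    vols = np.full(n_injections, injection_volume_uL)
    out = []
    for kd in (Kd_uM, Kd_uM / sigma_planted):
        iso = simulate_isotherm(
            kd, dH_kcal_mol, n=n, cell_conc_uM=cell_conc_uM,
            syringe_conc_uM=syringe_conc_uM, cell_volume_uL=cell_volume_uL,
            injection_volumes_uL=vols, temperature_K=temperature_K,
        )
        if noise_fraction > 0:
            floor = noise_fraction * np.abs(iso.heats_ucal).max() * 0.05
            noisy = (iso.heats_ucal * (1.0 + rng.normal(0.0, noise_fraction,
                                                        n_injections))
                     + rng.normal(0.0, floor, n_injections))
            iso.heats_ucal = noisy
        out.append(iso)
    truth = {"Kd_apo_uM": Kd_uM, "Kd_nucleotide_uM": Kd_uM / sigma_planted,
             "dH_kcal_mol": dH_kcal_mol, "n": n, "sigma": sigma_planted}
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# Markov dynamics
# ---------------------------------------------------------------------------

def gen_markov_features(
    T_true: np.ndarray,
    emission_means: np.ndarray,
    emission_sds: np.ndarray | float = 0.1,
    n_traj: int = 1,
    length: int = 10_000,
    seed: int = 0,
    start_state: int | None = None,
) -> tuple[list[FeatureTrajectory], list[np.ndarray], dict]:
    """Hidden-state chains from ``T_true`` with Gaussian feature emissions.

    Returns (trajectories, true state label sequences, truth dict with the
    stationary distribution of ``T_true``).
    """
    t = np.asarray(T_true, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("T_true must be square")
    if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("T_true must be row-stochastic")
    means = np.atleast_2d(np.asarray(emission_means, dtype=float))
    if means.shape[0] != t.shape[0]:
        raise ValueError("one emission mean per hidden state required")
    sds = np.broadcast_to(np.asarray(emission_sds, dtype=float),
                          means.shape).copy()
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.abs(np.real(evecs[:, i]))
    pi /= pi.sum()

    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0
    trajs, labels = [], []
    for k in range(n_traj):
        s = (int(rng.choice(t.shape[0], p=pi)) if start_state is None
             else start_state)
        seq = np.empty(length, dtype=np.int64)
        draws = rng.random(length)
        for j in range(length):
            seq[j] = s
            s = int(np.searchsorted(cum[s], draws[j], side="right"))
        feats = means[seq] + rng.normal(0.0, 1.0, (length, means.shape[1])) * sds[seq]
        trajs.append(FeatureTrajectory(frames=feats, traj_id=f"traj{k}"))
        labels.append(seq)
    return trajs, labels, {"stationary": pi, "T": t}


# ---------------------------------------------------------------------------
# conformer shift ensembles
# ---------------------------------------------------------------------------

def gen_ensemble_shifts(
    site_means: dict[str, dict[str, float]],
    sds: float | dict[str, float] = 0.1,
    n_conformers: int = 500,
    seed: int = 0,
) -> tuple[EnsembleShiftTable, pd.DataFrame]:
    """Gaussian conformer shift ensembles per state.

    ``site_means`` maps state label -> {site -> mean shift (ppm)}; ``sds``
    is a common spread or a per-state spread.  Returns the ensemble table
    and the planted signed Δω per site between consecutive state pairs
    (later state minus earlier state, in insertion order).
    """
    states = list(site_means)
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    sites = list(site_means[states[0]])
    for s in states:
        if list(site_means[s]) != sites:
            raise ValueError("site sets must match across states")
    rng = np.random.default_rng(seed)
    rows = []
    for s in states:
        sd = sds[s] if isinstance(sds, dict) else float(sds)
        for c in range(n_conformers):
            for site in sites:
                rows.append({
                    "conformer": f"{s}_{c}", "state": s, "site": site,
                    "shift_ppm": site_means[s][site] + rng.normal(0.0, sd),
                })
    tab = EnsembleShiftTable(data=pd.DataFrame(rows))
    planted = pd.DataFrame({
        "site": sites,
        **{
            f"{b}-{a}": [site_means[b][x] - site_means[a][x] for x in sites]
            for a, b in zip(states[:-1], states[1:])
        },
    }).set_index("site")
    return tab, planted
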