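"""CONCISE: coordinated chemical-shift behaviour along a binding equilibrium.

Residues whose (dH, scaled dN) shifts move linearly across a ligation series
report on a single underlying conformational equilibrium (e.g. open ->
intermediate -> closed).  For each such residue the per-state shift
deviations are projected on the residue's leading principal axis (PC1); the
standardized PC1 scores are pooled over residues, and a normal density
fitted per state.  The density means track the position of the equilibrium
in each state; their widths report how coordinated the response is — an
uncoordinated protein (e.g. an allosterically uncoupled mutant) shows
broader densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peakio import StateSet

__all__ = [
    "ResidueTrajectory",
    "ConciseResult",
    "residue_pca",
    "filter_linear_residues",
    "state_densities",
    "concise_analysis",
]

#: default fraction of variance PC1 must carry for a residue to count as
#: "linearly responding"
DEFAULT_LINEARITY_MIN = 0.85


@dataclass
class ResidueTrajectory:
    """One residue's shift trajectory across states, reduced to PC1.

    scores are standardized across states (mean 0, variance 1); unresponsive
    residues (zero total variance) carry ``linearity=None`` and are flagged.
    """

    residue: int
    deviations: np.ndarray        # n_states x 2, (dH, scaled dN), state-mean removed
    pc1: np.ndarray | None        # unit 2-vector
    linearity: float | None       # lambda1 / (lambda1 + lambda2)
    scores: np.ndarray | None     # standardized PC1 scores per state
    unresponsive: bool = False


@dataclass
class ConciseResult:
    """Per-state normal densities over pooled standardized PC1 scores."""

    state_order: list[str]
    retained: list[int]
    scores: pd.DataFrame          # residues x states
    densities: pd.DataFrame       # states x (mean, sd)
    degenerate_width: bool = False


def _deviation_vectors(states: StateSet, residue: int) -> np.ndarray:
    t = np.array([
        [states.table(lab).shift(residue, "H"),
         states.scaling_factor * states.table(lab).shift(residue, "N")]
        for lab in states.labels
    ])
    return t - t.mean(axis=0)


def residue_pca(states: StateSet, residue: int, orient: str = "loading") -> ResidueTrajectory:
    """PCA of one residue's per-state (dH, scaled dN) deviations.

    ``linearity`` is the fraction of across-state variance on PC1.  Scores
    are standardized to mean 0 / variance 1 across states.

    The sign of PC1 is arbitrary; two orientation conventions are offered:

    - ``"loading"`` (default): the largest-magnitude loading of PC1 is made
      positive.  Residues whose responses run *against* the consensus
      direction keep inverted scores, so uncoordinated responses broaden the
      pooled densities.
    - ``"endpoint"``: the last state in the declared order gets a
      non-negative score (tie -> +).  This normalises every residue onto the
      declared direction of the equilibrium regardless of its own response
      sign.

    Under a global sign flip of the input data the endpoint convention
    leaves every score unchanged, while the loading convention flips all
    scores coherently (the equilibrium axis is mirrored): density widths
    and relative structure are unaffected either way.
    """
    if orient not in ("loading", "endpoint"):
        raise ValueError(f"unknown orientation '{orient}'")
    if states.n_states < 3:
        raise ValueError("residue PCA needs >= 3 states (2 states are "
                         "trivially collinear)")
    dev = _deviation_vectors(states, residue)
    cov = dev.T @ dev / dev.shape[0]
    evals, evecs = np.linalg.eigh(cov)       # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    total = lam1 + lam2
    if total <= 0 or not np.any(np.abs(dev) > 0):
        return ResidueTrajectory(residue, dev, None, None, None, unresponsive=True)
    pc1 = evecs[:, 1]
    raw = dev @ pc1
    if orient == "loading":
        i = int(np.argmax(np.abs(pc1)))
        if pc1[i] < 0:
            pc1, raw = -pc1, -raw
    else:  # endpoint: last declared state scores >= 0
        if raw[-1] < 0:
            pc1, raw = -pc1, -raw
    sd = raw.std()                            # population sd -> variance 1
    scores = raw / sd if sd > 0 else raw
    return ResidueTrajectory(
        residue=residue, deviations=dev, pc1=pc1,
        linearity=lam1 / total, scores=scores,
    )


def filter_linear_residues(
    trajectories: dict[int, ResidueTrajectory],
    csp_table: pd.DataFrame | None = None,
    linearity_min: float = DEFAULT_LINEARITY_MIN,
    csp_min: float = 0.0,
) -> set[int]:
    """Residues that responded linearly (and, optionally, significantly).

    ``csp_table`` is a ``compute_csp`` output over the endpoint pair; when
    given, residues with endpoint CSP below ``csp_min`` are excluded.
    """
    retained = set()
    for r, tr in trajectories.items():
        if tr.unresponsive or tr.linearity is None:
            continue
        if tr.linearity < linearity_min:
            continue
        if csp_table is not None and csp_min > 0:
            if r not in csp_table.index or csp_table.loc[r, "csp_ppm"] < csp_min:
                continue
        retained.add(r)
    return retained


def state_densities(
    trajectories: dict[int, ResidueTrajectory],
    retained: set[int],
    state_order: list[str],
) -> ConciseResult:
    """Fit a normal density (moment estimates) per state over pooled scores."""
    keep = sorted(r for r in retained
                  if r in trajectories and not trajectories[r].unresponsive)
    if len(keep) < 3:
        raise ValueError(f"need >= 3 retained residues, have {len(keep)}")
    score_mat = pd.DataFrame(
        {r: trajectories[r].scores for r in keep}, index=state_order
    ).T
    dens = pd.DataFrame({
        "mean_score": score_mat.mean(axis=0),
        "sd_score": score_mat.std(axis=0, ddof=1),
    })
    degenerate = bool((dens["sd_score"] == 0).any())
    return ConciseResult(
        state_order=list(state_order), retained=keep,
        scores=score_mat, densities=dens, degenerate_width=degenerate,
    )


def concise_analysis(
    states: StateSet,
    linearity_min: float = DEFAULT_LINEARITY_MIN,
    csp_min: float = 0.0,
    orient: str = "loading",
    significance: bool = True,
) -> ConciseResult:
    """End-to-end CONCISE on an aligned state series.

    By default residues must both respond linearly (``linearity_min``) and
    pass the linewidth significance filter over all state pairs — a residue
    wiggling within its linewidth carries no equilibrium information but
    would otherwise dilute the pooled densities.
    """
    from .peakio import compute_csp, significance_filter

    candidates = set(states.retained)
    if significance:
        significant, _ = significance_filter(states, pair=None,
                                             mode="any-dimension")
        candidates &= significant
    trajs = {r: residue_pca(states, r, orient=orient) for r in candidates}
    csp = compute_csp(states, states.labels[0], states.labels[-1])
    retained = filter_linear_residues(
        trajs, csp_table=csp, linearity_min=linearity_min, csp_min=csp_min
    )
    return state_densities(trajs, retained, states.labels)
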