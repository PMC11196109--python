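"""Ensemble chemical-shift comparison and the replica-averaged restraint.

Two tools connect simulated conformational ensembles to exchange NMR
observables:

- ``ensemble_delta_omega``: for each labeled site, the difference between
  the mean predicted shift of two conformational states (e.g. an excited
  state vs the ground state), with a bootstrap standard error over
  conformers.  This is the simulated counterpart of the chemical-shift
  difference Δω measured by CEST/CPMG.
- ``regression_pred_vs_exp``: ordinary least-squares comparison of
  predicted vs experimental |Δω| across sites, with a per-site sign
  (direction-of-change) agreement report.

``cs_restraint_penalty`` evaluates the harmonic replica-averaged
chemical-shift restraint used to bias simulations toward experimental
shifts:

    E_cs = alpha * sum_k sum_l ( delta_exp[k,l] - mean_m delta_calc[k,l,m] )^2

with alpha an energy/ppm^2 force constant and m running over the M replicas.
Averaging over replicas before squaring lets the ensemble, not each single
replica, match the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnsembleShiftTable",
    "RestraintSpec",
    "ensemble_delta_omega",
    "regression_pred_vs_exp",
    "cs_restraint_penalty",
]


@dataclass
class EnsembleShiftTable:
    """Per-conformer predicted shifts, labeled by conformational state.

    ``data`` columns: conformer, state, site, shift_ppm.  Each state needs
    at least 2 conformers and every conformer of a state must report the
    same site set.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"conformer", "state", "site", "shift_ppm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"ensemble table missing columns: {sorted(missing)}")
        for state, grp in self.data.groupby("state"):
            n_conf = grp["conformer"].nunique()
            if n_conf < 2:
                raise ValueError(f"state '{state}' has {n_conf} conformer(s); "
                                 "need >= 2")
            sites_per_conf = grp.groupby("conformer")["site"].apply(frozenset)
            if sites_per_conf.nunique() != 1:
                raise ValueError(f"inconsistent site sets within state '{state}'")

    @property
    def states(self) -> list[str]:
        return sorted(self.data["state"].unique())

    def site_matrix(self, state: str) -> pd.DataFrame:
        """conformers x sites shift matrix for one state."""
        grp = self.data[self.data["state"] == state]
        if grp.empty:
            raise KeyError(f"state '{state}' not in ensemble table")
        return grp.pivot(index="conformer", columns="site", values="shift_ppm")


def ensemble_delta_omega(
    tab: EnsembleShiftTable,
    state_a: str,
    state_b: str,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site Δω between two state ensembles, with bootstrap SE.

    Δω (signed) = mean shift in ``state_b`` minus mean shift in ``state_a``
    per site; ``delta_omega_ppm`` is the magnitude used for comparison with
    exchange experiments, ``delta_omega_signed_ppm`` keeps the direction.
    SE is a nonparametric bootstrap over conformers within each state.
    """
    a = tab.site_matrix(state_a)
    b = tab.site_matrix(state_b)
    sites = sorted(set(a.columns) & set(b.columns))
    if not sites:
        raise ValueError("no common sites between the two states")
    a, b = a[sites].to_numpy(), b[sites].to_numpy()
    signed = b.mean(axis=0) - a.mean(axis=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, len(sites)))
    for i in range(n_bootstrap):
        ia = rng.integers(0, a.shape[0], a.shape[0])
        ib = rng.integers(0, b.shape[0], b.shape[0])
        boots[i] = b[ib].mean(axis=0) - a[ia].mean(axis=0)
    se = boots.std(axis=0, ddof=1)
    return pd.DataFrame({
        "site": sites,
        "delta_omega_ppm": np.abs(signed),
        "delta_omega_signed_ppm": signed,
        "bootstrap_se_ppm": se,
    }).set_index("site")


def regression_pred_vs_exp(
    pairs: pd.DataFrame | list[tuple[float, float]],
    x_col: str = "exp",
    y_col: str = "pred",
) -> dict:
    """OLS fit of predicted vs experimental Δω magnitudes.

    ``pairs`` is either a DataFrame with ``exp``/``pred`` columns (optional
    ``exp_signed``/``pred_signed`` for the direction report) or a list of
    (exp, pred) tuples.  Returns slope, intercept, R², and per-point sign
    agreement when signed values are available.  Note the fit is *not*
    symmetric in x and y (R² is, the slope is not).
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(pairs, columns=[x_col, y_col])
    if len(pairs) < 2:
        raise ValueError("need at least 2 points")
    x = pairs[x_col].to_numpy(dtype=float)
    y = pairs[y_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": None,
                "direction_agreement": _directions(pairs)}
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
        "slope_stderr": float(fit.stderr),
        "direction_agreement": _directions(pairs),
    }


def _directions(pairs: pd.DataFrame) -> list[bool] | None:
    if {"exp_signed", "pred_signed"} <= set(pairs.columns):
        return list(np.sign(pairs["exp_signed"]) == np.sign(pairs["pred_signed"]))
    return None


@dataclass
class RestraintSpec:
    """Inputs of the replica-averaged shift restraint.

    ``delta_exp``: (sites,) experimental shifts; ``delta_calc``:
    (sites, M) per-replica calculated shifts for the same site order, a
    site being any (residue, atom-type) channel.
    """

    alpha: float
    delta_exp: np.ndarray
    delta_calc: np.ndarray

    def __post_init__(self) -> None:
        self.delta_exp = np.asarray(self.delta_exp, dtype=float).ravel()
        self.delta_calc = np.atleast_2d(np.asarray(self.delta_calc, dtype=float))
        if self.alpha < 0:
            raise ValueError("force constant alpha must be >= 0")
        if self.delta_calc.shape[0] != self.delta_exp.shape[0]:
            raise ValueError(
                f"site mismatch: {self.delta_exp.shape[0]} experimental vs "
                f"{self.delta_calc.shape[0]} calculated")
        if self.delta_calc.shape[1] < 1:
            raise ValueError("need at least one replica")

    @property
    def n_replicas(self) -> int:
        return self.delta_calc.shape[1]


def cs_restraint_penalty(spec: RestraintSpec) -> tuple[float, np.ndarray]:
    """Replica-averaged harmonic restraint energy and per-site contributions.

    Returns ``(E_cs, contributions)`` with
    ``E_cs = alpha * sum_site (delta_exp - replica_mean)^2``.
    """
    replica_mean = spec.delta_calc.mean(axis=1)
    contrib = spec.alpha * (spec.delta_exp - replica_mean) ** 2
    return float(contrib.sum()), contrib
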