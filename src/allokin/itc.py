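"""Single-site ITC binding analysis and the cooperativity coefficient.

An isothermal titration calorimetry experiment injects ligand X into a cell
of macromolecule M and records the heat of each injection.  For a 1:1 site
the bound-complex concentration follows the binding quadratic

    [MX] = ((Mt + Xt + Kd) - sqrt((Mt + Xt + Kd)^2 - 4 Mt Xt)) / 2

(with Mt the *site* concentration, n * [M]).  Two forward models are
provided: the discrete finite-injection model (exact quadratic before/after
each injection with displaced-volume dilution; the default and the fit
model) and the continuum Wiseman isotherm, the analytic derivative

    dQ/dXt = dH V0 [ 1/2 + (1 - (1+r)/2 - Rm/2)
                     / sqrt(Rm^2 - 2 Rm (1 - r) + (1 + r)^2) ]

with Rm = Xt/Mt and r = Kd/Mt, retained for the continuum-limit cross-check.

Thermodynamic decomposition uses dG = R T ln Kd (Kd in molar, so dG < 0 for
sub-molar affinity) and T dS = dH - dG.  The binding cooperativity
coefficient between two experiments is sigma = Kd(apo) / Kd(nucleotide),
sigma > 1 meaning the nucleotide primes the enzyme for substrate binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "BindingIsotherm",
    "BindingFit",
    "simulate_isotherm",
    "fit_single_site",
    "thermo_decompose",
    "cooperativity_sigma",
    "GAS_CONSTANT_KCAL",
]

#: gas constant, kcal / (mol K)
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass
class BindingIsotherm:
    """Integrated injection heats plus the hardware context of the run."""

    injection_volumes_uL: np.ndarray
    heats_ucal: np.ndarray
    cell_conc_uM: float
    syringe_conc_uM: float
    cell_volume_uL: float
    temperature_K: float = 300.0
    convention: str = "displaced"  # or "overfill"

    def __post_init__(self) -> None:
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.injection_volumes_uL.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats differ in length")
        if np.any(self.injection_volumes_uL <= 0):
            raise ValueError("injection volumes must be positive")
        if not np.all(np.isfinite(self.heats_ucal)):
            raise ValueError("non-finite injection heat")
        for name in ("cell_conc_uM", "syringe_conc_uM", "cell_volume_uL",
                     "temperature_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.convention not in ("displaced", "overfill"):
            raise ValueError(f"unknown dilution convention '{self.convention}'")

    @property
    def n_injections(self) -> int:
        return len(self.heats_ucal)

    def molar_ratios(self) -> np.ndarray:
        """Total ligand over total macromolecule after each injection."""
        mt, xt = _totals(self)
        return xt / mt


@dataclass
class BindingFit:
    """Fitted single-site parameters and derived thermodynamics."""

    Kd_uM: float
    dH_kcal_mol: float
    n: float
    offset_ucal: float
    dG_kcal_mol: float
    TdS_kcal_mol: float
    minus_TdS_kcal_mol: float
    Kd_stderr_uM: float | None
    dH_stderr: float | None
    n_stderr: float | None
    residual_norm_ucal: float
    converged: bool
    c_value: float
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _bound_complex(mt: np.ndarray, xt: np.ndarray, kd: float) -> np.ndarray:
    """Exact 1:1 quadratic root for [MX]; mt is the site concentration."""
    b = mt + xt + kd
    disc = np.maximum(b * b - 4.0 * mt * xt, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def _totals(iso: BindingIsotherm) -> tuple[np.ndarray, np.ndarray]:
    """Total macromolecule / ligand concentrations (uM) after each injection."""
    v0 = iso.cell_volume_uL
    m = np.empty(iso.n_injections)
    x = np.empty(iso.n_injections)
    if iso.convention == "displaced":
        mc, xc = iso.cell_conc_uM, 0.0
        for i, dv in enumerate(iso.injection_volumes_uL):
            f = 1.0 - dv / v0
            mc *= f
            xc = xc * f + iso.syringe_conc_uM * dv / v0
            m[i], x[i] = mc, xc
    else:  # overfill: track moles in the growing volume
        cum = np.cumsum(iso.injection_volumes_uL)
        m[:] = iso.cell_conc_uM * v0 / (v0 + cum)
        x[:] = iso.syringe_conc_uM * cum / (v0 + cum)
    return m, x


def _finite_injection_heats(
    iso: BindingIsotherm, kd_uM: float, dh_kcal: float, n: float
) -> np.ndarray:
    """Per-injection heats (ucal): dH * V0 * d[MX] with exact quadratics.

    Chosen so the heats telescope: their sum equals dH * V0 * [MX]_final
    exactly (heat conservation).
    """
    mt, xt = _totals(iso)
    mx = _bound_complex(n * mt, xt, kd_uM)            # uM
    prev = np.concatenate([[0.0], mx[:-1]])
    # uM * uL = pmol; kcal/mol * pmol = 1e-12 kcal = 1e-3 ucal
    return 1e-3 * dh_kcal * iso.cell_volume_uL * (mx - prev)


def wiseman_derivative(rm: np.ndarray | float, r: np.ndarray | float) -> np.ndarray | float:
    """The analytic single-site isotherm derivative d[MX]/d[Xtot].

    ``rm`` is the molar ratio Xtot/Mtot and ``r`` the reduced dissociation
    constant Kd/Mtot (both with Mtot the site concentration).
    """
    root = np.sqrt(np.asarray(rm) ** 2 - 2.0 * np.asarray(rm) * (1.0 - r)
                   + (1.0 + r) ** 2)
    return 0.5 + (1.0 - (1.0 + np.asarray(r)) / 2.0 - np.asarray(rm) / 2.0) / root


def _wiseman_heats(
    iso: BindingIsotherm, kd_uM: float, dh_kcal: float, n: float
) -> np.ndarray:
    """Continuum-isotherm heats, evaluated at midpoint compositions.

    Per injection, the first-order heat is the total differential
    d[MX] = (d[MX]/dXtot) dXtot + (d[MX]/dMtot) dMtot: the printed isotherm
    derivative along the titrant axis plus its mirror term accounting for
    the dilution of the macromolecule, so the model converges to the
    finite-injection model as injections shrink.
    """
    mt, xt = _totals(iso)
    site = n * mt
    prev_xt = np.concatenate([[0.0], xt[:-1]])
    prev_site = np.concatenate([[n * iso.cell_conc_uM], site[:-1]])
    site_mid = 0.5 * (site + prev_site)
    xt_mid = 0.5 * (xt + prev_xt)
    r = kd_uM / site_mid
    rm = xt_mid / site_mid
    d_dx = wiseman_derivative(rm, r)
    # symmetric partner: swap the roles of ligand and macromolecule
    rm_m = np.where(xt_mid > 0, site_mid / xt_mid, np.inf)
    r_m = np.where(xt_mid > 0, kd_uM / xt_mid, np.inf)
    d_dm = np.where(np.isfinite(rm_m), wiseman_derivative(rm_m, r_m), 0.0)
    dmx = d_dx * (xt - prev_xt) + d_dm * (site - prev_site)
    return 1e-3 * dh_kcal * iso.cell_volume_uL * dmx


def simulate_isotherm(
    Kd_uM: float,
    dH_kcal_mol: float,
    n: float = 1.0,
    cell_conc_uM: float = 100.0,
    syringe_conc_uM: float = 1000.0,
    cell_volume_uL: float = 300.0,
    injection_volumes_uL: np.ndarray | list[float] | None = None,
    temperature_K: float = 300.0,
    model: str = "finite-injection",
    convention: str = "displaced",
) -> BindingIsotherm:
    """Noise-free single-site isotherm under either forward model."""
    if Kd_uM <= 0 or n <= 0:
        raise ValueError("Kd and n must be positive")
    if injection_volumes_uL is None:
        injection_volumes_uL = np.full(25, 2.0)
    vols = np.asarray(injection_volumes_uL, dtype=float)
    if len(vols) < 5:
        raise ValueError("need at least 5 injections")
    iso = BindingIsotherm(
        injection_volumes_uL=vols, heats_ucal=np.zeros(len(vols)),
        cell_conc_uM=cell_conc_uM, syringe_conc_uM=syringe_conc_uM,
        cell_volume_uL=cell_volume_uL, temperature_K=temperature_K,
        convention=convention,
    )
    if model == "finite-injection":
        heats = _finite_injection_heats(iso, Kd_uM, dH_kcal_mol, n)
    elif model == "wiseman-derivative":
        heats = _wiseman_heats(iso, Kd_uM, dH_kcal_mol, n)
    else:
        raise ValueError(f"unknown model '{model}'")
    iso.heats_ucal = heats
    return iso


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_single_site(
    iso: BindingIsotherm,
    fit_n: bool = True,
    fit_offset: bool = False,
    subtract_dilution: str = "none",
    blank_heats_ucal: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> BindingFit:
    """Weighted least-squares fit of the finite-injection model.

    ``subtract_dilution`` is one of ``"none"``, ``"last-injections"`` (mean
    of the final 3 post-saturation heats is removed from every injection) or
    ``"blank-table"`` (per-injection blank heats subtracted).
    """
    if iso.n_injections < 5:
        raise ValueError("need at least 5 usable injections")
    heats = iso.heats_ucal.copy()
    if subtract_dilution == "last-injections":
        heats = heats - heats[-3:].mean()
    elif subtract_dilution == "blank-table":
        if blank_heats_ucal is None:
            raise ValueError("blank-table mode needs blank_heats_ucal")
        blank = np.asarray(blank_heats_ucal, dtype=float)
        if blank.shape != heats.shape:
            raise ValueError("blank table length mismatch")
        heats = heats - blank
    elif subtract_dilution != "none":
        raise ValueError(f"unknown dilution mode '{subtract_dilution}'")

    notes: list[str] = []
    scale = float(np.max(np.abs(heats)))
    if scale == 0.0:
        notes.append("all heats are zero: dH ~ 0 and Kd is unidentifiable")
        return BindingFit(
            Kd_uM=np.nan, dH_kcal_mol=0.0, n=np.nan, offset_ucal=0.0,
            dG_kcal_mol=np.nan, TdS_kcal_mol=np.nan, minus_TdS_kcal_mol=np.nan,
            Kd_stderr_uM=None, dH_stderr=None, n_stderr=None,
            residual_norm_ucal=0.0, converged=False, c_value=np.nan,
            warnings=notes,
        )

    w = np.ones_like(heats) if weights is None else np.asarray(weights, float)
    # heats sum ~ dH * V0 * [MX]_final; crude dH start from total heat
    dh0 = float(heats.sum() / (1e-3 * iso.cell_volume_uL * iso.cell_conc_uM)) or -1.0
    params = lmfit.Parameters()
    params.add("log10_Kd_uM", value=1.0, min=-4.0, max=6.0)
    params.add("dH", value=dh0)
    params.add("n", value=1.0, min=0.05, max=10.0, vary=fit_n)
    params.add("offset", value=0.0, vary=fit_offset)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = _finite_injection_heats(
            iso, 10.0 ** p["log10_Kd_uM"].value, p["dH"].value, p["n"].value
        ) + p["offset"].value
        return w * (heats - model)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(residual, params, method="leastsq")
    kd = 10.0 ** result.params["log10_Kd_uM"].value
    dh = result.params["dH"].value
    nfit = result.params["n"].value
    offset = result.params["offset"].value
    if not result.success:
        notes.append(
            "fit did not converge; last parameters: "
            f"Kd={kd:.4g} uM, dH={dh:.4g}, n={nfit:.4g}"
        )
    kd_err = None
    if result.params["log10_Kd_uM"].stderr is not None:
        kd_err = kd * np.log(10.0) * result.params["log10_Kd_uM"].stderr
    c = iso.cell_conc_uM * nfit / kd
    if not (0.1 <= c <= 1e4):
        notes.append(f"c-value {c:.3g} outside [0.1, 1e4]: weak identifiability")
    dg, tds, mtds = thermo_decompose(kd, dh, iso.temperature_K)
    return BindingFit(
        Kd_uM=kd, dH_kcal_mol=dh, n=nfit, offset_ucal=offset,
        dG_kcal_mol=dg, TdS_kcal_mol=tds, minus_TdS_kcal_mol=mtds,
        Kd_stderr_uM=kd_err,
        dH_stderr=result.params["dH"].stderr,
        n_stderr=result.params["n"].stderr if fit_n else None,
        residual_norm_ucal=float(np.linalg.norm(residual(result.params))),
        converged=bool(result.success), c_value=c, warnings=notes,
    )


def thermo_decompose(
    Kd_uM: float, dH_kcal_mol: float, temperature_K: float = 300.0
) -> tuple[float, float, float]:
    """(dG, TdS, -TdS) in kcal/mol from Kd (uM) and dH at temperature T."""
    if Kd_uM <= 0 or temperature_K <= 0:
        raise ValueError("Kd and T must be positive")
    dg = GAS_CONSTANT_KCAL * temperature_K * np.log(Kd_uM * 1e-6)
    tds = dH_kcal_mol - dg
    return float(dg), float(tds), float(-tds)


def cooperativity_sigma(
    fit_apo: BindingFit, fit_nucleotide: BindingFit
) -> tuple[float, float | None]:
    """sigma = Kd(apo) / Kd(nucleotide-saturated), with propagated stderr.

    sigma > 1: the nucleotide enhances substrate affinity (positive
    cooperativity); sigma < 1: negative cooperativity.
    """
    for f in (fit_apo, fit_nucleotide):
        if not f.converged:
            raise ValueError("cooperativity requires two converged fits")
        if not f.Kd_uM > 0:
            raise ValueError("non-positive Kd")
    sigma = fit_apo.Kd_uM / fit_nucleotide.Kd_uM
    err = None
    if fit_apo.Kd_stderr_uM is not None and fit_nucleotide.Kd_stderr_uM is not None:
        rel = np.hypot(fit_apo.Kd_stderr_uM / fit_apo.Kd_uM,
                       fit_nucleotide.Kd_stderr_uM / fit_nucleotide.Kd_uM)
        err = float(sigma * rel)
    return float(sigma), err


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def read_isotherm(path) -> BindingIsotherm:
    """Read an injections table with a '#key: value' header block.

    Required header keys: cell_conc_uM, syringe_conc_uM, cell_volume_uL;
    optional: temperature_K, convention.  Data rows:
    injection,volume_uL,heat_ucal.
    """
    from pathlib import Path

    meta: dict[str, str] = {}
    vols, heats = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if parts[0].lower() == "injection":
            continue
        if len(parts) != 3:
            raise ValueError(f"bad injection row: {line!r}")
        vols.append(float(parts[1]))
        heats.append(float(parts[2]))
    missing = {"cell_conc_uM", "syringe_conc_uM", "cell_volume_uL"} - set(meta)
    if missing:
        raise ValueError(f"missing header keys: {sorted(missing)}")
    return BindingIsotherm(
        injection_volumes_uL=np.array(vols), heats_ucal=np.array(heats),
        cell_conc_uM=float(meta["cell_conc_uM"]),
        syringe_conc_uM=float(meta["syringe_conc_uM"]),
        cell_volume_uL=float(meta["cell_volume_uL"]),
        temperature_K=float(meta.get("temperature_K", 300.0)),
        convention=meta.get("convention", "displaced"),
    )


def fit_report(fit: BindingFit, sigma: tuple[float, float | None] | None = None) -> str:
    lines = [
        f"Kd        = {fit.Kd_uM:.4g} uM"
        + (f" +/- {fit.Kd_stderr_uM:.2g}" if fit.Kd_stderr_uM else ""),
        f"dH        = {fit.dH_kcal_mol:.4g} kcal/mol",
        f"n         = {fit.n:.4g}",
        f"dG        = {fit.dG_kcal_mol:.4g} kcal/mol",
        f"-TdS      = {fit.minus_TdS_kcal_mol:.4g} kcal/mol",
        f"c-value   = {fit.c_value:.4g}",
        f"converged = {fit.converged}",
    ]
    if sigma is not None:
        s, e = sigma
        lines.append(f"sigma     = {s:.4g}" + (f" +/- {e:.2g}" if e else ""))
    for wmsg in fit.warnings:
        lines.append(f"warning: {wmsg}")
    return "\n".join(lines)


def isotherm_frame(iso: BindingIsotherm) -> pd.DataFrame:
    return pd.DataFrame({
        "injection": np.arange(1, iso.n_injections + 1),
        "volume_uL": iso.injection_volumes_uL,
        "molar_ratio": iso.molar_ratios(),
        "heat_ucal": iso.heats_ucal,
    })
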