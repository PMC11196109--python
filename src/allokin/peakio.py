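"""Per-state amide peak tables, state alignment, chemical-shift perturbations.

A ligand-binding (or mutation) series is observed as a set of 2D amide
fingerprints, one per ligation state.  Each fingerprint reduces to a table of
(residue, atom, shift) entries with optional linewidths.  This module reads
those tables, aligns residues across states, computes combined 1H/15N
chemical-shift perturbations

    CSP = sqrt(ddH**2 + (0.154 * ddN)**2)

with the conventional 0.154 nitrogen scaling, and applies the
linewidth-based significance filter used to select residues for covariance
analysis: a residue is kept only when its shift change strictly exceeds half
the sum of the two states' linewidths in the required dimension(s).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("allokin")

#: conventional scaling applied to 15N shift differences before combining
#: with 1H differences (ppm ranges of the two nuclei differ ~6.5-fold)
NITROGEN_SCALING = 0.154

#: fallback linewidths (ppm) when a table carries none; usage is logged
DEFAULT_LINEWIDTH_PPM = {"H": 0.01, "N": 0.05}

VALID_ATOMS = ("H", "N", "C")


class PeakTableError(ValueError):
    """Raised for malformed or inconsistent peak-table input."""


@dataclass
class PeakTable:
    """Assignments of one ligation state: (residue, atom) -> shift [ppm]."""

    state_label: str
    data: pd.DataFrame  # columns: residue, atom, shift_ppm, linewidth_ppm

    def __post_init__(self) -> None:
        required = {"residue", "atom", "shift_ppm"}
        missing = required - set(self.data.columns)
        if missing:
            raise PeakTableError(f"peak table missing columns: {sorted(missing)}")
        if "linewidth_ppm" not in self.data.columns:
            self.data = self.data.assign(linewidth_ppm=np.nan)
        dup = self.data.duplicated(subset=["residue", "atom"])
        if dup.any():
            bad = self.data.loc[dup, ["residue", "atom"]].to_records(index=False)
            raise PeakTableError(
                f"duplicate (residue, atom) entries in state "
                f"'{self.state_label}': {list(map(tuple, bad))}"
            )
        if not np.isfinite(self.data["shift_ppm"].to_numpy(dtype=float)).all():
            raise PeakTableError(f"non-finite shift in state '{self.state_label}'")
        lw = self.data["linewidth_ppm"].to_numpy(dtype=float)
        if np.any(lw[~np.isnan(lw)] < 0):
            raise PeakTableError(f"negative linewidth in state '{self.state_label}'")
        bad_atoms = set(self.data["atom"]) - set(VALID_ATOMS)
        if bad_atoms:
            raise PeakTableError(f"unknown atom labels: {sorted(bad_atoms)}")

    @property
    def residues(self) -> set[int]:
        return set(self.data["residue"].astype(int))

    def shift(self, residue: int, atom: str) -> float:
        sel = self.data[(self.data["residue"] == residue) & (self.data["atom"] == atom)]
        if sel.empty:
            raise KeyError((residue, atom))
        return float(sel["shift_ppm"].iloc[0])

    def linewidth(self, residue: int, atom: str) -> float:
        """Linewidth in ppm; falls back to the documented default (logged)."""
        sel = self.data[(self.data["residue"] == residue) & (self.data["atom"] == atom)]
        if sel.empty:
            raise KeyError((residue, atom))
        lw = float(sel["linewidth_ppm"].iloc[0])
        if math.isnan(lw):
            lw = DEFAULT_LINEWIDTH_PPM[atom]
            logger.debug(
                "state %s residue %d %s: no linewidth, using default %.3f ppm",
                self.state_label, residue, atom, lw,
            )
        return lw


@dataclass
class StateSet:
    """Aligned peak tables over an ordered series of ligation states."""

    labels: list[str]
    tables: dict[str, PeakTable]
    scaling_factor: float = NITROGEN_SCALING
    retained: list[int] = field(default_factory=list)
    dropped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise PeakTableError("a StateSet needs at least 2 states")
        if len(set(self.labels)) != len(self.labels):
            raise PeakTableError("state labels must be unique")
        if self.scaling_factor <= 0:
            raise PeakTableError("scaling_factor must be positive")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def table(self, label: str) -> PeakTable:
        try:
            return self.tables[label]
        except KeyError:
            raise KeyError(f"unknown state label '{label}' "
                           f"(have {self.labels})") from None

    def shift_matrix(self, atom: str) -> pd.DataFrame:
        """Retained residues x states matrix of raw shifts for one nucleus."""
        out = {
            lab: [self.tables[lab].shift(r, atom) for r in self.retained]
            for lab in self.labels
        }
        return pd.DataFrame(out, index=self.retained)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_ASSIGNMENT_RE = re.compile(
    r"^([A-Za-z]{0,3})(\d+)N-?H$"  # e.g. F100N-H, 100N-H
)


def read_peak_table(
    path: str | Path,
    dialect: str = "delimited",
    state_label: str | None = None,
    spectrometer_mhz: float | None = None,
) -> PeakTable:
    """Read one state's peak table from a plain-text file.

    Parameters
    ----------
    path:
        Input file.  Lines starting with ``#`` are comments.
    dialect:
        ``"delimited"`` — rows ``[state,]residue,atom,shift_ppm[,linewidth_ppm]``
        (comma or whitespace separated); or ``"assignment-list"`` — rows
        ``<res><atom-pair>  <Nshift>  <Hshift>`` such as ``F100N-H 119.8 8.21``,
        which expands into separate N and H entries.
    state_label:
        Label for the state; defaults to the file stem (delimited rows that
        carry a state column override it).
    spectrometer_mhz:
        When given, linewidth columns are interpreted as Hz and converted to
        ppm for the 1H dimension (ppm = Hz / MHz).  Only meaningful for the
        delimited dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("delimited", "assignment-list"):
        raise PeakTableError(f"unsupported dialect '{dialect}'")
    label = state_label or path.stem
    rows: list[dict] = []
    errors: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            if dialect == "delimited":
                rows.extend(_parse_delimited_line(line, label))
            else:
                rows.extend(_parse_assignment_line(line))
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise PeakTableError(f"{path}: " + "; ".join(errors))
    if not rows:
        raise PeakTableError(f"{path}: no data rows")
    frame = pd.DataFrame(rows)
    state_labels = set(frame.pop("state"))
    if len(state_labels) > 1:
        raise PeakTableError(f"{path}: multiple state labels {sorted(state_labels)}")
    if spectrometer_mhz is not None:
        frame["linewidth_ppm"] = frame["linewidth_ppm"] / float(spectrometer_mhz)
    return PeakTable(state_label=next(iter(state_labels)), data=frame)


def _parse_delimited_line(line: str, default_state: str) -> list[dict]:
    fields = [f for f in re.split(r"[,\s]+", line) if f]
    lowered = [f.lower() for f in fields]
    if "residue" in lowered and "atom" in lowered:  # header row
        return []
    state = default_state
    # optional leading state column: first field non-numeric
    if fields and not fields[0].lstrip("+-").replace(".", "", 1).isdigit():
        if fields[0] in VALID_ATOMS and len(fields) <= 3:
            raise ValueError(f"cannot parse fields {fields!r}")
        state = fields.pop(0)
    if len(fields) not in (3, 4):
        raise ValueError(f"expected 3-5 fields, got {fields!r}")
    residue_s, atom, shift_s = fields[:3]
    try:
        residue = int(residue_s)
    except ValueError:
        raise ValueError(f"non-integer residue '{residue_s}'") from None
    if residue <= 0:
        raise ValueError(f"residue must be positive, got {residue}")
    if atom not in VALID_ATOMS:
        raise ValueError(f"unknown atom '{atom}'")
    try:
        shift = float(shift_s)
    except ValueError:
        raise ValueError(f"non-numeric shift '{shift_s}'") from None
    lw = np.nan
    if len(fields) == 4:
        try:
            lw = float(fields[3])
        except ValueError:
            raise ValueError(f"non-numeric linewidth '{fields[3]}'") from None
    return [{"state": state, "residue": residue, "atom": atom,
             "shift_ppm": shift, "linewidth_ppm": lw}]


def _parse_assignment_line(line: str) -> list[dict]:
    parts = line.split()
    if len(parts) != 3:
        raise ValueError(f"expected '<assignment> <Nshift> <Hshift>', got {line!r}")
    m = _ASSIGNMENT_RE.match(parts[0])
    if not m:
        raise ValueError(f"unrecognised assignment token '{parts[0]}'")
    residue = int(m.group(2))
    if residue <= 0:
        raise ValueError(f"residue must be positive, got {residue}")
    try:
        n_shift, h_shift = float(parts[1]), float(parts[2])
    except ValueError:
        raise ValueError(f"non-numeric shift in {line!r}") from None
    return [
        {"state": "_", "residue": residue, "atom": "N",
         "shift_ppm": n_shift, "linewidth_ppm": np.nan},
        {"state": "_", "residue": residue, "atom": "H",
         "shift_ppm": h_shift, "linewidth_ppm": np.nan},
    ]


# ---------------------------------------------------------------------------
# alignment, CSP, significance filter
# ---------------------------------------------------------------------------

def align_states(
    tables: list[PeakTable],
    scaling_factor: float = NITROGEN_SCALING,
) -> StateSet:
    """Keep only residues having both H and N assignments in every state.

    Residues broadened out of (or unassigned in) any one state are dropped,
    mirroring how exchange-broadened resonances vanish from some forms of a
    titration series.
    """
    if len(tables) < 2:
        raise PeakTableError("need at least 2 peak tables to align")
    labels = [t.state_label for t in tables]
    if len(set(labels)) != len(labels):
        raise PeakTableError(f"duplicate state labels: {labels}")

    def complete(t: PeakTable) -> set[int]:
        by_atom = t.data.groupby("atom")["residue"].apply(set)
        return set.intersection(
            by_atom.get("H", set()), by_atom.get("N", set())
        )

    per_state = [complete(t) for t in tables]
    retained = sorted(set.intersection(*per_state))
    union = set.union(*(t.residues for t in tables))
    dropped = sorted(union - set(retained))
    if not retained:
        raise PeakTableError("no common residues across states")
    return StateSet(
        labels=labels,
        tables={t.state_label: t for t in tables},
        scaling_factor=scaling_factor,
        retained=list(retained),
        dropped=dropped,
    )


def compute_csp(states: StateSet, ref: str, endpoint: str) -> pd.DataFrame:
    """Combined chemical-shift perturbations between two states.

    Returns a table indexed by residue with signed ``ddH_ppm``/``ddN_ppm``
    (endpoint minus reference) and ``csp_ppm`` =
    sqrt(ddH^2 + (scaling * ddN)^2).
    """
    t_ref, t_end = states.table(ref), states.table(endpoint)
    rows = []
    for r in states.retained:
        ddh = t_end.shift(r, "H") - t_ref.shift(r, "H")
        ddn = t_end.shift(r, "N") - t_ref.shift(r, "N")
        csp = math.hypot(ddh, states.scaling_factor * ddn)
        rows.append({"residue": r, "ddH_ppm": ddh, "ddN_ppm": ddn, "csp_ppm": csp})
    out = pd.DataFrame(rows).set_index("residue")
    out.attrs["ref"] = ref
    out.attrs["endpoint"] = endpoint
    return out


def write_csp(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index().to_csv(path, index=False, float_format="%.6f")


def significance_filter(
    states: StateSet,
    pair: tuple[str, str] | None = None,
    mode: str = "any-dimension",
) -> tuple[set[int], pd.DataFrame]:
    """Linewidth-based residue selection for covariance analysis.

    A residue passes in one dimension when its shift change between the two
    states strictly exceeds half the sum of the two states' linewidths in
    that dimension.  ``mode="any-dimension"`` keeps residues passing in H
    or N; ``"both-dimensions"`` requires both.  When ``pair`` is None the
    maximum change over all state pairs is used per dimension (convenience
    mode for a full titration series).

    Returns the retained residue set and a per-residue margin table
    (change minus threshold per nucleus, positive = significant).
    """
    if mode not in ("any-dimension", "both-dimensions"):
        raise PeakTableError(f"unknown mode '{mode}'")
    if pair is not None:
        pairs = [(states.table(pair[0]), states.table(pair[1]))]
    else:
        tabs = [states.table(lab) for lab in states.labels]
        pairs = [(tabs[i], tabs[j])
                 for i in range(len(tabs)) for j in range(i + 1, len(tabs))]

    rows = []
    for r in states.retained:
        margins = {}
        for atom in ("H", "N"):
            best = -math.inf
            for ta, tb in pairs:
                change = abs(tb.shift(r, atom) - ta.shift(r, atom))
                threshold = 0.5 * ta.linewidth(r, atom) + 0.5 * tb.linewidth(r, atom)
                best = max(best, change - threshold)
            margins[atom] = best
        passes = {atom: margins[atom] > 0 for atom in ("H", "N")}  # strict
        ok = (passes["H"] or passes["N"]) if mode == "any-dimension" \
            else (passes["H"] and passes["N"])
        rows.append({"residue": r, "margin_H_ppm": margins["H"],
                     "margin_N_ppm": margins["N"], "retained": ok})
    frame = pd.DataFrame(rows).set_index("residue")
    retained = set(frame.index[frame["retained"]])
    return retained, frame
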