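import numpy as np
import pandas as pd
import pytest

from allokin.peakio import PeakTable, align_states
from allokin.synthetic_data import ClusterSpec, NetworkSpec


def make_table(state, entries):
    """entries: iterable of (residue, atom, shift[, linewidth])."""
    rows = []
    for e in entries:
        r, a, s = e[:3]
        lw = e[3] if len(e) > 3 else np.nan
        rows.append({"residue": r, "atom": a, "shift_ppm": s,
                     "linewidth_ppm": lw})
    return PeakTable(state_label=state, data=pd.DataFrame(rows))


def make_states(shifts, linewidths=None, scaling=0.154):
    """shifts: {state: {residue: (H, N)}} -> aligned StateSet."""
    tables = []
    for state, per_res in shifts.items():
        entries = []
        for r, (h, n) in per_res.items():
            lw = linewidths or {}
            entries.append((r, "H", h, lw.get("H", np.nan)))
            entries.append((r, "N", n, lw.get("N", np.nan)))
        tables.append(make_table(state, entries))
    return align_states(tables, scaling_factor=scaling)


def monotone_network_spec(seed, sign_flips=()):
    """Two planted networks that both follow the monotone activation
    coordinate (apo -> nucleotide -> ternary), the study condition for
    equilibrium-density analyses."""
    rng = np.random.default_rng(seed + 1000)
    clusters = [
        ClusterSpec(residues=list(range(10, 25)), direction_H_ppm=0.1,
                    direction_N_ppm=0.65, magnitudes=rng.uniform(0.6, 1.4, 15)),
        ClusterSpec(residues=list(range(120, 135)), direction_H_ppm=0.08,
                    direction_N_ppm=0.5, magnitudes=rng.uniform(0.6, 1.4, 15)),
    ]
    return NetworkSpec(seed=seed, clusters=clusters,
                       sign_flips=set(sign_flips))


@pytest.fixture(scope="session")
def default_network():
    """Default planted ligation series (seed 1) plus its truth record."""
    from allokin.synthetic_data import gen_shift_tables

    spec = NetworkSpec(seed=1)
    states, truth = gen_shift_tables(spec)
    return states, truth
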