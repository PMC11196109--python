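"""CHESCA: chemical-shift covariance analysis of allosteric networks.

Residue pairs whose shift responses to a perturbation series (ligand
binding, mutation) are linearly correlated are candidates for an allosteric
network.  The analysis builds a residues x states response matrix of
centered signed shift deviations, computes the Pearson correlation between
residue response vectors, clusters residues by complete-linkage
agglomeration on 1 - |Rij| (cut at 1 - Rcutoff, display cutoff 0.98), and
quantifies coupling with correlation scores:

    CorrScore(A, B)  = #(|Rij| > Rcutoff) / #pairs      (i in A, j in B)
    R_AB (community) = #(|Rij| > Rcutoff) / (nA * nB)   (cutoff 0.8)

Community membership (functionally annotated residue groups) is supplied by
the user as a plain-text mapping, not hardcoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform

from .peakio import StateSet

__all__ = [
    "ResponseMatrix",
    "CorrelationNetwork",
    "response_matrix",
    "correlation_matrix",
    "cluster_residues",
    "correlation_score",
    "community_scores",
    "read_community_map",
]

#: display cutoff for residue-level networks
DEFAULT_RCUTOFF = 0.98
#: cutoff for community-level correlation scores
DEFAULT_COMMUNITY_RCUTOFF = 0.8


@dataclass
class ResponseMatrix:
    """Signed, across-state-centered shift deviations.

    ``values`` has one row per residue; columns are the per-state dH
    deviations followed by the per-state scaled dN deviations (so each
    nucleus is centered to zero mean across states).
    """

    residues: list[int]
    states: list[str]
    values: np.ndarray  # n_residues x (2 * n_states)

    def vectors(self, mode: str = "concatenated-HN") -> np.ndarray:
        s = len(self.states)
        if mode == "concatenated-HN":
            return self.values
        if mode == "H-only":
            return self.values[:, :s]
        if mode == "N-only":
            return self.values[:, s:]
        raise ValueError(f"unknown correlation mode '{mode}'")


@dataclass
class CorrelationNetwork:
    """Symmetric |unit-diagonal| residue correlation matrix + metadata."""

    matrix: pd.DataFrame          # residues x residues, Pearson R
    rcutoff: float = DEFAULT_RCUTOFF
    mode: str = "concatenated-HN"
    excluded_zero_variance: list[int] = field(default_factory=list)
    clusters: dict[int, list[int]] = field(default_factory=dict)
    singletons: list[int] = field(default_factory=list)
    svd_singular_values: np.ndarray | None = None
    svd_variance_fractions: np.ndarray | None = None

    @property
    def residues(self) -> list[int]:
        return list(self.matrix.index)

    def edges(self, rcutoff: float | None = None) -> pd.DataFrame:
        """Residue pairs with |R| strictly above the cutoff."""
        cut = self.rcutoff if rcutoff is None else rcutoff
        res = self.residues
        m = self.matrix.to_numpy()
        rows = [
            {"residue_i": res[i], "residue_j": res[j], "R": m[i, j]}
            for i in range(len(res)) for j in range(i + 1, len(res))
            if abs(m[i, j]) > cut
        ]
        return pd.DataFrame(rows, columns=["residue_i", "residue_j", "R"])


def response_matrix(states: StateSet, residues: set[int] | list[int]) -> ResponseMatrix:
    """Build the centered residues x states response matrix (both nuclei)."""
    if states.n_states < 3:
        raise ValueError("covariance analysis needs >= 3 states")
    kept, rows = [], []
    for r in sorted(residues):
        if r not in states.retained:
            import logging
            logging.getLogger("allokin").warning(
                "residue %d missing from some state; excluded", r)
            continue
        h = np.array([states.table(lab).shift(r, "H") for lab in states.labels])
        n = np.array([states.table(lab).shift(r, "N") for lab in states.labels])
        n = states.scaling_factor * n
        rows.append(np.concatenate([h - h.mean(), n - n.mean()]))
        kept.append(r)
    return ResponseMatrix(residues=kept, states=list(states.labels),
                          values=np.array(rows))


def correlation_matrix(
    m: ResponseMatrix,
    mode: str = "concatenated-HN",
    rcutoff: float = DEFAULT_RCUTOFF,
) -> CorrelationNetwork:
    """Pearson correlations between residue response vectors."""
    vec = m.vectors(mode)
    if vec.shape[1] < 3:
        raise ValueError("need vectors of length >= 3 for correlation")
    sd = vec.std(axis=1)
    nonzero = sd > 0
    excluded = [r for r, ok in zip(m.residues, nonzero) if not ok]
    kept = [r for r, ok in zip(m.residues, nonzero) if ok]
    if not kept:
        raise ValueError("all residues have zero response variance")
    corr = np.corrcoef(vec[nonzero])
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=kept, columns=kept)
    return CorrelationNetwork(matrix=frame, rcutoff=rcutoff, mode=mode,
                              excluded_zero_variance=excluded)


def cluster_residues(
    net: CorrelationNetwork,
    response: ResponseMatrix | None = None,
) -> CorrelationNetwork:
    """Complete-linkage clustering on 1 - |R|, cut at 1 - Rcutoff.

    A cluster therefore only survives if *every* internal pair exceeds the
    cutoff in |R| — the strict reading of a displayed correlation network.
    Single-residue clusters are reported separately.  When the response
    matrix is supplied its SVD (singular values + variance fractions) is
    attached as a coherence diagnostic.
    """
    res = net.residues
    dist = 1.0 - np.abs(net.matrix.to_numpy())
    np.fill_diagonal(dist, 0.0)
    if len(res) > 1:
        z = complete(squareform(dist, checks=False))
        labels = fcluster(z, t=1.0 - net.rcutoff, criterion="distance")
    else:
        labels = np.array([1])
    groups: dict[int, list[int]] = {}
    for r, lab in zip(res, labels):
        groups.setdefault(int(lab), []).append(r)
    clusters = {lab: sorted(g) for lab, g in groups.items() if len(g) > 1}
    net.clusters = {i + 1: g for i, (_, g) in enumerate(sorted(clusters.items()))}
    net.singletons = sorted(r for _, g in groups.items() if len(g) == 1 for r in g)
    if response is not None:
        sv = np.linalg.svd(response.values, compute_uv=False)
        net.svd_singular_values = sv
        total = float((sv ** 2).sum())
        net.svd_variance_fractions = sv ** 2 / total if total > 0 else sv * 0.0
    return net


def _pair_count(
    net: CorrelationNetwork,
    subset_i: list[int],
    subset_j: list[int],
    rcutoff: float,
) -> tuple[int, int]:
    """(#pairs |R|>cutoff, #pairs) over i in A, j in B, i != j (unordered)."""
    m = net.matrix
    above = total = 0
    si, sj = set(subset_i), set(subset_j)
    seen = set()
    for i in si:
        for j in sj:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if abs(float(m.loc[i, j])) > rcutoff:  # strict: ties excluded
                above += 1
    return above, total


def correlation_score(
    net: CorrelationNetwork,
    subset_i: set[int] | list[int],
    subset_j: set[int] | list[int],
    rcutoff: float | None = None,
) -> float:
    """Fraction of cross pairs whose |R| strictly exceeds the cutoff.

    With ``subset_i`` a single residue and ``subset_j`` the rest of the
    protein this is the per-residue correlation score; with both subsets the
    whole protein it is the global score.
    """
    if not subset_i or not subset_j:
        raise ValueError("correlation_score: empty subset")
    cut = net.rcutoff if rcutoff is None else rcutoff
    missing = (set(subset_i) | set(subset_j)) - set(net.residues)
    if missing:
        raise KeyError(f"residues not in network: {sorted(missing)}")
    above, total = _pair_count(net, sorted(subset_i), sorted(subset_j), cut)
    if total == 0:
        raise ValueError("no residue pairs between subsets")
    return above / total


def community_scores(
    net: CorrelationNetwork,
    communities: dict[str, set[int]],
    rcutoff: float = DEFAULT_COMMUNITY_RCUTOFF,
) -> pd.DataFrame:
    """Community-level correlation score matrix R_AB.

    Off-diagonal entries use the nA*nB normalisation; diagonal entries
    exclude self-pairs and normalise by nA*(nA-1).  Residues in a community
    but absent from the network are ignored; a community with no residues in
    the network is an error.
    """
    present: dict[str, list[int]] = {}
    resset = set(net.residues)
    for name, members in communities.items():
        if not members:
            raise ValueError(f"community '{name}' is empty")
        inside = sorted(set(members) & resset)
        if not inside:
            raise ValueError(f"community '{name}' has no residues in the network")
        present[name] = inside
    names = list(present)
    out = pd.DataFrame(0.0, index=names, columns=names)
    mat = np.abs(net.matrix.to_numpy())
    idx = {r: i for i, r in enumerate(net.residues)}
    for a_i, a in enumerate(names):
        for b in names[a_i:]:
            ra = [idx[r] for r in present[a]]
            rb = [idx[r] for r in present[b]]
            sub = mat[np.ix_(ra, rb)]
            if a == b:
                na = len(ra)
                if na == 1:
                    score = 0.0
                else:
                    above = int((sub > rcutoff).sum()) - na  # diagonal is 1 > cutoff
                    score = above / (na * (na - 1))
                out.loc[a, a] = score
            else:
                above = int((sub > rcutoff).sum())
                score = above / (len(ra) * len(rb))
                out.loc[a, b] = out.loc[b, a] = score
    return out


def read_community_map(path: str | Path) -> dict[str, set[int]]:
    """Read a label,start,end community file (multiple rows per label).

    A residue may belong to at most one community; overlaps are an error.
    """
    path = Path(path)
    communities: dict[str, set[int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.replace(",", " ").split()]
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'label start end'")
        label, lo, hi = parts[0], int(parts[1]), int(parts[2])
        if hi < lo:
            raise ValueError(f"{path}:{lineno}: end < start")
        communities.setdefault(label, set()).update(range(lo, hi + 1))
    owner: dict[int, str] = {}
    for label, members in communities.items():
        for r in members:
            if r in owner and owner[r] != label:
                raise ValueError(
                    f"residue {r} assigned to both '{owner[r]}' and '{label}'")
            owner[r] = label
    return communities
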