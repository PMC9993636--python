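"""Binary CIVD-factor classification and the median-joining profile network.

Each subject is reduced to three binary characters: CIVD response
(presence/absence), and high/low eNO-independent and neurogenic phase-2
band amplitudes, where "high" means strictly above the mean amplitude of
the subjects without an apparent CIVD response.  The resulting 3-bit
profiles are joined into a median-joining network (Bandelt's method for
binary characters): a minimum-spanning network augmented with majority-
consensus (median) vectors wherever they shorten the total connection
length.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: profile bit order
PROFILE_BITS = ("civd", "eno_independent_high", "neurogenic_high")

TYPICAL_CIVD = (1, 1, 0)
TYPICAL_NONCIVD = (0, 0, 1)


@dataclass
class ClassificationResult:
    profiles: pd.DataFrame       # subject_id, civd, *_high, profile (tuple)
    thresholds: dict             # band -> non-CIVD group mean
    excluded: list = field(default_factory=list)


def classify_subjects(phenotypes: pd.DataFrame) -> ClassificationResult:
    """Label high/low phase-2 amplitudes against the non-CIVD group means.

    ``phenotypes`` is the per-subject table from the detection stage with
    columns civd_present, eno_independent_phase2 and neurogenic_phase2.
    Ties sit exactly on the threshold and are labeled low (strict
    inequality).  Subjects with missing phase-2 amplitudes are excluded with
    a warning.
    """
    df = phenotypes.copy()
    cols = ["eno_independent_phase2", "neurogenic_phase2"]
    missing = df[cols].isna().any(axis=1)
    excluded = list(df.loc[missing, "subject_id"])
    if excluded:
        warnings.warn(f"excluded {len(excluded)} subjects with missing phase-2 amplitudes")
        df = df.loc[~missing]
    non = df.loc[~df["civd_present"].astype(bool)]
    if non.empty:
        raise ValueError(
            "no non-CIVD subjects: the high/low thresholds are defined as the "
            "mean phase-2 amplitudes of the non-CIVD reference group"
        )
    thresholds = {c: float(non[c].mean()) for c in cols}
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "civd": df["civd_present"].astype(bool).astype(int),
            "eno_independent_high": (df[cols[0]] > thresholds[cols[0]]).astype(int),
            "neurogenic_high": (df[cols[1]] > thresholds[cols[1]]).astype(int),
        }
    ).reset_index(drop=True)
    out["profile"] = list(zip(out["civd"], out["eno_independent_high"],
                              out["neurogenic_high"]))
    return ClassificationResult(profiles=out, thresholds=thresholds, excluded=excluded)


def label_typical_groups(profiles: pd.DataFrame) -> pd.Series:
    """'typical_civd', 'typical_noncivd' or 'intermediate' per subject."""
    def lab(p):
        if tuple(p) == TYPICAL_CIVD:
            return "typical_civd"
        if tuple(p) == TYPICAL_NONCIVD:
            return "typical_noncivd"
        return "intermediate"

    return profiles["profile"].map(lab)


def _hamming(a, b) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mst_length(vectors: list[tuple]) -> int:
    """Total length of a minimum spanning tree over Hamming distances."""
    if len(vectors) <= 1:
        return 0
    g = nx.Graph()
    for i, j in itertools.combinations(range(len(vectors)), 2):
        g.add_edge(i, j, weight=_hamming(vectors[i], vectors[j]))
    return int(sum(d["weight"] for *_, d in nx.minimum_spanning_edges(g, data=True)))


def _msn(vectors: list[tuple], epsilon: int = 0) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over binary vectors.

    Kruskal-style: process distances in increasing order; an edge at
    distance d is kept if its endpoints are not yet connected by edges of
    distance <= d + epsilon (epsilon=0 gives the union of all MSTs).
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(vectors)))
    pairs = sorted(
        ((i, j, _hamming(vectors[i], vectors[j]))
         for i, j in itertools.combinations(range(len(vectors)), 2)),
        key=lambda t: t[2],
    )
    by_d: dict[int, list] = {}
    for i, j, d in pairs:
        by_d.setdefault(d, []).append((i, j))
    keep = nx.Graph()
    keep.add_nodes_from(range(len(vectors)))
    for d in sorted(by_d):
        # connectivity before considering this distance stratum
        comp = {n: c for c, nodes in enumerate(nx.connected_components(keep))
                for n in nodes}
        for i, j in by_d[d]:
            if comp[i] != comp[j]:
                keep.add_edge(i, j, weight=d)
    return keep


def _median_candidates(vectors: list[tuple]) -> set[tuple]:
    """Majority-consensus vectors of all triplets (binary characters)."""
    out = set()
    for a, b, c in itertools.combinations(vectors, 3):
        med = tuple(int(x + y + z >= 2) for x, y, z in zip(a, b, c))
        if med not in vectors:
            out.add(med)
    return out


def median_joining(
    profiles: pd.DataFrame | list[tuple], epsilon: int = 0
) -> nx.Graph:
    """Median-joining network over binary profiles.

    Accepts the classification table (with ``profile`` and one row per
    subject) or a bare list of tuples.  Median (inferred) vectors are added
    greedily while they reduce the total spanning length, then unused
    medians are pruned; for small character counts the result is refined by
    exhaustive search over all median subsets, so the returned network
    attains the minimum possible spanning length.  Nodes carry ``count``
    (subject tally; 0 for medians) and ``median`` flags; edges carry
    Hamming-distance ``weight``.
    """
    if isinstance(profiles, pd.DataFrame):
        observed = [tuple(p) for p in profiles["profile"]]
    else:
        observed = [tuple(p) for p in profiles]
    if not observed:
        raise ValueError("at least one observed profile is required")
    counts: dict[tuple, int] = {}
    for p in observed:
        counts[p] = counts.get(p, 0) + 1
    obs = sorted(counts)
    n_chars = len(obs[0])

    best = _best_median_set(obs, n_chars)
    nodes = obs + sorted(best)
    g = _msn(nodes, epsilon)
    net = nx.Graph()
    for idx, v in enumerate(nodes):
        net.add_node(v, count=counts.get(v, 0), median=v not in counts)
    for i, j, d in g.edges(data="weight"):
        net.add_edge(nodes[i], nodes[j], weight=d)
    return net


def _best_median_set(obs: list[tuple], n_chars: int) -> set[tuple]:
    """Smallest median set achieving the minimum spanning length.

    Candidate medians are iterated majority-consensus vectors (the median
    closure).  With few characters the closure is tiny, so the subset
    search is exhaustive: minimal total MST length first, then fewest
    medians.
    """
    closure = set(obs)
    while True:
        new = _median_candidates(sorted(closure)) - closure
        if not new:
            break
        closure |= new
    cands = sorted(closure - set(obs))
    base = _mst_length(obs)
    best_len, best_set = base, set()
    # smallest subsets first so ties resolve toward fewer medians
    for r in range(1, len(cands) + 1):
        improved = False
        for sub in itertools.combinations(cands, r):
            length = _mst_length(obs + list(sub))
            if length < best_len:
                best_len, best_set = length, set(sub)
                improved = True
        if best_set and not improved:
            break
    # prune medians that do not contribute (keep minimal achieving set)
    for m in sorted(best_set):
        trial = best_set - {m}
        if _mst_length(obs + sorted(trial)) == best_len:
            best_set = trial
    return best_set


def network_summary(net: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "profile": "".join(map(str, v)),
            "count": d["count"],
            "median": d["median"],
            "degree": net.degree(v),
        }
        for v, d in net.nodes(data=True)
    ]
    return pd.DataFrame(rows).sort_values("profile").reset_index(drop=True)
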