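"""Spatial mutation statistics on protein structures.

Builds residue contact graphs (two residues are in contact when any pair of
their atoms lies within a distance cutoff, 5 Å by default), calls
single-residue hotspots and 3D hotspots (neighborhoods of residues mutually
within one contact radius) against a background expectation, tests a named
residue set (e.g. a dimer interface) for mutation depletion, and contrasts
evolutionary conservation between hotspot and non-hotspot residues.

3D hotspot calling operationalizes "a group of amino acids no more than
5 Å apart": each residue's neighborhood ball (the residue plus its direct
contacts) is tested by aggregating observed and expected mass, significant
balls are merged into connected clusters, and a cluster is high-confidence
when every supplied structure model supports it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass
class ContactGraph:
    """Residue adjacency under a distance cutoff, for one structure model."""

    n_residues: int
    edges: frozenset[tuple[int, int]]
    model_id: str = ""
    cutoff: float = 5.0

    def __post_init__(self):
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on residue {i}")
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise ValueError(f"edge ({i},{j}) outside 1..{self.n_residues}")
            canon.add((min(i, j), max(i, j)))
        self.edges = frozenset(canon)
        self._adj: dict[int, set[int]] = {}
        for i, j in self.edges:
            self._adj.setdefault(i, set()).add(j)
            self._adj.setdefault(j, set()).add(i)

    def neighbors(self, residue: int) -> set[int]:
        return set(self._adj.get(residue, set()))

    def ball(self, residue: int) -> set[int]:
        """The residue plus its direct contacts."""
        return {residue} | self.neighbors(residue)


def contact_graph_from_coordinates(
    atoms: pd.DataFrame,
    cutoff: float = 5.0,
    n_residues: int | None = None,
    model_id: str = "",
) -> ContactGraph:
    """Build a contact graph from an atom table (columns: residue, x, y, z).

    Residue indices are 1-based. An edge joins residues i != j whenever the
    minimum inter-atomic distance between them is <= cutoff.
    """
    coords = atoms[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite atom coordinates")
    res = atoms["residue"].to_numpy(dtype=int)
    nres = n_residues or int(res.max())
    missing = set(range(1, nres + 1)) - set(res.tolist())
    if missing:
        warnings.warn(
            f"{len(missing)} residue(s) have no atoms and will be isolated "
            f"nodes: {sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff)
    edges = {
        (int(min(res[a], res[b])), int(max(res[a], res[b])))
        for a, b in pairs
        if res[a] != res[b]
    }
    return ContactGraph(
        n_residues=nres, edges=frozenset(edges), model_id=model_id,
        cutoff=cutoff,
    )


def atoms_from_structure(
    path: str | Path, chain: str | None = None, residue_offset: int = 0
) -> pd.DataFrame:
    """Extract an atom table from a PDB/mmCIF file via gemmi.

    ``residue_offset`` is added to the file's residue numbers so that
    numbering matches the 1-based full-length protein coordinate system
    (predicted full-length models need offset 0; truncated crystal
    structures may not).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    rows = []
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for residue in ch:
                for atom in residue:
                    rows.append(
                        {
                            "chain": ch.name,
                            "residue": residue.seqid.num + residue_offset,
                            "x": atom.pos.x,
                            "y": atom.pos.y,
                            "z": atom.pos.z,
                        }
                    )
        break  # first model only
    return pd.DataFrame(rows)


def contact_graph_from_tsv(path: str | Path, n_residues: int,
                           cutoff: float = 5.0) -> list[ContactGraph]:
    """Read precomputed contacts (res_i, res_j, model_id) into graphs."""
    df = pd.read_csv(path, sep="\t")
    graphs = []
    for model_id, sub in df.groupby("model_id", sort=True):
        edges = frozenset(
            (int(r.res_i), int(r.res_j)) for r in sub.itertuples()
        )
        graphs.append(ContactGraph(n_residues, edges, str(model_id), cutoff))
    return graphs


# ---------------------------------------------------------------------------
# Interface consensus
# ---------------------------------------------------------------------------

@dataclass
class ResidueSet:
    """A named residue set with per-residue support counts."""

    name: str
    residues: frozenset[int]
    support: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.residues = frozenset(int(r) for r in self.residues)


def consensus_interface(
    pair_contacts: Sequence[Iterable[int]],
    min_support: int = 4,
    total_pairs: int | None = None,
    name: str = "interface",
) -> ResidueSet:
    """Consensus cross-chain contact residues over chain-pair observations.

    Each element of ``pair_contacts`` is the set of reference-chain residues
    in cross-chain contact for one interacting chain pair; a residue enters
    the consensus when it appears in at least ``min_support`` pairs (4 of 6
    by default, matching consensus calling over crystallographic dimers).
    """
    total = total_pairs if total_pairs is not None else len(pair_contacts)
    if total and not 1 <= min_support <= total:
        raise ValueError("need total_pairs >= min_support >= 1")
    support: dict[int, int] = {}
    for contact_set in pair_contacts:
        for r in set(contact_set):
            support[int(r)] = support.get(int(r), 0) + 1
    members = frozenset(r for r, c in support.items() if c >= min_support)
    return ResidueSet(name=name, residues=members, support=support)


# ---------------------------------------------------------------------------
# Hotspot calling
# ---------------------------------------------------------------------------

@dataclass
class HotspotCall:
    """One significant residue (or residue cluster)."""

    residues: frozenset[int]
    observed: int
    expected: float
    p_value: float
    q_value: float
    high_confidence: bool = False
    model_ids: tuple[str, ...] = ()

    def __post_init__(self):
        assert self.expected > 0

    @property
    def residue(self) -> int:
        """Representative residue (lowest index) for single-residue calls."""
        return min(self.residues)


def _as_counts(observed: Mapping[int, int] | np.ndarray, n: int) -> np.ndarray:
    if isinstance(observed, Mapping):
        out = np.zeros(n)
        for r, c in observed.items():
            out[r - 1] = c
        return out
    out = np.asarray(observed, dtype=float)
    if len(out) != n:
        raise ValueError(f"expected {n} residues, got {len(out)}")
    return out


def _normalize_expected(expected: np.ndarray | None, n: int) -> np.ndarray:
    if expected is None:
        return np.full(n, 1.0 / n)
    e = np.asarray(expected, dtype=float)
    if np.any(e < 0) or e.sum() <= 0:
        raise ValueError("expected mass must be non-negative with positive sum")
    return e / e.sum()


def call_linear_hotspots(
    observed: Mapping[int, int] | np.ndarray,
    expected: np.ndarray | None = None,
    n_residues: int | None = None,
    alpha: float = 0.005,
    gate: str = "q",
) -> list[HotspotCall]:
    """Single-residue hotspots by one-sided binomial tests against expectation.

    Each residue's count is tested against Binomial(n_total, p_residue);
    Benjamini–Hochberg q-values are computed over all residues with
    positive expected mass and calls are gated at ``alpha`` on q (default)
    or raw p (``gate="p"``).
    """
    n = n_residues or (
        len(observed) if not isinstance(observed, Mapping)
        else max(observed, default=1)
    )
    obs = _as_counts(observed, n)
    exp = _normalize_expected(expected, n)
    n_total = int(obs.sum())
    if n_total == 0:
        raise ValueError("no observed mutations")
    testable = np.where(exp > 0)[0]
    pvals = np.array(
        [
            stats.binomtest(int(obs[i]), n_total, exp[i],
                            alternative="greater").pvalue
            for i in testable
        ]
    )
    qvals = stats.false_discovery_control(pvals, method="bh")
    gatevals = qvals if gate == "q" else pvals
    calls = []
    for idx, i in enumerate(testable):
        if gatevals[idx] < alpha:
            calls.append(
                HotspotCall(
                    residues=frozenset([int(i) + 1]),
                    observed=int(obs[i]),
                    expected=float(n_total * exp[i]),
                    p_value=float(pvals[idx]),
                    q_value=float(qvals[idx]),
                )
            )
    calls.sort(key=lambda c: (c.p_value, c.residue))
    return calls


def call_spatial_hotspots(
    observed: Mapping[int, int] | np.ndarray,
    graphs: Sequence[ContactGraph],
    expected: np.ndarray | None = None,
    alpha: float = 0.005,
    gate: str = "q",
) -> list[HotspotCall]:
    """3D hotspots: significant contact-graph neighborhoods, merged.

    Per graph, every residue's neighborhood ball (residue + direct
    contacts) is tested by aggregating observed counts and expected mass
    into a one-sided binomial test, with BH correction within the graph.
    Significant balls are merged into connected clusters on the union of
    graph edges; a cluster is reported when at least one model supports it
    and flagged ``high_confidence`` when every model does. With empty
    graphs the procedure reduces exactly to the single-residue caller.
    """
    if not graphs:
        raise ValueError("need at least one contact graph")
    n = graphs[0].n_residues
    if any(g.n_residues != n for g in graphs):
        raise ValueError("all graphs must share the protein length")
    obs = _as_counts(observed, n)
    exp = _normalize_expected(expected, n)
    n_total = int(obs.sum())
    if n_total == 0:
        raise ValueError("no observed mutations")

    sig_centers: dict[str, set[int]] = {}
    ball_stats: dict[int, tuple[int, float, float, float]] = {}
    for g in graphs:
        testable, pvals = [], []
        for r in range(1, n + 1):
            ball = sorted(g.ball(r))
            bidx = [b - 1 for b in ball]
            p_ball = float(exp[bidx].sum())
            if p_ball <= 0 or p_ball >= 1:
                continue
            o_ball = int(obs[bidx].sum())
            pv = stats.binomtest(o_ball, n_total, p_ball,
                                 alternative="greater").pvalue
            testable.append((r, o_ball, p_ball))
            pvals.append(pv)
        if not testable:
            sig_centers[g.model_id] = set()
            continue
        qvals = stats.false_discovery_control(np.array(pvals), method="bh")
        centers = set()
        for (r, o_ball, p_ball), pv, qv in zip(testable, pvals, qvals):
            gv = qv if gate == "q" else pv
            if gv < alpha:
                centers.add(r)
                prev = ball_stats.get(r)
                if prev is None or pv < prev[2]:
                    ball_stats[r] = (o_ball, n_total * p_ball, pv, qv)
        sig_centers[g.model_id] = centers

    any_centers = set().union(*sig_centers.values())
    if not any_centers:
        return []
    # connected clusters over union adjacency restricted to significant centers
    union_adj: dict[int, set[int]] = {r: set() for r in any_centers}
    for g in graphs:
        for i, j in g.edges:
            if i in any_centers and j in any_centers:
                union_adj[i].add(j)
                union_adj[j].add(i)
    clusters, seen = [], set()
    for r in sorted(any_centers):
        if r in seen:
            continue
        comp, stack = set(), [r]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(union_adj[u] - comp)
        seen |= comp
        clusters.append(comp)

    calls = []
    for comp in clusters:
        # cluster-level tally: union of member balls across graphs
        members = set(comp)
        for g in graphs:
            for r in comp:
                if r in sig_centers.get(g.model_id, ()):
                    members |= g.ball(r)
        midx = [m - 1 for m in sorted(members)]
        o = int(obs[midx].sum())
        e = float(n_total * exp[midx].sum())
        best = min(
            (ball_stats[r] for r in comp if r in ball_stats),
            key=lambda t: t[2],
        )
        supporting = tuple(
            mid for mid, centers in sig_centers.items() if centers & comp
        )
        calls.append(
            HotspotCall(
                residues=frozenset(members),
                observed=o,
                expected=e,
                p_value=best[2],
                q_value=best[3],
                high_confidence=all(
                    centers & comp for centers in sig_centers.values()
                ),
                model_ids=supporting,
            )
        )
    calls.sort(key=lambda c: (c.p_value, c.residue))
    return calls


# ---------------------------------------------------------------------------
# Interface depletion and conservation
# ---------------------------------------------------------------------------

@dataclass
class DepletionResult:
    """Depletion of mutations in a residue set relative to expectation."""

    observed_in_set: int
    expected_in_set: float
    fold_depletion: float
    p_value: float

    def __post_init__(self):
        assert self.fold_depletion >= 0


def interface_depletion_test(
    observed: Mapping[int, int] | np.ndarray,
    interface: ResidueSet,
    expected: np.ndarray | None = None,
    n_residues: int | None = None,
) -> DepletionResult:
    """Two-sided binomial test of mutation burden inside a residue set.

    fold_depletion = expected / observed (capped at +inf when observed is
    zero). The expectation defaults to the mutability-weighted mass of the
    set; with no expectation supplied, uniform-per-residue is used.
    """
    if not interface.residues:
        raise ValueError("interface residue set is empty")
    n = n_residues or (
        len(observed) if not isinstance(observed, Mapping)
        else max(max(observed, default=1), max(interface.residues))
    )
    obs = _as_counts(observed, n)
    exp = _normalize_expected(expected, n)
    idx = [r - 1 for r in sorted(interface.residues)]
    p_set = float(exp[idx].sum())
    if p_set <= 0:
        raise ValueError("interface has zero expected mass")
    n_total = int(obs.sum())
    x = int(obs[idx].sum())
    expected_in = n_total * p_set
    pv = stats.binomtest(x, n_total, p_set, alternative="two-sided").pvalue
    fold = expected_in / x if x > 0 else float("inf")
    return DepletionResult(
        observed_in_set=x,
        expected_in_set=expected_in,
        fold_depletion=fold,
        p_value=float(pv),
    )


def conservation_contrast(
    hotspot_residues: Iterable[int],
    non_hotspot_residues: Iterable[int],
    scores: Mapping[int, float],
) -> dict:
    """Rank-sum contrast of conservation scores between residue groups.

    Scores follow the convention that lower means more evolutionarily
    constrained; ``hotspots_more_conserved`` is True when the hotspot group
    has the lower median score.
    """
    hot, cold = set(hotspot_residues), set(non_hotspot_residues)
    if hot & cold:
        raise ValueError(f"residue sets overlap: {sorted(hot & cold)[:5]}")
    if not hot or not cold:
        raise ValueError("both residue sets must be non-empty")
    xs = [scores[r] for r in sorted(hot)]
    ys = [scores[r] for r in sorted(cold)]
    no_ties = len(set(xs + ys)) == len(xs) + len(ys)
    method = "exact" if (no_ties and len(xs) <= 25 and len(ys) <= 25) else "auto"
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "hotspots_more_conserved": float(np.median(xs)) < float(np.median(ys)),
        "n_hotspot": len(xs),
        "n_non_hotspot": len(ys),
    }
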