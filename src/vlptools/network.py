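"""Interregional activity-correlation networks and cross-genotype comparison.

Per genotype, the per-animal region densities give a regions x regions
Pearson correlation matrix with two-sided p-values from the exact
t-transform ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
freedom. A functional-connectivity graph keeps the region pairs whose
correlation clears an r cutoff (default 0.85) at p below an alpha (default
0.05). Correlation structure is compared between genotypes through
Fisher's variance-stabilizing z-transform ``z = atanh(r)``: the difference
z-score is ``(z_A - z_B) / sqrt(1/(n_A - 3) + 1/(n_B - 3))`` and its
two-sided p comes from the standard normal CDF.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from vlptools.quant import ActivityTable

__all__ = [
    "CorrelationResult", "ThresholdedGraph", "GroupComparison",
    "group_average_regions", "pearson_matrix", "corr_pvalue",
    "build_graph", "fisher_z", "compare_groups", "graph_summary",
]

#: r is clipped to +/- (1 - CLIP_EPS) before atanh so degenerate perfect
#: correlations map to a large finite z instead of propagating infinities.
CLIP_EPS = 1e-12


@dataclass
class CorrelationResult:
    """Pairwise-complete Pearson correlations for one group of animals."""

    group: str
    regions: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    region_meta: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_csv(self, which: str = "r") -> str:
        frame = {"r": self.r, "p": self.p, "n": self.n}[which]
        buf = io.StringIO()
        frame.to_csv(buf, index_label="region")
        return buf.getvalue()


@dataclass
class ThresholdedGraph:
    """Regions-as-nodes graph of correlations passing the edge rule."""

    graph: nx.Graph
    r_cut: float
    p_cut: float
    signed: bool

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def edge_list_tsv(self) -> str:
        lines = ["region_i\tregion_j\tr\tp"]
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(f"{u}\t{v}\t{d['r']:.10g}\t{d['p']:.10g}")
        return "\n".join(lines) + "\n"

    def to_graphml(self) -> str:
        buf = io.BytesIO()
        nx.write_graphml(self.graph, buf)
        return buf.getvalue().decode()


@dataclass
class GroupComparison:
    """Per-pair Fisher-z difference statistics between two groups."""

    groups: tuple[str, str]
    records: pd.DataFrame  # region_i, region_j, r_A, r_B, z_A, z_B, Z, p_diff, significant
    alpha: float

    def significant_pairs(self) -> pd.DataFrame:
        return self.records[self.records["significant"]]

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.records.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def group_average_regions(
    table: ActivityTable,
    grouping: dict[str, str],
) -> ActivityTable:
    """Average each animal's densities over broader-region groupings.

    Every region present must be covered by ``grouping``; missing member
    values are excluded from the mean, and a broader region with no
    non-missing member for an animal stays missing.
    """
    uncovered = [r for r in table.regions if r not in grouping]
    if uncovered:
        raise KeyError(f"regions not covered by grouping: {uncovered}")
    broader_order: list[str] = []
    for r in table.regions:
        b = grouping[r]
        if b not in broader_order:
            broader_order.append(b)
    cols = {}
    for b in broader_order:
        members = [r for r in table.regions if grouping[r] == b]
        cols[b] = table.values[members].mean(axis=1, skipna=True)
    values = pd.DataFrame(cols, index=table.values.index)
    meta = {b: (b, b) for b in broader_order}
    return ActivityTable(values=values, groups=table.groups,
                         region_meta=meta, unit=table.unit)


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient via the exact t-transform."""
    if n < 3 or not np.isfinite(r):
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _permutation_pvalues(
    df: pd.DataFrame, r_obs: pd.DataFrame, n_perm: int, seed: int
) -> pd.DataFrame:
    """Per-pair permutation p: shuffle one region's animals, compare |r|."""
    rng = np.random.default_rng(seed)
    regions = list(df.columns)
    p = pd.DataFrame(np.nan, index=regions, columns=regions)
    for i, ri in enumerate(regions):
        for rj in regions[i + 1:]:
            pair = df[[ri, rj]].dropna()
            if len(pair) < 3 or not np.isfinite(r_obs.loc[ri, rj]):
                continue
            x = pair[ri].to_numpy()
            y = pair[rj].to_numpy()
            obs = abs(r_obs.loc[ri, rj])
            xc = x - x.mean()
            yc = y - y.mean()
            denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
            hits = 1  # count the identity permutation
            for _ in range(n_perm):
                perm = rng.permutation(yc)
                if denom > 0 and abs((xc * perm).sum() / denom) >= obs - 1e-15:
                    hits += 1
            p.loc[ri, rj] = p.loc[rj, ri] = hits / (n_perm + 1)
    return p


def pearson_matrix(
    table: ActivityTable | pd.DataFrame,
    group: str | None = None,
    method: str = "t",
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Pairwise-complete Pearson r, p and n matrices for one group.

    ``method='t'`` (default) uses the exact t-transform p-values;
    ``method='permutation'`` uses seeded sign-blind permutation p-values
    (at least 10,000 shuffles recommended for small cohorts).
    """
    meta: dict[str, tuple[str, str]] = {}
    if isinstance(table, ActivityTable):
        meta = table.region_meta
        df = table.for_group(group) if group is not None else table.values
    else:
        df = table
    if len(df) < 2:
        raise ValueError("correlation needs at least 2 animals")
    if df.shape[1] < 2:
        raise ValueError("correlation needs at least 2 regions")
    r = df.corr(method="pearson", min_periods=2)
    notna = df.notna().astype(int)
    n = pd.DataFrame(notna.T.to_numpy() @ notna.to_numpy(),
                     index=df.columns, columns=df.columns)
    np.fill_diagonal(r.values, 1.0)
    if method == "t":
        p = r.copy()
        for ri in df.columns:
            for rj in df.columns:
                p.loc[ri, rj] = corr_pvalue(r.loc[ri, rj], int(n.loc[ri, rj]))
    elif method == "permutation":
        p = _permutation_pvalues(df, r, n_perm, seed)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    np.fill_diagonal(p.values, np.nan)
    return CorrelationResult(group=group or "", regions=list(df.columns),
                             r=r, p=p, n=n, region_meta=meta)


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r), r clipped off +/-1."""
    r = np.clip(np.asarray(r, dtype=float), -(1 - CLIP_EPS), 1 - CLIP_EPS)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def build_graph(
    c: CorrelationResult,
    r_cut: float = 0.85,
    p_cut: float = 0.05,
    signed: bool = True,
) -> ThresholdedGraph:
    """Keep region pairs with p < p_cut and r > r_cut (|r| > r_cut if unsigned).

    Missing r or p never yields an edge. Only the lower triangle is
    traversed, mirroring the masked symmetric matrix, so no duplicate
    undirected edges arise. Nodes carry their broader-area label for
    colouring.
    """
    if not (0 <= p_cut <= 1):
        raise ValueError("p_cut must lie in [0, 1]")
    if not (-1 <= r_cut <= 1):
        raise ValueError("r_cut must lie in [-1, 1]")
    g = nx.Graph(group=c.group, r_cut=r_cut, p_cut=p_cut, signed=signed)
    for region in c.regions:
        area = c.region_meta.get(region, (region, ""))[1]
        g.add_node(region, area=area)
    regions = c.regions
    for i, ri in enumerate(regions):
        for rj in regions[:i]:
            r = c.r.loc[ri, rj]
            p = c.p.loc[ri, rj]
            if not (np.isfinite(r) and np.isfinite(p)):
                continue
            passes_r = (r > r_cut) if signed else (abs(r) > r_cut)
            if passes_r and p < p_cut:
                g.add_edge(rj, ri, r=float(r), p=float(p))
    return ThresholdedGraph(graph=g, r_cut=r_cut, p_cut=p_cut, signed=signed)


def compare_groups(
    cA: CorrelationResult,
    cB: CorrelationResult,
    alpha: float = 0.05,
    bh: bool = False,
) -> GroupComparison:
    """Fisher-z comparison of two groups' correlation matrices.

    For each region pair: ``Z = (atanh(r_A) - atanh(r_B)) /
    sqrt(1/(n_A-3) + 1/(n_B-3))`` and ``p = 2 * (1 - Phi(|Z|))``.
    Pairs with n <= 3 in either group are reported with missing statistics
    (the standard error is undefined there). ``bh=True`` appends
    Benjamini-Hochberg q-values as an extra column without changing the
    alpha-level ``significant`` annotation.
    """
    if list(cA.regions) != list(cB.regions):
        raise ValueError("groups must share an identical ordered region set")
    rows = []
    regions = cA.regions
    for i, ri in enumerate(regions):
        for rj in regions[i + 1:]:
            rA, rB = cA.r.loc[ri, rj], cB.r.loc[ri, rj]
            nA, nB = int(cA.n.loc[ri, rj]), int(cB.n.loc[ri, rj])
            if nA <= 3 or nB <= 3 or not (np.isfinite(rA) and np.isfinite(rB)):
                rows.append((ri, rj, rA, rB, np.nan, np.nan, np.nan, np.nan,
                             False, f"undefined: n_A={nA}, n_B={nB}"))
                continue
            zA, zB = fisher_z(rA), fisher_z(rB)
            se = np.sqrt(1.0 / (nA - 3) + 1.0 / (nB - 3))
            Z = (zA - zB) / se
            p = float(2.0 * stats.norm.sf(abs(Z)))
            rows.append((ri, rj, float(rA), float(rB), zA, zB, float(Z), p,
                         p < alpha, ""))
    records = pd.DataFrame(rows, columns=[
        "region_i", "region_j", "r_A", "r_B", "z_A", "z_B", "Z", "p_diff",
        "significant", "note"])
    if bh:
        records["q_bh"] = _bh_qvalues(records["p_diff"].to_numpy())
    return GroupComparison(groups=(cA.group, cB.group), records=records,
                           alpha=alpha)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def graph_summary(g: ThresholdedGraph) -> dict:
    """Degrees, edge count, and edges tallied by broader-area pair."""
    degrees = pd.Series(dict(g.graph.degree()), dtype=int).sort_index()
    pairs: dict[tuple[str, str], int] = {}
    for u, v in g.graph.edges():
        a = g.graph.nodes[u].get("area", "")
        b = g.graph.nodes[v].get("area", "")
        key = tuple(sorted((a, b)))
        pairs[key] = pairs.get(key, 0) + 1
    by_area = pd.DataFrame(
        [(a, b, k) for (a, b), k in sorted(pairs.items())],
        columns=["area_i", "area_j", "edges"])
    return {"degrees": degrees, "edge_count": g.edge_count,
            "edges_by_area": by_area}
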