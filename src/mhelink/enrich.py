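"""Gene-set enrichment and enrichment networks.

Two enrichment routes: one-sided hypergeometric over-representation of
the differential gene list (Fisher/ORA), and a rank-based logistic test
for gene lists ordered by PLS loadings (set membership regressed on the
normal-quantile-transformed rank).  On top of the significant terms two
graphs are built: a pathway-pathway network whose edges mark gene-overlap
(Jaccard) between significant terms, and a bipartite term-module
multi-enrichment network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def harmonize(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect member lists with a universe, dropping emptied sets."""
        out, desc = {}, {}
        for name, members in self.sets.items():
            kept = members & universe
            if kept:
                out[name] = kept
                desc[name] = self.descriptions.get(name, "")
            else:
                warnings.warn(f"gene set {name!r} empty after harmonization",
                              stacklevel=2)
        return GeneSetCollection(out, desc)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(need name, description, >=1 member)")
            name = parts[0]
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} empty")
            sets[name] = members
            desc[name] = parts[1]
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets, desc)


def fisher_ora(selected: list[str], universe: list[str],
               collection: GeneSetCollection, alpha: float = 0.05,
               relaxed: float = 0.10, two_sided: bool = False
               ) -> pd.DataFrame:
    """Hypergeometric over-representation test per gene set.

    One-sided by default (P[overlap >= observed]); ``two_sided`` doubles
    the smaller tail.  Both significance tiers are flagged: primary
    (p < alpha) and relaxed (p < relaxed).
    """
    uni = set(universe)
    sel = set(selected)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    if not sel:
        warnings.warn("empty selected list: all p-values are 1", stacklevel=2)
    coll = collection.harmonize(uni)
    N, n = len(uni), len(sel)
    rows = []
    for name, members in sorted(coll.sets.items()):
        K = len(members)
        k = len(members & sel)
        if n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            if two_sided:
                p = float(min(1.0, 2 * min(p, stats.hypergeom.cdf(k, N, K, n))))
        table = np.array([[k, n - k], [K - k, N - K - (n - k)]])
        odds = (table[0, 0] * table[1, 1]) / max(table[0, 1] * table[1, 0], 1)
        rows.append({"set": name, "n_set": K, "n_selected": n, "overlap": k,
                     "universe": N, "odds_ratio": float(odds), "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = out["p"] < alpha
    out["relaxed"] = out["p"] < relaxed
    return out


# ---------------------------------------------------------------------------
# Rank-based logistic enrichment of PLS loadings
# ---------------------------------------------------------------------------


def _rank_index(ranking: pd.DataFrame) -> pd.Series:
    """Centered normal quantiles of the loading rank (robust to scale)."""
    n = len(ranking)
    q = stats.norm.ppf((ranking["rank"].to_numpy(float) - 0.5) / n)
    return pd.Series(q, index=ranking["gene"].to_numpy())


def _score_test(x: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """Rao score test of beta = 0 in logistic membership ~ index."""
    mbar = m.mean()
    u = float(((m - mbar) * x).sum())
    v = float(mbar * (1 - mbar) * ((x - x.mean()) ** 2).sum())
    z = u / np.sqrt(v) if v > 0 else 0.0
    return z, 2.0 * stats.norm.sf(abs(z))


def ranked_enrichment(ranking: pd.DataFrame, collection: GeneSetCollection,
                      alpha: float = 0.05, min_set_size: int = 3
                      ) -> pd.DataFrame:
    """Logistic-regression enrichment over a loading-ranked gene list.

    For each set, membership of every gene in the ranking is regressed on
    the normal-quantile-transformed rank; the Wald z and two-sided p are
    reported, with BH correction across sets.  Positive coefficients mean
    enrichment towards the top (most positive loadings).  On separation or
    non-convergence the always-defined Rao score test is used instead and
    flagged in the ``method`` column.
    """
    import statsmodels.api as sm

    idx = _rank_index(ranking)
    universe = set(idx.index)
    x = idx.to_numpy(float)
    design = sm.add_constant(x)
    rows = []
    for name, members in sorted(collection.sets.items()):
        members = members & universe
        if len(members) < min_set_size:
            warnings.warn(f"set {name!r} has < {min_set_size} members in the "
                          "ranking; skipped", stacklevel=2)
            continue
        m = np.array([g in members for g in idx.index], float)
        coef = z = p = np.nan
        method = "wald"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(m, design).fit(disp=0, maxiter=100)
            coef = float(fit.params[1])
            bse = float(fit.bse[1])
            if not fit.mle_retvals.get("converged", False) or not np.isfinite(bse) or bse > 1e3:
                raise RuntimeError("unstable fit")
            z = coef / bse
            p = 2.0 * stats.norm.sf(abs(z))
        except Exception:
            method = "score"
            z, p = _score_test(x, m)
            coef = z  # sign carrier; magnitude not an MLE
        rows.append({"set": name, "n_set": len(members), "coef": coef,
                     "z": float(z), "p": float(p), "method": method,
                     "direction": "top" if z > 0 else "bottom"})
    if not rows:
        return pd.DataFrame(columns=["set", "n_set", "coef", "z", "p",
                                     "method", "direction", "fdr",
                                     "significant"]).set_index("set")
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def pathway_network(ora: pd.DataFrame, collection: GeneSetCollection,
                    jaccard_min: float = 0.10,
                    include_relaxed: bool = True) -> nx.Graph:
    """Pathway-pathway graph over the significant ORA terms.

    Nodes are terms significant at the primary tier (and, if
    ``include_relaxed``, the relaxed tier, attribute-flagged); an edge
    joins two terms when the Jaccard index of their member sets reaches
    ``jaccard_min``, weighted by that index.
    """
    keep = ora[ora["significant"] | (include_relaxed & ora["relaxed"])]
    G = nx.Graph()
    for name in sorted(keep.index):
        G.add_node(name, p=float(keep.loc[name, "p"]),
                   tier="primary" if keep.loc[name, "significant"] else "relaxed")
    names = sorted(G.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            jac = jaccard(collection.sets.get(a, set()),
                          collection.sets.get(b, set()))
            if jac >= jaccard_min:
                G.add_edge(a, b, weight=round(jac, 6), kind="term-term")
    return G


def multi_enrichment_network(per_module: dict[str, pd.DataFrame],
                             alpha: float = 0.05,
                             use_fdr: bool = True) -> nx.Graph:
    """Bipartite term-module graph from per-module ranked enrichment.

    A term is linked to every module in whose PLS-loading enrichment it is
    significant.  Terms significant in >= 2 modules are flagged
    ``central``, module-specific terms ``peripheral``.
    """
    if not per_module:
        raise ValueError("need at least one module")
    G = nx.Graph()
    col = "fdr" if use_fdr else "p"
    for module in sorted(per_module):
        G.add_node(f"module:{module}", kind="module")
        table = per_module[module]
        sig = table[table[col] < alpha] if len(table) else table
        for term in sorted(sig.index):
            if not G.has_node(term):
                G.add_node(term, kind="term")
            G.add_edge(term, f"module:{module}",
                       weight=float(sig.loc[term, col]), kind="term-module")
    terms = [n for n, d in G.nodes(data=True) if d.get("kind") == "term"]
    if not terms:
        warnings.warn("no significant terms in any module: empty network",
                      stacklevel=2)
    for t in terms:
        G.nodes[t]["role"] = "central" if G.degree(t) >= 2 else "peripheral"
    return G


def write_network(G: nx.Graph, edge_tsv: str | Path,
                  graphml: str | Path | None = None) -> None:
    """Write a graph as a canonical, deterministic edge list (and GraphML)."""
    rows = [{"source": a, "target": b,
             "type": d.get("kind", ""), "weight": d.get("weight", 1.0)}
            for a, b, d in G.edges(data=True)]
    rows.sort(key=lambda r: (r["source"], r["target"]))
    pd.DataFrame(rows, columns=["source", "target", "type", "weight"]).to_csv(
        edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(G, graphml)
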