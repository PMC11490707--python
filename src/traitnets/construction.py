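"""Trait network construction.

An observation x trait-value matrix (CWMs across sites, or the raw one-hot
matrix across species) is turned into a pairwise Pearson correlation matrix
with two-sided p-values, thresholded into a binary adjacency, and built
into an undirected networkx graph whose nodes are trait values and whose
edges are the retained correlations.

On 0/1 columns the Pearson product-moment r is exactly the phi
coefficient, so fossil-mode (direct species x trait) networks are phi
co-occurrence networks without any special casing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrices import CWMMatrix, flat_ids

__all__ = [
    "TraitCorrelation",
    "correlate",
    "threshold_adjacency",
    "build_network",
    "build_trait_network",
    "write_graphml",
    "write_edge_list",
    "write_node_table",
]


@dataclass
class TraitCorrelation:
    """Pairwise trait-value correlations with per-pair p-values.

    ``r`` and ``p`` are symmetric DataFrames indexed by the (trait, level)
    MultiIndex of the non-constant trait values; ``dropped`` lists the
    trait values excluded for having zero variance across observations
    (absent or universal in every community).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n_obs: int
    dropped: list = field(default_factory=list)

    @property
    def trait_values(self) -> pd.MultiIndex:
        return self.r.columns


def correlate(observations: CWMMatrix | pd.DataFrame) -> TraitCorrelation:
    """Pearson correlation of every trait-value pair across observations.

    Two-sided p-values come from the exact t transform
    ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom. Constant
    columns have undefined r; they are removed from the matrix, warned
    about, and recorded in ``dropped`` (the corresponding trait values
    later vanish from the network node set).
    """
    df = observations.values if isinstance(observations, CWMMatrix) else observations
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 observations for correlation, got {n}")

    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    keep = sd > 0
    dropped = [tuple(c) if isinstance(c, tuple) else c
               for c in df.columns[~keep]]
    if dropped:
        warnings.warn(
            f"{len(dropped)} constant trait-value column(s) dropped "
            f"(zero variance): {dropped[:6]}",
            stacklevel=2,
        )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant trait-value columns; nothing to correlate")

    sub = df.loc[:, keep]
    r = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1 -> t infinite -> p = 0
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry

    cols = sub.columns
    return TraitCorrelation(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n_obs=n,
        dropped=dropped,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a flat vector."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def threshold_adjacency(
    corr: TraitCorrelation,
    r_star: float = 0.2,
    alpha: float = 0.05,
    rule: str = "p_and_r",
    signed: str = "abs",
    within_trait: bool = True,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Binary adjacency from the correlation matrix.

    Parameters
    ----------
    r_star : float
        Correlation magnitude threshold (default 0.2).
    alpha : float
        Significance level for the pairwise test (default 0.05).
    rule : {'p_and_r', 'p_only', 'r_only'}
        Edge inclusion rule; the default requires both ``p < alpha`` and
        the correlation clearing ``r_star``.
    signed : {'abs', 'positive_only'}
        Whether |r| or only r itself must clear ``r_star``. Within-trait
        one-hot levels are necessarily negatively correlated, so 'abs'
        (the default) keeps those edges, with the sign stored downstream.
    within_trait : bool
        If False, pairs of levels of the same parent trait are never
        connected (their correlation is structural, not ecological).
    p_adjust : {None, 'bh'}
        Optional Benjamini-Hochberg correction over the upper-triangle
        p-values before applying ``alpha``.
    """
    if not 0.0 <= r_star <= 1.0:
        raise ValueError(f"r_star must lie in [0, 1], got {r_star}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if rule not in ("p_and_r", "p_only", "r_only"):
        raise ValueError(f"unknown rule {rule!r}")
    if signed not in ("abs", "positive_only"):
        raise ValueError(f"unknown signed mode {signed!r}")
    if p_adjust not in (None, "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    r = corr.r.to_numpy()
    p = corr.p.to_numpy()
    k = r.shape[0]
    iu = np.triu_indices(k, 1)

    if p_adjust == "bh" and len(iu[0]):
        padj = np.eye(k) * 0.0
        flat = _bh_adjust(p[iu])
        padj = np.zeros_like(p)
        padj[iu] = flat
        padj = padj + padj.T
        p = padj

    rv = np.abs(r) if signed == "abs" else r
    pass_r = rv >= r_star
    pass_p = p < alpha
    if rule == "p_and_r":
        A = pass_r & pass_p
    elif rule == "p_only":
        A = pass_p
    else:
        A = pass_r
    if signed == "positive_only":
        A &= r > 0

    A = A.astype(np.int8)
    np.fill_diagonal(A, 0)

    cols = corr.r.columns
    if not within_trait and isinstance(cols, pd.MultiIndex):
        traits = cols.get_level_values(0).to_numpy()
        same = traits[:, None] == traits[None, :]
        A[same] = 0

    return pd.DataFrame(A, index=cols, columns=cols)


def build_network(
    adjacency: pd.DataFrame,
    corr: TraitCorrelation | None = None,
    provenance: dict | None = None,
) -> nx.Graph:
    """Build the undirected trait network from a binary adjacency.

    Nodes are flat ``trait:level`` identifiers annotated with ``trait``
    and ``level``; edges carry the correlation ``r``, its ``p`` value, and
    ``sign``. Trait values present in the adjacency but with no partner
    stay as degree-0 nodes. ``provenance`` (threshold, alpha, rule, mode)
    is stored on ``G.graph``.
    """
    A = adjacency.to_numpy()
    if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.diag(A).any():
        raise ValueError("adjacency has nonzero diagonal (self-loops)")
    if corr is not None and not adjacency.columns.equals(corr.r.columns):
        raise ValueError("adjacency and correlation matrices index different trait values")

    cols = adjacency.columns
    if isinstance(cols, pd.MultiIndex):
        names = flat_ids(cols)
        annot = [{"trait": t, "level": lv} for t, lv in cols]
    else:
        names = [str(c) for c in cols]
        annot = [{} for _ in cols]

    G = nx.Graph()
    G.graph.update(provenance or {})
    for name, attrs in zip(names, annot):
        G.add_node(name, **attrs)

    rmat = corr.r.to_numpy() if corr is not None else None
    pmat = corr.p.to_numpy() if corr is not None else None
    ii, jj = np.nonzero(np.triu(A, 1))
    for i, j in zip(ii, jj):
        attrs = {}
        if rmat is not None:
            rij = float(rmat[i, j])
            attrs = {"r": rij, "p": float(pmat[i, j]), "sign": int(np.sign(rij))}
        G.add_edge(names[i], names[j], **attrs)
    return G


def build_trait_network(
    observations: CWMMatrix | pd.DataFrame,
    r_star: float = 0.2,
    alpha: float = 0.05,
    rule: str = "p_and_r",
    signed: str = "abs",
    within_trait: bool = True,
    p_adjust: str | None = None,
) -> nx.Graph:
    """correlate -> threshold -> build, with provenance recorded."""
    corr = correlate(observations)
    A = threshold_adjacency(
        corr, r_star=r_star, alpha=alpha, rule=rule, signed=signed,
        within_trait=within_trait, p_adjust=p_adjust,
    )
    prov = {
        "r_star": r_star,
        "alpha": alpha,
        "rule": rule,
        "signed": signed,
        "within_trait": within_trait,
        "p_adjust": p_adjust or "none",
        "n_obs": corr.n_obs,
        "dropped_trait_values": ", ".join(
            f"{t}:{lv}" for t, lv in corr.dropped
        ) if corr.dropped else "",
    }
    return build_network(A, corr, provenance=prov)


# ---------------------------------------------------------------- exports

def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def write_edge_list(G: nx.Graph, path) -> None:
    """Tab-separated edge list: node_a, node_b, r, p."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tr\tp\n")
        for u, v, d in sorted(G.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('r', '')}\t{d.get('p', '')}\n")


def write_node_table(G: nx.Graph, path) -> None:
    """CSV node table: trait value, parent trait, degree."""
    rows = [
        {"trait_value": n, "trait": d.get("trait", ""), "degree": G.degree(n)}
        for n, d in sorted(G.nodes(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
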