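"""Significance of trait-network metrics.

Two complementary questions, two procedures:

* *Is the observed structure different from random?* Erdős–Rényi G(n, m)
  graphs with the observed node and edge counts give a null distribution
  for each metric, compared with the observation by a permutation-style
  test with the add-one convention p = (k+1)/(B+1).

* *Do two conditions differ?* Each condition's observation rows are
  resampled with replacement (same size) B times, the full network
  pipeline rerun per resample, and the two resulting metric ensembles
  compared: group medians/IQRs, percentile 95% CIs, Welch t, Mann–Whitney
  U, and a percentile CI of the per-replicate metric difference. The
  difference CI is the calibrated decision rule; t and U on bootstrap
  ensembles overstate evidence (B correlated replicates are not B
  independent observations) and are reported for comparability with
  common practice.

A master seed spawns one child stream per replicate, so enlarging B
extends an ensemble without reshuffling its early replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrices import CWMMatrix
from .metrics import METRIC_NAMES, compute_metrics

__all__ = [
    "NullEnsemble",
    "BootstrapEnsemble",
    "ComparisonResult",
    "sample_gnm_edges",
    "er_null_ensemble",
    "permutation_pvalue",
    "bootstrap_ensemble",
    "compare_groups",
]


# ------------------------------------------------------------ G(n,m) nulls

def sample_gnm_edges(n: int, m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of m distinct edges on n labelled nodes.

    Draws m upper-triangle index pairs without replacement, so every
    m-edge graph is equally likely (the G(n, m) model).
    """
    n_pairs = n * (n - 1) // 2
    if m > n_pairs:
        raise ValueError(f"m={m} exceeds C({n},2)={n_pairs}")
    iu, ju = np.triu_indices(n, 1)
    pick = rng.choice(n_pairs, size=m, replace=False)
    return iu[pick], ju[pick]


def _centralization_from_degrees(deg: np.ndarray) -> float:
    n = len(deg)
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def _fast_modularity(n: int, edges: list[tuple[int, int]]) -> tuple[float, int]:
    """(Q, module count) via igraph's C fast-greedy CNM; isolated nodes
    become singletons. Used inside replicate loops."""
    if not edges:
        return 0.0, n
    import igraph as ig
    g = ig.Graph(n=n, edges=edges)
    membership = g.community_fastgreedy().as_clustering().membership
    return float(g.modularity(membership)), len(set(membership))


@dataclass
class NullEnsemble:
    """Metrics of B Erdős–Rényi G(n, m) replicates of an observed network."""

    n_nodes: int
    n_edges: int
    B: int
    metrics: pd.DataFrame  # B rows, one column per metric
    seed: int | None = None


def er_null_ensemble(
    net: nx.Graph | tuple[int, int],
    B: int = 1000,
    seed: int | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
    algorithm: str = "greedy",
) -> NullEnsemble:
    """G(n, m) null ensemble matched to the observed network.

    Each replicate keeps the observed node and edge counts but rewires
    uniformly at random. ``metrics`` selects which metrics to compute per
    replicate; degree-based metrics use a fast degree-count path and only
    modularity requires building each replicate graph.
    """
    if isinstance(net, tuple):
        n, m = net
    else:
        n, m = net.number_of_nodes(), net.number_of_edges()
    if n < 2:
        raise ValueError("null model needs at least 2 nodes")
    if B < 1:
        raise ValueError("B must be >= 1")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")

    need_graph = bool({"modularity_Q", "n_modules"} & set(metrics))
    density = m / (n * (n - 1) / 2)
    children = np.random.SeedSequence(seed).spawn(B)

    rows = np.empty((B, len(metrics)))
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        ii, jj = sample_gnm_edges(n, m, rng)
        deg = np.bincount(np.concatenate([ii, jj]), minlength=n).astype(float)
        if need_graph:
            if algorithm == "fastgreedy":
                q_val, n_mod = _fast_modularity(n, list(zip(ii.tolist(), jj.tolist())))
            else:
                G = nx.Graph()
                G.add_nodes_from(range(n))
                G.add_edges_from(zip(ii.tolist(), jj.tolist()))
                rep = compute_metrics(G, algorithm=algorithm)
                q_val, n_mod = rep.modularity_Q, rep.n_modules
        for k, name in enumerate(metrics):
            if name == "edge_density":
                rows[b, k] = density
            elif name == "degree_centralization":
                rows[b, k] = _centralization_from_degrees(deg) if n >= 3 else np.nan
            elif name == "modularity_Q":
                rows[b, k] = q_val
            elif name == "n_modules":
                rows[b, k] = n_mod

    return NullEnsemble(
        n_nodes=n, n_edges=m, B=B,
        metrics=pd.DataFrame(rows, columns=list(metrics)),
        seed=seed,
    )


def permutation_pvalue(observed: float, null_values, side: str = "greater") -> float:
    """Monte-Carlo p-value of an observed metric against null replicates.

    p = (k + 1) / (B + 1) with k the number of null values at least as
    extreme as the observation; ties count as extreme, and the add-one
    convention keeps p strictly positive. ``two_sided`` doubles the
    smaller tail, capped at 1.
    """
    vals = np.asarray(null_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("empty null ensemble")
    B = vals.size
    p_greater = (np.sum(vals >= observed) + 1) / (B + 1)
    p_less = (np.sum(vals <= observed) + 1) / (B + 1)
    if side == "greater":
        return float(p_greater)
    if side == "less":
        return float(p_less)
    if side == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown side {side!r}")


# ------------------------------------------------------------- bootstrap

@dataclass
class BootstrapEnsemble:
    """Metrics of B row-resampled reruns of the network pipeline.

    The resampling unit is the observation row: sites in CWM mode,
    species in direct (fossil) mode. Replicates where a metric is
    undefined (too few usable trait values after resampling) hold NaN.
    """

    B: int
    metrics: pd.DataFrame
    resampling_unit: str = "rows"
    seed: int | None = None
    n_failed: int = 0


def _pipeline_metrics_fast(
    arr: np.ndarray,
    same_trait: np.ndarray | None,
    r_star: float,
    alpha: float,
    rule: str,
    signed: str,
    within_trait: bool,
    metrics: tuple[str, ...],
    algorithm: str,
) -> dict[str, float]:
    """Run correlate -> threshold -> metrics on a raw observation array.

    numpy-only mirror of the DataFrame pipeline, used inside bootstrap
    loops; equivalence with the public path is asserted by tests.
    """
    out = {name: np.nan for name in metrics}
    n_obs = arr.shape[0]
    if n_obs < 3:
        return out
    sd = arr.std(axis=0)
    keep = sd > 0
    n = int(keep.sum())
    if n < 2:
        return out
    sub = arr[:, keep]
    r = np.clip(np.corrcoef(sub, rowvar=False), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_obs - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_obs - 2)
    p[np.isnan(p)] = 0.0

    rv = np.abs(r) if signed == "abs" else r
    if rule == "p_and_r":
        A = (rv >= r_star) & (p < alpha)
    elif rule == "p_only":
        A = p < alpha
    else:
        A = rv >= r_star
    if signed == "positive_only":
        A &= r > 0
    A = A.astype(np.int8)
    np.fill_diagonal(A, 0)
    if not within_trait and same_trait is not None:
        A[same_trait[np.ix_(keep, keep)]] = 0

    m = int(np.triu(A, 1).sum())
    deg = A.sum(axis=0).astype(float)
    if "edge_density" in metrics:
        out["edge_density"] = m / (n * (n - 1) / 2)
    if "degree_centralization" in metrics and n >= 3:
        out["degree_centralization"] = _centralization_from_degrees(deg)
    if {"modularity_Q", "n_modules"} & set(metrics):
        if algorithm == "fastgreedy":
            ii, jj = np.nonzero(np.triu(A, 1))
            q_val, n_mod = _fast_modularity(n, list(zip(ii.tolist(), jj.tolist())))
        else:
            G = nx.from_numpy_array(A)
            G.remove_edges_from(nx.selfloop_edges(G))
            rep = compute_metrics(G, algorithm=algorithm)
            q_val, n_mod = rep.modularity_Q, rep.n_modules
        if "modularity_Q" in metrics:
            out["modularity_Q"] = q_val
        if "n_modules" in metrics:
            out["n_modules"] = float(n_mod)
    return out


def bootstrap_ensemble(
    observations: CWMMatrix | pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    r_star: float = 0.2,
    alpha: float = 0.05,
    rule: str = "p_and_r",
    signed: str = "abs",
    within_trait: bool = True,
    metrics: tuple[str, ...] = METRIC_NAMES,
    algorithm: str = "greedy",
) -> BootstrapEnsemble:
    """Bootstrap the trait dataset and rebuild the network B times.

    Each replicate resamples the observation rows with replacement at the
    original size, reruns correlation, thresholding and metric
    computation, and stores the metric values. Undefined replicates
    (fewer than 3 rows is rejected up front; fewer than 2 non-constant
    trait values can still occur per replicate) are kept as NaN rows.
    """
    df = observations.values if isinstance(observations, CWMMatrix) else observations
    n_rows = len(df)
    if n_rows < 3:
        raise ValueError(f"need at least 3 observation rows to bootstrap, got {n_rows}")
    if B < 1:
        raise ValueError("B must be >= 1")

    arr = df.to_numpy(dtype=float)
    same_trait = None
    if isinstance(df.columns, pd.MultiIndex):
        traits = df.columns.get_level_values(0).to_numpy()
        same_trait = traits[:, None] == traits[None, :]

    children = np.random.SeedSequence(seed).spawn(B)
    rows = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n_rows, size=n_rows)
        rows.append(_pipeline_metrics_fast(
            arr[idx], same_trait, r_star, alpha, rule, signed,
            within_trait, metrics, algorithm,
        ))
    table = pd.DataFrame(rows, columns=list(metrics))
    n_failed = int(table.isna().all(axis=1).sum())
    if n_failed:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates had undefined metrics",
                      stacklevel=2)
    return BootstrapEnsemble(B=B, metrics=table, seed=seed, n_failed=n_failed)


# ------------------------------------------------------------ comparison

@dataclass
class ComparisonResult:
    """Two-group comparison of one bootstrap metric ensemble.

    ``significant`` is keyed to the percentile 95% CI of the
    replicate-wise metric difference excluding zero — the calibrated
    bootstrap decision. ``t``/``u`` tests treat the two ensembles as
    independent samples and are reported for comparability.
    """

    metric: str
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    ci_overlap: bool
    diff_ci: tuple[float, float]
    significant: bool
    t_stat: float
    t_p: float
    u_stat: float
    u_p: float
    B_a: int
    B_b: int

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        return (
            f"{self.metric}: median A={self.median_a:.4g} (IQR {self.iqr_a:.4g}), "
            f"B={self.median_b:.4g} (IQR {self.iqr_b:.4g}); "
            f"diff 95% CI [{self.diff_ci[0]:.4g}, {self.diff_ci[1]:.4g}] "
            f"{'excludes' if self.significant else 'includes'} 0; "
            f"U={self.u_stat:.1f} (p={self.u_p:.3g}), "
            f"t={self.t_stat:.3g} (p={self.t_p:.3g})"
        )


def compare_groups(a: BootstrapEnsemble, b: BootstrapEnsemble, metric: str) -> ComparisonResult:
    """Compare one metric between two bootstrap ensembles."""
    for ens, label in ((a, "a"), (b, "b")):
        if metric not in ens.metrics.columns:
            raise KeyError(f"metric {metric!r} missing from ensemble {label}")
    xa_full = a.metrics[metric].to_numpy(dtype=float)
    xb_full = b.metrics[metric].to_numpy(dtype=float)
    xa = xa_full[~np.isnan(xa_full)]
    xb = xb_full[~np.isnan(xb_full)]
    if xa.size == 0 or xb.size == 0:
        raise ValueError(f"metric {metric!r} undefined in every replicate of a group")

    ci_a = tuple(np.percentile(xa, [2.5, 97.5]))
    ci_b = tuple(np.percentile(xb, [2.5, 97.5]))
    overlap = (ci_a[0] <= ci_b[1]) and (ci_b[0] <= ci_a[1])

    # replicate-wise difference, paired by index over the common length
    k = min(xa_full.size, xb_full.size)
    d = xa_full[:k] - xb_full[:k]
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no replicate pairs with both metrics defined")
    diff_ci = tuple(np.percentile(d, [2.5, 97.5]))
    significant = not (diff_ci[0] <= 0.0 <= diff_ci[1])

    if np.ptp(np.concatenate([xa, xb])) == 0.0:
        warnings.warn(
            f"metric {metric!r} constant across both ensembles; tests return p = 1",
            stacklevel=2,
        )
        t_stat, t_p = 0.0, 1.0
        u_stat, u_p = xa.size * xb.size / 2.0, 1.0
    else:
        t_res = stats.ttest_ind(xa, xb, equal_var=False)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        u_res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        u_stat, u_p = float(u_res.statistic), float(u_res.pvalue)
        if np.isnan(t_p):  # zero variance within both groups, unequal means
            t_stat, t_p = float("inf") * np.sign(xa.mean() - xb.mean()), 0.0

    return ComparisonResult(
        metric=metric,
        median_a=float(np.median(xa)), median_b=float(np.median(xb)),
        iqr_a=float(np.subtract(*np.percentile(xa, [75, 25]))),
        iqr_b=float(np.subtract(*np.percentile(xb, [75, 25]))),
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_b=(float(ci_b[0]), float(ci_b[1])),
        ci_overlap=bool(overlap),
        diff_ci=(float(diff_ci[0]), float(diff_ci[1])),
        significant=bool(significant),
        t_stat=t_stat, t_p=t_p,
        u_stat=u_stat, u_p=u_p,
        B_a=int(xa.size), B_b=int(xb.size),
    )
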