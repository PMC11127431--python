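"""Beta-diversity and group-comparison statistics.

* normalised weighted UniFrac between per-sample placement-mass
  distributions on a shared reference tree, averaged over the NifD and
  NifK markers;
* non-metric multidimensional scaling (two dimensions, Kruskal stress-1,
  monotone regression by pool-adjacent-violators, multiple restarts);
* PERMANOVA with label permutations (the +1 convention, so p is never 0);
* the Brunner–Munzel rank test of stochastic superiority
  P(X<Y) + 0.5 P(X=Y) = 0.5 for pairwise environment comparisons, with
  Bonferroni correction and a compact letter display;
* Spearman rank correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skbio import DistanceMatrix, TreeNode
from sklearn.isotonic import IsotonicRegression

from diazoscope.errors import ConfigError, InputError

__all__ = [
    "weighted_unifrac", "unifrac_matrix", "average_marker_distance",
    "aggregate_placements", "brunner_munzel", "pairwise_bm_bonferroni",
    "permanova", "nmds", "spearman",
    "BMResult", "PermanovaResult", "NMDSResult",
]


# ---------------------------------------------------------------------------
# placement-based weighted UniFrac


def aggregate_placements(placements) -> dict[str, float]:
    """Average the per-read leaf-mass vectors of one sample (sums to 1)."""
    if not placements:
        raise InputError("no placements to aggregate")
    acc: dict[str, float] = {}
    for p in placements:
        for leaf, w in p.weights.items():
            acc[leaf] = acc.get(leaf, 0.0) + w
    total = sum(acc.values())
    if total <= 0:
        raise InputError("zero total placement mass")
    return {k: v / total for k, v in acc.items()}


def _branch_masses(tree: TreeNode, masses: dict[str, float]) -> dict[int, float]:
    """Mass descending through each branch (postorder accumulation)."""
    out: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            out[id(node)] = masses.get(node.name, 0.0)
        else:
            out[id(node)] = sum(out[id(c)] for c in node.children)
    return out


def weighted_unifrac(masses_a: dict[str, float], masses_b: dict[str, float],
                     tree: TreeNode) -> float:
    """Normalised weighted UniFrac between two placement-mass distributions.

    With P_S(b) the fraction of sample S's mass descending through branch
    b and l_b the branch length:

        d = sum_b l_b |P_A(b) - P_B(b)| / sum_b l_b (P_A(b) + P_B(b))

    Both distributions must be normalised on the same tree; a sample with
    zero total mass has no defined distance.
    """
    ta, tb = sum(masses_a.values()), sum(masses_b.values())
    if ta <= 0 or tb <= 0:
        raise InputError("undefined distance: a sample has zero placement mass")
    pa = {k: v / ta for k, v in masses_a.items()}
    pb = {k: v / tb for k, v in masses_b.items()}
    ba = _branch_masses(tree, pa)
    bb = _branch_masses(tree, pb)
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        num += length * abs(ba[id(node)] - bb[id(node)])
        den += length * (ba[id(node)] + bb[id(node)])
    if den == 0:
        return 0.0
    return num / den


def unifrac_matrix(sample_masses: dict[str, dict[str, float]],
                   tree: TreeNode) -> DistanceMatrix:
    """Pairwise normalised weighted UniFrac over samples."""
    ids = sorted(sample_masses)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = weighted_unifrac(sample_masses[ids[i]], sample_masses[ids[j]], tree)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def average_marker_distance(d_nifd: DistanceMatrix,
                            d_nifk: DistanceMatrix) -> DistanceMatrix:
    """Element-wise mean of the NifD and NifK distance matrices."""
    if tuple(d_nifd.ids) != tuple(d_nifk.ids):
        raise InputError("distance matrices cover different sample sets")
    return DistanceMatrix((d_nifd.data + d_nifk.data) / 2.0, d_nifd.ids)


# ---------------------------------------------------------------------------
# Brunner–Munzel


@dataclass
class BMResult:
    statistic: float          # W
    df: float
    pvalue: float
    estimate: float           # p_hat = P(X<Y) + 0.5 P(X=Y)
    p_adj: float | None = None
    method: str = "t"         # "t" or "permutation" (separation fallback)


def _bm_phat(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    my = ranks[nx:].mean()
    return (my - (ny + 1) / 2) / nx


def brunner_munzel(x, y, n_perm: int = 10_000, seed: int = 0) -> BMResult:
    """Two-sided Brunner–Munzel test with Welch-type degrees of freedom.

    Under complete separation both rank variances vanish and the
    t-statistic is undefined; the estimate p_hat (0 or 1) is reported and
    the p-value falls back to a label-permutation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("both groups need at least 2 values")
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rx_within = sps.rankdata(x)
    ry_within = sps.rankdata(y)
    mx, my = rx.mean(), ry.mean()
    vx = np.sum((rx - rx_within - mx + (nx + 1) / 2) ** 2) / (nx - 1)
    vy = np.sum((ry - ry_within - my + (ny + 1) / 2) ** 2) / (ny - 1)
    phat = (my - (ny + 1) / 2) / nx

    pooled = nx * vx + ny * vy
    if pooled <= 0:
        # complete separation (or all-tied data with p_hat = 0.5)
        warnings.warn("degenerate rank variances; permutation p-value used",
                      stacklevel=2)
        rng = np.random.default_rng(seed)
        combined = np.concatenate([x, y])
        obs = abs(phat - 0.5)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(combined)
            hits += abs(_bm_phat(perm[:nx], perm[nx:]) - 0.5) >= obs - 1e-12
        p = (1 + hits) / (1 + n_perm)
        return BMResult(statistic=math.inf if phat > 0.5 else -math.inf,
                        df=math.nan, pvalue=p, estimate=phat,
                        method="permutation")

    w = nx * ny * (my - mx) / ((nx + ny) * math.sqrt(pooled))
    df = pooled ** 2 / ((nx * vx) ** 2 / (nx - 1) + (ny * vy) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(w), df)
    return BMResult(statistic=float(w), df=float(df), pvalue=float(p),
                    estimate=float(phat))


def pairwise_bm_bonferroni(groups: dict[str, list[float]],
                           alpha: float = 0.05,
                           seed: int = 0) -> tuple[dict[str, str],
                                                   dict[tuple[str, str], BMResult]]:
    """All-pairs Brunner–Munzel with Bonferroni correction and letters.

    Groups with fewer than 2 values are excluded with a warning.  Groups
    sharing a letter are not significantly different at ``alpha`` after
    correction.
    """
    usable = {}
    for name, values in groups.items():
        vals = [v for v in values if v is not None and np.isfinite(v)]
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has <2 values; excluded", stacklevel=2)
            continue
        usable[name] = vals
    names = sorted(usable)
    if len(names) < 2:
        raise InputError("need at least 2 groups with >=2 values")
    k = len(names) * (len(names) - 1) // 2
    results: dict[tuple[str, str], BMResult] = {}
    different: set[tuple[str, str]] = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = brunner_munzel(usable[a], usable[b], seed=seed)
            res.p_adj = min(1.0, k * res.pvalue)
            results[(a, b)] = res
            if res.p_adj < alpha:
                different.add((a, b))

    letters = _compact_letter_display(names, different)
    return letters, results


def _compact_letter_display(names: list[str],
                            different: set[tuple[str, str]]) -> dict[str, str]:
    """Letters such that two groups share one iff not significantly different."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if (a, b) not in different:
                g.add_edge(a, b)
    cliques = sorted((sorted(c) for c in nx.find_cliques(g)),
                     key=lambda c: (names.index(c[0]), c))
    letters: dict[str, str] = {n: "" for n in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, clique in enumerate(cliques):
        for n in clique:
            letters[n] += alphabet[li % len(alphabet)]
    return letters


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    pvalue: float
    n_perm: int


def _permanova_stats(d2: np.ndarray, labels: np.ndarray,
                     groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for gr in groups:
        m = labels == gr
        ng = int(m.sum())
        ss_within += d2[np.ix_(m, m)][np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    g = len(groups)
    f = (ss_between / (g - 1)) / (ss_within / (n - g)) if ss_within > 0 else math.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    R^2 = SS_between / SS_total from squared distances; the p-value uses
    the (1 + hits) / (1 + n_perm) convention.
    """
    labels = np.asarray(list(labels))
    if len(labels) != dm.shape[0]:
        raise InputError("label count does not match distance matrix")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    counts = {g: int((labels == g).sum()) for g in groups}
    if min(counts.values()) == 0:
        raise InputError("empty group")
    d2 = dm.data.astype(float) ** 2
    f_obs, r2 = _permanova_stats(d2, labels, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_stats(d2, perm, groups)
        hits += f_perm >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2),
                           pvalue=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    ids: list[str]
    stress: float
    seed: int
    n_restarts: int
    stress_path: list[float] = field(default_factory=list)


def _kruskal_stress(dist_hat: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(dist_hat ** 2))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((dist_hat - disparities) ** 2)) / denom)


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    l = np.sqrt(np.clip(vals[order], 0, None))
    return vecs[:, order] * l


def nmds(dm: DistanceMatrix, dims: int = 2, n_restarts: int = 4,
         max_iter: int = 300, seed: int = 0, tol: float = 1e-7) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    The disparities are the monotone (pool-adjacent-violators) regression
    of the configuration distances on the input dissimilarities; the
    configuration is updated by the Guttman transform, which never
    increases stress within a restart.  The first restart starts from the
    classical metric scaling of the dissimilarities; the rest start from
    random configurations.  The best restart is returned.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InputError("non-finite distances")
    n = d.shape[0]
    ids = list(dm.ids)
    if n <= 2:
        coords = np.zeros((n, dims))
        if n == 2:
            coords[1, 0] = d[0, 1]
        return NMDSResult(coords, ids, 0.0, seed, n_restarts, [0.0])

    iu = np.triu_indices(n, 1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)

    best: NMDSResult | None = None
    for restart in range(n_restarts):
        if restart == 0:
            x = _classical_mds(d, dims)
        else:
            x = rng.normal(size=(n, dims)) * (diss.mean() or 1.0)
        path: list[float] = []
        prev = math.inf
        x_best = x
        for _ in range(max_iter):
            delta = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            dist_hat = delta[iu]
            disparities = np.empty_like(dist_hat)
            disparities[order] = iso.fit_transform(
                np.arange(len(order)), dist_hat[order])
            stress = _kruskal_stress(dist_hat, disparities)
            if stress > prev:       # keep the stress path non-increasing
                break
            path.append(stress)
            x_best = x
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform
            disp_full = np.zeros_like(delta)
            disp_full[iu] = disparities
            disp_full += disp_full.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(delta > 0, disp_full / delta, 0.0)
            b = -ratio
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
        if best is None or path[-1] < best.stress:
            best = NMDSResult(x_best.copy(), ids, float(path[-1]), seed,
                              n_restarts, path)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Spearman


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
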