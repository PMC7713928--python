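"""Distance-matrix statistics: PERMANOVA, post hoc contrasts, dispersion.

The omnibus test is a one-way permutational MANOVA on an arbitrary distance
matrix: the pseudo-F compares among-group to within-group squared distances
and its null distribution is obtained by permuting group labels; R^2 is the
among-group fraction of total squared distance.  Post hoc pairwise tests run
the same statistic on every group-pair submatrix with multiplicity-adjusted
p-values.  Dispersion homogeneity (the multivariate extension of Levene's
test) embeds the distance matrix by principal coordinates, measures each
point's distance to its group centroid with the standard correction for
negative eigenvalues, and compares group mean dispersions by a permutation
ANOVA.

The test objects follow the fit/results idiom: build a model from a distance
matrix and labels, call ``fit`` and read estimates off the results object or
print its ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "Permanova",
    "PermanovaResults",
    "permanova",
    "pairwise_permanova",
    "p_adjust",
    "DispersionHomogeneity",
    "DispersionResults",
    "dispersion_homogeneity",
]


class DistanceMatrixError(ValueError):
    """Invalid distance matrix or grouping."""


class DistanceMatrix:
    """Symmetric non-negative distance matrix with row ids and group labels."""

    def __init__(self, values, ids=None, groups=None):
        d = np.asarray(values, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DistanceMatrixError("distance matrix must be square")
        n = d.shape[0]
        if not np.allclose(d, d.T, atol=1e-9):
            raise DistanceMatrixError("distance matrix must be symmetric (1e-9)")
        d = 0.5 * (d + d.T)
        if np.any(np.diag(d) != 0):
            raise DistanceMatrixError("diagonal must be exactly zero")
        if np.any(d < 0):
            raise DistanceMatrixError("distances must be non-negative")
        self.values = d
        self.ids = list(ids) if ids is not None else [str(i) for i in range(n)]
        if len(self.ids) != n:
            raise DistanceMatrixError("ids length must match matrix size")
        self.groups = None if groups is None else np.asarray(list(groups), dtype=object)
        if self.groups is not None and len(self.groups) != n:
            raise DistanceMatrixError("groups length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_points(cls, points, ids=None, groups=None) -> "DistanceMatrix":
        """Euclidean distances between rows of a point matrix."""
        from scipy.spatial.distance import pdist, squareform

        x = np.atleast_2d(np.asarray(points, float))
        if x.shape[0] < x.shape[1] and x.ndim == 2 and x.shape[0] == 1:
            x = x.T
        d = squareform(pdist(x))
        return cls(d, ids=ids, groups=groups)

    def submatrix(self, mask: np.ndarray) -> "DistanceMatrix":
        idx = np.nonzero(mask)[0]
        return DistanceMatrix(
            self.values[np.ix_(idx, idx)],
            ids=[self.ids[i] for i in idx],
            groups=None if self.groups is None else self.groups[idx],
        )


def _group_labels(dm: DistanceMatrix, groups) -> np.ndarray:
    if groups is None:
        groups = dm.groups
    if groups is None:
        raise DistanceMatrixError("group labels are required")
    g = np.asarray(list(groups), dtype=object)
    if len(g) != dm.n:
        raise DistanceMatrixError("groups length must match matrix size")
    return g


def _check_group_sizes(g: np.ndarray, min_size: int = 2) -> list:
    levels = list(dict.fromkeys(g))
    if len(levels) < 2:
        raise DistanceMatrixError("need at least 2 groups")
    for lv in levels:
        if np.sum(g == lv) < min_size:
            raise DistanceMatrixError(f"group {lv!r} has fewer than {min_size} members")
    return levels


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(d2: np.ndarray, g: np.ndarray, levels) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix and labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for lv in levels:
        mask = g == lv
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    return float(ss_total), float(ss_within)


@dataclass
class PermanovaResults:
    """One-way PERMANOVA fit: pseudo-F, R^2 and the permutation p-value."""

    statistic: float
    r_squared: float
    pvalue: float
    n_permutations: int
    df_among: int
    df_within: int
    n_observations: int
    n_groups: int

    def summary(self) -> str:
        lines = [
            "One-way PERMANOVA (permutation MANOVA on a distance matrix)",
            f"  observations: {self.n_observations}   groups: {self.n_groups}",
            f"  df (among, within): ({self.df_among}, {self.df_within})",
            f"  pseudo-F: {self.statistic:.4f}",
            f"  R^2:      {self.r_squared:.4f}",
            f"  p-value:  {self.pvalue:.4f}  ({self.n_permutations} permutations)",
        ]
        return "\n".join(lines)


class Permanova:
    """Permutational MANOVA model over a distance matrix and group labels."""

    def __init__(self, distance: DistanceMatrix, groups=None):
        self.distance = distance
        self.groups = _group_labels(distance, groups)
        self.levels = _check_group_sizes(self.groups)
        self._d2 = distance.values**2

    def _f_and_r2(self, g: np.ndarray) -> tuple[float, float]:
        d2 = self._d2
        n = self.distance.n
        a = len(self.levels)
        ss_total, ss_within = _permanova_ss(d2, g, self.levels)
        ss_among = max(ss_total - ss_within, 0.0)
        if ss_within <= 0:
            f = np.inf if ss_among > 0 else 0.0
        else:
            f = (ss_among / (a - 1)) / (ss_within / (n - a))
        r2 = ss_among / ss_total if ss_total > 0 else 0.0
        return f, r2

    def fit(self, n_permutations: int = 999, seed=None) -> PermanovaResults:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        n = self.distance.n
        a = len(self.levels)
        f_obs, r2 = self._f_and_r2(self.groups)
        if f_obs == 0.0 and r2 == 0.0:
            # no variance anywhere: the statistic carries no evidence
            return PermanovaResults(0.0, 0.0, 1.0, n_permutations, a - 1, n - a, n, a)
        count = 0
        g = self.groups.copy()
        for _ in range(n_permutations):
            rng.shuffle(g)
            f_perm, _ = self._f_and_r2(g)
            if f_perm >= f_obs:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        return PermanovaResults(
            statistic=float(f_obs),
            r_squared=float(r2),
            pvalue=float(p),
            n_permutations=n_permutations,
            df_among=a - 1,
            df_within=n - a,
            n_observations=n,
            n_groups=a,
        )


def permanova(
    d: DistanceMatrix, groups=None, n_permutations: int = 999, seed=None
) -> PermanovaResults:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(d, groups).fit(n_permutations=n_permutations, seed=seed)


def p_adjust(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni``, ``holm`` or ``bh``."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mapping = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}
    if method not in mapping:
        raise ValueError(f"unknown adjustment method {method!r}")
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, method=mapping[method])
    return np.clip(adj, 0.0, 1.0)


def pairwise_permanova(
    d: DistanceMatrix,
    groups=None,
    n_permutations: int = 999,
    seed=None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Post hoc PERMANOVA on every group pair, with adjusted p-values.

    Pairs where either group has fewer than 2 members are flagged (NaN
    statistics) rather than computed.
    """
    g = _group_labels(d, groups)
    levels = list(dict.fromkeys(g))
    if len(levels) < 2:
        raise DistanceMatrixError("need at least 2 groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        mask = (g == a) | (g == b)
        if np.sum(g == a) < 2 or np.sum(g == b) < 2:
            rows.append(
                {"group_a": a, "group_b": b, "F": np.nan, "R2": np.nan,
                 "p": np.nan, "computed": False}
            )
            continue
        sub = d.submatrix(mask)
        res = Permanova(sub, g[mask]).fit(n_permutations=n_permutations, seed=rng)
        rows.append(
            {"group_a": a, "group_b": b, "F": res.statistic, "R2": res.r_squared,
             "p": res.pvalue, "computed": True}
        )
    out = pd.DataFrame(rows)
    ok = out["computed"].to_numpy()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok] = p_adjust(out.loc[ok, "p"].to_numpy(), method=adjust)
    out["p_adjusted"] = adj
    return out


# ---------------------------------------------------------------------------
# multivariate dispersion homogeneity


def _pcoa_embedding(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real and 'imaginary' parts.

    Returns (real_coords, imag_coords): axes with positive eigenvalues carry
    ordinary coordinates; axes with negative eigenvalues (non-Euclidean
    distances) contribute squared distances with a minus sign.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ (d**2) @ j
    gower = 0.5 * (gower + gower.T)
    eigval, eigvec = np.linalg.eigh(gower)
    tol = 1e-10 * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    if not pos.any():
        raise DistanceMatrixError("degenerate input: no positive principal axes")
    return real, imag


def _dist_to_centroids(
    real: np.ndarray, imag: np.ndarray, g: np.ndarray, levels
) -> np.ndarray:
    """Distance of each point to its group centroid, negative axes corrected."""
    z = np.empty(real.shape[0])
    for lv in levels:
        mask = g == lv
        cr = real[mask].mean(axis=0)
        d2 = ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.size:
            ci = imag[mask].mean(axis=0)
            d2 = d2 - ((imag[mask] - ci) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(z: np.ndarray, g: np.ndarray, levels) -> float:
    n = z.size
    a = len(levels)
    grand = z.mean()
    ss_among = sum(np.sum(g == lv) * (z[g == lv].mean() - grand) ** 2 for lv in levels)
    ss_within = sum(((z[g == lv] - z[g == lv].mean()) ** 2).sum() for lv in levels)
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return float((ss_among / (a - 1)) / (ss_within / (n - a)))


@dataclass
class DispersionResults:
    """Levene-style homogeneity test of multivariate dispersions."""

    statistic: float
    pvalue: float
    n_permutations: int
    group_means: pd.Series
    distances: np.ndarray
    pairwise: pd.DataFrame = field(default=None)

    def summary(self) -> str:
        lines = [
            "Homogeneity of multivariate dispersions (PCoA distance-to-centroid)",
            f"  F: {self.statistic:.4f}   p (permutation): {self.pvalue:.4f} "
            f"({self.n_permutations} permutations)",
            "  mean distance to centroid by group:",
        ]
        for name, val in self.group_means.items():
            lines.append(f"    {name}: {val:.4f}")
        return "\n".join(lines)


class DispersionHomogeneity:
    """Dispersion-homogeneity model over a distance matrix and labels."""

    def __init__(self, distance: DistanceMatrix, groups=None):
        self.distance = distance
        self.groups = _group_labels(distance, groups)
        self.levels = _check_group_sizes(self.groups)
        if np.all(distance.values == 0):
            raise DistanceMatrixError("degenerate input: all distances zero")
        real, imag = _pcoa_embedding(distance.values)
        self.distances_to_centroid = _dist_to_centroids(
            real, imag, self.groups, self.levels
        )

    def fit(
        self,
        n_permutations: int = 999,
        seed=None,
        pairwise: bool = True,
        adjust: str = "bonferroni",
    ) -> DispersionResults:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        z = self.distances_to_centroid
        g = self.groups
        f_obs = _anova_f(z, g, self.levels)
        count = 0
        gp = g.copy()
        for _ in range(n_permutations):
            rng.shuffle(gp)
            if _anova_f(z, gp, self.levels) >= f_obs:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        means = pd.Series(
            {lv: float(z[g == lv].mean()) for lv in self.levels}, name="mean_dispersion"
        )
        pw = None
        if pairwise:
            rows = []
            for a, b in itertools.combinations(self.levels, 2):
                mask = (g == a) | (g == b)
                za, gsub = z[mask], g[mask]
                f_pair = _anova_f(za, gsub, [a, b])
                cnt = 0
                gp2 = gsub.copy()
                for _ in range(n_permutations):
                    rng.shuffle(gp2)
                    if _anova_f(za, gp2, [a, b]) >= f_pair:
                        cnt += 1
                rows.append(
                    {"group_a": a, "group_b": b, "F": f_pair,
                     "p": (1 + cnt) / (1 + n_permutations)}
                )
            pw = pd.DataFrame(rows)
            pw["p_adjusted"] = p_adjust(pw["p"].to_numpy(), method=adjust)
        return DispersionResults(
            statistic=float(f_obs),
            pvalue=float(p),
            n_permutations=n_permutations,
            group_means=means,
            distances=z,
            pairwise=pw,
        )


def dispersion_homogeneity(
    d: DistanceMatrix,
    groups=None,
    n_permutations: int = 999,
    seed=None,
    adjust: str = "bonferroni",
) -> DispersionResults:
    """Functional wrapper around :class:`DispersionHomogeneity`."""
    return DispersionHomogeneity(d, groups).fit(
        n_permutations=n_permutations, seed=seed, adjust=adjust
    )
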