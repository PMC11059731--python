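"""Permutation tests on distance matrices and the FISH-IR concordance.

PERMANOVA uses the one-way pseudo-F of Anderson:

    SS_T = (1/N) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    F    = [(SS_T - SS_W)/(a - 1)] / [SS_W/(N - a)]

with a permutation p-value (b+1)/(m+1) for b exceedances among m random
label permutations, or an exact p over all distinct relabelings when their
number is small.  PERMDISP embeds the distances by principal coordinates,
measures each sample's deviation from its group centroid (imaginary axes
subtracted in the squared sense), and applies a one-way ANOVA F with a
permutation p on the deviations.

The concordance statistic compares FISH-IR probe counts with metabarcoding
"pseudoabundances": a group's relative abundance (%) times the total
absolute abundance of aerobic anoxygenic phototrophs divided by 100.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.distance import DistanceMatrix

_EXHAUSTIVE_LIMIT = 10_000


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"


@dataclass
class ConcordanceResult:
    group: str
    rho: float
    p: float
    n: int
    method: str = "t-approximation"


@dataclass
class PermTestResult:
    test: str                      # "permanova" or "permdisp"
    statistic: float               # pseudo-F / dispersion F
    p: float
    n_perm: int                    # permutations actually used
    method: str                    # "exhaustive" or "random"
    group_sizes: dict[str, int] = field(default_factory=dict)


def pseudoabundance(class_rel_pct, aap_abs):
    """Absolute estimate (cells/mL): relative abundance (%) x total / 100."""
    pct = np.asarray(class_rel_pct, dtype=float)
    aap = np.asarray(aap_abs, dtype=float)
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("relative abundance must be a percentage in [0, 100]")
    if (aap < 0).any():
        raise ValueError("absolute abundance must be >= 0")
    out = pct * aap / 100.0
    return float(out) if out.ndim == 0 else out


def spearman(x, y) -> SpearmanResult:
    """Spearman rho with average-rank ties; exact permutation p for n <= 9.

    Missing values are dropped pairwise-complete.  A constant vector makes
    rho undefined: returned as NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), n, "undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # rho is affine in sum(rx * ry_perm); enumerate all n! pairings
        perms = np.array(list(itertools.permutations(ry)))
        s = perms @ rx
        mu = n * rx.mean() * ry.mean()
        denom = (n * rx.std()) * ry.std() * n
        rho_all = (s - mu) / denom * n  # = corr of rx with permuted ry
        b = int((np.abs(rho_all) >= abs(rho) - 1e-12).sum())
        return SpearmanResult(rho, b / len(perms), n, "exact-permutation")
    p = float(sps.spearmanr(x, y).pvalue)
    return SpearmanResult(rho, p, n, "t-approximation")


def concordance(fish_pct, taxon_rel_pct, aap_abs,
                group: str = "") -> ConcordanceResult:
    """Spearman concordance of FISH-IR probe counts with pseudoabundances.

    Both sides are placed on the absolute cells/mL scale with the shared
    total AAP abundance: probe counts = fish_pct x aap_abs / 100 and
    pseudoabundance = taxon_rel_pct x aap_abs / 100.
    """
    fish_counts = pseudoabundance(fish_pct, aap_abs)
    pseudo = pseudoabundance(taxon_rel_pct, aap_abs)
    res = spearman(fish_counts, pseudo)
    return ConcordanceResult(group=group, rho=res.rho, p=res.p, n=res.n,
                             method=res.method)


# ---------------------------------------------------------------------------
# permutation tests


def _codes_and_sizes(groups) -> tuple[np.ndarray, list[str], np.ndarray]:
    g = pd.Series(list(groups))
    cats = pd.Categorical(g)
    codes = np.asarray(cats.codes)
    levels = [str(c) for c in cats.categories]
    sizes = np.bincount(codes, minlength=len(levels))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = [levels[i] for i in np.where(sizes < 2)[0]]
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    return codes, levels, sizes


def _n_distinct_relabelings(sizes: np.ndarray) -> float:
    n = int(sizes.sum())
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(int(s))
    return out


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_t = d2.sum() / (2 * n)
    ss_w = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ss_w += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    with np.errstate(divide="ignore"):
        # ss_w == 0 (perfect separation) yields +inf, like standard tools
        return float(((ss_t - ss_w) / (k - 1)) / (ss_w / (n - k)))


def _distinct_assignments(codes: np.ndarray):
    """All distinct multiset permutations of the label vector."""
    from sympy.utilities.iterables import multiset_permutations
    for perm in multiset_permutations(list(codes)):
        yield np.asarray(perm)


def permanova_oneway(dist: DistanceMatrix, groups, n_perm: int = 9999,
                     seed: int = 0) -> PermTestResult:
    """One-way PERMANOVA on a distance matrix.

    Uses exhaustive enumeration over all distinct relabelings when there
    are at most 10,000 of them, otherwise `n_perm` seeded random
    permutations with p = (b+1)/(m+1).
    """
    codes, levels, sizes = _codes_and_sizes(groups)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    if d2.shape[0] != len(codes):
        raise ValueError("groups length must match distance matrix size")
    k = len(levels)
    f_obs = _pseudo_f(d2, codes, k)

    n_distinct = _n_distinct_relabelings(sizes)
    if n_distinct <= _EXHAUSTIVE_LIMIT:
        b = sum(_pseudo_f(d2, perm, k) >= f_obs - 1e-12
                for perm in _distinct_assignments(codes))
        p = b / n_distinct  # observed labeling is among the assignments
        method, m = "exhaustive", int(n_distinct)
    else:
        rng = np.random.default_rng(seed)
        b = sum(_pseudo_f(d2, rng.permutation(codes), k) >= f_obs - 1e-12
                for _ in range(n_perm))
        p = (b + 1) / (n_perm + 1)
        method, m = "random", n_perm
    return PermTestResult(
        test="permanova", statistic=float(f_obs), p=float(p), n_perm=m,
        method=method,
        group_sizes={lv: int(s) for lv, s in zip(levels, sizes)})


def _pcoa_embed(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary axes."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-8 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _centroid_deviations(real: np.ndarray, imag: np.ndarray,
                         codes: np.ndarray, k: int) -> np.ndarray:
    z = np.empty(len(codes))
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        dr = real[idx] - real[idx].mean(axis=0)
        z2 = (dr ** 2).sum(axis=1)
        if imag.shape[1]:
            di = imag[idx] - imag[idx].mean(axis=0)
            z2 = z2 - (di ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(z2, 0.0, None))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(k):
        zg = z[codes == g]
        ss_b += len(zg) * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    if ss_w == 0:
        return 0.0 if ss_b == 0 else float("inf")
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def permdisp(dist: DistanceMatrix, groups, n_perm: int = 9999,
             seed: int = 0) -> PermTestResult:
    """Homogeneity of multivariate dispersions (deviations from centroid).

    Deviations are held fixed and their group labels permuted, the
    standard resampling scheme for this test.
    """
    codes, levels, sizes = _codes_and_sizes(groups)
    d = np.asarray(dist.data, dtype=float)
    if d.shape[0] != len(codes):
        raise ValueError("groups length must match distance matrix size")
    k = len(levels)
    real, imag = _pcoa_embed(d)
    z = _centroid_deviations(real, imag, codes, k)
    f_obs = _anova_f(z, codes, k)
    rng = np.random.default_rng(seed)
    b = sum(_anova_f(z, rng.permutation(codes), k) >= f_obs - 1e-12
            for _ in range(n_perm))
    p = (b + 1) / (n_perm + 1)
    return PermTestResult(
        test="permdisp", statistic=float(f_obs), p=float(p), n_perm=n_perm,
        method="random",
        group_sizes={lv: int(s) for lv, s in zip(levels, sizes)})
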