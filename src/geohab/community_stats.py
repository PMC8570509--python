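"""Indicator-species analysis and exploratory factor analysis.

IndVal
------
For a site-by-species presence/absence table with a site -> habitat-group
assignment, a species' indicator value for a group (or group combination)
is ``sqrt(A * B)`` where A is specificity (how exclusively the species'
occurrences concentrate in the group) and B is fidelity (the share of the
group's sites it occupies). The default, group-size-corrected variant
("IndVal.g") computes A from group mean presences, so unequal group sizes
do not bias specificity; the original site-count variant is available with
``variant='indval'``. Significance is a permutation test on site labels
with the add-one estimator ``p = (1 + #{perm >= obs}) / (1 + n_perm)``;
``n_perm='exact'`` enumerates every distinct label arrangement instead.

Factor analysis
---------------
Principal-component extraction on the correlation matrix, Kaiser retention
(eigenvalue >= 1 by default), varimax rotation, and reporting of rotated
loadings, communalities h2 (row sums of squared rotated loadings),
uniquenesses u2 = 1 - h2, and per-factor SS loadings / proportion /
cumulative variance. Variables listed as reverse-scored are negated before
standardization (used for variables whose raw sense is negatively related
to the rest, so rotated loadings come out positive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IndValResult",
    "FactorResult",
    "indval",
    "significant_indicators",
    "factor_analysis",
    "communality_check",
    "varimax",
    "tucker_congruence",
    "load_indicator_counts",
]


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

def _split_community(community: pd.DataFrame):
    if "group" not in community.columns:
        raise ValueError("community table needs a 'group' column")
    groups = community["group"].to_numpy()
    X = community.drop(columns="group").to_numpy(dtype=float)
    species = [c for c in community.columns if c != "group"]
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("at least 2 site groups are required")
    counts = {g: int((groups == g).sum()) for g in uniq}
    empty = [g for g, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"groups with zero sites: {empty}")
    return X, groups, species, uniq


def _combo_stats(X: np.ndarray, groups: np.ndarray, uniq: np.ndarray,
                 combos: list[tuple], variant: str) -> np.ndarray:
    """stat matrix, combos x species."""
    masks = {g: groups == g for g in uniq}
    n_g = {g: masks[g].sum() for g in uniq}
    sums = {g: X[masks[g]].sum(axis=0) for g in uniq}   # occupied sites per g
    means = {g: sums[g] / n_g[g] for g in uniq}
    total_mean = sum(means.values())        # denominator of A (group-based)
    total_sum = sum(sums.values())          # denominator of A (site-based)
    out = np.zeros((len(combos), X.shape[1]))
    for ci, combo in enumerate(combos):
        if variant == "indval.g":
            num = sum(means[g] for g in combo)
            den = total_mean
        else:
            num = sum(sums[g] for g in combo)
            den = total_sum
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        occupied = sum(sums[g] for g in combo)
        sites = sum(n_g[g] for g in combo)
        B = occupied / sites
        out[ci] = np.sqrt(A * B)
    return out


@dataclass
class IndValResult:
    """Best group (combination) per species with permutation p-values."""

    table: pd.DataFrame  # species, group, A, B, stat, p_value
    mode: str
    variant: str
    n_perm: int | str
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.table)


def indval(
    community: pd.DataFrame,
    n_perm: int | str = 999,
    mode: str = "single_group",
    variant: str = "indval.g",
    seed: int | None = None,
) -> IndValResult:
    """Indicator value of every species for its best group (combination).

    ``community``: index = site ids, column ``group`` plus one 0/1 column
    per species. ``mode='group_combinations'`` scores every non-trivial
    subset of groups (all orders up to K-1) instead of single groups.
    ``n_perm='exact'`` replaces Monte-Carlo permutation with full
    enumeration of distinct label arrangements (feasible for small
    communities); the exact p is the share of arrangements whose best stat
    reaches the observed one.
    """
    if mode not in ("single_group", "group_combinations"):
        raise ValueError(f"unknown mode {mode!r}")
    if variant not in ("indval.g", "indval"):
        raise ValueError(f"unknown variant {variant!r}")
    X, groups, species, uniq = _split_community(community)
    if mode == "single_group":
        combos = [(g,) for g in uniq]
    else:
        combos = [c for r in range(1, len(uniq))
                  for c in itertools.combinations(uniq, r)]
    obs = _combo_stats(X, groups, uniq, combos, variant)
    best_idx = obs.argmax(axis=0)          # ties -> first combo (lowest ids)
    best_stat = obs[best_idx, np.arange(len(species))]

    # observed A and B for the chosen combination
    rows = []
    masks = {g: groups == g for g in uniq}
    n_g = {g: masks[g].sum() for g in uniq}
    sums = {g: X[masks[g]].sum(axis=0) for g in uniq}
    means = {g: sums[g] / n_g[g] for g in uniq}
    for si, name in enumerate(species):
        combo = combos[best_idx[si]]
        if variant == "indval.g":
            den = sum(means[g][si] for g in uniq)
            num = sum(means[g][si] for g in combo)
        else:
            den = sum(sums[g][si] for g in uniq)
            num = sum(sums[g][si] for g in combo)
        A = num / den if den > 0 else 0.0
        B = (sum(sums[g][si] for g in combo)
             / sum(n_g[g] for g in combo))
        rows.append({"species": name,
                     "group": combo[0] if len(combo) == 1 else combo,
                     "A": A, "B": B, "stat": best_stat[si]})

    if n_perm == "exact":
        p = _exact_p(X, groups, uniq, combos, variant, best_stat)
        n_perm_out: int | str = "exact"
    else:
        if not isinstance(n_perm, int) or n_perm < 1:
            raise ValueError("n_perm must be a positive integer or 'exact'")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(species))
        labels = groups.copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            perm = _combo_stats(X, labels, uniq, combos, variant).max(axis=0)
            exceed += perm >= best_stat - 1e-12
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_perm_out = n_perm
    for r, pv in zip(rows, p):
        r["p_value"] = float(pv)
    table = pd.DataFrame(rows)
    return IndValResult(table, mode, variant, n_perm_out, seed)


def _exact_p(X, groups, uniq, combos, variant, best_stat):
    """Exact permutation p by enumerating distinct label arrangements."""
    from sympy.utilities.iterables import multiset_permutations

    n_sites = len(groups)
    if n_sites > 10:
        raise ValueError("exact enumeration is limited to <= 10 sites")
    exceed = np.zeros(X.shape[1])
    total = 0
    for perm in multiset_permutations(list(groups)):
        labels = np.asarray(perm)
        stat = _combo_stats(X, labels, uniq, combos, variant).max(axis=0)
        exceed += stat >= best_stat - 1e-12
        total += 1
    return exceed / total


def significant_indicators(result: IndValResult,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Rows with p < alpha, sorted by group then descending stat.

    The returned frame carries a ``n_significant_by_group`` attribute in
    ``DataFrame.attrs`` with the per-group counts.
    """
    tab = result.table[result.table.p_value < alpha].copy()
    tab["_g"] = tab["group"].astype(str)
    tab = tab.sort_values(["_g", "stat"], ascending=[True, False])
    tab = tab.drop(columns="_g").reset_index(drop=True)
    tab.attrs["n_significant_by_group"] = (
        tab.groupby(tab["group"].astype(str)).size().to_dict())
    return tab


def load_indicator_counts(path=None) -> pd.DataFrame:
    """Packaged per-habitat-group indicator-species counts (survey table)."""
    import importlib.resources

    if path is None:
        ref = importlib.resources.files("geohab.data").joinpath(
            "indicator_counts.csv")
        with ref.open() as fh:
            return pd.read_csv(fh, keep_default_na=False)
    return pd.read_csv(path, keep_default_na=False)


# ---------------------------------------------------------------------------
# factor analysis
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000
            ) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    Maximizes the variance of squared loadings within each factor, with
    Kaiser row normalization by default. The rotation matrix R is
    orthonormal and satisfies rotated = loadings @ R.
    """
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1)) if normalize else np.ones(n)
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / n))
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    out = (L @ R) * h[:, None]
    return out, R


@dataclass
class FactorResult:
    loadings: pd.DataFrame        # variables x RC1..RCk, rotated
    eigenvalues: np.ndarray       # all eigenvalues, descending
    n_factors: int
    communalities: pd.Series      # h2 per variable
    uniquenesses: pd.Series       # u2 = 1 - h2
    ss_loadings: pd.Series        # per factor
    proportion_var: pd.Series
    cumulative_var: pd.Series
    rotation_matrix: np.ndarray
    reverse_scored: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Loadings with h2/u2 columns in the conventional report layout."""
        out = self.loadings.copy()
        out["h2"] = self.communalities
        out["u2"] = self.uniquenesses
        return out

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SS loadings": self.ss_loadings,
            "Proportion of variance": self.proportion_var,
            "Cumulative variance": self.cumulative_var,
        }).T


def factor_analysis(
    env: pd.DataFrame,
    retention: float = 1.0,
    rotation: str = "varimax",
    reverse_scored: list[str] | None = None,
) -> FactorResult:
    """Principal-component factor analysis with Kaiser retention.

    Variables are standardized (reverse-scored ones negated first); the
    correlation matrix's components with eigenvalue >= ``retention`` are
    kept and varimax-rotated (``rotation=None`` skips rotation). Factors
    are ordered by SS loadings and sign-aligned so each column's largest
    loading is positive.
    """
    if rotation not in ("varimax", None, "none"):
        raise ValueError(f"unsupported rotation {rotation!r}")
    reverse_scored = list(reverse_scored or [])
    data = env.copy()
    n, n_vars = data.shape
    if n <= n_vars:
        raise ValueError("need more observations than variables")
    unknown = [v for v in reverse_scored if v not in data.columns]
    if unknown:
        raise ValueError(f"reverse-scored variables not in table: {unknown}")
    for v in reverse_scored:
        data[v] = -data[v]
    sd = data.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    Z = (data - data.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_factors = int((eigval >= retention).sum())
    if n_factors < 1:
        raise ValueError("no factor meets the retention criterion")
    L = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    if rotation == "varimax" and n_factors > 1:
        L, rot = varimax(L)
    else:
        rot = np.eye(n_factors)
    # order factors by explained variance, align signs
    ss = (L**2).sum(axis=0)
    col_order = np.argsort(ss)[::-1]
    L = L[:, col_order]
    rot = rot[:, col_order]
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    L = L * signs
    rot = rot * signs
    names = [f"RC{i + 1}" for i in range(n_factors)]
    loadings = pd.DataFrame(L, index=data.columns, columns=names)
    h2 = pd.Series((L**2).sum(axis=1), index=data.columns, name="h2")
    ss = pd.Series((L**2).sum(axis=0), index=names, name="SS loadings")
    prop = ss / n_vars
    return FactorResult(
        loadings=loadings,
        eigenvalues=eigval,
        n_factors=n_factors,
        communalities=h2,
        uniquenesses=1.0 - h2,
        ss_loadings=ss,
        proportion_var=prop,
        cumulative_var=prop.cumsum(),
        rotation_matrix=rot,
        reverse_scored=reverse_scored,
    )


def communality_check(result: FactorResult, h2_min: float = 0.3) -> pd.Series:
    """Per-variable pass/fail: h2 >= h2_min (inclusive) passes."""
    return result.communalities >= h2_min


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Tucker congruence between two loading matrices.

    Columns of ``b`` are matched to ``a`` greedily by absolute congruence
    (signs are irrelevant to congruence of a rotated solution).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    k = a.shape[1]
    phi = np.zeros((k, b.shape[1]))
    for i in range(k):
        for j in range(b.shape[1]):
            num = float(a[:, i] @ b[:, j])
            den = math.sqrt(float(a[:, i] @ a[:, i]) * float(b[:, j] @ b[:, j]))
            phi[i, j] = abs(num) / den if den > 0 else 0.0
    used, total = set(), 0.0
    for i in range(k):
        j = max((j for j in range(b.shape[1]) if j not in used),
                key=lambda j: phi[i, j])
        used.add(j)
        total += phi[i, j]
    return total / k
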