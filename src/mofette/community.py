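"""Community-composition statistics implemented from first principles.

Rarefaction (multivariate-hypergeometric subsampling without replacement),
observed richness and rarefaction curves, Bray-Curtis dissimilarity,
distance-based PERMANOVA with permutation (or exhaustive) p-values, and
SIMPER decomposition of mean between-group dissimilarity into per-OTU
percent contributions with cumulative ranking.

These are the statistics behind the diversity claims of CO2-vent soil
surveys; they are re-implemented here rather than delegated so that every
arithmetic step (and its determinism under a seed) is testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OtuTable


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (d < -1e-12).any() or (d > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.data = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "exhaustive" or "monte-carlo"


@dataclass
class SimperTable:
    """Ranked per-OTU contributions to mean between-group dissimilarity."""

    table: pd.DataFrame  # columns: contribution, pct_con, pct_cum
    overall_mean_dissimilarity_pct: float


# ---------------------------------------------------------------------------
# rarefaction and richness


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without
    replacement (multivariate hypergeometric); reproducible given seed."""
    totals = table.sample_totals()
    if depth > totals.min():
        low = totals.idxmin()
        raise ValueError(
            f"rarefaction depth {depth} exceeds total of sample {low} ({totals.min()})"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        counts=pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns),
        groups=table.groups.copy(),
    )


def observed_richness(table: OtuTable) -> pd.Series:
    """Number of OTUs with count > 0 per sample."""
    return (table.counts > 0).sum(axis=1).rename("richness")


def rarefaction_curve(
    table: OtuTable,
    depths: list[int],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean rarefied richness per sample at each depth (depth × sample)."""
    totals = table.sample_totals()
    bad = [d for d in depths if d > totals.min()]
    if bad:
        raise ValueError(f"depths {bad} exceed the smallest sample total {totals.min()}")
    rows = {}
    for d in depths:
        acc = np.zeros(len(table.sample_ids))
        for r in range(replicates):
            sub = rarefy(table, d, seed=seed * 10_000 + d * 131 + r)
            acc += observed_richness(sub).to_numpy()
        rows[d] = acc / replicates
    return pd.DataFrame.from_dict(rows, orient="index", columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Bray-Curtis


def bray_curtis(table: OtuTable | pd.DataFrame | np.ndarray, sample_ids=None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = Σ|x-y| / Σ(x+y).

    A pair of all-zero samples is defined as distance 0 with a warning.
    """
    if isinstance(table, OtuTable):
        x = table.counts.to_numpy(dtype=float)
        ids = table.sample_ids
    elif isinstance(table, pd.DataFrame):
        x = table.to_numpy(dtype=float)
        ids = list(table.index)
    else:
        x = np.asarray(table, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(x))]
    if (x < 0).any():
        raise ValueError("negative counts")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if (den == 0).any():
            warnings.warn("all-zero sample pair: Bray-Curtis distance defined as 0")
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return DistanceMatrix(data=d, sample_ids=ids)


# ---------------------------------------------------------------------------
# PERMANOVA


def _distinct_label_count(sizes: np.ndarray) -> float:
    n = int(sizes.sum())
    count = math.factorial(n)
    for s in sizes:
        count //= math.factorial(int(s))
    return count


def _multiset_permutations(codes: np.ndarray):
    """All distinct arrangements of a label multiset, lexicographically."""
    arr = sorted(codes.tolist())
    n = len(arr)
    while True:
        yield tuple(arr)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and arr[i] >= arr[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while arr[j] <= arr[i]:
            j -= 1
        arr[i], arr[j] = arr[j], arr[i]
        arr[i + 1 :] = reversed(arr[i + 1 :])


def _ss_within(d2: np.ndarray, label_matrix: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """SS_within for each row of label assignments (m × n integer array)."""
    m = label_matrix.shape[0]
    ss = np.zeros(m)
    for g, n_g in enumerate(sizes):
        ind = (label_matrix == g).astype(float)  # m × n
        ss += 0.5 * np.einsum("mi,ij,mj->m", ind, d2, ind) / float(n_g)
    return ss


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based one-way PERMANOVA.

    Partitions SS_total = Σ_{i<j} d²_ij / n into within- and between-group
    parts; pseudo-F = (SS_B/(a-1)) / (SS_W/(n-a)).  The p-value is the
    proportion of label permutations whose F reaches the observed one,
    with the +1 correction for Monte-Carlo sampling.  When the number of
    distinct label assignments does not exceed ``n_permutations``, they
    are enumerated exhaustively instead.
    """
    labels = pd.Series(groups)
    if set(labels.index) == set(dist.sample_ids) and list(labels.index) != list(
        range(len(labels))
    ):
        labels = labels.loc[dist.sample_ids]
    codes, uniques = pd.factorize(labels.to_numpy())
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes == 0).any():
        raise ValueError("every group needs at least one sample")
    n = len(codes)
    d2 = dist.data**2
    ss_total = float(d2[np.triu_indices(n, k=1)].sum()) / n
    if ss_total == 0.0:
        return PermanovaResult(
            pseudo_F=0.0, R2=0.0, p_value=1.0, n_permutations=0, seed=seed, method="degenerate"
        )
    ss_w_obs = float(_ss_within(d2, codes[None, :], sizes)[0])
    ss_b_obs = ss_total - ss_w_obs
    if ss_w_obs == 0.0:
        f_obs = math.inf
    else:
        f_obs = (ss_b_obs / (a - 1)) / (ss_w_obs / (n - a))
    r2 = ss_b_obs / ss_total

    n_distinct = _distinct_label_count(sizes)
    if n_distinct <= n_permutations:
        perms = np.array(list(_multiset_permutations(codes)), dtype=int)
        ss_w = _ss_within(d2, perms, sizes)
        with np.errstate(divide="ignore"):
            f_perm = ((ss_total - ss_w) / (a - 1)) / np.where(ss_w > 0, ss_w / (n - a), np.nan)
        f_perm = np.where(np.isnan(f_perm), math.inf, f_perm)
        p = float((f_perm >= f_obs - 1e-12).sum()) / len(perms)
        return PermanovaResult(
            pseudo_F=f_obs, R2=r2, p_value=p, n_permutations=len(perms), seed=seed,
            method="exhaustive",
        )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    ss_w = _ss_within(d2, perms, sizes)
    with np.errstate(divide="ignore"):
        f_perm = ((ss_total - ss_w) / (a - 1)) / np.where(ss_w > 0, ss_w / (n - a), np.nan)
    f_perm = np.where(np.isnan(f_perm), math.inf, f_perm)
    hits = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs, R2=r2, p_value=p, n_permutations=n_permutations, seed=seed,
        method="monte-carlo",
    )


# ---------------------------------------------------------------------------
# SIMPER


def simper(table: OtuTable, proportions: bool = False) -> SimperTable:
    """SIMPER decomposition between the table's two groups.

    Per-OTU contribution = mean over all between-group sample pairs (j, k)
    of |x_ij - x_ik| / Σ_s (x_sj + x_sk); the contributions sum to the
    mean between-group Bray-Curtis dissimilarity.  %Con normalises to 100
    and the table is sorted by %Con descending (ties broken by OTU id).
    """
    levels = pd.unique(table.groups)
    if len(levels) != 2:
        raise ValueError(f"SIMPER needs exactly 2 groups, got {list(levels)}")
    x = table.counts.to_numpy(dtype=float)
    if proportions:
        totals = x.sum(axis=1, keepdims=True)
        x = np.divide(x, np.where(totals > 0, totals, 1.0))
    mask1 = (table.groups == levels[0]).to_numpy()
    g1, g2 = x[mask1], x[~mask1]
    contrib = np.zeros(x.shape[1])
    n_pairs = 0
    for row in g1:
        den = row.sum() + g2.sum(axis=1)  # per pair
        safe = np.where(den > 0, den, 1.0)
        contrib += (np.abs(row - g2) / safe[:, None]).sum(axis=0)
        n_pairs += len(g2)
    contrib /= n_pairs
    total = contrib.sum()
    pct = 100.0 * contrib / total if total > 0 else np.zeros_like(contrib)
    df = pd.DataFrame(
        {"contribution": contrib, "pct_con": pct}, index=table.counts.columns
    )
    df = df.sort_values(["pct_con", "contribution"], ascending=False, kind="mergesort")
    # deterministic tie-break on OTU id
    df = df.iloc[
        np.lexsort((df.index.to_numpy(), -df["pct_con"].to_numpy()))
    ]
    df["pct_cum"] = df["pct_con"].cumsum()
    return SimperTable(table=df, overall_mean_dissimilarity_pct=100.0 * total)


def cumulative_percent(contributions, ndigits: int = 2) -> list[float]:
    """Running cumulative of percent contributions, rounded as printed
    SIMPER tables round (%Cum_k = Σ_{i≤k} %Con_i)."""
    out: list[float] = []
    acc = 0.0
    for c in contributions:
        acc += float(c)
        out.append(round(acc, ndigits))
    return out
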