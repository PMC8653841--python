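"""Diversity and group-comparison statistics for cohort feature tables.

Covers the standard amplicon toolkit used around the transmission analysis:
Shannon diversity, Bray-Curtis and unweighted UniFrac distances, principal
coordinate analysis, ANOSIM (global, pairwise, and exact-enumeration modes),
a Kruskal-Wallis differential-feature screen, and one/two-tailed rank-sum
comparisons, plus the couple/sibling pair construction used for
within-household similarity contrasts.

Bray-Curtis is computed on relative abundances; unweighted UniFrac (via
scikit-bio) depends only on presence/absence. Permutation p-values follow the
add-one convention, so they are never zero; the exact mode enumerates all
distinct label arrangements instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from famtrack.core_data import CohortMetadata, FeatureTable, ValidationError

__all__ = [
    "shannon",
    "beta_distance",
    "anosim",
    "pairwise_anosim",
    "kruskal_wallis_screen",
    "rank_sum_compare",
    "pcoa",
    "PCoAResult",
    "family_pairs",
]


def shannon(counts: Sequence[float] | np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity ``-sum p log_base p`` over positive-count taxa.

    Base 2 by default (bits), matching common amplicon practice; pass
    ``base=math.e`` for nats.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValidationError("shannon expects a single count vector")
    if (c < 0).any():
        raise ValidationError("negative counts")
    if c.sum() <= 0:
        raise ValidationError("all-zero count vector")
    return float(stats.entropy(c, base=base))


def beta_distance(
    table: FeatureTable,
    metric: str = "bray_curtis",
    tree: str | TreeNode | None = None,
) -> DistanceMatrix:
    """Pairwise sample distances: Bray-Curtis or unweighted UniFrac.

    Bray-Curtis is computed on relative abundances. Unweighted UniFrac needs a
    rooted tree covering every ASV in the table; offenders are listed if any
    are missing.
    """
    if metric in ("bray_curtis", "braycurtis"):
        rel = table.relative_abundance().to_numpy()
        condensed = pdist(rel, metric="braycurtis")
        return DistanceMatrix(squareform(condensed), ids=table.sample_ids)
    if metric in ("unweighted_unifrac", "unifrac"):
        if tree is None:
            raise ValidationError("unweighted UniFrac requires a rooted tree")
        if isinstance(tree, str):
            import io

            tree = TreeNode.read(io.StringIO(tree))
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(table.asv_ids) - tips)
        if missing:
            raise ValidationError(f"ASVs missing from the tree: {missing}")
        return beta_diversity(
            "unweighted_unifrac",
            table.counts(),
            ids=table.sample_ids,
            taxa=table.asv_ids,
            tree=tree,
        )
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _anosim_r(rank_sq: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = rank_sq[iu][same[iu]]
    between = rank_sq[iu][~same[iu]]
    m = n * (n - 1) / 2
    return float((between.mean() - within.mean()) / (m / 2))


def anosim(
    dm: DistanceMatrix,
    labels: Sequence,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    ``R = (mean between-group rank - mean within-group rank) / (M/2)`` with
    ``M = n(n-1)/2`` over the ranked pairwise distances. The p-value uses
    ``n_perm`` random label permutations with the add-one convention
    ``p = (1 + #{R_perm >= R_obs}) / (1 + n_perm)``; with ``n_perm="exact"``
    every distinct label arrangement is enumerated and
    ``p = #{R_perm >= R_obs} / #arrangements`` (the identity included).
    """
    labels = np.asarray(list(labels))
    if len(labels) != dm.shape[0]:
        raise ValidationError("labels must match the distance matrix")
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    singletons = values[counts < 2].tolist()
    if singletons:
        raise ValidationError(f"groups with fewer than 2 members: {singletons}")
    cond = dm.condensed_form()
    rank_sq = squareform(stats.rankdata(cond))
    r_obs = _anosim_r(rank_sq, labels)
    if n_perm == "exact":
        perms = set(itertools.permutations(labels))
        r_all = np.array([_anosim_r(rank_sq, np.asarray(p)) for p in perms])
        p = float(np.mean(r_all >= r_obs - 1e-12))
        return r_obs, p
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(lab)
        if _anosim_r(rank_sq, lab) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_perm))
    return r_obs, p


def pairwise_anosim(
    dm: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """ANOSIM for every pair of groups; returns a tidy (group_a, group_b, R, p)."""
    labels = np.asarray(list(labels))
    ids = np.asarray(dm.ids)
    rows = []
    values, counts = np.unique(labels, return_counts=True)
    usable = values[counts >= 2]
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(usable, 2):
        mask = (labels == a) | (labels == b)
        sub = dm.filter(ids[mask])
        r, p = anosim(sub, labels[mask], n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append({"group_a": a, "group_b": b, "R": r, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature screens and rank tests
# ---------------------------------------------------------------------------


def kruskal_wallis_screen(
    abundance: pd.DataFrame,
    groups: Sequence,
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature Kruskal-Wallis H test across groups.

    ``abundance`` is samples x features; ``groups`` aligns with its rows.
    Constant features are skipped and reported. ``correction="bh"`` applies
    Benjamini-Hochberg to the p-values (off by default). Returns the feature
    statistics (with a ``significant`` flag at ``alpha``) and the skipped list.
    """
    groups = np.asarray(list(groups))
    if abundance.shape[0] != len(groups):
        raise ValidationError("groups must align with abundance rows")
    if len(np.unique(groups)) < 2:
        raise ValidationError("need at least two groups")
    masks = [groups == g for g in np.unique(groups)]
    rows, skipped = [], []
    for feature in abundance.columns:
        x = abundance[feature].to_numpy(dtype=float)
        if np.all(x == x[0]):
            skipped.append(feature)
            continue
        h, p = stats.kruskal(*[x[m] for m in masks])
        rows.append({"feature": feature, "H": h, "p": p})
    result = pd.DataFrame(rows, columns=["feature", "H", "p"])
    if correction == "bh" and len(result):
        result["p_adj"] = stats.false_discovery_control(result["p"], method="bh")
        result["significant"] = result["p_adj"] < alpha
    else:
        result["significant"] = result["p"] < alpha
    return result, skipped


def rank_sum_compare(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Exact p-value when the smaller sample has at most 8 observations and
    there are no ties; normal approximation (with tie and continuity
    correction) otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(
        alternative
    )
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x k axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    explained: np.ndarray  # proportion of positive-eigenvalue variance, k axes


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical metric MDS via double-centering of the squared distances.

    Negative eigenvalues (non-Euclidean distances) are returned, not clipped;
    coordinates are built from the leading non-negative eigenvalues only.
    """
    n = dm.shape[0]
    if k >= n:
        raise ValidationError(f"k must be < number of samples ({n})")
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lead = np.maximum(evals[:k], 0.0)
    coords = evecs[:, :k] * np.sqrt(lead)
    pos_total = evals[evals > 0].sum()
    explained = lead / pos_total if pos_total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCoAResult(coordinates=frame, eigenvalues=evals, explained=explained)


# ---------------------------------------------------------------------------
# Couple / sibling pair construction
# ---------------------------------------------------------------------------

COUPLE_ROLE_PAIRS = (("M", "F"), ("PGM", "PGF"), ("MGM", "MGF"))


def family_pairs(
    dm: DistanceMatrix,
    metadata: CohortMetadata,
    kind: str,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Distances of related vs unrelated sample pairs.

    ``kind="couple"``: couples are the (M, F), (PGM, PGF) and (MGM, MGF) role
    pairs within a household; the complement is the same role pairs across
    households. ``kind="sibling"``: child pairs within vs across households.
    Returns (within-pair distances, complement distances, pair counts).
    """
    ids = [s for s in dm.ids if s in metadata.samples.index]
    sub = metadata.samples.loc[ids]
    within, between = [], []
    if kind == "couple":
        for role_a, role_b in COUPLE_ROLE_PAIRS:
            a_ids = sub.index[sub["role"] == role_a]
            b_ids = sub.index[sub["role"] == role_b]
            for sa in a_ids:
                for sb in b_ids:
                    d = dm[sa, sb]
                    if sub.at[sa, "household"] == sub.at[sb, "household"]:
                        within.append(d)
                    else:
                        between.append(d)
    elif kind == "sibling":
        kids = sub.index[sub["role"] == "C"]
        for sa, sb in itertools.combinations(kids, 2):
            d = dm[sa, sb]
            if sub.at[sa, "household"] == sub.at[sb, "household"]:
                within.append(d)
            else:
                between.append(d)
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    counts = {"within": len(within), "complement": len(between)}
    return np.asarray(within), np.asarray(between), counts
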