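"""Screens linking microbiome features to host variables.

Three analyses are covered:

* immune screening — tie-corrected Spearman correlations between feature
  relative abundances and immune indices, thresholded at |rho| and p, with a
  "strong" flag at a higher |rho|, and the overlap of edge-bearing features
  with the transmissible set;
* diet effects — per-taxon two-sided rank-sum comparison of relative
  abundance between consumers (Y) and non-consumers (N) of each food, with
  antibiotic-exposed subjects excluded, and a Welch t test of the
  family-derived proportion between picky and non-picky children;
* family time — Spearman correlation between child-member community
  similarity (1 - Bray-Curtis) and the member's daily hours with the child,
  plus per-role family-time comparisons.

All screens are rank-based or deterministic given their inputs; no random
number generation is involved outside simulations in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from famtrack.core_data import CohortMetadata, FeatureTable, TaxonomyMap, ValidationError
from famtrack.transmission import ContributionSummary

__all__ = [
    "spearman_screen",
    "transmissible_overlap",
    "OverlapSummary",
    "diet_effect_screen",
    "picky_transmission_test",
    "familytime_similarity",
    "FamilyTimeResult",
]

logger = logging.getLogger(__name__)


def spearman_screen(
    abundance: pd.DataFrame,
    indices: pd.DataFrame,
    r_min: float = 0.3,
    p_max: float = 0.05,
    strong: float = 0.5,
) -> pd.DataFrame:
    """Spearman edge list between features and host indices.

    ``abundance`` (samples x features) and ``indices`` (samples x indices)
    must share their row index. Edges are retained at ``|rho| > r_min`` and
    ``p < p_max``; ``passes_strong_threshold`` flags ``|rho| > strong``.
    Constant features or indices are skipped (logged). Returns a tidy frame
    (feature_id, index_name, rho, p, sign, passes_strong_threshold).
    """
    common = abundance.index.intersection(indices.index)
    if len(common) < 4:
        raise ValidationError("need at least 4 paired observations")
    a = abundance.loc[common]
    b = indices.loc[common]
    skipped = [c for c in a.columns if a[c].nunique() <= 1]
    skipped += [c for c in b.columns if b[c].nunique() <= 1]
    if skipped:
        logger.info("constant columns skipped in spearman screen: %s", skipped)
    a = a[[c for c in a.columns if a[c].nunique() > 1]]
    b = b[[c for c in b.columns if b[c].nunique() > 1]]
    n = len(common)
    ra = a.rank().to_numpy()
    rb = b.rank().to_numpy()
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    rho = ra.T @ rb / n
    rho = np.clip(rho, -1.0, 1.0)
    # t approximation for the Spearman p-value (two-sided), matching the
    # standard large-sample treatment with tie-corrected ranks
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    rows = []
    for i, feature in enumerate(a.columns):
        for j, index_name in enumerate(b.columns):
            r_ij, p_ij = float(rho[i, j]), float(p[i, j])
            if abs(r_ij) > r_min and p_ij < p_max:
                rows.append(
                    {
                        "feature_id": feature,
                        "index_name": index_name,
                        "rho": r_ij,
                        "p": p_ij,
                        "sign": 1 if r_ij > 0 else -1,
                        "passes_strong_threshold": abs(r_ij) > strong,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "index_name", "rho", "p", "sign", "passes_strong_threshold"],
    )


@dataclass
class OverlapSummary:
    n_edge_features: int
    n_overlap: int
    fraction: float
    by_class: pd.DataFrame | None  # class-level breakdown of overlapping features


def transmissible_overlap(
    edges: pd.DataFrame,
    transmissible: Iterable[str],
    tax: TaxonomyMap | None = None,
) -> OverlapSummary:
    """Share of edge-bearing features that belong to the transmissible set."""
    transmissible = set(transmissible)
    if edges.empty or not transmissible:
        raise ValidationError("edges and transmissible set must be non-empty")
    features = set(edges["feature_id"])
    overlap = features & transmissible
    by_class = None
    if tax is not None and overlap:
        labels = tax.rank_labels(sorted(overlap), "class")
        by_class = (
            pd.Series(labels, name="class")
            .value_counts()
            .rename_axis("class")
            .reset_index(name="n_features")
        )
        by_class["fraction"] = by_class["n_features"] / len(overlap)
    return OverlapSummary(
        n_edge_features=len(features),
        n_overlap=len(overlap),
        fraction=len(overlap) / len(features),
        by_class=by_class,
    )


def diet_effect_screen(
    abundance: pd.DataFrame,
    diet_flags: pd.DataFrame,
    p_max: float = 0.05,
    antibiotics: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-sided rank-sum test of each taxon's abundance between diet groups.

    ``abundance`` is subjects x taxa (relative abundance); ``diet_flags`` is
    subjects x foods with Y/N entries. Subjects flagged ``Y`` in
    ``antibiotics`` are excluded before testing. Foods with a single group
    are skipped (returned in the second element). Returns a tidy frame
    (taxon, food, p, significant).
    """
    common = abundance.index.intersection(diet_flags.index)
    a = abundance.loc[common]
    flags = diet_flags.loc[common]
    if antibiotics is not None:
        exposed = antibiotics.reindex(common).fillna("N") == "Y"
        a, flags = a[~exposed.to_numpy()], flags[~exposed.to_numpy()]
    rows, skipped = [], []
    for food in flags.columns:
        yes = flags[food] == "Y"
        no = flags[food] == "N"
        if yes.sum() == 0 or no.sum() == 0:
            skipped.append(food)
            logger.info("food %r has a single diet group; skipped", food)
            continue
        for taxon in a.columns:
            x = a.loc[yes.to_numpy(), taxon].to_numpy(dtype=float)
            y = a.loc[no.to_numpy(), taxon].to_numpy(dtype=float)
            if np.all(np.concatenate([x, y]) == x[0] if x.size else True):
                continue
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"taxon": taxon, "food": food, "p": float(p)})
    result = pd.DataFrame(rows, columns=["taxon", "food", "p"])
    result["significant"] = result["p"] < p_max
    return result, skipped


def picky_transmission_test(
    contributions: ContributionSummary,
    diet_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Welch t test of the family-derived proportion by food preference.

    For each food and niche, children who do not ingest the food (N) are
    compared with children who do (Y) on their family-derived proportion
    ``1 - alpha_unknown``. The reported difference is mean(N) - mean(Y), so a
    positive value means picky children derive more of their community from
    the family. Foods with fewer than 2 children per group are skipped.
    """
    trans = contributions.transmitted
    rows = []
    for niche in sorted(trans["niche"].unique()):
        sub = trans[trans["niche"] == niche].set_index("child")
        for food in diet_flags.columns:
            flags = diet_flags[food].reindex(sub.index)
            yes = sub.loc[(flags == "Y").to_numpy(), "transmitted_fraction"]
            no = sub.loc[(flags == "N").to_numpy(), "transmitted_fraction"]
            if len(yes) < 2 or len(no) < 2:
                continue
            t, p = stats.ttest_ind(no, yes, equal_var=False)
            rows.append(
                {
                    "food": food,
                    "niche": niche,
                    "n_N": int(len(no)),
                    "n_Y": int(len(yes)),
                    "difference": float(no.mean() - yes.mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows, columns=["food", "niche", "n_N", "n_Y", "difference", "t", "p"])


@dataclass
class FamilyTimeResult:
    pairs: pd.DataFrame  # child, member, role, niche, similarity, family_time
    correlations: pd.DataFrame  # niche, rho, p, n_pairs (NaN rho when undefined)
    role_comparison: pd.DataFrame  # role_a, role_b, statistic, p (family-time contrast)


def familytime_similarity(
    pairs: pd.DataFrame,
    family_time: pd.Series | None = None,
) -> FamilyTimeResult:
    """Correlate child-member community similarity with shared family time.

    ``pairs`` must carry columns ``child``, ``member``, ``role``, ``niche``,
    ``similarity`` (1 - Bray-Curtis of the same-niche pair) and
    ``family_time`` (hours/day); alternatively pass ``family_time`` indexed by
    member subject id and it is joined in. Spearman correlation is computed
    per niche; zero variance in hours yields an undefined (NaN) correlation,
    reported as such. Family-time differences between roles are tested with
    pairwise two-sided rank-sum comparisons.
    """
    pairs = pairs.copy()
    if "family_time" not in pairs.columns:
        if family_time is None:
            raise ValidationError("family_time column or series required")
        pairs["family_time"] = pairs["member"].map(family_time)
    pairs = pairs.dropna(subset=["family_time", "similarity"])
    if len(pairs) < 4:
        raise ValidationError("need at least 4 (similarity, hours) pairs")
    rows = []
    for niche, sub in pairs.groupby("niche"):
        if sub["family_time"].nunique() <= 1 or len(sub) < 4:
            rows.append({"niche": niche, "rho": np.nan, "p": np.nan, "n_pairs": len(sub)})
            continue
        rho, p = stats.spearmanr(sub["similarity"], sub["family_time"])
        rows.append({"niche": niche, "rho": float(rho), "p": float(p), "n_pairs": len(sub)})
    correlations = pd.DataFrame(rows, columns=["niche", "rho", "p", "n_pairs"])

    ft = pairs.drop_duplicates(subset=["member"])[["member", "role", "family_time"]]
    comp_rows = []
    roles = sorted(ft["role"].unique())
    import itertools as _it

    from famtrack.community_stats import rank_sum_compare

    for a, b in _it.combinations(roles, 2):
        xa = ft.loc[ft["role"] == a, "family_time"].to_numpy()
        xb = ft.loc[ft["role"] == b, "family_time"].to_numpy()
        if xa.size == 0 or xb.size == 0:
            continue
        stat, p = rank_sum_compare(xa, xb, "two_sided")
        comp_rows.append({"role_a": a, "role_b": b, "statistic": stat, "p": p})
    role_comparison = pd.DataFrame(comp_rows, columns=["role_a", "role_b", "statistic", "p"])
    return FamilyTimeResult(pairs=pairs, correlations=correlations, role_comparison=role_comparison)


def child_member_similarity(
    tables: Mapping[str, FeatureTable],
    metadata: CohortMetadata,
) -> pd.DataFrame:
    """Per child-member same-niche pair: similarity = 1 - Bray-Curtis.

    Builds the input frame for :func:`familytime_similarity` from per-niche
    tables and cohort metadata.
    """
    from famtrack.community_stats import beta_distance

    rows = []
    for niche, table in sorted(tables.items()):
        dm = beta_distance(table, "bray_curtis")
        samples = metadata.samples_in_niche(niche)
        samples = samples[samples.index.isin(table.sample_ids)]
        kids = samples[samples["role"] == "C"]
        adults = samples[samples["role"] != "C"]
        for kid_sample, kid_row in kids.iterrows():
            hh_adults = adults[adults["household"] == kid_row["household"]]
            for ad_sample, ad_row in hh_adults.iterrows():
                member = str(ad_row["subject_id"])
                rows.append(
                    {
                        "child": str(kid_row["subject_id"]),
                        "member": member,
                        "role": ad_row["role"],
                        "niche": niche,
                        "similarity": 1.0 - float(dm[kid_sample, ad_sample]),
                        "family_time": float(metadata.subjects.at[member, "family_time"]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["child", "member", "role", "niche", "similarity", "family_time"]
    )
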