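"""Cohort summaries of source tracking: member contributions, transmission
ratios, and the putative-familial-transmissible-bacteria classification.

The transmission ratio (TR) of a taxon, per household and niche, is the
fraction of the children's counts of that taxon attributed to family-member
sources:

    TR(h, niche, g) = sum_{j in g} sum_{i known} a_ij / sum_{j in g} x_j

where ``a_ij`` is the per-ASV attribution from the mixture fit and ``g`` is a
group of ASVs collapsed to a taxonomic rank (family by default). TR is
undefined when the taxon has no counts in the household's children. The
cohort-level TR of a taxon is the unweighted mean over households where it is
defined (an abundance-weighted mean is available as an option).

Taxa with cohort TR above a small epsilon in a niche form that niche's
putative transmissible set; the "common" set is the intersection across
niches. The epsilon (default 0.05) absorbs the attribution leakage created by
pseudocount smoothing of the source communities: with smoothing, every taxon
receives a strictly positive — but bounded — known-source share, so a literal
"TR > 0" rule would mark nearly everything transmissible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from famtrack.core_data import TaxonomyMap, ValidationError
from famtrack.source_tracking import CohortTracking

__all__ = [
    "ContributionSummary",
    "TRTable",
    "TransmissibleSets",
    "member_contributions",
    "transmission_ratio",
    "classify_transmissible",
]

UNKNOWN = "Unknown"


@dataclass
class ContributionSummary:
    """Per-child and cohort-mean source contributions per niche."""

    per_child: pd.DataFrame  # child, household, niche, source, proportion
    role_means: pd.DataFrame  # niche, source, mean_proportion, n_children
    transmitted: pd.DataFrame  # child, household, niche, transmitted_fraction
    transmitted_means: pd.Series  # niche -> cohort mean transmitted fraction

    def transmitted_fraction(self, niche: str) -> float:
        return float(self.transmitted_means[niche])

    def role_mean(self, niche: str, role: str) -> float:
        sel = self.role_means[
            (self.role_means["niche"] == niche) & (self.role_means["source"] == role)
        ]
        if sel.empty:
            raise KeyError(f"no children with source {role!r} in niche {niche!r}")
        return float(sel["mean_proportion"].iloc[0])


def member_contributions(tracking: CohortTracking) -> ContributionSummary:
    """Summarize mixing proportions: role-wise means and transmitted fractions.

    Role means average over the children that actually have that role as a
    source; children lacking a role do not enter its denominator. The
    transmitted fraction of a child is ``1 - alpha_unknown``.
    """
    if not tracking.results:
        raise ValidationError("no mixture estimates to summarize")
    per_child = tracking.alpha_frame()
    role_means = (
        per_child.groupby(["niche", "source"], as_index=False)
        .agg(mean_proportion=("proportion", "mean"), n_children=("proportion", "size"))
    )
    unknown = per_child[per_child["source"] == UNKNOWN].copy()
    unknown["transmitted_fraction"] = 1.0 - unknown["proportion"]
    transmitted = unknown[["child", "household", "niche", "transmitted_fraction"]].reset_index(
        drop=True
    )
    transmitted_means = transmitted.groupby("niche")["transmitted_fraction"].mean()
    return ContributionSummary(
        per_child=per_child,
        role_means=role_means,
        transmitted=transmitted,
        transmitted_means=transmitted_means,
    )


@dataclass
class TRTable:
    """Transmission ratios per (household, niche, taxon) and cohort means."""

    rank: str
    per_household: pd.DataFrame  # household, niche, taxon, tr, child_counts
    cohort: pd.DataFrame  # niche, taxon, tr, n_households

    def cohort_tr(self, niche: str, taxon: str) -> float:
        sel = self.cohort[(self.cohort["niche"] == niche) & (self.cohort["taxon"] == taxon)]
        if sel.empty:
            raise KeyError(f"taxon {taxon!r} undefined in niche {niche!r}")
        return float(sel["tr"].iloc[0])


def transmission_ratio(
    tracking: CohortTracking,
    tax: TaxonomyMap,
    rank: str = "family",
    weighted: bool = False,
) -> TRTable:
    """Per-taxon transmission ratios at a taxonomic rank.

    ASVs are collapsed to ``rank`` groups; a household with several children
    pools their counts. Entries are undefined (absent, not 0) when the
    children of a household carry no counts of the taxon. Cohort TR is the
    mean over defined households — unweighted by default, weighted by the
    children's taxon counts when ``weighted``.
    """
    rows = []
    # pool (household, niche): numerator/denominator per taxon group
    pooled: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for rec in tracking.results:
        key = (rec.household, rec.niche)
        labels = tax.rank_labels(rec.asv_ids, rank)
        frame = pooled.setdefault(key, {})
        known = rec.estimate.attribution[:-1].sum(axis=0)
        for label, x_j, k_j in zip(labels, rec.sink, known):
            num, den = frame.get(label, (0.0, 0.0))
            frame[label] = (num + float(k_j), den + float(x_j))
    for (household, niche), groups in sorted(pooled.items()):
        for taxon, (num, den) in sorted(groups.items()):
            if den <= 0:
                continue  # undefined entry: taxon absent from the children
            rows.append(
                {
                    "household": household,
                    "niche": niche,
                    "taxon": taxon,
                    "tr": min(1.0, num / den),
                    "child_counts": den,
                }
            )
    per_household = pd.DataFrame(
        rows, columns=["household", "niche", "taxon", "tr", "child_counts"]
    )
    if per_household.empty:
        cohort = pd.DataFrame(columns=["niche", "taxon", "tr", "n_households"])
    elif weighted:
        def _wmean(g: pd.DataFrame) -> pd.Series:
            return pd.Series(
                {
                    "tr": float(np.average(g["tr"], weights=g["child_counts"])),
                    "n_households": int(len(g)),
                }
            )

        cohort = (
            per_household.groupby(["niche", "taxon"])
            .apply(_wmean, include_groups=False)
            .reset_index()
        )
    else:
        cohort = (
            per_household.groupby(["niche", "taxon"], as_index=False)
            .agg(tr=("tr", "mean"), n_households=("household", "nunique"))
        )
    return TRTable(rank=rank, per_household=per_household, cohort=cohort)


@dataclass
class TransmissibleSets:
    """Putative familial transmissible taxa per niche and across niches."""

    epsilon: float
    per_niche: dict[str, set[str]]
    common: set[str]
    detected_common: set[str]  # taxa merely detected in children of all niches
    cohort_tr: pd.DataFrame  # the classification input, for reporting


def classify_transmissible(
    tr: TRTable,
    niches: Sequence[str] | None = None,
    epsilon: float = 0.05,
) -> TransmissibleSets:
    """Classify taxa as putative familial transmissible bacteria.

    A taxon enters a niche's set when its cohort TR exceeds ``epsilon``; the
    common set is the intersection over the requested niches. ``detected_common``
    additionally reports the taxa merely detected (TR defined) in children of
    every niche, since detection and transmissibility are distinct notions.
    """
    cohort = tr.cohort
    if niches is None:
        niches = sorted(cohort["niche"].unique())
    per_niche: dict[str, set[str]] = {}
    detected: dict[str, set[str]] = {}
    for niche in niches:
        sub = cohort[cohort["niche"] == niche]
        detected[niche] = set(sub["taxon"])
        per_niche[niche] = set(sub.loc[sub["tr"] > epsilon, "taxon"])
    common = set.intersection(*per_niche.values()) if per_niche else set()
    detected_common = set.intersection(*detected.values()) if detected else set()
    return TransmissibleSets(
        epsilon=epsilon,
        per_niche=per_niche,
        common=common,
        detected_common=detected_common,
        cohort_tr=cohort[cohort["niche"].isin(list(niches))].reset_index(drop=True),
    )
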