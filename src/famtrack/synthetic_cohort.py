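"""Synthetic three-generation household cohorts with known ground truth.

The generator emulates the structure of a household-based 16S cohort:
24 families spanning three generations (roles C, M, F, PGM, PGF, MGM, MGF),
three body niches (gut, oral, skin), household-specific community shifts, and
children whose communities are convex mixtures of their family members'
communities plus an independent environmental component.

Ground truth is recorded for every planted signal so downstream stages can be
scored: the true mixing proportions per child and niche, the transmissible
taxon set (supported only in member sources), the environment-only set
(supported only in the unknown source), diet-responsive taxa with fold sizes,
and immune-correlated ASVs with signs.

Construction, per niche:

* a niche *base* profile over member-supported ASVs (heavy-tailed gamma
  weights, normalised);
* per household, a profile drawn from a Dirichlet centred on the base
  (low concentration => strong household effect);
* per adult member, a profile drawn from a Dirichlet centred on the
  household profile (high concentration => within-household similarity);
* per child, a true mixing vector alpha over the present adult roles plus
  the unknown source, and counts drawn multinomially at a log-normal depth
  from ``sum_i alpha_i gamma_i + alpha_unknown gamma_env``, where
  ``gamma_env`` is supported on environment-only ASVs and independent per
  child.

Planted effects perturb the child mixture before the multinomial draw:
diet-responsive ASVs are multiplied by a fold size in consumers, and
immune-responsive ASVs are driven by a per-child latent factor that also
enters the corresponding immune index (plus noise calibrated to the target
Spearman correlation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from famtrack.core_data import (
    ADULT_ROLES,
    DIET_FOODS,
    IMMUNE_INDICES,
    NICHES,
    CohortMetadata,
    FeatureTable,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_tree",
    "alpha_recovery",
]

UNKNOWN = "Unknown"

# Default true mixing templates per niche: mother-heavy known part, unknown
# fractions chosen so that default runs produce magnitudes familiar from
# household cohorts (gut ~45% unknown, oral ~39%, skin ~23%).
DEFAULT_ALPHA_TEMPLATES: dict[str, dict[str, float]] = {
    "gut": {"M": 0.12, "F": 0.10, "PGM": 0.09, "PGF": 0.09, "MGM": 0.08, "MGF": 0.07, UNKNOWN: 0.45},
    "oral": {"M": 0.16, "F": 0.12, "PGM": 0.10, "PGF": 0.09, "MGM": 0.08, "MGF": 0.06, UNKNOWN: 0.39},
    "skin": {"M": 0.22, "F": 0.15, "PGM": 0.12, "PGF": 0.11, "MGM": 0.09, "MGF": 0.08, UNKNOWN: 0.23},
}

# Adult immune-index scales (mean, sd) per role, in clinical units
# (immunoglobulins g/L, lymphocyte subsets as percentages).
IMMUNE_SCALES: dict[str, dict[str, tuple[float, float]]] = {
    "C": {"IgA": (1.1, 0.6), "IgG": (8.8, 2.1), "IgM": (1.1, 0.5), "CD3": (70.1, 8.0),
          "CD4": (36.8, 7.5), "CD8": (26.8, 5.6), "CD19": (13.9, 6.3), "CD56": (6.7, 4.3)},
    "M": {"IgA": (2.4, 0.8), "IgG": (11.7, 2.9), "IgM": (1.2, 0.4), "CD3": (73.3, 8.5),
          "CD4": (29.1, 7.7), "CD8": (26.9, 8.5), "CD19": (8.3, 3.1), "CD56": (10.5, 6.9)},
    "F": {"IgA": (2.4, 0.9), "IgG": (11.7, 1.5), "IgM": (1.0, 0.4), "CD3": (73.8, 7.7),
          "CD4": (39.2, 6.5), "CD8": (29.8, 6.1), "CD19": (8.8, 3.7), "CD56": (11.1, 6.2)},
    "PGM": {"IgA": (2.4, 0.6), "IgG": (10.9, 1.8), "IgM": (1.0, 0.4), "CD3": (73.6, 7.8),
            "CD4": (43.9, 7.6), "CD8": (26.9, 8.7), "CD19": (10.0, 5.2), "CD56": (10.2, 5.3)},
    "PGF": {"IgA": (2.3, 0.7), "IgG": (12.7, 1.7), "IgM": (0.9, 0.4), "CD3": (64.2, 12.9),
            "CD4": (39.5, 10.2), "CD8": (26.5, 9.5), "CD19": (9.9, 6.6), "CD56": (14.7, 11.7)},
    "MGM": {"IgA": (3.0, 1.0), "IgG": (12.7, 2.3), "IgM": (1.0, 0.5), "CD3": (66.6, 11.1),
            "CD4": (40.3, 9.0), "CD8": (22.6, 6.2), "CD19": (11.1, 4.4), "CD56": (13.0, 7.2)},
    "MGF": {"IgA": (2.7, 1.0), "IgG": (12.0, 2.1), "IgM": (0.6, 0.3), "CD3": (67.9, 9.0),
            "CD4": (33.7, 10.5), "CD8": (30.2, 14.3), "CD19": (6.9, 3.2), "CD56": (18.4, 7.9)},
}

# Age (mean, sd) and family-time hours/day (mean, sd) per role.
AGE_SCALES = {"C": (4.6, 2.7), "M": (34.3, 3.3), "F": (35.2, 3.3), "PGM": (62.4, 4.3),
              "PGF": (63.4, 5.3), "MGM": (59.7, 5.3), "MGF": (59.5, 5.4)}
FT_SCALES = {"M": (9.7, 5.4), "F": (8.2, 5.3), "PGM": (12.1, 7.8), "PGF": (9.6, 8.8),
             "MGM": (6.3, 6.3), "MGF": (4.9, 5.3)}

# Probability each subject class consumes each food.
ADULT_DIET_P = {"fish": 0.6, "eggs": 0.7, "milk": 0.5, "meat": 0.8, "vegetables": 0.9,
                "fruits": 0.8, "liquor": 0.4, "cigarette": 0.3}
CHILD_DIET_P = {"fish": 0.5, "eggs": 0.7, "milk": 0.6, "meat": 0.6, "vegetables": 0.6,
                "fruits": 0.8}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults match the emulated study design."""

    n_households: int = 24
    two_child_households: int = 10
    grandparent_counts: Mapping[str, int] = field(
        default_factory=lambda: {"PGM": 18, "PGF": 19, "MGM": 15, "MGF": 10}
    )
    niches: tuple[str, ...] = NICHES
    n_asvs: int = 300  # per niche
    n_transmissible_families: int = 30
    n_env_families: int = 10
    transmissible_fraction: float = 0.75  # fraction of ASVs in transmissible families
    env_fraction: float = 0.25  # fraction of ASVs in environment-only families

    base_concentration: float = 0.8  # gamma shape of the niche base profile
    household_concentration: float | None = 30.0  # Dirichlet conc around the base
    household_mixing_weight: float = 0.3  # share of a member's community from the household
    member_concentration: float | None = 200.0  # Dirichlet conc around the member mean
    env_concentration: float | None = 50.0  # per-child env community concentration

    alpha_templates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ALPHA_TEMPLATES.items()}
    )
    alpha_concentration: float | None = 60.0  # Dirichlet jitter of the child mixture
    familytime_tilt: float = 0.05  # per-hour multiplicative tilt of member shares

    depth_median: float = 1e4  # log-normal sequencing depth, median reads
    depth_sigma: float = 0.3
    adult_presence: Mapping[str, float] = field(
        default_factory=lambda: {"gut": 0.67, "oral": 0.73, "skin": 1.0}
    )

    diet_foods_planted: tuple[str, ...] = ("meat", "vegetables")
    diet_fold: float = 3.0
    n_diet_asvs: int = 10  # per planted food, gut niche
    diet_level: float = 0.0015  # baseline relative abundance of a planted diet ASV
    antibiotic_rate: float = 0.08

    n_immune_asvs: int = 30
    immune_rho: float = 0.6  # target Spearman between planted ASVs and their index
    immune_level: float = 0.0012  # expected relative abundance of a planted immune ASV
    immune_beta: float = 0.9  # latent-factor scale on log abundance
    immune_lambda: float = 0.68  # index loading on the latent factor (calibrated to rho)

    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.transmissible_fraction, self.env_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("taxon fractions must lie in [0, 1]")
        if abs(self.transmissible_fraction + self.env_fraction - 1.0) > 1e-9:
            raise ValidationError("transmissible and environment fractions must partition the ASVs")
        for niche in self.niches:
            tpl = self.alpha_templates.get(niche)
            if tpl is None:
                raise ValidationError(f"no alpha template for niche {niche!r}")
            if any(v < 0 for v in tpl.values()):
                raise ValidationError("alpha template entries must be >= 0")
            if abs(sum(tpl.values()) - 1.0) > 1e-9:
                raise ValidationError(f"alpha template for {niche!r} does not sum to 1")


@dataclass
class GroundTruth:
    """Planted signals of a synthetic cohort, for scoring recovery."""

    alpha: dict[str, dict[str, dict[str, float]]]  # subject -> niche -> source -> prop
    transmissible_families: set[str]
    env_families: set[str]
    transmissible_asvs: dict[str, set[str]]  # niche -> ASVs in member support
    env_asvs: dict[str, set[str]]
    diet_responsive: dict[str, dict[str, float]]  # "food|niche" -> asv -> fold
    immune_asvs: list[dict]  # records: index, asv, sign, rho

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "transmissible_families": sorted(self.transmissible_families),
            "env_families": sorted(self.env_families),
            "transmissible_asvs": {k: sorted(v) for k, v in self.transmissible_asvs.items()},
            "env_asvs": {k: sorted(v) for k, v in self.env_asvs.items()},
            "diet_responsive": self.diet_responsive,
            "immune_asvs": self.immune_asvs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            alpha=payload["alpha"],
            transmissible_families=set(payload["transmissible_families"]),
            env_families=set(payload["env_families"]),
            transmissible_asvs={k: set(v) for k, v in payload["transmissible_asvs"].items()},
            env_asvs={k: set(v) for k, v in payload["env_asvs"].items()},
            diet_responsive=payload["diet_responsive"],
            immune_asvs=payload["immune_asvs"],
        )


@dataclass
class SyntheticCohort:
    tables: dict[str, FeatureTable]
    taxonomy: TaxonomyMap
    metadata: CohortMetadata
    tree: str  # Newick
    truth: GroundTruth

    def write(self, outdir: str | Path, header_comment: str | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for niche, table in self.tables.items():
            table.to_tsv(outdir / f"counts_{niche}.tsv", header_comment)
        self.taxonomy.to_tsv(outdir / "taxonomy.tsv")
        self.metadata.to_tsv(outdir / "metadata.tsv", header_comment)
        (outdir / "tree.nwk").write_text(self.tree + "\n")
        self.truth.to_json(outdir / "ground_truth.json")


def alpha_recovery(truth: GroundTruth, tracking) -> pd.DataFrame:
    """Score estimated mixing proportions against the planted truth.

    For each tracked (child, niche), the L1 distance between the estimated
    and true proportion vectors. True mass of roles that were unavailable as
    sources (member not sampled, or dropped at rarefaction) is folded into
    the unknown component, since an absent source's contribution is by
    definition part of what the model cannot attribute.
    """
    rows = []
    for rec in tracking.results:
        true_alpha = dict(truth.alpha[rec.child][rec.niche])
        est = rec.alpha_by_role()
        avail = set(rec.source_roles)
        folded = {r: v for r, v in true_alpha.items() if r in avail}
        folded[UNKNOWN] = true_alpha.get(UNKNOWN, 0.0) + sum(
            v for r, v in true_alpha.items() if r != UNKNOWN and r not in avail
        )
        labels = set(folded) | set(est)
        l1 = sum(abs(folded.get(lab, 0.0) - est.get(lab, 0.0)) for lab in labels)
        rows.append(
            {
                "child": rec.child,
                "niche": rec.niche,
                "n_sources": len(rec.source_roles),
                "l1": l1,
                "unknown_error": abs(folded[UNKNOWN] - est.get(UNKNOWN, 0.0)),
            }
        )
    return pd.DataFrame(rows, columns=["child", "niche", "n_sources", "l1", "unknown_error"])


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------


def generate_tree(asv_ids: Sequence[str], seed: int | None = None) -> str:
    """Random rooted binary tree over ``asv_ids`` in Newick form.

    Pairs of subtrees are joined uniformly at random; branch lengths are
    i.i.d. exponential(1). The same seed reproduces the identical string.
    """
    ids = [str(a) for a in asv_ids]
    if len(ids) < 2:
        raise ValidationError("need at least 2 ASV ids to build a tree")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ASV ids")
    rng = np.random.default_rng(seed)
    nodes = list(ids)
    while len(nodes) > 1:
        i, k = sorted(rng.choice(len(nodes), size=2, replace=False))
        bl = rng.exponential(1.0, size=2)
        right = nodes.pop(k)
        left = nodes.pop(i)
        nodes.append(f"({left}:{bl[0]:.6f},{right}:{bl[1]:.6f})")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _dirichlet(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    """Dirichlet draw via gamma variates; zero concentrations stay exactly zero."""
    g = np.where(conc > 0, rng.gamma(np.maximum(conc, 1e-300)), 0.0)
    total = g.sum()
    if total == 0:
        raise ValidationError("degenerate Dirichlet draw: all concentrations zero")
    return g / total


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
               size: int | None = None) -> np.ndarray | float:
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Identical ``config.seed`` yields byte-identical emitted files.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    niches = list(cfg.niches)
    households = [f"H{i + 1:02d}" for i in range(cfg.n_households)]

    # --- household composition ------------------------------------------------
    two_child = set(rng.choice(households, size=cfg.two_child_households, replace=False))
    gp_presence: dict[str, set[str]] = {}
    for role in ("PGM", "PGF", "MGM", "MGF"):
        count = min(int(cfg.grandparent_counts.get(role, 0)), cfg.n_households)
        gp_presence[role] = set(rng.choice(households, size=count, replace=False))

    subject_rows = []
    for hh in households:
        kids = ["C1", "C2"] if hh in two_child else ["C1"]
        for tag in kids:
            subject_rows.append((f"{hh}_{tag}", hh, "C"))
        for role in ("M", "F"):
            subject_rows.append((f"{hh}_{role}", hh, role))
        for role in ("PGM", "PGF", "MGM", "MGF"):
            if hh in gp_presence[role]:
                subject_rows.append((f"{hh}_{role}", hh, role))

    subjects = pd.DataFrame(subject_rows, columns=["subject_id", "household", "role"])
    subjects = subjects.set_index("subject_id")

    # covariates
    ages, sexes, fts = [], [], []
    for sid, row in subjects.iterrows():
        role = row["role"]
        mean, sd = AGE_SCALES[role]
        ages.append(round(float(_truncnorm(rng, mean, sd, 0.0, 100.0)), 1))
        if role == "C":
            sexes.append("F" if rng.random() < 0.5 else "M")
            fts.append(np.nan)
        else:
            sexes.append("F" if role in ("M", "PGM", "MGM") else "M")
            mean, sd = FT_SCALES[role]
            fts.append(round(float(_truncnorm(rng, mean, sd, 0.5, 24.0)), 1))
    subjects["age"] = ages
    subjects["sex"] = sexes
    subjects["family_time"] = fts
    subjects["antibiotics"] = np.where(
        rng.random(len(subjects)) < cfg.antibiotic_rate, "Y", "N"
    )

    # diet flags; children inherit liquor/cigarette from any household adult
    for food in DIET_FOODS:
        flags = []
        for sid, row in subjects.iterrows():
            if row["role"] == "C" and food in ("liquor", "cigarette"):
                flags.append(None)  # filled below from household adults
            elif row["role"] == "C":
                flags.append("Y" if rng.random() < CHILD_DIET_P[food] else "N")
            else:
                flags.append("Y" if rng.random() < ADULT_DIET_P[food] else "N")
        subjects[f"diet_{food}"] = flags
    for food in ("liquor", "cigarette"):
        col = f"diet_{food}"
        by_hh = subjects[subjects["role"] != "C"].groupby("household")[col].apply(
            lambda s: "Y" if (s == "Y").any() else "N"
        )
        mask = subjects["role"] == "C"
        subjects.loc[mask, col] = subjects.loc[mask, "household"].map(by_hh)

    # --- taxonomy --------------------------------------------------------------
    fam_t = [f"famT{i + 1:02d}" for i in range(cfg.n_transmissible_families)]
    fam_e = [f"famE{i + 1:02d}" for i in range(cfg.n_env_families)]
    n_member = int(round(cfg.n_asvs * cfg.transmissible_fraction))
    n_env = cfg.n_asvs - n_member

    asv_ids: dict[str, list[str]] = {}
    member_idx: dict[str, np.ndarray] = {}
    env_idx: dict[str, np.ndarray] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    offset = 0
    for niche in niches:
        ids = [f"ASV{offset + j + 1:06d}" for j in range(cfg.n_asvs)]
        asv_ids[niche] = ids
        member_idx[niche] = np.arange(n_member)
        env_idx[niche] = np.arange(n_member, cfg.n_asvs)
        for j, asv in enumerate(ids):
            if j < n_member:
                fam = fam_t[j % len(fam_t)]
            else:
                fam = fam_e[(j - n_member) % len(fam_e)]
            k = int(fam[4:])  # family number within its class
            phylum = f"Phylum{(k - 1) % 8 + 1:02d}"
            klass = f"Class{(k - 1) % 12 + 1:02d}"
            order = f"Order{(k - 1) % 18 + 1:02d}"
            genus = f"gen_{fam}_{j % 3 + 1}"
            lineages[asv] = ("Bacteria", phylum, klass, order, fam, genus)
        offset += cfg.n_asvs
    taxonomy = TaxonomyMap(lineages)
    all_ids = [a for niche in niches for a in asv_ids[niche]]
    tree = generate_tree(all_ids, seed=int(rng.integers(2**31)))

    # --- base profiles ----------------------------------------------------------
    base_member: dict[str, np.ndarray] = {}
    base_env: dict[str, np.ndarray] = {}
    for niche in niches:
        bm = np.zeros(cfg.n_asvs)
        bm[member_idx[niche]] = rng.gamma(cfg.base_concentration, size=n_member)
        base_member[niche] = bm / bm.sum()
        be = np.zeros(cfg.n_asvs)
        be[env_idx[niche]] = rng.gamma(cfg.base_concentration, size=n_env)
        base_env[niche] = be / be.sum()

    # --- planted effect targets (gut niche) -------------------------------------
    gut = niches[0] if "gut" not in niches else "gut"
    order_by_abund = np.argsort(base_member[gut])[::-1]
    member_ranked = [asv_ids[gut][int(j)] for j in order_by_abund if int(j) < n_member]
    # immune ASVs sit in the low-abundance tail (their level is overridden by
    # the latent factor anyway); diet ASVs in the mid tier: abundant enough to
    # test, small enough that the fold perturbs the mixture only mildly
    immune_start = min(120, max(0, n_member - cfg.n_immune_asvs))
    immune_pool = member_ranked[immune_start : immune_start + cfg.n_immune_asvs]
    diet_pool = member_ranked[60 : immune_start] + member_ranked[immune_start + cfg.n_immune_asvs :]

    immune_records: list[dict] = []
    immune_sets: dict[str, list[tuple[str, int]]] = {m: [] for m in IMMUNE_INDICES}
    for k, asv in enumerate(immune_pool):
        index = IMMUNE_INDICES[k % len(IMMUNE_INDICES)]
        sign = 1 if (k // len(IMMUNE_INDICES)) % 3 < 2 else -1
        immune_sets[index].append((asv, sign))
        immune_records.append(
            {"index": index, "asv": asv, "sign": sign, "rho": cfg.immune_rho}
        )
    immune_asv_pos = {
        asv: (asv_ids[gut].index(asv), m, sign)
        for m, pairs in immune_sets.items()
        for asv, sign in pairs
    }

    diet_responsive: dict[str, dict[str, float]] = {}
    diet_targets: dict[str, dict[int, float]] = {}
    cursor = 0
    for food in cfg.diet_foods_planted:
        chosen = diet_pool[cursor : cursor + cfg.n_diet_asvs]
        cursor += cfg.n_diet_asvs
        diet_responsive[f"{food}|{gut}"] = {a: cfg.diet_fold for a in chosen}
        diet_targets[food] = {asv_ids[gut].index(a): cfg.diet_fold for a in chosen}

    def _apply_diet(p: np.ndarray, sid: str, niche: str) -> np.ndarray:
        """Planted diet effect: a stable baseline level, multiplied by the
        fold size in consumers, so the Y/N contrast is the fold itself."""
        if niche != gut:
            return p
        for food, targets in diet_targets.items():
            consumes = subjects.at[sid, f"diet_{food}"] == "Y"
            for j, fold in targets.items():
                p[j] = cfg.diet_level * (fold if consumes else 1.0)
        return p

    # --- profiles ---------------------------------------------------------------
    hh_profiles: dict[tuple[str, str], np.ndarray] = {}
    member_profiles: dict[tuple[str, str], np.ndarray] = {}
    for niche in niches:
        for hh in households:
            if cfg.household_concentration is None:
                prof = base_member[niche].copy()
            else:
                prof = _dirichlet(rng, cfg.household_concentration * base_member[niche])
            hh_profiles[(hh, niche)] = prof
        for sid, row in subjects.iterrows():
            if row["role"] == "C":
                continue
            h = hh_profiles[(row["household"], niche)]
            # each adult is mostly an individual community plus a shared
            # household component; the blend drives within-household similarity
            if cfg.household_concentration is None:
                indiv = base_member[niche].copy()
            else:
                indiv = _dirichlet(rng, cfg.household_concentration * base_member[niche])
            mean = cfg.household_mixing_weight * h + (1 - cfg.household_mixing_weight) * indiv
            if cfg.member_concentration is None:
                member_profiles[(sid, niche)] = mean
            else:
                member_profiles[(sid, niche)] = _dirichlet(rng, cfg.member_concentration * mean)

    # --- sample presence ---------------------------------------------------------
    present: dict[tuple[str, str], bool] = {}
    for niche in niches:
        p_adult = cfg.adult_presence.get(niche, 1.0)
        for sid, row in subjects.iterrows():
            if row["role"] == "C":
                present[(sid, niche)] = True
            else:
                present[(sid, niche)] = bool(rng.random() < p_adult)

    # --- children: latent immune factors, true alphas, counts ---------------------
    child_ids = [s for s in subjects.index if subjects.at[s, "role"] == "C"]
    u_latent = {m: {c: float(rng.normal()) for c in child_ids} for m in IMMUNE_INDICES}

    truth_alpha: dict[str, dict[str, dict[str, float]]] = {}
    count_rows: dict[str, dict[str, np.ndarray]] = {niche: {} for niche in niches}
    depth_of: dict[tuple[str, str], int] = {}

    ft_center = 9.0  # hours/day around which the family-time tilt is neutral

    # adults first (fixed iteration order)
    for niche in niches:
        for sid, row in subjects.iterrows():
            if row["role"] == "C" or not present[(sid, niche)]:
                continue
            depth = max(500, int(rng.lognormal(math.log(cfg.depth_median), cfg.depth_sigma)))
            depth_of[(sid, niche)] = depth
            p = _apply_diet(member_profiles[(sid, niche)].copy(), sid, niche)
            p = p / p.sum()
            count_rows[niche][sid] = rng.multinomial(depth, p)

    for niche in niches:
        template = dict(cfg.alpha_templates[niche])
        for sid in child_ids:
            hh = subjects.at[sid, "household"]
            adults = [
                a for a in subjects.index
                if subjects.at[a, "household"] == hh
                and subjects.at[a, "role"] != "C"
                and present[(a, niche)]
            ]
            roles_present = [subjects.at[a, "role"] for a in adults]
            # restrict the template to present roles; redistribute missing known
            # mass proportionally among present known roles, keep unknown fixed
            known = {r: template.get(r, 0.0) for r in roles_present}
            unknown = template.get(UNKNOWN, 0.0)
            known_total = sum(known.values())
            target_known = 1.0 - unknown
            if known_total > 0:
                known = {r: v * target_known / known_total for r, v in known.items()}
            else:
                unknown = 1.0
            # family-time tilt: members who spend more hours contribute more
            if cfg.familytime_tilt and known and sum(known.values()) > 0:
                tilted = {}
                for a, r in zip(adults, roles_present):
                    ft = subjects.at[a, "family_time"]
                    tilted[r] = known[r] * math.exp(cfg.familytime_tilt * (float(ft) - ft_center))
                scale = target_known / sum(tilted.values()) if tilted else 0.0
                known = {r: v * scale for r, v in tilted.items()}
            labels = roles_present + [UNKNOWN]
            template_vec = np.array([known.get(r, 0.0) for r in roles_present] + [unknown])
            if cfg.alpha_concentration is None:
                alpha = template_vec.copy()
            else:
                alpha = _dirichlet(rng, cfg.alpha_concentration * template_vec)
            truth_alpha.setdefault(sid, {})[niche] = {
                lab: float(a) for lab, a in zip(labels, alpha)
            }

            if cfg.env_concentration is None:
                gamma_env = base_env[niche].copy()
            else:
                gamma_env = _dirichlet(rng, cfg.env_concentration * base_env[niche])

            p = alpha[-1] * gamma_env
            for a, w in zip(adults, alpha[:-1]):
                p = p + w * member_profiles[(a, niche)]
            if p.sum() <= 0:
                raise ValidationError(f"degenerate mixture for child {sid} in {niche}")
            p = _apply_diet(p, sid, niche)
            if niche == gut and immune_asv_pos:
                for asv, (j, m, sign) in immune_asv_pos.items():
                    p[j] = cfg.immune_level * math.exp(
                        cfg.immune_beta * sign * u_latent[m][sid]
                    )
            p = p / p.sum()
            depth = max(500, int(rng.lognormal(math.log(cfg.depth_median), cfg.depth_sigma)))
            depth_of[(sid, niche)] = depth
            count_rows[niche][sid] = rng.multinomial(depth, p)

    # --- immune indices ------------------------------------------------------------
    lam = cfg.immune_lambda
    for m in IMMUNE_INDICES:
        vals = []
        for sid, row in subjects.iterrows():
            mean, sd = IMMUNE_SCALES[row["role"]][m]
            if row["role"] == "C":
                z = lam * u_latent[m][sid] + math.sqrt(max(0.0, 1 - lam**2)) * rng.normal()
            else:
                z = rng.normal()
            vals.append(round(max(0.0, mean + sd * z), 3))
        subjects[f"imm_{m}"] = vals

    # --- assemble tables and metadata -----------------------------------------------
    tables: dict[str, FeatureTable] = {}
    sample_rows = []
    for niche in niches:
        ordered = [s for s in subjects.index if s in count_rows[niche]]
        mat = np.vstack([count_rows[niche][s] for s in ordered])
        sample_ids = [f"{s}_{niche}" for s in ordered]
        tables[niche] = FeatureTable(
            pd.DataFrame(mat, index=sample_ids, columns=asv_ids[niche])
        )
        for s, samp in zip(ordered, sample_ids):
            sample_rows.append(
                (samp, s, subjects.at[s, "household"], subjects.at[s, "role"], niche)
            )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "subject_id", "household", "role", "niche"]
    ).set_index("sample_id")

    metadata = CohortMetadata(samples=samples, subjects=subjects)

    truth = GroundTruth(
        alpha=truth_alpha,
        transmissible_families=set(fam_t),
        env_families=set(fam_e),
        transmissible_asvs={n: set(np.array(asv_ids[n])[member_idx[n]]) for n in niches},
        env_asvs={n: set(np.array(asv_ids[n])[env_idx[n]]) for n in niches},
        diet_responsive=diet_responsive,
        immune_asvs=immune_records,
    )
    return SyntheticCohort(tables=tables, taxonomy=taxonomy, metadata=metadata,
                           tree=tree, truth=truth)
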