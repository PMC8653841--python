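"""End-to-end orchestration: simulate/load -> prepare -> stats -> track -> tr -> assoc.

Every stage persists its outputs as plain text (TSV/CSV/JSON) under the run
directory and can restart from the previous stage's persisted artifacts, so
the pipeline is re-enterable stage by stage. All randomness derives from the
single run seed; a rerun with the same configuration is byte-identical
(except the run report, which records wall-clock timings).

Stage map:

* ``simulate`` — synthetic cohort (or skipped when input paths are given);
* ``prepare`` — rarefaction per niche, subject-level cross-niche merge;
* ``stats`` — Shannon, unweighted UniFrac + PCoA, household ANOSIM
  (global + pairwise, Bray-Curtis), Kruskal-Wallis differential features at
  the individual level, couple/sibling distance contrasts;
* ``track`` — EM source tracking of every child in every niche;
* ``tr`` — member contributions, transmission ratios at the configured rank,
  transmissible-taxon classification;
* ``assoc`` — immune Spearman screen + transmissible overlap, diet screens,
  picky-eater test, family-time similarity.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from famtrack import __version__
from famtrack.core_data import (
    ADULT_ROLES,
    CohortMetadata,
    FamtrackError,
    FeatureTable,
    TaxonomyMap,
    ValidationError,
    merge_individual,
    rarefy,
    read_cohort,
    table_by_subject,
)
from famtrack.source_tracking import (
    UNKNOWN,
    CohortTracking,
    EMConfig,
    TrackedChild,
    track_cohort,
)
from famtrack.synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort
from famtrack.transmission import (
    classify_transmissible,
    member_contributions,
    transmission_ratio,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "stats", "track", "tr", "assoc")


@dataclass
class PipelineConfig:
    """Run configuration; see the YAML keys of the same names."""

    outdir: str | Path = "famtrack_out"
    seed: int = 0
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    counts_paths: dict | None = None  # niche -> TSV path (when simulate=False)
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    rarefaction_depth: int = 7115
    rarefy_before_tracking: bool = True
    em: dict = field(default_factory=dict)  # EMConfig overrides
    tr_rank: str = "family"
    tr_epsilon: float = 0.05
    r_min: float = 0.3
    p_max: float = 0.05
    strong: float = 0.5
    n_perm: int = 999
    pairwise_n_perm: int = 199
    run_pairwise_anosim: bool = True
    beta_metric: str = "unweighted_unifrac"  # per-niche beta diversity metric

    _BETA_METRICS = ("unweighted_unifrac", "bray_curtis")

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("r_min", 0, 1),
            ("p_max", 0, 1),
            ("strong", 0, 1),
            ("tr_epsilon", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"{name} must lie in [{lo}, {hi}], got {v}")
        if self.beta_metric not in self._BETA_METRICS:
            raise ValidationError(
                f"beta_metric must be one of {self._BETA_METRICS}, got {self.beta_metric!r}"
            )
        if not self.simulate:
            missing = [
                k
                for k in ("counts_paths", "taxonomy_path", "metadata_path")
                if getattr(self, k) in (None, {})
            ]
            if missing:
                raise ValidationError(f"simulate=False requires: {missing}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


class Pipeline:
    """Stage runner holding the in-memory state between chained stages."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.report: dict = {
            "version": __version__,
            "seed": config.seed,
            "stages": {},
            "warnings": [],
        }
        # in-memory state
        self.tables: dict[str, FeatureTable] | None = None
        self.taxonomy: TaxonomyMap | None = None
        self.metadata: CohortMetadata | None = None
        self.tree: str | None = None
        self.rarefied: dict[str, FeatureTable] | None = None
        self.merged: FeatureTable | None = None
        self.tracking: CohortTracking | None = None

    # -- helpers ---------------------------------------------------------------

    def _stamp(self) -> str:
        return f"famtrack {__version__} seed={self.cfg.seed}"

    def _dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _write_frame(self, frame: pd.DataFrame, path: Path, index: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self._stamp()}\n")
            frame.to_csv(fh, index=index, float_format="%.10g",
                         sep="\t" if path.suffix == ".tsv" else ",",
                         lineterminator="\n")

    def _write_json(self, payload: dict, path: Path) -> None:
        payload = {"provenance": self._stamp(), **payload}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))

    def _timed(self, stage: str, fn) -> None:
        t0 = time.time()
        fn()
        self.report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    def _seed_for(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(
            np.random.SeedSequence([self.cfg.seed % 2**31, idx]).generate_state(1)[0] % 2**31
        )

    # -- data access with re-entry ----------------------------------------------

    def _ensure_inputs(self) -> None:
        if self.tables is not None:
            return
        sim = self.outdir / "simulate"
        if self.cfg.simulate and not (sim / "metadata.tsv").exists():
            self.stage_simulate()
            return
        if self.cfg.simulate:
            counts = {
                p.stem.replace("counts_", ""): p for p in sorted(sim.glob("counts_*.tsv"))
            }
            tax, meta = sim / "taxonomy.tsv", sim / "metadata.tsv"
            tree_path = sim / "tree.nwk"
        else:
            counts = dict(self.cfg.counts_paths or {})
            tax, meta = self.cfg.taxonomy_path, self.cfg.metadata_path
            tree_path = self.cfg.tree_path
        self.tables, self.taxonomy, self.metadata = read_cohort(counts, tax, meta)
        self.tree = Path(tree_path).read_text().strip() if tree_path and Path(tree_path).exists() else None

    def _ensure_prepared(self) -> None:
        if self.rarefied is not None:
            return
        prep = self.outdir / "prepared"
        if not (prep / "merged_individual.tsv").exists():
            self.stage_prepare()
            return
        self._ensure_inputs()
        self.rarefied = {
            p.stem.replace("rarefied_", ""): FeatureTable.read_tsv(p)
            for p in sorted(prep.glob("rarefied_*.tsv"))
        }
        self.merged = FeatureTable.read_tsv(prep / "merged_individual.tsv")

    def _ensure_tracking(self) -> None:
        if self.tracking is not None:
            return
        track_dir = self.outdir / "track"
        if not (track_dir / "attribution.tsv").exists():
            self.stage_track()
            return
        self._ensure_prepared()
        self.tracking = self._load_tracking(track_dir)

    # -- stages -------------------------------------------------------------------

    def stage_simulate(self) -> None:
        def run() -> None:
            if not self.cfg.simulate:
                logger.info("simulate=False; loading provided inputs instead")
                self._ensure_inputs()
                return
            cohort_kwargs = dict(self.cfg.cohort)
            cohort_kwargs.setdefault("seed", self._seed_for("simulate"))
            cohort = generate_cohort(CohortConfig(**cohort_kwargs))
            cohort.write(self._dir("simulate"), header_comment=self._stamp())
            self.tables = cohort.tables
            self.taxonomy = cohort.taxonomy
            self.metadata = cohort.metadata
            self.tree = cohort.tree

        self._timed("simulate", run)

    def stage_prepare(self) -> None:
        def run() -> None:
            self._ensure_inputs()
            out = self._dir("prepared")
            seed = self._seed_for("prepare")
            rarefied, dropped = {}, {}
            for i, (niche, table) in enumerate(sorted(self.tables.items())):
                res = rarefy(table, self.cfg.rarefaction_depth, seed=seed + i)
                rarefied[niche] = res.table
                dropped[niche] = res.dropped
                res.table.to_tsv(out / f"rarefied_{niche}.tsv", self._stamp())
            self.rarefied = rarefied
            by_subject = {
                n: table_by_subject(t, self.metadata) for n, t in rarefied.items()
            }
            self.merged = merge_individual(by_subject)
            self.merged.to_tsv(out / "merged_individual.tsv", self._stamp())
            self._write_json(
                {"depth": self.cfg.rarefaction_depth, "dropped": dropped},
                out / "rarefaction_report.json",
            )

        self._timed("prepare", run)

    def stage_stats(self) -> None:
        from famtrack.community_stats import (
            anosim,
            beta_distance,
            family_pairs,
            kruskal_wallis_screen,
            pairwise_anosim,
            pcoa,
            rank_sum_compare,
            shannon,
        )

        def run() -> None:
            self._ensure_prepared()
            out = self._dir("stats")
            seed = self._seed_for("stats")
            md = self.metadata

            # alpha diversity
            rows = []
            for niche, table in sorted(self.rarefied.items()):
                for sid in table.sample_ids:
                    rows.append(
                        {
                            "sample_id": sid,
                            "niche": niche,
                            "role": md.samples.at[sid, "role"],
                            "shannon": shannon(table.data.loc[sid].to_numpy()),
                        }
                    )
            self._write_frame(pd.DataFrame(rows), out / "shannon.tsv")

            # distances, PCoA, household ANOSIM per niche
            anosim_rows, pcoa_frames, pair_frames = [], [], []
            couple_rows = []
            if self.cfg.beta_metric == "unweighted_unifrac" and self.tree is None:
                raise ValidationError(
                    "beta_metric is unweighted_unifrac but no tree is available; "
                    "provide tree_path (Newick over all ASVs) or set "
                    "beta_metric: bray_curtis"
                )
            for i, (niche, table) in enumerate(sorted(self.rarefied.items())):
                dm_bc = beta_distance(table, "bray_curtis")
                if self.cfg.beta_metric == "unweighted_unifrac":
                    dm_main = beta_distance(table, "unweighted_unifrac", tree=self.tree)
                else:
                    dm_main = dm_bc
                frame = pd.DataFrame(
                    dm_main.data, index=list(dm_main.ids), columns=list(dm_main.ids)
                )
                frame.index.name = "sample_id"
                self._write_frame(frame, out / f"distance_{niche}.tsv", index=True)
                res = pcoa(dm_main, k=2)
                coords = res.coordinates.copy()
                coords["explained_1"] = res.explained[0]
                coords["explained_2"] = res.explained[1]
                coords.index.name = "sample_id"
                self._write_frame(coords.reset_index().assign(niche=niche), out / f"pcoa_{niche}.tsv")

                hh = md.samples.loc[list(table.sample_ids), "household"]
                big = hh.value_counts()
                keep = hh.index[hh.isin(big[big >= 2].index)]
                sub = dm_bc.filter(list(keep))
                r, p = anosim(sub, hh.loc[list(keep)], n_perm=self.cfg.n_perm, seed=seed + i)
                anosim_rows.append({"level": niche, "R": r, "p": p, "n_samples": len(keep)})
                if self.cfg.run_pairwise_anosim:
                    pw = pairwise_anosim(
                        sub, hh.loc[list(keep)], n_perm=self.cfg.pairwise_n_perm,
                        seed=seed + 100 + i,
                    )
                    pair_frames.append(pw.assign(niche=niche))

                # couple / sibling contrasts on the main (UniFrac) distances
                for kind in ("couple", "sibling"):
                    within, between, counts = family_pairs(dm_main, md, kind)
                    if len(within) and len(between):
                        stat, pv = rank_sum_compare(within, between, "less")
                        couple_rows.append(
                            {
                                "niche": niche,
                                "kind": kind,
                                "n_pairs": counts["within"],
                                "n_complement": counts["complement"],
                                "statistic": stat,
                                "p": pv,
                            }
                        )

            # individual level: merged niches, Bray-Curtis ANOSIM + KW screen
            hh = md.subjects.loc[list(self.merged.sample_ids), "household"]
            big = hh.value_counts()
            keep = hh.index[hh.isin(big[big >= 2].index)]
            dm_ind = beta_distance(self.merged.filter_samples(list(keep)), "bray_curtis")
            r, p = anosim(dm_ind, hh.loc[list(keep)], n_perm=self.cfg.n_perm, seed=seed + 50)
            anosim_rows.append({"level": "individual", "R": r, "p": p, "n_samples": len(keep)})
            self._write_frame(pd.DataFrame(anosim_rows), out / "anosim.tsv")
            if pair_frames:
                self._write_frame(pd.concat(pair_frames, ignore_index=True),
                                  out / "pairwise_anosim.tsv")
            self._write_frame(pd.DataFrame(couple_rows), out / "couple_sibling.tsv")

            rel = self.merged.filter_samples(list(keep)).relative_abundance()
            kw, skipped = kruskal_wallis_screen(rel, hh.loc[list(keep)])
            self._write_frame(kw, out / "kw_differential.tsv")
            self._write_json(
                {
                    "n_differential": int(kw["significant"].sum()),
                    "n_tested": int(len(kw)),
                    "n_skipped_constant": len(skipped),
                },
                out / "kw_summary.json",
            )

        self._timed("stats", run)

    def stage_track(self) -> None:
        def run() -> None:
            self._ensure_prepared()
            out = self._dir("track")
            tables = self.rarefied if self.cfg.rarefy_before_tracking else self.tables
            em_kwargs = dict(self.cfg.em)
            em_kwargs.setdefault("seed", self._seed_for("track"))
            self.tracking = track_cohort(tables, self.metadata, EMConfig(**em_kwargs))
            for child, niche, reason in self.tracking.skipped:
                self.report["warnings"].append(f"track: {child}/{niche} skipped ({reason})")
            alpha = self.tracking.alpha_frame()
            self._write_frame(alpha, out / "alpha.csv")
            summary = pd.DataFrame(
                [
                    {
                        "child": rec.child,
                        "niche": rec.niche,
                        "household": rec.household,
                        "n_sources": len(rec.source_roles),
                        "loglik": rec.estimate.loglik,
                        "objective": rec.estimate.objective,
                        "n_iter": rec.estimate.n_iter,
                        "restart": rec.estimate.restart,
                        "converged": rec.estimate.converged,
                    }
                    for rec in self.tracking.results
                ]
            )
            self._write_frame(summary, out / "fit_summary.csv")
            rows = []
            for rec in self.tracking.results:
                labels = rec.source_roles + (UNKNOWN,)
                a = rec.estimate.attribution
                nz = np.nonzero(a.sum(axis=0) > 0)[0]
                for j in nz:
                    for i, lab in enumerate(labels):
                        if a[i, j] > 1e-9:
                            rows.append(
                                (rec.child, rec.niche, rec.asv_ids[j], lab, a[i, j])
                            )
            attr = pd.DataFrame(
                rows, columns=["child", "niche", "asv", "source_role", "attributed_count"]
            )
            self._write_frame(attr, out / "attribution.tsv")

        self._timed("track", run)

    def _load_tracking(self, track_dir: Path) -> CohortTracking:
        """Rebuild tracking records from persisted alpha + attribution tables."""
        from famtrack.source_tracking import MixtureEstimate

        attr = pd.read_csv(track_dir / "attribution.tsv", sep="\t", comment="#")
        alpha = pd.read_csv(track_dir / "alpha.csv", comment="#")
        tables = self.rarefied if self.cfg.rarefy_before_tracking else self.tables
        results = []
        for (child, niche), sub in attr.groupby(["child", "niche"], sort=True):
            table = tables[niche]
            asv_ids = table.asv_ids
            a_sub = alpha[(alpha["child"] == child) & (alpha["niche"] == niche)]
            roles = tuple(r for r in a_sub["source"] if r != UNKNOWN)
            labels = roles + (UNKNOWN,)
            sample = self.metadata.samples_in_niche(niche)
            sample = sample[sample["subject_id"] == child].index[0]
            sink = table.data.loc[sample].to_numpy()
            att = np.zeros((len(labels), len(asv_ids)))
            col = {a: j for j, a in enumerate(asv_ids)}
            rowi = {lab: i for i, lab in enumerate(labels)}
            for _, r in sub.iterrows():
                att[rowi[r["source_role"]], col[r["asv"]]] = r["attributed_count"]
            avec = np.array(
                [float(a_sub[a_sub["source"] == lab]["proportion"].iloc[0]) for lab in labels]
            )
            est = MixtureEstimate(
                source_ids=labels,
                alpha=avec,
                gamma=np.full((len(labels), len(asv_ids)), np.nan),
                attribution=att,
                loglik=float("nan"),
                objective=float("nan"),
                objective_trace=np.array([]),
                n_iter=0,
                restart=0,
                converged=True,
            )
            results.append(
                TrackedChild(
                    child=child,
                    household=str(self.metadata.subjects.at[child, "household"]),
                    niche=niche,
                    asv_ids=asv_ids,
                    sink=sink,
                    source_roles=roles,
                    estimate=est,
                )
            )
        return CohortTracking(results=results)

    def stage_tr(self) -> None:
        def run() -> None:
            self._ensure_tracking()
            out = self._dir("tr")
            contrib = member_contributions(self.tracking)
            self._write_frame(contrib.role_means, out / "contributions.csv")
            self._write_frame(contrib.transmitted, out / "transmitted.csv")
            self._write_frame(
                contrib.transmitted_means.rename("mean_transmitted").reset_index(),
                out / "transmitted_means.csv",
            )
            tr = transmission_ratio(self.tracking, self.taxonomy, self.cfg.tr_rank)
            self._write_frame(tr.per_household, out / "tr_per_household.csv")
            self._write_frame(tr.cohort, out / "tr_cohort.csv")
            sets = classify_transmissible(tr, epsilon=self.cfg.tr_epsilon)
            self._write_json(
                {
                    "rank": self.cfg.tr_rank,
                    "epsilon": sets.epsilon,
                    "per_niche": {k: sorted(v) for k, v in sets.per_niche.items()},
                    "common": sorted(sets.common),
                    "detected_common": sorted(sets.detected_common),
                },
                out / "transmissible_sets.json",
            )

        self._timed("tr", run)

    def stage_assoc(self) -> None:
        from famtrack.association import (
            child_member_similarity,
            diet_effect_screen,
            familytime_similarity,
            picky_transmission_test,
            spearman_screen,
            transmissible_overlap,
        )

        def run() -> None:
            self._ensure_tracking()
            out = self._dir("assoc")
            md = self.metadata
            tables = self.rarefied if self.cfg.rarefy_before_tracking else self.tables

            # immune edges on children's gut relative abundance
            if "gut" in tables:
                gut = tables["gut"]
                kids = md.samples_in_niche("gut")
                kids = kids[(kids["role"] == "C") & kids.index.isin(gut.sample_ids)]
                rel = gut.relative_abundance().loc[kids.index]
                rel.index = pd.Index(kids["subject_id"], name="subject_id")
                imm = md.immune_frame(list(kids["subject_id"]))
                edges = spearman_screen(
                    rel, imm, r_min=self.cfg.r_min, p_max=self.cfg.p_max,
                    strong=self.cfg.strong,
                )
                self._write_frame(edges, out / "immune_edges.csv")
                gephi = edges.rename(
                    columns={"feature_id": "source", "index_name": "target", "rho": "weight"}
                )[["source", "target", "weight", "sign"]]
                self._write_frame(gephi, out / "immune_edges_gephi.tsv")

                sets_path = self.outdir / "tr" / "transmissible_sets.json"
                if sets_path.exists() and not edges.empty:
                    sets = json.loads(sets_path.read_text())
                    fams = set(sets["per_niche"].get("gut", []))
                    trans_asvs = [
                        a
                        for a in gut.asv_ids
                        if self.taxonomy.rank_value(a, self.cfg.tr_rank) in fams
                    ]
                    if trans_asvs:
                        ov = transmissible_overlap(edges, trans_asvs, self.taxonomy)
                        self._write_json(
                            {
                                "n_edge_features": ov.n_edge_features,
                                "n_overlap": ov.n_overlap,
                                "fraction": ov.fraction,
                                "by_class": ov.by_class.to_dict("records")
                                if ov.by_class is not None
                                else None,
                            },
                            out / "transmissible_overlap.json",
                        )

            # diet screen per niche on children
            diet_frames = []
            for niche, table in sorted(tables.items()):
                kids = md.samples_in_niche(niche)
                kids = kids[(kids["role"] == "C") & kids.index.isin(table.sample_ids)]
                if len(kids) < 4:
                    continue
                rel = table.relative_abundance().loc[kids.index]
                rel.index = pd.Index(kids["subject_id"], name="subject_id")
                diet = md.diet_frame(list(kids["subject_id"]))
                res, skipped = diet_effect_screen(
                    rel, diet, p_max=self.cfg.p_max,
                    antibiotics=md.subjects["antibiotics"]
                    if "antibiotics" in md.subjects.columns
                    else None,
                )
                diet_frames.append(res.assign(niche=niche))
                for food in skipped:
                    self.report["warnings"].append(
                        f"assoc: food {food!r} single-group in {niche}; skipped"
                    )
            if diet_frames:
                self._write_frame(pd.concat(diet_frames, ignore_index=True),
                                  out / "diet_effects.csv")

            # picky-eater test on family-derived proportions
            contrib = member_contributions(self.tracking)
            children = sorted(set(contrib.transmitted["child"]))
            picky = picky_transmission_test(contrib, md.diet_frame(children))
            self._write_frame(picky, out / "picky_ttest.csv")

            # family time vs similarity
            pairs = child_member_similarity(tables, md)
            ft = familytime_similarity(pairs)
            self._write_frame(ft.pairs, out / "familytime_pairs.csv")
            self._write_frame(ft.correlations, out / "familytime_correlations.csv")
            self._write_frame(ft.role_comparison, out / "familytime_roles.csv")

        self._timed("assoc", run)

    # -- entry point ---------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        for stage in stages:
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r}")
            getattr(self, f"stage_{stage}")()
        self._write_json({"config": {**asdict(self.cfg), "outdir": str(self.cfg.outdir)},
                          **self.report}, self.outdir / "run_report.json")
        return self.report


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the run report."""
    return Pipeline(config).run(stages)
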