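"""EM estimation of a sink community as a convex mixture of source communities.

Model
-----
A child ("sink") count vector ``x`` over J ASVs with total N is modelled as a
multinomial draw from ``p = sum_{i=1}^{K} alpha_i gamma_i + alpha_{K+1}
gamma_{K+1}``, where ``gamma_1..gamma_K`` are the (latent) communities of the
K known sources — the family members, each observed through its own count
vector ``y_i`` — and ``gamma_{K+1}`` is an unobserved "unknown" source that
absorbs whatever the known sources cannot explain. The mixing proportions
``alpha`` live on the simplex.

Estimation is expectation-maximization on the complete-data multinomial
likelihood with Dirichlet (pseudocount) smoothing of the source communities:

* E-step:  ``z_ij = alpha_i gamma_ij / sum_i' alpha_i' gamma_i'j``
* M-step:  ``alpha_i = sum_j x_j z_ij / N``;
  known sources  ``gamma_ij ∝ y_ij + pseudocount + x_j z_ij`` (joint
  refinement of the source communities by the reattributed sink counts);
  unknown source ``gamma_{K+1,j} ∝ u_j + x_j z_{K+1,j} + pseudocount·1[x_j > 0]``.

The unknown source must be constrained: left fully free, its J-1 parameters
overfit the sink's multinomial sampling noise and systematically inflate the
unknown proportion. It is therefore anchored by a residual
pseudo-observation ``u_j``: a preliminary known-sources-only mixture fit
yields fitted proportions ``m_j``, and ``u_j = N·max(x_j/N − m_j −
sqrt(m_j/N), 0)`` — the sink mass the known sources cannot explain, after
subtracting one standard error of sampling noise. ``u`` enters the M-step
and the objective exactly like an observed source count vector, making the
unknown as rigid as the known sources while still adapting by reattribution.

The maximized objective is the observed-data log posterior: the sink
multinomial log-likelihood plus the smoothed source multinomial terms
(anchor included); it is non-decreasing every iteration. Multiple restarts
with randomised mixing-proportion initialisations guard against local
optima; the best final objective wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from famtrack.core_data import (
    ADULT_ROLES,
    CohortMetadata,
    FamtrackError,
    FeatureTable,
    ValidationError,
)

__all__ = [
    "SourceSinkProblem",
    "EMConfig",
    "MixtureEstimate",
    "fit_mixture",
    "mixture_loglik",
    "attribute_sink_counts",
    "track_cohort",
    "CohortTracking",
]

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"
_GAMMA_FLOOR = 1e-12


@dataclass
class SourceSinkProblem:
    """A sink count vector plus the aligned known-source count matrix."""

    sink: np.ndarray  # (J,)
    sources: np.ndarray  # (K, J)
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.sink = np.asarray(self.sink, dtype=np.int64)
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=np.int64))
        if self.sink.ndim != 1:
            raise ValidationError("sink must be a vector")
        if self.sources.shape[1] != self.sink.shape[0]:
            raise ValidationError("sink and sources must share the same ASV axis")
        if (self.sink < 0).any() or (self.sources < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.sources.shape[0] < 1:
            raise ValidationError("need at least one known source")
        if not self.source_ids:
            self.source_ids = tuple(f"source_{i + 1}" for i in range(self.sources.shape[0]))
        if len(self.source_ids) != self.sources.shape[0]:
            raise ValidationError("source_ids must match the number of sources")

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    @property
    def total(self) -> int:
        return int(self.sink.sum())


@dataclass
class EMConfig:
    max_iter: int = 1000
    tol: float = 1e-6  # relative change of the EM objective
    restarts: int = 10
    pseudocount: float = 1.0  # Dirichlet smoothing of known sources
    seed: int = 0
    refine_sources: bool = True  # False: plug-in (fixed) known sources

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class MixtureEstimate:
    """Fitted mixture: proportions, source communities, per-ASV attribution."""

    source_ids: tuple[str, ...]  # K known labels + "Unknown"
    alpha: np.ndarray  # (K+1,)
    gamma: np.ndarray  # (K+1, J)
    attribution: np.ndarray  # (K+1, J): expected sink counts per source
    loglik: float  # sink multinomial log-likelihood (constant omitted)
    objective: float  # EM objective (sink + smoothed source terms)
    objective_trace: np.ndarray  # per-iteration objective of the winning restart
    n_iter: int
    restart: int
    converged: bool

    def alpha_by_source(self) -> dict[str, float]:
        return {sid: float(a) for sid, a in zip(self.source_ids, self.alpha)}

    @property
    def unknown_fraction(self) -> float:
        return float(self.alpha[-1])


def mixture_loglik(problem: SourceSinkProblem, alpha: np.ndarray, gamma: np.ndarray) -> float:
    """Multinomial log-likelihood of the sink under ``sum_i alpha_i gamma_i``.

    The multinomial coefficient (constant in the parameters) is omitted.
    Returns ``-inf`` if any taxon with positive sink count has zero mixture
    probability, and logs a warning.
    """
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    x = problem.sink
    p = alpha @ gamma
    pos = x > 0
    if np.any(p[pos] <= 0):
        logger.warning("zero mixture probability at a taxon with positive sink count")
        return float("-inf")
    return float(np.sum(x[pos] * np.log(p[pos])))


def attribute_sink_counts(sink: np.ndarray, alpha: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Expected sink counts per source: ``a_ij = x_j z_ij`` at the E-step.

    Columns are guaranteed to sum exactly to the sink counts: the unknown row
    absorbs the floating-point remainder.
    """
    x = np.asarray(sink, dtype=float)
    num = np.asarray(alpha, dtype=float)[:, None] * np.asarray(gamma, dtype=float)
    denom = num.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    # taxa where the mixture is zero but x > 0 cannot occur after smoothing;
    # attribute them to the unknown source defensively
    dead = (denom <= 0) & (x > 0)
    if dead.any():
        z[:, dead] = 0.0
        z[-1, dead] = 1.0
    a = x[None, :] * z
    a[-1] = x - a[:-1].sum(axis=0)
    np.clip(a[-1], 0.0, None, out=a[-1])
    return a


def _objective(x, alpha, gamma, source_counts, prior) -> float:
    """Observed-data log posterior maximized by the EM iterations."""
    p = alpha @ gamma
    pos = x > 0
    sink_term = np.sum(x[pos] * np.log(np.maximum(p[pos], _GAMMA_FLOOR)))
    w = source_counts + prior
    mask = w > 0
    src_term = np.sum(w[mask] * np.log(np.maximum(gamma[mask], _GAMMA_FLOOR)))
    return float(sink_term + src_term)


def fit_mixture(problem: SourceSinkProblem, config: EMConfig | None = None) -> MixtureEstimate:
    """Fit the convex-mixture model by EM with restarts.

    The best restart by final objective wins; ties go to the lowest restart
    index. Known sources with zero total counts are smoothed to uniform and a
    warning is logged.
    """
    cfg = config or EMConfig()
    x = problem.sink.astype(float)
    N = x.sum()
    if N < 1:
        raise ValidationError("sink has no counts")
    y = problem.sources.astype(float)
    K, J = y.shape

    zero_sources = np.where(y.sum(axis=1) == 0)[0]
    if zero_sources.size:
        logger.warning(
            "sources with zero total counts smoothed to uniform: %s",
            [problem.source_ids[i] for i in zero_sources],
        )

    support = x > 0
    # Dirichlet prior counts entering the M-step and the EM objective
    prior = np.empty((K + 1, J))
    prior[:K] = cfg.pseudocount
    prior[K] = cfg.pseudocount * support

    gamma_known0 = (y + cfg.pseudocount)
    gamma_known0 /= gamma_known0.sum(axis=1, keepdims=True)

    # stage 1: known-sources-only mixture fit -> residual anchor for the unknown
    a1 = np.full(K, 1.0 / K)
    for _ in range(200):
        num = a1[:, None] * gamma_known0
        denom = num.sum(axis=0)
        denom[denom == 0] = 1.0
        a_new = (x[None, :] * num / denom).sum(axis=1) / N
        a_new /= a_new.sum()
        if np.abs(a_new - a1).sum() < 1e-8:
            a1 = a_new
            break
        a1 = a_new
    fitted = a1 @ gamma_known0
    resid_raw = np.maximum(x / N - fitted - np.sqrt(fitted / N), 0.0)
    anchor = N * resid_raw
    source_counts = np.vstack([y, anchor])

    residual = resid_raw + 1e-6  # uniform floor keeps every taxon reachable
    residual /= residual.sum()

    best: dict | None = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % 2**31, r]))
        gamma = np.vstack([gamma_known0, residual])
        if r == 0:
            alpha = np.full(K + 1, 1.0 / (K + 1))
        else:
            alpha = rng.dirichlet(np.ones(K + 1))
            perturb = rng.dirichlet(np.ones(J))
            g_unknown = 0.8 * residual + 0.2 * perturb
            gamma = np.vstack([gamma_known0, g_unknown / g_unknown.sum()])

        trace = []
        obj = _objective(x, alpha, gamma, source_counts, prior)
        trace.append(obj)
        converged = False
        for it in range(cfg.max_iter):
            # E-step
            num = alpha[:, None] * gamma
            denom = num.sum(axis=0)
            safe = np.where(denom > 0, denom, 1.0)
            z = num / safe
            # M-step
            xz = x[None, :] * z
            alpha = xz.sum(axis=1) / N
            alpha = np.maximum(alpha, 0.0)
            alpha /= alpha.sum()
            if cfg.refine_sources:
                gamma_new = source_counts + prior + xz
            else:
                gamma_new = np.vstack(
                    [source_counts[:K] + prior[:K], (source_counts[K] + prior[K] + xz[K])[None, :]]
                )
            row_tot = gamma_new.sum(axis=1, keepdims=True)
            row_tot[row_tot == 0] = 1.0
            gamma = gamma_new / row_tot
            new_obj = _objective(x, alpha, gamma, source_counts, prior)
            trace.append(new_obj)
            if abs(new_obj - obj) <= cfg.tol * (abs(obj) + 1e-12):
                obj = new_obj
                converged = True
                break
            obj = new_obj
        if not converged:
            logger.warning("EM restart %d did not converge in %d iterations", r, cfg.max_iter)
        if best is None or obj > best["objective"]:
            best = {
                "alpha": alpha,
                "gamma": gamma,
                "objective": obj,
                "trace": np.asarray(trace),
                "n_iter": len(trace) - 1,
                "restart": r,
                "converged": converged,
            }

    assert best is not None
    attribution = attribute_sink_counts(problem.sink, best["alpha"], best["gamma"])
    loglik = mixture_loglik(problem, best["alpha"], best["gamma"])
    return MixtureEstimate(
        source_ids=tuple(problem.source_ids) + (UNKNOWN,),
        alpha=best["alpha"],
        gamma=best["gamma"],
        attribution=attribution,
        loglik=loglik,
        objective=best["objective"],
        objective_trace=best["trace"],
        n_iter=best["n_iter"],
        restart=best["restart"],
        converged=best["converged"],
    )


# ---------------------------------------------------------------------------
# Cohort-level tracking
# ---------------------------------------------------------------------------


@dataclass
class TrackedChild:
    """One child x niche source-tracking result."""

    child: str  # subject id
    household: str
    niche: str
    asv_ids: list[str]
    sink: np.ndarray
    source_roles: tuple[str, ...]  # roles aligned with the estimate's known sources
    estimate: MixtureEstimate

    def alpha_by_role(self) -> dict[str, float]:
        labels = self.source_roles + (UNKNOWN,)
        return {lab: float(a) for lab, a in zip(labels, self.estimate.alpha)}


@dataclass
class CohortTracking:
    """All per-(child, niche) mixture estimates of a cohort run."""

    results: list[TrackedChild]
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # (child, niche, reason)

    def get(self, child: str, niche: str) -> TrackedChild | None:
        for rec in self.results:
            if rec.child == child and rec.niche == niche:
                return rec
        return None

    def alpha_frame(self):
        import pandas as pd

        rows = []
        for rec in self.results:
            for role, a in rec.alpha_by_role().items():
                rows.append(
                    {
                        "child": rec.child,
                        "household": rec.household,
                        "niche": rec.niche,
                        "source": role,
                        "proportion": a,
                    }
                )
        return pd.DataFrame(rows)


def track_cohort(
    tables: Mapping[str, FeatureTable],
    metadata: CohortMetadata,
    config: EMConfig | None = None,
    source_roles: Sequence[str] = ADULT_ROLES,
) -> CohortTracking:
    """Fit the mixture for every child in every niche.

    Sources for a child are the same-household, same-niche samples of the
    non-child roles in ``source_roles``; absent roles are simply omitted, so
    the number of known sources varies by household. Children with no member
    sample in a niche are skipped with a logged warning.
    """
    cfg = config or EMConfig()
    results: list[TrackedChild] = []
    skipped: list[tuple[str, str, str]] = []
    child_subjects = list(metadata.children().index)

    for ni, (niche, table) in enumerate(sorted(tables.items())):
        samples = metadata.samples_in_niche(niche)
        samples = samples[samples.index.isin(table.sample_ids)]
        by_subject = {str(row["subject_id"]): sid for sid, row in samples.iterrows()}
        for ci, child in enumerate(child_subjects):
            child_sample = by_subject.get(child)
            if child_sample is None:
                skipped.append((child, niche, "no child sample"))
                continue
            household = str(metadata.subjects.at[child, "household"])
            member_samples = samples[
                (samples["household"] == household)
                & (samples["role"].isin(list(source_roles)))
            ]
            if member_samples.empty:
                logger.warning("child %s has no member samples in %s; skipped", child, niche)
                skipped.append((child, niche, "no member samples"))
                continue
            roles = tuple(member_samples["role"])
            sink = table.data.loc[child_sample].to_numpy()
            if sink.sum() == 0:
                skipped.append((child, niche, "empty sink"))
                continue
            sources = table.data.loc[member_samples.index].to_numpy()
            problem = SourceSinkProblem(sink=sink, sources=sources, source_ids=roles)
            fit_seed = int(
                np.random.SeedSequence([int(cfg.seed) % 2**31, ni, ci]).generate_state(1)[0]
                % 2**31
            )
            fit_cfg = EMConfig(
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                restarts=cfg.restarts,
                pseudocount=cfg.pseudocount,
                seed=fit_seed,
                refine_sources=cfg.refine_sources,
            )
            est = fit_mixture(problem, fit_cfg)
            results.append(
                TrackedChild(
                    child=child,
                    household=household,
                    niche=niche,
                    asv_ids=table.asv_ids,
                    sink=sink,
                    source_roles=roles,
                    estimate=est,
                )
            )
    return CohortTracking(results=results, skipped=skipped)
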