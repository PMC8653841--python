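"""Data model and I/O for ASV feature tables, taxonomy, and cohort metadata.

The in-memory containers are thin, validated wrappers around pandas objects:

* :class:`FeatureTable` — samples x ASVs integer count matrix.
* :class:`TaxonomyMap` — ASV id -> seven-rank lineage (domain..species),
  missing ranks explicitly marked ``unassigned``.
* :class:`CohortMetadata` — per-sample household/role/niche assignment plus
  per-subject covariates (age, sex, diet flags, family time, immune indices).

Operations implemented here are the table-level primitives the rest of the
pipeline builds on: rarefaction, relative-abundance conversion, taxonomic
collapsing, and cross-niche merging at the individual level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "ROLES",
    "NICHES",
    "UNASSIGNED",
    "IMMUNE_INDICES",
    "FamtrackError",
    "ParseError",
    "ValidationError",
    "EmptyTableError",
    "FeatureTable",
    "TaxonomyMap",
    "CohortMetadata",
    "RarefactionResult",
    "read_cohort",
    "rarefy",
    "collapse_to_rank",
    "merge_individual",
    "table_by_subject",
]

#: The seven standard taxonomic ranks, most to least inclusive.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Household member roles: child, mother, father, paternal/maternal grandparents.
ROLES = ("C", "M", "F", "PGM", "PGF", "MGM", "MGF")

#: Roles usable as transmission sources (all non-child members).
ADULT_ROLES = ("M", "F", "PGM", "PGF", "MGM", "MGF")

#: Body niches sampled in the cohort design.
NICHES = ("gut", "oral", "skin")

UNASSIGNED = "unassigned"

#: Immune index short names; CD19/CD56 stand for the CD3-/CD19+ and
#: CD3-/CD56+ lymphocyte fractions.
IMMUNE_INDICES = ("IgA", "IgG", "IgM", "CD3", "CD4", "CD8", "CD19", "CD56")

DIET_FOODS = ("fish", "eggs", "milk", "meat", "vegetables", "fruits", "liquor", "cigarette")


class FamtrackError(Exception):
    """Base class for all famtrack-specific failures."""


class ParseError(FamtrackError, ValueError):
    """A file did not conform to the expected dialect."""


class ValidationError(FamtrackError, ValueError):
    """Inputs are well-formed but mutually inconsistent or out of contract."""


class EmptyTableError(ValidationError):
    """An operation would produce a table with no samples."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


class FeatureTable:
    """Samples x ASVs matrix of non-negative integer counts.

    Parameters
    ----------
    data:
        DataFrame with unique sample ids as the index and unique ASV ids as
        columns. Values must be non-negative integers.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise ValidationError("FeatureTable requires a pandas DataFrame")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            # accept float frames that are integral (e.g. after pandas ops)
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be integers")
            data = data.astype(np.int64)
        if values.size and (data.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self._data = data.astype(np.int64) if data.size else data
        self._data.index = self._data.index.astype(str)
        self._data.columns = self._data.columns.astype(str)

    # -- accessors ----------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self._data.sum(axis=1)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, FeatureTable) and self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover
        n, j = self.shape
        return f"<FeatureTable {n} samples x {j} ASVs>"

    # -- transformations ----------------------------------------------------

    def filter_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self._data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return FeatureTable(self._data.loc[list(sample_ids)])

    def relative_abundance(self) -> pd.DataFrame:
        """Counts converted to per-sample proportions (rows sum to 1)."""
        totals = self._data.sum(axis=1)
        zero = totals[totals == 0].index.tolist()
        if zero:
            raise ValidationError(f"samples with zero total counts: {zero}")
        rel = self._data.div(totals, axis=0)
        return rel

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        header, header_line = "", 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip() and not line.startswith("#"):
                    header, header_line = line, lineno
                    break
        if not header:
            raise ParseError(f"{path}: line 1: empty header")
        first = header.rstrip("\n").split("\t")[0]
        if first != "sample_id":
            raise ParseError(
                f"{path}: line {header_line}: expected first header column "
                f"'sample_id', got {first!r}"
            )
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        try:
            df = df.apply(pd.to_numeric)
        except ValueError:
            # locate the offending line for a useful message
            for i, (_, row) in enumerate(df.iterrows(), start=header_line + 1):
                for v in row:
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise ParseError(f"{path}: line {i}: non-numeric count {v!r}") from None
            raise
        try:
            return cls(df)
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df = self._data.copy()
            df.index.name = "sample_id"
            df.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def read_biom(cls, path: str | Path) -> "FeatureTable":
        """Import a BIOM v2.1 (HDF5) table.

        Only the dense reconstruction of the sparse observation matrix is
        supported; metadata groups are ignored.
        """
        import h5py
        from scipy import sparse

        with h5py.File(path, "r") as fh:
            obs_ids = [x.decode() for x in fh["observation/ids"][:]]
            sample_ids = [x.decode() for x in fh["sample/ids"][:]]
            grp = fh["observation/matrix"]
            mat = sparse.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(obs_ids), len(sample_ids)),
            )
        dense = np.asarray(mat.todense()).T  # samples x observations
        return cls(pd.DataFrame(dense.astype(np.int64), index=sample_ids, columns=obs_ids))


# ---------------------------------------------------------------------------
# TaxonomyMap
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


class TaxonomyMap:
    """ASV id -> ranked lineage with ranks addressable by name.

    Lineages are stored as 7-tuples over :data:`RANKS`; ranks absent from the
    input are filled with ``unassigned``. Input dialect is a semicolon-joined
    lineage string with optional Greengenes/SILVA-style rank prefixes
    (``d__``, ``p__``, ... ``s__``), which are stripped.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        clean: dict[str, tuple[str, ...]] = {}
        for asv, lin in lineages.items():
            lin = tuple(str(x) for x in lin)
            if len(lin) > len(RANKS):
                raise ValidationError(f"{asv}: lineage has {len(lin)} ranks (max {len(RANKS)})")
            lin = tuple(x if x else UNASSIGNED for x in lin)
            lin = lin + (UNASSIGNED,) * (len(RANKS) - len(lin))
            clean[str(asv)] = lin
        self._lineages = clean

    @staticmethod
    def parse_lineage(text: str) -> tuple[str, ...]:
        parts = [p.strip() for p in str(text).split(";")]
        parts = [_PREFIX_RE.sub("", p) for p in parts]
        parts = [p if p else UNASSIGNED for p in parts]
        if len(parts) > len(RANKS):
            raise ParseError(f"lineage has {len(parts)} ranks (max {len(RANKS)}): {text!r}")
        return tuple(parts) + (UNASSIGNED,) * (len(RANKS) - len(parts))

    def __contains__(self, asv: str) -> bool:
        return asv in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    @property
    def asv_ids(self) -> list[str]:
        return list(self._lineages)

    def lineage(self, asv: str) -> tuple[str, ...]:
        return self._lineages[asv]

    def rank_value(self, asv: str, rank: str) -> str:
        """Taxon name of ``asv`` at ``rank`` (``unassigned`` if unknown ASV)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
        lin = self._lineages.get(asv)
        return lin[RANKS.index(rank)] if lin is not None else UNASSIGNED

    def rank_labels(self, asv_ids: Iterable[str], rank: str) -> list[str]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
        idx = RANKS.index(rank)
        return [
            self._lineages[a][idx] if a in self._lineages else UNASSIGNED for a in asv_ids
        ]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyMap":
        path = Path(path)
        lineages: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].lower() in {"asv_id", "feature id", "feature_id"}:
                    continue
                if len(parts) < 2:
                    raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
                try:
                    lineages[parts[0]] = cls.parse_lineage(parts[1])
                except ParseError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
        return cls(lineages)

    def to_tsv(self, path: str | Path) -> None:
        prefixes = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
        with open(path, "w") as fh:
            fh.write("asv_id\tlineage\n")
            for asv, lin in self._lineages.items():
                pieces = [
                    f"{pre}{name}" if name != UNASSIGNED else f"{pre}"
                    for pre, name in zip(prefixes, lin)
                ]
                # trim trailing fully-unassigned ranks for compactness
                while pieces and pieces[-1].endswith("__"):
                    pieces.pop()
                fh.write(f"{asv}\t{'; '.join(pieces)}\n")


# ---------------------------------------------------------------------------
# CohortMetadata
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("subject_id", "household", "role", "niche")


@dataclass
class CohortMetadata:
    """Sample assignment plus subject covariates for a family cohort.

    ``samples`` is indexed by sample id with columns ``subject_id``,
    ``household``, ``role``, ``niche``. ``subjects`` is indexed by subject id
    and carries ``household``, ``role``, ``age``, ``sex``, ``family_time``
    (hours/day with the child; NaN for children), ``antibiotics`` (Y/N),
    ``diet_<food>`` Y/N flags, and ``imm_<index>`` immune measurements.
    """

    samples: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.copy()
        self.subjects = self.subjects.copy()
        self.samples.index = self.samples.index.astype(str)
        self.subjects.index = self.subjects.index.astype(str)
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValidationError(f"sample metadata missing columns: {missing_cols}")
        if self.samples.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        bad_roles = sorted(set(self.samples["role"]) - set(ROLES))
        if bad_roles:
            raise ValidationError(f"unknown roles: {bad_roles}")
        unknown_subjects = sorted(
            set(self.samples["subject_id"]) - set(self.subjects.index)
        )
        if unknown_subjects:
            raise ValidationError(f"samples reference unknown subjects: {unknown_subjects}")
        dup = self.samples.groupby(["subject_id", "niche"]).size()
        dup = dup[dup > 1]
        if len(dup):
            raise ValidationError(
                f"subject sampled more than once in a niche: {dup.index.tolist()}"
            )
        if "family_time" in self.subjects.columns and "role" in self.subjects.columns:
            kids = self.subjects[self.subjects["role"] == "C"]
            if kids["family_time"].notna().any():
                raise ValidationError("family_time must be undefined for children")

    # -- convenience queries -------------------------------------------------

    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def samples_in_niche(self, niche: str) -> pd.DataFrame:
        return self.samples[self.samples["niche"] == niche]

    def children(self) -> pd.DataFrame:
        return self.subjects[self.subjects["role"] == "C"]

    def subject_of(self, sample_id: str) -> str:
        return str(self.samples.at[sample_id, "subject_id"])

    def immune_frame(self, subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
        cols = [f"imm_{i}" for i in IMMUNE_INDICES if f"imm_{i}" in self.subjects.columns]
        frame = self.subjects[cols].rename(columns=lambda c: c[4:])
        if subject_ids is not None:
            frame = frame.loc[list(subject_ids)]
        return frame

    def diet_frame(self, subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
        cols = [c for c in self.subjects.columns if c.startswith("diet_")]
        frame = self.subjects[cols].rename(columns=lambda c: c[5:])
        if subject_ids is not None:
            frame = frame.loc[list(subject_ids)]
        return frame

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per sample (subject covariates repeated)."""
        flat = self.samples.join(
            self.subjects.drop(columns=["household", "role"], errors="ignore"),
            on="subject_id",
        )
        flat.index.name = "sample_id"
        return flat

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def from_frame(cls, flat: pd.DataFrame) -> "CohortMetadata":
        missing = [c for c in SAMPLE_COLUMNS if c not in flat.columns]
        if missing:
            raise ParseError(f"metadata missing columns: {missing}")
        samples = flat[list(SAMPLE_COLUMNS)].copy()
        subject_cols = [c for c in flat.columns if c not in ("niche",)]
        subjects = (
            flat[subject_cols]
            .drop_duplicates(subset="subject_id")
            .set_index("subject_id")
        )
        return cls(samples=samples, subjects=subjects)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortMetadata":
        flat = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype={0: str})
        flat.index = flat.index.astype(str)
        if "subject_id" in flat.columns:
            flat["subject_id"] = flat["subject_id"].astype(str)
        try:
            return cls.from_frame(flat)
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Bundled reading
# ---------------------------------------------------------------------------


def read_cohort(
    counts_path: str | Path | Mapping[str, str | Path],
    taxonomy_path: str | Path,
    metadata_path: str | Path,
):
    """Read and cross-validate a (counts, taxonomy, metadata) bundle.

    ``counts_path`` may be a single table path or a mapping ``niche -> path``;
    the return shape follows the input (single :class:`FeatureTable` or a dict
    of them). Samples present in counts but absent from metadata raise a
    :class:`ValidationError` listing the offenders.
    """
    metadata = CohortMetadata.read_tsv(metadata_path)
    taxonomy = TaxonomyMap.read_tsv(taxonomy_path)

    def _load(path: str | Path) -> FeatureTable:
        table = FeatureTable.read_tsv(path)
        orphans = sorted(set(table.sample_ids) - set(metadata.sample_ids()))
        if orphans:
            raise ValidationError(
                f"{path}: samples missing from metadata: {orphans}"
            )
        return table

    if isinstance(counts_path, Mapping):
        tables = {niche: _load(p) for niche, p in counts_path.items()}
        return tables, taxonomy, metadata
    return _load(counts_path), taxonomy, metadata


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


class RarefactionResult(NamedTuple):
    table: FeatureTable
    dropped: list[str]


def rarefy(table: FeatureTable, depth: int = 7115, seed: int | None = None) -> RarefactionResult:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and reported in the
    result. The default depth follows the upstream 16S workflow this package
    targets (7,115 reads). Identical seed implies identical output.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not keep:
        raise EmptyTableError(f"no sample reaches depth {depth}")
    counts = table.data.loc[keep].to_numpy()
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return RarefactionResult(
        FeatureTable(pd.DataFrame(out, index=keep, columns=table.asv_ids)), dropped
    )


def collapse_to_rank(table: FeatureTable, tax: TaxonomyMap, rank: str = "family") -> FeatureTable:
    """Pool ASV counts by their taxon at ``rank``.

    ASVs unassigned at the rank (or absent from the taxonomy) are pooled into
    one ``unassigned`` group. Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
    labels = tax.rank_labels(table.asv_ids, rank)
    collapsed = table.data.T.groupby(pd.Index(labels, name=rank)).sum().T
    ordered = sorted(c for c in collapsed.columns if c != UNASSIGNED)
    if UNASSIGNED in collapsed.columns:
        ordered.append(UNASSIGNED)
    return FeatureTable(collapsed[ordered])


def table_by_subject(table: FeatureTable, metadata: CohortMetadata) -> FeatureTable:
    """Re-index a per-niche table from sample ids to subject ids."""
    subjects = [metadata.subject_of(s) for s in table.sample_ids]
    if len(set(subjects)) != len(subjects):
        dup = sorted({s for s in subjects if subjects.count(s) > 1})
        raise ValidationError(f"duplicate subject within a niche: {dup}")
    df = table.data.copy()
    df.index = pd.Index(subjects, name="subject_id")
    return FeatureTable(df)


def merge_individual(tables: Mapping[str, FeatureTable]) -> FeatureTable:
    """Combine per-niche subject-indexed tables into one row per subject.

    Columns are niche-tagged ASV ids (``<niche>:<asv_id>``) so identical ASV
    ids in two niches stay distinct; a subject missing a niche contributes
    zeros for that niche's columns. Row totals equal the sum of the subject's
    per-niche totals.
    """
    if not tables:
        raise ValidationError("no tables to merge")
    subjects = sorted({s for t in tables.values() for s in t.sample_ids})
    blocks = []
    for niche, t in tables.items():
        block = t.data.reindex(subjects, fill_value=0)
        block.columns = [f"{niche}:{a}" for a in t.asv_ids]
        blocks.append(block)
    merged = pd.concat(blocks, axis=1)
    merged.index.name = "subject_id"
    return FeatureTable(merged)
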