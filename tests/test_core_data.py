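import numpy as np
import pandas as pd
import pytest

from famtrack.core_data import (
    EmptyTableError,
    FeatureTable,
    ParseError,
    TaxonomyMap,
    ValidationError,
    collapse_to_rank,
    merge_individual,
    rarefy,
    read_cohort,
    table_by_subject,
)


def _write_mini_cohort(tmp_path, drop_sample=None):
    counts = pd.DataFrame(
        np.arange(1, 19).reshape(6, 3),
        index=[f"s{i}" for i in range(1, 7)],
        columns=["a1", "a2", "a3"],
    )
    counts.index.name = "sample_id"
    cpath = tmp_path / "counts.tsv"
    counts.to_csv(cpath, sep="\t")
    (tmp_path / "taxonomy.tsv").write_text(
        "asv_id\tlineage\n"
        "a1\td__Bacteria; p__P1; c__C1; o__O1; f__FamA\n"
        "a2\td__Bacteria; p__P1; c__C1; o__O1; f__FamA; g__G2\n"
        "a3\td__Bacteria; p__P2\n"
    )
    rows = []
    for i in range(1, 7):
        if drop_sample == f"s{i}":
            continue
        role = ["C", "M", "F", "C", "M", "F"][i - 1]
        hh = "H1" if i <= 3 else "H2"
        sid = f"{hh}_{role}"
        rows.append(
            {
                "sample_id": f"s{i}",
                "subject_id": sid,
                "household": hh,
                "role": role,
                "niche": "gut",
                "age": 30,
                "sex": "F",
                "family_time": "" if role == "C" else 8.0,
            }
        )
    pd.DataFrame(rows).set_index("sample_id").to_csv(tmp_path / "metadata.tsv", sep="\t")
    return tmp_path / "counts.tsv", tmp_path / "taxonomy.tsv", tmp_path / "metadata.tsv"


class TestReadCohort:
    def test_round_trip_ids_match(self, tmp_path):
        paths = _write_mini_cohort(tmp_path)
        table, tax, meta = read_cohort(*paths)
        assert table.sample_ids == [f"s{i}" for i in range(1, 7)]
        assert set(table.asv_ids) <= set(tax.asv_ids)
        assert set(table.sample_ids) == set(meta.sample_ids())

    def test_sample_missing_from_metadata_fails(self, tmp_path):
        paths = _write_mini_cohort(tmp_path, drop_sample="s4")
        with pytest.raises(ValidationError, match="s4"):
            read_cohort(*paths)

    def test_short_lineage_padded_unassigned(self, tmp_path):
        paths = _write_mini_cohort(tmp_path)
        _, tax, _ = read_cohort(*paths)
        assert tax.rank_value("a3", "phylum") == "P2"
        assert tax.rank_value("a3", "family") == "unassigned"
        assert tax.rank_value("a1", "species") == "unassigned"

    def test_malformed_counts_name_line(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample_id\ta1\ta2\ns1\t3\toops\n")
        with pytest.raises(ParseError, match="line 2"):
            FeatureTable.read_tsv(bad)

    def test_bad_header_is_parse_error(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("whatever\ta1\ns1\t3\n")
        with pytest.raises(ParseError, match="line 1"):
            FeatureTable.read_tsv(bad)


class TestFeatureTable:
    def test_rejects_negative_and_duplicates(self):
        with pytest.raises(ValidationError):
            FeatureTable(pd.DataFrame([[-1]], index=["s"], columns=["a"]))
        with pytest.raises(ValidationError):
            FeatureTable(pd.DataFrame([[1], [2]], index=["s", "s"], columns=["a"]))

    def test_relative_abundance_rows_sum_to_one(self, tiny_table):
        rel = tiny_table.relative_abundance()
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_biom_round_trip(self, tmp_path, tiny_table):
        import h5py
        from scipy import sparse

        mat = sparse.csr_matrix(tiny_table.counts().T)  # observations x samples
        path = tmp_path / "table.biom"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("observation/ids", data=[a.encode() for a in tiny_table.asv_ids])
            fh.create_dataset("sample/ids", data=[s.encode() for s in tiny_table.sample_ids])
            grp = fh.create_group("observation/matrix")
            grp.create_dataset("data", data=mat.data)
            grp.create_dataset("indices", data=mat.indices)
            grp.create_dataset("indptr", data=mat.indptr)
        loaded = FeatureTable.read_biom(path)
        assert loaded.data.equals(tiny_table.data)


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = FeatureTable(pd.DataFrame([[6, 4]], index=["s"], columns=["a", "b"]))
        out = rarefy(t, depth=10, seed=0)
        assert out.table.data.loc["s"].tolist() == [6, 4]
        assert out.dropped == []

    def test_shallow_sample_dropped_and_reported(self):
        t = FeatureTable(
            pd.DataFrame([[6, 4], [2, 1]], index=["deep", "shallow"], columns=["a", "b"])
        )
        out = rarefy(t, depth=10, seed=0)
        assert out.table.sample_ids == ["deep"]
        assert out.dropped == ["shallow"]

    def test_zero_taxon_cannot_gain_counts(self):
        t = FeatureTable(pd.DataFrame([[100, 0]], index=["s"], columns=["a", "b"]))
        out = rarefy(t, depth=10, seed=3)
        assert out.table.data.loc["s"].tolist() == [10, 0]

    def test_all_samples_below_depth_is_error(self, tiny_table):
        with pytest.raises(EmptyTableError):
            rarefy(tiny_table, depth=10**6, seed=0)

    def test_counts_never_exceed_originals_and_sum_to_depth(self, tiny_table):
        out = rarefy(tiny_table, depth=3, seed=11)
        assert (out.table.data <= tiny_table.data.loc[out.table.sample_ids]).all().all()
        assert (out.table.sample_totals() == 3).all()

    def test_same_seed_same_output(self, tiny_table):
        a = rarefy(tiny_table, depth=3, seed=5).table
        b = rarefy(tiny_table, depth=3, seed=5).table
        assert a.data.equals(b.data)

    def test_hypergeometric_marginal_mean(self):
        # 300 identical (60, 40) samples rarefied to 10: mean of taxon 1
        # approaches 10 * 60/100 = 6 within Monte-Carlo error
        n = 300
        t = FeatureTable(
            pd.DataFrame(
                np.tile([60, 40], (n, 1)), index=[f"s{i}" for i in range(n)],
                columns=["a", "b"],
            )
        )
        out = rarefy(t, depth=10, seed=7)
        mean = out.table.data["a"].mean()
        # hypergeometric sd ~ 1.22 per draw -> se ~ 0.07; allow 4 se
        assert abs(mean - 6.0) < 0.3


class TestCollapseAndMerge:
    def test_same_family_counts_pooled(self, tiny_table, tiny_taxonomy):
        fam = collapse_to_rank(tiny_table, tiny_taxonomy, "family")
        assert fam.data.loc["s1", "FamA"] == 5 + 3
        assert fam.data.loc["s1", "FamB"] == 0

    def test_distinct_families_only_relabel(self, tiny_table):
        tax = TaxonomyMap(
            {a: ("Bacteria", "P", "C", "O", f"Fam{a}") for a in tiny_table.asv_ids}
        )
        fam = collapse_to_rank(tiny_table, tax, "family")
        assert fam.shape == tiny_table.shape

    def test_totals_conserved_and_unassigned_pooled(self, tiny_table, tiny_taxonomy):
        tax = TaxonomyMap({"a1": tiny_taxonomy.lineage("a1")})  # a2, a3 unknown
        fam = collapse_to_rank(tiny_table, tax, "family")
        assert (fam.sample_totals() == tiny_table.sample_totals()).all()
        assert "unassigned" in fam.asv_ids

    def test_unknown_rank_rejected(self, tiny_table, tiny_taxonomy):
        with pytest.raises(ValueError, match="rank"):
            collapse_to_rank(tiny_table, tiny_taxonomy, "kingdom")

    def test_merge_missing_niche_contributes_zeros(self):
        gut = FeatureTable(pd.DataFrame([[3, 2]], index=["subj1"], columns=["a", "b"]))
        oral = FeatureTable(pd.DataFrame([[5]], index=["subj2"], columns=["a"]))
        merged = merge_individual({"gut": gut, "oral": oral})
        assert merged.data.loc["subj1", "oral:a"] == 0
        assert merged.data.loc["subj2", "gut:a"] == 0

    def test_merge_conserves_per_subject_totals(self):
        gut = FeatureTable(pd.DataFrame([[3, 2]], index=["x"], columns=["a", "b"]))
        oral = FeatureTable(pd.DataFrame([[5, 1]], index=["x"], columns=["a", "c"]))
        merged = merge_individual({"gut": gut, "oral": oral})
        assert merged.sample_totals()["x"] == 11

    def test_shared_asv_ids_stay_distinct(self):
        gut = FeatureTable(pd.DataFrame([[3]], index=["x"], columns=["a"]))
        oral = FeatureTable(pd.DataFrame([[5]], index=["x"], columns=["a"]))
        merged = merge_individual({"gut": gut, "oral": oral})
        assert set(merged.asv_ids) == {"gut:a", "oral:a"}

    def test_duplicate_subject_within_niche_rejected(self, tiny_table, tiny_metadata):
        meta = tiny_metadata
        meta.samples.loc["s2", "subject_id"] = "H1_C1"  # same subject twice
        with pytest.raises(ValidationError, match="duplicate subject"):
            table_by_subject(tiny_table, meta)


class TestTaxonomyDialect:
    def test_prefixes_stripped_and_too_long_rejected(self):
        lin = TaxonomyMap.parse_lineage("d__Bacteria; p__Firmicutes; f__Lachnospiraceae")
        assert lin[0] == "Bacteria" and lin[1] == "Firmicutes"
        with pytest.raises(ParseError):
            TaxonomyMap.parse_lineage(";".join("x" * 1 for _ in range(8)))

    def test_tsv_round_trip(self, tmp_path, tiny_taxonomy):
        path = tmp_path / "tax.tsv"
        tiny_taxonomy.to_tsv(path)
        loaded = TaxonomyMap.read_tsv(path)
        for asv in tiny_taxonomy.asv_ids:
            assert loaded.lineage(asv) == tiny_taxonomy.lineage(asv)
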