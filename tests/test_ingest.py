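import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genagephen import ingest

HEADER = "gene_id\tsymbol\tchromosome\tstart\tend\tbiotype\tbranch\n"


def write_age_table(path, rows):
    with open(path, "w") as fh:
        fh.write(HEADER)
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return path


GOOD_ROW = ("G1", "S1", "1", 100, 200, "protein_coding", "br0")


class TestReadGeneAgeTable:
    def test_mt_and_rna_rows_filtered_with_tally(self, tmp_path):
        rows = [
            ("G1", "S1", "1", 100, 200, "protein_coding", "br0"),
            ("G2", "S2", "MT", 100, 200, "protein_coding", "br0"),
            ("G3", "S3", "X", 100, 200, "protein_coding", "br1"),
            ("G4", "S4", "2", 100, 200, "lncRNA", "br1"),
            ("G5", "S5", "Y", 100, 200, "protein_coding", "br2"),
        ]
        records, report = ingest.read_gene_age_table(
            write_age_table(tmp_path / "ages.tsv", rows))
        assert len(records) == 3
        assert report.removed == {"mitochondrial": 1, "unplaced": 0, "RNA": 1}
        report.validate()

    def test_empty_file_with_header(self, tmp_path):
        records, report = ingest.read_gene_age_table(
            write_age_table(tmp_path / "ages.tsv", []))
        assert len(records) == 0
        assert report.retained == 0 and report.removed_total == 0

    def test_unplaced_scaffold_removed(self, tmp_path):
        rows = [GOOD_ROW, ("G2", "S2", "GL000220.1", 1, 9, "protein_coding", "br0")]
        records, report = ingest.read_gene_age_table(
            write_age_table(tmp_path / "ages.tsv", rows))
        assert report.removed["unplaced"] == 1
        assert list(records["gene_id"]) == ["G1"]

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tsymbol\tchromosome\tstart\tend\tbiotype\n"
                        "G1\tS1\t1\t1\t2\tprotein_coding\n")
        with pytest.raises(ingest.IngestError, match="branch"):
            ingest.read_gene_age_table(path)

    def test_malformed_coordinate_reports_line(self, tmp_path):
        rows = [GOOD_ROW, ("G2", "S2", "1", "oops", 200, "protein_coding", "br0")]
        with pytest.raises(ingest.IngestError, match="line 3"):
            ingest.read_gene_age_table(write_age_table(tmp_path / "a.tsv", rows))

    def test_start_after_end_rejected(self, tmp_path):
        rows = [("G1", "S1", "1", 300, 200, "protein_coding", "br0")]
        with pytest.raises(ingest.IngestError, match="start > end"):
            ingest.read_gene_age_table(write_age_table(tmp_path / "a.tsv", rows))

    def test_canonical_dialect_round_trips_byte_identically(self, tmp_path):
        rows = [GOOD_ROW, ("G2", "S2", "X", 5, 9, "protein_coding", "br3")]
        records, _ = ingest.read_gene_age_table(
            write_age_table(tmp_path / "a.tsv", rows))
        first = tmp_path / "out1.tsv"
        records.to_csv(first, sep="\t", index=False)
        reread, _ = ingest.read_gene_age_table(first)
        second = tmp_path / "out2.tsv"
        reread.to_csv(second, sep="\t", index=False)
        assert first.read_bytes() == second.read_bytes()


def write_links(path, rows, direction="gene_to_phenotype"):
    cols = ingest.HPO_DIALECTS[direction]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return path


class TestAnnotations:
    def test_duplicate_gene_term_pairs_collapse(self, tmp_path):
        rows = [("G1", "S1", "HP:1", "Seizure")] * 2
        links = ingest.read_hpo_annotations(write_links(tmp_path / "l.tsv", rows))
        assert len(links) == 1

    def test_four_line_fixture_field_mapping_both_dialects(self, tmp_path):
        g2p = [("G1", "S1", "HP:1", "Seizure"),
               ("G1", "S1", "HP:2", "Ataxia"),
               ("G2", "S2", "HP:1", "Seizure"),
               ("G3", "S3", "HP:3", "Male infertility")]
        p2g = [(r[2], r[3], r[0], r[1]) for r in g2p]
        a = ingest.read_hpo_annotations(write_links(tmp_path / "a.tsv", g2p))
        b = ingest.read_hpo_annotations(
            write_links(tmp_path / "b.tsv", p2g, "phenotype_to_gene"),
            direction="phenotype_to_gene")
        assert len(a) == 4
        assert a.sort_values(["gene_id", "hpo_id"]).reset_index(drop=True).equals(
            b.sort_values(["gene_id", "hpo_id"]).reset_index(drop=True))

    def test_unknown_dialect_errors(self, tmp_path):
        with pytest.raises(ingest.IngestError, match="dialect"):
            ingest.read_hpo_annotations(tmp_path / "x.tsv", direction="sideways")

    def test_neoplasm_term_survives_reader_and_falls_to_filter_stage(self, tmp_path):
        rows = [("G1", "S1", "HP:0002664", "Neoplasm"),
                ("G1", "S1", "HP:1", "Seizure")]
        links = ingest.read_hpo_annotations(write_links(tmp_path / "l.tsv", rows))
        assert set(links["hpo_id"]) == {"HP:0002664", "HP:1"}
        kept, report = ingest.apply_term_filters(links, {"HP:0002664"})
        assert set(kept["hpo_id"]) == {"HP:1"}
        assert report.removed["neoplasm-term"] == 1


class TestTermFilters:
    def links(self, ids):
        return pd.DataFrame({"gene_id": [f"G{i}" for i in range(len(ids))],
                             "gene_symbol": "S", "hpo_id": ids,
                             "hpo_name": "name"})

    def test_single_neoplasm_link_removed(self):
        kept, report = ingest.apply_term_filters(
            self.links(["HP:1", "HP:2664", "HP:2"]), {"HP:2664"})
        assert len(kept) == 2 and report.removed["neoplasm-term"] == 1

    def test_all_neoplasm_empties_output(self):
        kept, report = ingest.apply_term_filters(
            self.links(["HP:2664", "HP:2664"]), {"HP:2664"})
        assert kept.empty and report.removed_total == 2

    def test_empty_term_set_passes_through(self):
        links = self.links(["HP:1", "HP:2"])
        kept, report = ingest.apply_term_filters(links, set())
        assert kept.equals(links) and report.retained == 2

    def test_removal_matches_membership_oracle(self):
        rng = np.random.default_rng(0)
        ids = [f"HP:{i}" for i in rng.integers(0, 40, size=200)]
        subtree = {f"HP:{i}" for i in range(0, 40, 3)}
        kept, report = ingest.apply_term_filters(self.links(ids), subtree)
        expected = [t for t in ids if t not in subtree]
        assert list(kept["hpo_id"]) == expected
        assert report.removed["neoplasm-term"] == len(ids) - len(expected)


class TestSystemMapping:
    def mapping(self):
        return pd.DataFrame({"hpo_id": ["HP:1", "HP:2", "HP:3", "HP:3"],
                             "system": ["OP1", "OP7", "OP1", "OP7"]})

    def links(self, ids):
        return pd.DataFrame({"gene_id": "G1", "gene_symbol": "S",
                             "hpo_id": ids, "hpo_name": "n"})

    def test_term_labelled_with_its_system(self):
        labelled, _ = ingest.map_terms_to_systems(self.links(["HP:1"]),
                                                  self.mapping())
        assert list(labelled["system"]) == ["OP1"]

    def test_orphan_term_flagged_and_excluded(self):
        labelled, report = ingest.map_terms_to_systems(
            self.links(["HP:1", "HP:99"]), self.mapping())
        assert list(labelled["hpo_id"]) == ["HP:1"]
        assert report.removed["unmapped-system"] == 1

    def test_multi_axial_term_labels_every_ancestor_system(self):
        # oracle: brute-force ancestor walk over the toy two-system ontology
        labelled, _ = ingest.map_terms_to_systems(self.links(["HP:3"]),
                                                  self.mapping())
        assert sorted(labelled["system"]) == ["OP1", "OP7"]


class TestClassifyReproductive:
    def links(self, pairs):
        return pd.DataFrame(
            {"gene_id": [g for g, _ in pairs], "gene_symbol": "S",
             "hpo_id": [f"HP:{i}" for i in range(len(pairs))],
             "hpo_name": [n for _, n in pairs]})

    def test_male_only_terms(self):
        out = ingest.classify_reproductive(
            self.links([("G1", "Male infertility")]))
        assert out.loc[0, "reproductive_class"] == "male_specific"
        assert bool(out.loc[0, "is_reproductive"])

    def test_both_sexes(self):
        out = ingest.classify_reproductive(self.links(
            [("G1", "Female hypogonadism"), ("G1", "Male hypogonadism")]))
        assert out.loc[0, "reproductive_class"] == "both"

    def test_female_substring_does_not_count_as_male(self):
        out = ingest.classify_reproductive(
            self.links([("G1", "Female infertility")]))
        assert out.loc[0, "reproductive_class"] == "female_specific"

    def test_hand_enumerated_ten_gene_fixture(self):
        pairs = [
            ("G0", "Seizure"),
            ("G1", "Male infertility"), ("G1", "Ataxia"),
            ("G2", "Female infertility"),
            ("G3", "Abnormal reproductive system morphology"),
            ("G4", "Female hypogonadism"), ("G4", "Male hypogonadism"),
            ("G5", "MALE PATTERN BALDNESS"),
            ("G6", "Premature ovarian failure in females"),
            ("G7", "Decreased male libido"), ("G7", "Female sexual dysfunction"),
            ("G8", "Tall stature"),
            ("G9", "Azoospermia in males"),
        ]
        out = ingest.classify_reproductive(self.links(pairs))
        got = dict(zip(out["gene_id"], out["reproductive_class"]))
        assert got == {
            "G0": "none", "G1": "male_specific", "G2": "female_specific",
            "G3": "none", "G4": "both", "G5": "male_specific",
            "G6": "female_specific", "G7": "both", "G8": "none",
            "G9": "male_specific"}
        repro = dict(zip(out["gene_id"], out["is_reproductive"]))
        assert repro["G3"] and not repro["G0"] and not repro["G8"]

    @settings(max_examples=25, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_invariant_to_link_order(self, rnd):
        pairs = [("G1", "Male infertility"), ("G1", "Seizure"),
                 ("G2", "Female infertility"), ("G2", "Male hypogonadism"),
                 ("G3", "Abnormal reproductive system physiology")]
        links = self.links(pairs)
        shuffled = links.sample(frac=1, random_state=rnd.randrange(10**6))
        base = ingest.classify_reproductive(links)
        perm = ingest.classify_reproductive(shuffled.reset_index(drop=True))
        assert base.sort_values("gene_id").reset_index(drop=True).equals(
            perm.sort_values("gene_id").reset_index(drop=True))


class TestDiseaseProfiles:
    def records(self):
        return pd.DataFrame({
            "gene_id": ["G1", "G2"], "symbol": ["S1", "S2"],
            "chromosome": ["1", "X"], "start": [10, 20], "end": [100, 200],
            "biotype": "protein_coding", "branch": ["br0", "br3"]})

    def labelled(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "gene_symbol",
                                           "hpo_id", "hpo_name", "system"])

    def test_m_counts_distinct_systems(self):
        labelled = self.labelled([
            ("G1", "S", "HP:1", "Seizure", "OP1"),
            ("G1", "S", "HP:2", "Male infertility", "OP7")])
        prof = ingest.build_disease_profiles(self.records(), labelled)
        assert prof.loc[0, "m"] == 2
        assert prof.loc[0, "systems"] == frozenset({"OP1", "OP7"})

    def test_many_links_one_system_gives_m_one(self):
        labelled = self.labelled([
            ("G1", "S", f"HP:{i}", "Seizure", "OP1") for i in range(5)])
        prof = ingest.build_disease_profiles(self.records(), labelled)
        assert prof.loc[0, "m"] == 1

    def test_gene_without_age_record_excluded(self):
        labelled = self.labelled([
            ("G1", "S", "HP:1", "Seizure", "OP1"),
            ("GX", "S", "HP:1", "Seizure", "OP1")])
        prof = ingest.build_disease_profiles(self.records(), labelled)
        assert list(prof["gene_id"]) == ["G1"]

    def test_single_system_share_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        rows, records = [], []
        for i in range(60):
            m = int(rng.integers(1, 4))
            systems = rng.choice(["OP1", "OP2", "OP7"], size=m, replace=False)
            for s in systems:
                rows.append((f"G{i}", "S", f"HP:{s}", "x", s))
            records.append((f"G{i}", f"S{i}", "1", 1, 2, "protein_coding", "br0"))
        rec = pd.DataFrame(records, columns=["gene_id", "symbol", "chromosome",
                                             "start", "end", "biotype", "branch"])
        prof = ingest.build_disease_profiles(rec, self.labelled(rows))
        by_gene = {}
        for g, *_rest, s in rows:
            by_gene.setdefault(g, set()).add(s)
        expected = sum(1 for v in by_gene.values() if len(v) == 1) / len(by_gene)
        assert (prof["m"] == 1).mean() == pytest.approx(expected)


class TestKaKs:
    def write(self, tmp_path, rows):
        path = tmp_path / "kaks.tsv"
        with open(path, "w") as fh:
            fh.write("gene_id\tpartner\tka_ks\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
        return path

    def test_views_and_rejection(self, tmp_path):
        path = self.write(tmp_path, [("G1", "chimpanzee", 0.25),
                                     ("G2", "chimpanzee", 1.3),
                                     ("G3", "chimpanzee", -0.1)])
        kaks, report = ingest.read_kaks_table(path)
        assert list(kaks["gene_id"]) == ["G1", "G2"]
        assert list(kaks["purifying"]) == [True, False]
        assert report.removed["invalid-kaks"] == 1


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.sampled_from(["1", "5", "X", "MT", "KI27", "22"]),
                min_size=0, max_size=40),
       st.lists(st.sampled_from(["protein_coding", "lncRNA", "miRNA"]),
                min_size=40, max_size=40))
def test_filter_report_conserves_records(tmp_path_factory, chroms, biotypes):
    tmp = tmp_path_factory.mktemp("fuzz")
    rows = [(f"G{i}", f"S{i}", c, 1, 10, b, "br0")
            for i, (c, b) in enumerate(zip(chroms, biotypes))]
    _, report = ingest.read_gene_age_table(
        write_age_table(tmp / "ages.tsv", rows))
    assert report.removed_total + report.retained == report.input_count == len(rows)
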