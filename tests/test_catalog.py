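"""Catalog construction, sequence extraction, opportunities, renormalization."""

import numpy as np
import pandas as pd
import pytest

from ddcat import catalog as C
from ddcat.patterns import (Categorization, parse_pattern, pattern_size,
                            standard_categorization)


TOY_GENOME = {"chr1": "TTGTCAACGG",   # TGT[C]AAC at pos 5 (1-based)
              "chr2": "AGTTGACAT"}    # GTT[G]ACA at pos 5


class TestExtraction:
    def test_forward_strand_worked_example(self):
        seq = C.extract_mutation_sequence(TOY_GENOME, "chr1", 5, "C", "T")
        assert seq == "TGTCTAAC"

    def test_purine_reference_is_reverse_complemented(self):
        seq = C.extract_mutation_sequence(TOY_GENOME, "chr2", 5, "G", "A")
        assert seq == "TGTCTAAC"

    def test_collapsing_is_involution_consistent(self, fix, rng):
        """A record and its reverse-complement representation yield the
        same collapsed sequence."""
        chrom = "chr1"
        s = fix.genome[chrom]
        for _ in range(50):
            pos = int(rng.integers(4, len(s) - 3))
            ref = s[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fwd = C.extract_mutation_sequence(fix.genome, chrom, pos, ref, alt)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            rc_genome = {chrom: "".join(comp[b] for b in reversed(s))}
            rc_pos = len(s) - pos + 1
            rev = C.extract_mutation_sequence(rc_genome, chrom, rc_pos,
                                              comp[ref], comp[alt])
            assert fwd == rev

    @pytest.mark.parametrize("chrom,pos,ref,alt,reason", [
        ("chr1", 5, "G", "T", "reference_mismatch"),
        ("chr1", 2, "T", "A", "out_of_bounds"),
        ("chr1", 9, "G", "T", "out_of_bounds"),
        ("chr1", 5, "C", "C", "non_snv"),
        ("chr1", 5, "CC", "T", "non_snv"),
    ])
    def test_rejections(self, chrom, pos, ref, alt, reason):
        with pytest.raises(C.ExtractionError) as exc:
            C.extract_mutation_sequence(TOY_GENOME, chrom, pos, ref, alt)
        assert exc.value.reason == reason

    def test_n_in_window_rejected(self):
        genome = {"chr1": "TTGNCAACGG"}
        with pytest.raises(C.ExtractionError) as exc:
            C.extract_mutation_sequence(genome, "chr1", 5, "C", "T")
        assert exc.value.reason == "ambiguous_base"


def _records(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "position",
                                       "reference_allele", "mutated_allele"])


class TestBuildCatalog:
    def test_single_record_single_count(self, standard_cat):
        cohort = C.extract_cohort(TOY_GENOME, _records(
            [("s1", "chr1", 5, "C", "T")]))
        cat = C.build_catalog(cohort, standard_cat)
        assert cat.counts.sum() == 1
        assert cat.counts.max() == 1

    def test_counts_conserved_and_rejects_tallied(self, standard_cat):
        rows = [("s1", "chr1", 5, "C", "T"),
                ("s1", "chr2", 5, "G", "A"),
                ("s2", "chr1", 5, "C", "A"),
                ("s2", "chr1", 5, "G", "A"),     # mismatch -> rejected
                ("s2", "chrX", 5, "C", "A")]     # unknown chromosome
        cohort = C.extract_cohort(TOY_GENOME, _records(rows))
        assert cohort.rejections == {"reference_mismatch": 1,
                                     "unknown_chromosome": 1}
        cat = C.build_catalog(cohort, standard_cat)
        assert cat.counts.sum() == 3

    def test_identical_records_give_identical_rows(self, standard_cat):
        rows = [("a", "chr1", 5, "C", "T"), ("b", "chr1", 5, "C", "T")]
        cat = C.build_catalog(C.extract_cohort(TOY_GENOME, _records(rows)),
                              standard_cat)
        assert np.array_equal(cat.counts[0], cat.counts[1])

    def test_duplicates_kept_unless_dedup_requested(self, standard_cat):
        rows = [("a", "chr1", 5, "C", "T")] * 3
        kept = C.extract_cohort(TOY_GENOME, _records(rows))
        assert kept.seq_index.size == 3
        deduped = C.extract_cohort(TOY_GENOME, _records(rows), deduplicate=True)
        assert deduped.seq_index.size == 1

    def test_fixture_catalog_totals(self, fix, standard_cat):
        cat = C.build_catalog(fix.wgs_sequences, standard_cat)
        assert cat.counts.shape == (30, 96)
        assert cat.counts.sum() == fix.wgs_sequences.seq_index.size


class TestNormalizeRows:
    def test_proportions(self):
        v = C.normalize_rows(np.array([[2, 2, 0], [1, 0, 0]]))
        assert np.allclose(v, [[0.5, 0.5, 0], [1, 0, 0]])
        assert np.allclose(v.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_mutation_sample_rejected(self):
        with pytest.raises(ValueError, match="zero mutations"):
            C.normalize_rows(np.array([[1, 1], [0, 0]]))


class TestOpportunities:
    def test_seven_base_genome_hand_enumeration(self, standard_cat):
        """AAACAAA has one eligible center (the C) contributing 3
        opportunities: A[C>A]A, A[C>G]A, A[C>T]A."""
        opp = C.count_opportunities({"chr1": "AAACAAA"}, standard_cat)
        assert opp.u.sum() == 3
        labels = [p.text for p in standard_cat.patterns]
        for alt in "AGT":
            assert opp.u[labels.index(f"NNAC{alt}ANN")] == 1

    def test_total_is_three_per_eligible_position(self, fix, standard_cat):
        opp = C.count_opportunities(fix.genome, standard_cat)
        assert opp.u.sum() == 3 * opp.n_positions
        assert opp.n_positions == len(fix.genome["chr1"]) - 6

    def test_all_n_genome_raises(self, standard_cat):
        with pytest.raises(ValueError, match="eligible"):
            C.count_opportunities({"chr1": "N" * 100}, standard_cat)

    def test_region_restriction_uses_central_base(self, standard_cat):
        genome = {"chr1": "AAACAAAG"}
        bed = pd.DataFrame([("chr1", 3, 4)], columns=["chrom", "start", "end"])
        opp = C.count_opportunities(genome, standard_cat, regions=bed)
        assert opp.u.sum() == 3          # only the C at 0-based position 3
        bed_off = pd.DataFrame([("chr1", 0, 3)],
                               columns=["chrom", "start", "end"])
        with pytest.raises(ValueError):
            C.count_opportunities(genome, standard_cat, regions=bed_off)

    def test_uniform_genome_frequencies_proportional_to_size(self,
                                                             standard_cat):
        """On an i.i.d. uniform genome every standard category covers 256
        sequences, so opportunity counts should be near-equal."""
        from ddcat.synthetic import simulate_genome
        g = simulate_genome(length=300_000, gc_content=0.5, seed=9)
        opp = C.count_opportunities(g, standard_cat)
        freq = opp.u / opp.u.sum()
        expected = np.full(96, 1 / 96)
        assert np.abs(freq - expected).max() < 0.05 / 96 * 5


class TestRenormalization:
    def test_identity_when_regimes_match(self, rng):
        h = rng.dirichlet(np.ones(5), size=3)
        u = np.array([10, 20, 30, 40, 50])
        assert np.allclose(C.renormalize_signatures(h, u, u), h)

    def test_hand_two_category_case(self):
        out = C.renormalize_signatures(np.array([[0.5, 0.5]]),
                                       np.array([1.0, 1.0]),
                                       np.array([2.0, 1.0]))
        assert np.allclose(out, [[2 / 3, 1 / 3]])

    def test_rows_sum_to_one(self, rng):
        h = rng.dirichlet(np.ones(8), size=4)
        u_src = rng.integers(1, 100, 8)
        u_dst = rng.integers(1, 100, 8)
        out = C.renormalize_signatures(h, u_src, u_dst)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_unobservable_category_warns(self):
        h = np.array([[0.5, 0.5]])
        with pytest.warns(UserWarning, match="unobservable"):
            out = C.renormalize_signatures(h, np.array([0.0, 1.0]),
                                           np.array([1.0, 1.0]))
        assert np.allclose(out, [[0.0, 1.0]])


class TestIO:
    def test_mutation_table_roundtrip(self, tmp_path, fix):
        path = tmp_path / "muts.tsv"
        fix.cohorts.wgs_records.to_csv(path, sep="\t", index=False)
        df = C.read_mutation_table(path)
        assert len(df) == len(fix.cohorts.wgs_records)

    def test_column_mapping(self, tmp_path):
        path = tmp_path / "muts.tsv"
        pd.DataFrame({"donor": ["s1"], "chr": ["chr1"], "pos": [5],
                      "ref": ["C"], "alt": ["T"]}).to_csv(path, sep="\t",
                                                          index=False)
        df = C.read_mutation_table(path, column_map={
            "donor": "sample_id", "chr": "chromosome", "pos": "position",
            "ref": "reference_allele", "alt": "mutated_allele"})
        assert list(df.columns) == list(C.DEFAULT_COLUMNS)
        with pytest.raises(ValueError, match="missing columns"):
            C.read_mutation_table(path)

    def test_catalog_tsv(self, tmp_path, fix, standard_cat):
        cat = C.build_catalog(fix.wgs_sequences, standard_cat)
        path = tmp_path / "catalog.tsv"
        cat.to_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert back.shape == (30, 96)
        assert back.to_numpy().sum() == cat.counts.sum()
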