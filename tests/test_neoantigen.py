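"""Unit, oracle, and property tests for the neoantigen stage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timeatlas import SimConfig
from timeatlas.neoantigen import (
    AMINO_ACIDS,
    CLASS_I_LENGTHS,
    CLASS_II_LENGTHS,
    HlaType,
    MutationRecord,
    PeptideWindow,
    allele_locus,
    average_neoantigen_abundance,
    build_mutation_db,
    call_neoantigens,
    calls_to_frame,
    classify_binder,
    concordance_analysis,
    enumerate_candidates,
    ifot_normalize,
    make_peptide_window,
    mhc_protein_expression,
    parse_protein_change,
    predict_ranks,
    quantify_abundance,
    wildtype_peptide,
)
from timeatlas.predictors import HashRankPredictor, PredictorError, TableRankPredictor
from timeatlas.simulate import generate_peptidome, generate_truth_labels


def brute_force_candidates(sequence: str, offset: int, lengths) -> set:
    """Independent enumeration oracle: all substrings of the allowed
    lengths whose span covers the mutated position."""
    out = set()
    for length in lengths:
        for start in range(1, len(sequence) - length + 2):
            if start <= offset <= start + length - 1:
                out.add(sequence[start - 1 : start - 1 + length])
    return out


class TestMutationDb:
    def test_shared_mutation_collapses_with_both_tags(self):
        t1 = pd.DataFrame(
            [{"gene": "BAP1", "accession": "P1", "protein_change": "p.N645K", "source": "cohortA"}]
        )
        t2 = pd.DataFrame(
            [{"gene": "BAP1", "accession": "P1", "protein_change": "p.N645K", "source": "cohortB"}]
        )
        db = build_mutation_db([t1, t2])
        assert len(db) == 1
        assert db[0].sources == ("cohortA", "cohortB")

    def test_protein_change_parsing(self):
        assert parse_protein_change("p.N645K") == ("N", 645, "K")
        with pytest.raises(ValueError):
            parse_protein_change("c.1935T>A")

    def test_synonymous_and_malformed_rows_dropped(self):
        table = pd.DataFrame(
            [
                {"gene": "G1", "accession": "P1", "protein_change": "p.L10L", "source": "s"},
                {"gene": "G2", "accession": "P2", "protein_change": "nonsense", "source": "s"},
                {"gene": "G3", "accession": "P3", "protein_change": "p.A5V", "source": "s"},
            ]
        )
        db = build_mutation_db([table])
        assert [m.gene for m in db] == ["G3"]


class TestPeptideWindow:
    def test_centered_full_window(self):
        protein = "".join(AMINO_ACIDS[i % 20] for i in range(29))
        wt = protein[14]
        mut = "A" if wt != "A" else "C"
        rec = MutationRecord("G", "P", 15, wt, mut)
        window = make_peptide_window(protein, rec)
        assert len(window.sequence) == 29
        assert window.mutation_offset == 15
        assert window.sequence[14] == mut

    def test_nterm_clipping(self):
        protein = "ACDEFGHIKLMNPQRSTVWY" * 3
        wt = protein[4]
        rec = MutationRecord("G", "P", 5, wt, "W" if wt != "W" else "Y")
        window = make_peptide_window(protein, rec)
        # residues 1..19 -> length 19, mutation at offset 5
        assert len(window.sequence) == 19
        assert window.mutation_offset == 5
        assert window.sequence[:4] == protein[:4]
        assert window.sequence[5:] == protein[5:19]

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="reference inconsistency"):
            make_peptide_window("AAAA", MutationRecord("G", "P", 2, "C", "D"))
        with pytest.raises(ValueError, match="reference inconsistency"):
            make_peptide_window("AAAA", MutationRecord("G", "P", 9, "A", "D"))


class TestEnumerateCandidates:
    def test_centered_29mer_counts(self):
        seq = "ACDEFGHIKLMNPQYSTVWACDEFGHIKL"
        assert len(seq) == 29
        window = PeptideWindow(seq, 15, MutationRecord("G", "P", 15, "A", seq[14]))
        class_i = enumerate_candidates(window, "I")
        class_ii = enumerate_candidates(window, "II")
        assert len(class_i) == 77  # sum of k for k = 8..14
        assert len(class_ii) == 15
        assert {c.sequence for c in class_i} == brute_force_candidates(seq, 15, CLASS_I_LENGTHS)
        assert {c.sequence for c in class_ii} == brute_force_candidates(seq, 15, CLASS_II_LENGTHS)

    def test_clipped_window_8mers(self):
        seq = "ACDEFGHIKLMNPQRSTVW"  # length 19
        window_cands = enumerate_candidates(sequence=seq, mutation_offset=5, mhc_class="I")
        eight = [c for c in window_cands if c.length == 8]
        assert len(eight) == 5
        assert {c.sequence for c in eight} == brute_force_candidates(seq, 5, [8])

    def test_short_window_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            out = enumerate_candidates(sequence="ACDEFG", mutation_offset=3, mhc_class="I")
        assert out == []

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_windows(self, data):
        rng_seq = data.draw(
            st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=29), label="sequence"
        )
        offset = data.draw(st.integers(1, len(rng_seq)), label="offset")
        mhc_class = data.draw(st.sampled_from(["I", "II"]))
        lengths = CLASS_I_LENGTHS if mhc_class == "I" else CLASS_II_LENGTHS
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            cands = enumerate_candidates(
                sequence=rng_seq, mutation_offset=offset, mhc_class=mhc_class
            )
        assert {c.sequence for c in cands} == brute_force_candidates(rng_seq, offset, lengths)
        for c in cands:
            assert c.sequence[c.mutation_index - 1] == rng_seq[offset - 1]


class TestClassifyBinder:
    @pytest.mark.parametrize(
        "mhc_class,mut,wt,expected",
        [
            ("I", 0.5, 3.0, "high"),
            ("I", 1.5, 3.0, "intermediate"),
            ("I", 0.5, 1.5, "non_binder"),   # WT also a potential binder
            ("I", 2.0, 2.0, "non_binder"),   # WT not strictly above threshold
            ("I", 2.0, 2.01, "intermediate"),
            ("I", 1.0, 3.0, "high"),          # boundary: mut <= 1 inclusive
            ("II", 4.0, 12.0, "high"),
            ("II", 8.0, 12.0, "intermediate"),
            ("II", 4.0, 8.0, "non_binder"),
            ("II", 10.0, 10.0, "non_binder"),
            ("II", 5.0, 11.0, "high"),
        ],
    )
    def test_tier_rules(self, mhc_class, mut, wt, expected):
        assert classify_binder(mut, wt, mhc_class) == expected

    def test_rank_domain_errors(self):
        for bad in (0.0, -1.0, 101.0):
            with pytest.raises(ValueError):
                classify_binder(bad, 50.0, "I")
            with pytest.raises(ValueError):
                classify_binder(1.0, bad, "I")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        wt=st.floats(0.01, 100.0),
        mut_hi=st.floats(0.01, 100.0),
        mut_lo=st.floats(0.01, 100.0),
        mhc_class=st.sampled_from(["I", "II"]),
    )
    def test_tier_monotone_in_mutant_rank(self, wt, mut_hi, mut_lo, mhc_class):
        """For fixed WT rank, a stronger (lower) mutant rank never demotes."""
        from timeatlas.neoantigen import TIER_ORDER

        lo, hi = sorted((mut_lo, mut_hi))
        tier_lo = classify_binder(lo, wt, mhc_class)
        tier_hi = classify_binder(hi, wt, mhc_class)
        assert TIER_ORDER[tier_lo] >= TIER_ORDER[tier_hi]


class TestPredictRanks:
    def test_wt_reversion_and_determinism(self):
        window_seq = "ACDEFGHIKLMN"
        cands = enumerate_candidates(sequence=window_seq, mutation_offset=5, mhc_class="I")
        pred = HashRankPredictor()
        ranks = predict_ranks(cands, "W", ["HLA-A*01:01"], pred)
        again = predict_ranks(cands, "W", ["HLA-A*01:01"], pred)
        pd.testing.assert_frame_equal(ranks, again)
        for row in ranks.itertuples(index=False):
            diffs = [i for i, (x, y) in enumerate(zip(row.peptide, row.wt_peptide)) if x != y]
            assert len(diffs) == 1
            assert row.wt_peptide[diffs[0]] == "W"
            assert 0 < row.mut_rank <= 100 and 0 < row.wt_rank <= 100

    def test_background_ranks_never_cross_binder_thresholds(self, rng):
        pred = HashRankPredictor()
        for _ in range(300):
            pep = "".join(rng.choice(list(AMINO_ACIDS), size=9))
            assert pred.rank(pep, "HLA-A*01:01") > 10.2

    def test_planted_binders_get_low_ranks(self):
        cfg = SimConfig(cells_per_sample=300, n_genes=500, seed=9)
        pep = generate_peptidome(cfg, generate_truth_labels(cfg))
        pred = pep.predictor()
        for (peptide, allele), rank in pep.planted_ranks.items():
            assert pred.rank(peptide, allele) == rank
            limit = 1.0 if allele_locus(allele) in ("HLA-A", "HLA-B", "HLA-C") else 5.0
            assert rank <= limit

    def test_predictor_failure_names_peptide(self):
        cands = enumerate_candidates(sequence="ACDEFGHIKL", mutation_offset=5, mhc_class="I")
        empty = TableRankPredictor({})
        with pytest.raises(PredictorError, match=cands[0].sequence):
            predict_ranks(cands, "W", ["HLA-A*01:01"], empty)


class TestAbundance:
    def test_rectangle_and_triangle_closed_forms(self):
        assert quantify_abundance([0, 3], [2, 2]) == pytest.approx(6.0, abs=1e-12)
        assert quantify_abundance([0, 1, 2], [0, 4, 0]) == pytest.approx(4.0, abs=1e-12)

    def test_piecewise_linear_matches_segment_sum(self, rng):
        t = np.sort(rng.uniform(0, 10, size=12))
        y = rng.uniform(0, 5, size=12)
        expected = sum(
            (t[i + 1] - t[i]) * (y[i] + y[i + 1]) / 2 for i in range(11)
        )
        assert quantify_abundance(t, y) == pytest.approx(expected, abs=1e-12)

    def test_unsorted_warns_negative_raises(self):
        with pytest.warns(UserWarning, match="unsorted"):
            assert quantify_abundance([1, 0], [2, 2]) == pytest.approx(2.0)
        with pytest.raises(ValueError, match="negative"):
            quantify_abundance([0, 1], [1, -1])
        with pytest.raises(ValueError, match="2 chromatogram"):
            quantify_abundance([0], [1])

    def test_ifot_normalization(self):
        out = ifot_normalize(pd.Series({"p1": 1.0, "p2": 3.0}))
        assert out["p1"] == pytest.approx(2.5e4)
        assert out["p2"] == pytest.approx(7.5e4)
        assert out.sum() == pytest.approx(1e5, rel=1e-6)


@pytest.fixture(scope="module")
def planted():
    """Fully detected planted peptidome (detect_prob = 1)."""
    cfg = SimConfig(cells_per_sample=300, n_genes=500, detect_prob=1.0, seed=13)
    truth = generate_truth_labels(cfg)
    pep = generate_peptidome(cfg, truth)
    return cfg, truth, pep


class TestCalls:

    def test_every_mutation_detected_when_forced(self, planted):
        cfg, truth, pep = planted
        per_sample = pep.peaks.groupby("sample_id").size()
        assert (per_sample == cfg.n_mutations_per_patient).all()

    def test_end_to_end_calls_equal_planted_truth(self, planted):
        cfg, truth, pep = planted
        pred = pep.predictor()
        calls = []
        for h in pep.hla_types:
            calls.extend(call_neoantigens(h, pep.windows, pep.peaks, pred))
        frame = calls_to_frame(calls)
        got = set(zip(frame.accession, frame.position, frame.sample_id, frame.mhc_class))
        want = set(
            zip(
                pep.truth_calls.accession, pep.truth_calls.position,
                pep.truth_calls.sample_id, pep.truth_calls.mhc_class,
            )
        )
        assert got == want
        # AUC attributed once per mutation: matches the generated peak AUC
        merged = frame.merge(
            pep.truth_calls, on=["accession", "position", "sample_id", "mhc_class"]
        )
        np.testing.assert_allclose(merged["auc_x"], merged["auc_y"], rtol=1e-12)

    def test_no_class_ii_alleles_no_class_ii_calls(self, planted):
        cfg, truth, pep = planted
        pred = pep.predictor()
        original = pep.hla_types[0]
        class_i_only = HlaType(
            patient_id=original.patient_id,
            alleles=original.class_alleles("I"),
        )
        calls = call_neoantigens(class_i_only, pep.windows, pep.peaks, pred)
        assert all(c.mhc_class == "I" for c in calls)

    def test_allele_restriction_monotone(self, planted):
        cfg, truth, pep = planted
        pred = pep.predictor()
        original = pep.hla_types[0]
        full = calls_to_frame(call_neoantigens(original, pep.windows, pep.peaks, pred))
        # replace HLA type with alleles that carry no planted binders
        decoy = HlaType(
            patient_id=original.patient_id,
            alleles=("HLA-A*02:01", "HLA-B*07:02", "HLA-DRB1*13:01"),
        )
        none = call_neoantigens(decoy, pep.windows, pep.peaks, pred)
        assert none == []
        subset = HlaType(patient_id=original.patient_id, alleles=original.alleles[:4])
        fewer = calls_to_frame(call_neoantigens(subset, pep.windows, pep.peaks, pred))
        full_keys = set(zip(full.accession, full.position, full.mhc_class))
        fewer_keys = set(zip(fewer.accession, fewer.position, fewer.mhc_class))
        assert fewer_keys <= full_keys

    def test_high_tier_mode_is_subset(self, planted):
        cfg, truth, pep = planted
        pred = pep.predictor()
        h = pep.hla_types[1]
        potential = calls_to_frame(call_neoantigens(h, pep.windows, pep.peaks, pred))
        high = calls_to_frame(
            call_neoantigens(h, pep.windows, pep.peaks, pred, tier_mode="high")
        )
        assert set(high.mutation) <= set(potential.mutation)
        assert (high.tier == "high").all()


class TestAbundanceSummaries:
    def test_average_is_mean_of_aucs(self):
        calls = pd.DataFrame(
            {
                "sample_id": ["S1"] * 3 + ["S2"],
                "mhc_class": ["I"] * 3 + ["I"],
                "auc": [2.0, 4.0, 6.0, 5.0],
            }
        )
        out = average_neoantigen_abundance(calls).set_index("sample_id")
        assert out.loc["S1", "mean_auc"] == pytest.approx(4.0)
        assert out.loc["S1", "n_calls"] == 3
        scaled = calls.assign(auc=calls["auc"] * 10)
        out2 = average_neoantigen_abundance(scaled).set_index("sample_id")
        assert out2.loc["S1", "mean_auc"] == pytest.approx(40.0)

    def test_empty_calls_warn(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = average_neoantigen_abundance(pd.DataFrame(columns=["sample_id", "mhc_class", "auc"]))
        assert out.empty


class TestMhcExpression:
    def test_single_locus_and_class_totals(self):
        quant = pd.DataFrame(
            [
                {"sample_id": "S1", "locus": "HLA-A", "ifot": 7.0},
                {"sample_id": "S1", "locus": "NOT_A_LOCUS", "ifot": 9.0},
            ]
        )
        wide, totals = mhc_protein_expression(quant)
        assert totals.loc["S1", "MHC_I"] == 7.0
        assert totals.loc["S1", "MHC_II"] == 0.0
        assert wide.loc["S1", "HLA-DRB1"] == 0.0  # absent row counts as zero

    def test_class_totals_match_brute_force(self, rng):
        from timeatlas.neoantigen import CLASS_I_LOCI, CLASS_II_LOCI

        rows = []
        for s in ("S1", "S2"):
            for locus in CLASS_I_LOCI + CLASS_II_LOCI:
                rows.append({"sample_id": s, "locus": locus, "ifot": rng.uniform(0, 10)})
        quant = pd.DataFrame(rows)
        wide, totals = mhc_protein_expression(quant)
        for s in ("S1", "S2"):
            sub = quant[quant.sample_id == s]
            assert totals.loc[s, "MHC_I"] == pytest.approx(
                sub[sub.locus.isin(CLASS_I_LOCI)].ifot.sum()
            )
            assert totals.loc[s, "MHC_II"] == pytest.approx(
                sub[sub.locus.isin(CLASS_II_LOCI)].ifot.sum()
            )


class TestConcordance:
    def test_chi2_matches_closed_form(self):
        cfg = SimConfig(cells_per_sample=300, n_genes=500, detect_prob=1.0, seed=13)
        truth = generate_truth_labels(cfg)
        pep = generate_peptidome(cfg, truth)
        pred = pep.predictor()
        calls = []
        for h in pep.hla_types:
            calls.extend(call_neoantigens(h, pep.windows, pep.peaks, pred))
        frame = calls_to_frame(calls)
        result = concordance_analysis(frame, pep.mhc_expression, truth)
        obs = result.table.to_numpy(dtype=float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        chi2_oracle = ((obs - expected) ** 2 / expected).sum()
        assert result.chi2 == pytest.approx(chi2_oracle, abs=1e-9)
        # planted positive abundance shift: subtype I richer in high/high
        prop = result.high_high_proportion
        assert prop["I"] > prop["II"]

    def test_requires_two_subtypes(self):
        calls = pd.DataFrame(
            {
                "sample_id": ["S1", "S2"], "mutation": ["m1", "m2"],
                "mhc_class": ["I", "I"], "alleles": ["HLA-A*01:01"] * 2,
                "auc": [1.0, 2.0],
            }
        )
        expr = pd.DataFrame({"HLA-A": [1.0, 2.0]}, index=["S1", "S2"])
        with pytest.raises(ValueError, match="2 samples per subtype"):
            concordance_analysis(calls, expr, pd.Series({"S1": "I", "S2": "I"}))
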