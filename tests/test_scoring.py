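"""Opening energy, SP score, Z-scores, filters, ranking and the funnel."""

import itertools

import numpy as np
import pytest

from spscreen import (
    CandidateScore,
    PredictedMRNA,
    SPRecord,
    SynthSpec,
    Thresholds,
    annotate_energies,
    apply_filters,
    attach_z_scores,
    decompose_loops,
    gen_record_set,
    opening_energy,
    parse_dotbracket,
    rank_candidates,
    read_deeploc,
    read_signalp,
    run_screen,
    sp_score,
    start_window,
    structure_from_pairs,
    summary_stats,
    synthetic_vector,
    total_energy,
    write_synthetic_inputs,
    z_scores,
)
from spscreen.constructs import VectorContext


def _mrna(sequence: str, start_index: int) -> PredictedMRNA:
    return PredictedMRNA(name="t", sequence=sequence, start_index=start_index)


def _annotated(structure):
    return annotate_energies(decompose_loops(structure), structure.sequence)


class TestOpeningEnergy:
    def test_unpaired_window_is_zero(self):
        # a hairpin far upstream of the window contributes nothing
        seq = "GGGAAACCC" + "A" * 191
        st = parse_dotbracket(seq, "(((...)))" + "." * 191)
        mrna = _mrna(seq, start_index=100)
        assert opening_energy(mrna, _annotated(st)) == 0.0

    def test_hairpin_inside_window_sums_its_loops(self):
        # hairpin helix entirely inside the +/-15 window around the start
        seq = "A" * 95 + "GGGAAACCC" + "A" * 96
        db = "." * 95 + "(((...)))" + "." * 96
        st = parse_dotbracket(seq, db)
        mrna = _mrna(seq, start_index=100)
        assert opening_energy(mrna, _annotated(st)) == pytest.approx(
            total_energy(st), abs=1e-9
        )
        assert opening_energy(mrna, _annotated(st)) == pytest.approx(-1.20, abs=1e-9)

    def test_loop_inclusion_rule_one_endpoint_suffices(self):
        # a distal 4-pair helix encloses (as an internal loop) a small helix
        # sitting inside the window; the enclosing internal loop has a branch
        # endpoint in the window and counts, the distal stacks do not
        seq = "G" * 4 + "A" * 90 + "GG" + "A" * 10 + "CC" + "A" * 88 + "C" * 4
        n = len(seq)  # 200
        pairs = [(0, 199), (1, 198), (2, 197), (3, 196), (94, 107), (95, 106)]
        st = structure_from_pairs(seq, pairs)
        mrna = _mrna(seq, start_index=100)  # window [85, 118)
        loops = _annotated(st)
        e = opening_energy(mrna, loops)
        distal_stacks = sum(
            lp.energy for lp in loops
            if lp.kind == "stack" and lp.closing_pair[0] < 3
        )
        assert distal_stacks == pytest.approx(3 * -3.30, abs=1e-9)
        assert e == pytest.approx(total_energy(st) - distal_stacks, abs=1e-9)

    def test_window_clipped_at_sequence_bounds(self):
        seq = "GGGAAACCC"
        st = parse_dotbracket(seq, "(((...)))")
        mrna = _mrna(seq, start_index=0)
        lo, hi = start_window(mrna)
        assert (lo, hi) == (0, 9)
        assert opening_energy(mrna, _annotated(st)) == pytest.approx(-1.20, abs=1e-9)

    def test_anchor_variants(self):
        mrna = _mrna("A" * 300, start_index=150)
        assert start_window(mrna, flank=15, anchor="codon") == (135, 168)
        assert start_window(mrna, flank=15, anchor="a") == (135, 166)


class TestSPScore:
    def test_printed_pairs_reproduce(self, table_fixture):
        for f in table_fixture.values():
            assert round(sp_score(f.mfe, f.opening_energy), 2) == f.sp_score

    def test_equal_inputs_give_unity(self):
        assert sp_score(-123.4, -123.4) == pytest.approx(1.0)

    def test_zero_opening_is_unscorable_not_fatal(self, caplog):
        with caplog.at_level("WARNING", logger="spscreen"):
            assert sp_score(-400.0, 0.0) is None
        assert "unscorable" in caplog.text


class TestZScores:
    def test_closed_form(self):
        assert z_scores([1, 2, 3]) == pytest.approx([-1.2247448, 0.0, 1.2247448])

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            z_scores([2.0, 2.0, 2.0])

    def test_population_normalisation(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(5, 3, size=50).tolist()
        zs = np.array(z_scores(vals))
        assert abs(zs.mean()) < 1e-9
        assert abs(zs.std(ddof=0) - 1) < 1e-9

    def test_affine_consistency_with_published_scores(self, table_fixture):
        # mu, sigma solved from the two top rows predict the other six
        f = table_fixture
        sigma = (f["SP1"].sp_score - f["SP2"].sp_score) / (
            f["SP1"].z_score - f["SP2"].z_score
        )
        mu = f["SP1"].sp_score - f["SP1"].z_score * sigma
        assert mu == pytest.approx(1.49, abs=0.01)
        assert sigma == pytest.approx(0.746, abs=0.001)
        for name in ["SP3", "SP4", "SP5", "hBMP2", "hBMP2-TIS", "hIL2"]:
            predicted = (f[name].sp_score - mu) / sigma
            assert predicted == pytest.approx(f[name].z_score, abs=0.1)


class TestSummaryStats:
    def test_published_mfe_stats(self, top5):
        mean, sd = summary_stats([f.mfe for f in top5])
        assert round(mean, 1) == -466.7
        assert round(sd, 1) == 19.6

    def test_published_opening_stats(self, top5):
        mean, sd = summary_stats([f.opening_energy for f in top5])
        assert round(mean, 1) == -72.6
        assert round(sd, 1) == 13.6

    def test_singleton(self):
        assert summary_stats([5.0]) == (5.0, 0.0)


class TestFilters:
    def test_funnel_matches_ground_truth(self, small_vector):
        for seed in range(5):
            records, scores, truth = gen_record_set(SynthSpec(n_records=80, seed=seed))
            _, funnel = apply_filters(records, scores, small_vector)
            assert funnel.stages == truth.expected_funnel

    def test_funnel_counts_non_increasing(self, small_vector):
        records, scores, _ = gen_record_set(SynthSpec(n_records=60, seed=9))
        _, funnel = apply_filters(records, scores, small_vector)
        counts = funnel.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_zero_thresholds_flat_after_dedup(self, small_vector):
        records, scores, _ = gen_record_set(SynthSpec(n_records=60, seed=2))
        thr = Thresholds(sec_spi_min=0.0, extracellular_min=0.0,
                         require_strong_kozak=False)
        _, funnel = apply_filters(records, scores, small_vector, thr)
        counts = dict(funnel.stages)
        assert counts["signalp_pass"] == counts["unique_nt"]
        assert counts["deeploc_pass"] == counts["unique_nt"]
        assert counts["kozak_strong"] == counts["unique_nt"]

    def test_exact_threshold_score_is_retained(self):
        rec = SPRecord("X1", aa_sequence="MVG", nt_sequence="ATGGTGGGT")
        vec = VectorContext(utr5="GCCACC", propeptide_cds="")
        survivors, _ = apply_filters([rec], {"X1": (0.5, 0.5)}, vec)
        assert [r.uniprot_accession for r in survivors] == ["X1"]

    def test_missing_predictor_score_excluded(self):
        rec = SPRecord("X1", aa_sequence="MVG", nt_sequence="ATGGTGGGT")
        vec = VectorContext(utr5="GCCACC", propeptide_cds="")
        survivors, funnel = apply_filters([rec], {}, vec)
        assert survivors == []
        assert dict(funnel.stages)["signalp_pass"] == 0

    def test_last_three_filters_commute(self, small_vector):
        # SignalP, DeepLoc and Kozak are independent predicates: applying
        # them in any order yields the same survivor set
        records, scores, _ = gen_record_set(SynthSpec(n_records=80, seed=13))
        survivors, _ = apply_filters(records, scores, small_vector)
        expected = {r.uniprot_accession for r in survivors}
        from spscreen import classify_kozak, dedup_records, validate_record

        base = [r for r in records if validate_record(r).overall_pass]
        base, _ = dedup_records(base)
        preds = {
            "signalp": lambda r: scores[r.uniprot_accession][0] >= 0.5,
            "deeploc": lambda r: scores[r.uniprot_accession][1] >= 0.5,
            "kozak": lambda r: classify_kozak(small_vector, r.nt_sequence) == "strong",
        }
        for order in itertools.permutations(preds):
            current = list(base)
            for key in order:
                current = [r for r in current if preds[key](r)]
            assert {r.uniprot_accession for r in current} == expected


class TestRanking:
    def _fixture_candidates(self, table_fixture):
        return [
            CandidateScore(
                accession=f.record.uniprot_accession if f.name not in ("hBMP2-TIS",)
                else f.name,
                mfe=f.mfe,
                opening_energy=f.opening_energy,
                sp_score=sp_score(f.mfe, f.opening_energy),
            )
            for f in table_fixture.values()
        ]

    def test_published_order(self, table_fixture):
        ranked = rank_candidates(self._fixture_candidates(table_fixture))
        accs = [c.accession for c in ranked]
        assert accs == [
            "A0A7K5LQ98", "A0A6P7IG99", "A0A5N3WKB5", "A0A7E6DRJ2", "A0A7J8F7B8",
            "P12643", "hBMP2-TIS", "P60568",
        ]
        assert [c.rank for c in ranked] == list(range(1, 9))

    def test_top_k_one_is_top_screen_hit(self, table_fixture):
        (best,) = rank_candidates(self._fixture_candidates(table_fixture), top_k=1)
        assert best.accession == "A0A7K5LQ98"

    def test_identical_candidates_order_by_accession(self):
        a = CandidateScore("B", mfe=-100, opening_energy=-50, sp_score=2.0)
        b = CandidateScore("A", mfe=-100, opening_energy=-50, sp_score=2.0)
        ranked = rank_candidates([a, b])
        assert [c.accession for c in ranked] == ["A", "B"]

    def test_top_k_larger_than_n_returns_all(self, table_fixture, caplog):
        with caplog.at_level("WARNING", logger="spscreen"):
            ranked = rank_candidates(self._fixture_candidates(table_fixture), top_k=99)
        assert len(ranked) == 8

    def test_unscorable_excluded(self):
        good = CandidateScore("A", mfe=-100, opening_energy=-50, sp_score=2.0)
        bad = CandidateScore("B", mfe=-100, opening_energy=0.0, sp_score=None)
        ranked = rank_candidates([good, bad])
        assert [c.accession for c in ranked] == ["A"]

    def test_attach_z_scores_population(self, table_fixture):
        cands = self._fixture_candidates(table_fixture)
        attach_z_scores(cands)
        zs = [c.z_score for c in cands]
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)
        assert np.std(zs) == pytest.approx(1.0, abs=1e-9)


class TestReadersAndScreen:
    def test_signalp_deeploc_readers(self, tmp_path):
        spec = SynthSpec(n_records=25, seed=6)
        paths = write_synthetic_inputs(tmp_path, spec)
        _, scores, _ = gen_record_set(spec)
        signalp = read_signalp(paths["signalp"])
        deeploc = read_deeploc(paths["deeploc"])
        assert set(signalp) == set(deeploc) == set(scores)
        for acc in scores:
            assert signalp[acc] == pytest.approx(scores[acc][0], abs=5e-5)
            assert deeploc[acc] == pytest.approx(scores[acc][1], abs=5e-5)

    def test_run_screen_end_to_end(self):
        vec = synthetic_vector(propeptide_codons=10, utr3_length=6,
                               polya_tail_length=5)
        vec = VectorContext(
            utr5=vec.utr5[-30:], propeptide_cds=vec.propeptide_cds,
            utr3=vec.utr3, polya_region=vec.polya_region[:12],
            polya_tail_length=5,
        )
        records, scores, truth = gen_record_set(SynthSpec(n_records=14, seed=8))
        ranked, funnel = run_screen(records, scores, vec)
        assert funnel.stages == truth.expected_funnel
        n_final = truth.expected_funnel[-1][1]
        assert len(ranked) <= n_final
        for c in ranked:
            assert c.mfe is not None and c.mfe <= 0
            assert c.opening_energy is not None and c.opening_energy <= 0
            assert c.kozak == "strong"
            if c.sp_score is not None and c.opening_energy != 0:
                assert c.sp_score == pytest.approx(c.mfe / c.opening_energy)
        if len(ranked) >= 2:
            scores_desc = [c.sp_score for c in ranked]
            assert scores_desc == sorted(scores_desc, reverse=True)
            assert all(c.z_score is not None for c in ranked)
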