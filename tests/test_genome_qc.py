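"""Assembly QC metrics: filtering, N50, GC modality, completeness."""

import numpy as np
import pytest

from achromatium.errors import InputError
from achromatium.genome_qc import (
    PLACEHOLDER_MARKERS,
    ContigRecord,
    MarkerSurvey,
    completeness,
    contigs_from_fasta,
    estimate_genome_size,
    filter_contigs,
    gc_unimodality,
    n50,
    read_contig_csv,
    read_marker_survey,
    survey_report,
)
from achromatium.synthetic import gen_contig_set, gen_marker_survey


def contigs(lengths, gc=0.4):
    return [ContigRecord(f"c{i}", l, gc) for i, l in enumerate(lengths)]


def n50_oracle(lengths):
    """Brute force: sort descending, cumulate, pick first >= half."""
    srt = sorted(lengths, reverse=True)
    half = sum(srt) / 2
    acc = 0
    for l in srt:
        acc += l
        if acc >= half:
            return l


class TestFilter:
    def test_strictly_less_than_cutoff_removed(self):
        kept = filter_contigs(contigs([499, 500, 501]), 500)
        assert [c.length_bp for c in kept] == [500, 501]

    def test_empty_input(self):
        assert filter_contigs([], 500) == []

    def test_all_short(self):
        assert filter_contigs(contigs([100] * 10), 500) == []

    def test_order_preserved(self):
        kept = filter_contigs(contigs([900, 600, 700]), 500)
        assert [c.length_bp for c in kept] == [900, 600, 700]


class TestN50:
    @pytest.mark.parametrize(
        "lengths, expected",
        [([10], 10), ([1, 2, 3, 4, 5], 4), ([5, 5, 5, 5], 5),
         ([100, 1, 1], 100), ([2, 2, 2, 3], 2)],
    )
    def test_known_values(self, lengths, expected):
        assert n50(contigs(lengths)) == expected

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            lengths = rng.integers(1, 50000, size=rng.integers(1, 1000)).tolist()
            assert n50(contigs(lengths)) == n50_oracle(lengths)

    def test_order_invariant_after_filter(self):
        rng = np.random.default_rng(3)
        lengths = rng.integers(100, 9000, size=200).tolist()
        a = n50(filter_contigs(contigs(lengths)))
        b = n50(filter_contigs(contigs(lengths[::-1])))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            n50([])


class TestGcUnimodality:
    def test_identical_values(self):
        out = gc_unimodality([0.39] * 50)
        assert out == {"n_modes": 1, "unimodal": True}

    def test_single_component_is_unimodal(self):
        rng = np.random.default_rng(0)
        gc = np.clip(rng.normal(0.39, 0.03, 500), 0, 1)
        assert gc_unimodality(gc)["unimodal"] is True

    def test_two_separated_components_flagged(self):
        rng = np.random.default_rng(1)
        gc = np.concatenate([
            rng.normal(0.35, 0.02, 250), rng.normal(0.60, 0.02, 250)
        ])
        out = gc_unimodality(np.clip(gc, 0, 1))
        assert out["n_modes"] == 2
        assert out["unimodal"] is False

    def test_generator_mixture_round_trip(self):
        single, _ = gen_contig_set(500, gc_modes=[(0.39, 0.03, 1.0)], seed=5)
        assert gc_unimodality([c.gc_fraction for c in single])["unimodal"]
        mixed, _ = gen_contig_set(
            500, gc_modes=[(0.35, 0.02, 0.5), (0.60, 0.02, 0.5)], seed=5
        )
        assert not gc_unimodality([c.gc_fraction for c in mixed])["unimodal"]

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            gc_unimodality([0.4] * 9)


class TestCompleteness:
    def test_ratio_semantics(self):
        survey, _ = gen_marker_survey(1.0, 100, seed=0)
        partial = MarkerSurvey(
            survey.marker_ids,
            {m: (i < 40) for i, m in enumerate(sorted(survey.marker_ids))},
        )
        assert completeness(partial) == pytest.approx(0.40)

    def test_degenerate_endpoints(self):
        none, _ = gen_marker_survey(0.0, 50, seed=1)
        full, _ = gen_marker_survey(1.0, 50, seed=1)
        assert completeness(none) == 0.0
        assert completeness(full) == 1.0

    def test_empty_marker_set_rejected(self):
        with pytest.raises(InputError):
            MarkerSurvey(frozenset(), {})

    def test_estimator_recovers_truth(self):
        # small-scale recovery check; the full 200-replicate version runs
        # in the acceptance suite
        obs = [completeness(gen_marker_survey(0.8, 1000, seed=s)[0])
               for s in range(30)]
        se = np.std(obs, ddof=1) / np.sqrt(len(obs))
        assert abs(np.mean(obs) - 0.8) < 2 * max(se, 1e-4)


class TestGenomeSize:
    @pytest.mark.parametrize(
        "assembly, frac, expected",
        [(1.3, 0.40, 3.3), (2.8, 0.80, 3.5), (3.8, 0.80, 4.8)],
    )
    def test_study_cells(self, assembly, frac, expected):
        assert estimate_genome_size(assembly, frac) == expected

    def test_complete_genome_is_identity(self):
        assert estimate_genome_size(2.76, 1.0) == 2.8

    def test_estimate_not_below_assembly(self):
        for frac in (0.1, 0.5, 0.99, 1.0):
            assert estimate_genome_size(2.0, frac) >= 2.0

    def test_zero_completeness_rejected(self):
        with pytest.raises(InputError, match="completeness"):
            estimate_genome_size(1.3, 0.0)

    def test_survey_report_bundles(self):
        survey, _ = gen_marker_survey(1.0, 10, seed=2)
        rep = survey_report(survey, 2.8)
        assert rep.completeness == 1.0
        assert rep.estimated_genome_size_mbp == 2.8
        assert rep.n_found == 10


class TestIO:
    def test_fasta_gc_excludes_ambiguous(self, tmp_path):
        fasta = tmp_path / "contigs.fasta"
        fasta.write_text(">c1\nGGCCAATT\n>c2\nGGNNNNAA\n")
        recs = contigs_from_fasta(fasta)
        assert recs[0].gc_fraction == pytest.approx(0.5)
        assert recs[0].length_bp == 8
        # N excluded from denominator: 2 GC / 4 unambiguous
        assert recs[1].gc_fraction == pytest.approx(0.5)
        assert recs[1].length_bp == 8

    def test_contig_csv(self, tmp_path):
        csv = tmp_path / "contigs.csv"
        csv.write_text("contig_id,length_bp,gc_fraction\nc1,1200,0.39\n")
        recs = read_contig_csv(csv)
        assert recs[0] == ContigRecord("c1", 1200, 0.39)

    def test_marker_survey_csv(self, tmp_path):
        csv = tmp_path / "markers.csv"
        lines = ["marker_id,present"]
        for i, m in enumerate(PLACEHOLDER_MARKERS[:10]):
            lines.append(f"{m},{int(i < 4)}")
        csv.write_text("\n".join(lines) + "\n")
        survey = read_marker_survey(csv)
        assert completeness(survey) == pytest.approx(0.4)
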