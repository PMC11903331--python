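"""Sample/transcript gates, spliced frequency, PSR and neojunction calls."""

import numpy as np
import pandas as pd
import pytest

from njatlas import io as njio
from njatlas.cohort_filtering import (
    CohortSample,
    PipelineError,
    ThresholdConfig,
    call_neojunctions,
    compute_frequency,
    compute_psr,
    discover,
    gate_samples,
    gate_transcripts,
    make_observation,
    sample_expresses,
)
from njatlas.junction_catalog import (
    CanonicalAssignment,
    SpliceTypeCall,
    TranscriptModel,
)
from njatlas.synthetic_data import write_cohort


def _tumour(sid, purity):
    return CohortSample(sid, "tumour", purity)


class TestSampleGate:
    def test_purity_boundary_inclusive(self):
        samples = [_tumour("a", 0.59), _tumour("b", 0.60), _tumour("c", 0.90)]
        kept = gate_samples(samples)
        assert [s.sample_id for s in kept] == ["b", "c"]

    def test_normal_without_purity_retained(self):
        kept = gate_samples([_tumour("t", 0.9), CohortSample("n", "normal")])
        assert {s.sample_id for s in kept} == {"t", "n"}

    def test_tumour_without_purity_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="lacks purity"):
            kept = gate_samples([_tumour("t", 0.9), _tumour("u", None)])
        assert [s.sample_id for s in kept] == ["t"]

    def test_all_low_purity_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            gate_samples([_tumour("a", 0.2), _tumour("b", 0.5)])


class TestTranscriptGate:
    def _tx(self, tid, chrom="chr1", coding=True):
        return TranscriptModel(
            tid, tid + "g", chrom, "+", [(1, 100), (201, 300)],
            cds_span=(10, 290) if coding else None,
        )

    def test_median_tpm_in_one_subtype_suffices(self):
        expr = pd.DataFrame(
            {"s1": [12.0], "s2": [12.0], "s3": [3.0], "s4": [3.0]}, index=["t1"]
        )
        subtype = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        kept = gate_transcripts([self._tx("t1")], expr, subtype)
        assert len(kept) == 1
        assert kept[0].median_tpm_by_subtype == {"A": 12.0, "B": 3.0}

    def test_below_threshold_everywhere_dropped(self):
        expr = pd.DataFrame({"s1": [9.9], "s2": [9.9]}, index=["t1"])
        assert gate_transcripts(
            [self._tx("t1")], expr, {"s1": "A", "s2": "B"}
        ) == []

    def test_noncoding_and_mitochondrial_dropped(self):
        expr = pd.DataFrame({"s1": [100.0], "s2": [100.0]}, index=["t1", "t2"])
        txs = [self._tx("t1", coding=False), self._tx("t2", chrom="chrM")]
        assert gate_transcripts(txs, expr, {"s1": "A"}) == []

    def test_missing_from_matrix_excluded_with_warning(self):
        expr = pd.DataFrame({"s1": [100.0]}, index=["other"])
        with pytest.warns(UserWarning, match="missing"):
            assert gate_transcripts([self._tx("t1")], expr, {"s1": "A"}) == []


class TestFrequencyAndExpression:
    @pytest.mark.parametrize(
        "target, canonical, expected",
        [(10, 990, 0.01), (50, 0, 1.0), (0, 0, 0.0)],
    )
    def test_spliced_frequency(self, target, canonical, expected):
        assert compute_frequency(target, canonical) == pytest.approx(expected)

    def test_negative_reads_rejected(self):
        with pytest.raises(ValueError):
            compute_frequency(-1, 5)

    @pytest.mark.parametrize(
        "target, canonical, expressed",
        [
            (10, 10, True),  # all three gates at their boundaries
            (9, 1000, False),  # count gate
            (10, 5, False),  # depth 15 < 20
            (10, 1000, False),  # frequency 0.0099 < 1%
            (10, 990, True),  # frequency exactly 1%, inclusive
        ],
    )
    def test_expression_gates(self, target, canonical, expressed):
        obs = make_observation(("chr1", 1, 2, "+"), "s", target, canonical)
        assert obs.expressed is expressed

    def test_exclusive_frequency_boundary_option(self):
        cfg = ThresholdConfig(freq_inclusive=False)
        obs = make_observation(("chr1", 1, 2, "+"), "s", 10, 990, cfg)
        assert obs.expressed is False  # exactly 1% fails the strict reading

    def test_psr_arithmetic(self):
        key = ("chr1", 1, 2, "+")
        obs = [
            make_observation(key, f"s{i}", 50 if i < 3 else 0, 1000)
            for i in range(20)
        ]
        assert compute_psr(obs, 20) == pytest.approx(0.15)
        assert compute_psr([], 5) == 0.0
        with pytest.raises(PipelineError):
            compute_psr(obs, 0)


def _one_junction_catalogue():
    key = ("chr1", 201, 320, "+")
    canonical = ("chr1", 201, 300, "+")
    splice = SpliceTypeCall("A3_loss", -20, "frameshift", "TX1", "GENE1")
    return key, canonical, {key: (splice, CanonicalAssignment(key, canonical, "donor"))}


@pytest.mark.parametrize(
    "n_expr_t, n_expr_n, public, specific",
    [
        (2, 0, True, True),  # tumour PSR exactly 10%: public (inclusive)
        (10, 1, True, False),  # normal PSR exactly 1%: not specific (exclusive)
        (1, 0, False, True),  # tumour PSR 5% below the public cut
    ],
)
def test_call_flag_boundaries(n_expr_t, n_expr_n, public, specific):
    key, canonical, catalogue = _one_junction_catalogue()
    tumour = {
        f"t{i}": {canonical: 1000, **({key: 50} if i < n_expr_t else {})}
        for i in range(20)
    }
    normal = {
        f"n{i}": {canonical: 1000, **({key: 50} if i < n_expr_n else {})}
        for i in range(100)
    }
    (call,) = call_neojunctions(tumour, normal, catalogue)
    assert call.public is public
    assert call.cancer_specific is specific


def test_cohort_sum_prefilter_drops_sparse_junction():
    """A junction with fewer than 10 target reads cohort-wide never reaches
    per-sample evaluation."""
    key, canonical, catalogue = _one_junction_catalogue()
    tumour = {f"t{i}": {canonical: 1000, key: 1} for i in range(5)}
    assert call_neojunctions(tumour, {}, catalogue) == []


def test_psr_monotone_in_per_sample_reads():
    """Raising any sample's target reads never decreases the PSR."""
    key, canonical, catalogue = _one_junction_catalogue()
    rng = np.random.default_rng(7)
    base = {f"t{i}": {canonical: 1000, key: int(rng.integers(0, 40))}
            for i in range(12)}
    (call,) = call_neojunctions(base, {}, catalogue)
    for bump_sample in base:
        bumped = {s: dict(r) for s, r in base.items()}
        bumped[bump_sample][key] += 25
        (call2,) = call_neojunctions(bumped, {}, catalogue)
        assert call2.psr_tumour >= call.psr_tumour


def test_planted_truth_recovery_exact(tmp_path, planted_cohort):
    """On a cohort with >=2x threshold margins, public/cancer-specific flags
    equal the planted truth with precision = recall = 1."""
    config, cohort = planted_cohort
    write_cohort(cohort, tmp_path)
    records = njio.read_sj_dir(tmp_path / "junctions")
    calls, _ = discover(
        records,
        njio.read_metadata(tmp_path / "metadata.tsv"),
        njio.read_gtf(tmp_path / "annotation.gtf"),
        njio.read_expression(tmp_path / "expression.tsv"),
    )
    called = {njio.key_to_str(c.junction): c for c in calls}
    assert set(called) == set(cohort.truth)  # no spurious junctions
    for key, rec in cohort.truth.items():
        call = called[key]
        assert call.public == rec["expected_public"]
        assert call.cancer_specific == rec["expected_cancer_specific"]
        assert call.psr_tumour == pytest.approx(rec["psr_tumour"])
        expressing = {
            o.sample_id for o in call.tumour_observations if o.expressed
        }
        assert expressing == set(rec["expressing_tumour_samples"])
    assert [c.psr_tumour for c in calls] == sorted(
        (c.psr_tumour for c in calls), reverse=True
    )
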