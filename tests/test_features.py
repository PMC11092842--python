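"""Feature panel: golden values on the hand-built micro bundle, plus unit
and property tests for each feature operation and the transform contract."""

import numpy as np
import pandas as pd
import pytest

from cnvsig.features import (
    FeatureConfig,
    FeatureExtractor,
    FeatureTransformer,
    LOG_FEATURES,
    feature_columns,
    positional_distances,
    popmax_frequency,
    smoothed_conservation_max,
)
from cnvsig.intervals import GenomicInterval
from cnvsig.io import (
    CNVRecord,
    ChromosomeArms,
    ChromosomeStructure,
    ConservationTrack,
    SVFrequencyRecord,
)


def cnv(chrom, start, end, cnv_type="DEL", cid="c"):
    return CNVRecord(GenomicInterval(chrom, start, end), cnv_type, cid)


# ---------------------------------------------------------------------------
# positional distances
# ---------------------------------------------------------------------------

STRUCTURE = ChromosomeStructure(
    {"1": ChromosomeArms(0, GenomicInterval("1", 50, 60), 200)}
)


@pytest.mark.parametrize(
    "start, end, expected",
    [
        ((10), 20, (30, 10)),  # P arm
        (55, 58, (0, 55)),  # inside centromere: clamp + nearer-arm telomere
        (150, 180, (90, 20)),  # Q arm
        (40, 55, (0, 40)),  # spans centromere start, midpoint on P arm
    ],
)
def test_positional_distances(start, end, expected):
    assert positional_distances(cnv("1", start, end), STRUCTURE) == expected


def test_positional_distances_unknown_chromosome():
    with pytest.raises(KeyError):
        positional_distances(cnv("7", 0, 10), STRUCTURE)


# ---------------------------------------------------------------------------
# conservation smoothing
# ---------------------------------------------------------------------------

def track_from_values(chrom, start, values):
    t = ConservationTrack()
    for i, v in enumerate(values):
        t.add_run(chrom, start + i, start + i + 1, float(v))
    return t.finalize()


def test_smoothing_spike_window3():
    track = track_from_values("1", 0, [0, 0, 10, 0, 0])
    got = smoothed_conservation_max(cnv("1", 0, 5), track, window=3)
    assert got == pytest.approx(10 / 3)


def test_smoothing_window1_is_raw_max():
    track = track_from_values("1", 100, [1.0, -3.0, 7.5, 2.0])
    assert smoothed_conservation_max(cnv("1", 100, 104), track, window=1) == 7.5


def test_smoothing_constant_track_any_window():
    track = track_from_values("1", 0, [2.5] * 50)
    for w in (1, 3, 11):
        assert smoothed_conservation_max(cnv("1", 10, 30), track, window=w) == pytest.approx(2.5)


def test_smoothing_no_scores_returns_sentinel():
    track = track_from_values("1", 0, [1.0])
    assert smoothed_conservation_max(cnv("2", 0, 10), track, window=3, sentinel=-9.0) == -9.0


def test_smoothing_rejects_even_window():
    track = track_from_values("1", 0, [1.0, 2.0])
    with pytest.raises(ValueError):
        smoothed_conservation_max(cnv("1", 0, 2), track, window=4)


def brute_force_smoothed_max(values, start, cnv_start, cnv_end, window):
    """Independent moving-average oracle over an explicit position->score map."""
    scores = {start + i: v for i, v in enumerate(values) if not np.isnan(v)}
    half = window // 2
    best = -np.inf
    found = False
    for p in range(cnv_start, cnv_end):
        window_vals = [scores[q] for q in range(p - half, p + half + 1) if q in scores]
        if window_vals:
            found = True
            best = max(best, sum(window_vals) / len(window_vals))
    return best if found else None


def test_smoothing_matches_brute_force_on_random_tracks():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(5, 60))
        start = int(rng.integers(0, 50))
        values = rng.normal(0, 3, size=n)
        values[rng.random(n) < 0.3] = np.nan  # gaps
        window = int(rng.choice([1, 3, 5, 9]))
        a = int(rng.integers(start, start + n - 1))
        b = int(rng.integers(a + 1, start + n + 5))
        track = ConservationTrack()
        for i, v in enumerate(values):
            if not np.isnan(v):
                track.add_run("1", start + i, start + i + 1, float(v))
        track.finalize()
        expected = brute_force_smoothed_max(values, start, a, b, window)
        got = smoothed_conservation_max(cnv("1", a, b), track, window=window, sentinel=np.nan)
        if expected is None:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# popmax
# ---------------------------------------------------------------------------

def sv(chrom, start, end, sv_type, af):
    return SVFrequencyRecord(GenomicInterval(chrom, start, end), sv_type, {"g": af})


def test_popmax_examples():
    c = cnv("1", 0, 100, "DEL")
    assert popmax_frequency(c, []) == 0.0
    rec = SVFrequencyRecord(GenomicInterval("1", 0, 120), "DEL", {"a": 0.01, "b": 0.05})
    assert popmax_frequency(c, [rec]) == 0.05  # RO = 100/120 > 0.5
    dup = SVFrequencyRecord(GenomicInterval("1", 0, 100), "DUP", {"a": 0.3})
    assert popmax_frequency(c, [dup]) == 0.0  # type mismatch


def test_popmax_order_invariant_and_matches_brute_force():
    rng = np.random.default_rng(11)
    c = cnv("1", 1000, 3000, "DEL")
    records = []
    for _ in range(200):
        s = int(rng.integers(0, 4000))
        e = s + int(rng.integers(100, 4000))
        t = "DEL" if rng.random() < 0.5 else "DUP"
        records.append(sv("1", s, e, t, float(rng.random())))
    from cnvsig.intervals import reciprocal_overlap

    expected = max(
        (r.max_frequency for r in records
         if r.sv_type == "DEL" and reciprocal_overlap(c.interval, r.interval) >= 0.5),
        default=0.0,
    )
    assert popmax_frequency(c, records) == expected
    shuffled = list(records)
    rng.shuffle(shuffled)
    assert popmax_frequency(c, shuffled) == expected


# ---------------------------------------------------------------------------
# golden feature matrix on the micro bundle (independent hand computation)
# ---------------------------------------------------------------------------

GOLDEN_CNVS = [
    ("c1", "1", 21000, 26000, "DEL"),
    ("c2", "1", 19500, 20050, "DUP"),
    ("c3", "1", 55000, 58000, "DEL"),  # inside centromere
    ("c4", "1", 95000, 99000, "DUP"),  # Q arm
    ("c5", "1", 40000, 41000, "DEL"),  # exact match of a rare DEL record
    ("c6", "1", 20110, 20160, "DEL"),  # abuts the padded exon (half-open)
    ("c7", "1", 25000, 75000, "DEL"),  # spans the centromere, two genes
    ("c8", "1", 19000, 19100, "DUP"),  # promoter-only hit
]

# columns: cent, tel, gc, bp, genes, diseases, exons, promoters, snvs,
#          popmax, phylop, phastcons, hi_3, ts_0, ts_40, hi_idx, pli, loeuf
GOLDEN_VALUES = {
    "c1": (24000, 21000, 0.5, 5000, 1, 2, 0, 0, 1, 0.05, 11.0, 0.4, 2, 1, 1, 2.5, 0.99, 0.1),
    "c2": (29950, 19500, 525 / 550, 550, 1, 2, 1, 1, 0, 0.0, 1.0, 0.4, 1, 0, 1, 2.5, 0.99, 0.1),
    "c3": (0, 42000, 0.5, 3000, 0, 0, 0, 0, 0, 0.0, 1.0, 0.4, 0, 0, 0, 100.0, 0.0, 2.0),
    "c4": (35000, 1000, 0.5, 4000, 0, 0, 0, 0, 0, 0.0, 1.0, 0.4, 0, 0, 0, 100.0, 0.0, 2.0),
    "c5": (9000, 40000, 0.5, 1000, 0, 0, 0, 0, 0, 0.001, 1.0, 0.4, 0, 0, 0, 100.0, 0.0, 2.0),
    "c6": (29840, 20110, 0.5, 50, 1, 2, 0, 0, 0, 0.0, 1.0, 0.4, 1, 0, 1, 2.5, 0.99, 0.1),
    "c7": (0, 25000, 0.5, 50000, 2, 3, 2, 0, 1, 0.0, 1.0, 0.4, 2, 1, 1, 2.5, 0.99, 0.1),
    "c8": (30900, 19000, 1.0, 100, 0, 0, 0, 1, 0, 0.0, 1.0, 0.4, 0, 0, 0, 100.0, 0.0, 2.0),
}


def golden_frame(vocabulary):
    columns = feature_columns(vocabulary)
    rows = {}
    for cid, (cent, tel, gc, bp, genes, dis, ex, prom, snv, pop, phy, pha,
              hi3, ts0, ts40, hidx, pli, loeuf) in GOLDEN_VALUES.items():
        row = dict.fromkeys(columns, 0.0)
        row.update(
            centromere_distance=cent, telomere_distance=tel, gc_content=gc,
            bp_length=bp, gene_count=genes, disease_count=dis, exon_count=ex,
            promoter_count=prom, pathogenic_snv_count=snv, popmax_af=pop,
            phylop_max=phy, phastcons_max=pha, hi_index_min=hidx, pli_max=pli,
            loeuf_min=loeuf,
        )
        row["hi_3"], row["ts_0"], row["ts_40"] = hi3, ts0, ts40
        rows[cid] = row
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)[columns]


def test_feature_matrix_matches_hand_computation(micro_bundle):
    """All 17 features (one-hot expanded) agree with independent hand values."""
    extractor = FeatureExtractor(micro_bundle, FeatureConfig(smoothing_window=1))
    records = [cnv(c, s, e, t, cid) for cid, c, s, e, t in GOLDEN_CNVS]
    got = extractor.extract(records)
    expected = golden_frame(micro_bundle.dosage_vocabulary)
    pd.testing.assert_frame_equal(got, expected, rtol=1e-9, atol=1e-12,
                                  check_names=False)


def test_extraction_deterministic_and_empty(micro_bundle):
    extractor = FeatureExtractor(micro_bundle, FeatureConfig(smoothing_window=1))
    records = [cnv(c, s, e, t, cid) for cid, c, s, e, t in GOLDEN_CNVS[:3]]
    a, b = extractor.extract(records), extractor.extract(records)
    pd.testing.assert_frame_equal(a, b)
    empty = extractor.extract([])
    assert list(empty.columns) == feature_columns(micro_bundle.dosage_vocabulary)
    assert len(empty) == 0


def test_monotone_counts_under_containment(micro_bundle):
    """Enlarging a CNV never decreases count features or bp length."""
    extractor = FeatureExtractor(micro_bundle, FeatureConfig(smoothing_window=1))
    rng = np.random.default_rng(5)
    monotone = ["gene_count", "exon_count", "promoter_count",
                "pathogenic_snv_count", "bp_length", "disease_count"]
    for _ in range(50):
        s = int(rng.integers(0, 90_000))
        e = s + int(rng.integers(100, 9_000))
        grow_l = int(rng.integers(0, min(s, 5_000) + 1))
        grow_r = int(rng.integers(0, 5_000))
        small = extractor.extract_one(cnv("1", s, e, "DEL", "small"))
        big = extractor.extract_one(cnv("1", s - grow_l, e + grow_r, "DEL", "big"))
        for col in monotone:
            assert big[col] >= small[col]


# ---------------------------------------------------------------------------
# transform contract
# ---------------------------------------------------------------------------

def test_transformer_log_list_and_scaling():
    cols = ["gene_count", "gc_content"]
    train = pd.DataFrame({"gene_count": [0, np.e - 1, np.e**2 - 1], "gc_content": [2, 4, 6]})
    t = FeatureTransformer().fit(train)
    out = t.transform(train)
    # gene_count is log1p'd -> [0, 1, 2] -> scaled [0, .5, 1]
    assert np.allclose(out["gene_count"], [0, 0.5, 1])
    # gc_content is not in the log list -> [2,4,6] -> [0, .5, 1]
    assert np.allclose(out["gc_content"], [0, 0.5, 1])


def test_transformer_clamps_and_constant_columns():
    train = pd.DataFrame({"gc_content": [0.2, 0.6], "pli_max": [0.5, 0.5]})
    t = FeatureTransformer().fit(train)
    test = pd.DataFrame({"gc_content": [0.0, 1.0], "pli_max": [0.9, 0.1]})
    out = t.transform(test)
    assert np.allclose(out["gc_content"], [0.0, 1.0])  # clamped
    assert np.allclose(out["pli_max"], [0.0, 0.0])  # constant train column -> 0


def test_transformer_unfitted_raises():
    with pytest.raises(RuntimeError):
        FeatureTransformer().transform(pd.DataFrame({"a": [1.0]}))


def test_log_feature_list_is_the_six_skewed_counts():
    assert set(LOG_FEATURES) == {
        "gene_count", "disease_count", "exon_count", "promoter_count",
        "pathogenic_snv_count", "bp_length",
    }


def test_scaled_study_features_lie_in_unit_interval(study):
    t = FeatureTransformer().fit(study["X_train"])
    out = t.transform(study["X_test"])
    assert (out.to_numpy() >= 0).all() and (out.to_numpy() <= 1).all()
    raw_counts = study["X_train"][list(LOG_FEATURES)].to_numpy()
    assert (raw_counts >= 0).all()
    assert np.allclose(raw_counts, np.round(raw_counts))
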