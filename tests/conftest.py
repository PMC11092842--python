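"""Shared fixtures: a hand-computable micro annotation bundle and a
session-scoped synthetic study (bundle + labelled train/test CNV sets +
trained per-type models) reused across test modules."""

from __future__ import annotations

from pathlib import Path

import pytest

from cnvsig import classifier as clf
from cnvsig.features import FeatureExtractor
from cnvsig.fixtures import FixtureConfig, generate_bundle, generate_labeled_cnvs
from cnvsig.io import load_bundle

# --------------------------------------------------------------------------
# micro bundle: every file written by hand so features can be hand-computed
# --------------------------------------------------------------------------
#
# chromosome "1", length 100,000; p telomere 0, centromere [50000, 60000),
# q telomere 100,000. Sequence: [0,10000) = "AT"..., [10000,20000) = "GC"...,
# [20000,100000) = "ACGT"... so GC content is 0 / 1 / 0.5 by region.
#
# gene G1 '+' [20000,30000), exons [20000,20100) and [29000,29100),
#   promoter [19000,20000), 2 diseases
# gene G2 '-' [70000,80000), exon [75000,75200), promoter [80000,81000),
#   1 disease
# pathogenic SNV at 0-based 25000 (1-based 25001)
# SV records: DEL [20000,30000) af .05/.02; DUP [20000,30000) af .3;
#   DEL [40000,41000) af .001
# phylop: 1.0 everywhere except 11.0 on [22000,22005); phastcons: 0.4
# dosage: R1 [20000,30000) HI=3 TS=40 (2.5, 0.99, 0.1);
#   R2 [25000,35000) HI=3 TS=0 (metrics missing, 0.2, 1.5)


@pytest.fixture(scope="session")
def micro_bundle_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("micro_bundle")
    seq = "AT" * 5000 + "GC" * 5000 + "ACGT" * 20000
    assert len(seq) == 100_000
    with open(d / "genome.fa", "w") as fh:
        fh.write(">1\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    (d / "genes.tsv").write_text(
        "#chrom\tstart\tend\tstrand\tsymbol\texon_starts\texon_ends\n"
        "1\t20000\t30000\t+\tG1\t20000,29000\t20100,29100\n"
        "1\t70000\t80000\t-\tG2\t75000\t75200\n"
    )
    (d / "diseases.tsv").write_text(
        "#symbol\tdisease_id\nG1\tOMIM:1\nG1\tOMIM:2\nG2\tOMIM:3\n"
    )
    (d / "pathogenic_snvs.tsv").write_text(
        "#chrom\tpos\tsignificance\n1\t25001\tPathogenic\n"
    )
    (d / "sv_frequencies.tsv").write_text(
        "#chrom\tstart\tend\tsvtype\taf_global\taf_sub\n"
        "1\t20000\t30000\tDEL\t0.05\t0.02\n"
        "1\t20000\t30000\tDUP\t0.3\t0.1\n"
        "1\t40000\t41000\tDEL\t0.001\t0.0005\n"
    )
    (d / "phylop.bedGraph").write_text(
        "1\t0\t22000\t1.0\n1\t22000\t22005\t11.0\n1\t22005\t100000\t1.0\n"
    )
    (d / "phastcons.bedGraph").write_text("1\t0\t100000\t0.4\n")
    (d / "dosage_regions.tsv").write_text(
        "#chrom\tstart\tend\thi_score\tts_score\thi_index\tpli\tloeuf\n"
        "1\t20000\t30000\t3\t40\t2.5\t0.99\t0.1\n"
        "1\t25000\t35000\t3\t0\t.\t0.2\t1.5\n"
    )
    (d / "chromosome_structure.tsv").write_text(
        "#chrom\tp_telomere\tcentromere_start\tcentromere_end\tq_telomere\n"
        "1\t0\t50000\t60000\t100000\n"
    )
    (d / "bundle.yaml").write_text(
        "genome: genome.fa\ngenes: genes.tsv\ndiseases: diseases.tsv\n"
        "pathogenic_snvs: pathogenic_snvs.tsv\nsv_frequencies: sv_frequencies.tsv\n"
        "phylop: phylop.bedGraph\nphastcons: phastcons.bedGraph\n"
        "dosage_regions: dosage_regions.tsv\nchromosome_structure: chromosome_structure.tsv\n"
    )
    return d


@pytest.fixture(scope="session")
def micro_bundle(micro_bundle_dir):
    return load_bundle(micro_bundle_dir / "bundle.yaml", strict=True)


# --------------------------------------------------------------------------
# session study: generated bundle, train/test CNVs, trained per-type models
# --------------------------------------------------------------------------

STUDY_CONFIG = FixtureConfig(
    seed=3, cnv_counts={"benign": 100, "VUS": 100, "pathogenic": 100}
)
STUDY_ROSTER = ("random_forest", "logistic_regression", "decision_tree")
STUDY_DRAWS = 25
STUDY_FOLDS = 5
STUDY_SEED = 13
TRAIN_CNV_SEED, TEST_CNV_SEED = 5, 6


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Full synthetic study: noiseless train/test sets from the same rule."""
    d = tmp_path_factory.mktemp("study_bundle")
    bundle, manifest = generate_bundle(STUDY_CONFIG, d)
    train_records, train_manifest = generate_labeled_cnvs(
        STUDY_CONFIG, bundle, cnv_seed=TRAIN_CNV_SEED
    )
    test_records, test_manifest = generate_labeled_cnvs(
        STUDY_CONFIG, bundle, cnv_seed=TEST_CNV_SEED
    )
    extractor = FeatureExtractor(bundle)
    X_train = extractor.extract(train_records)
    X_test = extractor.extract(test_records)
    models = {}
    for cnv_type in ("DEL", "DUP"):
        rows = [rec for rec in train_records if rec.cnv_type == cnv_type]
        models[cnv_type] = clf.train_model(
            X_train.loc[[rec.id for rec in rows]],
            [rec.collapsed_label for rec in rows],
            cnv_type,
            roster=STUDY_ROSTER,
            k=STUDY_FOLDS,
            n_draws=STUDY_DRAWS,
            seed=STUDY_SEED,
        )
    return {
        "dir": d,
        "roster": STUDY_ROSTER,
        "draws": STUDY_DRAWS,
        "folds": STUDY_FOLDS,
        "seed": STUDY_SEED,
        "bundle": bundle,
        "manifest": manifest,
        "config": STUDY_CONFIG,
        "train_records": train_records,
        "test_records": test_records,
        "train_manifest": train_manifest,
        "test_manifest": test_manifest,
        "X_train": X_train,
        "X_test": X_test,
        "models": models,
    }
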