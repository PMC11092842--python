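"""The 17-feature panel for CNV clinical-significance classification.

Six feature groups are computed per CNV:

* genomic position — distance to the centromere and to the arm telomere;
* composition — GC fraction and bp length;
* functional annotation — counts of overlapping genes, gene-linked diseases,
  exons (padded by 10 bp for canonical splice regions), promoters (the
  1,000 bp upstream of each TSS), and pathogenic short variants;
* population frequency — the highest population allele frequency among
  type-matched SV records with >= 50% reciprocal overlap ("popmax");
* conservation — the maximum of a centred moving average of per-base PhyloP
  and phastCons scores inside the CNV;
* dosage sensitivity — one-hot counts of categorical haploinsufficiency /
  triplosensitivity evidence scores over overlapping curated regions, plus
  the min HI index, max pLI and min LOEUF among them.

Count features and bp length are log(1+x)-transformed, then every feature is
min-max scaled with statistics fitted on training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cnvsig.intervals import GenomicInterval, OverlapIndex, reciprocal_overlap
from cnvsig.io import (
    AnnotationBundle,
    CNVRecord,
    ChromosomeStructure,
    ConservationTrack,
    DosageRegion,
    SVFrequencyRecord,
)

logger = logging.getLogger(__name__)

#: features that are log(1+x)-transformed before scaling (right-skewed counts)
LOG_FEATURES = (
    "gene_count",
    "disease_count",
    "exon_count",
    "promoter_count",
    "pathogenic_snv_count",
    "bp_length",
)

BASE_COLUMNS = (
    "centromere_distance",
    "telomere_distance",
    "gc_content",
    "bp_length",
    "gene_count",
    "disease_count",
    "exon_count",
    "promoter_count",
    "pathogenic_snv_count",
    "popmax_af",
    "phylop_max",
    "phastcons_max",
)

METRIC_COLUMNS = ("hi_index_min", "pli_max", "loeuf_min")


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature panel.

    ``smoothing_window`` is the centred moving-average width in bp (odd).
    Missing-dosage sentinels sit at the loss-tolerant extreme of each metric
    so that absence of curated evidence reads as tolerance.
    """

    smoothing_window: int = 1001
    exon_pad: int = 10
    promoter_upstream: int = 1000
    reciprocal_overlap_threshold: float = 0.5
    hi_index_sentinel: float = 100.0
    pli_sentinel: float = 0.0
    loeuf_sentinel: float = 2.0
    conservation_sentinel: float = 0.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def feature_columns(vocabulary: Sequence[str]) -> list[str]:
    """The fixed column manifest, with dosage one-hot groups expanded."""
    return (
        list(BASE_COLUMNS)
        + [f"hi_{cat}" for cat in vocabulary]
        + [f"ts_{cat}" for cat in vocabulary]
        + list(METRIC_COLUMNS)
    )


# ---------------------------------------------------------------------------
# individual feature operations
# ---------------------------------------------------------------------------

def positional_distances(cnv: CNVRecord, structure: ChromosomeStructure) -> tuple[int, int]:
    """Distances (bp) from the CNV to the centromere and to the arm telomere.

    The CNV boundary closest to the centromere defines the centromere
    distance (end coordinate on the P arm, start coordinate on the Q arm);
    the boundary furthest from the centromere defines the telomere distance.
    Arm assignment uses the CNV midpoint; a CNV whose midpoint falls inside
    the centromere gets centromere distance 0 and the smaller of the two arm
    telomere distances. Both distances are clamped at 0.
    """
    arms = structure[cnv.interval.chrom]
    start, end = cnv.interval.start, cnv.interval.end
    mid = (start + end) / 2
    p_tel_dist = max(0, start - arms.p_telomere)
    q_tel_dist = max(0, arms.q_telomere - end)
    if mid < arms.centromere.start:  # P arm
        return max(0, arms.centromere.start - end), p_tel_dist
    if mid >= arms.centromere.end:  # Q arm
        return max(0, start - arms.centromere.end), q_tel_dist
    return 0, min(p_tel_dist, q_tel_dist)


def gc_content(cnv: CNVRecord, bundle: AnnotationBundle) -> float:
    """Fraction of called bases (ACGT, case-insensitive) that are G or C."""
    seq = bundle.sequence(cnv.interval).upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        logger.warning("CNV %s: no called bases in interval, GC content set to 0", cnv.id)
        return 0.0
    return gc / acgt


def bp_length(cnv: CNVRecord) -> int:
    return cnv.interval.length


def popmax_frequency(
    cnv: CNVRecord,
    sv_records: Sequence[SVFrequencyRecord],
    ro_threshold: float = 0.5,
) -> float:
    """Highest population AF among type-matched records with sufficient reciprocal overlap."""
    best = 0.0
    for rec in sv_records:
        if rec.sv_type != cnv.cnv_type:
            continue
        if reciprocal_overlap(cnv.interval, rec.interval) >= ro_threshold:
            best = max(best, rec.max_frequency)
    return best


def smoothed_conservation_max(
    cnv: CNVRecord,
    track: ConservationTrack,
    window: int = 1001,
    sentinel: float = 0.0,
) -> float:
    """Maximum of the centred moving average of per-base scores inside the CNV.

    Raw single-base conservation scores are volatile; smoothing with a
    centred window decorrelates the maximum from CNV size. For each base p
    inside the CNV the smoothed value is the mean of the raw scores present
    within ``window`` bases centred on p; bases with no score are excluded
    from the mean. When no score exists anywhere within the CNV plus half a
    window, ``sentinel`` is returned.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    iv = cnv.interval
    raw = track.dense(iv.chrom, iv.start - half, iv.end + half)
    finite = np.isfinite(raw)
    if not finite.any():
        logger.warning("CNV %s: no conservation scores near interval, using sentinel", cnv.id)
        return float(sentinel)
    vals = np.where(finite, raw, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    n = iv.length
    sums = csum[window : window + n] - csum[:n]
    cnts = ccnt[window : window + n] - ccnt[:n]
    with np.errstate(invalid="ignore"):
        smoothed = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    if not np.isfinite(smoothed).any():
        logger.warning("CNV %s: no conservation scores near interval, using sentinel", cnv.id)
        return float(sentinel)
    return float(np.nanmax(smoothed))


def dosage_features(
    cnv: CNVRecord,
    regions: Sequence[DosageRegion],
    vocabulary: Sequence[str],
    config: FeatureConfig | None = None,
) -> tuple[dict[str, int], dict[str, int], float, float, float]:
    """One-hot HI/TS category counts plus min HI index, max pLI, min LOEUF.

    One-hot counts are summed across all overlapping regions. When no region
    overlaps (or a metric is uncurated everywhere), the metric falls back to
    its loss-tolerant sentinel.
    """
    config = config or FeatureConfig()
    hi = {cat: 0 for cat in vocabulary}
    ts = {cat: 0 for cat in vocabulary}
    hi_idx: list[float] = []
    pli: list[float] = []
    loeuf: list[float] = []
    for region in regions:
        hi[region.hi_score] = hi.get(region.hi_score, 0) + 1
        ts[region.ts_score] = ts.get(region.ts_score, 0) + 1
        if region.hi_index is not None:
            hi_idx.append(region.hi_index)
        if region.pli is not None:
            pli.append(region.pli)
        if region.loeuf is not None:
            loeuf.append(region.loeuf)
    return (
        hi,
        ts,
        min(hi_idx) if hi_idx else config.hi_index_sentinel,
        max(pli) if pli else config.pli_sentinel,
        min(loeuf) if loeuf else config.loeuf_sentinel,
    )


# ---------------------------------------------------------------------------
# bundle-wide extractor
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Computes the full feature matrix for CNV lists against one bundle.

    Overlap indexes are built once per bundle; extraction is deterministic
    given identical inputs.
    """

    def __init__(self, bundle: AnnotationBundle, config: FeatureConfig | None = None):
        self.bundle = bundle
        self.config = config or FeatureConfig()
        cfg = self.config
        self._gene_index = OverlapIndex(
            [g.interval for g in bundle.genes], bundle.genes
        )
        exon_ivs, exon_payloads = [], []
        for gene in bundle.genes:
            for exon in gene.exons:
                padded = GenomicInterval(
                    exon.chrom, max(0, exon.start - cfg.exon_pad), exon.end + cfg.exon_pad, exon.strand
                )
                exon_ivs.append(padded)
                exon_payloads.append(gene.symbol)
        self._exon_index = OverlapIndex(exon_ivs, exon_payloads)
        promoters = [g.promoter(cfg.promoter_upstream) for g in bundle.genes]
        self._promoter_index = OverlapIndex(promoters, [g.symbol for g in bundle.genes])
        self._dosage_index = OverlapIndex(
            [r.interval for r in bundle.dosage_regions], bundle.dosage_regions
        )
        self._sv_by_type: dict[str, OverlapIndex] = {}
        for sv_type in ("DEL", "DUP"):
            recs = [r for r in bundle.sv_frequencies if r.sv_type == sv_type]
            self._sv_by_type[sv_type] = OverlapIndex([r.interval for r in recs], recs)

    # -- composite operations ------------------------------------------------

    def functional_counts(self, cnv: CNVRecord) -> tuple[int, int, int, int, int]:
        """(gene, disease, exon, promoter, pathogenic SNV) overlap counts."""
        genes = self._gene_index.query(cnv.interval)
        gene_count = len(genes)
        disease_count = sum(len(self.bundle.diseases.get(g.symbol, ())) for g in genes)
        exon_count = self._exon_index.query_count(cnv.interval)
        promoter_count = self._promoter_index.query_count(cnv.interval)
        snvs = self.bundle.pathogenic_snvs.get(cnv.interval.chrom)
        if snvs is None:
            snv_count = 0
        else:
            snv_count = int(
                np.searchsorted(snvs, cnv.interval.end, side="left")
                - np.searchsorted(snvs, cnv.interval.start, side="left")
            )
        return gene_count, disease_count, exon_count, promoter_count, snv_count

    def popmax_frequency(self, cnv: CNVRecord) -> float:
        candidates = self._sv_by_type[cnv.cnv_type].query(cnv.interval)
        return popmax_frequency(cnv, candidates, self.config.reciprocal_overlap_threshold)

    def dosage_features(self, cnv: CNVRecord):
        regions = self._dosage_index.query(cnv.interval)
        return dosage_features(cnv, regions, self.bundle.dosage_vocabulary, self.config)

    def extract_one(self, cnv: CNVRecord) -> dict[str, float]:
        cfg = self.config
        cent, tel = positional_distances(cnv, self.bundle.chromosome_structure)
        genes, diseases, exons, promoters, snvs = self.functional_counts(cnv)
        hi, ts, hi_index_min, pli_max, loeuf_min = self.dosage_features(cnv)
        row: dict[str, float] = {
            "centromere_distance": cent,
            "telomere_distance": tel,
            "gc_content": gc_content(cnv, self.bundle) if self.bundle.genome is not None else 0.0,
            "bp_length": bp_length(cnv),
            "gene_count": genes,
            "disease_count": diseases,
            "exon_count": exons,
            "promoter_count": promoters,
            "pathogenic_snv_count": snvs,
            "popmax_af": self.popmax_frequency(cnv),
            "phylop_max": smoothed_conservation_max(
                cnv, self.bundle.phylop, cfg.smoothing_window, cfg.conservation_sentinel
            ),
            "phastcons_max": smoothed_conservation_max(
                cnv, self.bundle.phastcons, cfg.smoothing_window, cfg.conservation_sentinel
            ),
        }
        for cat in self.bundle.dosage_vocabulary:
            row[f"hi_{cat}"] = hi.get(cat, 0)
            row[f"ts_{cat}"] = ts.get(cat, 0)
        row["hi_index_min"] = hi_index_min
        row["pli_max"] = pli_max
        row["loeuf_min"] = loeuf_min
        return row

    def extract(self, cnvs: Sequence[CNVRecord]) -> pd.DataFrame:
        """Feature matrix: one row per CNV, columns per the fixed manifest."""
        columns = feature_columns(self.bundle.dosage_vocabulary)
        rows, index = [], []
        for cnv in cnvs:
            try:
                rows.append(self.extract_one(cnv))
            except Exception as exc:
                raise RuntimeError(f"feature extraction failed for CNV {cnv.id!r}: {exc}") from exc
            index.append(cnv.id)
        frame = pd.DataFrame(rows, index=index, columns=columns, dtype=float)
        return frame


def extract_features(
    cnvs: Sequence[CNVRecord],
    bundle: AnnotationBundle,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Convenience wrapper building a :class:`FeatureExtractor` once."""
    return FeatureExtractor(bundle, config).extract(cnvs)


# ---------------------------------------------------------------------------
# transform contract
# ---------------------------------------------------------------------------

class FeatureTransformer:
    """log1p on the skewed count features, then train-fitted min-max scaling.

    Scaling statistics come from training rows only; transformed test values
    are clamped to [0, 1] so that the scaler's behaviour outside the train
    range is defined. A constant training column maps to 0.
    """

    def __init__(self, log_features: Sequence[str] = LOG_FEATURES):
        self.log_features = tuple(log_features)
        self.mins_: pd.Series | None = None
        self.maxs_: pd.Series | None = None

    @property
    def fitted(self) -> bool:
        return self.mins_ is not None

    def _log(self, frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.astype(float).copy()
        present = [c for c in self.log_features if c in frame.columns]
        frame[present] = np.log1p(frame[present])
        return frame

    def fit(self, train: pd.DataFrame) -> "FeatureTransformer":
        logged = self._log(train)
        self.mins_ = logged.min(axis=0)
        self.maxs_ = logged.max(axis=0)
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("FeatureTransformer must be fitted before use")
        logged = self._log(frame)
        span = (self.maxs_ - self.mins_).replace(0.0, np.nan)
        scaled = (logged - self.mins_) / span
        scaled = scaled.fillna(0.0)  # constant training columns map to 0
        # pandas alignment may reorder columns; keep the caller's order
        return scaled.clip(0.0, 1.0)[list(frame.columns)]

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)

    # -- JSON sidecar ---------------------------------------------------------

    def to_dict(self) -> dict:
        if not self.fitted:
            raise RuntimeError("cannot serialize an unfitted transformer")
        return {
            "log_features": list(self.log_features),
            "mins": {k: float(v) for k, v in self.mins_.items()},
            "maxs": {k: float(v) for k, v in self.maxs_.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureTransformer":
        t = cls(log_features=data["log_features"])
        t.mins_ = pd.Series(data["mins"], dtype=float)
        t.maxs_ = pd.Series(data["maxs"], dtype=float)
        return t
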