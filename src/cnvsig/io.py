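"""Readers and writers for CNV call sets and annotation resources.

All resources are plain-text, tab-delimited (or FASTA / VCF / bedGraph /
fixed-step wiggle) so that an annotation bundle can be version-controlled and
regenerated deterministically. Coordinates are converted to the package's
internal 0-based half-open convention at the reader boundary; chromosome
names are normalized (no ``chr`` prefix).

Tabular schemas (header line starts with ``#``, columns tab-separated):

* CNVs: ``chrom  start  end  type  [id]  [labels]`` — ``type`` is DEL/DUP,
  ``labels`` a ``;``-separated list of submitted significance strings.
* genes: ``chrom  start  end  strand  symbol  exon_starts  exon_ends`` with
  comma-separated exon coordinate lists.
* diseases: ``symbol  disease_id`` (one association per row).
* pathogenic SNVs (TSV form): ``chrom  pos  significance`` with 1-based
  ``pos``; rows are kept when significance is Pathogenic / Likely pathogenic.
* SV frequencies: ``chrom  start  end  svtype  af_<population>...``.
* dosage regions: ``chrom  start  end  hi_score  ts_score  hi_index  pli
  loeuf`` (``.`` marks a missing metric).
* chromosome structure: ``chrom  p_telomere  centromere_start
  centromere_end  q_telomere``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
import yaml
from pyfaidx import Fasta

from cnvsig.intervals import GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

#: default categorical vocabulary for ClinGen-style dosage evidence scores
DEFAULT_DOSAGE_VOCABULARY = ("0", "1", "2", "3", "30", "40", "not_evaluated")

PATHOGENIC_SNV_LABELS = {"pathogenic", "likely pathogenic", "likely_pathogenic"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CNVRecord:
    """One CNV call: an interval plus type and (optionally) significance labels."""

    interval: GenomicInterval
    cnv_type: str  # DEL or DUP
    id: str = ""
    labels: list[str] | None = None
    collapsed_label: str | None = None  # set by curation only

    def __post_init__(self) -> None:
        if self.cnv_type not in ("DEL", "DUP"):
            raise ValueError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Identity key used for duplicate detection and leakage guards."""
        return (self.interval.chrom, self.interval.start, self.interval.end, self.cnv_type)


@dataclass
class GeneModel:
    """A gene span with strand, exons and the derived TSS / promoter."""

    interval: GenomicInterval
    symbol: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.symbol} must be stranded")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene span of {self.symbol}")

    @property
    def tss(self) -> int:
        """Transcription start boundary: gene start on '+', gene end on '-'."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    def promoter(self, upstream: int = 1000) -> GenomicInterval:
        """The ``upstream`` bases immediately 5' of the TSS on the gene's strand."""
        if self.interval.strand == "+":
            start = max(0, self.tss - upstream)
            end = max(start + 1, self.tss)
        else:
            start = self.tss
            end = self.tss + upstream
        return GenomicInterval(self.interval.chrom, start, end, self.interval.strand)


@dataclass
class SVFrequencyRecord:
    """A population SV record (deletion or duplication) with per-population AFs."""

    interval: GenomicInterval
    sv_type: str
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "DUP"):
            raise ValueError(f"sv_type must be DEL or DUP, got {self.sv_type!r}")
        for pop, af in self.frequencies.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for {pop} outside [0,1]: {af}")

    @property
    def max_frequency(self) -> float:
        return max(self.frequencies.values()) if self.frequencies else 0.0


@dataclass
class DosageRegion:
    """A curated dosage-sensitive region with categorical evidence scores.

    ``hi_score`` / ``ts_score`` are categorical evidence levels
    (haploinsufficiency / triplosensitivity); ``hi_index``, ``pli`` and
    ``loeuf`` are per-gene loss-of-function intolerance metrics and may be
    missing (``None``).
    """

    interval: GenomicInterval
    hi_score: str
    ts_score: str
    hi_index: float | None = None
    pli: float | None = None
    loeuf: float | None = None


class ConservationTrack:
    """Per-base conservation scores stored as sorted non-overlapping runs.

    Supports dense extraction over a window with NaN at uncovered bases,
    which is what the moving-average smoother consumes.
    """

    def __init__(self) -> None:
        # chrom -> (starts, ends, values) as parallel numpy arrays
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._pending: dict[str, list[tuple[int, int, float]]] = {}

    def add_run(self, chrom: str, start: int, end: int, value: float) -> None:
        if end <= start:
            raise ValueError(f"empty run [{start},{end}) on {chrom}")
        self._pending.setdefault(chrom, []).append((start, end, value))

    def finalize(self) -> "ConservationTrack":
        for chrom, runs in self._pending.items():
            runs.sort()
            starts = np.array([r[0] for r in runs], dtype=np.int64)
            ends = np.array([r[1] for r in runs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping conservation runs on {chrom}")
            values = np.array([r[2] for r in runs], dtype=np.float64)
            self._runs[chrom] = (starts, ends, values)
        self._pending.clear()
        return self

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._runs)

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for every base in ``[start, end)``; NaN where uncovered."""
        out = np.full(end - start, np.nan)
        runs = self._runs.get(chrom)
        if runs is None:
            return out
        starts, ends, values = runs
        lo = int(np.searchsorted(ends, start, side="right"))  # first run ending after start
        hi = int(np.searchsorted(starts, end, side="left"))  # first run starting at/after end
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out


@dataclass
class ChromosomeArms:
    """Telomere and centromere anchors for one chromosome."""

    p_telomere: int
    centromere: GenomicInterval
    q_telomere: int

    def __post_init__(self) -> None:
        if not (self.p_telomere < self.centromere.start <= self.centromere.end < self.q_telomere):
            raise ValueError("require p_telomere < centromere <= q_telomere ordering")


@dataclass
class ChromosomeStructure:
    arms: dict[str, ChromosomeArms]

    def __getitem__(self, chrom: str) -> ChromosomeArms:
        try:
            return self.arms[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} absent from structure table") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.arms


@dataclass
class AnnotationBundle:
    """Every loaded annotation resource, indexed by normalized chromosome names."""

    genes: list[GeneModel]
    diseases: dict[str, set[str]]  # gene symbol -> disease IDs
    pathogenic_snvs: dict[str, np.ndarray]  # chrom -> sorted 0-based positions
    sv_frequencies: list[SVFrequencyRecord]
    phylop: ConservationTrack
    phastcons: ConservationTrack
    dosage_regions: list[DosageRegion]
    chromosome_structure: ChromosomeStructure
    genome: Fasta | None = None
    dosage_vocabulary: tuple[str, ...] = DEFAULT_DOSAGE_VOCABULARY

    def sequence(self, interval: GenomicInterval) -> str:
        if self.genome is None:
            raise ValueError("bundle has no genome sequence")
        return str(self.genome[interval.chrom][interval.start:interval.end])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _data_rows(path: str | Path):
    """Yield (line_number, fields) for non-comment, non-blank TSV rows."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what}: {value!r}") from None


# ---------------------------------------------------------------------------
# CNV call sets
# ---------------------------------------------------------------------------

def read_cnvs_detailed(
    path: str | Path,
    format: str = "bed-tsv",
    known_chroms: set[str] | None = None,
) -> tuple[list[CNVRecord], dict[str, int]]:
    """Read CNVs, returning records plus a tally of skipped rows.

    The report counts ``skipped_type`` (records that are not deletions or
    duplications, e.g. inversions) and ``skipped_chrom`` (records on
    chromosomes absent from ``known_chroms`` when one is supplied).
    """
    report = {"read": 0, "skipped_type": 0, "skipped_chrom": 0}
    records: list[CNVRecord] = []
    if format == "bed-tsv":
        for lineno, fields in _data_rows(path):
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            chrom = normalize_chrom(fields[0])
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            cnv_type = fields[3].strip().upper()
            if cnv_type not in ("DEL", "DUP"):
                report["skipped_type"] += 1
                continue
            if known_chroms is not None and chrom not in known_chroms:
                logger.warning("%s:%d: unknown chromosome %s, record skipped", path, lineno, chrom)
                report["skipped_chrom"] += 1
                continue
            rid = fields[4] if len(fields) > 4 and fields[4] else f"cnv_{lineno}"
            labels = None
            if len(fields) > 5 and fields[5]:
                labels = [tok for tok in fields[5].split(";") if tok]
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(CNVRecord(iv, cnv_type, rid, labels))
            report["read"] += 1
    elif format == "vcf":
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                svtype = rec.info.get("SVTYPE")
                if svtype not in ("DEL", "DUP"):
                    report["skipped_type"] += 1
                    continue
                chrom = normalize_chrom(rec.chrom)
                if known_chroms is not None and chrom not in known_chroms:
                    logger.warning("unknown chromosome %s in %s, record skipped", chrom, path)
                    report["skipped_chrom"] += 1
                    continue
                # pysam exposes 0-based start and the END tag as stop
                iv = GenomicInterval(chrom, rec.start, rec.stop)
                records.append(CNVRecord(iv, svtype, rec.id or f"cnv_{report['read'] + 1}"))
                report["read"] += 1
    else:
        raise ValueError(f"unknown CNV format {format!r} (expected 'bed-tsv' or 'vcf')")
    if report["skipped_type"]:
        logger.info("%s: skipped %d non-DEL/DUP records", path, report["skipped_type"])
    return records, report


def read_cnvs(path: str | Path, format: str = "bed-tsv", known_chroms: set[str] | None = None) -> list[CNVRecord]:
    records, _ = read_cnvs_detailed(path, format=format, known_chroms=known_chroms)
    return records


def write_cnvs(records: Iterable[CNVRecord], path: str | Path) -> None:
    """Write CNVs to the tab-separated schema accepted by :func:`read_cnvs`."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\tid\tlabels\n")
        for rec in records:
            labels = ";".join(rec.labels) if rec.labels else ""
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}\t"
                f"{rec.cnv_type}\t{rec.id}\t{labels}\n"
            )


# ---------------------------------------------------------------------------
# annotation resources
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[GeneModel]:
    genes = []
    for lineno, fields in _data_rows(path):
        if len(fields) < 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns for gene rows")
        chrom = normalize_chrom(fields[0])
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        strand, symbol = fields[3], fields[4]
        exon_starts = [int(x) for x in fields[5].split(",") if x]
        exon_ends = [int(x) for x in fields[6].split(",") if x]
        if len(exon_starts) != len(exon_ends):
            raise ValueError(f"{path}:{lineno}: exon_starts / exon_ends length mismatch")
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in zip(exon_starts, exon_ends)]
        genes.append(GeneModel(GenomicInterval(chrom, start, end, strand), symbol, exons))
    return genes


def read_diseases(path: str | Path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns (symbol, disease_id)")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def read_pathogenic_snvs(path: str | Path, format: str = "tsv") -> dict[str, np.ndarray]:
    """Positions (0-based) of pathogenic / likely-pathogenic short variants."""
    positions: dict[str, list[int]] = {}
    if format == "tsv":
        for lineno, fields in _data_rows(path):
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns (chrom, pos)")
            if len(fields) > 2 and fields[2].strip().lower() not in PATHOGENIC_SNV_LABELS:
                continue
            chrom = normalize_chrom(fields[0])
            pos = _parse_int(fields[1], path, lineno, "position") - 1  # 1-based input
            positions.setdefault(chrom, []).append(pos)
    elif format == "vcf":
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                sig = rec.info.get("CLNSIG")
                if sig is not None:
                    sig_txt = sig if isinstance(sig, str) else ";".join(sig)
                    if sig_txt.replace("_", " ").strip().lower() not in PATHOGENIC_SNV_LABELS:
                        continue
                positions.setdefault(normalize_chrom(rec.chrom), []).append(rec.start)
    else:
        raise ValueError(f"unknown SNV format {format!r}")
    return {chrom: np.array(sorted(pos), dtype=np.int64) for chrom, pos in positions.items()}


def read_sv_frequencies(path: str | Path) -> list[SVFrequencyRecord]:
    records = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            fields = line.split("\t")
            if header is None or len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: row does not match header")
            row = dict(zip(header, fields))
            freqs = {
                col[3:]: float(row[col])
                for col in header
                if col.startswith("af_") and row[col] not in ("", ".")
            }
            records.append(
                SVFrequencyRecord(
                    GenomicInterval(
                        normalize_chrom(row["chrom"]), int(row["start"]), int(row["end"])
                    ),
                    row["svtype"].upper(),
                    freqs,
                )
            )
    return records


def read_conservation(path: str | Path) -> ConservationTrack:
    """Parse a bedGraph or fixed-step wiggle file into a conservation track."""
    track = ConservationTrack()
    with open(path) as fh:
        chrom = None
        pos = step = span = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = dict(tok.split("=") for tok in line.split()[1:])
                chrom = normalize_chrom(params["chrom"])
                pos = int(params["start"]) - 1  # wiggle is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) >= 4:  # bedGraph row
                track.add_run(
                    normalize_chrom(fields[0]), int(fields[1]), int(fields[2]), float(fields[3])
                )
            elif len(fields) == 1 and chrom is not None:  # fixedStep value
                track.add_run(chrom, pos, pos + span, float(fields[0]))
                pos += step
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized conservation row")
    return track.finalize()


def read_dosage_regions(
    path: str | Path,
    vocabulary: Sequence[str] = DEFAULT_DOSAGE_VOCABULARY,
    strict: bool = False,
) -> tuple[list[DosageRegion], tuple[str, ...]]:
    """Read the dosage-sensitivity table.

    Unknown categorical scores are appended to the vocabulary with a warning
    unless ``strict`` is set, in which case they raise. Returns the regions
    plus the (possibly extended) vocabulary actually in effect.
    """
    vocab = list(vocabulary)
    regions = []

    def _check(cat: str, lineno: int) -> str:
        if cat not in vocab:
            if strict:
                raise ValueError(f"{path}:{lineno}: unknown dosage category {cat!r}")
            logger.warning("%s:%d: unknown dosage category %r retained", path, lineno, cat)
            vocab.append(cat)
        return cat

    def _metric(value: str) -> float | None:
        return None if value in (".", "", "NA") else float(value)

    for lineno, fields in _data_rows(path):
        if len(fields) < 8:
            raise ValueError(f"{path}:{lineno}: expected 8 columns for dosage rows")
        regions.append(
            DosageRegion(
                GenomicInterval(normalize_chrom(fields[0]), int(fields[1]), int(fields[2])),
                _check(fields[3], lineno),
                _check(fields[4], lineno),
                _metric(fields[5]),
                _metric(fields[6]),
                _metric(fields[7]),
            )
        )
    return regions, tuple(vocab)


def read_chromosome_structure(path: str | Path) -> ChromosomeStructure:
    arms = {}
    for lineno, fields in _data_rows(path):
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns for structure rows")
        chrom = normalize_chrom(fields[0])
        arms[chrom] = ChromosomeArms(
            int(fields[1]),
            GenomicInterval(chrom, int(fields[2]), int(fields[3])),
            int(fields[4]),
        )
    return ChromosomeStructure(arms)


REQUIRED_BUNDLE_KEYS = (
    "genes",
    "diseases",
    "pathogenic_snvs",
    "sv_frequencies",
    "phylop",
    "phastcons",
    "dosage_regions",
    "chromosome_structure",
)


def load_bundle(
    config: Mapping[str, str] | str | Path,
    strict: bool = False,
    vocabulary: Sequence[str] = DEFAULT_DOSAGE_VOCABULARY,
) -> AnnotationBundle:
    """Assemble an :class:`AnnotationBundle` from a path-map config.

    ``config`` is either a mapping of resource name to file path or the path
    of a YAML file holding one (paths then resolve relative to the YAML's
    directory). ``genome`` (FASTA) is optional but required for GC content.
    """
    base = Path(".")
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        base = cfg_path.parent
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    missing = [key for key in REQUIRED_BUNDLE_KEYS if key not in config]
    if missing:
        raise ValueError(f"bundle config missing required resources: {', '.join(missing)}")

    def _p(key: str) -> Path:
        return base / config[key]

    genes = read_genes(_p("genes"))
    diseases = read_diseases(_p("diseases"))
    snvs = read_pathogenic_snvs(_p("pathogenic_snvs"), format=str(config.get("pathogenic_snvs_format", "tsv")))
    sv_freq = read_sv_frequencies(_p("sv_frequencies"))
    phylop = read_conservation(_p("phylop"))
    phastcons = read_conservation(_p("phastcons"))
    dosage, vocab = read_dosage_regions(_p("dosage_regions"), vocabulary=vocabulary, strict=strict)
    structure = read_chromosome_structure(_p("chromosome_structure"))
    genome = Fasta(str(_p("genome"))) if "genome" in config else None

    logger.info(
        "bundle loaded: %d genes, %d disease-linked genes, %d SNV chroms, %d SV records, %d dosage regions",
        len(genes), len(diseases), len(snvs), len(sv_freq), len(dosage),
    )
    return AnnotationBundle(
        genes=genes,
        diseases=diseases,
        pathogenic_snvs=snvs,
        sv_frequencies=sv_freq,
        phylop=phylop,
        phastcons=phastcons,
        dosage_regions=dosage,
        chromosome_structure=structure,
        genome=genome,
        dosage_vocabulary=vocab,
    )
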