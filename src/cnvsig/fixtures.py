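"""Self-contained synthetic annotation bundles and labelled CNV sets.

The generator emits every resource the pipeline consumes — genome FASTA with
position-varying GC, stranded gene models with exons, a disease map,
pathogenic short variants clustered in dosage-sensitive regions, population
SV frequency records, conservation tracks with bumps over exons, a
dosage-region table and a chromosome-structure table — all as plain-text
files that round-trip through the package's readers.

Labels follow a known generative rule over in-scope features only:

* pathogenic iff the CNV overlaps a dosage region with haploinsufficiency
  evidence category "3", or overlaps at least ``exon_threshold`` exons while
  rarer than ``af_threshold`` in the population records;
* benign iff shorter than ``benign_max_length``, at population frequency
  >= ``af_threshold`` and touching no exon;
* VUS otherwise.

Each observed label is then flipped to a uniformly chosen other class with
probability ``label_noise``; the pre-noise rule label is kept in the
manifest as ground truth. Bundle generation and CNV generation take
independent seeds so train/test sets can share annotations without sharing
variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from cnvsig.features import FeatureConfig, FeatureExtractor
from cnvsig.intervals import GenomicInterval
from cnvsig.io import AnnotationBundle, CNVRecord, load_bundle, write_cnvs

CLASSES = ("benign", "VUS", "pathogenic")


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic bundle and CNV sets."""

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 500_000
    n_genes: int = 90
    exons_per_gene: tuple[int, int] = (2, 9)
    gene_length: tuple[int, int] = (3_000, 12_000)
    dosage_fraction: float = 0.3  # fraction of genes with a curated dosage region
    hi3_fraction: float = 0.35  # fraction of dosage regions with HI category "3"
    n_sv_records: int = 150
    n_common_sv: int = 40  # short, intergenic, high-AF records (benign scaffold)
    conservation_bump_height: float = 5.0
    conservation_bumps_per_chrom: int = 12
    cnv_counts: dict = field(default_factory=lambda: {"benign": 100, "VUS": 100, "pathogenic": 100})
    label_noise: float = 0.0
    # generative-rule parameters
    exon_threshold: int = 8
    af_threshold: float = 0.01
    benign_max_length: int = 2_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for name in ("n_chromosomes", "chromosome_length", "n_genes", "n_sv_records"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _chrom_names(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def _write_fasta(path: Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def generate_bundle(config: FixtureConfig, out_dir: str | Path) -> tuple[AnnotationBundle, dict]:
    """Write a complete annotation bundle under ``out_dir``; return it loaded.

    Output is byte-identical for a fixed config (fixed RNG call order, fixed
    float formatting). Raises when the requested gene count exceeds what the
    chromosome arms can hold at the configured gene lengths.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chroms = _chrom_names(config.n_chromosomes)
    L = config.chromosome_length
    cen_start, cen_end = int(L * 0.45), int(L * 0.55)
    arms = [(5_000, cen_start - 5_000), (cen_end + 5_000, L - 5_000)]

    # --- capacity check: genes are laid out on per-arm grids -----------------
    per_chrom = int(np.ceil(config.n_genes / max(1, config.n_chromosomes)))
    per_arm = int(np.ceil(per_chrom / 2))
    max_gene_len = config.gene_length[1]
    for arm_start, arm_end in arms:
        if per_arm * (max_gene_len + 2_000) > arm_end - arm_start:
            raise ValueError(
                f"cannot place {per_arm} genes of up to {max_gene_len} bp on a "
                f"{arm_end - arm_start} bp arm; reduce n_genes or gene_length"
            )

    # --- genome with position-varying GC -------------------------------------
    sequences = {}
    for ci, chrom in enumerate(chroms):
        # GC probability oscillates along the chromosome between ~0.30 and ~0.60
        pos = np.arange(L)
        gc_prob = 0.45 + 0.15 * np.sin(2 * np.pi * pos / 80_000 + ci)
        is_gc = rng.random(L) < gc_prob
        pick = rng.random(L) < 0.5
        bases = np.where(is_gc, np.where(pick, "G", "C"), np.where(pick, "A", "T"))
        sequences[chrom] = "".join(bases.tolist())
    _write_fasta(out / "genome.fa", sequences)

    # --- gene models ----------------------------------------------------------
    gene_rows = []
    disease_rows = []
    gene_count = 0
    for chrom in chroms:
        placed = 0
        for arm_start, arm_end in arms:
            slots = np.linspace(arm_start, arm_end - max_gene_len, per_arm, dtype=int)
            for slot in slots:
                if gene_count >= config.n_genes or placed >= per_chrom:
                    break
                glen = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
                gstart = int(slot + rng.integers(0, 1_000))
                gend = gstart + glen
                strand = "+" if rng.random() < 0.5 else "-"
                symbol = f"GENE{gene_count + 1:03d}"
                n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
                # exon grid inside the gene span, non-overlapping
                bounds = np.linspace(gstart, gend, n_exons + 1, dtype=int)
                ex_starts, ex_ends = [], []
                for k in range(n_exons):
                    seg_start, seg_end = int(bounds[k]), int(bounds[k + 1])
                    width = max(60, int((seg_end - seg_start) * 0.3))
                    es = seg_start + int(rng.integers(0, max(1, seg_end - seg_start - width)))
                    ex_starts.append(es)
                    ex_ends.append(min(seg_end, es + width))
                gene_rows.append(
                    (chrom, gstart, gend, strand, symbol,
                     ",".join(map(str, ex_starts)), ",".join(map(str, ex_ends)))
                )
                for d in range(int(rng.integers(0, 5))):
                    disease_rows.append((symbol, f"OMIM:{600000 + gene_count * 10 + d}"))
                gene_count += 1
                placed += 1

    with open(out / "genes.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tsymbol\texon_starts\texon_ends\n")
        for row in gene_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(out / "diseases.tsv", "w") as fh:
        fh.write("#symbol\tdisease_id\n")
        for row in disease_rows:
            fh.write("\t".join(row) + "\n")

    # --- dosage regions (subset of genes) + clustered pathogenic SNVs ---------
    n_dosage = int(round(config.dosage_fraction * len(gene_rows)))
    dosage_idx = sorted(rng.choice(len(gene_rows), size=n_dosage, replace=False).tolist())
    dosage_rows = []
    snv_rows = []
    categories = ["0", "1", "2", "30", "40", "not_evaluated"]
    for j, gi in enumerate(dosage_idx):
        chrom, gstart, gend = gene_rows[gi][0], gene_rows[gi][1], gene_rows[gi][2]
        is_hi3 = rng.random() < config.hi3_fraction
        hi = "3" if is_hi3 else categories[int(rng.integers(0, len(categories)))]
        ts = categories[int(rng.integers(0, len(categories)))] if rng.random() < 0.8 else "3"
        if hi == "3":
            hi_index = float(rng.uniform(0.5, 10.0))
            pli = float(rng.uniform(0.9, 1.0))
            loeuf = float(rng.uniform(0.05, 0.35))
        else:
            hi_index = float(rng.uniform(20.0, 95.0))
            pli = float(rng.uniform(0.0, 0.6))
            loeuf = float(rng.uniform(0.5, 1.8))
        missing = rng.random() < 0.1
        dosage_rows.append(
            (chrom, gstart, gend, hi, ts,
             "." if missing else f"{hi_index:.4f}", f"{pli:.4f}", f"{loeuf:.4f}")
        )
        # pathogenic SNVs cluster inside haploinsufficient regions
        n_snv = int(rng.poisson(12 if hi == "3" else 2))
        for _ in range(n_snv):
            pos = int(rng.integers(gstart, gend))
            snv_rows.append((chrom, pos + 1, "Pathogenic"))  # 1-based in the table
    # sparse background SNVs
    for chrom in chroms:
        for _ in range(10):
            snv_rows.append((chrom, int(rng.integers(1, L)), "Likely pathogenic"))
    snv_rows.sort()

    with open(out / "dosage_regions.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\thi_score\tts_score\thi_index\tpli\tloeuf\n")
        for row in dosage_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(out / "pathogenic_snvs.tsv", "w") as fh:
        fh.write("#chrom\tpos\tsignificance\n")
        for row in snv_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    # --- SV population-frequency records --------------------------------------
    # exon-free intergenic gaps host the common (high-AF) records
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for row in gene_rows:
        gene_spans[row[0]].append((row[1] - 1_500, row[2] + 1_500))
    sv_rows = []
    n_common = min(config.n_common_sv, config.n_sv_records)
    made_common = 0
    while made_common < n_common:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(200, max(201, config.benign_max_length - 400)))
        start = int(rng.integers(5_000, L - length - 5_000))
        if any(s < start + length and start < e for s, e in gene_spans[chrom]):
            continue
        svtype = "DEL" if rng.random() < 0.5 else "DUP"
        af = float(rng.uniform(config.af_threshold * 3, 0.3))
        sv_rows.append((chrom, start, start + length, svtype,
                        f"{af:.5f}", f"{af * rng.uniform(0.3, 1.0):.5f}"))
        made_common += 1
    for _ in range(config.n_sv_records - n_common):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(500, 30_000))
        start = int(rng.integers(5_000, L - length - 5_000))
        svtype = "DEL" if rng.random() < 0.5 else "DUP"
        af = float(rng.uniform(0.0, config.af_threshold * 0.5))
        sv_rows.append((chrom, start, start + length, svtype,
                        f"{af:.5f}", f"{af * rng.uniform(0.3, 1.0):.5f}"))
    with open(out / "sv_frequencies.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tsvtype\taf_global\taf_sub\n")
        for row in sv_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    # --- conservation tracks (background runs + bumps over exons) --------------
    exon_list: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for row in gene_rows:
        starts = [int(x) for x in row[5].split(",")]
        ends = [int(x) for x in row[6].split(",")]
        exon_list[row[0]].extend(zip(starts, ends))
    chunk = 250
    for name, low, high, bump_hi in (
        ("phylop", -1.5, 1.0, config.conservation_bump_height),
        ("phastcons", 0.0, 0.25, 0.95),
    ):
        with open(out / f"{name}.bedGraph", "w") as fh:
            for chrom in chroms:
                exons = sorted(exon_list[chrom])
                bumps: list[tuple[int, int, float]] = []
                if exons:
                    n_bumps = min(config.conservation_bumps_per_chrom, len(exons))
                    chosen = sorted(rng.choice(len(exons), size=n_bumps, replace=False).tolist())
                    bumps = [
                        (exons[k][0], exons[k][1], float(bump_hi * rng.uniform(0.7, 1.0)))
                        for k in chosen
                    ]
                for start in range(0, L, chunk):
                    value = float(rng.uniform(low, high))
                    pieces = [(start, min(start + chunk, L), value)]
                    for bs, be, bv in bumps:
                        split = []
                        for ps, pe, pv in pieces:
                            if be <= ps or bs >= pe:
                                split.append((ps, pe, pv))
                                continue
                            if ps < bs:
                                split.append((ps, bs, pv))
                            split.append((max(ps, bs), min(pe, be), bv))
                            if be < pe:
                                split.append((be, pe, pv))
                        pieces = split
                    for ps, pe, pv in pieces:
                        if pe > ps:
                            fh.write(f"{chrom}\t{ps}\t{pe}\t{pv:.4f}\n")

    # --- chromosome structure ---------------------------------------------------
    with open(out / "chromosome_structure.tsv", "w") as fh:
        fh.write("#chrom\tp_telomere\tcentromere_start\tcentromere_end\tq_telomere\n")
        for chrom in chroms:
            fh.write(f"{chrom}\t0\t{cen_start}\t{cen_end}\t{L}\n")

    # --- bundle config + manifest -------------------------------------------------
    bundle_cfg = {
        "genome": "genome.fa",
        "genes": "genes.tsv",
        "diseases": "diseases.tsv",
        "pathogenic_snvs": "pathogenic_snvs.tsv",
        "sv_frequencies": "sv_frequencies.tsv",
        "phylop": "phylop.bedGraph",
        "phastcons": "phastcons.bedGraph",
        "dosage_regions": "dosage_regions.tsv",
        "chromosome_structure": "chromosome_structure.tsv",
    }
    with open(out / "bundle.yaml", "w") as fh:
        yaml.safe_dump(bundle_cfg, fh, sort_keys=True)

    manifest = {
        "config": asdict(config),
        "n_genes": len(gene_rows),
        "n_disease_links": len(disease_rows),
        "n_dosage_regions": len(dosage_rows),
        "n_hi3_regions": sum(1 for r in dosage_rows if r[3] == "3"),
        "n_pathogenic_snvs": len(snv_rows),
        "n_sv_records": len(sv_rows),
        "chromosomes": chroms,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return load_bundle(out / "bundle.yaml", strict=True), manifest


def rule_label(row, config: FixtureConfig) -> str:
    """The deterministic generative label for one raw feature row."""
    if row["hi_3"] >= 1 or (
        row["exon_count"] >= config.exon_threshold and row["popmax_af"] < config.af_threshold
    ):
        return "pathogenic"
    if (
        row["bp_length"] < config.benign_max_length
        and row["popmax_af"] >= config.af_threshold
        and row["exon_count"] == 0
    ):
        return "benign"
    return "VUS"


def generate_labeled_cnvs(
    config: FixtureConfig,
    bundle: AnnotationBundle,
    cnv_seed: int = 1,
    feature_config: FeatureConfig | None = None,
) -> tuple[list[CNVRecord], dict]:
    """Sample CNVs meeting the per-class quotas of the generative rule.

    Proposals are tailored per class and verified against the rule computed
    from the actual bundle features, so manifest class counts match the
    request exactly (pre-noise). Returns the records (with observed labels
    attached) and a manifest holding rule labels, observed labels and the
    noise outcome per record.
    """
    rng = np.random.default_rng(cnv_seed)
    extractor = FeatureExtractor(bundle, feature_config)
    chroms = sorted(bundle.chromosome_structure.arms)
    arms = bundle.chromosome_structure

    hi3_regions = [r for r in bundle.dosage_regions if r.hi_score == "3"]
    common_sv = [
        r for r in bundle.sv_frequencies
        if r.max_frequency >= config.af_threshold and r.interval.length < config.benign_max_length
    ]
    genes = bundle.genes

    def propose(target: str) -> CNVRecord:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        q_tel = arms[chrom].q_telomere
        if target == "pathogenic" and hi3_regions and rng.random() < 0.6:
            region = hi3_regions[int(rng.integers(0, len(hi3_regions)))]
            pad_l = int(rng.integers(100, 5_000))
            pad_r = int(rng.integers(100, 5_000))
            iv = GenomicInterval(
                region.interval.chrom,
                max(0, region.interval.start - pad_l),
                region.interval.end + pad_r,
            )
            cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
        elif target == "pathogenic":
            gene = genes[int(rng.integers(0, len(genes)))]
            pad = int(rng.integers(500, 8_000))
            iv = GenomicInterval(
                gene.interval.chrom,
                max(0, gene.interval.start - pad),
                gene.interval.end + pad,
            )
            cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
        elif target == "benign" and common_sv:
            rec = common_sv[int(rng.integers(0, len(common_sv)))]
            jitter = int(rng.integers(-40, 41))
            length = rec.interval.length
            start = max(0, rec.interval.start + jitter)
            iv = GenomicInterval(rec.interval.chrom, start, start + length)
            cnv_type = rec.sv_type
        else:  # VUS (or fallback)
            length = int(rng.integers(800, 25_000))
            start = int(rng.integers(2_000, max(2_001, q_tel - length - 2_000)))
            iv = GenomicInterval(chrom, start, start + length)
            cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
        return CNVRecord(iv, cnv_type, id="proposal")

    records: list[CNVRecord] = []
    rule_labels: list[str] = []
    counter = 0
    for target in CLASSES:
        quota = int(config.cnv_counts.get(target, 0))
        accepted = 0
        attempts = 0
        while accepted < quota:
            attempts += 1
            if attempts > 200 * max(1, quota):
                raise RuntimeError(
                    f"could not sample {quota} {target} CNVs from this bundle; "
                    "adjust the fixture configuration"
                )
            cand = propose(target)
            row = extractor.extract_one(cand)
            if rule_label(row, config) != target:
                continue
            counter += 1
            records.append(
                CNVRecord(cand.interval, cand.cnv_type, id=f"cnv_{counter:05d}")
            )
            rule_labels.append(target)
            accepted += 1

    # label noise: flip to a uniformly chosen other class with prob epsilon
    observed: list[str] = []
    flipped: list[bool] = []
    for lbl in rule_labels:
        if config.label_noise > 0 and rng.random() < config.label_noise:
            others = [c for c in CLASSES if c != lbl]
            observed.append(others[int(rng.integers(0, 2))])
            flipped.append(True)
        else:
            observed.append(lbl)
            flipped.append(False)
    for rec, lbl in zip(records, observed):
        rec.labels = [lbl]
        rec.collapsed_label = lbl

    manifest = {
        "cnv_seed": cnv_seed,
        "label_noise": config.label_noise,
        "counts_pre_noise": {c: rule_labels.count(c) for c in CLASSES},
        "counts_observed": {c: observed.count(c) for c in CLASSES},
        "records": [
            {
                "id": rec.id,
                "chrom": rec.interval.chrom,
                "start": rec.interval.start,
                "end": rec.interval.end,
                "type": rec.cnv_type,
                "rule_label": rule,
                "observed_label": obs,
                "flipped": flip,
            }
            for rec, rule, obs, flip in zip(records, rule_labels, observed, flipped)
        ],
    }
    return records, manifest


def write_cnv_set(records: Sequence[CNVRecord], manifest: dict, out_dir: str | Path) -> None:
    """Write ``cnvs.tsv`` plus ``cnv_manifest.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cnvs(records, out / "cnvs.tsv")
    with open(out / "cnv_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
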