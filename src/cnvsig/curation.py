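"""Curation of labelled CNV tables into training / test sets.

Submitted clinical-significance strings are collapsed into three classes
(benign / VUS / pathogenic) with a pathogenic-dominant rule, then records
are filtered in a fixed order: non-CNV types, ambiguous labels, coordinate
duplicates and conflicts, sub-50 bp calls, and (for test sets) records whose
coordinates match a training submission. A conservation report accounts for
every input record.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from cnvsig.io import CNVRecord

BENIGN, VUS, PATHOGENIC, AMBIGUOUS = "benign", "VUS", "pathogenic", "AMBIGUOUS"

_PATHOGENIC_LABELS = {"pathogenic", "likely pathogenic", "likely_pathogenic"}
_BENIGN_LABELS = {"benign", "likely benign", "likely_benign"}
_VUS_LABELS = {
    "vus",
    "uncertain significance",
    "uncertain_significance",
    "variant of uncertain significance",
}

#: minimum CNV size retained (structural variants are defined as >= 50 bp)
MIN_CNV_SIZE = 50


def collapse_label(submitted_labels: Sequence[str]) -> str:
    """Collapse submitted significance strings to one of the three classes.

    Any pathogenic or likely-pathogenic designation dominates; otherwise any
    VUS designation yields VUS; records with only benign / likely-benign
    designations are benign. Anything else (e.g. "drug response", "risk
    factor") is AMBIGUOUS and is dropped by curation.
    """
    if not submitted_labels:
        raise ValueError("collapse_label requires at least one submitted label")
    normalized = [lbl.strip().lower() for lbl in submitted_labels]
    if any(lbl in _PATHOGENIC_LABELS for lbl in normalized):
        return PATHOGENIC
    if any(lbl in _VUS_LABELS for lbl in normalized):
        return VUS
    if all(lbl in _BENIGN_LABELS for lbl in normalized):
        return BENIGN
    return AMBIGUOUS


@dataclass
class CurationReport:
    """Per-rule removal tallies; input = retained + sum(removed)."""

    input: int = 0
    removed_non_cnv: int = 0
    removed_ambiguous_label: int = 0
    removed_duplicate: int = 0
    removed_conflict: int = 0
    removed_size: int = 0
    removed_leakage: int = 0
    retained: int = 0
    retained_by_class: dict = field(default_factory=dict)
    retained_by_type: dict = field(default_factory=dict)

    @property
    def removed_total(self) -> int:
        return (
            self.removed_non_cnv
            + self.removed_ambiguous_label
            + self.removed_duplicate
            + self.removed_conflict
            + self.removed_size
            + self.removed_leakage
        )

    def to_dict(self) -> dict:
        return asdict(self)


def curate(
    records: Iterable[CNVRecord],
    training_coordinates: set[tuple[str, int, int, str]] | None = None,
    min_size: int = MIN_CNV_SIZE,
) -> tuple[list[CNVRecord], CurationReport]:
    """Apply the curation rules in order and return kept records plus a report.

    Rule order: (1) drop records that are not deletions or duplications;
    (2) collapse labels and drop AMBIGUOUS; (3) among records sharing
    (chrom, start, end, type): keep one when collapsed labels agree, drop all
    when they conflict; (4) drop records shorter than ``min_size``;
    (5) drop records whose coordinate key appears in ``training_coordinates``
    (leakage guard for test sets). Records that already carry a
    ``collapsed_label`` keep it, making curation idempotent.

    The kept list preserves first-occurrence input order, so permuting input
    rows never changes the kept set (only which duplicate survives its
    group, and duplicates agree by construction).
    """
    records = list(records)
    report = CurationReport(input=len(records))

    # (1) non-CNV types are normally rejected by the reader; double-check here
    stage1 = []
    for rec in records:
        if rec.cnv_type not in ("DEL", "DUP"):
            report.removed_non_cnv += 1
        else:
            stage1.append(rec)

    # (2) label collapse
    stage2 = []
    for rec in stage1:
        label = rec.collapsed_label or collapse_label(rec.labels or [])
        if label == AMBIGUOUS:
            report.removed_ambiguous_label += 1
            continue
        stage2.append(
            CNVRecord(rec.interval, rec.cnv_type, rec.id, rec.labels, collapsed_label=label)
        )

    # (3) duplicate / conflict resolution on (chrom, start, end, type)
    groups: OrderedDict[tuple, list[CNVRecord]] = OrderedDict()
    for rec in stage2:
        groups.setdefault(rec.key, []).append(rec)
    stage3 = []
    for key, members in groups.items():
        labels = {m.collapsed_label for m in members}
        if len(labels) > 1:
            report.removed_conflict += len(members)
        else:
            stage3.append(members[0])
            report.removed_duplicate += len(members) - 1

    # (4) size filter
    stage4 = []
    for rec in stage3:
        if rec.interval.length < min_size:
            report.removed_size += 1
        else:
            stage4.append(rec)

    # (5) leakage guard against training coordinates
    kept = []
    for rec in stage4:
        if training_coordinates is not None and rec.key in training_coordinates:
            report.removed_leakage += 1
        else:
            kept.append(rec)

    report.retained = len(kept)
    by_class: dict[str, int] = {}
    by_type: dict[str, int] = {}
    for rec in kept:
        by_class[rec.collapsed_label] = by_class.get(rec.collapsed_label, 0) + 1
        by_type[rec.cnv_type] = by_type.get(rec.cnv_type, 0) + 1
    report.retained_by_class = by_class
    report.retained_by_type = by_type
    assert report.input == report.retained + report.removed_total
    return kept, report
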