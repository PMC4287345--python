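"""Readers and writers for the external file dialects.

All tabular files are UTF-8 TSV/CSV with explicit headers; missing
values are empty cells (never '.'). Every reader either returns objects
satisfying their type invariants or raises :class:`FormatError` naming
the file, column or record at fault. Writers order rows
deterministically so repeated runs produce byte-identical files.

Dialects:

* sequences — FASTA; header token 1 is the isoform id, an optional
  ``gene=`` attribute (or a separate isoform→gene map) gives the gene;
* mutations — MAF-subset TSV (``Tumor_Sample_Barcode``, ``Hugo_Symbol``,
  ``Transcript_ID``, ``Protein_position``, ``Reference_AA``,
  ``Alternate_AA``, ``Variant_Classification``); only
  ``Missense_Mutation`` rows are admitted;
* regions — TSV of 1-based inclusive intervals (with a BED-dialect
  0-based half-open exporter);
* activity — CSV, first column sample id, one column per drug;
* clinical, STITCH-style interactions, fingerprint and gene→GO-term TSVs;
* association results — TSV in the canonical column order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .association import (
    AssociationResult,
    AssociationThresholds,
    DrugActivityTable,
    RESULT_COLUMNS,
    results_to_frame,
)
from .regions import (
    DEFAULT_DISORDER_THRESHOLD,
    DEFAULT_FOLDINDEX_WINDOW,
    DEFAULT_MIN_IDR_LENGTH,
    MissenseMutation,
    Pfr,
    ProteinIsoform,
)
from .synthetic import PlantedEffect, SyntheticTruth
from .validation import ClinicalRecord, Fingerprint, InteractionRecord

__all__ = [
    "FormatError",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_mutations",
    "write_mutations",
    "read_regions",
    "write_regions",
    "write_regions_bed",
    "read_activity",
    "write_activity",
    "read_clinical",
    "read_interactions",
    "read_fingerprints",
    "read_annotations",
    "write_results",
    "read_results",
    "read_truth",
    "write_truth",
]

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Transcript_ID",
    "Protein_position",
    "Reference_AA",
    "Alternate_AA",
    "Variant_Classification",
]

REGION_COLUMNS = ["region_id", "gene_id", "isoform_id", "source", "start", "end", "name"]


class FormatError(ValueError):
    """An input file violates its declared dialect."""


def _read_table(path: str | Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


# -- sequences ---------------------------------------------------------------

def read_fasta(
    path: str | Path, gene_map: Mapping[str, str] | None = None
) -> list[ProteinIsoform]:
    """Read protein isoforms from FASTA.

    The first header token is the isoform id; the gene comes from a
    ``gene=`` attribute in the description, else from ``gene_map``, else
    falls back to the isoform id.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    isoforms = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        iso_id = record.id
        if iso_id in seen:
            raise FormatError(f"{path}: duplicate isoform id {iso_id!r}")
        seen.add(iso_id)
        gene = None
        for token in record.description.split():
            if token.startswith("gene="):
                gene = token[len("gene="):]
        if gene is None and gene_map is not None:
            gene = gene_map.get(iso_id)
        if gene is None:
            gene = iso_id
        try:
            isoforms.append(
                ProteinIsoform(gene_id=gene, isoform_id=iso_id, sequence=str(record.seq))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return isoforms


def write_fasta(isoforms: Sequence[ProteinIsoform], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iso in sorted(isoforms, key=lambda i: i.isoform_id):
            fh.write(f">{iso.isoform_id} gene={iso.gene_id}\n")
            for i in range(0, len(iso.sequence), 60):
                fh.write(iso.sequence[i : i + 60] + "\n")


# -- mutations ---------------------------------------------------------------

def read_mutations(path: str | Path) -> list[MissenseMutation]:
    """Read missense mutations from a MAF-subset TSV.

    Non-missense rows (by ``Variant_Classification``) are skipped with a
    summary log line; malformed missense rows abort with their line
    numbers. Positions are 1-based.
    """
    frame = _read_table(path, "\t", MUTATION_COLUMNS)
    mutations: list[MissenseMutation] = []
    n_skipped = 0
    bad_lines: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        if row.Variant_Classification != "Missense_Mutation":
            n_skipped += 1
            continue
        try:
            position = int(row.Protein_position)
        except ValueError:
            bad_lines.append(f"line {line_no}: non-integer Protein_position "
                             f"{row.Protein_position!r}")
            continue
        try:
            mutations.append(
                MissenseMutation(
                    sample_id=row.Tumor_Sample_Barcode,
                    gene_id=row.Hugo_Symbol,
                    isoform_id=row.Transcript_ID,
                    position=position,
                    ref_aa=row.Reference_AA,
                    alt_aa=row.Alternate_AA,
                )
            )
        except ValueError as exc:
            bad_lines.append(f"line {line_no}: {exc}")
    if bad_lines:
        detail = "; ".join(bad_lines[:10])
        raise FormatError(f"{path}: {len(bad_lines)} malformed row(s): {detail}")
    if n_skipped:
        logger.info("%s: skipped %d non-missense rows", path, n_skipped)
    return mutations


def write_mutations(mutations: Sequence[MissenseMutation], path: str | Path) -> None:
    rows = [
        {
            "Tumor_Sample_Barcode": m.sample_id,
            "Hugo_Symbol": m.gene_id,
            "Transcript_ID": m.isoform_id,
            "Protein_position": m.position,
            "Reference_AA": m.ref_aa,
            "Alternate_AA": m.alt_aa,
            "Variant_Classification": "Missense_Mutation",
        }
        for m in sorted(
            mutations, key=lambda m: (m.sample_id, m.gene_id, m.isoform_id, m.position)
        )
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# -- regions -----------------------------------------------------------------

def read_regions(
    path: str | Path, isoform_lengths: Mapping[str, int] | None = None
) -> list[Pfr]:
    """Read functional regions (1-based inclusive intervals) from TSV.

    With ``isoform_lengths`` given, regions extending past their isoform
    are rejected with the offending region id.
    """
    frame = _read_table(path, "\t", REGION_COLUMNS)
    regions: list[Pfr] = []
    for row in frame.itertuples(index=False):
        try:
            region = Pfr(
                region_id=row.region_id,
                gene_id=row.gene_id,
                isoform_id=row.isoform_id,
                source=row.source,
                start=int(row.start),
                end=int(row.end),
                name=row.name,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if isoform_lengths is not None:
            length = isoform_lengths.get(region.isoform_id)
            if length is not None and region.end > length:
                raise FormatError(
                    f"{path}: region {region.region_id!r} ends at {region.end}, "
                    f"beyond isoform length {length}"
                )
        regions.append(region)
    return regions


def write_regions(regions: Sequence[Pfr], path: str | Path) -> None:
    rows = [
        {c: getattr(r, c) for c in REGION_COLUMNS}
        for r in sorted(regions, key=lambda r: r.region_id)
    ]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[Pfr], path: str | Path) -> None:
    """Export regions in BED dialect (0-based half-open, isoform as contig)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.isoform_id, r.start, r.region_id)):
            fh.write(f"{r.isoform_id}\t{r.start - 1}\t{r.end}\t{r.region_id}\n")


# -- drug activity -----------------------------------------------------------

def read_activity(path: str | Path) -> DrugActivityTable:
    """Read the samples × drugs activity-area CSV (empty cell = missing)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    frame = pd.read_csv(path, index_col=0)
    try:
        return DrugActivityTable(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_activity(table: DrugActivityTable, path: str | Path) -> None:
    frame = table.frame.sort_index()
    frame = frame[sorted(frame.columns)]
    frame.to_csv(path, index_label="sample_id")


# -- clinical / chemistry / annotations --------------------------------------

def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read clinical records (``patient_id, drug_id, time_days, event``)."""
    frame = _read_table(path, "\t", ["patient_id", "drug_id", "time_days", "event"])
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                ClinicalRecord(
                    patient_id=row.patient_id,
                    drug_id=row.drug_id,
                    time=float(row.time_days),
                    event=bool(int(row.event)),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read STITCH-dialect chemical–protein interactions."""
    frame = _read_table(path, "\t", ["chemical_id", "protein_id", "combined_score"])
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                InteractionRecord(
                    chemical_id=row.chemical_id,
                    protein_id=row.protein_id,
                    score=int(row.combined_score),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read hex-encoded chemical fingerprints; all must share one bit length."""
    frame = _read_table(path, "\t", ["chemical_id", "fingerprint_hex"])
    fps = []
    length = None
    for i, row in enumerate(frame.itertuples(index=False)):
        hexstr = row.fingerprint_hex.strip()
        try:
            bits = np.array(
                [b == "1" for byte in bytes.fromhex(hexstr) for b in f"{byte:08b}"]
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {i + 2}: invalid hex fingerprint {hexstr!r}"
            ) from exc
        if length is None:
            length = bits.size
        elif bits.size != length:
            raise FormatError(
                f"{path}: line {i + 2}: fingerprint length {bits.size} != {length}"
            )
        fps.append(Fingerprint(chemical_id=row.chemical_id, bits=bits))
    return fps


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a gene→GO-term table (GAF-style two-column TSV)."""
    frame = _read_table(path, "\t", ["gene_id", "term_id"])
    annotations: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        annotations.setdefault(row.gene_id, set()).add(row.term_id)
    return annotations


# -- association results -----------------------------------------------------

def write_results(results: Iterable[AssociationResult], path: str | Path) -> None:
    """Write the association result TSV, sorted by (drug, region)."""
    frame = results_to_frame(results)
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def read_results(path: str | Path) -> list[AssociationResult]:
    frame = _read_table(path, "\t", RESULT_COLUMNS)

    def _opt_float(v: str) -> float | None:
        return None if v == "" else float(v)

    results = []
    for row in frame.itertuples(index=False):
        results.append(
            AssociationResult(
                region_id=row.region_id,
                gene_id=row.gene_id,
                drug_id=row.drug_id,
                source=row.source,
                n_region_mut=int(row.n_region_mut),
                n_other_mut=int(row.n_other_mut),
                n_unmut=int(row.n_unmut),
                p_stage1=_opt_float(row.p_stage1),
                p_gene=_opt_float(row.p_gene),
                p_stage2=_opt_float(row.p_stage2),
                q_stage1=_opt_float(row.q_stage1),
                delta_median=_opt_float(row.delta_median),
                direction=row.direction or None,
                status=row.status,
            )
        )
    return results


# -- synthetic truth ---------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "baseline_mean": truth.baseline_mean,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "effects": [dataclasses.asdict(e) for e in truth.effects],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return SyntheticTruth(
            effects=tuple(PlantedEffect(**e) for e in payload["effects"]),
            baseline_mean=payload["baseline_mean"],
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed truth file ({exc})") from exc


# -- run configuration -------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Resolved settings of a run; echoed next to the outputs for provenance."""

    thresholds: AssociationThresholds = AssociationThresholds()
    comparison: str = "gene_unmutated"
    foldindex_window: int = DEFAULT_FOLDINDEX_WINDOW
    disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD
    min_idr_length: int = DEFAULT_MIN_IDR_LENGTH
    seed: int = 0
    inputs: dict = dataclasses.field(default_factory=dict)
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        thresholds = AssociationThresholds(**d.pop("thresholds", {}))
        return cls(thresholds=thresholds, **d)
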