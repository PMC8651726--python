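"""Readers and writers for peptide-level HDX-MS tables.

The on-disk dialect is deliberately simple: comma-separated UTF-8 with a
mandatory header row and dot decimals, modelled on vendor "state data"
exports.  Uptake is stored in Da-equivalents (one incorporated deuteron is
one unit-mass shift).  Residue coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .corrections import exchangeable_amides

__all__ = [
    "PeptideRecord",
    "UptakeRecord",
    "IdentificationRecord",
    "UPTAKE_COLUMNS",
    "read_fasta_sequence",
    "read_uptake_table",
    "write_uptake_table",
    "records_to_frame",
    "frame_to_records",
    "filter_identifications",
    "export_summary_table",
    "coverage_fraction",
]

#: Mandatory column schema of an uptake table.
UPTAKE_COLUMNS = (
    "protein",
    "start",
    "end",
    "sequence",
    "state",
    "exposure_s",
    "replicate",
    "uptake_Da",
)


@dataclass(frozen=True)
class PeptideRecord:
    """A proteolytic peptide with protein coordinates.

    ``start``/``end`` are 1-based inclusive residue indices on the parent
    protein; ``n_exchangeable`` is the number of backbone amides that can
    retain deuterium (length − prolines − 1).
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    n_exchangeable: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.start}-{self.end} has coordinates inconsistent "
                f"with sequence length {len(self.sequence)}"
            )
        if self.n_exchangeable < 0:
            object.__setattr__(
                self, "n_exchangeable", exchangeable_amides(self.sequence)
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class UptakeRecord:
    """One deuterium-content measurement for (peptide, state, time, replicate)."""

    peptide: PeptideRecord
    state: str
    exposure: float  # s
    replicate: int
    uptake: float  # Da-equivalents

    def __post_init__(self) -> None:
        if self.exposure < 0:
            raise ValueError(f"exposure must be non-negative, got {self.exposure}")
        if self.uptake < 0:
            # Negative uptake can only arise from measurement noise; keep the
            # record but make the anomaly visible.
            warnings.warn(
                f"negative uptake {self.uptake:.4f} Da for peptide "
                f"{self.peptide.start}-{self.peptide.end} ({self.state}, "
                f"{self.exposure} s, rep {self.replicate})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class IdentificationRecord:
    """Peptide-identification evidence used for acceptance filtering."""

    peptide: PeptideRecord
    precursor_mass_error: float  # ppm
    n_fragmentations: int
    fragments_per_residue: float
    n_files_identified: int
    n_files_total: int
    mode: str  # "DDA" or "DIA"

    def __post_init__(self) -> None:
        if self.n_fragmentations < 0 or self.n_files_identified < 0:
            raise ValueError("identification counts must be non-negative")
        if self.n_files_identified > self.n_files_total:
            raise ValueError("n_files_identified exceeds n_files_total")


def read_fasta_sequence(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (id, sequence)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def records_to_frame(records: list[UptakeRecord]) -> pd.DataFrame:
    """Flatten uptake records into the canonical table schema."""
    rows = [
        (
            r.peptide.protein_id,
            r.peptide.start,
            r.peptide.end,
            r.peptide.sequence,
            r.state,
            r.exposure,
            r.replicate,
            r.uptake,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(UPTAKE_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> tuple[list[UptakeRecord], dict[tuple[int, int], PeptideRecord]]:
    """Build uptake records and a peptide registry keyed by (start, end)."""
    registry: dict[tuple[int, int], PeptideRecord] = {}
    records: list[UptakeRecord] = []
    for row in frame.itertuples(index=False):
        key = (int(row.start), int(row.end))
        pep = registry.get(key)
        if pep is None:
            pep = PeptideRecord(
                protein_id=str(row.protein),
                sequence=str(row.sequence),
                start=int(row.start),
                end=int(row.end),
            )
            registry[key] = pep
        records.append(
            UptakeRecord(
                peptide=pep,
                state=str(row.state),
                exposure=float(row.exposure_s),
                replicate=int(row.replicate),
                uptake=float(row.uptake_Da),
            )
        )
    return records, registry


def read_uptake_table(path: str | Path) -> tuple[list[UptakeRecord], dict[tuple[int, int], PeptideRecord]]:
    """Parse an uptake CSV into records plus a peptide registry.

    A missing mandatory column is a hard error naming the column; rows with
    unparseable numerics raise with the 1-based data line number for context.
    """
    frame = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in UPTAKE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"uptake table {path} is missing mandatory column(s): {missing}")
    numeric = {"start": int, "end": int, "exposure_s": float, "replicate": int, "uptake_Da": float}
    for col, caster in numeric.items():
        try:
            frame[col] = frame[col].map(caster)
        except (TypeError, ValueError) as exc:
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()].tolist()
            lines = [i + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValueError(
                f"column '{col}' contains unparseable values at line(s) {lines}: {exc}"
            ) from exc
    return frame_to_records(frame)


def write_uptake_table(records: list[UptakeRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write an uptake table in canonical formatting (round-trip stable)."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.6g")


def _dia_checks(rec: IdentificationRecord) -> list[str]:
    failed = []
    if rec.n_fragmentations < 2:
        failed.append(f"n_fragmentations {rec.n_fragmentations} < 2")
    if rec.fragments_per_residue < 0.2:
        failed.append(f"fragments_per_residue {rec.fragments_per_residue} < 0.2")
    if not abs(rec.precursor_mass_error) < 10.0:
        failed.append(f"|mass error| {abs(rec.precursor_mass_error)} ppm not below 10 ppm")
    if rec.n_files_identified * 4 < rec.n_files_total * 3:
        failed.append(
            f"identified in {rec.n_files_identified}/{rec.n_files_total} files, below 3/4"
        )
    return failed


def filter_identifications(
    records: list[IdentificationRecord],
) -> tuple[list[IdentificationRecord], list[tuple[IdentificationRecord, list[str]]]]:
    """Apply acquisition-mode-specific identification acceptance rules.

    DDA peptides pass iff the precursor mass error is strictly below 15 ppm.
    DIA peptides pass iff fragmented at least twice, with at least 0.2
    fragments per residue, precursor mass error strictly below 10 ppm, and
    identified in at least 3 of 4 (i.e. 75% of) MS/MS files.

    Returns the accepted records and, for each rejection, every failed
    criterion so filtering decisions can be audited.  The ``>= 0.2`` reading
    of the fragments-per-residue rule is a documented convention and appears
    verbatim in the rejection messages.
    """
    accepted: list[IdentificationRecord] = []
    rejected: list[tuple[IdentificationRecord, list[str]]] = []
    for rec in records:
        if rec.mode == "DDA":
            failed = (
                []
                if abs(rec.precursor_mass_error) < 15.0
                else [f"|mass error| {abs(rec.precursor_mass_error)} ppm not below 15 ppm"]
            )
        elif rec.mode == "DIA":
            failed = _dia_checks(rec)
        else:
            raise ValueError(f"unknown acquisition mode: {rec.mode!r}")
        if failed:
            rejected.append((rec, failed))
        else:
            accepted.append(rec)
    return accepted, rejected


def coverage_fraction(peptides: list[PeptideRecord], protein_length: int) -> float:
    """Fraction of protein residues covered by the union of peptide intervals."""
    covered = set()
    for pep in peptides:
        covered.update(range(pep.start, pep.end + 1))
    return len(covered & set(range(1, protein_length + 1))) / protein_length


_SUMMARY_REQUIRED = ("protein_id", "protein_length", "pH_read", "d_frac", "timepoints_s", "replicate_counts")


def export_summary_table(
    metadata: dict,
    peptides: list[PeptideRecord],
    path: str | Path,
    back_exchange: dict[tuple[int, int], float] | None = None,
) -> pd.DataFrame:
    """Write a community-style HDX summary: metadata block plus peptide rows.

    ``metadata`` must provide protein_id, protein_length, pH_read, d_frac,
    timepoints_s and replicate_counts; an incomplete dict raises an error
    listing every missing field.  ``back_exchange`` maps (start, end) to BE%
    from maximally labelled controls; when absent the column is marked
    unavailable rather than invented.
    """
    missing = [k for k in _SUMMARY_REQUIRED if k not in metadata]
    if missing:
        raise ValueError(f"summary metadata incomplete; missing field(s): {missing}")
    length = int(metadata["protein_length"])
    coverage = coverage_fraction(peptides, length)
    redundancy = sum(p.length for p in peptides) / length

    rows = []
    for pep in sorted(peptides, key=lambda p: (p.start, p.end, p.sequence)):
        be = back_exchange.get((pep.start, pep.end)) if back_exchange else None
        rows.append(
            {
                "protein": pep.protein_id,
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "n_exchangeable": pep.n_exchangeable,
                "back_exchange_pct": "NA" if be is None else f"{be:.2f}",
            }
        )
    frame = pd.DataFrame(rows)

    buf = _stdio.StringIO()
    buf.write(f"# protein_id: {metadata['protein_id']}\n")
    buf.write(f"# protein_length: {length}\n")
    buf.write(f"# pH_read: {metadata['pH_read']}\n")
    buf.write(f"# d_frac: {metadata['d_frac']}\n")
    buf.write(f"# timepoints_s: {metadata['timepoints_s']}\n")
    buf.write(f"# replicate_counts: {metadata['replicate_counts']}\n")
    buf.write(f"# n_peptides: {len(peptides)}\n")
    buf.write(f"# coverage: {coverage:.4f}\n")
    buf.write(f"# redundancy: {redundancy:.3f}\n")
    if back_exchange:
        mean_be = sum(back_exchange.values()) / len(back_exchange)
        buf.write(f"# mean_back_exchange_pct: {mean_be:.2f}\n")
    else:
        buf.write("# mean_back_exchange_pct: NA (no maximally labelled control supplied)\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
    return frame
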