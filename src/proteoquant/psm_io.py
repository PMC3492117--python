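"""Protein database and PSM-table I/O, identification filtering, and
two-peptide protein inference.

The PSM table dialect is a UTF-8 TSV with mandatory columns
``spectrum_id, peptide, protein_ids, log_expectation, confidence`` and,
for iTRAQ 4-plex runs, the four reporter-intensity columns
``i114, i115, i116, i117``.  ``protein_ids`` is a semicolon-separated list
of locus tags; a peptide mapping to more than one protein marks its
spectra as shared.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pmass

from .errors import DuplicateEntryError, FormatError, UnknownProteinError

#: the 20 standard amino acids accepted in database sequences
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: iTRAQ 4-plex reporter channels (low-mass reporter m/z values)
REPORTER_CHANNELS = ("114", "115", "116", "117")

_MANDATORY_COLUMNS = ("spectrum_id", "peptide", "protein_ids", "log_expectation", "confidence")
_INTENSITY_COLUMNS = ("i114", "i115", "i116", "i117")


def average_mass_kda(sequence: str) -> float:
    """Average (not monoisotopic) molecular mass of a protein sequence, in kDa.

    Sum of average residue masses plus one water, via pyteomics' standard
    composition tables.
    """
    return _pmass.calculate_mass(sequence=sequence, average=True) / 1000.0


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: a locus tag with its mass and functional category."""

    protein_id: str
    description: str = ""
    sequence: str | None = None
    molecular_mass_kDa: float = 0.0
    category: str = "other"

    def __post_init__(self) -> None:
        if self.molecular_mass_kDa <= 0:
            raise ValueError(
                f"{self.protein_id}: molecular_mass_kDa must be > 0, got {self.molecular_mass_kDa}"
            )
        if self.sequence is not None:
            recomputed = average_mass_kda(self.sequence)
            if not math.isclose(recomputed, self.molecular_mass_kDa, rel_tol=1e-3):
                raise ValueError(
                    f"{self.protein_id}: stored mass {self.molecular_mass_kDa:.4f} kDa "
                    f"disagrees with sequence mass {recomputed:.4f} kDa by more than 0.1%"
                )

    @property
    def length(self) -> int | None:
        return None if self.sequence is None else len(self.sequence)


@dataclass(frozen=True)
class PSM:
    """One identified spectrum.

    ``log_expectation`` is log10 of the search-engine expectation value
    (more negative = more confident).  ``confidence`` is an optional
    engine-reported identification confidence in [0, 1].
    ``reporter_intensities`` maps the four iTRAQ channels to nonnegative
    intensities; absent entirely for label-free runs.
    """

    spectrum_id: str
    peptide: str
    protein_ids: tuple[str, ...]
    log_expectation: float
    confidence: float | None = None
    reporter_intensities: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(f"{self.spectrum_id}: empty peptide")
        if not self.protein_ids:
            raise ValueError(f"{self.spectrum_id}: PSM must map to at least one protein")
        if self.reporter_intensities is not None:
            missing = set(REPORTER_CHANNELS) - set(self.reporter_intensities)
            if missing:
                raise ValueError(
                    f"{self.spectrum_id}: reporter intensities missing channels {sorted(missing)}"
                )

    @property
    def is_shared(self) -> bool:
        """True if the peptide maps to more than one protein."""
        return len(self.protein_ids) > 1


@dataclass
class DetectedProtein:
    """A protein passing the identification filters, with its spectral count."""

    protein_id: str
    spectral_count: int
    n_distinct_peptides: int
    member_psms: list[PSM] = field(default_factory=list)
    shared_only: bool = False


def read_fasta_db(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA database into :class:`ProteinRecord` objects.

    Masses are computed from sequence using average residue masses plus one
    water, reported in kDa.  Duplicate headers and non-amino-acid characters
    are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        protein_id = entry.id
        if protein_id in seen:
            raise DuplicateEntryError(f"duplicate FASTA header: {protein_id}")
        seen.add(protein_id)
        seq = str(entry.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in STANDARD_AA:
                raise FormatError(
                    f"{protein_id}: non-amino-acid character {ch!r} at position {pos + 1}"
                )
        description = entry.description[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                description=description,
                sequence=seq,
                molecular_mass_kDa=average_mass_kda(seq),
            )
        )
    return records


def _parse_intensity(cell: object, row_number: int, column: str) -> float:
    """Blank cells mean a missing (zero) channel; anything non-numeric is an error."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return 0.0
    try:
        value = float(cell)
    except (TypeError, ValueError):
        raise FormatError(
            f"row {row_number}: non-numeric intensity {cell!r} in column {column}"
        ) from None
    if value < 0:
        raise FormatError(f"row {row_number}: negative intensity {value} in column {column}")
    return value


def read_psm_table(path: str | Path) -> list[PSM]:
    """Read a PSM TSV into :class:`PSM` objects, preserving row order.

    If the four ``i114..i117`` columns are absent the PSMs carry no reporter
    intensities; blank intensity cells become 0 (handled downstream as
    unquantifiable).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _MANDATORY_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"PSM table is missing mandatory column {column!r}")
    present = [c for c in _INTENSITY_COLUMNS if c in frame.columns]
    if present and len(present) != len(_INTENSITY_COLUMNS):
        missing = sorted(set(_INTENSITY_COLUMNS) - set(present))
        raise FormatError(f"PSM table has partial intensity columns; missing {missing}")
    has_intensities = bool(present)

    psms: list[PSM] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        try:
            log_e = float(row_map["log_expectation"])
        except ValueError:
            raise FormatError(
                f"row {i}: non-numeric log_expectation {row_map['log_expectation']!r}"
            ) from None
        conf_cell = row_map["confidence"]
        if conf_cell == "":
            confidence = None
        else:
            try:
                confidence = float(conf_cell)
            except ValueError:
                raise FormatError(f"row {i}: non-numeric confidence {conf_cell!r}") from None
        intensities = None
        if has_intensities:
            intensities = {
                channel: _parse_intensity(row_map[f"i{channel}"], i, f"i{channel}")
                for channel in REPORTER_CHANNELS
            }
        protein_ids = tuple(p for p in str(row_map["protein_ids"]).split(";") if p)
        psms.append(
            PSM(
                spectrum_id=str(row_map["spectrum_id"]),
                peptide=str(row_map["peptide"]),
                protein_ids=protein_ids,
                log_expectation=log_e,
                confidence=confidence,
                reporter_intensities=intensities,
            )
        )
    return psms


def write_psm_table(psms: Sequence[PSM], path: str | Path) -> None:
    """Write PSMs back to the TSV dialect read by :func:`read_psm_table`."""
    rows = []
    any_intensities = any(p.reporter_intensities is not None for p in psms)
    for p in psms:
        row = {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide,
            "protein_ids": ";".join(p.protein_ids),
            "log_expectation": p.log_expectation,
            "confidence": "" if p.confidence is None else p.confidence,
        }
        if any_intensities:
            inten = p.reporter_intensities or {c: 0.0 for c in REPORTER_CHANNELS}
            for channel in REPORTER_CHANNELS:
                row[f"i{channel}"] = inten[channel]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_psms(psms: Iterable[PSM], max_log_expectation: float = -1.5) -> list[PSM]:
    """Keep PSMs identified with expectation strictly below the threshold.

    The default −1.5 (log10 scale) is the identification filter applied to
    iTRAQ-labelled peptides before ratio analysis.
    """
    return [p for p in psms if p.log_expectation < max_log_expectation]


def infer_proteins(
    psms: Sequence[PSM],
    records: Sequence[ProteinRecord],
    min_peptides: int = 2,
    min_confidence: float | None = 0.999,
    shared_policy: str = "all",
) -> list[DetectedProtein]:
    """Group PSMs into detected proteins under the two-peptide rule.

    A protein is *detected* iff it has at least ``min_peptides`` distinct
    member peptides and, when confidence scores are present, its best member
    confidence reaches ``min_confidence`` (default 0.999, i.e. a 99.9%
    identification confidence).  A PSM whose peptide maps to k proteins
    contributes one spectrum to each of the k groups (``shared_policy="all"``,
    the default) or to none of them (``"unique-only"``); either way shared
    membership is flagged so downstream consumers can audit it.

    Output is sorted by protein_id, making the grouping invariant under PSM
    input permutation.
    """
    if shared_policy not in ("all", "unique-only"):
        raise ValueError(f"unknown shared_policy {shared_policy!r}")
    known = {r.protein_id for r in records}
    groups: dict[str, list[PSM]] = defaultdict(list)
    for psm in psms:
        for pid in psm.protein_ids:
            if pid not in known:
                raise UnknownProteinError(f"PSM {psm.spectrum_id} references unknown protein {pid}")
            if shared_policy == "unique-only" and psm.is_shared:
                continue
            groups[pid].append(psm)

    detected: list[DetectedProtein] = []
    for pid in sorted(groups):
        members = groups[pid]
        peptides = {p.peptide for p in members}
        if len(peptides) < min_peptides:
            continue
        confidences = [p.confidence for p in members if p.confidence is not None]
        if min_confidence is not None and confidences and max(confidences) < min_confidence:
            continue
        detected.append(
            DetectedProtein(
                protein_id=pid,
                spectral_count=len(members),
                n_distinct_peptides=len(peptides),
                member_psms=list(members),
                shared_only=all(p.is_shared for p in members),
            )
        )
    return detected
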