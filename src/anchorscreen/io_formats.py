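"""Input/output: proteome FASTA, screening-criteria config, candidate TSV.

All residue coordinates reported anywhere in this package are 1-based and
inclusive.  Candidate tables are written as TSV (product descriptions
routinely contain commas) with a fixed column order and two-decimal float
rendering, so repeated runs on identical input produce byte-identical
output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml
from Bio import SeqIO

from .scl_classifier import SCL_CLASSES, TABLE2_CLASSES

logger = logging.getLogger("anchorscreen")

#: the 20 canonical amino acids plus accepted ambiguity/rare codes
ALLOWED_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | set("XBZU")
_NUCLEOTIDE_RESIDUES = set("ACGTUN")


class FastaError(ValueError):
    """Raised for malformed proteome FASTA input."""


class CriteriaError(ValueError):
    """Raised for invalid screening-criteria configuration."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein from a proteome FASTA file."""

    id: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = str(raw).upper().strip()
    while seq.endswith("*"):  # terminal stop characters from gene callers
        seq = seq[:-1]
    if not seq:
        raise FastaError(f"record {rec_id!r} has an empty sequence")
    bad = set(seq) - ALLOWED_RESIDUES
    if bad:
        raise FastaError(
            f"record {rec_id!r} contains illegal residues: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into ProteinRecords.

    Order is preserved; sequences are uppercased and trailing '*' stop
    characters are stripped.  Duplicate ids and empty sequences are hard
    errors.  A file that looks like nucleotide data (>= 95% of residues in
    A/C/G/T/U/N) only triggers a warning, since some proteins are
    legitimately glycine/alanine rich.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, description=desc, sequence=seq))
    if records:
        residues = "".join(r.sequence for r in records)
        nt = sum(residues.count(c) for c in _NUCLEOTIDE_RESIDUES)
        if nt >= 0.95 * len(residues):
            logger.warning(
                "input looks like nucleotide data (%.0f%% of residues in "
                "A/C/G/T/U/N); expected amino-acid FASTA", 100 * nt / len(residues)
            )
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write ProteinRecords back to FASTA (60-column wrapping)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Screening criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds and switches of the anchor-screening rubric.

    Defaults encode the published screening rubric: proteins shorter than
    600 residues, intracellular possibility at most 0.5, the six
    membrane/exported localization classes, and terminal 20-residue
    windows whose outside probability must exceed 0.5 on the displayed
    terminus and stay below 0.5 on the anchoring terminus; for the
    N-terminally-anchored and secretory classes the N-in probability must
    additionally exceed 0.8.
    """

    max_length: int = 600
    intracellular_max: float = 0.5
    n_in_min: float = 0.8
    terminal_window: int = 20
    window_outside_min: float = 0.5
    opposite_window_outside_max: float = 0.5
    allowed_classes: frozenset[str] = frozenset(TABLE2_CLASSES)
    soft_weights: dict = field(
        default_factory=lambda: {
            "signal_possibility": 1.0,
            "n_anchored_possibility": 1.0,
            "display_outside": 1.0,
        }
    )
    strict_windows: bool = True
    require_spi_for_c_anchor: bool = True
    window_agg: str = "mean"
    n_anchor_span: int = 40

    def validate(self) -> "ScreenCriteria":
        if self.max_length < 1:
            raise CriteriaError("max_length must be >= 1")
        for name in ("intracellular_max", "n_in_min", "window_outside_min",
                     "opposite_window_outside_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CriteriaError(f"{name} must be in [0, 1], got {v}")
        if self.terminal_window < 1:
            raise CriteriaError("terminal_window must be >= 1")
        if not self.allowed_classes:
            raise CriteriaError("allowed_classes must be non-empty")
        unknown = set(self.allowed_classes) - set(SCL_CLASSES)
        if unknown:
            raise CriteriaError(f"unknown SCL classes: {sorted(unknown)}")
        if self.window_agg not in ("mean", "max"):
            raise CriteriaError("window_agg must be 'mean' or 'max'")
        return self


def load_criteria(path: str | Path | None = None) -> ScreenCriteria:
    """Load screening criteria from a YAML key/value file.

    With no file, the published defaults are returned.  Unknown keys are
    rejected; thresholds are range-checked.
    """
    base = ScreenCriteria()
    if path is None:
        return base.validate()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise CriteriaError("criteria config must be a key/value document")
    known = {f.name for f in fields(ScreenCriteria)}
    unknown = set(data) - known
    if unknown:
        raise CriteriaError(f"unknown criteria keys: {sorted(unknown)}")
    if "allowed_classes" in data:
        data["allowed_classes"] = frozenset(data["allowed_classes"])
    return replace(base, **data).validate()


# ---------------------------------------------------------------------------
# Candidate table TSV
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "protein_id",
    "locus_tag",
    "product",
    "pathway",
    "scl_class",
    "intracellular_possibility",
    "signal_possibility",
    "n_anchored_possibility",
    "cleavage_window",
    "anchored_site",
    "rank_score",
    "pass",
    "fail_reasons",
]

_FLOAT_COLUMNS = {
    "intracellular_possibility",
    "signal_possibility",
    "n_anchored_possibility",
    "rank_score",
}


def _render(col: str, value) -> str:
    if col in _FLOAT_COLUMNS:
        return f"{float(value):.2f}"
    if col == "pass":
        return "true" if value else "false"
    if col == "fail_reasons":
        if isinstance(value, str):
            return value
        return ",".join(value)
    return str(value)


def write_candidate_table(rows: list[dict], path: str | Path,
                          provenance: str | None = None) -> None:
    """Write candidate rows as a deterministic TSV.

    Rows are sorted with passing candidates first (rank score descending,
    id ascending on ties), failing rows after.  Floats render with two
    decimals; only '#' comment lines may carry provenance, never the data
    rows, so identical inputs give byte-identical files.
    """
    ordered = sorted(
        rows,
        key=lambda r: (
            not bool(r["pass"]),
            -float(r["rank_score"]),
            str(r["protein_id"]),
        ),
    )
    with open(path, "w", newline="") as fh:
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for row in ordered:
            writer.writerow([_render(c, row[c]) for c in CANDIDATE_COLUMNS])


def read_candidate_table(path: str | Path) -> list[dict]:
    """Read a candidate TSV back (floats parsed, fail_reasons split)."""
    rows: list[dict] = []
    with open(path) as fh:
        lines = [l for l in fh if not l.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    for rec in reader:
        row: dict = dict(rec)
        for col in _FLOAT_COLUMNS:
            row[col] = float(row[col])
        row["pass"] = rec["pass"] == "true"
        row["fail_reasons"] = [r for r in rec["fail_reasons"].split(",") if r]
        rows.append(row)
    return rows
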