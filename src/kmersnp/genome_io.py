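"""Genome FASTA input, file-name validation and the tab-delimited manifest.

The manifest is a two-column, tab-delimited file (``path<TAB>genome_id``),
one genome per line.  The genome ID, derived from the file name with its
extension dropped, is the taxon label that appears on every tree, so file
names are restricted to characters that survive in Newick labels and shell
pipelines: letters, digits, dash and underscore, with a single extension
dot.  Violations are reported as data (a ``NameErrors``-style report)
rather than raised one at a time, so a user can fix a whole directory in
one pass.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRecord",
    "InputManifest",
    "NameViolation",
    "NameRule",
    "ManifestError",
    "validate_file_name",
    "make_manifest",
    "read_genomes",
    "read_genome_fasta",
    "list_genome_names",
    "write_name_errors",
]

FASTA_EXTENSIONS = (".fasta", ".fa", ".fna", ".fas")

_ID_RE = re.compile(r"^[A-Za-z0-9_-]+$")


class NameRule(str, Enum):
    MULTIPLE_DOTS = "multiple_dots"
    CONTAINS_SPACE = "contains_space"
    ILLEGAL_CHARACTER = "illegal_character"


@dataclass(frozen=True)
class NameViolation:
    file_name: str
    rule_broken: NameRule


@dataclass
class GenomeRecord:
    """One genome: an ID plus its ordered sequences (contigs or reads)."""

    genome_id: str
    sequences: List[Tuple[str, str]]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if not _ID_RE.match(self.genome_id):
            raise ValueError(
                f"genome_id {self.genome_id!r} contains characters outside "
                "[A-Za-z0-9_-]"
            )
        if not self.sequences:
            raise ValueError(f"genome {self.genome_id!r} has no sequences")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.sequences)


@dataclass
class InputManifest:
    """Ordered (path, genome_id) pairs naming the genomes of a run."""

    entries: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [gid for _, gid in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate genome IDs in manifest: {dupes}")
        for path, _ in self.entries:
            if " " in path:
                raise ValueError(f"manifest path contains a space: {path!r}")

    @property
    def genome_ids(self) -> List[str]:
        return [gid for _, gid in self.entries]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for p, gid in self.entries:
                fh.write(f"{p}\t{gid}\n")

    @classmethod
    def read(cls, path) -> "InputManifest":
        entries: List[Tuple[str, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if "\t" in line:
                    fields = line.split("\t")
                else:
                    fields = line.split()
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'path<TAB>genome_id', "
                        f"got {line!r}"
                    )
                entries.append((fields[0], fields[1]))
        return cls(entries=entries)


class ManifestError(RuntimeError):
    """Raised when a genome directory cannot be turned into a manifest."""

    def __init__(self, message: str, violations: Sequence[NameViolation] = ()):
        super().__init__(message)
        self.violations = list(violations)


def validate_file_name(file_name: str) -> List[NameViolation]:
    """Check a genome file name against the naming rules.

    Returns an empty list iff the name has at most one dot (the extension
    separator), no spaces, and otherwise only letters, digits, dash and
    underscore.  Each broken rule is reported once; a space is reported as
    ``contains_space`` only, not doubly as an illegal character.
    """
    if not file_name:
        raise ValueError("file_name must be non-empty")
    violations: List[NameViolation] = []
    if file_name.count(".") > 1:
        violations.append(NameViolation(file_name, NameRule.MULTIPLE_DOTS))
    if " " in file_name:
        violations.append(NameViolation(file_name, NameRule.CONTAINS_SPACE))
    stripped = file_name.replace(".", "").replace(" ", "")
    if stripped and not _ID_RE.match(stripped):
        violations.append(NameViolation(file_name, NameRule.ILLEGAL_CHARACTER))
    return violations


_RULE_TEXT = {
    NameRule.MULTIPLE_DOTS: "file name contains more than one dot",
    NameRule.CONTAINS_SPACE: "file name contains a space",
    NameRule.ILLEGAL_CHARACTER: (
        "file name contains characters other than A-Z a-z 0-9 - _"
    ),
}


def write_name_errors(violations: Iterable[NameViolation], path) -> None:
    """Write a plain-text naming-violation report.

    File names may contain only letters, digits, dash and underscore plus a
    single extension dot, and no spaces; offending files are listed with the
    rule each one broke.
    """
    with open(path, "w") as fh:
        fh.write(
            "Genome file names may contain only the characters A-Z a-z 0-9 "
            "- _ ,\nat most one dot (separating the extension), and no "
            "spaces.\nThe following files violate these rules and must be "
            "renamed:\n\n"
        )
        for v in violations:
            fh.write(f"{v.file_name}\t{_RULE_TEXT[v.rule_broken]}\n")


def make_manifest(directory) -> InputManifest:
    """Build a manifest from every FASTA file in ``directory``.

    The genome ID is the file name with its extension dropped; entries are
    sorted lexicographically by genome ID so downstream outputs are
    deterministic.  Aborts with a :class:`ManifestError` carrying the full
    violation list if any FASTA file name is invalid, or if any absolute
    path contains a space.  Non-FASTA files are ignored with a warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ManifestError(f"not a directory: {directory}")
    fasta_files: List[Path] = []
    for entry in sorted(directory.iterdir()):
        if entry.is_file() and entry.suffix.lower() in FASTA_EXTENSIONS:
            fasta_files.append(entry)
        elif entry.is_file():
            logger.warning("ignoring non-FASTA file %s", entry.name)
    if not fasta_files:
        raise ManifestError(f"no genomes found in {directory}")
    violations: List[NameViolation] = []
    for f in fasta_files:
        violations.extend(validate_file_name(f.name))
    if violations:
        names = ", ".join(sorted({v.file_name for v in violations}))
        raise ManifestError(
            f"invalid genome file names: {names}", violations=violations
        )
    entries = []
    for f in fasta_files:
        abs_path = str(f.resolve())
        if " " in abs_path:
            raise ManifestError(
                f"path contains a space: {abs_path!r}; move the genomes to a "
                "directory whose full path has no spaces"
            )
        entries.append((abs_path, f.stem))
    entries.sort(key=lambda e: e[1])
    return InputManifest(entries=entries)


def read_genome_fasta(path, genome_id: str) -> GenomeRecord:
    """Read one FASTA file into a :class:`GenomeRecord` (uppercased)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"genome file not found: {path}")
    sequences: List[Tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences.append((rec.id, str(rec.seq).upper()))
    if not sequences:
        raise ValueError(f"no FASTA records in {path} (genome {genome_id!r})")
    return GenomeRecord(
        genome_id=genome_id, sequences=sequences, source_path=str(path)
    )


def read_genomes(manifest: InputManifest) -> List[GenomeRecord]:
    """Read every manifest entry, preserving manifest order."""
    return [read_genome_fasta(path, gid) for path, gid in manifest.entries]


def list_genome_names(manifest: InputManifest) -> List[str]:
    """Genome IDs in manifest order (one per line when serialized)."""
    return list(manifest.genome_ids)
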