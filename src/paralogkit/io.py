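"""Domain types and readers/writers for the formats the pipeline touches.

Transcriptome assemblies arrive as FASTA plus an isotig->isogroup map (an
isogroup clusters the isoforms/alleles of one putative gene); genomes as
contig FASTA; the linkage map assigns contigs to chromosomes; optional
side tables carry GO terms, best annotation hits and per-sequence coding
potential scores. Similarity hits use the standard 12-column tabular
format (qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore) with 1-based inclusive coordinates and minus-strand
subject hits encoded by sstart > send.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "IsogroupMap",
    "PipelineConfig",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_isogroup_map",
    "isogroup_map_from_pattern",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_linkage_map",
    "read_go_map",
    "read_score_table",
    "read_annotation_map",
]

_VALID_RESIDUES = frozenset("ACGTN")
_GO_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """An input file violates its documented format or invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence (transcript isotig or genome contig)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise FormatError(f"empty sequence for id {self.id!r}")
        res = self.residues.upper()
        bad = set(res) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return dataclasses.replace(
            self, residues=str(Seq(self.residues).reverse_complement())
        )


class IsogroupMap:
    """Mapping isotig-id -> isogroup-id.

    Every isotig belongs to exactly one isogroup. Isotigs absent from the
    map are treated by callers as singleton isogroups.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = dict(mapping or {})

    def __getitem__(self, isotig: str) -> str:
        return self._map[isotig]

    def get(self, isotig: str, default: str | None = None) -> str | None:
        return self._map.get(isotig, default)

    def __contains__(self, isotig: str) -> bool:
        return isotig in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._map)

    def items(self):
        return self._map.items()

    def group_of(self, isotig: str) -> str:
        """Isogroup of *isotig*; unmapped isotigs form singleton groups."""
        return self._map.get(isotig, f"__singleton__{isotig}")

    def groups(self) -> dict[str, list[str]]:
        """Inverse map isogroup -> sorted isotig ids."""
        inv: dict[str, list[str]] = {}
        for isotig, group in self._map.items():
            inv.setdefault(group, []).append(isotig)
        for members in inv.values():
            members.sort()
        return inv


@dataclass
class PipelineConfig:
    """Tunable thresholds of the duplicate-gene workflow.

    Defaults are the workflow's standard operating point: candidate pairs
    need an alignment of at least ``min_alignment_length`` bp (300) at more
    than ``min_percent_id`` percent identity (80); same-contig pairs more
    than ``lgd_min_distance`` bp apart (5000) are local duplications; the
    similarity search retains hits with E-value <= ``evalue_threshold``
    (1e-20).
    """

    min_alignment_length: int = 300
    min_percent_id: float = 80.0
    lgd_min_distance: int = 5000
    evalue_threshold: float = 1e-20
    n_control_pairs: int = 3000
    n_permutations: int = 100_000
    rng_seed: int = 0
    kmer: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41
    min_codons: int = 100
    anchor_score_window: float = 0.10
    refilter_external_hits: bool = False

    def __post_init__(self) -> None:
        if self.min_alignment_length <= 0 or self.lgd_min_distance <= 0:
            raise ValueError("length thresholds must be positive")
        if not (0 < self.min_percent_id < 100):
            raise ValueError("min_percent_id must lie in (0, 100)")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; duplicate ids and empty sequences are
    rejected with the offending id named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if not str(rec.seq):
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _read_tsv_rows(path: str | Path, n_cols: int) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated columns, "
                    f"got {len(parts)}"
                )
            yield lineno, parts


def read_isogroup_map(path: str | Path) -> IsogroupMap:
    """Read a two-column TSV of isotig-id, isogroup-id."""
    mapping: dict[str, str] = {}
    for lineno, (isotig, group) in ((ln, p) for ln, p in _read_tsv_rows(path, 2)):
        if isotig in mapping and mapping[isotig] != group:
            raise FormatError(
                f"{path}:{lineno}: isotig {isotig!r} listed under two isogroups "
                f"({mapping[isotig]!r} and {group!r})"
            )
        mapping[isotig] = group
    return IsogroupMap(mapping)


def isogroup_map_from_pattern(ids: Iterable[str], pattern: str) -> IsogroupMap:
    """Build an isogroup map by extracting group ids from sequence ids.

    *pattern* is a regex with one capture group holding the isogroup id,
    e.g. ``r"(isogroup\\d+)_"``. Ids the pattern does not match are left
    unmapped (singleton isogroups downstream).
    """
    rx = re.compile(pattern)
    mapping: dict[str, str] = {}
    for sid in ids:
        m = rx.search(sid)
        if m:
            mapping[sid] = m.group(1)
    return IsogroupMap(mapping)


def read_tabular_hits(path: str | Path) -> list:
    """Read 12-column tabular similarity hits (coordinates kept 1-based)."""
    from .align import AlignmentHit  # deferred to avoid import cycle

    hits = []
    for lineno, parts in _read_tsv_rows(path, 12):
        try:
            hits.append(
                AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_id=float(parts[2]),
                    align_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    raw_score=int(round(float(parts[11]))),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed hit row ({exc})") from exc
    return hits


def write_tabular_hits(hits: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.to_tabular_line() + "\n")


def read_linkage_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of genome-contig-id, chromosome-id."""
    mapping: dict[str, str] = {}
    for lineno, (contig, chrom) in _read_tsv_rows(path, 2):
        if contig in mapping and mapping[contig] != chrom:
            raise FormatError(
                f"{path}:{lineno}: contig {contig!r} mapped to two chromosomes"
            )
        mapping[contig] = chrom
    return mapping


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV of sequence-id, GO-term (one term per row)."""
    mapping: dict[str, set[str]] = {}
    for lineno, (sid, term) in _read_tsv_rows(path, 2):
        if not _GO_RE.match(term):
            raise FormatError(f"{path}:{lineno}: invalid GO term {term!r}")
        mapping.setdefault(sid, set()).add(term)
    return mapping


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of sequence-id, coding-potential score in [0,1]."""
    table: dict[str, float] = {}
    for lineno, (sid, raw) in _read_tsv_rows(path, 2):
        score = float(raw)
        if not (0.0 <= score <= 1.0):
            raise FormatError(
                f"{path}:{lineno}: score {score} for {sid!r} outside [0, 1]"
            )
        table[sid] = score
    return table


def read_annotation_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sequence-id, best annotation accession."""
    mapping: dict[str, str] = {}
    for _, (sid, acc) in _read_tsv_rows(path, 2):
        mapping[sid] = acc
    return mapping
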