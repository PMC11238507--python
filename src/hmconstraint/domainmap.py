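"""Domain family alignments and homologous residue ("meta-position") maps.

A protein domain family is a set of homologous regions ("copies" or
instances) from many proteins, multiply aligned. Each *match column* of the
alignment defines one meta-position: the set of evolutionarily equivalent
residues across all copies. Constraint is later aggregated "vertically"
over those residue sets, so the only job of this module is to turn an
alignment into an exact residue -> column map, in pure protein coordinates.

Conventions
-----------
* Member headers follow the ``protein_id/start-end`` dialect with 1-based
  inclusive envelope coordinates.
* ``'-'`` and ``'.'`` are gaps; lowercase letters are insert-state residues:
  they consume a protein position but are never mapped to a match column.
* Match columns come from the Stockholm ``#=GC RF`` reference line when
  present, otherwise from a gap-fraction rule (a column is a match column
  iff its gap fraction is <= ``max_gap_fraction``, default 0.5 — the usual
  profile-HMM convention).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

from .errors import EmptyInputError, FormatError, MemberError

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

_HEADER_RE = re.compile(r"^(?P<pid>\S+)/(?P<start>\d+)-(?P<end>\d+)$")


def _is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


def _is_insert_residue(ch: str) -> bool:
    return ch.isalpha() and ch.islower()


@dataclass(frozen=True)
class AlignedMember:
    """One domain instance: an aligned row plus its protein coordinates."""

    protein_id: str
    env_start: int  # 1-based inclusive start of the instance in its protein
    env_end: int  # 1-based inclusive end
    aligned_seq: str

    def __post_init__(self) -> None:
        if self.env_start < 1 or self.env_end < self.env_start:
            raise MemberError(
                f"{self.protein_id}: bad envelope {self.env_start}-{self.env_end}"
            )
        n_res = sum(1 for c in self.aligned_seq if not _is_gap(c))
        span = self.env_end - self.env_start + 1
        if n_res != span:
            raise MemberError(
                f"{self.protein_id}/{self.env_start}-{self.env_end}: "
                f"{n_res} residues in alignment row but envelope spans {span}"
            )

    @property
    def n_residues(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass
class DomainFamilyAlignment:
    """A multiple alignment of domain instances with designated match columns."""

    family_id: str
    members: list[AlignedMember]
    n_columns: int
    match_columns: list[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptyInputError(f"family {self.family_id}: no members")
        for m in self.members:
            if len(m.aligned_seq) != self.n_columns:
                raise FormatError(
                    f"family {self.family_id}: member {m.protein_id} has "
                    f"{len(m.aligned_seq)} columns, expected {self.n_columns}"
                )
        mc = self.match_columns
        if any(b <= a for a, b in zip(mc, mc[1:])):
            raise FormatError(f"family {self.family_id}: match columns not increasing")
        if mc and (mc[0] < 0 or mc[-1] >= self.n_columns):
            raise FormatError(f"family {self.family_id}: match column out of range")


@dataclass(frozen=True)
class MetaPosition:
    """One match column of one family: the homologous residue set."""

    family_id: str
    column: int
    residues: tuple[tuple[str, int], ...]  # (protein_id, 1-based position)
    n_copies: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_copies", len(set(self.residues)))


def _parse_member_header(header: str, row: int) -> tuple[str, int, int]:
    m = _HEADER_RE.match(header.strip())
    if m is None:
        raise MemberError(
            f"alignment row {row}: header {header!r} does not match "
            "'protein_id/start-end'"
        )
    return m.group("pid"), int(m.group("start")), int(m.group("end"))


def match_columns_by_gap_fraction(
    rows: Sequence[str], max_gap_fraction: float = 0.5
) -> list[int]:
    """Designate match columns by the <=50%-gap rule (inserts count as gaps)."""
    n = len(rows[0])
    out = []
    for j in range(n):
        gaps = sum(1 for r in rows if _is_gap(r[j]) or _is_insert_residue(r[j]))
        if gaps / len(rows) <= max_gap_fraction:
            out.append(j)
    return out


def read_alignment(
    path: str | Path,
    format: str | None = None,
    max_gap_fraction: float = 0.5,
) -> DomainFamilyAlignment:
    """Read one domain family alignment (Stockholm 1.0 or aligned FASTA).

    Match columns are taken from the ``#=GC RF`` line when present (any
    non-gap RF character marks a match state); otherwise they fall back to
    the gap-fraction rule. The family accession comes from ``#=GF AC`` /
    ``#=GF ID`` when present, else the file stem.
    """
    fams = read_alignments(path, format=format, max_gap_fraction=max_gap_fraction)
    if len(fams) > 1:
        raise FormatError(f"{path}: contains {len(fams)} families, expected one")
    return fams[0]


def read_alignments(
    path: str | Path,
    format: str | None = None,
    max_gap_fraction: float = 0.5,
) -> list[DomainFamilyAlignment]:
    """Read every family alignment in a file (Stockholm files may hold several)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path}: empty alignment file")
    if format is None:
        format = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "aligned-fasta"
    biofmt = {"stockholm": "stockholm", "aligned-fasta": "fasta"}.get(format)
    if biofmt is None:
        raise FormatError(f"unknown alignment format {format!r}")

    try:
        alns = list(AlignIO.parse(str(path), biofmt))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not alns:
        raise EmptyInputError(f"{path}: no alignments found")

    out = []
    for idx, aln in enumerate(alns):
        members = []
        for row, rec in enumerate(aln):
            pid, start, end = _parse_member_header(rec.id, row)
            members.append(
                AlignedMember(
                    protein_id=pid,
                    env_start=start,
                    env_end=end,
                    aligned_seq=str(rec.seq),
                )
            )
        lengths = {len(m.aligned_seq) for m in members}
        if len(lengths) != 1:
            raise FormatError(f"{path}: ragged alignment (row lengths {sorted(lengths)})")
        n_columns = lengths.pop()

        rf = aln.column_annotations.get("reference_annotation")
        if rf is not None:
            match_columns = [j for j, c in enumerate(rf) if not _is_gap(c)]
        else:
            match_columns = match_columns_by_gap_fraction(
                [m.aligned_seq for m in members], max_gap_fraction
            )

        family_id = None
        for key in ("accession", "id"):
            # Biopython does not expose #=GF for alignments uniformly; fall
            # back to parsing the raw header lines below.
            family_id = getattr(aln, "annotations", {}).get(key) if hasattr(aln, "annotations") else None
            if family_id:
                break
        if not family_id:
            family_id = _stockholm_family_id(path, idx) if biofmt == "stockholm" else None
        if not family_id:
            family_id = path.stem if len(alns) == 1 else f"{path.stem}.{idx + 1}"

        out.append(
            DomainFamilyAlignment(
                family_id=family_id,
                members=members,
                n_columns=n_columns,
                match_columns=match_columns,
            )
        )
    return out


def _stockholm_family_id(path: Path, index: int) -> str | None:
    """Pull the index-th '#=GF AC' (or ID) accession out of a Stockholm file."""
    acs: list[str | None] = []
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#=GF AC"):
                current = line.split(None, 2)[2].strip()
            elif line.startswith("#=GF ID") and current is None:
                current = line.split(None, 2)[2].strip()
            elif line.startswith("//"):
                acs.append(current)
                current = None
    return acs[index] if index < len(acs) else None


def residue_to_column(
    member: AlignedMember, match_columns: Iterable[int]
) -> dict[int, int]:
    """Map each protein position of a member to its match column.

    Residues landing in insert columns (or lowercase insert-state residues
    anywhere) consume a protein position but are not mapped. The returned
    mapping is injective by construction: each match column holds at most
    one residue of the member.
    """
    match_set = set(match_columns)
    mapping: dict[int, int] = {}
    pos = member.env_start
    for col, ch in enumerate(member.aligned_seq):
        if _is_gap(ch):
            continue
        if not _is_insert_residue(ch) and col in match_set:
            mapping[pos] = col
        pos += 1
    return mapping


def build_meta_positions(
    families: Iterable[DomainFamilyAlignment],
) -> list[MetaPosition]:
    """One MetaPosition per (family, match column), residues deduplicated.

    Within a family, a protein residue belongs to at most one domain
    instance: when instances on the same protein overlap, the instance with
    the smaller ``env_start`` claims the shared residues. Exact duplicate
    members (same protein and envelope) are dropped with a warning.
    """
    out: list[MetaPosition] = []
    for fam in sorted(families, key=lambda f: f.family_id):
        seen_instances: set[tuple[str, int, int]] = set()
        claimed: dict[str, set[int]] = {}
        per_column: dict[int, list[tuple[str, int]]] = {c: [] for c in fam.match_columns}
        for member in sorted(fam.members, key=lambda m: (m.protein_id, m.env_start)):
            key = (member.protein_id, member.env_start, member.env_end)
            if key in seen_instances:
                logger.warning(
                    "family %s: duplicate member %s/%d-%d, keeping first",
                    fam.family_id, *key,
                )
                continue
            seen_instances.add(key)
            taken = claimed.setdefault(member.protein_id, set())
            for pos, col in residue_to_column(member, fam.match_columns).items():
                if pos in taken:
                    continue  # earlier (lower env_start) instance wins
                taken.add(pos)
                per_column[col].append((member.protein_id, pos))
        for col in fam.match_columns:
            residues = tuple(sorted(set(per_column[col])))
            out.append(MetaPosition(family_id=fam.family_id, column=col, residues=residues))
    return out


def meta_positions_to_frame(metas: Iterable[MetaPosition]) -> pd.DataFrame:
    """Long-format table: one row per (family, column, protein, position)."""
    rows = [
        (m.family_id, m.column, pid, pos, m.n_copies)
        for m in metas
        for pid, pos in m.residues
    ]
    return pd.DataFrame(
        rows, columns=["family_id", "column", "protein_id", "protein_position", "n_copies"]
    )


def write_meta_positions(metas: Iterable[MetaPosition], path: str | Path) -> None:
    meta_positions_to_frame(metas).to_csv(path, sep="\t", index=False)


def write_alignment(fam: DomainFamilyAlignment, path: str | Path, format: str = "stockholm") -> None:
    """Write a family back out (Stockholm with #=GC RF, or aligned FASTA)."""
    path = Path(path)
    if format == "stockholm":
        with open(path, "w") as fh:
            fh.write(_stockholm_block(fam))
    elif format == "aligned-fasta":
        with open(path, "w") as fh:
            for m in fam.members:
                fh.write(f">{m.protein_id}/{m.env_start}-{m.env_end}\n{m.aligned_seq}\n")
    else:
        raise FormatError(f"unknown alignment format {format!r}")


def write_alignments(fams: Iterable[DomainFamilyAlignment], path: str | Path) -> None:
    """Write several families into one Stockholm file."""
    with open(path, "w") as fh:
        for fam in fams:
            fh.write(_stockholm_block(fam))


def _stockholm_block(fam: DomainFamilyAlignment) -> str:
    match_set = set(fam.match_columns)
    rf = "".join("x" if j in match_set else "." for j in range(fam.n_columns))
    names = [f"{m.protein_id}/{m.env_start}-{m.env_end}" for m in fam.members]
    width = max(len(n) for n in names + ["#=GC RF"]) + 2
    lines = ["# STOCKHOLM 1.0", f"#=GF AC {fam.family_id}"]
    for name, m in zip(names, fam.members):
        lines.append(f"{name:<{width}}{m.aligned_seq}")
    lines.append(f"{'#=GC RF':<{width}}{rf}")
    lines.append("//")
    return "\n".join(lines) + "\n"
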