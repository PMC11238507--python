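"""Possible-SNV enumeration, consequence calls and variant-space joins.

Every coding transcript of length L (in coding bases) has exactly 3L
possible single-nucleotide variants. This module enumerates all of them,
classifies their protein consequence with the standard nuclear codon
table, attaches the trinucleotide reference context (on the coding
strand), and joins two external layers onto that space:

* observed population variants, through the rarity filter (a possible SNV
  is "observed rare" iff a matching allele was seen at 0 < AF < 0.1%;
  alleles at AF >= 0.1% are common and leave the assessable set entirely);
* domain meta-positions from :mod:`hmconstraint.domainmap`, through the
  identity between codon index and protein position.

Coordinates are 1-based genomic in all I/O (VCF convention) and 0-based
half-open internally; protein positions are 1-based.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import DataError, ModelError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> single-letter amino acid, '*' for stop (standard nuclear code)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

CONSEQUENCES = ("missense", "synonymous", "nonsense", "stop_lost", "start_lost")

#: columns of the possible-variant table produced by :func:`enumerate_snvs`
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "transcript_id", "gene_id", "protein_id",
    "strand", "cds_pos", "codon_index", "aa_ref", "aa_alt", "consequence",
    "context",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """A coding transcript: spliced CDS plus its genomic exon map.

    ``cds_exons`` are genomic intervals, 0-based half-open, sorted by
    genomic start. For minus-strand transcripts the spliced CDS is the
    reverse complement of the concatenated exon sequence.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    cds_seq: str
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.protein_id:
            self.protein_id = self.transcript_id
        self.cds_seq = self.cds_seq.upper()
        L = len(self.cds_seq)
        if L == 0 or L % 3:
            raise ModelError(f"{self.transcript_id}: CDS length {L} not a positive multiple of 3")
        exon_len = sum(e - s for s, e in self.cds_exons)
        if exon_len != L:
            raise ModelError(
                f"{self.transcript_id}: exons cover {exon_len} bp but CDS is {L} bp"
            )
        if any(e <= s for s, e in self.cds_exons):
            raise ModelError(f"{self.transcript_id}: empty or inverted exon")
        starts = [s for s, _ in self.cds_exons]
        if starts != sorted(starts):
            raise ModelError(f"{self.transcript_id}: exons not sorted by genomic start")
        prot = self.protein()
        if "*" in prot[:-1]:
            raise ModelError(f"{self.transcript_id}: internal stop codon")

    def protein(self) -> str:
        return str(Seq(self.cds_seq).translate())

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    def genomic_positions(self) -> np.ndarray:
        """0-based genomic position of each CDS base, in coding order."""
        chunks = [np.arange(s, e) for s, e in self.cds_exons]
        pos = np.concatenate(chunks)
        if self.strand == "-":
            pos = pos[::-1]
        return pos


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into memory as chrom -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def read_transcripts(
    cds_fasta: str | Path, exon_table: str | Path
) -> list[TranscriptModel]:
    """Build transcript models from a CDS FASTA and an exon coordinate TSV.

    The exon table has columns transcript_id, gene_id, chrom, strand,
    exon_start, exon_end (1-based inclusive genomic coordinates, one row
    per coding exon).
    """
    from Bio import SeqIO

    cds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    tbl = pd.read_csv(exon_table, sep="\t", dtype={"chrom": str})
    out = []
    for tid, grp in tbl.groupby("transcript_id", sort=True):
        if tid not in cds:
            raise DataError(f"transcript {tid} in exon table but not in CDS FASTA")
        grp = grp.sort_values("exon_start")
        exons = [(int(s) - 1, int(e)) for s, e in zip(grp["exon_start"], grp["exon_end"])]
        out.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(grp["gene_id"].iloc[0]),
                chrom=str(grp["chrom"].iloc[0]),
                strand=str(grp["strand"].iloc[0]),
                cds_exons=exons,
                cds_seq=cds[tid],
            )
        )
    return out


def trinucleotide_context(
    transcript: TranscriptModel,
    cds_pos: int,
    genome: Mapping[str, str] | None = None,
) -> str:
    """Reference 3-mer around a CDS base, reported on the coding strand.

    Mutability is a property of the genomic neighbourhood, so flanking
    bases are read from the genome when one is supplied — this handles
    exon junctions correctly. Without a genome, a flank is taken from the
    spliced CDS only when the neighbouring CDS base is also the genomic
    neighbour; otherwise it is 'N' and the variant is unassessable.
    """
    L = len(transcript.cds_seq)
    if not 1 <= cds_pos <= L:
        raise ValueError(f"cds_pos {cds_pos} outside 1..{L}")
    gpos = transcript.genomic_positions()
    g = int(gpos[cds_pos - 1])
    if genome is not None:
        chrom_seq = genome[transcript.chrom]
        lo, hi = g - 1, g + 2
        if lo < 0 or hi > len(chrom_seq):
            return "N" * 3
        window = chrom_seq[lo:hi]
        return revcomp(window) if transcript.strand == "-" else window

    def flank(offset: int) -> str:
        idx = cds_pos - 1 + offset
        if not 0 <= idx < L:
            return "N"
        step = int(gpos[idx]) - g
        adjacent = step == (offset if transcript.strand == "+" else -offset)
        return transcript.cds_seq[idx] if adjacent else "N"

    return flank(-1) + transcript.cds_seq[cds_pos - 1] + flank(+1)


def _consequence(codon_index: int, ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    aa_ref = CODON_TO_AA[ref_codon]
    aa_alt = CODON_TO_AA[alt_codon]
    if codon_index == 1 and alt_codon != "ATG":
        cons = "start_lost"
    elif aa_ref == aa_alt:
        cons = "synonymous"
    elif aa_alt == "*":
        cons = "nonsense"
    elif aa_ref == "*":
        cons = "stop_lost"
    else:
        cons = "missense"
    return aa_ref, aa_alt, cons


def enumerate_snvs(
    transcript: TranscriptModel,
    genome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Enumerate all 3L possible SNVs of a transcript.

    Returns one row per (CDS position, alternate base) with genomic
    coordinates (strand-aware), protein consequence and coding-strand
    trinucleotide context. See :data:`VARIANT_COLUMNS`.
    """
    t = transcript
    L = len(t.cds_seq)
    gpos = t.genomic_positions()
    contexts = [trinucleotide_context(t, p, genome) for p in range(1, L + 1)]

    rows = []
    for i in range(L):
        cds_ref = t.cds_seq[i]
        codon_index = i // 3 + 1
        within = i % 3
        codon = t.cds_seq[i - within : i - within + 3]
        g = int(gpos[i]) + 1  # 1-based genomic
        for alt in BASES:
            if alt == cds_ref:
                continue
            alt_codon = codon[:within] + alt + codon[within + 1 :]
            aa_ref, aa_alt, cons = _consequence(codon_index, codon, alt_codon)
            if t.strand == "+":
                g_ref, g_alt = cds_ref, alt
            else:
                g_ref, g_alt = revcomp(cds_ref), revcomp(alt)
            rows.append(
                (
                    t.chrom, g, g_ref, g_alt, t.transcript_id, t.gene_id,
                    t.protein_id, t.strand, i + 1, codon_index, aa_ref, aa_alt,
                    cons, contexts[i],
                )
            )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    assert len(df) == 3 * L
    return df


def enumerate_all(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    frames = [enumerate_snvs(t, genome) for t in transcripts]
    if not frames:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# observed variants and the rarity filter

OBSERVED_COLUMNS = ["chrom", "pos", "ref", "alt", "af"]


def read_observed_variants(path: str | Path) -> pd.DataFrame:
    """Read observed population variants from a VCF (AF INFO, PASS) or TSV."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".bcf", ".gz"}:
        return _read_observed_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(OBSERVED_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: observed-variant TSV missing columns {sorted(missing)}")
    return df[OBSERVED_COLUMNS].copy()


def _read_observed_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.filter.keys() and "PASS" not in rec.filter.keys():
                continue
            afs = rec.info.get("AF", None)
            if afs is None:
                continue
            if not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for alt, af in zip(rec.alts or (), afs):
                if alt is None or len(rec.ref) != 1 or len(alt) != 1:
                    continue  # SNVs only
                rows.append((rec.chrom, rec.pos, rec.ref, alt, float(af)))
    return pd.DataFrame(rows, columns=OBSERVED_COLUMNS)


def apply_rarity_filter(
    possible: pd.DataFrame,
    observed: pd.DataFrame,
    maf_threshold: float = 0.001,
) -> pd.DataFrame:
    """Flag each possible SNV as observed-rare, common, or absent.

    Adds two boolean columns:

    ``observed_rare``
        an exact (chrom, pos, ref, alt) match exists with 0 < AF < threshold;
    ``common``
        a match exists with AF >= threshold. Common alleles are excluded
        from both the observed and the expected side of the constraint
        calculation downstream.

    Alleles reported more than once keep their maximum AF (logged).
    """
    if not 0 < maf_threshold < 1:
        raise ValueError("maf_threshold must be in (0, 1)")
    key = ["chrom", "pos", "ref", "alt"]
    obs = observed.copy()
    if (obs["af"] < 0).any() or (obs["af"] > 1).any():
        raise DataError("allele frequencies must lie in [0, 1]")
    n_dup = obs.duplicated(subset=key).sum()
    if n_dup:
        logger.warning("observed variants: %d duplicate allele records, keeping max AF", n_dup)
        obs = obs.groupby(key, as_index=False)["af"].max()
    out = possible.merge(obs[key + ["af"]], on=key, how="left")
    af = out["af"]
    out["observed_rare"] = (af > 0) & (af < maf_threshold)
    out["common"] = af >= maf_threshold
    return out


def join_meta_positions(
    possible: pd.DataFrame, meta_table: pd.DataFrame
) -> pd.DataFrame:
    """Annotate variants with their domain meta-position, if any.

    ``meta_table`` is the long-format table from
    :func:`hmconstraint.domainmap.meta_positions_to_frame`; protein
    position equals codon index (transcript -> protein identity). Variants
    whose residue lies outside match columns stay unannotated
    (family_id/column NA). Synonymous variants are joined too: the
    expectation model is calibrated on them.
    """
    mt = meta_table.rename(columns={"protein_position": "codon_index"})
    mt = mt[["protein_id", "codon_index", "family_id", "column", "n_copies"]]
    dups = mt.duplicated(subset=["protein_id", "codon_index"])
    if dups.any():
        # a residue belongs to at most one meta-position per family by
        # construction; across families keep the first (sorted) family
        mt = mt[~dups]
    return possible.merge(mt, on=["protein_id", "codon_index"], how="left")
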