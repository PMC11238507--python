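"""Shared fixtures: hand-built toy alignments/transcripts and one small
simulated study. All fixtures are generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from hmconstraint import simgen
from hmconstraint.varspace import TranscriptModel, revcomp

# A 3-member family with internal gaps, an insert column (RF '.') and
# lowercase insert residues. Hand-derived facts (column walk):
#   match columns = {0,1,2,4,5,6}
#   A1/3-7: 3->0, 4->1, 5->2, 6->4, 7->5
#   B1/1-5: 1->0, 2->2, 4->4, 5->6          (pos 3 = insert residue 'x')
#   C1/2-8: 2->0, 3->1, 4->2, 6->4, 7->5, 8->6   (pos 5 = insert 'e')
TOY_STOCKHOLM = """\
# STOCKHOLM 1.0
#=GF AC PFTOY
A1/3-7   ACD.EF-
B1/1-5   A-DxE-G
C1/2-8   GCDeEFW
#=GC RF  xxx.xxx
//
"""

TOY_MAPPINGS = {
    "A1": {3: 0, 4: 1, 5: 2, 6: 4, 7: 5},
    "B1": {1: 0, 2: 2, 4: 4, 5: 6},
    "C1": {2: 0, 3: 1, 4: 2, 6: 4, 7: 5, 8: 6},
}
TOY_COPY_COUNTS = {0: 3, 1: 2, 2: 3, 4: 3, 5: 2, 6: 2}


@pytest.fixture
def toy_stockholm(tmp_path):
    p = tmp_path / "toy.sto"
    p.write_text(TOY_STOCKHOLM)
    return p


def place_cds(
    cds: str,
    strand: str = "+",
    chrom: str = "chrT",
    transcript_id: str = "T1",
    gene_id: str = "G1",
    split: int | None = None,
    intron: int = 20,
    flank: int = 8,
) -> tuple[TranscriptModel, dict[str, str]]:
    """Embed an exact CDS in a deterministic toy genome (two exons)."""
    rng = np.random.default_rng(abs(hash((cds, strand, chrom))) % 2**31)
    L = len(cds)
    if split is None:
        split = L // 2
    e1, e2 = cds[:split], cds[split:]
    iv = "".join(rng.choice(list("ACGT"), size=intron))
    lf = "".join(rng.choice(list("ACGT"), size=flank))
    rf = "".join(rng.choice(list("ACGT"), size=flank))
    if strand == "+":
        genome = lf + e1 + iv + e2 + rf
        x = len(lf)
        exons = [(x, x + len(e1)), (x + len(e1) + intron, x + len(e1) + intron + len(e2))]
    else:
        genome = lf + revcomp(e2) + iv + revcomp(e1) + rf
        x = len(lf)
        exons = [(x, x + len(e2)), (x + len(e2) + intron, x + len(e2) + intron + len(e1))]
    t = TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_exons=exons,
        cds_seq=cds,
    )
    return t, {chrom: genome}


def oracle_consequence(cds: str, i: int, alt: str) -> tuple[str, str, str]:
    """Classify an SNV at 0-based CDS index i by re-translating the whole
    mutated CDS with Biopython — independent of the enumeration path."""
    mutated = cds[:i] + alt + cds[i + 1 :]
    ci = i // 3
    aa_ref = str(Seq(cds[3 * ci : 3 * ci + 3]).translate())
    aa_alt = str(Seq(mutated[3 * ci : 3 * ci + 3]).translate())
    if ci == 0 and mutated[:3] != "ATG":
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


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A valid CDS: ATG start, no internal stop, stop at the end."""
    aas = rng.choice(list(simgen.AMINO_ACIDS), size=n_codons - 2)
    body = "".join(rng.choice(simgen._AA_TO_CODONS[a]) for a in aas)
    return "ATG" + body + rng.choice(simgen.STOP_CODONS)


@pytest.fixture(scope="session")
def small_config() -> simgen.SimConfig:
    return simgen.SimConfig(
        seed=11,
        n_families=2,
        copies_per_family=(4, 6),
        columns_per_family=(10, 14),
        n_filler_genes=2,
        filler_length=60,
        cohort_scale=0.6,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simgen.gen_reference(small_config)


@pytest.fixture(scope="session")
def small_master(small_reference):
    return simgen.annotate_reference(small_reference)


@pytest.fixture(scope="session")
def default_reference():
    """Default study conditions (per-column missense expectation near 20)."""
    return simgen.gen_reference(simgen.SimConfig(seed=5))


@pytest.fixture(scope="session")
def default_master(default_reference):
    return simgen.annotate_reference(default_reference)
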