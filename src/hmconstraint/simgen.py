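"""Synthetic study generator with known ground truth.

Generates everything the constraint pipeline consumes — domain family
alignments, the transcripts and toy genome that carry the domain copies,
a trinucleotide rate table with CpG methylation strata, coverage and
methylation tracks, an observed population cohort simulated under
per-column purifying selection, and labelled evaluation sets — all
deterministic under a seed.

The generative model mirrors the quantity the score estimates: each
possible SNV is present as a rare variant in the cohort with probability
1 - exp(-(1 - s) * k_true * mu_adj), i.e. Poisson presence at the
neutral rate thinned by the column's depletion s (s = 0 for synonymous
and non-domain variants). Domain copies are sequence-diverged only at
weakly selected columns, so alignments are correct by construction;
alignment inference is not simulated. A configurable fraction of sites
instead carries a common allele (AF >= 0.1%) to exercise the rarity
filter.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import domainmap, nullmodel, varspace
from .domainmap import AlignedMember, DomainFamilyAlignment
from .errors import ConfigError
from .nullmodel import CoverageModel, RateTable, is_cpg_context
from .varspace import CODON_TO_AA, TranscriptModel, revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
STOP_CODONS = _AA_TO_CODONS.pop("*")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults define the standard conditions."""

    seed: int = 0
    n_families: int = 4
    copies_per_family: tuple[int, int] = (12, 20)
    columns_per_family: tuple[int, int] = (20, 35)
    n_filler_genes: int = 3
    filler_length: int = 120  # filler protein length (aa), calibration mass
    #: expected rare-variant count per unit of relative mutability (k_true);
    #: the default keeps per-variant presence probabilities small (~0.15)
    #: while per-column missense expectations land near 20, the regime in
    #: which aggregation over copies is what creates statistical power
    cohort_scale: float = 0.15
    #: per-column depletion s: ("uniform", lo, hi) | ("constant", s) |
    #: ("beta", a, b) | explicit sequence recycled over columns
    selection_profile: tuple | Sequence[float] = ("uniform", 0.0, 0.9)
    #: P(pathogenic | s): step rule ("step", s_threshold, p_low, p_high)
    label_rule: tuple = ("step", 0.8, 0.02, 0.95)
    n_pathogenic: int = 250
    n_benign: int = 250
    n_case_dnms: int = 150
    n_control_dnms: int = 100
    dnm_enrichment: float = 20.0  # case DNM weight boost at s >= 0.8 columns
    divergence: float = 0.3  # per-column substitution rate between copies
    p_insert: float = 0.2  # per-copy chance of a 1-2 residue insertion
    p_delete: float = 0.03  # per-copy, per-column chance of a deletion
    common_fraction: float = 0.01  # sites carrying a common (AF >= 0.1%) allele
    maf_log10_range: tuple[float, float] = (-5.0, -3.1)  # rare AF spectrum
    depth: float = 50.0  # sequencing depth everywhere (uncorrected by default)
    intron_length: int = 60
    flank_length: int = 30

    def __post_init__(self) -> None:
        for lo, hi in (self.copies_per_family, self.columns_per_family):
            if lo < 1 or hi < lo:
                raise ConfigError("ranges must satisfy 1 <= lo <= hi")
        if self.n_families < 0 or self.cohort_scale <= 0:
            raise ConfigError("n_families must be >= 0 and cohort_scale > 0")
        if not 0 <= self.common_fraction < 1:
            raise ConfigError("common_fraction must be in [0, 1)")

    def selection_values(self, n: int, rng: np.random.Generator) -> np.ndarray:
        prof = self.selection_profile
        if isinstance(prof, tuple) and prof and isinstance(prof[0], str):
            kind = prof[0]
            if kind == "uniform":
                s = rng.uniform(prof[1], prof[2], size=n)
            elif kind == "constant":
                s = np.full(n, float(prof[1]))
            elif kind == "beta":
                s = rng.beta(prof[1], prof[2], size=n)
            else:
                raise ConfigError(f"unknown selection profile {kind!r}")
        else:
            vals = np.asarray(list(prof), dtype=float)
            s = np.resize(vals, n)
        if ((s < 0) | (s > 1)).any():
            raise ConfigError("selection s must lie in [0, 1]")
        return s

    def p_pathogenic(self, s: np.ndarray) -> np.ndarray:
        kind = self.label_rule[0]
        if kind == "step":
            _, thr, p_low, p_high = self.label_rule
            return np.where(np.asarray(s) >= thr, p_high, p_low)
        if kind == "linear":
            _, p0, p1 = self.label_rule
            return p0 + (p1 - p0) * np.asarray(s)
        raise ConfigError(f"unknown label rule {kind!r}")


@dataclass
class SimReference:
    """Generated inputs plus ground truth for one synthetic study."""

    config: SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    alignments: list[DomainFamilyAlignment]
    rates: RateTable
    coverage: pd.DataFrame
    methylation: pd.DataFrame
    truth: pd.DataFrame  # family_id, column, s
    k_true: float

    def meta_table(self) -> pd.DataFrame:
        metas = domainmap.build_meta_positions(self.alignments)
        return domainmap.meta_positions_to_frame(metas)


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [rng.choice(_AA_TO_CODONS[aa]) for aa in protein]
    return "".join(codons)


def _gen_rate_table(rng: np.random.Generator) -> RateTable:
    rates: dict[tuple[str, str, int], float] = {}
    for ctx in nullmodel.ALL_CONTEXTS:
        for alt in "ACGT":
            if alt == ctx[1]:
                continue
            base = float(rng.lognormal(mean=0.0, sigma=0.35))
            rates[(ctx, alt, 0)] = base
            if is_cpg_context(ctx):
                rates[(ctx, alt, 1)] = base * 2.0
                rates[(ctx, alt, 2)] = base * 5.0
    return RateTable(rates)


def _gen_family(
    family_id: str,
    n_copies: int,
    n_columns: int,
    s: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[DomainFamilyAlignment, list[str], list[int]]:
    """One family: aligned copies + per-copy domain protein segments.

    Copies diverge from a consensus with per-column probability
    divergence * (1 - s): strongly selected columns stay conserved.
    Occasional insertions (lowercase + '.' columns) and deletions ('-')
    exercise the full alignment dialect. Returns the alignment, the
    per-copy domain amino-acid strings (residues actually present) and
    the global alignment-column index of each of the n_columns match
    states.
    """
    consensus = rng.choice(list(AMINO_ACIDS), size=n_columns)
    copy_rows: list[list[str]] = []  # per copy: match-state char per column
    inserts: list[tuple[int, str] | None] = []  # (after-column, residues)
    for _ in range(n_copies):
        aa = consensus.copy()
        mutate = rng.random(n_columns) < cfg.divergence * (1.0 - s)
        for j in np.nonzero(mutate)[0]:
            choices = [a for a in AMINO_ACIDS if a != aa[j]]
            aa[j] = rng.choice(choices)
        deleted = rng.random(n_columns) < cfg.p_delete
        row = [("-" if deleted[j] else aa[j]) for j in range(n_columns)]
        copy_rows.append(row)
        if rng.random() < cfg.p_insert:
            after = int(rng.integers(0, n_columns - 1))
            ins = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 3)))).lower()
            inserts.append((after, ins))
        else:
            inserts.append(None)

    # global column layout: match column q, then insert columns of any copy
    # whose insertion follows q (each insertion owns private columns)
    layout: list[tuple[str, int, int]] = []  # (kind, match-col or copy, sub-index)
    match_global: list[int] = []
    for q in range(n_columns):
        match_global.append(len(layout))
        layout.append(("m", q, 0))
        for ci, ins in enumerate(inserts):
            if ins is not None and ins[0] == q:
                for k in range(len(ins[1])):
                    layout.append(("i", ci, k))

    members = []
    domain_seqs = []
    for ci, row in enumerate(copy_rows):
        chars = []
        for kind, a, b in layout:
            if kind == "m":
                chars.append(row[a])
            else:
                chars.append(inserts[ci][1][b] if a == ci else ".")
        aligned = "".join(chars)
        residues = [c for c in aligned if c not in "-."]
        domain_aa = "".join(c.upper() for c in residues)
        env_start = 6  # after Met + 4 N-terminal flank residues
        member = AlignedMember(
            protein_id=f"{family_id}_c{ci}",
            env_start=env_start,
            env_end=env_start + len(residues) - 1,
            aligned_seq=aligned,
        )
        members.append(member)
        domain_seqs.append(domain_aa)

    fam = DomainFamilyAlignment(
        family_id=family_id,
        members=members,
        n_columns=len(layout),
        match_columns=match_global,
    )
    return fam, domain_seqs, match_global


def _place_transcript(
    name: str,
    gene_id: str,
    protein_id: str,
    protein: str,
    chrom: str,
    strand: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[TranscriptModel, str]:
    """Embed a coding sequence in a fresh chromosome, split over two exons."""
    cds = _reverse_translate(protein, rng) + rng.choice(STOP_CODONS)
    L = len(cds)
    split = int(rng.integers(4, L - 4))  # deliberately codon-unaligned sometimes
    e1, e2 = cds[:split], cds[split:]
    intron = _random_seq(rng, cfg.intron_length)
    lflank = _random_seq(rng, cfg.flank_length)
    rflank = _random_seq(rng, cfg.flank_length)
    if strand == "+":
        chrom_seq = lflank + e1 + intron + e2 + rflank
        x1 = len(lflank)
        exons = [(x1, x1 + len(e1)), (x1 + len(e1) + len(intron), x1 + len(e1) + len(intron) + len(e2))]
    else:
        chrom_seq = lflank + revcomp(e2) + intron + revcomp(e1) + rflank
        x1 = len(lflank)
        exons = [(x1, x1 + len(e2)), (x1 + len(e2) + len(intron), x1 + len(e2) + len(intron) + len(e1))]
    t = TranscriptModel(
        transcript_id=name,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_exons=exons,
        cds_seq=cds,
        protein_id=protein_id,
    )
    return t, chrom_seq


def gen_reference(config: SimConfig) -> SimReference:
    """Generate the full reference universe for one synthetic study."""
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    alignments: list[DomainFamilyAlignment] = []
    truth_rows = []
    gene_counter = 0

    for fi in range(config.n_families):
        fam_id = f"PF{90000 + fi:05d}"
        n_copies = int(rng.integers(config.copies_per_family[0], config.copies_per_family[1] + 1))
        n_cols = int(rng.integers(config.columns_per_family[0], config.columns_per_family[1] + 1))
        s = config.selection_values(n_cols, rng)
        fam, domain_seqs, match_global = _gen_family(fam_id, n_copies, n_cols, s, config, rng)
        alignments.append(fam)
        for q, col in enumerate(match_global):
            truth_rows.append((fam_id, col, float(s[q])))
        for ci, domain_aa in enumerate(domain_seqs):
            protein = (
                "M"
                + _random_seq(rng, 4, AMINO_ACIDS)
                + domain_aa
                + _random_seq(rng, 5, AMINO_ACIDS)
            )
            chrom = f"chr{gene_counter + 1}"
            strand = "+" if gene_counter % 2 == 0 else "-"
            t, chrom_seq = _place_transcript(
                name=f"T{gene_counter:03d}",
                gene_id=f"G{gene_counter:03d}",
                protein_id=f"{fam_id}_c{ci}",
                protein=protein,
                chrom=chrom,
                strand=strand,
                cfg=config,
                rng=rng,
            )
            genome[chrom] = chrom_seq
            transcripts.append(t)
            gene_counter += 1

    for _ in range(config.n_filler_genes):
        protein = "M" + _random_seq(rng, config.filler_length - 1, AMINO_ACIDS)
        chrom = f"chr{gene_counter + 1}"
        strand = "+" if gene_counter % 2 == 0 else "-"
        t, chrom_seq = _place_transcript(
            name=f"T{gene_counter:03d}",
            gene_id=f"G{gene_counter:03d}",
            protein_id=f"T{gene_counter:03d}",
            protein=protein,
            chrom=chrom,
            strand=strand,
            cfg=config,
            rng=rng,
        )
        genome[chrom] = chrom_seq
        transcripts.append(t)
        gene_counter += 1

    rates = _gen_rate_table(rng)
    coverage = pd.DataFrame(
        [(c, 0, len(seq), config.depth) for c, seq in genome.items()],
        columns=["chrom", "start", "end", "median_depth"],
    )
    meth_rows = []
    for chrom, seq in genome.items():
        for i in range(len(seq) - 1):
            if seq[i : i + 2] == "CG":
                lvl = int(rng.choice([0, 1, 2], p=[0.2, 0.3, 0.5]))
                meth_rows.append((chrom, i + 1, lvl))
                meth_rows.append((chrom, i + 2, lvl))
    methylation = pd.DataFrame(meth_rows, columns=["chrom", "pos", "level"])
    truth = pd.DataFrame(truth_rows, columns=["family_id", "column", "s"])
    return SimReference(
        config=config,
        genome=genome,
        transcripts=transcripts,
        alignments=alignments,
        rates=rates,
        coverage=coverage,
        methylation=methylation,
        truth=truth,
        k_true=config.cohort_scale,
    )


def annotate_reference(reference: SimReference) -> pd.DataFrame:
    """Master possible-variant table with mu_adj, meta-positions and true s."""
    master = varspace.enumerate_all(reference.transcripts, reference.genome)
    master = nullmodel.attach_site_annotations(
        master, reference.coverage, reference.methylation
    )
    master = nullmodel.adjusted_mu(master, reference.rates, CoverageModel())
    master = varspace.join_meta_positions(master, reference.meta_table())
    master = master.merge(reference.truth, on=["family_id", "column"], how="left")
    master["s"] = master["s"].fillna(0.0)
    master.loc[master["consequence"] != "missense", "s"] = 0.0
    return master


def scale_for_target_expected(reference: SimReference, target: float) -> float:
    """k_true giving a mean per-column missense expectation of ``target``."""
    master = annotate_reference(reference)
    mis = master[(master["consequence"] == "missense") & master["family_id"].notna()]
    per_col = mis.groupby(["family_id", "column"])["mu_adj"].sum()
    return float(target / per_col.mean())


def simulate_cohort(
    reference: SimReference,
    master: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one observed cohort: (chrom, pos, ref, alt, af) table.

    Presence of each possible SNV as a rare variant is Bernoulli with
    p = 1 - exp(-(1 - s) * k_true * mu_adj); a ``common_fraction`` of
    sites instead segregates a common allele (drawn independently of
    selection, AF in [0.002, 0.05]).
    """
    cfg = reference.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if master is None:
        master = annotate_reference(reference)
    mu = master["mu_adj"].fillna(0.0).to_numpy()
    s = master["s"].to_numpy()
    lam = (1.0 - s) * reference.k_true * mu
    p_rare = 1.0 - np.exp(-lam)
    u = rng.random(len(master))
    common = rng.random(len(master)) < cfg.common_fraction
    rare = (~common) & (u < p_rare) & (mu > 0)

    lo, hi = cfg.maf_log10_range
    af = np.zeros(len(master))
    af[rare] = 10.0 ** rng.uniform(lo, hi, size=int(rare.sum()))
    af[common] = rng.uniform(0.002, 0.05, size=int(common.sum()))
    keep = rare | common
    out = master.loc[keep, ["chrom", "pos", "ref", "alt"]].copy()
    out["af"] = af[keep]
    return out.reset_index(drop=True)


def gen_labels(
    reference: SimReference,
    master: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Labelled evaluation sets with ground truth attached.

    ``clinvar``: pathogenic/benign missense variants; P(pathogenic)
    follows the configured label rule in the column's depletion s, benign
    weights are the complement. ``dnm``: case DNMs drawn with mutability
    weights boosted at strongly depleted columns, control DNMs with plain
    mutability weights. Both tables carry the true ``s`` for assertions.
    """
    cfg = reference.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if master is None:
        master = annotate_reference(reference)
    pool = master[
        (master["consequence"] == "missense")
        & master["family_id"].notna()
        & master["assessable"]
    ].reset_index(drop=True)
    if pool.empty:
        raise ConfigError("no domain missense variants to label")
    key = ["chrom", "pos", "ref", "alt", "s"]

    p_path = cfg.p_pathogenic(pool["s"].to_numpy())

    def _sample(weights: np.ndarray, n: int) -> pd.DataFrame:
        w = np.clip(weights, 0.0, None)
        if w.sum() == 0:
            w = np.ones_like(w)
        n = min(n, (w > 0).sum())
        idx = rng.choice(len(pool), size=n, replace=False, p=w / w.sum())
        return pool.iloc[idx][key].copy()

    path = _sample(p_path, cfg.n_pathogenic)
    benign = _sample(1.0 - p_path, cfg.n_benign)
    path["label"] = 1
    benign["label"] = 0
    clinvar = (
        pd.concat([path, benign], ignore_index=True)
        .drop_duplicates(subset=key[:4], keep="first")
        .reset_index(drop=True)
    )

    mu = pool["mu_adj"].to_numpy()
    s = pool["s"].to_numpy()
    case_w = mu * (1.0 + cfg.dnm_enrichment * (s >= 0.8))
    control_w = mu
    case = _sample(case_w, cfg.n_case_dnms)
    control = _sample(control_w, cfg.n_control_dnms)
    case["label"], case["group"] = 1, "case"
    control["label"], control["group"] = 0, "control"
    dnm = (
        pd.concat([case, control], ignore_index=True)
        .drop_duplicates(subset=key[:4], keep="first")
        .reset_index(drop=True)
    )
    return {"clinvar": clinvar, "dnm": dnm}


# ---------------------------------------------------------------------------
# fixture materialisation


def write_reference(reference: SimReference, outdir: str | Path) -> dict[str, Path]:
    """Write every reference artifact in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "cds": outdir / "cds.fa",
        "exons": outdir / "exons.tsv",
        "alignments": outdir / "alignments.sto",
        "rates": outdir / "rates.tsv",
        "coverage": outdir / "coverage.tsv",
        "methylation": outdir / "methylation.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in reference.genome.items():
            fh.write(f">{chrom}\n{seq}\n")
    with open(paths["cds"], "w") as fh:
        for t in reference.transcripts:
            fh.write(f">{t.transcript_id}\n{t.cds_seq}\n")
    exon_rows = [
        (t.transcript_id, t.gene_id, t.chrom, t.strand, s + 1, e)
        for t in reference.transcripts
        for s, e in t.cds_exons
    ]
    pd.DataFrame(
        exon_rows,
        columns=["transcript_id", "gene_id", "chrom", "strand", "exon_start", "exon_end"],
    ).to_csv(paths["exons"], sep="\t", index=False)
    domainmap.write_alignments(reference.alignments, paths["alignments"])
    reference.rates.write(paths["rates"])
    reference.coverage.to_csv(paths["coverage"], sep="\t", index=False)
    reference.methylation.to_csv(paths["methylation"], sep="\t", index=False)
    reference.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def make_fixtures(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise a complete small test universe (reference + cohort + labels)."""
    outdir = Path(outdir)
    reference = gen_reference(config)
    paths = write_reference(reference, outdir)
    master = annotate_reference(reference)
    observed = simulate_cohort(reference, master)
    labels = gen_labels(reference, master)
    paths["observed"] = outdir / "observed.tsv"
    observed.to_csv(paths["observed"], sep="\t", index=False)
    paths["labels_clinvar"] = outdir / "labels_clinvar.tsv"
    labels["clinvar"].to_csv(paths["labels_clinvar"], sep="\t", index=False)
    paths["labels_dnm"] = outdir / "labels_dnm.tsv"
    labels["dnm"].to_csv(paths["labels_dnm"], sep="\t", index=False)
    return paths
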