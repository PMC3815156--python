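"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the four-cohort breast-tumor study design (benign,
ER+, triple-negative, HER2-positive; 8 samples per group by default):
negative-binomial gene counts with planted HER2-specific differential
expression, multinomial isoform splits with planted splicing switches,
dual-aligner mpileup files with planted somatic variants plus the artifact
classes the variant filters target, a stochastic-block-model interactome
with planted communities, and EC50 / survival tables with planted gene
associations.  Truth files are side-cars; the pipeline never reads them.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq

GROUPS = ("benign", "ER+", "TN", "HER2")

_READ_END_WINDOW = 5  # matches the variant caller's default end-bias window


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design where one is stated (4 groups x 8
    samples, 2x50 nt reads, four or more alternate reads for a confident
    variant) and otherwise hold a realistic, recoverable regime: a 2-fold
    log2 shift for planted DE genes, moderate negative-binomial
    overdispersion, a 0.4 isoform-proportion switch, variant depths of
    20-60 with VAFs 0.2-0.6.
    """

    n_per_group: int = 8
    n_genes: int = 600
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.15
    n_isoforms_per_gene: int = 2
    n_as_genes: int = 20
    splice_shift: float = 0.4
    n_variants: int = 20
    variant_depth_range: tuple[int, int] = (20, 60)
    vaf_range: tuple[float, float] = (0.2, 0.6)
    artifact_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "strand_biased": 0.25,
            "end_biased": 0.25,
            "low_depth": 0.25,
            "germline_shared": 0.5,
        }
    )
    n_noncoding: int = 2
    read_length: int = 50
    n_network_genes: int = 300
    community_sizes: tuple[int, ...] = (40, 30, 30, 25)
    p_within: float = 0.5
    p_between: float = 0.02
    n_patients: int = 200
    n_cell_lines: int = 18
    hazard_effect: float = 1.0
    drug_effect: float = 2.0
    censoring: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group, self.n_genes, self.n_isoforms_per_gene) < 1:
            raise ValueError("dimensions must be positive")
        if self.n_de_genes > self.n_genes:
            raise ValueError("more planted DE genes than genes")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.splice_shift <= 1:
            raise ValueError("splice_shift must lie in [0, 1]")
        lo, hi = self.vaf_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("vaf_range must lie within (0, 1]")
        for name, frac in self.artifact_fractions.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"artifact fraction {name} outside [0, 1]")
        if not (0 <= self.p_within <= 1 and 0 <= self.p_between <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if sum(self.community_sizes) > self.n_network_genes:
            raise ValueError("community sizes exceed network gene count")
        if self.read_length < 2 * _READ_END_WINDOW:
            raise ValueError("read_length shorter than twice the end-bias window")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator per simulation stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class VariantTruth:
    sample: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    klass: str  # true_somatic | strand_artifact | end_artifact | low_depth | germline | shared | non_exonic
    gene: str
    consequence: str


@dataclass
class TruthSet:
    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> direction
    spliced_transcripts: set[str] = field(default_factory=set)
    variants: list[VariantTruth] = field(default_factory=list)
    communities: dict[str, int] = field(default_factory=dict)
    outcome_genes: set[str] = field(default_factory=set)
    drug_genes: set[str] = field(default_factory=set)


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def sample_names(config: SimulationConfig) -> list[str]:
    return [f"{g}_{i + 1}" for g in GROUPS for i in range(config.n_per_group)]


def sample_groups(config: SimulationConfig) -> pd.Series:
    names = sample_names(config)
    return pd.Series({s: s.rsplit("_", 1)[0] for s in names}, name="group")


# ---------------------------------------------------------------------------
# gene counts


def generate_cohort_counts(config: SimulationConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Negative-binomial gene counts with HER2-specific planted DE genes.

    Gene base means are log-normal (median ~100 reads, comfortably above
    the detection filter); planted genes have their HER2-group mean shifted
    by ``de_log2fc`` log2 units, half up and half down.  Per-sample library
    scale factors (2**U(-0.5, 0.5)) are applied so normalization has work
    to do.
    """
    rng = config.rng(1)
    genes = _gene_names(config.n_genes)
    samples = sample_names(config)
    groups = sample_groups(config)

    base_mean = np.exp(rng.normal(np.log(100.0), 0.8, size=config.n_genes))
    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    directions = np.where(np.arange(config.n_de_genes) % 2 == 0, 1, -1)
    truth = TruthSet(
        de_genes={genes[i]: int(d) for i, d in zip(de_idx, directions)}
    )

    scale = np.exp2(rng.uniform(-0.5, 0.5, size=len(samples)))
    mu = np.tile(base_mean[:, None], (1, len(samples)))
    her2_cols = np.array([groups[s] == "HER2" for s in samples])
    for i, d in zip(de_idx, directions):
        mu[i, her2_cols] *= 2.0 ** (d * config.de_log2fc)
    mu = mu * scale[None, :]

    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=genes, columns=samples), truth


# ---------------------------------------------------------------------------
# isoform counts


def generate_isoform_counts(
    counts: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, TruthSet]:
    """Multinomial isoform splits of the gene counts with planted switches.

    Every gene gets ``n_isoforms_per_gene`` isoforms with Dirichlet base
    proportions shared across samples; for planted genes the HER2 samples
    move ``splice_shift`` proportion mass from the first isoform to the
    second.  Isoform counts sum exactly to the gene count per sample.
    Returns (isoform counts, transcript->gene map, truth).
    """
    if config.n_isoforms_per_gene < 1:
        raise ValueError("n_isoforms_per_gene must be >= 1")
    rng = config.rng(2)
    k = config.n_isoforms_per_gene
    groups = sample_groups(config).reindex(counts.columns)
    her2 = (groups == "HER2").to_numpy()

    as_idx = rng.choice(len(counts.index), size=min(config.n_as_genes, len(counts.index)), replace=False)
    as_genes = {counts.index[i] for i in as_idx}

    tx_rows = []
    tx_names = []
    t2g = {}
    truth = TruthSet()
    for gene in counts.index:
        base = rng.dirichlet(np.full(k, 5.0))
        if k >= 2 and gene in as_genes:
            shifted = base.copy()
            delta = min(config.splice_shift, base[0])
            shifted[0] -= delta
            shifted[1] += delta
        else:
            shifted = base
        names = [f"{gene}.T{j + 1}" for j in range(k)]
        if k >= 2 and gene in as_genes and config.splice_shift > 0:
            truth.spliced_transcripts.update(names[:2])
        gene_counts = counts.loc[gene].to_numpy(dtype=int)
        mat = np.zeros((k, gene_counts.size), dtype=int)
        for j, total in enumerate(gene_counts):
            props = shifted if her2[j] else base
            mat[:, j] = rng.multinomial(total, props)
        tx_rows.append(mat)
        tx_names.extend(names)
        t2g.update({nm: gene for nm in names})

    iso = pd.DataFrame(np.vstack(tx_rows), index=tx_names, columns=counts.columns)
    return iso, pd.Series(t2g, name="gene"), truth


# ---------------------------------------------------------------------------
# pileups, genome, gene model, known sites

_GENE_SPACING = 400
_EXON_LEN = 300
_GENOME_MARGIN = 100


def _classify_substitution(seq: str, gene_start: int, strand: str, pos0: int, alt: str) -> str:
    """Codon consequence of a substitution inside a single-exon CDS."""
    idx = pos0 - gene_start
    cds = seq[gene_start : gene_start + _EXON_LEN]
    mutated = cds[:idx] + alt + cds[idx + 1 :]
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        idx = _EXON_LEN - 1 - idx
    ci = idx // 3
    ref_aa = str(Seq(cds[ci * 3 : ci * 3 + 3]).translate())
    alt_aa = str(Seq(mutated[ci * 3 : ci * 3 + 3]).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stopgain"
    if ref_aa == "*":
        return "stoploss"
    return "missense"


def _pick_nonsynonymous(rng, seq, gene_start, strand, pos0):
    """Alt allele at pos0 giving a missense/stopgain change, or None when
    every substitution is synonymous (4-fold degenerate third positions)."""
    ref = seq[pos0]
    alts = [b for b in "ACGT" if b != ref]
    rng.shuffle(alts)
    for alt in alts:
        csq = _classify_substitution(seq, gene_start, strand, pos0, alt)
        if csq in ("missense", "stopgain"):
            return alt, csq
    return None, None


class _PileupSite:
    """One planted site's read evidence for one sample and one aligner."""

    def __init__(self, chrom, pos, ref, alt, ref_plus, ref_minus, alt_plus, alt_minus, alt_offsets, ref_offsets):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt
        self.ref_plus, self.ref_minus = ref_plus, ref_minus
        self.alt_plus, self.alt_minus = alt_plus, alt_minus
        self.alt_offsets, self.ref_offsets = alt_offsets, ref_offsets

    def line(self, with_markers: bool = False) -> str:
        symbols = (
            ["."] * self.ref_plus
            + [","] * self.ref_minus
            + [self.alt] * self.alt_plus
            + [self.alt.lower()] * self.alt_minus
        )
        offsets = list(self.ref_offsets) + list(self.alt_offsets)
        depth = len(symbols)
        quals = "I" * depth
        rendered = list(symbols)
        if with_markers and depth >= 2:
            rendered[0] = "^~" + rendered[0]
            rendered[-1] = rendered[-1] + "$"
        return "\t".join(
            [
                self.chrom,
                str(self.pos),
                self.ref,
                str(depth),
                "".join(rendered),
                quals,
                ",".join(str(o) for o in offsets),
            ]
        )


def _split_strands(total: int) -> tuple[int, int]:
    return (total + 1) // 2, total // 2


def generate_pileup_pair(config: SimulationConfig, outdir: str | os.PathLike) -> TruthSet:
    """Write per-sample dual-dialect pileups plus genome/gene-model files.

    Emits ``<sample>.bwa.pileup`` and ``<sample>.tophat.pileup`` for every
    sample carrying at least one planted site, ``genome.fa``,
    ``genes.refflat`` and ``known_sites.vcf``.  Planted classes:

    * ``true_somatic`` — clean coding variants in 1-2 HER2 samples; depth,
      VAF, both-strand support and interior read offsets all clear the
      filter chain by construction.
    * ``strand_artifact`` — alternate reads on one strand only in the
      TopHat dialect.
    * ``end_artifact`` — all alternate read offsets inside the end window.
    * ``low_depth`` — total depth 3 with 2 alternate reads.
    * ``germline`` — clean but present in the known-sites catalog.
    * ``shared`` — clean but present in one sample of every group.
    * ``non_exonic`` — clean but intergenic.
    """
    rng = config.rng(3)
    os.makedirs(outdir, exist_ok=True)
    fr = config.artifact_fractions
    n_true = config.n_variants
    n_strand = round(fr.get("strand_biased", 0) * n_true)
    n_end = round(fr.get("end_biased", 0) * n_true)
    n_low = round(fr.get("low_depth", 0) * n_true)
    n_germ_total = round(fr.get("germline_shared", 0) * n_true)
    n_germ = n_germ_total // 2
    n_shared = n_germ_total - n_germ
    n_coding = n_true + n_strand + n_end + n_low + n_germ + n_shared

    chrom = "chr1"
    genome_len = _GENOME_MARGIN * 2 + n_coding * _GENE_SPACING + config.n_noncoding * 50
    seq = "".join(rng.choice(list("ACGT"), size=genome_len))
    samples = sample_names(config)
    her2_samples = [s for s in samples if s.startswith("HER2")]
    other_groups = [g for g in GROUPS if g != "HER2"]

    # gene model: one single-exon CDS gene per coding variant slot
    refflat_lines = []
    gene_starts = []
    for i in range(n_coding):
        start = _GENOME_MARGIN + i * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        gene = f"GENE{i + 1:04d}"
        refflat_lines.append(
            "\t".join(
                [
                    gene,
                    f"{gene}.T1",
                    chrom,
                    strand,
                    str(start),
                    str(start + _EXON_LEN),
                    str(start),
                    str(start + _EXON_LEN),
                    "1",
                    f"{start},",
                    f"{start + _EXON_LEN},",
                ]
            )
        )
        gene_starts.append((start, strand, gene))

    truth = TruthSet()
    per_sample: dict[str, dict[str, list[_PileupSite]]] = {
        s: {"bwa": [], "tophat": []} for s in samples
    }
    known_sites: list[tuple[str, int, str, str]] = []

    def clean_evidence(depth, vaf):
        alt_n = max(4, int(round(depth * vaf)))
        alt_n = min(alt_n, depth - 2)
        ap, am = _split_strands(alt_n)
        ref_n = depth - alt_n
        rp, rm = _split_strands(ref_n)
        offs = rng.integers(_READ_END_WINDOW, config.read_length // 2, size=alt_n)
        roffs = rng.integers(0, config.read_length // 2, size=ref_n)
        return rp, rm, ap, am, list(map(int, offs)), list(map(int, roffs))

    def add_site(sample, pos0, ref, alt, kind):
        depth = int(rng.integers(*config.variant_depth_range))
        vaf = float(rng.uniform(*config.vaf_range))
        rp, rm, ap, am, offs, roffs = clean_evidence(depth, vaf)
        if kind == "strand":
            bwa = _PileupSite(chrom, pos0 + 1, ref, alt, rp, rm, ap, am, offs, roffs)
            ap2 = ap + am
            th = _PileupSite(chrom, pos0 + 1, ref, alt, rp, rm, ap2, 0, offs, roffs)
        elif kind == "end":
            offs = list(map(int, rng.integers(0, _READ_END_WINDOW, size=ap + am)))
            bwa = _PileupSite(chrom, pos0 + 1, ref, alt, rp, rm, ap, am, offs, roffs)
            th = _PileupSite(chrom, pos0 + 1, ref, alt, rp, rm, ap, am, offs, roffs)
        elif kind == "low":
            site = _PileupSite(chrom, pos0 + 1, ref, alt, 1, 0, 1, 1, [10, 12], [8])
            bwa = th = site
        else:
            bwa = _PileupSite(chrom, pos0 + 1, ref, alt, rp, rm, ap, am, offs, roffs)
            th = _PileupSite(chrom, pos0 + 1, ref, alt, rp, rm, ap, am, offs, roffs)
        per_sample[sample]["bwa"].append(bwa)
        per_sample[sample]["tophat"].append(th)

    slot = 0

    def coding_slot():
        nonlocal slot
        start, strand, gene = gene_starts[slot]
        slot += 1
        while True:
            pos0 = start + int(rng.integers(3, _EXON_LEN - 3))
            alt, csq = _pick_nonsynonymous(rng, seq, start, strand, pos0)
            if alt is not None:
                return start, strand, gene, pos0, alt, csq

    def plant(klass, kind, sample_list, in_known=False):
        start, strand, gene, pos0, alt, csq = coding_slot()
        ref = seq[pos0]
        for s in sample_list:
            add_site(s, pos0, ref, alt, kind)
            truth.variants.append(
                VariantTruth(s, chrom, pos0 + 1, ref, alt, klass, gene, csq)
            )
        if in_known:
            known_sites.append((chrom, pos0 + 1, ref, alt))

    for _ in range(n_true):
        n_carriers = 2 if rng.random() < 0.25 and len(her2_samples) >= 2 else 1
        carriers = list(rng.choice(her2_samples, size=n_carriers, replace=False))
        plant("true_somatic", "clean", carriers)
    for _ in range(n_strand):
        plant("strand_artifact", "strand", [str(rng.choice(her2_samples))])
    for _ in range(n_end):
        plant("end_artifact", "end", [str(rng.choice(her2_samples))])
    for _ in range(n_low):
        plant("low_depth", "low", [str(rng.choice(her2_samples))])
    for _ in range(n_germ):
        plant("germline", "clean", [str(rng.choice(her2_samples))], in_known=True)
    for _ in range(n_shared):
        carriers = [str(rng.choice(her2_samples))] + [
            f"{g}_{int(rng.integers(config.n_per_group)) + 1}" for g in other_groups
        ]
        plant("shared", "clean", carriers)

    # intergenic positions after the last gene
    nc_base = _GENOME_MARGIN + n_coding * _GENE_SPACING
    for i in range(config.n_noncoding):
        pos0 = nc_base + 10 + i * 45
        ref = seq[pos0]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        s = str(rng.choice(her2_samples))
        add_site(s, pos0, ref, alt, "clean")
        truth.variants.append(
            VariantTruth(s, chrom, pos0 + 1, ref, alt, "non_exonic", "", "non-exonic")
        )

    # decoy known sites never planted in any sample
    for _ in range(3):
        pos0 = int(rng.integers(0, _GENOME_MARGIN - 1))
        ref = seq[pos0]
        known_sites.append((chrom, pos0 + 1, ref, {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]))

    # reference-only background lines exercise format conservation; kept in
    # the gene-free margin so they never collide with planted sites
    for s in samples:
        for pos0 in rng.choice(_GENOME_MARGIN - 1, size=3, replace=False):
            pos0 = int(pos0)
            depth = int(rng.integers(5, 15))
            rp, rm = _split_strands(depth)
            roffs = list(map(int, rng.integers(0, config.read_length // 2, size=depth)))
            site = _PileupSite(chrom, pos0 + 1, seq[pos0], "N", rp, rm, 0, 0, [], roffs)
            per_sample[s]["bwa"].append(site)
            per_sample[s]["tophat"].append(site)

    outdir = os.fspath(outdir)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, genome_len, 60):
            fh.write(seq[i : i + 60] + "\n")
    with open(os.path.join(outdir, "genes.refflat"), "w") as fh:
        fh.write("\n".join(refflat_lines) + "\n")
    with open(os.path.join(outdir, "known_sites.vcf"), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c, p, r, a in sorted(set(known_sites)):
            fh.write(f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\n")
    for s in samples:
        for dialect in ("bwa", "tophat"):
            sites = sorted(per_sample[s][dialect], key=lambda x: x.pos)
            with open(os.path.join(outdir, f"{s}.{dialect}.pileup"), "w") as fh:
                for i, site in enumerate(sites):
                    fh.write(site.line(with_markers=(i % 4 == 0)) + "\n")
    return truth


# ---------------------------------------------------------------------------
# interactome and gene sets


def generate_network_and_sets(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> tuple["object", dict[str, set[str]], TruthSet]:
    """Stochastic-block-model interactome with planted communities + GMT sets.

    Nodes are gene symbols; the first ``sum(community_sizes)`` genes form
    the planted communities (within-probability ``p_within``), the rest are
    background (all pairs at ``p_between``).  Gene sets: one per community,
    plus random decoy sets.
    """
    import warnings

    import networkx as nx

    if config.p_within < config.p_between:
        warnings.warn("p_within < p_between: planted modules are unrecoverable")
    rng = config.rng(4)
    genes = _gene_names(config.n_network_genes)
    sizes = list(config.community_sizes)
    rest = config.n_network_genes - sum(sizes)
    blocks = sizes + ([rest] if rest else [])
    p_matrix = [
        [
            (config.p_within if (i == j and i < len(sizes)) else config.p_between)
            for j in range(len(blocks))
        ]
        for i in range(len(blocks))
    ]
    g_int = nx.stochastic_block_model(blocks, p_matrix, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(g_int, {i: genes[i] for i in range(config.n_network_genes)})

    truth = TruthSet()
    start = 0
    gene_sets: dict[str, set[str]] = {}
    for ci, size in enumerate(sizes):
        comm = genes[start : start + size]
        truth.communities.update({g: ci for g in comm})
        gene_sets[f"community_{ci + 1}"] = set(comm)
        start += size
    for d in range(3):
        gene_sets[f"decoy_{d + 1}"] = set(
            rng.choice(genes, size=min(15, config.n_network_genes), replace=False)
        )

    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "network.tsv"), "w") as fh:
            for a, b in sorted(graph.edges):
                fh.write(f"{a}\t{b}\n")
        write_gmt(gene_sets, os.path.join(outdir, "sets.gmt"))
    return graph, gene_sets, truth


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = set(f[2:])
    return sets


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(
    genes: list[str], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, TruthSet]:
    """EC50 and survival tables with planted gene associations.

    Cell-line expression is array-scale (standard normal per gene); EC50 is
    a decreasing monotone function of the mean expression of the planted
    drug genes plus log-normal noise.  Patient expression is likewise
    standard normal; survival times are exponential with log hazard equal
    to ``hazard_effect`` per SD of the planted module's mean expression,
    with uniform censoring at rate ``censoring``.

    Returns (cell-line expression genes x lines with an 'EC50' row attached
    as a Series, survival DataFrame patients x [time, event, genes...],
    truth).
    """
    rng = config.rng(5)
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    n_module = min(20, max(2, len(genes) // 10))
    module = sorted(rng.choice(genes, size=n_module, replace=False))
    drug_genes = module[: max(1, n_module // 3)]
    if config.hazard_effect != 0 and not module:
        raise ValueError("nonzero effect with empty outcome gene set")

    lines = [f"LINE{i + 1:02d}" for i in range(config.n_cell_lines)]
    expr_lines = pd.DataFrame(
        rng.normal(size=(len(genes), len(lines))), index=genes, columns=lines
    )
    drive = expr_lines.loc[drug_genes].mean(axis=0)
    drive = (drive - drive.mean()) / (drive.std(ddof=0) or 1.0)
    ec50 = pd.Series(
        np.exp(-config.drug_effect * drive + rng.normal(0, 0.3, size=len(lines))),
        index=lines,
        name="EC50",
    )

    patients = [f"PT{i + 1:03d}" for i in range(config.n_patients)]
    expr_pat = pd.DataFrame(
        rng.normal(size=(len(genes), len(patients))), index=genes, columns=patients
    )
    risk = expr_pat.loc[module].mean(axis=0)
    risk = (risk - risk.mean()) / (risk.std(ddof=0) or 1.0)
    rate = np.exp(config.hazard_effect * risk.to_numpy())
    t_event = rng.exponential(1.0 / rate) * 24.0  # months scale
    if config.censoring > 0:
        c_rate = config.censoring / (1 - config.censoring)
        t_cens = rng.exponential(1.0 / (c_rate * rate.mean())) * 24.0
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"time": time, "event": event}, index=patients)
    survival = pd.concat([survival, expr_pat.T], axis=1)

    truth = TruthSet(outcome_genes=set(module), drug_genes=set(drug_genes))
    return expr_lines, ec50, survival, truth


# ---------------------------------------------------------------------------
# orchestration


def write_all(config: SimulationConfig, outdir: str | os.PathLike) -> dict[str, TruthSet]:
    """Emit every pipeline input file plus truth side-car TSVs."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)

    counts, t_counts = generate_cohort_counts(config)
    counts.rename_axis("gene").to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    sample_groups(config).rename_axis("sample").to_csv(
        os.path.join(outdir, "groups.tsv"), sep="\t"
    )
    iso, t2g, t_iso = generate_isoform_counts(counts, config)
    iso.rename_axis("transcript").to_csv(os.path.join(outdir, "isoforms.tsv"), sep="\t")
    t2g.rename_axis("transcript").to_csv(
        os.path.join(outdir, "transcript_to_gene.tsv"), sep="\t"
    )
    t_pile = generate_pileup_pair(config, outdir)
    _, gene_sets, t_net = generate_network_and_sets(config, outdir)
    expr_lines, ec50, survival, t_pheno = generate_phenotypes(list(counts.index), config)
    expr_lines.rename_axis("gene").to_csv(os.path.join(outdir, "cell_line_expr.tsv"), sep="\t")
    ec50.rename_axis("cell_line").to_csv(os.path.join(outdir, "ec50.tsv"), sep="\t")
    survival.rename_axis("patient").to_csv(os.path.join(outdir, "survival.tsv"), sep="\t")

    pd.Series(t_counts.de_genes, name="direction").rename_axis("gene").to_csv(
        os.path.join(truth_dir, "de_genes.tsv"), sep="\t"
    )
    pd.Series(sorted(t_iso.spliced_transcripts), name="transcript").to_csv(
        os.path.join(truth_dir, "spliced_transcripts.tsv"), sep="\t", index=False
    )
    pd.DataFrame([asdict(v) for v in t_pile.variants]).to_csv(
        os.path.join(truth_dir, "variants.tsv"), sep="\t", index=False
    )
    pd.Series(t_net.communities, name="module").rename_axis("gene").to_csv(
        os.path.join(truth_dir, "communities.tsv"), sep="\t"
    )
    pd.Series(sorted(t_pheno.outcome_genes), name="gene").to_csv(
        os.path.join(truth_dir, "outcome_genes.tsv"), sep="\t", index=False
    )
    return {
        "counts": t_counts,
        "isoforms": t_iso,
        "pileups": t_pile,
        "network": t_net,
        "phenotypes": t_pheno,
    }
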