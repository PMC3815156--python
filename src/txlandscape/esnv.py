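"""Consensus expressed single-nucleotide variant (eSNV) calling.

Expressed SNVs are nucleotide substitutions observed in RNA-seq reads
relative to the reference genome.  Calling them confidently from tumor RNA
is hard: allele-specific expression, strand and read-end artifacts, and the
huge dynamic range of transcript abundance all inflate false detections.
This module implements a dual-aligner consensus workflow: candidate sites
from a BWA-style pileup (depth and allele-ratio thresholds) are confirmed
against a TopHat/Bowtie-style pileup (strand-balance and read-end checks),
annotated against a gene model for protein consequence, screened against
known-variant catalogs, and finally restricted to variants exclusive to a
target tumor cohort.

All filters are conjunctive predicates, so the surviving set is invariant
to the order in which they are applied; per-candidate filter attribution is
recorded.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq

BASES = ("A", "C", "G", "T")

#: default read-end window: alt evidence confined within this many bases of
#: the nearer read end is treated as an alignment artifact
END_WINDOW = 5

HIGH_CONF_ALT_DEPTH = 4
LOW_CONF_ALT_DEPTH = 2
MIN_TOTAL_DEPTH = 4
MIN_ALT_RATIO = 0.1
MIN_STRAND_RATIO = 0.1

NONSYNONYMOUS = frozenset({"missense", "stopgain", "stoploss"})

ALL_FILTERS = (
    "depth",
    "ratio",
    "alt_depth",
    "strand",
    "consensus",
    "consequence",
    "known",
    "end_bias",
)


class MpileupError(ValueError):
    """Malformed mpileup line."""


class AlleleObservation(NamedTuple):
    chrom: str
    pos: int  # 1-based
    base: str
    strand: str  # '+' or '-'
    read_offset: int | None  # bases from the nearer read end, 0-based
    source: str


@dataclass
class SiteSummary:
    """Per-site allele evidence from one aligner's pileup."""

    chrom: str
    pos: int
    ref_allele: str
    ref_depth: int
    alt_allele: str
    alt_depth: int
    total_depth: int
    strand_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    alt_offsets: list[int | None] = field(default_factory=list)

    @property
    def alt_ratio(self) -> float:
        return self.alt_depth / self.total_depth if self.total_depth else 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_allele)


@dataclass
class VariantCall:
    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_depth: int
    total_depth: int
    confidence: str  # 'high' | 'low'
    consequence: str = "non-exonic"
    gene: str = ""
    filters_passed: frozenset[str] = frozenset()
    filters_failed: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def passes_all(self) -> bool:
        return not self.filters_failed


# ---------------------------------------------------------------------------
# mpileup parsing


def _parse_base_column(bases: str, ref: str, lineno: int) -> list[tuple[str | None, str | None]]:
    """Expand one mpileup base string into (base, strand) symbols.

    '.'/',' are reference matches on the +/- strand, letters are mismatches
    with case encoding strand, '^q' marks a read start (the next character
    is a mapping quality, not a base), '$' a read end, and +N/-N introduce
    indel sequences which are skipped.  'N', '*', '>' and '<' consume depth
    but carry no allele information (returned as (None, None)).
    """
    out: list[tuple[str | None, str | None]] = []
    ref = ref.upper()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise MpileupError(f"line {lineno}: indel marker without length")
            i = j + int(bases[i + 1 : j])
            continue
        if c == ".":
            out.append((ref, "+"))
        elif c == ",":
            out.append((ref, "-"))
        elif c in "ACGT":
            out.append((c, "+"))
        elif c in "acgt":
            out.append((c.upper(), "-"))
        elif c in "Nn*><":
            out.append((None, None))
        else:
            raise MpileupError(f"line {lineno}: unexpected symbol {c!r}")
        i += 1
    return out


def parse_mpileup(path_or_handle, source: str = "bwa") -> Iterator[list[AlleleObservation]]:
    """Stream per-site allele observations from an mpileup text file.

    Yields one list of :class:`AlleleObservation` per pileup line.  The
    standard six columns are chrom, pos (1-based), ref, depth, bases,
    quals; an optional seventh column carries comma-separated read offsets
    (distance from the nearer read end) aligned with the base symbols —
    absent offsets are recorded as ``None``.
    """
    handle = open(path_or_handle) if not hasattr(path_or_handle, "read") else path_or_handle
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise MpileupError(f"line {lineno}: expected >=6 columns, got {len(fields)}")
            chrom, pos_s, ref, depth_s, bases = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise MpileupError(f"line {lineno}: non-integer pos/depth") from exc
            symbols = _parse_base_column(bases, ref, lineno)
            if len(symbols) != depth:
                raise MpileupError(
                    f"line {lineno}: depth {depth} != {len(symbols)} base symbols"
                )
            offsets: list[int | None]
            if len(fields) >= 7 and fields[6] != "":
                offsets = [int(x) if x != "." else None for x in fields[6].split(",")]
                if len(offsets) != depth:
                    raise MpileupError(f"line {lineno}: offset column length mismatch")
            else:
                offsets = [None] * depth
            obs = [
                AlleleObservation(chrom, pos, b, s, off, source)
                for (b, s), off in zip(symbols, offsets)
                if b is not None
            ]
            yield obs
    finally:
        if not hasattr(path_or_handle, "read"):
            handle.close()


def summarize_alleles(
    observations: Iterable[AlleleObservation], ref_allele: str
) -> SiteSummary | None:
    """Collapse one site's observations into allele/strand counts.

    The alternate allele is the most-supported non-reference base
    (lexicographic tie-break).  Sites with no alternate evidence return
    ``None`` and are omitted downstream.
    """
    obs = list(observations)
    if not obs:
        return None
    ref_allele = ref_allele.upper()
    counts: dict[str, list[int]] = {b: [0, 0] for b in BASES}
    offsets: dict[str, list[int | None]] = {b: [] for b in BASES}
    chrom, pos = obs[0].chrom, obs[0].pos
    for o in obs:
        counts[o.base][0 if o.strand == "+" else 1] += 1
        offsets[o.base].append(o.read_offset)
    alt_candidates = [b for b in BASES if b != ref_allele and sum(counts[b]) > 0]
    if not alt_candidates:
        return None
    alt = max(alt_candidates, key=lambda b: (sum(counts[b]), b))
    # max() prefers the later lexicographic base on ties; flip to the earlier
    best = sum(counts[alt])
    alt = min(b for b in alt_candidates if sum(counts[b]) == best)
    return SiteSummary(
        chrom=chrom,
        pos=pos,
        ref_allele=ref_allele,
        ref_depth=sum(counts[ref_allele]),
        alt_allele=alt,
        alt_depth=sum(counts[alt]),
        total_depth=len(obs),
        strand_counts={b: (c[0], c[1]) for b, c in counts.items()},
        alt_offsets=offsets[alt],
    )


def summarize_pileup(path, ref_lookup=None, source: str = "bwa") -> dict[tuple[str, int], SiteSummary]:
    """Summarize every pileup site with alternate-allele evidence.

    ``ref_lookup`` maps (chrom, pos) to the reference base; when ``None``
    the pileup's own reference column is trusted (read from the file in a
    first pass is unnecessary because the column is present per line).
    """
    sites: dict[tuple[str, int], SiteSummary] = {}
    handle = open(path) if not hasattr(path, "read") else path
    text = handle.read()
    if not hasattr(path, "read"):
        handle.close()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line:
            continue
        ref = line.split("\t")[2]
        for obs in parse_mpileup(io.StringIO(line), source=source):
            s = summarize_alleles(obs, ref)
            if s is not None:
                sites[(s.chrom, s.pos)] = s
    return sites


# ---------------------------------------------------------------------------
# filters


def candidate_filter(
    site: SiteSummary,
    min_depth: int = MIN_TOTAL_DEPTH,
    min_ratio: float = MIN_ALT_RATIO,
) -> str:
    """Classify a summarized site as 'high', 'low' or 'reject'.

    Sites with total depth < 4 or alternate-allele ratio < 0.1 are
    rejected; >= 4 alternate reads is high confidence; 2-3 alternate reads
    is low confidence, retained only for recurrence reporting.
    """
    if site.total_depth < min_depth or site.alt_ratio < min_ratio:
        return "reject"
    if site.alt_depth >= HIGH_CONF_ALT_DEPTH:
        return "high"
    if site.alt_depth >= LOW_CONF_ALT_DEPTH:
        return "low"
    return "reject"


def strand_bias_filter(site: SiteSummary, min_ratio: float = MIN_STRAND_RATIO) -> bool:
    """Pass iff the alternate allele is seen on both strands with a
    plus/minus count ratio (min over max) above ``min_ratio``."""
    plus, minus = site.strand_counts.get(site.alt_allele, (0, 0))
    if plus < 1 or minus < 1:
        return False
    return min(plus, minus) / max(plus, minus) > min_ratio


def consensus_calls(
    bwa_sites: dict[tuple[str, int], SiteSummary],
    tophat_sites: dict[tuple[str, int], SiteSummary],
) -> set[tuple[str, int, str]]:
    """Sites supported by both aligners with the same alternate allele."""
    return {s.key for s in bwa_sites.values()} & {s.key for s in tophat_sites.values()}


def end_bias_filter(
    alt_offsets: Iterable[int | None], window: int = END_WINDOW
) -> tuple[bool, bool]:
    """Read-end artifact check on the alt-supporting read offsets.

    Returns ``(passed, offsets_known)``.  Fails only when every alternate
    observation with a known offset lies within ``window`` bases of the
    nearer read end; when no offsets are known the variant passes with the
    second element False so callers can flag it.
    """
    known = [o for o in alt_offsets if o is not None]
    if not known:
        return True, False
    return (not all(o < window for o in known)), True


def load_known_sites(path) -> set[tuple[str, int, str]]:
    """(chrom, pos, alt) triples from a VCF or 3+-column TSV of known
    variants (dbSNP-style catalogs)."""
    known: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 5 and not f[1].startswith("."):  # VCF: CHROM POS ID REF ALT
                chrom, pos, alt = f[0], int(f[1]), f[4]
            else:  # TSV: chrom pos alt
                chrom, pos, alt = f[0], int(f[1]), f[2]
            for a in alt.split(","):
                known.add((chrom, pos, a.upper()))
    return known


def filter_known(
    keys: Iterable[tuple[str, int, str]],
    known: set[tuple[str, int, str]],
    allele_aware: bool = True,
) -> set[tuple[str, int, str]]:
    """Drop candidate (chrom, pos, alt) keys present in a known catalog.

    Allele-aware by default: a known site with a *different* alternate
    allele does not remove the candidate.  Position-only matching mimics
    annotation tools that ignore the allele.
    """
    if allele_aware:
        return {k for k in keys if k not in known}
    known_pos = {(c, p) for c, p, _ in known}
    return {k for k in keys if (k[0], k[1]) not in known_pos}


# ---------------------------------------------------------------------------
# annotation

CODON_TABLE = 1  # standard genetic code


@dataclass
class Transcript:
    gene: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: list[int]
    exon_ends: list[int]

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS, genomic order, 0-based
        half-open."""
        out = []
        for s, e in zip(self.exon_starts, self.exon_ends):
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out


def read_refflat(path) -> list[Transcript]:
    """Parse a refFlat gene model (tab-delimited, exon bounds 0-based
    half-open with trailing commas in the exon lists)."""
    transcripts = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            transcripts.append(
                Transcript(
                    gene=f[0],
                    name=f[1],
                    chrom=f[2],
                    strand=f[3],
                    tx_start=int(f[4]),
                    tx_end=int(f[5]),
                    cds_start=int(f[6]),
                    cds_end=int(f[7]),
                    exon_starts=[int(x) for x in f[9].rstrip(",").split(",")],
                    exon_ends=[int(x) for x in f[10].rstrip(",").split(",")],
                )
            )
    return transcripts


def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    transcripts: list[Transcript],
    genome: dict[str, str],
) -> tuple[str, str]:
    """Protein consequence of a substitution against a refFlat gene model.

    ``pos`` is 1-based.  The variant's codon is located through each
    overlapping transcript's coding intervals (minus-strand transcripts are
    reverse-complemented); the reference and mutated codons are translated
    and compared.  Returns ``(consequence, gene)`` with consequence one of
    synonymous / missense / stopgain / stoploss / non-exonic.  Transcripts
    whose coding length is not a multiple of 3 are skipped.
    """
    import warnings

    pos0 = pos - 1
    for tx in transcripts:
        if tx.chrom != chrom or not (tx.cds_start <= pos0 < tx.cds_end):
            continue
        intervals = tx.coding_intervals()
        if not any(s <= pos0 < e for s, e in intervals):
            continue  # intronic within the CDS span
        cds = "".join(genome[chrom][s:e] for s, e in intervals)
        if len(cds) % 3 != 0:
            warnings.warn(f"transcript {tx.name}: CDS length not divisible by 3; skipped")
            continue
        # position of the variant within the genomic-order CDS
        idx = 0
        for s, e in intervals:
            if s <= pos0 < e:
                idx += pos0 - s
                break
            idx += e - s
        if cds[idx] != ref.upper():
            # reference mismatch — trust the genome, still classify
            ref = cds[idx]
        mutated = cds[:idx] + alt.upper() + cds[idx + 1 :]
        if tx.strand == "-":
            cds_t = str(Seq(cds).reverse_complement())
            mut_t = str(Seq(mutated).reverse_complement())
            idx_t = len(cds) - 1 - idx
        else:
            cds_t, mut_t, idx_t = cds, mutated, idx
        codon_i = idx_t // 3
        ref_aa = str(Seq(cds_t[codon_i * 3 : codon_i * 3 + 3]).translate(table=CODON_TABLE))
        alt_aa = str(Seq(mut_t[codon_i * 3 : codon_i * 3 + 3]).translate(table=CODON_TABLE))
        if ref_aa == alt_aa:
            return "synonymous", tx.gene
        if alt_aa == "*":
            return "stopgain", tx.gene
        if ref_aa == "*":
            return "stoploss", tx.gene
        return "missense", tx.gene
    return "non-exonic", ""


# ---------------------------------------------------------------------------
# per-sample chain and cohort database


def call_sample(
    bwa_pileup,
    tophat_pileup,
    sample: str,
    transcripts: list[Transcript] | None = None,
    genome: dict[str, str] | None = None,
    known: set[tuple[str, int, str]] | None = None,
    end_window: int = END_WINDOW,
    allele_aware: bool = True,
) -> list[VariantCall]:
    """Run the full consensus chain for one sample.

    Returns every candidate (high or low confidence from the BWA pileup)
    with its filter attribution; call sites pass when ``filters_failed`` is
    empty.  Annotation and known-site screening are skipped when the gene
    model / catalogs are not supplied.
    """
    bwa_sites = summarize_pileup(bwa_pileup, source="bwa")
    th_sites = summarize_pileup(tophat_pileup, source="tophat")
    consensus = consensus_calls(bwa_sites, th_sites)
    known = known or set()

    calls = []
    for (chrom, pos), site in sorted(bwa_sites.items()):
        grade = candidate_filter(site)
        failed: set[str] = set()
        passed: set[str] = set()
        if site.total_depth < MIN_TOTAL_DEPTH:
            failed.add("depth")
        else:
            passed.add("depth")
        if site.alt_ratio < MIN_ALT_RATIO:
            failed.add("ratio")
        else:
            passed.add("ratio")
        if site.alt_depth >= HIGH_CONF_ALT_DEPTH:
            passed.add("alt_depth")
        else:
            failed.add("alt_depth")
        if grade == "reject" and site.alt_depth < LOW_CONF_ALT_DEPTH:
            continue

        th = th_sites.get((chrom, pos))
        if th is not None and th.alt_allele == site.alt_allele:
            (passed if strand_bias_filter(th) else failed).add("strand")
        else:
            failed.add("strand")
        (passed if site.key in consensus else failed).add("consensus")

        consequence, gene = "non-exonic", ""
        if transcripts is not None and genome is not None:
            consequence, gene = annotate_variant(
                chrom, pos, site.ref_allele, site.alt_allele, transcripts, genome
            )
        (passed if consequence in NONSYNONYMOUS else failed).add("consequence")

        novel = filter_known([site.key], known, allele_aware=allele_aware)
        (passed if site.key in novel else failed).add("known")

        offsets = th.alt_offsets if th is not None and th.alt_allele == site.alt_allele else site.alt_offsets
        ok, _known_offsets = end_bias_filter(offsets, window=end_window)
        (passed if ok else failed).add("end_bias")

        calls.append(
            VariantCall(
                sample=sample,
                chrom=chrom,
                pos=pos,
                ref=site.ref_allele,
                alt=site.alt_allele,
                alt_depth=site.alt_depth,
                total_depth=site.total_depth,
                confidence="high" if site.alt_depth >= HIGH_CONF_ALT_DEPTH else "low",
                consequence=consequence,
                gene=gene,
                filters_passed=frozenset(passed),
                filters_failed=frozenset(failed),
            )
        )
    return calls


class CohortVariantDB:
    """Per-variant, per-sample call store with group labels.

    Mirrors the study design of loading every tumor's calls into one
    queryable table keyed by (chrom, pos, ref, alt).
    """

    def __init__(self, sample_groups: dict[str, str]):
        self.sample_groups = dict(sample_groups)
        self._records: dict[tuple[str, int, str, str], dict[str, VariantCall]] = defaultdict(dict)

    def add_calls(self, calls: Iterable[VariantCall]) -> None:
        for c in calls:
            if c.sample not in self.sample_groups:
                raise KeyError(f"sample {c.sample!r} has no group label")
            self._records[c.key][c.sample] = c

    def variants(self) -> list[tuple[str, int, str, str]]:
        return sorted(self._records)

    def calls_for(self, key) -> dict[str, VariantCall]:
        return self._records.get(tuple(key), {})

    def cohort_exclusive(
        self, target_group: str, passing_only: bool = True
    ) -> dict[tuple[str, int, str, str], list[VariantCall]]:
        """Variants with >=1 qualifying call in the target group and none in
        any other group.

        ``passing_only`` restricts the exclusivity test to calls that pass
        every filter (the default); otherwise any stored candidate in
        another cohort vetoes the variant.
        """
        out = {}
        for key, per_sample in self._records.items():
            eligible = [
                c
                for c in per_sample.values()
                if (c.passes_all if passing_only else True)
            ]
            target = [c for c in eligible if self.sample_groups[c.sample] == target_group]
            others = [c for c in eligible if self.sample_groups[c.sample] != target_group]
            if target and not others:
                out[key] = sorted(target, key=lambda c: c.sample)
        return out

    def recurrence_report(
        self,
        high_threshold: int = HIGH_CONF_ALT_DEPTH,
        low_threshold: int = LOW_CONF_ALT_DEPTH,
    ) -> list[dict]:
        """Per-variant recurrence across samples.

        A variant is recurrent when it is high confidence in >=2 samples, or
        high confidence in one sample and low confidence (2-3 alternate
        reads) in at least one more.
        """
        report = []
        for key in self.variants():
            per_sample = self._records[key]
            depths = {s: c.alt_depth for s, c in per_sample.items()}
            n_high = sum(d >= high_threshold for d in depths.values())
            n_low = sum(low_threshold <= d < high_threshold for d in depths.values())
            report.append(
                {
                    "chrom": key[0],
                    "pos": key[1],
                    "ref": key[2],
                    "alt": key[3],
                    "n_high": n_high,
                    "n_low": n_low,
                    "alt_depths": depths,
                    "recurrent": n_high >= 2 or (n_high >= 1 and n_low >= 1),
                }
            )
        return report


# ---------------------------------------------------------------------------
# VCF I/O (minimal VCF 4.2)

_VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=depth,Description="Total depth below 4">
##FILTER=<ID=ratio,Description="Alternate allele ratio below 0.1">
##FILTER=<ID=alt_depth,Description="Fewer than 4 alternate reads">
##FILTER=<ID=strand,Description="Strand bias in second aligner">
##FILTER=<ID=consensus,Description="Not supported by both aligners">
##FILTER=<ID=consequence,Description="Not a non-synonymous coding change">
##FILTER=<ID=known,Description="Present in a known-variant catalog">
##FILTER=<ID=end_bias,Description="Alternate reads confined to read ends">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Protein consequence">
##INFO=<ID=ALTD,Number=1,Type=Integer,Description="Alternate allele read depth">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=CONF,Number=1,Type=String,Description="Call confidence (high/low)">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Iterable[VariantCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt, c.sample)):
            info = (
                f"GENE={c.gene or '.'};CSQ={c.consequence};ALTD={c.alt_depth};"
                f"DP={c.total_depth};CONF={c.confidence};SAMPLE={c.sample}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t"
                f"{'PASS' if c.passes_all else ';'.join(sorted(c.filters_failed))}\t{info}\n"
            )


def read_vcf(path) -> list[VariantCall]:
    """Round-trip reader for :func:`write_vcf` output (via pysam)."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            failed = frozenset() if "PASS" in rec.filter else frozenset(rec.filter)
            calls.append(
                VariantCall(
                    sample=info.get("SAMPLE", ""),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    alt_depth=int(info["ALTD"]),
                    total_depth=int(info["DP"]),
                    confidence=info["CONF"],
                    consequence=info["CSQ"],
                    gene="" if info.get("GENE") in (None, ".") else info["GENE"],
                    filters_failed=failed,
                )
            )
    return calls
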