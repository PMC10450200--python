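"""Synthetic genomes, 3'-anchored poly(A) reads and count matrices with ground truth.

Everything here is deterministic for a fixed seed. Each sample draws from its
own RNG stream keyed by ``(seed, sample_id)``, so adding samples to a design
never changes the reads of existing ones.

Coordinates are 0-based half-open internally; GFF3 is written 1-based closed
and BED 0-based half-open, per the standard dialects.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import revcomp, rng_for

_BASES = np.array(list("ACGT"))

#: spacer between simulated genes (an intergenic "desert")
INTERGENIC_GAP = 300
#: CDS placeholder length upstream of the 3'UTR
CDS_LEN = 150
#: width of an annotated PAS interval around the cleavage point
PAS_WIDTH = 4


@dataclass
class SimGene:
    """Geometry of one simulated gene with exactly two PAS.

    ``cds_end`` is the genomic coordinate (0-based) of the last CDS base.
    ``pas_proximal`` / ``pas_distal`` are the cleavage points: the genomic
    coordinate of the last templated base of each isoform, strictly ordered
    in transcription direction. ``templated_a_run`` is the length of the
    genomic A-run planted immediately downstream of each cleavage point
    (0 when absent).
    """

    id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    cds_end: int
    pas_proximal: int
    pas_distal: int
    utr_sequence: str
    templated_a_run: int

    def __post_init__(self) -> None:
        if self.strand == "+":
            if not (self.cds_end < self.pas_proximal < self.pas_distal):
                raise ValueError(f"{self.id}: PAS not ordered downstream of CDS end")
        else:
            if not (self.cds_end > self.pas_proximal > self.pas_distal):
                raise ValueError(f"{self.id}: PAS not ordered downstream of CDS end")
        if len(self.utr_sequence) < abs(self.pas_distal - self.cds_end):
            raise ValueError(f"{self.id}: UTR sequence shorter than CDS→distal span")

    def utr_offset(self, pos: int) -> int:
        """Transcription-direction distance from the first UTR base to ``pos``."""
        return pos - self.cds_end - 1 if self.strand == "+" else self.cds_end - 1 - pos


@dataclass
class SimCondition:
    """Per-sample generative parameters for poly(A)-tail reads."""

    tail_mean: float
    tail_sd: float
    distal_usage: float
    depth: float

    def __post_init__(self) -> None:
        if self.tail_mean < 0:
            raise ValueError("tail_mean must be >= 0")
        if not 0.0 <= self.distal_usage <= 1.0:
            raise ValueError("distal_usage must lie in [0, 1]")


@dataclass
class SimGenome:
    sequences: dict[str, str]
    genes: list[SimGene]

    def fasta_text(self, width: int = 70) -> str:
        out = io.StringIO()
        for name, seq in self.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
        return out.getvalue()

    def gff_text(self) -> str:
        out = io.StringIO()
        out.write("##gff-version 3\n")
        for g in self.genes:
            start1, end1 = g.gene_start + 1, g.gene_end  # 1-based closed
            if g.strand == "+":
                utr1 = (g.cds_end + 2, g.pas_distal + 1)
            else:
                utr1 = (g.pas_distal + 1, g.cds_end)
            out.write(
                f"{g.chrom}\tpatpipe\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.id};Name={g.id}\n"
            )
            out.write(
                f"{g.chrom}\tpatpipe\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.id}.t1;Parent={g.id}\n"
            )
            out.write(
                f"{g.chrom}\tpatpipe\tthree_prime_UTR\t{utr1[0]}\t{utr1[1]}\t.\t"
                f"{g.strand}\t.\tID={g.id}.utr;Parent={g.id}.t1\n"
            )
        return out.getvalue()

    def bed_text(self) -> str:
        """BED6 PAS annotation; name=<gene>:<rank>, score=0."""
        lines = []
        for g in self.genes:
            for rank, pos in (("proximal", g.pas_proximal), ("distal", g.pas_distal)):
                half = PAS_WIDTH // 2
                start, end = pos - half, pos + PAS_WIDTH - half
                lines.append((g.chrom, start, end, f"{g.id}:{rank}", 0, g.strand))
        lines.sort(key=lambda r: (r[0], r[1]))
        return "".join("\t".join(map(str, r)) + "\n" for r in lines)

    def write(self, outdir: str, prefix: str = "sim") -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, f"{prefix}.fa"),
            "gff": os.path.join(outdir, f"{prefix}.gff3"),
            "bed": os.path.join(outdir, f"{prefix}.pas.bed"),
        }
        for key, text in (
            ("fasta", self.fasta_text()),
            ("gff", self.gff_text()),
            ("bed", self.bed_text()),
        ):
            with open(paths[key], "w") as fh:
                fh.write(text)
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_genome(
    n_genes: int,
    utr_len_range: tuple[int, int] = (300, 1500),
    templated_a_prob: float = 0.3,
    seed: int = 0,
    minus_fraction: float = 0.4,
) -> SimGenome:
    """Simulate a single-contig genome in which every gene has two PAS.

    A fraction ``templated_a_prob`` of genes carries a genomic A-run
    (length 4-12) immediately downstream of *each* cleavage point, to
    exercise the non-templated-A rule. The base at every cleavage point and
    the base following any planted run are forced non-A so per-read truth is
    unambiguous.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = utr_len_range
    if not (0 < lo <= hi):
        raise ValueError("invalid utr_len_range")
    if not 0.0 <= templated_a_prob <= 1.0:
        raise ValueError("templated_a_prob must be a probability")

    rng = rng_for(seed, "genome")
    chrom = "simchr"
    chunks: list[str] = []
    genes: list[SimGene] = []
    cursor = 0

    for i in range(n_genes):
        gid = f"G{i + 1:04d}"
        strand = "-" if rng.random() < minus_fraction else "+"
        utr_len = int(rng.integers(lo, hi + 1))
        prox_frac = rng.uniform(0.25, 0.6)
        prox_off = max(2, min(utr_len - 2, int(round(utr_len * prox_frac))))
        a_run = int(rng.integers(4, 13)) if rng.random() < templated_a_prob else 0

        # build the gene in sense orientation, then place on the chosen strand
        body = _random_seq(rng, CDS_LEN + utr_len + a_run + 40)
        utr0 = CDS_LEN  # sense offset of first UTR base
        prox_s = utr0 + prox_off - 1  # sense offset of proximal cleavage base
        dist_s = utr0 + utr_len - 1
        for cleave in (prox_s, dist_s):
            if body[cleave] == "A":
                body[cleave] = "T"
            after = cleave + 1
            if a_run:
                body[after : after + a_run] = "A"
                after += a_run
            if body[after] == "A":
                body[after] = "G"
        sense = "".join(body)

        gap = "".join(_random_seq(rng, INTERGENIC_GAP))
        chunks.append(gap)
        cursor += INTERGENIC_GAP
        gene_start = cursor
        if strand == "+":
            chunks.append(sense)
            cds_end = gene_start + CDS_LEN - 1
            pas_prox = gene_start + prox_s
            pas_dist = gene_start + dist_s
            utr_seq = sense[utr0 : dist_s + 1]
        else:
            chunks.append(revcomp(sense))
            gene_end_off = len(sense) - 1
            cds_end = gene_start + gene_end_off - (CDS_LEN - 1)
            pas_prox = gene_start + gene_end_off - prox_s
            pas_dist = gene_start + gene_end_off - dist_s
            utr_seq = sense[utr0 : dist_s + 1]
        cursor += len(sense)
        genes.append(
            SimGene(
                id=gid,
                chrom=chrom,
                strand=strand,
                gene_start=gene_start,
                gene_end=cursor,
                cds_end=cds_end,
                pas_proximal=pas_prox,
                pas_distal=pas_dist,
                utr_sequence=utr_seq,
                templated_a_run=a_run,
            )
        )
    chunks.append("".join(_random_seq(rng, INTERGENIC_GAP)))
    return SimGenome(sequences={chrom: "".join(chunks)}, genes=genes)


# --------------------------------------------------------------------------
# read simulation


@dataclass
class SimRead:
    read_id: str
    gene_id: str
    site_rank: str  # proximal | distal
    cleavage_pos: int
    tail_length: int
    tail_nontemplated: int
    seq: str  # read orientation: templated anchor + tail A's
    qual: str
    anchor_len: int


@dataclass
class PatReadSim:
    """Reads for one or more samples plus per-read / per-site ground truth."""

    genome: SimGenome
    samples: dict[str, list[SimRead]]
    read_len: int

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for sample, reads in self.samples.items():
            for r in reads:
                rows.append(
                    (
                        sample,
                        r.read_id,
                        r.gene_id,
                        r.site_rank,
                        r.cleavage_pos,
                        r.tail_length,
                        r.tail_nontemplated,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "sample",
                "read_id",
                "gene_id",
                "site_rank",
                "cleavage_pos",
                "tail_length",
                "tail_nontemplated",
            ],
        )

    def site_counts(self) -> pd.DataFrame:
        """Per gene × site × sample read counts (truth)."""
        t = self.truth
        return (
            t.groupby(["gene_id", "site_rank", "sample"])
            .size()
            .unstack("sample", fill_value=0)
            .reset_index()
        )

    def fastq_text(self, sample: str) -> str:
        out = io.StringIO()
        for r in self.samples[sample]:
            out.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
        return out.getvalue()

    def sam_text(self, sample: str) -> str:
        """Truth alignments of the templated anchor, tail soft-clipped."""
        genes = {g.id: g for g in self.genome.genes}
        out = io.StringIO()
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in self.genome.sequences.items():
            out.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in self.samples[sample]:
            g = genes[r.gene_id]
            tail = len(r.seq) - r.anchor_len
            if g.strand == "+":
                flag = 0
                pos = r.cleavage_pos - r.anchor_len + 1  # 0-based start
                cigar = f"{r.anchor_len}M{tail}S" if tail else f"{r.anchor_len}M"
                seq, qual = r.seq, r.qual
            else:
                flag = 16
                pos = r.cleavage_pos
                cigar = f"{tail}S{r.anchor_len}M" if tail else f"{r.anchor_len}M"
                seq, qual = revcomp(r.seq), r.qual[::-1]
            out.write(
                f"{r.read_id}\t{flag}\t{g.chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{qual}\n"
            )
        return out.getvalue()

    def write(self, outdir: str) -> dict[str, dict[str, str]]:
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, dict[str, str]] = {}
        for sample in self.samples:
            fq = os.path.join(outdir, f"{sample}.fastq")
            sam = os.path.join(outdir, f"{sample}.sam")
            with open(fq, "w") as fh:
                fh.write(self.fastq_text(sample))
            with open(sam, "w") as fh:
                fh.write(self.sam_text(sample))
            paths[sample] = {"fastq": fq, "sam": sam}
        truth_path = os.path.join(outdir, "truth_reads.tsv")
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = {"tsv": truth_path}
        return paths


def _truncnorm_int(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Tail lengths: normal truncated at 0, rounded to int."""
    if sd <= 0:
        return np.full(n, int(round(mean)))
    draws = rng.normal(mean, sd, size=n)
    while True:
        neg = draws < 0
        if not neg.any():
            break
        draws[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    return np.rint(draws).astype(int)


def simulate_pat_reads(
    genes: list[SimGene] | SimGenome,
    conditions: dict[str, SimCondition],
    read_len: int = 50,
    error_rate: float = 0.0,
    qual_high: int = 37,
    qual_low: int = 3,
    seed: int = 0,
    min_anchor: int = 20,
) -> PatReadSim:
    """Simulate 3'-anchored reads: a ``read_len`` templated anchor ending at
    the cleavage point followed by the full non-templated tail.

    ``conditions`` maps sample id -> :class:`SimCondition`. Substitution
    errors are applied at ``error_rate`` with Phred dropped to ``qual_low``.
    """
    if isinstance(genes, SimGenome):
        genome = genes
    else:
        raise TypeError("pass the SimGenome returned by simulate_genome")
    if read_len < min_anchor:
        raise ValueError(f"read_len must be >= minimum templated anchor ({min_anchor})")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be a probability < 1")

    glist = genome.genes
    qh, ql = chr(qual_high + 33), chr(qual_low + 33)
    samples: dict[str, list[SimRead]] = {}
    for sample_id in sorted(conditions):
        cond = conditions[sample_id]
        rng = rng_for(seed, f"reads:{sample_id}")
        reads: list[SimRead] = []
        for g in glist:
            n_reads = int(rng.poisson(cond.depth))
            if n_reads == 0:
                continue
            use_distal = rng.random(n_reads) < cond.distal_usage
            tails = _truncnorm_int(rng, cond.tail_mean, cond.tail_sd, n_reads)
            for j in range(n_reads):
                rank = "distal" if use_distal[j] else "proximal"
                cleave = g.pas_distal if use_distal[j] else g.pas_proximal
                off = g.utr_offset(cleave)  # 0-based within utr_sequence
                anchor_src = g.utr_sequence[max(0, off + 1 - read_len) : off + 1]
                if len(anchor_src) < read_len:  # pad from CDS side: re-slice genome
                    if g.strand == "+":
                        anchor_src = genome.sequences[g.chrom][
                            cleave + 1 - read_len : cleave + 1
                        ]
                    else:
                        anchor_src = revcomp(
                            genome.sequences[g.chrom][cleave : cleave + read_len]
                        )
                tail = int(tails[j])
                seq = list(anchor_src + "A" * tail)
                qual = [qh] * len(seq)
                if error_rate > 0:
                    err = rng.random(len(seq)) < error_rate
                    for k in np.flatnonzero(err):
                        alts = [b for b in "ACGT" if b != seq[k]]
                        seq[k] = alts[int(rng.integers(0, 3))]
                        qual[k] = ql
                rid = f"{sample_id}:{g.id}:{j}"
                reads.append(
                    SimRead(
                        read_id=rid,
                        gene_id=g.id,
                        site_rank=rank,
                        cleavage_pos=cleave,
                        tail_length=tail,
                        tail_nontemplated=max(0, tail - g.templated_a_run),
                        seq="".join(seq),
                        qual="".join(qual),
                        anchor_len=len(anchor_src),
                    )
                )
        samples[sample_id] = reads
    return PatReadSim(genome=genome, samples=samples, read_len=read_len)


# --------------------------------------------------------------------------
# count matrices


@dataclass
class CountSim:
    counts: pd.DataFrame  # features × samples
    truth: pd.DataFrame  # feature, baseline, lfc
    design: pd.DataFrame  # sample, condition


def simulate_counts(
    n_genes: int,
    design: list[tuple[str, str]],
    dispersion: float = 0.05,
    lfc_table: dict[str, float] | None = None,
    lib_sizes: list[int] | None = None,
    seed: int = 0,
    baseline_log_sd: float = 1.5,
    feature_prefix: str = "G",
    treated_label: str | None = None,
) -> CountSim:
    """Negative-binomial count matrices with injected per-feature log2FC.

    ``design`` is a list of (sample_id, condition); the second distinct
    condition (or ``treated_label``) receives the fold changes.
    ``dispersion=0`` degrades to Poisson.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if lib_sizes is None:
        lib_sizes = [1_000_000] * len(design)
    if len(lib_sizes) != len(design):
        raise ValueError("lib_sizes length must match design")
    if any(ls <= 0 for ls in lib_sizes):
        raise ValueError("lib_sizes must be positive")

    features = [f"{feature_prefix}{i + 1:05d}" for i in range(n_genes)]
    conds = [c for _, c in design]
    if treated_label is None:
        uniq = list(dict.fromkeys(conds))
        treated_label = uniq[1] if len(uniq) > 1 else uniq[0]

    rng0 = rng_for(seed, "counts:baseline")
    rel = np.exp(rng0.normal(0.0, baseline_log_sd, size=n_genes))
    rel /= rel.sum()
    lfc = np.array([(lfc_table or {}).get(f, 0.0) for f in features])

    cols = {}
    for (sample_id, cond), lib in zip(design, lib_sizes):
        rng = rng_for(seed, f"counts:{sample_id}")
        mu = rel * lib * (2.0 ** (lfc if cond == treated_label else 0.0))
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            cols[sample_id] = rng.poisson(lam)
        else:
            cols[sample_id] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    truth = pd.DataFrame({"feature_id": features, "baseline": rel, "lfc": lfc})
    design_df = pd.DataFrame(design, columns=["sample", "condition"])
    return CountSim(counts=counts, truth=truth, design=design_df)


# --------------------------------------------------------------------------
# lightweight generators for downstream-stat testing


def simulate_tail_summaries(
    n_genes: int,
    n_reps: int = 3,
    base_mean: float = 44.0,
    base_sd: float = 15.0,
    depth: float = 100.0,
    shift: float = 0.0,
    n_shifted: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene × sample tail summaries (mean of ``~depth`` read-level draws).

    Returns a long summary table (gene_id, sample, condition, n_reads,
    mean_tail) plus a truth table flagging shifted genes.
    """
    rows = []
    shifted = set(f"G{i + 1:05d}" for i in range(n_shifted))
    design = [(f"ctrl_{r + 1}", "control") for r in range(n_reps)] + [
        (f"diff_{r + 1}", "differentiated") for r in range(n_reps)
    ]
    for sample, cond in design:
        rng = rng_for(seed, f"tails:{sample}")
        for i in range(n_genes):
            gid = f"G{i + 1:05d}"
            mu = base_mean + (shift if (cond == "differentiated" and gid in shifted) else 0.0)
            n = max(1, int(rng.poisson(depth)))
            tails = _truncnorm_int(rng, mu, base_sd, n)
            rows.append((gid, sample, cond, n, float(tails.mean())))
    summaries = pd.DataFrame(
        rows, columns=["gene_id", "sample", "condition", "n_reads", "mean_tail"]
    )
    truth = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:05d}" for i in range(n_genes)],
            "shifted": [f"G{i + 1:05d}" in shifted for i in range(n_genes)],
            "true_shift": [shift if f"G{i + 1:05d}" in shifted else 0.0 for i in range(n_genes)],
        }
    )
    return summaries, truth


def simulate_apa_site_counts(
    n_genes: int,
    n_reps: int = 3,
    depth: float = 500.0,
    usage_control: float = 0.2,
    usage_affected: float = 0.8,
    frac_affected: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site count table for APA testing: two sites per gene, a fraction of
    genes switching distal usage between conditions.

    Matches the distribution of per-site counts the read simulator would
    produce (reads ~ Poisson(depth), site choice ~ Bernoulli(usage)), without
    materialising reads. Returns (long count table, truth).
    """
    rng_pick = rng_for(seed, "apa:genes")
    affected = rng_pick.random(n_genes) < frac_affected
    design = [(f"ctrl_{r + 1}", "control") for r in range(n_reps)] + [
        (f"diff_{r + 1}", "differentiated") for r in range(n_reps)
    ]
    rows = []
    for sample, cond in design:
        rng = rng_for(seed, f"apa:{sample}")
        n_reads = rng.poisson(depth, size=n_genes)
        usage = np.where(
            affected & (cond == "differentiated"), usage_affected, usage_control
        )
        distal = rng.binomial(n_reads, usage)
        for i in range(n_genes):
            gid = f"G{i + 1:05d}"
            rows.append((gid, "proximal", sample, cond, int(n_reads[i] - distal[i])))
            rows.append((gid, "distal", sample, cond, int(distal[i])))
    counts = pd.DataFrame(
        rows, columns=["gene_id", "site_rank", "sample", "condition", "count"]
    )
    truth = pd.DataFrame(
        {"gene_id": [f"G{i + 1:05d}" for i in range(n_genes)], "affected": affected}
    )
    return counts, truth
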