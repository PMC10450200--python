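"""Per-read poly(A) tail calling from 3'-anchored reads.

The caller works in read orientation: an A-run is extended leftward from the
3' end, tolerating low-quality bases as wildcards and budgeting high-quality
mismatches against a cumulative error fraction, then compared against the
genome downstream of the alignment to split templated from non-templated
adenosines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._utils import revcomp


@dataclass
class TailCallParams:
    adapter: str = ""
    max_error_fraction: float = 0.2  # 1 error in 5 bases
    min_quality: int = 10  # Phred; <= this is treated as a wildcard
    min_nontemplated: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.max_error_fraction < 1.0:
            raise ValueError("max_error_fraction must be in (0, 1)")
        if self.min_nontemplated < 0:
            raise ValueError("min_nontemplated must be >= 0")


@dataclass
class PolyAReadCall:
    read_id: str
    gene_id: str | None
    chrom: str
    strand: str
    cleavage_pos: int  # 0-based, last aligned (templated) base, strand-aware
    tail_total: int
    tail_nontemplated: int
    is_polyadenylated: bool

    def __post_init__(self) -> None:
        if not 0 <= self.tail_nontemplated <= self.tail_total:
            raise ValueError("0 <= tail_nontemplated <= tail_total violated")


def _phred(qchar: str) -> int:
    return ord(qchar) - 33


def trim_adapter(
    seq: str,
    quals: str,
    adapter: str,
    max_mismatch_fraction: float = 0.1,
    min_overlap: int = 5,
) -> tuple[str, str]:
    """Remove the adapter occurrence closest to the 3' end.

    Full-length internal matches allow ``max_mismatch_fraction`` mismatches;
    a partial match hanging off the 3' end needs >= ``min_overlap`` matching
    prefix bases of the adapter. Quality string is trimmed in lockstep. No
    match leaves the read unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(seq), len(adapter)
    best = None
    for start in range(n - min_overlap, -1, -1):
        overlap = min(m, n - start)
        window = seq[start : start + overlap]
        allowed = int(max_mismatch_fraction * overlap)
        mism = sum(1 for a, b in zip(window, adapter) if a != b)
        if mism <= allowed:
            best = start
            break  # scanned from the 3' end; first hit is the closest
    if best is None:
        return seq, quals
    return seq[:best], quals[:best]


def call_tail(seq: str, quals: str, params: TailCallParams | None = None) -> tuple[int, int]:
    """Call the 3'-terminal A-run of an adapter-trimmed read.

    Extends leftward from the 3' end. A non-A base with Phred <=
    ``min_quality`` is a wildcard; a non-A base above that consumes error
    budget, and extension stops once cumulative errors would exceed
    ``max_error_fraction`` x current run length. The accepted run is then
    trimmed so both ends are literal 'A'.

    Returns ``(tail_total, tail_start_offset)``; ``(0, len(seq))`` when no
    tail is found.
    """
    params = params or TailCallParams()
    n = len(seq)
    if n == 0:
        return 0, 0
    errors = 0
    start = n  # leftmost accepted position
    for i in range(n - 1, -1, -1):
        base = seq[i].upper()
        if base == "A":
            start = i
            continue
        if _phred(quals[i]) <= params.min_quality:
            start = i  # wildcard: tolerated, not an error
            continue
        run_len = n - i
        if (errors + 1) > params.max_error_fraction * run_len:
            break
        errors += 1
        start = i
    # right/left trim to literal A at both ends
    end = n
    while end > start and seq[end - 1].upper() != "A":
        end -= 1
    while start < end and seq[start].upper() != "A":
        start += 1
    total = end - start
    return (total, start) if total > 0 else (0, n)


def count_nontemplated(
    tail_total: int,
    genome,
    chrom: str,
    aligned_end: int,
    strand: str,
    max_walk: int = 200,
) -> int:
    """Non-templated tail length: ``tail_total`` minus the genomic A-run
    immediately downstream of the aligned 3' end (floored at 0).

    ``aligned_end`` is the 0-based coordinate of the first reference base
    past the alignment in transcription direction. ``genome`` maps contig
    name -> sequence (dict, pyfaidx.Fasta, or similar).
    """
    ref = genome[chrom]
    reflen = len(ref)
    if not -1 <= aligned_end <= reflen:  # -1/reflen: walk starts off-contig
        raise IndexError(f"alignment end {aligned_end} outside {chrom}")
    templated = 0
    pos = aligned_end
    match = "A" if strand == "+" else "T"  # read-strand A on the reference
    step = 1 if strand == "+" else -1
    while 0 <= pos < reflen and templated < max_walk:
        if str(ref[pos]).upper() != match:
            break
        templated += 1
        pos += step
    return max(0, tail_total - templated)


# --------------------------------------------------------------------------
# gene assignment


@dataclass
class _GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    utr_start: int  # 0-based half-open genomic span of the 3'UTR
    utr_end: int
    tx_end: int  # transcript end coordinate (0-based, strand-aware)


@dataclass
class GeneAnnotation:
    """Interval lookup of 3'UTRs plus a downstream extension window."""

    records: list[_GeneRecord] = field(default_factory=list)
    extension: int = 2000

    @classmethod
    def from_genes(cls, genes, extension: int = 2000) -> "GeneAnnotation":
        recs = []
        for g in genes:
            if g.strand == "+":
                span = (g.cds_end + 1, g.pas_distal + 1)
                tx_end = g.pas_distal
            else:
                span = (g.pas_distal, g.cds_end)
                tx_end = g.pas_distal
            recs.append(_GeneRecord(g.id, g.chrom, g.strand, span[0], span[1], tx_end))
        return cls(records=recs, extension=extension)

    @classmethod
    def from_gff(cls, path: str, extension: int = 2000) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        recs = []
        for utr in db.features_of_type("three_prime_UTR"):
            parents = list(db.parents(utr, level=1))
            gene_id = utr.id
            for p in parents:
                gene_id = (
                    p.attributes.get("Parent", [p.id])[0]
                    if p.featuretype == "mRNA"
                    else p.id
                )
            start0, end0 = utr.start - 1, utr.end  # GFF is 1-based closed
            tx_end = end0 - 1 if utr.strand == "+" else start0
            recs.append(
                _GeneRecord(gene_id, utr.seqid, utr.strand, start0, end0, tx_end)
            )
        return cls(records=recs, extension=extension)

    def assign(self, chrom: str, strand: str, pos: int) -> str | None:
        """Gene whose 3'UTR (or extension window) contains ``pos``.

        Ties are broken by distance to the annotated transcript end.
        """
        in_utr = []
        in_ext = []
        for r in self.records:
            if r.chrom != chrom or r.strand != strand:
                continue
            if r.utr_start <= pos < r.utr_end:
                in_utr.append(r)
            elif r.strand == "+" and r.tx_end < pos <= r.tx_end + self.extension:
                in_ext.append(r)
            elif r.strand == "-" and r.tx_end - self.extension <= pos < r.tx_end:
                in_ext.append(r)
        pool = in_utr or in_ext
        if not pool:
            return None
        return min(pool, key=lambda r: abs(pos - r.tx_end)).gene_id


def assign_to_gene(annotation: GeneAnnotation, chrom: str, strand: str, pos: int):
    return annotation.assign(chrom, strand, pos)


# --------------------------------------------------------------------------
# file-level pipeline


def call_reads_from_alignments(
    sam_path: str,
    genome,
    annotation: GeneAnnotation | None = None,
    params: TailCallParams | None = None,
) -> pd.DataFrame:
    """Call tails for every mapped read in a SAM/BAM file.

    The alignment is expected to cover the templated portion only (tail
    soft-clipped or trimmed pre-alignment). Returns a PolyAReadCall table.
    """
    import pysam

    params = params or TailCallParams()
    rows = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.get_forward_sequence()
            quals = aln.get_forward_qualities()
            if seq is None:
                continue
            qstr = "".join(chr(q + 33) for q in quals)
            if params.adapter:
                seq, qstr = trim_adapter(seq, qstr, params.adapter)
            # the tail lives in the unaligned 3' portion: aligned bases are
            # genome-templated by definition and cannot extend the run
            qlen = len(seq)
            if aln.is_reverse:
                clip3 = aln.query_alignment_start
            else:
                clip3 = qlen - aln.query_alignment_end
            clip3 = min(clip3, qlen)
            if clip3 > 0:
                tail_total, _ = call_tail(seq[-clip3:], qstr[-clip3:], params)
            else:
                tail_total = 0
            strand = "-" if aln.is_reverse else "+"
            if strand == "+":
                cleave = aln.reference_end - 1
                after = aln.reference_end
            else:
                cleave = aln.reference_start
                after = aln.reference_start - 1
            chrom = aln.reference_name
            nont = count_nontemplated(tail_total, genome, chrom, after, strand)
            gene = annotation.assign(chrom, strand, cleave) if annotation else None
            rows.append(
                (
                    aln.query_name,
                    gene,
                    chrom,
                    strand,
                    cleave,
                    tail_total,
                    nont,
                    nont >= params.min_nontemplated,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "gene_id",
            "chrom",
            "strand",
            "cleavage_pos",
            "tail_total",
            "tail_nontemplated",
            "is_polyadenylated",
        ],
    )
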