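"""Canonical miRNA seed-site scanning and gained-site accounting.

Site types follow the canonical seed-match definitions: the 6mer core is the
reverse complement of miRNA positions 2-7; 7mer-m8 extends the match to
position 8; 7mer-A1 requires an adenosine in the UTR opposite miRNA
position 1 (regardless of the miRNA base); 8mer satisfies both. At a given
core locus only the strongest type is reported (8mer > 7mer-m8 > 7mer-A1 >
6mer), so per-type counts partition the matched loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
#: default census excludes bare 6mers (prediction tables weight 7-8mers)
DEFAULT_CENSUS_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass
class SeedSite:
    gene_id: str
    mirna_id: str
    site_type: str
    position: int  # 0-based start of the full site on the sense UTR strand
    region: str = "common"  # common | gained
    conserved_site: bool = False
    conserved_mirna: bool = False


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """UTR-strand match strings for each site type of one miRNA."""
    m = _dna(mirna_seq)
    if len(m) < 8:
        raise ValueError("mirna_seq must be >= 8 nt")
    core = revcomp(m[1:7])  # positions 2-7
    m8 = revcomp(m[1:8])  # positions 2-8 (7 nt, m8 base 5' in the UTR)
    return {
        "6mer": core,
        "7mer-A1": core + "A",
        "7mer-m8": m8,
        "8mer": m8 + "A",
    }


def find_seed_sites(
    region_seq: str,
    mirna_seq: str,
    mirna_id: str = "",
    gene_id: str = "",
    site_types: tuple[str, ...] = SITE_TYPES,
) -> list[SeedSite]:
    """Scan a sense-strand UTR region for canonical seed matches.

    Every 6mer-core locus is classified once with the strongest applicable
    type among ``site_types``. Windows containing non-ACGTU characters are
    skipped with a warning.
    """
    pats = seed_patterns(mirna_seq)
    utr = _dna(region_seq)
    core = pats["6mer"]
    sites: list[SeedSite] = []
    warned = False
    for i in range(0, len(utr) - 6 + 1):
        window = utr[i : i + 6]
        if any(b not in "ACGT" for b in window):
            if not warned:
                warnings.warn("non-ACGTU characters in UTR; windows skipped")
                warned = True
            continue
        if window != core:
            continue
        has_m8 = i >= 1 and utr[i - 1] == pats["7mer-m8"][0]
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1 and "8mer" in site_types:
            stype, start = "8mer", i - 1
        elif has_m8 and "7mer-m8" in site_types:
            stype, start = "7mer-m8", i - 1
        elif has_a1 and "7mer-A1" in site_types:
            stype, start = "7mer-A1", i
        elif "6mer" in site_types:
            stype, start = "6mer", i
        else:
            continue
        sites.append(
            SeedSite(
                gene_id=gene_id, mirna_id=mirna_id, site_type=stype, position=start
            )
        )
    return sites


# --------------------------------------------------------------------------
# gained-site census


def gained_site_census(
    events: pd.DataFrame,
    utr_sequences: dict[str, str],
    mirna_seqs: dict[str, str],
    proximal_offsets: dict[str, int],
    distal_offsets: dict[str, int] | None = None,
    site_types: tuple[str, ...] = DEFAULT_CENSUS_TYPES,
    conserved_sites: set[tuple[str, str, int]] | None = None,
    conserved_mirnas: set[str] | None = None,
) -> pd.DataFrame:
    """Count seed sites in gained vs common 3'UTR regions of lengthened genes.

    For each gene in ``events`` with classification 'lengthening', the common
    region is the UTR up to the proximal cleavage offset and the gained
    region the sequence between proximal and distal cleavage offsets
    (sense-strand offsets into ``utr_sequences[gene]``). Genes with missing
    sequence are skipped. Returns one row per site with conservation flags.
    """
    conserved_sites = conserved_sites or set()
    conserved_mirnas = conserved_mirnas or set()
    lengthened = events.loc[events["classification"] == "lengthening", "gene_id"]
    rows = []
    for gene in lengthened:
        seq = utr_sequences.get(gene)
        if seq is None:
            continue
        p_off = proximal_offsets[gene]
        d_off = (distal_offsets or {}).get(gene, len(seq))
        regions = {"common": seq[:p_off], "gained": seq[p_off:d_off]}
        for region_name, region_seq in regions.items():
            for mirna_id, mseq in mirna_seqs.items():
                for s in find_seed_sites(
                    region_seq, mseq, mirna_id=mirna_id, gene_id=gene,
                    site_types=site_types,
                ):
                    s.region = region_name
                    s.conserved_site = (gene, mirna_id, s.position) in conserved_sites
                    s.conserved_mirna = mirna_id in conserved_mirnas
                    rows.append(vars(s))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "mirna_id",
            "site_type",
            "position",
            "region",
            "conserved_site",
            "conserved_mirna",
        ],
    )


def census_summary(census: pd.DataFrame, mirna_de: pd.DataFrame | None = None) -> dict:
    """Totals, per-gene medians and conservation shares of a site census.

    Percentages are integer-rounded shares of gained sites that are
    non-conserved sites / belong to non-conserved miRNA families.
    """
    gained = census[census["region"] == "gained"]
    common = census[census["region"] == "common"]
    n_gained, n_common = int(len(gained)), int(len(common))

    def _median_per_gene(df: pd.DataFrame):
        if df.empty:
            return None
        return float(df.groupby("gene_id").size().median())

    n_noncons_site = int((~gained["conserved_site"]).sum())
    n_noncons_mirna = int((~gained["conserved_mirna"]).sum())
    out = {
        "n_gained": n_gained,
        "n_common": n_common,
        "median_gained_per_gene": _median_per_gene(gained),
        "median_common_per_gene": _median_per_gene(common),
        "n_gained_nonconserved_sites": n_noncons_site,
        "n_gained_nonconserved_mirnas": n_noncons_mirna,
        "pct_gained_nonconserved_sites": (
            int(round(100.0 * n_noncons_site / n_gained)) if n_gained else None
        ),
        "pct_gained_nonconserved_mirnas": (
            int(round(100.0 * n_noncons_mirna / n_gained)) if n_gained else None
        ),
    }
    if mirna_de is not None and not gained.empty:
        per_mirna = gained.groupby("mirna_id").size()
        de = mirna_de.reindex(per_mirna.index)
        for direction, name in ((1, "up"), (-1, "down")):
            sel = per_mirna[
                (de["significant"].fillna(False)) & (np.sign(de["log2fc"]) == direction)
            ]
            out[f"n_gained_{name}_mirna_sites"] = int(sel.sum()) if len(sel) else 0
            out[f"top_{name}_mirna"] = sel.idxmax() if len(sel) else None
    return out


def conservation_chisq(
    census: pd.DataFrame, correction: bool = False
) -> dict:
    """Two chi-squared tests of conservation composition.

    (1) within gained sites: conserved vs non-conserved against equal
    frequencies; (2) gained vs common: 2x2 contingency of region x
    conservation. Zero margins raise.
    """
    gained = census[census["region"] == "gained"]
    common = census[census["region"] == "common"]
    gc = int(gained["conserved_site"].sum())
    gn = int((~gained["conserved_site"]).sum())
    cc = int(common["conserved_site"].sum())
    cn = int((~common["conserved_site"]).sum())
    if gc + gn == 0:
        raise ValueError("no gained sites")
    chi_within, p_within = stats.chisquare([gc, gn])
    table = np.array([[gc, gn], [cc, cn]], dtype=float)
    if table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        raise ValueError("degenerate gained-vs-common table (zero margin)")
    chi_between, p_between, _, _ = stats.chi2_contingency(table, correction=correction)
    return {
        "chi2_within_gained": float(chi_within),
        "p_within_gained": float(p_within),
        "chi2_gained_vs_common": float(chi_between),
        "p_gained_vs_common": float(p_between),
    }


def utr_delta_shift_by_targets(
    pairs: pd.DataFrame, delta_utr: pd.DataFrame, per_mirna: bool = True
) -> pd.DataFrame:
    """KS shift of Δ3'UTR length for targets vs non-targets (delegates to the
    miRNA-integration shift test with metric = utr_delta)."""
    from .mirna_integration import target_shift_test

    return target_shift_test(pairs, delta_utr, metric="utr_delta", per_mirna=per_mirna)
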