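"""Alternative-polyadenylation analysis: PAS counting, differential site
usage, RED, event classification and 3'UTR length change."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .expression_stats import DISPERSION_FLOOR, estimate_dispersions

RED_PSEUDOCOUNT = 0.5


@dataclass
class PasSite:
    gene_id: str
    site_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    region: str = "3UTR"  # 3UTR | extension | intron | exonic
    counts: dict[str, int] = field(default_factory=dict)
    rank: str | None = None  # proximal | distal | other

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("PAS interval width must be >= 1")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0


def read_pas_bed(path: str) -> list[PasSite]:
    """Load a BED6 PAS table (name = gene:site-rank)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            gene, _, rank = name.partition(":")
            sites.append(
                PasSite(
                    gene_id=gene,
                    site_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rank=rank or None,
                )
            )
    return sites


def count_pas_reads(
    calls: pd.DataFrame,
    sites: list[PasSite],
    sample: str | None = None,
    flank: int = 10,
) -> list[PasSite]:
    """Assign polyadenylated read cleavage positions to PAS.

    A read counts toward a site when its cleavage position lies within the
    site interval extended by ``flank`` on both ends (matching strand); with
    several candidates the nearest site midpoint wins. Counts accumulate into
    ``site.counts`` keyed by sample.
    """
    by_key: dict[tuple[str, str], list[PasSite]] = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s)

    df = calls[calls["is_polyadenylated"]]
    samples = df["sample"] if "sample" in df.columns else pd.Series(sample, index=df.index)
    for (chrom, strand, pos), sub in df.groupby(
        ["chrom", "strand", "cleavage_pos"], sort=False
    ):
        cands = [
            s
            for s in by_key.get((chrom, strand), [])
            if s.start - flank <= pos < s.end + flank
        ]
        if not cands:
            continue
        best = min(cands, key=lambda s: abs(pos - s.midpoint))
        for smp, n in samples.loc[sub.index].value_counts().items():
            best.counts[smp] = best.counts.get(smp, 0) + int(n)
    return sites


def pas_count_table(sites: list[PasSite], samples: list[str]) -> pd.DataFrame:
    rows = [
        [s.gene_id, s.site_id, s.strand, s.midpoint, s.region]
        + [s.counts.get(x, 0) for x in samples]
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "site_id", "strand", "midpoint", "region"] + samples
    )


def normalize_site_counts(
    table: pd.DataFrame, samples: list[str], size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Divide per-sample site counts by depth size factors (geometric mean 1
    of per-sample totals unless supplied)."""
    if size_factors is None:
        totals = table[samples].sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValueError("sample with zero total PAS counts")
        size_factors = totals / np.exp(np.log(totals).mean())
    out = table.copy()
    out[samples] = table[samples] / size_factors[samples]
    return out


def filter_sites(
    norm_table: pd.DataFrame,
    samples: list[str],
    min_norm_count: float = 2.0,
    mode: str = "per_sample",
) -> pd.DataFrame:
    """Retain sites with >= ``min_norm_count`` normalized counts in every
    sample (``mode='per_sample'``, strict reading) or on average
    (``mode='mean'``)."""
    vals = norm_table[samples]
    if mode == "per_sample":
        keep = (vals >= min_norm_count).all(axis=1)
    elif mode == "mean":
        keep = vals.mean(axis=1) >= min_norm_count
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return norm_table.loc[keep]


# --------------------------------------------------------------------------
# differential site usage


def _nb_glm_lrt(y: np.ndarray, cond: np.ndarray, offset: np.ndarray, phi: float):
    """NB GLM of site counts ~ condition with log-offset; returns (lfc, p)."""
    import statsmodels.api as sm

    X_full = np.column_stack([np.ones(y.size), cond])
    X_null = X_full[:, :1]
    fam = sm.families.NegativeBinomial(alpha=max(phi, DISPERSION_FLOOR))
    fit_full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
    fit_null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
    lr = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    return float(fit_full.params[1] / np.log(2.0)), float(stats.chi2.sf(lr, df=1))


def diff_site_usage(
    counts: pd.DataFrame,
    design: dict[str, str],
    group_order: tuple[str, str] = ("control", "differentiated"),
) -> pd.DataFrame:
    """Per-site usage test: NB LRT on site counts with the per-sample gene
    total as offset, so the condition coefficient is the usage log2 change.

    ``counts`` is long format (gene_id, site_rank|site_id, sample, count).
    Samples where the gene total is zero are dropped for that gene.
    """
    site_col = "site_id" if "site_id" in counts.columns else "site_rank"
    g0, g1 = group_order
    wide = counts.pivot_table(
        index=["gene_id", site_col], columns="sample", values="count", fill_value=0
    )
    samples = [s for s in wide.columns if design.get(s) in group_order]
    wide = wide[samples]
    gene_totals = wide.groupby(level="gene_id").sum()

    # pooled dispersion over all sites (usage-level residual variation)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_norm = wide.to_numpy(float) / gene_totals.reindex(
            wide.index.get_level_values("gene_id")
        ).to_numpy(float)
    scale = np.nanmean(wide.to_numpy(float))
    pseudo = np.nan_to_num(frac_norm) * scale
    idx_groups = [
        np.array([i for i, s in enumerate(samples) if design[s] == g]) for g in group_order
    ]
    common_phi, _ = estimate_dispersions(pseudo, idx_groups)

    rows = []
    for (gene, site), y in wide.iterrows():
        tot = gene_totals.loc[gene]
        use = tot > 0
        if use.sum() < 4 or len({design[s] for s in np.array(samples)[use]}) < 2:
            continue
        yv = y.to_numpy(float)[use.to_numpy()]
        cond = np.array(
            [1 if design[s] == g1 else 0 for s in np.array(samples)[use.to_numpy()]]
        )
        offset = np.log(tot.to_numpy(float)[use.to_numpy()])
        try:
            lfc, p = _nb_glm_lrt(yv, cond, offset, float(common_phi))
        except Exception:
            continue
        rows.append((gene, site, lfc, p))
    out = pd.DataFrame(rows, columns=["gene_id", "site", "lfc", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"])
    return out


# --------------------------------------------------------------------------
# RED and event classification


def red(
    dif_dist: float,
    ctrl_dist: float,
    dif_prox: float,
    ctrl_prox: float,
    pseudocount: float = RED_PSEUDOCOUNT,
) -> float:
    """Relative expression difference between distal and proximal sites:
    ``log2(dif_dist/ctrl_dist) - log2(dif_prox/ctrl_prox)``.

    A pseudocount guards zero means; non-positive guarded means are an error.
    """
    vals = np.asarray([dif_dist, ctrl_dist, dif_prox, ctrl_prox], dtype=float) + pseudocount
    if np.any(vals <= 0):
        raise ValueError("RED requires positive means after pseudocount")
    dd, cd, dp, cp = vals
    return float(np.log2(dd / cd) - np.log2(dp / cp))


def classify_event(
    red_value: float,
    distal_lfc: float,
    distal_fdr: float,
    proximal_lfc: float,
    proximal_fdr: float,
    fdr_cut: float = 0.1,
    red_cut: float = 1.0,
) -> str:
    """Lengthening / shortening / none per the RED + per-site significance rule."""
    dist_up = distal_fdr < fdr_cut and distal_lfc > 0
    dist_down = distal_fdr < fdr_cut and distal_lfc < 0
    prox_up = proximal_fdr < fdr_cut and proximal_lfc > 0
    prox_down = proximal_fdr < fdr_cut and proximal_lfc < 0
    if red_value > red_cut and (dist_up or prox_down):
        return "lengthening"
    if red_value < -red_cut and (dist_down or prox_up):
        return "shortening"
    return "none"


def delta_utr_length(
    proximal_len: float,
    distal_len: float,
    distal_usage_control: float,
    distal_usage_diff: float,
) -> float:
    """Signed change in usage-weighted mean 3'UTR length (nt).

    Lengths are transcription-direction distances from the CDS end to each
    site midpoint; usage is the distal fraction among the top-2 sites.
    """
    mean_ctrl = (1 - distal_usage_control) * proximal_len + distal_usage_control * distal_len
    mean_diff = (1 - distal_usage_diff) * proximal_len + distal_usage_diff * distal_len
    return float(mean_diff - mean_ctrl)


def pas_region_chisq(region_counts: pd.DataFrame) -> tuple[float, float]:
    """Chi-squared on the region x condition contingency of expressed sites."""
    table = region_counts.to_numpy(float)
    if table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        raise ValueError("degenerate contingency table (empty margin)")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.warn("expected cell count < 1 in PAS region chi-squared")
    return float(chi2), float(p)


# --------------------------------------------------------------------------
# event assembly


def select_top_two_sites(
    norm_table: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Pick each gene's two most expressed sites (summed normalized counts)
    and rank them proximal/distal by transcription-direction midpoint order.
    Ties in expression prefer the more distal site."""
    out = []
    for gene, sub in norm_table.groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        sub = sub.copy()
        sub["_total"] = sub[samples].sum(axis=1)
        strand = sub["strand"].iloc[0]
        # distal-preferring tiebreak: sort by (total, transcription-direction midpoint)
        direction = 1.0 if strand == "+" else -1.0
        sub = sub.sort_values(
            by=["_total", "midpoint"],
            ascending=[False, strand == "-"],
        )
        top2 = sub.head(2).copy()
        order = top2["midpoint"] * direction
        top2["rank"] = np.where(order == order.min(), "proximal", "distal")
        out.append(top2.drop(columns="_total"))
    if not out:
        return pd.DataFrame(columns=list(norm_table.columns) + ["rank"])
    return pd.concat(out, ignore_index=True)


def build_apa_events(
    ranked: pd.DataFrame,
    usage: pd.DataFrame,
    design: dict[str, str],
    samples: list[str],
    group_order: tuple[str, str] = ("control", "differentiated"),
    cds_end: dict[str, float] | None = None,
    fdr_cut: float = 0.1,
    red_cut: float = 1.0,
) -> pd.DataFrame:
    """Combine ranked top-2 sites with per-site usage tests into APA events.

    ``ranked`` is the output of :func:`select_top_two_sites` (normalized
    counts); ``usage`` the output of :func:`diff_site_usage` on the same
    sites keyed by (gene_id, site_id). RED is computed from guarded
    normalized means; classification and Δ3'UTR length follow.
    """
    g0, g1 = group_order
    cols0 = [s for s in samples if design.get(s) == g0]
    cols1 = [s for s in samples if design.get(s) == g1]
    site_col = "site" if "site" in usage.columns else "site_id"
    ukey = usage.set_index(["gene_id", site_col])

    rows = []
    for gene, sub in ranked.groupby("gene_id", sort=True):
        if set(sub["rank"]) != {"proximal", "distal"}:
            continue
        prox = sub[sub["rank"] == "proximal"].iloc[0]
        dist = sub[sub["rank"] == "distal"].iloc[0]
        try:
            u_p = ukey.loc[(gene, prox["site_id"])]
            u_d = ukey.loc[(gene, dist["site_id"])]
        except KeyError:
            continue
        red_val = red(
            dif_dist=dist[cols1].mean(),
            ctrl_dist=dist[cols0].mean(),
            dif_prox=prox[cols1].mean(),
            ctrl_prox=prox[cols0].mean(),
        )
        cls = classify_event(
            red_val,
            float(u_d["lfc"]),
            float(u_d["fdr"]),
            float(u_p["lfc"]),
            float(u_p["fdr"]),
            fdr_cut=fdr_cut,
            red_cut=red_cut,
        )
        origin = (cds_end or {}).get(gene)
        strand = prox["strand"]
        if origin is None:
            origin = prox["midpoint"]  # fall back: proximal site as origin
        sgn = 1.0 if strand == "+" else -1.0
        len_p = abs(sgn * (prox["midpoint"] - origin))
        len_d = abs(sgn * (dist["midpoint"] - origin))
        tot0 = prox[cols0].mean() + dist[cols0].mean()
        tot1 = prox[cols1].mean() + dist[cols1].mean()
        use0 = dist[cols0].mean() / tot0 if tot0 > 0 else np.nan
        use1 = dist[cols1].mean() / tot1 if tot1 > 0 else np.nan
        d_utr = delta_utr_length(len_p, len_d, use0, use1)
        rows.append(
            (
                gene,
                prox["site_id"],
                dist["site_id"],
                red_val,
                float(u_d["lfc"]),
                float(u_d["fdr"]),
                float(u_p["lfc"]),
                float(u_p["fdr"]),
                cls,
                d_utr,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "proximal_site",
            "distal_site",
            "red",
            "distal_lfc",
            "distal_fdr",
            "proximal_lfc",
            "proximal_fdr",
            "classification",
            "delta_utr_len",
        ],
    )


def apa_event_summary(events: pd.DataFrame) -> dict:
    """Bookkeeping over classified APA events; ``pct_lengthening`` is the
    lengthening share of significant events, integer-rounded percent."""
    sig = events[events["classification"].isin(["lengthening", "shortening"])]
    n_sig = int(len(sig))
    n_len = int((sig["classification"] == "lengthening").sum())
    n_short = int((sig["classification"] == "shortening").sum())
    pct = int(round(100.0 * n_len / n_sig)) if n_sig else None
    med_len = (
        float(sig.loc[sig["classification"] == "lengthening", "delta_utr_len"].median())
        if n_len
        else None
    )
    return {
        "n_genes": int(events["gene_id"].nunique()),
        "n_significant": n_sig,
        "n_lengthening": n_len,
        "n_shortening": n_short,
        "pct_lengthening": pct,
        "median_lengthening_delta_utr": med_len,
    }
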