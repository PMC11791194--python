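"""Hypergeometric enrichment of CpG sets in genomic annotations.

All tests are foreground/background hypergeometric draws over a CpG
universe (the array CpGs with map positions): N background CpGs, K of them
inside the annotation, n foreground CpGs, k of those inside. Fold change is
observed over expected overlap, FC = k / (n*K/N); one-sided p-values for
enrichment (upper tail, FC > 1) and depletion (lower tail, FC < 1) are kept
in natural-log space. Supported annotation families:

* chromatin states and arbitrary region sets (point overlap by default);
* polycomb repressive complexes, a CpG counting as PRC1/PRC2-bound when it
  overlaps ChIP-seq peaks of at least two distinct member factors;
* transcription-factor binding datasets, with a +/-200 bp buffer around
  each CpG, a K/N <= 0.5 specificity cap (the four Yamanaka factors are
  always kept), and a median-p rule across a factor's datasets;
* GREAT-style gene regulatory domains (basal 5 kb upstream / 1 kb
  downstream of the TSS, extension up to 50 kb clipped at neighboring
  basal domains) for gene-set enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import CpGMap, RegionSet, ValidationError

logger = logging.getLogger(__name__)

PRC_COMPLEXES: dict[str, set[str]] = {
    "PRC1": {"RING1", "RNF2", "BMI1"},
    "PRC2": {"EED", "SUZ12", "EZH2"},
}
YAMANAKA_FACTORS = frozenset({"OCT4", "SOX2", "KLF4", "MYC"})


@dataclass
class EnrichmentRow:
    """One hypergeometric enrichment/depletion result."""

    set_name: str
    N: int  # background size
    K: int  # background CpGs in the set
    n: int  # foreground size
    k: int  # foreground CpGs in the set
    fold_change: float
    odds_ratio: float
    log_p_enrichment: float  # ln P(X >= k)
    log_p_depletion: float  # ln P(X <= k)
    source_label: str | None = None
    n_genes: int | None = None
    degenerate: bool = False

    @property
    def p_enrichment(self) -> float:
        return float(math.exp(self.log_p_enrichment))

    @property
    def p_depletion(self) -> float:
        return float(math.exp(self.log_p_depletion))

    @property
    def log10_p_enrichment(self) -> float:
        return self.log_p_enrichment / math.log(10.0)


def rows_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append(
            {
                "set_name": r.set_name,
                "source_label": r.source_label,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "fold_change": r.fold_change,
                "odds_ratio": r.odds_ratio,
                "log10_p_enrichment": r.log_p_enrichment / math.log(10.0),
                "log10_p_depletion": r.log_p_depletion / math.log(10.0),
                "n_genes": r.n_genes,
            }
        )
    return pd.DataFrame(recs)


def overlap_cpgs(
    cpg_map: CpGMap, regions: RegionSet, buffer_bp: int = 0
) -> set[str]:
    """CpGs whose (buffered) base interval intersects any interval of the set.

    A CpG at 1-based position p occupies [p-1, p); with a buffer b it
    becomes [p-1-b, p+b). Chromosomes present in the regions but absent
    from the map are ignored with a log notice.
    """
    if buffer_bp < 0:
        raise ValidationError("buffer_bp must be >= 0")
    by_chrom = regions.by_chromosome()
    tab = cpg_map.table
    map_chroms = set(tab["chromosome"])
    for c in set(by_chrom) - map_chroms:
        logger.info("chromosome %s in region set %s absent from CpG map", c, regions.set_name)
    hits: set[str] = set()
    for chrom, ivals in by_chrom.items():
        sub = tab[tab["chromosome"] == chrom]
        if sub.empty:
            continue
        pos = sub["position"].to_numpy(dtype=np.int64)
        starts, ends = ivals[:, 0], ivals[:, 1]
        # CpG interval [p-1-b, p+b) meets merged [s,e) iff s < p+b and e > p-1-b
        idx = np.searchsorted(starts, pos + buffer_bp, side="left") - 1
        ok = (idx >= 0) & (ends[np.clip(idx, 0, None)] > pos - 1 - buffer_bp)
        hits.update(sub.loc[sub.index[ok], "cpg_id"])
    return hits


def hypergeom_enrichment(
    foreground: Iterable[str],
    set_members: Iterable[str],
    background: Iterable[str],
    set_name: str = "",
    source_label: str | None = None,
) -> EnrichmentRow:
    """Exact hypergeometric enrichment of ``foreground`` in ``set_members``.

    The member set is intersected with the background before testing; the
    foreground must be a subset of the background.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValidationError("foreground and background must be non-empty")
    if not fg <= bg:
        raise ValidationError(
            f"{len(fg - bg)} foreground CpGs are not in the background"
        )
    members = set(set_members) & bg
    N, K, n = len(bg), len(members), len(fg)
    k = len(fg & members)
    if K == 0:
        return EnrichmentRow(
            set_name, N, 0, n, 0, math.nan, math.nan, 0.0, 0.0,
            source_label=source_label, degenerate=True,
        )
    fc = k / (n * K / N)
    log_p_enr = float(stats.hypergeom.logsf(k - 1, N, K, n))
    log_p_dep = float(stats.hypergeom.logcdf(k, N, K, n))
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a / b) / (c / d)
    return EnrichmentRow(
        set_name, N, K, n, k, fc, float(odds), log_p_enr, log_p_dep,
        source_label=source_label,
    )


def region_set_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    region_sets: Iterable[RegionSet],
    cpg_map: CpGMap,
    buffer_bp: int = 0,
) -> list[EnrichmentRow]:
    """One hypergeometric row per region set (e.g. chromatin states)."""
    rows = []
    for rs in region_sets:
        members = overlap_cpgs(cpg_map, rs, buffer_bp=buffer_bp)
        rows.append(
            hypergeom_enrichment(
                foreground, members, background,
                set_name=rs.set_name, source_label=rs.source_label,
            )
        )
    return rows


def prc_annotate(
    member_peaks: Mapping[str, RegionSet],
    cpg_map: CpGMap,
    complex_members: Mapping[str, set[str]] = PRC_COMPLEXES,
) -> dict[str, set[str]]:
    """CpGs bound by each polycomb complex (>= 2 distinct member factors)."""
    member_hits = {}
    for name, rs in member_peaks.items():
        member_hits[name] = overlap_cpgs(cpg_map, rs, buffer_bp=0)
    out: dict[str, set[str]] = {}
    for cx, members in complex_members.items():
        avail = [m for m in members if m in member_hits]
        missing = sorted(set(members) - set(avail))
        if missing:
            logger.info("complex %s: no peak set for member(s) %s", cx, missing)
        if len(avail) < 2:
            logger.warning("complex %s has < 2 member peak sets; empty annotation", cx)
            out[cx] = set()
            continue
        counts: dict[str, int] = {}
        for m in avail:
            for cpg in member_hits[m]:
                counts[cpg] = counts.get(cpg, 0) + 1
        out[cx] = {cpg for cpg, c in counts.items() if c >= 2}
    return out


def tf_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    tf_peak_sets: Mapping[tuple[str, str], RegionSet],
    cpg_map: CpGMap,
    buffer_bp: int = 200,
    ratio_cap: float = 0.5,
    always_keep: frozenset[str] = YAMANAKA_FACTORS,
) -> list[EnrichmentRow]:
    """Per-TF enrichment with the specificity cap and median-p dataset rule.

    TFs whose binding sites cover more than ``ratio_cap`` of the background
    are dropped (unless always kept); among a TF's datasets the row whose
    enrichment p is the median is reported — for an even count, the more
    significant of the two middle rows, so a concrete dataset's full row is
    always reported.
    """
    bg = set(background)
    per_tf: dict[str, list[EnrichmentRow]] = {}
    for (tf, dataset), rs in tf_peak_sets.items():
        members = overlap_cpgs(cpg_map, rs, buffer_bp=buffer_bp)
        row = hypergeom_enrichment(
            foreground, members, bg, set_name=tf, source_label=dataset
        )
        if row.K / row.N > ratio_cap and tf not in always_keep:
            continue
        per_tf.setdefault(tf, []).append(row)
    out = []
    for tf in sorted(per_tf):
        rows = sorted(per_tf[tf], key=lambda r: r.log_p_enrichment)
        m = len(rows)
        pick = rows[m // 2] if m % 2 == 1 else rows[m // 2 - 1]
        out.append(pick)
    return out


@dataclass
class GeneDomainTable:
    """GREAT-style basal and extended regulatory domains, 0-based half-open."""

    table: pd.DataFrame  # gene_id chromosome strand tss basal_start basal_end ext_start ext_end

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValidationError(f"duplicate gene ids: {dups.tolist()}")
        bad = self.table[
            (self.table["ext_start"] > self.table["basal_start"])
            | (self.table["ext_end"] < self.table["basal_end"])
        ]
        if len(bad):
            raise ValidationError("extended domain does not contain basal domain")

    def __len__(self) -> int:
        return len(self.table)


def build_gene_domains(
    tss_table: pd.DataFrame,
    proximal_up: int = 5000,
    proximal_down: int = 1000,
    distal_max: int = 50000,
) -> GeneDomainTable:
    """Build basal-plus-extension regulatory domains from a TSS table.

    ``tss_table`` columns: gene_id, chromosome, tss (1-based), strand (+/-).
    The basal domain spans ``proximal_up`` upstream to ``proximal_down``
    downstream of the TSS (strand-aware); the extension grows each flank by
    up to ``distal_max`` bp but stops at the nearest neighboring gene's
    basal domain and at the chromosome start.
    """
    req = {"gene_id", "chromosome", "tss", "strand"}
    missing = req - set(tss_table.columns)
    if missing:
        raise ValidationError(f"TSS table missing columns: {sorted(missing)}")
    bad_strand = set(tss_table["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValidationError(f"strand must be + or -, got {sorted(bad_strand)}")
    df = tss_table.copy()
    tss0 = df["tss"].astype(np.int64) - 1  # 0-based TSS coordinate
    plus = df["strand"] == "+"
    df["basal_start"] = np.where(plus, tss0 - proximal_up, tss0 - proximal_down)
    df["basal_end"] = np.where(plus, tss0 + proximal_down + 1, tss0 + proximal_up + 1)
    df["basal_start"] = df["basal_start"].clip(lower=0)

    df = df.sort_values(["chromosome", "basal_start"], kind="mergesort").reset_index(drop=True)
    ext_start = np.empty(len(df), dtype=np.int64)
    ext_end = np.empty(len(df), dtype=np.int64)
    for chrom, grp in df.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        bs = grp["basal_start"].to_numpy(np.int64)
        be = grp["basal_end"].to_numpy(np.int64)
        prev_end = np.concatenate([[0], np.maximum.accumulate(be)[:-1]])
        next_start = np.concatenate([bs[1:], [np.iinfo(np.int64).max]])
        ext_start[idx] = np.maximum(bs - distal_max, np.minimum(prev_end, bs))
        ext_end[idx] = np.minimum(be + distal_max, np.maximum(next_start, be))
    df["ext_start"] = np.maximum(ext_start, 0)
    df["ext_end"] = ext_end
    cols = ["gene_id", "chromosome", "strand", "tss", "basal_start", "basal_end",
            "ext_start", "ext_end"]
    return GeneDomainTable(df[cols])


def _cpgs_per_gene(domains: GeneDomainTable, cpg_map: CpGMap) -> dict[str, set[str]]:
    """Map each gene to CpGs falling in its extended regulatory domain."""
    out: dict[str, set[str]] = {}
    tab = cpg_map.table
    for chrom, genes in domains.table.groupby("chromosome", sort=False):
        sub = tab[tab["chromosome"] == chrom]
        if sub.empty:
            for g in genes["gene_id"]:
                out[g] = set()
            continue
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy(np.int64)  # 1-based; CpG base is [p-1, p)
        ids = sub["cpg_id"].to_numpy()
        for g, s, e in genes[["gene_id", "ext_start", "ext_end"]].itertuples(index=False):
            lo = np.searchsorted(pos, s + 1, side="left")  # p-1 >= s  <=>  p >= s+1
            hi = np.searchsorted(pos, e, side="right")     # p-1 < e   <=>  p <= e
            out[g] = set(ids[lo:hi])
    return out


def gene_set_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    gene_domains: GeneDomainTable,
    gene_sets: Mapping[str, Iterable[str]],
    cpg_map: CpGMap,
    min_overlap_genes: int = 3,
    p_report: float = 1e-3,
) -> list[EnrichmentRow]:
    """GREAT-style region-based gene-set enrichment over the CpG universe.

    Each gene set's member CpGs are the union of its genes' extended-domain
    CpGs; the test is the standard foreground/background hypergeometric.
    Rows are reported only when >= ``min_overlap_genes`` genes carry a
    foreground CpG and the enrichment p is below ``p_report``.
    """
    if not gene_sets:
        return []
    fg = set(foreground)
    per_gene = _cpgs_per_gene(gene_domains, cpg_map)
    out = []
    for name, genes in gene_sets.items():
        genes = list(genes)
        known = [g for g in genes if g in per_gene]
        if len(known) < len(genes):
            logger.info(
                "gene set %s: %d gene(s) absent from domain table",
                name, len(genes) - len(known),
            )
        member_cpgs: set[str] = set()
        n_overlap_genes = 0
        for g in known:
            member_cpgs |= per_gene[g]
            if per_gene[g] & fg:
                n_overlap_genes += 1
        if n_overlap_genes < min_overlap_genes:
            continue
        row = hypergeom_enrichment(fg, member_cpgs, background, set_name=name)
        row.n_genes = n_overlap_genes
        if row.log_p_enrichment < math.log(p_report):
            out.append(row)
    return out
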