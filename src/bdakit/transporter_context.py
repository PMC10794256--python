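"""Transporter-gene context of complete BGCs.

For every candidate BGC that is not at a contig edge, three regions are
examined: the trimmed cluster span ("in_cluster") and the 20 kb flanks
upstream ("5prime") and downstream ("3prime"), clipped at contig bounds.
Transporter genes (TCDB family labels) are assigned to regions by
overlap, each region is tiled into non-overlapping 1 kb windows, and
per-window family frequencies (genes per kb, assigned by gene start
coordinate) feed a Wilcoxon rank-sum test per family and region:
windows of the region versus all other windows of the BGC class.  A
family is flagged enriched at raw p < 0.05 (no multiplicity correction
by default) and exclusive when it occurs in only one region.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .bgc_io import BGCRecord

__all__ = [
    "TransporterAnnotation",
    "RegionConfig",
    "REGIONS",
    "assign_regions",
    "window_spans",
    "window_frequencies",
    "windowed_frequency",
    "rank_sum_test",
    "enrichment_scan",
    "read_transporter_table",
    "write_transporter_table",
]

REGIONS = ("5prime", "in_cluster", "3prime")

_TCDB_FAMILY_RE = re.compile(r"^\d+(\.[A-Za-z0-9]+)+$")


@dataclass(frozen=True)
class TransporterAnnotation:
    """One transporter gene: interval plus TCDB family labels."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    tcdb_family: str  # dotted code, e.g. "3.A.1"
    tcdb_superfamily: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start >= end")
        if not _TCDB_FAMILY_RE.match(self.tcdb_family):
            raise ValueError(
                f"{self.gene_id}: {self.tcdb_family!r} is not a TCDB dotted code"
            )


@dataclass(frozen=True)
class RegionConfig:
    proximate_margin: int = 20_000
    window: int = 1_000

    def __post_init__(self) -> None:
        if self.proximate_margin <= 0 or self.window <= 0:
            raise ValueError("RegionConfig values must be > 0")
        if self.window > self.proximate_margin:
            raise ValueError("window must not exceed proximate_margin")


def region_spans(
    bgc: BGCRecord, config: RegionConfig = RegionConfig()
) -> dict[str, tuple[int, int]]:
    """The three region spans of a BGC, clipped at contig bounds.

    Spans may be empty (start == end) when the cluster touches a contig
    end; empty spans are dropped.
    """
    spans = {
        "5prime": (max(0, bgc.region_start - config.proximate_margin), bgc.region_start),
        "in_cluster": (bgc.region_start, bgc.region_end),
        "3prime": (bgc.region_end, min(bgc.contig_length, bgc.region_end + config.proximate_margin)),
    }
    return {k: v for k, v in spans.items() if v[1] > v[0]}


def assign_regions(
    bgc: BGCRecord,
    annotations: Iterable[TransporterAnnotation],
    config: RegionConfig = RegionConfig(),
) -> dict[str, str]:
    """Assign transporter genes to the BGC's regions by overlap.

    Only complete (non contig-edge) BGCs are analysed; passing an edge
    record is an error.  Genes overlapping the cluster span are
    in_cluster (priority over flanks for straddlers); otherwise genes
    overlapping a flank go to 5prime/3prime; genes outside all regions,
    or on other contigs, are dropped.  Returns gene_id -> region.
    """
    if bgc.contig_edge:
        raise ValueError(f"{bgc.bgc_id} is at a contig edge; filter before analysis")
    spans = region_spans(bgc, config)
    out: dict[str, str] = {}
    for ann in annotations:
        if ann.contig_id != bgc.contig_id:
            continue
        for region in ("in_cluster", "5prime", "3prime"):  # overlap priority
            if region not in spans:
                continue
            s, e = spans[region]
            if ann.start < e and ann.end > s:
                out[ann.gene_id] = region
                break
    return out


def window_spans(span: tuple[int, int], width: int) -> list[tuple[int, int]]:
    """Tile a span into non-overlapping windows; the last may be partial."""
    s, e = span
    return [(w, min(w + width, e)) for w in range(s, e, width)]


def window_frequencies(
    span: tuple[int, int],
    annotations: Iterable[TransporterAnnotation],
    config: RegionConfig = RegionConfig(),
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-window, per-family frequencies (genes per kb) over a span.

    A gene counts in the window containing its start coordinate.
    Returns (family -> per-window frequency array, window widths in kb);
    partial terminal windows use their actual width.
    """
    wins = window_spans(span, config.window)
    widths_kb = np.array([(e - s) / 1000.0 for s, e in wins])
    counts: dict[str, np.ndarray] = {}
    for ann in annotations:
        if not span[0] <= ann.start < span[1]:
            continue
        idx = (ann.start - span[0]) // config.window
        counts.setdefault(ann.tcdb_family, np.zeros(len(wins)))[idx] += 1
    return {fam: c / widths_kb for fam, c in counts.items()}, widths_kb


def windowed_frequency(
    span: tuple[int, int],
    annotations: Iterable[TransporterAnnotation],
    config: RegionConfig = RegionConfig(),
) -> dict[str, float]:
    """Width-weighted mean per-window frequency per family (genes/kb)."""
    freqs, widths = window_frequencies(span, annotations, config)
    total_kb = float(widths.sum())
    return {fam: float(np.sum(f * widths)) / total_kb for fam, f in freqs.items()}


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) with midrank ties.

    Exact two-sided p by enumeration of rank assignments when
    n_x + n_y <= 10; tie-corrected normal approximation otherwise.
    Returns (U statistic for x, two-sided p).  When every value is
    identical across both samples, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if np.all(combined == combined[0]):
        return u_x, 1.0
    if nx + ny <= 10:
        mu = nx * ny / 2.0
        observed = abs(u_x - mu)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(nx + ny), nx):
            u = float(ranks[list(idx)].sum() - nx * (nx + 1) / 2.0)
            total += 1
            if abs(u - mu) >= observed - 1e-12:
                extreme += 1
        return u_x, extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Enrichment scan
# ---------------------------------------------------------------------------


def enrichment_scan(
    records: Sequence[BGCRecord],
    annotations: Sequence[TransporterAnnotation],
    config: RegionConfig = RegionConfig(),
    alpha: float = 0.05,
    top_k: int = 10,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-class transporter-family enrichment over the three regions.

    For each BGC class the windows of all complete member BGCs are
    pooled per region; the top ``top_k`` most abundant families (by gene
    count over all regions) are tested per region: that region's windows
    against all other windows of the class.  ``enriched`` flags raw
    p < alpha (Benjamini-Hochberg across the scan when ``fdr`` is set);
    ``exclusive`` flags families found in only one region.
    """
    by_contig: dict[str, list[TransporterAnnotation]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig_id, []).append(ann)

    rows = []
    classes = sorted({r.bgc_class for r in records})
    for cls in classes:
        members = [r for r in records if r.bgc_class == cls and not r.contig_edge]
        if not members:
            continue
        # pooled per-region window samples per family, and gene counts
        region_freqs: dict[str, dict[str, list[np.ndarray]]] = {r: {} for r in REGIONS}
        region_widths: dict[str, list[np.ndarray]] = {r: [] for r in REGIONS}
        fam_counts: dict[str, int] = {}
        fam_regions: dict[str, set[str]] = {}
        families_seen: set[str] = set()
        for bgc in members:
            anns = by_contig.get(bgc.contig_id, [])
            for region, span in region_spans(bgc, config).items():
                freqs, widths = window_frequencies(span, anns, config)
                region_widths[region].append(widths)
                for fam, f in freqs.items():
                    families_seen.add(fam)
                    region_freqs[region].setdefault(fam, []).append(f)
                    n_genes = int(round(float(np.sum(f * widths))))
                    fam_counts[fam] = fam_counts.get(fam, 0) + n_genes
                    if n_genes:
                        fam_regions.setdefault(fam, set()).add(region)
        if not families_seen:
            continue
        top = sorted(fam_counts, key=lambda f: (-fam_counts[f], f))[:top_k]
        # pooled per-region sample vectors, zeros for windows without genes
        per_bgc = {
            region: list(_iter_region(members, by_contig, config, region))
            for region in REGIONS
        }
        for fam in top:
            samples: dict[str, np.ndarray] = {}
            for region in REGIONS:
                arrs = [
                    freq_map.get(fam, np.zeros(widths.size))
                    for widths, freq_map in per_bgc[region]
                ]
                samples[region] = np.concatenate(arrs) if arrs else np.zeros(0)
            for region in REGIONS:
                x = samples[region]
                if x.size == 0:
                    continue
                y = np.concatenate([samples[r] for r in REGIONS if r != region])
                if y.size == 0:
                    continue
                _, p = rank_sum_test(x, y)
                mean_freq = float(x.mean())
                exclusive = fam_regions.get(fam, set()) == {region}
                rows.append((cls, region, fam, mean_freq, p, exclusive))
    out = pd.DataFrame(
        rows,
        columns=["bgc_class", "region", "tcdb_family", "mean_frequency", "p_value", "exclusive"],
    )
    if out.empty:
        out["enriched"] = pd.Series(dtype=bool)
        return out
    if fdr:
        out["p_adj"] = _benjamini_hochberg(out["p_value"].to_numpy())
        out["enriched"] = out["p_adj"] < alpha
    else:
        out["enriched"] = out["p_value"] < alpha
    return out


def _iter_region(members, by_contig, config, region):
    """Yield (window widths, family->frequency map) per member BGC region."""
    for bgc in members:
        spans = region_spans(bgc, config)
        if region not in spans:
            continue
        anns = by_contig.get(bgc.contig_id, [])
        freqs, widths = window_frequencies(spans[region], anns, config)
        yield widths, freqs


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_transporter_table(
    annotations: Sequence[TransporterAnnotation], handle: TextIO
) -> None:
    handle.write("gene_id\tcontig_id\tstart\tend\ttcdb_family\ttcdb_superfamily\n")
    for a in annotations:
        handle.write(
            f"{a.gene_id}\t{a.contig_id}\t{a.start}\t{a.end}\t"
            f"{a.tcdb_family}\t{a.tcdb_superfamily}\n"
        )


def read_transporter_table(handle: TextIO) -> list[TransporterAnnotation]:
    out = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("gene_id\t"):
            continue
        gene_id, contig_id, start, end, fam, sup = (line.split("\t") + [""])[:6]
        out.append(
            TransporterAnnotation(gene_id, contig_id, int(start), int(end), fam, sup)
        )
    return out
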