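"""Windowed feature-density statistics.

The reference genome is tiled with fixed-width non-overlapping windows
(default 10 kb; trailing partial windows dropped).  Feature load per window
is either bp of overlap (TEs, CNE bases, coding bases) or a count by the
midpoint rule (genes, CNE count mode).  On top of the table:

* TE enrichment in lineage-specific EBR windows vs the rest of the genome
  (two-sided Mann–Whitney U; families kept only if abundant, i.e. mean
  load >= 100 bp in EBR or non-EBR windows; Benjamini–Hochberg FDR across
  the lineage x family tests);
* density ratios of CNEs/genes inside vs outside msHSBs, with an optional
  minimum region size (the "> 1.5 Mbp" variant);
* the coding-as-CNE control: relabelling coding bases as CNE bases and
  measuring the mean per-window ratio of inflated to real CNE bases;
* assignment of genes to EBRs (+/- flank) and msHSBs (full containment)
  for export to external GO tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import Feature, GenomicInterval

DEFAULT_WINDOW = 10_000
DEFAULT_MIN_ABUNDANCE = 100.0
DEFAULT_FLANK = 300_000
DEFAULT_MSHSB_FLOOR = 1_500_000

_WINDOW_COLUMNS = ["chrom", "start", "end"]


@dataclass
class EnrichmentResult:
    lineage: str
    family: str
    n_ebr_windows: int
    n_other_windows: int
    mean_ebr: float
    mean_other: float
    mean_diff: float
    p_raw: float
    q_bh: float
    direction: str  # enriched | depleted
    abundant: bool


def make_windows(chrom_sizes: Mapping[str, int], w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Tile chromosomes with [0,w), [w,2w), ...; partial trailing windows dropped."""
    if w <= 0:
        raise ValueError(f"window width must be > 0, got {w}")
    rows = []
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom] // w
        for i in range(n):
            rows.append((chrom, i * w, (i + 1) * w))
    if not rows:
        warnings.warn(f"window width {w} exceeds every chromosome; empty table")
        return pd.DataFrame(columns=_WINDOW_COLUMNS)
    return pd.DataFrame(rows, columns=_WINDOW_COLUMNS)


def _window_index(table: pd.DataFrame) -> tuple[dict[str, int], dict[str, int], int]:
    """Per-chromosome (row offset, window count) assuming make_windows layout."""
    offsets: dict[str, int] = {}
    counts: dict[str, int] = {}
    w = None
    for chrom, sub in table.groupby("chrom", sort=False):
        offsets[chrom] = int(sub.index[0])
        counts[chrom] = len(sub)
        if w is None and len(sub):
            w = int(sub.iloc[0]["end"] - sub.iloc[0]["start"])
    return offsets, counts, w or DEFAULT_WINDOW


def load_features(
    table: pd.DataFrame,
    features: Iterable[Feature],
    mode: str = "bp",
    column: str | None = None,
) -> pd.DataFrame:
    """Accumulate feature load per window.

    bp mode: overlap length; a feature split across windows contributes
    each part to its window.  count mode: one count in the window holding
    the feature midpoint.  Loads land in per-family columns (or ``column``
    if given, pooling all families).
    """
    if mode not in {"bp", "count"}:
        raise ValueError(f"unknown mode {mode!r}")
    table = table.copy()
    offsets, counts, w = _window_index(table)
    loads: dict[str, np.ndarray] = {}

    def col_array(name: str) -> np.ndarray:
        if name not in loads:
            loads[name] = (
                table[name].to_numpy(dtype=float, copy=True)
                if name in table.columns
                else np.zeros(len(table))
            )
        return loads[name]

    for feat in features:
        iv = feat.interval
        chrom = iv.seq_id
        if chrom not in offsets:
            continue
        name = column or (feat.name or "feature")
        arr = col_array(name)
        off, nwin = offsets[chrom], counts[chrom]
        if mode == "count":
            mid = (iv.start + iv.end) // 2
            k = mid // w
            if 0 <= k < nwin:
                arr[off + k] += 1
        else:
            first = iv.start // w
            last = (iv.end - 1) // w
            for k in range(first, last + 1):
                if k < 0 or k >= nwin:
                    continue
                lo = max(iv.start, k * w)
                hi = min(iv.end, (k + 1) * w)
                arr[off + k] += hi - lo
    for name, arr in loads.items():
        table[name] = arr
    return table


def flag_windows(
    table: pd.DataFrame,
    intervals: Sequence[GenomicInterval],
    column: str,
    contained: bool = False,
    size_floor: int = 0,
) -> pd.DataFrame:
    """Boolean column: window overlaps (default) or is contained in an interval.

    ``size_floor`` ignores intervals shorter than the floor (containment
    semantics for msHSB variants).
    """
    table = table.copy()
    flags = np.zeros(len(table), dtype=bool)
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    chroms = table["chrom"].to_numpy()
    for iv in intervals:
        if iv.length < size_floor:
            continue
        on_chrom = chroms == iv.seq_id
        if contained:
            hit = on_chrom & (starts >= iv.start) & (ends <= iv.end)
        else:
            hit = on_chrom & (starts < iv.end) & (ends > iv.start)
        flags |= hit
    table[column] = flags
    return table


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _mwu(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p: exact for tiny samples, else normal approx."""
    if min(x.size, y.size) == 0:
        return float("nan")
    method = "exact" if min(x.size, y.size) <= 8 and not _has_ties(x, y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def te_enrichment(
    table: pd.DataFrame,
    ebr_intervals_by_lineage: Mapping[str, Sequence[GenomicInterval]],
    families: Sequence[str],
    min_abundance_bp: float = DEFAULT_MIN_ABUNDANCE,
    alpha: float = 0.05,
    fdr: float = 0.10,
) -> list[EnrichmentResult]:
    """Per (lineage, family) Mann–Whitney enrichment of loads in EBR windows.

    Only abundant families (mean load >= ``min_abundance_bp`` in EBR or
    non-EBR windows) enter the FDR family; others are reported with
    ``abundant=False`` and NaN q.
    """
    results: list[EnrichmentResult] = []
    testable: list[int] = []
    pvals: list[float] = []
    for lineage in sorted(ebr_intervals_by_lineage):
        flagged = flag_windows(table, ebr_intervals_by_lineage[lineage], "contains_EBR")
        in_ebr = flagged["contains_EBR"].to_numpy()
        n_ebr = int(in_ebr.sum())
        n_other = int((~in_ebr).sum())
        for family in families:
            loads = flagged[family].to_numpy(dtype=float)
            x, y = loads[in_ebr], loads[~in_ebr]
            mean_ebr = float(x.mean()) if x.size else float("nan")
            mean_other = float(y.mean()) if y.size else float("nan")
            abundant = (x.size and mean_ebr >= min_abundance_bp) or (
                y.size and mean_other >= min_abundance_bp
            )
            if n_ebr == 0:
                warnings.warn(f"no EBR windows for lineage {lineage!r}; p = NA")
                p = float("nan")
                abundant = False
            elif abundant:
                p = _mwu(x, y)
            else:
                p = float("nan")
            diff = mean_ebr - mean_other
            results.append(
                EnrichmentResult(
                    lineage=lineage,
                    family=family,
                    n_ebr_windows=n_ebr,
                    n_other_windows=n_other,
                    mean_ebr=mean_ebr,
                    mean_other=mean_other,
                    mean_diff=diff,
                    p_raw=p,
                    q_bh=float("nan"),
                    direction="enriched" if diff >= 0 else "depleted",
                    abundant=bool(abundant),
                )
            )
            if abundant and not np.isnan(p):
                testable.append(len(results) - 1)
                pvals.append(p)
    if pvals:
        qs = bh_fdr(pvals)
        for idx, q in zip(testable, qs):
            results[idx].q_bh = float(q)
    return results


def density_ratio(
    table: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    feature: str,
    size_floor: int = 0,
) -> tuple[float, float, float, float]:
    """(mean in-region, mean elsewhere, ratio, Mann–Whitney p) of window loads.

    A window is in-region iff fully contained in a region of length >=
    ``size_floor``.
    """
    flagged = flag_windows(table, regions, "_in_region", contained=True, size_floor=size_floor)
    mask = flagged["_in_region"].to_numpy()
    loads = flagged[feature].to_numpy(dtype=float)
    x, y = loads[mask], loads[~mask]
    mean_in = float(x.mean()) if x.size else float("nan")
    mean_out = float(y.mean()) if y.size else float("nan")
    if not y.size or mean_out == 0:
        raise ValueError("mean density outside regions is zero; ratio undefined")
    return mean_in, mean_out, mean_in / mean_out, _mwu(x, y)


def coding_as_cne_control(
    table: pd.DataFrame,
    cne_col: str = "cne_bp",
    coding_col: str = "coding_bp",
    mshsb_regions: Sequence[GenomicInterval] | None = None,
) -> dict:
    """Mean per-window (cne + coding)/cne over windows with cne > 0.

    Computed genome-wide and, if msHSB regions are supplied, separately for
    msHSB-contained and other windows.  Windows without CNE bases are
    excluded from the means (their count is reported).
    """
    cne = table[cne_col].to_numpy(dtype=float)
    coding = table[coding_col].to_numpy(dtype=float)
    has_cne = cne > 0
    if not has_cne.any():
        raise ValueError("no window with CNE bases > 0")
    ratio = np.full(len(table), np.nan)
    ratio[has_cne] = (cne[has_cne] + coding[has_cne]) / cne[has_cne]
    out = {
        "genome_wide": float(np.nanmean(ratio)),
        "n_windows_used": int(has_cne.sum()),
        "n_windows_excluded": int((~has_cne).sum()),
    }
    if mshsb_regions is not None:
        flagged = flag_windows(table, mshsb_regions, "_in_mshsb", contained=True)
        in_ms = flagged["_in_mshsb"].to_numpy()
        for label, mask in (("mshsb", in_ms), ("non_mshsb", ~in_ms)):
            sel = mask & has_cne
            out[label] = float(ratio[sel].mean()) if sel.any() else float("nan")
    return out


def assign_genes(
    genes: Sequence[Feature],
    ebrs: Sequence[tuple[str, GenomicInterval]] = (),
    mshsbs: Sequence[tuple[str, GenomicInterval]] = (),
    flank: int = DEFAULT_FLANK,
    mshsb_floor: int = DEFAULT_MSHSB_FLOOR,
) -> dict[str, list[str]]:
    """Gene lists per region for external GO analysis.

    A gene joins an EBR list iff it overlaps the EBR widened by ``flank``
    on each side; it joins an msHSB list iff fully contained in an msHSB of
    length >= ``mshsb_floor``.  A gene may land in several EBR lists.
    """
    lists: dict[str, list[str]] = {}
    for rid, iv in ebrs:
        lo = max(0, iv.start - flank)
        hi = iv.end + flank
        hits = [
            g.name
            for g in genes
            if g.interval.seq_id == iv.seq_id
            and g.interval.start < hi
            and g.interval.end > lo
        ]
        lists[rid] = hits
    for rid, iv in mshsbs:
        if iv.length < mshsb_floor:
            lists[rid] = []
            continue
        lists[rid] = [g.name for g in genes if iv.contains(g.interval)]
    return lists
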