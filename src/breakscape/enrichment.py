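"""ChIP enrichment statistics around double-strand breaks.

Break calling screens MRE11-like coverage against local background; peak
enrichment is summarized as the per-peak fold change of treated over
untreated mean per-bp coverage with a 0.1 pseudocount, reported per
distance-to-break shell or per side of the damaged (γH2AX) domains. The
distance shells are disjoint by default: D10K means d <= 10 kb, D250K
means 10 kb < d <= 250 kb, D1M means 250 kb < d <= 1 Mb, and CTRL is
everything farther (peaks on break-free chromosomes included).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CoverageTrack,
    DamageDomain,
    DSBSite,
    GenomicInterval,
    SignalPeak,
    ValidationError,
    min_distance,
)
from .stats import DegenerateInputError, welch_t

EPSILON = 0.1  # ChIP fold-change pseudocount

CATEGORIES = ("D10K", "D250K", "D1M", "CTRL")
_SHELL_BOUNDS = (("D10K", 10_000), ("D250K", 250_000), ("D1M", 1_000_000))


@dataclass
class DomainCallParams:
    """Parameters of the γH2AX domain caller."""

    z_hi: float = 2.0  # seed threshold on the per-bin z score
    z_lo: float = 1.0  # extension threshold
    merge_gap: int = 100_000  # bp; closer domains are merged
    min_width: int = 100_000  # bp; shorter domains are dropped


def call_dsb_sites(
    mre11_track: CoverageTrack,
    candidates: list[DSBSite],
    min_fc: float = 3.0,
    flank: int = 500,
) -> list[DSBSite]:
    """Candidates whose mean +/-``flank`` signal exceeds ``min_fc`` times
    the local background (median of a +/-10x``flank`` window, core
    excluded), sorted by position."""
    if flank < mre11_track.bin_size:
        raise ValidationError("flank must be at least one bin")
    called = []
    for site in candidates:
        v = mre11_track.values[site.chrom]
        bs = mre11_track.bin_size
        mid = site.midpoint
        chrom_len = len(v) * bs
        core = GenomicInterval(
            site.chrom, max(0, mid - flank), min(chrom_len, mid + flank)
        )
        signal = mre11_track.mean_over(core)
        b_core0, b_core1 = core.start // bs, (core.end - 1) // bs + 1
        b_lo = max(0, (mid - 10 * flank) // bs)
        b_hi = min(len(v), (mid + 10 * flank) // bs)
        window = np.concatenate([v[b_lo:b_core0], v[b_core1:b_hi]])
        background = float(np.median(window)) if window.size else 0.0
        if signal >= min_fc * background:
            called.append(site)
    return sorted(called, key=lambda s: (s.chrom, s.midpoint))


def classify_peak_distance(peak: SignalPeak, dsbs: list[DSBSite]) -> str:
    """Distance category of a peak summit relative to the nearest break.

    Shells are disjoint with inclusive upper bounds; peaks on break-free
    chromosomes are at infinite distance (CTRL). Cumulative aggregation is
    a reporting choice made in category_fold_change.
    """
    same = [s for s in dsbs if s.chrom == peak.chrom]
    if not same:
        return "CTRL"
    d = min_distance(peak.summit, same)
    for name, bound in _SHELL_BOUNDS:
        if d <= bound:
            return name
    return "CTRL"


def peak_fold_change(
    peak: SignalPeak, treated: CoverageTrack, untreated: CoverageTrack
) -> tuple[float, float, float]:
    """(treated mean, untreated mean, FC) over the peak interval."""
    t = treated.mean_over(peak.interval)
    u = untreated.mean_over(peak.interval)
    return t, u, (t + EPSILON) / (u + EPSILON)


def _category_tests(table: pd.DataFrame) -> pd.DataFrame:
    ctrl = table.loc[table.category == "CTRL", "fold_change"].to_numpy()
    rows = []
    for cat in CATEGORIES:
        fcs = table.loc[table.category == cat, "fold_change"].to_numpy()
        row = {"category": cat, "n": int(fcs.size)}
        row["mean_fc"] = float(fcs.mean()) if fcs.size else float("nan")
        row["p_vs_ctrl"] = float("nan")
        if cat != "CTRL" and fcs.size >= 2 and ctrl.size >= 2:
            try:
                row["p_vs_ctrl"] = welch_t(fcs, ctrl, tails="one").p_value
            except DegenerateInputError:
                pass
        rows.append(row)
    return pd.DataFrame(rows, columns=["category", "n", "mean_fc", "p_vs_ctrl"])


def category_fold_change(
    peaks: list[SignalPeak],
    dsbs: list[DSBSite],
    treated: CoverageTrack,
    untreated: CoverageTrack,
    cumulative: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak enrichment table plus per-category summary.

    Per-peak signal is the mean per-bp coverage over the peak interval
    (robust to peak-width variation); categories are disjoint shells by
    default, cumulative when requested (CTRL stays >1 Mb either way).
    """
    if treated.bin_size != untreated.bin_size:
        raise ValidationError("treated/untreated bin grids differ")
    rows = []
    for peak in peaks:
        t, u, fc = peak_fold_change(peak, treated, untreated)
        cat = classify_peak_distance(peak, dsbs)
        rows.append(
            {
                "chrom": peak.chrom,
                "summit": peak.summit,
                "category": cat,
                "signal_treated": t,
                "signal_untreated": u,
                "fold_change": fc,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "summit",
            "category",
            "signal_treated",
            "signal_untreated",
            "fold_change",
        ],
    )
    if cumulative and len(table):
        # widen shells: D250K absorbs D10K peaks, D1M absorbs both
        cumtable = table.copy()
        summaries = []
        order = {"D10K": 0, "D250K": 1, "D1M": 2, "CTRL": 3}
        ctrl = table.loc[table.category == "CTRL", "fold_change"].to_numpy()
        for cat in CATEGORIES:
            if cat == "CTRL":
                fcs = ctrl
            else:
                fcs = table.loc[
                    table.category.map(order) <= order[cat], "fold_change"
                ].to_numpy()
            row = {"category": cat, "n": int(fcs.size)}
            row["mean_fc"] = float(fcs.mean()) if fcs.size else float("nan")
            row["p_vs_ctrl"] = float("nan")
            if cat != "CTRL" and fcs.size >= 2 and ctrl.size >= 2:
                try:
                    row["p_vs_ctrl"] = welch_t(fcs, ctrl, tails="one").p_value
                except DegenerateInputError:
                    pass
            summaries.append(row)
        return cumtable, pd.DataFrame(
            summaries, columns=["category", "n", "mean_fc", "p_vs_ctrl"]
        )
    return table, _category_tests(table)


def call_anchor_sites(
    rad21_peaks: list[SignalPeak],
    ctcf_peaks: list[SignalPeak],
    max_center_gap: int = 500,
) -> list[SignalPeak]:
    """Cohesin anchors: RAD21 peaks whose summit lies within
    ``max_center_gap`` bp of some CTCF summit (each reported once)."""
    ctcf_by_chrom: dict[str, np.ndarray] = {}
    for p in ctcf_peaks:
        ctcf_by_chrom.setdefault(p.chrom, []).append(p.summit)
    ctcf_by_chrom = {c: np.sort(np.array(s)) for c, s in ctcf_by_chrom.items()}
    anchors = []
    for p in rad21_peaks:
        summits = ctcf_by_chrom.get(p.chrom)
        if summits is None or summits.size == 0:
            continue
        k = int(np.searchsorted(summits, p.summit))
        gaps = [
            abs(p.summit - summits[j])
            for j in (k - 1, k)
            if 0 <= j < summits.size
        ]
        if gaps and min(gaps) <= max_center_gap:
            anchors.append(p)
    return anchors


def call_damage_domains(
    gh2ax_treated: CoverageTrack,
    gh2ax_untreated: CoverageTrack,
    params: DomainCallParams | None = None,
    dsbs: list[DSBSite] | None = None,
) -> list[DamageDomain]:
    """Segment γH2AX gain into damage domains.

    Per bin, z = (treated - untreated) / sd(untreated over the chromosome);
    runs of z > z_lo containing a seed bin (z > z_hi) become domains;
    domains closer than merge_gap are merged, then those shorter than
    min_width are dropped. A domain is flagged damaged when it contains a
    (called) break midpoint.
    """
    params = params or DomainCallParams()
    if gh2ax_treated.bin_size != gh2ax_untreated.bin_size:
        raise ValidationError("treated/untreated bin grids differ")
    bs = gh2ax_treated.bin_size
    domains: list[DamageDomain] = []
    for chrom in gh2ax_treated.chroms():
        t = gh2ax_treated.values[chrom]
        u = gh2ax_untreated.values[chrom]
        sd = u.std()
        if sd == 0:
            raise ValidationError(
                f"zero untreated variance on {chrom}; the z score is undefined "
                "(inject noise or supply a real background track)"
            )
        z = (t - u) / sd
        above = z > params.z_lo
        # run-length segments of above-threshold bins
        boundaries = np.flatnonzero(np.diff(above.astype(int)))
        starts = [0] if above[0] else []
        starts += [int(b) + 1 for b in boundaries if not above[b]]
        ends = [int(b) + 1 for b in boundaries if above[b]]
        if above[-1]:
            ends.append(len(z))
        segments = [
            (s, e) for s, e in zip(starts, ends) if (z[s:e] > params.z_hi).any()
        ]
        # merge segments separated by less than merge_gap
        merged: list[list[int]] = []
        gap_bins = params.merge_gap // bs
        for s, e in segments:
            if merged and s - merged[-1][1] < gap_bins:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        chrom_len = len(t) * bs
        for s, e in merged:
            start, end = s * bs, min(e * bs, chrom_len)
            if end - start < params.min_width:
                continue
            damaged = any(
                site.chrom == chrom and start <= site.midpoint < end
                for site in (dsbs or [])
            )
            domains.append(
                DamageDomain(
                    GenomicInterval(chrom, start, end), kind="GH2AX", damaged=damaged
                )
            )
    return domains


def anchor_domain_enrichment(
    anchors: list[SignalPeak],
    domains: list[DamageDomain],
    treated: CoverageTrack,
    untreated: CoverageTrack,
) -> tuple[pd.DataFrame, dict]:
    """Anchor enrichment inside vs outside damaged domains.

    Each anchor is labelled inside when its summit falls within a damaged
    domain; the summary reports mean FCs per side and a one-tailed Welch
    test of inside > outside.
    """
    damaged = [d for d in domains if d.damaged]
    rows = []
    for anchor in anchors:
        inside = any(
            d.interval.chrom == anchor.chrom and d.interval.contains(anchor.summit)
            for d in damaged
        )
        t, u, fc = peak_fold_change(anchor, treated, untreated)
        rows.append(
            {
                "chrom": anchor.chrom,
                "summit": anchor.summit,
                "inside": inside,
                "signal_treated": t,
                "signal_untreated": u,
                "fold_change": fc,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "summit",
            "inside",
            "signal_treated",
            "signal_untreated",
            "fold_change",
        ],
    )
    fin = table.loc[table.inside, "fold_change"].to_numpy()
    fout = table.loc[~table.inside, "fold_change"].to_numpy()
    summary = {
        "n_inside": int(fin.size),
        "n_outside": int(fout.size),
        "mean_fc_inside": float(fin.mean()) if fin.size else float("nan"),
        "mean_fc_outside": float(fout.mean()) if fout.size else float("nan"),
        "test": None,
    }
    if fin.size >= 2 and fout.size >= 2:
        try:
            summary["test"] = welch_t(fin, fout, tails="one")
        except DegenerateInputError:
            pass
    return table, summary
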