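"""Downstream HTGTS junction analytics.

A junction library is filtered of bait-proximal rejoining events (prey
within +/- 20 kb of the bait on the bait chromosome), the remainder is
classified cis-deletion vs translocation by chromosome identity, each prey
is assigned a damage context (break site, γH2AX domain, or outside), and
junction-level microhomology is measured from the flanking sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DamageDomain, DSBSite, JunctionRecord, ValidationError
from .stats import DegenerateInputError, paired_t

BAIT_WINDOW = 20_000  # bp, bait-proximal annotation window
BREAK_WINDOW = 2_500  # bp, "break site" context around a cut
EPSILON = 0.1  # pseudocount on normalized junction rates

CIS_DELETION = "cis_deletion"
TRANSLOCATION = "translocation"
CONTEXTS = ("break_site", "gh2ax_domain", "outside")


@dataclass
class JunctionCallSet:
    """A bait's labelled junction records."""

    bait: DSBSite
    records: list[JunctionRecord] = field(default_factory=list)
    labels: pd.DataFrame | None = None


def filter_bait_proximal(
    records: list[JunctionRecord], bait: DSBSite, window: int = BAIT_WINDOW
) -> tuple[list[JunctionRecord], list[JunctionRecord]]:
    """Partition records into (kept, removed-as-bait-proximal).

    Removed records have their prey on the bait chromosome within +/-
    ``window`` bp of the bait position; the partition is exact.
    """
    kept, removed = [], []
    for r in records:
        if r.prey_chrom == bait.chrom and abs(r.prey_pos - bait.midpoint) <= window:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def classify_cis_trans(record: JunctionRecord, bait: DSBSite) -> str:
    """cis_deletion iff prey is on the bait chromosome, else translocation."""
    return CIS_DELETION if record.prey_chrom == bait.chrom else TRANSLOCATION


def assign_damage_context(
    record: JunctionRecord,
    dsbs: list[DSBSite],
    domains: list[DamageDomain],
    break_window: int = BREAK_WINDOW,
) -> str:
    """break_site > gh2ax_domain > outside, in that precedence."""
    for site in dsbs:
        if (
            site.chrom == record.prey_chrom
            and abs(record.prey_pos - site.midpoint) <= break_window
        ):
            return "break_site"
    for dom in domains:
        if (
            dom.damaged
            and dom.interval.chrom == record.prey_chrom
            and dom.interval.contains(record.prey_pos)
        ):
            return "gh2ax_domain"
    return "outside"


def microhomology_length(bait_flank: str, prey_flank: str) -> int:
    """Largest k with the last k bases of the bait flank equal to the first
    k bases of the prey flank; 'N' never matches."""
    if not bait_flank or not prey_flank:
        raise ValidationError("empty junction flank")
    for k in range(min(len(bait_flank), len(prey_flank)), 0, -1):
        suffix = bait_flank[-k:]
        if "N" in suffix:
            continue
        if suffix == prey_flank[:k]:
            return k
    return 0


def junction_distance_kbp(pos_a: int, pos_b: int, chrom_a: str = "", chrom_b: str = "") -> int:
    """Junction separation in whole kbp (floor of |Δ| / 1000)."""
    if chrom_a and chrom_b and chrom_a != chrom_b:
        raise ValidationError("junction distance across chromosomes is undefined")
    return abs(pos_a - pos_b) // 1000


def bin_junction_counts(
    records: list[JunctionRecord], bin_size: int = 1_000
) -> pd.DataFrame:
    """Unique prey events per bin.

    Events are deduplicated by (prey chrom, prey pos, prey strand) before
    binning; returns columns chrom/start/count.
    """
    unique = {(r.prey_chrom, r.prey_pos, r.prey_strand) for r in records}
    counts: dict[tuple[str, int], int] = {}
    for chrom, pos, _strand in unique:
        key = (chrom, (pos // bin_size) * bin_size)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"chrom": chrom, "start": start, "count": n}
        for (chrom, start), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "count"])


def condition_fold_change(
    counts_a: pd.Series,
    counts_b: pd.Series,
    totals: tuple[float, float],
) -> tuple[pd.DataFrame, dict]:
    """Fold change of library-size-normalized per-site junction counts.

    Counts are indexed by prey-site id; rates are events per 1,000 library
    junctions; FC = (rate_a + 0.1) / (rate_b + 0.1). Returns a per-site
    table and a summary with the aggregate FC and a one-tailed paired t
    across sites (a > b).
    """
    total_a, total_b = totals
    if total_a <= 0 or total_b <= 0:
        raise ValidationError("library totals must be positive")
    sites = sorted(set(counts_a.index) | set(counts_b.index))
    ca = counts_a.reindex(sites, fill_value=0).astype(float)
    cb = counts_b.reindex(sites, fill_value=0).astype(float)
    rate_a = ca / total_a * 1_000.0
    rate_b = cb / total_b * 1_000.0
    table = pd.DataFrame(
        {
            "site": sites,
            "count_a": ca.to_numpy(),
            "count_b": cb.to_numpy(),
            "rate_a": rate_a.to_numpy(),
            "rate_b": rate_b.to_numpy(),
            "fc": ((rate_a + EPSILON) / (rate_b + EPSILON)).to_numpy(),
        }
    )
    agg_a = float(ca.sum()) / total_a * 1_000.0
    agg_b = float(cb.sum()) / total_b * 1_000.0
    summary = {
        "n_sites": len(sites),
        "aggregate_fc": (agg_a + EPSILON) / (agg_b + EPSILON),
        "mean_site_fc": float(table.fc.mean()) if sites else float("nan"),
    }
    if len(sites) >= 2:
        try:
            summary["t_a_gt_b"] = paired_t(
                rate_a.to_numpy(), rate_b.to_numpy(), tails="one"
            )
        except DegenerateInputError:
            summary["t_a_gt_b"] = None
    else:
        summary["t_a_gt_b"] = None
    return table, summary


def mh_profile(mh_lengths) -> tuple[pd.Series, dict]:
    """Histogram of microhomology lengths (per-integer bins from 0) plus a
    summary with the fraction of junctions using >=1 bp microhomology."""
    lengths = np.asarray(list(mh_lengths), dtype=int)
    if lengths.size == 0:
        hist = pd.Series(dtype=int)
        return hist, {"n": 0, "fraction_mh": float("nan"), "mean_mh": float("nan")}
    top = int(lengths.max())
    hist = pd.Series(
        np.bincount(lengths, minlength=top + 1), index=np.arange(top + 1)
    )
    return hist, {
        "n": int(lengths.size),
        "fraction_mh": float((lengths >= 1).mean()),
        "mean_mh": float(lengths.mean()),
    }


def annotate(
    records: list[JunctionRecord],
    bait: DSBSite,
    dsbs: list[DSBSite],
    domains: list[DamageDomain],
    bait_window: int = BAIT_WINDOW,
    break_window: int = BREAK_WINDOW,
) -> JunctionCallSet:
    """Full per-record labelling: bait-proximal flag, cis/trans class,
    damage context and microhomology length."""
    proximal_ids = {
        r.read_id for r in filter_bait_proximal(records, bait, bait_window)[1]
    }
    rows = []
    for r in records:
        proximal = r.read_id in proximal_ids
        rows.append(
            {
                "read_id": r.read_id,
                "bait_proximal": proximal,
                "class": "" if proximal else classify_cis_trans(r, bait),
                "context": assign_damage_context(r, dsbs, domains, break_window),
                "mh_len": microhomology_length(r.bait_flank, r.prey_flank),
                "prey_chrom": r.prey_chrom,
                "prey_pos": r.prey_pos,
            }
        )
    labels = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "bait_proximal",
            "class",
            "context",
            "mh_len",
            "prey_chrom",
            "prey_pos",
        ],
    )
    return JunctionCallSet(bait=bait, records=list(records), labels=labels)
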