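"""Observed/expected Hi-C normalization and domain-level interaction stats.

The expected profile is the raw per-distance mean contact count computed
from the matrix itself (zeros included, no smoothing); O/E divides each
entry by the expected value at its bin separation, removing distance decay.
Domain scores are means of O/E over bin pairs inside a domain (intra) or
over the cross rectangle between two domains (inter). Viewpoint tracks and
translocation-window scores operate on raw normalized counts with the
pseudocounts used by the study (1 for 4C-like log2FC tracks, 0.1 for
summed 5x5 translocation windows).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ContactMatrix, DamageDomain, ValidationError
from .stats import DegenerateInputError, one_sample_t, welch_t

logger = logging.getLogger(__name__)

TRANS_RESOLUTION = 250_000  # bp; translocation windows are defined at 250 kb


@dataclass
class ExpectedProfile:
    """Per-distance (in bins) mean contact count for one chromosome."""

    chrom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("negative expected value")


@dataclass(frozen=True)
class DomainScore:
    """Mean O/E over the bin pairs of a domain or domain pair."""

    domain_id: str
    score: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValidationError("DomainScore requires n_pairs > 0")


def expected_profile(m: ContactMatrix) -> ExpectedProfile:
    """Raw mean of counts at each bin separation d (including zeros)."""
    if not m.is_intra:
        raise ValidationError("expected_profile requires an intra-chromosomal matrix")
    n = m.shape[0]
    values = np.array([m.counts.diagonal(d).mean() for d in range(n)])
    return ExpectedProfile(m.chrom_a, values)


def oe_normalize(m: ContactMatrix) -> ContactMatrix:
    """O/E matrix; entries at separations with zero expectation are NaN."""
    prof = expected_profile(m).values
    n = m.shape[0]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = prof[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(e > 0, m.counts / np.where(e > 0, e, 1.0), np.nan)
    return ContactMatrix(m.chrom_a, m.chrom_b, m.resolution, oe)


def _domain_bins(domain: DamageDomain, m: ContactMatrix) -> np.ndarray:
    """Indices of bins overlapping the domain interval."""
    iv = domain.interval
    b0 = iv.start // m.resolution
    b1 = min((iv.end - 1) // m.resolution + 1, m.shape[0])
    return np.arange(b0, b1)


def intra_domain_score(oe: ContactMatrix, domain: DamageDomain) -> DomainScore:
    """Mean O/E over unordered within-domain bin pairs, diagonal excluded."""
    if not oe.is_intra:
        raise ValidationError("intra_domain_score requires an intra matrix")
    if domain.interval.chrom != oe.chrom_a:
        raise ValidationError("domain is on a different chromosome")
    bins = _domain_bins(domain, oe)
    if len(bins) < 2:
        raise ValidationError(
            f"domain {domain.id} spans {len(bins)} bin(s); score undefined"
        )
    sub = oe.counts[np.ix_(bins, bins)]
    iu = np.triu_indices(len(bins), k=1)
    vals = sub[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError(f"domain {domain.id}: all O/E entries masked")
    return DomainScore(domain.id, float(vals.mean()), int(vals.size))


def inter_domain_score(
    oe: ContactMatrix, domain_a: DamageDomain, domain_b: DamageDomain
) -> DomainScore:
    """Mean O/E over the cross rectangle (i in A, j in B)."""
    if domain_a.interval.chrom != domain_b.interval.chrom:
        raise ValidationError("inter_domain_score requires an intrachromosomal pair")
    if domain_a.interval.overlaps(domain_b.interval):
        raise ValidationError("overlapping domains in inter_domain_score")
    bins_a = _domain_bins(domain_a, oe)
    bins_b = _domain_bins(domain_b, oe)
    if len(bins_a) == 0 or len(bins_b) == 0:
        raise ValidationError("empty domain in inter_domain_score")
    vals = oe.counts[np.ix_(bins_a, bins_b)].ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError("all O/E entries masked in rectangle")
    return DomainScore(
        f"{domain_a.id}|{domain_b.id}", float(vals.mean()), int(vals.size)
    )


def _group_summary(fcs: np.ndarray) -> dict:
    out: dict = {"n": int(fcs.size)}
    if fcs.size:
        out["mean_fc"] = float(fcs.mean())
        try:
            out["t_vs_1"] = one_sample_t(fcs, 1.0, tails="one")
        except (DegenerateInputError, ValidationError):
            out["t_vs_1"] = None
    else:
        out["mean_fc"] = float("nan")
        out["t_vs_1"] = None
    return out


def intra_domain_fc(
    treated: ContactMatrix,
    untreated: ContactMatrix,
    domains: list[DamageDomain],
) -> tuple[pd.DataFrame, dict]:
    """Per-domain treated/untreated O/E score fold changes plus summaries.

    Domains are grouped by their ``damaged`` flag; a one-tailed t of the
    damaged-group FCs against 1 and a damaged-vs-control Welch comparison
    are reported. Domains with an undefined score in either condition are
    dropped (and logged).
    """
    if treated.resolution != untreated.resolution:
        raise ValidationError("treated/untreated resolution mismatch")
    oe_t = oe_normalize(treated)
    oe_u = oe_normalize(untreated)
    rows = []
    for dom in domains:
        if dom.interval.chrom != treated.chrom_a:
            continue
        try:
            st = intra_domain_score(oe_t, dom)
            su = intra_domain_score(oe_u, dom)
        except ValidationError as exc:
            logger.info("dropping domain %s: %s", dom.id, exc)
            continue
        if su.score == 0:
            logger.info("dropping domain %s: zero untreated score", dom.id)
            continue
        rows.append(
            {
                "domain_id": dom.id,
                "chrom": dom.interval.chrom,
                "start": dom.interval.start,
                "end": dom.interval.end,
                "damaged": dom.damaged,
                "score_treated": st.score,
                "score_untreated": su.score,
                "n_pairs": st.n_pairs,
                "fc": st.score / su.score,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "domain_id",
            "chrom",
            "start",
            "end",
            "damaged",
            "score_treated",
            "score_untreated",
            "n_pairs",
            "fc",
        ],
    )
    damaged = table.loc[table.damaged, "fc"].to_numpy()
    control = table.loc[~table.damaged, "fc"].to_numpy()
    summary = {
        "damaged": _group_summary(damaged),
        "control": _group_summary(control),
    }
    if damaged.size >= 2 and control.size >= 2:
        try:
            summary["damaged_vs_control"] = welch_t(damaged, control, tails="one")
        except DegenerateInputError:
            summary["damaged_vs_control"] = None
    else:
        summary["damaged_vs_control"] = None
    return table, summary


def inter_domain_pair_fc(
    treated: ContactMatrix,
    untreated: ContactMatrix,
    pairs: list[tuple[DamageDomain, DamageDomain]],
) -> tuple[pd.DataFrame, dict]:
    """Treated/untreated fold change of cross-rectangle O/E per domain pair.

    Pairs where both domains are damaged summarize the DSB-DSB set; pairs
    where neither is damaged summarize the Ctrl-Ctrl set.
    """
    oe_t = oe_normalize(treated)
    oe_u = oe_normalize(untreated)
    rows = []
    for dom_a, dom_b in pairs:
        st = inter_domain_score(oe_t, dom_a, dom_b)
        su = inter_domain_score(oe_u, dom_a, dom_b)
        if su.score == 0:
            logger.info("dropping pair %s: zero untreated score", st.domain_id)
            continue
        if dom_a.damaged and dom_b.damaged:
            group = "damaged"
        elif not dom_a.damaged and not dom_b.damaged:
            group = "control"
        else:
            group = "mixed"
        rows.append(
            {
                "pair_id": st.domain_id,
                "chrom": dom_a.interval.chrom,
                "group": group,
                "separation": abs(
                    dom_a.interval.midpoint - dom_b.interval.midpoint
                ),
                "score_treated": st.score,
                "score_untreated": su.score,
                "n_pairs": st.n_pairs,
                "fc": st.score / su.score,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "chrom",
            "group",
            "separation",
            "score_treated",
            "score_untreated",
            "n_pairs",
            "fc",
        ],
    )
    summary = {
        group: _group_summary(table.loc[table.group == group, "fc"].to_numpy())
        for group in ("damaged", "control")
    }
    return table, summary


def domain_pairs(
    domains: list[DamageDomain], damaged: bool
) -> list[tuple[DamageDomain, DamageDomain]]:
    """All intrachromosomal pairs of distinct non-overlapping domains with
    the requested damage status."""
    selected = [d for d in domains if d.damaged == damaged]
    pairs = []
    for i, a in enumerate(selected):
        for b in selected[i + 1 :]:
            if (
                a.interval.chrom == b.interval.chrom
                and not a.interval.overlaps(b.interval)
            ):
                pairs.append((a, b))
    return pairs


def match_control_pairs(
    dsb_pairs: list[tuple[DamageDomain, DamageDomain]],
    control_pairs: list[tuple[DamageDomain, DamageDomain]],
    rng: np.random.Generator,
) -> list[tuple[DamageDomain, DamageDomain]]:
    """Sample control pairs matching the separation distribution of DSB
    pairs (nearest-separation matching without replacement, seeded)."""
    if not control_pairs:
        return []
    sep = lambda pair: abs(pair[0].interval.midpoint - pair[1].interval.midpoint)
    available = list(control_pairs)
    rng.shuffle(available)
    matched = []
    for target in dsb_pairs:
        if not available:
            break
        ts = sep(target)
        best = min(range(len(available)), key=lambda k: abs(sep(available[k]) - ts))
        matched.append(available.pop(best))
    return matched


def viewpoint_track(
    treated: ContactMatrix,
    untreated: ContactMatrix,
    anchor_bin: int,
    half_window: int = 2_000_000,
    pc: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """4C-like log2FC of raw contacts from one anchor bin, +/- 2 Mb.

    Returns (bin indices, log2((treated + pc) / (untreated + pc))); the
    window is clipped at chromosome ends.
    """
    if treated.shape != untreated.shape or treated.resolution != untreated.resolution:
        raise ValidationError("viewpoint_track requires matching matrices")
    n = treated.shape[1]
    if not 0 <= anchor_bin < treated.shape[0]:
        raise ValidationError(f"anchor bin {anchor_bin} out of range")
    w = half_window // treated.resolution
    lo, hi = max(0, anchor_bin - w), min(n, anchor_bin + w + 1)
    bins = np.arange(lo, hi)
    t = treated.counts[anchor_bin, lo:hi]
    u = untreated.counts[anchor_bin, lo:hi]
    return bins, np.log2((t + pc) / (u + pc))


def trans_window_score(m: ContactMatrix, site_a: int, site_b: int) -> float:
    """Sum of counts over the 5x5 bin block centred on the interaction
    point (1.25 Mb x 1.25 Mb at 250 kb), clipped at matrix edges."""
    if m.is_intra:
        raise ValidationError("trans_window_score requires an inter matrix")
    if m.resolution != TRANS_RESOLUTION:
        warnings.warn(
            f"trans window defined at {TRANS_RESOLUTION} bp resolution, "
            f"matrix is {m.resolution} bp; proceeding with 5x5 bins",
            stacklevel=2,
        )
    ia, ib = site_a // m.resolution, site_b // m.resolution
    na, nb = m.shape
    if not (0 <= ia < na and 0 <= ib < nb):
        raise ValidationError("site outside matrix")
    block = m.counts[
        max(0, ia - 2) : min(na, ia + 3), max(0, ib - 2) : min(nb, ib + 3)
    ]
    return float(block.sum())


def trans_window_log2fc(sum_t: float, sum_u: float, pc: float = 0.1) -> float:
    """log2 fold change of summed window interactions with pseudocount."""
    if sum_t < 0 or sum_u < 0:
        raise ValidationError("negative window sum")
    return float(np.log2((sum_t + pc) / (sum_u + pc)))
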