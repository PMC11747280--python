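"""Synthetic study generator.

Emulates the statistical structure of an AsiSI break-induction experiment
on a TAD-partitioned genome: CTCF/cohesin anchors at TAD borders and
interiors, break sites placed well apart near anchors, ChIP coverage
tracks with damage-induced anchor enrichment inside γH2AX domains,
distance-decay Hi-C contact matrices with TAD blocks and break-break
clustering, and HTGTS junction libraries whose translocation frequency
tracks inter-chromosomal contact frequency. Every injected effect size is
a config parameter whose default mirrors the study conditions; everything
is a pure function of (config, seed).
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .junctions import microhomology_length
from .model import (
    ASISI_MOTIF,
    DAMAGE_STATES,
    GENOTYPES,
    ContactMatrix,
    CoverageTrack,
    DamageDomain,
    DSBSite,
    GenomeLayout,
    GenomicInterval,
    JunctionRecord,
    SignalPeak,
    ValidationError,
)

# rng stream ids (mixed with the top-level seed)
_S_LAYOUT, _S_INTENSITY, _S_FIELD, _S_CHIP, _S_HIC, _S_TRANS, _S_JUNC = range(7)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GenomeParams:
    n_chrom: int = 2
    chrom_length: int = 25_000_000
    tad_mean_size: int = 1_000_000
    anchors_per_tad: int = 2  # interior anchors; every TAD border is one too
    n_asisi: int = 16
    n_cut: int = 8  # sites actually broken under damage
    n_baits: int = 2
    min_cut_spacing: int = 2_400_000  # bp between cuts (scaled-down bait isolation)
    cut_anchor_offset: int = 5_000  # cut sits this far from an interior anchor
    gh2ax_halfwidth: int = 1_000_000  # damage domain reach around each cut
    with_sequence: bool = False


@dataclass
class ChipParams:
    bin_size: int = 100
    background: float = 0.2  # flat background density (rpkm-like)
    reads_scale: float = 10.0  # Poisson counts per density unit per bin
    peak_height: float = 30.0  # RAD21 triangular apex
    ctcf_height: float = 25.0
    mre11_height: float = 20.0
    orphan_height: float = 10.0  # non-colocalized (NIPBL-like) peaks
    orphan_fraction: float = 0.15
    peak_halfwidth: int = 500  # triangular peaks span 1 kb
    # damage-induced anchor enrichment inside γH2AX domains, per genotype
    anchor_fc: dict[str, float] = field(
        default_factory=lambda: {
            "WT": 1.43,
            "LIG4-": 1.73,
            "SMC1A_Pdef": 1.17,
            "ATMi": 1.30,
            "RAD21-": 1.0,
        }
    )
    # optional distance-graded enrichment: genotype -> (<=10 kb, <=250 kb, <=1 Mb)
    anchor_fc_shells: dict[str, tuple[float, float, float]] | None = None
    rad21_depletion_scale: float = 0.05  # residual RAD21 signal under the degron
    gh2ax_height: float = 4.0  # plateau over damaged domains
    gh2ax_background: float = 1.0
    gh2ax_background_sd: float = 0.4  # log-sd of the shared regional field
    gh2ax_field_scale: int = 50_000  # correlation length of that field
    gh2ax_reads_scale: float = 100.0


@dataclass
class HicParams:
    resolution: int = 10_000
    alpha: float = 1.0  # contact decay exponent
    depth: float = 1e6  # expected intra counts per chromosome
    tad_boost: float = 2.0  # same-TAD contact multiplier (beta)
    # damage-induced boost of same damaged-TAD contacts, per genotype
    intra_damage_fc: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.02, "SMC1A_Pdef": 1.02}
    )
    # damage-induced boost between two distinct damaged TADs, per genotype
    gamma: dict[str, float] = field(
        default_factory=lambda: {"RAD21-": 1.16, "SMC1A_Pdef": 1.04, "ATMi": 1.03}
    )
    # same, between two distinct undamaged TADs
    gamma_ctrl: dict[str, float] = field(default_factory=lambda: {"RAD21-": 1.06})
    trans_resolution: int = 250_000
    trans_baseline: float = 5.0  # expected counts per inter bin pair
    trans_site_sd: float = 0.5  # log-sd of per-site contact propensity
    # damage-induced boost of contacts between damaged-domain bins on
    # different chromosomes, per genotype
    gamma_trans: dict[str, float] = field(
        default_factory=lambda: {
            "WT": 1.31,
            "RAD21-": 1.39,
            "SMC1A_Pdef": 1.72,
            "ATMi": 1.35,
        }
    )
    # genotype-specific global trans baseline scale (damage-independent)
    trans_baseline_scale: dict[str, float] = field(
        default_factory=lambda: {"RAD21-": 1.385}
    )


@dataclass
class JunctionParams:
    n_junctions: int = 5_000
    flank_len: int = 20
    mh_geometric_p: float = 0.65  # P(success) of the geometric MH length law
    trans_rate: float = 0.15  # translocations per library junction
    cis_rate: float = 0.05  # cis-deletions per library junction
    background_rate: float = 0.02  # genome-background preys per junction
    trans_multiplier: float = 1.0  # condition scaling of the translocation rate
    cis_multiplier: float = 1.0
    bait_proximal_fraction: float | None = None  # None: remainder of the rates
    bait_window: int = 20_000
    prey_scatter: int = 300  # bp jitter of prey positions around the cut
    max_mh: int = 12


#: per-genotype junction-parameter overrides mirroring the study conditions
GENOTYPE_JUNCTION_DEFAULTS: dict[str, dict] = {
    "WT": {},
    "RAD21-": {"trans_multiplier": 4.3, "cis_multiplier": 6.0},
    "ATMi": {"trans_multiplier": 1.9},
    "SMC1A_Pdef": {"trans_multiplier": 2.1, "cis_multiplier": 2.1},
    "LIG4-": {"trans_multiplier": 0.05, "cis_multiplier": 0.05,
              "mh_geometric_p": 0.35},
}


def junction_params_for(genotype: str, base: JunctionParams) -> JunctionParams:
    """A genotype-conditioned copy of the junction parameters."""
    if genotype not in GENOTYPES:
        raise ValidationError(f"unknown genotype {genotype!r}")
    return replace(base, **GENOTYPE_JUNCTION_DEFAULTS.get(genotype, {}))


@dataclass
class SimulationConfig:
    seed: int
    genome: GenomeParams = field(default_factory=GenomeParams)
    chip: ChipParams = field(default_factory=ChipParams)
    hic: HicParams = field(default_factory=HicParams)
    junctions: JunctionParams = field(default_factory=JunctionParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        g = self.genome
        if g.n_cut > g.n_asisi:
            raise ValidationError("n_cut cannot exceed n_asisi")
        if g.n_baits > g.n_cut:
            raise ValidationError("n_baits cannot exceed n_cut")
        for name, value in [
            ("tad_boost", self.hic.tad_boost),
            ("trans_baseline", self.hic.trans_baseline),
            *[(f"anchor_fc[{k}]", v) for k, v in self.chip.anchor_fc.items()],
            *[(f"gamma[{k}]", v) for k, v in self.hic.gamma.items()],
        ]:
            if value <= 0:
                raise ValidationError(f"fold-change parameter {name} must be > 0")
        if not 0 < self.junctions.mh_geometric_p <= 1:
            raise ValidationError("mh_geometric_p must be in (0, 1]")


@dataclass
class GroundTruth:
    """Exactly reproducible record of what the generator injected."""

    cut_ids: list[str]
    bait_ids: list[str]
    damaged_domains: list[DamageDomain]  # γH2AX reach around each cut
    control_domains: list[DamageDomain]  # matched undamaged intervals
    site_intensity: dict[str, float]  # per-site trans contact propensity
    config: SimulationConfig


@dataclass
class LayoutBundle:
    layout: GenomeLayout
    tads: list[DamageDomain]
    anchors: dict[str, np.ndarray]
    orphan_rad21: dict[str, np.ndarray]
    orphan_ctcf: dict[str, np.ndarray]
    sites: list[DSBSite]
    truth: GroundTruth

    @property
    def cut_sites(self) -> list[DSBSite]:
        ids = set(self.truth.cut_ids)
        return [s for s in self.sites if s.id in ids]

    def site_by_id(self, site_id: str) -> DSBSite:
        for s in self.sites:
            if s.id == site_id:
                return s
        raise ValidationError(f"unknown site id {site_id}")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _check_condition(genotype: str, damage: str) -> None:
    if genotype not in GENOTYPES:
        raise ValidationError(f"unknown genotype {genotype!r}")
    if damage not in DAMAGE_STATES:
        raise ValidationError(f"unknown damage state {damage!r}")


# ---------------------------------------------------------------------------
# layout

def build_layout(config: SimulationConfig) -> LayoutBundle:
    """Genome, TAD partition, anchors, AsiSI sites and ground truth."""
    g = config.genome
    rng = _rng(config, _S_LAYOUT)
    chrom_names = [f"chr{i + 1}" for i in range(g.n_chrom)]
    chrom_lengths = {c: g.chrom_length for c in chrom_names}

    tads: list[DamageDomain] = []
    anchors: dict[str, np.ndarray] = {}
    interior: dict[str, list[int]] = {}
    for chrom in chrom_names:
        # TADs tile the chromosome; sizes jitter around the mean
        edges = [0]
        while edges[-1] < g.chrom_length:
            size = int(g.tad_mean_size * rng.uniform(0.6, 1.4))
            edges.append(min(edges[-1] + size, g.chrom_length))
        chrom_anchors: list[int] = list(edges[1:-1])
        interior[chrom] = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            tads.append(
                DamageDomain(GenomicInterval(chrom, lo, hi), "TAD", damaged=False)
            )
            pad = min(50_000, (hi - lo) // 4)
            pts = rng.integers(lo + pad, hi - pad, size=g.anchors_per_tad)
            interior[chrom].extend(int(p) for p in pts)
            chrom_anchors.extend(int(p) for p in pts)
        anchors[chrom] = np.sort(np.unique(chrom_anchors))

    # cuts: near interior anchors, mutually separated by min_cut_spacing
    quotas = {
        chrom: g.n_cut // g.n_chrom + (1 if i < g.n_cut % g.n_chrom else 0)
        for i, chrom in enumerate(chrom_names)
    }
    cut_positions: dict[str, list[int]] = {c: [] for c in chrom_names}
    for chrom in chrom_names:
        candidates = [
            p
            for p in interior[chrom]
            if g.min_cut_spacing // 2 < p < g.chrom_length - g.min_cut_spacing // 2
        ]
        # greedy placement over shuffled anchors; reshuffle on dead ends
        for _ in range(100):
            rng.shuffle(candidates)
            placed: list[int] = []
            for p in candidates:
                if len(placed) >= quotas[chrom]:
                    break
                pos = p + g.cut_anchor_offset
                if all(abs(pos - q) >= g.min_cut_spacing for q in placed):
                    placed.append(pos)
            if len(placed) >= quotas[chrom]:
                cut_positions[chrom] = placed
                break
        if len(cut_positions[chrom]) < quotas[chrom]:
            raise ValidationError(
                f"cannot place {quotas[chrom]} cuts {g.min_cut_spacing} bp apart "
                f"on {chrom}; reduce n_cut, shrink min_cut_spacing or lengthen "
                "the chromosome"
            )

    # uncut AsiSI sites: uniform, well away from any cut
    n_uncut = g.n_asisi - g.n_cut
    uncut_positions: dict[str, list[int]] = {c: [] for c in chrom_names}
    attempts = 0
    while sum(len(v) for v in uncut_positions.values()) < n_uncut:
        attempts += 1
        if attempts > 10_000 * max(1, n_uncut):
            raise ValidationError("cannot place uncut AsiSI sites; genome too full")
        chrom = chrom_names[int(rng.integers(g.n_chrom))]
        pos = int(rng.integers(100_000, g.chrom_length - 100_000))
        if all(abs(pos - q) >= 200_000 for q in cut_positions[chrom]) and all(
            abs(pos - q) >= 200_000 for q in uncut_positions[chrom]
        ):
            uncut_positions[chrom].append(pos)

    cut_width = 8 if g.with_sequence else 1
    positioned = sorted(
        [(c, p, True) for c in chrom_names for p in cut_positions[c]]
        + [(c, p, False) for c in chrom_names for p in uncut_positions[c]],
        key=lambda t: (t[0], t[1]),
    )
    sites: list[DSBSite] = []
    cut_ids: list[str] = []
    for k, (chrom, pos, is_cut) in enumerate(positioned):
        site = DSBSite(
            id=f"site{k:03d}",
            cut=GenomicInterval(chrom, pos, pos + cut_width),
        )
        sites.append(site)
        if is_cut:
            cut_ids.append(site.id)

    # baits: one cut per chromosome until the quota is met
    bait_ids: list[str] = []
    cut_by_chrom: dict[str, list[str]] = {}
    for s in sites:
        if s.id in cut_ids:
            cut_by_chrom.setdefault(s.chrom, []).append(s.id)
    round_robin = 0
    while len(bait_ids) < g.n_baits:
        chrom = chrom_names[round_robin % g.n_chrom]
        for sid in cut_by_chrom.get(chrom, []):
            if sid not in bait_ids:
                bait_ids.append(sid)
                break
        round_robin += 1
    sites = [
        replace_site_bait(s, s.id in bait_ids) for s in sites
    ]

    # γH2AX damage domains around each cut, clipped to the chromosome
    damaged_domains = [
        DamageDomain(
            GenomicInterval(
                s.chrom,
                max(0, s.midpoint - g.gh2ax_halfwidth),
                min(g.chrom_length, s.midpoint + g.gh2ax_halfwidth),
            ),
            "GH2AX",
            damaged=True,
        )
        for s in sites
        if s.id in cut_ids
    ]

    # control intervals: γH2AX-sized, at least one halfwidth from any damage
    control_domains: list[DamageDomain] = []
    grid = 100_000
    width = 2 * g.gh2ax_halfwidth
    candidates = []
    for chrom in chrom_names:
        for start in range(0, g.chrom_length - width, grid):
            mid = start + width // 2
            if all(
                d.interval.chrom != chrom
                or not (
                    d.interval.start - g.gh2ax_halfwidth
                    < mid
                    < d.interval.end + g.gh2ax_halfwidth
                )
                for d in damaged_domains
            ):
                candidates.append((chrom, start))
    rng.shuffle(candidates)
    for chrom, start in candidates:
        if len(control_domains) >= g.n_cut:
            break
        iv = GenomicInterval(chrom, start, start + width)
        if all(
            not iv.overlaps(d.interval) for d in control_domains
        ):
            control_domains.append(DamageDomain(iv, "GH2AX", damaged=False))

    # flag damaged TADs (>= 1 cut inside)
    cut_mids = {(s.chrom, s.midpoint) for s in sites if s.id in cut_ids}
    tads = [
        DamageDomain(
            t.interval,
            "TAD",
            damaged=any(
                c == t.interval.chrom and t.interval.contains(m)
                for c, m in cut_mids
            ),
        )
        for t in tads
    ]

    # orphan (non-colocalized) peak positions, fixed per layout
    orphan_rad21: dict[str, np.ndarray] = {}
    orphan_ctcf: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        n_orphan = max(1, round(config.chip.orphan_fraction * len(anchors[chrom])))
        orphan_rad21[chrom] = np.sort(
            rng.integers(10_000, g.chrom_length - 10_000, size=n_orphan)
        )
        orphan_ctcf[chrom] = np.sort(
            rng.integers(10_000, g.chrom_length - 10_000, size=n_orphan)
        )

    # damage-independent per-site contact propensity (lognormal, mean 1)
    rng_int = _rng(config, _S_INTENSITY)
    sd = config.hic.trans_site_sd
    site_intensity = {
        s.id: float(np.exp(rng_int.normal(0.0, sd) - sd**2 / 2)) for s in sites
    }

    truth = GroundTruth(
        cut_ids=cut_ids,
        bait_ids=bait_ids,
        damaged_domains=damaged_domains,
        control_domains=control_domains,
        site_intensity=site_intensity,
        config=config,
    )
    layout = GenomeLayout(chrom_names, chrom_lengths)
    bundle = LayoutBundle(
        layout, tads, anchors, orphan_rad21, orphan_ctcf, sites, truth
    )
    if g.with_sequence:
        attach_sequence(bundle, config)
    return bundle


def replace_site_bait(site: DSBSite, is_bait: bool) -> DSBSite:
    return DSBSite(site.id, site.cut, is_bait=is_bait)


def attach_sequence(bundle: LayoutBundle, config: SimulationConfig) -> None:
    """Random genome sequence with the AsiSI motif planted at every site
    and chance occurrences elsewhere purged (one-base substitutions)."""
    rng = _rng(config, _S_LAYOUT, 1)
    sequences: dict[str, str] = {}
    for chrom in bundle.layout.chrom_names:
        length = bundle.layout.chrom_lengths[chrom]
        seq = bytearray(
            rng.choice(_BASES, size=length).tobytes()
        )
        text = seq.decode()
        # purge chance motifs so the site list is exactly the planted set
        for m in list(re.finditer(ASISI_MOTIF, text)):
            seq[m.start()] = ord("A") if seq[m.start()] != ord("A") else ord("T")
        for site in bundle.sites:
            if site.chrom == chrom:
                start = site.cut.start
                seq[start : start + len(ASISI_MOTIF)] = ASISI_MOTIF.encode()
        sequences[chrom] = seq.decode()
    bundle.layout.sequences = sequences
    bundle.layout.__post_init__()


# ---------------------------------------------------------------------------
# ChIP tracks

def _add_triangle(
    arr: np.ndarray, center: int, apex: float, halfwidth: int, bin_size: int
) -> None:
    b0 = max(0, (center - halfwidth) // bin_size)
    b1 = min(len(arr), (center + halfwidth) // bin_size + 1)
    x = (np.arange(b0, b1) + 0.5) * bin_size
    arr[b0:b1] += apex * np.clip(1.0 - np.abs(x - center) / halfwidth, 0.0, None)


def _enrichment_factor(
    genotype: str,
    damage: str,
    pos: int,
    chrom: str,
    cut_sites: list[DSBSite],
    damaged_domains: list[DamageDomain],
    chip: ChipParams,
) -> float:
    if damage != "DSB":
        return 1.0
    inside = any(
        d.interval.chrom == chrom and d.interval.contains(pos)
        for d in damaged_domains
    )
    if not inside:
        return 1.0
    if chip.anchor_fc_shells and genotype in chip.anchor_fc_shells:
        same = [s for s in cut_sites if s.chrom == chrom]
        if not same:
            return 1.0
        d = min(abs(pos - s.midpoint) for s in same)
        fc10, fc250, fc1m = chip.anchor_fc_shells[genotype]
        if d <= 10_000:
            return fc10
        if d <= 250_000:
            return fc250
        if d <= 1_000_000:
            return fc1m
        return 1.0
    return chip.anchor_fc.get(genotype, 1.0)


def simulate_chip(
    bundle: LayoutBundle,
    genotype: str,
    damage: str,
    config: SimulationConfig,
) -> tuple[dict[str, CoverageTrack], dict[str, list[SignalPeak]]]:
    """Coverage tracks for MRE11 / RAD21 / CTCF / γH2AX plus peak lists.

    RAD21 and CTCF form 1 kb triangular peaks at anchors; under damage the
    RAD21 anchors inside damaged domains are multiplied by the genotype's
    enrichment factor. MRE11 peaks appear only at cut sites under damage.
    γH2AX is a plateau over damaged domains riding on a smooth regional
    background shared between the damage states of a genotype. Per-bin
    Poisson noise at ``reads_scale`` counts per density unit.
    """
    _check_condition(genotype, damage)
    chip = config.chip
    bs = chip.bin_size
    layout = bundle.layout
    cut_sites = bundle.cut_sites
    damaged_domains = bundle.truth.damaged_domains
    gidx = GENOTYPES.index(genotype)
    didx = DAMAGE_STATES.index(damage)

    rad21_scale = (
        chip.rad21_depletion_scale if genotype == "RAD21-" else 1.0
    )
    tracks = {f: {} for f in ("MRE11", "RAD21", "CTCF", "GH2AX")}
    rad21_peaks: list[SignalPeak] = []
    ctcf_peaks: list[SignalPeak] = []

    for cidx, chrom in enumerate(layout.chrom_names):
        n_bins = layout.n_bins(chrom, bs)
        dens = {
            "MRE11": np.full(n_bins, chip.background),
            "RAD21": np.full(n_bins, chip.background),
            "CTCF": np.full(n_bins, chip.background),
        }
        for pos in bundle.anchors[chrom]:
            boost = _enrichment_factor(
                genotype, damage, int(pos), chrom, cut_sites, damaged_domains, chip
            )
            apex_r = chip.peak_height * rad21_scale * boost
            _add_triangle(dens["RAD21"], int(pos), apex_r, chip.peak_halfwidth, bs)
            _add_triangle(
                dens["CTCF"], int(pos), chip.ctcf_height, chip.peak_halfwidth, bs
            )
        for pos in bundle.orphan_rad21[chrom]:
            # cohesin loading (NIPBL-like) sites gain damage signal too
            boost = _enrichment_factor(
                genotype, damage, int(pos), chrom, cut_sites, damaged_domains, chip
            )
            _add_triangle(
                dens["RAD21"],
                int(pos),
                chip.orphan_height * rad21_scale * boost,
                chip.peak_halfwidth,
                bs,
            )
        for pos in bundle.orphan_ctcf[chrom]:
            _add_triangle(
                dens["CTCF"], int(pos), chip.orphan_height, chip.peak_halfwidth, bs
            )
        if damage == "DSB":
            for site in cut_sites:
                if site.chrom == chrom:
                    _add_triangle(
                        dens["MRE11"],
                        site.midpoint,
                        chip.mre11_height,
                        chip.peak_halfwidth,
                        bs,
                    )

        # γH2AX: shared regional field (same realization for NT and DSB)
        rng_field = _rng(config, _S_FIELD, gidx, cidx)
        fs = chip.gh2ax_field_scale
        n_grid = math.ceil(layout.chrom_lengths[chrom] / fs) + 1
        grid_vals = rng_field.normal(0.0, chip.gh2ax_background_sd, size=n_grid)
        centers = (np.arange(n_bins) + 0.5) * bs
        g = np.interp(centers, np.arange(n_grid) * fs, grid_vals)
        gh2ax = chip.gh2ax_background * np.exp(
            g - chip.gh2ax_background_sd**2 / 2
        )
        if damage == "DSB":
            for dom in damaged_domains:
                if dom.interval.chrom == chrom:
                    b0 = dom.interval.start // bs
                    b1 = min(n_bins, (dom.interval.end - 1) // bs + 1)
                    gh2ax[b0:b1] += chip.gh2ax_height
        dens["GH2AX"] = gh2ax

        for fidx, factor in enumerate(("MRE11", "RAD21", "CTCF", "GH2AX")):
            scale = (
                chip.gh2ax_reads_scale if factor == "GH2AX" else chip.reads_scale
            )
            rng_noise = _rng(config, _S_CHIP, gidx, didx, cidx, fidx)
            tracks[factor][chrom] = (
                rng_noise.poisson(dens[factor] * scale).astype(float) / scale
            )

        hw = chip.peak_halfwidth
        chrom_len = layout.chrom_lengths[chrom]
        for pos in bundle.anchors[chrom]:
            iv = GenomicInterval(
                chrom, max(0, int(pos) - hw), min(chrom_len, int(pos) + hw)
            )
            rad21_peaks.append(
                SignalPeak(iv, int(pos), chip.peak_height * rad21_scale)
            )
            ctcf_peaks.append(SignalPeak(iv, int(pos), chip.ctcf_height))
        for pos in bundle.orphan_rad21[chrom]:
            iv = GenomicInterval(
                chrom, max(0, int(pos) - hw), min(chrom_len, int(pos) + hw)
            )
            rad21_peaks.append(
                SignalPeak(iv, int(pos), chip.orphan_height * rad21_scale)
            )
        for pos in bundle.orphan_ctcf[chrom]:
            iv = GenomicInterval(
                chrom, max(0, int(pos) - hw), min(chrom_len, int(pos) + hw)
            )
            ctcf_peaks.append(SignalPeak(iv, int(pos), chip.orphan_height))

    coverage = {
        factor: CoverageTrack(bin_size=bs, values=vals)
        for factor, vals in tracks.items()
    }
    peaks = {
        "RAD21": sorted(rad21_peaks, key=lambda p: (p.chrom, p.summit)),
        "CTCF": sorted(ctcf_peaks, key=lambda p: (p.chrom, p.summit)),
    }
    return coverage, peaks


# ---------------------------------------------------------------------------
# Hi-C contacts

def _tad_assignment(
    bundle: LayoutBundle, chrom: str, resolution: int
) -> tuple[np.ndarray, np.ndarray]:
    """(tad index, damaged flag) per bin (by bin center)."""
    n_bins = bundle.layout.n_bins(chrom, resolution)
    centers = (np.arange(n_bins) + 0.5) * resolution
    chrom_tads = [t for t in bundle.tads if t.interval.chrom == chrom]
    starts = np.array([t.interval.start for t in chrom_tads])
    damaged = np.array([t.damaged for t in chrom_tads])
    idx = np.clip(np.searchsorted(starts, centers, side="right") - 1, 0, None)
    return idx, damaged[idx]


def simulate_contacts(
    bundle: LayoutBundle,
    genotype: str,
    damage: str,
    config: SimulationConfig,
) -> dict[tuple[str, str], ContactMatrix]:
    """Poisson contact matrices: intra per chromosome at ``resolution``,
    inter per chromosome pair at ``trans_resolution``.

    Intra expectation ∝ (d + 1)^-alpha, multiplied by the TAD boost for
    same-TAD pairs (removed under cohesin depletion), by the intra-damage
    factor within a damaged TAD, by gamma between two distinct damaged
    TADs, and by gamma_ctrl between two distinct undamaged TADs (damage
    condition only); scaled so the expected total per chromosome is
    ``depth``. Inter expectation is a uniform baseline carrying per-site
    contact propensities at damaged-domain bins, boosted by gamma_trans
    under damage.
    """
    _check_condition(genotype, damage)
    hic = config.hic
    layout = bundle.layout
    gidx = GENOTYPES.index(genotype)
    didx = DAMAGE_STATES.index(damage)
    out: dict[tuple[str, str], ContactMatrix] = {}

    beta = 1.0 if genotype == "RAD21-" else hic.tad_boost
    intra_fc = hic.intra_damage_fc.get(genotype, 1.0)
    gamma = hic.gamma.get(genotype, 1.0)
    gamma_ctrl = hic.gamma_ctrl.get(genotype, 1.0)

    for cidx, chrom in enumerate(layout.chrom_names):
        n = layout.n_bins(chrom, hic.resolution)
        idx = np.arange(n)
        dist = np.abs(np.subtract.outer(idx, idx))
        expect = (dist + 1.0) ** (-hic.alpha)
        tad_idx, tad_damaged = _tad_assignment(bundle, chrom, hic.resolution)
        same_tad = tad_idx[:, None] == tad_idx[None, :]
        both_damaged = tad_damaged[:, None] & tad_damaged[None, :]
        both_control = ~tad_damaged[:, None] & ~tad_damaged[None, :]
        expect[same_tad] *= beta
        if damage == "DSB":
            expect[same_tad & both_damaged] *= intra_fc
            expect[~same_tad & both_damaged] *= gamma
            expect[~same_tad & both_control] *= gamma_ctrl
        iu = np.triu_indices(n)
        expect *= hic.depth / expect[iu].sum()
        rng = _rng(config, _S_HIC, gidx, didx, cidx)
        draws = rng.poisson(expect[iu]).astype(float)
        counts = np.zeros((n, n))
        counts[iu] = draws
        counts = counts + counts.T
        counts[np.diag_indices(n)] /= 2.0
        out[(chrom, chrom)] = ContactMatrix(chrom, chrom, hic.resolution, counts)

    # inter-chromosomal matrices at trans resolution
    res = hic.trans_resolution
    baseline = hic.trans_baseline * hic.trans_baseline_scale.get(genotype, 1.0)
    g_trans = hic.gamma_trans.get(genotype, 1.0) if damage == "DSB" else 1.0
    prop = {}  # per chromosome: per-bin propensity (1 outside damaged bins)
    for chrom in layout.chrom_names:
        n_bins = layout.n_bins(chrom, res)
        p = np.ones(n_bins)
        dam = np.zeros(n_bins, dtype=bool)
        for site in bundle.cut_sites:
            if site.chrom != chrom:
                continue
            hw = config.genome.gh2ax_halfwidth
            b0 = max(0, (site.midpoint - hw) // res)
            b1 = min(n_bins, (site.midpoint + hw - 1) // res + 1)
            p[b0:b1] = bundle.truth.site_intensity[site.id]
            dam[b0:b1] = True
        prop[chrom] = (p, dam)
    for ia, ca in enumerate(layout.chrom_names):
        for ib, cb in enumerate(layout.chrom_names):
            if ib <= ia:
                continue
            pa, da = prop[ca]
            pb, db = prop[cb]
            expect = baseline * np.outer(pa, pb)
            hot = np.outer(da, db)
            expect[hot] *= g_trans
            rng = _rng(config, _S_TRANS, gidx, didx, ia, ib)
            counts = rng.poisson(expect).astype(float)
            out[(ca, cb)] = ContactMatrix(ca, cb, res, counts)
    return out


# ---------------------------------------------------------------------------
# junction libraries

def _random_flank(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _flank_pair(
    rng: np.random.Generator, m: int, length: int
) -> tuple[str, str]:
    """Flank sequences embedding exactly ``m`` bp of microhomology."""
    for _ in range(100):
        bait = list(_random_flank(rng, length))
        prey = list(_random_flank(rng, length))
        if m > 0:
            prey[:m] = bait[-m:]
        if m < length:
            # force a mismatch at the first extension position
            choices = [b for b in "ACGT" if b != bait[-(m + 1)]]
            prey[m] = choices[int(rng.integers(len(choices)))]
        bait_s, prey_s = "".join(bait), "".join(prey)
        if microhomology_length(bait_s, prey_s) == m:
            return bait_s, prey_s
    raise ValidationError(f"cannot embed microhomology of length {m}")


def _window_score(
    matrix: ContactMatrix, chrom_a: str, pos_a: int, pos_b: int
) -> float:
    """5x5 window sum around (pos_a, pos_b), honoring matrix orientation."""
    if matrix.chrom_a == chrom_a:
        ia, ib = pos_a // matrix.resolution, pos_b // matrix.resolution
        counts = matrix.counts
    else:
        ia, ib = pos_b // matrix.resolution, pos_a // matrix.resolution
        counts = matrix.counts
    na, nb = counts.shape
    block = counts[
        max(0, ia - 2) : min(na, ia + 3), max(0, ib - 2) : min(nb, ib + 3)
    ]
    return float(block.sum())


def simulate_junctions(
    bundle: LayoutBundle,
    contacts: dict[tuple[str, str], ContactMatrix],
    bait_id: str,
    config: SimulationConfig,
    params: JunctionParams | None = None,
    replicate: int = 0,
) -> list[JunctionRecord]:
    """An HTGTS library for one bait.

    Junction categories per library read: bait-proximal rejoining,
    translocation to another chromosome's cut site (sampled with
    probability proportional to the bait-prey trans-window contact score),
    cis-deletion to a same-chromosome cut site (weight decaying with
    distance), and genome background. Microhomology lengths are geometric;
    flank sequences embed exactly the drawn overlap.
    """
    params = params or config.junctions
    bait = bundle.site_by_id(bait_id)
    if bait_id not in bundle.truth.cut_ids:
        raise ValidationError(f"bait {bait_id} is not a cut site")
    bait_index = bundle.truth.cut_ids.index(bait_id)
    rng = _rng(config, _S_JUNC, bait_index, replicate)

    p_t = params.trans_rate * params.trans_multiplier
    p_c = params.cis_rate * params.cis_multiplier
    p_bg = params.background_rate
    if params.bait_proximal_fraction is None:
        p_bp = 1.0 - (p_t + p_c + p_bg)
        if p_bp < 0:
            raise ValidationError(
                "junction category rates exceed 1; lower the rates or set "
                "bait_proximal_fraction explicitly"
            )
    else:
        p_bp = params.bait_proximal_fraction
        if not 0 <= p_bp <= 1:
            raise ValidationError("bait_proximal_fraction must be in [0, 1]")
        rest = p_t + p_c + p_bg
        scale = (1.0 - p_bp) / rest if rest > 0 else 0.0
        p_t, p_c, p_bg = p_t * scale, p_c * scale, p_bg * scale
    n_bp, n_t, n_c, n_bg = rng.multinomial(
        params.n_junctions, [p_bp, p_t, p_c, p_bg]
    )

    layout = bundle.layout
    order = {c: i for i, c in enumerate(layout.chrom_names)}

    trans_sites = [s for s in bundle.cut_sites if s.chrom != bait.chrom]
    if n_t and not trans_sites:
        raise ValidationError("no translocation prey sites on other chromosomes")
    trans_weights = []
    for s in trans_sites:
        key = (
            (bait.chrom, s.chrom)
            if order[bait.chrom] < order[s.chrom]
            else (s.chrom, bait.chrom)
        )
        trans_weights.append(
            _window_score(contacts[key], bait.chrom, bait.midpoint, s.midpoint)
        )
    trans_weights = np.asarray(trans_weights, dtype=float)

    cis_sites = [
        s for s in bundle.cut_sites if s.chrom == bait.chrom and s.id != bait_id
    ]
    cis_weights = np.array(
        [
            (abs(s.midpoint - bait.midpoint) / config.hic.resolution + 1.0)
            ** (-config.hic.alpha)
            for s in cis_sites
        ]
    )

    records: list[JunctionRecord] = []

    def _emit(prey_chrom: str, prey_pos: int) -> None:
        m = min(int(rng.geometric(params.mh_geometric_p)) - 1, params.max_mh)
        bait_flank, prey_flank = _flank_pair(rng, m, params.flank_len)
        records.append(
            JunctionRecord(
                read_id=f"jx{len(records):06d}",
                bait_chrom=bait.chrom,
                bait_pos=bait.midpoint,
                bait_strand="+",
                prey_chrom=prey_chrom,
                prey_pos=int(
                    np.clip(prey_pos, 0, layout.chrom_lengths[prey_chrom] - 1)
                ),
                prey_strand="+" if rng.integers(2) else "-",
                bait_flank=bait_flank,
                prey_flank=prey_flank,
            )
        )

    for _ in range(n_bp):
        offset = int(rng.integers(-params.bait_window, params.bait_window + 1))
        _emit(bait.chrom, bait.midpoint + offset)
    if n_t:
        probs = trans_weights / trans_weights.sum()
        for k in rng.choice(len(trans_sites), size=n_t, p=probs):
            site = trans_sites[int(k)]
            _emit(
                site.chrom,
                site.midpoint
                + int(rng.integers(-params.prey_scatter, params.prey_scatter + 1)),
            )
    if n_c:
        if not cis_sites:
            raise ValidationError("no cis prey sites on the bait chromosome")
        probs = cis_weights / cis_weights.sum()
        for k in rng.choice(len(cis_sites), size=n_c, p=probs):
            site = cis_sites[int(k)]
            _emit(
                site.chrom,
                site.midpoint
                + int(rng.integers(-params.prey_scatter, params.prey_scatter + 1)),
            )
    lengths = np.array(
        [layout.chrom_lengths[c] for c in layout.chrom_names], dtype=float
    )
    for _ in range(n_bg):
        chrom = layout.chrom_names[
            int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        ]
        _emit(chrom, int(rng.integers(0, layout.chrom_lengths[chrom])))
    return records
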