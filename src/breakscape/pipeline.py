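"""End-to-end pipeline: simulate -> break calling -> enrichment -> Hi-C ->
junctions, with TSV outputs and a plain-text summary.

All randomness flows from the single top-level seed in the config; given
the same config the pipeline's outputs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, hic, io, junctions as jx
from .model import DamageDomain, DSBSite, GenomicInterval, ValidationError
from .simulate import (
    ChipParams,
    GenomeParams,
    HicParams,
    JunctionParams,
    LayoutBundle,
    SimulationConfig,
    build_layout,
    junction_params_for,
    simulate_chip,
    simulate_contacts,
    simulate_junctions,
)
from .stats import significance_stars

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class AnalysisParams:
    min_fc: float = 3.0  # break-calling threshold over local background
    flank: int = 500  # bp around the cut for break calling
    anchor_gap: int = 500  # RAD21/CTCF colocalization gap
    break_window: int = 2_500  # "break site" junction context
    domain: enrichment.DomainCallParams = field(
        default_factory=enrichment.DomainCallParams
    )


@dataclass
class PipelineConfig:
    sim: SimulationConfig
    genotypes: list[str] = field(default_factory=lambda: ["WT"])
    analysis: AnalysisParams = field(default_factory=AnalysisParams)


def _merge(cls, overrides: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**overrides)


def load_config(path: str | Path) -> PipelineConfig:
    """Structured YAML config -> PipelineConfig; the seed is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValidationError(f"{path}: config must set a top-level seed")
    sim = SimulationConfig(
        seed=int(raw["seed"]),
        genome=_merge(GenomeParams, raw.get("genome", {})),
        chip=_merge(ChipParams, raw.get("chip", {})),
        hic=_merge(HicParams, raw.get("hic", {})),
        junctions=_merge(JunctionParams, raw.get("junctions", {})),
    )
    analysis_raw = dict(raw.get("analysis", {}))
    domain_raw = analysis_raw.pop("domain", {})
    analysis = _merge(AnalysisParams, analysis_raw)
    analysis.domain = _merge(enrichment.DomainCallParams, domain_raw)
    return PipelineConfig(
        sim=sim,
        genotypes=list(raw.get("genotypes", ["WT"])),
        analysis=analysis,
    )


def intra_domain_fc_all(
    contacts_t: dict,
    contacts_u: dict,
    domains: list[DamageDomain],
) -> tuple[pd.DataFrame, dict]:
    """intra_domain_fc aggregated over every chromosome."""
    tables = []
    for (ca, cb), m_t in sorted(contacts_t.items()):
        if ca != cb:
            continue
        chrom_domains = [d for d in domains if d.interval.chrom == ca]
        if not chrom_domains:
            continue
        table, _ = hic.intra_domain_fc(m_t, contacts_u[(ca, cb)], chrom_domains)
        tables.append(table)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "domain_id", "chrom", "start", "end", "damaged",
                "score_treated", "score_untreated", "n_pairs", "fc",
            ]
        )
    )
    summary = {
        "damaged": hic._group_summary(table.loc[table.damaged, "fc"].to_numpy()),
        "control": hic._group_summary(table.loc[~table.damaged, "fc"].to_numpy()),
    }
    return table, summary


def inter_domain_fc_all(
    contacts_t: dict,
    contacts_u: dict,
    domains: list[DamageDomain],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """DSB-DSB pairs plus separation-matched Ctrl-Ctrl pairs, all
    chromosomes pooled."""
    tables = []
    for (ca, cb), m_t in sorted(contacts_t.items()):
        if ca != cb:
            continue
        chrom_domains = [d for d in domains if d.interval.chrom == ca]
        dsb_pairs = hic.domain_pairs(chrom_domains, damaged=True)
        ctrl_pool = hic.domain_pairs(chrom_domains, damaged=False)
        ctrl_pairs = hic.match_control_pairs(dsb_pairs, ctrl_pool, rng)
        pairs = dsb_pairs + ctrl_pairs
        if not pairs:
            continue
        table, _ = hic.inter_domain_pair_fc(m_t, contacts_u[(ca, cb)], pairs)
        tables.append(table)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "pair_id", "chrom", "group", "separation",
                "score_treated", "score_untreated", "n_pairs", "fc",
            ]
        )
    )
    summary = {
        group: hic._group_summary(table.loc[table.group == group, "fc"].to_numpy())
        for group in ("damaged", "control")
    }
    return table, summary


def _site_counts(
    call_set: jx.JunctionCallSet,
    cut_sites: list[DSBSite],
    junction_class: str,
    window: int,
) -> pd.Series:
    # No coordinate dedup here: synthetic libraries carry one record per
    # molecule, so coordinate collisions are genuine independent events
    # (dedup is a stand-in for molecular dedup on real libraries and lives
    # in bin_junction_counts).
    labels = call_set.labels
    chosen = labels[(~labels.bait_proximal) & (labels["class"] == junction_class)]
    by_id = {r.read_id: r for r in call_set.records}
    counts = {s.id: 0 for s in cut_sites}
    for read_id in chosen.read_id:
        r = by_id[read_id]
        for s in cut_sites:
            if s.chrom == r.prey_chrom and abs(r.prey_pos - s.midpoint) <= window:
                counts[s.id] += 1
                break
    return pd.Series(counts)


def translocation_site_counts(
    call_set: jx.JunctionCallSet,
    cut_sites: list[DSBSite],
    window: int = 2_500,
) -> pd.Series:
    """Translocation events per cut site (preys within ``window`` bp)."""
    return _site_counts(call_set, cut_sites, jx.TRANSLOCATION, window)


def cis_site_counts(
    call_set: jx.JunctionCallSet,
    cut_sites: list[DSBSite],
    window: int = 2_500,
) -> pd.Series:
    """Cis-deletion events per cut site (preys within ``window`` bp)."""
    return _site_counts(call_set, cut_sites, jx.CIS_DELETION, window)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _domains_to_bed(domains: list[DamageDomain], path: Path) -> None:
    io.write_bed(
        [
            GenomicInterval(
                d.interval.chrom,
                d.interval.start,
                d.interval.end,
                name=f"{d.kind}_{'damaged' if d.damaged else 'control'}",
            )
            for d in domains
        ],
        path,
    )


def write_simulated_inputs(
    bundle: LayoutBundle, out_dir: Path, config: PipelineConfig
) -> None:
    """On-disk snapshot of the simulated study inputs plus ground truth."""
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_bed(
        [
            GenomicInterval(s.chrom, s.cut.start, s.cut.end, name=s.id)
            for s in bundle.sites
        ],
        out_dir / "asisi_sites.bed",
    )
    _domains_to_bed(bundle.tads, out_dir / "tads.bed")
    _domains_to_bed(
        bundle.truth.damaged_domains + bundle.truth.control_domains,
        out_dir / "gh2ax_truth_domains.bed",
    )
    truth = bundle.truth
    io.write_manifest(
        {
            "seed": config.sim.seed,
            "cut_ids": ",".join(truth.cut_ids),
            "bait_ids": ",".join(truth.bait_ids),
            "n_tads": len(bundle.tads),
            "n_damaged_tads": sum(t.damaged for t in bundle.tads),
            **{
                f"site_intensity.{k}": f"{v:.6g}"
                for k, v in sorted(truth.site_intensity.items())
            },
        },
        out_dir / "ground_truth.txt",
    )


def run_pipeline(
    config_path: str | Path, out_dir: str | Path, seed: int | None = None
) -> Path:
    """Execute simulate -> dsb-call -> enrich -> hic -> junctions.

    Writes per-stage TSVs, a run log (parameters and record counts) and a
    one-page summary of fold changes and tests; returns the output dir.
    ``seed`` overrides the config's seed when given.
    """
    config = load_config(config_path)
    if seed is not None:
        config.sim.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"breakscape run, seed={config.sim.seed}"]
    summary_lines: list[str] = []

    bundle = build_layout(config.sim)
    write_simulated_inputs(bundle, out / "inputs", config)
    log_lines.append(
        f"layout: {config.sim.genome.n_chrom} chromosomes x "
        f"{config.sim.genome.chrom_length} bp, {len(bundle.tads)} TADs, "
        f"{len(bundle.sites)} AsiSI sites ({len(bundle.truth.cut_ids)} cut)"
    )

    analysis = config.analysis
    wt_trans_counts: dict[str, pd.Series] = {}
    wt_cis_counts: dict[str, pd.Series] = {}
    per_genotype_counts: dict[str, dict[str, tuple[pd.Series, pd.Series]]] = {}

    for genotype in config.genotypes:
        gdir = out / genotype.replace("-", "neg")
        gdir.mkdir(exist_ok=True)
        summary_lines.append(f"== {genotype} ==")

        tracks_dsb, peaks = simulate_chip(bundle, genotype, "DSB", config.sim)
        tracks_nt, _ = simulate_chip(bundle, genotype, "NT", config.sim)

        called = enrichment.call_dsb_sites(
            tracks_dsb["MRE11"], bundle.sites, analysis.min_fc, analysis.flank
        )
        called_ids = {s.id for s in called}
        truth_ids = set(bundle.truth.cut_ids)
        recall = len(called_ids & truth_ids) / max(1, len(truth_ids))
        precision = len(called_ids & truth_ids) / max(1, len(called_ids))
        io.write_bed(
            [GenomicInterval(s.chrom, s.cut.start, s.cut.end, name=s.id) for s in called],
            gdir / "called_dsbs.bed",
        )
        log_lines.append(
            f"{genotype}: dsb-call n={len(called)} recall={recall:.3f} "
            f"precision={precision:.3f}"
        )
        summary_lines.append(
            f"DSB calling: {len(called)} called "
            f"(recall {recall:.2f}, precision {precision:.2f})"
        )

        domains = enrichment.call_damage_domains(
            tracks_dsb["GH2AX"], tracks_nt["GH2AX"], analysis.domain, dsbs=called
        )
        _domains_to_bed(domains, gdir / "gh2ax_domains.bed")
        log_lines.append(f"{genotype}: gh2ax domains n={len(domains)}")

        cat_table, cat_summary = enrichment.category_fold_change(
            peaks["RAD21"], called, tracks_dsb["RAD21"], tracks_nt["RAD21"]
        )
        _write_tsv(cat_table, gdir / "rad21_shell_enrichment.tsv")
        _write_tsv(cat_summary, gdir / "rad21_shell_summary.tsv")
        for row in cat_summary.itertuples(index=False):
            star = (
                significance_stars(row.p_vs_ctrl)
                if row.p_vs_ctrl == row.p_vs_ctrl
                else ""
            )
            summary_lines.append(
                f"RAD21 {row.category}: mean FC {row.mean_fc:.3f} "
                f"(n={row.n}){(' ' + star) if star else ''}"
            )

        anchors = enrichment.call_anchor_sites(
            peaks["RAD21"], peaks["CTCF"], analysis.anchor_gap
        )
        anchor_table, anchor_summary = enrichment.anchor_domain_enrichment(
            anchors, domains, tracks_dsb["RAD21"], tracks_nt["RAD21"]
        )
        _write_tsv(anchor_table, gdir / "anchor_enrichment.tsv")
        test = anchor_summary["test"]
        star = significance_stars(test.p_value) if test else ""
        summary_lines.append(
            f"Anchors inside/outside damaged domains: "
            f"{anchor_summary['mean_fc_inside']:.3f} vs "
            f"{anchor_summary['mean_fc_outside']:.3f} "
            f"(n={anchor_summary['n_inside']}/{anchor_summary['n_outside']})"
            f"{(' ' + star) if star else ''}"
        )
        log_lines.append(
            f"{genotype}: anchors n={len(anchors)} inside="
            f"{anchor_summary['n_inside']} outside={anchor_summary['n_outside']}"
        )

        contacts_dsb = simulate_contacts(bundle, genotype, "DSB", config.sim)
        contacts_nt = simulate_contacts(bundle, genotype, "NT", config.sim)

        intra_table, intra_summary = intra_domain_fc_all(
            contacts_dsb, contacts_nt, bundle.tads
        )
        _write_tsv(intra_table, gdir / "intra_domain_fc.tsv")
        summary_lines.append(
            f"Intra-TAD O/E FC: damaged {intra_summary['damaged']['mean_fc']:.4f} "
            f"(n={intra_summary['damaged']['n']}), control "
            f"{intra_summary['control']['mean_fc']:.4f} "
            f"(n={intra_summary['control']['n']})"
        )

        pair_rng = np.random.default_rng([config.sim.seed, 97])
        pair_table, pair_summary = inter_domain_fc_all(
            contacts_dsb, contacts_nt, bundle.tads, pair_rng
        )
        _write_tsv(pair_table, gdir / "inter_domain_pair_fc.tsv")
        summary_lines.append(
            f"Inter-domain O/E FC: DSB-DSB "
            f"{pair_summary['damaged']['mean_fc']:.4f} "
            f"(n={pair_summary['damaged']['n']}), Ctrl-Ctrl "
            f"{pair_summary['control']['mean_fc']:.4f} "
            f"(n={pair_summary['control']['n']})"
        )

        # 4C-like viewpoint from the first bait
        bait0 = bundle.site_by_id(bundle.truth.bait_ids[0])
        m_t = contacts_dsb[(bait0.chrom, bait0.chrom)]
        m_u = contacts_nt[(bait0.chrom, bait0.chrom)]
        bins, log2fc = hic.viewpoint_track(m_t, m_u, m_t.bin_of(bait0.midpoint))
        vp = pd.DataFrame(
            {
                "chrom": bait0.chrom,
                "start": bins * m_t.resolution,
                "end": np.minimum(
                    (bins + 1) * m_t.resolution,
                    bundle.layout.chrom_lengths[bait0.chrom],
                ),
                "log2fc": log2fc,
            }
        )
        _write_tsv(vp, gdir / "viewpoint_log2fc.tsv")

        jparams = junction_params_for(genotype, config.sim.junctions)
        per_genotype_counts[genotype] = {}
        for bait_id in bundle.truth.bait_ids:
            records = simulate_junctions(bundle, contacts_dsb, bait_id, config.sim, jparams)
            io.write_junctions(records, gdir / f"junctions_{bait_id}.tsv")
            bait = bundle.site_by_id(bait_id)
            call_set = jx.annotate(
                records, bait, called, domains, break_window=analysis.break_window
            )
            _write_tsv(call_set.labels, gdir / f"junctions_{bait_id}_labels.tsv")
            kept = call_set.labels[~call_set.labels.bait_proximal]
            class_counts = (
                kept["class"].value_counts().rename_axis("class").reset_index(name="n")
            )
            _write_tsv(class_counts, gdir / f"junctions_{bait_id}_classes.tsv")
            hist, mh_summary = jx.mh_profile(call_set.labels.mh_len)
            _write_tsv(
                hist.rename_axis("mh_len").reset_index(name="n"),
                gdir / f"junctions_{bait_id}_mh.tsv",
            )
            binned = jx.bin_junction_counts(records)
            _write_tsv(binned, gdir / f"junctions_{bait_id}_binned.tsv")
            tc = translocation_site_counts(call_set, bundle.cut_sites)
            cc = cis_site_counts(call_set, bundle.cut_sites)
            per_genotype_counts[genotype][bait_id] = (tc, cc)
            log_lines.append(
                f"{genotype}/{bait_id}: junctions n={len(records)} "
                f"bait_proximal={int(call_set.labels.bait_proximal.sum())} "
                f"translocations={int((kept['class'] == jx.TRANSLOCATION).sum())} "
                f"cis={int((kept['class'] == jx.CIS_DELETION).sum())} "
                f"mean_mh={mh_summary['mean_mh']:.3f}"
            )
        if genotype == "WT":
            for bait_id, (tc, cc) in per_genotype_counts["WT"].items():
                wt_trans_counts[bait_id] = tc
                wt_cis_counts[bait_id] = cc
        summary_lines.append("")

    # condition fold changes vs WT
    if "WT" in per_genotype_counts:
        n_junc = config.sim.junctions.n_junctions
        rows = []
        for genotype in config.genotypes:
            if genotype == "WT":
                continue
            for bait_id, (tc, cc) in per_genotype_counts[genotype].items():
                _, t_summary = jx.condition_fold_change(
                    tc, wt_trans_counts[bait_id], (n_junc, n_junc)
                )
                _, c_summary = jx.condition_fold_change(
                    cc, wt_cis_counts[bait_id], (n_junc, n_junc)
                )
                rows.append(
                    {
                        "genotype": genotype,
                        "bait": bait_id,
                        "translocation_fc": t_summary["aggregate_fc"],
                        "cis_deletion_fc": c_summary["aggregate_fc"],
                    }
                )
        if rows:
            fc_table = pd.DataFrame(rows)
            _write_tsv(fc_table, out / "junction_condition_fc.tsv")
            for genotype, group in fc_table.groupby("genotype", sort=True):
                summary_lines.append(
                    f"{genotype} vs WT: translocations x"
                    f"{group.translocation_fc.mean():.2f}, cis-deletions x"
                    f"{group.cis_deletion_fc.mean():.2f}"
                )

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
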