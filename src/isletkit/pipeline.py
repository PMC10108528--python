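"""End-to-end orchestration: synthetic world -> QC -> consensus -> differential
-> annotation -> congruence -> motifs -> enhancers -> report.

``run_all`` executes every stage from a single :class:`PipelineConfig`,
writes TSV/BED/JSON artifacts into the output directory, and finishes with
a run manifest of SHA-256 checksums; identical config and seeds produce
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import congruence as cong
from . import differential as diff
from . import enhancers as enh
from . import motifs as mot
from .genes import read_gtf, tss_regions
from .intervals import RegionSet, read_fragment_table, read_regions, write_regions
from .simulate import SyntheticConfig, World, generate_world

log = logging.getLogger("isletkit")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    With ``synthetic`` set, the world is generated into ``outdir/world`` and
    all track paths are taken from it; otherwise the explicit path fields
    must point at user-supplied tracks. Every random stage derives its seed
    from ``seed`` (no wall-clock seeding anywhere).
    """

    outdir: Path
    synthetic: SyntheticConfig | None = None
    # explicit inputs (used when synthetic is None)
    gtf: Path | None = None
    atac: dict = field(default_factory=dict)        # (cell, rep) -> narrowPeak path
    fragments: dict = field(default_factory=dict)   # (cell, rep) -> fragment BED path
    expression: Path | None = None
    expression_de: Path | None = None
    histone: dict = field(default_factory=dict)     # mark -> BED path
    tf: dict = field(default_factory=dict)          # TF name -> BED path
    catalog: Path | None = None
    fasta: Path | None = None
    pwms: dict = field(default_factory=dict)        # motif id -> pfm path
    motif_map: Path | None = None
    chrom_sizes: dict = field(default_factory=dict)
    # parameters
    cell_types: tuple[str, ...] = ("alpha", "beta", "delta")
    comparison: tuple[str, str] = ("alpha", "beta")
    min_replicates: int = 2
    alpha: float = 0.05
    promoter_window: int = 3000
    motif_p_threshold: float = 1e-4
    n_perm: int = 100
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; return the in-memory results dictionary.

    Artifacts land under ``config.outdir``; the final ``manifest.json``
    records a checksum per output file.
    """
    logging.basicConfig(level=config.log_level, format="[%(name)s] %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # -- stage: simulate -----------------------------------------------------
    world: World | None = None
    if config.synthetic is not None:
        log.info("simulate: generating synthetic world (seed=%d)", config.synthetic.seed)
        world = generate_world(config.synthetic, outdir / "world")
        config.gtf = world.paths["gtf"]
        config.atac = world.paths["atac"]
        config.fragments = world.paths["fragments"]
        config.expression = world.paths["expression"]
        config.expression_de = world.paths["expression_de"]
        config.histone = world.paths["histone"]
        config.tf = world.paths["tf"]
        config.catalog = world.paths["catalog"]
        config.fasta = world.paths["fasta"]
        config.pwms = world.paths["pwms"]
        config.motif_map = world.paths["motif_map"]
        config.chrom_sizes = dict(config.synthetic.chrom_sizes)
        config.cell_types = tuple(config.synthetic.cell_types)
        results["world"] = world

    genes = read_gtf(config.gtf)
    peak_sets = {
        key: read_regions(p, format="narrowpeak", meta={"cell_type": key[0], "replicate": key[1], "track_kind": "atac"})
        for key, p in sorted(config.atac.items())
    }
    frag_tables = {key: read_fragment_table(p) for key, p in sorted(config.fragments.items())}

    # -- stage: qc -----------------------------------------------------------
    log.info("qc: FRiP per sample")
    qc_rows = []
    for key in sorted(peak_sets):
        m = ann.compute_frip(frag_tables[key], peak_sets[key])
        qc_rows.append(
            {"cell_type": key[0], "replicate": key[1], "frip": m.frip,
             "n_fragments": m.n_fragments, "n_in_peaks": m.n_in_peaks, "pass": m.passed}
        )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(outdir / "qc_frip.tsv", sep="\t", index=False, float_format="%.6g")
    results["qc"] = qc

    # -- stage: consensus ----------------------------------------------------
    log.info("consensus: min %d replicates", config.min_replicates)
    consensus = diff.build_consensus(list(peak_sets.values()), min_replicates=config.min_replicates)
    write_regions(consensus, outdir / "consensus.bed")
    by_cell: dict[str, RegionSet] = {}
    for cell in config.cell_types:
        reps = [rs for key, rs in peak_sets.items() if key[0] == cell]
        by_cell[cell] = diff.build_consensus(reps, min_replicates=config.min_replicates)
        write_regions(by_cell[cell], outdir / f"consensus_{cell}.bed")
    results["consensus"] = consensus
    results["consensus_by_cell"] = by_cell

    # -- stage: counting + similarity ---------------------------------------
    log.info("counting: %d regions x %d samples", len(consensus), len(frag_tables))
    cm = diff.count_fragments(consensus, frag_tables)
    cm.norm_factors = diff.tmm_factors(cm)
    corr, pcs = diff.sample_similarity(cm)
    corr.to_csv(outdir / "sample_correlation.tsv", sep="\t", float_format="%.6g")
    if pcs is not None:
        pcs.to_csv(outdir / "sample_pca.tsv", sep="\t", float_format="%.6g")
    results["count_matrix"] = cm
    results["correlation"] = corr
    results["pca"] = pcs

    # -- stage: differential -------------------------------------------------
    results["differential"] = {}
    pairs = [
        (a, b)
        for i, a in enumerate(config.cell_types)
        for b in config.cell_types[i + 1 :]
    ]
    for a, b in pairs:
        log.info("differential: %s vs %s", a, b)
        dps = diff.nb_exact_test(cm, a, b, alpha=config.alpha)
        table = diff.differential_table(dps, (a, b))
        table.to_csv(outdir / f"differential_{a}_vs_{b}.tsv", sep="\t", index=False, float_format="%.6g")
        results["differential"][(a, b)] = dps

    # -- stage: annotate -----------------------------------------------------
    log.info("annotate: classifying %d consensus peaks", len(consensus))
    idx = ann.build_feature_index(genes, promoter_window=config.promoter_window, genome_bp=config.chrom_sizes or None)
    annotated = ann.classify_peaks(consensus, idx)
    dist = ann.category_distribution(annotated, idx)
    dist.to_csv(outdir / "category_distribution.tsv", sep="\t", float_format="%.6g")
    profile = ann.tss_profile(consensus, tss_regions(genes))
    np.savetxt(outdir / "tss_profile.tsv", profile[None, :], fmt="%d", delimiter="\t")
    results["feature_index"] = idx
    results["annotated"] = annotated
    results["category_distribution"] = dist
    results["tss_profile"] = profile

    # -- stage: congruence ---------------------------------------------------
    a, b = config.comparison
    log.info("congruence: %s vs %s", a, b)
    expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    de = pd.read_csv(config.expression_de, sep="\t", index_col=0) if config.expression_de else None
    assoc, audit = cong.associate_tss_peaks(results["differential"][(a, b)], genes, window=config.promoter_window)
    calls, summary, n_missing = cong.classify_congruence(assoc, expr, (a, b), de=de)
    cong.congruence_table(calls).to_csv(outdir / "congruence.tsv", sep="\t", index=False, float_format="%.6g")
    repressed_a = [c.gene for c in calls if c.klass == "incongruent_repressed_in_a"]
    poised_calls, poised_frac = cong.poised_stepwise_test(repressed_a, expr, origin_cell=a)
    results["congruence"] = {"calls": calls, "summary": summary, "n_missing": n_missing}
    results["poised"] = {"calls": poised_calls, "fractions": poised_frac}

    # -- stage: motifs -------------------------------------------------------
    results["motifs"] = None
    if config.fasta and config.pwms:
        log.info("motifs: scanning %d PWMs", len(config.pwms))
        pwms = [mot.read_pwm(p, format="jaspar_pfm") for _, p in sorted(config.pwms.items())]
        seqs = _read_fasta(Path(config.fasta))
        hits = mot.scan_motifs(seqs, pwms, p_threshold=config.motif_p_threshold)
        hit_table = pd.DataFrame(
            {
                "sequence": [h.interval.chrom for h in hits],
                "start": [h.interval.start for h in hits],
                "end": [h.interval.end for h in hits],
                "motif_id": [h.motif_id for h in hits],
                "strand": [h.strand for h in hits],
                "score": [h.score for h in hits],
                "p": [h.p_at_score for h in hits],
            }
        )
        hit_table.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False, float_format="%.6g")
        results["motifs"] = {"pwms": pwms, "hits": hits}

    # -- stage: enhancers ----------------------------------------------------
    results["enhancers"] = None
    if config.histone.get("H3K27ac") and config.histone.get("H3K4me1") and config.tf:
        log.info("enhancers: calling the putative -> active -> conservative chain")
        h3k27ac = read_regions(config.histone["H3K27ac"], meta={"track_kind": "histone"})
        h3k4me1 = read_regions(config.histone["H3K4me1"], meta={"track_kind": "histone"})
        h3k4me3 = (
            read_regions(config.histone["H3K4me3"], meta={"track_kind": "histone"})
            if config.histone.get("H3K4me3")
            else RegionSet([])
        )
        tf_tracks = {name: read_regions(p, meta={"track_kind": "chip_tf", "label": name}) for name, p in sorted(config.tf.items())}
        putative = enh.call_putative(h3k27ac, h3k4me1, tf_tracks)
        for c in putative:
            c.state = enh.classify_state(c.region, h3k27ac, h3k4me1, h3k4me3)
        putative = [c for c in putative if c.state in ("active", "poised")]
        _, active = enh.filter_accessible(putative, by_cell)
        conservative: list = []
        if config.catalog and Path(config.catalog).exists():
            catalog = read_regions(config.catalog, meta={"track_kind": "enhancer_catalog"})
            conservative = enh.filter_catalog(active, catalog)
        else:
            log.warning("enhancers: no catalog track; skipping the conservative list")
        enh.enhancer_table(putative).to_csv(outdir / "enhancers_putative.tsv", sep="\t", index=False)
        enh.enhancer_table(active).to_csv(outdir / "enhancers_active.tsv", sep="\t", index=False)
        enh.enhancer_table(conservative).to_csv(outdir / "enhancers_conservative.tsv", sep="\t", index=False)
        spec_part = enh.specificity_partition(active)
        spec_part.to_csv(outdir / "enhancer_specificity.tsv", sep="\t", float_format="%.6g")
        first_tf = sorted(tf_tracks)[0]
        ov = enh.overlap_stats(consensus, tf_tracks[first_tf])
        perm = None
        if config.chrom_sizes and active:
            perm = enh.permutation_enrichment(
                RegionSet([c.region for c in active]),
                h3k27ac,
                config.chrom_sizes,
                n_perm=config.n_perm,
                seed=config.seed,
            )
        results["enhancers"] = {
            "putative": putative,
            "active": active,
            "conservative": conservative,
            "specificity": spec_part,
            "overlap_stats": {first_tf: ov},
            "permutation": perm,
        }

    # -- stage: report -------------------------------------------------------
    report = write_report(results, outdir, config)
    results["report"] = report

    manifest = {"files": {}}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def write_report(results: dict, outdir: Path, config: PipelineConfig) -> dict:
    """Summary JSON + human-readable text report of every stage's headline numbers."""
    outdir = Path(outdir)
    rep: dict = {}
    qc = results.get("qc")
    rep["frip"] = (
        {f"{r.cell_type}_{r.replicate}": round(float(r.frip), 4) for r in qc.itertuples()}
        if qc is not None
        else None
    )
    consensus = results.get("consensus")
    rep["n_consensus_peaks"] = len(consensus) if consensus is not None else None
    rep["differential"] = {}
    for (a, b), dps in results.get("differential", {}).items():
        n_sig = sum(p.significant for p in dps)
        rep["differential"][f"{a}_vs_{b}"] = {
            "n_tested": len(dps),
            "n_significant": n_sig,
            "frac_significant": round(n_sig / len(dps), 4) if dps else None,
        }
    dist = results.get("category_distribution")
    if dist is not None:
        rep["category_distribution"] = {k: round(float(v), 2) for k, v in dist["peak_pct"].items()}
        rep["genome_background"] = {k: round(float(v), 2) for k, v in dist["genome_pct"].items()}
    congr = results.get("congruence")
    if congr:
        rep["congruence_pct"] = {k: round(float(v), 2) for k, v in congr["summary"].items()}
    poised = results.get("poised")
    if poised:
        rep["poised_fractions"] = {k: round(float(v), 4) for k, v in poised["fractions"].items()}
    mo = results.get("motifs")
    if mo:
        per_motif: dict[str, int] = {}
        for h in mo["hits"]:
            per_motif[h.motif_id] = per_motif.get(h.motif_id, 0) + 1
        rep["motif_hits"] = per_motif
    en = results.get("enhancers")
    if en:
        rep["enhancers"] = {
            "n_putative": len(en["putative"]),
            "n_active": len(en["active"]),
            "n_conservative": len(en["conservative"]),
            "specificity_pct": {k: round(float(v), 2) for k, v in en["specificity"]["pct"].items()},
        }
        if en["permutation"]:
            p = en["permutation"]
            rep["enhancers"]["permutation"] = {
                "observed": p.observed_overlap, "null_mean": round(p.null_mean, 2),
                "z": round(p.z, 2), "p_empirical": round(p.p_empirical, 6),
            }
    (outdir / "report.json").write_text(json.dumps(rep, indent=2, sort_keys=True))

    lines = ["isletkit run report", "===================", ""]
    for key, val in sorted(rep.items()):
        lines.append(f"{key}: {json.dumps(val, sort_keys=True) if val is not None else 'absent'}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return rep


def config_from_json(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from JSON (synthetic block becomes a SyntheticConfig)."""
    raw = json.loads(Path(path).read_text())
    syn = raw.pop("synthetic", None)
    if syn is not None:
        from .simulate import MotifSpec

        if "motif_set" in syn:
            syn["motif_set"] = tuple(MotifSpec(**m) for m in syn["motif_set"])
        for key in ("cell_types", "tf_names"):
            if key in syn:
                syn[key] = tuple(syn[key])
        syn = SyntheticConfig(**syn)
    for key in ("cell_types", "comparison"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "outdir" in raw:
        raw["outdir"] = Path(raw["outdir"])
    return PipelineConfig(synthetic=syn, **raw)
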