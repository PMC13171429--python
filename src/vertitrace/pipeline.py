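"""End-to-end orchestration of the vertical-inheritance evidence report.

The pipeline runs the independent screens in order — GC composition, Z-curve
segmentation, pairwise dN/dS vs the core-gene background with a bootstrap
equality-of-means test, ancestral-state reconstruction with gain/loss
counting and dating, gene/species-tree incongruence, neighborhood synteny,
and protein subtyping — and assembles a Report whose verdict block states
each line of evidence separately. Converging criteria, not a composite
score: a vertically inherited gene should show no composition anomaly, no
segmentation near its locus, conserved synteny, core-like dN/dS, and a
single phylogenetic origin with few losses and no unexplained incongruence.

Stages are independent where data flow allows; a stage failure is recorded
in the report without aborting the others. All randomness derives from the
master seed through fixed per-stage offsets recorded in the report.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean

from . import boot_stats, codon_dnds, composition, subtype_synteny, trait_evo, zseg
from .seqio import Report, read_fasta, read_loci, read_newick, read_trait_table
from .subtype_synteny import Msa
from .trait_evo import CalibrationPoint, MkModel

_BOOT_SEED_OFFSET = 7  # bootstrap stage seed = (master * 1000 + offset) % 2^31


@dataclass
class PipelineConfig:
    """Validated paths and parameters for a full run; all stages optional."""

    seed: int = 0
    genomes: str | None = None
    focal_loci: str | None = None
    loci_dialect: str = "bed"
    focal_protein_msa: str | None = None
    focal_cds: str | None = None
    core_alignments: list[dict] = field(default_factory=list)
    species_tree: str | None = None
    gene_tree: str | None = None
    traits: str | None = None
    calibrations: list[dict] = field(default_factory=list)
    variant_msa: str | None = None
    neighborhoods: list[dict] = field(default_factory=list)
    # stage parameters
    t0: float = 100.0
    min_len: int = 1000
    window_bp: int = 10_000
    bootstrap_B: int = 1000
    subtype_threshold: float = 85.0
    origin_threshold: float = 0.5
    asr_model: str = "ER"
    gc_dev_max: float = 0.02  # max |gene - genome| GC fraction called "no deviation"
    synteny_min: float = 0.5
    alpha: float = 0.05
    trim_nterm: int = 0
    trim_range: tuple[int, int] | None = None

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        def resolve(p):
            if p is None:
                return None
            q = Path(p)
            if base is not None and not q.is_absolute():
                q = base / q
            if not q.exists():
                raise FileNotFoundError(f"config path does not exist: {p}")
            return str(q)

        for name in ("genomes", "focal_loci", "focal_protein_msa", "focal_cds",
                     "species_tree", "gene_tree", "traits", "variant_msa"):
            setattr(self, name, resolve(getattr(self, name)))
        for block in self.core_alignments:
            for key in ("protein_msa", "cds"):
                block[key] = resolve(block[key])
        for block in self.neighborhoods:
            block["loci"] = resolve(block["loci"])
            block["families"] = resolve(block["families"])
        if self.t0 <= 0 or self.min_len < 2 or self.bootstrap_B < 1:
            raise ValueError("invalid stage parameters")


def _stage(report: Report, name: str, fn) -> dict | None:
    try:
        payload = fn()
        report.add_stage(name, {"ok": True, **payload})
        return payload
    except Exception as exc:  # stage isolation: record, keep going
        report.add_stage(
            name,
            {"ok": False, "error": f"{type(exc).__name__}: {exc}",
             "trace": traceback.format_exc(limit=3)},
        )
        return None


def _omegas_from(protein_msa_path, cds_path, label) -> list[float]:
    prot = read_fasta(protein_msa_path, alphabet="aa")
    cds = read_fasta(cds_path, alphabet="nt", partial=True)
    aln = codon_dnds.backtranslate(prot, cds)
    return codon_dnds.pairwise_matrix(aln, label=label).retained_omegas


def run_pipeline(config: PipelineConfig) -> Report:
    """Run every configured stage and assemble the evidence report."""
    report = Report(
        inputs={k: v for k, v in vars(config).items() if not k.startswith("_")},
        parameters={
            "t0": config.t0, "min_len": config.min_len,
            "window_bp": config.window_bp, "bootstrap_B": config.bootstrap_B,
            "subtype_threshold": config.subtype_threshold,
            "origin_threshold": config.origin_threshold,
        },
        seed=config.seed,
    )
    genomes = loci = None
    if config.genomes:
        genomes = read_fasta(config.genomes, genomes=True)
    if config.focal_loci and genomes is not None:
        loci = read_loci(config.focal_loci, dialect=config.loci_dialect, genomes=genomes)

    # --- GC composition -------------------------------------------------
    if genomes is not None and loci:
        def gc_stage():
            records, summary = composition.gene_vs_genome_gc(loci, genomes)
            return {
                "records": [
                    {"strain": r.strain, "gene_gc": r.gene_gc,
                     "genome_gc": r.genome_gc, "deviation": r.deviation}
                    for r in records
                ],
                "gene_gc_mean": summary.gene_mean,
                "gene_gc_sd": summary.gene_sd,
                "genome_gc_mean": summary.genome_mean,
                "genome_gc_sd": summary.genome_sd,
                "deviation_mean": summary.deviation_mean,
                "max_abs_deviation": max(
                    abs(r.deviation) for r in records
                ),
            }
        _stage(report, "gc", gc_stage)

    # --- Z-curve segmentation -------------------------------------------
    if genomes is not None and loci:
        def zseg_stage():
            params = zseg.SegmentationParams(t0=config.t0, min_len=config.min_len)
            by_id = {g.id: g for g in genomes}
            out = []
            for loc in loci:
                seg = zseg.segment_sequence(by_id[loc.genome_id].sequence, params)
                scan = zseg.scan_locus(seg, loc, config.window_bp)
                out.append({
                    "genome": loc.genome_id,
                    "gene": loc.gene_id,
                    "n_breakpoints": len(seg.breakpoints),
                    "breakpoints": seg.breakpoints,
                    "nearest_breakpoint_distance": (
                        scan.distance if scan.distance != float("inf") else None
                    ),
                    "segmentation_within_window": scan.within_window,
                })
            return {"per_genome": out,
                    "any_segmentation_near_locus": any(
                        o["segmentation_within_window"] for o in out)}
        _stage(report, "zseg", zseg_stage)

    # --- dN/dS + bootstrap ----------------------------------------------
    focal_omegas = core_omegas = None
    if config.focal_protein_msa and config.focal_cds:
        def dnds_stage():
            nonlocal focal_omegas, core_omegas
            focal_omegas = _omegas_from(
                config.focal_protein_msa, config.focal_cds, "focal"
            )
            core_omegas = []
            for block in config.core_alignments:
                core_omegas.extend(
                    _omegas_from(block["protein_msa"], block["cds"],
                                 block.get("label", "core"))
                )
            payload = {
                "focal_mean_omega": mean(focal_omegas) if focal_omegas else None,
                "focal_n_retained": len(focal_omegas),
                "core_mean_omega": mean(core_omegas) if core_omegas else None,
                "core_n_retained": len(core_omegas),
            }
            if focal_omegas:
                bs = boot_stats.box_summary(focal_omegas)
                payload["focal_box"] = vars(bs)
            if focal_omegas and core_omegas:
                seed = (config.seed * 1000 + _BOOT_SEED_OFFSET) % (2**31)
                res = boot_stats.boot_mean_eq_test(
                    focal_omegas, core_omegas, B=config.bootstrap_B, seed=seed
                )
                payload["bootstrap"] = {
                    "t_obs": res.t_obs, "B": res.B, "p_value": res.p_value,
                    "seed": res.seed, "n_focal": res.n_a, "n_core": res.n_b,
                }
            return payload
        _stage(report, "dnds", dnds_stage)

    # --- trait evolution -------------------------------------------------
    if config.species_tree and config.traits:
        def asr_stage():
            tree = read_newick(config.species_tree, require_rooted=True)
            traits = read_trait_table(config.traits, tree=tree)
            asr = trait_evo.mk_asr(
                tree, traits, MkModel(config.asr_model),
                origin_threshold=config.origin_threshold,
            )
            payload = {
                "rates": asr.rates,
                "log_likelihood": asr.log_likelihood,
                "n_gains": len(asr.gains),
                "n_losses": len(asr.losses),
                "gains": asr.gains,
                "losses": asr.losses,
                "origin_node": asr.origin,
                "origin_marginal": asr.marginals.get(asr.origin),
                "marginals": asr.marginals,
            }
            if config.calibrations:
                cals = [
                    CalibrationPoint(tuple(c["tips"]), c["age"],
                                     tuple(c["ci"]) if c.get("ci") else None)
                    for c in config.calibrations
                ]
                dating = trait_evo.date_nodes(tree, cals)
                payload["dating"] = {
                    "rate": dating.rate,
                    "origin_age_Ma": dating.ages.get(asr.origin),
                    "origin_age_ci": (dating.age_ci or {}).get(asr.origin),
                }
            return payload
        _stage(report, "asr", asr_stage)

    if config.species_tree and config.gene_tree:
        def lgt_stage():
            sp = read_newick(config.species_tree, require_rooted=True)
            gt = read_newick(config.gene_tree, require_rooted=True)
            flags = trait_evo.lgt_flags(gt, sp)
            return {
                "flagged_tips": [f.tip for f in flags if f.flagged],
                "recipient_candidates": [
                    f.tip for f in flags if f.recipient_candidate
                ],
                "proposed_donors": {
                    f.tip: sorted(f.proposed_donor) for f in flags if f.flagged
                },
            }
        _stage(report, "lgt", lgt_stage)

    # --- subtypes ---------------------------------------------------------
    if config.variant_msa:
        def subtype_stage():
            msa = Msa.from_seqset(read_fasta(config.variant_msa, alphabet="aa"))
            if config.trim_nterm or config.trim_range:
                msa = subtype_synteny.trim_alignment(
                    msa, config.trim_nterm, config.trim_range
                )
            mat = subtype_synteny.identity_matrix(msa)
            assign = subtype_synteny.cluster_subtypes(
                mat, threshold=config.subtype_threshold
            )
            return {
                "n_variants": len(msa.ids),
                "n_subtypes": len(set(assign.subtype_of.values())),
                "labels": assign.label_of,
            }
        _stage(report, "subtype", subtype_stage)

    # --- synteny ----------------------------------------------------------
    if len(config.neighborhoods) >= 2:
        def synteny_stage():
            profiles = []
            for block in config.neighborhoods:
                nloci = read_loci(block["loci"], dialect=block.get("dialect", "bed"))
                families = {}
                with open(block["families"]) as fh:
                    for line in fh:
                        if line.strip():
                            gid, fam = line.rstrip("\n").split("\t")[:2]
                            families[gid] = fam
                profiles.append(
                    subtype_synteny.build_neighborhood(
                        nloci, block["focal_gene_id"], families,
                        window_bp=config.window_bp,
                    )
                )
            scores = []
            for i in range(len(profiles)):
                for j in range(i + 1, len(profiles)):
                    scores.append(
                        subtype_synteny.neighborhood_synteny(profiles[i], profiles[j])
                    )
            return {"pairwise_scores": scores,
                    "min_score": min(scores), "mean_score": mean(scores)}
        _stage(report, "synteny", synteny_stage)

    report.verdict = build_verdict(report, config)
    return report


def build_verdict(report: Report, config: PipelineConfig) -> dict:
    """One boolean line of evidence per LGT criterion; never a composite score."""
    verdict: dict = {}
    gc = report.stages.get("gc")
    if gc and gc.get("ok"):
        verdict["gc_deviation_small"] = gc["max_abs_deviation"] <= config.gc_dev_max
    zs = report.stages.get("zseg")
    if zs and zs.get("ok"):
        verdict["no_segmentation_near_locus"] = not zs["any_segmentation_near_locus"]
    dn = report.stages.get("dnds")
    if dn and dn.get("ok") and "bootstrap" in dn:
        verdict["dnds_consistent_with_core"] = (
            dn["bootstrap"]["p_value"] >= config.alpha
        )
    asr = report.stages.get("asr")
    if asr and asr.get("ok"):
        verdict["single_origin"] = asr["n_gains"] == 1
        verdict["few_losses"] = asr["n_losses"] <= 3
    lgt = report.stages.get("lgt")
    if lgt and lgt.get("ok"):
        verdict["no_incongruent_tips"] = not lgt["flagged_tips"]
        verdict["transfer_recipients"] = lgt["recipient_candidates"]
    sy = report.stages.get("synteny")
    if sy and sy.get("ok"):
        verdict["synteny_conserved"] = sy["min_score"] >= config.synteny_min
    return verdict
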