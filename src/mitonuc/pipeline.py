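"""End-to-end orchestration: ingest -> LD check -> clustering -> F-statistics
-> demography -> per-isolate profiles, with a consolidated report.

The report is a pure function of (inputs, config, seed): no timestamps enter
the JSON (they go to the log), keys are sorted and a content hash of the
input files is embedded, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering as cl
from . import diversity as dv
from . import fstats as fs
from . import ld as ldmod
from . import mismatch as mm
from . import profiles as pf
from .seqdata import GapMode, collapse_haplotypes, read_alignment

logger = logging.getLogger("mitonuc.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mito_fasta: str
    nuclear_fasta: str
    metadata: str
    output_dir: str = "mitonuc_out"
    gap_mode_diversity: str = "ignore_gap_columns"
    gap_mode_matrix: str = "fifth_state"
    ld_threshold_r: float = 0.5
    ld_alpha: float = 0.05
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    replicates: int = 4
    burn_in: int = 300
    reps: int = 1100
    assignment_thresholds: dict = field(
        default_factory=lambda: {"mito": 0.8, "nuclear": 0.6, "combined": 0.7}
    )
    hierarchy_min_n: int = 10
    hierarchy_depth: int = 2
    n_perm: int = 1000
    groupings: tuple[str, ...] = ("habitat",)
    mismatch_bootstrap: int = 200
    run_hierarchical: bool = True
    run_mismatch_bootstrap: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "groupings" in raw:
            raw["groupings"] = tuple(raw["groupings"])
        cfg = cls(**raw)
        for p in (cfg.mito_fasta, cfg.nuclear_fasta, cfg.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _hash_inputs(*paths: str) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def _round(x, nd=6):
    if x is None:
        return None
    return round(float(x), nd)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return (and write) the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    report: dict = {
        # output_dir and input paths are environment-specific and excluded so
        # that identical data + settings give a byte-identical report
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k not in ("output_dir", "mito_fasta", "nuclear_fasta", "metadata")
        },
        "input_hash": _hash_inputs(config.mito_fasta, config.nuclear_fasta,
                                   config.metadata),
    }
    stage = "ingest"
    try:
        logger.info("stage: ingest")
        mito = read_alignment(config.mito_fasta, config.metadata, "haploid", "mito")
        nuc = read_alignment(config.nuclear_fasta, config.metadata, "diploid", "nuclear")
        isolates = sorted({s.isolate_id for s in nuc.samples})
        for iso in isolates:
            if len(nuc.sequences_for_isolate(iso)) < 2:
                raise ValueError(f"isolate {iso!r} has <1 individual at the nuclear locus")
        report["n_individuals"] = len(nuc.individuals)
        report["isolates"] = isolates

        stage = "haplotypes"
        logger.info("stage: haplotypes")
        tables = {}
        for ds in (mito, nuc):
            for gm in (GapMode.ignore_gap_columns, GapMode.fifth_state):
                tab = collapse_haplotypes(ds, gm)
                tables[(ds.locus_name, gm)] = tab
                report.setdefault("haplotypes", {})[f"{ds.locus_name}:{gm.value}"] = {
                    "h": tab.h, "S": tab.S,
                }

        stage = "diversity"
        logger.info("stage: diversity")
        gmd = GapMode(config.gap_mode_diversity)
        div: dict[str, dict[str, dv.DiversitySummary]] = {"mito": {}, "nuclear": {}}
        flags = {}
        for iso in isolates:
            div["mito"][iso] = dv.summarize_unit(mito, iso, gmd)
            div["nuclear"][iso] = dv.summarize_unit(nuc, iso, gmd)
            flags[iso] = dv.pi_ratio_flag(div["mito"][iso], div["nuclear"][iso])
        report["diversity"] = {
            locus: {
                iso: {
                    "n": d.n_alleles, "S": d.S, "h": d.h,
                    "Hd": _round(d.Hd), "pi": _round(d.pi),
                    "tajimas_D": _round(d.tajimas_D),
                }
                for iso, d in per.items()
            }
            for locus, per in div.items()
        }
        report["pi_ratio_flags"] = {
            iso: {"ratio": _round(f.ratio), "flag": f.secondary_contact_flag}
            for iso, f in flags.items()
        }

        stage = "ld_filter"
        logger.info("stage: LD screen")
        gmm = GapMode(config.gap_mode_matrix)
        ld_results = {}
        filters = {}
        for ds in (mito, nuc):
            pairs = ldmod.pairwise_ld(ds, gmm, alpha=config.ld_alpha)
            filt = ldmod.exclude_linked_sites(pairs, config.ld_threshold_r,
                                              config.ld_alpha)
            ld_results[ds.locus_name] = pairs
            filters[ds.locus_name] = filt
            report.setdefault("ld", {})[ds.locus_name] = {
                "n_tests": filt.n_tests,
                "n_excluded_sites": len(filt.excluded_sites),
                "n_retained_sites": len(filt.retained_sites),
            }

        stage = "clustering"
        logger.info("stage: clustering")
        locus_offset = {"mito": 101, "nuclear": 202, "combined": 303}
        matrices = {
            "mito": cl.build_genotype_matrix(mito=mito, gap_mode=gmm),
            "nuclear": cl.build_genotype_matrix(nuclear=nuc, gap_mode=gmm),
            "combined": cl.build_genotype_matrix(mito=mito, nuclear=nuc, gap_mode=gmm),
        }
        selections = {}
        first_runs = {}
        for name, matrix in matrices.items():
            sel = cl.select_k(matrix, config.k_range, replicates=config.replicates,
                              burn_in=config.burn_in, reps=config.reps,
                              seed=config.seed + locus_offset[name])
            selections[name] = sel
            run = sel.best_run() if sel.runs else None
            first_runs[name] = run
            report.setdefault("clustering", {})[name] = {
                "chosen_K": sel.chosen_K, "reliable": sel.reliable,
                "deltaK": {str(k): _round(v, 2) for k, v in sel.deltaK.items()},
                "lnPD_mean": {str(k): _round(v, 2) for k, v in sel.lnPD_mean.items()},
                "note": sel.note,
                "alpha": _round(run.alpha, 4) if run else None,
            }

        # robustness: full vs LD-filtered nuclear clustering
        stage = "ld_robustness"
        logger.info("stage: LD robustness comparison")
        nuc_filtered = cl.build_genotype_matrix(
            nuclear=nuc, gap_mode=gmm, nuclear_filter=filters["nuclear"]
        )
        if nuc_filtered.n_loci >= 2:
            sel_f = cl.select_k(nuc_filtered, config.k_range,
                                replicates=config.replicates,
                                burn_in=config.burn_in, reps=config.reps,
                                seed=config.seed + 77)
            conc = cl.compare_clusterings(
                (selections["nuclear"], first_runs["nuclear"]),
                (sel_f, sel_f.best_run()),
            )
            report["ld_robustness"] = {
                "same_k": conc.same_k,
                "agreement": _round(conc.agreement, 4),
                "n_changed": len(conc.changed_individuals),
            }
        else:
            report["ld_robustness"] = {"note": "filtered matrix too small"}

        stage = "heterozygote_flags"
        het = cl.flag_intercluster_heterozygotes(first_runs["nuclear"]) \
            if first_runs["nuclear"] else []
        report["intercluster_heterozygotes"] = {
            "n_flagged": len(het),
            "fraction": _round(len(het) / len(nuc.individuals), 4),
            "individuals": [ind for ind, _, _ in het],
        }

        if config.run_hierarchical:
            stage = "hierarchical"
            logger.info("stage: hierarchical clustering")
            hier = {}
            for name in ("mito", "nuclear", "combined"):
                res = cl.hierarchical_analysis(
                    matrices[name], config.k_range,
                    threshold=config.assignment_thresholds.get(name, 0.7),
                    min_n=config.hierarchy_min_n,
                    max_depth=config.hierarchy_depth,
                    replicates=config.replicates,
                    burn_in=config.burn_in, reps=config.reps,
                    seed=config.seed + 13,
                )

                def node_dict(node):
                    return {
                        "label": node.label,
                        "n": len(node.individuals),
                        "chosen_K": node.selection.chosen_K if node.selection else None,
                        "unassigned": list(node.unassigned),
                        "note": node.note,
                        "children": [node_dict(c) for c in node.children],
                    }

                hier[name] = node_dict(res.root)
            report["hierarchical"] = hier

        stage = "fstats"
        logger.info("stage: F-statistics")
        meta_by_iso = {}
        for s in nuc.samples:
            meta_by_iso.setdefault(s.isolate_id, s)
        fst_report = {}
        for crit in config.groupings:
            grouping = {
                iso: getattr(meta_by_iso[iso], crit) or "unknown" for iso in isolates
            }
            per_locus = {}
            for ds in (mito, nuc):
                n_groups = len(set(grouping.values()))
                res = fs.amova(ds, grouping if n_groups > 1 else None, gmd,
                               n_perm=config.n_perm, seed=config.seed + 29)
                per_locus[ds.locus_name] = {
                    "levels": list(res.level_names),
                    "variance_components": [_round(v) for v in res.variance_components],
                    "percentages": [_round(p, 2) for p in res.percentages],
                    "phi": {k: _round(v, 4) for k, v in res.phi.items()},
                    "p_values": {k: _round(v, 4) for k, v in res.p_values.items()},
                    "notes": list(res.notes),
                }
            fst_report[crit] = per_locus
        report["amova"] = fst_report
        fis_res = fs.fis(nuc, None, gmd, n_perm=config.n_perm,
                         seed=config.seed + 31)
        report["fis_per_isolate"] = {
            iso: {"fis": _round(v[0], 4), "p": _round(v[1], 4)}
            for iso, v in fis_res.items()
        }

        stage = "mismatch"
        logger.info("stage: mismatch distributions")
        mism = {}
        fits: dict[str, dict[str, mm.MismatchFit | None]] = {"mito": {}, "nuclear": {}}
        for locus, ds in (("mito", mito), ("nuclear", nuc)):
            tab = tables[(locus, gmd)]
            for iso in isolates:
                seqs = ds.sequences_for_isolate(iso)
                dist = mm.mismatch_distribution(seqs, gmd, unit_id=iso)
                profile = mm.classify_profile(dist, tab, iso)
                fit = None
                if dist.jmax >= 1 and len(np.nonzero(dist.frequencies)[0]) >= 2:
                    fit = mm.fit_sudden_expansion(dist, seed=config.seed + 41)
                    if config.run_mismatch_bootstrap:
                        fit = mm.goodness_of_fit(
                            dist, fit, n_bootstrap=config.mismatch_bootstrap,
                            seed=config.seed + 43,
                        )
                fits[locus][iso] = fit
                mism.setdefault(locus, {})[iso] = {
                    "counts": list(dist.counts),
                    "profile": profile,
                    "tau": _round(fit.tau, 3) if fit else None,
                    "theta0": _round(fit.theta0, 3) if fit else None,
                    "theta1": _round(fit.theta1, 1) if fit else None,
                    "SSD": _round(fit.SSD, 5) if fit else None,
                    "p_ssd": _round(fit.p_ssd, 4) if fit else None,
                    "raggedness": _round(fit.raggedness, 4) if fit else None,
                    "p_raggedness": _round(fit.p_raggedness, 4) if fit else None,
                }
        report["mismatch"] = mism

        stage = "profiles"
        logger.info("stage: genetic profiles")
        mito_table = tables[("mito", gmd)]
        nuc_run = first_runs["nuclear"]
        gp_report = {}
        iso_of = dict(zip(matrices["nuclear"].individuals, matrices["nuclear"].isolates))
        for iso in isolates:
            smaj = pf.s_maj(mito_table, iso)
            kt1 = (pf.k_t1(nuc_run, iso_of, iso) if nuc_run is not None else 1)
            mito_run = first_runs["mito"]
            majority = None
            if mito_run is not None:
                rows = [i for i, ind in enumerate(mito_run.individuals)
                        if iso_of.get(ind) == iso]
                if rows:
                    majority = f"cluster_{int(np.bincount(mito_run.Q[rows].argmax(axis=1)).argmax())}"
            summary = pf.IsolateSummary(
                isolate_id=iso,
                mito=div["mito"][iso],
                nuc=div["nuclear"][iso],
                pi_ratio=flags[iso],
                k_t1=kt1,
                s_maj=smaj,
                majority_lineage=majority,
                mismatch_mito=fits["mito"][iso],
                mismatch_nuc=fits["nuclear"][iso],
                habitat=meta_by_iso[iso].habitat,
            )
            gp = pf.classify_gp(summary)
            gp_report[iso] = {
                "gp": gp.gp,
                "matches": list(gp.matches),
                "ambiguous": gp.ambiguous,
                "S_maj": smaj,
                "K_T1": kt1,
                "majority_lineage": majority,
            }
        report["genetic_profiles"] = gp_report
    except Exception as exc:  # noqa: BLE001
        logger.exception("stage %s failed", stage)
        (out / "report_partial.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(fh)
        fh.close()

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "summary.txt").write_text(_text_summary(report))
    return report


def _text_summary(report: dict) -> str:
    lines = [
        "mito-nuclear analysis summary",
        "=============================",
        f"individuals: {report.get('n_individuals')}  "
        f"isolates: {len(report.get('isolates', []))}",
        f"input hash: {report.get('input_hash')}",
        "",
    ]
    for name, c in report.get("clustering", {}).items():
        lines.append(
            f"{name}: K={c['chosen_K']} (reliable={c['reliable']}) "
            f"alpha={c.get('alpha')}"
        )
    het = report.get("intercluster_heterozygotes", {})
    lines.append(
        f"inter-cluster heterozygotes: {het.get('n_flagged', 0)} "
        f"({100 * (het.get('fraction') or 0):.1f}%)"
    )
    lines.append("")
    lines.append("isolate  GP  K_T1  S_maj  pi_ratio_flag")
    flags = report.get("pi_ratio_flags", {})
    for iso, row in report.get("genetic_profiles", {}).items():
        lines.append(
            f"{iso:8s} {str(row['gp']):4s} {row['K_T1']:4d}  "
            f"{str(row['S_maj']):5s}  {flags.get(iso, {}).get('flag')}"
        )
    return "\n".join(lines) + "\n"
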