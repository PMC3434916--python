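"""End-to-end analysis pipeline: load/generate -> hybrid filter -> summary
statistics -> neutrality tests -> population structure -> IM fit -> nested
models -> demographic conversions -> demographic-null Tajima retest.

One global seed deterministically derives a seed per stage (hash of the stage
name), so full reruns with the same configuration reproduce every artifact.
Optional stages degrade gracefully: MK/HKA are skipped without an outgroup and
the IM stages are skipped without two group labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coalsim, im_infer, neutrality, popstruct, sumstats, synthetic_data
from .seq_core import MultiLocusDataset, flag_hybrids, load_dataset

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Pipeline configuration; persisted verbatim into the output directory."""

    outdir: str = "sundapop_run"
    seed: int = 0
    # input: either a generator scenario or file paths
    scenario: str | None = "paper_like"  # paper_like / two_pop_recovery / None
    scenario_kwargs: dict = field(default_factory=dict)
    fasta_paths: dict | None = None
    popmap_path: str | None = None
    annotation_path: str | None = None
    # stage settings (desk-scale defaults; study-scale values can be set here)
    tajima_reps: int = 2000
    structure_k_range: tuple[int, int] = (1, 4)
    structure_runs: int = 5
    structure_burnin: int = 5000
    structure_reps: int = 20000
    group_max_diff: int = 0
    im_settings: dict = field(default_factory=dict)
    im_priors: dict = field(default_factory=dict)
    nested_models: list | None = None
    null_reps: int = 500
    u_syn_min: float = 0.7e-9
    u_syn_max: float = 2.61e-9
    gen_years: float = 60.0
    min_hybrid_loci: int | None = None
    run_im: bool = True
    run_structure: bool = True
    compute_rho: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.__dict__, default_flow_style=False))
    report: dict = {"stages": {}, "warnings": [], "seed": config.seed}

    # ---- input stage -------------------------------------------------------
    refs = None
    if config.scenario is not None:
        sc = (
            synthetic_data.paper_like(**config.scenario_kwargs)
            if config.scenario == "paper_like"
            else synthetic_data.two_pop_recovery(**config.scenario_kwargs)
        )
        gen = synthetic_data.generate(sc, seed=stage_seed(config.seed, "generate"))
        ds = gen.dataset
        refs = gen.refs
        (out / "truth_manifest.json").write_text(json.dumps(gen.manifest, indent=2, default=str))
    else:
        ds = load_dataset(config.fasta_paths, config.popmap_path, config.annotation_path)
    report["stages"]["input"] = {
        "individuals": len(ds.individuals),
        "loci": {a.locus_name: a.aligned_length for a in ds.loci},
    }

    # ---- hybrid filter -----------------------------------------------------
    if refs:
        hyb_report, ds = flag_hybrids(ds, refs, min_loci=config.min_hybrid_loci)
        report["stages"]["hybrid_filter"] = {
            "flagged": hyb_report.flagged_individuals,
            "haplotypes_per_locus": 2 * len(ds.individuals),
        }
    else:
        report["stages"]["hybrid_filter"] = {"skipped": "no reference haplotypes"}

    # ---- summary statistics ------------------------------------------------
    table = sumstats.population_table(ds)
    table.to_csv(out / "summary_stats.tsv", sep="\t", index=False)
    report["stages"]["sumstats"] = {"rows": len(table)}
    if config.compute_rho:
        rho = {}
        for aln in ds.loci:
            rho[aln.locus_name] = coalsim.estimate_rho(
                aln, seed=stage_seed(config.seed, f"rho:{aln.locus_name}"), cache_dir=out / "cache"
            )
        pd.Series(rho, name="rho_per_site").to_csv(out / "rho.tsv", sep="\t")
        report["stages"]["rho"] = rho

    # ---- neutrality --------------------------------------------------------
    taj_rows = []
    observed_d: dict[str, list[float | None]] = {"pooled": [], "sm": [], "b": []}
    group_inds = {
        "sm": ds.popmap.individuals_of_group("sumatra_malay"),
        "b": ds.popmap.individuals_of_group("borneo"),
    }
    for aln in ds.loci:
        for label, inds in (("Total", None), ("sm", group_inds["sm"]), ("b", group_inds["b"])):
            if inds is not None and len(inds) < 2:
                continue
            res = neutrality.tajima_test(
                aln,
                inds,
                reps=config.tajima_reps,
                seed=stage_seed(config.seed, f"tajima:{aln.locus_name}:{label}"),
            )
            taj_rows.append(
                {
                    "locus": aln.locus_name,
                    "sample": label,
                    "D": res.D,
                    "S": res.S,
                    "n": res.n,
                    "lo": res.null_interval[0] if res.null_interval else None,
                    "hi": res.null_interval[1] if res.null_interval else None,
                    "p": res.p_two_sided,
                }
            )
            key = {"Total": "pooled", "sm": "sm", "b": "b"}[label]
            observed_d[key].append(res.D)
    pd.DataFrame(taj_rows).to_csv(out / "tajima.tsv", sep="\t", index=False)
    ml = neutrality.multilocus_d_test(
        ds, reps=config.tajima_reps, seed=stage_seed(config.seed, "multilocus_d")
    )
    report["stages"]["tajima"] = {
        "multilocus_average_D": ml["observed_average_D"],
        "multilocus_p": ml["p_two_sided"],
    }

    if ds.outgroups:
        mk_rows = []
        for aln in ds.loci:
            if aln.locus_name not in ds.outgroups:
                continue
            counts = neutrality.mk_counts(aln, ds.outgroups[aln.locus_name])
            mk = neutrality.mk_test(**counts)
            mk_rows.append({"locus": aln.locus_name, **counts, "fisher_p": mk.fisher_p, "g_p": mk.g_p})
        pd.DataFrame(mk_rows).to_csv(out / "mk_test.tsv", sep="\t", index=False)
        report["stages"]["mk"] = {r["locus"]: r["fisher_p"] for r in mk_rows}
        try:
            hka = neutrality.hka_from_dataset(ds)
            report["stages"]["hka"] = {"chi2": hka.chi2_total, "df": hka.df, "p": hka.p}
        except ValueError as exc:
            report["stages"]["hka"] = {"skipped": str(exc)}
    else:
        report["stages"]["mk"] = {"skipped": "no outgroup"}
        report["stages"]["hka"] = {"skipped": "no outgroup"}

    # ---- population structure ---------------------------------------------
    if config.run_structure:
        fst = popstruct.fst_matrix(ds)
        with open(out / "fst.tsv", "w") as fh:
            for locus_name, m in fst.items():
                fh.write(f"# {locus_name}\n")
                m.to_csv(fh, sep="\t")
        dm = popstruct.da_matrix(ds)
        pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(
            out / "da.tsv", sep="\t"
        )
        if len(dm.labels) >= 3:
            newick = popstruct.nj_tree(dm)
            (out / "tree.nwk").write_text(newick + "\n")
        else:
            newick = None
            logger.info("fewer than 3 populations: NJ tree skipped")
        alleles, individuals = popstruct.dataset_to_alleles(ds, max_diff=config.group_max_diff)
        runs: dict[int, list] = {}
        k_lo, k_hi = config.structure_k_range
        for K in range(k_lo, k_hi + 1):
            runs[K] = [
                popstruct.admixture_fit(
                    alleles,
                    K,
                    burn_in=config.structure_burnin,
                    reps=config.structure_reps,
                    seed=stage_seed(config.seed, f"structure:K{K}:r{r}"),
                )
                for r in range(config.structure_runs)
            ]
        dk = popstruct.select_k(runs)
        dk.table.to_csv(out / "delta_k.tsv", sep="\t", index=False)
        best_runs = runs[dk.selected_k]
        best = max(best_runs, key=lambda r: r.lnP)
        pd.DataFrame(
            best.Q, index=individuals, columns=[f"cluster{j + 1}" for j in range(best.K)]
        ).to_csv(out / "q_matrix.tsv", sep="\t")
        report["stages"]["structure"] = {
            "selected_k": dk.selected_k,
            "delta_k": dict(zip(dk.table["K"], dk.table["delta_k"])),
            "newick": newick,
        }
    else:
        report["stages"]["structure"] = {"skipped": "disabled"}

    # ---- IM inference ------------------------------------------------------
    groups = set(ds.popmap.group.values()) - {"unassigned"}
    if config.run_im and groups == {"sumatra_malay", "borneo"}:
        obs_vec, cfg = im_infer.observed_im_summaries(ds)
        fit = im_infer.fit_im_from_summaries(
            obs_vec,
            cfg,
            priors=config.im_priors or None,
            settings=config.im_settings or None,
            seed=stage_seed(config.seed, "im_fit"),
        )
        est = fit.estimates
        report["stages"]["im_fit"] = {
            "estimates": dict(zip(coalsim.PARAM_NAMES, est.as_array().tolist())),
            "hpd90": {k: list(v) for k, v in fit.hpd.items()},
            "max_loglik": fit.max_loglik,
            "blocks": {k: list(v) for k, v in fit.config.blocks.items()},
            "boundary_flags": fit.boundary_flags,
        }
        (out / "im_fit.json").write_text(json.dumps(report["stages"]["im_fit"], indent=2))

        nested = im_infer.nested_model_tests(
            fit, obs_vec=obs_vec, models=config.nested_models
        )
        nested_rows = [
            {
                "model": t.model,
                "llr": t.llr,
                "reference": t.reference,
                "p": t.p,
                "rejected": t.rejected,
            }
            for t in nested.tests.values()
        ]
        pd.DataFrame(nested_rows).to_csv(out / "nested_tests.tsv", sep="\t", index=False)
        report["stages"]["nested_tests"] = {
            "isolation_verdict": nested.isolation_verdict,
            "tests": {r["model"]: r["p"] for r in nested_rows},
        }

        # conversions: per-locus silent/replacement sites and Ka/Ks when an
        # outgroup is available, else geometric-mean rates cannot be formed
        from .seq_core import classify_sites

        locus_meta = []
        for aln in ds.loci:
            counts, cls = classify_sites(aln)
            kaks = 0.1
            if aln.locus_name in ds.outgroups:
                try:
                    _, _, ratio = neutrality.ka_ks(aln, ds.outgroups[aln.locus_name][0], cls)
                    kaks = ratio if ratio is not None else 0.1
                except ValueError:
                    pass
            locus_meta.append(
                {
                    "locus": aln.locus_name,
                    "silent_sites": counts.n_silent,
                    "replacement_sites": counts.n_replacement,
                    "ka_ks": max(kaks, 1e-6),
                }
            )
        conv = im_infer.convert_parameters(
            est, config.u_syn_min, config.u_syn_max, config.gen_years, locus_meta
        )
        report["stages"]["conversions"] = conv.as_dict()
        (out / "demographic_table.json").write_text(
            json.dumps(conv.as_dict(), indent=2, default=str)
        )

        null = im_infer.demographic_null_tajima(
            est,
            cfg,
            observed_d,
            reps=config.null_reps,
            seed=stage_seed(config.seed, "demographic_null"),
        )
        report["stages"]["demographic_null"] = null["average"]
        (out / "demographic_null.json").write_text(json.dumps(null, indent=2, default=str))
    else:
        report["stages"]["im_fit"] = {"skipped": "IM disabled or group labels incomplete"}

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
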