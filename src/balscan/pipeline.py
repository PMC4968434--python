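"""End-to-end scan orchestration with structured configuration.

The full scan runs, in order: data load/simulation -> polarization ->
LD pruning -> DAPC with supplementary projection of the disease group ->
per-SNP F_st outlier scan against a genome background -> the neutrality
battery with coalescent p-values and adaptive-BH adjustment -> high-LD
set extraction -> EM phasing of the unphased cohort -> per-group
haplotype frequencies -> median-joining network -> rho TMRCA.  Every
stage writes a TSV; a manifest records parameters and seeds so a run is
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dapc as dapc_mod
from . import fst as fst_mod
from . import io as io_mod
from . import ld as ld_mod
from . import network as net_mod
from . import neutrality as neut_mod
from . import phasing as phase_mod

from .simulate import (
    BackgroundConfig,
    CoalescentConfig,
    DeepCladeConfig,
    make_cohort,
    simulate_background_fst,
    simulate_deep_clades,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "balscan_out",
    "scenario": {
        # reference cohort mirrors a 1000-Genomes-style panel: chromosome
        # counts per continental cluster, clade-A (H1-like) frequencies
        # 0.21 / 0.50 / 0.06, 30 clade-diagnostic sites, and an 18-person
        # disease sample drawn from the European cluster with a mild
        # clade-A enrichment (0.50 -> 0.53)
        "n_per_group": {"AFR": 492, "EUR": 758, "EAS": 572},
        "freq_cladeA": {"AFR": 0.21, "EUR": 0.50, "EAS": 0.06},
        "split_depth": 30,
        "within_clade_S": 8,
        "locus_length": 4000,
        "disease": {"group": "NCWS", "source": "EUR", "n": 18, "enrichment": 0.03},
        "background": {"n_snps": 20000, "fst_target": 0.05},
    },
    "neutrality": {"reps": 10000, "alpha": 0.01},
    "fst": {"estimator": "wright", "percentile": 99.0},
    "ld": {"window_snps": 50, "step_snps": 10, "r2_threshold": 0.1, "high_ld_threshold": 0.95},
    "dapc": {"k": "auto", "n_rand": 30},
    "phase": {"restarts": 10},
    "network": {"epsilon": 0},
    "tmrca": {"fixed_differences": 120, "divergence_time_years": 6.0e6},
}

_ALLOWED = {
    "seed": int,
    "output_dir": str,
    "scenario": dict,
    "neutrality": dict,
    "fst": dict,
    "ld": dict,
    "dapc": dict,
    "phase": dict,
    "network": dict,
    "tmrca": dict,
}


# free-form maps keyed by user-chosen group names
_FREE_FORM = {"scenario.n_per_group", "scenario.freq_cladeA"}


def _merge(base: dict, user: dict, path: str) -> None:
    for k, v in user.items():
        here = f"{path}.{k}" if path else str(k)
        if here in _FREE_FORM:
            base[k] = dict(v)
            continue
        if k not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(v, dict) and isinstance(base[k], dict):
            _merge(base[k], v, here)
        else:
            base[k] = v


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key in user or {}:
        if key not in _ALLOWED:
            raise ConfigError(f"unknown config key {key!r}")
    _merge(cfg, user or {}, "")
    return cfg


def validate_config(path_or_dict) -> dict:
    """Schema/range check; raises ConfigError naming the offending key."""
    if isinstance(path_or_dict, (str, Path)):
        p = Path(path_or_dict)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = path_or_dict or {}
    cfg = merge_config(user)
    ld = cfg["ld"]
    if not 0 < ld["r2_threshold"] < 1:
        raise ConfigError(f"ld.r2_threshold {ld['r2_threshold']} outside (0,1)")
    if not 0 < ld["high_ld_threshold"] <= 1:
        raise ConfigError(f"ld.high_ld_threshold {ld['high_ld_threshold']} outside (0,1]")
    if ld["step_snps"] > ld["window_snps"]:
        raise ConfigError("ld.step_snps exceeds ld.window_snps")
    if not 0 < cfg["fst"]["percentile"] < 100:
        raise ConfigError(f"fst.percentile {cfg['fst']['percentile']} outside (0,100)")
    if cfg["neutrality"]["reps"] < 0:
        raise ConfigError("neutrality.reps must be >= 0")
    if not 0 < cfg["neutrality"]["alpha"] < 1:
        raise ConfigError(f"neutrality.alpha outside (0,1)")
    sc = cfg["scenario"]
    for g, f in sc["freq_cladeA"].items():
        if not 0 <= f <= 1:
            raise ConfigError(f"scenario.freq_cladeA[{g}] outside [0,1]")
    bg = sc["background"]
    if not 0 < bg["fst_target"] < 1:
        raise ConfigError("scenario.background.fst_target outside (0,1)")
    if cfg["tmrca"]["fixed_differences"] <= 0:
        raise ConfigError("tmrca.fixed_differences must be positive")
    return cfg


def run_full_scan(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the whole scan on the configured synthetic scenario.

    Returns a result bundle (in-memory objects plus the paths written).
    All randomness derives from the single global seed via fixed
    per-stage offsets.
    """
    cfg = validate_config(config)
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sc = cfg["scenario"]
    bundle: dict = {"config": cfg}

    stage = "simulate"
    try:
        within = CoalescentConfig(n=2, fixed_S=int(sc["within_clade_S"]))
        dc = DeepCladeConfig(
            freq_cladeA_per_group={g: float(f) for g, f in sc["freq_cladeA"].items()},
            n_per_group={g: int(n) for g, n in sc["n_per_group"].items()},
            split_depth=int(sc["split_depth"]),
            within_clade=within,
            locus_length=int(sc["locus_length"]),
            seed=seed,
        )
        H, clades, groups = simulate_deep_clades(dc)
        dis = sc["disease"]
        G, panel, truth, cohort_H = make_cohort(
            H,
            groups,
            clades,
            disease_group=dis["group"],
            disease_source=dis["source"],
            n_disease=int(dis["n"]),
            disease_enrichment=float(dis["enrichment"]),
            seed=seed + 1,
        )
        panel.to_tsv(outdir / "panel.tsv")
        io_mod.write_vcf(cohort_H, outdir / "cohort.vcf")
        bundle.update(H=H, cohort_H=cohort_H, genotypes=G, panel=panel, clade_truth=truth)

        ref_clusters = list(sc["n_per_group"])
        ref_samples = [s for s in panel.samples if panel.cluster[s] != dis["group"]]
        dis_samples = [s for s in panel.samples if panel.cluster[s] == dis["group"]]
        ref_idx = [i for i, s in enumerate(G.sample_ids) if s in set(ref_samples)]
        dis_idx = [i for i, s in enumerate(G.sample_ids) if s in set(dis_samples)]
        G_ref = G.subset_individuals(ref_idx)
        G_dis = G.subset_individuals(dis_idx)

        stage = "ld_prune"
        prune_cfg = ld_mod.LdPruneConfig(
            window_snps=int(cfg["ld"]["window_snps"]),
            step_snps=int(cfg["ld"]["step_snps"]),
            r2_threshold=float(cfg["ld"]["r2_threshold"]),
        )
        kept = ld_mod.ld_prune(G_ref, prune_cfg)
        (outdir / "pruned_snps.txt").write_text("\n".join(kept) + "\n")
        bundle["pruned_snps"] = kept

        stage = "dapc"
        site_ids = [s.id for s in G.sites]
        kept_idx = [site_ids.index(k) for k in kept]
        y_ref = np.array([panel.cluster[s] for s in G_ref.sample_ids])
        model = dapc_mod.fit_dapc(
            G_ref.subset_sites(kept_idx),
            y_ref,
            k=cfg["dapc"]["k"],
            n_rand=int(cfg["dapc"]["n_rand"]),
            seed=seed + 2,
        )
        post_ref = dapc_mod.posterior_membership(model, G_ref.subset_sites(kept_idx))
        _, post_dis = dapc_mod.project_supplementary(model, G_dis.subset_sites(kept_idx))
        posteriors = pd.concat([post_ref, post_dis])
        posteriors.to_csv(outdir / "dapc_posteriors.tsv", sep="\t")
        summary = dapc_mod.membership_summary(
            pd.concat([post_ref, post_dis]),
            list(y_ref) + [dis["group"]] * len(post_dis),
        )
        summary.to_csv(outdir / "dapc_summary.tsv", sep="\t")
        bundle.update(dapc_model=model, dapc_posteriors=posteriors, dapc_summary=summary)

        stage = "fst_scan"
        bg_cfg = BackgroundConfig(
            n_snps=int(sc["background"]["n_snps"]),
            fst_target=float(sc["background"]["fst_target"]),
            n_per_cluster={c: int(sc["n_per_group"][c]) for c in ref_clusters},
            seed=seed + 3,
        )
        background = simulate_background_fst(bg_cfg, estimator=cfg["fst"]["estimator"])
        ref_H = H  # reference chromosomes only (pre-cohort), labeled by group
        all_records = []
        for i, ca in enumerate(ref_clusters):
            for cb in ref_clusters[i + 1 :]:
                iA = np.flatnonzero(groups == ca)
                iB = np.flatnonzero(groups == cb)
                fvals = fst_mod.fst_per_site(ref_H, iA, iB, estimator=cfg["fst"]["estimator"])
                dA, dB = fst_mod.daf(ref_H, iA), fst_mod.daf(ref_H, iB)
                recs = [
                    fst_mod.FstRecord(site=s, pair=(ca, cb), fst=float(f), daf_A=float(a), daf_B=float(b))
                    for s, f, a, b in zip(ref_H.sites, fvals, dA, dB)
                    if not np.isnan(f)
                ]
                fst_mod.empirical_outliers(
                    recs, background[(ca, cb)], percentile=float(cfg["fst"]["percentile"])
                )
                all_records += recs
        fst_df = fst_mod.records_to_frame(all_records)
        fst_df.to_csv(outdir / "fst_scan.tsv", sep="\t", index=False)
        bundle.update(fst_records=all_records, fst_table=fst_df, background=background)

        stage = "neutrality"
        results = []
        neut_groups = {c: np.flatnonzero(groups == c) for c in ref_clusters}
        for grp, idx in neut_groups.items():
            Hg = H.subset_chromosomes(idx)
            results.append(
                neut_mod.neutrality_battery(
                    Hg,
                    locus="locus1",
                    locus_length=int(sc["locus_length"]),
                    group=grp,
                    reps=int(cfg["neutrality"]["reps"]),
                    seed=seed + 10,
                )
            )
        # disease cohort chromosomes
        dis_cols = cohort_H.chromosomes_of(dis_samples)
        if len(dis_cols):
            results.append(
                neut_mod.neutrality_battery(
                    cohort_H.subset_chromosomes(dis_cols),
                    locus="locus1",
                    locus_length=int(sc["locus_length"]),
                    group=dis["group"],
                    reps=int(cfg["neutrality"]["reps"]),
                    seed=seed + 11,
                )
            )
        neut_df = neut_mod.neutrality_table(results, alpha=float(cfg["neutrality"]["alpha"]))
        neut_df.to_csv(outdir / "neutrality.tsv", sep="\t", index=False)
        bundle.update(neutrality_results=results, neutrality_table=neut_df)

        stage = "high_ld_set"
        outlier_ids = sorted(
            {r.site.id for r in all_records if r.outlier},
            key=lambda i: [s.id for s in H.sites].index(i),
        )
        anchors = outlier_ids or [s.id for s in H.sites if s.id.startswith("split")][:1]
        ld_set = ld_mod.high_ld_set(
            H, anchors, threshold=float(cfg["ld"]["high_ld_threshold"])
        )
        pd.DataFrame(
            {"snp": ld_set.members}
        ).assign(anchor=[m in ld_set.anchors for m in ld_set.members]).to_csv(
            outdir / "high_ld_set.tsv", sep="\t", index=False
        )
        bundle["high_ld_set"] = ld_set

        stage = "phase"
        member_idx = [site_ids.index(m) for m in ld_set.members if m in site_ids]
        member_idx = sorted(member_idx)[: phase_mod.MAX_SITES]
        freqs = phase_mod.em_haplotype_frequencies(
            G_dis.subset_sites(member_idx),
            restarts=int(cfg["phase"]["restarts"]),
            seed=seed + 4,
        )
        hs = phase_mod.assign_phase(G_dis.subset_sites(member_idx), freqs)
        bundle["phased_disease"] = hs

        stage = "hapfreq"
        # reference chromosomes are already phased; merge with phased cohort
        ref_sub = H.subset_sites(member_idx)
        ref_counts = {}
        for j in range(ref_sub.n_chromosomes):
            hstr = "".join(str(int(x)) for x in ref_sub.data[:, j])
            g = str(groups[j])
            ref_counts.setdefault(hstr, {}).setdefault(g, 0)
            ref_counts[hstr][g] += 1
        for sid, (h1, h2, _) in hs.assignments.items():
            for hstr in (h1, h2):
                ref_counts.setdefault(hstr, {}).setdefault(dis["group"], 0)
                ref_counts[hstr][dis["group"]] += 1
        freq_table = _counts_to_freq_table(ref_counts)
        freq_table.to_csv(outdir / "haplotype_freqs.tsv", sep="\t")
        bundle["haplotype_freqs"] = freq_table

        stage = "network"
        member_sites = [H.sites[i].id for i in member_idx]
        net = net_mod.build_mj_network(
            ref_counts, epsilon=int(cfg["network"]["epsilon"]), site_ids=member_sites
        )
        outgroup = "0" * len(member_idx)  # all-ancestral outgroup haplotype
        net = net_mod.root_by_outgroup(net, outgroup)
        io_mod.write_network(net, outdir / "network.gml", format="gml")
        bundle["network"] = net

        stage = "tmrca"
        calib = net_mod.CalibrationInfo(
            fixed_differences=int(cfg["tmrca"]["fixed_differences"]),
            divergence_time_years=float(cfg["tmrca"]["divergence_time_years"]),
            locus_length=int(sc["locus_length"]),
        )
        est = net_mod.rho_tmrca(net, calib)
        pd.DataFrame(
            [
                {
                    "rho": est.rho,
                    "sigma_rho": est.sigma_rho,
                    "rate_per_year": calib.rate_per_year,
                    "tmrca_years": est.tmrca_years,
                    "ci_low_years": est.ci_years[0],
                    "ci_high_years": est.ci_years[1],
                }
            ]
        ).to_csv(outdir / "tmrca.tsv", sep="\t", index=False)
        bundle["tmrca"] = est

        manifest = {
            "package": "balscan",
            "seed": seed,
            "stage_seeds": {
                "simulate": seed,
                "cohort": seed + 1,
                "dapc": seed + 2,
                "background": seed + 3,
                "phase": seed + 4,
                "neutrality": [seed + 10, seed + 11],
            },
            "config": cfg,
            "outputs": sorted(p.name for p in outdir.iterdir()),
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        bundle["manifest"] = manifest
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return bundle


def _counts_to_freq_table(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    groups = sorted({g for d in counts.values() for g in d})
    rows = {}
    for h, d in sorted(counts.items()):
        rows[h] = {g: d.get(g, 0) for g in groups}
    df = pd.DataFrame(rows).T
    return df / df.sum(axis=0)
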