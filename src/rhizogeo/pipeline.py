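"""End-to-end analysis pipeline.

Runs harmonize -> concatenate -> tree + bootstrap supports -> genospecies /
symbiovar assignment -> diversity -> cross-tabulation and composition test
-> spatial statistics (Mantel, PCoA, sliding windows, PERMANOVA) ->
optional per-locus congruence tests, from a single config. Housekeeping and
symbiotic analyses always run separately. All stages are seeded and the
JSON summary is byte-identical across reruns with the same config.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import diversity_metrics as div
from .errors import RhizogeoError
from . import genospecies_assign as ga
from . import msa_core, phylogeo_stats, synthetic_study, tree_infer
from .likelihood_engine import SubstitutionModel, congruence_test

log = logging.getLogger("rhizogeo")

DEFAULTS = {
    "support_threshold": 60.0,
    "bootstrap_reps": 100,
    "mantel_perms": 999,
    "window": {"width_km": 80.0, "step_km": 10.0, "n_resamples": 1},
    "permanova_perms": 999,
    "congruence": {"enabled": False, "n_bootstrap": 100, "model": "K2P+G"},
    "seed": 0,
}

_MODEL_FACTORY = {
    "JC69": lambda: SubstitutionModel.jc69(),
    "K2P": lambda: SubstitutionModel.k2p(),
    "K2P+G": lambda: SubstitutionModel.k2p(gamma_shape=0.5),
    "T92+G": lambda: SubstitutionModel.t92(gamma_shape=0.5),
    "GTR+G": lambda: SubstitutionModel.gtr(gamma_shape=0.5),
    "GTR+G+I": lambda: SubstitutionModel.gtr(gamma_shape=0.5,
                                             p_invariant=0.1),
}


def _merged(config: dict) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _load_inputs(cfg: dict):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", cfg["seed"])
        study = synthetic_study.simulate_study(
            synthetic_study.StudyConfig(**sim))
        hk = study.hk_loci()
        sym = study.sym_locus()
        meta = ga.validate_metadata(study.metadata)
        return hk, sym, meta, study
    paths = cfg["inputs"]
    hk = [msa_core.read_fasta(p, locus_name=name)
          for name, p in paths["hk_loci"].items()]
    sym = msa_core.read_fasta(paths["sym_locus"]["path"],
                              locus_name=paths["sym_locus"]["name"])
    meta = ga.validate_metadata(pd.read_csv(paths["metadata"]))
    return hk, sym, meta, None


def _analyse_level(loci, meta, cfg, seed, label):
    """Concatenate, build NJ tree, bootstrap, root, assign. Returns dict."""
    harmonized = msa_core.harmonize(loci, "intersection",
                                    trim=cfg.get("trim"))
    concat = msa_core.concatenate(harmonized)
    aln = concat.as_locus_alignment(label)
    builder = tree_infer.nj_builder()
    tree = tree_infer.bootstrap_supports(
        aln, builder, n_replicates=int(cfg["bootstrap_reps"]),
        seed=np.random.default_rng(seed))
    rooted = tree_infer.root_tree(tree, outgroup=cfg.get("outgroup"))
    assignment = ga.assign_clades(rooted, meta,
                                  support_threshold=cfg["support_threshold"])
    return {"concat": concat, "aln": aln, "tree": rooted,
            "assignment": assignment, "harmonized": harmonized}


def _diversity_tables(level: dict, meta, loci) -> pd.DataFrame:
    aln = level["aln"]
    labels = level["assignment"].labels
    rows = []
    for group in sorted(set(labels.values())):
        ids = [s for s, l in labels.items() if l == group]
        row = {"group": group, "n": len(ids)}
        if len(ids) >= 2:
            row["nucleotide"] = div.nucleotide_diversity(aln, ids)
            row["locus"] = div.locus_diversity(loci, ids)
        rows.append(row)
    return pd.DataFrame(rows)


def _group_diversity(level: dict, meta, loci) -> pd.DataFrame:
    """Collection-level diversity (Table-4 layout): nucleotide, locus,
    Shannon and Simpson over genospecies counts."""
    aln = level["aln"]
    labels = level["assignment"].labels
    ref_ids = [s for s in meta.index
               if meta.loc[s, "collection"] == "reference" and s in aln.rows]
    groups = {
        "references": ref_ids,
        "current": [s for s in labels if meta.loc[s, "collection"] == "current"],
        "previous": [s for s in labels if meta.loc[s, "collection"] == "previous"],
    }
    groups["all_local"] = groups["current"] + groups["previous"]
    rows = []
    for name, ids in groups.items():
        row = {"group": name, "n": len(ids)}
        if len(ids) >= 2:
            row["nucleotide"] = div.nucleotide_diversity(aln, ids)
            row["locus"] = div.locus_diversity(loci, ids)
            if name == "references":
                counts = meta.loc[ids, "reference_species"].value_counts()
            else:
                counts = pd.Series([labels[s] for s in ids]).value_counts()
            sp = div.species_diversity(counts.to_dict())
            row.update(sp)
        rows.append(row)
    return pd.DataFrame(rows)


def _spatial_stats(level: dict, meta, loci, cfg, seed) -> dict:
    labels = level["assignment"].labels
    local = [s for s in labels if pd.notna(meta.loc[s, "latitude"])]
    sub_meta = meta.loc[local]
    d_geo = phylogeo_stats.geo_distance(sub_meta)
    ids = d_geo.labels
    aln = level["aln"]
    d_nuc = msa_core.p_distance(aln.subset(ids))
    mlh = {a.locus_name: div.haplotypes(a, [i for i in ids if i in a.rows])
           for a in loci}
    d_hap = div.allele_sharing_distance(mlh).submatrix(ids)
    d_sp = phylogeo_stats.species_distance(labels, ids)
    d_ph = phylogeo_stats.value_distance(sub_meta.loc[ids, "soil_pH"], ids)
    d_alt = phylogeo_stats.value_distance(sub_meta.loc[ids, "elevation"], ids)
    src = (sub_meta.loc[ids, "collection"] == "previous").astype(float)
    d_src = phylogeo_stats.value_distance(src, ids)

    nperm = int(cfg["mantel_perms"])
    ss = np.random.SeedSequence(seed).spawn(64)
    k = iter(range(64))
    mantel_rows = []
    levels = {"nucleotide": d_nuc, "haplotype": d_hap, "species": d_sp}
    for lname, d_gen in levels.items():
        for cov_name, d2 in (("Geo", d_geo), ("Source", d_src),
                             ("pH", d_ph), ("Alt", d_alt)):
            row = {"level": lname, "D2": cov_name, "Cov": ""}
            try:
                res = phylogeo_stats.mantel(
                    d_gen, d2, n_perm=nperm,
                    seed=int(ss[next(k)].generate_state(1)[0] % 2**31))
                row.update(r=res.r, p=res.p_value)
            except RhizogeoError as exc:  # e.g. constant matrix at one level
                log.warning("mantel %s~%s undefined: %s", lname, cov_name, exc)
                row.update(r=np.nan, p=np.nan)
            mantel_rows.append(row)
        row = {"level": lname, "D2": "Geo", "Cov": "Source"}
        try:
            res = phylogeo_stats.partial_mantel(
                d_gen, d_geo, d_src, n_perm=nperm,
                seed=int(ss[next(k)].generate_state(1)[0] % 2**31),
                covariate_name="Source")
            row.update(r=res.r, p=res.p_value)
        except RhizogeoError as exc:
            log.warning("partial mantel %s undefined: %s", lname, exc)
            row.update(r=np.nan, p=np.nan)
        mantel_rows.append(row)
    mantel_table = pd.DataFrame(mantel_rows)

    pc = phylogeo_stats.pcoa(d_nuc, n_axes=2)
    w = cfg["window"]
    curves = {}
    for lname, d_gen in levels.items():
        curves[lname] = phylogeo_stats.sliding_window(
            d_geo, d_gen, level=lname, width_km=float(w["width_km"]),
            step_km=float(w["step_km"]),
            n_resamples=int(w.get("n_resamples", 1)),
            seed=int(ss[next(k)].generate_state(1)[0] % 2**31))
    covars = sub_meta.loc[ids, ["longitude", "latitude", "elevation",
                                "soil_pH"]]
    covars.columns = ["Long", "Lat", "Alt", "pH"]
    perman = phylogeo_stats.permanova(
        d_nuc, covars, n_perm=int(cfg["permanova_perms"]),
        seed=int(ss[next(k)].generate_state(1)[0] % 2**31))
    return {"mantel": mantel_table, "pcoa": pc, "windows": curves,
            "permanova": perman, "d_geo": d_geo}


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the full analysis; write artifacts under ``outdir``.

    Returns the machine-readable summary (also written as summary.json).
    Raises on any stage error (the pipeline never silently skips a stage
    that was enabled).
    """
    cfg = _merged(config)
    os.makedirs(outdir, exist_ok=True)
    master = int(cfg["seed"])
    seeds = {name: int(s.generate_state(1)[0] % 2**31)
             for name, s in zip(
                 ["hk_boot", "sym_boot", "spatial", "composition"],
                 np.random.SeedSequence(master).spawn(4))}

    hk_loci, sym_locus, meta, study = _load_inputs(cfg)
    log.info("inputs: %d hk loci, sym locus %s, %d strains",
             len(hk_loci), sym_locus.locus_name, len(meta))

    hk = _analyse_level(hk_loci, meta, cfg, seeds["hk_boot"], "hk_concat")
    sym = _analyse_level([sym_locus], meta, cfg, seeds["sym_boot"], "sym")

    n_no_sym = len(set(hk["assignment"].labels) - set(sym["assignment"].labels))
    if n_no_sym:
        log.info("%d strains lack the symbiotic locus; dropped from cross-tab",
                 n_no_sym)
    crosstab = ga.cross_tabulate(hk["assignment"], sym["assignment"])

    # composition: collections x genospecies
    labels = hk["assignment"].labels
    colls = sorted({meta.loc[s, "collection"] for s in labels})
    cats = sorted(set(labels.values()))
    comp = np.array([[sum(1 for s in labels
                          if labels[s] == c and meta.loc[s, "collection"] == co)
                      for c in cats] for co in colls])
    comp_p = ga.composition_test(comp[:2], seed=seeds["composition"]) \
        if len(colls) >= 2 else float("nan")

    div_hk = _diversity_tables(hk, meta, hk["harmonized"])
    div_sym = _diversity_tables(sym, meta, sym["harmonized"])
    grp_hk = _group_diversity(hk, meta, hk["harmonized"])
    spatial = _spatial_stats(hk, meta, hk["harmonized"], cfg, seeds["spatial"])

    congruence_out = []
    if cfg["congruence"]["enabled"]:
        model = _MODEL_FACTORY[cfg["congruence"].get("model", "K2P+G")]()
        ref_tree = hk["tree"]
        css = np.random.SeedSequence(master + 1).spawn(len(hk_loci) + 1)
        for a, s in zip(hk_loci + [sym_locus], css):
            res = congruence_test(
                a, ref_tree, model,
                n_bootstrap=int(cfg["congruence"]["n_bootstrap"]),
                seed=np.random.default_rng(
                    int(s.generate_state(1)[0] % 2**31)))
            congruence_out.append(res)

    # ---- artifacts ----------------------------------------------------------
    hk["assignment"].to_dataframe().to_csv(
        os.path.join(outdir, "assignment_hk.csv"), index=False)
    sym["assignment"].to_dataframe().to_csv(
        os.path.join(outdir, "assignment_sym.csv"), index=False)
    crosstab.to_csv(os.path.join(outdir, "crosstab.csv"))
    div_hk.to_csv(os.path.join(outdir, "diversity_hk.csv"), index=False)
    div_sym.to_csv(os.path.join(outdir, "diversity_sym.csv"), index=False)
    grp_hk.to_csv(os.path.join(outdir, "diversity_groups.csv"), index=False)
    spatial["mantel"].to_csv(os.path.join(outdir, "mantel.csv"), index=False)
    spatial["permanova"].table.to_csv(os.path.join(outdir, "permanova.csv"))
    pd.DataFrame(spatial["pcoa"].coordinates,
                 index=spatial["pcoa"].labels).to_csv(
        os.path.join(outdir, "pcoa.csv"))
    for lname, curve in spatial["windows"].items():
        pd.DataFrame({"center_km": curve.window_centers,
                      "observed": curve.observed, "null": curve.null,
                      "n_pairs": curve.pair_counts}).to_csv(
            os.path.join(outdir, f"window_{lname}.csv"), index=False)
    tree_infer.write_newick(hk["tree"], os.path.join(outdir, "tree_hk.nwk"))
    tree_infer.write_newick(sym["tree"], os.path.join(outdir, "tree_sym.nwk"))
    if study is not None:
        study.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)

    summary = {
        "config": cfg,
        "n_strains": int(len(meta)),
        "hk_concat_columns": int(hk["concat"].n_columns),
        "n_genospecies": len({l for l in labels.values()
                              if not l.startswith("unclustered")}),
        "crosstab_total": int(crosstab.loc["Total", "Total"]),
        "n_dropped_from_crosstab": int(crosstab.attrs["n_dropped"]),
        "composition_p": None if np.isnan(comp_p) else round(float(comp_p), 6),
        "mantel": [
            {k: (None if isinstance(v, float) and np.isnan(v)
                 else round(v, 6) if isinstance(v, float) else v)
             for k, v in row.items()}
            for row in spatial["mantel"].to_dict("records")],
        "congruence": [
            {"locus": r.locus_name, "delta": round(r.delta, 4),
             "p_value": round(r.p_value, 6)} for r in congruence_out],
        "seeds": seeds,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
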