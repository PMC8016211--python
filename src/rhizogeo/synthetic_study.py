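"""Synthetic multilocus studies with known ground truth.

Generates the full input bundle the pipeline consumes — per-locus FASTA,
strain metadata with geography and soil pH, and a hidden truth table — by
simulating sequences along a genospecies tree. The defaults emulate a
regional survey of common-bean-nodulating rhizobia: ~95 strains in 8
genospecies dominated by two lineages, four housekeeping loci on a clonal
tree plus one symbiotic locus subject to horizontal transfer, two
collections sampled in a few-hundred-km region with contrasting soil pH
ranges, and a reference panel of distinct deep lineages (one per
genospecies, plus off-panel species absent from the local sample).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .likelihood_engine import LikTree, SubstitutionModel, _Node, \
    simulate_alignment
from .msa_core import LocusAlignment

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_WEIGHTS = (0.34, 0.32, 0.09, 0.07, 0.06, 0.05, 0.04, 0.03)


@dataclass
class StudyConfig:
    n_genospecies: int = 8
    n_strains: int = 95
    genospecies_weights: tuple = _DEFAULT_WEIGHTS
    locus_names: tuple = ("locus16S", "glnII", "recA", "rpoB")
    locus_lengths: tuple = (548, 461, 349, 784)
    sym_locus_name: str = "nodC"
    sym_locus_length: int = 465
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel.gtr(
            exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
            base_frequencies=(0.23, 0.27, 0.29, 0.21),
            gamma_shape=0.5))
    between_genospecies_depth: float = 0.05  # root-to-crown, subs/site
    within_genospecies_depth: float = 0.005  # crown-to-tip, subs/site
    hgt_probability: float = 0.3
    spatial_decay: float = 0.0  # lambda; 0 = single uniform field
    region_extent_km: float = 400.0
    collections: dict = field(default_factory=lambda:
                              {"current": 0.76, "previous": 0.24})
    ph_ranges: dict = field(default_factory=lambda:
                            {"current": (4.68, 6.44),
                             "previous": (6.0, 8.78)})
    ph_associated_clade: int | None = 4  # genospecies present only above cutoff
    ph_cutoff: float = 6.5  # just above the current collection's pH ceiling
    sym_absent_clade: int | None = 7  # genospecies lacking the symbiotic locus
    n_offpanel_references: int = 3
    elevation_range_m: tuple = (800.0, 2200.0)
    region_center: tuple = (7.0, 38.5)  # lat, lon (southern Ethiopia)
    seed: int = 0

    def __post_init__(self):
        if self.within_genospecies_depth >= self.between_genospecies_depth:
            raise ConfigError("within-depth must be < between-depth")
        if not 0 <= self.hgt_probability <= 1:
            raise ConfigError("hgt_probability must be in [0, 1]")
        if self.spatial_decay < 0:
            raise ConfigError("spatial_decay must be >= 0")
        if abs(sum(self.collections.values()) - 1.0) > 1e-9:
            raise ConfigError("collection fractions must sum to 1")
        if self.ph_associated_clade is not None:
            admissible = [c for c, (lo, hi) in self.ph_ranges.items()
                          if hi > self.ph_cutoff]
            if not admissible:
                raise ConfigError(
                    "ph_associated_clade has no admissible collection range")
            if self.ph_associated_clade >= self.n_genospecies:
                raise ConfigError("ph_associated_clade out of range")


@dataclass
class SyntheticStudy:
    config: StudyConfig
    loci: dict  # locus name -> LocusAlignment (references included)
    metadata: pd.DataFrame
    truth: pd.DataFrame
    hk_tree_newick: str
    sym_tree_newick: str

    def hk_loci(self) -> list[LocusAlignment]:
        return [self.loci[n] for n in self.config.locus_names]

    def sym_locus(self) -> LocusAlignment:
        return self.loci[self.config.sym_locus_name]


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------

def _random_ultrametric(labels: list[str], depth: float,
                        rng: np.random.Generator) -> _Node:
    """Random-join ultrametric tree of the given tip depth."""
    if len(labels) == 1:
        nd = _Node(labels[0], depth)
        return nd
    nodes = [(_Node(lab), 0.0) for lab in labels]
    m = len(nodes)
    heights = np.sort(rng.uniform(0.15, 1.0, size=m - 1)) * depth
    heights[-1] = depth
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        parent = _Node()
        a.length = max(h - ha, 1e-6)
        b.length = max(h - hb, 1e-6)
        parent.add(a)
        parent.add(b)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, h))
    root = nodes[0][0]
    root.length = 0.0
    return root


def _build_group_tree(groups: dict[str, list[str]], between: float,
                      within: float, rng: np.random.Generator) -> LikTree:
    """Backbone over groups, each tip replaced by a within-group subtree.

    Singleton groups become plain tips at the backbone depth.
    """
    backbone = _random_ultrametric(list(groups), between, rng)
    def replace_tips(nd: _Node):
        for k, child in enumerate(list(nd.children)):
            if child.children:
                replace_tips(child)
            else:
                members = groups[child.name]
                if len(members) == 1:
                    child.name = members[0]
                    child.length += within
                else:
                    sub = _random_ultrametric(members, within, rng)
                    sub.length = child.length
                    nd.children[k] = sub
                    sub.parent = nd
    if not backbone.children:  # single group
        members = groups[backbone.name]
        backbone = _random_ultrametric(members, within, rng)
    else:
        replace_tips(backbone)
    return LikTree(backbone)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def _genospecies_name(g: int) -> str:
    return f"Rhizobium_gsp{g + 1:02d}"


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete study bundle; deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genospecies
    w = np.asarray(config.genospecies_weights[:G], dtype=float)
    w = w / w.sum()

    # --- strains, collections, genospecies -------------------------------
    gsp = rng.choice(G, size=config.n_strains, p=w)
    coll_names = list(config.collections)
    coll_p = np.array([config.collections[c] for c in coll_names])
    collection = rng.choice(len(coll_names), size=config.n_strains, p=coll_p)
    if config.ph_associated_clade is not None:
        admissible = [i for i, c in enumerate(coll_names)
                      if config.ph_ranges[c][1] > config.ph_cutoff]
        for s in np.flatnonzero(gsp == config.ph_associated_clade):
            if collection[s] not in admissible:
                collection[s] = rng.choice(admissible)
    prefix = {"current": "NAE", "previous": "HBR"}
    strain_ids = [f"{prefix.get(coll_names[collection[s]], 'STR')}{s + 1:03d}"
                  for s in range(config.n_strains)]

    # --- reference panel ---------------------------------------------------
    ref_ids, ref_species, ref_gsp = [], [], []
    for g in range(G):
        ref_ids.append(f"REF_{_genospecies_name(g)}")
        ref_species.append(_genospecies_name(g))
        ref_gsp.append(g)
    offpanel = [f"REF_offpanel{k + 1:02d}"
                for k in range(config.n_offpanel_references)]

    # --- housekeeping tree -------------------------------------------------
    groups = {f"g{g}": [sid for sid, gg in zip(strain_ids, gsp) if gg == g]
              + [ref_ids[g]] for g in range(G)}
    for k, op in enumerate(offpanel):
        groups[f"op{k}"] = [op]
    hk_tree = _build_group_tree(groups, config.between_genospecies_depth,
                                config.within_genospecies_depth, rng)

    # --- symbiotic tree: HGT regrafts strains into donor clades -----------
    sym_clade = gsp.copy()
    hgt_flag = rng.random(config.n_strains) < config.hgt_probability
    for s in np.flatnonzero(hgt_flag):
        donors = [g for g in range(G) if g != gsp[s]]
        sym_clade[s] = rng.choice(donors)
    sym_groups = {}
    for g in range(G):
        members = [sid for sid, gg, isin in
                   zip(strain_ids, sym_clade, gsp != config.sym_absent_clade)
                   if gg == g and (config.sym_absent_clade is None or isin)]
        members.append(ref_ids[g])
        sym_groups[f"g{g}"] = members
    for k, op in enumerate(offpanel):
        sym_groups[f"op{k}"] = [op]
    sym_tree = _build_group_tree(sym_groups, config.between_genospecies_depth,
                                 config.within_genospecies_depth, rng)

    # --- sequences ---------------------------------------------------------
    loci: dict[str, LocusAlignment] = {}
    for name, length in zip(config.locus_names, config.locus_lengths):
        loci[name] = simulate_alignment(hk_tree, config.model, length,
                                        seed=rng, locus_name=name)
    loci[config.sym_locus_name] = simulate_alignment(
        sym_tree, config.model, config.sym_locus_length, seed=rng,
        locus_name=config.sym_locus_name)

    # --- geography ---------------------------------------------------------
    ext = config.region_extent_km
    lam = config.spatial_decay
    if lam == 0:
        xy = rng.uniform(0, ext, size=(config.n_strains, 2))
    else:
        centers = rng.uniform(0, ext, size=(G, 2))
        sigma = ext / (1.0 + 3.0 * lam)
        xy = centers[gsp] + rng.normal(0, sigma, size=(config.n_strains, 2))
        xy = np.clip(xy, 0, ext)
    lat0, lon0 = config.region_center
    lat = lat0 + (xy[:, 1] - ext / 2) / 111.195
    lon = lon0 + (xy[:, 0] - ext / 2) / (111.195 * np.cos(np.radians(lat0)))

    # --- pH and elevation ---------------------------------------------------
    ph = np.empty(config.n_strains)
    for s in range(config.n_strains):
        lo, hi = config.ph_ranges[coll_names[collection[s]]]
        if (config.ph_associated_clade is not None
                and gsp[s] == config.ph_associated_clade):
            lo = max(lo, config.ph_cutoff)
        ph[s] = rng.uniform(lo, hi)
    elev = rng.uniform(*config.elevation_range_m, size=config.n_strains)

    # --- tables -------------------------------------------------------------
    meta_rows = []
    truth_rows = []
    for s, sid in enumerate(strain_ids):
        meta_rows.append({
            "strain_id": sid, "collection": coll_names[collection[s]],
            "reference_species": None,
            "latitude": round(float(lat[s]), 6),
            "longitude": round(float(lon[s]), 6),
            "elevation": round(float(elev[s]), 1),
            "soil_pH": round(float(ph[s]), 2),
        })
        truth_rows.append({
            "strain_id": sid,
            "true_genospecies": _genospecies_name(gsp[s]),
            "true_sym_donor": _genospecies_name(sym_clade[s]),
            "hgt": bool(hgt_flag[s]),
            "latitude": round(float(lat[s]), 6),
            "longitude": round(float(lon[s]), 6),
            "soil_pH": round(float(ph[s]), 2),
            "collection": coll_names[collection[s]],
        })
    for rid, rsp in zip(ref_ids, ref_species):
        meta_rows.append({"strain_id": rid, "collection": "reference",
                          "reference_species": rsp, "latitude": None,
                          "longitude": None, "elevation": None,
                          "soil_pH": None})
    for k, op in enumerate(offpanel):
        meta_rows.append({"strain_id": op, "collection": "reference",
                          "reference_species": f"Offpanel_sp{k + 1:02d}",
                          "latitude": None, "longitude": None,
                          "elevation": None, "soil_pH": None})
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)

    return SyntheticStudy(config=config, loci=loci, metadata=metadata,
                          truth=truth, hk_tree_newick=hk_tree.newick(),
                          sym_tree_newick=sym_tree.newick())


def write_study(study: SyntheticStudy, outdir) -> None:
    """Emit locus_<name>.fasta, metadata.csv and truth.csv (harness-only)."""
    import os
    os.makedirs(outdir, exist_ok=True)
    from .msa_core import write_fasta
    for name, aln in study.loci.items():
        write_fasta(aln, os.path.join(outdir, f"locus_{name}.fasta"))
    study.metadata.to_csv(os.path.join(outdir, "metadata.csv"), index=False)
    study.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(assignment_labels: dict[str, str],
                      truth: pd.DataFrame,
                      mantel_p: float | None = None,
                      composition_p: float | None = None,
                      alpha: float = 0.05) -> dict:
    """Compare pipeline outputs with the generating truth.

    Assignment accuracy is the fraction of local strains whose label equals
    the reference species of their true genospecies (labels are matched via
    the reference panel, so "unclustered"/"novel" never count as correct).
    """
    tr = truth.set_index("strain_id")
    n, correct = 0, 0
    for sid, true_g in tr["true_genospecies"].items():
        if sid not in assignment_labels:
            continue
        n += 1
        if assignment_labels[sid] == true_g:
            correct += 1
    out = {"assignment_accuracy": correct / n if n else float("nan"),
           "n_scored": n}
    if mantel_p is not None:
        out["mantel_decision"] = ("structure" if mantel_p <= alpha
                                  else "no structure")
    if composition_p is not None:
        out["composition_decision"] = ("different" if composition_p <= alpha
                                       else "similar")
    return out
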