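"""End-to-end orchestration: params → modules → PCoA → stats → pFDA → ASR.

A single YAML config drives the full study on any directory of adjacency
CSVs plus a metadata TSV (and, for the phylogenetic stages, a Newick
tree). Every stage writes a plain-text artifact into the output directory
and the run manifest records seeds and content digests, so a rerun with
identical inputs and config is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .modules import detect_modules, parcellation
from .morphospace import GowerPCoA, build_param_table, gower_distance, log_transform
from .netio import BoneNetwork, Group, read_adjacency, read_meta
from .netparams import compute_params
from .phylocomp import (asr_bm, juvenile_substitute, parsimony_proxies, pfda,
                        read_tree, split_ontogenetic_tips)
from .stats import ancova_slopes, ks_test, mann_whitney, ols, permanova, relative_sizes


@dataclass
class RunConfig:
    adjacency: list[str]
    meta: str
    outdir: str
    tree: str | None = None
    gtom_order: int = 1
    n_permutations: int = 10000
    seed: int = 0
    lambda_grid_step: float = 0.01
    clades: dict[str, list[str]] = field(default_factory=dict)
    group_column: str = "stage"
    nonbird_taxa: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in self.adjacency if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"adjacency files not found: {missing}")
        if not Path(self.meta).exists():
            raise FileNotFoundError(f"metadata TSV not found: {self.meta}")
        if self.tree and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree not found: {self.tree}")
        if self.n_permutations < 1 or self.gtom_order < 1:
            raise ValueError("n_permutations and gtom_order must be >= 1")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params_for(net: BoneNetwork, gtom_order: int):
    p = compute_params(net)
    part = detect_modules(net, gtom_order=gtom_order)
    p.n_Q_modules = part.n_modules
    p.n_S_modules = part.n_s_modules
    p.Q_max = part.Q
    p.P = parcellation(part.assignment)
    return p, part


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(vars(config)))
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    metas = read_meta(config.meta)
    networks: dict[str, BoneNetwork] = {}
    for path in config.adjacency:
        sid = Path(path).stem
        try:
            networks[sid] = read_adjacency(path, metas.get(sid))
        except Exception as exc:
            raise RuntimeError(f"stage netio failed on specimen {sid}: {exc}") from exc

    # -- stage 1: network parameters + module partitions ----------------
    params, rows = {}, []
    part_dir = out / "partitions"
    part_dir.mkdir(exist_ok=True)
    for sid, net in networks.items():
        try:
            p, part = _params_for(net, config.gtom_order)
        except Exception as exc:
            raise RuntimeError(f"stage params failed on specimen {sid}: {exc}") from exc
        params[sid] = p
        rows.append({"specimen_id": sid, **p.as_dict()})
        (part_dir / f"{sid}.json").write_text(json.dumps({
            "assignment": part.assignment,
            "Q": part.Q,
            "n_modules": part.n_modules,
            "q_curve": part.q_curve,
            "s_pvalues": {str(k): v for k, v in part.s_pvalues.items()},
            "n_s_modules": part.n_s_modules,
            "n_s_modules_innermost": part.n_s_modules_innermost,
        "n_s_modules_total": part.n_s_modules_total,
            "asymmetry": part.asymmetry,
        }, indent=1, sort_keys=True))
    params_df = pd.DataFrame(rows).set_index("specimen_id").sort_index()
    params_df.to_csv(out / "params.csv")
    manifest["stages"]["params"] = _digest(out / "params.csv")

    # -- stage 2: morphospace -------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_param_table(params)
        logged = log_transform(table)
        dist = gower_distance(logged)
    est = GowerPCoA().fit(dist)
    coords = est.coordinates_.sort_index()
    coords.to_csv(out / "pcoa.csv")
    pd.DataFrame({
        "eigenvalue": est.eigenvalues_,
        "variance_fraction": est.variance_fractions_,
    }).to_csv(out / "eigenvalues.csv", index=False)
    manifest["stages"]["pcoa"] = _digest(out / "pcoa.csv")

    # -- stage 3: group comparisons (Table-1 style) ----------------------
    stage_of = {sid: metas[sid].stage.value if sid in metas and metas[sid].stage
                else None for sid in params_df.index}

    def comparison_group(sid: str) -> str | None:
        """Crown birds split by stage; everything else pools by group."""
        m = metas.get(sid)
        if m is None or m.stage is None:
            return None
        if m.group is None or m.group is Group.CROWN_BIRD:
            return f"bird_{m.stage.value}" if m.group else m.stage.value
        return m.group.value

    group_of = {sid: comparison_group(sid) for sid in params_df.index}
    joint = params_df.join(coords)
    groups = pd.Series(group_of, name="group").dropna()
    t1_rows = []
    uniq = sorted(groups.unique())
    for var in joint.columns:
        for i, ga in enumerate(uniq):
            for gb in uniq[i + 1:]:
                xa = joint.loc[groups[groups == ga].index, var].dropna()
                xb = joint.loc[groups[groups == gb].index, var].dropna()
                if len(xa) < 2 or len(xb) < 2:
                    continue
                m = mann_whitney(xa, xb)
                k = ks_test(xa, xb)
                t1_rows.append({
                    "variable": var, "group_a": ga, "group_b": gb,
                    "z": m.statistic, "z_sign": m.sign, "p_mwu": m.p,
                    "D": k.statistic, "p_ks": k.p, "n_a": len(xa), "n_b": len(xb),
                })
    pd.DataFrame(t1_rows).to_csv(out / "table1.csv", index=False)
    manifest["stages"]["table1"] = _digest(out / "table1.csv")

    # -- stage 4: size regressions (Table-2 style) ------------------------
    rel = relative_sizes(metas)
    t2_rows = []

    def is_bird(sid: str) -> bool:
        m = metas.get(sid)
        return m is not None and (m.group is None or m.group is Group.CROWN_BIRD)

    juv = [s for s in joint.index
           if stage_of.get(s) == "juvenile" and s in rel and is_bird(s)]
    ad = [s for s in joint.index
          if stage_of.get(s) == "adult" and s in rel and is_bird(s)]
    if len(juv) >= 3 and len(ad) >= 3:
        for var in joint.columns:
            rj = ols(rel[juv], joint.loc[juv, var])
            ra = ols(rel[ad], joint.loc[ad, var])
            an = ancova_slopes(rel[juv], joint.loc[juv, var],
                               rel[ad], joint.loc[ad, var])
            t2_rows.append({
                "variable": var,
                "slope_juv": rj.slope, "R2_juv": rj.R2, "p_juv": rj.p_slope,
                "slope_ad": ra.slope, "R2_ad": ra.R2, "p_ad": ra.p_slope,
                "ancova_F": an.F, "ancova_p": an.p,
            })
    pd.DataFrame(t2_rows).to_csv(out / "table2.csv", index=False)
    manifest["stages"]["table2"] = _digest(out / "table2.csv")

    # -- stage 5: PERMANOVA on the morphospace ----------------------------
    shared = [s for s in coords.index if group_of.get(s)]
    x = coords.loc[shared].to_numpy()
    d_euc = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    perm = permanova(
        d_euc, [group_of[s] for s in shared],
        n_permutations=config.n_permutations,
        seed=np.random.default_rng(config.seed),
    )
    perm_out = {
        "F": perm.overall.statistic, "p": perm.overall.p,
        "n_permutations": config.n_permutations,
        "pairwise": perm.pairwise.to_dict(orient="records"),
    }
    (out / "permanova.json").write_text(json.dumps(perm_out, indent=1))
    manifest["stages"]["permanova"] = _digest(out / "permanova.json")

    # -- stages 6-7: phylogenetic layer ------------------------------------
    if config.tree:
        tree = read_tree(config.tree)
        pair_taxa = sorted({metas[s].taxon for s in juv}
                           & {metas[s].taxon for s in ad})
        split = split_ontogenetic_tips(
            tree, pair_taxa, nonbird=set(config.nonbird_taxa))
        tipname = {}
        for sid in shared:
            taxon = metas[sid].taxon
            if taxon in pair_taxa:
                tipname[sid] = f"{taxon}_{'juv' if stage_of[sid] == 'juvenile' else 'ad'}"
            else:
                tipname[sid] = taxon
        present = {l.taxon.label for l in split.leaf_node_iter()}
        train_ids = [s for s in shared if metas[s].taxon in pair_taxa
                     and tipname[s] in present]
        test_ids = [s for s in shared if s not in train_ids and tipname[s] in present]
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, config.lambda_grid_step),
                         6)
        n_axes = max(1, min(4, coords.shape[1]))
        train_x = coords.loc[train_ids].iloc[:, :n_axes].copy()
        train_x.index = [tipname[s] for s in train_ids]
        test_x = coords.loc[test_ids].iloc[:, :n_axes].copy()
        test_x.index = [tipname[s] for s in test_ids]
        res = pfda(train_x, [stage_of[s] for s in train_ids], test_x, split,
                   lambda_grid=grid)
        (out / "pfda.json").write_text(json.dumps({
            "lambda": res.lambda_,
            "error": res.error,
            "confusion": res.confusion.to_dict(),
            "posteriors": res.posteriors.round(6).to_dict(orient="index"),
            "predictions": res.predictions.to_dict(),
        }, indent=1, sort_keys=True))
        manifest["stages"]["pfda"] = _digest(out / "pfda.json")

        # ASR of PCo1/PCo2 for adult semaphoronts, and juvenile-substituted
        asr_out = {}
        adult_by_taxon = {metas[s].taxon: s for s in shared
                          if stage_of[s] == "adult"}
        juv_by_taxon = {metas[s].taxon: s for s in shared
                        if stage_of[s] == "juvenile"}
        taxa = [l.taxon.label for l in tree.leaf_node_iter()
                if l.taxon.label in adult_by_taxon]
        for axis in ("PCo1", "PCo2"):
            if axis not in coords.columns:
                continue
            adult_vals = {t: float(coords.loc[adult_by_taxon[t], axis]) for t in taxa}
            adult_asr = asr_bm(tree, adult_vals, clades=config.clades or None)
            entry = {
                "adult": {
                    "sd": adult_asr.sd_proxy,
                    "logprod": adult_asr.logprod_proxy,
                    "logprod_valid": adult_asr.logprod_valid,
                    "root": adult_asr.root_value,
                    "clades": adult_asr.clade_values,
                }
            }
            subst_taxa = [t for t in taxa if t in juv_by_taxon
                          and juv_by_taxon[t] in rel]
            if len(subst_taxa) >= 3:
                jt = pd.Series({t: float(coords.loc[juv_by_taxon[t], axis])
                                for t in subst_taxa})
                rs = pd.Series({t: float(rel[juv_by_taxon[t]]) for t in subst_taxa})
                youngest = rs.idxmin()
                hatch = juvenile_substitute(jt, rs, youngest)
                mixed = dict(adult_vals)
                mixed.update({t: float(v) for t, v in hatch.items()})
                sub_asr = asr_bm(tree, mixed, clades=config.clades or None)
                cmp_ = parsimony_proxies(adult_asr, sub_asr)
                entry["substituted"] = {
                    "sd": sub_asr.sd_proxy,
                    "logprod": sub_asr.logprod_proxy,
                    "logprod_valid": sub_asr.logprod_valid,
                    "root": sub_asr.root_value,
                    "clades": sub_asr.clade_values,
                    "sd_difference": cmp_.sd_difference,
                }
            asr_out[axis] = entry
        (out / "asr.json").write_text(json.dumps(asr_out, indent=1, sort_keys=True))
        manifest["stages"]["asr"] = _digest(out / "asr.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
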