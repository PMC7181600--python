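"""Synthetic skull networks, ontogenetic fusion series, and trait-bearing trees.

The generators emulate the structure of the real study inputs so that every
pipeline stage can be exercised end to end: bilaterally symmetric skulls
with paired (_L/_R) and unpaired midline (_M) bones and planted
connectivity modules; ontogenetic series in which sutures close on a
schedule, monotonically reducing the bone count as relative skull size
grows; and pure-birth clock trees carrying Brownian traits with
juvenile/adult tip pairs. All generators are deterministic given a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .netio import BoneLabel, BoneNetwork, Group, Side, SpecimenMeta, Stage, fuse_bones

# ---------------------------------------------------------------------
# Skull generator


@dataclass
class SkullTemplate:
    """Recipe for a mirror-symmetric skull network with planted modules.

    Defaults give a 28-bone juvenile-like skull (12 left/right pairs plus
    4 midline bones) with three planted modules, dense within-module
    wiring (p_in = 0.9) and sparse between-module wiring (p_out = 0.05).
    """

    n_pairs: int = 12
    n_midline: int = 4
    n_modules: int = 3
    p_in: float = 0.9
    p_out: float = 0.05
    p_pair_contact: float = 0.5  # direct left-right contact of the same bone
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.n_modules < 1 or self.n_pairs < self.n_modules:
            raise ValueError("need at least one bone pair per module")

    def module_plan(self) -> dict[str, int]:
        """Mirror-symmetric planted module of each bone stem name."""
        plan = {}
        for i in range(self.n_pairs):
            plan[f"bone{i:02d}"] = i % self.n_modules
        for j in range(self.n_midline):
            plan[f"mid{j:02d}"] = j % self.n_modules
        return plan


def _pair_labels(template: SkullTemplate) -> list[BoneLabel]:
    labels = []
    for i in range(template.n_pairs):
        labels.append(BoneLabel(f"bone{i:02d}", Side.LEFT))
        labels.append(BoneLabel(f"bone{i:02d}", Side.RIGHT))
    for j in range(template.n_midline):
        labels.append(BoneLabel(f"mid{j:02d}", Side.MIDLINE))
    return labels


def make_skull(template: SkullTemplate, meta: SpecimenMeta | None = None) -> BoneNetwork:
    """Draw one mirror-symmetric, connected skull network.

    Edges among left-side bones (and among midline bones, and between
    midline and left bones) are sampled at p_in within the planted module
    and p_out between modules; the right side is an exact mirror copy.
    Same-bone left-right contacts appear with probability p_pair_contact.
    Connectivity is then enforced by adding the minimal number of
    mirror-symmetric bridging edges between components.
    """
    rng = np.random.default_rng(template.seed)
    labels = _pair_labels(template)
    plan = template.module_plan()
    idx = {str(l): i for i, l in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n), dtype=int)

    def put(u: str, v: str) -> None:
        i, j = idx[u], idx[v]
        a[i, j] = a[j, i] = 1

    def prob(stem_u: str, stem_v: str) -> float:
        return template.p_in if plan[stem_u] == plan[stem_v] else template.p_out

    left = [f"bone{i:02d}" for i in range(template.n_pairs)]
    mid = [f"mid{j:02d}" for j in range(template.n_midline)]
    # left-left (mirrored to right-right)
    for u, v in itertools.combinations(left, 2):
        if rng.random() < prob(u, v):
            put(f"{u}_L", f"{v}_L")
            put(f"{u}_R", f"{v}_R")
    # midline-midline (self-mirror)
    for u, v in itertools.combinations(mid, 2):
        if rng.random() < prob(u, v):
            put(f"{u}_M", f"{v}_M")
    # midline-left, mirrored to midline-right
    for u in mid:
        for v in left:
            if rng.random() < prob(u, v):
                put(f"{u}_M", f"{v}_L")
                put(f"{u}_M", f"{v}_R")
    # direct left-right contact of the same bone (midline sutures)
    for v in left:
        if rng.random() < template.p_pair_contact:
            put(f"{v}_L", f"{v}_R")
    _connect_symmetric(a, labels, idx)
    if meta is None:
        meta = SpecimenMeta(specimen_id=f"synthetic_{template.seed}")
    return BoneNetwork(labels, a, meta)


def _connect_symmetric(a: np.ndarray, labels: list[BoneLabel], idx: dict[str, int]) -> None:
    """Join components with mirror-symmetric bridges until connected."""
    import networkx as nx

    while True:
        g = nx.from_numpy_array(a)
        comps = sorted(nx.connected_components(g), key=min)
        if len(comps) <= 1:
            return
        u = min(comps[0])
        v = min(comps[1])
        a[u, v] = a[v, u] = 1
        mu = idx[str(labels[u].mirror())]
        mv = idx[str(labels[v].mirror())]
        a[mu, mv] = a[mv, mu] = 1


# ---------------------------------------------------------------------
# Ontogenetic fusion


@dataclass
class FusionSchedule:
    """Ordered suture-closure events: (stage fraction, bone_a, bone_b)."""

    events: list[tuple[float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        stages = [s for s, _, _ in self.events]
        if any(not 0 < s <= 1 for s in stages):
            raise ValueError("stage fractions must lie in (0, 1]")
        if stages != sorted(stages):
            raise ValueError("fusion events must be ordered by stage")


def default_fusion_schedule(
    net: BoneNetwork, n_fusions: int, seed: int = 0
) -> FusionSchedule:
    """Pick ``n_fusions`` adjacent bone pairs to fuse at evenly spaced stages.

    Fusions are sampled among existing contacts (a suture can only close
    where bones touch) on a working copy, so later events reference the
    fused units created by earlier ones.
    """
    rng = np.random.default_rng(seed)
    work = net
    events: list[tuple[float, str, str]] = []
    for t in range(n_fusions):
        ii, jj = np.nonzero(np.triu(work.adjacency, k=1))
        if not len(ii):
            break
        pick = rng.integers(len(ii))
        la, lb = str(work.labels[ii[pick]]), str(work.labels[jj[pick]])
        stage = (t + 1) / n_fusions
        events.append((stage, la, lb))
        work = fuse_bones(work, la, lb, new_name=f"fused{t:02d}")
    return FusionSchedule(events)


def apply_fusions(net: BoneNetwork, events: list[tuple[float, str, str]]) -> BoneNetwork:
    out = net
    for t, (_, la, lb) in enumerate(events):
        out = fuse_bones(out, la, lb, new_name=f"fused{t:02d}")
    return out


def simulate_ontogeny(
    template: SkullTemplate,
    schedule: FusionSchedule,
    stages: list[float],
) -> list[tuple[BoneNetwork, float]]:
    """Skull networks along an ontogenetic series.

    At each stage (an ascending relative-size fraction in (0, 1]) all
    fusion events with stage fraction <= that stage have been applied
    cumulatively; each returned network carries relative size as a
    percentage. N is non-increasing along the series.
    """
    if list(stages) != sorted(stages):
        raise ValueError("stages must be sorted ascending")
    base = make_skull(template)
    out = []
    for s in stages:
        due = [e for e in schedule.events if e[0] <= s]
        net = apply_fusions(base, due)
        meta = SpecimenMeta(
            specimen_id=f"{base.meta.specimen_id}_s{int(round(s * 100)):03d}",
            relative_size=100.0 * s,
        )
        net = BoneNetwork(net.labels, net.adjacency, meta)
        out.append((net, 100.0 * s))
    return out


# ---------------------------------------------------------------------
# Trees with Brownian traits


def simulate_bm_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, float], dict[str, float]]:
    """Pure-birth (Yule) clock tree with a Brownian trait at every node.

    Returns (tree, tip values, true internal-node values); internal nodes
    are labelled ``nd0, nd1, ...`` in preorder so reconstructed values can
    be compared against the truth. Deterministic given the seed.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    # speciation times: k lineages wait Exp(k * birth_rate)
    times = [0.0]
    t = 0.0
    for k in range(1, n_tips):
        t += rng.exponential(1.0 / (k * birth_rate))
        times.append(t)
    depth = t + rng.exponential(1.0 / (n_tips * birth_rate))

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.time = 0.0
    active = [tree.seed_node]
    for split_time in times[1:]:
        node = active[rng.integers(len(active))]  # this lineage splits now
        active.remove(node)
        for _ in range(2):
            child = node.new_child()
            child.birth = split_time
            active.append(child)
        node.split = split_time
    # assign edge lengths: each node's edge spans (parent split, own split/present)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        start = getattr(parent, "split", 0.0) if parent is not None else 0.0
        end = getattr(node, "split", depth)
        if parent is not None:
            node.edge.length = end - start
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.require_taxon(label=f"t{i}")
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        node.label = f"nd{i}"
    # Brownian trait
    values: dict[int, float] = {id(tree.seed_node): root_value}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_val = values[id(node.parent_node)]
        bl = node.edge.length
        values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(sigma2 * bl))
    tips = {n.taxon.label: values[id(n)] for n in tree.leaf_node_iter()}
    internals = {n.label: values[id(n)] for n in tree.preorder_internal_node_iter()}
    return tree, tips, internals


# ---------------------------------------------------------------------
# Full synthetic study


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset in the shape of the real analysis."""

    networks: dict[str, BoneNetwork]
    metas: dict[str, SpecimenMeta]
    tree: dendropy.Tree            # taxon-level clock tree (one tip per taxon)
    juvenile_pairs: list[str]      # taxa with juvenile/adult specimen pairs


def make_study(
    n_species: int = 12,
    n_outgroup: int = 5,
    seed: int = 0,
    adult_fusions: tuple[int, int] = (8, 13),
    juvenile_fusions: tuple[int, int] = (0, 4),
    outgroup_fusions: tuple[int, int] = (0, 3),
) -> SyntheticStudy:
    """Generate a cohort of juvenile/adult skull pairs plus outgroup adults.

    Each crown species starts from the same skull body plan (with a
    species-specific random wiring seed); its adult applies many suture
    closures, its juvenile few, and its relative size tracks the fraction
    of closures applied. Outgroup taxa keep nearly unfused adult skulls,
    emulating the ancestral condition. A Yule tree over all taxa, with the
    outgroup taxa attached as the earliest-diverging tips, provides the
    phylogenetic frame.
    """
    rng = np.random.default_rng(seed)
    networks: dict[str, BoneNetwork] = {}
    metas: dict[str, SpecimenMeta] = {}
    species = [f"sp{i:02d}" for i in range(n_species)]
    outgroups = [f"og{i:02d}" for i in range(n_outgroup)]

    for sp in species:
        template = SkullTemplate(seed=int(rng.integers(2**31 - 1)))
        base = make_skull(template)
        n_ad = int(rng.integers(adult_fusions[0], adult_fusions[1] + 1))
        schedule = default_fusion_schedule(base, n_ad, seed=int(rng.integers(2**31 - 1)))
        n_juv = int(rng.integers(juvenile_fusions[0], juvenile_fusions[1] + 1))
        adult_box = float(rng.uniform(40.0, 120.0))
        juv_frac = (n_juv + 1) / (n_ad + 1)  # size tracks fusion progress
        juv_frac = min(max(juv_frac + rng.normal(0, 0.05), 0.05), 0.95)
        for stage, n_f, frac in (
            (Stage.JUVENILE, n_juv, juv_frac),
            (Stage.ADULT, n_ad, 1.0),
        ):
            sid = f"{sp}_{'juv' if stage is Stage.JUVENILE else 'ad'}"
            side = (adult_box * frac) ** (1 / 3)
            meta = SpecimenMeta(
                specimen_id=sid, taxon=sp, stage=stage, group=Group.CROWN_BIRD,
                skull_box=(side, side, side),
            )
            net = apply_fusions(base, schedule.events[:n_f])
            networks[sid] = BoneNetwork(net.labels, net.adjacency, meta)
            metas[sid] = meta

    for og in outgroups:
        template = SkullTemplate(seed=int(rng.integers(2**31 - 1)))
        base = make_skull(template)
        n_f = int(rng.integers(outgroup_fusions[0], outgroup_fusions[1] + 1))
        schedule = default_fusion_schedule(base, max(n_f, 1),
                                           seed=int(rng.integers(2**31 - 1)))
        sid = f"{og}_ad"
        side = float(rng.uniform(40.0, 120.0)) ** (1 / 3)
        meta = SpecimenMeta(
            specimen_id=sid, taxon=og, stage=Stage.ADULT,
            group=Group.STEM_ARCHOSAUR, skull_box=(side, side, side),
        )
        net = apply_fusions(base, schedule.events[:n_f])
        networks[sid] = BoneNetwork(net.labels, net.adjacency, meta)
        metas[sid] = meta

    tree = _study_tree(species, outgroups, seed=int(rng.integers(2**31 - 1)))
    return SyntheticStudy(networks=networks, metas=metas, tree=tree,
                          juvenile_pairs=species)


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write a study to disk in the exact formats the pipeline reads.

    Emits one adjacency CSV per specimen, ``meta.tsv``, ``tree.nwk`` and a
    ``truth.json`` with the generator's ground truth; returns a mapping of
    artifact names to paths.
    """
    import json
    from pathlib import Path

    from .netio import write_adjacency, write_meta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, net in sorted(study.networks.items()):
        p = out / f"{sid}.csv"
        write_adjacency(net, p)
        paths[sid] = str(p)
    write_meta(study.metas.values(), out / "meta.tsv")
    paths["meta"] = str(out / "meta.tsv")
    (out / "tree.nwk").write_text(
        study.tree.as_string(schema="newick", suppress_rooting=True))
    paths["tree"] = str(out / "tree.nwk")
    truth = {
        "juvenile_pairs": study.juvenile_pairs,
        "n_specimens": len(study.networks),
        "bones_per_specimen": {sid: net.n_nodes
                               for sid, net in sorted(study.networks.items())},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = str(out / "truth.json")
    return paths


def _study_tree(species: list[str], outgroups: list[str], seed: int) -> dendropy.Tree:
    """Clock tree: a crown-species Yule tree nested inside an outgroup ladder."""
    tree, _, _ = simulate_bm_tree(len(species) + len(outgroups), seed=seed)
    # relabel tips: earliest-diverging tips become outgroups
    depths = {}
    for leaf in tree.leaf_node_iter():
        node, d = leaf, 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        depths[leaf] = d
    ordered = sorted(tree.leaf_node_iter(), key=lambda l: (depths[l], l.taxon.label))
    names = outgroups + species
    for leaf, name in zip(ordered, names):
        leaf.taxon.label = name
    return tree
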