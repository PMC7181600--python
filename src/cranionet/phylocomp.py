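"""Phylogenetic comparative layer.

Tree preparation (mean-edge temporal consensus, juvenile/adult tip
splitting), phylogenetic flexible discriminant analysis (LDA after
whitening by a Pagel's-λ-scaled Brownian covariance), maximum-likelihood
ancestral state reconstruction under Brownian motion, the hypothetical-
hatchling substitution of juvenile trait values, and the SD / log-product
parsimony proxies used to compare reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .stats import ols

# ---------------------------------------------------------------------
# Tree utilities


def read_tree(path_or_str, schema: str = "newick") -> dendropy.Tree:
    """Read a tree; all trees in this package are rooted time trees."""
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        t = dendropy.Tree.get(data=path_or_str, schema=schema)
    else:
        t = dendropy.Tree.get(path=str(path_or_str), schema=schema)
    t.is_rooted = True
    return t


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance of every node from the root."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        el = node.edge.length or 0.0
        depths[node] = el + (depths[parent] if parent is not None else 0.0)
    return depths


def phylo_covariance(tree: dendropy.Tree, tips: list[str] | None = None) -> pd.DataFrame:
    """Brownian covariance: V_ij = depth of the MRCA of tips i and j."""
    depths = node_depths(tree)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if tips is None:
        tips = list(leaves)
    missing = [t for t in tips if t not in leaves]
    if missing:
        raise KeyError(f"tips not in tree: {missing}")
    n = len(tips)
    v = np.zeros((n, n))
    # V_ij = (depth_i + depth_j - patristic_ij) / 2 on a rooted tree
    pdm = tree.phylogenetic_distance_matrix()
    for i, a in enumerate(tips):
        v[i, i] = depths[leaves[a]]
        for j in range(i + 1, n):
            b = tips[j]
            dist = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
            v[i, j] = v[j, i] = (depths[leaves[a]] + depths[leaves[b]] - dist) / 2.0
    return pd.DataFrame(v, index=tips, columns=tips)


def consensus_edges(trees: list[dendropy.Tree], topology: dendropy.Tree) -> dendropy.Tree:
    """Temporal consensus: the given topology with mean edge lengths.

    Every input tree must share the topology's splits; each edge length in
    the output is the arithmetic mean of that edge's lengths across the
    input set.
    """
    if not trees:
        raise ValueError("empty tree set")
    tns = dendropy.TaxonNamespace()
    topo = topology.clone(depth=1)
    topo.migrate_taxon_namespace(tns)
    topo.is_rooted = True
    topo.encode_bipartitions()
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    ref_masks = {e.bipartition.split_bitmask for e in topo.preorder_edge_iter()
                 if e.head_node.parent_node is not None}
    for t in trees:
        tc = t.clone(depth=1)
        tc.migrate_taxon_namespace(tns)
        tc.is_rooted = True
        tc.encode_bipartitions()
        masks = {}
        for e in tc.preorder_edge_iter():
            if e.head_node.parent_node is None:
                continue
            masks[e.bipartition.split_bitmask] = e.length or 0.0
        extra = set(masks) - ref_masks
        missing = ref_masks - set(masks)
        if extra or missing:
            offending = (extra or missing).pop()
            raise ValueError(
                f"tree does not match the consensus topology at split {offending:b}"
            )
        for m, l in masks.items():
            sums[m] = sums.get(m, 0.0) + l
            counts[m] = counts.get(m, 0) + 1
    for e in topo.preorder_edge_iter():
        if e.head_node.parent_node is None:
            continue
        m = e.bipartition.split_bitmask
        e.length = sums[m] / counts[m]
    return topo


def split_ontogenetic_tips(
    tree: dendropy.Tree,
    species: list[str],
    bird_bl: float = 1.0,
    nonbird_bl: float = 10.0,
    nonbird: set[str] | None = None,
    juv_suffix: str = "_juv",
    ad_suffix: str = "_ad",
) -> dendropy.Tree:
    """Replace each listed tip with a juvenile/adult cherry.

    Each species tip becomes an internal node carrying two pendant tips,
    ``<species>_juv`` and ``<species>_ad``, with pendant length ``bird_bl``
    (default one year) or ``nonbird_bl`` (default ten years, reflecting the
    longer ontogenetic growth of crocodilians and large-bodied non-avian
    dinosaurs) for species listed in ``nonbird``. Tip depth is preserved by
    shortening the original pendant edge; when that edge is shorter than
    the cherry length the attachment edge is set to zero (the tree grows by
    the difference) — discriminant analysis needs only relative depths.
    """
    nonbird = nonbird or set()
    out = tree.clone(depth=1)
    leaves = {leaf.taxon.label: leaf for leaf in out.leaf_node_iter()}
    missing = [s for s in species if s not in leaves]
    if missing:
        raise KeyError(f"species not found in tree: {missing}")
    for sp in species:
        node = leaves[sp]
        bl = nonbird_bl if sp in nonbird else bird_bl
        orig = node.edge.length if node.edge.length is not None else bl
        node.edge.length = max(orig - bl, 0.0)
        node.taxon = None
        for suffix in (juv_suffix, ad_suffix):
            taxon = out.taxon_namespace.require_taxon(label=f"{sp}{suffix}")
            child = node.new_child(taxon=taxon, edge_length=bl)
    return out


# ---------------------------------------------------------------------
# Phylogenetic flexible discriminant analysis


def _inv_sqrt(m: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root with an eigenvalue floor."""
    w, u = np.linalg.eigh((m + m.T) / 2.0)
    w = np.maximum(w, floor)
    return u @ np.diag(1.0 / np.sqrt(w)) @ u.T


def lambda_scale(v: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's λ transform: off-diagonal covariances multiplied by λ."""
    out = lam * v
    np.fill_diagonal(out, np.diag(v))
    return out


@dataclass
class PfdaResult:
    lambda_: float
    confusion: pd.DataFrame
    error: float
    posteriors: pd.DataFrame
    predictions: pd.Series
    lambda_errors: pd.Series


class PhylogeneticFDA:
    """Discriminant analysis after phylogenetic whitening (pFDA).

    Tip trait vectors are correlated through shared ancestry. For each
    candidate Pagel's λ the Brownian covariance of the tree is λ-scaled
    (off-diagonals × λ), the traits are whitened by its inverse square
    root, and a linear discriminant analysis is fitted to the whitened
    training rows. λ is chosen to minimize the leave-one-out training
    misclassification rate (ties → smallest λ, i.e. the weakest assumed
    phylogenetic signal). Test taxa are whitened jointly with the training
    taxa through their own positions in the tree before classification.

    Parameters
    ----------
    tree : dendropy.Tree
        Time-calibrated tree containing every training and test tip.
    lambda_grid : sequence of float, default 0, 0.01, ..., 1
    eig_floor : float
        Floor for covariance eigenvalues in the inverse square root.
    """

    def __init__(self, tree: dendropy.Tree, lambda_grid=None, eig_floor: float = 1e-10):
        self.tree = tree
        self.lambda_grid = lambda_grid
        self.eig_floor = eig_floor

    def get_params(self, deep: bool = True) -> dict:
        return {"tree": self.tree, "lambda_grid": self.lambda_grid,
                "eig_floor": self.eig_floor}

    def set_params(self, **params) -> "PhylogeneticFDA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals -----------------------------------------------------
    def _check_rank(self, x: np.ndarray, y: np.ndarray) -> None:
        resid = np.vstack([x[y == g] - x[y == g].mean(axis=0) for g in np.unique(y)])
        if np.linalg.matrix_rank(resid) < x.shape[1]:
            raise ValueError(
                "singular within-group covariance: reduce the number of "
                "trait axes or pool groups"
            )

    def _whiten(self, v: pd.DataFrame, lam: float) -> np.ndarray:
        return _inv_sqrt(lambda_scale(v.to_numpy(), lam), self.eig_floor)

    def _loo_error(self, xw: np.ndarray, y: np.ndarray) -> float:
        wrong = 0
        n = len(y)
        for i in range(n):
            mask = np.arange(n) != i
            if len(np.unique(y[mask])) < 2:
                wrong += 1
                continue
            lda = LinearDiscriminantAnalysis()
            lda.fit(xw[mask], y[mask])
            wrong += int(lda.predict(xw[i:i + 1])[0] != y[i])
        return wrong / n

    # -- estimator API -------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "PhylogeneticFDA":
        """Fit on training taxa; ``X`` must be indexed by tip label."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame indexed by tip labels")
        y = pd.Series(np.asarray(y), index=X.index)
        if y.nunique() < 2:
            raise ValueError("need at least 2 groups")
        self._check_rank(X.to_numpy(float), y.to_numpy())
        grid = (np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
                if self.lambda_grid is None else np.asarray(self.lambda_grid, float))
        v_train = phylo_covariance(self.tree, list(X.index))
        errors = {}
        for lam in grid:
            w = self._whiten(v_train, lam)
            errors[float(lam)] = self._loo_error(w @ X.to_numpy(float), y.to_numpy())
        lambda_errors = pd.Series(errors).sort_index()
        best = lambda_errors[lambda_errors == lambda_errors.min()]
        self.lambda_ = float(best.index.min())
        self.lambda_errors_ = lambda_errors
        self.error_ = float(lambda_errors.min())
        self.X_ = X.astype(float)
        self.y_ = y
        self.classes_ = np.unique(y)
        # LOO-based training confusion at the chosen lambda
        w = self._whiten(v_train, self.lambda_)
        xw = w @ X.to_numpy(float)
        yv = y.to_numpy()
        conf = pd.DataFrame(0, index=self.classes_, columns=self.classes_)
        n = len(yv)
        for i in range(n):
            mask = np.arange(n) != i
            lda = LinearDiscriminantAnalysis()
            lda.fit(xw[mask], yv[mask])
            conf.loc[yv[i], lda.predict(xw[i:i + 1])[0]] += 1
        self.confusion_ = conf
        return self

    def predict_proba(self, X_test: pd.DataFrame) -> pd.DataFrame:
        """Group posteriors for test taxa (rows indexed by tip label)."""
        if not hasattr(self, "lambda_"):
            raise RuntimeError("fit before predict")
        tips = list(self.X_.index) + list(X_test.index)
        v = phylo_covariance(self.tree, tips)
        w = self._whiten(v, self.lambda_)
        x_all = np.vstack([self.X_.to_numpy(float), X_test.to_numpy(float)])
        xw = w @ x_all
        n_train = len(self.X_)
        lda = LinearDiscriminantAnalysis()
        lda.fit(xw[:n_train], self.y_.to_numpy())
        proba = lda.predict_proba(xw[n_train:])
        return pd.DataFrame(proba, index=X_test.index, columns=lda.classes_)

    def predict(self, X_test: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(X_test)
        return proba.idxmax(axis=1)

    def result_(self, X_test: pd.DataFrame | None = None) -> PfdaResult:
        if X_test is not None and len(X_test):
            posteriors = self.predict_proba(X_test)
            predictions = posteriors.idxmax(axis=1)
        else:
            posteriors = pd.DataFrame(columns=self.classes_)
            predictions = pd.Series(dtype=object)
        return PfdaResult(
            lambda_=self.lambda_,
            confusion=self.confusion_,
            error=self.error_,
            posteriors=posteriors,
            predictions=predictions,
            lambda_errors=self.lambda_errors_,
        )


def pfda(train_X: pd.DataFrame, train_groups, test_X: pd.DataFrame,
         tree: dendropy.Tree, lambda_grid=None) -> PfdaResult:
    """Function wrapper over :class:`PhylogeneticFDA`."""
    est = PhylogeneticFDA(tree, lambda_grid=lambda_grid).fit(train_X, train_groups)
    return est.result_(test_X)


# ---------------------------------------------------------------------
# Brownian-motion ancestral state reconstruction


@dataclass
class AsrResult:
    node_values: dict[str, float]      # internal node key -> value
    sd_proxy: float
    logprod_proxy: float
    logprod_valid: bool
    clade_values: dict[str, float] = field(default_factory=dict)
    root_value: float = float("nan")


def _node_key(node: dendropy.Node, idx: int) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"node{idx}"


def asr_bm(
    tree: dendropy.Tree,
    tip_values: dict[str, float] | pd.Series,
    clades: dict[str, list[str]] | None = None,
) -> AsrResult:
    """Maximum-likelihood ancestral states under Brownian motion.

    Under BM with a constant diffusion rate, the joint log-likelihood of
    all node values is a weighted sum of squared changes along edges
    (weights 1/branch length), so the ML internal states solve a sparse
    linear system: the weighted graph Laplacian restricted to internal
    nodes, with tip values as boundary conditions. The root estimate is
    the GLS phylogenetic mean (1'V⁻¹x)/(1'V⁻¹1).

    Also reports two parsimony proxies over the internal-node values: the
    sample standard deviation and Σ log|value| (flagged invalid when any
    value is ≤ 0 in absolute terms, i.e. log undefined).
    """
    tip_values = dict(tip_values.items())
    tree.is_rooted = True
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    leaves = [n for n in nodes if n.is_leaf()]
    internal = [n for n in nodes if not n.is_leaf()]
    missing = [l.taxon.label for l in leaves if l.taxon.label not in tip_values]
    if missing:
        raise KeyError(f"missing tip values: {missing}")
    n = len(nodes)
    w = np.zeros((n, n))
    for node in nodes:
        if node.parent_node is None:
            continue
        bl = node.edge.length
        if bl is None or bl <= 0:
            raise ValueError(f"non-positive branch length above {_node_key(node, 0)}")
        i, j = index[id(node)], index[id(node.parent_node)]
        w[i, j] = w[j, i] = 1.0 / bl
    lap = np.diag(w.sum(axis=1)) - w
    int_idx = [index[id(nd)] for nd in internal]
    tip_idx = [index[id(nd)] for nd in leaves]
    x = np.array([tip_values[l.taxon.label] for l in leaves], dtype=float)
    a = np.linalg.solve(lap[np.ix_(int_idx, int_idx)], -lap[np.ix_(int_idx, tip_idx)] @ x)
    node_values = {_node_key(nd, i): float(v)
                   for i, (nd, v) in enumerate(zip(internal, a))}
    vals = np.array(list(node_values.values()))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    nonzero = np.abs(vals) > 0
    logprod = float(np.log(np.abs(vals[nonzero])).sum()) if nonzero.any() else float("-inf")
    clade_values = {}
    if clades:
        for name, tips in clades.items():
            taxa = [tree.taxon_namespace.get_taxon(t) for t in tips]
            if any(t is None for t in taxa):
                raise KeyError(f"clade {name}: unknown tips among {tips}")
            mrca = tree.mrca(taxa=taxa)
            pos = internal.index(mrca) if mrca in internal else None
            if pos is None:  # MRCA of one tip is the tip itself
                clade_values[name] = float(tip_values[mrca.taxon.label])
            else:
                clade_values[name] = float(a[pos])
    root_pos = internal.index(tree.seed_node)
    return AsrResult(
        node_values=node_values,
        sd_proxy=sd,
        logprod_proxy=logprod,
        logprod_valid=bool((vals > 0).all()),
        clade_values=clade_values,
        root_value=float(a[root_pos]),
    )


# ---------------------------------------------------------------------
# Juvenile substitution and parsimony proxies


def juvenile_substitute(
    juv_traits: pd.Series,
    rel_sizes: pd.Series,
    youngest_id: str,
) -> pd.Series:
    """Standardize juvenile trait values to hypothetical hatchlings.

    Juveniles are sampled at unequal ontogenetic stages, so the raw values
    mix evolutionary and ontogenetic signal. Each value is replaced by its
    residual from the OLS of trait on relative size, plus the fitted value
    at the youngest sampled individual's relative size — i.e. every
    juvenile is slid down the common ontogenetic trend to the youngest
    stage in the sample.
    """
    juv_traits, rel_sizes = juv_traits.align(rel_sizes, join="inner")
    if youngest_id not in rel_sizes.index:
        raise KeyError(f"{youngest_id!r} not among the juveniles")
    if rel_sizes[youngest_id] > rel_sizes.min() + 1e-12:
        raise ValueError(
            f"{youngest_id!r} does not have the minimum relative size"
        )
    fit = ols(rel_sizes.to_numpy(), juv_traits.to_numpy())
    fitted = fit.intercept + fit.slope * rel_sizes
    resid = juv_traits - fitted
    anchor = fit.intercept + fit.slope * rel_sizes[youngest_id]
    return resid + anchor


@dataclass
class ParsimonyComparison:
    sd_adult: float
    sd_substituted: float
    sd_difference: float        # adult - substituted; > 0 favours substitution
    logprod_adult: float
    logprod_substituted: float
    logprod_valid: bool


def parsimony_proxies(asr_adult: AsrResult, asr_substituted: AsrResult) -> ParsimonyComparison:
    """Compare two reconstructions on the same tree; lower SD = more parsimonious."""
    return ParsimonyComparison(
        sd_adult=asr_adult.sd_proxy,
        sd_substituted=asr_substituted.sd_proxy,
        sd_difference=asr_adult.sd_proxy - asr_substituted.sd_proxy,
        logprod_adult=asr_adult.logprod_proxy,
        logprod_substituted=asr_substituted.logprod_proxy,
        logprod_valid=asr_adult.logprod_valid and asr_substituted.logprod_valid,
    )
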