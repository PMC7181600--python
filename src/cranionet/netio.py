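"""Reading, validating and transforming skull bone-contact networks.

A specimen's skull is modelled as an undirected, unweighted graph: nodes are
bones (or fused bone units), edges are physical contacts (sutures or
articulations). Input is a square 0/1 adjacency CSV with identical row and
column labels. Bone laterality is encoded in the label suffix: ``_L`` /
``_R`` for the left/right copy of a paired bone, ``_M`` for unpaired midline
elements (case-insensitive).
"""

from __future__ import annotations

import enum
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class AdjacencyFormatError(ValueError):
    """Raised when an adjacency CSV violates the matrix contract."""


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


_SIDE_SUFFIX = {"l": Side.LEFT, "r": Side.RIGHT, "m": Side.MIDLINE}
_SUFFIX_FOR_SIDE = {Side.LEFT: "L", Side.RIGHT: "R", Side.MIDLINE: "M"}


@dataclass(frozen=True)
class BoneLabel:
    """A bone name plus its side, parsed from a ``name_L|R|M`` label."""

    name: str
    side: Side

    @classmethod
    def parse(cls, raw: str) -> "BoneLabel":
        raw = raw.strip()
        if "_" in raw:
            stem, _, suffix = raw.rpartition("_")
            side = _SIDE_SUFFIX.get(suffix.lower())
            if side is not None and stem:
                return cls(name=stem, side=side)
        # No recognized suffix: treat as a midline element named verbatim.
        return cls(name=raw, side=Side.MIDLINE)

    def __str__(self) -> str:  # round-trips through parse()
        return f"{self.name}_{_SUFFIX_FOR_SIDE[self.side]}"

    @property
    def is_paired(self) -> bool:
        return self.side is not Side.MIDLINE

    def mirror(self) -> "BoneLabel":
        """The contralateral label (identity for midline bones)."""
        if self.side is Side.LEFT:
            return BoneLabel(self.name, Side.RIGHT)
        if self.side is Side.RIGHT:
            return BoneLabel(self.name, Side.LEFT)
        return self


class Stage(str, enum.Enum):
    JUVENILE = "juvenile"
    ADULT = "adult"


class Group(str, enum.Enum):
    CROWN_BIRD = "crown_bird"
    STEM_ARCHOSAUR = "stem_archosaur"
    OUTGROUP = "outgroup"


@dataclass
class SpecimenMeta:
    """Specimen-level metadata: taxon, ontogenetic stage and skull size."""

    specimen_id: str
    taxon: str = ""
    stage: Stage | None = None
    group: Group | None = None
    skull_box: tuple[float, float, float] | None = None
    relative_size: float | None = None
    clade_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.skull_box is not None:
            box = tuple(float(v) for v in self.skull_box)
            if len(box) != 3 or any(v <= 0 for v in box):
                raise ValueError(
                    f"skull_box must be three positive lengths, got {self.skull_box!r}"
                )
            self.skull_box = box
        if self.relative_size is not None and not self.relative_size > 0:
            raise ValueError(f"relative_size must be positive, got {self.relative_size}")

    @property
    def box_volume(self) -> float | None:
        if self.skull_box is None:
            return None
        return float(np.prod(self.skull_box))


@dataclass
class BoneNetwork:
    """One specimen's validated bone-contact graph."""

    labels: list[BoneLabel]
    adjacency: np.ndarray
    meta: SpecimenMeta
    allow_disconnected: bool = False

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        validate_adjacency(self.adjacency, [str(l) for l in self.labels])
        if len(set(map(str, self.labels))) != len(self.labels):
            raise AdjacencyFormatError("duplicate bone labels")
        if not self.allow_disconnected and self.n_nodes > 0 and not self.is_connected:
            raise AdjacencyFormatError(
                f"{self.meta.specimen_id}: bone network is disconnected "
                "(pass allow_disconnected=True to override)"
            )

    # -- basic views ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx()) if self.n_nodes else False

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        names = [str(l) for l in self.labels]
        g.add_nodes_from(names)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from((names[i], names[j]) for i, j in zip(ii, jj))
        return g

    def index_of(self, label: BoneLabel | str) -> int:
        key = str(label)
        for i, lab in enumerate(self.labels):
            if str(lab) == key:
                return i
        raise KeyError(f"unknown bone label {key!r}")

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def validate_adjacency(a: np.ndarray, labels: Sequence[str]) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise AdjacencyFormatError(f"matrix is not square: shape {a.shape}")
    if a.shape[0] != len(labels):
        raise AdjacencyFormatError(
            f"{len(labels)} labels but {a.shape[0]} matrix rows"
        )
    bad = np.argwhere((a != 0) & (a != 1))
    if bad.size:
        i, j = bad[0]
        raise AdjacencyFormatError(
            f"non-binary cell at ({labels[i]}, {labels[j]}): {a[i, j]!r}"
        )
    asym = np.argwhere(a != a.T)
    if asym.size:
        i, j = asym[0]
        raise AdjacencyFormatError(
            f"asymmetric cells ({labels[i]}, {labels[j]}): "
            f"{a[i, j]!r} vs {a[j, i]!r}"
        )
    diag = np.nonzero(np.diag(a))[0]
    if diag.size:
        raise AdjacencyFormatError(f"nonzero diagonal at {labels[diag[0]]}")


def read_adjacency(
    path: str | Path | io.StringIO,
    meta: SpecimenMeta | None = None,
    allow_disconnected: bool = False,
) -> BoneNetwork:
    """Read a square 0/1 bone-adjacency CSV into a :class:`BoneNetwork`.

    The first row and first column hold bone labels in identical order;
    symmetry, a zero diagonal and binary cells are enforced.
    """
    df = pd.read_csv(path, index_col=0)
    row_labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if row_labels != col_labels:
        raise AdjacencyFormatError(
            "row and column labels differ or are reordered: "
            f"{row_labels[:3]}... vs {col_labels[:3]}..."
        )
    try:
        a = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise AdjacencyFormatError(f"non-numeric cell: {exc}") from exc
    if np.isnan(a).any():
        i, j = np.argwhere(np.isnan(a))[0]
        raise AdjacencyFormatError(f"empty cell at ({row_labels[i]}, {row_labels[j]})")
    validate_adjacency(a, row_labels)
    if meta is None:
        name = Path(path).stem if isinstance(path, (str, Path)) else "specimen"
        meta = SpecimenMeta(specimen_id=name)
    labels = [BoneLabel.parse(l) for l in row_labels]
    return BoneNetwork(labels, a.astype(int), meta, allow_disconnected=allow_disconnected)


def write_adjacency(net: BoneNetwork, path: str | Path) -> None:
    names = [str(l) for l in net.labels]
    pd.DataFrame(net.adjacency.astype(int), index=names, columns=names).to_csv(path)


# -- metadata TSV ------------------------------------------------------

_META_COLUMNS = [
    "specimen_id", "taxon", "stage", "group",
    "box_length", "box_width", "box_height", "clade_tags",
]


def read_meta(path: str | Path) -> dict[str, SpecimenMeta]:
    """Read the specimen metadata TSV; returns a specimen_id → meta map."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("specimen_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"metadata TSV missing columns: {missing}")
    out: dict[str, SpecimenMeta] = {}
    for _, row in df.iterrows():
        box = None
        dims = [row.get(c, "") for c in ("box_length", "box_width", "box_height")]
        if all(d != "" for d in dims):
            box = tuple(float(d) for d in dims)
        out[row["specimen_id"]] = SpecimenMeta(
            specimen_id=row["specimen_id"],
            taxon=row.get("taxon", ""),
            stage=Stage(row["stage"]) if row.get("stage") else None,
            group=Group(row["group"]) if row.get("group") else None,
            skull_box=box,
            clade_tags=frozenset(t for t in row.get("clade_tags", "").split(";") if t),
        )
    return out


def write_meta(metas: Iterable[SpecimenMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        box = m.skull_box or ("", "", "")
        rows.append({
            "specimen_id": m.specimen_id,
            "taxon": m.taxon,
            "stage": m.stage.value if m.stage else "",
            "group": m.group.value if m.group else "",
            "box_length": box[0], "box_width": box[1], "box_height": box[2],
            "clade_tags": ";".join(sorted(m.clade_tags)),
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# -- transformations ---------------------------------------------------

def fuse_bones(
    net: BoneNetwork,
    a: BoneLabel | str,
    b: BoneLabel | str,
    new_name: str,
    new_side: Side = Side.MIDLINE,
) -> BoneNetwork:
    """Merge two bones into one unit whose contacts are the union of both.

    Fusion models ontogenetic suture closure: the fused unit inherits every
    contact of either parent bone (minus the closed contact between them),
    so N drops by exactly one and no self-loop is created.
    """
    ia, ib = net.index_of(a), net.index_of(b)
    if ia == ib:
        raise ValueError(f"cannot fuse a bone with itself: {a}")
    keep = [i for i in range(net.n_nodes) if i not in (ia, ib)]
    merged_row = np.clip(net.adjacency[ia] + net.adjacency[ib], 0, 1)[keep]
    sub = net.adjacency[np.ix_(keep, keep)]
    n = len(keep)
    new_adj = np.zeros((n + 1, n + 1), dtype=int)
    new_adj[:n, :n] = sub
    new_adj[:n, n] = merged_row
    new_adj[n, :n] = merged_row
    new_labels = [net.labels[i] for i in keep] + [BoneLabel(new_name, new_side)]
    return BoneNetwork(new_labels, new_adj, net.meta,
                       allow_disconnected=net.allow_disconnected)


def drop_unpaired(net: BoneNetwork, strict: bool = False) -> BoneNetwork:
    """Delete all midline (unpaired) bones with their incident contacts.

    Mirrors the deletion experiment that tests whether left–right module
    asymmetry is an artefact of unpaired elements. The result may be
    disconnected; by default that is recorded as a warning, not an error.
    """
    keep = [i for i, lab in enumerate(net.labels) if lab.is_paired]
    if not keep:
        raise ValueError("no paired bones would remain after deletion")
    sub = net.adjacency[np.ix_(keep, keep)]
    labels = [net.labels[i] for i in keep]
    out = BoneNetwork(labels, sub, net.meta, allow_disconnected=True)
    if not out.is_connected:
        msg = f"{net.meta.specimen_id}: network disconnected after unpaired-bone deletion"
        if strict:
            raise AdjacencyFormatError(msg)
        warnings.warn(msg, stacklevel=2)
    return out


def is_mirror_symmetric(net: BoneNetwork) -> bool:
    """True when swapping every _L and _R label leaves the adjacency invariant."""
    index = {str(l): i for i, l in enumerate(net.labels)}
    perm = []
    for lab in net.labels:
        m = str(lab.mirror())
        if m not in index:
            return False
        perm.append(index[m])
    perm = np.asarray(perm)
    return bool(np.array_equal(net.adjacency, net.adjacency[np.ix_(perm, perm)]))
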