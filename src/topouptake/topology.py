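"""Superlevel-set merge trees of 3D intensity functions.

The superlevel set at threshold I' is the set of voxels with f >= I'.
Sweeping the threshold downward from the global maximum, connected
components (under 26-adjacency: voxels sharing a face, edge, or vertex)
are born at strict local maxima and merge at saddles.  The resulting
rooted binary tree — the merge tree — records for every branch:

* ``b``        birth value (the maximum's value for a leaf, the merge
               value for an internal branch),
* ``d``        elder-rule death: the value at which the branch's label
               maximum joins a component led by a *larger* maximum (the
               older component persists, the younger dies),
* ``d_prime``  childhood death: the first value at which the branch's set
               of maxima is augmented by any other maximum — its first
               merge regardless of elder status.

The leaf with the largest birth never loses a merge, so its elder death
equals the terminal filtration value (0 by default, chosen below the
smallest positive intensity so the final superlevel set is the whole ROI).

The sweep is a single pass over ROI voxels in decreasing intensity order
with union-find component tracking; births and deaths are reported at
attained voxel values (the fine-filtration limit).  Ties are broken by a
deterministic total order (value, then flat voxel index); plateau voxels
are never strict maxima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LocalMaximum",
    "Branch",
    "MergeTree",
    "find_local_maxima",
    "superlevel_components",
    "build_merge_tree",
    "tree_to_json",
    "tree_from_json",
    "tree_to_newick",
]

# 26 neighbor offsets of the 3x3x3 box minus the center
_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ],
    dtype=np.int64,
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LocalMaximum:
    """A strict 26-neighborhood local maximum of f, ranked by decreasing value."""

    voxel: tuple[int, int, int]
    value: float
    rank: int  # 1-based; rank 1 is the global maximum


@dataclass
class Branch:
    id: int
    kind: str  # "leaf" | "internal"
    label_max: int  # rank of the largest maximum in the branch (elder rule)
    birth: float
    elder_death: float | None
    childhood_death: float | None
    children: tuple[int, int] | None = None
    maxima_set: frozenset[int] = frozenset()
    parent: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"


@dataclass
class MergeTree:
    """A rooted binary merge tree (or forest, if the ROI is disconnected)."""

    branches: list[Branch]
    maxima: list[LocalMaximum]
    terminal_value: float = 0.0
    connected: bool = True
    roots: list[int] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.maxima)

    @property
    def leaves(self) -> list[Branch]:
        return [b for b in self.branches if b.is_leaf]

    @property
    def internal(self) -> list[Branch]:
        return [b for b in self.branches if not b.is_leaf]

    def leaf_for_rank(self, rank: int) -> Branch:
        for b in self.branches:
            if b.is_leaf and b.label_max == rank:
                return b
        raise KeyError(f"no leaf with maximum rank {rank}")

    def persistence_pairs(self) -> list[tuple[float, float]]:
        """(birth, elder death) per leaf, in rank order."""
        return [(lf.birth, lf.elder_death) for lf in sorted(self.leaves, key=lambda b: b.label_max)]

    def childhood_pairs(self) -> list[tuple[float, float]]:
        """(birth, childhood death) per leaf, in rank order."""
        return [
            (lf.birth, lf.childhood_death) for lf in sorted(self.leaves, key=lambda b: b.label_max)
        ]


def _positive_domain(f) -> tuple[np.ndarray, np.ndarray]:
    """Return (array, boolean domain of positive voxels) for an IntensityFunction or array."""
    if hasattr(f, "f"):
        arr = np.asarray(f.f, dtype=float)
    else:
        arr = np.asarray(f, dtype=float)
    if arr.ndim != 3:
        raise ValueError("intensity function must be a 3D array")
    domain = arr > 0
    return arr, domain


def find_local_maxima(f) -> list[LocalMaximum]:
    """Strict 26-neighborhood local maxima of f, ordered by decreasing value.

    A voxel is a maximum iff its value is strictly greater than all 26
    neighbors of its 3×3×3 box (clipped at array borders; voxels outside
    the ROI have f = 0).  Plateau voxels are therefore never maxima.
    Returned maxima are ranked 1..m by decreasing value, ties broken by
    flat voxel index.
    """
    arr, domain = _positive_domain(f)
    if not domain.any():
        raise ValueError("intensity function has no positive voxels")
    footprint = _STRUCT_26.copy()
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(arr, footprint=footprint, mode="constant", cval=0.0)
    is_max = (arr > neigh_max) & domain
    coords = np.argwhere(is_max)
    flat = np.ravel_multi_index(coords.T, arr.shape)
    values = arr[tuple(coords.T)]
    order = np.lexsort((flat, -values))
    return [
        LocalMaximum(voxel=tuple(int(c) for c in coords[o]), value=float(values[o]), rank=r + 1)
        for r, o in enumerate(order)
    ]


def superlevel_components(f, threshold: float) -> np.ndarray:
    """Label the superlevel set {f >= threshold} by 26-connected component.

    Components are labeled by the rank of the largest local maximum they
    contain (0 marks voxels outside the superlevel set).  The superlevel
    set is taken within the positive support of f.
    """
    arr, domain = _positive_domain(f)
    sel = (arr >= threshold) & domain
    out = np.zeros(arr.shape, dtype=np.int32)
    if not sel.any():
        return out
    lab, n = ndimage.label(sel, structure=_STRUCT_26)
    maxima = find_local_maxima(f)
    # map scipy's arbitrary component ids to the rank of the best contained maximum
    best = np.full(n + 1, np.iinfo(np.int32).max, dtype=np.int64)
    for mx in maxima:
        cid = lab[mx.voxel]
        if cid > 0 and mx.rank < best[cid]:
            best[cid] = mx.rank
    out[sel] = best[lab[sel]]
    return out


def build_merge_tree(f, terminal_value: float = 0.0) -> MergeTree:
    """Build the superlevel-set merge tree of f by a descending union-find sweep.

    Voxels are added in decreasing intensity order (ties by flat index).
    A voxel with no previously-added neighbor founds a new component — a
    leaf born at its value.  A voxel adjacent to k >= 2 distinct components
    merges them at its value: every merging branch receives its childhood
    death there, the branch led by the smaller maximum receives its elder
    death (elder rule), and an internal branch is born.  A disconnected
    ROI yields a forest with ``connected=False``; every surviving root
    takes the terminal value as its remaining death values.
    """
    arr, domain = _positive_domain(f)
    if not domain.any():
        raise ValueError("intensity function has no positive voxels")
    minpos = float(arr[domain].min())
    if terminal_value >= minpos:
        raise ValueError(
            f"terminal value {terminal_value} must be below the smallest "
            f"positive intensity {minpos}"
        )

    shape = arr.shape
    coords = np.argwhere(domain)
    flat = np.ravel_multi_index(coords.T, shape)
    values = arr[tuple(coords.T)]
    order = np.lexsort((flat, -values))
    coords, flat, values = coords[order], flat[order], values[order]

    # precompute in-domain neighbor flat indices per voxel (ragged, via lists)
    n_flat = int(np.prod(shape))
    added = np.zeros(n_flat, dtype=bool)
    uf_parent: dict[int, int] = {}  # union-find over flat voxel ids
    comp_branch: dict[int, int] = {}  # uf root -> active branch id
    comp_label: dict[int, int] = {}  # uf root -> label maximum rank
    branches: list[Branch] = []
    maxima: list[LocalMaximum] = []
    leaf_ids: list[int] = []  # rank-1 -> leaf branch id

    def find(x: int) -> int:
        root = x
        while uf_parent[root] != root:
            root = uf_parent[root]
        while uf_parent[x] != root:
            uf_parent[x], x = root, uf_parent[x]
        return root

    strides = np.array(
        [shape[1] * shape[2], shape[2], 1], dtype=np.int64
    )
    off_flat = _OFFSETS @ strides

    dims = np.array(shape)
    for idx in range(len(flat)):
        v_flat = int(flat[idx])
        val = float(values[idx])
        ci, cj, ck = coords[idx]
        interior = (
            0 < ci < dims[0] - 1 and 0 < cj < dims[1] - 1 and 0 < ck < dims[2] - 1
        )
        if interior:
            neigh = v_flat + off_flat
            roots = {find(int(nf)) for nf in neigh if added[nf]}
        else:
            roots = set()
            for di, dj, dk in _OFFSETS:
                ni, nj, nk = ci + di, cj + dj, ck + dk
                if 0 <= ni < dims[0] and 0 <= nj < dims[1] and 0 <= nk < dims[2]:
                    nf = int(ni * strides[0] + nj * strides[1] + nk)
                    if added[nf]:
                        roots.add(find(nf))

        if not roots:
            # founds a new component: a leaf, labeled by this maximum
            rank = len(maxima) + 1
            maxima.append(
                LocalMaximum(voxel=(int(ci), int(cj), int(ck)), value=val, rank=rank)
            )
            bid = len(branches)
            leaf_ids.append(bid)
            branches.append(
                Branch(
                    id=bid,
                    kind="leaf",
                    label_max=rank,
                    birth=val,
                    elder_death=None,
                    childhood_death=None,
                    maxima_set=frozenset({rank}),
                )
            )
            uf_parent[v_flat] = v_flat
            comp_branch[v_flat] = bid
            comp_label[v_flat] = rank
        elif len(roots) == 1:
            root = roots.pop()
            uf_parent[v_flat] = root
        else:
            # merge k >= 2 components at this voxel's value, in decreasing
            # label-maximum order (k-1 binary merges at the same value)
            ordered = sorted(roots, key=lambda r: comp_label[r])
            winner = ordered[0]
            for loser in ordered[1:]:
                wb = branches[comp_branch[winner]]
                lb = branches[comp_branch[loser]]
                wb.childhood_death = val
                lb.childhood_death = val
                # elder rule: the component with the smaller maximum dies
                dying_rank = comp_label[loser]
                branches[leaf_ids[dying_rank - 1]].elder_death = val
                bid = len(branches)
                parent = Branch(
                    id=bid,
                    kind="internal",
                    label_max=comp_label[winner],
                    birth=val,
                    elder_death=None,
                    childhood_death=None,
                    children=(wb.id, lb.id),
                    maxima_set=wb.maxima_set | lb.maxima_set,
                )
                wb.parent = bid
                lb.parent = bid
                branches.append(parent)
                uf_parent[loser] = winner
                comp_branch[winner] = bid
                comp_label[winner] = parent.label_max
            uf_parent[v_flat] = winner
        added[v_flat] = True

    # finalize surviving roots
    root_ids = []
    seen = set()
    for r in list(comp_branch):
        rr = find(r)
        if rr in seen:
            continue
        seen.add(rr)
        bid = comp_branch[rr]
        br = branches[bid]
        br.childhood_death = terminal_value
        root_ids.append(bid)
        # the root's label maximum never loses a merge
        branches[leaf_ids[br.label_max - 1]].elder_death = terminal_value

    # internal branches inherit the elder death of their label maximum
    elder_by_rank = {
        b.label_max: b.elder_death for b in branches if b.is_leaf
    }
    for b in branches:
        if not b.is_leaf:
            b.elder_death = elder_by_rank[b.label_max]

    connected = len(root_ids) == 1
    return MergeTree(
        branches=branches,
        maxima=maxima,
        terminal_value=terminal_value,
        connected=connected,
        roots=sorted(root_ids),
    )


# ---------------------------------------------------------------------------
# serialization


def tree_to_json(tree: MergeTree) -> str:
    payload = {
        "terminal_value": tree.terminal_value,
        "connected": tree.connected,
        "roots": tree.roots,
        "maxima": [
            {"voxel": list(mx.voxel), "value": mx.value, "rank": mx.rank}
            for mx in tree.maxima
        ],
        "branches": [
            {
                "id": b.id,
                "kind": b.kind,
                "label_max": b.label_max,
                "birth": b.birth,
                "elder_death": b.elder_death,
                "childhood_death": b.childhood_death,
                "children": list(b.children) if b.children else None,
                "maxima_set": sorted(b.maxima_set),
                "parent": b.parent,
            }
            for b in tree.branches
        ],
    }
    return json.dumps(payload, indent=1)


def tree_from_json(text: str) -> MergeTree:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed merge-tree JSON: {e}") from e
    for key in ("terminal_value", "maxima", "branches", "roots"):
        if key not in payload:
            raise ValueError(f"malformed merge-tree JSON: missing field {key!r}")
    maxima = [
        LocalMaximum(voxel=tuple(mx["voxel"]), value=mx["value"], rank=mx["rank"])
        for mx in payload["maxima"]
    ]
    branches = [
        Branch(
            id=b["id"],
            kind=b["kind"],
            label_max=b["label_max"],
            birth=b["birth"],
            elder_death=b["elder_death"],
            childhood_death=b["childhood_death"],
            children=tuple(b["children"]) if b["children"] else None,
            maxima_set=frozenset(b["maxima_set"]),
            parent=b.get("parent"),
        )
        for b in payload["branches"]
    ]
    return MergeTree(
        branches=branches,
        maxima=maxima,
        terminal_value=payload["terminal_value"],
        connected=payload.get("connected", True),
        roots=payload["roots"],
    )


def tree_to_newick(tree: MergeTree) -> str:
    """Newick export with branch length b − d' per branch (leaves named M<rank>)."""

    def render(bid: int) -> str:
        b = tree.branches[bid]
        length = b.birth - b.childhood_death
        if b.is_leaf:
            return f"M{b.label_max}:{length:.10g}"
        left, right = b.children
        return f"({render(left)},{render(right)})M{b.label_max}i:{length:.10g}"

    trees = [render(r) + ";" for r in tree.roots]
    return "\n".join(trees)
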