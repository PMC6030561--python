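"""Discrete-trait ancestral state reconstruction on a species tree.

ICM localization (restricted vs nonrestricted) or architecture (lamellar vs
vesicular) is mapped onto a rooted species tree and reconstructed by
minimum-change (Fitch) parsimony.  Multifurcations are handled natively: the
engine computes exact per-node minimum-change cost vectors (unit-cost
dynamic programming over all states), so the reported ``min_changes`` is the
true minimum over all full labelings even on polytomous trees.  All
maximum-parsimony labelings can be enumerated, which supports questions such
as "is there an MP labeling with a nonrestricted root whose gains all fall
inside one clade?".

Newick reading/writing is delegated to dendropy; branch lengths are carried
but unused by parsimony.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import dendropy
import pandas as pd

from .errors import ConfigError, DataError, NewickParseError

INF = float("inf")


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text into a rooted dendropy tree.

    Raises :class:`NewickParseError` on malformed input (with the parser's
    position message) or duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def read_newick_file(path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


@dataclass
class TraitTree:
    """A rooted tree with leaf trait states and reconstruction results."""

    tree: dendropy.Tree
    leaf_states: dict  # leaf label -> state
    alphabet: tuple
    excluded: list = dc_field(default_factory=list)
    node_state_sets: dict = dc_field(default_factory=dict)  # node key -> frozenset
    min_changes: int | None = None

    def leaf_labels(self):
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def attach_traits(
    tree: dendropy.Tree,
    table,
    alphabet=None,
    missing_policy: str = "error",
) -> TraitTree:
    """Join a leaf→state table onto the tree by exact leaf-name match.

    ``table`` may be a path to a two-column CSV (species, state), a DataFrame
    with those columns, or a dict.  Leaves absent from the table are an error
    (``missing_policy='error'``) or pruned with a report
    (``missing_policy='exclude'``).  States outside the declared alphabet
    raise an error naming the offending row.
    """
    if missing_policy not in ("error", "exclude"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")
    if isinstance(table, dict):
        states = dict(table)
    else:
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, comment="#")
        cols = list(table.columns[:2])
        states = dict(zip(table[cols[0]].astype(str), table[cols[1]].astype(str)))
    if alphabet is None:
        alphabet = tuple(sorted(set(states.values())))
    bad = {k: v for k, v in states.items() if v not in alphabet}
    if bad:
        raise DataError(f"states outside alphabet {alphabet}: {bad}")

    tree = tree.clone(depth=1)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in states]
    if missing and missing_policy == "error":
        raise DataError(f"leaves without a trait state: {sorted(missing)}")
    if missing:
        drop = set(missing)
        for lf in list(tree.leaf_node_iter()):
            if lf.taxon and lf.taxon.label in drop:
                lf.parent_node.remove_child(lf)
        # clean up childless internal nodes left behind, then unifurcations
        changed = True
        while changed:
            changed = False
            for node in list(tree.postorder_node_iter()):
                if node.taxon is None and not node.child_nodes() and \
                        node.parent_node is not None:
                    node.parent_node.remove_child(node)
                    changed = True
        tree.suppress_unifurcations()
    leaf_states = {l: states[l] for l in leaves if l in states}
    return TraitTree(tree=tree, leaf_states=leaf_states, alphabet=tuple(alphabet),
                     excluded=sorted(missing))


# ---------------------------------------------------------------------------
# parsimony engine
# ---------------------------------------------------------------------------


def _node_key(node) -> tuple:
    """Stable identifier of a node: the sorted tuple of its descendant leaves."""
    return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _cost_vectors(tt: TraitTree) -> dict:
    """Unit-cost minimum-change vectors c_v(s) for every node, bottom-up."""
    costs = {}
    for node in tt.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tt.leaf_states:
                raise DataError(f"leaf {label!r} has no trait state")
            s0 = tt.leaf_states[label]
            costs[id(node)] = {s: (0 if s == s0 else INF) for s in tt.alphabet}
        else:
            vec = {}
            for s in tt.alphabet:
                total = 0.0
                for ch in node.child_nodes():
                    cv = costs[id(ch)]
                    total += min(cv[t] + (0 if t == s else 1) for t in tt.alphabet)
                vec[s] = total
            costs[id(node)] = vec
    return costs


def fitch_parsimony(tt: TraitTree) -> TraitTree:
    """Minimum-change ancestral reconstruction (exact on multifurcations).

    Fills ``tt.node_state_sets`` — for each node the states achieving the
    subtree minimum (on binary trees these equal the classic Fitch downpass
    sets) — and ``tt.min_changes``.  Returns ``tt``.
    """
    if not tt.leaf_states:
        raise DataError("no leaf states attached")
    costs = _cost_vectors(tt)
    tt.node_state_sets = {}
    for node in tt.tree.postorder_node_iter():
        cv = costs[id(node)]
        m = min(cv.values())
        tt.node_state_sets[_node_key(node)] = frozenset(
            s for s, c in cv.items() if c == m
        )
    root_costs = costs[id(tt.tree.seed_node)]
    tt.min_changes = int(min(root_costs.values()))
    return tt


def root_state_set(tt: TraitTree) -> frozenset:
    if tt.min_changes is None:
        raise DataError("run fitch_parsimony first")
    return tt.node_state_sets[_node_key(tt.tree.seed_node)]


def brute_force_min_changes(tt: TraitTree) -> int:
    """Exhaustive minimum over all internal labelings (test oracle; small trees)."""
    internal = [n for n in tt.tree.preorder_node_iter() if not n.is_leaf()]
    leaves = {id(n): tt.leaf_states[n.taxon.label]
              for n in tt.tree.leaf_node_iter()}
    best = None
    for combo in itertools.product(tt.alphabet, repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), combo))
        assign.update(leaves)
        changes = sum(
            1
            for n in tt.tree.preorder_node_iter()
            if n.parent_node is not None and assign[id(n)] != assign[id(n.parent_node)]
        )
        best = changes if best is None else min(best, changes)
    return int(best)


def mp_labelings(tt: TraitTree, max_labelings: int = 200000):
    """Yield every maximum-parsimony full labeling as {node_key: state}.

    Backtracks over the unit-cost DP: the root ranges over its optimal
    states; each child, given its parent's state s, over every state t with
    ``c(t) + [t != s]`` minimal.
    """
    costs = _cost_vectors(tt)
    root = tt.tree.seed_node
    rv = costs[id(root)]
    m = min(rv.values())
    count = 0

    def options(node, parent_state):
        cv = costs[id(node)]
        best = min(cv[t] + (0 if t == parent_state else 1) for t in tt.alphabet)
        return [t for t in tt.alphabet
                if cv[t] + (0 if t == parent_state else 1) == best]

    def expand(nodes, assign):
        nonlocal count
        if not nodes:
            count += 1
            if count > max_labelings:
                raise DataError("too many MP labelings to enumerate")
            yield dict(assign)
            return
        node, rest = nodes[0], nodes[1:]
        for t in options(node, assign[_node_key(node.parent_node)]):
            assign[_node_key(node)] = t
            yield from expand(rest, assign)
        del assign[_node_key(node)]

    order = [n for n in tt.tree.preorder_node_iter() if n.parent_node is not None]
    for s in (s for s, c in rv.items() if c == m):
        yield from expand(order, {_node_key(root): s})


def _changes_of(tt: TraitTree, labeling: dict):
    """Branches (child node keys) on which the state changes, with the states."""
    out = []
    for node in tt.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a = labeling[_node_key(node.parent_node)]
        b = labeling[_node_key(node)]
        if a != b:
            out.append((_node_key(node), a, b))
    return out


def map_changes(tt: TraitTree, resolution: str = "all_mp"):
    """Locate state changes on branches under a maximum-parsimony labeling.

    ``acctran`` prefers changing as early (rootward) as possible at ties,
    ``deltran`` delays changes; both return one labeling's change list.
    ``all_mp`` enumerates every MP labeling and returns a dict with the
    union and intersection of change-bearing branches plus the list of
    labelings' change sets.  Branches are identified by the sorted leaf set
    of the child node.
    """
    if resolution not in ("acctran", "deltran", "all_mp"):
        raise ConfigError(f"unknown resolution {resolution!r}")
    if tt.min_changes is None:
        fitch_parsimony(tt)
    if resolution == "all_mp":
        union, inter, per = set(), None, []
        for lab in mp_labelings(tt):
            ch = {c[0] for c in _changes_of(tt, lab)}
            per.append(sorted(ch))
            union |= ch
            inter = ch if inter is None else (inter & ch)
        return {"union": sorted(union), "intersection": sorted(inter or set()),
                "n_labelings": len(per), "per_labeling": per}

    costs = _cost_vectors(tt)
    prefer_change = resolution == "acctran"

    def pick(cands, parent_state):
        same = [t for t in cands if t == parent_state]
        diff = sorted(t for t in cands if t != parent_state)
        if prefer_change:
            return diff[0] if diff else same[0]
        return same[0] if same else diff[0]

    labeling = {}
    root = tt.tree.seed_node
    rv = costs[id(root)]
    m = min(rv.values())
    labeling[_node_key(root)] = sorted(s for s, c in rv.items() if c == m)[0]
    for node in tt.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        ps = labeling[_node_key(node.parent_node)]
        cv = costs[id(node)]
        best = min(cv[t] + (0 if t == ps else 1) for t in tt.alphabet)
        cands = [t for t in tt.alphabet if cv[t] + (0 if t == ps else 1) == best]
        labeling[_node_key(node)] = pick(cands, ps)
    return _changes_of(tt, labeling)


def random_trait_tree(rng, n_leaves: int, n_states: int = 2,
                      polytomy_prob: float = 0.3) -> TraitTree:
    """Random rooted tree with random leaf states (validation utility).

    Built by repeatedly joining 2 (or, with ``polytomy_prob``, 3) subtrees,
    so multifurcations occur; states are drawn uniformly from the first
    ``n_states`` letters.
    """
    alphabet = tuple("ABC"[:n_states])
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        k = 3 if (len(parts) >= 3 and rng.random() < polytomy_prob) else 2
        idx = rng.choice(len(parts), size=k, replace=False)
        group = "(" + ",".join(parts[i] for i in sorted(idx)) + ")"
        parts = [p for i, p in enumerate(parts) if i not in idx] + [group]
    tree = read_newick(parts[0] + ";")
    states = {f"L{i}": alphabet[rng.integers(n_states)] for i in range(n_leaves)}
    return attach_traits(tree, states, alphabet=alphabet)


def clade_leafset(tt: TraitTree, members) -> frozenset:
    """Leaf set of the smallest clade (MRCA subtree) containing ``members``."""
    taxa = [t for t in tt.tree.taxon_namespace if t.label in set(members)]
    mrca = tt.tree.mrca(taxa=taxa)
    return frozenset(lf.taxon.label for lf in mrca.leaf_iter())


def report(tt: TraitTree) -> str:
    """Structured-text reconstruction report."""
    lines = [
        f"min_changes: {tt.min_changes}",
        f"root_states: {sorted(root_state_set(tt))}",
    ]
    changes = map_changes(tt, "all_mp")
    lines.append(f"n_mp_labelings: {changes['n_labelings']}")
    lines.append("changed_branches_union:")
    for br in changes["union"]:
        lines.append(f"  - {','.join(br)}")
    lines.append("changed_branches_intersection:")
    for br in changes["intersection"]:
        lines.append(f"  - {','.join(br)}")
    return "\n".join(lines)
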