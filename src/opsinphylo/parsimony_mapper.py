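"""Fitch parsimony mapping of lesion characters and functional-status painting.

Each lesion is treated as an unordered binary character (absent/present, with
``?`` for taxa that could not be assessed).  The optimizer returns the exact
parsimony length and *every* most-parsimonious reconstruction's set of gain
branches rather than picking an ACCTRAN/DELTRAN resolution; downstream
consumers use the MPR with the fewest independent gains (deterministic
tie-break) as the headline reconstruction, with ambiguity preserved in the
returned list.

Painting is monotone by construction: on each root-to-tip path the earliest
branch carrying any optimized lesion is *transitional* (the gene mixes
functional and dead history on it) and everything below is *pseudogenic*;
a gene never reverts to functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_io import SpeciesTree
from .lesion_scanner import LesionRecord

INF = float("inf")

FUNCTIONAL = "functional"
TRANSITIONAL = "transitional"
PSEUDOGENIC = "pseudogenic"


@dataclass
class BinaryCharacter:
    """Presence/absence of one lesion across tree tips ('?' = unassessable)."""

    character_id: str
    states: dict[int, str]  # tip node_id -> "0" | "1" | "?"

    def __post_init__(self) -> None:
        bad = {s for s in self.states.values()} - {"0", "1", "?"}
        if bad:
            raise ValueError(f"invalid character states: {bad}")
        if all(s == "?" for s in self.states.values()):
            raise ValueError(f"character {self.character_id} is all-missing")


@dataclass
class BranchPainting:
    """Per-branch functional status for one gene."""

    gene: str
    status: dict[tuple[int, int], str]
    inactivation_branches: list[tuple[int | None, int]] = field(default_factory=list)


def character_from_lesion(
    lesion: LesionRecord,
    tree: SpeciesTree,
    scored_taxa: set[str] | None = None,
    count_polymorphic: bool = True,
) -> BinaryCharacter:
    """Binary character for one lesion: carriers 1, other scored tips 0, rest ?.

    Polymorphic carriers count as present by default, matching the convention
    of painting a lesion onto the branch even when only some haplotypes in a
    species carry it (configurable).
    """
    carriers = set(lesion.taxa)
    if not count_polymorphic:
        carriers -= {t for t, poly in lesion.polymorphic.items() if poly}
    states: dict[int, str] = {}
    for nid in tree.leaf_ids:
        label = tree.nodes[nid].label or str(nid)
        if label in carriers:
            states[nid] = "1"
        elif scored_taxa is None or label in scored_taxa:
            states[nid] = "0"
        else:
            states[nid] = "?"
    cid = f"{lesion.gene}:{lesion.lesion_type}:{lesion.start}-{lesion.end}"
    return BinaryCharacter(cid, states)


def fitch_optimize(
    tree: SpeciesTree,
    char: BinaryCharacter,
    max_enumeration: int = 200_000,
) -> tuple[int, list[frozenset[tuple[int, int]]]]:
    """Exact binary parsimony with enumeration of all MPR gain-branch sets.

    Returns ``(min_changes, gain_sets)`` where each element of ``gain_sets``
    is the set of 0->1 branches of one most-parsimonious reconstruction
    (distinct reconstructions with identical gain sets are collapsed).  A
    reconstruction that places state 1 at the root contributes the virtual
    branch ``(None, root_id)``.  Missing tips contribute no cost in either
    state rather than being imputed.
    """
    post = tree.postorder()
    cost: dict[int, list[float]] = {}
    for nid in post:
        node = tree.nodes[nid]
        if node.is_leaf:
            s = char.states.get(nid, "?")
            if s == "?":
                cost[nid] = [0.0, 0.0]
            else:
                cost[nid] = [0.0 if s == "0" else INF, 0.0 if s == "1" else INF]
        else:
            c0 = c1 = 0.0
            for ch in node.children:
                c0 += min(cost[ch][0], cost[ch][1] + 1)
                c1 += min(cost[ch][1], cost[ch][0] + 1)
            cost[nid] = [c0, c1]

    root = tree.root_id
    min_changes = int(min(cost[root]))

    # enumerate optimal assignments top-down, collecting gain sets per subtree
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def subtree_gainsets(nid: int, state: int) -> list[frozenset]:
        key = (nid, state)
        if key in memo:
            return memo[key]
        node = tree.nodes[nid]
        if node.is_leaf:
            memo[key] = [frozenset()]
            return memo[key]
        per_child: list[list[frozenset]] = []
        for ch in node.children:
            options: list[frozenset] = []
            seen: set[frozenset] = set()
            for cs in (0, 1):
                if cost[ch][cs] + (1 if cs != state else 0) == \
                        min(cost[ch][0] + (1 if state != 0 else 0),
                            cost[ch][1] + (1 if state != 1 else 0)):
                    gain = frozenset([(nid, ch)]) if (state, cs) == (0, 1) else frozenset()
                    for sub in subtree_gainsets(ch, cs):
                        full = sub | gain
                        if full not in seen:
                            seen.add(full)
                            options.append(full)
            per_child.append(options)
        combined: list[frozenset] = [frozenset()]
        for options in per_child:
            nxt: list[frozenset] = []
            seen2: set[frozenset] = set()
            for acc in combined:
                for opt in options:
                    u = acc | opt
                    if u not in seen2:
                        seen2.add(u)
                        nxt.append(u)
                if len(nxt) > max_enumeration:
                    raise RuntimeError(
                        f"MPR enumeration exceeded {max_enumeration} gain sets "
                        f"for character {char.character_id}")
            combined = nxt
        memo[key] = combined
        return combined

    gain_sets: list[frozenset] = []
    seen: set[frozenset] = set()
    for rs in (0, 1):
        if cost[root][rs] == min_changes:
            root_gain = frozenset([(None, root)]) if rs == 1 else frozenset()
            for sub in subtree_gainsets(root, rs):
                full = sub | root_gain
                if full not in seen:
                    seen.add(full)
                    gain_sets.append(full)

    def sort_key(s: frozenset) -> tuple:
        return (len(s), sorted(str(b) for b in s))

    gain_sets.sort(key=sort_key)
    return min_changes, gain_sets


def best_gain_set(gain_sets: list[frozenset]) -> frozenset:
    """Headline MPR: fewest independent gains, lexicographic tie-break."""
    return min(gain_sets, key=lambda s: (len(s), sorted(str(b) for b in s)))


def paint_gene_status(
    tree: SpeciesTree,
    lesions: list[LesionRecord],
    gene: str | None = None,
    scored_taxa: set[str] | None = None,
    count_polymorphic: bool = True,
) -> BranchPainting:
    """Paint functional/transitional/pseudogenic status from optimized lesions.

    Every lesion is optimized independently; on each root-to-tip path the
    earliest branch carrying any lesion gain becomes transitional, branches
    below it pseudogenic, branches above functional.
    """
    gene = gene or (lesions[0].gene if lesions else "gene")
    lesion_branches: set[tuple[int | None, int]] = set()
    for lesion in lesions:
        char = character_from_lesion(lesion, tree, scored_taxa, count_polymorphic)
        _, gain_sets = fitch_optimize(tree, char)
        lesion_branches |= best_gain_set(gain_sets)

    status: dict[tuple[int, int], str] = {}
    inactivations: list[tuple[int | None, int]] = []

    root_dead = (None, tree.root_id) in lesion_branches
    if root_dead:
        inactivations.append((None, tree.root_id))

    def walk(nid: int, dead: bool) -> None:
        for ch in tree.nodes[nid].children:
            br = (nid, ch)
            if dead:
                status[br] = PSEUDOGENIC
                walk(ch, True)
            elif br in lesion_branches:
                status[br] = TRANSITIONAL
                inactivations.append(br)
                walk(ch, True)
            else:
                status[br] = FUNCTIONAL
                walk(ch, False)

    walk(tree.root_id, root_dead)
    return BranchPainting(gene=gene, status=status,
                          inactivation_branches=inactivations)


def count_independent_inactivations(painting: BranchPainting) -> int:
    """Number of maximal pseudogenic subtrees (= transitional branches)."""
    return len(painting.inactivation_branches)
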