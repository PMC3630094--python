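"""Codon-alignment simulator with pseudogenization, lesions and tuning plans.

Sequences evolve along a rooted tree under a GY94-style codon process:
single-nucleotide changes with rate proportional to kappa (transitions),
omega (nonsynonymous changes) and the target frequency, simulated exactly
with per-site Gillespie waiting times so pathway counts are available for
oracle tests.  Stop codons are unreachable while a gene is functional and
become ordinary states after a pseudogenization event (nonsense drift in
dead genes).  Introns evolve as neutral nucleotides with the canonical GT/AG
dinucleotides held fixed unless a splice lesion is scheduled.

A lesion plan places inactivating events (frameshift indels, nonsense
codons, splice disruptions, key-residue missense changes) at fractions along
chosen branches; from the first lesion on a branch the subtree evolves with
omega = 1.  A tuning plan forces codon states at chosen sites on chosen
branches (those sites are otherwise invariant), which gives exact control
over ancestral-reconstruction truth.  Everything emitted is deterministic
under a fixed seed, and a TruthLog records every event with its final
alignment coordinates plus the true sequences at every node.

Branch lengths are in units of expected neutral substitutions per codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    CodonAlignment,
    GENETIC_CODE,
    GeneModel,
    Segment,
    SpeciesTree,
    STOP_CODONS,
)

SENSE_CODONS = [c for c in GENETIC_CODE if c not in STOP_CODONS]
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

LESION_KINDS = ("frameshift_deletion", "frameshift_insertion", "nonsense",
                "splice_donor", "splice_acceptor", "key_missense")

# neighbor table: codon -> [(target, is_transition, is_synonymous, is_stop)]
_NEIGHBORS: dict[str, list[tuple[str, bool, bool, bool]]] = {}
for _c in GENETIC_CODE:
    lst = []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _c[_pos]:
                continue
            _t = _c[:_pos] + _b + _c[_pos + 1:]
            lst.append((
                _t,
                (_c[_pos], _b) in TRANSITIONS,
                GENETIC_CODE[_c] == GENETIC_CODE[_t],
                _t in STOP_CODONS,
            ))
    _NEIGHBORS[_c] = lst


@dataclass
class LesionEvent:
    """One scheduled inactivating event on a branch.

    ``cds_codon`` anchors exon lesions (1-based codon index); ``intron``
    selects the intron (1-based) for splice lesions; ``to`` is the forced
    codon (nonsense/missense) or dinucleotide (splice).  ``offset`` shifts
    an indel's first base within the anchor codon (0-2).
    """

    branch: tuple[int, int]
    fraction: float
    lesion_type: str
    size: int = 0
    cds_codon: int | None = None
    intron: int | None = None
    to: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_KINDS:
            raise ValueError(f"unknown lesion type {self.lesion_type}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0,1]")
        if self.lesion_type.startswith("frameshift") and self.size % 3 == 0:
            raise ValueError("frameshift lesion size must not be a multiple of 3")


@dataclass
class TuningChange:
    """Forced codon state at a site, applied at the end of a branch."""

    branch: tuple[int, int]
    site: int  # codon index == residue number under the identity numbering map
    codon: str


@dataclass
class SimSpec:
    """Complete description of one simulated gene history."""

    tree: SpeciesTree
    codons: int                       # including the terminal stop when present
    kappa: float = 3.0
    omega: float = 0.2                # purifying-selection default on functional branches
    branch_omega: dict[tuple[int, int], float] = field(default_factory=dict)
    lesions: list[LesionEvent] = field(default_factory=list)
    tuning_root: dict[int, str] = field(default_factory=dict)   # site -> codon
    tuning_changes: list[TuningChange] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)  # (after_codon, length)
    gene_name: str = "gene"
    reference_taxon: str | None = None   # default: first tip label
    terminal_stop: bool = True
    allow_stop_drift: bool = True
    seed: int = 0

    def validate(self) -> None:
        branches = set(self.tree.branches())
        for ev in self.lesions:
            if ev.branch not in branches:
                raise ValueError(f"lesion on branch {ev.branch} absent from tree")
            if ev.lesion_type in ("splice_donor", "splice_acceptor"):
                if ev.intron is None or not 1 <= ev.intron <= len(self.introns):
                    raise ValueError(f"splice lesion needs a valid intron, got {ev.intron}")
            elif ev.cds_codon is None or not 1 <= ev.cds_codon <= self.codons:
                raise ValueError(f"exon lesion needs a valid cds_codon, got {ev.cds_codon}")
        for ch in self.tuning_changes:
            if ch.branch not in branches:
                raise ValueError(f"tuning change on branch {ch.branch} absent from tree")
        exon_bounds = self._exon_codon_ranges()
        for ev in self.lesions:
            if ev.lesion_type.startswith("frameshift"):
                base0 = (ev.cds_codon - 1) * 3 + ev.offset
                last = base0 + ev.size - 1 if ev.lesion_type.endswith("deletion") else base0
                if not any(lo * 3 <= base0 and last < hi * 3 for lo, hi in exon_bounds):
                    raise ValueError(
                        f"indel at codon {ev.cds_codon} crosses an exon boundary")

    def _exon_codon_ranges(self) -> list[tuple[int, int]]:
        """Exon extents as (first_codon-1, last_codon) pairs in codon units."""
        bounds = [0] + sorted(k for k, _ in self.introns) + [self.codons]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


@dataclass
class TruthEvent:
    branch: tuple[int, int]
    lesion_type: str
    fraction: float
    start: int   # final 1-based alignment columns
    end: int
    detail: str
    carriers: list[str]
    segment: str = ""


@dataclass
class TruthLog:
    """Ground truth for one simulation: events, node sequences, branch omegas."""

    events: list[TruthEvent]
    node_cds: dict[int, str]
    node_introns: dict[int, list[str]]
    branch_omega: dict[tuple[int, int], float]
    switch_points: dict[tuple[int, int], float]
    seed: int


def _neutral_rate_scale(kappa: float) -> float:
    """Scale so the mean neutral leave-rate over sense codons is 1 per codon."""
    totals = []
    for c in SENSE_CODONS:
        totals.append(sum((kappa if ts else 1.0)
                          for _, ts, _, stop in _NEIGHBORS[c] if not stop))
    return 1.0 / (sum(totals) / len(totals))


def _evolve_codon(codon: str, t: float, omega: float, kappa: float,
                  allow_stops: bool, mu: float, rng: np.random.Generator) -> str:
    """Exact Gillespie simulation of one codon site for duration t."""
    while True:
        targets: list[str] = []
        rates: list[float] = []
        dead = GENETIC_CODE[codon] == "*"
        for tgt, ts, syn, stop in _NEIGHBORS[codon]:
            if stop and not allow_stops:
                continue
            w = kappa if ts else 1.0
            if not dead and not stop and not syn:
                w *= omega
            targets.append(tgt)
            rates.append(w * mu)
        total = sum(rates)
        if total <= 0:
            return codon
        dt = rng.exponential(1.0 / total)
        if dt > t:
            return codon
        t -= dt
        codon = targets[rng.choice(len(targets), p=np.array(rates) / total)]


def _evolve_intron(seq: str, t: float, kappa: float, frozen: set[int],
                   rng: np.random.Generator) -> str:
    """Neutral nucleotide evolution (K80-like) at rate 1/3 per site."""
    chars = list(seq)
    per_target = 1.0 / (3 * (kappa + 2.0))  # transversion rate; total = 1/3
    for i in range(len(chars)):
        if i in frozen:
            continue
        remaining = t
        while True:
            cur = chars[i]
            targets = [b for b in "ACGT" if b != cur]
            rates = [per_target * (kappa if (cur, b) in TRANSITIONS else 1.0)
                     for b in targets]
            total = sum(rates)
            dt = rng.exponential(1.0 / total)
            if dt > remaining:
                break
            remaining -= dt
            chars[i] = targets[rng.choice(3, p=np.array(rates) / total)]
    return "".join(chars)


def simulate(spec: SimSpec, seed: int | None = None
             ) -> tuple[CodonAlignment, GeneModel, TruthLog]:
    """Run the simulation and assemble alignment, gene model and truth log."""
    spec.validate()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tree = spec.tree
    mu = _neutral_rate_scale(spec.kappa)

    n = spec.codons
    frozen_sites = set(spec.tuning_root) | {ch.site for ch in spec.tuning_changes}
    for ev in spec.lesions:
        if ev.lesion_type in ("nonsense", "key_missense"):
            frozen_sites.add(ev.cds_codon)
    if spec.terminal_stop:
        frozen_sites.add(n)

    # root state
    root_codons = [SENSE_CODONS[i] for i in
                   rng.choice(len(SENSE_CODONS), size=n)]
    for site, codon in spec.tuning_root.items():
        root_codons[site - 1] = codon
    if spec.terminal_stop:
        root_codons[n - 1] = "TAA"
    intron_lens = [m for _, m in spec.introns]
    root_introns = []
    for m in intron_lens:
        inner = "".join("ACGT"[i] for i in rng.choice(4, size=max(m - 4, 0)))
        root_introns.append("GT" + inner + "AG")

    events_by_branch: dict[tuple[int, int], list[LesionEvent]] = {}
    for ev in spec.lesions:
        events_by_branch.setdefault(ev.branch, []).append(ev)
    for evs in events_by_branch.values():
        evs.sort(key=lambda e: e.fraction)
    tuning_by_branch: dict[tuple[int, int], list[TuningChange]] = {}
    for ch in spec.tuning_changes:
        tuning_by_branch.setdefault(ch.branch, []).append(ch)

    node_cds: dict[int, list[str]] = {tree.root_id: root_codons}
    node_introns: dict[int, list[str]] = {tree.root_id: root_introns}
    node_dead: dict[int, bool] = {tree.root_id: False}
    node_frozen: dict[int, set[int]] = {tree.root_id: set(frozen_sites)}
    branch_omega: dict[tuple[int, int], float] = {}
    switch_points: dict[tuple[int, int], float] = {}
    applied_events: list[tuple[LesionEvent, list[str]]] = []

    def splice_frozen(intron_idx: int, length: int) -> set[int]:
        return {0, 1, length - 2, length - 1}

    for nid in tree.preorder():
        if nid == tree.root_id:
            continue
        parent = tree.nodes[nid].parent
        br = (parent, nid)
        t = tree.nodes[nid].edge_length
        cds = list(node_cds[parent])
        introns = list(node_introns[parent])
        dead = node_dead[parent]
        frozen = set(node_frozen[parent])
        omega0 = 1.0 if dead else spec.branch_omega.get(br, spec.omega)
        branch_omega[br] = omega0

        checkpoints = [(ev.fraction, ev) for ev in events_by_branch.get(br, [])]
        checkpoints.append((1.0, None))
        pos = 0.0
        cur_omega = omega0
        for frac, ev in checkpoints:
            span = max(frac - pos, 0.0) * t
            if span > 0:
                allow = spec.allow_stop_drift and dead
                for i in range(len(cds)):
                    if (i + 1) in frozen:
                        continue
                    cds[i] = _evolve_codon(cds[i], span, cur_omega, spec.kappa,
                                           allow, mu, rng)
                for k in range(len(introns)):
                    fz = splice_frozen(k, len(introns[k]))
                    introns[k] = _evolve_intron(introns[k], span, spec.kappa,
                                                fz, rng)
            pos = frac
            if ev is None:
                continue
            # apply the lesion: sequence edit now, gap bookkeeping at assembly
            if ev.lesion_type == "nonsense":
                cds[ev.cds_codon - 1] = ev.to or "TAA"
                frozen.add(ev.cds_codon)
            elif ev.lesion_type == "key_missense":
                cds[ev.cds_codon - 1] = ev.to
                frozen.add(ev.cds_codon)
            elif ev.lesion_type == "splice_donor":
                s = introns[ev.intron - 1]
                introns[ev.intron - 1] = (ev.to or "GA") + s[2:]
            elif ev.lesion_type == "splice_acceptor":
                s = introns[ev.intron - 1]
                introns[ev.intron - 1] = s[:-2] + (ev.to or "AA")
            if not dead:
                dead = True
                switch_points[br] = ev.fraction
                cur_omega = 1.0
            carriers = [tree.nodes[l].label or str(l)
                        for l in tree.subtree_leaf_ids(nid)]
            applied_events.append((ev, carriers))
        for ch in tuning_by_branch.get(br, []):
            cds[ch.site - 1] = ch.codon
        node_cds[nid] = cds
        node_introns[nid] = introns
        node_dead[nid] = dead
        node_frozen[nid] = frozen

    return _assemble(spec, tree, node_cds, node_introns, branch_omega,
                     switch_points, applied_events, rng, seed)


# ---------------------------------------------------------------------------
# alignment assembly
# ---------------------------------------------------------------------------

def _layout(spec: SimSpec) -> list[tuple[str, int, int]]:
    """(kind, cds_base_start, length) blocks in order; cds_base is 0-based."""
    blocks: list[tuple[str, int, int]] = []
    prev = 0
    for after_codon, length in sorted(spec.introns):
        blocks.append(("exon", prev * 3, (after_codon - prev) * 3))
        blocks.append(("intron", after_codon * 3, length))
        prev = after_codon
    blocks.append(("exon", prev * 3, (spec.codons - prev) * 3))
    return [b for b in blocks if b[2] > 0]


def _assemble(spec, tree, node_cds, node_introns, branch_omega, switch_points,
              applied_events, rng, seed):
    blocks = _layout(spec)
    # original (pre-insertion) column of each CDS base and intron base
    cds_col: dict[int, int] = {}
    intron_col: dict[tuple[int, int], int] = {}
    col = 0
    intron_idx = 0
    for kind, start, length in blocks:
        if kind == "exon":
            for b in range(length):
                col += 1
                cds_col[start + b] = col
        else:
            for b in range(length):
                col += 1
                intron_col[(intron_idx, b)] = col
            intron_idx += 1
    total_orig = col

    tips = [(nid, tree.nodes[nid].label or str(nid)) for nid in tree.leaf_ids]

    rev: list[tuple[str, int, int]] = [None] * (total_orig + 1)  # type: ignore
    for b, c in cds_col.items():
        rev[c] = ("cds", b, 0)
    for (k, b), c in intron_col.items():
        rev[c] = ("intron", k, b)

    # insertions: (original column after which bases go, inserted bases, carriers)
    insertions: list[tuple[int, str, set[str]]] = []
    deletions: list[tuple[int, int, set[str], LesionEvent]] = []
    final_events: list[TruthEvent] = []
    pending: list[tuple[LesionEvent, list[str], str, int, int]] = []

    for ev, carriers in applied_events:
        cset = set(carriers)
        if ev.lesion_type == "frameshift_deletion":
            b0 = (ev.cds_codon - 1) * 3 + ev.offset
            c0, c1 = cds_col[b0], cds_col[b0 + ev.size - 1]
            deletions.append((c0, c1, cset, ev))
            pending.append((ev, carriers, f"{ev.size}-bp frameshift deletion", c0, c1))
        elif ev.lesion_type == "frameshift_insertion":
            b0 = (ev.cds_codon - 1) * 3 + ev.offset
            anchor = cds_col[b0]
            bases = "".join("ACGT"[i] for i in rng.choice(4, size=ev.size))
            insertions.append((anchor, bases, cset))
            pending.append((ev, carriers, f"{ev.size}-bp frameshift insertion",
                            anchor, anchor))  # final coords fixed later
        elif ev.lesion_type in ("nonsense", "key_missense"):
            b0 = (ev.cds_codon - 1) * 3
            c0, c1 = cds_col[b0], cds_col[b0 + 2]
            detail = (f"premature {ev.to or 'TAA'}" if ev.lesion_type == "nonsense"
                      else f"forced {ev.to} at codon {ev.cds_codon}")
            pending.append((ev, carriers, detail, c0, c1))
        elif ev.lesion_type == "splice_donor":
            c0 = intron_col[(ev.intron - 1, 0)]
            pending.append((ev, carriers, f"GT to {ev.to or 'GA'}", c0, c0 + 1))
        else:  # splice_acceptor
            length = len(node_introns[tree.root_id][ev.intron - 1])
            c0 = intron_col[(ev.intron - 1, length - 2)]
            pending.append((ev, carriers, f"AG to {ev.to or 'AA'}", c0, c0 + 1))

    insertions.sort(key=lambda x: x[0])

    def final_col(orig: int) -> int:
        shift = sum(len(b) for a, b, _ in insertions if a < orig)
        return orig + shift

    # build rows
    rows: dict[str, str] = {}
    for nid, label in tips:
        cds = node_cds[nid]
        cds_str = "".join(cds)
        introns = node_introns[nid]
        chars: list[str] = []
        ins_by_anchor: dict[int, list[tuple[str, set[str]]]] = {}
        for a, b, cset in insertions:
            ins_by_anchor.setdefault(a, []).append((b, cset))
        for c in range(1, total_orig + 1):
            kind, i, j = rev[c]
            ch = cds_str[i] if kind == "cds" else introns[i][j]
            for c0, c1, cset, _ in deletions:
                if c0 <= c <= c1 and label in cset:
                    ch = "-"
            chars.append(ch)
            for bases, cset in ins_by_anchor.get(c, []):
                chars.append("".join(bases) if label in cset
                             else "-" * len(bases))
        rows[label] = "".join(chars)

    taxa = [label for _, label in tips]
    aln = CodonAlignment(taxa, rows)

    # gene model in final coordinates: walk the original blocks and expand each
    # by the insertions it contains (insertions anchored at a block's last
    # original column extend that block)
    segs: list[Segment] = []
    orig_pos = 1
    for kind, start, length in blocks:
        o_start, o_end = orig_pos, orig_pos + length - 1
        f_start = final_col(o_start)
        f_end = final_col(o_end) + sum(len(b) for a, b, _ in insertions
                                       if a == o_end)
        segs.append(Segment(kind, f_start, f_end))
        orig_pos = o_end + 1

    numbering = {i: i for i in range(1, spec.codons + (0 if spec.terminal_stop else 1))}
    reference = spec.reference_taxon or taxa[0]
    model = GeneModel(
        gene_name=spec.gene_name,
        segments=segs,
        frame_anchor=segs[0].start,
        numbering_map=numbering,
        reference_taxon=reference,
    )

    # finalize event coordinates
    seg_names: dict[int, str] = {}
    counts = {"exon": 0, "intron": 0}
    for s in segs:
        counts[s.kind] += 1
        for c in range(s.start, s.end + 1):
            seg_names[c] = f"{s.kind}{counts[s.kind]}"
    for ev, carriers, detail, c0, c1 in pending:
        if ev.lesion_type == "frameshift_insertion":
            f0 = final_col(c0) + 1  # first inserted column sits after the anchor
            f1 = f0 + ev.size - 1
        else:
            f0, f1 = final_col(c0), final_col(c1)
        final_events.append(TruthEvent(
            branch=ev.branch, lesion_type=ev.lesion_type, fraction=ev.fraction,
            start=f0, end=f1, detail=detail, carriers=list(carriers),
            segment=seg_names.get(f0, "?"),
        ))

    truth = TruthLog(
        events=final_events,
        node_cds={nid: "".join(c) for nid, c in node_cds.items()},
        node_introns=dict(node_introns),
        branch_omega=branch_omega,
        switch_points=switch_points,
        seed=seed,
    )
    return aln, model, truth


# ---------------------------------------------------------------------------
# composite cetartiodactyl tree and the packaged three-gene emulation
# ---------------------------------------------------------------------------

# Composite whale/hippo/bovid species tree.  Internal node ids are explicit
# (26 = whale+hippo ancestor, 27 = crown Cetacea, 28 = Mysticeti,
# 35 = Odontoceti, ...) so branches can be addressed by the ancestor:descendant
# numbering used in the field; tip labels carry their tip number as a prefix.
# Structure: (label, edge_length, children).
_COMPOSITE = (
    "52", None, [
        ("Bos_taurus", 0.3, []),
        ("26", 0.1, [
            ("Hippopotamus_amphibius", 0.25, []),
            ("27", 0.08, [
            ("28", 0.04, [
                ("29", 0.03, [
                    ("1_Balaena_mysticetus", 0.05, []),
                    ("50", 0.02, [
                        ("2_Eubalaena_japonica", 0.03, []),
                        ("3_Eubalaena_australis", 0.03, []),
                    ]),
                ]),
                ("30", 0.02, [
                    ("4_Caperea_marginata", 0.06, []),
                    ("31", 0.02, [
                        ("9_Balaenoptera_acutorostrata", 0.05, []),
                        ("32", 0.012, [
                            ("8_Balaenoptera_borealis", 0.04, []),
                            ("33", 0.012, [
                                ("6_Eschrichtius_robustus", 0.04, []),
                                ("34", 0.012, [
                                    ("7_Megaptera_novaeangliae", 0.035, []),
                                    ("5_Balaenoptera_physalus", 0.035, []),
                                ]),
                            ]),
                        ]),
                    ]),
                ]),
            ]),
            ("35", 0.04, [
                ("36", 0.03, [
                    ("10_Physeter_macrocephalus", 0.05, []),
                    ("11_Kogia_breviceps", 0.05, []),
                ]),
                ("37", 0.012, [
                    ("12_Platanista_minor", 0.065, []),
                    ("38", 0.012, [
                        ("39", 0.02, [
                            ("16_Berardius_bairdii", 0.04, []),
                            ("40", 0.01, [
                                ("15_Ziphius_cavirostris", 0.035, []),
                                ("41", 0.01, [
                                    ("13_Mesoplodon_bidens", 0.03, []),
                                    ("14_Tasmacetus_shepherdi", 0.03, []),
                                ]),
                            ]),
                        ]),
                        ("42", 0.012, [
                            ("43", 0.015, [
                                ("17_Pontoporia_blainvillei", 0.045, []),
                                ("18_Inia_geoffrensis", 0.045, []),
                            ]),
                            ("44", 0.012, [
                                ("45", 0.012, [
                                    ("22_Delphinapterus_leucas", 0.035, []),
                                    ("46", 0.012, [
                                        ("19_Neophocaena_phocaenoides", 0.025, []),
                                        ("47", 0.008, [
                                            ("20_Phocoenoides_dalli", 0.02, []),
                                            ("21_Phocoena_phocoena", 0.02, []),
                                        ]),
                                    ]),
                                ]),
                                ("48", 0.018, [
                                    ("25_Globicephala_melas", 0.03, []),
                                    ("49", 0.008, [
                                        ("24_Tursiops_truncatus", 0.025, []),
                                        ("23_Orcinus_orca", 0.025, []),
                                    ]),
                                ]),
                            ]),
                        ]),
                    ]),
                ]),
            ]),
            ]),
        ]),
    ],
)


def _newick_of(node) -> str:
    label, length, children = node
    s = "(" + ",".join(_newick_of(c) for c in children) + ")" + label \
        if children else label
    return s + (f":{length:g}" if length is not None else "")


COMPOSITE_TREE_NEWICK = _newick_of(_COMPOSITE) + ";"


def composite_tree() -> SpeciesTree:
    """The node-numbered composite species tree used by all packaged fixtures."""
    return SpeciesTree.from_newick(COMPOSITE_TREE_NEWICK)


def _codon_for(residue: str, like: str | None = None) -> str:
    table = {"D": "GAT", "N": "AAT", "A": "GCT", "S": "TCT", "T": "ACT",
             "E": "GAA", "G": "GGA", "H": "CAT", "Y": "TAT", "P": "CCT",
             "K": "AAA", "L": "CTT"}
    return table[residue]


RH1_SITES = (83, 292, 299)
LWS_SITES = (180, 197, 277, 285, 308)


def opsin_history_specs(tree: SpeciesTree | None = None, seed: int = 0) -> dict[str, SimSpec]:
    """Three-gene emulation of the inferred cetacean opsin history.

    The short-wave cone opsin is knocked out independently on the stem
    mysticete (shared 4-bp frameshift deletion) and stem odontocete (E113G
    counterion replacement) branches; the long-wave cone opsin is knocked
    out on five branches (stem Balaenidae, stem Balaenopteroidea, Sowerby's
    beaked whale, giant and pygmy sperm whales) with eight frameshift indels
    and three splice disruptions in total; rod opsin stays intact with
    tuning-site substitutions producing one basal blue shift, three parallel
    blue shifts and seven red shifts.
    """
    tree = tree or composite_tree()
    b = lambda a, d: (a, d)  # noqa: E731

    sws1 = SimSpec(
        tree=tree, codons=338, kappa=3.0, omega=0.2, seed=seed,
        gene_name="SWS1",
        reference_taxon="Hippopotamus_amphibius",
        introns=[(80, 60), (160, 60), (240, 60), (300, 60)],
        tuning_root={113: _codon_for("E")},
        lesions=[
            LesionEvent(b(27, 28), 0.15, "frameshift_deletion", size=4, cds_codon=30),
            LesionEvent(b(27, 35), 0.15, "key_missense", cds_codon=113,
                        to=_codon_for("G")),
            LesionEvent(b(35, 36), 0.5, "splice_donor", intron=4, to="GA"),
            LesionEvent(b(36, 10), 0.3, "frameshift_insertion", size=1, cds_codon=103),
            LesionEvent(b(48, 25), 0.4, "frameshift_insertion", size=4, cds_codon=200),
            LesionEvent(b(31, 9), 0.5, "nonsense", cds_codon=250),
        ],
    )

    lws = SimSpec(
        tree=tree, codons=364, kappa=3.0, omega=0.15, seed=seed + 1,
        gene_name="LWS",
        reference_taxon="Hippopotamus_amphibius",
        introns=[(60, 50), (120, 50), (180, 50), (240, 50), (300, 50)],
        tuning_root={180: _codon_for("A"), 197: _codon_for("H"),
                     277: _codon_for("Y"), 285: _codon_for("T"),
                     308: _codon_for("A")},
        tuning_changes=[
            TuningChange(b(27, 28), 308, _codon_for("S")),
            TuningChange(b(42, 44), 308, _codon_for("S")),
            TuningChange(b(43, 18), 308, _codon_for("P")),
        ],
        lesions=[
            LesionEvent(b(28, 29), 0.3, "frameshift_deletion", size=1, cds_codon=40),
            LesionEvent(b(30, 31), 0.3, "frameshift_deletion", size=4, cds_codon=100),
            LesionEvent(b(41, 13), 0.3, "frameshift_insertion", size=2, cds_codon=150),
            LesionEvent(b(36, 10), 0.3, "frameshift_deletion", size=2, cds_codon=200),
            LesionEvent(b(36, 11), 0.3, "frameshift_insertion", size=1, cds_codon=250),
            LesionEvent(b(31, 9), 0.5, "frameshift_deletion", size=1, cds_codon=130),
            LesionEvent(b(33, 6), 0.5, "frameshift_insertion", size=4, cds_codon=170),
            LesionEvent(b(29, 1), 0.5, "frameshift_deletion", size=2, cds_codon=80),
            LesionEvent(b(31, 32), 0.5, "splice_donor", intron=2, to="GC"),
            LesionEvent(b(29, 50), 0.5, "splice_acceptor", intron=3, to="AA"),
            LesionEvent(b(36, 10), 0.6, "splice_donor", intron=4, to="GA"),
        ],
    )

    rh1 = SimSpec(
        tree=tree, codons=348, kappa=3.0, omega=0.1, seed=seed + 2,
        gene_name="RH1",
        reference_taxon="Hippopotamus_amphibius",
        tuning_root={83: _codon_for("D"), 292: _codon_for("A"),
                     299: _codon_for("S"), 195: _codon_for("K")},
        tuning_changes=[
            TuningChange(b(26, 27), 83, _codon_for("N")),
            TuningChange(b(26, 27), 292, _codon_for("S")),
            TuningChange(b(26, 27), 195, _codon_for("T")),
            TuningChange(b(28, 29), 292, _codon_for("A")),
            TuningChange(b(30, 4), 299, _codon_for("A")),
            TuningChange(b(33, 6), 292, _codon_for("A")),
            TuningChange(b(34, 7), 83, _codon_for("D")),
            TuningChange(b(35, 36), 299, _codon_for("A")),
            TuningChange(b(38, 39), 299, _codon_for("A")),
            TuningChange(b(42, 43), 292, _codon_for("A")),
            TuningChange(b(43, 17), 83, _codon_for("D")),
            TuningChange(b(43, 18), 299, _codon_for("T")),
            TuningChange(b(44, 45), 83, _codon_for("D")),
            TuningChange(b(45, 22), 292, _codon_for("A")),
        ],
    )
    return {"SWS1": sws1, "LWS": lws, "RH1": rh1}


def crown_branches(tree: SpeciesTree, stem_descendants: list[int]
                   ) -> list[tuple[int, int]]:
    """All branches strictly inside the subtrees rooted at the given nodes."""
    out: list[tuple[int, int]] = []
    for top in stem_descendants:
        stack = [top]
        while stack:
            nid = stack.pop()
            for ch in tree.nodes[nid].children:
                out.append((nid, ch))
                stack.append(ch)
    return out


def opsin_history_fixture(seed: int = 0) -> dict:
    """Simulate the packaged three-gene history; returns alignments, models,
    truth logs, the tree and the specs, keyed by gene name."""
    tree = composite_tree()
    specs = opsin_history_specs(tree, seed)
    out: dict = {"tree": tree, "specs": specs, "genes": {}}
    for gene, spec in specs.items():
        aln, model, truth = simulate(spec)
        out["genes"][gene] = {"alignment": aln, "model": model, "truth": truth}
    return out


def write_fixture(outdir, seed: int = 0) -> list:
    """Materialize the packaged three-gene fixture as plain-text files.

    Writes FASTA and NEXUS alignments, gene-model YAMLs, the tree, JSON truth
    logs and a ready-to-run pipeline config; returns the written paths.
    """
    import json
    from pathlib import Path

    import yaml

    from .data_io import save_gene_model, write_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = opsin_history_fixture(seed)
    tree: SpeciesTree = fx["tree"]
    written = []

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(COMPOSITE_TREE_NEWICK + "\n")
    written.append(tree_path)

    genes_cfg = []
    for gene, parts in fx["genes"].items():
        aln, model, truth = parts["alignment"], parts["model"], parts["truth"]
        fasta = outdir / f"{gene}.fasta"
        write_alignment(aln, fasta, "fasta")
        nexus = outdir / f"{gene}.nex"
        write_alignment(aln, nexus, "nexus")
        model_path = outdir / f"{gene}_model.yaml"
        save_gene_model(model, model_path)
        truth_path = outdir / f"{gene}_truth.json"
        truth_path.write_text(json.dumps({
            "seed": truth.seed,
            "events": [{
                "branch": list(e.branch), "lesion_type": e.lesion_type,
                "fraction": e.fraction, "start": e.start, "end": e.end,
                "detail": e.detail, "carriers": e.carriers,
                "segment": e.segment} for e in truth.events],
            "branch_omega": {f"{a}:{d}": w
                             for (a, d), w in truth.branch_omega.items()},
            "switch_points": {f"{a}:{d}": f
                              for (a, d), f in truth.switch_points.items()},
            "node_cds": {str(k): v for k, v in truth.node_cds.items()},
        }, indent=1))
        written += [fasta, nexus, model_path, truth_path]
        entry = {"name": gene, "alignment": fasta.name, "format": "fasta",
                 "gene_model": model_path.name}
        if gene == "RH1":
            entry["tuning_table"] = "rh1"
        elif gene == "LWS":
            entry["tuning_table"] = "lws"
        if gene == "SWS1":
            entry["key_residue_rules"] = [{
                "gene": "SWS1", "residue": 113, "intact": ["E"],
                "inactivating": ["G"],
                "rationale": "Schiff's base counterion; E113G disrupts "
                             "opsin-chromophore binding"}]
        genes_cfg.append(entry)

    crown = crown_branches(tree, [28, 35])
    config = {
        "genes": genes_cfg,
        "tree": tree_path.name,
        "outdir": "reports",
        "seed": seed,
        "branch_categories": {
            "crown_odontocete_plus_crown_mysticete":
                [f"{a}:{d}" for a, d in sorted(crown)],
            "odontocete_stem": ["27:35"],
            "mysticete_stem": ["27:28"],
        },
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    written.append(config_path)
    return written
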