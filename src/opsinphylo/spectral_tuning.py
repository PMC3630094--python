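"""Rule-based lambda_max inference and per-branch spectral-shift calls.

Visual pigment absorbance maxima (lambda_max) are assigned by exact lookup of
the residues at a handful of key tuning sites against tables of directly
measured pigments: a three-site rule for rod opsin (sites 83/292/299, bovine
numbering) and the "five-sites" rule for the L-cone opsin (180/197/277/285/
308).  No interpolation is performed — a residue combination that has never
been expressed and measured is *unknown*.

A branch is called blue-shifted when the descendant lambda_max is lower than
the ancestral one and red-shifted when higher.  Range-valued assignments
compare by interval order: the call is made only when the interval lies
strictly on one side of the other value.  Branches on which the gene is
already pseudogenic are never assigned shifts.

Secondary rod-opsin tuning sites (96, 102, 122, 183, 194, 195, 253, 261,
289, 317) can be tracked descriptively but are never converted to
lambda_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .data_io import SpeciesTree
from .parsimony_mapper import BranchPainting, PSEUDOGENIC, TRANSITIONAL

RH1_SECONDARY_SITES = (96, 102, 122, 183, 194, 195, 253, 261, 289, 317)

LambdaValue = float | tuple[float, float] | None  # point, [low,high], or unknown


@dataclass
class TuningRuleTable:
    """Residue-tuple -> lambda_max lookup for one opsin."""

    opsin: str
    site_numbers: tuple[int, ...]
    rows: dict[str, LambdaValue]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        for tup, val in self.rows.items():
            if len(tup) != len(self.site_numbers):
                raise ValueError(f"tuple {tup} length != {len(self.site_numbers)} sites")
            if val is not None:
                lo, hi = (val, val) if isinstance(val, float) else val
                if not (300.0 <= lo <= hi <= 700.0):
                    raise ValueError(f"lambda_max {val} outside 300-700 nm")

    @classmethod
    def from_tsv(cls, path_or_name) -> "TuningRuleTable":
        rows: dict[str, LambdaValue] = {}
        provenance: dict[str, str] = {}
        opsin = None
        sites: tuple[int, ...] = ()
        with open(path_or_name) as fh:
            header: list[str] | None = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                rec = dict(zip(header, line.split("\t")))
                opsin = rec["opsin"]
                sites = tuple(int(s) for s in rec["sites"].split(","))
                if rec["lambda_low"] == "unknown":
                    val: LambdaValue = None
                elif rec["lambda_low"] == rec["lambda_high"]:
                    val = float(rec["lambda_low"])
                else:
                    val = (float(rec["lambda_low"]), float(rec["lambda_high"]))
                if rec["tuple"] in rows:
                    raise ValueError(f"duplicate tuple {rec['tuple']}")
                rows[rec["tuple"]] = val
                provenance[rec["tuple"]] = rec.get("provenance", "")
        if opsin is None:
            raise ValueError(f"no rule rows found in {path_or_name}")
        return cls(opsin, sites, rows, provenance)


def builtin_table(name: str) -> TuningRuleTable:
    """Load a packaged rule table: 'rh1' (three-site) or 'lws' (five-sites)."""
    fname = {"rh1": "rh1_rules.tsv", "lws": "lws_rules.tsv"}[name.lower()]
    ref = resources.files("opsinphylo.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return TuningRuleTable.from_tsv(path)


def assign_lambda(residue_tuple: str, table: TuningRuleTable) -> LambdaValue:
    """Exact-tuple lambda_max lookup; misses and unmeasured rows return None."""
    if len(residue_tuple) != len(table.site_numbers):
        raise ValueError(
            f"tuple {residue_tuple!r} length != table sites {table.site_numbers}")
    return table.rows.get(residue_tuple)


def _interval(val: LambdaValue) -> tuple[float, float] | None:
    if val is None:
        return None
    if isinstance(val, tuple):
        return val
    return (val, val)


def compare_lambda(anc: LambdaValue, desc: LambdaValue) -> str:
    """'blue' | 'red' | 'none' | 'unknown' by strict interval order."""
    a, d = _interval(anc), _interval(desc)
    if a is None or d is None:
        return "unknown"
    if a == d:
        return "none"
    if d[1] < a[0]:
        return "blue"
    if d[0] > a[1]:
        return "red"
    return "unknown"  # overlapping intervals cannot be ordered


@dataclass
class BranchShift:
    branch: tuple[int, int]
    ancestor_tuple: str
    descendant_tuple: str
    ancestor_lambda: LambdaValue
    descendant_lambda: LambdaValue
    shift: str  # blue | red | none | unknown
    delta: float | None = None


@dataclass
class TuningAssignment:
    """Per-node lambda_max and per-branch shift classification for one opsin."""

    opsin: str
    node_tuples: dict[int, str]
    node_lambda: dict[int, LambdaValue]
    shifts: list[BranchShift]


def classify_branch_shifts(
    tree: SpeciesTree,
    node_tuples: dict[int, str],
    table: TuningRuleTable,
    painting: BranchPainting | None = None,
) -> TuningAssignment:
    """Call blue/red shifts on every branch where the key-site tuple changes.

    ``node_tuples`` maps node id to its residue string at the table's sites
    (tips from observed data, internal nodes from ancestral reconstruction).
    Branches that are pseudogenic or transitional in ``painting`` are excluded
    from shift calling: a dead gene has no pigment to tune.
    """
    node_lambda = {nid: assign_lambda(tup, table)
                   for nid, tup in node_tuples.items()}
    shifts: list[BranchShift] = []
    for anc, desc in tree.branches():
        if anc not in node_tuples or desc not in node_tuples:
            continue
        if painting is not None and painting.status.get((anc, desc)) in \
                (PSEUDOGENIC, TRANSITIONAL):
            continue
        t_anc, t_desc = node_tuples[anc], node_tuples[desc]
        if t_anc == t_desc:
            continue
        l_anc, l_desc = node_lambda[anc], node_lambda[desc]
        shift = compare_lambda(l_anc, l_desc)
        delta = None
        if isinstance(l_anc, float) and isinstance(l_desc, float):
            delta = l_desc - l_anc
        shifts.append(BranchShift((anc, desc), t_anc, t_desc,
                                  l_anc, l_desc, shift, delta))
    return TuningAssignment(table.opsin, dict(node_tuples), node_lambda, shifts)
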