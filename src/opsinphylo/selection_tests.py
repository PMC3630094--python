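"""Branch-category dN/dS estimation and chi-square neutrality tests.

The machinery follows the classic mutational-opportunity logic: each codon
offers nine single-nucleotide changes, partitioned into synonymous and
nonsynonymous *sites* (fractional, weighted by the stationary frequency of
the change), and observed substitutions along branches are classified the
same way, averaging over minimal mutational pathways when ancestor and
descendant differ at more than one codon position.

Under strict neutrality (omega = 1) the nonsynonymous share of substitutions
equals the nonsynonymous share of sites, so for a pooled branch set with
T = obs_N + obs_S observed substitutions,

    exp_N = T * N_sites / (N_sites + S_sites),      exp_S = T - exp_N,
    omega = (obs_N / exp_N) / (obs_S / exp_S),
    chi2  = (obs_N-exp_N)^2/exp_N + (obs_S-exp_S)^2/exp_S,   df = 1,

with no continuity correction.  Site counting supports two codon-frequency
conventions (CF2: position-specific nucleotide frequencies, CF3: empirical
codon frequencies) and an optional transition/transversion weight kappa so
the expectation stays calibrated when the substitution process is
transition-biased.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .asr import AncestralStateTable
from .data_io import (
    CodonAlignment,
    GENETIC_CODE,
    GeneModel,
    SpeciesTree,
    STOP_CODONS,
    reference_codon_columns,
)
from .parsimony_mapper import BranchPainting, FUNCTIONAL, PSEUDOGENIC, TRANSITIONAL

logger = logging.getLogger("opsinphylo")

CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class SiteCounts:
    """Fractional nonsynonymous/synonymous site totals for an alignment."""

    N_sites: float
    S_sites: float
    codons: int  # analyzable codons (averaged over taxa)
    codon_frequency_model: str  # "CF2" | "CF3" | "uniform"

    @property
    def total(self) -> float:
        return self.N_sites + self.S_sites


@dataclass
class BranchCategoryTest:
    """Observed vs neutral-expected substitution counts for one branch pool."""

    category: str
    branches: list[tuple[int, int]]
    obs_N: float
    obs_S: float
    exp_N: float
    exp_S: float
    omega: float  # may be inf when obs_S == 0
    chi2: float
    p: float
    df: int = 1


@dataclass
class SimOmega:
    """True per-branch omega of a simulation, with mid-branch neutral switches."""

    branch_omega: dict[tuple[int, int], float]
    switch_points: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for br, f in self.switch_points.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"switch fraction {f} on {br} outside [0,1]")


# ---------------------------------------------------------------------------
# site counting
# ---------------------------------------------------------------------------

def _target_weights(cf: str, aln_codons: list[str]) -> dict:
    """Stationary weighting of mutation targets under the CF convention."""
    if cf == "uniform":
        return {"mode": "uniform"}
    if cf == "CF3":
        counts: dict[str, float] = {c: 1e-9 for c in CODONS}
        for c in aln_codons:
            if c in counts:
                counts[c] += 1.0
        return {"mode": "CF3", "freq": counts}
    if cf == "CF2":
        pos = np.full((3, 4), 1e-9)
        idx = {b: i for i, b in enumerate("ACGT")}
        for c in aln_codons:
            for k, b in enumerate(c):
                pos[k, idx[b]] += 1.0
        pos /= pos.sum(axis=1, keepdims=True)
        return {"mode": "CF2", "pos": pos, "idx": idx}
    raise ValueError(f"unknown codon frequency model {cf}")


def _weight(cf_state: dict, codon: str, position: int, new_base: str) -> float:
    mode = cf_state["mode"]
    if mode == "uniform":
        return 1.0
    if mode == "CF3":
        target = codon[:position] + new_base + codon[position + 1:]
        return cf_state["freq"][target]
    return float(cf_state["pos"][position, cf_state["idx"][new_base]])


def codon_site_fractions(codon: str, cf_state: dict, kappa: float = 1.0
                         ) -> tuple[float, float] | None:
    """(N, S) site fractions of one codon; None if it is a stop or untranslatable.

    Each codon position contributes exactly one site, split among its three
    possible changes in proportion to their weights; changes to stop codons
    are excluded and the position renormalized.
    """
    if codon in STOP_CODONS or any(b not in "ACGT" for b in codon):
        return None
    aa = GENETIC_CODE[codon]
    n_total = s_total = 0.0
    for pos in range(3):
        wn = ws = 0.0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            target = codon[:pos] + b + codon[pos + 1:]
            if target in STOP_CODONS:
                continue
            w = _weight(cf_state, codon, pos, b)
            if (codon[pos], b) in TRANSITIONS:
                w *= kappa
            if GENETIC_CODE[target] == aa:
                ws += w
            else:
                wn += w
        tot = wn + ws
        if tot > 0:
            n_total += wn / tot
            s_total += ws / tot
    return n_total, s_total


def count_sites(
    aln: CodonAlignment,
    model: GeneModel,
    cf: str = "CF3",
    kappa: float = 1.0,
) -> SiteCounts:
    """Fractional N/S site counts, averaged over taxa.

    Stop codons (including terminal stops), gapped and ambiguous codons are
    excluded from the analyzable set and logged.
    """
    codon_cols = reference_codon_columns(aln, model)
    all_codons: list[str] = []
    per_taxon: dict[str, list[str]] = {}
    for taxon in aln.taxa:
        row = aln[taxon]
        codons = ["".join(row[c - 1] for c in cols) for cols in codon_cols]
        per_taxon[taxon] = codons
        all_codons.extend(c for c in codons
                          if c in GENETIC_CODE and c not in STOP_CODONS)
    cf_state = _target_weights(cf, all_codons)

    n_sum = s_sum = 0.0
    analyzable = 0
    skipped = 0
    for taxon in aln.taxa:
        for codon in per_taxon[taxon]:
            frac = codon_site_fractions(codon, cf_state, kappa)
            if frac is None:
                skipped += 1
                continue
            n_sum += frac[0]
            s_sum += frac[1]
            analyzable += 1
    if skipped:
        logger.info("%s: %d codons excluded from site counting (stop/gap/ambiguous)",
                    model.gene_name, skipped)
    ntaxa = len(aln.taxa)
    return SiteCounts(
        N_sites=n_sum / ntaxa,
        S_sites=s_sum / ntaxa,
        codons=round(analyzable / ntaxa),
        codon_frequency_model=cf,
    )


# ---------------------------------------------------------------------------
# observed substitutions
# ---------------------------------------------------------------------------

def classify_codon_change(anc: str, desc: str) -> tuple[float, float] | None:
    """(N, S) substitutions between two codons, averaged over minimal pathways.

    Pathways passing through stop codons are excluded; returns None when the
    codons are untranslatable or no stop-free pathway exists.
    """
    if anc == desc:
        return (0.0, 0.0)
    for c in (anc, desc):
        if any(b not in "ACGT" for b in c) or c in STOP_CODONS:
            return None
    diff = [i for i in range(3) if anc[i] != desc[i]]
    paths: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = anc
        n = s = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + desc[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        if ok:
            paths.append((n, s))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def count_branch_substitutions(
    table: AncestralStateTable,
    tree: SpeciesTree,
    branches: list[tuple[int, int]],
    codon_columns: list[tuple[int, int, int]],
) -> tuple[float, float]:
    """Pooled (obs_N, obs_S) over a branch set from MAP ancestor/descendant codons.

    ``codon_columns`` are the 1-based columns of each codon in the alignment
    the ancestral table was built on (the reference-frame codons).
    """
    obs_n = obs_s = 0.0
    for anc, desc in branches:
        if not tree.has_branch(anc, desc):
            raise KeyError(f"branch {anc}:{desc} not in tree")
        for cols in codon_columns:
            a = "".join(table.map_state(anc, c) for c in cols)
            d = "".join(table.map_state(desc, c) for c in cols)
            counted = classify_codon_change(a, d)
            if counted is not None:
                obs_n += counted[0]
                obs_s += counted[1]
    return obs_n, obs_s


# ---------------------------------------------------------------------------
# neutrality test
# ---------------------------------------------------------------------------

def chi_square_neutrality(obs_N: float, obs_S: float,
                          exp_N: float, exp_S: float) -> tuple[float, float]:
    """Chi-square statistic (df=1) and p-value for observed vs expected counts."""
    chi2 = (obs_N - exp_N) ** 2 / exp_N + (obs_S - exp_S) ** 2 / exp_S
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def neutrality_test(
    obs_N: float,
    obs_S: float,
    sites: SiteCounts,
    category: str = "",
    branches: list[tuple[int, int]] | None = None,
) -> BranchCategoryTest:
    """Test a pooled branch set against the strictly neutral expectation.

    With zero observed synonymous substitutions omega is reported as inf;
    the chi-square test itself remains valid.
    """
    total = obs_N + obs_S
    if total <= 0:
        raise ValueError("neutrality test requires obs_N + obs_S > 0")
    exp_n = total * sites.N_sites / sites.total
    exp_s = total - exp_n
    rate_n = obs_N / exp_n
    rate_s = obs_S / exp_s
    omega = rate_n / rate_s if rate_s > 0 else float("inf")
    chi2, p = chi_square_neutrality(obs_N, obs_S, exp_n, exp_s)
    return BranchCategoryTest(
        category=category,
        branches=branches or [],
        obs_N=obs_N, obs_S=obs_S,
        exp_N=exp_n, exp_S=exp_s,
        omega=omega, chi2=chi2, p=p,
    )


def omega_by_status(
    painting: BranchPainting,
    table: AncestralStateTable,
    tree: SpeciesTree,
    codon_columns: list[tuple[int, int, int]],
    sites: SiteCounts,
) -> dict[str, BranchCategoryTest]:
    """Pooled omega per functional status class, with the neutrality test
    applied to every non-empty pool (the pseudogenic pool is the one of
    interest; the others are reported for context)."""
    pools: dict[str, list[tuple[int, int]]] = {
        FUNCTIONAL: [], TRANSITIONAL: [], PSEUDOGENIC: []}
    for br, status in painting.status.items():
        pools[status].append(br)
    out: dict[str, BranchCategoryTest] = {}
    for status, branches in pools.items():
        if not branches:
            continue
        obs_n, obs_s = count_branch_substitutions(table, tree, branches,
                                                  codon_columns)
        if obs_n + obs_s == 0:
            continue
        out[status] = neutrality_test(obs_n, obs_s, sites,
                                      category=status, branches=branches)
    return out
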