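"""Maximum-likelihood marginal ancestral reconstruction under GTR (REV).

The model is the general time-reversible nucleotide substitution model:
rate(i->j) = s_ij * pi_j with six symmetric exchangeabilities s_ij and
stationary base frequencies pi, normalized to one expected substitution per
site per unit branch length.  Likelihoods are computed with Felsenstein's
pruning algorithm over site patterns; gaps and ambiguity codes enter as
partial-likelihood vectors (all-ones for missing data), the same treatment
PAML's Baseml applies.

Marginal reconstruction is empirical-Bayes: for each internal node the
posterior over {A,C,G,T} at each column is proportional to the product of
the likelihood messages arriving from every direction, computed with one
post-order (tip-ward) and one pre-order (root-ward) sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .data_io import AMBIGUITY, CodonAlignment, SpeciesTree, translate_codon

logger = logging.getLogger("opsinphylo")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# exchangeability order: AC, AG, AT, CG, CT, GT
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class GtrModel:
    """GTR parameters: six exchangeabilities (AC,AG,AT,CG,CT,GT) and pi."""

    exchangeabilities: np.ndarray  # shape (6,)
    base_frequencies: np.ndarray   # shape (4,), sums to 1
    gamma_shape: float | None = None
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        self.base_frequencies = np.asarray(self.base_frequencies, float)
        if np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be positive")
        if np.any(self.base_frequencies < 0) or \
                abs(self.base_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must be >=0 and sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """Q normalized to mean rate 1."""
        s = np.zeros((4, 4))
        for k, (i, j) in enumerate(EXCH_PAIRS):
            s[i, j] = s[j, i] = self.exchangeabilities[k]
        q = s * self.base_frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.base_frequencies, np.diag(q))
        return q / mu

    def eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric eigendecomposition of the reversible Q (for fast expm)."""
        q = self.rate_matrix()
        d = np.sqrt(self.base_frequencies)
        b = (q * d[:, None]) / d[None, :]
        lam, v = np.linalg.eigh((b + b.T) / 2.0)
        left = v.T * d[None, :]           # rows: V^T D^{1/2}
        right = (v / d[:, None])          # D^{-1/2} V
        return lam, right, left

    def rate_categories(self) -> np.ndarray:
        """Mean-one discrete-gamma category rates (or [1] when disabled)."""
        if self.gamma_shape is None:
            return np.array([1.0])
        k = self.gamma_categories
        quantiles = (np.arange(k) + 0.5) / k
        rates = gamma_dist.ppf(quantiles, a=self.gamma_shape,
                               scale=1.0 / self.gamma_shape)
        return rates / rates.mean()


def transition_matrix(model: GtrModel, t: float,
                      eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                      ) -> np.ndarray:
    lam, right, left = eig if eig is not None else model.eig()
    p = (right * np.exp(lam * t)[None, :]) @ left
    return np.clip(p, 0.0, None)


def _leaf_partial(char: str) -> np.ndarray:
    v = np.zeros(4)
    compatible = AMBIGUITY.get(char.upper())
    if compatible is None:  # gap or unknown symbol: missing data
        return np.ones(4)
    for b in compatible:
        v[BASE_INDEX[b]] = 1.0
    return v


def encode_alignment(aln: CodonAlignment) -> dict[str, np.ndarray]:
    """Per-taxon (L,4) partial-likelihood arrays."""
    return {t: np.array([_leaf_partial(c) for c in aln[t]]) for t in aln.taxa}


def _patterns(aln: CodonAlignment) -> tuple[CodonAlignment, np.ndarray, np.ndarray]:
    """Unique column patterns, their weights, and column->pattern index."""
    cols = list(zip(*[aln[t] for t in aln.taxa]))
    uniq: dict[tuple, int] = {}
    col_to_pat = np.zeros(len(cols), dtype=int)
    weights: list[int] = []
    for i, col in enumerate(cols):
        if col not in uniq:
            uniq[col] = len(uniq)
            weights.append(0)
        col_to_pat[i] = uniq[col]
        weights[uniq[col]] += 1
    pat_rows = {t: "".join(col[j] for col in uniq) for j, t in enumerate(aln.taxa)}
    pat_aln = CodonAlignment(list(aln.taxa), pat_rows)
    return pat_aln, np.array(weights, float), col_to_pat


def _tipward_partials(
    tree: SpeciesTree,
    leaf_partials: dict[int, np.ndarray],
    pmats: dict[int, np.ndarray],
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Post-order conditional likelihoods; returns partials and log scalers."""
    some = next(iter(leaf_partials.values()))
    npat = some.shape[0]
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(npat)
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            partials[nid] = leaf_partials[nid].T.copy()  # (4, P)
        else:
            prod = np.ones((4, npat))
            for ch in node.children:
                prod *= pmats[ch] @ partials[ch]
            mx = prod.max(axis=0)
            mx[mx == 0] = 1.0
            log_scale += np.log(mx)
            partials[nid] = prod / mx[None, :]
    return partials, log_scale


def pruning_loglik(
    tree: SpeciesTree,
    aln: CodonAlignment,
    model: GtrModel,
    branch_lengths: dict[int, float] | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree."""
    pat_aln, weights, _ = _patterns(aln)
    enc = encode_alignment(pat_aln)
    leaf_partials = {tree.id_of_label(t): enc[t] for t in pat_aln.taxa}
    bl = branch_lengths or {nid: tree.nodes[nid].edge_length
                            for nid in tree.preorder() if nid != tree.root_id}
    eig = model.eig()
    rates = model.rate_categories()
    pi = model.base_frequencies
    site_lik = np.zeros(len(weights))
    total_extra = 0.0
    for rate in rates:
        pmats = {nid: transition_matrix(model, bl[nid] * rate, eig)
                 for nid in bl}
        partials, log_scale = _tipward_partials(tree, leaf_partials, pmats)
        lik = pi @ partials[tree.root_id]
        site_lik += np.exp(np.log(np.clip(lik, 1e-300, None)) + log_scale) / len(rates)
    return float(np.dot(weights, np.log(np.clip(site_lik, 1e-300, None))) + total_extra)


def empirical_base_frequencies(aln: CodonAlignment) -> np.ndarray:
    counts = np.ones(4)  # pseudocount keeps frequencies strictly positive
    for t in aln.taxa:
        for c in aln[t]:
            if c in BASE_INDEX:
                counts[BASE_INDEX[c]] += 1
    return counts / counts.sum()


def fit_gtr(
    aln: CodonAlignment,
    tree: SpeciesTree,
    gamma: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[GtrModel, dict[int, float], dict]:
    """Fit exchangeabilities and branch lengths by maximum likelihood.

    Base frequencies are fixed at their empirical estimates; the GT
    exchangeability is the reference (fixed at 1).  Optimization is
    deterministic: L-BFGS-B from empirical frequencies and uniform starting
    branch lengths, on log-transformed parameters.  Returns the model, the
    fitted branch lengths keyed by child node id, and an info dict with the
    log-likelihood trace.
    """
    if len(aln.taxa) < 3:
        logger.warning("fit_gtr on <3 taxa: branch lengths may be confounded")
    pat_aln, weights, _ = _patterns(aln)
    enc = encode_alignment(pat_aln)
    leaf_partials = {tree.id_of_label(t): enc[t] for t in pat_aln.taxa}
    branch_ids = [nid for nid in tree.preorder() if nid != tree.root_id]
    pi = empirical_base_frequencies(aln)
    nb = len(branch_ids)

    def unpack(x: np.ndarray) -> tuple[GtrModel, dict[int, float]]:
        exch = np.append(np.exp(x[:5]), 1.0)
        shape = float(np.exp(x[5 + nb])) if gamma else None
        model = GtrModel(exch, pi, gamma_shape=shape)
        bl = {nid: float(np.exp(x[5 + i])) for i, nid in enumerate(branch_ids)}
        return model, bl

    def negloglik(x: np.ndarray) -> float:
        model, bl = unpack(x)
        eig = model.eig()
        rates = model.rate_categories()
        site_lik = np.zeros(len(weights))
        for rate in rates:
            pmats = {nid: transition_matrix(model, bl[nid] * rate, eig)
                     for nid in branch_ids}
            partials, log_scale = _tipward_partials(tree, leaf_partials, pmats)
            lik = model.base_frequencies @ partials[tree.root_id]
            site_lik += np.exp(np.log(np.clip(lik, 1e-300, None)) + log_scale) \
                / len(rates)
        return -float(np.dot(weights, np.log(np.clip(site_lik, 1e-300, None))))

    x0 = np.concatenate([
        np.zeros(5),
        np.log(np.full(nb, 0.05)),
        [0.0] if gamma else [],
    ])
    lb = np.concatenate([np.full(5, -8.0), np.full(nb, np.log(1e-8)),
                         [-4.0] if gamma else []])
    ub = np.concatenate([np.full(5, 8.0), np.full(nb, np.log(20.0)),
                         [4.0] if gamma else []])
    trace: list[float] = [-negloglik(x0)]

    def callback(xk: np.ndarray) -> None:
        trace.append(-negloglik(xk))

    res = minimize(negloglik, x0, method="L-BFGS-B",
                   bounds=list(zip(lb, ub)),
                   callback=callback,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7})
    model, bl = unpack(res.x)
    if max(bl.values()) <= 2e-8:
        logger.warning("all fitted branch lengths at lower bound: "
                       "sequences may be identical (non-identifiable)")
    info = {"loglik": -float(res.fun), "converged": bool(res.success),
            "iterations": int(res.nit), "trace": trace}
    return model, bl, info


@dataclass
class AncestralStateTable:
    """Marginal posteriors and MAP sequences per node.

    ``posteriors`` holds (L,4) arrays for internal nodes; ``sequences`` holds
    the MAP nucleotide string per internal node and the observed row per tip.
    """

    node_ids: list[int]
    posteriors: dict[int, np.ndarray]
    sequences: dict[int, str]
    tip_ids: set[int] = field(default_factory=set)

    def map_state(self, nid: int, col: int) -> str:
        """MAP nucleotide at a 1-based column."""
        return self.sequences[nid][col - 1]

    def max_posterior(self, nid: int, col: int) -> float:
        if nid in self.tip_ids:
            return 1.0
        return float(self.posteriors[nid][col - 1].max())


def marginal_reconstruct(
    aln: CodonAlignment,
    tree: SpeciesTree,
    model: GtrModel,
    branch_lengths: dict[int, float] | None = None,
) -> AncestralStateTable:
    """Empirical-Bayes marginal posteriors for every internal node and column."""
    if model.gamma_shape is not None:
        logger.info("marginal reconstruction uses the mean rate "
                    "(gamma heterogeneity collapsed)")
    pat_aln, _, col_to_pat = _patterns(aln)
    enc = encode_alignment(pat_aln)
    leaf_partials = {tree.id_of_label(t): enc[t] for t in pat_aln.taxa}
    bl = branch_lengths or {nid: tree.nodes[nid].edge_length
                            for nid in tree.preorder() if nid != tree.root_id}
    eig = model.eig()
    pmats = {nid: transition_matrix(model, bl[nid], eig) for nid in bl}
    partials, _ = _tipward_partials(tree, leaf_partials, pmats)
    pi = model.base_frequencies

    npat = partials[tree.root_id].shape[1]
    above: dict[int, np.ndarray] = {tree.root_id: np.tile(pi[:, None], (1, npat))}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        messages = {ch: pmats[ch] @ partials[ch] for ch in node.children}
        for ch in node.children:
            sib = np.ones((4, npat))
            for other in node.children:
                if other != ch:
                    sib *= messages[other]
            contrib = above[nid] * sib
            up = pmats[ch].T @ contrib
            mx = up.max(axis=0)
            mx[mx == 0] = 1.0
            above[ch] = up / mx[None, :]

    node_ids = list(tree.preorder())
    tip_ids = set(tree.leaf_ids)
    posteriors: dict[int, np.ndarray] = {}
    sequences: dict[int, str] = {}
    for nid in node_ids:
        if nid in tip_ids:
            label = tree.nodes[nid].label or str(nid)
            sequences[nid] = aln[label]
            continue
        joint = above[nid] * partials[nid]
        norm = joint.sum(axis=0)
        norm[norm == 0] = 1.0
        post_pat = (joint / norm[None, :]).T  # (P, 4)
        post = post_pat[col_to_pat]
        posteriors[nid] = post
        sequences[nid] = "".join(BASES[i] for i in post.argmax(axis=1))
    return AncestralStateTable(node_ids, posteriors, sequences, tip_ids)


def codon_columns_by_residue(
    aln: CodonAlignment,
    reference_taxon: str,
    numbering_map: dict[int, int],
) -> dict[int, tuple[int, int, int]]:
    """Residue number -> the three 1-based columns of that codon.

    Operates on an exon-only (projected) alignment whose reference row defines
    the frame from its first non-gap column.
    """
    ref = aln[reference_taxon]
    cols = [c for c in range(1, aln.length + 1) if ref[c - 1] != "-"]
    cols = cols[: len(cols) - len(cols) % 3]
    out: dict[int, tuple[int, int, int]] = {}
    for codon_idx, residue in numbering_map.items():
        i = (codon_idx - 1) * 3
        if i + 2 < len(cols):
            out[residue] = (cols[i], cols[i + 1], cols[i + 2])
    return out


def node_residues(
    table: AncestralStateTable,
    site_columns: dict[int, tuple[int, int, int]],
    sites: list[int],
    min_posterior: float = 0.5,
) -> dict[int, tuple[str, bool]]:
    """Per-node residue tuple at the requested sites.

    Returns node_id -> (residue string, confident flag).  A site whose codon
    is gapped at a tip, or whose MAP posterior falls below ``min_posterior``
    at an internal node, is rendered '?' and the tuple flagged.
    """
    out: dict[int, tuple[str, bool]] = {}
    for nid in table.node_ids:
        residues = []
        confident = True
        for site in sites:
            cols = site_columns.get(site)
            if cols is None:
                residues.append("?")
                confident = False
                continue
            codon = "".join(table.map_state(nid, c) for c in cols)
            if any(ch not in "ACGT" for ch in codon):
                residues.append("?")
                confident = False
                continue
            if min(table.max_posterior(nid, c) for c in cols) < min_posterior:
                confident = False
            residues.append(translate_codon(codon))
        out[nid] = ("".join(residues), confident)
    return out
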