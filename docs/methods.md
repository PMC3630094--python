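# Methods

`opsinphylo` analyses the molecular decay and spectral retuning of retinal
opsin genes (rod opsin RH1 and the cone opsins SWS1 and LWS) on a fixed,
dated species tree.  This note documents the models, the numerical choices,
the synthetic data generator, and what the test suite does and does not
establish about real data.

## Coordinates, frames and reference anchoring

All alignment columns are 1-based and inclusive everywhere a user sees them;
half-open arithmetic exists only internally.  Every frame-dependent question
(codon boundaries, indel lengths, premature-stop positions, residue
numbering) is anchored on a designated *reference taxon* — an intact
outgroup sequence — because rows carrying inactivating lesions cannot define
a reading frame.  The gene model maps CDS codon indices to a reference
residue numbering (bovine rhodopsin numbering for the tuning sites), so
"site 113" means the same biological residue in every gene and at every
node.

## Lesion scanning

Four classes of inactivating mutation are detected in codon-aware
alignments:

- **Frameshift indels.**  Indel polarity is assigned against the reference:
  a gap run in the focal taxon where the reference has sequence is a
  deletion, sequence where the reference is gapped is an insertion.  A
  maximal run whose length is not a multiple of 3 is a frameshift.
  Adjacent but non-contiguous runs are never merged, even if jointly
  in-frame — each run is one record, which is conservative and matches
  per-row reporting in published lesion catalogues.
- **Premature stop codons.**  Each taxon's exon sequence is gap-stripped
  and translated in *its own* frame (i.e. the frame implied by its upstream
  indels, the reading a ribosome would attempt).  The first in-frame stop
  strictly upstream of the reference's terminal stop is reported.  The
  alternative — scanning in the unshifted reference frame — was considered
  and rejected: after a frameshift the original frame is biologically
  meaningless.  Stops caused solely by alignment gaps cannot arise because
  codons are assembled from the taxon's own bases.
- **Splice sites.**  The first two and last two bases of each intron are
  checked against the canonical GT donor / AG acceptor; any deviation is a
  lesion (detail recorded as e.g. "GT to GC").  Introns fully deleted in a
  taxon are unassessable and logged, not called.
- **Key-residue missense.**  Rule tables name residues whose replacement
  abolishes function (e.g. glutamate at the Schiff's base counterion
  position 113 of a short-wave opsin; glycine there disrupts chromophore
  binding).  Taxa whose translated residue falls in the inactivating set
  are reported as one merged record.

Records identical in type, coordinates and detail are merged across taxa.
Polymorphic lesions are flagged per taxon and count as "present" for
downstream mapping by default (configurable).

## Parsimony mapping and status painting

Each lesion becomes an unordered binary character (present/absent/missing).
Fitch/Sankoff dynamic programming gives the exact parsimony length, and all
most-parsimonious reconstructions are enumerated; the headline
reconstruction is the MPR with the fewest independent gains (deterministic
lexicographic tie-break), so the origin count is the minimum over MPRs.
Missing tips contribute no cost in either state rather than being imputed.
Outgroup polarity comes from the data (outgroups are scored absent), not
from a hard root constraint.

Painting is derived, not optimized: on each root-to-tip path, the earliest
branch carrying any lesion gain is *transitional* (the gene dies somewhere
on it), everything below is *pseudogenic*, everything above *functional*.
This makes painting monotone by construction — a pseudogene never reverts —
and the number of independent inactivations equals the number of
transitional branches (= maximal pseudogenic subtrees).

## Ancestral reconstruction

Nucleotide-level maximum likelihood under the general time-reversible (GTR)
model: rate(i→j) = s_ij·π_j, normalized to one expected substitution per
site.  Base frequencies are fixed at empirical estimates (with a
pseudocount); the five free exchangeabilities (GT is the reference) and all
branch lengths are optimized jointly by L-BFGS-B on log-transformed
parameters, started deterministically (uniform exchangeabilities, 0.05
branch lengths), converging at the default function tolerance of 1e-6.
The log-likelihood trace over accepted iterates is recorded and is
monotone.  Likelihoods use Felsenstein pruning over compressed site
patterns with per-pattern rescaling; gaps and IUPAC ambiguity codes are
partial-likelihood vectors (all ones for missing data).  Discrete-gamma
rate heterogeneity (4 categories, mean-one median discretization) is
available behind a flag and off by default; reconstruction then uses the
mean rate.

Marginal ancestral states are empirical-Bayes: one tip-ward and one
root-ward sweep give, for every internal node and column, the posterior
over {A,C,G,T}; the MAP nucleotide sequence is translated on exon columns.
Reconstruction is nucleotide-level then translated (not codon-model-based);
this mirrors the standard practice for this analysis and is the main known
divergence risk from codon-aware reconstruction at sites under selection.
Sites whose MAP posterior falls below a threshold (default 0.5) are flagged
low-confidence.

## Spectral tuning

λ_max is assigned by exact lookup of the residues at a few key sites
against tables of directly measured expressed pigments: a three-site rule
for RH1 (sites 83/292/299) and the "five-sites" rule for LWS
(180/197/277/285/308).  There is no interpolation; an unmeasured residue
combination is *unknown*.  The tables ship as editable TSV data files so
new mutagenesis measurements can be added without a release.

A branch is blue-shifted when the descendant λ_max is lower, red-shifted
when higher.  Range-valued entries (e.g. 522–531 nm) compare by strict
interval order; overlapping intervals give *unknown*, and no Δλ is reported
for ranges.  Branches painted transitional or pseudogenic for the gene are
excluded from shift calling — a dead gene has no pigment to tune.
Secondary RH1 tuning sites (96, 102, 122, 183, 194, 195, 253, 261, 289,
317) can be tracked descriptively but are never converted to λ_max.

## Selection tests

Site counts follow mutational-opportunity logic: each codon position
contributes one site, split between synonymous and nonsynonymous in
proportion to the weights of its three possible changes.  Weights follow a
codon-frequency convention — CF3 (empirical codon frequencies), CF2
(position-specific nucleotide frequencies) or uniform — optionally times a
transition/transversion factor κ (default 1).  Changes to stop codons are
excluded and the position renormalized; stop-containing, gapped and
ambiguous codons are excluded from the analyzable set.  N_sites + S_sites =
3 × analyzable codons exactly.

Observed substitutions on a branch compare MAP ancestor and descendant
codons, averaging over minimal mutational pathways (orderings of the
changed positions) with stop-passing pathways excluded, so counts are
fractional.  This is endpoint counting: it assumes few multiple hits per
codon per branch and will undercount on saturated branches — the
calibration tests therefore use short branches, and the long-branch
convergence test uses 10,000 codons at 0.2 expected neutral substitutions
per codon.  MAP sequences (not posterior-weighted ancestor pairs) are used;
with the confident reconstructions produced at these divergences the
difference is negligible, and the published-table arithmetic is independent
of this choice since it takes printed counts as inputs.

The neutrality test for a pooled branch set is the χ² goodness-of-fit with
one degree of freedom and no continuity correction:

    T = obs_N + obs_S
    exp_N = T · N_sites / (N_sites + S_sites),  exp_S = T − exp_N
    ω = (obs_N / exp_N) / (obs_S / exp_S)
    χ² = (obs_N − exp_N)²/exp_N + (obs_S − exp_S)²/exp_S

obs_S = 0 yields ω = ∞ with the test still defined.  When the data-generating
process is transition-biased (κ > 1), κ must enter the site counts for the
neutral expectation to be correct — synonymous changes are enriched among
transitions — and the calibration suite passes the generator's κ
accordingly.  With κ-aware CF3 counting, the test's type-I error on neutral
simulations is statistically indistinguishable from the nominal 5% (500
replicates at 300 codons).

## The synthetic data generator

The simulator emulates the study design this package is built for: coding
genes under purifying selection (default ω = 0.15–0.2, κ = 3, uniform codon
frequencies) on a dated tree, with scheduled pseudogenization.  Codon sites
evolve independently under a GY94-style process simulated with exact
Gillespie waiting times (no matrix exponentials), so pathway counts are
exact and the true sequence at every node is recorded.  Branch lengths are
expected neutral substitutions per codon.  Stop codons are unreachable
while a gene is functional and become ordinary neutral states after
pseudogenization (nonsense drift).  Introns evolve as neutral nucleotides
at one third of the codon rate with the GT/AG dinucleotides frozen unless a
splice lesion is scheduled.

A lesion plan places events at fractions along branches; from the first
lesion the remaining branch and entire subtree evolve at ω = 1.  Frameshift
indels are realized at alignment assembly (gap masks for deletions; new
columns, shared by all carriers, for insertions), with every coordinate in
the truth log expressed in final alignment columns.  A tuning plan forces
codon states at chosen sites on chosen branches; tuning sites are otherwise
invariant, which gives exact ancestral truth for reconstruction tests at
the price of not testing reconstruction at freely evolving tuning sites.

The packaged three-gene fixture reproduces the canonical cetacean history
at real gene sizes (SWS1 338 codons with four introns, LWS 364 codons with
five introns, RH1 348 codons): SWS1 knocked out independently on the stem
baleen-whale branch (shared 4-bp frameshift deletion) and the stem
toothed-whale branch (E113G); LWS knocked out on five branches (stem
Balaenidae, stem Balaenopteroidea, Sowerby's beaked whale, giant and pygmy
sperm whales) with eight frameshift indels and three splice disruptions in
total; RH1 intact, with tuning substitutions producing one basal blue shift
(DAS→NSS, 501→484 nm), three parallel blue shifts and exactly seven red
shifts inside Cetacea.  The composite species tree carries explicit integer
node ids (26 = whale+hippo ancestor, 27 = crown Cetacea, 28 = Mysticeti,
35 = Odontoceti, …) so branches are addressable as `ancestor:descendant`;
a bovid and a hippopotamid anchor outgroup polarity and the basal
reconstruction.  The exact topology inside clades whose internal numbering
the analysis does not reference is a design choice of this package.

What passing fixture tests show: the pipeline recovers *planted* histories
exactly — lesion coordinates, inactivation branches, ancestral tuning
states, shift classes, and neutral vs purifying pools.  What they do not
show: robustness to alignment error, indel-rate realism, rate variation
across sites and lineages beyond discrete-gamma, codon-usage skew, or
promoter/regulatory inactivation, none of which the generator emulates.

## Reproducing published numbers

Three kinds of check are wired into the suite: (i) arithmetic identities
from printed inputs (the branch-category ω/χ² table; one χ² value is
reproducible only from unrounded inputs that were not published — the test
documents this by failing on that single value, see its docstring);
(ii) structural reproductions on the synthetic fixture (counts of
independent inactivations, lesion tallies, shift sets); (iii) a
supplementary-data reproduction that runs only when the study's own NEXUS
alignments are placed under `data/supplement/` as `sws1_exons.nex`,
`sws1_full.nex`, `lws_exons.nex`, `rh1_exons.nex` plus `lws_model.yaml` /
`rh1_model.yaml` gene models — those files are third-party data and are not
distributed here, so that test fails with an explanatory message in their
absence.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| ω (functional) | 0.15–0.2 | dN/dS | typical purifying selection on mammalian opsins |
| κ | 3.0 | ts/tv rate ratio | typical mammalian nuclear value |
| branch lengths | 0.01–0.3 | neutral subs/codon | shallow mammalian divergences; keeps endpoint counting unbiased |
| gene sizes | 338/364/348 | codons | real coding lengths of the three opsins |
| ASR confidence threshold | 0.5 | posterior | below this a reconstructed residue is flagged |
| χ² df | 1 | — | one free proportion (N vs S split) |
| CF model | CF3 | — | empirical codon frequencies, the richer convention |

## Known limitations

- Endpoint substitution counting saturates on long branches (> ~0.5
  expected substitutions per codon); use more, shorter branches.
- Marginal (not joint) reconstruction; per-node posteriors are not a joint
  distribution over branches.
- The MPR enumerator is exponential in the worst case and guarded by a cap;
  real lesion characters have few MPRs.
- λ_max inference is strictly table lookup; epistasis outside the tabled
  sites is invisible by design.
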